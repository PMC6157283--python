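"""Genome-wide per-site heritability scan and its summaries.

One animal model (plus its null counterpart) is fitted per CpG site with the
site's M-values as the outcome and age and gender as fixed effects; the
kinship eigendecomposition is computed once per sample subset and shared by
every site. Summaries reproduce the standard genome-wide reporting:
number/fraction of sites with strong evidence for nonzero h^2 (delta-DIC
rule), mean/median/IQR of the point estimates among selected sites, the
median with the zero component included, and the cross-time-point
correlation of estimates over sites selected at both time points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import KinshipMatrix, kinship_matrix
from .methylation import MethylationMatrix
from .model import GridSpec, HeritabilityModel, PriorSpec, TraitData
from .pedigree import Pedigree
from .selection import DEFAULT_DIC_THRESHOLD, select

__all__ = ["SiteResult", "ScanSummary", "scan", "summarize", "cross_timepoint",
           "results_to_frame"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiteResult:
    """Per-site heritability record."""

    site_id: str
    h2_mode: float
    h2_mean: float
    ci95: tuple[float, float]
    dic_null: float
    dic_genetic: float
    delta_dic: float
    selected: bool
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class ScanSummary:
    n_sites: int
    n_selected: int
    mean_selected: float | None
    median_selected: float | None
    iqr_selected: float | None
    median_with_zero_component: float
    histogram: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)

    @property
    def fraction_selected(self) -> float:
        return self.n_selected / self.n_sites


def _derive_seed(seed: int, site_index: int) -> int:
    return int(np.random.SeedSequence([seed, site_index]).generate_state(1)[0] % (2**31))


def scan(m: MethylationMatrix, ped: Pedigree | KinshipMatrix,
         covariates: pd.DataFrame, engine: str = "grid",
         priors: PriorSpec | None = None, seed: int = 0,
         grid: GridSpec | None = None,
         dic_threshold: float = DEFAULT_DIC_THRESHOLD,
         n_iter: int = 10_000, burn_in: int = 2_000) -> list[SiteResult]:
    """Fit the genetic and null models at every site of an M-value matrix.

    ``covariates`` must contain columns id, age, gender covering the
    matrix's samples. Per-site seeds (used by the Gibbs engine) are derived
    deterministically from (seed, site index). Per-site failures are
    recorded as warned NaN results, never abort the scan.
    """
    if m.scale != "M":
        raise ValueError("scan expects M-values; run beta_to_m first")
    K_full = ped if isinstance(ped, KinshipMatrix) else kinship_matrix(ped)
    missing = [s for s in m.sample_ids if s not in K_full.ids]
    if missing:
        raise KeyError(f"samples absent from pedigree/kinship: {missing[:5]}")
    K = K_full.subset(m.sample_ids)
    K.eig()  # one factorization shared across all sites
    cov = covariates.copy()
    cov["id"] = cov["id"].astype(str)
    cov = cov.set_index("id").loc[m.sample_ids]
    X = np.column_stack([np.ones(len(K)), cov["age"].to_numpy(float),
                         cov["gender"].to_numpy(float)])
    results: list[SiteResult] = []
    cache: dict = {}  # shared y-independent grid quantities across sites
    for idx, site_id in enumerate(m.site_ids):
        try:
            data = TraitData(m.values[idx], X, m.sample_ids,
                             covariate_names=["intercept", "age", "gender"])
            genetic = HeritabilityModel(data, K, priors, design_cache=cache).fit(
                engine=engine, grid=grid, seed=_derive_seed(seed, idx),
                n_iter=n_iter, burn_in=burn_in)
            null = HeritabilityModel(data, None, priors, formulation="null",
                                     design_cache=cache).fit(engine="grid", grid=grid)
            sel = select(null.dic, genetic.dic, dic_threshold)
            results.append(SiteResult(
                site_id=site_id, h2_mode=genetic.h2_mode, h2_mean=genetic.h2_mean,
                ci95=genetic.h2_ci95, dic_null=null.dic, dic_genetic=genetic.dic,
                delta_dic=sel.delta_dic, selected=sel.selected,
                warnings=tuple(genetic.warnings + null.warnings)))
        except Exception as exc:  # failures become warned records
            logger.warning("site %s failed: %s", site_id, exc)
            results.append(SiteResult(site_id=site_id, h2_mode=np.nan, h2_mean=np.nan,
                                      ci95=(np.nan, np.nan), dic_null=np.nan,
                                      dic_genetic=np.nan, delta_dic=np.nan,
                                      selected=False, warnings=(f"fit_failed: {exc}",)))
    return results


def results_to_frame(results: list[SiteResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "site_id": r.site_id, "h2_mode": r.h2_mode, "h2_mean": r.h2_mean,
        "ci_lo": r.ci95[0], "ci_hi": r.ci95[1], "dic_null": r.dic_null,
        "dic_genetic": r.dic_genetic, "delta_dic": r.delta_dic,
        "selected": r.selected, "warnings": ";".join(r.warnings),
    } for r in results])


def summarize(results: list[SiteResult], exclude_flagged: bool = False,
              hist_bins: int = 50) -> ScanSummary:
    """Genome-wide summary of point estimates.

    ``median_with_zero_component`` is the median of h2_mode over *all*
    sites (non-selected sites contribute their actual near-zero estimates,
    not literal zeros). Selected-only statistics are None when nothing was
    selected.
    """
    if not results:
        raise ValueError("no scan results to summarize")
    if exclude_flagged:
        results = [r for r in results if not r.warnings]
    modes = np.array([r.h2_mode for r in results])
    sel = np.array([r.selected for r in results])
    ok = np.isfinite(modes)
    modes, sel = modes[ok], sel[ok]
    hist = np.histogram(modes, bins=hist_bins, range=(0, 1))
    if sel.any():
        ms = modes[sel]
        q1, q3 = np.percentile(ms, [25, 75])
        mean_s, med_s, iqr_s = float(ms.mean()), float(np.median(ms)), float(q3 - q1)
    else:
        mean_s = med_s = iqr_s = None
    return ScanSummary(n_sites=int(ok.sum()), n_selected=int(sel.sum()),
                       mean_selected=mean_s, median_selected=med_s,
                       iqr_selected=iqr_s,
                       median_with_zero_component=float(np.median(modes)),
                       histogram=hist)


def cross_timepoint(results_a: list[SiteResult],
                    results_b: list[SiteResult]) -> tuple[int, float]:
    """Sites selected at BOTH time points: count and Pearson r of h2_mode."""
    by_id_b = {r.site_id: r for r in results_b}
    pairs = [(ra.h2_mode, by_id_b[ra.site_id].h2_mode)
             for ra in results_a
             if ra.selected and ra.site_id in by_id_b and by_id_b[ra.site_id].selected]
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} sites selected at both time points; "
                         "need at least 3 for a correlation")
    x, y = map(np.array, zip(*pairs))
    r = stats.pearsonr(x, y).statistic
    return len(pairs), float(r)
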