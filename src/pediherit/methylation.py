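"""Methylation matrices: beta/M transforms and SNP-probe filtering.

Array methylation at a CpG site is reported as a beta value (methylated
proportion, in (0,1)). Statistical modelling uses the M-value, the
logit-type transform M = log2(beta / (1 - beta)), which is unbounded and
closer to homoscedastic. Probes overlapping known SNPs are removed before
heritability scans because their apparent "methylation" partly reflects
genotype, which would inflate heritability estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["MethylationMatrix", "beta_to_m", "m_to_beta", "filter_snp_sites",
           "read_methylation_tsv", "write_methylation_tsv"]

logger = logging.getLogger(__name__)


@dataclass
class MethylationMatrix:
    """Sites x samples matrix tagged with its measurement scale."""

    site_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str  # "beta" or "M"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match site/sample ids")
        if self.scale not in ("beta", "M"):
            raise ValueError(f"unknown scale: {self.scale!r}")
        if np.isnan(self.values).any():
            raise ValueError("methylation matrix contains NaN")
        if self.scale == "beta" and not ((self.values > 0) & (self.values < 1)).all():
            raise ValueError("beta values must lie strictly in (0, 1)")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def site(self, site_id: str) -> np.ndarray:
        return self.values[self.site_ids.index(site_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.sample_ids)


def beta_to_m(beta: MethylationMatrix, epsilon: float = 1e-6) -> MethylationMatrix:
    """Elementwise M = log2(beta / (1 - beta)), beta clipped to [eps, 1-eps].

    Clipping guards against infinities from betas rounded to 0 or 1 upstream.
    """
    if beta.scale != "beta":
        raise ValueError("input is already on the M scale")
    b = np.clip(beta.values, epsilon, 1.0 - epsilon)
    return MethylationMatrix(list(beta.site_ids), list(beta.sample_ids),
                             np.log2(b / (1.0 - b)), scale="M")


def m_to_beta(m: MethylationMatrix) -> MethylationMatrix:
    """Inverse transform beta = 2^M / (1 + 2^M)."""
    if m.scale != "M":
        raise ValueError("input is not on the M scale")
    e = np.exp2(m.values)
    return MethylationMatrix(list(m.site_ids), list(m.sample_ids),
                             e / (1.0 + e), scale="beta")


def filter_snp_sites(m: MethylationMatrix, exclusion_ids: Iterable[str]) -> MethylationMatrix:
    """Drop SNP-associated probes; surviving sites keep their original order."""
    excl = set(exclusion_ids)
    keep = [i for i, s in enumerate(m.site_ids) if s not in excl]
    removed = m.n_sites - len(keep)
    unmatched = len(excl) - removed
    logger.info("removed %d SNP-related sites (%d exclusion ids not in matrix)",
                removed, unmatched)
    if not keep:
        logger.warning("all sites removed by SNP exclusion list")
    return MethylationMatrix([m.site_ids[i] for i in keep], list(m.sample_ids),
                             m.values[keep], scale=m.scale)


def read_methylation_tsv(path: str | Path, scale: str) -> MethylationMatrix:
    """Read a TSV with site ids in the first column, one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return MethylationMatrix(df.index.astype(str).tolist(),
                             df.columns.astype(str).tolist(),
                             df.to_numpy(float), scale=scale)


def write_methylation_tsv(m: MethylationMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="site_id")
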