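"""Independent Monte Carlo check of kinship coefficients by gene dropping.

Gene dropping simulates the transmission of distinctly labelled founder
alleles down the pedigree: each founder receives two unique allele labels,
and every non-founder inherits one allele chosen uniformly at random from
each available parent. The kinship coefficient phi(i, j) is then estimated
as the proportion of replicates in which an allele drawn at random from i
matches (is identical by descent with) one drawn at random from j.

This estimator never touches the tabular recursion in
:mod:`pediherit.kinship`, so it serves as an independent oracle for it.
"""

from __future__ import annotations

import numpy as np

from .pedigree import Pedigree

__all__ = ["gene_drop_kinship"]


def gene_drop_kinship(ped: Pedigree, n_rep: int = 100_000,
                      seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Monte Carlo kinship matrix and its standard error.

    Returns
    -------
    phi_hat : (n, n) array
        Estimated kinship coefficients, ordered as ``ped.ids``. The exact
        per-replicate pair probability is averaged over the four allele
        pairings, so diagonal entries and close relatives have reduced MC
        variance compared to sampling a single allele pair.
    se : (n, n) array
        Binomial-style standard error sqrt(p*(1-p)/n_rep) of each entry
        (an upper bound, since the averaged statistic has lower variance).
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    order = ped.topological_order()
    pos = {i: k for k, i in enumerate(ped.ids)}
    alleles = np.empty((n_rep, n, 2), dtype=np.int64)
    next_label = 0
    for iid in order:
        k = pos[iid]
        f, m = ped.parents(iid)
        for slot, parent in enumerate((f, m)):
            if parent is None:
                alleles[:, k, slot] = next_label
                next_label += 1
                # unique label per founder gamete *per replicate*:
                # offset by replicate index times a stride below
            else:
                choice = rng.integers(0, 2, size=n_rep)
                alleles[:, k, slot] = alleles[np.arange(n_rep), pos[parent], choice]
    # Founder labels above are shared across replicates, which is fine:
    # IBD comparisons happen within a replicate only.
    phi = np.zeros((n, n))
    a0 = alleles[:, :, 0]
    a1 = alleles[:, :, 1]
    for i in range(n):
        for j in range(i, n):
            # P(random allele of i IBD random allele of j), averaged over
            # the four allele pairings within each replicate
            match = ((a0[:, i] == a0[:, j]).astype(float)
                     + (a0[:, i] == a1[:, j])
                     + (a1[:, i] == a0[:, j])
                     + (a1[:, i] == a1[:, j])) / 4.0
            if i == j:
                # self-kinship: 1/2 * (1 + F_i) with F_i = P(two own alleles IBD)
                f_i = (a0[:, i] == a1[:, i]).astype(float)
                match = 0.5 * (1.0 + f_i)
            phi[i, j] = phi[j, i] = match.mean()
    se = np.sqrt(np.clip(phi * (1 - phi), 0, None) / n_rep)
    return phi, se
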