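"""Kinship coefficients from pedigrees.

The kinship coefficient phi(i, j) is the probability that one allele sampled
at random from i and one from j are identical by descent. It is computed by
the standard recursion over a parents-before-offspring ordering:

* phi(i, i) = 1/2 + 1/2 * phi(father_i, mother_i)  (1/2 if any parent missing)
* phi(i, j) = 1/2 * (phi(father_i, j) + phi(mother_i, j)) for j already
  processed, with missing-parent terms contributing 0.

The additive (numerator) relationship matrix is A = 2K; under the animal
model the additive genetic values have covariance sigma_g^2 * A.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = ["KinshipMatrix", "kinship_matrix", "relationship_matrix"]


class KinshipMatrix:
    """Symmetric matrix of kinship coefficients over an ordered id list.

    The eigendecomposition of A = 2K (used throughout model fitting) is
    computed lazily and cached; any subsetting invalidates the cache.
    """

    def __init__(self, ids: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(ids), len(ids)):
            raise ValueError("kinship matrix shape does not match id list")
        self.ids = list(ids)
        self.values = values
        self._index = {i: k for k, i in enumerate(self.ids)}
        self._eig: tuple[np.ndarray, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.ids)

    def phi(self, i: str, j: str) -> float:
        """Kinship coefficient for a pair of ids."""
        return float(self.values[self._index[i], self._index[j]])

    def relationship(self) -> np.ndarray:
        """Additive relationship matrix A = 2K."""
        return 2.0 * self.values

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues and eigenvectors of A = 2K (ascending; cached).

        A is symmetric PSD up to roundoff; eigenvalues are clipped at 0.
        """
        if self._eig is None:
            w, v = np.linalg.eigh(self.relationship())
            self._eig = (np.clip(w, 0.0, None), v)
        return self._eig

    def subset(self, ids: list[str]) -> "KinshipMatrix":
        """Principal submatrix over ``ids``, in the requested order."""
        try:
            idx = [self._index[i] for i in ids]
        except KeyError as e:
            raise KeyError(f"id not in kinship matrix: {e.args[0]!r}") from None
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)])

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(list(df.index), df.to_numpy())


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Compute the kinship matrix of a pedigree by the tabular recursion.

    Rows/columns follow the pedigree's record order. Missing parents are
    treated as unique unrelated founders (they contribute 0 to every
    kinship term).
    """
    n = len(ped)
    order = ped.topological_order()
    pos = {i: k for k, i in enumerate(order)}
    phi = np.zeros((n, n))
    for k, iid in enumerate(order):
        f, m = ped.parents(iid)
        fk = pos[f] if f is not None else None
        mk = pos[m] if m is not None else None
        phi_fm = phi[fk, mk] if (fk is not None and mk is not None) else 0.0
        phi[k, k] = 0.5 + 0.5 * phi_fm
        for j in range(k):
            val = 0.0
            if fk is not None:
                val += 0.5 * phi[fk, j]
            if mk is not None:
                val += 0.5 * phi[mk, j]
            phi[k, j] = phi[j, k] = val
    # permute from topological order back to record order
    perm = np.array([pos[i] for i in ped.ids])
    return KinshipMatrix(ped.ids, phi[np.ix_(perm, perm)])


def relationship_matrix(K: KinshipMatrix) -> np.ndarray:
    """Additive relationship matrix A = 2K (diagonal 1 for non-inbred ids)."""
    return K.relationship()
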