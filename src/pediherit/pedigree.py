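"""Pedigree parsing and validation.

A pedigree is a list of individual records with optional father/mother
links. Kinship computation (see :mod:`pediherit.kinship`) requires that
every named parent is itself a record and that the parent graph is acyclic,
so both are enforced at construction time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from collections import deque
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["Individual", "Pedigree", "PedigreeError", "read_pedigree"]

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown",
              "male": "male", "female": "female", "unknown": "unknown",
              "m": "male", "f": "female"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class Individual:
    """One pedigree record. ``father``/``mother`` are ``None`` for founders."""

    id: str
    father: str | None
    mother: str | None
    sex: str = "unknown"
    family: str = "0"


class Pedigree:
    """Validated collection of :class:`Individual` records.

    Invariants enforced here:

    * individual ids are unique,
    * every named parent exists as a record,
    * no individual is its own ancestor (the parent graph is acyclic),

    which together guarantee a parents-before-offspring (topological)
    ordering exists; :meth:`topological_order` computes one.
    """

    def __init__(self, records: Iterable[Individual]):
        self.records: list[Individual] = list(records)
        self._index: dict[str, int] = {}
        for i, rec in enumerate(self.records):
            if rec.id in self._index:
                raise PedigreeError(f"duplicate individual id: {rec.id!r}")
            self._index[rec.id] = i
        for rec in self.records:
            for role, pid in (("father", rec.father), ("mother", rec.mother)):
                if pid is not None and pid not in self._index:
                    raise PedigreeError(
                        f"{role} {pid!r} of individual {rec.id!r} is not in the pedigree"
                    )
        self._topo = self._toposort()

    # -- basic container behaviour -------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, individual_id: str) -> Individual:
        return self.records[self._index[individual_id]]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    @property
    def ids(self) -> list[str]:
        """Individual ids in file/record order."""
        return [r.id for r in self.records]

    def parents(self, individual_id: str) -> tuple[str | None, str | None]:
        rec = self[individual_id]
        return rec.father, rec.mother

    def founders(self) -> list[str]:
        return [r.id for r in self.records if r.father is None and r.mother is None]

    # -- validation helpers --------------------------------------------
    def _toposort(self) -> list[str]:
        """Kahn's algorithm on the parent->child graph; raises on cycles."""
        n_parents = {r.id: sum(p is not None for p in (r.father, r.mother))
                     for r in self.records}
        children: dict[str, list[str]] = {r.id: [] for r in self.records}
        for r in self.records:
            for p in (r.father, r.mother):
                if p is not None:
                    children[p].append(r.id)
        queue = deque(i for i in self.ids if n_parents[i] == 0)
        order: list[str] = []
        while queue:
            i = queue.popleft()
            order.append(i)
            for c in children[i]:
                n_parents[c] -= 1
                if n_parents[c] == 0:
                    queue.append(c)
        if len(order) != len(self.records):
            cycle = sorted(i for i in self.ids if n_parents[i] > 0)
            raise PedigreeError(
                "pedigree contains a cycle (individual is its own ancestor) "
                f"involving: {', '.join(cycle)}"
            )
        return order

    def topological_order(self) -> list[str]:
        """Ids ordered so that every parent precedes its offspring."""
        return list(self._topo)

    def generation_depth(self) -> dict[str, int]:
        """0 for founders, else 1 + max(parent depths)."""
        depth: dict[str, int] = {}
        for i in self._topo:
            f, m = self.parents(i)
            parent_depths = [depth[p] for p in (f, m) if p is not None]
            depth[i] = 1 + max(parent_depths) if parent_depths else 0
        return depth


def _parse_parent(token: str) -> str | None:
    token = token.strip()
    return None if token in ("", "0", "NA", ".") else token


def read_pedigree(path: str | Path | io.TextIOBase, dialect: str = "linkage") -> Pedigree:
    """Read a pedigree from a LINKAGE/PLINK-style ``.fam`` or CSV file.

    Columns (in order): family id, individual id, father id, mother id, sex.
    ``0`` or empty denotes a missing parent; sex is coded 1=male, 2=female,
    0=unknown (the words are also accepted). Extra columns are ignored.

    Parameters
    ----------
    path
        File path or open text handle.
    dialect
        ``"linkage"`` (whitespace-delimited) or ``"csv"`` (comma-delimited).
    """
    if dialect not in ("linkage", "csv"):
        raise ValueError(f"unknown pedigree dialect: {dialect!r}")
    if isinstance(path, (str, Path)):
        with open(path, "rt") as fh:
            text = fh.read()
    else:
        text = path.read()
    records: list[Individual] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split(",") if dialect == "csv" else line.split()
        fields = [f.strip() for f in fields]
        if fields[0].lower() in ("fid", "family", "family_id") and ln == 1:
            continue  # optional header
        if len(fields) < 5:
            raise PedigreeError(f"line {ln}: expected 5 columns (FID IID PAT MAT SEX), got {len(fields)}")
        fam, iid, pat, mat, sex = fields[:5]
        sex_norm = _SEX_CODES.get(sex.lower())
        if sex_norm is None:
            raise PedigreeError(f"line {ln}: unrecognized sex code {sex!r}")
        records.append(Individual(id=iid, father=_parse_parent(pat),
                                  mother=_parse_parent(mat), sex=sex_norm, family=fam))
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write in PLINK ``.fam``-style layout (FID IID PAT MAT SEX)."""
    sex_out = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "wt") as fh:
        for r in ped.records:
            fh.write(f"{r.family}\t{r.id}\t{r.father or '0'}\t{r.mother or '0'}\t{sex_out[r.sex]}\n")
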