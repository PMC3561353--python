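"""Pedigree container and additive relationship machinery.

The additive (numerator) relationship matrix A holds twice the kinship
coefficients: A_ij is the expected fraction of alleles shared identical by
descent between i and j, times two.  It is built by the tabular recursion

    A_ii = 1 + 0.5 * A_{sire(i), dam(i)}
    A_ij = 0.5 * (A_{j, sire(i)} + A_{j, dam(i)})   for j earlier than i,

with founders mutually unrelated and non-inbred.  For the animal model we also
need A^-1, assembled directly from the pedigree: writing the Mendelian-sampling
variance of i as d_i (1 for unknown parents, 0.5 - 0.25*(F_s + F_d) for two
known parents, 0.75 - 0.25*F_p for one), A^-1 = sum_i (1/d_i) k_i k_i' where
k_i has +1 at i and -1/2 at each known parent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Tabular pedigree: one row per individual, parents listed before offspring.

    ``frame`` columns: id, sire, dam, family, group (sire/dam empty for
    founders).  A ``tank`` column may be present for simulated offspring.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "sire", "dam", "family", "group"}
        missing = required - set(self.frame.columns)
        if missing:
            raise PedigreeError(f"pedigree frame missing columns {sorted(missing)}")
        ids = self.frame["id"]
        if ids.duplicated().any():
            raise PedigreeError("duplicate individual ids in pedigree")
        seen: set[str] = set()
        for ind, sire, dam in zip(ids, self.frame["sire"], self.frame["dam"]):
            for parent in (sire, dam):
                if _known(parent):
                    if parent == ind:
                        raise PedigreeError(f"{ind} is its own parent")
                    if parent not in seen:
                        raise PedigreeError(
                            f"parent {parent} of {ind} not listed before it"
                        )
            seen.add(ind)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> list[str]:
        return list(self.frame["id"])

    @property
    def founders(self) -> pd.DataFrame:
        mask = ~self.frame["sire"].map(_known) & ~self.frame["dam"].map(_known)
        return self.frame[mask]

    @property
    def offspring(self) -> pd.DataFrame:
        mask = self.frame["sire"].map(_known) | self.frame["dam"].map(_known)
        return self.frame[mask]

    def subset_with_ancestors(self, individual_ids) -> "Pedigree":
        """Restrict to the given individuals plus all their ancestors."""
        wanted = set(individual_ids)
        parent_of = {
            r.id: (r.sire, r.dam) for r in self.frame.itertuples(index=False)
        }
        stack = list(wanted)
        while stack:
            ind = stack.pop()
            for parent in parent_of.get(ind, ()):  # may include unknown markers
                if _known(parent) and parent not in wanted:
                    wanted.add(parent)
                    stack.append(parent)
        return Pedigree(self.frame[self.frame["id"].isin(wanted)].reset_index(drop=True))

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Positional sire/dam indices (-1 for unknown), in frame order."""
        pos = {ind: i for i, ind in enumerate(self.frame["id"])}
        sire = np.array(
            [pos[s] if _known(s) else -1 for s in self.frame["sire"]], dtype=np.int64
        )
        dam = np.array(
            [pos[d] if _known(d) else -1 for d in self.frame["dam"]], dtype=np.int64
        )
        return sire, dam


def _known(parent) -> bool:
    return not (parent is None or (isinstance(parent, float) and np.isnan(parent))
                or parent == "" or parent == "0")


def build_relationship_matrix(pedigree: Pedigree) -> pd.DataFrame:
    """Additive relationship matrix A by the tabular method.

    Returns a DataFrame indexed by individual id in pedigree order.  Diagonal
    entries are 1 + F_i with F_i the inbreeding coefficient.
    """
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        a[i, i] = 1.0 + (0.5 * a[s, d] if s >= 0 and d >= 0 else 0.0)
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * a[j, s]
            if d >= 0:
                val += 0.5 * a[j, d]
            a[i, j] = a[j, i] = val
    ids = pedigree.ids
    return pd.DataFrame(a, index=ids, columns=ids)


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """F_i = A_ii - 1 for every individual, in pedigree order."""
    a = build_relationship_matrix(pedigree)
    return np.diag(a.to_numpy()) - 1.0


def mendelian_sampling_variances(pedigree: Pedigree,
                                 inbreeding: np.ndarray | None = None) -> np.ndarray:
    """Mendelian-sampling variance d_i per individual (units of V_A)."""
    sire, dam = pedigree.parent_indices()
    if inbreeding is None:
        inbreeding = inbreeding_coefficients(pedigree)
    f = np.asarray(inbreeding, dtype=float)
    d = np.ones(len(pedigree))
    both = (sire >= 0) & (dam >= 0)
    d[both] = 0.5 - 0.25 * (f[sire[both]] + f[dam[both]])
    one_s = (sire >= 0) & (dam < 0)
    one_d = (sire < 0) & (dam >= 0)
    d[one_s] = 0.75 - 0.25 * f[sire[one_s]]
    d[one_d] = 0.75 - 0.25 * f[dam[one_d]]
    return d


def build_a_inverse(pedigree: Pedigree,
                    assume_noninbred: bool = False) -> sparse.csr_matrix:
    """Sparse inverse of the additive relationship matrix (Henderson's rules).

    ``assume_noninbred`` skips the O(n^2) inbreeding computation and is exact
    whenever no parent is itself inbred (e.g. two-generation pedigrees).
    """
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    if assume_noninbred:
        d = np.where((sire >= 0) & (dam >= 0), 0.5,
                     np.where((sire >= 0) | (dam >= 0), 0.75, 1.0))
    else:
        d = mendelian_sampling_variances(pedigree)
    rows, cols, vals = [], [], []
    alpha = 1.0 / d
    for i in range(n):
        members = [(i, 1.0)]
        if sire[i] >= 0:
            members.append((sire[i], -0.5))
        if dam[i] >= 0:
            members.append((dam[i], -0.5))
        for j, cj in members:
            for k, ck in members:
                rows.append(j)
                cols.append(k)
                vals.append(alpha[i] * cj * ck)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
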