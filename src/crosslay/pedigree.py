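"""Pedigree handling and the additive (numerator) relationship matrix.

The animal models fitted elsewhere in this package assume additive genetic
effects distributed N(0, A * sigma_a^2), where A is the numerator
relationship matrix computed recursively from the pedigree.  This module
provides pedigree validation and topological ordering, depth trimming,
inbreeding coefficients (Meuwissen & Luo algorithm), the tabular A matrix,
and its sparse inverse via Henderson's rules with inbreeding.

Unknown parents are treated as unrelated, non-inbred founders.  Animals are
re-ordered internally so that parents precede offspring; original ids are
preserved in the output tables.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

__all__ = ["Pedigree", "gene_drop_relationship"]

UNKNOWN = -1
#: dense A matrices are only materialised up to this many animals
DENSE_LIMIT = 4000


class PedigreeError(ValueError):
    pass


def _as_str(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    s = str(x).strip()
    return "" if s.lower() in ("", "nan", "none", "0", ".") else s


class Pedigree:
    """A validated, topologically ordered pedigree.

    Parameters
    ----------
    table : DataFrame
        Columns ``animal``, ``sire``, ``dam`` and optionally ``generation``
        and ``group``.  Unknown parents are empty strings / NaN / ``0``.
    """

    def __init__(self, table: pd.DataFrame):
        tab = table.copy()
        required = {"animal", "sire", "dam"}
        missing = required - set(tab.columns)
        if missing:
            raise PedigreeError(f"pedigree table lacks columns {sorted(missing)}")
        if "generation" not in tab.columns:
            tab["generation"] = 0
        if "group" not in tab.columns:
            tab["group"] = "base"
        tab["animal"] = tab["animal"].map(_as_str)
        tab["sire"] = tab["sire"].map(_as_str)
        tab["dam"] = tab["dam"].map(_as_str)
        if tab["animal"].duplicated().any():
            dups = tab.loc[tab["animal"].duplicated(), "animal"].tolist()
            raise PedigreeError(f"duplicate animal ids: {dups[:5]}")
        if (tab["animal"] == "").any():
            raise PedigreeError("empty animal id")

        order = self._topological_order(tab)
        tab = tab.iloc[order].reset_index(drop=True)

        self.table = tab
        self.ids: list[str] = tab["animal"].tolist()
        self._pos = {a: i for i, a in enumerate(self.ids)}
        known = set(self.ids)
        self.sire_idx = np.array(
            [self._pos.get(s, UNKNOWN) if s in known else UNKNOWN for s in tab["sire"]],
            dtype=np.int64,
        )
        self.dam_idx = np.array(
            [self._pos.get(d, UNKNOWN) if d in known else UNKNOWN for d in tab["dam"]],
            dtype=np.int64,
        )
        self._F: np.ndarray | None = None

    # ------------------------------------------------------------------ #
    @staticmethod
    def _topological_order(tab: pd.DataFrame) -> list[int]:
        """Kahn's algorithm; raises naming a cycle member on failure."""
        ids = tab["animal"].tolist()
        pos = {a: i for i, a in enumerate(ids)}
        n = len(ids)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=int)
        for i, (s, d) in enumerate(zip(tab["sire"], tab["dam"])):
            for p in (s, d):
                if p in pos:
                    if pos[p] == i:
                        raise PedigreeError(f"animal {ids[i]} is its own parent")
                    children[pos[p]].append(i)
                    indeg[i] += 1
        # stable order: generation first when present, then input order
        gen = tab["generation"].to_numpy()
        ready = sorted(np.flatnonzero(indeg == 0), key=lambda i: (gen[i], i))
        out: list[int] = []
        queue = list(ready)
        while queue:
            queue.sort(key=lambda i: (gen[i], i))
            i = queue.pop(0)
            out.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(out) < n:
            cyclic = [ids[i] for i in range(n) if indeg[i] > 0]
            raise PedigreeError(f"pedigree contains a cycle involving {cyclic[:5]}")
        return out

    # ------------------------------------------------------------------ #
    def __len__(self) -> int:
        return len(self.ids)

    def position(self, animals: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._pos[str(a)] for a in animals], dtype=np.int64)
        except KeyError as exc:
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from None

    # ------------------------------------------------------------------ #
    def trim(self, keep: Sequence[str], depth: int) -> "Pedigree":
        """Restrict to ``keep`` plus ancestors up to ``depth`` generations back.

        Severed parents become unknown.  ``depth=1`` keeps the focal animals
        and their parents only.
        """
        if depth < 1:
            raise PedigreeError("trim depth must be >= 1")
        keep_idx = set(self.position(keep).tolist())
        retained = set(keep_idx)
        frontier = set(keep_idx)
        for _ in range(depth):
            nxt = set()
            for i in frontier:
                for p in (self.sire_idx[i], self.dam_idx[i]):
                    if p != UNKNOWN and p not in retained:
                        nxt.add(p)
            retained |= nxt
            frontier = nxt
        rows = sorted(retained)
        tab = self.table.iloc[rows].copy()
        kept_ids = set(tab["animal"])
        tab["sire"] = [s if s in kept_ids else "" for s in tab["sire"]]
        tab["dam"] = [d if d in kept_ids else "" for d in tab["dam"]]
        return Pedigree(tab.reset_index(drop=True))

    # ------------------------------------------------------------------ #
    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F (Meuwissen & Luo 1992); founders get 0."""
        if self._F is None:
            self._F = _inbreeding_ml(self.sire_idx, self.dam_idx)
        return self._F

    def relationship_matrix(self) -> np.ndarray:
        """Dense numerator relationship matrix A (tabular method).

        diag(A) = 1 + F; entries in [0, 2]; positive semi-definite.
        """
        n = len(self)
        if n > DENSE_LIMIT:
            raise PedigreeError(
                f"dense A limited to {DENSE_LIMIT} animals (pedigree has {n}); trim first"
            )
        return _a_tabular(self.sire_idx, self.dam_idx)

    def a_inverse(self) -> sparse.csr_matrix:
        """Sparse inverse of A via Henderson's rules with inbreeding."""
        F = self.inbreeding()
        rows, cols, vals = _a_inverse_triplets(self.sire_idx, self.dam_idx, F)
        n = len(self)
        ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        ainv.sum_duplicates()
        return ainv

    def log_det_a(self) -> float:
        """log|A| from the recursion |A| = prod_i (within-family variance d_i)."""
        F = self.inbreeding()
        s, d = self.sire_idx, self.dam_idx
        Fs = np.where(s >= 0, F[np.maximum(s, 0)], 0.0)
        Fd = np.where(d >= 0, F[np.maximum(d, 0)], 0.0)
        both = (s >= 0) & (d >= 0)
        one = (s >= 0) ^ (d >= 0)
        dvec = np.ones(len(self))
        dvec[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
        dvec[one] = 0.75 - 0.25 * (Fs[one] + Fd[one])
        return float(np.sum(np.log(dvec)))

    # ------------------------------------------------------------------ #
    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, dtype=str, comment="#", keep_default_na=False))

    def a_triplets(self) -> pd.DataFrame:
        """A as a 3-column sparse triplet table (i, j, value), lower triangle."""
        A = self.relationship_matrix()
        i, j = np.tril_indices_from(A)
        nz = A[i, j] != 0
        return pd.DataFrame(
            {
                "animal_i": np.array(self.ids)[i[nz]],
                "animal_j": np.array(self.ids)[j[nz]],
                "value": A[i[nz], j[nz]],
            }
        )


# ---------------------------------------------------------------------- #
@njit(cache=True)
def _a_tabular(sire, dam):  # pragma: no cover - exercised via wrapper
    n = sire.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            asj = A[j, s] if s >= 0 else 0.0
            adj = A[j, d] if d >= 0 else 0.0
            aij = 0.5 * (asj + adj)
            A[i, j] = aij
            A[j, i] = aij
        asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    return A


@njit(cache=True)
def _inbreeding_ml(sire, dam):  # pragma: no cover
    """Meuwissen & Luo (1992) O(n * depth^2) inbreeding coefficients."""
    n = sire.shape[0]
    F = np.zeros(n)
    point = np.zeros(n, dtype=np.int64)
    L = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        Fs = F[s] if s >= 0 else 0.0
        Fd = F[d] if d >= 0 else 0.0
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (Fs + Fd)
        elif s >= 0 or d >= 0:
            D[i] = 0.75 - 0.25 * (Fs + Fd)
        else:
            D[i] = 1.0
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        fi = -1.0
        L[i] = 1.0
        j = i
        while j != -1:
            k = j
            r = L[k]
            ks, kd = sire[k], dam[k]
            if ks >= 0:
                while point[k] > ks:
                    k = point[k]
                L[ks] += 0.5 * r
                if ks != point[k]:
                    point[ks] = point[k]
                    point[k] = ks
            if kd >= 0:
                k = j
                while point[k] > kd:
                    k = point[k]
                L[kd] += 0.5 * r
                if kd != point[k]:
                    point[kd] = point[k]
                    point[k] = kd
            fi += r * r * D[j]
            L[j] = 0.0
            k = j
            j = point[j]
            point[k] = -1
        F[i] = fi
    return F


def _a_inverse_triplets(sire, dam, F):
    """Henderson rule contributions for A^{-1} (vectorised assembly)."""
    n = sire.shape[0]
    Fs = np.where(sire >= 0, F[np.maximum(sire, 0)], 0.0)
    Fd = np.where(dam >= 0, F[np.maximum(dam, 0)], 0.0)
    both = (sire >= 0) & (dam >= 0)
    one = (sire >= 0) ^ (dam >= 0)
    dvec = np.ones(n)
    dvec[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
    dvec[one] = 0.75 - 0.25 * (Fs[one] + Fd[one])
    alpha = 1.0 / dvec

    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    idx = np.arange(n)
    add(idx, idx, alpha)
    for parent in (sire, dam):
        m = parent >= 0
        add(idx[m], parent[m], -0.5 * alpha[m])
        add(parent[m], idx[m], -0.5 * alpha[m])
        add(parent[m], parent[m], 0.25 * alpha[m])
    m2 = both
    add(sire[m2], dam[m2], 0.25 * alpha[m2])
    add(dam[m2], sire[m2], 0.25 * alpha[m2])
    return (
        np.concatenate(rows),
        np.concatenate(cols),
        np.concatenate(vals),
    )


# ---------------------------------------------------------------------- #
def gene_drop_relationship(
    ped: Pedigree, n_drops: int = 100_000, seed: int = 0, return_se: bool = False
):
    """Monte-Carlo estimate of A by gene dropping.

    Each replicate assigns two unique alleles to every founder and drops
    them down the pedigree by Mendelian sampling; a_ij is estimated as
    2 * P(a random allele of i is identical by descent to a random allele
    of j), i.e. half the expected number of IBD allele pairs.  Intended as
    an independent check of :meth:`Pedigree.relationship_matrix` on small
    pedigrees.  With ``return_se=True`` also returns the matrix of
    Monte-Carlo standard errors of the estimates.
    """
    n = len(ped)
    rng = np.random.default_rng(seed)
    allele = np.empty((n, 2, n_drops), dtype=np.int32)
    counter = 0
    for i in range(n):
        for k, parent in enumerate((ped.sire_idx[i], ped.dam_idx[i])):
            if parent == UNKNOWN:
                allele[i, k, :] = counter
                counter += 1
            else:
                pick = rng.integers(0, 2, size=n_drops)
                allele[i, k, :] = allele[parent, pick, np.arange(n_drops)]
    A = np.zeros((n, n))
    SE = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            ibd = np.zeros(n_drops)
            for a in range(2):
                for b in range(2):
                    ibd += allele[i, a] == allele[j, b]
            # on the diagonal the two self-pairs are always IBD, so
            # 0.5 * E[#IBD pairs] = 0.5 * (2 + 2F) = 1 + F as required
            A[i, j] = A[j, i] = 0.5 * ibd.mean()
            SE[i, j] = SE[j, i] = 0.5 * ibd.std(ddof=1) / np.sqrt(n_drops)
    if return_se:
        return A, SE
    return A
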