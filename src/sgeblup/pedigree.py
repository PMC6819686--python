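"""Pedigree machinery: numerator relationship matrix A, its sparse inverse, and A22.

A pedigree is held as a :class:`PedigreeTable` in topological order (parents
before offspring) with a contiguous 0-based internal index and an explicit
id <-> index map.  Inbreeding coefficients come from the Meuwissen & Luo
algorithm; A-inverse from Henderson's rules with inbreeding; A22 from the
tabular method restricted to the ancestor closure of the genotyped animals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

UNKNOWN = -1  # internal code for an unknown parent


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates, bad parents)."""


@dataclass
class PedigreeTable:
    """Topologically ordered pedigree with inbreeding coefficients.

    Attributes
    ----------
    ids : np.ndarray
        Animal identifiers in topological order (parents precede offspring).
    sire, dam : np.ndarray
        0-based positional index of each animal's parents, ``-1`` if unknown.
    birth_period : np.ndarray
        Integer birth period (generation, year...) per animal; 0 if unknown.
    F : np.ndarray
        Inbreeding coefficient per animal (filled by :func:`compute_inbreeding`).
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    birth_period: np.ndarray
    F: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.birth_period = np.asarray(self.birth_period, dtype=np.int64)
        n = len(self.ids)
        if self.F is None:
            self.F = compute_inbreeding(self)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            bad = (par >= np.arange(n)) & (par != UNKNOWN)
            if bad.any():
                raise PedigreeError(
                    f"{name} index not earlier in order for animals "
                    f"{self.ids[bad][:5].tolist()}"
                )
        self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def indices_of(self, ids) -> np.ndarray:
        """Map external animal ids to 0-based row positions."""
        try:
            return np.array([self._index[a] for a in ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from exc

    def to_frame(self) -> pd.DataFrame:
        """External representation; unknown parents coded 0."""
        def back(par):
            return np.where(par == UNKNOWN, 0, np.append(self.ids, 0)[par])
        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": back(self.sire),
                "dam": back(self.dam),
                "birth_period": self.birth_period,
                "F": self.F,
            }
        )


def _toposort(animals, sires, dams):
    """Order child-after-parents; detect cycles. Returns permutation of positions."""
    n = len(animals)
    pos = {a: i for i, a in enumerate(animals)}
    children = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (sires[i], dams[i]):
            if p != 0:
                j = pos[p]
                children[j].append(i)
                indeg[i] += 1
    order, stack = [], [i for i in range(n) if indeg[i] == 0]
    while stack:
        i = stack.pop()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    if len(order) != n:
        cyclic = [animals[i] for i in range(n) if indeg[i] > 0]
        raise PedigreeError(f"pedigree cycle involving animals {cyclic[:10]}")
    return order


def make_pedigree(animal, sire, dam, birth_period=None) -> PedigreeTable:
    """Build a validated, topologically ordered :class:`PedigreeTable`.

    Unknown parents are coded 0 (or NaN/empty upstream).  Parents that never
    appear as animals are auto-inserted as founders with a warning.
    """
    animal = list(animal)
    sire = [0 if pd.isna(s) else s for s in sire]
    dam = [0 if pd.isna(d) else d for d in dam]
    if birth_period is None:
        birth_period = [0] * len(animal)
    birth_period = [0 if pd.isna(b) else int(b) for b in birth_period]
    if len(set(animal)) != len(animal):
        dup = pd.Series(animal)
        raise PedigreeError(
            f"duplicate animal ids: {dup[dup.duplicated()].unique()[:5].tolist()}"
        )
    for a, s, d in zip(animal, sire, dam):
        if a == 0:
            raise PedigreeError("animal id 0 is reserved for unknown parents")
        if a == s or a == d:
            raise PedigreeError(f"animal {a!r} listed as its own parent")
    known = set(animal)
    missing = [p for p in set(sire) | set(dam) if p != 0 and p not in known]
    if missing:
        logger.warning(
            "%d parents absent from animal column; inserted as founders: %s",
            len(missing), sorted(missing)[:5],
        )
        animal = sorted(missing) + animal
        sire = [0] * len(missing) + sire
        dam = [0] * len(missing) + dam
        birth_period = [0] * len(missing) + birth_period

    order = _toposort(animal, np.array(sire, dtype=object), np.array(dam, dtype=object))
    animal = [animal[i] for i in order]
    pos = {a: i for i, a in enumerate(animal)}
    sire_ix = np.array([pos[sire[i]] if sire[i] != 0 else UNKNOWN for i in order])
    dam_ix = np.array([pos[dam[i]] if dam[i] != 0 else UNKNOWN for i in order])
    bp = np.array([birth_period[i] for i in order])
    return PedigreeTable(np.array(animal, dtype=object), sire_ix, dam_ix, bp)


def read_pedigree(path) -> PedigreeTable:
    """Read a pedigree CSV (animal,sire,dam[,birth_period]); unknown parent = 0/empty."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise PedigreeError("pedigree CSV needs at least 3 columns (animal,sire,dam)")
    cols = list(df.columns)
    bp = df[cols[3]] if df.shape[1] >= 4 else None
    return make_pedigree(df[cols[0]], df[cols[1]], df[cols[2]], bp)


def compute_inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo (1992) algorithm.

    F_i = A_ii - 1, computed animal-by-animal from the decomposition
    A = T D T' without forming A.  Exact, O(n * pedigree depth^2).
    """
    n = len(ped.ids)
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    # d_i = Mendelian sampling variance given parents' inbreeding
    d = np.zeros(n)
    for i in range(n):
        s, m = sire[i], dam[i]
        if s == UNKNOWN and m == UNKNOWN:
            d[i] = 1.0
        elif s == UNKNOWN or m == UNKNOWN:
            p = s if s != UNKNOWN else m
            d[i] = 0.75 - 0.25 * F[p]
        else:
            d[i] = 0.5 - 0.25 * (F[s] + F[m])
        if s == UNKNOWN or m == UNKNOWN:
            F[i] = 0.0
        else:
            # F_i = 0.5 * a(sire, dam); both parents precede i, so their
            # closure d-values are already final.
            F[i] = 0.5 * _a_pair(sire, dam, d, s, m)
    return F


def _a_pair(sire, dam, d, x, y) -> float:
    """Additive relationship a(x, y) via the L-vector trick on the joint closure."""
    seen = set()
    stack = [x, y]
    while stack:
        j = stack.pop()
        if j == UNKNOWN or j in seen:
            continue
        seen.add(j)
        stack.extend((sire[j], dam[j]))
    keys = sorted(seen, reverse=True)
    Lx = {j: 0.0 for j in keys}
    Ly = {j: 0.0 for j in keys}
    Lx[x] = 1.0
    Ly[y] = 1.0
    a = 0.0
    for j in keys:
        for L in (Lx, Ly):
            lj = L[j]
            if lj:
                for p in (sire[j], dam[j]):
                    if p != UNKNOWN:
                        L[p] += 0.5 * lj
        a += Lx[j] * Ly[j] * d[j]
    return a


def mendelian_variances(ped: PedigreeTable) -> np.ndarray:
    """Within-family (Mendelian sampling) variances d_i used by Henderson's rules.

    d_i = 0.5 - 0.25 (F_s + F_d) with both parents known; 0.75 - 0.25 F_p with
    one known parent; 1 with none.
    """
    F = ped.F
    n = len(ped.ids)
    d = np.empty(n)
    for i in range(n):
        s, m = ped.sire[i], ped.dam[i]
        if s == UNKNOWN and m == UNKNOWN:
            d[i] = 1.0
        elif s == UNKNOWN or m == UNKNOWN:
            p = s if s != UNKNOWN else m
            d[i] = 0.75 - 0.25 * F[p]
        else:
            d[i] = 0.5 - 0.25 * (F[s] + F[m])
    if (d <= 0).any():
        raise PedigreeError("non-positive Mendelian sampling variance in pedigree")
    return d


def build_A_inverse(ped: PedigreeTable) -> sp.csr_matrix:
    """Sparse A-inverse by Henderson's rules with inbreeding."""
    d = mendelian_variances(ped)
    n = len(ped.ids)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i); cols.append(j); vals.append(v)

    for i in range(n):
        inv_d = 1.0 / d[i]
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        add(i, i, inv_d)
        for p in parents:
            add(i, p, -0.5 * inv_d)
            add(p, i, -0.5 * inv_d)
            for q in parents:
                add(p, q, 0.25 * inv_d)
    A_inv = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    A_inv.sum_duplicates()
    return A_inv


def logdet_A(ped: PedigreeTable) -> float:
    """log|A| = sum log d_i (from A = T D T' with unit-triangular T)."""
    return float(np.sum(np.log(mendelian_variances(ped))))


def tabular_A(ped: PedigreeTable) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method (oracle-scale)."""
    n = len(ped.ids)
    A = np.zeros((n, n))
    for i in range(n):
        s, m = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if m != UNKNOWN:
            row += 0.5 * A[m, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, m] if (s != UNKNOWN and m != UNKNOWN) else 0.0)
    return A


def ancestor_closure(ped: PedigreeTable, indices: np.ndarray) -> np.ndarray:
    """Sorted positional indices of the given animals plus all their ancestors."""
    seen = set()
    stack = list(np.asarray(indices, dtype=np.int64))
    while stack:
        j = stack.pop()
        if j in seen:
            continue
        seen.add(int(j))
        for p in (ped.sire[j], ped.dam[j]):
            if p != UNKNOWN:
                stack.append(int(p))
    return np.array(sorted(seen), dtype=np.int64)


def build_A22(ped: PedigreeTable, genotyped_ids) -> np.ndarray:
    """Pedigree relationship submatrix for the genotyped animals.

    Runs the tabular method only on the ancestor closure of the genotyped set,
    so the full pedigree never needs a dense A.
    """
    gidx = ped.indices_of(genotyped_ids)
    closure = ancestor_closure(ped, gidx)
    # build a sub-pedigree on the closure (parent indices remapped)
    remap = {int(j): k for k, j in enumerate(closure)}
    sub_sire = np.array(
        [remap[int(ped.sire[j])] if ped.sire[j] != UNKNOWN else UNKNOWN for j in closure]
    )
    sub_dam = np.array(
        [remap[int(ped.dam[j])] if ped.dam[j] != UNKNOWN else UNKNOWN for j in closure]
    )
    sub = PedigreeTable(
        ped.ids[closure], sub_sire, sub_dam, ped.birth_period[closure],
        F=ped.F[closure],
    )
    A_sub = tabular_A(sub)
    pos = np.array([remap[int(j)] for j in gidx])
    return A_sub[np.ix_(pos, pos)]


def write_pedigree_csv(ped: PedigreeTable, path) -> None:
    ped.to_frame().drop(columns="F").to_csv(path, index=False)


def write_coordinate_matrix(mat, path, ids=None) -> None:
    """Write a (sparse or dense) symmetric matrix as 'i<TAB>j<TAB>value' text, 1-based."""
    coo = sp.coo_matrix(mat)
    with open(path, "w") as fh:
        fh.write("i\tj\tvalue\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if j < i or v == 0.0:
                continue
            fh.write(f"{i + 1}\t{j + 1}\t{v:.12g}\n")
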