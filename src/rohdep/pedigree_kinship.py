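"""Pedigree-based inbreeding and relationship matrices.

Inbreeding coefficients use the Meuwissen-Luo algorithm (linear memory per
animal via the L/D decomposition of A).  The numerator relationship matrix A
comes from the tabular method and its sparse inverse from Henderson's rules
with exact parental inbreeding in the Mendelian-sampling variance.  Unknown
parents are treated as unique, unrelated, non-inbred founders.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import ValidationError, make_pedigree, pedigree_indices


def _mendelian_d(F: np.ndarray, sire: np.ndarray, dam: np.ndarray,
                 j: int) -> float:
    """Within-family (Mendelian-sampling) variance share d_j of animal j."""
    s, d = sire[j], dam[j]
    if s >= 0 and d >= 0:
        return 0.5 - 0.25 * (F[s] + F[d])
    if s >= 0:
        return 0.75 - 0.25 * F[s]
    if d >= 0:
        return 0.75 - 0.25 * F[d]
    return 1.0


def inbreeding_meuwissen_luo(ped: pd.DataFrame) -> pd.Series:
    """Pedigree inbreeding coefficients F for every animal.

    F_j is obtained from A_jj = sum_k L_jk^2 d_k, visiting only the ancestors
    of j (descending-index heap), so each animal costs O(#ancestors).
    The pedigree must be topologically ordered (``make_pedigree`` output).
    """
    _, sire, dam = pedigree_indices(ped)
    if (sire >= np.arange(len(sire))).any() or (dam >= np.arange(len(dam))).any():
        raise ValidationError("pedigree is not topologically ordered")
    n = len(ped)
    F = np.zeros(n)
    D = np.empty(n)
    for i in range(n):
        D[i] = _mendelian_d(F, sire, dam, i)
        if sire[i] < 0 or dam[i] < 0:
            continue  # F stays 0
        L = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j)
            aii += lj * lj * D[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p in L:
                        L[p] += 0.5 * lj
                    else:
                        L[p] = 0.5 * lj
                        heapq.heappush(heap, -p)
        F[i] = aii - 1.0
    return pd.Series(F, index=ped["animal"].to_numpy(), name="F_PED")


def build_A(ped: pd.DataFrame, subset=None):
    """Dense numerator relationship matrix by the tabular method.

    a_ij = (a_{i,s(j)} + a_{i,d(j)})/2 for i preceding j and
    a_jj = 1 + a_{s(j),d(j)}/2.  Returns (A_block, animal ids) for ``subset``
    (default: all animals, pedigree order).
    """
    idx, sire, dam = pedigree_indices(ped)
    n = len(ped)
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        col = np.zeros(j)
        if s >= 0:
            col += A[:j, s]
        if d >= 0:
            col += A[:j, d]
        col *= 0.5
        A[:j, j] = col
        A[j, :j] = col
        A[j, j] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    animals = list(ped["animal"])
    if subset is None:
        return A, animals
    try:
        rows = [idx[a] for a in subset]
    except KeyError as e:
        raise KeyError(f"animal {e.args[0]!r} not in pedigree") from None
    return A[np.ix_(rows, rows)], list(subset)


def build_A_inverse(ped: pd.DataFrame) -> sp.csr_matrix:
    """Sparse A^-1 over all pedigree animals via Henderson's rules,
    using exact parental inbreeding in d_j."""
    _, sire, dam = pedigree_indices(ped)
    F = inbreeding_meuwissen_luo(ped).to_numpy()
    n = len(ped)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for j in range(n):
        b = 1.0 / _mendelian_d(F, sire, dam, j)
        add(j, j, b)
        par = [p for p in (sire[j], dam[j]) if p >= 0]
        for p in par:
            add(p, j, -0.5 * b)
            add(j, p, -0.5 * b)
        for p in par:
            for q in par:
                add(p, q, 0.25 * b)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def truncate_pedigree(ped: pd.DataFrame, n_generations: int,
                      cohort=None) -> pd.DataFrame:
    """Truncate ancestry of a cohort to a maximum generation depth.

    ``cohort`` defaults to the animals with no recorded offspring (the
    phenotyped tip generation).  Ancestors strictly deeper than
    ``n_generations`` along every descent path to the cohort are dropped and
    the links into them severed (parents set unknown).  Depth of an ancestor
    is its minimum path length to any cohort animal, so an animal reachable
    both as a parent and a great-grandparent is kept at depth 1.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if cohort is None:
        parents = set(ped["sire"].dropna()) | set(ped["dam"].dropna())
        cohort = [a for a in ped["animal"] if a not in parents]
    cohort = set(cohort)
    par = {r.animal: (r.sire, r.dam) for r in ped.itertuples(index=False)}
    depth = {a: 0 for a in cohort if a in par}
    frontier = list(depth)
    while frontier:
        nxt = []
        for a in frontier:
            for p in par.get(a, (None, None)):
                if p and p in par and depth[a] + 1 < depth.get(p, np.inf):
                    depth[p] = depth[a] + 1
                    nxt.append(p)
        frontier = nxt
    keep = {a for a, d in depth.items() if d <= n_generations}
    records = []
    for r in ped.itertuples(index=False):
        if r.animal not in keep:
            continue
        s = r.sire if (r.sire in keep) else None
        d = r.dam if (r.dam in keep) else None
        records.append((r.animal, s, d))
    return make_pedigree(records)


@dataclass
class KinshipResult:
    f_ped: pd.Series
    A: np.ndarray
    A_animals: list
    A_inverse: sp.csr_matrix


def kinship_summary(ped: pd.DataFrame, subset=None) -> KinshipResult:
    """Convenience bundle: F_PED, dense A block, and sparse A^-1."""
    f = inbreeding_meuwissen_luo(ped)
    A, animals = build_A(ped, subset)
    return KinshipResult(f, A, animals, build_A_inverse(ped))
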