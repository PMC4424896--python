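"""Group-merit elite selection under a coancestry penalty.

Selects a fixed-size elite subset maximizing

    GM(S) = mean BV(S) − c · Θ(S)

where Θ is the group coancestry of the subset (mean kinship over ordered
pairs including self) and c the penalty weight.  Sweeping c traces the
gain–diversity frontier; diversity is reported as the status number
N_s = 0.5/Θ under a pedigree matrix or founder genome equivalents N_ge
under a marker-based matrix.

Optimization is greedy seeding by BV followed by best-improvement swap
hill climbing — deterministic given the inputs.  An exhaustive enumerator
is provided for small instances as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .kinship import KinshipMatrix, group_coancestry


@dataclass
class SelectionResult:
    selected_ids: list[str]
    mean_bv: float
    group_coancestry: float
    diversity: float            # N_s (pedigree) or N_ge (genomic) = 0.5/Θ
    penalty_weight: float
    flavor: str
    group_merit: float


def _as_series(bv, ids) -> pd.Series:
    if isinstance(bv, pd.Series):
        return bv.astype(float)
    return pd.Series(np.asarray(bv, float), index=ids)


def _merit(bv_vec: np.ndarray, k: np.ndarray, subset: np.ndarray, c: float) -> float:
    nsel = subset.size
    theta = k[np.ix_(subset, subset)].sum() / (2.0 * nsel * nsel)
    return float(bv_vec[subset].mean() - c * theta)


def group_merit_select(
    bv,
    kinship: KinshipMatrix,
    n_select: int,
    penalty_weight: float = 0.0,
) -> SelectionResult:
    """Greedy + swap local search for the maximum group-merit subset.

    Seed: the top ``n_select`` individuals by BV (exact when the penalty is
    zero or all candidates are unrelated).  Then repeatedly apply the best
    improving single swap until a local optimum.
    """
    bv_s = _as_series(bv, kinship.ids)
    ids = kinship.ids
    if set(bv_s.index) < set(ids):
        raise ValueError("breeding values missing for some kinship individuals")
    bv_vec = bv_s.loc[ids].to_numpy()
    k = kinship.values
    n = len(ids)
    if n_select > n:
        raise ValueError(f"n_select={n_select} exceeds {n} candidates")
    if penalty_weight < 0:
        raise ValueError("penalty_weight must be >= 0")

    order = np.argsort(-bv_vec, kind="stable")
    inside = np.zeros(n, dtype=bool)
    subset = order[:n_select].copy()
    inside[subset] = True

    nsel = n_select
    c = penalty_weight
    # incremental bookkeeping: row sums of K over the subset
    rowsum = k[:, subset].sum(axis=1)
    ssum = float(rowsum[subset].sum())          # Σ K over subset pairs
    bsum = float(bv_vec[subset].sum())

    def merit_from(bs, ss):
        return bs / nsel - c * ss / (2.0 * nsel * nsel)

    current = merit_from(bsum, ssum)
    kdiag = np.diag(k)
    improved = True
    while improved:
        improved = False
        best_gain, best_move = 1e-12, None
        outside = np.flatnonzero(~inside)
        if outside.size == 0:
            break
        for oi, i_out in enumerate(subset):
            # subset sums after removing i_out ...
            ss_minus = ssum - 2.0 * rowsum[i_out] + k[i_out, i_out]
            bs_minus = bsum - bv_vec[i_out]
            # ... then adding each outside candidate j, vectorized over j
            add_row = rowsum[outside] - k[outside, i_out]
            ss_new = ss_minus + 2.0 * add_row + kdiag[outside]
            bs_new = bs_minus + bv_vec[outside]
            merits = bs_new / nsel - c * ss_new / (2.0 * nsel * nsel)
            j = int(np.argmax(merits))
            gain = merits[j] - current
            if gain > best_gain:
                best_gain = gain
                best_move = (oi, outside[j])
        if best_move is not None:
            oi, j_in = best_move
            i_out = subset[oi]
            inside[i_out] = False
            inside[j_in] = True
            rowsum += k[:, j_in] - k[:, i_out]
            subset[oi] = j_in
            ssum = float(k[np.ix_(subset, subset)].sum())
            bsum = float(bv_vec[subset].sum())
            current = merit_from(bsum, ssum)
            improved = True

    theta = ssum / (2.0 * nsel * nsel)
    sel_ids = [ids[i] for i in sorted(subset, key=lambda i: -bv_vec[i])]
    return SelectionResult(
        selected_ids=sel_ids,
        mean_bv=float(bsum / nsel),
        group_coancestry=float(theta),
        diversity=float(0.5 / theta) if theta > 0 else float("inf"),
        penalty_weight=float(c),
        flavor=kinship.flavor,
        group_merit=float(current),
    )


def exhaustive_select(
    bv, kinship: KinshipMatrix, n_select: int, penalty_weight: float = 0.0
) -> SelectionResult:
    """Enumerate all subsets (oracle for small instances, C(n, k) bounded)."""
    ids = kinship.ids
    n = len(ids)
    from math import comb

    if comb(n, n_select) > 2_000_000:
        raise ValueError("instance too large for exhaustive enumeration")
    bv_vec = _as_series(bv, ids).loc[ids].to_numpy()
    k = kinship.values
    best, best_sub = -np.inf, None
    for sub in combinations(range(n), n_select):
        m = _merit(bv_vec, k, np.asarray(sub), penalty_weight)
        if m > best:
            best, best_sub = m, sub
    sub = np.asarray(best_sub)
    theta = k[np.ix_(sub, sub)].sum() / (2.0 * n_select**2)
    return SelectionResult(
        selected_ids=[ids[i] for i in sorted(sub, key=lambda i: -bv_vec[i])],
        mean_bv=float(bv_vec[sub].mean()),
        group_coancestry=float(theta),
        diversity=float(0.5 / theta) if theta > 0 else float("inf"),
        penalty_weight=float(penalty_weight),
        flavor=kinship.flavor,
        group_merit=float(best),
    )


def gain_diversity_curve(
    bv, kinship: KinshipMatrix, n_select: int, penalty_grid
) -> pd.DataFrame:
    """One selection per penalty, with monotone repair: gain never increases
    and diversity never decreases along the penalty grid.

    Repair replaces a higher-penalty solution by the lower-penalty one when
    the local search happens to find higher gain at the higher penalty.
    """
    grid = list(penalty_grid)
    if not grid:
        raise ValueError("penalty grid is empty")
    grid = sorted(grid)
    results = [group_merit_select(bv, kinship, n_select, c) for c in grid]
    for i in range(1, len(results)):
        if results[i].mean_bv > results[i - 1].mean_bv:
            prev = results[i - 1]
            results[i] = SelectionResult(
                selected_ids=list(prev.selected_ids),
                mean_bv=prev.mean_bv,
                group_coancestry=prev.group_coancestry,
                diversity=prev.diversity,
                penalty_weight=float(grid[i]),
                flavor=prev.flavor,
                group_merit=prev.group_merit,
            )
    return pd.DataFrame(
        {
            "penalty": [r.penalty_weight for r in results],
            "mean_bv": [r.mean_bv for r in results],
            "group_coancestry": [r.group_coancestry for r in results],
            "diversity": [r.diversity for r in results],
            "selected_ids": [";".join(r.selected_ids) for r in results],
        }
    )
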