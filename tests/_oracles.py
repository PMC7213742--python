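"""Independent oracles used by the test suite.

These deliberately avoid the package's solver path (cobra/optlang/GLPK):
the FBA oracle enumerates candidate polytope vertices with numpy linear
algebra, and the gap-fill oracle solves small LPs with scipy's HiGHS via
``linprog``.  They are only tractable for toy networks, which is the point.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linprog

_TOL = 1e-8


def _network_arrays(model):
    reactions = list(model.reactions)
    metabolites = list(model.metabolites)
    met_index = {m.id: i for i, m in enumerate(metabolites)}
    S = np.zeros((len(metabolites), len(reactions)))
    lower = np.empty(len(reactions))
    upper = np.empty(len(reactions))
    objective = np.zeros(len(reactions))
    for j, reaction in enumerate(reactions):
        for metabolite, coeff in reaction.metabolites.items():
            S[met_index[metabolite.id], j] = coeff
        lower[j] = reaction.lower_bound
        upper[j] = reaction.upper_bound
        objective[j] = reaction.objective_coefficient
    return S, lower, upper, objective, [r.id for r in reactions]


def enumerate_fba_optimum(model) -> Optional[float]:
    """Max objective over exhaustively enumerated polytope vertices.

    Each variable is assigned lower bound / upper bound / free; free
    variables are solved from steady state.  Every vertex of the flux
    polytope appears under some assignment, so the maximum over feasible
    candidates is the LP optimum.  Returns None if no feasible point is
    found.  Only usable for tiny models (3^n assignments).
    """
    S, lower, upper, objective, _ = _network_arrays(model)
    n = S.shape[1]
    assert n <= 8, "vertex enumeration is for toy models only"
    best = None
    for assignment in itertools.product((0, 1, 2), repeat=n):
        fixed = [i for i, a in enumerate(assignment) if a != 2]
        free = [i for i, a in enumerate(assignment) if a == 2]
        v = np.zeros(n)
        for i in fixed:
            v[i] = lower[i] if assignment[i] == 0 else upper[i]
        if free:
            rhs = -S[:, fixed] @ v[fixed] if fixed else np.zeros(S.shape[0])
            solution, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
            v[free] = solution
        if np.max(np.abs(S @ v)) > _TOL:
            continue
        if np.any(v < lower - _TOL) or np.any(v > upper + _TOL):
            continue
        value = float(objective @ v)
        if best is None or value > best:
            best = value
    return best


def _medium_bounds(model, medium: Dict[str, float]):
    """Replicate the medium contract: listed exchanges open to -rate,
    unlisted exchanges closed to uptake."""
    lower = {}
    for reaction in model.reactions:
        if len(reaction.metabolites) == 1:
            lower[reaction.id] = -float(medium.get(reaction.id, 0.0))
    return lower


def min_universal_flux(
    draft,
    universal,
    subset: Iterable[str],
    medium: Dict[str, float],
    growth_threshold: float,
) -> Optional[float]:
    """Minimum summed |flux| through ``subset`` universal reactions needed to
    reach ``growth_threshold`` on ``medium``, by scipy linprog (HiGHS).

    Only the subset is available from the universal database.  Returns None
    when infeasible.  Variables are fluxes v plus one auxiliary t >= |v| per
    subset reaction; constraints are S v = 0, bounds, objective >= threshold.
    """
    subset = set(subset)
    reactions = list(draft.reactions) + [
        r for r in universal.reactions if r.id in subset
    ]
    met_ids = sorted(
        {m.id for r in reactions for m in r.metabolites}
    )
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    n = len(reactions)
    S = np.zeros((len(met_ids), n))
    lower = np.empty(n)
    upper = np.empty(n)
    objective = np.zeros(n)
    medium_lower = {}
    for j, reaction in enumerate(reactions):
        for metabolite, coeff in reaction.metabolites.items():
            S[met_index[metabolite.id], j] = coeff
        lower[j], upper[j] = reaction.bounds
        objective[j] = reaction.objective_coefficient
        if len(reaction.metabolites) == 1:
            medium_lower[j] = -float(medium.get(reaction.id, 0.0))
    for j, lb in medium_lower.items():
        lower[j] = lb

    subset_positions = [j for j, r in enumerate(reactions) if r.id in subset]
    k = len(subset_positions)
    # variable vector: [v_0..v_{n-1}, t_0..t_{k-1}]
    c = np.zeros(n + k)
    c[n:] = 1.0
    A_eq = np.hstack([S, np.zeros((S.shape[0], k))])
    b_eq = np.zeros(S.shape[0])
    rows = []
    rhs = []
    for slot, j in enumerate(subset_positions):
        row = np.zeros(n + k)  # v_j - t_slot <= 0
        row[j] = 1.0
        row[n + slot] = -1.0
        rows.append(row)
        rhs.append(0.0)
        row = np.zeros(n + k)  # -v_j - t_slot <= 0
        row[j] = -1.0
        row[n + slot] = -1.0
        rows.append(row)
        rhs.append(0.0)
    growth_row = np.zeros(n + k)  # -(objective . v) <= -threshold
    growth_row[:n] = -objective
    rows.append(growth_row)
    rhs.append(-growth_threshold)
    bounds = [(lower[j], upper[j]) for j in range(n)] + [(0, None)] * k
    result = linprog(
        c,
        A_ub=np.array(rows),
        b_ub=np.array(rhs),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if not result.success:
        return None
    return float(result.fun)


def exhaustive_gapfill_optimum(
    draft,
    universal,
    candidates: Sequence[str],
    medium: Dict[str, float],
    growth_threshold: float,
) -> Tuple[Optional[float], Optional[Set[str]]]:
    """Global minimum universal flux over all candidate subsets.

    Returns (minimal flux sum, one minimizing subset) or (None, None) when
    even the full candidate set is infeasible.  Exponential in candidates —
    toy fixtures only.
    """
    assert len(candidates) <= 10, "subset enumeration is for toy universals only"
    best_value, best_subset = None, None
    for size in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            value = min_universal_flux(
                draft, universal, subset, medium, growth_threshold
            )
            if value is not None and (best_value is None or value < best_value - _TOL):
                best_value, best_subset = value, set(subset)
    return best_value, best_subset
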