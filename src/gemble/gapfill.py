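"""Iterative, condition-shuffled gap-filling against growth phenotype data.

Given a draft model, a universal reaction database (another model) and a
table of binary growth calls on defined media, each gap-fill step solves a
single linear program:

* all universal reactions are merged into the draft (candidates);
* the medium of the condition is applied (unlisted exchanges closed);
* the draft's own objective (biomass) is constrained to at least a growth
  threshold;
* the new objective minimizes the summed absolute flux through candidate
  reactions — linear because the solver already represents each flux as a
  difference of two non-negative (forward/reverse) variables.

Candidates carrying more than a flux tolerance in the optimum form the
solution and are added to the draft permanently before the next condition
is processed.  Because later conditions can reuse reactions added earlier
at zero cost, the order of conditions shapes the final network; shuffling
that order (and optionally subsampling conditions) across repeated cycles
yields distinct gap-filled variants, which are compressed into an ensemble
of all unique results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import cobra
import numpy as np
import pandas as pd
from optlang.exceptions import SolverError

from . import model as model_core
from .ensemble import Ensemble, Member, build_from_models
from .errors import GapfillInfeasibleError

DEFAULT_GROWTH_THRESHOLD = 0.05
DEFAULT_FLUX_TOLERANCE = 1e-6


@dataclass
class MediumCondition:
    """One growth condition: a medium plus the observed binary growth call."""

    id: str
    medium: Dict[str, float]
    growth: bool

    def __post_init__(self):
        for rid, rate in self.medium.items():
            if rate < 0:
                raise ValueError(
                    f"condition {self.id!r}: uptake rate for {rid!r} is negative"
                )


@dataclass
class GapfillSolution:
    """Reactions drawn from the universal database for one condition."""

    condition_id: str
    added_reaction_ids: Set[str] = field(default_factory=set)
    objective_achieved: float = 0.0


# ---------------------------------------------------------------------------
# Phenotype table I/O
# ---------------------------------------------------------------------------

def write_phenotypes(conditions: Sequence[MediumCondition], path) -> None:
    """CSV with columns condition_id, growth, then one column per exchange id
    (cell = max uptake rate; 0 means absent from the medium)."""
    exchange_ids = sorted({rid for c in conditions for rid in c.medium})
    rows = []
    for condition in conditions:
        row = {"condition_id": condition.id, "growth": int(condition.growth)}
        for rid in exchange_ids:
            row[rid] = condition.medium.get(rid, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_phenotypes(path) -> List[MediumCondition]:
    frame = pd.read_csv(path)
    required = {"condition_id", "growth"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: phenotype table needs columns {sorted(required)}")
    exchange_ids = [c for c in frame.columns if c not in required]
    conditions = []
    for _, row in frame.iterrows():
        medium = {
            rid: float(row[rid]) for rid in exchange_ids if float(row[rid]) > 0
        }
        conditions.append(
            MediumCondition(
                id=str(row["condition_id"]),
                medium=medium,
                growth=bool(int(row["growth"])),
            )
        )
    return conditions


# ---------------------------------------------------------------------------
# Single-condition gap-filling LP
# ---------------------------------------------------------------------------

def _merge_universal(model: cobra.Model, universal: cobra.Model) -> Tuple[cobra.Model, List[str]]:
    """Copy of ``model`` with every universal reaction available.

    Candidates are universal reactions absent from the model, plus universal
    reactions present but blocked (bounds (0, 0)) — those are opened to
    their universal-database bounds.  Returns (merged model, candidate ids).
    """
    merged = model.copy()
    candidates: List[str] = []
    new_reactions = []
    for reaction in universal.reactions:
        if merged.reactions.has_id(reaction.id):
            existing = merged.reactions.get_by_id(reaction.id)
            if existing.bounds == (0.0, 0.0):
                existing.bounds = reaction.bounds
                candidates.append(reaction.id)
        else:
            new_reactions.append(reaction.copy())
            candidates.append(reaction.id)
    if new_reactions:
        merged.add_reactions(new_reactions)
    return merged, candidates


def gapfill_one_condition(
    model: cobra.Model,
    universal: cobra.Model,
    condition: MediumCondition,
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
    flux_tolerance: float = DEFAULT_FLUX_TOLERANCE,
) -> GapfillSolution:
    """Minimal-flux gap-fill of one positive-growth condition.

    Returns the set of universal reactions carrying flux above
    ``flux_tolerance`` in the optimum of the flux-sum-minimization LP; the
    empty set if the model already reaches ``growth_threshold``.  The input
    model is not mutated.
    """
    if not condition.growth:
        raise ValueError(
            f"condition {condition.id!r} is a no-growth call; gap-filling is "
            "only performed on positive conditions"
        )
    merged, candidates = _merge_universal(model, universal)
    model_core.set_medium(merged, condition.medium)

    biomass_expression = merged.objective.expression
    growth_constraint = merged.problem.Constraint(
        biomass_expression, lb=growth_threshold, name="gapfill_growth"
    )
    merged.add_cons_vars([growth_constraint])
    candidate_reactions = [merged.reactions.get_by_id(rid) for rid in candidates]
    # forward/reverse variables are non-negative, so their sum is |flux|
    flux_sum = sum(
        r.forward_variable + r.reverse_variable for r in candidate_reactions
    )
    merged.objective = merged.problem.Objective(flux_sum, direction="min")

    try:
        merged.slim_optimize(error_value=math.nan)
        status = merged.solver.status
    except SolverError:
        status = "infeasible"
    if status != "optimal":
        raise GapfillInfeasibleError(
            condition.id,
            "no flux distribution reaches the growth threshold even with the "
            "full universal database",
        )
    added = {
        r.id for r in candidate_reactions if abs(r.flux) > flux_tolerance
    }
    achieved = float(growth_constraint.primal)
    return GapfillSolution(
        condition_id=condition.id,
        added_reaction_ids=added,
        objective_achieved=achieved,
    )


def _insert_reactions(model: cobra.Model, universal: cobra.Model, rids: Set[str]):
    """Add gap-fill solution reactions to ``model`` with their universal bounds."""
    new = []
    for rid in sorted(rids):
        donor = universal.reactions.get_by_id(rid)
        if model.reactions.has_id(rid):
            model.reactions.get_by_id(rid).bounds = donor.bounds
        else:
            new.append(donor.copy())
    if new:
        model.add_reactions(new)


def iterative_gapfill(
    model: cobra.Model,
    universal: cobra.Model,
    conditions: Sequence[MediumCondition],
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
    flux_tolerance: float = DEFAULT_FLUX_TOLERANCE,
) -> Tuple[cobra.Model, Set[str]]:
    """Gap-fill each condition in the given order, accumulating reactions.

    After each condition the solution reactions are inserted permanently, so
    later conditions can reuse them at no cost.  Returns the gap-filled
    model and the union of all added reaction ids; the returned model
    reaches ``growth_threshold`` on every input condition.
    """
    for condition in conditions:
        if not condition.growth:
            raise ValueError(
                f"condition {condition.id!r} is a no-growth call; iterative "
                "gap-filling takes positive conditions only"
            )
    work = model.copy()
    added: Set[str] = set()
    for position, condition in enumerate(conditions):
        try:
            solution = gapfill_one_condition(
                work, universal, condition, growth_threshold, flux_tolerance
            )
        except GapfillInfeasibleError as exc:
            raise GapfillInfeasibleError(
                condition.id,
                f"failed at position {position} of the condition order",
            ) from exc
        _insert_reactions(work, universal, solution.added_reaction_ids)
        added |= solution.added_reaction_ids
    return work, added


# ---------------------------------------------------------------------------
# Ensemble generation
# ---------------------------------------------------------------------------

def generate_gapfill_ensemble(
    model: cobra.Model,
    universal: cobra.Model,
    phenotypes: Sequence[MediumCondition],
    cycles: int = 10,
    condition_fraction: float = 1.0,
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
    flux_tolerance: float = DEFAULT_FLUX_TOLERANCE,
    seed: int = 0,
    skip_failed_cycles: bool = False,
    ensemble_id: str = "gapfill_ensemble",
) -> Ensemble:
    """Repeated shuffled gap-filling, compressed to all unique results.

    Per cycle: sample ``ceil(condition_fraction * #positive)`` positive
    conditions without replacement in random order (one seeded generator
    drives the whole run), run :func:`iterative_gapfill`, and record the
    added-reaction set.  The ensemble holds one member per *unique* added
    set; provenance records the first cycle and condition order that
    produced it.  No-growth conditions are never gap-filled on.
    """
    positives = [c for c in phenotypes if c.growth]
    if not positives:
        raise ValueError("no positive-growth conditions in the phenotype table")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if not 0 < condition_fraction <= 1:
        raise ValueError("condition_fraction must be in (0, 1]")

    rng = np.random.default_rng(seed)
    count = math.ceil(condition_fraction * len(positives))
    unique: Dict[frozenset, Tuple[int, List[str], Set[str]]] = {}
    failures: List[str] = []
    for cycle in range(cycles):
        order = [positives[i] for i in rng.permutation(len(positives))[:count]]
        try:
            _, added = iterative_gapfill(
                model, universal, order, growth_threshold, flux_tolerance
            )
        except GapfillInfeasibleError as exc:
            if skip_failed_cycles:
                failures.append(f"cycle {cycle}: {exc}")
                continue
            raise GapfillInfeasibleError(
                exc.condition_id, f"cycle {cycle} aborted ({exc})"
            ) from exc
        key = frozenset(added)
        if key not in unique:
            unique[key] = (cycle, [c.id for c in order], added)
    if not unique:
        raise GapfillInfeasibleError(
            "all", f"every cycle failed: {'; '.join(failures)}"
        )

    variants = []
    provenances = []
    for index, (cycle, order_ids, added) in enumerate(
        sorted(unique.values(), key=lambda item: item[0])
    ):
        variant = model.copy()
        _insert_reactions(variant, universal, added)
        variant.id = f"gapfilled_{index}"
        variants.append(variant)
        provenances.append(
            f"cycle {cycle}; condition order {','.join(order_ids)}; "
            f"added {','.join(sorted(added))}"
        )
    ensemble = build_from_models(variants, ensemble_id=ensemble_id)
    for variant, provenance in zip(variants, provenances):
        # member ids inherit the variant model ids (gapfilled_<i>)
        ensemble.members[variant.id].provenance = provenance
    return ensemble
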