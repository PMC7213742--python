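"""Ensemble-scale simulations: FBA, FVA and single deletions over members.

Every method returns a member-indexed :class:`pandas.DataFrame` (one row per
simulated member).  Per-member results are computed on a fresh extracted
copy of the base model, so tables are identical whatever the worker count or
member evaluation order, and the ensemble itself is never left in a
member-specific state by a simulation.

Infeasible members are kept as flagged rows (``status`` column) with NaN
values rather than dropped — distribution analyses need the denominator.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Union

import cobra
import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import model as model_core
from .ensemble import Ensemble, apply_attribute_states

MemberSpec = Union[str, float, Sequence[str]]


def select_members(
    ensemble: Ensemble, spec: MemberSpec = "all", seed: int = 0
) -> List[str]:
    """Resolve a member selection: ``"all"``, an explicit id list, or a
    fraction in (0, 1] sampled without replacement (``ceil(f * N)`` members,
    reproducible under ``seed``).  The returned list is sorted by member id.
    """
    all_ids = sorted(ensemble.members)
    if isinstance(spec, str):
        if spec != "all":
            raise ValueError(f"member spec string must be 'all', got {spec!r}")
        return all_ids
    if isinstance(spec, (int, float)) and not isinstance(spec, bool):
        fraction = float(spec)
        if not 0 < fraction <= 1:
            raise ValueError(f"member fraction must be in (0, 1], got {fraction}")
        count = math.ceil(fraction * len(all_ids))
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(all_ids), size=count, replace=False)
        return sorted(all_ids[i] for i in chosen)
    ids = list(spec)
    unknown = sorted(set(ids) - set(all_ids))
    if unknown:
        raise KeyError(f"unknown member ids: {', '.join(unknown)}")
    return sorted(ids)


def _chunks(items: Sequence[str], n: int) -> List[List[str]]:
    n = max(1, min(n, len(items)))
    size = math.ceil(len(items) / n)
    return [list(items[i : i + size]) for i in range(0, len(items), size)]


def _run_chunk(ensemble: Ensemble, member_ids: List[str], task, kwargs) -> Dict:
    return {m: task(ensemble.extract_member(m), **kwargs) for m in member_ids}


def _run_json_chunk(base_json: str, states: Dict[str, list], task, kwargs) -> Dict:
    """Worker task: rebuild the base model from JSON (no solver state crosses
    the process boundary), then simulate each member on a fresh copy."""
    base = cobra.io.from_json(base_json)
    results = {}
    for member_id, triples in states.items():
        model = base.copy()
        apply_attribute_states(model, [tuple(t) for t in triples])
        results[member_id] = task(model, **kwargs)
    return results


def _dispatch(ensemble, member_ids, workers, task, kwargs) -> Dict:
    if workers < 1:
        raise ValueError("workers must be positive")
    if workers == 1 or len(member_ids) <= 1:
        return _run_chunk(ensemble, member_ids, task, kwargs)
    base_json = cobra.io.to_json(ensemble.base_model)
    results: Dict = {}
    chunked = Parallel(n_jobs=workers)(
        delayed(_run_json_chunk)(
            base_json,
            {m: ensemble.member_state_triples(m) for m in chunk},
            task,
            kwargs,
        )
        for chunk in _chunks(member_ids, workers)
    )
    for part in chunked:
        results.update(part)
    return results


def _attach_metadata(table: pd.DataFrame, method: str, members, seed, **params):
    table.attrs["method"] = method
    table.attrs["members"] = list(members)
    table.attrs["seed"] = seed
    table.attrs["parameters"] = params
    return table


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def _member_fba(model) -> pd.Series:
    solution = model_core.optimize_fba(model)
    if not solution.ok:
        row = pd.Series(math.nan, index=[r.id for r in model.reactions], dtype=float)
        row["status"] = solution.status
        return row
    row = pd.Series(solution.fluxes, dtype=object).astype(float)
    row["status"] = "optimal"
    return row


def ensemble_fba(
    ensemble: Ensemble,
    members: MemberSpec = "all",
    workers: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """FBA for each selected member: one row per member, one flux column per
    reaction, plus a ``status`` column flagging infeasible members."""
    member_ids = select_members(ensemble, members, seed)
    rows = _dispatch(ensemble, member_ids, workers, _member_fba, {})
    table = pd.DataFrame({m: rows[m] for m in member_ids}).T
    table.index.name = "member"
    reaction_cols = sorted(c for c in table.columns if c != "status")
    table = table[reaction_cols + ["status"]]
    table[reaction_cols] = table[reaction_cols].astype(float)
    return _attach_metadata(table, "fba", member_ids, seed)


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

def _member_fva(model, fraction_of_optimum, reactions) -> pd.DataFrame:
    return model_core.run_fva(
        model, fraction_of_optimum=fraction_of_optimum, reactions=reactions
    )


def ensemble_fva(
    ensemble: Ensemble,
    members: MemberSpec = "all",
    fraction_of_optimum: float = 1.0,
    reactions: Optional[Sequence[str]] = None,
    workers: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """FVA for each selected member.

    Columns are a (reaction, bound) MultiIndex with ``minimum`` and
    ``maximum`` per reaction — the two-values-per-member arrangement FVA
    requires.
    """
    member_ids = select_members(ensemble, members, seed)
    rows = _dispatch(
        ensemble,
        member_ids,
        workers,
        _member_fva,
        {"fraction_of_optimum": fraction_of_optimum, "reactions": reactions},
    )
    records = {}
    for member_id in member_ids:
        frame = rows[member_id]
        records[member_id] = {
            (rid, bound): frame.at[rid, bound]
            for rid in frame.index
            for bound in ("minimum", "maximum")
        }
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "member"
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["reaction", "bound"])
    reaction_ids = sorted({rid for rid, _ in table.columns})
    table = table.reindex(
        columns=pd.MultiIndex.from_product(
            [reaction_ids, ["minimum", "maximum"]], names=["reaction", "bound"]
        )
    )
    return _attach_metadata(
        table, "fva", member_ids, seed, fraction_of_optimum=fraction_of_optimum
    )


# ---------------------------------------------------------------------------
# Deletions
# ---------------------------------------------------------------------------

def _member_deletions(model, kind, targets) -> pd.Series:
    frame = model_core.run_single_deletions(model, kind=kind, targets=targets)
    return frame["growth"]


def ensemble_deletions(
    ensemble: Ensemble,
    kind: str = "reaction",
    members: MemberSpec = "all",
    targets: Optional[Sequence[str]] = None,
    workers: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Single gene/reaction deletions for each member.

    Cell (m, t) is the objective of member m after deleting target t.
    Deleting a reaction a member lacks (bounds already (0,0)) leaves that
    member's objective unchanged.
    """
    member_ids = select_members(ensemble, members, seed)
    rows = _dispatch(
        ensemble,
        member_ids,
        workers,
        _member_deletions,
        {"kind": kind, "targets": targets},
    )
    table = pd.DataFrame({m: rows[m] for m in member_ids}).T
    table = table.sort_index(axis=1)
    table.index.name = "member"
    table.columns.name = kind
    return _attach_metadata(table, f"{kind}_deletion", member_ids, seed)


def essentiality_frequency(
    deletion_table: pd.DataFrame, threshold: float = model_core.FLUX_TOLERANCE
) -> pd.Series:
    """Fraction of members in which each deletion abolishes the objective.

    The ensemble voting view: a value of 1.0 means the target is essential
    in every member, 0.0 in none.  NaN objectives (infeasible members) count
    as no-growth.
    """
    no_growth = deletion_table.isna() | (deletion_table < threshold)
    return no_growth.mean(axis=0)
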