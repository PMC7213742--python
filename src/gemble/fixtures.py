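"""Deterministic synthetic fixtures: toy networks, degraded drafts, universal
databases, phenotype tables, and ensembles with a planted causal feature.

Every generator is a pure function of its :class:`FixtureSpec` (or explicit
arguments) and validates its own ground truth on creation, so tests and
examples never depend on downloaded data.

The toy network is a set of independent linear chains feeding one biomass
sink::

    EX_C<i>  <->  C<i>_e  --T_C<i>-->  C<i>_c  --CONV_C<i>-->  BIO --BIOMASS-->

With uptake bound u on each open exchange, the FBA optimum is u per open
carbon source — hand-computable by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import cobra
import numpy as np
from cobra import Metabolite, Model, Reaction

from . import model as model_core
from .ensemble import Ensemble, Feature, Member, feature_id
from .gapfill import DEFAULT_GROWTH_THRESHOLD, MediumCondition

BIG = 1000.0


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters shared by the fixture generators.

    seed drives every random choice; identical specs give identical
    fixtures.  ``uptake_bound`` is the default maximum uptake per carbon
    source (mmol gDW^-1 hr^-1); ``noise_sd`` is used only when generating
    noisy synthetic outcomes.
    """

    seed: int = 0
    n_carbon_sources: int = 1
    n_pathway_alternatives: int = 1
    noise_sd: float = 0.1
    uptake_bound: float = 10.0


def _reaction(rid: str, stoich: Dict[Metabolite, float], lb: float, ub: float,
              gene_rule: str = "") -> Reaction:
    reaction = Reaction(rid, lower_bound=lb, upper_bound=ub)
    reaction.add_metabolites(stoich)
    if gene_rule:
        reaction.gene_reaction_rule = gene_rule
    return reaction


def make_toy_model(spec: FixtureSpec = FixtureSpec()) -> Model:
    """Linear-chain toy model; FBA optimum = uptake_bound x carbon sources."""
    if spec.n_carbon_sources < 1:
        raise ValueError("need at least one carbon source")
    model = Model("toy")
    bio = Metabolite("BIO", name="biomass precursor", compartment="c")
    reactions = []
    for i in range(1, spec.n_carbon_sources + 1):
        c_e = Metabolite(f"C{i}_e", name=f"carbon {i} (extracellular)", compartment="e")
        c_c = Metabolite(f"C{i}_c", name=f"carbon {i} (cytosol)", compartment="c")
        reactions.append(_reaction(f"EX_C{i}", {c_e: -1}, -spec.uptake_bound, BIG))
        reactions.append(_reaction(f"T_C{i}", {c_e: -1, c_c: 1}, 0.0, BIG,
                                   gene_rule=f"g_t{i}"))
        reactions.append(_reaction(f"CONV_C{i}", {c_c: -1, bio: 1}, 0.0, BIG,
                                   gene_rule=f"g_c{i}a or g_c{i}b"))
    reactions.append(_reaction("BIOMASS", {bio: -1}, 0.0, BIG))
    model.add_reactions(reactions)
    model.objective = "BIOMASS"
    expected = spec.uptake_bound * spec.n_carbon_sources
    achieved = model.slim_optimize()
    assert abs(achieved - expected) < 1e-6, "toy model lost its hand-computable optimum"
    return model


def degrade_model(
    model: Model,
    remove: Iterable[str],
    n_decoys: int = 3,
) -> Tuple[Model, Model]:
    """Split a complete model into (draft, universal) for gap-fill recovery.

    The draft lacks the removed (non-exchange) reactions; the universal
    database holds them plus ``n_decoys`` dead-end decoy reactions whose
    product is never consumed, so no steady-state flux can pass through
    them and they can never be part of a minimal gap-fill solution.  The
    removed ids are recorded in ``universal.notes['ground_truth']``.
    """
    remove = sorted(set(remove))
    for rid in remove:
        if not model.reactions.has_id(rid):
            raise ValueError(f"cannot remove unknown reaction {rid!r}")
        if len(model.reactions.get_by_id(rid).metabolites) == 1:
            raise ValueError(f"refusing to remove exchange reaction {rid!r}")
    draft = model.copy()
    draft.id = f"{model.id}_draft"
    removed_reactions = [draft.reactions.get_by_id(rid) for rid in remove]

    universal = Model("universal")
    universal.add_reactions([r.copy() for r in removed_reactions])
    draft.remove_reactions(removed_reactions, remove_orphans=False)

    donor_metabolite = sorted(draft.metabolites, key=lambda m: m.id)[0]
    decoys = []
    for j in range(1, n_decoys + 1):
        dead = Metabolite(f"DEAD{j}_c", name=f"decoy dead-end {j}", compartment="c")
        decoys.append(
            _reaction(f"DECOY{j}", {donor_metabolite.copy(): -1, dead: 1}, 0.0, BIG)
        )
    universal.add_reactions(decoys)
    universal.notes["ground_truth"] = remove
    return draft, universal


def make_phenotype_table(
    complete_model: Model,
    conditions: Sequence[Tuple[str, Dict[str, float]]],
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
) -> List[MediumCondition]:
    """Binary growth calls: simulate the complete model on each medium.

    ``conditions`` is a list of (condition id, medium) pairs; the growth
    call is FBA objective > growth_threshold on that medium.
    """
    table = []
    for condition_id, medium in conditions:
        probe = complete_model.copy()
        model_core.set_medium(probe, medium)  # raises KeyError on unknown ids
        solution = model_core.optimize_fba(probe)
        grows = solution.ok and solution.objective_value > growth_threshold
        table.append(MediumCondition(id=condition_id, medium=dict(medium), growth=grows))
    return table


def make_two_pathway_gapfill_fixture(
    uptake_bound: float = 10.0,
) -> Tuple[Model, Model, List[MediumCondition]]:
    """Order-sensitivity fixture: two conditions whose sequential gap-fills
    interact through a shared pathway leg.

    Draft: uptake and transport for carbons S1 and S2, but no route to
    biomass.  Universal candidates::

        W1: S1_c -> I        (serves c1 via WB)
        WB: I -> BIO         (shared leg)
        U2: S2_c -> BIO      (direct route for c2)
        W2: S2_c -> 2 I      (cheap feeder into WB; its 2x coefficient
                              halves the flux it must carry)
        DECOY_GF: S1_c -> DEADGF_c   (dead end, never selected)

    Under minimal-flux gap-filling at threshold t: c1 alone must take
    {W1, WB} (cost 2t).  c2 alone takes {U2} (t) over {W2, WB} (1.5t).
    But once WB is already in the model, c2 prefers {W2} (t/2) over {U2}
    (t).  Hence order [c1, c2] yields {W1, WB, W2} and [c2, c1] yields
    {U2, W1, WB} — distinct unique members, no cost ties at any step.
    """
    s1_e = Metabolite("S1_e", compartment="e")
    s1_c = Metabolite("S1_c", compartment="c")
    s2_e = Metabolite("S2_e", compartment="e")
    s2_c = Metabolite("S2_c", compartment="c")
    inter = Metabolite("I_c", compartment="c")
    bio = Metabolite("BIO", compartment="c")
    dead = Metabolite("DEADGF_c", compartment="c")

    draft = Model("two_pathway_draft")
    draft.add_reactions([
        _reaction("EX_S1", {s1_e: -1}, -uptake_bound, BIG),
        _reaction("EX_S2", {s2_e: -1}, -uptake_bound, BIG),
        _reaction("T_S1", {s1_e: -1, s1_c: 1}, 0.0, BIG),
        _reaction("T_S2", {s2_e: -1, s2_c: 1}, 0.0, BIG),
        _reaction("BIOMASS", {bio: -1}, 0.0, BIG),
    ])
    draft.objective = "BIOMASS"

    universal = Model("two_pathway_universal")
    universal.add_reactions([
        _reaction("W1", {s1_c.copy(): -1, inter.copy(): 1}, 0.0, BIG),
        _reaction("WB", {inter.copy(): -1, bio.copy(): 1}, 0.0, BIG),
        _reaction("U2", {s2_c.copy(): -1, bio.copy(): 1}, 0.0, BIG),
        _reaction("W2", {s2_c.copy(): -1, inter.copy(): 2}, 0.0, BIG),
        _reaction("DECOY_GF", {s1_c.copy(): -1, dead: 1}, 0.0, BIG),
    ])

    conditions = [
        MediumCondition(id="c1", medium={"EX_S1": uptake_bound}, growth=True),
        MediumCondition(id="c2", medium={"EX_S2": uptake_bound}, growth=True),
    ]
    # the draft must fail both conditions on its own
    for condition in conditions:
        probe = draft.copy()
        model_core.set_medium(probe, condition.medium)
        assert probe.slim_optimize(error_value=0.0) < 1e-9
    return draft, universal, conditions


def make_synthetic_ensemble(
    spec: FixtureSpec = FixtureSpec(),
    n_members: int = 100,
    n_neutral_features: int = 5,
) -> Tuple[Ensemble, str]:
    """Ensemble with one planted causal feature for the curation loop.

    The base model is a single-carbon toy chain whose conversion step is
    capacity-limited (upper bound u/2), plus a bypass conversion reaction
    and ``n_neutral_features`` dead-end decoy reactions.  The bypass upper
    bound is the causal feature: members carrying it reach biomass u, the
    rest u/2.  Decoy bounds vary too but can never carry flux, so they are
    neutral by construction.  Returns (ensemble, causal feature id).
    """
    if n_members < 10:
        raise ValueError("need at least 10 members")
    u = spec.uptake_bound
    base = make_toy_model(FixtureSpec(seed=spec.seed, uptake_bound=u))
    base.id = "synthetic_ensemble_base"
    conv = base.reactions.get_by_id("CONV_C1")
    conv.upper_bound = u / 2
    c1_c = base.metabolites.get_by_id("C1_c")
    bio = base.metabolites.get_by_id("BIO")
    extra = [_reaction("BYPASS", {c1_c: -1, bio: 1}, 0.0, BIG)]
    for j in range(1, n_neutral_features + 1):
        dead = Metabolite(f"NDEAD{j}_c", compartment="c")
        extra.append(_reaction(f"NEUTRAL{j}", {c1_c: -1, dead: 1}, 0.0, BIG))
    base.add_reactions(extra)

    rng = np.random.default_rng(spec.seed)
    member_ids = [f"m{i:03d}" for i in range(n_members)]
    ensemble = Ensemble("synthetic_ensemble", base)

    varying = ["BYPASS"] + [f"NEUTRAL{j}" for j in range(1, n_neutral_features + 1)]
    presence = {rid: rng.integers(0, 2, size=n_members) for rid in varying}
    for rid in varying:
        # guarantee both states occur so every feature encodes variation
        if presence[rid].min() == presence[rid].max():
            presence[rid][0] = 1 - presence[rid][0]
    for rid in varying:
        ub_states = {
            m: (BIG if presence[rid][i] else 0.0)
            for i, m in enumerate(member_ids)
        }
        lb_states = {m: 0.0 for m in member_ids}
        fid_ub = feature_id(rid, "upper_bound")
        fid_lb = feature_id(rid, "lower_bound")
        ensemble.features[fid_ub] = Feature(fid_ub, rid, "upper_bound", ub_states)
        ensemble.features[fid_lb] = Feature(fid_lb, rid, "lower_bound", lb_states)
    for member_id in member_ids:
        ensemble.members[member_id] = Member(id=member_id, provenance="synthetic")

    causal = feature_id("BYPASS", "upper_bound")
    # self-check: the causal state alone decides the optimum (u vs u/2)
    for member_id in (member_ids[0], member_ids[1]):
        extracted = ensemble.extract_member(member_id)
        expected = u if ensemble.features[causal].states[member_id] else u / 2
        assert abs(extracted.slim_optimize() - expected) < 1e-6
    return ensemble, causal
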