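"""Single-model layer: I/O, medium handling, FBA, FVA and single deletions.

Models are plain :class:`cobra.Model` objects, so anything built with the
wider COBRA ecosystem interoperates directly. This module pins down the
contracts the ensemble layer relies on:

* exchange (boundary) reactions are exactly the reactions touching a single
  metabolite; uptake is negative flux, secretion positive;
* media are applied by opening the listed exchanges to the given uptake rate
  and closing every unlisted exchange;
* SBML files must carry explicit flux bounds (Level 3 + the flux-balance
  constraints package); files without them are rejected rather than patched
  with defaults;
* gene-protein-reaction rules are AND/OR expressions over gene ids, and an
  empty rule always evaluates true.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import cobra
import libsbml
import pandas as pd
from cobra.flux_analysis import flux_variability_analysis
from cobra.util.solver import linear_reaction_coefficients
from optlang.exceptions import SolverError

from .errors import (
    GeneRuleSyntaxError,
    ModelFormatError,
    ObjectiveConfigurationError,
)

#: Feasibility / zero-flux tolerance used throughout the package.
FLUX_TOLERANCE = 1e-6

MetabolicModel = cobra.Model


@dataclass
class FluxSolution:
    """Outcome of one flux balance optimization.

    status
        ``"optimal"``, ``"infeasible"`` or ``"unbounded"``.
    objective_value
        Optimal objective flux; NaN unless status is optimal.
    fluxes
        Reaction id -> flux value; empty unless status is optimal.
    """

    status: str
    objective_value: float
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _require_sbml_bounds(path: str) -> None:
    """Reject SBML documents that do not state flux bounds explicitly."""
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise ModelFormatError(
            f"SBML parse failure in {path}: {err.getMessage().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"{path}: no <model> element")
    for i in range(sbml_model.getNumReactions()):
        reaction = sbml_model.getReaction(i)
        fbc = reaction.getPlugin("fbc")
        if (
            fbc is None
            or not fbc.isSetLowerFluxBound()
            or not fbc.isSetUpperFluxBound()
        ):
            raise ModelFormatError(
                f"{path}: reaction {reaction.getId()!r} lacks explicit flux "
                "bounds (SBML Level 3 + fbc bounds are required; no defaults "
                "are assumed)"
            )


def read_model(path, format: Optional[str] = None) -> MetabolicModel:
    """Read a model from SBML (Level 3 + fbc) or the COBRA JSON dialect.

    ``format`` is ``"sbml"`` or ``"json"``; inferred from the file suffix
    when omitted.  SBML files must declare flux bounds for every reaction.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format == "sbml":
        _require_sbml_bounds(path)
        try:
            model = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # cobra raises CobraSBMLError and others
            raise ModelFormatError(f"cannot read SBML model {path}: {exc}") from exc
    elif format == "json":
        try:
            model = cobra.io.load_json_model(str(path))
        except KeyError as exc:
            raise ModelFormatError(
                f"{path}: reaction references undeclared metabolite or gene {exc}"
            ) from exc
        except Exception as exc:
            raise ModelFormatError(f"cannot read JSON model {path}: {exc}") from exc
    else:
        raise ValueError(f"unknown model format {format!r}")
    _validate(model, path)
    return model


def write_model(model: MetabolicModel, path, format: Optional[str] = None) -> None:
    """Write a model as SBML Level 3 + fbc, or as COBRA JSON."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    elif format == "json":
        cobra.io.save_json_model(model, str(path))
    else:
        raise ValueError(f"unknown model format {format!r}")


def _validate(model: MetabolicModel, source) -> None:
    for reaction in model.reactions:
        if reaction.lower_bound > reaction.upper_bound:
            raise ModelFormatError(
                f"{source}: reaction {reaction.id!r} has lower bound "
                f"{reaction.lower_bound} above upper bound {reaction.upper_bound}"
            )
        if len(reaction.metabolites) == 0:
            raise ModelFormatError(
                f"{source}: reaction {reaction.id!r} has empty stoichiometry"
            )


# ---------------------------------------------------------------------------
# Media
# ---------------------------------------------------------------------------

def exchange_reactions(model: MetabolicModel) -> List[cobra.Reaction]:
    """All boundary reactions: reactions touching exactly one metabolite."""
    return [r for r in model.reactions if len(r.metabolites) == 1]


def set_medium(model: MetabolicModel, medium: Mapping[str, float]) -> None:
    """Apply a growth medium in place.

    Each key is an exchange reaction id, each value the maximum uptake rate
    (non-negative, mmol gDW^-1 hr^-1).  Listed exchanges get lower bound
    ``-rate``; every exchange NOT listed is closed to uptake (lower bound 0).
    Upper bounds (secretion) are untouched.
    """
    exchanges = {r.id: r for r in exchange_reactions(model)}
    unknown = sorted(set(medium) - set(exchanges))
    if unknown:
        raise KeyError(
            f"medium names non-exchange or missing reactions: {', '.join(unknown)}"
        )
    for rid, rate in medium.items():
        if rate < 0:
            raise ValueError(f"uptake rate for {rid!r} must be non-negative")
    for rid, reaction in exchanges.items():
        reaction.lower_bound = -float(medium[rid]) if rid in medium else 0.0


# ---------------------------------------------------------------------------
# Gene-protein-reaction rules
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(?:(\()|(\))|([^\s()]+))")


def _tokenize(rule: str) -> List[Tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(rule):
        match = _TOKEN.match(rule, pos)
        if match is None or match.end() == pos:
            raise GeneRuleSyntaxError("unexpected character", pos)
        if match.group(1):
            tokens.append(("(", "(", match.start(1)))
        elif match.group(2):
            tokens.append((")", ")", match.start(2)))
        else:
            word = match.group(3)
            kind = word.lower() if word.lower() in ("and", "or") else "id"
            tokens.append((kind, word, match.start(3)))
        pos = match.end()
    return tokens


class _RuleParser:
    """Recursive-descent parser for ``expr := term (OR term)*`` grammar."""

    def __init__(self, rule: str, deleted: frozenset):
        self.rule = rule
        self.tokens = _tokenize(rule)
        self.index = 0
        self.deleted = deleted

    def _peek(self):
        return self.tokens[self.index] if self.index < len(self.tokens) else None

    def _take(self):
        token = self._peek()
        if token is None:
            raise GeneRuleSyntaxError("unexpected end of rule", len(self.rule))
        self.index += 1
        return token

    def parse(self) -> bool:
        value = self._expr()
        leftover = self._peek()
        if leftover is not None:
            raise GeneRuleSyntaxError(
                f"unexpected token {leftover[1]!r}", leftover[2]
            )
        return value

    def _expr(self) -> bool:
        value = self._term()
        while self._peek() is not None and self._peek()[0] == "or":
            self._take()
            value = self._term() or value
        return value

    def _term(self) -> bool:
        value = self._factor()
        while self._peek() is not None and self._peek()[0] == "and":
            self._take()
            value = self._factor() and value
        return value

    def _factor(self) -> bool:
        kind, text, pos = self._take()
        if kind == "(":
            value = self._expr()
            closing = self._take()
            if closing[0] != ")":
                raise GeneRuleSyntaxError("expected ')'", closing[2])
            return value
        if kind == "id":
            return text not in self.deleted
        raise GeneRuleSyntaxError(f"unexpected token {text!r}", pos)


def evaluate_gene_rule(rule: str, deleted: Iterable[str] = ()) -> bool:
    """Evaluate a gene rule with the given genes knocked out.

    Deleted genes are false, all others true; AND/OR are case-insensitive;
    the empty rule is true (a reaction with no gene association survives
    every gene deletion).
    """
    if not rule or not rule.strip():
        return True
    return _RuleParser(rule, frozenset(deleted)).parse()


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _require_objective(model: MetabolicModel) -> None:
    if not linear_reaction_coefficients(model):
        raise ObjectiveConfigurationError(
            f"model {model.id!r} has no objective reaction"
        )


_STATUS_MAP = {
    "optimal": "optimal",
    "infeasible": "infeasible",
    "unbounded": "unbounded",
    "infeasible_or_unbounded": "infeasible",
    "undefined": "infeasible",
}


def optimize_fba(model: MetabolicModel) -> FluxSolution:
    """Maximize the model objective subject to S v = 0 and flux bounds."""
    _require_objective(model)
    try:
        solution = model.optimize(raise_error=False)
    except SolverError as exc:  # numerically pathological problems
        return FluxSolution(status="infeasible", objective_value=math.nan)
    status = _STATUS_MAP.get(solution.status, "infeasible")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=math.nan)
    return FluxSolution(
        status="optimal",
        objective_value=float(solution.objective_value),
        fluxes={rid: float(v) for rid, v in solution.fluxes.items()},
    )


def run_fva(
    model: MetabolicModel,
    fraction_of_optimum: float = 1.0,
    reactions: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Flux ranges at a given fraction of the optimal objective.

    Returns a DataFrame indexed by reaction id with ``minimum`` and
    ``maximum`` columns.  Infeasibility of the base model propagates as
    :class:`cobra.exceptions.Infeasible`.
    """
    _require_objective(model)
    reaction_list = None
    if reactions is not None:
        reaction_list = [model.reactions.get_by_id(rid) for rid in reactions]
    result = flux_variability_analysis(
        model,
        reaction_list=reaction_list,
        fraction_of_optimum=fraction_of_optimum,
        processes=1,
    )
    return result[["minimum", "maximum"]]


def run_single_deletions(
    model: MetabolicModel,
    kind: str = "reaction",
    targets: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Objective after deleting each gene or reaction, one at a time.

    Reaction deletion clamps that reaction's bounds to (0, 0); gene deletion
    clamps every reaction whose gene rule evaluates false without the gene.
    The model is restored to its original bounds afterwards.  Returns a
    DataFrame indexed by target id with ``growth`` and ``status`` columns.
    """
    _require_objective(model)
    if kind not in ("gene", "reaction"):
        raise ValueError(f"kind must be 'gene' or 'reaction', got {kind!r}")
    if kind == "reaction":
        all_ids = [r.id for r in model.reactions]
    else:
        all_ids = [g.id for g in model.genes]
    if targets is None:
        targets = all_ids
    else:
        unknown = sorted(set(targets) - set(all_ids))
        if unknown:
            raise KeyError(f"unknown {kind} ids: {', '.join(unknown)}")

    rows = {}
    for target in targets:
        if kind == "reaction":
            affected = [model.reactions.get_by_id(target)]
        else:
            affected = [
                r
                for r in model.reactions
                if r.gene_reaction_rule
                and not evaluate_gene_rule(r.gene_reaction_rule, {target})
            ]
        saved = [(r, r.bounds) for r in affected]
        try:
            for reaction, _ in saved:
                reaction.bounds = (0.0, 0.0)
            value = model.slim_optimize(error_value=math.nan)
            status = _STATUS_MAP.get(model.solver.status, "infeasible")
            if status != "optimal":
                value = math.nan
        finally:
            for reaction, bounds in saved:
                reaction.bounds = bounds
        rows[target] = (value, status)

    frame = pd.DataFrame.from_dict(rows, orient="index", columns=["growth", "status"])
    frame.index.name = kind
    return frame
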