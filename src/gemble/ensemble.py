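"""Compact ensembles of metabolic model variants.

An :class:`Ensemble` stores one *base model* — the union of every reaction
any variant might use — plus, for each :class:`Feature` (one attribute of one
base-model reaction that varies), the state of every :class:`Member`.
A member is reconstituted purely by attribute assignment on the base model,
so an N-member ensemble costs one model plus an N x F state matrix instead
of N model copies.

Reactions absent from a member are encoded as bounds (0, 0) on the base
model rather than structural removal; presence/absence therefore appears as
a pair of bound features.
"""

from __future__ import annotations

import json
import math
import tempfile
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import cobra
import pandas as pd

from . import model as model_core
from .errors import (
    ArchiveFormatError,
    ArchiveVersionError,
    StoichiometryConflictError,
)

ARCHIVE_FORMAT = "gemble-ensemble"
ARCHIVE_VERSION = 1

BOUND_ATTRIBUTES = ("lower_bound", "upper_bound")
ATTRIBUTES = BOUND_ATTRIBUTES + ("gene_rule",)

#: cobra attribute name for each feature attribute.
_COBRA_ATTR = {
    "lower_bound": "lower_bound",
    "upper_bound": "upper_bound",
    "gene_rule": "gene_reaction_rule",
}


def feature_id(component_id: str, attribute: str) -> str:
    """Canonical feature id for a (reaction, attribute) pair."""
    return f"{component_id}__{attribute}"


@dataclass(eq=False)
class Feature:
    """One varying attribute of one base-model reaction.

    ``states`` maps member id -> the value that member holds for this
    attribute (a float for bounds, a rule string for gene_rule).
    """

    id: str
    component_id: str
    attribute: str
    states: Dict[str, Union[float, str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.attribute not in ATTRIBUTES:
            raise ValueError(f"unknown feature attribute {self.attribute!r}")


@dataclass
class Member:
    """One model variant, identified by its state for every feature."""

    id: str
    provenance: str = ""


class Ensemble:
    """Base model + features + members; can impersonate any member."""

    def __init__(self, id: str, base_model: cobra.Model):
        self.id = id
        self.base_model = base_model
        self.features: Dict[str, Feature] = {}
        self.members: Dict[str, Member] = {}
        self.current_member: Optional[str] = None

    def __len__(self) -> int:
        return len(self.members)

    def __repr__(self) -> str:
        return (
            f"<Ensemble {self.id}: {len(self.members)} members, "
            f"{len(self.features)} features>"
        )

    # -- construction ------------------------------------------------------

    def add_member(self, member: Member, states: Mapping[str, Union[float, str]]):
        """Register a member with one state per existing feature."""
        if member.id in self.members:
            raise ValueError(f"duplicate member id {member.id!r}")
        missing = set(self.features) - set(states)
        if missing:
            raise ValueError(f"member {member.id!r} lacks states for {sorted(missing)}")
        self.members[member.id] = member
        for fid, value in states.items():
            self.features[fid].states[member.id] = value

    # -- state switching ---------------------------------------------------

    def member_state_triples(self, member_id: str) -> List[tuple]:
        """(component_id, attribute, value) for every feature, for one member."""
        if member_id not in self.members:
            raise KeyError(f"unknown member {member_id!r}")
        return [
            (f.component_id, f.attribute, f.states[member_id])
            for f in self.features.values()
        ]

    def set_member_state(self, member_id: str) -> None:
        """Mutate the base model so it represents ``member_id`` exactly."""
        apply_attribute_states(self.base_model, self.member_state_triples(member_id))
        self.current_member = member_id

    def extract_member(self, member_id: str) -> cobra.Model:
        """A standalone copy of the base model in the member's state."""
        triples = self.member_state_triples(member_id)
        model = self.base_model.copy()
        apply_attribute_states(model, triples)
        model.id = f"{self.base_model.id}_{member_id}"
        return model

    # -- tables ------------------------------------------------------------

    def feature_state_table(self, binarize: bool = False) -> pd.DataFrame:
        """Member x feature table of states.

        With ``binarize=True``, each cell is 1 if the state permits flux:
        a bound state binarizes to 1 iff it is nonzero, a gene_rule state to
        1 iff the rule string is non-empty.
        """
        member_ids = sorted(self.members)
        fids = sorted(self.features)
        data = {
            fid: [self.features[fid].states[m] for m in member_ids] for fid in fids
        }
        table = pd.DataFrame(data, index=pd.Index(member_ids, name="member"))
        if binarize:
            def _bin(value):
                if isinstance(value, str):
                    return 1 if value.strip() else 0
                return 1 if abs(value) > 0 else 0

            table = table.map(_bin).astype(int)
        return table

    # -- curation ----------------------------------------------------------

    def set_feature_across_members(self, fid: str, value: Union[float, str]) -> None:
        """Set one feature to the same value for every member (a curation edit)."""
        if fid not in self.features:
            raise KeyError(f"unknown feature {fid!r}")
        feature = self.features[fid]
        if feature.attribute in BOUND_ATTRIBUTES:
            if isinstance(value, str):
                raise ValueError(
                    f"feature {fid!r} is a bound; value must be numeric"
                )
            value = float(value)
        else:
            if not isinstance(value, str):
                raise ValueError(f"feature {fid!r} is a gene rule; value must be str")
        for member_id in self.members:
            feature.states[member_id] = value
        if self.current_member is not None:
            self.set_member_state(self.current_member)


def apply_attribute_states(model: cobra.Model, triples) -> None:
    """Assign (component_id, attribute, value) states, setting both bounds of
    a reaction together so a transient lower > upper ordering cannot trip
    cobra's bound check."""
    by_reaction: Dict[str, Dict[str, Union[float, str]]] = {}
    for component_id, attribute, value in triples:
        by_reaction.setdefault(component_id, {})[attribute] = value
    for rid, attrs in by_reaction.items():
        reaction = model.reactions.get_by_id(rid)
        if "lower_bound" in attrs or "upper_bound" in attrs:
            lb = attrs.get("lower_bound", reaction.lower_bound)
            ub = attrs.get("upper_bound", reaction.upper_bound)
            reaction.bounds = (float(lb), float(ub))
        if "gene_rule" in attrs:
            reaction.gene_reaction_rule = attrs["gene_rule"]


# ---------------------------------------------------------------------------
# Construction from model collections
# ---------------------------------------------------------------------------

def _stoichiometry(reaction: cobra.Reaction) -> Dict[str, float]:
    return {m.id: float(c) for m, c in reaction.metabolites.items()}


def _member_id_for(source, taken) -> str:
    if isinstance(source, (str, Path)):
        base = Path(source).stem
    else:
        base = source.id or "member"
    candidate, suffix = base, 1
    while candidate in taken:
        suffix += 1
        candidate = f"{base}_{suffix}"
    return candidate


def _iter_batches(sources: Sequence, batch_size: int):
    for start in range(0, len(sources), batch_size):
        batch = sources[start : start + batch_size]
        loaded = []
        for source in batch:
            if isinstance(source, (str, Path)):
                loaded.append((source, model_core.read_model(source)))
            else:
                loaded.append((source, source))
        yield loaded


def build_from_models(
    sources: Sequence,
    batch_size: int = 10,
    ensemble_id: str = "ensemble",
) -> Ensemble:
    """Compress a collection of models (or model file paths) into an ensemble.

    The base model is the union of all reactions; a reaction absent from a
    source is recorded as bounds (0, 0) for that member.  One feature is
    created per (reaction, attribute) that actually varies.  Sources sharing
    a reaction id must agree on its stoichiometry.  Loading from paths keeps
    at most ``batch_size`` models in memory at a time; the result is
    independent of ``batch_size`` and of source order (up to member labels).
    """
    if len(sources) == 0:
        raise ValueError("need at least one source model")
    if batch_size < 1:
        raise ValueError("batch_size must be positive")

    base: Optional[cobra.Model] = None
    stoich: Dict[str, Dict[str, float]] = {}
    # per-reaction attribute records: rid -> {member -> (lb, ub, rule)}
    records: Dict[str, Dict[str, tuple]] = {}
    member_order: List[Member] = []

    for batch in _iter_batches(list(sources), batch_size):
        for source, model in batch:
            member = Member(
                id=_member_id_for(source, {m.id for m in member_order}),
                provenance=str(source) if isinstance(source, (str, Path)) else (
                    f"in-memory model {model.id!r}"
                ),
            )
            member_order.append(member)
            if base is None:
                base = model.copy()
                base.id = ensemble_id
            for reaction in model.reactions:
                coeffs = _stoichiometry(reaction)
                if reaction.id in stoich:
                    if stoich[reaction.id] != coeffs:
                        raise StoichiometryConflictError(reaction.id)
                else:
                    stoich[reaction.id] = coeffs
                    if not base.reactions.has_id(reaction.id):
                        donor = reaction.copy()
                        base.add_reactions([donor])
                records.setdefault(reaction.id, {})[member.id] = (
                    float(reaction.lower_bound),
                    float(reaction.upper_bound),
                    reaction.gene_reaction_rule,
                )

    assert base is not None
    ensemble = Ensemble(ensemble_id, base)
    member_ids = [m.id for m in member_order]

    for rid in sorted(records):
        per_member = records[rid]
        base_reaction = base.reactions.get_by_id(rid)
        absent = [m for m in member_ids if m not in per_member]
        values = {}
        for attr_idx, attribute in enumerate(ATTRIBUTES):
            states = {}
            for member_id in member_ids:
                if member_id in per_member:
                    states[member_id] = per_member[member_id][attr_idx]
                elif attribute in BOUND_ATTRIBUTES:
                    states[member_id] = 0.0
                else:  # rule value is irrelevant while the reaction is blocked
                    states[member_id] = base_reaction.gene_reaction_rule
            values[attribute] = states
        # presence/absence must yield both bound features even if one bound
        # happens to coincide (e.g. irreversible reactions have lb == 0)
        presence_varies = bool(absent) and len(absent) < len(member_ids)
        for attribute, states in values.items():
            varies = len(set(states.values())) > 1
            if varies or (presence_varies and attribute in BOUND_ATTRIBUTES):
                fid = feature_id(rid, attribute)
                ensemble.features[fid] = Feature(
                    id=fid, component_id=rid, attribute=attribute, states=states
                )

    for member in member_order:
        ensemble.members[member.id] = member
    return ensemble


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _zip_write(archive: zipfile.ZipFile, name: str, data: bytes) -> None:
    # fixed timestamp so identical ensembles produce byte-identical archives
    info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
    info.compress_type = zipfile.ZIP_DEFLATED
    archive.writestr(info, data)


def save_ensemble(ensemble: Ensemble, path) -> None:
    """Write a portable archive: base model as SBML + a JSON state document.

    The archive is a zip holding ``base.xml`` (SBML Level 3 + fbc) and
    ``ensemble.json`` with the feature/member/state matrix — never a
    per-member copy of the model.
    """
    path = Path(path)
    with tempfile.TemporaryDirectory() as tmp:
        sbml_path = Path(tmp) / "base.xml"
        model_core.write_model(ensemble.base_model, sbml_path, format="sbml")
        sbml_bytes = sbml_path.read_bytes()
    document = {
        "format": ARCHIVE_FORMAT,
        "version": ARCHIVE_VERSION,
        "id": ensemble.id,
        "members": [
            {"id": m.id, "provenance": m.provenance}
            for m in sorted(ensemble.members.values(), key=lambda m: m.id)
        ],
        "features": [
            {
                "id": f.id,
                "component_id": f.component_id,
                "attribute": f.attribute,
                "states": {m: f.states[m] for m in sorted(f.states)},
            }
            for f in sorted(ensemble.features.values(), key=lambda f: f.id)
        ],
    }
    payload = json.dumps(document, indent=1, sort_keys=True).encode()
    with zipfile.ZipFile(path, "w") as archive:
        _zip_write(archive, "base.xml", sbml_bytes)
        _zip_write(archive, "ensemble.json", payload)


def load_ensemble(path) -> Ensemble:
    """Read an archive written by :func:`save_ensemble`."""
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as archive:
            names = set(archive.namelist())
            if not {"base.xml", "ensemble.json"} <= names:
                raise ArchiveFormatError(
                    f"{path}: archive must contain base.xml and ensemble.json"
                )
            payload = archive.read("ensemble.json")
            sbml_bytes = archive.read("base.xml")
    except zipfile.BadZipFile as exc:
        raise ArchiveFormatError(f"{path}: not a zip archive") from exc
    try:
        document = json.loads(payload)
    except json.JSONDecodeError as exc:
        raise ArchiveFormatError(f"{path}: ensemble.json is not valid JSON") from exc
    if document.get("format") != ARCHIVE_FORMAT:
        raise ArchiveFormatError(f"{path}: not a {ARCHIVE_FORMAT} archive")
    if document.get("version") != ARCHIVE_VERSION:
        raise ArchiveVersionError(
            f"{path}: archive version {document.get('version')} "
            f"(this build reads version {ARCHIVE_VERSION})"
        )
    with tempfile.TemporaryDirectory() as tmp:
        sbml_path = Path(tmp) / "base.xml"
        sbml_path.write_bytes(sbml_bytes)
        base = model_core.read_model(sbml_path, format="sbml")
    base.id = document["id"]
    ensemble = Ensemble(document["id"], base)
    for entry in document["members"]:
        ensemble.members[entry["id"]] = Member(
            id=entry["id"], provenance=entry.get("provenance", "")
        )
    for entry in document["features"]:
        states = entry["states"]
        missing = set(ensemble.members) - set(states)
        if missing:
            raise ArchiveFormatError(
                f"{path}: feature {entry['id']!r} lacks states for {sorted(missing)}"
            )
        ensemble.features[entry["id"]] = Feature(
            id=entry["id"],
            component_id=entry["component_id"],
            attribute=entry["attribute"],
            states={
                m: (v if isinstance(v, str) else float(v)) for m, v in states.items()
            },
        )
    return ensemble
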