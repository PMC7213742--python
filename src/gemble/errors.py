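"""Exception types shared across gemble."""


class GembleError(Exception):
    """Base class for all gemble-specific errors."""


class ModelFormatError(GembleError):
    """A model file could not be parsed, or violates the model contract."""


class ObjectiveConfigurationError(GembleError):
    """An operation requiring an objective was called on a model without one."""


class GeneRuleSyntaxError(GembleError):
    """A gene-protein-reaction rule failed to parse.

    Carries ``position``, the 0-based character offset of the offending token.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class StoichiometryConflictError(GembleError):
    """Two source models define the same reaction id with different stoichiometry."""

    def __init__(self, reaction_id: str):
        super().__init__(
            f"reaction {reaction_id!r} has conflicting stoichiometry across source models"
        )
        self.reaction_id = reaction_id


class ArchiveFormatError(GembleError):
    """An ensemble archive is corrupt or not an ensemble archive."""


class ArchiveVersionError(GembleError):
    """An ensemble archive was written by an incompatible schema version."""


class GapfillInfeasibleError(GembleError):
    """No gap-fill solution exists for a condition, even with the full universal set."""

    def __init__(self, condition_id: str, detail: str = ""):
        msg = f"gap-filling infeasible for condition {condition_id!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)
        self.condition_id = condition_id
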