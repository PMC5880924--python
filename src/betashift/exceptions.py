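"""Exception hierarchy for betashift.

All library errors derive from :class:`BetashiftError` so callers can catch
one base class; subclasses distinguish the failure modes (bad file format,
unknown trait level, degenerate geometry, ...) that each operation's
contract treats differently.
"""


class BetashiftError(Exception):
    """Base class for all betashift errors."""


class FormatError(BetashiftError):
    """A file violates the declared on-disk format (e.g. a non-binary cell)."""


class ValidationError(BetashiftError):
    """Parsed data violate an invariant (duplicate ids, missing cells...)."""


class VocabularyError(ValidationError):
    """A trait level is not in the declared trait vocabulary."""


class AlignmentError(BetashiftError):
    """Two period matrices cannot be aligned (e.g. disjoint site sets)."""


class CoverageError(BetashiftError):
    """A species required downstream has no coordinates / trait record."""


class DegenerateInputError(BetashiftError):
    """Input is too degenerate for the requested computation."""


class EmptyPairError(DegenerateInputError):
    """Both assemblages of a pair are empty (a + b + c = 0)."""


class StandardizationError(BetashiftError):
    """A constant vector cannot be min-max standardized."""


class RankDeficiencyError(BetashiftError):
    """A regression design matrix is rank deficient."""


class ConfigError(BetashiftError):
    """A run or scenario configuration is invalid."""


class StageError(BetashiftError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
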