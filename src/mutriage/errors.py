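"""Exception hierarchy.

Every failure mode a caller may want to branch on gets its own class;
stage-level wrappers carry the stage name so pipeline errors are traceable.
"""


class MutriageError(Exception):
    """Base class for all package errors."""


# --- catalog parsing / validation -------------------------------------------

class CatalogParseError(MutriageError, ValueError):
    """A mutation token could not be parsed."""


class MalformedTokenError(CatalogParseError):
    """Token does not match WT + position + MUT."""


class SynonymousSubstitutionError(CatalogParseError):
    """Wild-type and mutant residue are identical."""


class NonStandardResidueError(CatalogParseError):
    """A letter outside the 20 standard amino acids."""


class CatalogFileError(MutriageError):
    """Missing mandatory column or unreadable catalog file."""


# --- annotation -------------------------------------------------------------

class AnnotationError(MutriageError):
    """Invalid annotation: overlapping domains, site outside host, bad interval."""


class PositionError(MutriageError, IndexError):
    """Residue position outside the annotated sequence."""


# --- substitution matrices --------------------------------------------------

class MatrixError(MutriageError):
    """Letter absent from matrix, asymmetry, or unknown normalization scheme."""


# --- evidence ---------------------------------------------------------------

class EvidenceError(MutriageError):
    """Malformed or out-of-range predictor evidence."""


class MissingEvidenceError(EvidenceError, KeyError):
    """A required evidence value is absent for a mutation/position."""


# --- scoring ----------------------------------------------------------------

class ScoringError(MutriageError):
    """Weight fitting or candidate selection failure."""


class PipelineStageError(MutriageError):
    """Wraps an error with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
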