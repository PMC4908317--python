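"""Exception hierarchy for the prediction pipeline.

Every error a caller is expected to handle programmatically has its own
class; all inherit from :class:`PrmPredError` so a pipeline stage can wrap
and re-raise with stage context.
"""


class PrmPredError(Exception):
    """Base class for all package-specific errors."""


# --- motif model / scanning ---------------------------------------------

class LengthMismatch(PrmPredError):
    """Peptides or windows whose length does not match the motif length."""


class AlphabetError(PrmPredError):
    """A residue outside the model alphabet where one is required."""


class InsufficientData(PrmPredError):
    """Too few observations to estimate a model."""


class UnattainableThreshold(PrmPredError):
    """Requested p-value is below the smallest attainable tail probability."""


class EmptySignificantSet(PrmPredError):
    """No motif column passes the information-content cutoff (N = 0)."""


class EmptyInput(PrmPredError):
    """An input collection (proteome, sequence, list) is empty."""


class DuplicateId(PrmPredError):
    """Duplicate identifiers where uniqueness is required."""


class DomainMismatch(PrmPredError):
    """Operation on hits from different proteins."""


# --- peptide features ----------------------------------------------------

class TrackMismatch(PrmPredError):
    """Per-residue track does not cover the protein or hit coordinates."""


class MissingReference(PrmPredError):
    """Reference row absent from a multiple alignment."""


class DegenerateModel(PrmPredError):
    """A contact model with no positive contact area."""


# --- protein features ----------------------------------------------------

class EmptyOntology(PrmPredError):
    """Ontology namespace contains no terms."""


class MissingAnnotation(PrmPredError):
    """A query protein carries no annotation in the requested namespace."""


class UnknownTerm(PrmPredError):
    """Annotation term absent from the ontology graph."""


class NoExpressionEvidence(PrmPredError):
    """No qualifying expression profile for a gene pair."""


class NoSignatureEvidence(PrmPredError):
    """No signature known to the model on one of the proteins."""


# --- classification ------------------------------------------------------

class DegenerateTraining(PrmPredError):
    """Training data contains a single class."""


class NoEvidence(PrmPredError):
    """All features in a classifier's scope are missing for a candidate."""


class UndefinedMetric(PrmPredError):
    """A metric is undefined for the given labels (e.g. single class)."""


# --- I/O and configuration ----------------------------------------------

class ConfigError(PrmPredError):
    """Configuration value outside its documented range."""


class ParseError(PrmPredError):
    """Malformed record in an input file; message names file and line."""


class SpecError(PrmPredError):
    """Inconsistent synthetic-fixture specification."""
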