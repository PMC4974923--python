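"""Exception hierarchy for the gait-emotion pipeline.

All pipeline errors derive from :class:`EmogaitError` so callers can catch
the package's failures without masking programming errors.
"""


class EmogaitError(Exception):
    """Base class for all pipeline errors."""


class FormatError(EmogaitError):
    """A recording file violates the documented tabular format."""


class IntegrityError(EmogaitError):
    """Data are structurally inconsistent (gaps, non-finite values, ...)."""


class VocabularyError(EmogaitError):
    """An emotion or wear-site token is outside the closed vocabulary."""


class CoverageError(EmogaitError):
    """A classification task requires a class absent from the data."""


class LengthError(EmogaitError):
    """A series or segment has the wrong length for the requested operation."""


class DegenerateFeatureError(EmogaitError):
    """A feature is 0/0-undefined on this input (zero-variance channel)."""


class DegeneracyError(EmogaitError):
    """A matrix is too degenerate to fit (e.g. all columns constant)."""


class SchemaError(EmogaitError):
    """Feature columns do not match the columns a model was fitted on."""


class TaskError(EmogaitError):
    """A classification task cannot be run (e.g. a single-class dataset)."""


class AliasingError(EmogaitError):
    """A requested oscillation frequency is at or above the Nyquist limit."""
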