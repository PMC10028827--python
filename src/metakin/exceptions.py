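"""Exception hierarchy for metakin."""


class MetakinError(Exception):
    """Base class for all metakin errors."""


class InvalidParameterError(MetakinError, ValueError):
    """A parameter value violates its contract (non-positive time, negative sd, ...)."""


class InvalidInputError(MetakinError, ValueError):
    """An input object violates its contract (empty trajectory, bad event time, ...)."""


class InsufficientDataError(MetakinError, ValueError):
    """Too few observations for the requested estimate."""


class DegenerateSampleError(MetakinError, ValueError):
    """All observations identical; the requested fit is undefined."""


class EmptyDensityError(MetakinError, ValueError):
    """No probability mass falls inside the requested binning."""


class MissingTargetError(MetakinError, KeyError):
    """A ligand has no residence-time target."""


class UnsupportedModelError(MetakinError, TypeError):
    """The operation requires a tree-ensemble model."""


class FormatError(MetakinError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(MetakinError, ValueError):
    """Parsed records violate schema-level constraints."""
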