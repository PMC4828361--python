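"""Exception hierarchy for the kinerisk pipeline."""


class KineriskError(Exception):
    """Base class for all kinerisk errors."""


class FormatError(KineriskError):
    """A marker-trajectory or report file does not conform to its format."""


class ModelValidationError(KineriskError):
    """A skeleton/muscle configuration violates its structural constraints."""


class MissingDataError(KineriskError):
    """An operation met missing samples it cannot handle."""


class DegenerateGeometryError(KineriskError):
    """A marker configuration is too degenerate (e.g. collinear) to fit a pose."""


class SegmentationError(KineriskError):
    """Pitch-phase event detection produced an invalid event sequence."""


class StatsError(KineriskError):
    """A statistical operation received inadmissible inputs."""
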