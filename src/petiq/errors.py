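"""Exception hierarchy for petiq."""


class PetIQError(Exception):
    """Base class for all petiq errors."""


class ConfigError(PetIQError):
    """Invalid configuration or parameter value."""


class GeometryError(PetIQError):
    """Phantom/patient geometry is inconsistent (overlaps, out-of-body objects)."""


class PlacementError(PetIQError):
    """A VOI cannot be placed while respecting its clearance constraints."""


class DegenerateVOIError(PetIQError):
    """A VOI is empty or too small for the requested statistic."""


class NoLesionError(PetIQError):
    """No lesion signal above background near the requested seed point."""


class FixtureError(PetIQError):
    """A reader-study table is internally inconsistent."""


class UndefinedMetricError(PetIQError):
    """A metric is undefined for the given inputs (e.g. zero denominator)."""


class InsufficientDataError(PetIQError):
    """Too few subjects/raters for the requested statistical procedure."""
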