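"""Exception hierarchy for taupaint.

Everything derives from :class:`TaupaintError` so callers can catch the
package's failures with one except clause while library code stays specific.
"""


class TaupaintError(Exception):
    """Base class for all taupaint errors."""


class LocalizationFormatError(TaupaintError):
    """A localization table is missing a required (mapped) column."""


class LocalizationParseError(TaupaintError):
    """A localization table cell could not be parsed; carries the row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class FrameRangeError(TaupaintError):
    """A localization frame index falls outside the acquisition program."""


class DegenerateGeometryError(TaupaintError):
    """Too few or collinear points for a planar tessellation / hull."""


class DescriptorError(TaupaintError):
    """Shape descriptors could not be computed; names the failing family."""

    def __init__(self, message: str, family: str | None = None):
        super().__init__(message)
        self.family = family


class CalibrationError(TaupaintError):
    """Background-threshold calibration was asked for with no data."""


class PlacementError(TaupaintError):
    """Simulator could not place aggregates at the required separation."""


class UndefinedScoreError(TaupaintError):
    """Enrichment score requested for an aggregate with zero localizations."""
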