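"""Exception hierarchy for the lvdp toolkit."""


class LvdpError(Exception):
    """Base class for all lvdp errors."""


class TraceError(LvdpError):
    """Invalid trace data (non-uniform grid, too short, NaNs...)."""


class InvalidStrainError(LvdpError):
    """Strain trace has no negative minimum (no systolic shortening)."""


class InvalidVolumesError(LvdpError):
    """EDV/ESV pair is inconsistent (edv <= esv or non-positive)."""


class InsufficientDataError(LvdpError):
    """Too few samples for the requested numerical operation."""


class EventDetectionError(LvdpError):
    """Diastolic event detection failed (no filling upstroke, etc.)."""


class EventOrderError(LvdpError):
    """Detected/supplied event times violate the physiological ordering."""


class InvalidParameterError(LvdpError):
    """Model parameter outside its admissible domain."""


class NonPhysiologicalPressuresError(LvdpError):
    """Pressure combination for which the tau estimate is undefined."""


class GradientError(LvdpError):
    """Invalid transmitral gradient input (negative dp, zero delta-Q...)."""


class DivergenceError(LvdpError):
    """Coupled fixed-point iteration left the valid pressure domain."""


class DegenerateFitError(LvdpError):
    """Least-squares fit is undefined (zero variance in x)."""


class ReferenceCurveError(LvdpError):
    """No usable source curves when building a reference curve."""


class MissingAWaveError(LvdpError):
    """A-wave dependent quantity requested for an E/A-fused record."""


class ParameterRejectionError(LvdpError):
    """Simulator parameter set admits no self-consistent patient."""


class UnitError(LvdpError):
    """A manifest declares a unit other than the expected one."""


class CohortMismatchError(LvdpError):
    """Cohort and estimate lists are not aligned."""


class AnchorOrderWarning(UserWarning):
    """Event anchor pressures violate the expected ordering."""
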