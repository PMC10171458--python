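"""Exception hierarchy shared across the pipeline stages."""


class SemDwiError(Exception):
    """Base class for all package errors."""


class DomainError(SemDwiError, ValueError):
    """A model parameter is outside its physical domain."""


class ConfigurationError(SemDwiError, ValueError):
    """A configuration value is inconsistent or missing (exit code 2)."""


class FormatError(SemDwiError, ValueError):
    """An input file violates its documented schema (exit code 2)."""


class CoordinateError(SemDwiError, ValueError):
    """A biopsy target or ROI falls outside the image volume (exit code 3)."""


class ClippedROIError(CoordinateError):
    """An ROI would extend beyond the volume bounds; never silently clipped."""


class DegenerateVoxelError(SemDwiError, ValueError):
    """A voxel's signal cannot support a fit (e.g. S(0) <= 0)."""


class FitInfeasibleError(SemDwiError, ValueError):
    """A b-value subset is too small for a two-parameter fit."""


class UndefinedStatisticError(SemDwiError, ValueError):
    """A statistic is undefined for the given data (e.g. zero rank variance)."""
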