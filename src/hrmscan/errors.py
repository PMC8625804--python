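"""Exception hierarchy for melt-curve analysis.

All errors raised by this package derive from :class:`HRMError` so callers
can catch one base class at pipeline boundaries (the CLI maps them to exit
codes).
"""


class HRMError(Exception):
    """Base class for all hrmscan errors."""


class ConfigError(HRMError):
    """Invalid or inconsistent configuration values."""


# --- curve_io ---------------------------------------------------------------

class NonMonotonicGrid(HRMError):
    """Temperature column is not strictly increasing (includes duplicates)."""


class LengthMismatch(HRMError):
    """Temperature and fluorescence vectors differ in length."""


class UnknownSample(HRMError):
    """A curve has no matching row in the sample metadata table."""


class EmptyInput(HRMError):
    """No usable data rows / curves in the input."""


class DisjointSpans(HRMError):
    """Curves share no common temperature interval to resample onto."""


class StepTooCoarse(HRMError):
    """Requested grid step leaves fewer than 10 points."""


# --- melt_core --------------------------------------------------------------

class WindowTooLarge(HRMError):
    """Savitzky-Golay window exceeds the number of grid points."""


class GridNotUniform(HRMError):
    """Operation requires a uniform temperature grid."""


class DegenerateBaselines(HRMError):
    """Upper and lower baseline lines cross inside the melting region."""


# --- reference_compare ------------------------------------------------------

class TooFewControls(HRMError):
    """Fewer than two control curves available to build a reference band."""


class GridMismatch(HRMError):
    """Sample and reference are not on the identical temperature grid."""


class MissingStratumControls(HRMError):
    """No same-sex controls for a stratified comparison and fallback disabled."""


# --- simulate ---------------------------------------------------------------

class SampleMismatch(HRMError):
    """Calls and ground truth do not cover the same sample ids."""


# --- warnings ---------------------------------------------------------------

class HRMWarning(UserWarning):
    """Base class for hrmscan warnings."""


class NoDomainsFound(HRMWarning):
    """No derivative peak survived the domain threshold."""


class FewControlsWarning(HRMWarning):
    """Reference band built from fewer than three controls."""


class StratumFallbackWarning(HRMWarning):
    """Stratified reference unavailable; fell back to all controls."""


class MixedSexWarning(HRMWarning):
    """`mixed` flag set on a non-male sample (only meaningful for males)."""
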