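"""Derivative analysis of melt curves: smoothing, melting-domain detection,
melting-region extraction and per-domain normalization.

A melting *domain* is one helix-to-coil transition inside an amplicon's melt
curve.  Long amplicons (> 300 bp) routinely melt in several domains, each
visible as a peak in the negative derivative −dF/dT.  The machinery here

1. smooths the raw fluorescence with a Savitzky–Golay filter and evaluates
   −dF/dT and its slope analytically from the local polynomial fit,
2. reports every −dF/dT peak whose height exceeds a fraction (default 0.10)
   of the curve's global −dF/dT maximum as a domain, bounded by the flanking
   local minima of −dF/dT,
3. extends each domain by a pad (default 2 °C on each side) into its
   *melting region*, and
4. normalizes the fluorescence inside a region to [0, 1] between two fitted
   baseline lines (fully-helical upper, fully-melted lower).

The domain's melting temperature Tm is the temperature of its −dF/dT peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_prominences, savgol_filter

from .curve_io import MeltCurve
from .errors import (
    ConfigError,
    DegenerateBaselines,
    GridNotUniform,
    NoDomainsFound,
    WindowTooLarge,
)

GRID_TOL = 1e-9


@dataclass(frozen=True)
class SmoothingConfig:
    """Tunables for smoothing, domain detection and region extraction.

    window, polyorder
        Savitzky–Golay filter size (grid points, odd) and polynomial order.
        The default 75-point cubic window spans ≈ 3 °C on the default
        0.04 °C grid: it suppresses instrument noise on the derivative
        ~20-fold while attenuating even a sharp transition (width parameter
        0.5 °C) by only ~6 % and leaving the peak position unbiased (the
        filter is symmetric).  Narrow the window for coarser grids.
    domain_threshold
        Peaks of −dF/dT below this fraction of the curve's global −dF/dT
        maximum are treated as noise, not domains.
    peak_prominence
        Minimum peak prominence, as a fraction of the global −dF/dT
        maximum.  A real melting transition rises from the inter-domain
        valley, so its prominence is comparable to its height; a noise
        wiggle riding on the flank of a tall transition can clear the
        height threshold but only ever has prominence of the noise scale.
    region_pad
        °C added on each side of a domain to form its melting region.
    min_domain_width
        Domains narrower than this (°C) are dissolved into their nearest
        neighbor; isolated noise spikes rarely survive both this and the
        height threshold.
    """

    window: int = 75
    polyorder: int = 3
    domain_threshold: float = 0.10
    peak_prominence: float = 0.10
    region_pad: float = 2.0
    min_domain_width: float = 0.5

    def __post_init__(self) -> None:
        if self.window % 2 != 1:
            raise ConfigError(f"window must be odd, got {self.window}")
        if not (self.window > self.polyorder >= 2):
            raise ConfigError(
                f"need window > polyorder >= 2, got window={self.window}, "
                f"polyorder={self.polyorder}"
            )
        if not (0.0 < self.domain_threshold < 1.0):
            raise ConfigError(
                f"domain_threshold must be in (0, 1), got {self.domain_threshold}"
            )
        if not (0.0 <= self.peak_prominence < 1.0):
            raise ConfigError(
                f"peak_prominence must be in [0, 1), got {self.peak_prominence}"
            )
        if self.region_pad < 0:
            raise ConfigError("region_pad must be >= 0")
        if self.min_domain_width < 0:
            raise ConfigError("min_domain_width must be >= 0")


@dataclass
class DerivativePair:
    """−dF/dT and its slope, both evaluated from the Savitzky–Golay fit."""

    grid: np.ndarray
    neg_dFdT: np.ndarray
    d2: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.grid) == len(self.neg_dFdT) == len(self.d2)):
            raise ValueError("grid, neg_dFdT and d2 must share one length")
        if not (np.all(np.isfinite(self.neg_dFdT)) and np.all(np.isfinite(self.d2))):
            raise ValueError("non-finite derivative values")


@dataclass(frozen=True)
class MeltDomain:
    """One detected melting transition.

    ``peak_temp`` is the domain's melting temperature Tm; ``domain_start`` /
    ``domain_end`` are the flanking −dF/dT minima (or grid ends);
    ``region_start`` / ``region_end`` extend the domain by the configured pad,
    clipped to the grid span.
    """

    index: int
    peak_temp: float
    peak_height_rel: float
    domain_start: float
    domain_end: float
    region_start: float
    region_end: float

    def __post_init__(self) -> None:
        if not (self.domain_start < self.peak_temp < self.domain_end):
            raise ValueError(
                f"domain boundaries must bracket the peak: "
                f"{self.domain_start} < {self.peak_temp} < {self.domain_end}"
            )
        if self.region_start > self.domain_start or self.region_end < self.domain_end:
            raise ValueError("melting region must contain the domain")


@dataclass
class NormalizedDomainCurve:
    """Fluorescence inside one melting region, normalized to [0, 1].

    ``domain`` is None for the whole-amplicon scope (the full curve treated
    as a single region).
    """

    grid: np.ndarray
    values: np.ndarray
    sample_id: str
    domain: MeltDomain | None = None

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.values):
            raise ValueError("grid and values must share one length")


def _grid_step(grid: np.ndarray) -> float:
    d = np.diff(grid)
    if d.size == 0 or not np.all(np.abs(d - d[0]) <= GRID_TOL):
        raise GridNotUniform("operation requires a uniform temperature grid")
    return float(d[0])


def smooth_derivatives(curve: MeltCurve, cfg: SmoothingConfig | None = None) -> DerivativePair:
    """Savitzky–Golay −dF/dT and its slope for one melt curve.

    Both derivatives come analytically from the local polynomial fit
    (``savgol_filter(..., deriv=...)``), not from finite-differencing the
    smoothed output.
    """
    cfg = cfg or SmoothingConfig()
    step = _grid_step(curve.temperatures)
    if cfg.window >= len(curve):
        raise WindowTooLarge(
            f"window {cfg.window} >= {len(curve)} grid points"
        )
    neg = -savgol_filter(curve.fluorescence, cfg.window, cfg.polyorder,
                         deriv=1, delta=step)
    d2 = -savgol_filter(curve.fluorescence, cfg.window, cfg.polyorder,
                        deriv=2, delta=step)
    return DerivativePair(grid=curve.temperatures, neg_dFdT=neg, d2=d2)


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima (slope + → − crossings)."""
    peaks, _ = find_peaks(y)
    return peaks


def peak_candidates(deriv: DerivativePair, cfg: SmoothingConfig | None = None) -> np.ndarray:
    """Indices of −dF/dT peaks that qualify as domain candidates.

    A candidate is a strict local maximum of −dF/dT whose height is at
    least ``domain_threshold`` and whose prominence is at least
    ``peak_prominence``, both as fractions of the global −dF/dT maximum.
    """
    cfg = cfg or SmoothingConfig()
    y = deriv.neg_dFdT
    ymax = float(np.max(y))
    if ymax <= 0:
        raise ValueError("neg_dFdT has no positive values; not a melt curve")
    peaks = _local_maxima(y)
    if peaks.size == 0:
        return peaks
    prom = peak_prominences(y, peaks)[0]
    keep = (y[peaks] >= cfg.domain_threshold * ymax) & (
        prom >= cfg.peak_prominence * ymax
    )
    return peaks[keep]


def _prominent_minima(y: np.ndarray, min_prominence: float) -> np.ndarray:
    """Indices of local minima of y whose depth (prominence of −y) exceeds
    ``min_prominence``.  Noise dimples riding on a transition's flank or top
    fail this filter; the real valley between two melting domains passes it."""
    minima, _ = find_peaks(-y)
    if minima.size == 0:
        return minima
    prom = peak_prominences(-y, minima)[0]
    return minima[prom >= min_prominence]


def _flanking_minima(y: np.ndarray, peak: int, minima: np.ndarray) -> tuple[int, int]:
    """Nearest qualifying minima on each side of ``peak`` (grid ends if none)."""
    left = minima[minima < peak]
    right = minima[minima > peak]
    lo = int(left[-1]) if left.size else 0
    hi = int(right[0]) if right.size else len(y) - 1
    return lo, hi


def find_domains(deriv: DerivativePair, cfg: SmoothingConfig | None = None) -> list[MeltDomain]:
    """Detect melting domains on a −dF/dT curve.

    Peaks are strict local maxima of −dF/dT; those below
    ``domain_threshold`` × (global −dF/dT maximum) in height, or below
    ``peak_prominence`` × that maximum in prominence, are discarded as
    noise.  Each surviving peak is bounded by the nearest −dF/dT local
    minimum on either side (or the grid end).  Domains narrower than
    ``min_domain_width`` are dissolved into their nearest neighbor.  Returns
    an empty list (with a :class:`NoDomainsFound` warning) when nothing
    survives the threshold.
    """
    cfg = cfg or SmoothingConfig()
    y = deriv.neg_dFdT
    grid = deriv.grid
    ymax = float(np.max(y))

    peaks = peak_candidates(deriv, cfg)
    heights = y[peaks] / ymax
    if peaks.size == 0:
        warnings.warn("no −dF/dT peak above the domain threshold",
                      NoDomainsFound, stacklevel=2)
        return []

    minima = _prominent_minima(y, cfg.peak_prominence * ymax)
    raw = []  # (peak_idx, height_rel, lo_idx, hi_idx)
    for p, h in zip(peaks, heights):
        lo, hi = _flanking_minima(y, int(p), minima)
        raw.append([int(p), float(h), lo, hi])
    raw.sort(key=lambda r: r[0])

    # Dissolve domains narrower than min_domain_width into their nearest
    # neighbor: the neighbor absorbs the span when the two spans touch,
    # otherwise the narrow (noise) peak is simply dropped.
    def width(r) -> float:
        return grid[r[3]] - grid[r[2]]

    while len(raw) > 1:
        narrow = min(raw, key=width)
        if width(narrow) >= cfg.min_domain_width:
            break
        raw.remove(narrow)
        nearest = min(raw, key=lambda r: abs(grid[r[0]] - grid[narrow[0]]))
        touches = narrow[2] <= nearest[3] + 1 and narrow[3] >= nearest[2] - 1
        if touches:
            nearest[2] = min(nearest[2], narrow[2])
            nearest[3] = max(nearest[3], narrow[3])
            if narrow[1] > nearest[1]:
                nearest[0], nearest[1] = narrow[0], narrow[1]

    raw.sort(key=lambda r: grid[r[0]])
    domains = []
    for i, (p, h, lo, hi) in enumerate(raw):
        domains.append(
            MeltDomain(
                index=i,
                peak_temp=float(grid[p]),
                peak_height_rel=h,
                domain_start=float(grid[lo]),
                domain_end=float(grid[hi]),
                region_start=max(float(grid[lo]) - cfg.region_pad, float(grid[0])),
                region_end=min(float(grid[hi]) + cfg.region_pad, float(grid[-1])),
            )
        )
    return domains


def melting_region(
    domain: MeltDomain,
    grid: np.ndarray,
    cfg: SmoothingConfig | None = None,
) -> tuple[float, float]:
    """Melting region of a domain: boundaries padded by ``region_pad`` °C on
    each side, clipped to the grid span."""
    cfg = cfg or SmoothingConfig()
    lo = max(domain.domain_start - cfg.region_pad, float(grid[0]))
    hi = min(domain.domain_end + cfg.region_pad, float(grid[-1]))
    return lo, hi


def melting_temperature(domain: MeltDomain) -> float:
    """Tm of a domain: the temperature of its −dF/dT peak."""
    return domain.peak_temp


def _baseline_normalize(
    temps: np.ndarray, values: np.ndarray, n_base: int
) -> np.ndarray:
    """Two-baseline normalization of one region (array level).

    Fits one least-squares line to the leading (fully helical, upper
    baseline U) and one to the trailing (fully melted, lower baseline L)
    window, maps F to (F − L)/(U − L), then applies the affine anchoring
    that pins the leading-window mean at exactly 1 and the trailing-window
    mean at exactly 0.
    """
    t_lead, f_lead = temps[:n_base], values[:n_base]
    t_trail, f_trail = temps[-n_base:], values[-n_base:]
    upper = np.polyval(np.polyfit(t_lead, f_lead, 1), temps)
    lower = np.polyval(np.polyfit(t_trail, f_trail, 1), temps)
    denom = upper - lower
    if np.any(denom <= 0):
        raise DegenerateBaselines(
            "upper and lower baselines cross inside the melting region"
        )
    q = (values - lower) / denom
    q_lead = float(np.mean(q[:n_base]))
    q_trail = float(np.mean(q[-n_base:]))
    if q_lead - q_trail <= 0:
        raise DegenerateBaselines(
            "leading baseline window does not sit above the trailing window"
        )
    v = (q - q_trail) / (q_lead - q_trail)
    return np.clip(v, -0.05, 1.05)


def region_slice(grid: np.ndarray, region: tuple[float, float]) -> slice:
    """Grid slice covering ``region`` (inclusive, tolerance-guarded)."""
    lo, hi = region
    i0 = int(np.searchsorted(grid, lo - GRID_TOL, side="left"))
    i1 = int(np.searchsorted(grid, hi + GRID_TOL, side="right"))
    return slice(i0, i1)


def baseline_window_size(n_points: int, baseline_frac: float) -> int:
    """Baseline window length: ``baseline_frac`` of the region, at least 5
    points, and never more than half the region."""
    n_base = max(5, int(round(baseline_frac * n_points)))
    if 2 * n_base > n_points:
        raise DegenerateBaselines(
            f"region of {n_points} points too short for two {n_base}-point "
            "baseline windows"
        )
    return n_base


def normalize_domain(
    curve: MeltCurve,
    region: tuple[float, float],
    baseline_frac: float = 0.10,
    domain: MeltDomain | None = None,
) -> NormalizedDomainCurve:
    """Normalize one melting region of a curve to [0, 1].

    Linear upper/lower baselines are fitted to the leading and trailing
    ``baseline_frac`` of the region (≥ 5 points each); the normalized value
    is (F − L)/(U − L) with the leading/trailing window means anchored at
    exactly 1 and 0.  Values are clipped to [−0.05, 1.05].
    """
    sl = region_slice(curve.temperatures, region)
    temps = curve.temperatures[sl]
    if temps.size < 20:
        raise ValueError(
            f"melting region {region} spans only {temps.size} grid points (< 20)"
        )
    n_base = baseline_window_size(temps.size, baseline_frac)
    v = _baseline_normalize(temps, curve.fluorescence[sl], n_base)
    return NormalizedDomainCurve(
        grid=temps, values=v, sample_id=curve.sample_id, domain=domain
    )


def scan_domains(curve: MeltCurve, cfg: SmoothingConfig | None = None) -> list[MeltDomain]:
    """Convenience: smooth a curve and detect its melting domains."""
    cfg = cfg or SmoothingConfig()
    return find_domains(smooth_derivatives(curve, cfg), cfg)
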