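"""scikit-learn style estimators for HRM melt-curve analysis.

The variant screen is novelty detection: the reference (normal) class is
learned from control melt curves and test samples are flagged when they
leave the control band.  :class:`HRMVariantDetector` therefore follows the
sklearn outlier-detector convention — ``fit(X)`` on controls, ``predict(X)``
returning +1 (normal) / −1 (variant) — and composes with sklearn model
selection.  ``X`` is an ``(n_samples, n_grid_points)`` fluorescence matrix;
the shared temperature grid is an estimator parameter.

:class:`SavGolDerivative` and :class:`DomainNormalizer` expose the two
curve-level preprocessing steps as transformers for pipeline use.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted
from scipy.signal import savgol_filter

from .curve_io import MeltCurve
from .errors import WindowTooLarge
from .melt_core import (
    MeltDomain,
    NormalizedDomainCurve,
    SmoothingConfig,
    _baseline_normalize,
    _grid_step,
    baseline_window_size,
    region_slice,
    scan_domains,
)
from .reference_compare import (
    AMPLICON_SCOPE,
    DifferenceResult,
    ReferenceBand,
    build_reference,
    difference_curve,
    longest_true_run,
)


def _check_grid(temperatures, n_features: int) -> np.ndarray:
    if temperatures is None:
        raise ValueError("the 'temperatures' parameter is required")
    grid = np.asarray(temperatures, dtype=float)
    if grid.ndim != 1 or grid.size != n_features:
        raise ValueError(
            f"temperatures has {grid.size} points but X has {n_features} features"
        )
    return grid


class SavGolDerivative(TransformerMixin, BaseEstimator):
    """Transform fluorescence rows into −dF/dT via Savitzky–Golay filtering.

    Parameters
    ----------
    temperatures : array-like of shape (n_features,)
        The shared uniform temperature grid of the input rows.
    window : int, default=75
        Filter window in grid points (odd).
    polyorder : int, default=3
        Local polynomial order; the derivative is evaluated analytically
        from the fit.
    """

    def __init__(self, temperatures=None, window: int = 75, polyorder: int = 3):
        self.temperatures = temperatures
        self.window = window
        self.polyorder = polyorder

    def fit(self, X, y=None):
        X = check_array(X)
        self.grid_ = _check_grid(self.temperatures, X.shape[1])
        self.step_ = _grid_step(self.grid_)
        SmoothingConfig(window=self.window, polyorder=self.polyorder)
        if self.window >= X.shape[1]:
            raise WindowTooLarge(f"window {self.window} >= {X.shape[1]} points")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "grid_")
        X = check_array(X)
        return -savgol_filter(X, self.window, self.polyorder, deriv=1,
                              delta=self.step_, axis=1)


class DomainNormalizer(TransformerMixin, BaseEstimator):
    """Normalize one melting region of each fluorescence row to [0, 1].

    Fits linear upper/lower baselines on the leading and trailing
    ``baseline_frac`` of the region and rescales between them; row means over
    the leading / trailing window are anchored at exactly 1 / 0.

    Parameters
    ----------
    temperatures : array-like of shape (n_features,)
    region : tuple (lo, hi) in °C, or None for the whole grid span.
    baseline_frac : float, default=0.10
    """

    def __init__(self, temperatures=None, region=None, baseline_frac: float = 0.10):
        self.temperatures = temperatures
        self.region = region
        self.baseline_frac = baseline_frac

    def fit(self, X, y=None):
        X = check_array(X)
        grid = _check_grid(self.temperatures, X.shape[1])
        region = self.region or (float(grid[0]), float(grid[-1]))
        self.slice_ = region_slice(grid, region)
        self.grid_ = grid[self.slice_]
        if self.grid_.size < 20:
            raise ValueError(f"region {region} spans < 20 grid points")
        self.n_base_ = baseline_window_size(self.grid_.size, self.baseline_frac)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "grid_")
        X = check_array(X)
        sub = X[:, self.slice_]
        return np.vstack(
            [_baseline_normalize(self.grid_, row, self.n_base_) for row in sub]
        )


class HRMVariantDetector(OutlierMixin, BaseEstimator):
    """HRM variant screen as a novelty detector.

    ``fit`` learns the normality band from control curves: melting domains
    are detected on the per-point median control curve (so every sample is
    scored over identical scopes) and a median ± SD reference band is built
    for the whole amplicon and for each domain's melting region.  ``predict``
    flags a sample as variant (−1) when its normalized curve leaves the
    median ± k·SD band for at least m consecutive grid points in any scope.

    Parameters
    ----------
    temperatures : array-like of shape (n_features,)
        Shared uniform temperature grid (°C).
    window, polyorder, domain_threshold, peak_prominence, region_pad, min_domain_width
        See :class:`~hrmscan.melt_core.SmoothingConfig`.
    baseline_frac : float, default=0.10
        Baseline-window fraction of each melting region.
    k : float, default=2.0
        Band half-width in control SDs.
    m : int, default=10
        Minimum consecutive out-of-band points (≈ 0.4 °C at 0.04 °C spacing).
    whole_amplicon, per_domain : bool
        Which of the two analysis passes to run.
    center : {'median', 'mean'}
        Reference center; the median resists outlying controls.
    domains : 'auto' or list of MeltDomain
        Pass precomputed domains to share scopes across stratified detectors.
    stratum : str
        Label recorded in the reference bands (e.g. 'male', 'all').

    Attributes
    ----------
    domains_ : list of MeltDomain
    scopes_ : list of (name, (lo, hi)) analyzed regions
    references_ : dict scope name -> ReferenceBand
    """

    def __init__(
        self,
        temperatures=None,
        window: int = 75,
        polyorder: int = 3,
        domain_threshold: float = 0.10,
        peak_prominence: float = 0.10,
        region_pad: float = 2.0,
        min_domain_width: float = 0.5,
        baseline_frac: float = 0.10,
        k: float = 2.0,
        m: int = 10,
        whole_amplicon: bool = True,
        per_domain: bool = True,
        center: Literal["median", "mean"] = "median",
        domains: Literal["auto"] | Sequence[MeltDomain] = "auto",
        stratum: str = "all",
    ):
        self.temperatures = temperatures
        self.window = window
        self.polyorder = polyorder
        self.domain_threshold = domain_threshold
        self.peak_prominence = peak_prominence
        self.region_pad = region_pad
        self.min_domain_width = min_domain_width
        self.baseline_frac = baseline_frac
        self.k = k
        self.m = m
        self.whole_amplicon = whole_amplicon
        self.per_domain = per_domain
        self.center = center
        self.domains = domains
        self.stratum = stratum

    def _config(self) -> SmoothingConfig:
        return SmoothingConfig(
            window=self.window,
            polyorder=self.polyorder,
            domain_threshold=self.domain_threshold,
            peak_prominence=self.peak_prominence,
            region_pad=self.region_pad,
            min_domain_width=self.min_domain_width,
        )

    def fit(self, X, y=None):
        """Learn reference bands from control fluorescence rows."""
        X = check_array(X)
        if X.shape[0] < 2:
            from .errors import TooFewControls

            raise TooFewControls(f"{X.shape[0]} control curve(s); need >= 2")
        cfg = self._config()
        grid = _check_grid(self.temperatures, X.shape[1])
        self.grid_ = grid
        self.n_features_in_ = X.shape[1]

        if isinstance(self.domains, str) and self.domains == "auto":
            median_curve = MeltCurve(
                sample_id="median_control",
                temperatures=grid,
                fluorescence=np.median(X, axis=0),
            )
            self.domains_ = scan_domains(median_curve, cfg)
        else:
            self.domains_ = list(self.domains)

        scopes: list[tuple[str, tuple[float, float]]] = []
        if self.whole_amplicon:
            scopes.append((AMPLICON_SCOPE, (float(grid[0]), float(grid[-1]))))
        if self.per_domain:
            for d in self.domains_:
                scopes.append((f"domain_{d.index}", (d.region_start, d.region_end)))
        self.scopes_ = scopes

        self.references_: dict[str, ReferenceBand] = {}
        self._normalizers_: dict[str, DomainNormalizer] = {}
        for name, region in scopes:
            norm = DomainNormalizer(
                temperatures=grid, region=region, baseline_frac=self.baseline_frac
            ).fit(X)
            rows = norm.transform(X)
            controls = [
                NormalizedDomainCurve(
                    grid=norm.grid_, values=row, sample_id=f"control_{i}"
                )
                for i, row in enumerate(rows)
            ]
            self._normalizers_[name] = norm
            self.references_[name] = build_reference(
                controls, stratum=self.stratum, center=self.center
            )
        return self

    def describe(self, X, sample_ids: Sequence[str] | None = None) -> list[DifferenceResult]:
        """Per-scope difference results for each row of X (flattened)."""
        check_is_fitted(self, "references_")
        X = check_array(X)
        if sample_ids is None:
            sample_ids = [f"sample_{i}" for i in range(X.shape[0])]
        out: list[DifferenceResult] = []
        for sid, row in zip(sample_ids, X):
            for name, _ in self.scopes_:
                norm = self._normalizers_[name]
                values = norm.transform(row[None, :])[0]
                sample = NormalizedDomainCurve(
                    grid=norm.grid_, values=values, sample_id=sid
                )
                out.append(
                    difference_curve(sample, self.references_[name], k=self.k, scope=name)
                )
        return out

    def decision_function(self, X) -> np.ndarray:
        """Signed inlier score: positive = normal, non-positive = variant.

        The score is (m − 0.5 − r)/m where r is the longest out-of-band run
        over all scopes, so it decreases as the deviation run grows and
        crosses zero exactly at the calling criterion r ≥ m.
        """
        check_is_fitted(self, "references_")
        X = check_array(X)
        scores = np.empty(X.shape[0])
        for i, row in enumerate(X):
            runs = [
                longest_true_run(np.abs(r.z) > self.k)
                for r in self.describe(row[None, :])
            ]
            worst = max(runs) if runs else 0
            scores[i] = (self.m - 0.5 - worst) / self.m
        return scores

    def predict(self, X) -> np.ndarray:
        """+1 for normal samples, −1 for variants (sklearn outlier convention)."""
        return np.where(self.decision_function(X) > 0, 1, -1)

    def predict_calls(self, X) -> np.ndarray:
        """String labels 'normal' / 'variant' for each row of X."""
        return np.where(self.predict(X) == 1, "normal", "variant")
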