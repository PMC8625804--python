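"""Reference bands, difference curves and variant/normal calling.

The normality reference for a melting region is the per-temperature median
of the control curves (robust to a stray control) together with the
per-temperature standard deviation of the controls, drawn as the gray band
of a difference plot.  A test sample is called *variant* when its normalized
curve leaves the median ± k·SD band for at least m consecutive grid points
(defaults k = 2, m = 10 ≈ 0.4 °C at 0.04 °C spacing) in any analyzed scope —
the whole amplicon or any single melting domain.

:func:`analyze_experiment` orchestrates the full two-step procedure: a
whole-amplicon pass, then a per-domain pass on domains detected once on the
median control curve (so every sample is scored over the same scopes), with
optional sex stratification of the reference set and OR-combination of the
mixed / unmixed preparations of the same individual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .curve_io import ExperimentSet, MeltCurve
from .errors import (
    FewControlsWarning,
    GridMismatch,
    MissingStratumControls,
    TooFewControls,
)
from .melt_core import NormalizedDomainCurve, SmoothingConfig

SD_FLOOR_ABS = 1e-6
SD_FLOOR_QUANTILE = 0.10

AMPLICON_SCOPE = "amplicon"


@dataclass
class ReferenceBand:
    """Per-temperature median and SD of a set of control curves."""

    grid: np.ndarray
    median: np.ndarray
    sd: np.ndarray
    n_controls: int
    stratum: str = "all"
    center: Literal["median", "mean"] = "median"

    def __post_init__(self) -> None:
        if not (len(self.grid) == len(self.median) == len(self.sd)):
            raise ValueError("grid, median and sd must share one length")
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")

    @property
    def sd_floor(self) -> float:
        """Per-point SD floor used when forming z-scores.

        Baseline-window points have near-zero spread by construction of the
        normalization; dividing by it would manufacture spurious calls, so
        the SD is floored at the region's 10th-percentile SD (and at 1e-6).
        """
        return float(max(np.quantile(self.sd, SD_FLOOR_QUANTILE), SD_FLOOR_ABS))


@dataclass
class DifferenceResult:
    """A sample's deviation from a reference band over one scope."""

    grid: np.ndarray
    diff: np.ndarray
    z: np.ndarray
    max_abs_z: float
    longest_run: int
    scope: str
    sample_id: str


@dataclass
class VariantCall:
    """Binary screening call for one sample (or one preparation group).

    ``call`` is ``"variant"`` iff the deviation criterion was met in at
    least one scope of at least one preparation.  Calls are screening
    results: a variant call flags the amplicon for confirmatory sequencing,
    it does not identify the change.
    """

    sample_id: str
    amplicon_id: str
    call: Literal["variant", "normal"]
    supporting_scopes: list[str] = field(default_factory=list)
    preparation_calls: dict[str, str] = field(default_factory=dict)
    parameters: tuple[float, int] = (2.0, 10)
    records: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = "variant" if self.supporting_scopes else "normal"
        if self.call != expected:
            raise ValueError(
                f"call {self.call!r} inconsistent with supporting scopes "
                f"{self.supporting_scopes}"
            )


def build_reference(
    controls: Sequence[NormalizedDomainCurve],
    stratum: str = "all",
    center: Literal["median", "mean"] = "median",
) -> ReferenceBand:
    """Median/SD reference band from normalized control curves.

    Requires ≥ 2 controls (warns below 3); all controls must be on the
    identical region grid.  ``center='mean'`` is offered for comparison with
    mean-based difference plots, but the median is the default because it is
    less affected by an outlying control.
    """
    if len(controls) < 2:
        raise TooFewControls(
            f"{len(controls)} control curve(s); need at least 2 to form a band"
        )
    if len(controls) < 3:
        warnings.warn(
            f"reference band from only {len(controls)} controls",
            FewControlsWarning, stacklevel=2,
        )
    grid = controls[0].grid
    for c in controls[1:]:
        if len(c.grid) != len(grid) or not np.allclose(c.grid, grid, atol=1e-9, rtol=0):
            raise GridMismatch(f"{c.sample_id}: control grids differ")
    # sorting along the control axis makes median and sd bit-identical under
    # any permutation of the input controls
    values = np.sort(np.vstack([c.values for c in controls]), axis=0)
    centered = np.median(values, axis=0) if center == "median" else values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    return ReferenceBand(
        grid=grid, median=centered, sd=sd,
        n_controls=len(controls), stratum=stratum, center=center,
    )


def longest_true_run(mask: np.ndarray) -> int:
    """Length of the longest run of consecutive True values."""
    if not mask.any():
        return 0
    padded = np.concatenate(([False], mask, [False])).astype(int)
    edges = np.flatnonzero(np.diff(padded))
    return int((edges[1::2] - edges[0::2]).max())


def difference_curve(
    sample: NormalizedDomainCurve,
    ref: ReferenceBand,
    k: float = 2.0,
    scope: str = AMPLICON_SCOPE,
) -> DifferenceResult:
    """Difference plot of one sample against a reference band.

    ``diff`` is sample − median point-wise; ``z`` divides by the floored SD
    (see :attr:`ReferenceBand.sd_floor`).  ``longest_run`` counts the longest
    consecutive stretch with |z| > k.
    """
    if len(sample.grid) != len(ref.grid) or not np.allclose(
        sample.grid, ref.grid, atol=1e-9, rtol=0
    ):
        raise GridMismatch(f"{sample.sample_id}: sample grid differs from reference")
    diff = sample.values - ref.median
    z = diff / np.maximum(ref.sd, ref.sd_floor)
    return DifferenceResult(
        grid=ref.grid,
        diff=diff,
        z=z,
        max_abs_z=float(np.max(np.abs(z))),
        longest_run=longest_true_run(np.abs(z) > k),
        scope=scope,
        sample_id=sample.sample_id,
    )


def classify_sample(
    result: DifferenceResult, k: float = 2.0, m: int = 10
) -> Literal["variant", "normal"]:
    """Variant iff |z| > k for at least m consecutive grid points."""
    if k <= 0:
        raise ValueError("k must be positive")
    if m < 1:
        raise ValueError("m must be >= 1")
    run = longest_true_run(np.abs(result.z) > k)
    return "variant" if run >= m else "normal"


def analyze_experiment(
    experiment: ExperimentSet,
    cfg: SmoothingConfig | None = None,
    k: float = 2.0,
    m: int = 10,
    stratify_by_sex: bool = True,
    combine_preparations: bool = True,
    baseline_frac: float = 0.10,
    stratum_fallback: bool = True,
    center: Literal["median", "mean"] = "median",
) -> list[VariantCall]:
    """Two-step HRM screen of one experiment.

    Pass 1 treats the whole amplicon as a single melting region; pass 2
    detects melting domains once on the median control curve and compares
    every sample domain-by-domain, so all samples share identical scopes.
    With ``stratify_by_sex``, male/female test samples are compared against
    same-sex control bands (falling back to all controls, with a warning,
    when a stratum has < 2 controls; set ``stratum_fallback=False`` to raise
    instead).  With ``combine_preparations``, samples sharing a
    ``preparation_group`` (the mixed and unmixed preparations of one
    individual) are OR-combined into a single call.
    """
    from .estimators import HRMVariantDetector  # deferred: avoids import cycle

    cfg = cfg or SmoothingConfig()
    controls = experiment.subset(role="control")
    if len(controls) < 2:
        raise TooFewControls(
            f"{len(controls)} control curve(s) in the experiment; need >= 2"
        )
    tests = [c for c in experiment.curves if c.meta.role != "control"]
    if not tests:
        return []

    def make_detector(ctrl: Sequence[MeltCurve], stratum: str, domains) -> HRMVariantDetector:
        det = HRMVariantDetector(
            temperatures=experiment.grid,
            window=cfg.window,
            polyorder=cfg.polyorder,
            domain_threshold=cfg.domain_threshold,
            peak_prominence=cfg.peak_prominence,
            region_pad=cfg.region_pad,
            min_domain_width=cfg.min_domain_width,
            baseline_frac=baseline_frac,
            k=k,
            m=m,
            center=center,
            domains=domains,
            stratum=stratum,
        )
        det.fit(np.vstack([c.fluorescence for c in ctrl]))
        return det

    # Domains are detected once, on the median of ALL controls, so every
    # stratum scores samples over identical scopes.
    base = make_detector(controls, "all", "auto")
    detectors = {"all": base}
    if stratify_by_sex:
        for sex in ("male", "female"):
            ctrl_s = [c for c in controls if c.meta.sex == sex]
            if len(ctrl_s) >= 2:
                detectors[sex] = make_detector(ctrl_s, sex, base.domains_)
            elif any(t.meta.sex == sex for t in tests):
                if not stratum_fallback:
                    raise MissingStratumControls(
                        f"{len(ctrl_s)} {sex} control(s) under sex stratification"
                    )
                warnings.warn(
                    f"only {len(ctrl_s)} {sex} control(s); falling back to the "
                    "unstratified reference",
                    FewControlsWarning, stacklevel=2,
                )

    per_sample: dict[str, dict] = {}
    for t in tests:
        det = detectors.get(t.meta.sex, base) if stratify_by_sex else base
        results = det.describe(t.fluorescence[None, :], sample_ids=[t.sample_id])
        scopes = [r.scope for r in results if classify_sample(r, k=k, m=m) == "variant"]
        per_sample[t.sample_id] = {
            "curve": t,
            "stratum": det.stratum,
            "results": results,
            "variant_scopes": scopes,
        }

    def record_rows(sid: str) -> list[dict]:
        info = per_sample[sid]
        return [
            {
                "sample_id": sid,
                "scope": r.scope,
                "stratum": info["stratum"],
                "max_abs_z": r.max_abs_z,
                "longest_run": longest_true_run(np.abs(r.z) > k),
                "scope_call": classify_sample(r, k=k, m=m),
            }
            for r in info["results"]
        ]

    # Group mixed/unmixed preparations of one individual for OR-combination.
    groups: dict[str, list[str]] = {}
    for t in tests:
        key = (
            t.meta.preparation_group
            if combine_preparations and t.meta.preparation_group
            else t.sample_id
        )
        groups.setdefault(key, []).append(t.sample_id)

    calls = []
    for key, sids in groups.items():
        scopes = sorted({s for sid in sids for s in per_sample[sid]["variant_scopes"]})
        prep_calls = {
            sid: ("variant" if per_sample[sid]["variant_scopes"] else "normal")
            for sid in sids
        }
        amplicon = per_sample[sids[0]]["curve"].meta.amplicon_id
        calls.append(
            VariantCall(
                sample_id=key,
                amplicon_id=amplicon,
                call="variant" if scopes else "normal",
                supporting_scopes=scopes,
                preparation_calls=prep_calls,
                parameters=(k, m),
                records=[row for sid in sids for row in record_rows(sid)],
            )
        )
    return calls
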