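"""Synthetic melt curves and cohorts with known ground truth.

Melting is modeled as a sum of two-state (logistic) transitions: each
melting domain contributes ``weight · amplitude / (1 + exp((T − Tm)/s))``,
a sigmoid falling from its full fluorescence to zero around its melting
temperature ``Tm`` with width parameter ``s``.  The logistic has closed-form
derivatives (−dF/dT peaks exactly at Tm), which makes every pipeline stage
checkable against analytic values.  On top of the transitions sit an
exponential-plus-linear background (unbound dye decay) and i.i.d. Gaussian
instrument noise.

A heterozygote melt is a mixture of duplex species: the wildtype homoduplex,
the variant homoduplex (shifted by a fraction of a °C) and heteroduplexes,
whose mismatch destabilizes the duplex and depresses its melting temperature
by typically 1–3 °C.  Mixing a hemizygous male sample with wildtype DNA (an
*artificial heterozygote*) deliberately creates these heteroduplexes, which
is what makes hemizygous variants detectable by melt-curve comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .curve_io import ExperimentSet, MeltCurve, SampleMeta
from .errors import SampleMismatch
from .reference_compare import VariantCall

DEFAULT_GRID = (65.0, 95.0, 0.04)  # °C: span and step of a typical melt ramp


@dataclass(frozen=True)
class TransitionSpec:
    """One two-state melting transition."""

    tm: float
    slope: float = 1.0  # logistic width parameter, °C
    weight: float = 1.0  # fraction of the total melt amplitude

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass(frozen=True)
class SimulationSpec:
    """Generative description of one synthetic melt curve.

    background = (intercept RFU, linear slope RFU/°C, exponential decay 1/°C):
    bg(T) = intercept·exp(−rate·(T − T_lo)) + slope·(T − T_lo).
    Defaults give a 1000-RFU single transition at 80 °C on the standard
    65–95 °C, 0.04 °C grid with a gently decaying linear background and
    Gaussian noise at 0.5 % of the melt amplitude.
    """

    transitions: tuple[TransitionSpec, ...] = (TransitionSpec(tm=80.0),)
    amplitude: float = 1000.0
    background: tuple[float, float, float] = (200.0, -2.0, 0.0)
    noise_sd: float = 5.0
    grid: tuple[float, float, float] = DEFAULT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        total = sum(t.weight for t in self.transitions)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"transition weights must sum to 1, got {total}")
        lo, hi, step = self.grid
        if step <= 0 or hi <= lo:
            raise ValueError(f"invalid grid {self.grid}")
        for t in self.transitions:
            if t.tm - 5 * t.slope < lo or t.tm + 5 * t.slope > hi:
                raise ValueError(
                    f"grid ({lo}, {hi}) does not cover tm={t.tm} ± 5·{t.slope}"
                )

    def temperatures(self) -> np.ndarray:
        lo, hi, step = self.grid
        n = int(np.floor((hi - lo) / step + 1e-9)) + 1
        return lo + step * np.arange(n)


@dataclass(frozen=True)
class DuplexMixtureSpec:
    """Duplex species mixture of a (possibly artificial) heterozygote.

    ``fractions`` are (wildtype homoduplex, variant homoduplex,
    heteroduplex) and must sum to 1.  ``het_delta`` is the heteroduplex Tm
    shift — negative, typically −1 to −3 °C, because the mismatch
    destabilizes the duplex; ``hom_delta`` is the (small) variant-homoduplex
    shift.  A 1:1 mix of hemizygous and wildtype DNA re-annealed after PCR
    gives fractions of roughly (0.25, 0.25, 0.5).
    """

    wt_tm: float = 80.0
    hom_delta: float = -0.3
    het_delta: float = -2.0
    fractions: tuple[float, float, float] = (0.25, 0.25, 0.5)

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")
        if abs(sum(self.fractions) - 1.0) > 1e-6:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort: per-sample labels and the specs.

    ``labels`` covers every simulated sample (controls are wildtype by
    construction); ``control_ids`` marks the samples that serve as the
    reference set and are therefore not scored by
    :func:`evaluate_detection`.
    """

    labels: dict[str, str]  # sample_id -> 'variant' | 'wildtype'
    seed: int
    base: SimulationSpec | None = None
    mix: DuplexMixtureSpec | None = None
    het_deltas: dict[str, float] = field(default_factory=dict)
    control_ids: frozenset[str] = frozenset()


@dataclass
class DetectionMetrics:
    """Confusion counts of variant calls against ground truth.

    Sensitivity/specificity are ``None`` (explicitly undefined), never 0,
    when their denominator is empty.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def specificity(self) -> float | None:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else None


def _signal(spec: SimulationSpec, temps: np.ndarray) -> np.ndarray:
    lo = spec.grid[0]
    intercept, lin, rate = spec.background
    f = intercept * np.exp(-rate * (temps - lo)) + lin * (temps - lo)
    for t in spec.transitions:
        f = f + spec.amplitude * t.weight / (1.0 + np.exp((temps - t.tm) / t.slope))
    return f


def simulate_melt_curve(
    spec: SimulationSpec,
    sample_id: str = "sim",
    meta: SampleMeta | None = None,
) -> MeltCurve:
    """One synthetic melt curve; deterministic for a given spec (incl. seed)."""
    temps = spec.temperatures()
    f = _signal(spec, temps)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        f = f + rng.normal(0.0, spec.noise_sd, size=temps.size)
    return MeltCurve(
        sample_id=sample_id,
        temperatures=temps,
        fluorescence=np.maximum(f, 0.0),
        meta=meta or SampleMeta(),
    )


def simulate_heterozygote(
    mix: DuplexMixtureSpec,
    base: SimulationSpec,
    sample_id: str = "het",
    meta: SampleMeta | None = None,
) -> MeltCurve:
    """Heterozygote melt: fraction-weighted mixture of three duplex species.

    The three species melt at ``wt_tm``, ``wt_tm + hom_delta`` and
    ``wt_tm + het_delta``, all sharing the base spec's slope, amplitude,
    background, grid and noise seed (so a (1, 0, 0) mixture reproduces the
    wildtype curve bit-for-bit at the same seed).
    """
    if len(base.transitions) != 1:
        raise ValueError("base spec must have a single reference transition")
    slope = base.transitions[0].slope
    tms = (mix.wt_tm, mix.wt_tm + mix.hom_delta, mix.wt_tm + mix.het_delta)
    transitions = tuple(
        TransitionSpec(tm=tm, slope=slope, weight=f)
        for tm, f in zip(tms, mix.fractions)
        if f > 0
    )
    spec = replace(base, transitions=transitions)
    return simulate_melt_curve(spec, sample_id=sample_id, meta=meta)


def simulate_cohort(
    n_controls: int,
    n_variants: int,
    mix: DuplexMixtureSpec | None = None,
    base: SimulationSpec | None = None,
    seed: int = 0,
    het_delta_range: tuple[float, float] | None = None,
    n_wildtype_tests: int = 0,
    amplicon_id: str = "amplicon01",
) -> tuple[ExperimentSet, CohortTruth]:
    """Simulated experiment: wildtype controls plus heterozygous variants.

    Controls are independent wildtype draws (role ``control``); variants are
    artificial-heterozygote draws (role ``test``, ``mixed=True``).  All
    samples are male, mirroring the hemizygous-mixing protocol.  When
    ``het_delta_range`` is given, each variant's heteroduplex shift is drawn
    uniformly from it; otherwise ``mix.het_delta`` is used for all.
    ``n_wildtype_tests`` adds wildtype draws in the ``test`` role — samples
    from the control distribution that are nonetheless scored, which is how
    the screen's specificity is estimated.
    """
    if n_controls < 2:
        raise ValueError("need at least 2 controls")
    mix = mix or DuplexMixtureSpec()
    base = base or SimulationSpec()
    rng = np.random.default_rng(seed)

    curves: list[MeltCurve] = []
    labels: dict[str, str] = {}
    het_deltas: dict[str, float] = {}
    for i in range(n_controls):
        sid = f"C{i + 1:03d}"
        spec = replace(base, seed=int(rng.integers(0, 2**31)))
        curves.append(
            simulate_melt_curve(
                spec,
                sample_id=sid,
                meta=SampleMeta(role="control", sex="male", amplicon_id=amplicon_id),
            )
        )
        labels[sid] = "wildtype"
    for i in range(n_wildtype_tests):
        sid = f"W{i + 1:03d}"
        spec = replace(base, seed=int(rng.integers(0, 2**31)))
        curves.append(
            simulate_melt_curve(
                spec,
                sample_id=sid,
                meta=SampleMeta(role="test", sex="male", amplicon_id=amplicon_id),
            )
        )
        labels[sid] = "wildtype"
    for i in range(n_variants):
        sid = f"V{i + 1:03d}"
        spec = replace(base, seed=int(rng.integers(0, 2**31)))
        m = mix
        if het_delta_range is not None:
            delta = float(rng.uniform(*sorted(het_delta_range)))
            m = replace(mix, het_delta=delta)
        het_deltas[sid] = m.het_delta
        curves.append(
            simulate_heterozygote(
                m,
                spec,
                sample_id=sid,
                meta=SampleMeta(role="test", sex="male", mixed=True,
                                amplicon_id=amplicon_id),
            )
        )
        labels[sid] = "variant"

    experiment = ExperimentSet(
        curves=curves, grid=curves[0].temperatures, provenance=("simulated",)
    )
    truth = CohortTruth(
        labels=labels, seed=seed, base=base, mix=mix, het_deltas=het_deltas,
        control_ids=frozenset(
            c.sample_id for c in curves if c.meta.role == "control"
        ),
    )
    return experiment, truth


def evaluate_detection(
    calls: Sequence[VariantCall], truth: CohortTruth
) -> DetectionMetrics:
    """Score variant calls against cohort ground truth.

    Every scored truth sample must have exactly one call (matched by sample
    id, either directly or through a call's per-preparation sub-calls).
    Samples listed in ``truth.control_ids`` form the reference set and are
    excluded from scoring.
    """
    scored = {s: l for s, l in truth.labels.items() if s not in truth.control_ids}
    call_by_id: dict[str, str] = {}
    for c in calls:
        if c.sample_id in scored:
            call_by_id[c.sample_id] = c.call
        else:
            # combined preparation-group call: attribute it to its members
            members = [s for s in c.preparation_calls if s in scored]
            if not members:
                raise SampleMismatch(f"call for unknown sample {c.sample_id!r}")
            for s in members:
                call_by_id[s] = c.call
    missing = set(scored) - set(call_by_id)
    if missing:
        raise SampleMismatch(f"no call for samples: {sorted(missing)}")

    tp = fn = tn = fp = 0
    for sid, label in scored.items():
        called_variant = call_by_id[sid] == "variant"
        if label == "variant":
            tp += called_variant
            fn += not called_variant
        else:
            tn += not called_variant
            fp += called_variant
    return DetectionMetrics(tp=tp, fn=fn, tn=tn, fp=fp)
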