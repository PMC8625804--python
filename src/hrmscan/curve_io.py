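"""Reading, writing and regridding of melt-curve exports.

Instrument melt exports are plain delimited text in one of two layouts:

* **wide** — first column is temperature, one additional column per well;
* **long** — columns ``sample_id`` (or ``sample``), ``temperature`` and
  ``fluorescence``.

A separate metadata table assigns each well a role (control / test /
positive_control), a sex, the artificial-heterozygote ``mixed`` flag and an
amplicon id.  Downstream analysis subtracts curves point-wise, so every curve
in an :class:`ExperimentSet` lives on one shared temperature grid; the
default regrid step of 0.04 °C matches the acquisition density of
high-resolution melt runs (25 fluorescence readings per °C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DisjointSpans,
    EmptyInput,
    LengthMismatch,
    MixedSexWarning,
    NonMonotonicGrid,
    StepTooCoarse,
    UnknownSample,
)

DEFAULT_STEP = 0.04  # °C; 25 readings per °C

ROLES = ("control", "test", "positive_control")
SEXES = ("male", "female", "unknown")

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}


@dataclass(frozen=True)
class SampleMeta:
    """Per-well annotations used for referencing and call combination.

    ``mixed`` marks an artificial heterozygote: hemizygous (male) DNA mixed
    with wildtype DNA before amplification so variants form heteroduplexes.
    ``preparation_group`` links the mixed and unmixed preparations of the
    same individual so their calls can be OR-combined.
    """

    role: str = "test"
    sex: str = "unknown"
    mixed: bool = False
    amplicon_id: str = ""
    preparation_group: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.mixed and self.sex != "male":
            warnings.warn(
                "'mixed' (artificial heterozygote) is only meaningful for "
                f"male samples; sex={self.sex!r}",
                MixedSexWarning,
                stacklevel=2,
            )


@dataclass
class MeltCurve:
    """One well's fluorescence-vs-temperature trace.

    Temperatures must be strictly increasing; fluorescence is in relative
    fluorescence units (RFU), finite and non-negative, one value per
    temperature.
    """

    sample_id: str
    temperatures: np.ndarray
    fluorescence: np.ndarray
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.ndim != 1 or self.fluorescence.ndim != 1:
            raise ValueError("temperatures and fluorescence must be 1-D")
        if self.temperatures.size != self.fluorescence.size:
            raise LengthMismatch(
                f"{self.sample_id}: {self.temperatures.size} temperatures vs "
                f"{self.fluorescence.size} fluorescence values"
            )
        if self.temperatures.size < 2:
            raise EmptyInput(f"{self.sample_id}: fewer than 2 readings")
        if not np.all(np.diff(self.temperatures) > 0):
            raise NonMonotonicGrid(
                f"{self.sample_id}: temperatures not strictly increasing"
            )
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError(f"{self.sample_id}: non-finite fluorescence")
        if np.any(self.fluorescence < 0):
            raise ValueError(f"{self.sample_id}: negative fluorescence")

    def __len__(self) -> int:
        return self.temperatures.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.temperatures[0]), float(self.temperatures[-1])

    def is_uniform(self, tol: float = 1e-9) -> bool:
        d = np.diff(self.temperatures)
        return bool(np.all(np.abs(d - d[0]) <= tol))

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.temperatures)))


@dataclass
class ExperimentSet:
    """A group of melt curves sharing one amplicon and one temperature grid."""

    curves: list[MeltCurve]
    grid: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.curves:
            raise EmptyInput("ExperimentSet with no curves")
        self.grid = np.asarray(self.grid, dtype=float)
        ids = [c.sample_id for c in self.curves]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        for c in self.curves:
            if c.temperatures.size != self.grid.size or not np.array_equal(
                c.temperatures, self.grid
            ):
                raise ValueError(
                    f"{c.sample_id}: curve grid differs from the set grid; "
                    "resample_to_common_grid first"
                )

    def __len__(self) -> int:
        return len(self.curves)

    def __getitem__(self, sample_id: str) -> MeltCurve:
        for c in self.curves:
            if c.sample_id == sample_id:
                return c
        raise KeyError(sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [c.sample_id for c in self.curves]

    def subset(self, **meta_filters) -> list[MeltCurve]:
        """Curves whose metadata match every keyword filter (e.g. role='control')."""
        out = []
        for c in self.curves:
            if all(getattr(c.meta, k) == v for k, v in meta_filters.items()):
                out.append(c)
        return out

    def fluorescence_matrix(self, curves: Sequence[MeltCurve] | None = None) -> np.ndarray:
        """(n_curves, n_points) fluorescence array on the shared grid."""
        cs = self.curves if curves is None else list(curves)
        return np.vstack([c.fluorescence for c in cs])


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer, float, np.floating)):
        if pd.isna(x):
            return False
        return bool(int(x))
    s = str(x).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot interpret {x!r} as a boolean")


def read_sample_metadata(meta_path: str | Path) -> dict[str, SampleMeta]:
    """Read the sample metadata table (CSV/TSV, delimiter auto-detected)."""
    df = pd.read_csv(meta_path, sep=None, engine="python", dtype=str)
    required = {"sample_id", "role", "sex", "mixed", "amplicon_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    out: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        prep = row.get("preparation_group", "")
        out[sid] = SampleMeta(
            role=str(row["role"]).strip(),
            sex=str(row["sex"]).strip(),
            mixed=_parse_bool(row["mixed"]),
            amplicon_id=str(row["amplicon_id"]).strip(),
            preparation_group="" if pd.isna(prep) else str(prep).strip(),
        )
    return out


def _find_column(df: pd.DataFrame, names: Sequence[str]) -> str | None:
    lowered = {c.lower().strip(): c for c in df.columns}
    for n in names:
        if n in lowered:
            return lowered[n]
    return None


def read_melt_export(
    curve_path: str | Path,
    meta_path: str | Path,
    layout: Literal["wide", "long", "auto"] = "auto",
) -> ExperimentSet:
    """Read a melt-curve export plus its sample metadata.

    Wide layout: first column temperature, one column per well.  Long layout:
    ``sample_id``/``sample``, ``temperature``, ``fluorescence`` columns.
    ``layout='auto'`` selects long when a sample-id column is present.
    Every curve must have a metadata row; a missing row raises
    :class:`~hrmscan.errors.UnknownSample`.
    """
    df = pd.read_csv(curve_path, sep=None, engine="python")
    if df.empty or df.shape[1] < 2:
        raise EmptyInput(f"{curve_path}: no data")
    meta = read_sample_metadata(meta_path)

    sample_col = _find_column(df, ("sample_id", "sample", "well"))
    if layout == "auto":
        layout = "long" if sample_col is not None else "wide"

    curves: list[MeltCurve] = []
    if layout == "long":
        if sample_col is None:
            raise ValueError(f"{curve_path}: long layout needs a sample-id column")
        temp_col = _find_column(df, ("temperature", "temp", "t"))
        fluo_col = _find_column(df, ("fluorescence", "rfu", "f", "signal"))
        if temp_col is None or fluo_col is None:
            raise ValueError(
                f"{curve_path}: long layout needs temperature and fluorescence columns"
            )
        for sid, grp in df.groupby(sample_col, sort=False):
            sid = str(sid)
            if sid not in meta:
                raise UnknownSample(f"{sid}: no metadata row")
            curves.append(
                MeltCurve(
                    sample_id=sid,
                    temperatures=grp[temp_col].to_numpy(float),
                    fluorescence=grp[fluo_col].to_numpy(float),
                    meta=meta[sid],
                )
            )
    else:
        temp = df.iloc[:, 0].to_numpy(float)
        for col in df.columns[1:]:
            sid = str(col).strip()
            if sid not in meta:
                raise UnknownSample(f"{sid}: no metadata row")
            values = df[col].to_numpy(float)
            if np.any(pd.isna(values)):
                raise LengthMismatch(f"{sid}: missing fluorescence values")
            curves.append(
                MeltCurve(sample_id=sid, temperatures=temp, fluorescence=values,
                          meta=meta[sid])
            )

    if not curves:
        raise EmptyInput(f"{curve_path}: no sample columns")

    grids_match = all(
        np.array_equal(c.temperatures, curves[0].temperatures) for c in curves
    )
    if not grids_match:
        curves = resample_to_common_grid(curves, step=DEFAULT_STEP)
    return ExperimentSet(
        curves=curves,
        grid=curves[0].temperatures,
        provenance=(str(curve_path), str(meta_path)),
    )


def write_melt_export(
    experiment: ExperimentSet,
    curve_path: str | Path,
    meta_path: str | Path | None = None,
) -> None:
    """Write an experiment back to wide CSV (+ optional metadata CSV).

    Values are written at full repr precision so a read→write→read round
    trip preserves fluorescence to better than 1e-9 RFU.
    """
    data = {"temperature": experiment.grid}
    for c in experiment.curves:
        data[c.sample_id] = c.fluorescence
    pd.DataFrame(data).to_csv(curve_path, index=False)
    if meta_path is not None:
        rows = []
        for c in experiment.curves:
            m = c.meta
            rows.append(
                {
                    "sample_id": c.sample_id,
                    "role": m.role,
                    "sex": m.sex,
                    "mixed": m.mixed,
                    "amplicon_id": m.amplicon_id,
                    "preparation_group": m.preparation_group,
                }
            )
        pd.DataFrame(rows).to_csv(meta_path, index=False)


def resample_to_common_grid(
    curves: Sequence[MeltCurve],
    step: float = DEFAULT_STEP,
    range: tuple[float, float] | None = None,
) -> list[MeltCurve]:
    """Linearly interpolate all curves onto one uniform grid.

    The grid covers the intersection of the curves' spans (or the explicit
    ``range``) at spacing ``step``; no extrapolation is performed.  Curves
    already on the exact target grid are returned unchanged, which makes the
    operation idempotent.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not curves:
        raise EmptyInput("no curves to resample")
    lo = max(c.temperatures[0] for c in curves)
    hi = min(c.temperatures[-1] for c in curves)
    if range is not None:
        rlo, rhi = range
        if rlo < lo - 1e-12 or rhi > hi + 1e-12:
            raise DisjointSpans(
                f"requested range ({rlo}, {rhi}) not covered by the common "
                f"span ({lo}, {hi})"
            )
        lo, hi = rlo, rhi
    if hi <= lo:
        raise DisjointSpans(f"no common temperature interval (lo={lo}, hi={hi})")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    if n < 10:
        raise StepTooCoarse(f"grid of {n} points (< 10) at step {step}")
    grid = lo + step * np.arange(n)
    out = []
    for c in curves:
        if np.array_equal(c.temperatures, grid):
            out.append(c)
        else:
            f = np.interp(grid, c.temperatures, c.fluorescence)
            out.append(replace(c, temperatures=grid, fluorescence=f))
    return out
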