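"""Machine-readable reports and difference-plot figures.

The TSV has one row per (sample, scope) with the deviation summary; the JSON
summary captures everything needed to reproduce and audit a run (parameters,
seed, detected domains with their Tm, the per-sample domain tally, per-scope
calls).  Figures mirror the standard three-panel HRM display per scope:
normalized melt curves, the negative derivative, and the difference plot
with the gray median ± k·SD control band.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from .curve_io import ExperimentSet
from .estimators import HRMVariantDetector, SavGolDerivative
from .melt_core import SmoothingConfig, scan_domains
from .reference_compare import VariantCall


def calls_table(calls: Sequence[VariantCall]) -> pd.DataFrame:
    """One row per (sample, scope), plus the aggregated per-call verdict."""
    rows = []
    for c in calls:
        for rec in c.records:
            rows.append(
                {
                    "call_id": c.sample_id,
                    "sample_id": rec["sample_id"],
                    "amplicon_id": c.amplicon_id,
                    "scope": rec["scope"],
                    "stratum": rec["stratum"],
                    "max_abs_z": rec["max_abs_z"],
                    "longest_run": rec["longest_run"],
                    "scope_call": rec["scope_call"],
                    "final_call": c.call,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["call_id", "sample_id", "scope"]).reset_index(drop=True)
    return df


def write_calls_tsv(calls: Sequence[VariantCall], path: str | Path) -> None:
    calls_table(calls).to_csv(path, sep="\t", index=False, float_format="%.6g")


def experiment_summary(
    experiment: ExperimentSet,
    detector: HRMVariantDetector,
    calls: Sequence[VariantCall],
    cfg: SmoothingConfig,
    k: float,
    m: int,
    seed: int | None = None,
) -> dict:
    """JSON-serializable audit record of one analysis run."""
    strata: dict[str, int] = {}
    for c in experiment.subset(role="control"):
        strata[c.meta.sex] = strata.get(c.meta.sex, 0) + 1

    # per-sample domain tally (diagnostic: which domains each curve shows)
    tally = {}
    for c in experiment.curves:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            tally[c.sample_id] = len(scan_domains(c, cfg))

    return {
        "amplicon_id": experiment.curves[0].meta.amplicon_id,
        "n_samples": len(experiment),
        "n_controls_per_stratum": strata,
        "seed": seed,
        "parameters": {
            "window": cfg.window,
            "polyorder": cfg.polyorder,
            "domain_threshold": cfg.domain_threshold,
            "region_pad": cfg.region_pad,
            "min_domain_width": cfg.min_domain_width,
            "k": k,
            "m": m,
        },
        "domains": [
            {
                "index": d.index,
                "tm": d.peak_temp,
                "relative_height": round(d.peak_height_rel, 6),
                "domain_start": d.domain_start,
                "domain_end": d.domain_end,
                "region_start": d.region_start,
                "region_end": d.region_end,
            }
            for d in detector.domains_
        ],
        "domains_per_sample": tally,
        "calls": [
            {
                "sample_id": c.sample_id,
                "amplicon_id": c.amplicon_id,
                "call": c.call,
                "supporting_scopes": c.supporting_scopes,
                "preparation_calls": c.preparation_calls,
            }
            for c in calls
        ],
        "note": "screening calls; variant calls require confirmation by sequencing",
    }


def write_summary_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def plot_scope(
    experiment: ExperimentSet,
    detector: HRMVariantDetector,
    scope: str,
    path: str | Path,
    k: float = 2.0,
) -> None:
    """Three-panel figure for one scope: normalized melt, −dF/dT, difference
    plot with the gray median ± k·SD control band."""
    ref = detector.references_[scope]
    norm = detector._normalizers_[scope]
    deriv = SavGolDerivative(
        temperatures=experiment.grid,
        window=detector.window,
        polyorder=detector.polyorder,
    ).fit(experiment.fluorescence_matrix())

    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    ax_melt, ax_deriv, ax_diff = axes
    band = 100 * k * np.maximum(ref.sd, ref.sd_floor)
    ax_diff.fill_between(ref.grid, -band, band, color="0.8",
                         label=f"controls ±{k:g} SD")

    for curve in experiment.curves:
        is_control = curve.meta.role == "control"
        color = "0.55" if is_control else None
        values = norm.transform(curve.fluorescence[None, :])[0]
        ax_melt.plot(norm.grid_, 100 * values, color=color, lw=1)
        nd = deriv.transform(curve.fluorescence[None, :])[0]
        sl = slice(*np.searchsorted(experiment.grid, (norm.grid_[0], norm.grid_[-1])))
        ax_deriv.plot(experiment.grid[sl], nd[sl], color=color, lw=1)
        if not is_control:
            ax_diff.plot(ref.grid, 100 * (values - ref.median), lw=1.2,
                         label=curve.sample_id)
        else:
            ax_diff.plot(ref.grid, 100 * (values - ref.median), color="0.55", lw=0.8)

    ax_melt.set_ylabel("normalized fluorescence (%)")
    ax_melt.set_title(f"{scope}: melt curves")
    ax_deriv.set_ylabel("−dF/dT (RFU/°C)")
    ax_deriv.set_title("negative derivative")
    ax_diff.set_ylabel("difference vs control median (%)")
    ax_diff.set_title("difference plot")
    for ax in axes:
        ax.set_xlabel("temperature (°C)")
    if len(experiment) <= 12:
        ax_diff.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110, metadata={"Software": "hrmscan"})
    plt.close(fig)


def write_plots(
    experiment: ExperimentSet,
    detector: HRMVariantDetector,
    out_dir: str | Path,
    k: float = 2.0,
) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for scope, _ in detector.scopes_:
        p = out_dir / f"{scope}.png"
        plot_scope(experiment, detector, scope, p, k=k)
        paths.append(p)
    return paths
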