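"""End-to-end orchestration: simulate → segment → quantify → colocalize → stats.

A run is driven by one :class:`~compartquant.config.RunConfig` and a single
seed; identical config + seed reproduce byte-identical output tables.
Per-channel colocalization thresholds are frozen from the control fields
before any non-control field is processed, honoring the
one-threshold-per-channel-for-all-conditions rule.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import colocalization as coloc
from . import io as cqio
from . import quantify, segmentation, stats
from .config import RunConfig
from .containers import CHANNEL_A, CHANNEL_B, PROTEIN_CHANNELS, FieldImage
from .synthetic import generate_experiment, puncta_midpoint_threshold

logger = logging.getLogger(__name__)

#: pooled-pixel cap per channel when deriving control thresholds
_THRESHOLD_POOL_CAP = 2_000_000


class PipelineError(RuntimeError):
    pass


@dataclass
class RunResult:
    """Tables and provenance of one completed pipeline run."""

    outdir: Path
    measurements: pd.DataFrame
    nc_table: pd.DataFrame
    condition_summary: pd.DataFrame
    nc_condition_means: pd.DataFrame
    coloc_records: pd.DataFrame
    coloc_summary: pd.DataFrame
    correlation_grid: pd.DataFrame
    regression_table: pd.DataFrame
    anova_table: pd.DataFrame
    thresholds: dict[str, float]
    provenance: dict = dc_field(default_factory=dict)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _fix_run_thresholds(config: RunConfig,
                        manifest_path: Path) -> dict[str, float]:
    """Freeze per-channel thresholds from the control fields only."""
    if config.threshold_method == "fixed":
        return {ch: float(config.threshold_values[ch]) for ch in PROTEIN_CHANNELS}
    if config.threshold_method == "puncta_midpoint":
        if config.simulation is None:
            raise PipelineError("puncta_midpoint thresholds need a simulation config")
        t = puncta_midpoint_threshold(config.simulation)
        return {ch: t for ch in PROTEIN_CHANNELS}
    pools: dict[str, list[np.ndarray]] = {ch: [] for ch in PROTEIN_CHANNELS}
    n_control = 0
    for field in cqio.read_manifest(manifest_path):
        if field.condition != config.control_condition:
            continue
        n_control += 1
        corrected, _, _ = segmentation.segment_field(field, config.segmentation)
        for ch in PROTEIN_CHANNELS:
            pools[ch].append(corrected[ch].reshape(-1))
    if n_control == 0:
        raise PipelineError(
            f"control condition {config.control_condition!r} has no fields")
    pooled = {}
    for ch, parts in pools.items():
        pool = np.concatenate(parts)
        if pool.size > _THRESHOLD_POOL_CAP:   # deterministic thinning
            step = pool.size // _THRESHOLD_POOL_CAP + 1
            pool = pool[::step]
        pooled[ch] = pool
    return coloc.fix_thresholds(pooled, config.threshold_method,
                                percentile=config.threshold_percentile)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute a full run and write every output table under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    if config.simulation is not None:
        sim_dir = outdir / "simulated"
        manifest_path = generate_experiment(
            config.simulation, sim_dir, n_replicates=config.n_replicates,
            master_seed=config.seed)
    else:
        manifest_path = Path(config.manifest)

    conditions = cqio.manifest_conditions(manifest_path)
    if config.control_condition not in conditions:
        raise PipelineError(
            f"control condition {config.control_condition!r} not in manifest "
            f"(found {conditions})")

    thresholds = _fix_run_thresholds(config, manifest_path)
    logger.info("frozen thresholds: %s", thresholds)

    measurement_tables: list[pd.DataFrame] = []
    coloc_records: list[coloc.ColocalizationRecord] = []
    dropped: list[dict] = []
    qc_dir = outdir / "qc_masks"
    qc_tables: list[pd.DataFrame] = []

    pixel_area = (config.simulation.pixel_area if config.simulation is not None
                  else 0.14)
    for field in cqio.read_manifest(manifest_path, pixel_area=pixel_area):
        try:
            corrected, masks, backgrounds = segmentation.segment_field(
                field, config.segmentation)
            masks.validate()
            m = quantify.measure_field(corrected, masks,
                                       config.nucleus_excludes_nucleoli)
            if len(m):
                measurement_tables.append(m)
            qc_tables.append(segmentation.segmentation_qc_table(corrected, masks))
            cqio.write_masks(qc_dir, field.field_id, masks)
            mask_a = coloc.threshold_channel(corrected[CHANNEL_A],
                                             thresholds[CHANNEL_A])
            mask_b = coloc.threshold_channel(corrected[CHANNEL_B],
                                             thresholds[CHANNEL_B])
            measured_ids = set(m["cell_id"]) if len(m) else set()
            for cid in masks.cell_ids:
                if cid not in measured_ids:
                    continue
                coloc_records.extend(coloc.coloc_per_cell(
                    mask_a, mask_b, masks, cid, condition=field.condition,
                    replicate=field.replicate, field_id=field.field_id,
                    pixel_area=field.pixel_area))
        except Exception as exc:            # per-field failures are logged, not fatal
            logger.exception("field %s failed: %s", field.field_id, exc)
            dropped.append({"field_id": field.field_id, "reason": str(exc)})

    if not measurement_tables:
        raise PipelineError("no usable cells in any field")
    measurements = pd.concat(measurement_tables, ignore_index=True)
    n_control_cells = measurements.loc[
        measurements["condition"] == config.control_condition, "cell_id"].count()
    if n_control_cells == 0:
        raise PipelineError("control condition yielded zero usable cells")

    measurements = quantify.normalize_to_control(measurements,
                                                 config.control_condition)
    nc_table = quantify.nc_ratio_table(measurements)
    summary = quantify.condition_summary(
        measurements, unit=config.anova_unit,
        min_cells=config.min_cells_per_condition)
    nc_means = quantify.nc_condition_means(
        nc_table, ratio_of_means=config.ratio_of_means,
        measurements=measurements if config.ratio_of_means else None)

    records = coloc.records_table(coloc_records) if coloc_records else pd.DataFrame()
    coloc_summary = (coloc.coloc_condition_summary(
        records, min_cells=config.min_cells_coloc,
        control_condition=config.control_condition)
        if len(records) else pd.DataFrame())

    corr_grid = stats.correlation_table(measurements, nc_table, conditions)
    reg_table = stats.regression_table(measurements, nc_table, conditions)
    anova_table = stats.anova_vs_control_table(
        measurements, config.control_condition, unit=config.anova_unit)

    cells_per_condition = (
        measurements[["condition", "field_id", "cell_id"]].drop_duplicates()
        .groupby("condition").size())
    provenance = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "seed": config.seed,
        "thresholds": thresholds,
        "cells_per_condition": {c: int(n)
                                for c, n in cells_per_condition.items()},
        "dropped_fields": dropped,
    }

    _write_outputs(outdir, measurements, nc_table, summary, nc_means, records,
                   coloc_summary, corr_grid, reg_table, anova_table, provenance,
                   qc_tables)
    result = RunResult(outdir, measurements, nc_table, summary, nc_means,
                       records, coloc_summary, corr_grid, reg_table,
                       anova_table, thresholds, provenance)
    if config.plots:
        report(result, plots=True)
    return result


def _write_outputs(outdir, measurements, nc_table, summary, nc_means, records,
                   coloc_summary, corr_grid, reg_table, anova_table,
                   provenance, qc_tables) -> None:
    measurements.to_csv(outdir / "measurements.csv", index=False)
    nc_table.to_csv(outdir / "nc_ratios.csv", index=False)
    summary.to_csv(outdir / "condition_summary.csv", index=False)
    nc_means.to_csv(outdir / "nc_condition_means.csv", index=False)
    records.to_csv(outdir / "colocalization.csv", index=False)
    coloc_summary.to_csv(outdir / "coloc_summary.csv", index=False)
    corr_grid.to_csv(outdir / "correlation_grid.csv", index=False)
    reg_table.to_csv(outdir / "regression_table.csv", index=False)
    anova_table.to_csv(outdir / "anova.csv", index=False)
    if qc_tables:
        pd.concat(qc_tables, ignore_index=True).to_csv(
            outdir / "segmentation_qc.csv", index=False)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    with open(outdir / "stats_report.json", "w") as fh:
        json.dump({
            "correlation_grid": corr_grid.to_dict(orient="records"),
            "regression_table": reg_table.to_dict(orient="records"),
            "anova": anova_table.to_dict(orient="records"),
        }, fh, indent=2, sort_keys=True, default=str)


REQUIRED_TABLES = ("measurements.csv", "nc_ratios.csv", "condition_summary.csv",
                   "colocalization.csv", "correlation_grid.csv",
                   "regression_table.csv", "anova.csv")


def report(result: RunResult | str | Path, plots: bool = False) -> dict:
    """Human-readable run summary; optional figure files.

    With ``plots=True`` writes, under ``<outdir>/figures``: ascending
    single-cell profiles per channel × compartment, one scatter +
    trendline per condition × quantity, and mean + SEM bar charts with
    significance stars.  Tables are mandatory: raises when any required
    table is missing.
    """
    if not isinstance(result, RunResult):
        outdir = Path(result)
        missing = [t for t in REQUIRED_TABLES if not (outdir / t).exists()]
        if missing:
            raise FileNotFoundError(f"missing pipeline tables: {missing}")
        result = _load_result(outdir)
    summary_text = _summary_text(result)
    (result.outdir / "report.txt").write_text(summary_text)
    info = {"report": str(result.outdir / "report.txt"), "figures": []}
    if plots:
        info["figures"] = _make_plots(result)
    return info


def _load_result(outdir: Path) -> RunResult:
    read = lambda name: pd.read_csv(outdir / name)
    with open(outdir / "provenance.json") as fh:
        provenance = json.load(fh)
    return RunResult(
        outdir, read("measurements.csv"), read("nc_ratios.csv"),
        read("condition_summary.csv"), read("nc_condition_means.csv"),
        read("colocalization.csv"), read("coloc_summary.csv"),
        read("correlation_grid.csv"), read("regression_table.csv"),
        read("anova.csv"), provenance.get("thresholds", {}), provenance)


def _summary_text(result: RunResult) -> str:
    lines = ["compartquant run summary", "========================", ""]
    lines.append("Per-channel thresholds: "
                 + ", ".join(f"{k}={v:.3g}" for k, v in result.thresholds.items()))
    lines.append("")
    lines.append("Mean N/C ratio per condition:")
    for row in result.nc_condition_means.itertuples():
        lines.append(f"  {row.condition:<14} {row.channel:<10} "
                     f"{row.nc_ratio:7.3f}  (n={row.n})")
    lines.append("")
    lines.append("Pearson r grid (condition × quantity):")
    for row in result.correlation_grid.itertuples():
        lines.append(f"  {row.condition:<14} {row.quantity:<10} r={row.r:+.3f} "
                     f"(n={row.n})")
    return "\n".join(lines) + "\n"


def _make_plots(result: RunResult) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = result.outdir / "figures"
    figdir.mkdir(exist_ok=True)
    written: list[str] = []
    meas, nc = result.measurements, result.nc_table
    conditions = list(pd.unique(meas["condition"]))

    # ascending single-cell profiles
    for (ch, comp), _ in meas.groupby(["channel", "compartment"]):
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for cond in conditions:
            vals = quantify.ascending_profile(meas, ch, comp, cond)
            ax.plot(np.arange(1, vals.size + 1), vals, label=cond, lw=1)
        ax.set(xlabel="cell rank", ylabel="normalized intensity",
               title=f"{ch} / {comp}")
        ax.legend(fontsize=6)
        path = figdir / f"profile_{ch}_{comp}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(str(path))

    # scatter + trendline per condition × quantity
    for cond in conditions:
        for quantity in ("nc_ratio", "nucleus", "cytoplasm"):
            sample = stats._paired_values(meas, nc, cond, quantity)
            fig, ax = plt.subplots(figsize=(3.6, 3.2))
            ax.scatter(sample.x, sample.y, s=6, alpha=0.6)
            if sample.n >= 2 and np.ptp(sample.x) > 0:
                fit = stats.linear_fit(sample)
                xs = np.linspace(sample.x.min(), sample.x.max(), 10)
                ax.plot(xs, fit.slope * xs + fit.intercept, "r-", lw=1)
                r2 = "NA" if fit.r_squared is None else f"{fit.r_squared:.2f}"
                ax.set_title(f"{cond} {quantity}  "
                             f"y={fit.slope:.2f}x+{fit.intercept:.2f}, R²={r2}",
                             fontsize=7)
            ax.set(xlabel="channel A", ylabel="channel B")
            path = figdir / f"scatter_{cond}_{quantity}.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            written.append(str(path))

    # bar charts with stars
    for (ch, comp), sub in result.condition_summary.groupby(
            ["channel", "compartment"]):
        sub = sub.set_index("condition").reindex(conditions).dropna(subset=["mean"])
        fig, ax = plt.subplots(figsize=(4.2, 3.2))
        ax.bar(sub.index, sub["mean"], yerr=sub["sem"].fillna(0), capsize=3)
        ann = result.anova_table
        ann = ann[(ann["channel"] == ch) & (ann["compartment"] == comp)]
        stars = dict(zip(ann["condition"], ann["stars"]))
        for i, cond in enumerate(sub.index):
            s = stars.get(cond, "")
            if s and s != "ns":
                ax.text(i, sub["mean"].iloc[i], s, ha="center", va="bottom")
        ax.set(ylabel="normalized mean + SEM", title=f"{ch} / {comp}")
        ax.tick_params(axis="x", labelrotation=45, labelsize=6)
        fig.tight_layout()
        path = figdir / f"bars_{ch}_{comp}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(str(path))
    return written
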