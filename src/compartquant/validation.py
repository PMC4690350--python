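"""Ground-truth recovery experiments used for validating the pipeline.

Each helper builds a synthetic experiment with known parameters, runs the
relevant pipeline stage, and returns the recovered quantity so it can be
compared against the configured truth.  Problem sizes are chosen to give
tight sampling error at interactive runtimes (a few seconds per call).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .colocalization import coloc_per_cell, records_table, threshold_channel
from .config import SimulationConfig
from .containers import (CHANNEL_A, CHANNEL_B, CYTOPLASM, NUCLEOLUS, NUCLEUS,
                         CompartmentMasks)
from .segmentation import correct_background, segment_field
from .stats import PairedSample, pearson_r
from .synthetic import generate_field, puncta_midpoint_threshold


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) of two boolean masks."""
    s = int(a.sum()) + int(b.sum())
    return 2.0 * int(np.logical_and(a, b).sum()) / s if s else float("nan")


def matched_dice(pred_labels: np.ndarray, truth_labels: np.ndarray) -> list[float]:
    """Per predicted object, Dice against its best-overlapping truth object."""
    out = []
    for pid in np.unique(pred_labels):
        if pid == 0:
            continue
        pm = pred_labels == pid
        ov = np.bincount(truth_labels[pm], minlength=truth_labels.max() + 1)
        if ov[1:].max() == 0:
            out.append(0.0)
            continue
        out.append(dice(pm, truth_labels == (ov[1:].argmax() + 1)))
    return out


def per_nucleolus_dice(pred: CompartmentMasks, truth: CompartmentMasks
                       ) -> list[float]:
    """Dice per individual nucleolar disk (connected component)."""
    from skimage.measure import label as cc_label

    # map predicted cell ids to truth ids via nucleus overlap
    out = []
    for pid in np.unique(pred.nucleus_labels):
        if pid == 0:
            continue
        ov = np.bincount(truth.nucleus_labels[pred.nucleus_labels == pid])
        if ov[1:].max() == 0:
            continue
        tid = ov[1:].argmax() + 1
        tcc = cc_label(truth.nucleolus_labels == tid)
        pcc = cc_label(pred.nucleolus_labels == pid)
        for k in range(1, tcc.max() + 1):
            tdisk = tcc == k
            hit = np.bincount(pcc[tdisk], minlength=pcc.max() + 1)
            if pcc.max() == 0 or hit[1:].max() == 0:
                out.append(0.0)
                continue
            out.append(dice(pcc == (hit[1:].argmax() + 1), tdisk))
    return out


# ---------------------------------------------------------------------------
# recovery experiments
# ---------------------------------------------------------------------------

def correlation_recovery_config(rho: float, n_cells: int = 200,
                                seed: int = 0) -> SimulationConfig:
    """Compact-geometry population for cross-channel correlation recovery.

    Nucleoli and puncta are disabled so the per-cell nuclear mean is the
    diffuse µ times the cell's brightness factor alone: the recovered r
    then estimates the latent ρ with pure sampling error (no geometric
    confound from shared nucleolar area between the channels).
    """
    return SimulationConfig(
        n_cells=n_cells, field_size=(768, 768), seed=seed,
        nucleus_radius_range=(5.0, 7.0), cytoplasm_radius_range=(9.0, 12.0),
        nucleolus_radius_range=(2.0, 3.0), n_nucleoli_range=(0, 0),
        coloc_fractions=None, cross_cell_correlation=rho)


def recovered_nuclear_correlation(rho: float, n_cells: int = 200,
                                  seed: int = 0) -> float:
    """Sample correlation of per-cell true nuclear means of the two channels."""
    cfg = correlation_recovery_config(rho, n_cells, seed)
    _, truth = generate_field(cfg, "control", seed=seed)
    nuc = truth.true_means[truth.true_means["compartment"] == NUCLEUS]
    wide = nuc.pivot_table(index="cell_id", columns="channel",
                           values="true_mean")
    r = pearson_r(PairedSample(wide[CHANNEL_A].to_numpy(),
                               wide[CHANNEL_B].to_numpy()))
    return float("nan") if r is None else r


def coloc_recovery_config(fraction: float, n_cells: int = 50,
                          seed: int = 0) -> SimulationConfig:
    """Uniform-intensity single-condition field with embedded overlap f."""
    model = {"control": {
        CHANNEL_A: {NUCLEUS: 100.0, CYTOPLASM: 100.0, NUCLEOLUS: 60.0},
        CHANNEL_B: {NUCLEUS: 80.0, CYTOPLASM: 80.0, NUCLEOLUS: 50.0}}}
    return SimulationConfig(
        n_cells=n_cells, field_size=(720, 720), seed=seed,
        intensity_model=model,
        coloc_fractions={"control": {NUCLEUS: fraction, CYTOPLASM: fraction}})


def recovered_coloc_fraction(fraction: float, n_cells: int = 50,
                             seed: int = 0,
                             compartment: str = NUCLEUS) -> float:
    """Mean per-cell B-in-A percentage recovered through segmentation +
    frozen-threshold colocalization on one synthetic field."""
    cfg = coloc_recovery_config(fraction, n_cells, seed)
    field, truth = generate_field(cfg, "control", seed=seed)
    corrected, masks, _ = segment_field(field)
    t = puncta_midpoint_threshold(cfg)
    mask_a = threshold_channel(corrected[CHANNEL_A], t)
    mask_b = threshold_channel(corrected[CHANNEL_B], t)
    recs = []
    for cid in masks.cell_ids:
        recs.extend(coloc_per_cell(mask_a, mask_b, masks, cid))
    table = records_table(recs)
    sub = table[(table["compartment"] == compartment) & table["pct_b_defined"]]
    return float(sub["pct_b_in_a"].mean())


def segmentation_recovery(condition: str = "control", seed: int = 0
                          ) -> dict[str, float]:
    """Mean and min Dice per compartment on one default-geometry field."""
    cfg = SimulationConfig(seed=seed)
    field, truth = generate_field(cfg, condition, seed=seed)
    _, masks, _ = segment_field(field)
    nuc = matched_dice(masks.nucleus_labels, truth.masks.nucleus_labels)
    cyt = matched_dice(masks.cytoplasm_labels, truth.masks.cytoplasm_labels)
    nlo = per_nucleolus_dice(masks, truth.masks)
    return {
        "n_cells_true": len(truth.geometries),
        "n_cells_found": len(masks.cell_ids),
        "nucleus_dice_mean": float(np.mean(nuc)),
        "nucleus_dice_min": float(np.min(nuc)),
        "cytoplasm_dice_mean": float(np.mean(cyt)),
        "cytoplasm_dice_min": float(np.min(cyt)),
        "nucleolus_dice_mean": float(np.mean(nlo)) if nlo else float("nan"),
        "nucleolus_dice_min": float(np.min(nlo)) if nlo else float("nan"),
    }


def trend_metrics(nc_means: pd.DataFrame, condition_summary: pd.DataFrame,
                  conditions: list[str]) -> dict[str, float]:
    """Headline trend statistics of a full-experiment run.

    Returns the Spearman rank correlation of the channel-A N/C series with
    experimental time order, the maximum relative deviation of channel-B
    N/C from its control value, and the nucleolar enrichment profile of
    both channels.
    """
    from scipy.stats import spearmanr

    def series(df, channel, value):
        sub = df[df["channel"] == channel].set_index("condition")
        return sub.loc[list(conditions), value].to_numpy(dtype=float)

    nc_a = series(nc_means, CHANNEL_A, "nc_ratio")
    nc_b = series(nc_means, CHANNEL_B, "nc_ratio")
    nlo = condition_summary[condition_summary["compartment"] == NUCLEOLUS]
    nlo_a = series(nlo, CHANNEL_A, "mean")
    nlo_b = series(nlo, CHANNEL_B, "mean")
    rho, _ = spearmanr(np.arange(len(conditions)), nc_a)
    recovery_idx = [i for i, c in enumerate(conditions) if "recovery" in c]
    return {
        "nc_a_series": nc_a,
        "nc_b_series": nc_b,
        "nucleolar_a_series": nlo_a,
        "nucleolar_b_series": nlo_b,
        "nc_a_spearman_vs_time": float(rho),
        "nc_b_max_rel_dev_from_control": float(
            np.max(np.abs(nc_b / nc_b[0] - 1.0))),
        "nucleolar_a_peak_in_recovery": bool(
            int(np.argmax(nlo_a)) in recovery_idx),
        "nucleolar_a_peak_over_control": float(np.max(nlo_a) / nlo_a[0]),
        "nucleolar_b_max_over_control": float(np.max(nlo_b) / nlo_b[0]),
    }
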