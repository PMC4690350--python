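"""Per-cell intensity quantification and population summaries.

All measurements operate on background-corrected images.  The primary
output is a long-format table with one row per cell × channel ×
compartment holding the mean pixel intensity (ADU/pixel) and the region
area; N/C ratios, control-normalized values, ascending single-cell
profiles and mean ± SEM condition summaries derive from it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (COMPARTMENTS, CYTOPLASM, NUCLEOLUS, NUCLEUS,
                         PROTEIN_CHANNELS, CompartmentMasks, FieldImage)

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["field_id", "cell_id", "condition", "replicate",
                       "channel", "compartment", "mean_intensity",
                       "area_px", "area_um2"]


class MissingControlError(ValueError):
    """Normalization impossible: no usable control cells (or zero control mean)."""


def measure_cell(field: FieldImage, masks: CompartmentMasks, cell_id: int,
                 nucleus_excludes_nucleoli: bool = False) -> pd.DataFrame | None:
    """Mean background-corrected intensity per compartment per protein channel.

    The nucleolar rows are emitted only when the cell has ≥1 nucleolar
    pixel.  Returns ``None`` (cell dropped, reason logged) when the
    nucleus or cytoplasm mask of the cell is empty.
    """
    rows = []
    region = {comp: masks.compartment_mask(cell_id, comp, nucleus_excludes_nucleoli)
              for comp in COMPARTMENTS}
    if not region[NUCLEUS].any() or not region[CYTOPLASM].any():
        logger.info("cell %s dropped: empty nucleus or cytoplasm mask", cell_id)
        return None
    for ch in PROTEIN_CHANNELS:
        img = np.asarray(field[ch], dtype=float)
        for comp in COMPARTMENTS:
            area = int(region[comp].sum())
            if comp == NUCLEOLUS and area == 0:
                continue
            rows.append((field.field_id, cell_id, field.condition, field.replicate,
                         ch, comp, float(img[region[comp]].sum()) / area,
                         area, area * field.pixel_area))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def measure_field(field: FieldImage, masks: CompartmentMasks,
                  nucleus_excludes_nucleoli: bool = False) -> pd.DataFrame:
    """Measurement table for every labeled cell of one field."""
    tables = [measure_cell(field, masks, cid, nucleus_excludes_nucleoli)
              for cid in masks.cell_ids]
    tables = [t for t in tables if t is not None]
    if not tables:
        return pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    return pd.concat(tables, ignore_index=True)


def nc_ratio_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-cell nucleocytoplasmic ratio per channel.

    ``nc_ratio`` is the nuclear mean divided by the cytoplasmic mean of
    the same cell; cells with zero cytoplasmic mean are flagged
    ``nc_defined = False`` and carry NaN.
    """
    wide = measurements.pivot_table(
        index=["field_id", "cell_id", "condition", "replicate", "channel"],
        columns="compartment", values="mean_intensity", aggfunc="first"
    ).reset_index()
    for comp in (NUCLEUS, CYTOPLASM):
        if comp not in wide:
            wide[comp] = np.nan
    cyt = wide[CYTOPLASM].to_numpy(dtype=float)
    nuc = wide[NUCLEUS].to_numpy(dtype=float)
    defined = np.isfinite(cyt) & (cyt > 0) & np.isfinite(nuc)
    ratio = np.full(len(wide), np.nan)
    ratio[defined] = nuc[defined] / cyt[defined]
    out = wide[["field_id", "cell_id", "condition", "replicate", "channel"]].copy()
    out["nc_ratio"] = ratio
    out["nc_defined"] = defined
    return out


def normalize_to_control(measurements: pd.DataFrame, control_condition: str
                         ) -> pd.DataFrame:
    """Add a ``normalized`` column: value ÷ same-replicate control mean.

    Normalization is per replicate, per channel, per compartment, so the
    control-group mean of normalized values is exactly 1 within every
    replicate.  Raises :class:`MissingControlError` when a replicate lacks
    control cells for a channel × compartment, or its control mean is 0.
    """
    if control_condition not in set(measurements["condition"]):
        raise MissingControlError(
            f"control condition {control_condition!r} absent from the table")
    out = measurements.reset_index(drop=True).copy()
    control = out[out["condition"] == control_condition]
    means = control.groupby(["replicate", "channel", "compartment"]
                            )["mean_intensity"].mean()
    normalized = np.empty(len(out))
    for (rep, ch, comp), sub in out.groupby(["replicate", "channel", "compartment"]):
        key = (rep, ch, comp)
        if key not in means.index:
            raise MissingControlError(
                f"no control cells for replicate={rep}, channel={ch}, "
                f"compartment={comp}")
        m = means.loc[key]
        if not np.isfinite(m) or m <= 0:
            raise MissingControlError(
                f"control mean is {m} for replicate={rep}, channel={ch}, "
                f"compartment={comp}")
        normalized[sub.index.to_numpy()] = sub["mean_intensity"].to_numpy() / m
    out["normalized"] = normalized
    return out


def ascending_profile(measurements: pd.DataFrame, channel: str, compartment: str,
                      condition: str, value: str = "normalized") -> np.ndarray:
    """Single-cell values of one condition sorted ascending (stable for ties)."""
    sel = measurements[(measurements["channel"] == channel)
                       & (measurements["compartment"] == compartment)
                       & (measurements["condition"] == condition)]
    vals = sel[value].to_numpy(dtype=float)
    return vals[np.argsort(vals, kind="stable")]


def condition_summary(measurements: pd.DataFrame, value: str = "normalized",
                      unit: str = "replicate",
                      min_cells: int = 35) -> pd.DataFrame:
    """Mean and SEM per condition × channel × compartment.

    ``unit="replicate"`` (default) first averages cells within each
    replicate, then reports mean and SEM across replicates (n =
    experiments); ``unit="cell"`` pools all cells.  SEM is NaN with
    ``sem_defined = False`` when only one unit remains.  Conditions with
    fewer cells than ``min_cells`` are flagged, with a warning.
    """
    if unit not in ("replicate", "cell"):
        raise ValueError("unit must be 'replicate' or 'cell'")
    group_cols = ["condition", "channel", "compartment"]
    if unit == "replicate":
        per_rep = measurements.groupby(group_cols + ["replicate"]
                                       )[value].mean().reset_index()
        g = per_rep.groupby(group_cols)[value]
    else:
        g = measurements.groupby(group_cols)[value]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out["sem_defined"] = out["n"] >= 2
    out.loc[~out["sem_defined"], "sem"] = np.nan
    cells = measurements.groupby(group_cols)["cell_id"].count().rename("n_cells")
    out = out.merge(cells.reset_index(), on=group_cols, how="left")
    out["below_min_cells"] = out["n_cells"] < min_cells
    low = out[out["below_min_cells"]]
    if len(low):
        logger.warning("%d condition cells below the %d-cell minimum",
                       len(low), min_cells)
    return out.drop(columns="sd")


def nc_condition_means(nc_table: pd.DataFrame, unit: str = "cell",
                       ratio_of_means: bool = False,
                       measurements: pd.DataFrame | None = None) -> pd.DataFrame:
    """Condition-level N/C ratio per channel.

    Default: average of per-cell ratios (undefined ratios excluded).
    ``ratio_of_means=True`` instead divides the condition-mean nuclear
    intensity by the condition-mean cytoplasmic intensity (requires the
    measurement table).
    """
    if ratio_of_means:
        if measurements is None:
            raise ValueError("ratio_of_means requires the measurement table")
        m = measurements.pivot_table(index=["condition", "channel"],
                                     columns="compartment",
                                     values="mean_intensity", aggfunc="mean")
        out = (m[NUCLEUS] / m[CYTOPLASM]).rename("nc_ratio").reset_index()
        out["n"] = measurements.groupby(["condition", "channel"]
                                        )["cell_id"].nunique().to_numpy()
        return out
    ok = nc_table[nc_table["nc_defined"]]
    group = ["condition", "channel"] + (["replicate"] if unit == "replicate" else [])
    out = ok.groupby(group)["nc_ratio"].agg(["mean", "count"]).reset_index()
    return out.rename(columns={"mean": "nc_ratio", "count": "n"})
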