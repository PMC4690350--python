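"""Asymmetric percent-area colocalization of the two protein channels.

Both channels are binarized with one frozen threshold per channel (chosen
once from control fields and maintained across all conditions).  For each
cell and compartment ROI the thresholded areas, the shared pixel count,
and the two directional percentages (A-in-B: share of channel-A-positive
area that is also B-positive, and vice versa) are recorded.  Percentages
with a zero denominator are flagged undefined and excluded from condition
means rather than set to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .containers import CYTOPLASM, NUCLEUS, CompartmentMasks

logger = logging.getLogger(__name__)

COLOC_COMPARTMENTS = (NUCLEUS, CYTOPLASM)


@dataclass
class ColocalizationRecord:
    """Thresholded overlap of one cell × compartment.

    ``pct_a_in_b`` = 100·shared/area_a (share of A-positive pixels that
    are also B-positive); ``pct_b_in_a`` analogous.  The integer identity
    pct_a_in_b·area_a = pct_b_in_a·area_b = 100·shared holds by
    construction.
    """

    field_id: str
    cell_id: int
    condition: str
    replicate: str
    compartment: str
    area_a: int
    area_b: int
    shared: int
    pct_a_in_b: float | None
    pct_b_in_a: float | None
    pixel_area: float

    def as_row(self) -> dict:
        d = self.__dict__.copy()
        d["pct_a_in_b"] = np.nan if self.pct_a_in_b is None else self.pct_a_in_b
        d["pct_b_in_a"] = np.nan if self.pct_b_in_a is None else self.pct_b_in_a
        d["pct_a_defined"] = self.pct_a_in_b is not None
        d["pct_b_defined"] = self.pct_b_in_a is not None
        return d


def threshold_channel(image: np.ndarray, threshold: float) -> np.ndarray:
    """Strict binarization: ``image > threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be ≥ 0")
    return np.asarray(image, dtype=float) > threshold


def fix_thresholds(control_pixels: dict[str, np.ndarray], method: str = "otsu",
                   values: dict[str, float] | None = None,
                   percentile: float = 99.0) -> dict[str, float]:
    """One frozen scalar threshold per protein channel from pooled control pixels.

    ``control_pixels`` maps channel → pooled 1D pixel array from the
    control fields (background-corrected).  Methods: ``otsu`` (default),
    ``fixed`` (pass-through of ``values``), ``percentile``.
    """
    out: dict[str, float] = {}
    for ch, pool in control_pixels.items():
        if method == "fixed":
            if values is None or ch not in values:
                raise ValueError(f"fixed method needs a value for channel {ch}")
            out[ch] = float(values[ch])
            continue
        pool = np.asarray(pool, dtype=float).reshape(-1)
        if pool.size == 0 or pool.max() == pool.min():
            raise ValueError(f"channel {ch}: constant-intensity pixel pool, "
                             "cannot derive a threshold")
        if method == "otsu":
            out[ch] = float(threshold_otsu(pool))
        elif method == "percentile":
            out[ch] = float(np.percentile(pool, percentile))
        else:
            raise ValueError(f"unknown threshold method {method!r}")
    return out


def coloc_per_cell(mask_a: np.ndarray, mask_b: np.ndarray,
                   masks: CompartmentMasks, cell_id: int,
                   condition: str = "", replicate: str = "", field_id: str = "",
                   pixel_area: float = 0.14) -> list[ColocalizationRecord]:
    """Nucleus and cytoplasm colocalization records for one cell.

    ``mask_a``/``mask_b`` are the already-thresholded binary channel
    masks.  Counting is restricted to the compartment ROI; the nuclear
    ROI includes nucleolar pixels.
    """
    if cell_id not in masks.cell_ids:
        raise KeyError(f"unknown cell id {cell_id}")
    records = []
    for comp in COLOC_COMPARTMENTS:
        roi = masks.compartment_mask(cell_id, comp)
        a = int(np.count_nonzero(mask_a & roi))
        b = int(np.count_nonzero(mask_b & roi))
        shared = int(np.count_nonzero(mask_a & mask_b & roi))
        records.append(ColocalizationRecord(
            field_id=field_id, cell_id=cell_id, condition=condition,
            replicate=replicate, compartment=comp, area_a=a, area_b=b,
            shared=shared,
            pct_a_in_b=100.0 * shared / a if a else None,
            pct_b_in_a=100.0 * shared / b if b else None,
            pixel_area=pixel_area))
    return records


def records_table(records: list[ColocalizationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records])


def coloc_condition_summary(records: pd.DataFrame, min_cells: int = 10,
                            control_condition: str | None = None) -> pd.DataFrame:
    """Mean ± SEM per condition × compartment × direction, plus significance.

    Undefined percentages are excluded from the means; the count of
    excluded cells is reported.  When ``control_condition`` is given,
    one-way ANOVA across conditions and Bonferroni-adjusted pairwise
    t-tests vs control are appended per compartment × direction (delegated
    to the stats layer).  Conditions with fewer than ``min_cells`` defined
    cells are flagged.
    """
    from . import stats as cstats

    rows = []
    for (comp, direction, flag) in ((c, d, f) for c in COLOC_COMPARTMENTS
                                    for d, f in (("pct_a_in_b", "pct_a_defined"),
                                                 ("pct_b_in_a", "pct_b_defined"))):
        sub = records[records["compartment"] == comp]
        groups: dict[str, np.ndarray] = {}
        for cond, g in sub.groupby("condition", sort=False):
            vals = g.loc[g[flag], direction].to_numpy(dtype=float)
            groups[cond] = vals
            n = vals.size
            rows.append({
                "compartment": comp, "direction": direction, "condition": cond,
                "mean": vals.mean() if n else np.nan,
                "sem": vals.std(ddof=1) / np.sqrt(n) if n >= 2 else np.nan,
                "n_cells": n,
                "n_undefined": int((~g[flag]).sum()),
                "below_min_cells": n < min_cells,
            })
        if control_condition is not None and control_condition in groups:
            usable = {c: v for c, v in groups.items() if v.size >= 2}
            if len(usable) >= 2 and control_condition in usable:
                adj = cstats.bonferroni_vs_control(usable, control_condition)
                for r in rows:
                    if r["compartment"] == comp and r["direction"] == direction:
                        r["p_adj_vs_control"] = adj.get(r["condition"], np.nan)
    out = pd.DataFrame(rows)
    n_excl = int(out["n_undefined"].sum()) if len(out) else 0
    if n_excl:
        logger.info("%d undefined percentages excluded from condition means", n_excl)
    return out
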