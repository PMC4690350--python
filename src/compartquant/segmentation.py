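"""Compartment demarcation: background, nuclei, nucleoli, cytoplasm.

The DNA stain defines nuclei (global Otsu threshold, hole filling,
minimum-area filter, optional distance-transform watershed to split
touching nuclei) and nucleoli (dark holes: smoothed pixels below a
fraction of the median nuclear DNA-stain intensity).  The cytoplasm of
each cell is demarcated either by a marker-based watershed of a
summed-protein-channel cell mask seeded at the nuclei (default) or by a
fixed-width annulus around the nucleus.  A one-pixel guard ring between
nucleus and cytoplasm avoids edge bleed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk, opening
from skimage.segmentation import clear_border, watershed

from .config import SegmentationParams
from .containers import (CHANNEL_A, CHANNEL_B, COMPARTMENTS, CompartmentMasks,
                         FieldImage, PROTEIN_CHANNELS)

logger = logging.getLogger(__name__)


class NoBackgroundRegionError(RuntimeError):
    """No cell-free pixels available — select a manual background ROI instead."""


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def estimate_background(image: np.ndarray, exclusion_mask: np.ndarray,
                        min_free_fraction: float = 0.01) -> float:
    """Mean intensity over pixels outside the (dilated) cell exclusion mask.

    Raises :class:`NoBackgroundRegionError` when fewer than
    ``min_free_fraction`` of the pixels are cell-free.
    """
    free = ~np.asarray(exclusion_mask, dtype=bool)
    if free.sum() < min_free_fraction * free.size:
        raise NoBackgroundRegionError(
            "fewer than {:.0%} cell-free pixels; provide a manual background ROI"
            .format(min_free_fraction))
    return float(np.asarray(image, dtype=float)[free].mean())


def correct_background(image: np.ndarray, background: float) -> np.ndarray:
    """Subtract a scalar background, clamping at zero."""
    if background < 0:
        raise ValueError("background must be ≥ 0")
    return np.maximum(np.asarray(image, dtype=float) - background, 0.0)


def auto_exclusion_mask(field: FieldImage, dilation_radius: int = 5) -> np.ndarray:
    """Heuristic cell mask (union of Otsu masks of all channels), dilated.

    Used to find a region devoid of cells for background estimation.
    """
    union = np.zeros(field.shape, dtype=bool)
    for arr in field.channels.values():
        arr = np.asarray(arr, dtype=float)
        if arr.max() > arr.min():
            union |= arr > threshold_otsu(arr)
    return dilation(union, disk(dilation_radius))


# ---------------------------------------------------------------------------
# nuclei
# ---------------------------------------------------------------------------

def segment_nuclei(dna_stain: np.ndarray, params: SegmentationParams | None = None
                   ) -> tuple[np.ndarray, set[int]]:
    """Label nuclei in the DNA-stain channel.

    Returns the label image and the set of IDs removed for touching the
    image border.  A blank (or sub-threshold) image yields zero labels
    with a warning, not an error.
    """
    params = params or SegmentationParams()
    dna = np.asarray(dna_stain, dtype=float)
    if dna.max() == dna.min():
        logger.warning("constant DNA-stain image: no nuclei segmented")
        return np.zeros(dna.shape, dtype=np.int32), set()
    thr = params.nuclear_threshold
    if thr is None:
        thr = threshold_otsu(dna)
    mask = dna > thr
    mask = ndi.binary_fill_holes(mask)
    labels = cc_label(mask)
    if params.split_touching_nuclei and labels.max() > 0:
        dist = ndi.distance_transform_edt(mask)
        smooth_dist = gaussian(dist, sigma=2.0)
        peaks = _distance_peaks(smooth_dist, mask)
        if peaks.max() > 0:
            labels = watershed(-smooth_dist, peaks, mask=mask)
    labels = _filter_small(labels, params.min_nucleus_area)
    border_excluded: set[int] = set()
    if params.exclude_border:
        kept = clear_border(labels)
        border_excluded = set(np.unique(labels[labels != kept]).tolist()) - {0}
        labels = kept
    labels, _ = _relabel_sequential(labels)
    if labels.max() == 0:
        logger.warning("no nuclei found above threshold %.3g", thr)
    return labels.astype(np.int32), border_excluded


def _distance_peaks(distance: np.ndarray, mask: np.ndarray,
                    rel_height: float = 0.6) -> np.ndarray:
    """Marker image from high-distance cores of each connected component.

    Each blob of pixels above ``rel_height`` × the component's distance
    maximum becomes one marker: an isolated convex nucleus keeps a single
    marker (level sets of its distance transform are connected), while two
    touching nuclei contribute one core each and get split.
    """
    comps = cc_label(mask)
    markers = np.zeros(distance.shape, dtype=np.int32)
    next_id = 1
    for cid in range(1, comps.max() + 1):
        region = comps == cid
        core = region & (distance > rel_height * distance[region].max())
        blobs = cc_label(core)
        for k in range(1, blobs.max() + 1):
            markers[blobs == k] = next_id
            next_id += 1
    return markers


def _filter_small(labels: np.ndarray, min_area: int) -> np.ndarray:
    if labels.max() == 0:
        return labels
    counts = np.bincount(labels.reshape(-1))
    small = np.flatnonzero(counts < min_area)
    out = labels.copy()
    out[np.isin(out, small[small > 0])] = 0
    return out


def _relabel_sequential(labels: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    ids = [i for i in np.unique(labels) if i > 0]
    mapping = {old: new for new, old in enumerate(ids, start=1)}
    out = np.zeros_like(labels)
    for old, new in mapping.items():
        out[labels == old] = new
    return out, mapping


# ---------------------------------------------------------------------------
# nucleoli
# ---------------------------------------------------------------------------

def segment_nucleoli(dna_stain: np.ndarray, nucleus_labels: np.ndarray,
                     params: SegmentationParams | None = None) -> np.ndarray:
    """Dark holes within each nucleus, labeled with the parent cell ID.

    Within nucleus *i*, candidate pixels are those whose smoothed
    DNA-stain intensity falls below ``dark_fraction`` × the median
    nuclear intensity; a morphological opening and minimum-area filter
    remove speckle.  Nuclei without qualifying holes legitimately yield
    nothing.
    """
    params = params or SegmentationParams()
    dna = np.asarray(dna_stain, dtype=float)
    smoothed = gaussian(dna, sigma=params.nucleolus_smooth_sigma,
                        preserve_range=True)
    out = np.zeros(dna.shape, dtype=np.int32)
    for cid in np.unique(nucleus_labels):
        if cid == 0:
            continue
        region = nucleus_labels == cid
        cutoff = params.dark_fraction * np.median(dna[region])
        # robust cores on the smoothed image; full extent reconstructed from
        # raw sub-cutoff pixels so hole boundaries are not eroded by the blur
        core = opening(region & (smoothed < cutoff), disk(1))
        candidates = region & (dna < cutoff)
        comp = cc_label(candidates)
        counts = np.bincount(comp.reshape(-1))
        touched = np.unique(comp[core])
        for k in touched:
            if k > 0 and counts[k] >= params.min_nucleolus_area:
                out[comp == k] = cid
    return out


# ---------------------------------------------------------------------------
# cytoplasm / whole cell
# ---------------------------------------------------------------------------

def segment_cytoplasm(field: FieldImage, nucleus_labels: np.ndarray,
                      params: SegmentationParams | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Whole-cell and cytoplasm label images sharing the nucleus IDs.

    Default (watershed) strategy: the cell mask is an Otsu threshold of
    the summed protein channels; cells are assigned to nuclei by a
    watershed seeded at the nuclei.  Cytoplasm = cell minus the nucleus
    dilated by ``guard_ring``.  Cells whose mask fails to cover their
    nucleus are dropped with a warning.  The alternative strategy labels
    a fixed-width annulus around each nucleus.
    """
    params = params or SegmentationParams()
    if params.cytoplasm_strategy == "annulus":
        return _annulus_cells(nucleus_labels, params)
    summed = sum(np.asarray(field[ch], dtype=float) for ch in PROTEIN_CHANNELS
                 if ch in field.channels)
    thr = params.cell_threshold
    if thr is None:
        # Otsu on the log-compressed histogram: robust against a bright
        # minority mode (puncta) that would otherwise pull the threshold
        # above the diffuse cytoplasmic signal
        if summed.max() > summed.min():
            thr = float(np.expm1(threshold_otsu(np.log1p(summed))))
        else:
            thr = np.inf
    cell_mask = (summed > thr) | (nucleus_labels > 0)
    cell_mask = ndi.binary_fill_holes(cell_mask)
    dist = ndi.distance_transform_edt(~(nucleus_labels > 0))
    cell_labels = watershed(dist, nucleus_labels, mask=cell_mask)
    dropped = []
    for cid in np.unique(nucleus_labels):
        if cid == 0:
            continue
        nuc = nucleus_labels == cid
        if not np.any((cell_labels == cid) & nuc):
            dropped.append(int(cid))
    if dropped:
        logger.warning("cell mask does not cover nuclei %s; cells dropped", dropped)
        cell_labels[np.isin(cell_labels, dropped)] = 0
    cytoplasm = _carve_cytoplasm(cell_labels, nucleus_labels, params.guard_ring)
    return cell_labels.astype(np.int32), cytoplasm


def _carve_cytoplasm(cell_labels, nucleus_labels, guard_ring: int) -> np.ndarray:
    guard = nucleus_labels > 0
    if guard_ring > 0:
        guard = dilation(guard, disk(guard_ring))
    cyt = np.where(guard, 0, cell_labels)
    # pixels of cell i overlapping any other nucleus guard stay 0; ensure
    # cytoplasm label matches its own cell id only
    return cyt.astype(np.int32)


def _annulus_cells(nucleus_labels, params) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-width ring around each nucleus; nearest nucleus wins contested px."""
    nuc = nucleus_labels > 0
    dist, (iy, ix) = ndi.distance_transform_edt(~nuc, return_indices=True)
    owner = nucleus_labels[iy, ix]
    ring = (dist > params.guard_ring) & (dist <= params.guard_ring + params.annulus_width)
    cytoplasm = np.where(ring, owner, 0).astype(np.int32)
    cell = np.where(nuc, nucleus_labels, cytoplasm).astype(np.int32)
    return cell, cytoplasm


# ---------------------------------------------------------------------------
# whole-field convenience
# ---------------------------------------------------------------------------

def segment_field(field: FieldImage, params: SegmentationParams | None = None,
                  background: dict[str, float] | None = None
                  ) -> tuple[FieldImage, CompartmentMasks, dict[str, float]]:
    """Background-correct and fully demarcate one field.

    Returns the corrected field, its :class:`CompartmentMasks`, and the
    per-channel background estimates used.
    """
    from .containers import DNA

    params = params or SegmentationParams()
    if background is None:
        exclusion = auto_exclusion_mask(field)
        background = {ch: estimate_background(field[ch], exclusion)
                      for ch in field.channels}
    corrected = FieldImage({ch: correct_background(field[ch], background[ch])
                            for ch in field.channels},
                           pixel_area=field.pixel_area, condition=field.condition,
                           replicate=field.replicate, field_id=field.field_id)
    nucleus_labels, border_excluded = segment_nuclei(corrected[DNA], params)
    nucleolus_labels = segment_nucleoli(corrected[DNA], nucleus_labels, params)
    cell_labels, cytoplasm_labels = segment_cytoplasm(corrected, nucleus_labels,
                                                      params)
    # drop nuclei whose cell vanished
    kept = set(np.unique(cell_labels).tolist()) - {0}
    for arr in (nucleus_labels, nucleolus_labels, cytoplasm_labels):
        arr[~np.isin(arr, list(kept) + [0])] = 0
    masks = CompartmentMasks(cell_labels, nucleus_labels, nucleolus_labels,
                             cytoplasm_labels, border_excluded=border_excluded)
    return corrected, masks, background


def segmentation_qc_table(field: FieldImage, masks: CompartmentMasks) -> pd.DataFrame:
    """Per-cell areas (px and µm²) per compartment for QC."""
    rows = []
    for cid in masks.cell_ids:
        entry = {"field_id": field.field_id, "cell_id": cid,
                 "condition": field.condition, "replicate": field.replicate}
        for comp in COMPARTMENTS:
            area = int(masks.compartment_mask(cid, comp).sum())
            entry[f"{comp}_area_px"] = area
            entry[f"{comp}_area_um2"] = area * field.pixel_area
        rows.append(entry)
    return pd.DataFrame(rows)
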