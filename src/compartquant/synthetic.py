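"""Synthetic multi-channel fluorescence fields with recoverable ground truth.

The generator renders populations of elliptical cells: a bright nucleus in
the DNA-stain channel with darker nucleolar disks inside it, and two
protein channels whose diffuse per-compartment means follow a per-condition
intensity table modulated by per-cell brightness factors.  Cross-cell
correlation between the two protein channels is injected through a shared
standard-normal latent factor mixed at weight √ρ, and pixel-level
colocalization through "puncta" pixel sets with a controlled B-in-A
overlap fraction.  Every stochastic choice flows from one seed, so a
(config, condition, seed) triple maps to bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .containers import (CHANNEL_A, CHANNEL_B, COMPARTMENTS, CYTOPLASM, DNA,
                         NUCLEOLUS, NUCLEUS, PROTEIN_CHANNELS, CompartmentMasks,
                         FieldImage)

logger = logging.getLogger(__name__)

MAX_PLACEMENT_TRIES_PER_CELL = 400


class FieldTooCrowdedError(RuntimeError):
    """Raised when non-overlapping cell placement fails within the retry budget."""


class ColocalizationInfeasibleError(ValueError):
    """Raised when a compartment cannot host the requested puncta sets."""


@dataclass
class CellGeometry:
    """Axis-aligned elliptical cell: outline, nucleus, and nucleolar disks."""

    cell_id: int
    center: tuple[float, float]                  # (row, col)
    cell_axes: tuple[float, float]               # half-axes (row, col)
    nucleus_axes: tuple[float, float]
    nucleoli: list[tuple[float, float, float]]   # (row, col, radius)


@dataclass
class GroundTruth:
    """Everything the generator knows: masks, true means, realized parameters."""

    masks: CompartmentMasks
    true_means: pd.DataFrame          # cell_id, channel, compartment, true_mean, area_px
    brightness_factors: pd.DataFrame  # cell_id, channel, compartment, factor
    realized_rho: dict[str, float]
    realized_coloc: dict[str, float]
    config: SimulationConfig
    condition: str
    seed: int
    saturated: bool = False
    geometries: list[CellGeometry] = dc_field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float]) -> tuple[slice, slice, np.ndarray]:
    """Boolean ellipse restricted to its bounding box (returned as slices)."""
    cy, cx = center
    ry, rx = axes
    y0, y1 = max(int(np.floor(cy - ry)), 0), min(int(np.ceil(cy + ry)) + 1, shape[0])
    x0, x1 = max(int(np.floor(cx - rx)), 0), min(int(np.ceil(cx + rx)) + 1, shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return slice(y0, y1), slice(x0, x1), inside


def place_cells(config: SimulationConfig, rng: np.random.Generator) -> list[CellGeometry]:
    """Sequentially place non-overlapping cells fully inside the field.

    Overlap is tested conservatively on bounding circles with a 2 px margin.
    Raises :class:`FieldTooCrowdedError` if a cell cannot be placed within
    the per-cell retry budget.
    """
    H, W = config.field_size
    margin = 2.0
    placed: list[CellGeometry] = []
    radii: list[float] = []
    for cid in range(1, config.n_cells + 1):
        cell_axes = tuple(rng.uniform(*config.cytoplasm_radius_range, size=2))
        nucleus_axes = tuple(rng.uniform(*config.nucleus_radius_range, size=2))
        # keep the nucleus strictly inside the cell outline
        nucleus_axes = tuple(min(na, ca - 2.0) for na, ca in zip(nucleus_axes, cell_axes))
        r_bound = max(cell_axes)
        for _ in range(MAX_PLACEMENT_TRIES_PER_CELL):
            cy = rng.uniform(r_bound + margin, H - r_bound - margin)
            cx = rng.uniform(r_bound + margin, W - r_bound - margin)
            ok = True
            for geo, r_other in zip(placed, radii):
                dy, dx = cy - geo.center[0], cx - geo.center[1]
                if dy * dy + dx * dx < (r_bound + r_other + margin) ** 2:
                    ok = False
                    break
            if ok:
                break
        else:
            raise FieldTooCrowdedError(
                f"could not place cell {cid}/{config.n_cells} in a "
                f"{H}x{W} field after {MAX_PLACEMENT_TRIES_PER_CELL} tries")
        n_nlo = int(rng.integers(config.n_nucleoli_range[0],
                                 config.n_nucleoli_range[1] + 1))
        nucleoli = _place_nucleoli(rng, (cy, cx), nucleus_axes, n_nlo,
                                   config.nucleolus_radius_range)
        placed.append(CellGeometry(cid, (cy, cx), cell_axes, nucleus_axes, nucleoli))
        radii.append(r_bound)
    return placed


def _place_nucleoli(rng, center, nucleus_axes, n, radius_range,
                    margin: float = 2.0) -> list[tuple[float, float, float]]:
    """Disjoint nucleolar disks inside the nucleus, kept off the nuclear rim."""
    out: list[tuple[float, float, float]] = []
    cy, cx = center
    ry, rx = nucleus_axes
    for _ in range(n):
        r = rng.uniform(*radius_range)
        for _ in range(60):
            # sample inside the shrunken ellipse that keeps the disk + margin inside
            ey, ex = ry - r - margin, rx - r - margin
            if ey <= 0 or ex <= 0:
                break
            t = rng.uniform(0, 2 * np.pi)
            u = np.sqrt(rng.uniform())
            py, px = cy + u * ey * np.sin(t), cx + u * ex * np.cos(t)
            if all((py - oy) ** 2 + (px - ox) ** 2 >= (r + orr + 1.0) ** 2
                   for oy, ox, orr in out):
                out.append((float(py), float(px), float(r)))
                break
    return out


# ---------------------------------------------------------------------------
# per-cell brightness factors
# ---------------------------------------------------------------------------

def sample_brightness_factors(config: SimulationConfig, condition: str,
                              n_cells: int, rng: np.random.Generator
                              ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-cell multiplicative brightness factors with latent A/B correlation.

    For each compartment k, factor_c = 1 + cv·(√ρ_k·z₀ + √(1−ρ_k)·z_c)
    with z₀, z_A, z_B iid N(0,1) per cell (the shared-latent sign is
    flipped for channel B when ρ_k < 0).  corr(factor_A, factor_B) = ρ_k
    by construction; factors are floored at 0.05 to keep intensities
    non-negative.

    Returns the long factor table and the realized per-compartment sample
    correlation of the factors.
    """
    rows = []
    realized: dict[str, float] = {}
    for comp in COMPARTMENTS:
        rho = config.rho(condition, comp)
        z0 = rng.standard_normal(n_cells)
        za = rng.standard_normal(n_cells)
        zb = rng.standard_normal(n_cells)
        w = np.sqrt(abs(rho))
        la = w * z0 + np.sqrt(1 - abs(rho)) * za
        lb = np.sign(rho) * w * z0 + np.sqrt(1 - abs(rho)) * zb if rho != 0 else zb
        fa = np.maximum(1.0 + config.cell_cv * la, 0.05)
        fb = np.maximum(1.0 + config.cell_cv * lb, 0.05)
        if n_cells >= 2 and fa.std() > 0 and fb.std() > 0:
            realized[comp] = float(np.corrcoef(fa, fb)[0, 1])
        else:
            realized[comp] = float("nan")
        for cid in range(n_cells):
            rows.append((cid + 1, CHANNEL_A, comp, fa[cid]))
            rows.append((cid + 1, CHANNEL_B, comp, fb[cid]))
    table = pd.DataFrame(rows, columns=["cell_id", "channel", "compartment", "factor"])
    return table, realized


# ---------------------------------------------------------------------------
# colocalization embedding
# ---------------------------------------------------------------------------

def embed_colocalization(pool: np.ndarray, n_a: int, n_b: int, fraction: float,
                         rng: np.random.Generator, compartment: str = "?"
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Draw puncta pixel index sets A and B with |A∩B| = round(fraction·|B|).

    ``pool`` is a flat array of candidate pixel indices; positions are
    uniform within it.  Raises :class:`ColocalizationInfeasibleError` when
    the pool cannot host both sets at the requested overlap.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    n_pool = pool.size
    shared = int(np.floor(fraction * n_b + 0.5))
    if n_b > n_pool or shared > n_a or n_a - shared > n_pool - n_b:
        raise ColocalizationInfeasibleError(
            f"compartment {compartment}: pool of {n_pool} px cannot host "
            f"|A|={n_a}, |B|={n_b} at overlap fraction {fraction}")
    b_idx = rng.choice(pool, size=n_b, replace=False)
    shared_idx = rng.choice(b_idx, size=shared, replace=False) if shared else \
        np.empty(0, dtype=pool.dtype)
    rest_pool = np.setdiff1d(pool, b_idx, assume_unique=False)
    extra = rng.choice(rest_pool, size=n_a - shared, replace=False) if n_a > shared \
        else np.empty(0, dtype=pool.dtype)
    a_idx = np.concatenate([shared_idx, extra])
    return a_idx, b_idx


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _render_masks(config: SimulationConfig,
                  geometries: list[CellGeometry]) -> CompartmentMasks:
    H, W = config.field_size
    cell = np.zeros((H, W), dtype=np.int32)
    nucleus = np.zeros_like(cell)
    nucleolus = np.zeros_like(cell)
    for geo in geometries:
        ys, xs, m = _ellipse_mask((H, W), geo.center, geo.cell_axes)
        cell[ys, xs][m] = geo.cell_id
        ys, xs, m = _ellipse_mask((H, W), geo.center, geo.nucleus_axes)
        nucleus[ys, xs][m] = geo.cell_id
        for (py, px, r) in geo.nucleoli:
            ys, xs, m = _ellipse_mask((H, W), (py, px), (r, r))
            nucleolus[ys, xs][m] = geo.cell_id
    cytoplasm = np.where((cell > 0) & (nucleus == 0), cell, 0)
    return CompartmentMasks(cell, nucleus, nucleolus, cytoplasm)


def generate_field(config: SimulationConfig, condition: str,
                   seed: int | None = None) -> tuple[FieldImage, GroundTruth]:
    """Render one field for ``condition`` and return it with its ground truth.

    The noiseless, background-free signal defines the per-cell true
    compartment means recorded in the ground truth; the background level
    is then added everywhere and noise applied last.
    """
    if condition not in config.intensity_model:
        raise KeyError(f"condition {condition!r} has no intensity table; "
                       f"known: {list(config.conditions)}")
    if seed is None:
        seed = config.seed
    cond_index = list(config.conditions).index(condition)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), cond_index]))

    geometries = place_cells(config, rng)
    masks = _render_masks(config, geometries)
    factors, realized_rho = sample_brightness_factors(
        config, condition, len(geometries), rng)
    fac = {(r.cell_id, r.channel, r.compartment): r.factor
           for r in factors.itertuples()}

    H, W = config.field_size
    table = config.intensity_model[condition]
    images = {DNA: np.zeros((H, W)), CHANNEL_A: np.zeros((H, W)),
              CHANNEL_B: np.zeros((H, W))}

    for geo in geometries:
        cid = geo.cell_id
        regions = {
            CYTOPLASM: masks.cytoplasm_labels == cid,
            NUCLEUS: (masks.nucleus_labels == cid) & (masks.nucleolus_labels != cid),
            NUCLEOLUS: masks.nucleolus_labels == cid,
        }
        for ch in PROTEIN_CHANNELS:
            for comp, region in regions.items():
                images[ch][region] = table[ch][comp] * fac[(cid, ch, comp)]
        images[DNA][masks.nucleus_labels == cid] = config.dna_nucleus_intensity
        images[DNA][regions[NUCLEOLUS]] = (config.dna_nucleus_intensity *
                                           config.dna_nucleolus_factor)

    realized_coloc = _embed_all_puncta(config, condition, masks, images, rng)

    true_means = _true_mean_table(images, masks, config.pixel_area)

    noise_sd = config.effective_noise_sd
    saturated = False
    out_channels: dict[str, np.ndarray] = {}
    for ch, img in images.items():
        sig = img + config.background_level
        if config.poisson_noise:
            sig = rng.poisson(np.maximum(sig, 0)).astype(float)
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)
        if sig.max() > 65535:
            saturated = True
        out_channels[ch] = np.clip(sig, 0.0, 65535.0)

    field = FieldImage(out_channels, pixel_area=config.pixel_area,
                       condition=condition, field_id=condition)
    truth = GroundTruth(masks=masks, true_means=true_means,
                        brightness_factors=factors, realized_rho=realized_rho,
                        realized_coloc=realized_coloc, config=config,
                        condition=condition, seed=int(seed),
                        saturated=saturated, geometries=geometries)
    return field, truth


def _embed_all_puncta(config, condition, masks, images, rng) -> dict[str, float]:
    """Overwrite puncta pixels in both protein channels; return realized B-in-A."""
    realized: dict[str, float] = {}
    if config.coloc_fractions is None:
        return realized
    flat = {ch: images[ch].reshape(-1) for ch in PROTEIN_CHANNELS}
    for comp in (NUCLEUS, CYTOPLASM):
        f = config.coloc_fraction(condition, comp)
        if f is None:
            continue
        total_shared = total_b = 0
        for cid in masks.cell_ids:
            # nuclear puncta pool includes nucleolar pixels (whole DNA-defined nucleus)
            roi = masks.compartment_mask(cid, comp)
            pool = np.flatnonzero(roi.reshape(-1))
            n = int(np.floor(config.puncta_density * pool.size + 0.5))
            if n == 0:
                continue
            a_idx, b_idx = embed_colocalization(pool, n, n, f, rng, comp)
            for ch, idx in ((CHANNEL_A, a_idx), (CHANNEL_B, b_idx)):
                flat[ch][idx] = config.puncta_intensity
            total_shared += np.intersect1d(a_idx, b_idx).size
            total_b += b_idx.size
        realized[comp] = total_shared / total_b if total_b else float("nan")
    return realized


def _true_mean_table(images, masks, pixel_area) -> pd.DataFrame:
    rows = []
    for cid in masks.cell_ids:
        for comp in COMPARTMENTS:
            region = masks.compartment_mask(cid, comp)
            area = int(region.sum())
            for ch in PROTEIN_CHANNELS:
                mean = float(images[ch][region].mean()) if area else float("nan")
                rows.append((cid, ch, comp, mean, area, area * pixel_area))
    return pd.DataFrame(rows, columns=["cell_id", "channel", "compartment",
                                       "true_mean", "area_px", "area_um2"])


def puncta_midpoint_threshold(config: SimulationConfig) -> float:
    """Threshold halfway between the brightest diffuse mean and the puncta level.

    On background-corrected synthetic images this separates puncta pixels
    from diffuse compartment signal in every condition, which a pooled
    Otsu (dominated by the cell-free background mode) cannot do.
    """
    return 0.5 * (config.max_protein_mean + config.puncta_intensity)


# ---------------------------------------------------------------------------
# experiment writer
# ---------------------------------------------------------------------------

def replicate_seed(master_seed: int, replicate: int, cond_index: int) -> int:
    """Deterministic, well-separated per-field seed below 2³¹."""
    ss = np.random.SeedSequence([int(master_seed), int(replicate), int(cond_index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_experiment(config: SimulationConfig, outdir: str | Path,
                        conditions: tuple[str, ...] | None = None,
                        n_replicates: int = 3,
                        master_seed: int | None = None) -> Path:
    """Write a full multi-condition, multi-replicate synthetic experiment.

    Produces one TIFF per channel per field, 16-bit label-mask TIFFs, a
    per-cell ground-truth CSV, a realized-parameter CSV, a manifest CSV
    (one row per field × channel) and a YAML echo of the config.  Returns
    the manifest path.
    """
    from . import io as cqio  # local import: io depends on containers only

    if conditions is None:
        conditions = config.conditions
    if len(conditions) < 1 or n_replicates < 1:
        raise ValueError("need ≥1 condition and ≥1 replicate")
    if master_seed is None:
        master_seed = config.seed
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)

    manifest_rows, truth_tables, param_rows = [], [], []
    for ri in range(1, n_replicates + 1):
        for ci, cond in enumerate(conditions):
            seed = replicate_seed(master_seed, ri, ci)
            field, truth = generate_field(config, cond, seed=seed)
            field_id = f"{cond}_rep{ri}"
            field.field_id = field_id
            field.replicate = f"rep{ri}"
            for ch in (DNA, CHANNEL_A, CHANNEL_B):
                path = outdir / "images" / f"{field_id}_{ch}.tif"
                cqio.write_image(path, field[ch])
                manifest_rows.append((field_id, cond, f"rep{ri}", ch,
                                      str(path.relative_to(outdir))))
            cqio.write_masks(outdir / "truth", field_id, truth.masks)
            tm = truth.true_means.copy()
            tm.insert(0, "field_id", field_id)
            tm.insert(1, "condition", cond)
            tm.insert(2, "replicate", f"rep{ri}")
            truth_tables.append(tm)
            for comp, rho in truth.realized_rho.items():
                param_rows.append((field_id, cond, f"rep{ri}", "rho", comp, rho))
            for comp, fk in truth.realized_coloc.items():
                param_rows.append((field_id, cond, f"rep{ri}", "coloc_fraction",
                                   comp, fk))
            param_rows.append((field_id, cond, f"rep{ri}", "seed", "", seed))

    manifest = pd.DataFrame(manifest_rows, columns=["field_id", "condition",
                                                    "replicate", "channel", "path"])
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    pd.concat(truth_tables, ignore_index=True).to_csv(
        outdir / "truth" / "ground_truth.csv", index=False)
    pd.DataFrame(param_rows, columns=["field_id", "condition", "replicate",
                                      "parameter", "compartment", "value"]
                 ).to_csv(outdir / "truth" / "ground_truth_params.csv", index=False)
    config_echo = dict(config.to_dict(), master_seed=int(master_seed),
                       n_replicates=n_replicates, conditions=list(conditions))
    with open(outdir / "config.yaml", "w") as fh:
        import yaml
        yaml.safe_dump(config_echo, fh, sort_keys=True)
    return manifest_path
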