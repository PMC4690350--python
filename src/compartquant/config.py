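"""Simulation and run configuration.

The default :class:`SimulationConfig` encodes a five-condition heat-shock
time course (control, heat shock, 1/2/3 h recovery) for a chaperone-like
channel A that accumulates in the nucleus and, transiently, in nucleoli,
and a co-chaperone-like channel B whose distribution barely changes and
which stays excluded from nucleoli.  Three replicate fields of 40 cells
give ≥115 cells per condition, matching typical single-cell imaging
cohorts for this kind of experiment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .containers import (CHANNEL_A, CHANNEL_B, CYTOPLASM, DEFAULT_PIXEL_AREA,
                         NUCLEOLUS, NUCLEUS, PROTEIN_CHANNELS)

#: condition labels of the default time course, in experimental order
DEFAULT_CONDITIONS = (
    "control",
    "heat_shock",
    "recovery_1h",
    "recovery_2h",
    "recovery_3h",
)

# Diffuse compartment means (ADU/pixel) per condition.  Channel A: nuclear
# signal rises monotonically through recovery while cytoplasmic signal
# drifts down (rising N/C ratio); nucleolar signal peaks at 1 h recovery.
# Channel B: near-constant everywhere, nucleolar level well below nuclear
# (nucleolar exclusion).  Values are qualitative mimics of the observed
# redistribution, not calibrated absolute intensities.
DEFAULT_INTENSITY_MODEL: dict[str, dict[str, dict[str, float]]] = {
    "control":     {CHANNEL_A: {NUCLEUS: 100.0, CYTOPLASM: 100.0, NUCLEOLUS: 60.0},
                    CHANNEL_B: {NUCLEUS: 80.0,  CYTOPLASM: 80.0,  NUCLEOLUS: 30.0}},
    "heat_shock":  {CHANNEL_A: {NUCLEUS: 130.0, CYTOPLASM: 95.0,  NUCLEOLUS: 80.0},
                    CHANNEL_B: {NUCLEUS: 82.0,  CYTOPLASM: 80.0,  NUCLEOLUS: 32.0}},
    "recovery_1h": {CHANNEL_A: {NUCLEUS: 160.0, CYTOPLASM: 90.0,  NUCLEOLUS: 200.0},
                    CHANNEL_B: {NUCLEUS: 84.0,  CYTOPLASM: 82.0,  NUCLEOLUS: 33.0}},
    "recovery_2h": {CHANNEL_A: {NUCLEUS: 190.0, CYTOPLASM: 85.0,  NUCLEOLUS: 170.0},
                    CHANNEL_B: {NUCLEUS: 82.0,  CYTOPLASM: 84.0,  NUCLEOLUS: 32.0}},
    "recovery_3h": {CHANNEL_A: {NUCLEUS: 220.0, CYTOPLASM: 80.0,  NUCLEOLUS: 140.0},
                    CHANNEL_B: {NUCLEUS: 80.0,  CYTOPLASM: 84.0,  NUCLEOLUS: 30.0}},
}

# Fraction of channel-B puncta pixels that coincide with channel-A puncta
# (the B-in-A overlap the generator controls directly), per condition and
# compartment: nuclear overlap rises from 38% to >65% after heat shock,
# cytoplasmic overlap falls from 80% to ~50% during recovery.
DEFAULT_COLOC_FRACTIONS: dict[str, dict[str, float]] = {
    "control":     {NUCLEUS: 0.38, CYTOPLASM: 0.80},
    "heat_shock":  {NUCLEUS: 0.65, CYTOPLASM: 0.80},
    "recovery_1h": {NUCLEUS: 0.68, CYTOPLASM: 0.55},
    "recovery_2h": {NUCLEUS: 0.68, CYTOPLASM: 0.50},
    "recovery_3h": {NUCLEUS: 0.65, CYTOPLASM: 0.50},
}


@dataclass
class SimulationConfig:
    """Ground-truth generator settings; defaults define the study conditions.

    Attributes
    ----------
    n_cells
        Cells per field.
    field_size
        (rows, cols) of each rendered field.
    pixel_area
        µm² per pixel.
    nucleus_radius_range, cytoplasm_radius_range, nucleolus_radius_range
        Half-axis sampling ranges (pixels) for the elliptical nucleus,
        the elliptical cell outline, and the circular nucleoli.
    n_nucleoli_range
        Inclusive range of nucleoli per nucleus.
    intensity_model
        ``condition -> channel -> compartment -> diffuse mean`` (ADU/pixel).
    cell_cv
        Cell-to-cell coefficient of variation of the per-compartment
        brightness factor (lognormal-free: factor = 1 + cv·latent).
    cross_cell_correlation
        Latent correlation ρ between the channel-A and channel-B
        brightness factors of a cell.  A float applies everywhere; a
        mapping may key by condition and/or compartment.
    coloc_fractions
        ``condition -> compartment -> f`` target B-in-A overlap fraction
        for the embedded puncta; ``None`` disables puncta entirely.
    puncta_density
        Fraction of compartment pixels converted to puncta per channel.
    puncta_intensity
        Absolute ADU value of puncta pixels (replaces the diffuse value),
        chosen ≳2× the brightest diffuse mean so that one frozen
        per-channel threshold isolates puncta in every condition.
    dna_nucleus_intensity, dna_nucleolus_factor
        DNA-stain level inside nuclei and the relative darkness of
        nucleoli in that channel (dark holes).
    background_level
        Constant camera/stray-light offset added to every pixel (ADU).
    noise_sd
        Gaussian read-noise SD (ADU); ``None`` → 2% of the brightest
        configured diffuse mean.
    poisson_noise
        Also apply Poisson shot noise to the pre-noise signal.
    seed
        Master seed for the field.
    """

    n_cells: int = 40
    field_size: tuple[int, int] = (640, 640)
    pixel_area: float = DEFAULT_PIXEL_AREA
    nucleus_radius_range: tuple[float, float] = (9.0, 13.0)
    cytoplasm_radius_range: tuple[float, float] = (15.0, 20.0)
    nucleolus_radius_range: tuple[float, float] = (3.0, 5.0)
    n_nucleoli_range: tuple[int, int] = (1, 3)
    intensity_model: dict = field(
        default_factory=lambda: json.loads(json.dumps(DEFAULT_INTENSITY_MODEL)))
    cell_cv: float = 0.15
    cross_cell_correlation: float | Mapping = 0.5
    coloc_fractions: dict | None = field(
        default_factory=lambda: json.loads(json.dumps(DEFAULT_COLOC_FRACTIONS)))
    puncta_density: float = 0.20
    puncta_intensity: float = 400.0
    dna_nucleus_intensity: float = 500.0
    dna_nucleolus_factor: float = 0.4
    background_level: float = 100.0
    noise_sd: float | None = None
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.intensity_model.keys())

    @property
    def max_protein_mean(self) -> float:
        return max(mu for cond in self.intensity_model.values()
                   for ch in cond.values() for mu in ch.values())

    @property
    def effective_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return float(self.noise_sd)
        return 0.02 * self.max_protein_mean

    def rho(self, condition: str, compartment: str) -> float:
        """Resolve the latent A/B correlation for one condition+compartment.

        ``cross_cell_correlation`` may be a scalar, a mapping keyed by
        compartment, or a mapping keyed by condition whose values are
        scalars or compartment mappings; ``"default"`` is the fallback key.
        """
        r = self.cross_cell_correlation
        if isinstance(r, Mapping):
            if compartment in r and condition not in r:
                r = r[compartment]
            else:
                r = r.get(condition, r.get("default", 0.0))
                if isinstance(r, Mapping):
                    r = r.get(compartment, r.get("default", 0.0))
        return float(r)

    def coloc_fraction(self, condition: str, compartment: str) -> float | None:
        if self.coloc_fractions is None:
            return None
        table = self.coloc_fractions.get(condition)
        if table is None:
            return None
        return table.get(compartment)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be ≥ 1")
        for name in ("nucleus_radius_range", "cytoplasm_radius_range",
                     "nucleolus_radius_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive and ordered")
        if self.nucleolus_radius_range[1] >= self.nucleus_radius_range[0]:
            raise ValueError("nucleolus radius must be smaller than nucleus radius")
        if self.nucleus_radius_range[1] >= self.cytoplasm_radius_range[0]:
            raise ValueError("nucleus must fit inside the cell outline")
        for cond, table in self.intensity_model.items():
            for ch in PROTEIN_CHANNELS:
                if ch not in table:
                    raise ValueError(f"{cond}: missing intensity row for {ch}")
                for k, mu in table[ch].items():
                    if mu < 0:
                        raise ValueError(f"negative mean µ[{cond}][{ch}][{k}]")
        if isinstance(self.cross_cell_correlation, (int, float)):
            if not -1.0 <= float(self.cross_cell_correlation) <= 1.0:
                raise ValueError("cross_cell_correlation must lie in [-1, 1]")
        if self.coloc_fractions is not None:
            for cond, table in self.coloc_fractions.items():
                for k, f in table.items():
                    if not 0.0 <= f <= 1.0:
                        raise ValueError(f"coloc fraction f[{cond}][{k}] outside [0,1]")
        if not 0.0 < self.puncta_density < 1.0:
            raise ValueError("puncta_density must lie in (0, 1)")
        if self.background_level < 0:
            raise ValueError("background_level must be ≥ 0")
        if self.cell_cv < 0:
            raise ValueError("cell_cv must be ≥ 0")

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["field_size"] = list(self.field_size)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        d = dict(d)
        for key in ("field_size", "nucleus_radius_range", "cytoplasm_radius_range",
                    "nucleolus_radius_range", "n_nucleoli_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class SegmentationParams:
    """Knobs of the compartment demarcation stage."""

    nuclear_threshold: float | None = None      # None → Otsu on the DNA stain
    min_nucleus_area: int = 60                  # px
    split_touching_nuclei: bool = True
    exclude_border: bool = True
    dark_fraction: float = 0.6                  # nucleolus cutoff × median nuclear DNA
    nucleolus_smooth_sigma: float = 1.0         # px
    min_nucleolus_area: int = 10                # px
    cytoplasm_strategy: str = "watershed"       # or "annulus"
    annulus_width: int = 6                      # px, annulus strategy only
    guard_ring: int = 1                         # px gap between nucleus and cytoplasm
    cell_threshold: float | None = None         # None → Otsu on summed protein channels


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    simulation: SimulationConfig | None = None
    manifest: str | None = None
    control_condition: str = "control"
    n_replicates: int = 3
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    threshold_method: str = "otsu"              # otsu | fixed | percentile | puncta_midpoint
    threshold_values: dict[str, float] | None = None
    threshold_percentile: float = 99.0
    nucleus_excludes_nucleoli: bool = False
    ratio_of_means: bool = False                # N/C as ratio of condition means
    anova_unit: str = "replicate"               # replicate | cell
    min_cells_per_condition: int = 35
    min_cells_coloc: int = 10
    outdir: str = "compartquant_run"
    seed: int = 0
    plots: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.simulation is None and self.manifest is None:
            raise ValueError("RunConfig needs either a simulation config or a manifest")
        if self.threshold_method == "fixed" and not self.threshold_values:
            raise ValueError("fixed threshold method requires threshold_values")
        if self.anova_unit not in ("replicate", "cell"):
            raise ValueError("anova_unit must be 'replicate' or 'cell'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("simulation") is not None:
            raw["simulation"] = SimulationConfig.from_dict(raw["simulation"])
        if raw.get("segmentation") is not None:
            raw["segmentation"] = SegmentationParams(**raw["segmentation"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d
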