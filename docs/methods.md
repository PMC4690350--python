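# Methods

## Scope and data model

`compartquant` quantifies the subcellular redistribution of two
immunostained proteins — a constitutive hsp70-family chaperone ("channel
A", hsc70-like) and its nucleotide-exchange co-chaperone ("channel B",
HspBP1-like) — across a heat-shock time course (control, heat shock, and
1/2/3 h recovery).  Each microscope field carries a DNA-stain channel
(DAPI-like) and the two protein channels.  Per field, the pipeline:

1. estimates and subtracts a scalar background per channel from a region
   devoid of cells,
2. demarcates nuclei (DNA stain), nucleoli (dark holes within nuclei) and
   cytoplasm per cell,
3. measures mean background-corrected pixel intensity (ADU/pixel) per
   cell × channel × compartment, the per-cell nucleocytoplasmic (N/C)
   ratio, and control-normalized intensities,
4. computes percent-area colocalization of the two channels per cell and
   compartment at thresholds frozen from the control fields, and
5. summarises populations: ascending single-cell profiles, mean ± SEM,
   Pearson correlation and OLS regression of the A/B pair per condition,
   and one-way ANOVA with Bonferroni post-hoc tests against control.

## Segmentation

* **Nuclei** — global Otsu threshold on the background-corrected DNA
  stain, hole filling (nucleoli appear as sub-threshold holes), a
  minimum-area filter (default 60 px), and removal of border-touching
  objects (recorded in `border_excluded`).  Touching nuclei are split by
  a watershed on the smoothed distance transform; markers are the blobs
  above 60% of each component's distance maximum, so an isolated convex
  nucleus keeps a single marker (its distance-transform level sets are
  connected) while fused nuclei contribute one core each.
* **Nucleoli** — within each nucleus, "dark holes": pixels whose
  DNA-stain intensity falls below `dark_fraction` (default 0.6) × the
  median nuclear intensity.  Candidate cores are detected on a Gaussian-
  smoothed image (σ = 1 px) and opened with a 1-px disk for robustness;
  the final extent is the connected raw-intensity sub-cutoff component
  containing a core, so hole boundaries are not eroded by the blur.
  Minimum nucleolus area 10 px.  Nuclei may legitimately yield none.
* **Cytoplasm** — default strategy: a whole-cell mask from thresholding
  the summed protein channels, partitioned among cells by a watershed
  seeded at the nuclei; cytoplasm = cell minus the nucleus dilated by a
  1-px guard ring (avoids nuclear-edge bleed).  The cell threshold is
  Otsu computed on the log1p-compressed histogram: a bright minority mode
  (puncta, see below) would otherwise pull a plain Otsu threshold above
  the diffuse cytoplasmic signal.  Alternative strategy: a fixed-width
  annulus around each nucleus (contested pixels go to the nearest
  nucleus).
* The nuclear compartment **includes** nucleolar pixels by default (the
  DNA-demarcated nucleus is the whole nuclear area; nucleolar values are
  reported separately); `nucleus_excludes_nucleoli` switches this off.

Background is the mean intensity over the complement of the dilated union
of per-channel Otsu masks; at least 1% of pixels must be cell-free, else
a manual ROI is required.  Correction is pixelwise `max(I − b, 0)`.

## Quantification and normalization

Mean intensity is Σ(pixels)/count per compartment.  The N/C ratio is
computed per cell and averaged (a ratio-of-condition-means mode is
available; for homogeneous cells the two agree).  Cells with an empty
nucleus or cytoplasm mask are dropped with a logged reason; a zero
cytoplasmic mean flags the ratio undefined rather than producing ±inf.
Normalization divides each value by the mean of the same channel ×
compartment over the control cells of the **same replicate**, so the
control mean is exactly 1 per replicate by construction.  Summaries
default to the replicate level (mean of per-replicate means, SEM over
n = experiments); cell-level pooling is available.

## Colocalization

Each protein channel is binarized with a strict `>` comparison against
one scalar threshold per channel, chosen once from pooled control-field
pixels and frozen for the entire experiment (methods: Otsu, fixed value,
percentile).  Per cell and compartment (nucleus, cytoplasm) the record
holds the thresholded areas, the shared pixel count, and both directional
percentages: A-in-B = 100·|A∩B|/|A| and B-in-A = 100·|A∩B|/|B|.  The
identity pct_A·|A| = pct_B·|B| = 100·|A∩B| holds exactly on the stored
integer counts.  Zero-denominator percentages are flagged undefined and
excluded from condition means (their count is reported), never set to 0.
Colocalization runs on background-corrected images, and the nuclear ROI
includes nucleolar pixels.

For synthetic runs the default run configuration uses the fixed-value
method at the generator's puncta midpoint (see below): a pooled Otsu on
a background-dominated histogram separates background from cells, which
marks entire compartments positive and makes every overlap ≈100% — the
right behaviour for diffuse real signal but uninformative for the
punctate structure the generator embeds.

## Statistics

Pearson r is the sample covariance over the product of sample standard
deviations (the n vs n−1 convention cancels; both conventions give the
same r).  OLS slope/intercept come from the closed normal equations,
R² = 1 − SS_res/SS_tot, with R² flagged undefined when y is constant and
an error for constant x.  One-way ANOVA uses the classical between/within
mean squares with (k−1, N−k) degrees of freedom; the all-identical case
(0/0) is flagged undefined.  Post-hoc comparisons against control are
two-sided equal-variance t-tests (Welch behind a flag) with Bonferroni
adjustment p_adj = min(1, m·p_raw).  scipy supplies only the F/t
distribution tails; scipy's own implementations serve as independent
oracles in the test suite.  Undefined statistics propagate as explicit
`None` flags.  Significance stars: * p<0.05, ** p<0.01, *** p<0.001.

Single-cell correlation/regression grids (per condition × {N/C ratio,
nucleus, cytoplasm}) pool per-replicate-normalized values across the
replicates; a per-replicate breakdown is available for diagnostics.
ANOVA defaults to replicate means as the unit of analysis (n =
experiments), with a cell-level option.

## Synthetic data generator

Cells are axis-aligned ellipses (cell outline ⊃ concentric nuclear
ellipse ⊃ 0–3 circular nucleoli), placed sequentially without overlap
(conservative bounding-circle test, 2-px margin, bounded retries with an
explicit "field too crowded" failure).  Default geometry: nucleus
half-axes 9–13 px, cell 15–20 px, nucleoli radius 3–5 px, field 640×640,
pixel area 0.14 µm².  Default cohort: 40 cells × 3 replicates = 120
cells per condition (mirroring cohorts of ≥115 cells per time point) and
five conditions.

**Intensity model.**  The DNA stain renders nuclei at 500 ADU with
nucleoli at 40% of that (dark holes); protein channels render diffuse
per-compartment means from a per-condition table.  The default table is
a qualitative mimic of the observed biology — channel A's nuclear mean
rises monotonically through recovery (100→220 ADU) while its cytoplasmic
mean drifts down (rising N/C ratio) and its nucleolar mean peaks at 1 h
recovery; channel B stays within a few percent everywhere and its
nucleolar mean sits far below its nuclear mean (nucleolar exclusion).
True per-condition intensity distributions are not published, so these
are trend mimics, not calibrated values.

**Cell-to-cell variability and correlation.**  Each cell × channel ×
compartment gets a multiplicative brightness factor
1 + cv·(√ρ·z₀ + √(1−ρ)·z_c), with z₀, z_A, z_B iid standard normal per
cell and compartment, cv = 0.15, and the shared-latent sign flipped for
channel B when ρ < 0.  corr(factor_A, factor_B) = ρ exactly by
construction (factors are floored at 0.05; at cv = 0.15 the floor is
≈6σ away and has no practical effect).  Factors are independent across
compartments, which makes the per-cell N/C ratio vary and lets ρ be set
per condition and/or compartment.

**Colocalization embedding.**  A fraction (default 20%) of each
compartment's pixels per channel is converted to "puncta" whose B-in-A
overlap |A∩B|/|B| equals the configured f to within one-pixel rounding,
positions uniform in the compartment.  Puncta pixels are set to a fixed
absolute intensity (default 400 ADU, ≈2× the brightest diffuse mean)
rather than a relative offset above the local mean: one threshold per
channel must stay frozen across all conditions, and with condition- and
compartment-dependent diffuse means no single threshold can bracket a
relative offset everywhere — with an absolute puncta level, the midpoint
between the brightest diffuse mean and the puncta level
(`puncta_midpoint_threshold`) separates puncta from diffuse signal in
every condition with a margin of ≈20 noise SD.  A relative offset of a
few noise SD was also rejected because threshold misclassification alone
then biases recovered fractions by more than the sampling error at
extreme f.

**Noise and output.**  Ground-truth per-cell means are recorded from the
noiseless, background-free rendering; the background level (default
100 ADU) is added everywhere and noise applied last — Gaussian read
noise with SD = 2% of the brightest configured diffuse mean (≈4.4 ADU),
optional Poisson shot noise.  In-memory images are float; files are
16-bit unsigned TIFF (rounded, clipped, saturation flagged).  All
randomness flows from one seed: identical (config, condition, seed) give
bit-identical output, and replicate seeds derive deterministically from
the master seed.

## Validation experiments and problem sizes

`compartquant.validation` holds the recovery experiments the tests and
`scripts/acceptance.py` run:

* **Statistical oracles** — 100 random instances (n ≤ 1000) against a
  brute-force covariance loop and scipy; agreement to 1e−12 (r), 1e−10
  (R²), 1e−9 (F).
* **Counting identity** — 1000 random mask pairs; the percent-overlap
  identity is checked in exact rational arithmetic.
* **Correlation recovery** — ρ ∈ {0, 0.5, 0.9}, 10 populations of 200
  cells each, compact geometry with nucleoli and puncta disabled so the
  per-cell true nuclear mean is µ × factor alone and the recovered r
  estimates ρ with pure sampling error (the nuclear mean of a cell with
  nucleoli mixes two diffuse levels through a geometry shared by both
  channels, which would add a positive correlation floor of ≈0.1 — a
  property of the synthetic geometry, not of the estimator under test).
  Tolerance ±0.06 on the mean ≈ 3 SE of r̄ at ρ = 0.
* **Colocalization recovery** — f ∈ {0, 0.38, 0.65, 0.8, 1}, one field
  of 50 cells each with a uniform single-condition intensity table, run
  through the full segmentation + frozen-threshold path; recovered mean
  B-in-A within ±5 points (observed ≤0.2).
* **Segmentation recovery** — default fields; per-object Dice against
  ground truth (observed: nuclei and nucleoli ≈1.0, cytoplasm ≈0.94,
  limited by the deliberate guard ring and cell-mask edge noise).
* **Trend reproduction** — the full default experiment; channel-A N/C
  strictly increasing across the time course, channel-B N/C within ±10%
  of control, channel-A nucleolar signal peaking in recovery, no
  channel-B nucleolar enrichment.

## Known limitations

* Geometry is idealised (ellipses, no texture, no point-spread
  function, 2D only); Dice scores on real images will be lower and the
  cytoplasm strategy choice will matter more.
* The generator's puncta are binary and non-overlapping with uniform
  positions; real punctate staining has graded intensities and spatial
  clustering, so threshold choice on real data is less forgiving.
* Passing recovery tests demonstrates correctness of the measurement
  chain on data matching the generator's assumptions, not accuracy on
  arbitrary real acquisitions.
* The published correlation-grid values derive from deposited per-cell
  supplements that are not bundled here; `correlation_table` accepts
  such a table directly once downloaded (see the tests for the expected
  schema).
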