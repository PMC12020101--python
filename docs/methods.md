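# Methods

## Scope and data model

The package analyses single-dose, single-well-per-compound LD screens. The
canonical objects are: a multi-channel field (`ImageSet`), integer label maps
for nuclei/cells/puncta (`LabelMap`), per-droplet morphometry
(`ObjectFeatures`), the four per-well screen parameters (`WellSummary`),
per-compound SD-distance scores (`PlateScores`) and the four-flag hit table.
Feature tables and plate maps are plain CSV; fields are multi-page TIFFs with
a JSON sidecar naming channel order and pixel size.

## Synthetic data generator

The generator emulates the statistical structure of a patient-fibroblast
screen rather than its photometric detail.

**Scene model.** Cells are non-overlapping ellipses placed by rejection
sampling (bounded retries, then a placement error), each with an interior
nuclear ellipse. Per cell, the droplet count is Poisson(λ) and droplet radii
are log-normal (median m, log-SD σ); droplets are disks packed in the
cytoplasm, largest first, with a 2.5 px surface gap so that diffraction-level
blur does not fuse resolvable droplets. When a droplet cannot be packed
without overlap it is still placed inside the cell (overlap allowed) — the
rendered droplet count therefore always equals the drawn Poisson counts, and
the ground truth records exactly what was rendered. Channels are rasterised
(nucleus, whole-cell, droplet; optional mitochondrial pair), blurred with a
Gaussian PSF and given additive Gaussian noise. Four independent RNG
substreams (placement, counts, radii, noise) make the count draw replayable
in isolation; identical spec + seed is pixel-identical.

**Closed forms.** With droplet count ~ Poisson(λ) and radius ~
LogNormal(ln m, σ): E[per-droplet area] = π m² e^{2σ²} and E[total area per
cell] = λ π m² e^{2σ²} (µm² via the pixel size). These are the oracles for
the generator's scaling laws (linear in the count multiplier, quadratic in
the radius multiplier) and for feature-mode well simulation.

**Defaults (one field).** 256×256 px at 0.65 µm/px; 6 cells of semi-major
26–34 px (aspect 0.8–0.95), nucleus fraction 0.3; patient phenotype λ = 8,
m = 3 px, σ = 0.2; PSF σ = 1 px; backgrounds ~8–10, foregrounds 70–200,
noise SD 4 — the high-SNR regime of fixed-cell high-content imaging. The
healthy-control phenotype multiplies λ by 0.15 ("few droplets"); compound
archetypes are multiplicative on λ and m (clearance 0.3/0.7,
fewer-but-larger 0.4/1.4, accumulation 1.5/1.2). No published per-well or
field-to-field variance estimates exist for screens of this kind, so these
are explicitly plausible defaults, not estimates; everything is a `SceneSpec`
field.

**Feature mode.** `simulate_well_features` skips rendering and draws each of
the four well parameters as expectation + N(0, sd), with a default
well-to-well SD of 5% of the patient-baseline expectation per parameter, and
a fixed compactness baseline of 1.15 (reciprocal form factor). A phenotype
may instead carry `param_shift_sd`, which places a parameter **exactly** at
expectation + k·sd. Planted effects are thus ideal displacements of known
magnitude: recovery benchmarks measure the calling machinery, not the luck
of one extra noise draw (a 5 SD planted mean with unit noise would otherwise
fail a 4 SD bar ~16% of the time per compound). The stochastic route —
multiplicative effects plus well noise — remains the default for every
non-planted well and for image mode.

**Plates.** The default layout mirrors the screen design: 16×24 wells,
12 negative-control wells (patient + vehicle), 12 positive-control wells for
each of two healthy lines, 12 fields/well, compounds at 10 µM in the
remaining wells. Per-well seeds are spawned from the plate seed, so feature
tables are byte-reproducible. The build manifest names every planted effect
and every planted hit.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: confluent or motile cells, illumination and
vignetting artifacts, droplet clustering beyond random packing, stain
cross-talk, focus drift, or edge effects across the plate. Results here
certify the analysis chain, not instrument robustness.

## Segmentation

Classic threshold-based high-content segmentation, all parameters exposed:

* **Nuclei** — Gaussian smooth (σ = 2), global Otsu threshold, hole fill,
  area filter (≥ 40 px²), distance-transform watershed to split touching
  nuclei. A blank channel warns and returns an empty map so plate runs
  survive failed wells.
* **Cells** — foreground from the smoothed whole-cell stain (Otsu) union the
  nuclear seeds; watershed on inverted intensity seeded by nuclei (one cell
  per nucleus); border-touching cells removed by default to avoid
  truncated-cell bias.
* **Puncta** — white top-hat (disk radius 8 px) to suppress diffuse
  background, threshold estimated from in-cell pixels but applied image-wide,
  8-connected components, area filter 4–400 px². Each punctum is assigned to
  the cell containing its centroid (majority-overlap available); puncta whose
  centroid lies outside every cell are dropped and tallied as
  `orphan_puncta` QC.

Label maps always carry consecutive positive labels; 4-connectivity is used
for hole filling and 8-connectivity for puncta, fixed.

## Morphometry

Area = pixel count · pixel_size²; perimeter by the 4-direction Crofton
estimator (least biased for small digitised objects; a digitised r = 30 px
disk gives form factor 1.008). Compactness = P²/(4πA) and form factor is
computed as its exact reciprocal, so C·FF = 1 to machine precision and the
two parameters are always directionally consistent. Well aggregation pools
droplets across fields: mean per-droplet area, unweighted means of
compactness/form factor, and total area normalised per cell
(Σ areas / Σ cells) so wells with different cell counts — e.g. mildly toxic
compounds — remain comparable; raw per-field sums are a flag away. Zero-cell
wells produce NaN parameters plus a QC flag, never zeros. The TMRE-like /
MitoTracker-like ratio is the per-cell mean background-subtracted intensity
quotient, with background estimated as the refined histogram mode of
non-cell pixels.

## Plate statistics

* **Z′** = 1 − 3(σ_pos+σ_neg)/|µ_pos−µ_neg| with sample SDs; symmetric,
  exactly 1 in the zero-variance limit, NaN (flagged) for equal means.
  Computed per positive-control line.
* **Scoring** — per parameter, z = (x − median)/sd over a reference set that
  defaults to all compound wells ("median of the samples": with hundreds of
  mostly-inert compounds the sample median estimates the null centre and is
  robust to the few true actives). Negative-control referencing and a
  1.4826·MAD robust SD are options. QC-flagged wells are excluded; a zero SD
  flags the parameter rather than producing infinities.
* **Hit rule** — pass bars 2/2/2/4 SD for area/total area/compactness/form
  factor; total area is one-sided (decrease), the others two-sided since
  either direction reflects a changed droplet state and the screen direction
  is recorded per compound. A hit requires all four passes; any undefined
  score excludes the compound explicitly. No multiple-testing correction is
  applied beyond the SD bars (an optional Benjamini–Hochberg layer exists,
  off by default). For replicated designs the canonical strictly-standardised
  mean difference is provided separately (`ssmd_replicate`); the screen's
  single-well-per-compound layout cannot estimate per-compound variance, so
  its "SSMD" is the robust z-score above.
* **Group comparison** — Shapiro–Wilk per group at α = 0.05; Student's t
  (equal variances; Welch via keyword) when both groups pass, two-sided
  Mann–Whitney U otherwise; all-tied groups fall through to Mann–Whitney
  with a flag. The gated procedure's empirical type-I error is ~0.05
  (measured over 10,000 null simulations in the acceptance script).

## Numerical and design choices

Wells are addressed "A01"–"P24" (0-based row/col stored alongside); CSVs are
UTF-8 with header and "." decimals; undefined statistics serialise as empty
fields. Medians of even-length references are midpoint medians; SDs are
ddof = 1 throughout. Determinism: all randomness flows from
`numpy.random.SeedSequence` spawning, so any artifact is reproducible from
its manifest (seed, parameters, version, output checksums).

Problem sizes used by the test suite and acceptance script were chosen to
exercise every code path at desk scale: 384-well feature plates (10 planted +
20 null seeds), 100 random plates for the scoring oracle, one rendered
well of four 256×256 fields plus an 8–10-well image-mode mini-plate, 10,000
null simulations for test calibration and 200 for power. Segmentation
accuracy is asserted as: pooled droplet count within 5% of planted, cell
count within ±1 per field, and per-droplet area within 20% of πr² for the
bulk (95th percentile) of uniquely matched droplets — droplets fused by
blur are counting errors, already covered by the count tolerance.

## Known limitations

Single 2-D fields only (no stacks, no deconvolution); threshold-based
segmentation will undercount heavily overlapping droplets and is not a
substitute for learned models on hard images; the feature-mode compactness/
form-factor baseline is a constant rather than an emergent property; the
null-plate calibration assumes exchangeable wells (no row/column gradients);
and the generator's variance defaults are conventions, not fitted to any
instrument.
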