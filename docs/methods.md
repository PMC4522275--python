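# Methods

## Image formation model

Brightfield chromogenic staining is modeled by the Beer–Lambert law.
With endmember spectra `s_k(b)` (peak-normalized to 1 at each
chromogen's absorbance maximum) and per-pixel abundances `a_k(x)` in
optical-density units,

    I(x, b) = I0 · 10^(−Σ_k a_k(x) · s_k(b)) + ε(x, b),

clipped to `[0, I0]`. `ε` is additive Gaussian noise with standard
deviation expressed as a fraction of the white reference `I0` (default
0.01·I0); Poisson shot noise can be enabled instead of or on top of it.
Fluorescence mode is additive: `I = Σ_k a_k s_k + AF·mask + ε`, with a
broad blue-weighted autofluorescence spectrum applied over tissue.

Converting brightfield intensities to OD,
`OD = −log10(max(I, ε₀)/I0)` with `ε₀ = I0·10^(−od_max)` and a clamp to
`[0, od_max]` (default 3.0), makes chromogen contributions linear, so
each pixel spectrum is decomposed by non-negative least squares against
the library. Because endmembers are peak-normalized, a coefficient is
the chromogen's OD contribution at its peak band; this scalar is the
"optical density" reported per cell and per region throughout.

### NNLS solver

`unmix_pixel` wraps the Lawson–Hanson active-set routine. For whole
cubes with K ≤ 12 endmembers the solver enumerates every support
(active set), solves the support-restricted least squares in closed
form for all pixels simultaneously, and keeps the feasible candidate
with the lowest SSE. The optimal support is always among the
candidates, so the result equals the NNLS optimum exactly; ties (within
1e-12 in SSE) resolve to the earliest support in (size, lexicographic)
order, making the solver deterministic. This is the step that makes
megapixel cubes tractable on one CPU (a 576² ×16-band cube unmixes in
about a second).

Near-collinear endmember pairs are the known hard case: the default
library deliberately contains a Warp-Red/Nuclear-Red-like pair at 8°
spectral angle, and `library_condition_report` quantifies separability
(pairwise angles, condition number) and flags pairs below 3°.

## Spectral libraries

Endmembers come from single-stain images: pixels whose total signal
(summed OD in brightfield, summed intensity in fluorescence) exceeds
the 0.90 quantile of the image are averaged and the mean spectrum
peak-normalized. Mean (not median) and the 0.90 quantile are declared
conventions, both configurable. Brightfield libraries are built in OD
space; autofluorescence handling applies to fluorescence only: the AF
spectrum is the per-band mean of unstained tissue, subtracted from each
raw endmember (clamped at zero, re-normalized) and retained so it can
also be used as an extra unmixing endmember.

## Segmentation

Nuclei are segmented from the nuclear-counterstain abundance map:
Gaussian smoothing (σ = 0.8 px) → Otsu threshold → Euclidean distance
transform → peak seeds (minimum separation 3 px) → marker-controlled
watershed → area filter (12–400 px²). The smoothing and peak-separation
defaults were chosen so that touching nuclei with ≤10% overlap are
reliably split at the simulated scale (median nucleus radius ≈ 4 px);
with them the default scene's ~1600 nuclei are recovered with <1% count
error and >98% of centroids within 3 px.

Tissue regions are classified per 32-px tile from composition features:
mean abundance per endmember, nucleus density (per 1000 px²), mean
nucleus area, and fraction of pixels above the tissue OD threshold
(0.05 summed OD). A Gaussian class-conditional model (per-class
per-feature variances with a shared ridge floor; a pooled-covariance
variant is available) with empirical priors assigns each tile the
maximum-posterior class; posterior ties break in the fixed order
follicle > t_zone > stroma > other. Tiles with under 20% tissue
coverage are labeled background without consulting the model. Training
uses majority ground-truth labels of tiles from ten representative
images; with the default synthetic conditions this recovers ~92% of
tissue pixels on held-out images. Tile-resolution rasterization is the
main loss term: boundary tiles carry mixed regions, so accuracy is
bounded by geometry (~94% for the default layout) regardless of the
classifier.

## Phenotyping

Each segmented cell is measured in two compartments: the nuclear
counterstain over the nucleus pixels, and the membrane markers
(lineage, tetraspanin) over the cell's membrane ring — the nucleus
labels expanded by 3 px, nucleus excluded. `expand_labels` assigns
contested pixels to the nearest cell, so rings of adjacent cells never
overlap; measuring the ring alone (rather than nucleus+ring) makes the
membrane OD estimate independent of nucleus size, which matters because
the negative-control cells are larger than lymphocytes.

Thresholds are derived once per staining batch from designated
negative-control cells — non-immune cells in the marker-negative
control region: the dim/bright cutoff is the nearest-rank 95th
percentile of control tetraspanin ODs, positivity the nearest-rank 99th
percentile of control lineage ODs (`k = ⌈p·n⌉`, both percentiles
configurable, at least 50 control cells required). Scoring is
four-way — lin−/dim, lin+/dim, lin+/bright, lin−/bright — with boundary
equality counting as positive/bright. Cells whose measurement mask is
empty get OD 0, never NaN. Images with less than 10% tissue (strict
`<`) are discarded before thresholds or statistics are computed.

## Region statistics

Per image × region: cell count, tetraspanin OD_mean, OD range, % bright
among all cells and within the lineage-positive subset (flagged with a
low-n warning below 20 cells). OD distributions are binned per 0.05 OD
into left-closed right-open bins starting at 0 (a value exactly on an
edge opens the upper bin) and normalized so the modal bin is 100%.

Two-group comparisons take one image as the statistical unit. Each
group passes through a Shapiro–Wilk gate at α = 0.05 (n < 3 or constant
samples count as non-Gaussian): both Gaussian → two-sided unpaired
Student's t test (equal variance; Welch by flag), otherwise a two-sided
Mann–Whitney U test — exact null distribution when `n_a+n_b ≤ 20` with
no ties, normal approximation with tie and continuity correction
otherwise. Significance is declared at `p ≤ 0.05`. The gated procedure
holds its nominal size: under a Gaussian null at n = 10 per group its
empirical type-I error over 2000 simulations stays within [0.03, 0.07].
No multiple-testing correction is applied. Scatter exports subsample at
most 2000 cells per region without replacement, seeded.

## Synthetic scenes: what they emulate and what they do not

A scene is a 576×576 px field emulating a 20× view of secondary
lymphoid tissue: a background margin, a marker-negative "other" band
(capsule/vessel surrogate — the source of negative-control cells), one
B-cell-follicle disk (radius 110 px) wrapped in a T-zone ring (width
90 px), and stroma (red-pulp/lamina-propria surrogate) elsewhere.
Bone-marrow-like fields are the same generator with `n_follicles = 0`.

Cells are disk nuclei with log-normal radii (σ = 0.12; median 3.8 px in
follicle and T zone, 5.4 px in stroma, 6.5 px in the control band),
placed by rejection sampling with center distance ≥ 0.9·(r₁+r₂)
(overlap ≤ 10%; configurable up to 30% to stress watershed splitting).
Densities per 1000 px² are 9 (follicle), 8.5 (T zone), 4 (stroma), 2.5
(other); together with the radii this mirrors the morphology contrast
between densely packed small lymphocytes and sparser, larger stromal
cells, and it is what makes tissue classes separable from tile
features. The default field holds ≈1600 nuclei.

Each cell draws a lineage class (positive fraction 0.9 / 0.1 / 0.45 / 0
by region) and a tetraspanin class (bright fraction 0.85 / 0.55 / 0.45
/ 0), then log-normal OD levels: bright median 0.30 (σ 0.30), dim
(background) median 0.035 (σ 0.25), lineage-positive 0.40, nuclear
0.60. Control-band cells draw their background from slightly higher
medians (tetraspanin 0.06, lineage 0.05, σ 0.30): non-immune stromal
and vascular structures bind chromogen nonspecifically, so the control
percentile acts as a conservative upper bound of background — the
reading under which percentile thresholds on negative controls produce
well-defined dim populations. The resulting per-cell OD ranges
(≈0.05–0.85 with means of 0.1–0.3 by region) match what chromogenic
tetraspanin staining of lymphoid tissue reports.

Membrane chromogen (lineage + tetraspanin, added linearly) is deposited
on each cell's membrane territory: the band within 3 px of its nucleus
restricted to pixels nearer to it than to any neighbor. An earlier
unrestricted-annulus variant let bright cells deposit into neighbors'
measurement rings; in dense regions that inflated scored bright
fractions by tens of points, which is a measurement artifact rather
than biology — the territory restriction models membrane compartments
that abut without mixing. The nuclear chromogen is confined to the
disk (overlapping disks add).

Everything is a pure function of (config, seed): layout, cell placement
and rendering consume independent streams spawned from the scene seed,
and identical configs reproduce cubes bit for bit.

What the generator does **not** emulate — and hence what passing tests
do not show about real slides: no point-spread function or chromatic
blur, no sectioning artifacts (folds, tears, uneven staining), no
intensity vignetting, no spatial correlation in staining background, no
irregular nucleus shapes or 3-D overlap projection, and regions with
sharp analytic boundaries rather than infiltrating margins. Recovery
rates on synthetic scenes are therefore upper bounds on slide
performance, not estimates of it.

## Numerical and interface choices

- Coordinates are pixel-centered, 0-based, row-major; masks and cubes
  share the frame. Region labels: background 0, follicle 1, t_zone 2,
  stroma 3, other 4.
- Degenerate inputs have defined behavior: empty scenes render clean
  background; all-zero nuclear maps segment to zero cells; empty OD
  samples and empty control pools raise with counts in the message.
- Problem sizes in the test suite and acceptance script (256²–672²
  scenes, 8–20 images per batch, 2000 null simulations) were chosen so
  each contract is exercised at meaningful n while a full run stays in
  the minutes range on a single CPU.
- Artifacts are diff-able text or plain TIFF: cubes and abundance maps
  as float32 multi-page TIFF with a JSON description (sidecar JSON as
  fallback), masks as uint16 TIFF, tables as CSV (UTF-8, '.' decimal),
  configs as flat `key = value` files, models and thresholds as JSON.
- The estimator-style classes (`SpectralUnmixer`, `TissueClassifier`,
  `PhenotypeScorer`) follow scikit-learn conventions (`fit`,
  `transform`/`predict`, `get_params`/`set_params`, fitted attributes
  with trailing underscores) so they compose with sklearn tooling;
  the module-level functions are thin wrappers over the same code.

## Known limitations

- The tissue classifier is tile-resolution; region boundaries are
  rasterized to 32-px blocks and boundary pixels dominate its error.
- Abundance units are relative to peak-normalized endmembers; absolute
  chromogen concentrations are out of scope.
- No spatial regularization or sparsity in unmixing; no automatic
  endmember discovery (libraries require designated single-stain
  inputs); no proprietary slide-scanner formats; no per-image adaptive
  thresholds; no multiple-testing correction.
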