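# Methods

This note documents the models and procedures implemented in
`phenoquant`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the package's numerical
conventions. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Transcription-site detection and microenvironment statistics

**Model.** A transcription site is a diffraction-limited punctum of
nascent mRNA in an RNA-FISH channel. Detection: the channel is Gaussian
pre-smoothed (physical σ, default 0.15 µm, matched to a typical confocal
PSF) to suppress single-voxel noise peaks; candidates are 26-neighborhood
local maxima exceeding a global threshold µ + k·σ of the smoothed channel
(default k = 4 — the assay's spots are "high intensity", several noise
SDs above background, so a global threshold suffices and keeps the
detector to one interpretable parameter); candidates within a physical
exclusion margin of the stack faces (default 0.3 µm) are discarded
because the truncated filter support there inflates local variance;
surviving candidates are non-maximum-suppressed at a physical radius
(default 0.45 µm), greedily from the brightest, ties broken toward the
voxel earliest in (z, y, x). Greedy-by-intensity suppression makes the
detected count non-increasing in k: raising the threshold only removes
candidates from the bottom of the intensity ordering, and a removed weak
candidate can only have been suppressing still-weaker ones. Sub-voxel
localization is not performed; the downstream statistics (densities,
per-site intensities, 0.1 µm-binned profiles) do not require it.

**Radial profiles.** For each site, voxels within r_max (default 2.0 µm)
are binned by Euclidean distance in micrometres — never in voxels, since
confocal z-spacing exceeds xy — at dr = 0.1 µm. Each per-site profile is
normalized by its outermost-shell mean, so the far field reads 1 and the
innermost bin reads as fold enrichment; the reported mean and variance
are across sites per bin. Alternatives ("mean", "none") are exposed
because the normalization convention and whether spread is taken across
sites or animals are genuinely open choices; across-sites/outer-shell is
the default. Sites near the border contribute partial shells and are
counted in `n_border_flagged`; a zero outer-shell mean drops the site
with a warning.

**Densities.** "Sites per pixel" is defined on the 2D xy grid: a site
counts if its xy centroid pixel is inside the (projection-drawn) region
mask, and the density is the exact count over the mask's pixel area.
Because the physical pixel size of such masks varies between setups, the
density is also reported in sites/µm² when a pixel size is supplied.

## ChIP coverage normalization

Tracks are uniformly binned, 0-based, half-open; bedGraph is the on-disk
format (bigWig read-only via pyBigWig). Normalization is per-bin control
subtraction (values may go negative), then a centered moving average:
the window in bp is converted to ⌈window/bin⌉ bins forced odd so it is
centered; edges use the truncated window (mean of available bins), with
a reflect mode behind a flag. Both subtraction and smoothing are linear,
so their order commutes to floating tolerance — a property the tests
assert. Replicate averaging is the per-bin arithmetic mean; pairwise
Pearson correlations over bins are reported so the analyst can judge
poolability, with zero-variance tracks reported as missing rather than
silently correlated. Per-library depth scaling (counts-per-million) is
available as an explicit pre-step but off by default, since subtraction
order versus depth scaling is not a settled convention.

## Single-larva MALDI lipidomics

Channels are pre-annotated m/z planes (as produced by upstream
annotation); peak picking and mass recalibration are out of scope. imzML
input is binned onto the provided channel list at ±5 ppm; a plain
directory of float TIFF planes plus a channels.tsv bypasses binning.

**Segmentation** runs on the total ion current (larvae are visible
across lipid channels, so the TIC is the most redundant image): Otsu
thresholding on the log-compressed TIC — log compression keeps the
background/tissue split stable when larvae differ strongly in brightness,
e.g. under multiplicative batch effects — then 4-connected components
above a minimum area (default 5 px), renumbered in row-major centroid
order for stable labeling. Morphological closing is exposed
(`closing_radius`) but defaults to off: any closing bridges larvae
separated by a single background pixel, and preserving adjacent animals
as separate labels matters more than filling interior holes at the
pixel sizes involved (~100 µm).

**Abundances** are the mean (default) or sum of each plane over each
label. Mean is the default because it is robust to body-size differences
between genotypes; sum is exposed since the raw-intensity convention is
also defensible.

**Batch adjustment ("combat_lite")** is a deliberate, named
simplification, not ComBat: per channel, each batch is centered and
scaled to the pooled mean/SD (population moments, ddof 0, which makes
the map exactly idempotent); group labels are never used; zero-variance
batches are centered only; fewer than 2 samples per batch passes through
with a warning. It removes location/scale batch structure only — no
empirical-Bayes shrinkage across channels.

**PCA** is column-standardized; constant columns are dropped with a
warning; each component's sign is fixed so its largest-magnitude loading
is positive (removing the eigenvector sign ambiguity).

**Class enrichment ("class_ranksum")** is likewise a named stand-in for
ontology enrichment: per channel the log2 fold change of group B over
group A (ratio of group means), per class the members' median log2FC and
a two-sided Wilcoxon rank-sum test of member versus non-member fold
changes. All-tied inputs report p = 1.

## Larval behavior

Speed is path length over elapsed time — the per-frame displacement
convention of video trackers — not net displacement over time; the two
differ greatly for curved paths, so the choice is stated prominently. A
larva is a "mover" iff net start-to-end displacement ≥ 1 mm **and**
average speed ≥ 0.02 mm/s; the assay itself supplies no moving
criterion, so both thresholds are exposed.

The head-cast detector operationalizes a behavior that is classically
scored by eye, so its output is validated against the generator's
injected events, not against manual counts. Displacements are smoothed
with a 0.5 s moving average (tracking-jitter suppression); headings are
the directions of the smoothed displacement vectors, held through
near-stationary stretches and unwrapped. An event requires, within a
1 s window: heading change ≥ 45°, and a run of at least 0.8 s of
consecutive frames with smoothed speed below the pause gate. Two details
are load-bearing. First, the pause-duration requirement: a sharp heading
reversal produced by turn noise cancels displacement inside the
smoothing window and fakes up to ~0.5 s of low speed, so the required
pause must exceed the smoothing window while staying below the
behavioral pause (~1 s). Second, the gate is relative — 40% of the
larva's own median smoothed speed, capped at 0.15 mm/s — because the
duration of the speed dip a true pause produces depends on the ratio of
gate to crawling speed; a fixed gate under-detects in fast crawlers and
over-triggers in slow ones. Under strong heading noise (10°/step) the
detector retains full recall with a residual ~5% overcount from
noise-generated reorientation episodes that are behaviorally
indistinguishable from unlabeled head casts. Events are separated by at
least the window length. All parameters are config-exposed. Rates are 60·count/duration. Detection on a still
trajectory is an error directing the caller to classify first.

## Morphometrics

Trichomes are counted as h-maxima (morphological reconstruction) with
prominence ≥ `min_prominence`: prominence — height above the highest
surrounding saddle — is invariant to additive illumination offsets,
unlike a raw threshold. One representative coordinate per maximum
plateau is kept, restricted to the user-supplied ROI (the anatomical
ventral/lateral boxes are landmarks the analyst draws; no automatic
landmark detection), then non-maximum-suppressed at `min_separation_px`
keeping the brighter punctum — two puncta closer than the separation
deliberately count as one.

Body metrics threshold the silhouette (Otsu default, fixed value via
argument), take the largest connected component, and report area =
pixel count × pixel area (exact by construction) and length = major-axis
length of the component's second-moment ellipse. The moment-axis
definition of "length" is this package's convention; a manually drawn
anteroposterior segment would differ for curved animals.

## Group statistics and the report

The t test is the pooled-variance Student test (the studies this
pipeline serves report "Student's t test"; Welch is a flag). The
statistic is (mean(b) − mean(a))/SE, so swapping groups negates t
exactly and a right tail always tests "second group greater" — the
orientation is echoed in every result to prevent silent sign errors.
Degenerate inputs: zero pooled variance with equal means gives t = 0,
p = 1; with unequal means it is an error rather than ±∞. Summaries are
mean, sample SD (n−1), and the mean ± 2 SD interval (the box-and-tails
convention). The comparison report takes a tidy metric/group/value
table, summarizes each group, tests metrics shared by exactly two
groups, and reports raw p values by default (matching the per-figure
convention of the studies served), warning when more than 10 metrics are
tested; Benjamini-Hochberg adjustment is optional. Missing metrics are
reported absent, never imputed.

## Synthetic generators: what they emulate, and what they do not

All randomness flows from one root seed through named substreams
(`SeedSequence([seed, crc32(name)])`), so generators are pure functions
of their configs and adding one call never shifts another's draws.

- **Confocal phantoms**: PSF-blurred puncta whose post-blur peak is
  `site_peak_snr × background_sd` over background, optional per-site
  log-normal amplitude spread, and a second channel with an isotropic
  (in µm) Gaussian enrichment field resampled to anisotropic voxels.
  Minimum inter-site separation defaults to 3 PSF σ so ground-truth
  matching is unambiguous; infeasible packings raise. Defaults (voxel
  0.25×0.08×0.08 µm, PSF σ 0.15 µm, background 100 ± 10 a.u., Gaussian
  noise) were fixed once for testability — the assays report no noise
  levels or site SNR. Not emulated: nuclear texture beyond i.i.d. noise,
  chromatic aberration, photobleaching, embryo anatomy. Passing tests
  therefore demonstrate correctness of the measurement code, not
  robustness to every real-world artifact.
- **Ion phantoms**: axis-aligned ellipses (axes jittered ±20%,
  non-overlapping with a gap, as animals separated in a mold), pixel
  values equal to per-larva abundances (channel-level log-normal ×
  per-larva log-normal × group fold change per lipid class), optional
  additive/multiplicative batch offsets, i.i.d. Gaussian noise. Not
  emulated: mass-spectral peak shapes, matrix effects, within-animal
  spatial structure.
- **Trajectories**: correlated random walk (per-step heading noise,
  default 10°/step at 30 Hz; per-step speed N(µ, σ) clipped at 0) with
  head casts injected as a 1 s pause plus a ±90° heading jump; event
  times are Poisson in number but placed with a refractory gap (pause +
  1 s) since an animal cannot cast twice at once — at the default
  1.5/min over 120 s the thinning changes the realized rate by < 2%.
  Still larvae are i.i.d. positional jitter (0.005 mm) around a fixed
  point. Not emulated: posture, peristalsis, arena walls.
- **Tracks/cuticle**: deterministic shapes (baseline + Gaussian peaks +
  impulses; minimum-spacing puncta) plus seeded noise, with pre-noise
  values retained.

## Problem sizes

Test and acceptance runs use desk-scale inputs chosen as the smallest
sizes at which every recovery property is comfortably measurable:
confocal stacks of 32×192×192 voxels (100 sites) for detection and
40×256×256 (20 well-separated sites) for enrichment recovery; 10–12
larvae per ion section; 26 larvae × 2 min × 30 Hz per behavioral cohort
(200 for the rate-calibration check); 10⁴ replicates at n = 13/13 for
the type-I-error calibration; 25 seeds for the end-to-end study. The
end-to-end study deliberately includes four unperturbed negative-control
metrics; with raw p values these trip at the 5% type-I rate, so the
expectation is "perturbed metrics flagged nearly always, controls
rarely", not zero false flags.

## Known limitations

- The global detection threshold assumes roughly stationary background;
  strongly vignetted stacks would need flat-field correction upstream.
- The head-cast detector's agreement with human scoring is untested by
  construction; only agreement with injected ground truth is claimed.
- "combat_lite" and "class_ranksum" are transparent simplifications and
  are named as such in the API to avoid overclaiming.
- imzML reading assumes centroided spectra and trusts the provided
  channel list; 3D reconstruction from serial sections is out of scope.
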