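# Methods

`smfish3d` quantifies single-molecule FISH (smFISH) signals in 3D widefield
stacks of small round suspension cells — effector T cells in the motivating
use case — and reports per-cell transcription-site activity, nascent-RNA
counts and the nuclear/cytoplasmic distribution of mature mRNA. This note
describes the models and procedures, the choices made where the design was
genuinely open, and what the synthetic validation does and does not show.

## Imaging model and coordinate conventions

Voxel indices are 0-based in (z, y, x) order with half-open ranges; a
subvoxel position references voxel centers, so physical position equals
index × voxel size. The default geometry emulates a 100×/1.4 NA objective
with a 6.5 µm-pixel sCMOS camera (65 nm lateral sampling) and 200 nm
z-steps over a 12 µm optical range, i.e. 61 planes; both are configurable.

A diffraction-limited emitter is modeled as an anisotropic 3D Gaussian with
σ = (350, 130, 130) nm in (z, y, x). These are typical widefield values for
this numerical aperture; the microscope's true PSF width is a configuration
parameter, not a fitted constant. No Gibson–Lanni or aberration modeling is
attempted — the Gaussian approximation is what the downstream least-squares
fit assumes, and the two are used consistently.

## Synthetic data generator

The simulator (`smfish3d.simulate`) renders fields that exercise every
downstream stage with known answers:

- **Cells** are ellipsoidal bodies (default diameter 9 µm) placed on a
  jittered grid so bodies never overlap; each contains one nucleus
  (default 6 µm). A configurable fraction of cells is *dividing* (one
  elongated body with two smaller, well-separated nuclei) and a fraction is
  placed crossing the field border (*edge* cells). Both exist to give the
  cell-exclusion filters true positives.
- **Mature mRNAs** are unit-intensity Gaussians (default integrated
  intensity 5000 photons, lognormal brightness jitter with CV 20%
  mimicking probe-count variability). Counts per cell and compartment are
  drawn from configurable integer laws (defaults: Poisson(22) cytoplasmic,
  Poisson(6) nuclear per channel); no distribution of mRNAs per cell is
  asserted as biologically true.
- **Transcription sites** (0, 1 or 2 per cell and channel, default
  probabilities 0.35/0.40/0.25) are rendered as a *single* superposed
  emitter of k unit intensities at one nuclear locus, because nascent RNAs
  co-localize below the diffraction limit; k defaults to uniform 2–20.
- **Autofluorescent granules** are dim distractors with 2× the PSF width
  at 2× unit intensity, at a configurable density (default 0.2 per
  100 µm³ per RNA channel); they are what the spot-width QC band is for.
- **Diffuse signals**: DAPI fills the nuclei; a weak uniform cell-body
  autofluorescence (8 photons/voxel) in the RNA channels provides the cue
  from which real T-cell outlines are drawn.
- **Noise** is Poisson shot noise on (signal + background, default 10
  photons) followed by additive Gaussian read noise (default SD 2),
  clipped at zero — an sCMOS model without gain or offset maps. At these
  defaults the peak-amplitude-to-background-noise ratio of a unit spot is
  ≈ 12.

Ground-truth spots are placed at least one voxel away from the nuclear
surface on either side. The compartment label of a truth spot is defined at
voxel resolution, so a spot closer than half a voxel to the surface would
have an ill-defined label; the one-voxel guard keeps every truth label
unambiguous. Consequently the synthetic localization accuracy does not
probe the (real, but label-ambiguous) population of mRNAs sitting exactly
on the nuclear envelope.

Everything is driven by one seeded generator: identical configuration
(including seed) reproduces stacks and truth tables bit-identically.

### What the simulator does not emulate

Real acquisitions have structured backgrounds, optical aberrations away
from focus, chromatic shifts between channels, irregular (non-ellipsoidal)
nuclei, touching cells, and probe-specific off-target binding. Passing the
synthetic suites therefore demonstrates that the *algorithmic chain* is
correct and well-calibrated under its stated model, not that real-data
accuracy will match the synthetic numbers.

## Detection and fitting

1. **Background subtraction**: 3D rolling-ball implemented as grayscale
   opening (separable box erosion/dilation) with radius 10× the lateral
   PSF σ, on a lightly pre-smoothed copy; the background estimate is then
   smoothed so the min/max filters' blocky steps do not inject
   high-frequency structure. Opening never exceeds the image, preserving
   isolated point-source intensity; radii below 3× the lateral σ are
   rejected because they would erode the spots themselves.
2. **Candidates**: local maxima of the negated Laplacian-of-Gaussian
   response matched to the PSF, thresholded at 10× the robust (MAD-based)
   noise SD of the response. The multiplier was set from measured
   behavior: noise maxima of the background-subtracted response reach
   ~7–8 SD over a full 61×384×384 field, while the weakest spots at the
   default SNR exceed 30 SD. Maxima within one voxel merge into the
   brighter one.
3. **Fitting**: each candidate is fit by bounded least squares to an
   anisotropic 3D Gaussian plus constant local background in an
   11×11×7 (x, y, z) window covering ±3σ of the default PSF. Candidates
   whose window crosses the stack border are discarded with reason
   `edge` rather than fit truncated — truncation would bias the
   integrated intensities that normalize nascent counts. Integrated
   intensity is A·(2π)^{3/2}·σzσyσx in voxel units.
4. **Spot QC**: a spot passes iff amplitude ≥ 5× the robust noise SD of
   the subtracted stack (or an absolute range if configured), every fitted
   σ lies within 0.45–1.8× the PSF prior, and the normalized fit residual
   is ≤ 0.5. Each rejection carries one primary reason
   (edge > fit > amplitude > width > residual). The width band is what
   removes granules; pure-noise fits either stay under the amplitude floor
   or collapse to sub-voxel "needles" caught by the width band.

The **single-molecule reference intensity** is the arithmetic mean (10%
trimmed mean available) of qc-pass *cytoplasmic* mature spots — cytoplasmic
rather than all mature spots because cytoplasmic molecules are guaranteed
single and fully synthesized; a field with fewer than 10 cytoplasmic spots
falls back to all qc-pass mature spots with a logged warning, and zero
usable spots is an error instructing pooling across fields.

## Segmentation

**Nuclei (3D)**: per-plane smoothing, global Otsu threshold, hole filling
and a distance-transform watershed split, followed by z-stitching: a label
in plane k merges into plane k+1 when their pairwise IoU ≥
`stitch_threshold` (default 0.25). This is deliberately the same stitching
semantics as CellPose's 3D `stitch_threshold` mode, so masks from an
external CellPose run drop in through `import_masks` unchanged. Objects
spanning fewer than 3 planes or outside 25–400% of the expected-diameter
sphere volume are removed. A neural segmenter is out of scope; the
classical pipeline mirrors the interface (diameter prior, stitch
threshold), which is sufficient for DAPI on round, well-separated nuclei.

**Cells (2D)**: T cells are round suspension cells, and the outline cue is
the diffuse background fluorescence of the RNA channel. The z
maximum-intensity projection is median-filtered (removing the bright
spots so the threshold separates cell body from background), smoothed and
Otsu-thresholded. Connected regions become cells; a region containing
nucleus centroids farther apart than 0.75 cell diameters is split by a
nucleus-seeded watershed (two touching cells), while closer pairs remain
one outline — that is a dividing cell, and splitting it would hide it from
the QC filter. Outlines are 2D by design; compartments come from the 3D
nuclear mask.

## Quantification

- **Assignment**: a qc-pass spot belongs to the cell outline under its
  rounded (y, x); spots over background are *orphans*, tallied per field
  and excluded from all per-cell statistics.
- **Localization**: a spot is nuclear iff the voxel containing its fitted
  3D position carries a nuclear label owned by the spot's cell; otherwise
  cytoplasmic. Nearest-voxel containment, not distance-to-surface — ties
  are impossible by construction. A nuclear label owned by a *different*
  cell marks a segmentation disagreement; the spot is orphaned and logged.
- **Transcription sites**: a nuclear object whose integrated intensity is
  ≥ 1.5× the single-molecule reference is a TsX. The 1.5 threshold is the
  classical operating point for separating bursting loci from single
  nuclear mRNAs. At most two sites per cell and channel are kept (diploid
  genome) — the brightest two; further candidates stay flagged and the
  cell's allelic state becomes `ambiguous`. TsX members leave the mature
  pool entirely: nascent and mature counts are disjoint.
- **Nascent counting**: round-half-up of site intensity / reference, floor
  1. Because the probes tile the coding sequence, partially synthesized
  transcripts contribute fractional intensity, so the count is a slight
  underestimate for genes transcribed in small bursts; this caveat is
  inherent to single-probe-set smFISH, not to the implementation.
- **Allelic classification**: 0 → none, 1 → mono, 2 → bi, >2 before the
  cap → ambiguous.
- **Cell filters**: `dividing` (≥2 nuclei in one outline), `edge` (outline
  touches the border), `miscalled_nucleus` (nucleus volume outside 25–400%
  of the expected sphere, or nucleus centroid outside its cell outline).
  Reasons accumulate, filtering is idempotent, and excluded cells stay in
  the output with `qc_pass = False` — nothing is silently dropped.

## Population statistics

Summaries per group and channel: percentage of qc-pass cells expressing
≥1 mature mRNA, median count among expressors, percentage with active TsX,
median nascent per site, percent bi-allelic among transcribing cells,
single/double-positive classes across the two channels, and per-cell
localization measures. The cytoplasm:nucleus ratio is
log10((C + 0.5)/(N + 0.5)): the 0.5 pseudocount keeps zero counts finite
and makes equal distribution map exactly to 0. The pseudocount lives in
the computed statistic; any pseudo-log *axis* scaling is a plotting
concern and deliberately not part of the computation.

Group comparisons: Kruskal–Wallis omnibus test, post hoc Tukey-HSD applied
to rank-transformed values. Tukey-HSD after Kruskal–Wallis is an unusual
pairing; applying Tukey on ranks honors that design while keeping the
post hoc consistent with the rank-based omnibus, and Dunn's test
(Bonferroni-adjusted) is available as the conventional alternative via
`posthoc="dunn"`. Two-group designs use the two-tailed ratio Student's
t-test, implemented as a t-test on log-transformed values (paired or
unpaired), which is the standard reading of "ratio t-test" for strictly
positive measurements compared as fold changes.

## Numerical choices and degenerate inputs

- Fit bounds: σ ∈ [0.2 voxel, 2× window extent], center inside the
  window, amplitude ≥ 0; non-convergence yields `qc_pass = False` with
  reason `fit`, never an exception.
- Rounding: nascent counts round half *up* (2.5 → 3); compartment lookup
  rounds positions to the nearest voxel.
- Empty inputs: a blank DAPI stack yields an empty mask with a warning; a
  blank RNA stack yields an empty spot table; empty statistic groups
  yield n = 0 rows with missing medians.
- Determinism: there is no hidden randomness anywhere in the analysis
  chain; only the simulator consumes a seed.

## Problem sizes used in the validation suites

The bundled validation runs 20 synthetic fields of 61×384×384 voxels with
4 cells each (~110 mature spots per RNA channel per field, >4000 truth
emitters over both channels), 200 Monte-Carlo refits for the localization
RMSE, 4 replicates per nascent count k ∈ {2..30}, and 2000 null
replicates for the Kruskal–Wallis calibration. These sizes give binomial
standard errors comfortably below the acceptance margins (e.g. ±0.2
percentage points on the 98% localization figure) while a full run of the
test suite stays in the tens of minutes on one CPU core.

## Known limitations

- The Gaussian PSF ignores depth-dependent aberrations; real z-sigmas vary
  across the stack.
- The classical nuclear segmenter assumes DAPI-bright, convex,
  well-separated nuclei; crowded fields or lobed nuclei need external
  (e.g. CellPose) masks via `import_masks`.
- Cell outlines from background fluorescence alone are slightly
  conservative (the dimmest cell rim falls below threshold), so a small
  ring of peripheral cytoplasmic spots becomes orphans rather than cell
  members.
- TsX calling keys on intensity and DAPI colocalization only; a very
  bright nuclear mature mRNA aggregate above 1.5× would be miscalled a
  site, as in any intensity-threshold approach.
- The nascent count treats the site as k superposed full-intensity
  mRNAs; partial transcripts bias k downward.
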