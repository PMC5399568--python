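# Methods

## Measurement model

The pipeline treats a primary lobe as a 2-3-plane, two-channel confocal
stack: a nuclear stain ("DAPI") and a cytoplasmic reporter ("RFP"). Cells
are never segmented; each cell is identified with the local intensity
maximum its nucleus produces in the Laplacian-filtered nuclear channel, and
its reporter expression is read from an annulus around that peak. The
per-lobe outputs are the cell count *N* and the percentage of cells whose
shell signal passes a relative threshold.

### Nuclei detection

*Filter.* "Laplacian filter" is concretised as the Laplacian of Gaussian
(LoG) at σ = nuclear diameter / 4, the blob-matched scale: at this σ a
Gaussian-profile nucleus produces a single sharp positive peak (the
response is negated so bright blobs are positive). A bare discrete
Laplacian is noise-dominated at realistic noise levels and was not used.
The plane mean is removed before filtering so the response is exactly
invariant to constant intensity offsets; the truncated discrete kernel is
otherwise not quite zero-sum.

*Peaks.* Candidates are strict maxima within a Chebyshev neighbourhood of
radius ⌊min_separation/2⌋ (strict inequality, so plateaus yield no peaks;
determinism is guaranteed by explicit tie-breaks: higher response first,
then smaller row, then smaller column). Candidates below
`abs_threshold_fraction` × (plane maximum response) are discarded; the
survivors are accepted greedily in order of descending response subject to
a pairwise Euclidean separation of `min_separation` (default: one nuclear
diameter, since nuclei cannot sit closer than their own size).

The threshold fraction defaults to **0.3** of the per-plane maximum. At the
reference conditions (nuclear peak 1000, noise sd 200, σ = 3) the LoG
response of a true nucleus is ≈ 56 response units while filtered-noise
maxima reach ≈ 0.24 of that; 0.3 sits between the noise ceiling and the
faintest true-nucleus response (≈ 0.75 of the plane maximum), giving an
essentially zero false-peak rate without costing recall. Because the
threshold is relative to the plane maximum, detection is invariant to
positive rescaling of the nuclear channel.

*Plane merging.* Per-plane peaks are pooled, sorted by descending response,
and accepted greedily; a peak within `merge_radius` (default: half a
nuclear diameter) of an accepted cell is treated as the same nucleus seen
on another plane. The accepted cell keeps the centre of its
highest-response member — the "maximal detecting point" later used as the
shell centre — rather than an averaged centre, so shell centres always
coincide with detected maxima.

### Shell quantification and classification

The shell is the annulus `gap ≤ d < gap + shell_width` around the nuclear
peak, with `gap` defaulting to one nuclear diameter: an empty gap of the
nuclei diameter skips the nucleus (radius ≈ diameter/2) with margin and
lands in cytoplasm. `shell_width` defaults to half a diameter. Distances
are Euclidean between pixel centres; the interval is half-open; out-of-image
pixels are dropped. Shell intensities are read from the maximum-intensity
projection of the reporter channel across planes, making the measurement
independent of which plane detected the nucleus. The per-cell statistic is
the shell mean (median and max are available).

A cell is positive when its shell value reaches `threshold_fraction`
(default 0.75) of the reference maximum. The reference is the per-lobe
maximum of the cells' shell statistics — the rule discriminates cells
within a lobe, and a raw pixel maximum would be dominated by single-pixel
noise — with an image-pixel-max scope available as an option. Cells whose
shell loses more than half its pixels to the image border are excluded
from the threshold-defining maximum (a clipped bright shell would bias the
threshold) but are still classified themselves.

*Background correction.* Shell statistics ride on a background level
common to all cells. A purely relative rule applied to raw values cannot
represent "no positive cells": in an all-negative lobe every shell mean
lies within noise of the background, hence above 75% of the lobe maximum,
and every cell would be called positive. By default the mean of the
projected reporter frame is therefore subtracted from each shell value
(clipped at zero) before thresholding. This estimator is deliberately
global and crude — it needs no segmentation, is exact in expectation for a
signal-free lobe, and its inflation by ring pixels in positive lobes only
widens the already-large positive/negative margin. Setting
`background_correction="none"` restores the literal raw-value rule.
Classification remains exactly invariant to positive rescaling of the
reporter channel in both modes (every term scales linearly).

### Group statistics

Per-lobe percentages are compared with the two-sided two-sample
Kolmogorov–Smirnov test: D = sup |F̂ₐ − F̂ᵦ|, exact p-value when
nₐ·nᵦ ≤ 10 000, asymptotic otherwise; groups smaller than 3 are rejected.
Summaries per group are mean, SEM (n−1 denominator), and 5%/95%
percentiles by linear interpolation between closest ranks. P-values are
reported per pairwise comparison without multiple-testing correction,
matching how such scatterplot panels are conventionally annotated.

A calibration caveat worth stating precisely: with 15 lobes per group, D
takes values k/15 only, and the attainable test sizes adjacent to
α = 0.05 are P(D ≥ 8/15) = 0.0262 (the exact-p rule used here) and
P(D ≥ 7/15) = 0.0755 (the asymptotic approximation's rejection region).
No deterministic KS rejection rule at these sample sizes has size 0.05;
the exact rule is conservative, which costs little power at the effect
sizes this assay measures (20% vs 60% positive separates with D = 1).

### Relative expression (qPCR)

Fold changes use 2^(−ΔΔCt) with a single reference gene: per sample
ΔCt = Ct_target − Ct_reference; per target ΔΔCt = ΔCt − mean control ΔCt;
per group the fold change is the mean of 2^(−ΔΔCt) with its SEM, so the
control group reports the mean of its own normalised values (≈ 1; exactly
1 with one control sample). Fold changes are invariant to adding any
constant to every Ct. Group differences are tested by Welch's t on the
per-sample ΔΔCt values — the underlying quantification model and test are
conventions, stated here because Ct-level data rarely record them.

## Synthetic data: what it emulates and what it does not

Each synthetic lobe contains `n_nuclei` nuclei at non-overlapping integer
pixel positions (rejection sampling, 10 000 attempts per nucleus, loud
failure at infeasible densities), rendered as isotropic Gaussian blobs
(sd = diameter/4) identical on every plane (an optional attenuation of
alternate planes exercises plane merging); the first
`round(positive_fraction · n)` cells in placement order carry an annular
reporter ring between radii `ring_inner_offset` and
`ring_inner_offset + ring_width`, exactly where the default shell samples.
Both channels get a constant background plus independent zero-mean
Gaussian noise clipped at zero. Fixed seeds give bit-identical stacks.

Reference conditions (the generator defaults): 512×512 frames, 3 planes,
100 nuclei of diameter 12 px, centre separation ≥ 36 px (which keeps each
cell's shell disjoint from every neighbour's ring), nuclear peak 1000 over
background 100, ring intensity 800, noise sd 200 — peak signal-to-noise
≈ 5, a deliberately unflattering noise level for confocal nuclear stains.
Cohort sizes default to 15 lobes per group, within the 10-35 lobes per
condition typical of this assay.

The generator does **not** model optical point-spread functions,
z-anisotropy, nucleus size/shape variation, touching or overlapping cells,
intensity gradients across the tissue, or Poisson photon statistics.
Passing tests therefore demonstrate correctness of the algorithms under
the stated statistical structure, not robustness to every pathology of
real tissue; on real data the density of nuclei (violating the separation
assumption) is the first parameter to examine.

## Numerical and design choices

- Coordinates are 0-based (row, column), origin top-left, everywhere.
- Strict-maximum plateau handling plus row/column tie-breaks make
  detection reproducible bit-for-bit; pipeline re-runs with one config and
  seed are byte-identical (no timestamps enter any output).
- Per-lobe synthesis seeds are SHA-256 hashes of (master seed, group
  label, lobe index) reduced mod 2³¹ — stable under group reordering.
- Empty shell masks (possible at image corners) contribute a shell value
  of 0 with a logged warning rather than an error.
- A lobe with zero detected cells reports its percentage as missing, never
  as 0.
- On-disk stacks are multi-page TIFF (plane-major page order, uint16 for
  integer data, float32 otherwise) with a JSON sidecar for channel names
  and labels; channels are matched by case-insensitive name with aliases.

## Validation experiments and problem sizes

The experiments in `lobequant.benchmarks` (asserted by the test suite,
reported by `scripts/acceptance.py`) use: 20 noisy lobes (2 000 nuclei)
for detection accuracy, 5 noise-free lobes for exactness, 100 random
64×64 responses against the exhaustive peak-finding oracle, 200 random
small samples against the pooled-ECDF KS oracle, 20 lobes at each true
positive fraction in {0, 25, 50, 75, 100}% for classification recovery,
1 000 same-distribution replicates (n = 15 per group) for KS calibration,
and 200 bootstrap replicates for power at 20% vs 60%. The power replicates
resample measured per-lobe percentages from pools of 40 fully-processed
lobes per condition, so they reflect genuine end-to-end measurement noise
at a tractable simulation cost.

## Known limitations

- The relative 75% rule cannot, even with background correction, drive
  false-positive rates in truly all-negative lobes to zero: the threshold
  is then set by the extreme of ~N(0, σ/√(shell pixels)) noise and a few
  percent of cells exceed 75% of it (measured ≈ 3-4 points of error at the
  0% condition, within the ≤ 5-point recovery bound; all other conditions
  recover to well under 1 point).
- Detection assumes roughly uniform nucleus size; strongly varying nuclei
  would need a multi-scale filter bank.
- The KS exact-size lattice effect above means reported α = 0.05 decisions
  at n = 15 are conservative (true size 0.0262).
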