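# Methods

## The model

A run is modelled as a masked `time × voxel` matrix

y(t, v) = Σ_i M_i(v) · a_i · s_i(t) + d(t) + h(t) + Σ_j C_j(v) · c_j(t) + ε(t, v)

where `M_i` are non-negative Gaussian spatial nodes (default: seven
default-mode-network regions at standard-space mm coordinates),
`s_i` are unit-variance Gaussian node courses drawn with a per-condition
target correlation matrix via a Cholesky transform, `d` is a
random-coefficient linear + one-cycle-cosine drift, `h` a >0.1 Hz sinusoid
with random phase, `C_j` compact Gaussian loadings carrying motion-like
(random-walk) and tissue-like (smoothed-noise) confound series `c_j`, and
`ε` white measurement noise. The drug manipulation lives exclusively in the
node correlation matrix; amplitudes are condition-independent, so any
downstream drug effect is a connectivity effect by construction.

Alertness ratings (VAS, 0–100) are generated per subject and condition with
requested condition means (defaults 67.0 drug / 81.4 placebo) and a
controlled across-subject correlation ρ between condition-averaged
alertness and the subject's condition-averaged *realized* Fisher-Z
connectivity on a designated connection. Realized (sampled) rather than
target connectivity is used because targets do not vary across subjects.
Subject-level noise is shared across conditions so the condition average
attains ρ in expectation; the noise term is demeaned across subjects so the
requested condition means are exact.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| run length | 1,316 volumes | TR = 2 s | two 210-volume resting windows flanking a task block |
| discard / trims | 2 initial; RS1 −4 tail, RS2 −4 head | volumes | saturation and task on/offset; RS1 = 204, RS2 = 206 retained |
| node FWHM | 15 | mm | half-maximum volume ≈ 1,770 mm³, a mid-size DMN region |
| baseline r | 0.5 | – | Fisher-Z ≈ 0.55, typical placebo-level DMN coupling |
| planted Δr | 0.4 on 3 of 21 pairs | – | drug-only decrease on three node-disjoint pairs (PSD-safe) |
| white noise | 0.3 | signal sd | keeps symmetric FastICA convergent while non-trivial |
| drift / >0.1 Hz / confounds | 0.5 / 0.3 / 0.4 | signal sd | gives the high-pass and nuisance regressors real targets |
| behavior noise | 10 | VAS points | free parameter; consistent with a paired t ≈ −4.6 on a 14-point condition difference at n = 10 |
| k (ICA modes) | 40 | – | decomposition order for full-scale data; reduced runs use 10 (see below) |
| q, cluster α, iterations | 0.05, 0.05, 1,000 | – | FDR level, cluster-level error, Monte-Carlo count |
| nuisance cutoff | 0.1 | Hz | sine/cosine pairs at every discrete frequency above it |

The default simulation grid is 31 × 40 × 25 voxels at 3 mm, origin
(−45, −63, −24) mm — the smallest 3-mm box containing all seven node
centers and the posterior-cingulate template center (−1, −47, 24). Reduced
runs keep the same mm extent at 6-mm voxels. A note on the segment
arithmetic: dropping the first four volumes of the 210-volume RS2 window
leaves 206 timepoints, not 204; the 204 figure holds for RS1 (210 − 2
discarded − 4 trimmed). The package implements the stated procedure, and
all windows and trims are configurable.

## Preprocessing and numerical choices

- Order is fixed: discard → linear detrend → high-pass → smooth; segments
  are extracted afterwards by original volume number (each series carries
  its acquisition numbering as provenance, so segmentation composes with
  filtering in either order).
- The high-pass removes the mean and the first *n* Fourier pairs of each
  course outright (exact projection, no filter roll-off); the cutoff is
  n / (T · TR) — 5 cycles over 1,314 volumes at TR 2 s ≈ 0.0019 Hz.
- Smoothing zero-pads outside the mask (logged approximation; interior
  voxels are exact).
- Per-voxel variance normalization is applied where the method calls for it
  — before temporal concatenation for group ICA, and to ROI segment courses
  before correlation — but **not** before dual regression. The
  Z-normalization in dual regression belongs to the spatial modes; scaling
  each voxel course to unit variance first erases the maps' amplitude
  profile (measured: subject-map correlation with the planted map falls
  from 1.0 to ~0.15 on noise-free data).
- FastICA uses the symmetric (parallel) scheme with the tanh (log-cosh)
  contrast, tolerance 1e−4, 1,000 iterations. The cubic (kurtosis) contrast
  is available but not the default: on realistic noisy mixtures it
  oscillates indefinitely. Non-convergence triggers seeded restarts (up to
  8), with the tolerance relaxed ten-fold every second attempt — symmetric
  FastICA has no fixed point to find inside a near-Gaussian noise subspace,
  and a loosely-converged rotation of that subspace is harmless. Mode sign
  is fixed by positive spatial skewness, and the selected DMN mode is
  re-oriented to correlate positively with the template.
- Fisher-Z clips |r| at 1 − 1e−7, so duplicated courses map to a finite
  value. Zero-variance courses/voxels are flagged, never propagated as NaN
  into test statistics.
- The smoothness estimator inverts a Gaussian autocorrelation model per
  axis, FWHM = Δ · sqrt(−2 ln 2 / ln ρ) with ρ = 1 − vardiff/(2 var), and
  floors each axis at one voxel width: smoothness below the sampling width
  is not resolvable, so white noise estimates at the voxel size. The
  estimate is the FWHM of the *kernel* that would produce the observed
  lag-one autocorrelation; the Monte-Carlo calibration applies a kernel of
  exactly that FWHM, making the estimate/simulate pair self-consistent.
- Monte-Carlo cluster calibration: per iteration, Gaussian noise on the
  grid, smoothed, standardized in-mask, thresholded two-tailed at the
  cluster-forming p (the pipeline couples it to the realized FDR p
  threshold of the map under test), clusters formed by face adjacency
  (6-connectivity) separately per sign; the minimum extent is the smallest
  size exceeded in at most α of iterations.
- The 2×2 within-subject RM-ANOVA is computed from the sum-of-squares
  decomposition (each factor tested against its factor-by-subject
  interaction); in this design every F equals the squared paired t of the
  corresponding within-subject contrast, which the tests verify against
  scipy and pingouin. Degenerate inputs (zero error SS) return F = 0,
  p = 1 rather than infinities.

## What the generator emulates — and what it does not

It emulates: the two-condition cross-over design with two resting segments,
condition-dependent pairwise coupling, slow drift, above-cutoff
physiological-like oscillation, localized artifact sources with recorded
confound series, and behavior linked to connectivity. Subjects share the
node geometry; between-subject variation enters through course sampling and
noise realizations only.

It does not emulate hemodynamic convolution or autocorrelated BOLD noise
(courses are temporally white), rigid-body motion rendering, anatomical
variability between subjects, or non-DMN brain networks beyond the
artifact sources. Three measured consequences for interpreting the tests:

1. **Spatial ICA returns node-level modes at the default coupling.** With
   baseline r = 0.5, half of each node's variance is node-specific, and the
   sparse single-node representation *is* the correct spatial-ICA solution
   — the network union map (which correlates only ≈ 1/√7 with any single
   blob) cannot emerge as one mode. The union mode does emerge (measured
   |r| 0.81–0.94) when the shared fluctuation dominates (uniform r = 0.9,
   node-specific variance 0.1), which is the regime the cohesive-network
   tests use. Passing those tests shows the machinery recovers a dominant
   network; it does not show that real DMN data are that cohesive.
2. **Nuisance regression of non-DMN mode courses partials the network.**
   When ICA isolates node-specific courses, removing the non-selected
   courses from ROI courses converts marginal correlations into
   quasi-partial ones; a planted change on one pair can then shift other
   pairs. On real data with many non-DMN networks the non-selected courses
   are largely independent of the DMN and the step is benign. The planted
   Δr recovery criterion is therefore evaluated on marginal connectivity
   (simulation → Fisher-Z → RM-ANOVA → FDR), where it is a clean property
   of the inference chain.
3. **Decomposition order must match source richness.** The synthetic brain
   holds ~17 genuine sources; at k ≥ 15 the estimated courses span enough
   of a 204-sample segment that temporal regression acquires a shared
   mask-wide beta bias and ROI definition degenerates. Reduced-scale runs
   therefore use k = 10; the k = 40 default is meant for full-scale data.

Projecting out the >0.1 Hz sine/cosine basis (≈ 122 of 204 temporal
dimensions per segment) perturbs any sample correlation at the 1/√df scale
(measured mean |ΔZ| ≈ 0.09); this is the price of the design, not an
implementation artifact, and the no-signal-destruction test accordingly
regresses only the confound series.

## Problem sizes used in the shipped runs

The test suite and the acceptance script run the voxel-level pipeline on a
16 × 20 × 13 grid at 6 mm (same mm extent as the default grid) with k = 10
and, where a run layout matters, either the full 1,316-volume layout or a
418-volume segments-only variant with identical segment arithmetic.
Statistical recovery studies use 50 simulated studies (drug effect) and 200
replicates (behavior link) at n = 10 subjects and T = 204. These sizes are
the package's reduced-scale defaults; every quantity reported by
`scripts/acceptance.py` is recomputed at run time from these simulations.

## Known limitations

- Gaussian node courses make single-node identifiability rest entirely on
  spatial sparsity; ICA mode identity (which node, which mixture) varies
  across seeds even when recovery quality does not.
- The positive-semidefiniteness of the planted correlation matrices limits
  how large a pairwise Δr can be at a given baseline (Δr = 0.4 requires
  baseline < 0.6 on disjoint pairs); node-level effects (loading changes)
  would allow stronger manipulations.
- ROI labelling assigns the nearest canonical center within 20 mm;
  on coarse grids clusters may merge or split, and labels then carry
  coordinate names or numeric suffixes.
- The cluster-forming threshold inherits the realized FDR p threshold; when
  nothing passes FDR a fallback of p = 0.001 is used for calibration only.
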