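# Methods

This note documents the models implemented in `sfcoupling`, the synthetic
cohorts they are validated on, the parameter choices that matter, and the
limits of what the validation shows.

## Coupling statistics

**Regional SFC.** For region *i*, SFC is the correlation between row *i* of
the structural connectome and row *i* of the functional connectome over
indices *j* with *j ≠ i*, `SC[i,j] ≠ 0` and `FC[i,j] ≠ 0`. The zero
exclusion is exact equality tested after computation: FC entries are
generically nonzero, so in practice the rule removes structural zeros, and
no tolerance parameter is introduced. A region needs at least `min_pairs`
(default 3, the smallest count with a nontrivial correlation) surviving
entries for a defined value; undefined regions propagate as NaN, never as 0.
Pearson correlation is the atlas-resolution convention and Spearman the
voxel-resolution one; both are one `method=` switch.

**Temporal SFC variance.** The panel is split into `n_windows` contiguous,
non-overlapping, equal-length windows (default 20; trailing remainder
timepoints are discarded). SFC is recomputed per window — including the
exclusion mask, which is recomputed within each window because window FC
matrices differ (an option to freeze the static mask would be a one-line
change in `_sfc_from_matrices` callers, but per-window masks are the
default since each window is its own connectome). The variance over defined
windows uses the n−1 (sample) denominator by default, switchable to
population (`ddof=0`); at least 2 defined windows are required.

**Density thresholding.** `threshold_density` keeps the
`ceil(keep_fraction × n_nonzero)` strongest unique edges (default 70%),
breaking ties by weight-descending then lexicographic edge index, so equal
weights threshold deterministically.

## Hurst estimation

Regional series are modelled as stationary fGn-like processes, for which
the detail-coefficient variance of an orthogonal DWT scales as
`Var d_j ∝ 2^{j(2H-1)}` across octaves *j*. Two estimators share the same
wavelet-variance computation:

- `logscale`: weighted least squares of `log2` variance on octave, weights
  equal to coefficient counts; slope *s* gives `H = (s+1)/2`.
- `ml` (default): coefficients at octave *j* treated as independent
  zero-mean Gaussians with variance `σ² 2^{2dj}`; `σ²` is profiled out and
  the likelihood maximized over the fractional-integration parameter
  `d ∈ (−0.49, 0.49)`, with `H = d + 1/2`. This avoids the log-of-variance
  bias of the regression estimator.

Defaults: wavelet `sym4` (least-asymmetric orthogonal family, filter
length 8), periodic extension with wrap-around coefficients retained
(series are much longer than the filter), `j_min = 2` to avoid
filter-initialization bias, `j_max = floor(log2 n) − 3` so the coarsest
octave retains several coefficients. Estimates are clipped to (0.01, 0.99)
with a per-region flag. On exact fGn at n = 4096 both modes recover H with
mean absolute error below 0.02 and agree within 0.08. For 60-sample
windows (windowed co-fluctuation) the octave range is reduced to
`1 … min(floor(log2 L) − 1, pywt.dwt_max_level)`; with so few scales the
per-window estimates are noisy, which is why the co-fluctuation analysis
reports a group summary rather than per-window values.

## Voxel connectivity

Each in-mask voxel has directed edges to its up-to-26 lattice neighbours
weighted `−ln p`. Pair connectivity is `(Π p_k)^{1/L}` along the Dijkstra
shortest path, with `L` counting **edges** — chosen so a single step
returns its own probability; a `root="voxels"` flag switches to node count.
Minimizing `Σ −ln p` and maximizing `Π p` select the same path (verified by
a dual max-product implementation). Ties between equal-probability paths
are resolved deterministically by processing nodes in (distance, index)
heap order and keeping the first-found predecessor; with continuous random
probability fields ties have probability zero. The directed likelihood
matrix is symmetrized by averaging the two directions by default
(`none`/`mean`/`max` available). Correctness is checked against min-plus
dynamic programming over walk lengths ≤ 6 — exact for these graphs because
positive weights make the cheapest walk a simple path.

## Inference

**Spin test.** The empirical statistic is the two-tailed Spearman
correlation over regions where both maps are defined. Each null draw
applies one Haar-uniform SO(3) rotation (QR of a Gaussian matrix with sign
and determinant correction) to the left hemisphere's coordinates and its
mirror conjugate `F R F` (`F = diag(−1,1,1)`) to the right, preserving
hemispheric symmetry; map A is reassigned by nearest rotated neighbour
(maximum cosine) within hemisphere, and the correlation recomputed.
`p_spin = (1 + #{|null| ≥ |r_emp|}) / (N + 1)`, the add-one estimator that
cannot return 0; the tail is counted on absolute values (two-sided). On
independent smooth Gaussian-process map pairs over a 400-region sphere the
empirical false-positive rate at α = 0.05 is 0.03–0.09 across seeds —
the mild anti-conservatism is a known property of
nearest-neighbour reassignment nulls.

**Fisher combination.** `T = −2 Σ ln p_i` referred to χ² with `2n` df
(`n = 9` subjects gives df = 18); the single-p combination is the identity
because the df = 2 survival function is `exp(−T/2)`.

**Bootstrap standardized regression.** Designs are built by centering the
designated predictor pair, appending their product as the interaction, and
squared centered terms as requested; columns are z-scored *after*
construction (within each bootstrap resample as well), so reported
`β_stand` are comparable across terms. Inference resamples rows with
replacement (default 10,000 reps), reporting 95% percentile intervals and
two-tailed sign-crossing p-values with add-one smoothing,
`p = 2 min[(1+#{β* ≤ 0}), (1+#{β* ≥ 0})]/(B+1)` — the bootstrap p-value
convention chosen here since several exist. VIF is `1/(1−R²_j)` of each
predictor on the others, flagged above 5; a lone predictor reports VIF 1.
Rank-deficient designs are rejected up front. Coverage of the true
standardized coefficients is ≥ 90/100 in simulation at n = 400.

**Tamhane's T2** is implemented as pairwise Welch *t* statistics with
Satterthwaite df and the conservative Sidák bound over all pairs — the
standard conservative form of the procedure. **Breusch–Pagan** follows the
three-step recipe: fit OLS, square the unstandardized residuals, regress
them on the predictors, and report the auxiliary regression's F statistic
and p-value. **Mediation** fits `m ~ x`, `y ~ x + m`, `y ~ x` by OLS with
intercepts, so total = direct + indirect holds to machine precision; the
indirect effect `a·b` is bootstrapped by joint row resampling and judged by
whether its percentile interval excludes zero.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
with known ground truth:

- **Regions.** Fibonacci lattices on mirror-symmetric half-spheres (left
  `x < 0`, right `x > 0`), no rejection sampling. The hierarchy gradient is
  angular distance from each hemisphere's pole plus a squared-exponential
  Gaussian-process perturbation (length-scale `smoothness`, default 0.5
  rad), standardized. Class labels are gradient quantile bins (default 5
  classes, the granular→agranular analogue). Myelin is affine in the
  gradient plus noise; the default slope (−0.3) and noise (0.45) give a
  gradient–myelin correlation near −0.6, matching the sign and rough
  strength of empirical T1w/T2w maps rather than a deterministic proxy.
- **Structural connectome.** `w_ij ∝ exp(−decay·d_ij −
  gradient_decay·|Δg|)` with multiplicative log-normal noise, thresholded
  to the requested density (default 0.35), symmetric with zero diagonal.
  `decay` is a rate, so large values concentrate weight on nearest
  neighbours.
- **fGn.** Exact circulant embedding (order 2n) of the fGn autocovariance
  `γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})`; negative embedding
  eigenvalues (possible only at extreme H with tiny n) are truncated at
  zero with a warning.
- **BOLD panel.** Region *i* is
  `√c_i · shared_i + √(1−c_i) · private_i`, where `private_i` is fGn with
  the prescribed `H_i` and `shared_i` the standardized SC-row-weighted
  mixture of per-region latent fGn sources. Strongly connected regions
  share similar mixtures, so realized SFC increases monotonically in the
  prescribed coupling `c_i` (Spearman ≈ 0.6 at 1200 timepoints).
- **Study-condition defaults** (`CohortSpec`): 400 regions, 5 classes,
  1200 timepoints at TR 0.72 s (one run), H declining 0.85 → 0.60 along
  the gradient rank with independent noise 0.12, and coupling
  `0.5 + 0.3·z(myelin) + 0.3·z(H) + 0.05·ε` clipped to [0.05, 0.95]. The
  noise scales were calibrated so the *measured* whole-brain pattern has
  the magnitude the empirical literature reports — standardized effects of
  myelin and Hurst on SFC of order 0.15–0.35 with VIF ≈ 2, and a strong
  but non-deterministic SFC–gradient correlation — rather than the
  near-deterministic maps that smaller noise produces, where the Hurst
  partial effect would be an artifact of estimator noise.
- **Transition fields.** Spatially smoothed Gaussian log-probability
  fields per direction, an `anisotropy` bias along +x, transitions off the
  lattice or into masked voxels zeroed, per-voxel normalization.
- **Seeding.** One master seed is split into named substreams via CRC-32
  labelled `SeedSequence` spawn keys (`sfcoupling._rng.substream`), so
  every generator and every stochastic inference routine is a pure
  function of (arguments, seed) and regeneration is bit-identical.

**What the generator does not emulate:** hemodynamic response, scanner
noise and motion, multi-run session structure, geometry of real cortical
surfaces, tractography biases, or voxel counts at brain scale (voxel tests
run on lattices ≤ 10³). Passing recovery tests therefore demonstrates
statistical correctness of the estimators under the assumed generative
model, not robustness to the artefacts of real acquisitions.

## Pipeline conventions

`run_atlas_analysis` executes: static and windowed FC → regional SFC and
temporal variance → Hurst map → spin tests of both statistics against
gradient, myelin, and Hurst → class-wise ANOVA with Tamhane post-hocs →
whole-brain bootstrap regressions (SFC and variance on myelin, Hurst,
their interaction, and the gradient covariate; an optional quadratic Hurst
term for the variance model, exposed because the linear-plus-interaction
and quadratic specifications both appear in practice) → per-class
regressions with BH-FDR across classes per predictor → mediation
(myelin → Hurst → variance) → optional windowed SFC–Hurst co-fluctuation.
Every reported p-value's adjustment status and every seed is recorded in
the result metadata; rerunning an identical config is bit-identical.
Optional exclusion of regions whose temporal variance lies more than
`outlier_sd` (conventionally 3) standard deviations from the mean is off
by default and reported when on. Multi-subject runs report each
statistic's mean and [min, max] range across subjects plus the Fisher
combination of per-subject p-values.

Validation problem sizes (50 replicates at n = 4096 for Hurst recovery,
200 map pairs × 500 rotations for spin calibration, 100 simulations ×
1000 bootstrap reps for coverage, and a single 400-region cohort at 1000
rotations / 2000 reps end-to-end) are chosen to give stable Monte-Carlo
estimates at interactive runtimes; all convergence-relevant knobs
(rotations, bootstrap reps, windows, density) are configuration defaults,
not constants.

## Known limitations

- The wavelet-ML estimator assumes within- and across-scale independence
  of wavelet coefficients; this is approximate for fGn, contributing the
  small (+0.02) positive bias visible at high H.
- The spin test's nearest-neighbour reassignment duplicates some regions
  and drops others per rotation, which slightly inflates the false-positive
  rate (up to ~0.09 at nominal 0.05 in our calibration).
- Per-window Hurst estimates at 60 samples use 3 octaves and are noisy;
  window-level co-fluctuation results are only meaningful as group
  summaries.
- Mediation assumes linear effects and no unmeasured confounding; the
  bootstrap interval quantifies sampling variability only.
- Tamhane's T2 is implemented in its conservative Sidák-bound form; exact
  small-sample multipliers would be slightly less conservative.
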