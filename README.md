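# sfcoupling

Structure–function coupling in cortical connectomes, its moment-to-moment
variance, and their biological correlates — intracortical myelination and
excitation–inhibition balance — with the full inferential stack needed to
analyse them, validated end-to-end on synthetic cohorts with known ground
truth.

## The scientific problem

Anatomical (structural) connectivity constrains but does not determine
functional connectivity, and the strength of that constraint varies
systematically across the cortex: coupling weakens from unimodal sensory
cortex toward transmodal association cortex. This package implements the
analysis stack used to quantify that pattern and probe its biology:

- **Structure–function coupling (SFC).** For region *i* with structural
  connectome row `SC[i]` and functional connectome row `FC[i]`,
  `SFC_i = corr(SC[i], FC[i])` (Pearson for atlas-resolution data, Spearman
  for voxel-resolution data), excluding the self-connection and any entry
  where either row is zero.
- **Temporal SFC variance.** The scan is split into `W` contiguous
  non-overlapping windows (default `W = 20`); `var_i = Var(SFC_i^(1), ...,
  SFC_i^(W))` measures how much a region's coupling fluctuates over time.
- **Hurst exponent `H` as an EI-ratio proxy.** Each region's time series is
  modelled as a stationary fractionally integrated process; `H` is estimated
  from the scaling of discrete-wavelet variances across octaves
  (`Var d_j ∝ 2^{j(2H-1)}`), by profile maximum likelihood or log-scale
  regression. Lower `H` indicates a heightened excitation–inhibition ratio.
- **Voxel connectivity by analytic tractography.** Given 26-neighbour fibre
  transition probabilities, voxel-pair connectivity is the geometric mean of
  transition probabilities along the most probable path — Dijkstra's
  algorithm on `-ln p` edge weights — thresholded to the strongest 70% of
  edges.
- **Inference.** Spatial permutation ("spin") tests that preserve spatial
  autocorrelation and hemispheric symmetry; Fisher's method
  `T = -2 Σ ln p_i ~ χ²(2n)` for multi-subject combination; one-way ANOVA
  with Tamhane's T2; Breusch–Pagan heteroscedasticity checks; OLS with
  standardized β, 10,000-rep nonparametric bootstrap confidence intervals,
  and VIF screening (flag > 5); BH-FDR; and the mediation model
  myelin → Hurst → temporal SFC variance.

Because the empirical inputs (tractography, BOLD, T1w/T2w maps) are not
reproducible at desk scale, the package ships a first-class synthetic-cohort
generator: quasi-uniform bilateral region sets on the sphere, smooth
hierarchy gradients, distance- and gradient-dependent structural
connectomes, exact fractional Gaussian noise (circulant embedding), and
BOLD-like panels with *prescribed* per-region Hurst exponents and
*prescribed* coupling to the structural backbone — so every statistic can be
validated by parameter recovery.

## Worked example

```python
import sfcoupling as sf

config = sf.AnalysisConfig(seed=7, spin_rotations=1000, n_boot=2000,
                           run_cofluctuation=False)
result = sf.run_atlas_analysis(config)
print(result.spin_table.round(4).to_string(index=False))
print(result.whole_brain["sfc"].table().round(3).to_string())
```

prints (400 regions, 1200 timepoints, default cohort — coupling, Hurst and
myelin all declining along the hierarchy gradient):

```
    map   target       r  p_spin  n_rotations
    sfc gradient -0.7629   0.001         1000
    sfc   myelin  0.5341   0.001         1000
    sfc    hurst  0.6990   0.001         1000
var_sfc gradient  0.4998   0.001         1000
var_sfc   myelin -0.5828   0.001         1000
var_sfc    hurst -0.5780   0.001         1000

                beta_stand  bci_low  bci_high  p_boot    vif  vif_flag
myelin               0.235    0.166     0.309   0.001  1.323     False
hurst                0.255    0.165     0.337   0.001  1.971     False
gradient            -0.449   -0.538    -0.360   0.001  2.163     False
myelin_x_hurst      -0.085   -0.144    -0.023   0.011  1.087     False
```

Reading the output: SFC declines along the hierarchy gradient (spin-test
Spearman `r = -0.76`, permutation `p = 0.001`) while its temporal variance
rises (`r = +0.50`); more myelinated and higher-`H` (lower EI-ratio) regions
are more tightly coupled, and both markers retain positive standardized
effects (`β = 0.235` and `0.255`, bootstrap intervals excluding zero) after
adjusting for each other, their interaction, and the gradient itself. The
mediation summary for the same run,

```
mediation: total=-0.0064 direct=-0.0050 indirect=-0.0014
           BCI=(-0.0019, -0.0010) proportion=0.223
```

says that about 22% of myelin's (negative) effect on coupling variance is
carried through the Hurst exponent.

A thin CLI wraps the same library calls:

```sh
sfcoupling generate cohort/ --seed 7        # write a synthetic cohort
sfcoupling run results/ --config cfg.yaml   # full analysis, all tables
sfcoupling spin regions.tsv gradient myelin # single-stage utilities
```

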