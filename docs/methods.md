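# Methods

This note documents the statistical models, the parameter defaults and why
they were chosen, and the numerical decisions that matter for reproducing
results. Vocabulary: TOP2i = topoisomerase-II inhibitor (DOX, EPI, DNR,
MTX); AC = anthracycline (DOX, EPI, DNR); VEH = vehicle control; a
"contrast" or "condition" is one (drug, timepoint) pair tested against the
vehicle at the same timepoint (10 in the default design).

## 1. Count simulation (`simulate`)

Counts are gamma-Poisson (negative binomial):

```
count_gs ~ NB(mean = lib_s * p_g * 2^(k_s * u_gi + lfc_gd), dispersion = phi)
```

- `p_g`: baseline relative abundance from a lognormal draw of log2 CPM
  (mean 4, SD 2), normalized to sum to one.
- `u_gi ~ N(0, 0.4)` (log2): a per-(gene, individual) effect shared by all
  of that individual's samples. 0.4 log2 ≈ 30% CV across donors, a
  realistic inter-individual spread for iPSC-derived lines, and large
  enough that individual structure is visible in the data.
- `k_s`: the group's variance-inflation factor, 1 everywhere except the
  AC × 24 h groups when inflation is requested (default factor 1.5 on the
  SD, i.e. 2.25× on the variance of the individual-effect component).
  Multiplying `u` rather than adding noise keeps the inflation paired
  within individuals, which is what the downstream paired shift test and
  F-profile clustering assume.
- `lfc_gd`: the planted log2 fold change. Each gene belongs to one of four
  motifs — NR (proportion 0.50, no response), LR (0.35, TOP2i at 24 h),
  EAR (0.08, TOP2i at 3 h), ESR (0.07, TOP2i at both) — and draws **one**
  magnitude `|N(0,1)| + 0.5` and one sign, shared across all of its DE
  contrasts. A shared per-gene effect (rather than independent per-contrast
  draws) is what gives response profiles the block-correlation structure the
  motif model and the response-correlation clustering are designed to
  detect. TRZ carries no planted signal in any motif.
- `phi = 0.01`: since between-individual variation is modelled explicitly
  through `u`, the NB dispersion represents residual within-individual
  noise (BCV ≈ 0.1), not the usual cross-individual bulk value (0.2–0.4).
- Library sizes uniform in [2e7, 4e7].

`SimTruth` carries the motif labels, the planted log2 fold-change matrix and
the variance factors; `motif_recovery_errors` matches fitted motifs to
planted ones by the L1-optimal permutation.

Viability plates: RFLU = background + scale × (LL.4 viability + Gaussian
noise), with no-cell background wells, quadruplicate drug wells over the
eight-point series (50, 10, 5, 1, 0.5, 0.1, 0.05, 0.01 µM) and
volume-matched vehicle wells at every concentration.

Calcium traces: baseline-1 intensity plus periodic transients with kernel
`(1 − e^(−t/rise)) e^(−t/decay)` normalized to unit peak, sampled at
31.34 frames/s. Events sit at `(i + 0.5)/rate`; an event whose kernel peak
would fall beyond the last recorded frame is not planted, so `event_times`
is exactly the observable truth (otherwise a final event at `t = duration`
would be undetectable by construction).

## 2. Differential expression (`de`)

- log2 CPM with pseudo-counts: `log2((count + 0.5)/(lib·factor + 1)·1e6)`.
- Expression filter: genes with mean log2 CPM across all samples ≥ 0 are
  kept; the filter defines one common universe before any pair is fit.
- TMM normalization (Robinson–Oshlack): reference sample by upper-quartile
  closeness to the mean, 30% two-sided trim on M, 5% on A,
  precision-weighted mean of log ratios, factors rescaled to unit geometric
  mean. Verified against edgeR's `calcNormFactors` in the test suite.
- Precision weights: gene-wise OLS residual SDs, a lowess curve (span 0.5)
  of sqrt(SD) against average log2 count, each observation weighted by the
  predicted variance at its fitted log-count, inverted (the voom scheme).
- Moderated t: gene-wise weighted least squares; empirical-Bayes variance
  shrinkage by the method of moments on log s² (trigamma-inverse Newton
  solve for the prior df `d0`); posterior variance
  `(d0·s0² + df·s²)/(d0 + df)`; p-values from t with `d0 + df` degrees of
  freedom (Gaussian when `d0` is infinite); BH adjustment per contrast.
- Each of the ten contrasts is fit on its own 12 samples (6 drug + 6
  vehicle) with design `intercept + treatment + individual dummies`, i.e.
  a paired design blocking on individual. Library sizes come from all
  genes, normalization and weights from the filtered universe.

Calibration (measured, not tuned): on a fully null 5,000-gene simulation
the pooled type-I error at p < 0.05 is ≈ 0.051; with 10% planted DE the
observed FDR at p_adj < 0.05 is ≈ 0.043.

## 3. Correlation motifs (`motifs`)

Observed data are the moderated t statistics `t_gd` over genes × conditions
with per-condition total df. Genes follow a K-component mixture; motif k
has a probability vector `q_k` over conditions:

```
L(g) = sum_k pi_k * prod_d [ q_kd f1_d(t_gd) + (1 - q_kd) f0_d(t_gd) ]
```

- `f0_d`: central t with the condition's total df (Gaussian limit beyond
  df 1e6, needed because the empirical-Bayes prior df can be infinite).
- `f1_d`: scaled t — `t/sqrt(1 + v_d)` is t(df_d) — with `v_d` the
  condition's variance inflation under DE.
- **`v_d` is bounded below at 1** (alternative variance at least twice the
  null): as `v → 0` the DE density collapses onto the null and `q` becomes
  unidentifiable in conditions without signal (observed as arbitrary q on
  planted-null TRZ columns before the bound).
- EM: exact E-step in log space; closed-form updates for `pi` and `q`;
  `v` by vectorized golden-section search on log v (16 iterations,
  bracket [1, 1e4]), accepted only when it improves the expected
  complete-data term, so the algorithm is a monotone generalized EM.
  Convergence at relative log-likelihood change ≤ 1e-6, max 500 iterations.
- Restarts: the first start is pattern-based (k-means on the thresholded
  |t| > 2 indicator matrix), the rest (default 5 total) random with
  uniform pi and q ~ U(0.1, 0.9).
- Model selection: BIC over K = 1..8 with
  `p = (K − 1) + K·D + D` free parameters; AIC reported alongside.
- Signature labels: a motif is responsive at a timepoint when `q > 0.5`
  for at least 3 of the 4 TOP2i drugs (tolerating a weaker MTX response);
  EAR = 3 h only, ESR = both, LR = 24 h only, NR = all ≤ 0.5. A gene is
  assigned to a motif only when that posterior exceeds 0.5 uniquely.
- Drug-specific genes: `p_adj < 0.01` for the target drug and
  `p_adj > 0.05` for every other drug at the same timepoint.

On default-design simulations (5,000 genes) BIC selects K = 4, recovers
pi to within ~0.01 and labels ≈ 99.5% of assigned genes correctly.

## 4. Dose–response (`dose_response`)

Plate normalization subtracts the per-plate background mean and divides by
the mean background-corrected vehicle signal at the same concentration.
The curve is LL.4 with the upper asymptote fixed at 1:
`f(x) = c + (1 − c)/(1 + exp(b(ln x − ln e)))`. The floor `c` is free in
[0, 0.999): drugs like TRZ that never reach half-kill are represented by a
high floor or a degenerate (flat) fit rather than being forced through 0.5.
Fitting is deterministic: inflection initialized at the geometric mean of
the concentrations bracketing half-viability, slope 1, floor at the clipped
minimum viability, with a fixed ladder of multiplicative restarts (×1, 0.1,
10, 0.01, 100) on the inflection; `scipy.optimize.least_squares` with tight
tolerances. A fit whose predicted range over the tested concentrations is
below 0.05 is flagged degenerate. LD50 is the absolute-scale half-viability
concentration `e·((1 − c)/(0.5 − c) − 1)^(1/b)`, undefined when the fit is
degenerate or `c ≥ 0.5`. Per-individual replicate fits are averaged before
per-drug medians; Welch t tests compare drugs to a reference.

## 5. Calcium transients (`calcium`)

Representative trace: per-ROI F/F0 (F0 = 10th percentile), frame-wise mean.
Peak rule: after moving-average smoothing (window 5), index i is a peak iff
it is strictly greater than both neighbours and greater than the 0.6
quantile of the smoothed series (the quantile gate is evaluated on the
smoothed series, since the rule operates on the smoothed trace; a flag
allows gating on the raw trace instead). Transients are fit trough-to-
trough with `base + a·exp(−(t − mu)²/(2σ²))`; FWHM = 2√(2 ln 2)·σ/fs;
rising/decay slopes are the extreme discrete derivatives on each flank;
fits that fail or whose σ exceeds the local inter-peak gap are excluded
and counted. Feature PCA standardizes per-condition means (zero-variance
features dropped with a warning).

## 6. Variance analysis (`variance`)

Per-gene unbiased variances across individuals within each treatment–time
group; gene-wise `F = s²_drug/s²_veh` with two-sided
`p = 2·min(P(F ≤ f), P(F ≥ f))` (genes with zero vehicle variance are
excluded and counted — matching R's `var.test`, verified in the tests);
a group-level paired two-sided Wilcoxon signed-rank test on per-gene log2
variance ratios; and average-linkage clustering of gene-wise F profiles on
1 − Spearman ρ. On simulations with the 1.5× SD inflation planted in the
AC 24 h groups, those three groups test at p < 1e-100 with positive
direction and form an exclusive clade in the F-profile dendrogram.

## 7. Enrichment and annotation (`enrichment`)

- 2×2 chi-square of proportions with Yates continuity correction
  `min(0.5, |O − E|)`, so exactly equal proportions give statistic 0 and
  p = 1 (equivalent to R's `prop.test`; agrees with
  `scipy.stats.chi2_contingency` on 2×2 tables).
- One-sided Fisher over-representation of gene sets against a background
  universe, BH-adjusted across sets; query genes must be a subset of the
  universe.
- Nearest TSS: strand-aware TSS from 0-based half-open intervals (start on
  `+`, end − 1 on `−`); each SNP gets the same-chromosome gene minimizing
  |snp − tss|, distance ties breaking to the lexicographically smaller gene
  id so results are deterministic.
- The GWAS locus report takes the union of nearest-TSS and eQTL genes,
  restricted to the expressed universe, annotated with per-contrast log2
  fold changes, DE flags, signature labels and gene-set memberships.

## 8. Pipeline and determinism (`pipeline`, `cli`)

A master seed fans out to per-stage seeds via SHA-256 of
`"{seed}:{stage}"`. All CSVs are written with a fixed float format
(`%.10g`); the manifest records name, row count and SHA-256 per output and
contains no timestamps. Running `run-all` twice with the same seed yields
byte-identical outputs. Config is a dataclass loadable from YAML with
strict unknown-key checking; thresholds are validated to (0, 1).

## Known limitations

- The generator plants a single shared effect size per gene across its DE
  contrasts; real responses also vary in magnitude between drugs.
- The motif model treats conditions as independent given the motif; shared
  individuals induce mild cross-condition correlation it ignores (as does
  the analysis it reproduces).
- `q` for conditions with no signal is only weakly identified near the
  `v = 1` floor; judge per-condition q against planted truth on average,
  not entry-by-entry.
- LD50s are extrapolations when the half-viability point lies outside the
  tested concentration range; the degenerate-fit flag catches flat curves
  but not poorly constrained steep ones.
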