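# Methods

## The model

SNP-array copy-number signals — Log R Ratio (LRR, total intensity, ~0 at
diploid copy number) and mirrored B Allele Frequency (mBAF, allelic
imbalance, ~0.5 at diploid) — are modeled as noisy piecewise-constant
sequences on a shared probe grid:

    y_ij = beta_ij + e_ij,   i = 1..M sequences, j = 1..N probes,

with the means `beta_ij` constant on runs of probes and, after
normalization, equal to 0 at normal copy number.  The estimator minimizes
the generalized fused lasso objective

    f(beta) = 1/2 sum_ij d_ij (y_ij - beta_ij)^2
            + sum_i lam1_i sum_j |beta_ij|
            + sum_i lam2_i sum_j |beta_ij - beta_{i,j-1}|
            + sum_j || lam3 * (beta_(j) - beta_(j-1)) ||_2 ,

where `d_ij` marks observed entries, the first penalty shrinks levels
toward the diploid baseline, the second (total variation) sparsifies
within-sequence jumps, and the third — an L2 norm over the column vector of
jumps, weighted entry-wise by `lam3` — lets a jump in one sequence lower
the marginal cost of a jump at the same probe in the others.  Together the
fusion and group terms act like a sparse group lasso on jumps: change
points may be shared by some, not necessarily all, sequences.

Sequences measured at different genomic positions (e.g. mBAF, defined only
at heterozygous probes, alongside LRR) are stacked on the sorted union of
their positions; unobserved entries enter no data term and their fitted
means are interpolated purely by the penalties from neighboring probes.
Fitting is per chromosome: a CNV never spans two chromosomes.

## The MM algorithm

Each norm `||x||` is smoothed to `||x||_{2,eps} = sqrt(||x||^2 + eps)`.
Concavity of the square root gives, at the current iterate, a quadratic
majorizer of every penalty term; the resulting surrogate separates across
sequence rows, and each row's minimizer solves a symmetric
positive-definite tridiagonal system A_i beta_i = b_i.  The diagonal of
A_i collects the data indicator, the lasso weight `lam1_i /
||beta_ij||_{2,eps}`, and the two fusion couplings `lam2_i /
||jump||_{2,eps}` and `lam3_i^2 / ||lam3 * column-jump||_{2,eps}`; the
off-diagonal is minus the coupling.  Systems are solved with a banded
Cholesky factorization (LAPACK via `scipy.linalg.solveh_banded`), giving
O(MN) per iteration.  Majorize-then-minimize guarantees the smoothed
objective never increases; against an independent quasi-Newton minimizer
of the same smoothed objective the fixed points agree to ~1e-8 relative on
random small instances.

Numerical choices:

* `eps = 1e-8` (on signals with noise SD near 1).  The smoothing bias of a
  fitted level is O(sqrt(eps)) ~ 1e-4, far below any jump of interest,
  while 1/sqrt(eps) bounds the surrogate weights and keeps the systems
  well conditioned.
* Convergence when the relative objective decrease or the largest change
  of any `beta` entry falls below `tol = 1e-6`; cap `max_iter = 500`.
  Non-convergence warns and returns the last iterate rather than raising.
* Initialization at the masked data (unobserved entries 0, the diploid
  baseline); with all penalties zero the fit returns the data exactly in
  one step.
* Exact scale equivariance (y, lambdas scaled by s; eps by s^2) holds for
  the data, lasso and fusion terms; the group-norm argument carries units
  lambda*signal, so with the group term active equivariance holds to
  O(sqrt(eps)) only.  This is a property of the smoothing, not of the
  estimator it approximates.

## Choosing the penalties

With `sigma_i` the robust noise SD of sequence i — estimated as
`dispersion(first differences of consecutive observed values)/sqrt(2)`,
MAD-based by default so the few differences that bridge real change points
do not inflate it — the defaults are

    lam1_i = c1 * sigma_i,
    lam2_i = rho(p) * c2 * sigma_i * sqrt(log N),
    lam3_i = (1 - rho(p)) * c3 * sigma_i * sqrt(p * M * log N),

with `rho(p) = 1 - p` interpolating the two constrained endpoints: p = 1
(all sequences share every CNV, e.g. LRR + mBAF of one subject) gives pure
group fusion, p = 0 (unrelated sequences) pure within-sequence fusion.
Multipliers default to `c1 = 0.1` (so lam1 ~ 0.1 on unit-noise signals)
and `c2 = c3 = 1`; the sqrt(log N) factor plays the usual
multiple-comparison role over the N-1 candidate jump positions.  An
optional per-boundary weight vector can down-weight the jump penalties in
regions known to harbor copy-number polymorphisms.  Penalties this size
are deliberately lax: estimation bias scales like lam2 (or lam3) divided
by segment length, so levels of short segments are shrunk noticeably —
which is why segment means are recomputed from the raw data afterwards and
why a second thresholding stage exists.

## Two-stage segmentation

Stage one fits with the lax defaults; stage two hard-thresholds the fitted
jumps `d_ij = beta_ij - beta_{i,j-1}` (those above a numerical floor of
1e-6 * sigma_i):

* **Ruler** (default): with `D_i` the largest absolute fitted jump of
  sequence i, `gamma_i = max(a*sigma_i, min(D_i, b*sigma_i))` estimates
  the scale of a plausible real jump; jumps below `c * gamma_i` are
  dropped.  Constants a=1, b=5, c=0.2.  On a pure-noise sequence the
  cutoff bottoms out at 0.2*sigma, so a handful of noise jumps can
  survive; the likelihood-ratio caller is the stage that rejects them.
* **mBIC**: candidates ranked by |jump| (ties: earlier index first) are
  added one at a time; the normal-means criterion
  `(n/2) log(RSS_0/RSS_k) - 1/2 sum_u log(L_u/n) - 1.5 k log n`
  is maximized over k (k = 0 allowed).  The penalty constant is exposed,
  and the nested search stops at `max_k = 50` candidates: the profile
  likelihood degenerates as k approaches n (the saturated model drives the
  RSS to zero), and realistic change-point counts sit far below the cap.
  mBIC yields exactly one segment on null chromosomes and is the stricter
  choice when segmentation output is consumed without calling.

Retained jumps partition each sequence; segment means are recomputed as
averages of observed data.  When one genome contributes several signals
(LRR + mBAF), their retained change points are unioned into one finer
segmentation per sample.  In `both` mode the mBAF track is centered at 0.5
before fitting so the sparsity penalty shrinks it toward its own diploid
baseline, and the two tracks are fused with p = 1.

## Copy-number calling

Each segment R of one subject is scored against the diploid state by

    LR(c) = log L_BAF(x_R; c)/L_BAF(x_R; 2) + log L_LRR(y_R; c)/L_LRR(y_R; 2)

for c in {0, 1, 3, 4}.  LRR is normal around state means
(-3.0, -0.66, 0, 0.40, 0.68) — the gain levels saturate, which is why
3-vs-4 confusion is the caller's soft spot — with the subject's own
estimated noise SD.  BAF under state c >= 1 is a mixture over genotype
clusters at fractions k/c with binomial(c, p_B) weights (p_B = 0.5
default), cluster SD 0.03 at the 0/1 boundaries and 0.05 inside, plus a 1%
uniform outlier component; under c = 0 (no DNA) BAF is uniform noise.
Because array software clips BAF to [0, 1], boundary clusters are modeled
as the exact law of clipped Gaussian noise: an atom holding the clipped
half of the cluster mass plus the interior half-density.  All states use
the same dominating measure (Lebesgue plus atoms at 0 and 1), so the
ratios are well defined; a 1e-12 per-probe density floor prevents a single
wild value from vetoing a segment.

The maximizing state is accepted only if `LR > r1` (default 10) and the
absolute LRR segment mean exceeds `r2 * sigma` (r2 = 1 for gains, 1.5 for
losses): long diploid segments often carry a small artifactual mean offset
that sheer probe count would otherwise promote to a call.  Ties in the
argmax prefer the state closer to diploid, and the deletion on the exact
0-vs-4 tie.  Calling is always per subject, even after joint segmentation.

## Synthetic data

The generators produce the three study designs the method targets, with
per-probe ground truth:

* **Cohort**: CNVs of specified length/state/carriers inserted into
  diploid samples; LRR ~ Normal(state mean, sd) (default sd 0.2; the
  benchmark scenario uses 0.25), BAF from the genotype-cluster mixture
  with Hardy-Weinberg genotypes, clipped to [0, 1].
* **Tumor dilution**: a tumor with allele-specific region counts (major,
  minor) mixed with a fraction alpha of normal cells; effective copy
  number `n_eff = 2 alpha + (1 - alpha) c_tumor` gives LRR mean
  `log2(n_eff/2)` (floored at -5 where arrays saturate) and BAF mean
  `(alpha g + (1 - alpha) b_t)/n_eff` per germline genotype g, with the
  affected haplotype chosen at random per probe.  (2, 0) regions encode
  copy-neutral LOH: LRR-invisible, BAF-visible.
* **Pedigree**: carrier sets drawn independently per sequence with
  probability p_share (at least one carrier forced).

What the generators do not emulate: real array noise is heavier-tailed
than Gaussian and shows GC-content waves and probe-specific biases;
genotypes here are linkage-free; probe spacing is uniform.  Detection
rates on these data are therefore an idealized ceiling demonstrating the
machinery, not predictions for a particular array product.  Scoring is
per SNP: TPR is the fraction of truth-variant probes called with a
variant of the same direction, FDR the fraction of variant-called probes
that are truly diploid (reported as 0 with a flag when nothing is called).

## Problem sizes and runtime

The test suite and the acceptance script run the benchmark cohort at
M = 20 samples x N = 2000 probes with CNVs of 5-50 probes at noise SD
0.25, the tumor scenario at N = 2000 with a 500-probe hemizygous deletion
across contamination levels 0-75%, and 200-300 Monte-Carlo replicates for
the calling and mBIC calibrations — sizes at which the whole suite
completes in about a minute on one core while the stochastic pass margins
remain wide.  The solver itself handles millions of probes; cost per
iteration is O(MN) and memory is a few matrices of that size.

## Known limitations

* Penalty levels follow fixed guidelines; no data-adaptive selection of
  c1-c3 or estimation of a varying sharing proportion p.
* The five-state caller does not emit copy-neutral LOH (such regions are
  segmented but typically reported as diploid by LRR-dominated calls) and
  assumes tumor-free mixture levels in its state means, so heavily
  contaminated aberrations are judged against attenuated evidence.
* Homozygous probes carry no mBAF information, and missingness is
  copy-number dependent (deletions increase apparent homozygosity); the
  union-grid treatment ignores that information channel.
* No GC-wave or intensity normalization is included; inputs are assumed
  pre-normalized.
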