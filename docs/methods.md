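# Methods

`cismr` implements a cis-instrument two-sample Mendelian randomisation (MR)
workflow of the kind used to anticipate drug effects from GWAS summary
statistics — here modelled on IL-6 receptor (IL6R) blockade, read out as a
decrease in natural-log C-reactive protein (lnCRP), against binary
infection outcomes such as sepsis. This note records the models, the
parameters that matter, the synthetic-data conditions, and the design
decisions taken where the method family leaves choices open.

## Causal model and estimators

For variant *j*, let γ̂_j (SE s_γj) be its association with the exposure
(lnCRP per effect allele) and Γ̂_j (SE s_Γj) its association with the
outcome (log-odds per effect allele), estimated in non-overlapping
cohorts. Under the instrumental-variable assumptions (relevance, no
confounding of the variant–outcome relation, and effect on the outcome
only through the exposure), each variant yields a Wald ratio

    β̂_j = Γ̂_j / γ̂_j,   se(β̂_j) = s_Γj / |γ̂_j|   (first order),

and the inverse-variance-weighted (IVW) estimate pools them with weights
w_j = γ̂_j² / s_Γj²:

    β̂_IVW = Σ w_j β̂_j / Σ w_j,   se = (Σ w_j)^(-1/2)  (fixed effects).

The first-order SE neglects uncertainty in γ̂_j, which is adequate for
strong instruments (the fixture's minimum F = (γ̂/s_γ)² is 31.1; simulation
shows the residual attenuation is well inside Monte-Carlo noise at that
strength). β̂_IVW is algebraically the zero-intercept weighted
least-squares slope of Γ̂ on γ̂ with weights 1/s_Γj², which the tests verify
against an independent solver. A multiplicative-heterogeneity variant
inflates the SE by max(1, √(Q/(n−1))) without moving the point estimate;
the default is fixed effects, with the other exposed by flag. Cochran's
Q = Σ w_j (β̂_j − β̂_IVW)² with n−1 df accompanies every pooled estimate.

Sensitivity estimators:

- **MR-Egger** — weighted regression of Γ̂ on γ̂ *with* an intercept, after
  re-signing instruments to γ̂ > 0 (the standard orientation convention;
  without it a directional pleiotropic effect defined per
  exposure-increasing allele averages out). The intercept estimates the
  mean directional pleiotropic effect; coefficient SEs are inflated by
  max(1, residual scale) so underdispersion never tightens them, and
  p-values use t with n−2 df. The regression itself is delegated to
  statsmodels WLS.
- **Weighted median** — the weight-ordered ratio distribution interpolated
  at the 50th percentile (cumulative midpoints p_j = Σ_{k<j} w'_k + w'_j/2);
  consistent while under half the total weight comes from invalid
  instruments. Its SE comes from a parametric bootstrap (β̂_j resampled
  from N(β̂_j, se_j²), weights fixed, default 1,000 draws, seed mandatory).
  Note the consistency guarantee is asymptotic in per-variant precision:
  at finite ratio noise an invalid mass f shifts the weighted 0.5-quantile
  by roughly 1.25·f·(ratio noise scale), so tests compare its drift against
  the IVW breakdown rather than asserting exact unbiasedness.
- **Unweighted IVW** — inverse-variance pooling of the Γ̂_j alone
  (per-allele, not per exposure unit), for weighting-free replication.
- **Radial outlier scan** — the per-variant Q contributions
  q_j = w_j (β̂_j − β̂_IVW)², each ≈ χ²₁ for a valid instrument, flag
  outliers at a Bonferroni-adjusted α (default 0.05/n; raw α by flag).
  First-order weights are used throughout so Σ q_j equals the IVW Q
  exactly. Removal is one pass, never iterated. Note the multiplicity
  arithmetic: with 26 instruments the familywise false-flag probability at
  the Bonferroni default is ~5%, and a genuine outlier also shifts β̂_IVW
  by w_out·Δ/Σw, nudging clean variants' residuals — so "no extra flags in
  a replicate" holds in roughly 90% of planted-outlier replicates even
  though the planted variant itself is flagged and carries the largest q_j
  essentially always. Detection claims are therefore phrased as unique
  identification (flagged + largest contribution).
- **Leave-one-out**, **single-SNP Wald ratios**, and **scenario re-runs**
  (window restriction, alternative exposure weights, unweighted,
  instrument subsets such as a single canonical variant) complete the
  suite; a scenario yielding zero instruments is reported as failed
  without aborting the run.

## Harmonisation

Outcome records are aligned to the exposure panel's effect allele by
allele matching, resolving strand relabelling (A↔T, C↔G). Palindromic
variants (A/T, C/G) cannot be resolved from labels; under the default
`infer_by_freq` policy the orientation is taken from allele frequency and
accepted only when both panels' EAF lie outside 0.5 ± `freq_window`
(default 0.08, a common two-sample convention — the window is an
assumption, not a reconstruction), otherwise the variant is dropped;
missing EAF on a palindrome always drops. Every exclusion carries a
reason code and matched + excluded = panel size. Harmonisation is
idempotent, and a double allele flip in the outcome panel (swap alleles,
negate beta, complement EAF) is a no-op. Proxy search returns the
candidate with maximal r² ≥ `r2_min` (default 0.8), ties to the smaller
position; a target absent from the LD matrix raises a distinct error
rather than "no proxy".

## Instrument construction

Cis windows are closed intervals [start − window, end + window] on the
gene's chromosome (default 300 kb; 10 kb as the restricted alternative).
LD pruning is greedy clumping: keep the remaining variant with the
smallest exposure p-value (ties to position, then ID), drop everything
with r² ≥ threshold against it (default 0.1, strict `<` retained). The
canonical ordering makes pruning independent of row order. Gene
coordinates are configuration inputs; nothing is fetched from annotation
services, and the LD matrix is a required plain-text input because no
reference panel is bundled. The "blockade" orientation negates exposure
betas and swaps alleles so reported ORs are per unit of exposure
*decrease*, mimicking a therapeutic antagonist; applying it twice is the
identity.

## Directional clustering with a noise class

Instruments' standardised multi-trait profiles (rows of z = beta/se,
oriented to the exposure-increasing allele; traits missing any instrument
are dropped) are scaled to unit length and modelled as a mixture of K von
Mises–Fisher components plus one uniform-on-the-sphere noise class.
Defaults: K = 10, 50 restarts, assignment threshold 0.8, max 500 EM
iterations, relative tolerance 1e-8, κ ∈ [1e-3, 1e4].

The EM M-step solves the Bessel-function ratio A_d(κ) = r̄ exactly
(Brent's method), so each iteration maximises the true objective and the
log-likelihood trace is provably non-decreasing — an invariant the tests
assert on every fit. Around that core, three safeguards address
degeneracies that dominate when rows are few relative to the trait
dimension (J ≤ 26, T ≈ 31):

1. **No singleton components.** k-means++ seeds supported by fewer than
   two rows are removed before EM; a vMF component anchored on one row
   drives κ to the cap and wins unbounded likelihood, which is structure
   the noise class should absorb.
2. **Restart selection by BIC over populated components.** Raw maximum
   likelihood always prefers splitting one concentrated bundle into
   near-duplicate high-κ fragments; ranking the restarts by
   −2·loglik + n_active·(T+1)·ln(J) keeps K fixed while preferring the
   restart that explains a bundle with one component. A post-fit greedy
   merge of the most-aligned component pair (accepted while the likelihood
   cost stays under one component's BIC penalty) removes residual
   duplicates.
3. **Chance-concentration retention.** After thresholded hard assignment
   and dissolution of clusters with fewer than `min_cluster_size` (= 4)
   members, each surviving cluster's Rayleigh-type statistic m·T·r̄² must
   exceed the 98th percentile of the same statistic obtained by running
   the same short EM search on isotropic data of identical shape (150
   Monte-Carlo draws, two restarts each, seeded). Isotropic rows in high
   dimension genuinely contain subsets that look concentrated once a
   fitting procedure has selected them; calibrating against the
   selection-matched null keeps pure-noise inputs (almost always) free of
   reported clusters while planted concentrated bundles sit far above the
   threshold. Because the null is an empirical quantile, a purely
   isotropic input can still occasionally yield one weak reported cluster;
   this residual multiplicity is inherent to maximum-likelihood selection
   at J < T.

Rows are internally sorted into a canonical content order before fitting,
so labels are exactly invariant to input row permutation. K_effective
counts clusters retaining at least one member; per-cluster MR is the
primary IVW restricted to a cluster's variants. Planted-partition
recovery (two κ=100 clusters of 7 plus 12 isotropic rows in 31 traits) is
the validation target; no attempt is made to reproduce any particular
real-data cluster membership, since the clustering literature's tools
differ in likelihood details that summary descriptions do not pin down.

## Cross-cohort meta-analysis

Published per-cohort ORs with 95% CIs are converted to the log scale
(β = ln OR, se = (ln hi − ln lo)/(2·1.959964); degenerate zero-width CIs
are rejected) and pooled by fixed-effects inverse variance with Wald CIs
and Cochran's Q. Pooling the printed UK Biobank sepsis OR 0.80
(0.66–0.96) with FinnGen streptococcal sepsis 0.79 (0.48–1.31) gives 0.80
(0.67–0.95), and with FinnGen respiratory sepsis 0.63 (0.29–1.35) gives
0.79 (0.66–0.95) — both reproduced by the test suite at two decimals.
Pooling the rounded printed UK Biobank and combined FinnGen sepsis ORs
gives 0.87 (0.76–1.01); a headline pooled value computed from unrounded
cohort estimates can differ in the second decimal, so that quantity is
documented here but not asserted anywhere.

The z-quantile 1.959964 is fixed for every CI/SE conversion; p-values are
two-sided normal except the Egger t test.

## Synthetic data

The generator defines the study conditions under which everything is
tested. Defaults: 26 instruments, MAF ~ U(0.05, 0.45), |γ| ~ U(0.02,
0.08) with random sign (per-allele lnCRP effects of realistic cis
magnitude; implied F statistics range from ~20 to ~3,000), exposure
n = 522,681, outcome 11,643 cases / 474,841 controls. SEs use
s_γ = (2·n·p(1−p))^(−1/2) for a unit-variance exposure and the logistic
score approximation s_Γ = (2·n·p(1−p)·φ(1−φ))^(−1/2) with case fraction
φ — a correct-order stand-in for a real case-control GWAS, not a genotype
simulation. True outcome effects satisfy Γ_j = β_causal·γ_j + α_j exactly,
with α from one of: none; balanced N(0, τ²); directional N(μ, τ²) defined
per exposure-increasing allele (the stored α carries sign(γ)); or
correlated δ·γ + noise, violating InSIDE-style independence. A `frac`
parameter limits the carrier fraction. A configurable share of outcome
records is re-expressed on the flipped strand and/or with swapped alleles
(defaults 0.3 and 0.3, with 15% palindromic variants) so harmonisation is
exercised on every simulated run. One master seed fans out to substreams;
identical seeds give byte-identical panels.

LD matrices are block-diagonal AR(1) (r = ρ^|i−j| within blocks). Trait
matrices for clustering are vMF draws about random unit directions plus
uniform noise rows, with random positive row rescaling to exercise the
scale invariance.

A deterministic 26-variant cis exposure panel (synthetic stand-in echoing
the study geometry: GRCh37 IL6R coordinates, seven variants within 10 kb
including rs2228145, weakest instrument calibrated to F = 31.1, pairwise
r² < 0.1) anchors the structural tests.

What passing tests show: the estimators are exact on their algebraic
identities, calibrated (type-I error, coverage) under the stated
conditions, and behave as theory predicts under planted pleiotropy,
outliers and cluster structure. What they do not show: behaviour under
real LD misspecification, sample overlap, winner's curse in instrument
discovery, phenotype misclassification, or selection/collider effects —
none of which the generator models.

## Problem sizes and determinism

Calibration runs use 1,000 replicates (null and effect-recovery),
pleiotropy and outlier experiments 200, the breakdown comparison 120, and
clustering recovery a single fixed-seed 26×31 matrix with 50 restarts —
sizes chosen so the full suite and the acceptance script each complete in
a few minutes on one CPU while keeping Monte-Carlo error well inside the
asserted bands. Every stochastic step (bootstrap, EM restarts, simulation)
takes an explicit seed; pipeline re-runs with the same configuration are
byte-identical.

## Known limitations

- First-order weights throughout; no second-order or modified radial
  weights, no correlated-instrument (generalised) IVW, no mode-based
  estimators, no multivariable MR, no Steiger filtering.
- Proxy substitution reuses the original exposure beta for the proxy
  (summary-level tools cannot re-estimate it); positions are 1-based on
  whatever build the inputs share, with no liftover.
- The binary-outcome SE model ignores covariate adjustment and relatedness
  corrections present in real biobank GWAS.
- The clustering noise calibration is Monte-Carlo and conservative by
  construction at the chosen quantile; extremely weak genuine clusters
  (κ within a factor of ~2 of the isotropic selection ceiling) will be
  absorbed into noise.
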