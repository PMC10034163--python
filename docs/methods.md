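# Methods

## The model

`mrpipe` implements two-sample summary-statistic Mendelian randomization
(MR). For each genetic instrument *j* the exposure GWAS provides an estimate
of the per-allele effect γ_j (standard error σ_γj) and the outcome GWAS an
estimate of Γ_j (standard error σ_Γj). Under the instrumental-variable
assumptions (relevance, independence from confounders, exclusion
restriction) the outcome effect decomposes as

    Γ_j = β γ_j + α_j ,

where β is the causal effect of the exposure on the outcome and α_j a
horizontal-pleiotropy term, zero for valid instruments. Each variant gives a
Wald ratio b_j = Γ̂_j / γ̂_j with first-order standard error σ_Γj / |γ̂_j|;
all set-level estimators combine these ratios with first-order
inverse-variance weights w_j = γ̂_j² / σ_Γj². Ignoring the exposure-side
error in the weights (the NOME approximation) is the convention of standard
two-sample MR software; second-order weights could be added behind the same
interface.

## Estimators

* **Fixed-effects IVW**: β̂ = Σ w_j b_j / Σ w_j, se = (Σ w_j)^{-1/2}.
  Algebraically identical to the zero-intercept weighted least-squares slope
  of Γ̂ on γ̂ with weights 1/σ_Γ², and to the radial through-origin slope;
  both identities are asserted in the test suite.
* **Random-effects IVW** (multiplicative): the fixed-effects se scaled by
  √max(1, Q/(J−1)), Q being Cochran's heterogeneity statistic. The floor at
  1 means homogeneous data reduce exactly to fixed effects.
* **MR-Egger**: weighted regression of Γ̂ on γ̂ with a free intercept after
  orienting every γ̂_j positive. The slope estimates β under the InSIDE
  assumption; the intercept estimates the mean directional pleiotropy and
  its t test (J−2 df) is the pleiotropy diagnostic. We solve the 2×2
  weighted normal equations in closed form and use the unfloored weighted
  residual variance on J−2 df, which makes the intercept test exact under
  the no-pleiotropy null — its empirical type-I error over 2000 null
  simulations sits near 0.05 (recomputed by `scripts/acceptance.py`).
* **Weighted median**: the 50% point of the weighted empirical distribution
  of ratios, interpolating the cumulative midpoints s_j = Σ_{k≤j} w'_k −
  w'_j/2; consistent while valid instruments carry more than half the
  weight. Standard error by parametric bootstrap (default 1000 draws of
  b_j* ~ N(b_j, se_bj), seeded).
* **Weighted mode**: argmax of a weighted Gaussian kernel density over the
  ratios, bandwidth 0.9·min(sd, iqr/1.34)·J^{−1/5} times a user factor,
  evaluated on a 512-point grid spanning [min−3h, max+3h]; doubling the
  grid moves the estimate by less than h/10 (tested). Degenerate spread
  returns the common ratio. Bootstrap se as for the median.

All confidence intervals are normal-theory β̂ ± z_{0.975}·se, matching how
the estimates are reported downstream; Egger p-values use the t
distribution, IVW the normal.

### Primary-estimate switching rule

The protocol this pipeline operationalizes selects random-effects IVW as
primary when J > 4 **or** when Cochran's Q shows no heterogeneity
(p ≥ 0.10), and fixed-effects IVW otherwise. This inverts the more common
convention (random effects *with* heterogeneity); we implement the rule as
stated and expose `ivw_mode` to override it. Because the random-effects
scale is floored at 1, the two variants differ only under observed
heterogeneity, so the practical consequence of the unusual rule is small.

## Diagnostics

* **Cochran's Q** about the fixed-effects estimate, χ²(J−1); per-variant
  contributions sum to Q exactly. Heterogeneity is called at p < 0.10.
* **Radial scan**: per-variant Q_j referred to χ²(1) with Bonferroni cut
  0.05/J.
* **RSS (MR-PRESSO-style) test**: observed RSS = Σ w_j (b_j − β̂_{−j})²
  with leave-one-out IVW estimates β̂_{−j}; the null distribution is built
  by parametric simulation (Γ*_j ~ N(γ̂_j β̂_{−j}, σ_Γj²),
  γ*_j ~ N(γ̂_j, σ_γj²), default 1000 draws). Global p-value and per-variant
  outlier p-values are empirical with a +1/(n+1) continuity correction (so
  never zero); outliers are Bonferroni-thresholded at 0.05/J. The
  distortion component compares the raw-vs-corrected shift against the
  displacement distribution obtained by removing equally many random
  variants — the reference method names this test without fully specifying
  it, so this operationalization is our own and is labelled as such.
* **Leave-one-out**: IVW re-estimated J times; the analysis is flagged
  robust when every reduced estimate keeps the full estimate's sign and
  every reduced CI overlaps the full CI. This robustness criterion is our
  operationalization (the protocol reports leave-one-out plots without
  defining "robust").

The pipeline removes the union of radial and RSS outliers before
estimation, logging the removed identifiers.

## Instrument selection and harmonization

Two named threshold profiles: **loose** (p < 1×10⁻⁵, clump r² < 0.01) for
exploration — the customary choice for microbial-abundance GWAS, where
genome-wide-significant hits are scarce — and **strict** (p < 5×10⁻⁶,
r² < 0.001) for validation; both clump greedily within ±10,000 kb, keeping
the smallest p-value per clump (ties broken by chromosome, then position)
with r² computed as the squared Pearson correlation of 0/1/2 genotypes in
the reference panel. The p-value screen uses strict `<`; the
weak-instrument screen keeps F = β̂²/se² ≥ 10 (boundary inclusive); both
follow the inequalities as conventionally printed. Variance explained per
variant is 2f(1−f)β̂² for a variance-standardized trait. The confounder
screen removes variants with any catalog association at p < 5×10⁻⁸ whose
trait name contains a configurable term (defaults: "cancer", "tumor",
"tumour"); protein exposures additionally pass an annotation filter keeping
only regulatory-annotated non-eQTL variants. The F ≥ 10 screen is applied
at selection time, before harmonization, with per-variant F re-reported in
the outputs.

Harmonization aligns outcome effects to the exposure's effect allele,
resolving swapped and strand-complemented allele pairs, orienting
palindromic (A/T, C/G) pairs by allele frequency, and dropping palindromic
pairs with minor-allele frequency above 0.42 (the intermediate zone where
frequency cannot resolve strand). The 0.42 exclusion is restricted to
palindromic pairs by default — they are the only pairs whose orientation is
actually ambiguous — with a flag extending it to all variants. Analyses
retaining fewer than 3 instruments at any stage are excluded with the
reason logged rather than estimated.

Multiple testing uses Benjamini–Hochberg FDR, by default within each
exposure–outcome pair across the five estimator p-values (the protocol
corrects "by the number of MR analysis methods"); a per-outcome
across-exposures family is one config flag away since the protocol is
ambiguous about the family. A pair is labelled significant only when its
primary IVW adjusted p-value is below 0.05.

## Power

For a continuous outcome measured on n individuals with instruments jointly
explaining r² of the exposure variance, the z statistic of the IVW estimate
has noncentrality √(n·r²)·β, so

    power = Φ( √(n r²)·|β| − z_{1−α/2} ),

and the minimum detectable effect at target power inverts this. With
n = 3,301 and r² = 0.02 this gives 80% power at β = 0.345 — the worked
example the package reproduces.

## The synthetic generator

`synthetic.simulate_pair` draws allele frequencies uniformly on
`eaf_range` (default 0.05–0.5), true instrument effects
γ_j ~ N(0, gamma_sd²) truncated away from zero at 0.01 (avoiding degenerate
Wald ratios), and sets Γ_j = β γ_j + α_j. Estimated effects add Gaussian
noise with the allele-frequency/sample-size standard error
1/√(2f(1−f)n) of a variance-1 trait; p-values are exact two-sided normal
tails of β̂/se. Defaults emulate the study scale of a microbiome-GWAS
exposure (n = 18,340) against a protein-level outcome (n = 3,301).
A `noiseless` switch gives the infinite-sample limit while keeping
finite-n standard errors.

Pleiotropy: a configurable fraction of instruments is invalid. *Balanced*
pleiotropy draws α_j ~ N(0, pleiotropy_sd²). *Directional* pleiotropy draws
α_j ~ N(pleiotropy_sd, pleiotropy_sd²) **aligned with sign(γ_j)** — i.e.
directional with respect to the exposure-increasing allele. The alignment
matters: with symmetric γ and sign-agnostic α, the pleiotropy cancels under
the Wald-ratio orientation and biases nothing, so only the aligned
construction produces the textbook directional-pleiotropy regime (IVW
biased, Egger intercept shifted, weighted median robust).

`simulate_panel` produces a diploid 0/1/2 panel for the same variants:
within an LD block each variant's haplotype copies a latent block haplotype
with probability r2^{1/4}, giving pairwise genotype r² ≈ the block target
(exact at r² = 1, verified empirically at intermediate values); blocks and
singletons occupy well-separated genomic regions so only intra-block pairs
fall within one clump window. All randomness flows from one integer seed
through four named child streams (variant layout, exposure noise, outcome
noise, panel) in that fixed order, so the panel never perturbs the summary
statistics and every output is reproducible byte-for-byte.

What the generator does **not** emulate: sample overlap between the two
GWAS, case-control traits, fine-scale LD decay within blocks, allele
frequencies differing between the GWAS and the panel, population
stratification, and winner's-curse selection of instruments. Passing tests
therefore demonstrate the statistical machinery under the stated generative
model, not robustness to those real-data complications.

## Study conditions used in the verification suites

These sizes are the package's fixed verification conditions, chosen as
realistic regimes for the corresponding checks:

* Egger intercept calibration: J = 20 instruments, default sample sizes,
  no pleiotropy, 2000 replicates; rejection rate at nominal 0.05.
* Contamination contrast: J = 20, n = 50,000 on both sides (a
  strong-instrument regime where the estimator contrast is attributable to
  the pleiotropy rather than weak-instrument noise), 30% invalid with
  directional pleiotropy_sd = 0.1, true β = 0.3, 200 replicates.
* Outlier detection: one ratio shifted by 10 outcome-SEs among J = 20,
  100 replicates, RSS null with 1000 simulations.
* Null calibration of the RSS global p-value: 200 homogeneous replicates,
  500 simulations each, Kolmogorov–Smirnov distance from uniform.
* End-to-end coverage: β ∈ {−0.3, 0, 0.3}, J = 50 valid instruments,
  66 replicates per β through the full pipeline (selection → harmonization
  → outlier removal → estimation), primary-IVW 95% CI coverage.

`scripts/acceptance.py` recomputes all of these from scratch under a
user-supplied seed.

## Numerical choices and edge cases

* p-values are floored at 1e-300 to stay within (0, 1]; empirical p-values
  are continuity-corrected.
* Monomorphic panel variants have zero genotype variance; their r² with
  anything is defined as 0 (they can never cause a clump drop).
* `weighted_mode` with zero spread returns the common ratio; `ivw` refuses
  fewer than 2 pairs, `mr_egger`/`weighted_median`/`weighted_mode` fewer
  than 3, the RSS test fewer than 4 — the pipeline's minimum-IV rule
  (≥ 3, with the RSS scan simply skipped at J = 3) makes these unreachable
  in normal operation.
* Bootstrap draws and simulation counts are configurable; defaults (1000)
  balance tail stability against desk-scale runtime.
* `fdr_adjust` rejects p-values outside (0, 1] rather than silently
  clamping.

## Known limitations

* No proxy-variant search: instruments missing from the outcome GWAS are
  dropped (the underlying protocol mentions none either).
* First-order weights only; no Steiger filtering, multivariable MR,
  MR-RAPS, or simple (unweighted) mode.
* The LD panel model is block-exchangeable, not a coalescent; clumping
  behaviour under realistic LD decay is untested.
* The annotation catalog is a local stand-in for external databases
  (trait-association, regulatory-annotation and frequency lookups); its
  schema includes an `EA_REF` allele column so frequency supplementation
  can orient frequencies, which those external sources provide implicitly.
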