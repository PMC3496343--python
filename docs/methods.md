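# Methods

`poolassoc` tests for case-control allele-frequency differences in pooled
DNA sequencing experiments, where DNA from many individuals is sequenced
as a single library per pool and only pooled allele read counts are
observed. This note records the statistical models, the numerical
choices, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Notation

For SNP *i* and pool *j*, `y_ij` is the number of reads supporting the
major allele, `R_ij` the total depth, `p_hat_ij = y_ij / R_ij` the
per-pool major-allele frequency estimate. `n` is the number of pools
(case + control) and `s` the number of distinct chromosomes per pool
(2 × persons for diploids). The null hypothesis is equality of the major
allele frequency in case and control chromosomes.

## Why a binomial model fails

Treating the pooled counts as binomial draws from `s × (number of
pools)` chromosomes — as Fisher's exact test on estimated chromosome
counts does — ignores two extra variance sources: chromosome sampling
into pools (a frequency variance floor of `p(1-p)/s` per pool however
deep the sequencing) and amplification/library noise, which attaches to
template molecules rather than reads and can dominate both. The result
is anti-conservatism: in our simulations at the default settings the
observed Type-1 error of Fisher's test reaches roughly nine times the
nominal 0.05 level.

## The EB2 model

The per-pool frequency estimate is assigned the variance function

    Var(p_hat_ij) = p_i (1 - p_i) (a / R_ij + b / s)

with two universal parameters `a` (read-level noise) and `b`
(between-pool noise) shared by all SNPs. Under ideal two-stage sampling
(s chromosomes into the pool, R reads drawn from them, nothing else)
`a -> 1` and `b -> 1`; real data have `b > 1`. Matching against a plain
binomial variance `p(1-p)/R*` defines the adjusted depth

    R*_ij = s R_ij / (a s + b R_ij),

interpretable as the number of effectively independent reads the pool
contributes; it is capped near `s/b` regardless of sequencing depth.
Adjusted allele counts `p_hat_ij R*_ij` and `(1 - p_hat_ij) R*_ij` are
summed over case and control pools into a 2×2 table and tested by
Pearson chi-square with one degree of freedom, without continuity
correction (the entries are model-adjusted, not raw counts, and may be
fractional).

### Estimating (a, b)

The per-SNP normalised dispersion statistic

    T_i = sum_j (y_ij - R_ij p_ig)^2 / (R_ij p_ig (1 - p_ig)) / (n - 2)

uses the pooled *group* mean `p_ig` of pool *j*'s group for centring, so
a real case-control difference does not contaminate the dispersion
estimate, and `n - 2` reflects the two estimated group means. Its
expectation is approximately `a + b (mean_j R_ij) / s`: `a` is the
intercept and `b` the slope of dispersion against depth.

The regression is carried out at per-pool resolution: each pool's
squared Pearson residual (rescaled by `n/(n-2)` to undo the estimated
group means on average) is regressed on its own `R_ij / s`. In designs
where every SNP has nearly the same *mean* depth, a regression of the
per-SNP aggregate `T_i` on mean depth has almost no leverage to
separate the `a/R` and `b/s` components — the two estimates are close
to collinear, and a mis-shaped variance law mis-weights deep versus
shallow pools in the test. The within-SNP depth spread identifies the
shape. The per-SNP statistics `T_i` are still computed and reported as
diagnostics, and standard errors for `(a, b)` are cluster-robust by SNP
(residuals within a SNP share its estimated group frequencies).

The fit is restricted to SNPs with pooled minor-allele frequency at or
above the common/rare threshold (default 0.05) whenever at least 20 such
SNPs exist. At very small minor counts the statistic's denominator
`p_ig(1 - p_ig)` is itself so noisy that `T_i` is attenuated (we measure
roughly a factor two at MAF 0.005 under a generating dispersion that is
constant on the frequency scale), and letting those SNPs into the
regression drags `(a, b)` down for everyone. Fitting on informative
SNPs keeps the test calibrated for common variants; rare variants are
still tested with the same global parameters, and their own attenuation
then errs on the conservative side — which is the behaviour we consider
acceptable for a screening method and which the Type-1 simulations
confirm.

## The EB1 comparator (Williams)

Williams' quasi-likelihood model inflates the count variance per pool to
`R_ij p (1-p) [1 + phi_i (R_ij - 1)]` with a per-SNP heterogeneity
parameter `phi_i`. Given `phi`, the group frequency estimates are
closed-form weighted means with weights `w_j = 1 / (1 + phi (R_j - 1))`;
`phi` is the non-negative root of "weighted Pearson statistic of the
two-group model = its residual degrees of freedom `n - 2`", found by
bracketed Brent root-finding (tolerance 1e-8, `phi` floored at 0 when
the data are under-dispersed). The test statistic is the increase in
the weighted Pearson statistic when the case-control factor is deleted,
referred to chi-square with 1 df. Because the group means solve the
quasi-score equations rather than minimising the Pearson objective, the
difference can be marginally negative in near-null data; it is floored
at zero. SNPs with zero total minor reads in either group are excluded
(there is no variance information from which to estimate `phi_i`), as
are SNPs with fewer than three covered pools. With only `n` data points
per SNP, `phi_i` is estimated imprecisely — the motivation for EB2's
globally shared parameters.

## Fisher baseline

Per group, the major-allele frequency is the unweighted mean of per-pool
frequencies over valid pools; chromosome counts are
`frequency × s × (number of valid pools)`, rounded to nearest (ties to
even); the 2×2 chromosome-count table is tested by the two-sided Fisher
exact test. The p-value is computed by summing hypergeometric
probabilities in log space (identical two-sided definition as
`scipy.stats.fisher_exact`, verified against it and against brute-force
enumeration in the test suite; reimplemented for speed at simulation
scale). Only for this test, pools must additionally pass the
chromosome-coverage filter below.

## Filtering pipeline

1. **Minimum depth** (default 8): summed depth per group must reach the
   threshold (per-pool mode available).
2. **MAF partition** (default 0.05, boundary inclusive as common):
   pooled minor-read fraction classifies each SNP common or rare.
3. **Random-error screen** (rare SNPs only): under the null that all
   minor reads are scattered sequencing errors, they land on pools in
   proportion to depth. The Pearson chi-square of minor counts against
   that expectation gets a Monte-Carlo p-value (default 10,000
   multinomial draws, add-one rule; drawn in batches with early stopping
   once ten exceedances are seen, since further draws cannot change the
   call). When the observed statistic exceeds every draw, the p-value is
   refined by the chi-square(m-1) upper tail capped at the Monte-Carlo
   floor, so Bonferroni thresholds below the floor stay decidable. A SNP
   is called a true rare variant iff p < alpha / (number of rare
   candidates screened) and at least one pool has more than two minor
   reads. Per-SNP Monte-Carlo streams are keyed on the SNP identifier,
   making the surviving set independent of input order.
4. **Chromosome coverage** (binomial path only): a pool is valid iff its
   depth gives probability strictly above 0.8 of covering at least k=80
   of the s chromosomes, computed by an exact occupancy dynamic
   programme (each read hits one of s chromosomes uniformly); since the
   probability is monotone in depth, the filter is applied through a
   single binary-searched depth threshold. For designs with s below the
   default k, k falls back to ceil(5s/6), preserving the 80-of-96 ratio.

## Error model

For each ordered base substitution a→ā, the error rate is (alternative
reads) / (total reads) summed over positions *not* called as SNPs —
in a blinded analysis, the rare candidates rejected by the error screen.
Counts at surviving SNPs are then de-biased: with `eps_mM` the rate of
the minor base being miscalled as major and `eps_Mm` the reverse,

    y_corr = (y_obs - R eps_mM) / (1 - eps_Mm - eps_mM)

is unbiased for the true major count; it is clamped to `[0, R]`
(clamping is logged), left real-valued downstream, and rounded only
where an integer table is required (Fisher). Rates below 1e-8 are
treated as zero. Only the SNP's own allele pair is used. A `scale`
multiplier supports sensitivity analysis for misspecified rates.

## Synthetic data generator

The generator emulates a targeted pooled-resequencing study: 500 cases
and 500 controls in 20 pools of 50 (s = 100), average per-person
coverage 40×. Genotypes are Hardy-Weinberg draws, `g ~ Bin(2, MAF)`.
Reads attach to chromosomes: each allele copy contributes
`Gamma(k, theta)` reads with `k = gamma_shape / 2 = 1/6` and
`theta = 3 × coverage = 120`, rounded per allele class. By infinite
divisibility a person's depth is `Gamma(1/3, 120)` (mean 40) and a
pool's depth has mean 2000 with a dataset-mean-depth variance of about
12,000 — amplification makes per-chromosome yields extremely uneven
(about 43% of chromosomes contribute no reads), which is deliberate:
it makes the pooled frequency estimate's allele split gamma-proportion
(Beta-like) rather than binomial, producing the strong between-pool
over-dispersion (around 6-7 times the chromosome-sampling floor) that
the extra-binomial tests exist to absorb. Symmetric base-calling errors
flip each read to the other allele with probability `error_rate`
(0-5%), applied binomially.

Three truth classes are generated: `null` (MAF 0; pure error reads,
used by the blinded pipeline to estimate error rates), `neutral` (equal
MAF 0.005-0.5 in both groups; Type-1 error), and `disease` (case MAF
raised by a multiplicative per-allele relative risk, default 1.5, so
that the case-control allele odds ratio equals rr exactly). One global
seed expands into per-replicate substreams
(`SeedSequence(seed, spawn_key=(error_index, replicate))`), so any
replicate is reproducible in isolation.

What the generator does *not* emulate: linkage disequilibrium between
SNPs (sites are independent), allele-specific PCR bias (which shifts
frequencies but affects both groups equally), position- or
quality-dependent error rates, unequal DNA contributions per person,
and alignment artefacts. Passing tests therefore demonstrate behaviour
under pooling, amplification and symmetric-error noise, not robustness
to systematic reference bias.

## Evaluation machinery

P-values convert to the chi-square(1) scale through the inverse survival
function (p = 1 → 0; p = 0 capped at the smallest positive double, with
the number of capped values reported). Q-Q summaries plot sorted
observed values against chi-square quantiles at plotting positions
k/(m+1); the slope is the through-the-origin least-squares coefficient
(the genomic-inflation convention: slope 1 for calibrated tests, slope c
under c-fold inflation). The 95% concentration band is pointwise, from
Beta(k, m+1-k) order-statistic quantiles mapped through the chi-square
quantile function; it is not a simultaneous band. Deterministic plotting
positions are used for the expected quantiles rather than random
quantiles, trading a little faithfulness to some published figures for a
noise-free diagnostic. Type-1/power tables report rejection rates per
truth class × MAF × error rate with exact (Clopper-Pearson) binomial
intervals; excluded or degenerate SNPs are tallied separately and never
counted as rejections, with the tested count as denominator.

## Study problem sizes

The replicated Type-1/power study used in the acceptance checks runs 70
replicates at each of three error rates (0, 1%, 5%) with 100 null and
245 neutral SNPs per replicate (35 per MAF grid point; no disease SNPs,
since the quantity of interest is Type-1 error), at nominal alpha 0.05.
That yields 2,450 neutral tests per MAF × error bin — enough to
estimate per-bin rejection rates with a standard error of about 0.01
at the observed rates. Power claims in the test suite use smaller smoke
grids (rr ∈ {1.0, 1.5, 2.0}) and assert monotonicity only.

## Numerical choices and degenerate inputs

* Major-allele orientation: larger total read count across pools; exact
  ties resolve to the reference allele; the operation is idempotent.
* A missing pool is encoded as depth 0 and skipped per-SNP, never
  dropped from the table.
* Occupancy probabilities use a forward dynamic programme in plain
  probability space (all updates are convex combinations, hence
  stable); enumeration and inclusion-exclusion cross-checks are in the
  test suite.
* Non-positive adjusted depths (possible when `b_hat < 0` at low depth)
  drop that pool for that SNP; a SNP losing an entire group is excluded.
* The dispersion regression refuses to run with fewer than two usable
  SNPs or without depth variation across SNPs.
* Multi-allelic sites are out of scope; the containers carry exactly one
  ref and one alt base per SNP.
* P-values are reported raw (the intended consumers are Q-Q diagnostics
  and replication follow-up, not per-SNP significance declarations).

## Known limitations

* EB2's chi-square is asymptotic; for very rare variants the adjusted
  table entries are small and the test is conservative — by design, but
  it costs power below MAF ≈ 0.01.
* The global (a, b) assume the over-dispersion mechanism is shared
  across SNPs; SNP-specific artefacts (e.g. a paralogous repeat) violate
  this and are only partially absorbed.
* The error screen's Monte-Carlo p-value has resolution 1/(draws+1);
  the chi-square tail refinement used beyond it is approximate, though
  decisions there are invariably far from the threshold.
* EB1's phi search can hit its upper bracket on pathological inputs;
  such SNPs are flagged `degenerate` rather than silently reported.
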