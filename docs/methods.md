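# Methods

This note records the modelling choices, numerical conventions and validation
designs behind `rhmscan`, in the spirit of a statistical package's methods
appendix.  Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is asserted from memory.

## 1. The repeatability test-day model

One trait at a time, on individual test-day records:

```
y = Xb + Z1 u + Z1 pu + Z2 pw + Z3 h [+ Z1 v] + e
```

* **Fixed effects.** Parity (5 classes; parities above 5 are collapsed into
  class 5), litter size (single/multiple), lambing season (2 classes:
  first/second half of the year), and fortnight-in-milk, the days-in-milk
  discretized as `min(ceil(DIM/14), 22)`.  Dummy coding with an intercept and
  the first observed level as reference; linearly dependent columns (e.g.
  unobserved classes) are dropped greedily left-to-right and recorded on the
  result.
* **Random effects.** `u` additive genomic with whole-genome GRM covariance;
  `pu` permanent environment across lactations (identity over animals, same
  incidence as `u`); `pw` permanent environment within parity (identity over
  animal x parity); `h` flock-by-test-day (identity over flock x date);
  optional `v` regional genomic with a window GRM; `e` residual.
* **Derived ratios.** With `sp2` the sum of all fitted components:
  heritability `h2 = su2/sp2`, regional heritability `h2_v = sv2/sp2`,
  repeatability across lactations `r_acr = (su2+spu2)/sp2`, within lactation
  `r_wit = (su2+spu2+spw2)/sp2`, and `FTD2 = sh2/sp2`.  Standard errors by
  the delta method using the inverse average-information matrix.

## 2. GRMs and their factorization

The GRM is the per-SNP-standardized estimator
`G = (1/m) sum_i z_i z_i' / (2 p_i q_i)` with `z_i` the allele-B-count
column centred at `2 p_i` and `p_i` estimated from the analysed samples.
Missing dosages are mean-imputed (zero contribution to `z_i`), which keeps
`G` positive semi-definite.  Regional GRMs use the same per-SNP frequencies
as the whole-genome GRM, so a window's `Gv` is exactly the SNP-count-weighted
slice of `G`'s accumulation.

Centring makes `G 1 = 0` when frequencies come from the same complete data,
so `G` is singular by design.  All downstream computation therefore goes
through the truncated eigendecomposition: eigenvalues below `1e-8` times the
largest are zeroed, the pseudo-inverse is `V L+ V'`, and the model never
inverts a GRM.  By default a window's SNPs remain in the whole-genome GRM of
the full model (the background term uses *all* SNPs); the scan option
`exclude_region_from_background` refits the background without the window's
SNPs for users who want the orthogonalized variant (slower: one extra
whole-genome GRM and null fit per window).

## 3. REML: likelihood, optimizer, boundaries

GRM-structured effects are reparametrized through the spectral square root
`G = L L'` (`L` of size animals x rank), turning every random effect into an
identity-covariance block.  With `W = [X, Z~]` and
`C = W'W + diag(se2/sk2)` the mixed-model-equations matrix, the restricted
log-likelihood is evaluated exactly as

```
-2 logL = (n-p) (log se2 + log 2pi) - sum_k q_k log(se2/sk2) + log|C|
          + (y'y - theta_hat' W'y)/se2
```

from a single Cholesky factorization per evaluation.  The constant follows
the full textbook convention `-1/2 [log|V| + log|X'V^-1X| + y'Py +
(n-p) log 2pi]`, so likelihood differences between nested models are exact;
the test suite verifies equality with a dense-V brute-force oracle to 1e-8
and with the closed-form residual-only solution `se2 = RSS/(n-p)`.

The optimizer is average-information (AI) REML:

* gradient and EM updates come from the same factorization via the block
  traces of `C^-1` (computed from the inverse Cholesky factor);
* the AI step is *projected*: components pushed below the boundary are
  clamped at the floor `1e-8 x var(y)` rather than blocking the update;
  steps that would decrease the likelihood are halved up to six times, then
  the EM update (monotone by construction) is taken instead;
* a component sitting on the floor whose gradient points further down has
  satisfied its KKT condition and is pinned there; pinned components stay in
  the model (the mixture null accounts for the boundary);
* convergence when `|dlogL| < 1e-6` (default; `max_iter` 200).
  Non-convergence flags the result instead of raising.

Per-window full models reuse the null model's cross-product blocks (only the
regional columns are appended) and warm-start from the null estimates with
`sv2` initialized at 1% of `sp2`; typical window fits converge in 3-7
iterations.

## 4. Windowing and significance

Windows are 100 adjacent post-QC SNPs shifted by 50 (defaults).  Full
windows are laid while `start + size` fits on the chromosome; the SNPs after
the last full window form one non-overlapping tail window, kept only with at
least 25 SNPs.  This is the only tiling under which a "tail shorter than 25
SNPs" rule can ever trigger - any half-overlap truncation scheme always
leaves at least `shift` SNPs - and it reproduces, e.g., spans
`[0,100) [50,150) [100,200) [200,230)` for a 230-SNP chromosome.

Each window's LRT is `2 (logL_full - logL_null)`, clamped at zero (the clamp
is recorded), with p-value 1 at zero and `0.5 Pr(chi2_1 >= LRT)` otherwise.
A scan of `W` half-overlapping windows is counted as `T = ceil(W/2)`
independent tests: the genome-wide threshold solves the mixture tail
`0.5 Pr(chi2_1 >= x) = alpha/T`, the suggestive threshold solves the plain
chi-square tail `Pr(chi2_1 >= x) = 1/T`.  The two conventions look
inconsistent but are the pair in standard use, and for half-overlapping
windows they coincide in meaning: one expected false positive over `W`
correlated windows under the mixture equals a `1/T` plain tail.  A config
flag `consistent_mixture_thresholds` applies the mixture tail to the
suggestive level too (which *lowers* that threshold).  `T` is always derived
from the realized window count of the scan at hand.  At `W = 827`,
`alpha = 0.05` the thresholds are 13.48 and 9.20 with per-test levels
1.2e-4 and 2.4e-3 (`-log10` of 3.92 and 2.62).

Classification is strict: genome-wide if `LRT >` the genome-wide threshold,
else suggestive if `LRT >` the suggestive threshold, else none.

## 5. Quality control

Genotypes, in fixed order with thresholds strict in the stated direction:
non-autosomes out (sheep autosomes "1"-"26" by default, configurable) ->
sample call rate > 0.95 -> SNP call rate > 0.95 -> MAF > 0.02 -> exact
Hardy-Weinberg p >= 0.001.  Frequencies and HWE counts are recomputed after
sample removal from observed genotypes only, and HWE is tested pooled across
flocks.  The HWE test is the exact conditional test (sum of heterozygote
configurations no more probable than the observed one), verified against a
full-enumeration oracle to 1e-12.

Phenotypes: lactations (animal x parity) whose last record exceeds 300 days
in milk are dropped, then lactations with fewer than 3 records, then records
missing the analysed trait (or any trait, matching a strict multi-trait
record policy).  Every removal is itemized per rule in a `QCReport` whose
counts reconcile exactly at each stage.

## 6. The synthetic-data generator

The generator emulates the study design the model assumes: ~26 autosomes of
biallelic SNPs with per-SNP frequency uniform in `maf_range` (default
0.05-0.5); a few hundred ewes (default 481) in 4 flocks; half-sib paternal
families (default 9, round-robin assignment with equal sizes) in which each
animal draws one allele per SNP from its sire's two haplotypes and one from
the population; up to 5 parities (default 3) of 3-9 roughly monthly test-day
records on a shared per-flock recording calendar over a six-year horizon, so
flock-by-test-day cells are common to flock-mates; fortnight-in-milk from
`DIM = test date - lambing date`.  Default variance components
(0.1276, 0.0734, 0.0620, 0.4530, 0.4041 for u/pu/pw/h/e, `sp2 = 1.12`) are
the fat-percentage-like structure of a repeatability test-day model on such
a population; default fixed-effect coefficients are small class effects with
a gently rising lactation curve around an intercept of 7.

Two deliberate deviations from naive simulation:

* **Breeding values are rescaled in the GRM metric.**  Per-SNP effects are
  drawn with the method-2 `1/(2pq)` weighting (so `u` has covariance
  proportional to the region's GRM) and rescaled so `u' G^+ u / rank(G)`
  equals the target variance *exactly*.  This is the quantity REML estimates:
  in a family-structured population the data-frequency GRM diagonal sits well
  below 1, and rescaling to a plain sample variance would make the generative
  "truth" a different estimand than the model's `su2`.  In the unrelated mode
  the two metrics agree closely.
* **Environmental components are plain draws**, not rescaled; recovery tests
  quote empirical replicate SEs, so exactness is only needed where a single
  fixed truth matters.

What the generator does **not** emulate: linkage disequilibrium (SNPs are in
linkage equilibrium; an optional AR(1) latent-correlation mode exists for
visual realism but the mappable signal is carried by the window-level
regional effect), maternal pedigree, selection, drift, unequal family sizes,
and trait-correlated multi-trait records (the four non-analysed trait
columns are independent placeholder noise at phenotypic scale).  Passing
tests therefore demonstrate correctness of the estimation machinery under
the model's own assumptions, not robustness to LD structure or model
misspecification in real genomes.

## 7. Validation study designs (fixed)

Run by `tests/test_acceptance.py` through `rhmscan.studies`; sizes are chosen
so each study completes in minutes on one CPU while keeping the asymptotics
honest.

* **Recovery** - 20 replicates of 300 animals x 3,000 SNPs (10 chromosomes)
  x ~10 records (3 parities x 3-4 test-days), truth proportions
  (0.11, 0.07, 0.06, 0.40, 0.36).  Pass: each component's replicate-mean
  within 2 empirical SEs of truth.  The half-sib default is essential here:
  `u` vs `pu` is identified only by GRM off-diagonal structure.
* **Null calibration** - 50 replicates of a 100-window scan (4 chromosomes x
  650 SNPs, 50-SNP windows shifted by 25) on 120 animals x ~9 records with no
  regional variance anywhere.  Pass: mixture-quantile exceedance at most
  `alpha + 3 SE` for alpha in {0.05, 0.01}; mean windows past the scan's own
  suggestive threshold within `3 sqrt(1/50)` of 1 per scan; LRT point mass at
  zero near one half.
* **Power/localization** - 20 replicates of 400 animals x 700 SNPs with one
  QTL window (chromosome-1 SNPs 100-200) carrying 5% of `sp2`, standard
  100/50 windowing.  Pass: the max-LRT window shares at least 50 SNPs with
  the truth in at least 18/20 replicates.

## 8. Known limitations

* Likelihood evaluation is dense in the MME dimension (records and random
  levels); the implementation is comfortable to ~10^4 records on one CPU but
  is not an out-of-core or sparse engine.
* With two genomic terms sharing the animal incidence (`u` and `v`), their
  separation rests on the contrast between whole-genome and window GRMs;
  expect strong negative correlation of the two estimates in small samples
  (this is intrinsic to RHM, not an implementation artifact).
* The suggestive/genome-wide threshold pair hard-codes nothing: scans with
  few windows get correspondingly lax thresholds, as the worked example in
  the README shows (12 windows -> genome-wide LRT > 5.73).
* Ratio standard errors are first-order delta approximations; they degrade
  near boundaries (a pinned component reports no SE of its own).
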