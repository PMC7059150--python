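# Methods

## Statistical model

### Age-association regression

Expression enters as `y = log2(TPM + 1)`; a gene is tested only if its TPM
exceeds 0.1 in at least 20% of the cohort's samples (both numbers
config-exposed). Per gene the model is ordinary least squares on

    y_ij = β_j + γ_j·Age_i + δ_j·Sex_i + Σ_{k=1..3} μ_jk·Genotype_ik
           + Σ_{k=1..N} α_jk·PC_ik + θ_j·RIN_i + λ_j·PMI_i + ε_ij

with age in continuous years (decade brackets such as "50–59" map to their
midpoint, 54.5), sex coded male = 1, three donor-level numeric genotype
covariates accepted as supplied (the pipeline does not compute them from
genotypes), RIN and post-mortem interval as technical covariates, and the
top-N principal components of the gene-centered log-expression matrix as
data-driven technical covariates (N = 5 by default). The sex and PMI
coefficients are distinct parameters. γ_j is tested two-sided against its
classical OLS standard error with n − p degrees of freedom;
Benjamini–Hochberg FDR is computed across all tested genes and the aging
call uses FDR ≤ 0.01. Any fitted coefficient (e.g. sex, for
sex-dimorphism scans) can be tested through the same machinery
(`test_covariate`).

PCs are computed *per analysis cohort* (switchable): each cohort's
regression adjusts the technical structure actually present in that
cohort. The sign of each component is fixed by making its largest-|loading|
gene positive, so results are machine-independent. Because the fit is a
shared-design multi-outcome OLS, all genes are fitted with one
pseudoinverse; a rank-deficient design raises an error naming the collinear
columns (QR with pivoting), and a zero-variance gene is reported with
p = 1 and flagged rather than dropped silently.

### Cohort definitions

* **disease-free** — donor has no disease annotation at all.
* **tissue-level healthy** — donor has none of the disease codes mapped to
  the tissue, and passes tissue predicates: for subcutaneous fat, no type-2
  diabetes *and* BMI < 30. BMI ≥ 30 counts as obese (clinical convention;
  the boundary is covered by a test). Donors with missing BMI where the
  predicate applies are excluded with a logged reason.
* **tissue-level disease** — the complement of tissue-healthy among
  retained samples; **common** — all retained samples.
* **unhealthy** — tissue-healthy donors aged [20, 40) pooled with donors
  aged [40, 70] meeting the *full* disease predicate (for adipose: T2D and
  BMI ≥ 30 jointly). Young donors meeting the disease predicate are
  excluded: their disease is not an aging phenotype and including them
  masks age association. Age 40 falls in the old arm.

Eligibility gates are read strictly: a tissue is analyzed only with more
than 80 samples, and the healthy-vs-disease contrast is run only when more
than 20% of samples come from disease donors. One sample per donor per
tissue is assumed; duplicates keep the highest-RIN sample. The shipped
tissue→disease map covers the three tissues with explicit published rules
(subcutaneous fat, tibial artery, lung); further tissues are added through
the YAML config.

### Differential expression

Counts (not TPM — the precision-weight model requires them) are
transformed to `log2((count + 0.5) / (libsize + 1) · 1e6)`. Genes with all
zero counts are dropped first. An unweighted OLS fit of the DE design
(`condition + sex + age + RIN + ischemic time + genotype`; PMI is *not* in
this design) gives per-gene residual standard deviations; lowess
(span 0.5) smooths sqrt(residual SD) against average log-count; each
observation's fitted log-count is interpolated through the trend (flat
extrapolation at the ends) and the predicted sqrt-SD, floored at 1e-4, is
raised to the power −4 to give its precision weight. Weighted least
squares then yields the condition coefficient (log2 fold change, disease
minus healthy), and residual variances are moderated: the prior df d0 and
prior variance s0² are obtained by matching the mean and variance of
log s²_g to the moments implied by the scaled-F model (digamma/trigamma
terms; the trigamma is inverted by Newton iteration). The posterior
variance is s²_post = (d0·s0² + d·s²_g)/(d0 + d); the moderated t uses
d0 + d degrees of freedom. If log s²_g shows no excess variance the
procedure falls back to d0 = ∞ (full shrinkage) with a warning; d0 = 0
reproduces the ordinary per-gene t-test exactly, which is used as a
reduction test against the aging-model fitter. DEGs are fdr < 0.05,
strictly. During development the whole stage was cross-checked against the
reference R implementation on a 200-gene dataset (hyperparameters and
moderated t agreeing to ~1e-4 relative); the shipped test suite validates
the same quantities against self-contained numerical oracles.

### Partition, concordance, enrichment

The background universe for any comparison is the intersection of the
genes tested in both analyses (config-overridable). CAG = significant in
common ∩ healthy, CSAG = common only, HSAG = healthy only; directions
come from the common-cohort sign for CAG/CSAG and the healthy-cohort sign
for HSAG. All overlaps use the upper-tail hypergeometric test
P(X ≥ k) with N = |background|, K = |set A|, n = |set B|,
k = |A ∩ B| — enrichment only; depletion is not reported. The two set
arguments are canonicalized before the scipy call so the test is exactly
symmetric. Direction concordance compares sign(γ̂) with sign(logFC) among
genes significant in both tables by default (switchable to all shared
genes); zero-direction genes are dropped rather than counted inconsistent,
and an exact binomial test against 0.5 is reported.

The disease catalog (long TSV: term, gene, optional p, source) is filtered
on load: GWAS rows need p < 5e-8 (strict), OMIM rows are kept
unconditionally, duplicate memberships collapse, and terms keep ≥ 5 genes
or are dropped. The GWAS+OMIM merge itself is out of scope — the catalog
arrives pre-merged. Enrichment runs per partition set × regulation
direction with BH-FDR within each column and a top-k (default 5) flag.

## Synthetic data generator

The generator emulates a single-tissue biobank study; multi-tissue designs
are emulated by independent runs. Per donor: age ~ Uniform(20, 70);
P(disease | age) = logistic(−4.0 + 0.08·age), i.e. ~8% at 20 y rising to
~83% at 70 y and ~40% overall — comparable to the ~39% tissue-disease
fraction of the adipose cohort the analysis design was built around; sex
Bernoulli(0.5); BMI ~ Normal(27 + 0.08·(age − 40), 4) kg·m⁻²; RIN, PMI and
ischemic time Gaussian with realistic scales (7.5 ± 0.8; 600 ± 180 min;
400 ± 150 min); three standard-normal genotype covariates.

Per gene g and sample i the natural-log mean is

    μ_gi = b_g + γ_g·Age_i·[mask] + d_g·Disease_i + δ_g·Male_i
           + technical loadings,

counts ~ NB(mean = exp(μ_gi)·s_i, var = μ + 0.08·μ²) with a lognormal
library-size factor s_i (sd 0.3 on the log scale, around an expected ~2e6
counts per sample); the TPM-like matrix renormalizes each sample to 1e6.
Defaults: 1,500 null genes plus 100 per effect class; γ = 0.015 nat/yr
(≈ 11% per decade, a 2.1-fold change over the 50-year span); disease
shifts d = 0.4 (disease-driven), 0.15 (disease-DE-only) and, for
core-aging genes, 0.3 *sign-coupled to γ* — real core aging genes overlap
disease DEGs with consistent directions, and this coupling reproduces
that; sex shift δ = 0.5. Signs are random per gene. For healthy-specific
genes the whole γ·Age term is multiplied by (1 − Disease): in disease
donors the protective regulation fails and expression falls back to
baseline. A consequence worth knowing when reading default-run summaries:
these genes are strong DEGs with direction *opposite* to their aging
direction, so the default dataset's overall concordant fraction reflects
the planted core-vs-protective mix (≈ 0.45) rather than the ≈ 1.0 obtained
when only sign-coupled effects are planted.

### Technical structure and why the loadings look the way they do

Expression loads on *latent* sample factors, not on the recorded
covariates directly: the measured RIN/PMI/ischemic values correlate 0.7
with the latent quality factors the genes actually respond to, and two
further factors (unmeasured heterogeneity such as cell-type composition)
have no observed proxy at all. Loading scales (natural log per factor SD)
are 0.25/0.20/0.18 for the quality proxies, 0.165/0.14 for the latent
factors, and 0.11 (decaying 0.8 per component) for ancestry. Two design
goals drive these choices. First, the leading principal axes of expression
must be technical — the regime bulk RNA-seq PC adjustment assumes — so
that including 5 PCs in the regression removes unmeasured structure
without absorbing the age or disease contrasts (whose axis variances sit
well below the five technical axes). Second, the latent/proxy distinction
matters: if genes loaded on the *exactly measured* covariates, the PCs
would become nearly pure disease detectors after conditioning on those
covariates (the small disease component that leaks into each PC is
unmasked once the dominant technical component is explained away), and the
disease-confound mechanism the study exists to detect would vanish from
the common cohort — the opposite of how these analyses behave on real
data, where confound-driven age associations are detected despite PC
adjustment.

What the generator does **not** emulate: batch effects, read-level
sampling, eQTL architecture beyond numeric ancestry covariates, nonlinear
age trajectories, donor-level correlation across tissues, and
age-dependent technical quality (RIN and PMI are independent of age here).
Passing tests therefore demonstrate that the pipeline recovers the
mechanisms it models under realistic noise — not that it is robust to
every artifact of production biobank data.

### Calibration conditions

Per-gene error-rate checks (type-I fraction, realized FDR at the aging
cutoff) run on a pure-noise variant of the generator: all-null genes with
the shared technical loadings switched off. With shared axes present, the
2,000 null genes are not independent — whole axes swing with the
age-sampling noise of a given cohort draw — and the realized false-positive
fraction of a single draw fluctuates far beyond the binomial band that an
independence-based calibration check assumes. The pure-noise condition
tests what it is meant to test: the regression's per-gene calibration.

## Numerical choices

* BH-FDR delegates to `statsmodels.stats.multitest` (`fdr_bh`); tests
  verify it against an independent hand-written step-up to 1e-12.
* Hypergeometric tails come from `scipy.stats.hypergeom.sf`, verified
  against exact rational enumeration for every configuration with
  N ≤ 15 to 1e-12.
* Lowess is `statsmodels`' implementation with `frac = 0.5`, 3 robustness
  iterations; non-finite trend predictions (possible for degenerate
  all-equal input) fall to the 1e-4 sqrt-SD floor.
* The trigamma inverse uses Newton steps from the asymptotic starting
  point 0.5 + 1/x, with closed-form limits for very large/small arguments.
* One root seed drives everything; per-stage substreams are derived with
  `SeedSequence([seed, stage_id])`, so one stage's randomness can be
  studied in isolation and identical configs give byte-identical outputs
  (verified via the run manifest, which hashes the scientific config and
  excludes the output directory and timestamps).
* Simulated study sizes (500 donors × 2,000 genes by default; smaller in
  some unit fixtures) are chosen so every planted mechanism is recovered
  with high power while the full suite and the acceptance script stay
  fast on a single CPU.

## Known limitations

* The aging regression assumes linear age trends; spline/PEER-style
  corrections and cross-tissue meta-analysis are out of scope.
* The DE stage implements the single condition contrast only (no
  duplicate-correlation random effects, no quantile normalization).
* Partition membership is threshold-based; a gene just missing FDR ≤ 0.01
  in one cohort moves between CAG and a specific set, so boundary genes in
  the CSAG/HSAG lists deserve inspection of their actual p-values — on
  real data as in the simulation.
* The disease catalog loader is agnostic about whether GWAS rows carry
  mapped or reported genes; it filters whatever gene column it is given.
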