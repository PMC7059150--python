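"""Synthetic GTEx-like cohort and expression generator with known ground truth.

The generator reproduces the statistical structure the healthy-vs-common aging
analysis relies on: donor age drives disease prevalence through a logistic
model, disease and age both shift gene expression, and technical covariates
(RIN, PMI, ischemic time, genotype-derived axes) load broadly across genes.
Because disease prevalence rises with age, genes whose expression responds
only to disease acquire a *marginal* age association in the full cohort that
disappears once disease donors are removed — the mechanism that separates
"common" aging genes from "healthy" aging genes.

Gene classes
------------
null                no effect of age, disease, or sex
core_aging          age slope ``gamma_age`` in every donor; carries a
                    sign-matched disease effect ``d_core_disease`` (aging and
                    disease regulation concordant)
disease_driven      no age slope; disease shift ``d_disease`` (large enough
                    that the age→disease confound makes the gene look
                    age-associated in the full cohort)
healthy_specific    age slope present only in disease-free donors
                    (age × (1 − disease) interaction)
disease_de_only     modest disease shift ``d_disease_de_only``; detectable by
                    differential expression but too small for the confound to
                    reach aging significance
sex_interaction     sex shift ``delta_sex``; no age or disease effect

Counts are negative binomial around a log-linear mean with a lognormal
library-size factor; a TPM-like matrix is obtained by per-sample total
normalization to 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

GENE_CLASSES = (
    "null",
    "core_aging",
    "disease_driven",
    "healthy_specific",
    "disease_de_only",
    "sex_interaction",
)

#: disease-annotation code attached to simulated disease donors
SIMULATED_DISEASE_CODE = "T2D"
#: tissue label used for all simulated samples
SIMULATED_TISSUE = "subcutaneous_fat"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort + expression model.

    Defaults emulate a GTEx-scale single-tissue study: 500 donors aged
    20–70 y whose tissue-relevant disease prevalence climbs from ~8% at 20 y
    to ~83% at 70 y (~40% overall, comparable to the disease fraction in
    GTEx subcutaneous fat), 2,000 genes of which 500 carry planted effects.
    """

    n_donors: int = 500
    age_range: tuple[float, float] = (20.0, 70.0)
    # logit P(disease) = intercept + slope * age
    disease_logit_intercept: float = -4.0
    disease_logit_slope: float = 0.08  # per year
    sex_prob: float = 0.5  # probability of male
    bmi_mean: float = 27.0  # kg/m^2 at age 40
    bmi_age_slope: float = 0.08  # kg/m^2 per year
    bmi_sd: float = 4.0
    rin_mean: float = 7.5
    rin_sd: float = 0.8
    pmi_mean: float = 600.0  # minutes
    pmi_sd: float = 180.0
    ischemic_mean: float = 400.0  # minutes
    ischemic_sd: float = 150.0
    n_genotype_covariates: int = 3
    lib_size_log_mean: float = 14.5  # ~2e6 expected counts per sample
    lib_size_log_sd: float = 0.3
    nb_dispersion: float = 0.08  # var = mu + dispersion * mu^2
    # per-class gene counts
    n_null: int = 1500
    n_core_aging: int = 100
    n_disease_driven: int = 100
    n_healthy_specific: int = 100
    n_disease_de_only: int = 100
    n_sex_interaction: int = 100
    # effect sizes, natural-log expression units
    gamma_age: float = 0.015  # per year
    d_disease: float = 0.4
    d_disease_de_only: float = 0.15
    d_core_disease: float = 0.3  # sign-coupled to the gene's gamma_age
    delta_sex: float = 0.5
    # baseline log-mean expression
    baseline_log_mean: float = 5.3
    baseline_log_sd: float = 1.0
    # broad technical/ancestry loadings (per standardized factor unit,
    # natural log). Expression responds to *latent* sample-quality factors
    # of which the recorded RIN/PMI/ischemic values are noisy proxies
    # (correlation ``technical_proxy_corr``), plus fully unmeasured
    # heterogeneity factors (e.g. cell-type composition). Distinct scales
    # keep the principal axes of expression aligned with this technical
    # structure — the regime bulk RNA-seq PC adjustment assumes — rather
    # than with the planted age or disease contrasts.
    rin_loading_sd: float = 0.25
    pmi_loading_sd: float = 0.20
    ischemic_loading_sd: float = 0.18
    technical_proxy_corr: float = 0.7
    n_latent_factors: int = 2
    latent_loading_sds: tuple[float, ...] = (0.165, 0.14)
    genotype_loading_sd: float = 0.11
    genotype_loading_decay: float = 0.8  # per successive genotype covariate
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = [
            f.name
            for f in fields(self)
            if f.name not in ("age_range", "seed")
        ]
        for name in numeric:
            value = getattr(self, name)
            if not np.all(np.isfinite(value)):
                raise ValueError(f"non-finite value for {name!r}: {value!r}")
        lo, hi = self.age_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"age_range must be finite with low < high, got {self.age_range}")
        if not 0.0 <= self.sex_prob <= 1.0:
            raise ValueError("sex_prob must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0.0 <= self.technical_proxy_corr <= 1.0:
            raise ValueError("technical_proxy_corr must be in [0, 1]")
        if self.n_latent_factors > len(self.latent_loading_sds):
            raise ValueError("latent_loading_sds must cover n_latent_factors")
        for name in (
            "n_donors",
            "n_genotype_covariates",
            "n_null",
            "n_core_aging",
            "n_disease_driven",
            "n_healthy_specific",
            "n_disease_de_only",
            "n_sex_interaction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def class_sizes(self) -> dict[str, int]:
        return {
            "null": self.n_null,
            "core_aging": self.n_core_aging,
            "disease_driven": self.n_disease_driven,
            "healthy_specific": self.n_healthy_specific,
            "disease_de_only": self.n_disease_de_only,
            "sex_interaction": self.n_sex_interaction,
        }

    @property
    def n_genes(self) -> int:
        return sum(self.class_sizes.values())


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream derived from one root seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, _STAGE_IDS[stage]]))


_STAGE_IDS = {"cohort": 1, "truth": 2, "loadings": 3, "counts": 4}


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the donor and sample attribute tables.

    Returns ``(donors, samples)``: one sample per donor. Donors carry age,
    sex, BMI (with an age trend), PMI, a disease-annotation code set
    (here a single tissue-relevant code), and standardized genotype-derived
    covariates; samples carry tissue, RIN and ischemic time.
    """
    rng = _stage_rng(config.seed, "cohort")
    n = config.n_donors
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)
    logit = config.disease_logit_intercept + config.disease_logit_slope * age
    p_disease = 1.0 / (1.0 + np.exp(-logit))
    disease = rng.uniform(size=n) < p_disease
    sex = np.where(rng.uniform(size=n) < config.sex_prob, "male", "female")
    bmi = rng.normal(config.bmi_mean + config.bmi_age_slope * (age - 40.0), config.bmi_sd)
    bmi = np.clip(bmi, 15.0, None)
    pmi = np.clip(rng.normal(config.pmi_mean, config.pmi_sd, size=n), 1.0, None)
    rin = np.clip(rng.normal(config.rin_mean, config.rin_sd, size=n), 1.0, 10.0)
    ischemic = np.clip(rng.normal(config.ischemic_mean, config.ischemic_sd, size=n), 1.0, None)

    donor_ids = [f"DONOR-{i:04d}" for i in range(n)]
    donors = pd.DataFrame(
        {
            "donor_id": donor_ids,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "disease_codes": [SIMULATED_DISEASE_CODE if d else "" for d in disease],
            "pmi": pmi,
        }
    )
    for k in range(config.n_genotype_covariates):
        donors[f"genotype_{k + 1}"] = rng.standard_normal(n)

    samples = pd.DataFrame(
        {
            "sample_id": [f"SAMP-{i:04d}" for i in range(n)],
            "donor_id": donor_ids,
            "tissue": SIMULATED_TISSUE,
            "rin": rin,
            "ischemic_time": ischemic,
        }
    )
    return donors, samples


def generate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Assign gene classes and signed effect sizes (the SyntheticTruth table)."""
    if config.n_genes == 0:
        raise ValueError("gene class sizes sum to zero genes")
    rng = _stage_rng(config.seed, "truth")
    classes = np.repeat(
        list(config.class_sizes.keys()), list(config.class_sizes.values())
    )
    n_genes = len(classes)
    gene_ids = [f"GENE-{i:05d}" for i in range(n_genes)]
    gamma = np.zeros(n_genes)
    d_dis = np.zeros(n_genes)
    delta = np.zeros(n_genes)
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    for i, cls in enumerate(classes):
        if cls == "core_aging":
            gamma[i] = signs[i] * config.gamma_age
            d_dis[i] = signs[i] * config.d_core_disease
        elif cls == "disease_driven":
            d_dis[i] = signs[i] * config.d_disease
        elif cls == "healthy_specific":
            gamma[i] = signs[i] * config.gamma_age
        elif cls == "disease_de_only":
            d_dis[i] = signs[i] * config.d_disease_de_only
        elif cls == "sex_interaction":
            delta[i] = signs[i] * config.delta_sex
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "gene_class": classes,
            "gamma_age": gamma,
            "d_disease": d_dis,
            "delta_sex": delta,
        }
    )


def generate_expression(
    donors: pd.DataFrame,
    samples: pd.DataFrame,
    config: SimulationConfig,
    truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw negative-binomial counts and a TPM-like matrix for the cohort.

    Per gene g and sample i the natural-log mean is

        mu_gi = b_g + gamma_g * age_i * mask_gi + d_g * disease_i
                + delta_g * male_i + technical loadings,

    where ``mask_gi`` is 1 for all donors (core_aging) or ``1 - disease_i``
    (healthy_specific). Counts ~ NB(mean = exp(mu_gi) * size_factor_i,
    dispersion); tpm_like = counts normalized to 1e6 per sample.

    Returns ``(counts, tpm_like, truth)`` with genes as rows, samples as
    columns, and the truth table aligned to matrix rows.
    """
    if truth is None:
        truth = generate_truth(config)
    n_genes = len(truth)
    if n_genes == 0:
        raise ValueError("gene class sizes sum to zero genes")
    n = len(samples)
    merged = samples.merge(donors, on="donor_id", how="left", validate="one_to_one")

    rng_load = _stage_rng(config.seed, "loadings")
    baseline = rng_load.normal(config.baseline_log_mean, config.baseline_log_sd, n_genes)

    # standardized technical covariates with broad gene loadings
    def z(x: np.ndarray) -> np.ndarray:
        s = x.std()
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

    # latent quality factors: the recorded covariates are noisy proxies
    c = config.technical_proxy_corr
    mix = np.sqrt(max(0.0, 1.0 - c * c))
    proxies = [z(merged["rin"].to_numpy()), z(merged["pmi"].to_numpy()),
               z(merged["ischemic_time"].to_numpy())]
    tech_cols = [c * p + mix * rng_load.standard_normal(n) for p in proxies]
    tech_cols += [rng_load.standard_normal(n) for _ in range(config.n_latent_factors)]
    tech_sds = [config.rin_loading_sd, config.pmi_loading_sd, config.ischemic_loading_sd]
    tech_sds += list(config.latent_loading_sds[: config.n_latent_factors])
    tech_load = rng_load.normal(0.0, 1.0, (n_genes, len(tech_cols))) * np.array(tech_sds)
    geno_names = [c for c in donors.columns if c.startswith("genotype_")]
    geno = np.column_stack([z(merged[col].to_numpy()) for col in geno_names]) if geno_names else np.zeros((n, 0))
    geno_sds = config.genotype_loading_sd * config.genotype_loading_decay ** np.arange(geno.shape[1])
    geno_load = rng_load.normal(0.0, 1.0, (n_genes, geno.shape[1])) * geno_sds

    age = merged["age"].to_numpy()
    disease = (merged["disease_codes"].fillna("") != "").to_numpy().astype(float)
    male = (merged["sex"] == "male").to_numpy().astype(float)

    gamma = truth["gamma_age"].to_numpy()[:, None]
    d_dis = truth["d_disease"].to_numpy()[:, None]
    delta = truth["delta_sex"].to_numpy()[:, None]
    hs_mask = (truth["gene_class"] == "healthy_specific").to_numpy()[:, None]
    # age enters uncentered: for healthy_specific genes the whole gamma*age
    # contribution is masked in disease donors (their expression falls back
    # to baseline, the "protective regulation fails in disease" mechanism)
    age_row = age[None, :]
    age_term = np.where(hs_mask, gamma * age_row * (1.0 - disease)[None, :], gamma * age_row)

    log_mu = (
        baseline[:, None]
        + age_term
        + d_dis * disease[None, :]
        + delta * male[None, :]
        + tech_load @ np.vstack(tech_cols)
        + geno_load @ geno.T
    )

    rng_counts = _stage_rng(config.seed, "counts")
    lib_factor = np.exp(rng_counts.normal(0.0, config.lib_size_log_sd, n))
    mu = np.exp(log_mu) * lib_factor[None, :]
    # NB with var = mu + phi mu^2  ->  n_param = 1/phi, p = n/(n+mu)
    phi = config.nb_dispersion
    r = 1.0 / phi
    p = r / (r + mu)
    counts = rng_counts.negative_binomial(r, p)

    counts_df = pd.DataFrame(counts, index=truth["gene_id"].to_numpy(),
                             columns=samples["sample_id"].to_numpy())
    totals = counts_df.sum(axis=0).replace(0, 1)
    tpm_df = counts_df / totals.to_numpy()[None, :] * 1e6
    return counts_df, tpm_df, truth.copy()


def simulate_dataset(config: SimulationConfig | None = None):
    """One-call convenience: cohort + expression with a shared config.

    Returns ``(donors, samples, counts, tpm, truth)``.
    """
    if config is None:
        config = SimulationConfig()
    donors, samples = generate_cohort(config)
    counts, tpm, truth = generate_expression(donors, samples, config)
    return donors, samples, counts, tpm, truth
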