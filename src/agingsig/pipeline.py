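"""End-to-end orchestration: simulate/load -> cohorts -> aging regressions
-> differential expression -> partition -> concordance -> enrichment.

Each stage writes its output before the next starts; one root seed governs
every stochastic step; a manifest records config hash, input checksums and
per-stage row counts so that identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import aging as aging_mod
from . import cohorts as cohorts_mod
from . import de as de_mod
from . import enrichment as enrich_mod
from . import io as io_mod
from . import signatures as sig_mod
from .simulate import SIMULATED_TISSUE, SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and the simulation block for one pipeline run."""

    out_dir: str = "agingsig_out"
    tissue: str = SIMULATED_TISSUE
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # input paths (used when simulate = False)
    expression_tpm: str | None = None
    expression_counts: str | None = None
    donors_path: str | None = None
    samples_path: str | None = None
    catalog_path: str | None = None
    genage_path: str | None = None
    gmt_paths: list[str] = field(default_factory=list)
    column_map: dict[str, str] = field(default_factory=dict)
    tissue_map: dict | None = None
    # thresholds
    aging_fdr: float = 0.01
    deg_fdr: float = 0.05
    n_pcs: int = 5
    filter_min_value: float = 0.1
    filter_min_fraction: float = 0.2
    young_range: tuple[float, float] = (20.0, 40.0)
    old_range: tuple[float, float] = (40.0, 70.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("aging_fdr", "deg_fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        cfg = cls(**raw)
        if sim:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        # out_dir is excluded: the manifest hash covers the scientific
        # configuration, not where results land
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return d


def _resolve_tissue_map(config: PipelineConfig) -> cohorts_mod.TissueDiseaseMap:
    if config.tissue_map is not None:
        return cohorts_mod.TissueDiseaseMap.from_dict(config.tissue_map)
    return cohorts_mod.default_tissue_map()


def _aging_run(log_expr, samples, donors, sample_ids, n_pcs, fdr):
    """Fit the age regression on one cohort (PCs computed per cohort)."""
    sub = samples[samples["sample_id"].isin(sample_ids)].reset_index(drop=True)
    expr = log_expr.loc[:, sub["sample_id"]]
    pcs = aging_mod.compute_expression_pcs(expr, n_pcs)
    design = aging_mod.build_design(sub, donors, pcs)
    return aging_mod.fit_age_regression(expr, design, fdr_threshold=fdr)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest dict.

    Outputs (all TSV/JSON) land under ``config.out_dir``. An ineligible
    tissue (too few samples, or too small a disease fraction for the DE
    contrast) halts with an explanatory error instead of writing partial
    downstream results.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    inputs: dict[str, str] = {}

    # ---- inputs -----------------------------------------------------------
    if config.simulate:
        sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
        donors, samples, counts, tpm, truth = simulate_dataset(sim_cfg)
        donors.to_csv(out / "donors.tsv", sep="\t", index=False)
        samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        io_mod.write_gct(counts, out / "counts.gct")
        io_mod.write_gct(tpm, out / "tpm.gct")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        stages["simulate"] = {"n_donors": len(donors), "n_genes": len(counts)}
    else:
        donors = io_mod.read_attribute_table(config.donors_path, config.column_map)
        samples = io_mod.read_attribute_table(config.samples_path, config.column_map)
        tpm = io_mod.read_expression(config.expression_tpm)
        counts = io_mod.read_expression(config.expression_counts, counts=True)
        for key in ("expression_tpm", "expression_counts", "donors_path", "samples_path"):
            inputs[key] = io_mod.file_checksum(getattr(config, key))
        stages["load"] = {"n_donors": len(donors), "n_genes": len(counts)}

    # ---- cohorts ----------------------------------------------------------
    tissue_map = _resolve_tissue_map(config)
    assignment = cohorts_mod.assign_cohorts(donors, samples, config.tissue, tissue_map)
    assignment.to_csv(out / "assignment.tsv", sep="\t", index=False)
    eligibility = cohorts_mod.check_tissue_eligibility(assignment)
    stages["cohorts"] = {
        "n_samples": eligibility["n_samples"],
        "n_healthy": int(assignment["tissue_healthy"].sum()),
        "n_disease": eligibility["n_disease"],
        **{k: eligibility[k] for k in ("analysis_eligible", "healthy_vs_disease_eligible")},
    }
    if not eligibility["analysis_eligible"]:
        raise RuntimeError(
            f"tissue {config.tissue!r} is not analysis-eligible: "
            f"{eligibility['n_samples']} samples (> 80 required)"
        )
    if not eligibility["healthy_vs_disease_eligible"]:
        raise RuntimeError(
            f"tissue {config.tissue!r} fails the disease-fraction gate: "
            f"{eligibility['disease_fraction']:.1%} of samples from disease donors "
            "(> 20% required)"
        )
    unhealthy_ids = cohorts_mod.build_unhealthy_cohort(
        assignment, donors, rule=tissue_map[config.tissue],
        young_range=config.young_range, old_range=config.old_range,
    )

    # ---- aging regressions ------------------------------------------------
    log_expr = aging_mod.preprocess_expression(
        tpm, config.filter_min_value, config.filter_min_fraction
    )
    kept = assignment.loc[~assignment["excluded"]]
    cohort_ids = {
        "common": kept.loc[kept["common"], "sample_id"].tolist(),
        "tissue_healthy": kept.loc[kept["tissue_healthy"], "sample_id"].tolist(),
        "unhealthy": unhealthy_ids,
    }
    aging_tables: dict[str, pd.DataFrame] = {}
    for name, ids in cohort_ids.items():
        table = _aging_run(log_expr, samples, donors, ids,
                           config.n_pcs, config.aging_fdr)
        table.to_csv(out / f"aging_{name}.tsv", sep="\t")
        aging_tables[name] = table
        stages[f"aging_{name}"] = {
            "n_samples": len(ids),
            "n_genes_tested": len(table),
            "n_aging_genes": int(table["significant"].sum()),
        }

    # ---- differential expression -----------------------------------------
    de_ids = kept.loc[kept["tissue_healthy"] | kept["tissue_disease"]]
    de_samples = samples[samples["sample_id"].isin(de_ids["sample_id"])].reset_index(drop=True)
    condition = de_ids.set_index("sample_id")["tissue_disease"].astype(int)
    de_design = de_mod.build_de_design(de_samples, donors, condition)
    de_counts = counts.loc[:, de_design.index]
    deg_table = de_mod.run_differential_expression(de_counts, de_design,
                                                   fdr_threshold=config.deg_fdr)
    deg_table.to_csv(out / "degs.tsv", sep="\t")
    stages["diff_expr"] = {
        "n_genes_tested": len(deg_table),
        "n_degs": int(deg_table["is_deg"].sum()),
        "d0": deg_table.attrs["d0"],
        "s0_sq": deg_table.attrs["s0_sq"],
    }

    # ---- partition + concordance -----------------------------------------
    part = sig_mod.partition(aging_tables["common"], aging_tables["tissue_healthy"])
    part.membership_frame().to_csv(out / "partition.tsv", sep="\t", index=False)
    stages["partition"] = {
        "n_cag": len(part.cag), "n_csag": len(part.csag), "n_hsag": len(part.hsag),
        "n_background": len(part.background),
    }
    concordance = sig_mod.direction_concordance(aging_tables["tissue_healthy"], deg_table)
    with open(out / "concordance.json", "w") as fh:
        json.dump({k: v for k, v in concordance.items() if k != "per_gene"},
                  fh, indent=2, sort_keys=True)
    stages["concordance"] = {
        "n_shared": concordance["n_shared"],
        "n_consistent": concordance["n_consistent"],
    }

    # ---- enrichment (optional inputs) ------------------------------------
    if config.catalog_path:
        inputs["catalog"] = io_mod.file_checksum(config.catalog_path)
        catalog = enrich_mod.load_catalog(config.catalog_path)
        enr = enrich_mod.disease_enrichment(part, catalog)
        enr.to_csv(out / "disease_enrichment.tsv", sep="\t", index=False)
        stages["enrichment"] = {"n_terms": len(catalog), "n_rows": len(enr)}
    else:
        stages["enrichment"] = {"skipped": True}
    if config.genage_path:
        genage = set(pd.read_csv(config.genage_path, sep="\t", header=None)[0])
        ga = enrich_mod.genage_overlap(part, genage)
        ga.to_csv(out / "genage_overlap.tsv", sep="\t", index=False)
        stages["genage"] = {"n_genes": len(genage)}
    if config.gmt_paths:
        own_sets = {"CAG": part.cag, "CSAG": part.csag, "HSAG": part.hsag}
        collections: dict[str, set[str]] = {}
        for p in config.gmt_paths:
            collections.update(io_mod.read_gmt(p))
        cmp_table = sig_mod.compare_external(own_sets, collections, part.background)
        cmp_table.to_csv(out / "external_comparison.tsv", sep="\t", index=False)
        stages["external"] = {"n_collections": len(collections)}

    manifest = io_mod.write_manifest(
        out / "manifest.json",
        config=config.to_dict(), seed=config.seed, inputs=inputs, stages=stages,
    )
    return manifest
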