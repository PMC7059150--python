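"""Disease-gene-catalog enrichment of the aging-gene partition.

The catalog maps disease/trait terms to gene sets, merged from GWAS and OMIM
sources. Two filters are applied on load: GWAS associations must reach
genome-wide significance (p < 5e-8, strict), and a term must retain at least
five genes. Enrichment of each partition set, split by regulation direction,
is then scored with the same upper-tail hypergeometric test used everywhere
else, with BH-FDR within each set x direction column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .aging import bh_fdr
from .signatures import SignaturePartition, overlap_test

logger = logging.getLogger(__name__)

GWAS_P_THRESHOLD = 5e-8
MIN_GENES_PER_TERM = 5


@dataclass
class DiseaseCatalog:
    """term -> gene set, with source tags, after filtering."""

    terms: dict[str, set[str]] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "gene": g, "source": self.sources.get(t, "merged")}
            for t in sorted(self.terms)
            for g in sorted(self.terms[t])
        ]
        return pd.DataFrame(rows, columns=["term", "gene", "source"])


def load_catalog(
    catalog: pd.DataFrame | str,
    gwas_p_threshold: float = GWAS_P_THRESHOLD,
    min_genes: int = MIN_GENES_PER_TERM,
) -> DiseaseCatalog:
    """Build the disease catalog from a long-format table.

    Required columns: ``term`` and ``gene``; optional ``p`` (association
    p-value, used only for GWAS rows) and ``source`` ({gwas, omim, merged};
    rows without a source are treated as merged). GWAS rows with p at or
    above the genome-wide threshold are dropped; rows of other sources keep
    their genes unconditionally; duplicate (term, gene) pairs collapse to
    one membership; terms left with fewer than ``min_genes`` genes are
    dropped.
    """
    if isinstance(catalog, str):
        catalog = pd.read_csv(catalog, sep="\t", dtype=str)
    missing = {"term", "gene"} - set(catalog.columns)
    if missing:
        raise ValueError(f"catalog is missing required columns: {sorted(missing)}")
    df = catalog.copy()
    if "source" not in df.columns:
        df["source"] = "merged"
    df["source"] = df["source"].fillna("merged").str.lower()
    if "p" in df.columns:
        p = pd.to_numeric(df["p"], errors="coerce")
        gwas = df["source"] == "gwas"
        drop = gwas & ~(p < gwas_p_threshold)
        if drop.any():
            logger.info("dropped %d GWAS associations at p >= %g", int(drop.sum()),
                        gwas_p_threshold)
        df = df.loc[~drop]
    terms: dict[str, set[str]] = {}
    sources: dict[str, str] = {}
    for (term, source), grp in df.groupby(["term", "source"], sort=True):
        terms.setdefault(term, set()).update(grp["gene"])
        sources[term] = source if term not in sources or sources[term] == source else "merged"
    kept = {t: g for t, g in terms.items() if len(g) >= min_genes}
    n_dropped = len(terms) - len(kept)
    if n_dropped:
        logger.info("dropped %d terms with fewer than %d genes", n_dropped, min_genes)
    return DiseaseCatalog(kept, {t: sources[t] for t in kept})


def disease_enrichment(
    part: SignaturePartition,
    catalog: DiseaseCatalog,
    background=None,
    top_k: int = 5,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each partition set x direction against
    every catalog term.

    Catalog genes outside the background are dropped (logged); terms left
    disjoint from the background are skipped. An empty partition column
    reports p = 1 for every term. BH-FDR is applied within each
    set x direction column, and the top-``top_k`` terms by p per column are
    flagged in a ``top`` column.
    """
    if background is None:
        background = part.background
    background = set(background)
    sets = {}
    for name, genes in (("CAG", part.cag), ("CSAG", part.csag), ("HSAG", part.hsag)):
        for direction, label in ((1, "up"), (-1, "down")):
            sets[(name, label)] = {
                g for g in genes if part.directions.get(g, 0) == direction
            } & background
    rows = []
    for term, genes in sorted(catalog.terms.items()):
        mapped = set(genes) & background
        if genes and not mapped:
            logger.info("catalog term %r disjoint from background; skipped", term)
            continue
        if len(mapped) < len(genes):
            logger.debug("term %r: %d genes outside background dropped", term,
                         len(genes) - len(mapped))
        for (set_name, direction), own in sets.items():
            if own:
                rec = overlap_test(mapped, own, background)
            else:
                rec = {"N": len(background), "K": len(mapped), "n": 0, "k": 0, "p": 1.0}
            rec.update({"term": term, "set": set_name, "direction": direction})
            rows.append(rec)
    table = pd.DataFrame(rows,
                         columns=["term", "set", "direction", "N", "K", "n", "k", "p"])
    if not len(table):
        table["fdr"] = []
        table["top"] = []
        return table
    table["fdr"] = 1.0
    table["top"] = False
    for (set_name, direction), grp in table.groupby(["set", "direction"]):
        table.loc[grp.index, "fdr"] = bh_fdr(grp["p"].to_numpy())
        top_idx = grp.nsmallest(top_k, "p").index
        table.loc[top_idx, "top"] = True
    return table


def genage_overlap(
    part: SignaturePartition,
    genage_genes,
    background=None,
    p_flag: float = 0.01,
) -> pd.DataFrame:
    """Overlap of each partition set with a curated aging-gene list (GenAge
    style). Enrichment at p below ``p_flag`` is flagged, matching the usual
    reporting convention for this comparison."""
    if background is None:
        background = part.background
    background = set(background)
    genage = set(genage_genes) & background
    rows = []
    for name, genes in (("CAG", part.cag), ("CSAG", part.csag), ("HSAG", part.hsag)):
        if genage:
            rec = overlap_test(genes & background, genage, background)
        else:
            rec = {"N": len(background), "K": 0, "n": len(genes & background),
                   "k": 0, "p": 1.0}
        rec["set"] = name
        rec["enriched"] = rec["p"] < p_flag
        rows.append(rec)
    return pd.DataFrame(rows, columns=["set", "N", "K", "n", "k", "p", "enriched"])
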