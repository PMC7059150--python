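"""Three-way aging-gene partition, overlap enrichment, and direction
concordance.

Aging genes detected in the all-donor ("common") cohort and in the
tissue-healthy cohort are partitioned into core aging genes (CAGs,
significant in both), common-specific aging genes (CSAGs, common only) and
healthy-specific aging genes (HSAGs, healthy only). Overlaps between gene
sets are scored by the upper-tail hypergeometric test on a shared background
universe; direction concordance compares the sign of a gene's age
coefficient with the sign of its disease log-fold-change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .aging import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class SignaturePartition:
    """CAG / CSAG / HSAG sets with per-gene directions and the background."""

    cag: set[str]
    csag: set[str]
    hsag: set[str]
    background: set[str]
    common_sig: set[str] = field(default_factory=set)
    healthy_sig: set[str] = field(default_factory=set)
    # direction of the age association; common-cohort sign for CAG/CSAG,
    # healthy-cohort sign for HSAG
    directions: dict[str, int] = field(default_factory=dict)

    def membership_frame(self) -> pd.DataFrame:
        rows = []
        for name, genes in (("CAG", self.cag), ("CSAG", self.csag), ("HSAG", self.hsag)):
            for g in sorted(genes):
                rows.append({"gene_id": g, "set": name,
                             "direction": self.directions.get(g, 0)})
        return pd.DataFrame(rows, columns=["gene_id", "set", "direction"])


def partition(
    common_table: pd.DataFrame,
    healthy_table: pd.DataFrame,
    sig_col: str = "significant",
) -> SignaturePartition:
    """Partition aging genes by which cohort detects them.

    Both tables must come from the aging regression (per-gene rows with a
    boolean significance flag and a ``direction`` column). The background is
    the intersection of the genes tested in both analyses; genes tested in
    only one are excluded and logged.
    """
    background = set(common_table.index) & set(healthy_table.index)
    dropped = (len(common_table) - len(background), len(healthy_table) - len(background))
    if any(dropped):
        logger.info("partition background: dropped %d common-only and %d healthy-only "
                    "tested genes", *dropped)
    common_sig = set(common_table.index[common_table[sig_col]]) & background
    healthy_sig = set(healthy_table.index[healthy_table[sig_col]]) & background
    cag = common_sig & healthy_sig
    csag = common_sig - healthy_sig
    hsag = healthy_sig - common_sig
    directions: dict[str, int] = {}
    for g in common_sig:
        directions[g] = int(common_table.loc[g, "direction"])
    for g in hsag:
        directions[g] = int(healthy_table.loc[g, "direction"])
    return SignaturePartition(
        cag=cag, csag=csag, hsag=hsag, background=background,
        common_sig=common_sig, healthy_sig=healthy_sig, directions=directions,
    )


def overlap_test(set_a, set_b, background) -> dict:
    """Upper-tail hypergeometric overlap test.

    With N = |background|, K = |set_a|, n = |set_b| and k = |A ∩ B|, the
    p-value is P(X >= k) for X ~ Hypergeometric(N, K, n). Both sets must be
    subsets of the background.
    """
    background = set(background)
    if not background:
        raise ValueError("background universe is empty")
    a = set(set_a)
    b = set(set_b)
    if not a <= background or not b <= background:
        raise ValueError("sets must be subsets of the background universe")
    N, K, n, k = len(background), len(a), len(b), len(a & b)
    # the tail is symmetric in (K, n); canonicalize so the test is exactly so
    lo, hi = min(K, n), max(K, n)
    p = float(stats.hypergeom.sf(k - 1, N, lo, hi))
    return {"N": N, "K": K, "n": n, "k": k, "p": min(p, 1.0)}


def direction_concordance(
    aging_table: pd.DataFrame,
    deg_table: pd.DataFrame,
    aging_sig_col: str = "significant",
    deg_sig_col: str = "is_deg",
    restrict_to_significant: bool = True,
) -> dict:
    """Sign agreement between age regulation and disease regulation.

    For genes present in both tables (by default, significant in both), a
    gene is consistent when sign(age estimate) == sign(logFC). Zero-direction
    genes are excluded. Reports counts, the concordant fraction, and an exact
    binomial test against 0.5.
    """
    shared = aging_table.index.intersection(deg_table.index)
    a = aging_table.loc[shared]
    d = deg_table.loc[shared]
    if restrict_to_significant:
        keep = a[aging_sig_col].to_numpy() & d[deg_sig_col].to_numpy()
        a, d = a.loc[keep], d.loc[keep]
    a_dir = a["direction"].to_numpy()
    d_dir = d["direction"].to_numpy()
    nonzero = (a_dir != 0) & (d_dir != 0)
    a_dir, d_dir = a_dir[nonzero], d_dir[nonzero]
    consistent = a_dir == d_dir
    n_total = int(consistent.size)
    n_consistent = int(consistent.sum())
    if n_total:
        p = stats.binomtest(n_consistent, n_total, 0.5).pvalue
        fraction = n_consistent / n_total
    else:
        p, fraction = 1.0, float("nan")
    per_gene = pd.DataFrame(
        {"aging_direction": a_dir, "disease_direction": d_dir, "consistent": consistent},
        index=a.index[nonzero] if n_total else [],
    )
    return {
        "n_shared": n_total,
        "n_consistent": n_consistent,
        "n_inconsistent": n_total - n_consistent,
        "fraction_consistent": fraction,
        "binomial_p": float(p),
        "per_gene": per_gene,
    }


def compare_external(
    own_sets: dict[str, set[str]],
    gmt_collections: dict[str, set[str]],
    background,
) -> pd.DataFrame:
    """Hypergeometric overlap of each own set against each external gene
    list, BH-corrected across all comparisons.

    External genes outside the background are dropped (fraction logged);
    external sets with no background genes at all are skipped with a warning.
    """
    background = set(background)
    rows = []
    for ext_name, ext_genes in gmt_collections.items():
        ext = set(ext_genes)
        mapped = ext & background
        if ext and not mapped:
            logger.warning("external set %r is disjoint from the background; skipped",
                           ext_name)
            continue
        if len(mapped) < len(ext):
            logger.info("external set %r: %d/%d genes outside background dropped",
                        ext_name, len(ext) - len(mapped), len(ext))
        for own_name, own in own_sets.items():
            rec = overlap_test(set(own) & background, mapped, background)
            rec.update({"own_set": own_name, "external_set": ext_name})
            rows.append(rec)
    table = pd.DataFrame(rows, columns=["own_set", "external_set", "N", "K", "n", "k", "p"])
    if len(table):
        table["fdr"] = bh_fdr(table["p"].to_numpy())
    else:
        table["fdr"] = []
    return table
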