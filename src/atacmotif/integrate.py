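"""Linking accessible sites to genes and calling regulatory roles.

Each ACS is annotated with its nearest transcription start site (distance
from the ACS midpoint, sign oriented by the gene's strand so positive
means downstream of the TSS) and binned into the location classes used
for promoter-context analysis: TSS (|d| <= 1 kb), proximal (1-10 kb) and
distal (> 10 kb).  Differential ACS whose accessibility change is
sign-concordant with a significant expression change of the linked gene
are called enhancers; anti-concordant ones repressors.  A hypergeometric
test asks whether differentially expressed genes are over-represented
among the targets of a motif, and a Pearson test correlates two gene
fold-change vectors (e.g. a knockdown signature against maturation).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enrichment import hypergeometric_test

logger = logging.getLogger(__name__)

TSS_BOUND = 1_000       # |distance| <= 1 kb -> "TSS" class
PROXIMAL_BOUND = 10_000  # 1 kb < |distance| <= 10 kb -> "proximal"


def location_class(signed_distance: float) -> str:
    """TSS / proximal / distal from a signed midpoint-to-TSS distance (bp)."""
    d = abs(signed_distance)
    if d <= TSS_BOUND:
        return "TSS"
    if d <= PROXIMAL_BOUND:
        return "proximal"
    return "distal"


def nearest_tss(acs, tss_table: pd.DataFrame) -> pd.DataFrame:
    """Nearest gene per ACS with signed distance and location class.

    ``tss_table`` is indexed by gene id with columns chrom, strand, tss.
    Distance is ACS midpoint minus TSS, sign flipped for minus-strand
    genes (positive = downstream of the TSS).  Ties on |distance| go to
    the lexicographically smallest gene id; ACS on chromosomes without any
    TSS are left unlinked (logged).
    """
    if len(tss_table) == 0:
        raise ValueError("empty TSS table")
    rows = []
    by_chrom = {c: sub.sort_values("tss") for c, sub in tss_table.groupby("chrom")}
    n_unlinked = 0
    for r in acs:
        sub = by_chrom.get(r.chrom)
        if sub is None:
            rows.append((r.id, None, np.nan, None))
            n_unlinked += 1
            continue
        tss = sub["tss"].to_numpy()
        absd = np.abs(r.midpoint - tss)
        best = absd.min()
        cand = np.flatnonzero(absd == best)
        gene = min(sub.index[cand])  # deterministic tie-break
        row = sub.loc[gene]
        d = r.midpoint - int(row["tss"])
        if row["strand"] == "-":
            d = -d
        rows.append((r.id, gene, d, location_class(d)))
    if n_unlinked:
        logger.warning("%d ACS on chromosomes without any TSS left unlinked",
                       n_unlinked)
    return pd.DataFrame(rows, columns=["acs_id", "gene_id", "signed_distance",
                                       "location_class"]).set_index("acs_id")


def classify_regulatory_role(acs_class: str, acs_log2fc: float,
                             gene_log2fc: float, gene_significant: bool) -> str:
    """Enhancer / repressor / unlinked for one ACS-gene pair.

    An ACS acts as an enhancer when its accessibility change and the
    linked gene's expression change are both significant and share sign;
    as a repressor when the signs oppose; otherwise it is unlinked.
    """
    if acs_class == "Stable" or not gene_significant:
        return "unlinked"
    s_acs, s_gene = np.sign(acs_log2fc), np.sign(gene_log2fc)
    if s_acs == 0 or s_gene == 0:
        return "unlinked"
    return "enhancer" if s_acs == s_gene else "repressor"


def annotate_links(acs, tss_table: pd.DataFrame, diff_table: pd.DataFrame,
                   gene_table: pd.DataFrame, gene_fdr_threshold: float = 0.05,
                   max_distance: int | None = None) -> pd.DataFrame:
    """Full ACS-to-gene annotation: distance, location class, role.

    ``diff_table`` carries per-ACS log2fc and class (from the differential
    fit); ``gene_table`` per-gene log2fc and fdr.  ``max_distance``
    optionally unlinks ACS farther than that from every TSS.
    """
    links = nearest_tss(acs, tss_table)
    roles = []
    for acs_id, row in links.iterrows():
        gene = row["gene_id"]
        if gene is None or gene not in gene_table.index \
                or acs_id not in diff_table.index:
            roles.append("unlinked")
            continue
        if max_distance is not None and abs(row["signed_distance"]) > max_distance:
            roles.append("unlinked")
            continue
        g = gene_table.loc[gene]
        significant = ("fdr" not in g) or (g["fdr"] < gene_fdr_threshold)
        roles.append(classify_regulatory_role(
            diff_table.loc[acs_id, "class"], diff_table.loc[acs_id, "log2fc"],
            g["log2fc"], bool(significant)))
    links["role"] = roles
    return links


def motif_target_enrichment(motif_id: str, match_matrix, gene_links: pd.DataFrame,
                            de_gene_ids, universe_gene_ids) -> dict:
    """Are DE genes over-represented among a motif's linked target genes?

    A gene is a motif target when at least one of its linked ACS carries a
    match.  Returns the hypergeometric upper-tail p with the counts
    (k = DE targets, K = targets, n = DE genes, N = universe size).
    """
    universe = set(universe_gene_ids)
    de = set(de_gene_ids)
    if not universe:
        raise ValueError("empty gene universe")
    if not de <= universe:
        raise ValueError("DE genes must be a subset of the universe")
    N_col = match_matrix.N[motif_id]
    carrying = set(N_col.index[N_col > 0])
    linked = gene_links.dropna(subset=["gene_id"])
    targets = {g for a, g in linked["gene_id"].items()
               if a in carrying and g in universe}
    k = len(targets & de)
    K = len(targets)
    n = len(de)
    N = len(universe)
    return {"motif_id": motif_id, "k": k, "K": K, "n": n, "N": N,
            "p_value": hypergeometric_test(k, K, n, N)}


def foldchange_correlation(fc_a: pd.Series, fc_b: pd.Series) -> tuple[float, float]:
    """Pearson r and two-sided p between two per-gene fold-change vectors.

    Vectors are aligned on their shared genes (>= 3 required); the p-value
    uses the t-transform with n - 2 degrees of freedom.
    """
    shared = fc_a.index.intersection(fc_b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    a = fc_a.loc[shared].to_numpy(dtype=float)
    b = fc_b.loc[shared].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a fold-change vector")
    res = sps.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
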