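"""Evidence merging, scoring, tissue prioritization and replication.

A gene enters the base prioritized list when at least one of the four
merge sources supports it: coding consequences (NS), multilayer molecular
associations (ML), TWAS (MX or SMR), or coregulation (DEPICT).  The
evidence score additionally counts MX and SMR separately and adds the
methylation-mediation chains (3xSMR), for six sources total; genes with a
score of at least four form the most-highly-prioritized tier.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SOURCES = ("NS", "ML", "MX", "SMR", "DEPICT", "3xSMR")
MERGE_SOURCES = ("NS", "ML", "TWAS", "DEPICT")  # TWAS = MX or SMR


def merge_evidence(
    ns_genes=(),
    ml_genes=(),
    mx_genes=(),
    smr_genes=(),
    depict_genes=(),
    chain_genes=(),
    trait_genes: dict[str, set[str]] | None = None,
    known_genes=(),
) -> pd.DataFrame:
    """Gene x source boolean table with score, tier and novelty flag.

    Base membership = union of the four merge sources (mediation evidence
    contributes to the score but cannot create membership on its own).
    ``tier``: base (>=1 merge source), multi (score >= 2), high (score >= 4).
    ``novel`` = absent from the caller-supplied known-gene list.
    """
    sets = {
        "NS": set(ns_genes), "ML": set(ml_genes), "MX": set(mx_genes),
        "SMR": set(smr_genes), "DEPICT": set(depict_genes), "3xSMR": set(chain_genes),
    }
    base = sets["NS"] | sets["ML"] | sets["MX"] | sets["SMR"] | sets["DEPICT"]
    known = set(known_genes)
    rows = []
    for gene in sorted(base):
        flags = {s: gene in sets[s] for s in SOURCES}
        score = sum(flags.values())
        tier = "high" if score >= 4 else ("multi" if score >= 2 else "base")
        row = {"gene": gene, **flags, "score": score, "tier": tier,
               "novel": gene not in known}
        if trait_genes:
            for trait, members in trait_genes.items():
                row[trait] = gene in members
        rows.append(row)
    cols = ["gene", *SOURCES, "score", "tier", "novel"]
    if trait_genes:
        cols += list(trait_genes)
    return pd.DataFrame(rows, columns=cols)


def score_evidence_sets(evidence: dict[str, set[str]], min_sources: int = 4) -> pd.DataFrame:
    """Count supporting sources per gene over arbitrary evidence sets and
    keep genes meeting ``min_sources`` — the most-highly-prioritized filter."""
    genes = sorted(set().union(*evidence.values())) if evidence else []
    rows = [
        {"gene": g, "score": sum(g in s for s in evidence.values())} for g in genes
    ]
    out = pd.DataFrame(rows, columns=["gene", "score"])
    return out[out["score"] >= min_sources].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Tissue prioritization
# ---------------------------------------------------------------------------

def tissue_priority(
    results: dict[str, dict[tuple[str, str], np.ndarray]],
) -> pd.DataFrame:
    """Rank tissues by the grand mean of per-cell average squared Z.

    ``results[tissue][(trait, method)]`` is the vector of gene-level
    Z-scores tested in that cell.  Empty cells are omitted with a warning;
    a tissue with no non-empty cell is dropped.  Ties in the grand mean are
    broken by tissue name.
    """
    rows = []
    for tissue, cells in results.items():
        s_values = {}
        for (trait, method), z in cells.items():
            z = np.asarray(z, dtype=float)
            if z.size == 0:
                log.warning("tissue_priority: empty cell %s/%s/%s omitted", tissue, trait, method)
                continue
            s_values[(trait, method)] = float(np.mean(z**2))
        if not s_values:
            log.warning("tissue_priority: tissue %s has no data; dropped", tissue)
            continue
        for (trait, method), s in s_values.items():
            rows.append({"tissue": tissue, "trait": trait, "method": method, "S": s})
    table = pd.DataFrame(rows, columns=["tissue", "trait", "method", "S"])
    if table.empty:
        table["grand_mean"] = []
        table["rank"] = []
        return table
    grand = table.groupby("tissue")["S"].mean().rename("grand_mean").reset_index()
    grand = grand.sort_values(["grand_mean", "tissue"], ascending=[False, True])
    grand["rank"] = np.arange(1, len(grand) + 1)
    return table.merge(grand, on="tissue").sort_values(
        ["rank", "trait", "method"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Replication
# ---------------------------------------------------------------------------

def replicate(
    selected_genes: list[str],
    replication_results: pd.DataFrame,
    traits_of_evidence: dict[str, set[str]] | None = None,
    alpha: float = 0.05,
    count_not_testable: bool = True,
) -> pd.DataFrame:
    """Per-gene minimum replication p across methods and traits of evidence.

    ``replication_results`` columns: gene, method, trait, p.  A gene absent
    from the replication models is marked not testable; by default it still
    counts in the denominator as not replicated (conservative).
    """
    rows = []
    for gene in selected_genes:
        sub = replication_results[replication_results["gene"] == gene]
        if traits_of_evidence and gene in traits_of_evidence:
            sub = sub[sub["trait"].isin(traits_of_evidence[gene])]
        if sub.empty:
            rows.append({"gene": gene, "min_p_rep": np.nan, "testable": False,
                         "replicated": False})
        else:
            mp = float(sub["p"].min())
            rows.append({"gene": gene, "min_p_rep": mp, "testable": True,
                         "replicated": mp < alpha})
    out = pd.DataFrame(rows, columns=["gene", "min_p_rep", "testable", "replicated"])
    denom = len(out) if count_not_testable else int(out["testable"].sum())
    out.attrs["n_replicated"] = int(out["replicated"].sum())
    out.attrs["fraction_replicated"] = (
        out.attrs["n_replicated"] / denom if denom else np.nan
    )
    return out


def cross_tissue_consistency(
    gene: str,
    per_tissue_results: pd.DataFrame,
    traits_of_evidence: set[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, bool | None]:
    """Effect-sign matrix per tissue x method and a consistency flag.

    Flag is True iff some tissue shows a nominally significant association
    (p < alpha) for a trait of evidence with the same effect sign in both
    TWAS methods.  A gene untested everywhere gets flag ``None`` (distinct
    from False).
    """
    sub = per_tissue_results[per_tissue_results["gene"] == gene]
    if traits_of_evidence is not None:
        sub = sub[sub["trait"].isin(traits_of_evidence)]
    if sub.empty:
        return pd.DataFrame(columns=["tissue", "trait", "method", "sign", "p"]), None
    matrix = sub.assign(sign=np.sign(sub["b"]))[["tissue", "trait", "method", "sign", "p"]]
    flag = False
    for (tissue, trait), cell in matrix.groupby(["tissue", "trait"]):
        methods = cell.groupby("method")["sign"].first()
        if len(methods) >= 2 and methods.nunique() == 1 and (cell["p"] < alpha).any():
            flag = True
            break
    return matrix.reset_index(drop=True), flag
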