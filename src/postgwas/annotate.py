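"""Coding-consequence and multilayer molecular-association prioritization.

Both operations consume locally supplied lookup tables (variant
consequences with SIFT/PolyPhen labels; per-layer QTL association tables)
rather than querying web services, so runs are deterministic and
versionable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ld import LdPanel

log = logging.getLogger(__name__)

SIFT_LABELS = {"deleterious", "tolerated", "NA"}
POLYPHEN_LABELS = {"probably_damaging", "possibly_damaging", "benign", "NA"}
LAYERS = ("methylation", "expression", "protein", "metabolite")


def coding_consequences(
    lead_snps: list[str],
    panel: LdPanel,
    consequence_table: pd.DataFrame,
    r2_threshold: float = 0.50,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Genes carrying a nonsynonymous SNP linked (r^2 > threshold) to a lead.

    Each returned gene lists its nsSNPs, whether any nsSNP is itself a
    lead, and a ``severe`` flag requiring BOTH predictors adverse (SIFT
    deleterious AND PolyPhen possibly/probably damaging).
    """
    bad_sift = set(consequence_table["sift"].unique()) - SIFT_LABELS
    bad_pp = set(consequence_table["polyphen"].unique()) - POLYPHEN_LABELS
    if bad_sift or bad_pp:
        raise ValueError(f"unknown predictor label(s): {bad_sift | bad_pp}")
    proxies = panel.proxy_expand(lead_snps, r2_threshold=r2_threshold, window_bp=window_bp)
    ns = consequence_table[consequence_table["consequence"] == "nonsynonymous"]
    joined = proxies.merge(ns, left_on="proxy_snp", right_on="SNP")
    if joined.empty:
        return pd.DataFrame(columns=["gene", "ns_snps", "any_lead", "severe"])
    joined["is_lead"] = joined["proxy_snp"].isin(set(lead_snps))
    joined["adverse"] = (joined["sift"] == "deleterious") & joined["polyphen"].isin(
        ["possibly_damaging", "probably_damaging"]
    )
    out = (
        joined.groupby("gene")
        .agg(
            ns_snps=("proxy_snp", lambda s: ",".join(sorted(set(s)))),
            any_lead=("is_lead", "any"),
            severe=("adverse", "any"),
        )
        .reset_index()
    )
    return out


def multilayer_hits(
    lead_snps: list[str],
    qtl_tables: dict[str, pd.DataFrame],
    lead_genes: dict[str, str],
    p_threshold: float = 5e-8,
) -> pd.DataFrame:
    """Leads associated with ALL four molecular layers at ``p_threshold``.

    ``qtl_tables`` must provide the keys methylation/expression/protein/
    metabolite, each a table with ``SNP`` and ``p`` columns;
    ``lead_genes`` maps each lead to its annotated nearby gene.
    """
    missing = [layer for layer in LAYERS if layer not in qtl_tables]
    if missing:
        raise ValueError(f"missing molecular layer table(s): {missing}")
    rows = []
    for lead in lead_snps:
        hits = {}
        for layer in LAYERS:
            tab = qtl_tables[layer]
            sub = tab[(tab["SNP"] == lead) & (tab["p"] < p_threshold)]
            hits[layer] = len(sub)
        if all(v > 0 for v in hits.values()):
            rows.append(
                {"SNP": lead, "gene": lead_genes.get(lead, "")} |
                {f"n_{layer}": hits[layer] for layer in LAYERS}
            )
    return pd.DataFrame(
        rows, columns=["SNP", "gene"] + [f"n_{l}" for l in LAYERS]
    )
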