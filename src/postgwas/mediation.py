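"""Three-way SMR mediation: DNA -> methylation -> expression -> trait.

Three scans are intersected into chain records:

* ESMR: trait GWAS vs cis-eQTL (gene expression leg),
* MSMR: trait GWAS vs cis-mQTL (methylation leg),
* M2E:  cis-eQTL outcome vs cis-mQTL exposure (site -> gene leg), paired
  within a cis distance.

A (site, gene) chain is emitted only when all three legs pass their
Bonferroni + HEIDI thresholds.  A direction-consistency flag —
sign(b_m->y) == sign(b_m->e * b_e->y) — is reported for inspection but
never used as a filter.  The module also provides the nearest-gene
distance summary used to contrast methylation sites near genes with and
without functional evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import smr as psmr
from .ld import LdPanel

log = logging.getLogger(__name__)

M2E_CIS_BP = 2_000_000

CHAIN_COLUMNS = [
    "site", "gene", "trait", "b_m2e", "b_e2y", "b_m2y",
    "p_m2e", "p_e2y", "p_m2y", "heidi_m2e", "heidi_e2y", "heidi_m2y",
    "consistent", "distance_bp",
]


def m2e_scan(
    eqtl: pd.DataFrame,
    mqtl: pd.DataFrame,
    panel: LdPanel,
    alpha: float = 0.05,
    cis_bp: int = M2E_CIS_BP,
    **scan_kwargs,
) -> pd.DataFrame:
    """SMR of methylation (exposure) against expression (outcome) for every
    site-gene pair within ``cis_bp``.

    Each eligible pair is tested with the site's mQTL records as exposure
    and the gene's eQTL records as per-SNP outcome; Bonferroni corrects for
    the number of pairs tested.
    """
    sites = mqtl[["probe_id", "probe_bp"]].drop_duplicates()
    genes = eqtl[["probe_id", "probe_bp"]].drop_duplicates().rename(
        columns={"probe_id": "gene_probe", "probe_bp": "gene_bp"}
    )
    pairs = sites.merge(genes, how="cross")
    pairs = pairs[(pairs["probe_bp"] - pairs["gene_bp"]).abs() <= cis_bp]
    frames = []
    eqtl_by_gene = dict(tuple(eqtl.groupby("probe_id", sort=False)))
    mqtl_by_site = dict(tuple(mqtl.groupby("probe_id", sort=False)))
    for _, pr in pairs.iterrows():
        site, gene = pr["probe_id"], pr["gene_probe"]
        exp = mqtl_by_site[site]
        out = eqtl_by_gene[gene][["SNP", "A1", "A2", "freq", "b", "se", "p", "n"]]
        res = psmr.smr_scan(out, exp, panel, alpha=1.0, **scan_kwargs)
        if res.empty:
            continue
        res = res.assign(gene_id=gene, pair=f"{site}::{gene}")
        frames.append(res)
    if not frames:
        out = pd.DataFrame(columns=psmr.SMR_COLUMNS + ["pair"])
        out.attrs["bonferroni_threshold"] = np.nan
        return out
    result = pd.concat(frames, ignore_index=True)
    n_tested = len(result)
    threshold = alpha / n_tested
    result["pass_bonferroni"] = result["p_SMR"] < threshold
    heidi_ok = (~result["heidi_testable"]) | (result["p_HEIDI"] >= psmr.HEIDI_PASS)
    result["pass"] = result["pass_bonferroni"] & heidi_ok
    result.attrs["bonferroni_threshold"] = threshold
    result.attrs["n_tested"] = n_tested
    return result


def run_3smr(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    mqtl: pd.DataFrame,
    panel: LdPanel,
    alpha: float = 0.05,
    **scan_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """The three scans (ESMR, MSMR, M2E), each with its own run-specific
    Bonferroni threshold and the HEIDI >= 0.01 filter."""
    esmr = psmr.smr_scan(gwas, eqtl, panel, alpha=alpha, **scan_kwargs)
    msmr = psmr.smr_scan(gwas, mqtl, panel, alpha=alpha, **scan_kwargs)
    m2e = m2e_scan(eqtl, mqtl, panel, alpha=alpha, **scan_kwargs)
    return esmr, msmr, m2e


def intersect_chains(
    esmr: pd.DataFrame,
    msmr: pd.DataFrame,
    m2e: pd.DataFrame,
    trait: str = "BP",
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Chains = join of the three pass sets.

    (site, gene) is emitted iff the site passes MSMR, the gene passes ESMR,
    and the pair passes the methylation-to-expression scan.  By
    construction no chain can appear without all three legs.
    """
    e_pass = esmr[esmr["pass"]] if len(esmr) else esmr
    m_pass = msmr[msmr["pass"]] if len(msmr) else msmr
    pair_pass = m2e[m2e["pass"]] if len(m2e) else m2e
    rows = []
    e_by_gene = {r["gene_id"]: r for _, r in e_pass.iterrows()}
    m_by_site = {r["probe"]: r for _, r in m_pass.iterrows()}
    for _, pr in pair_pass.iterrows():
        site, gene = pr["probe"], pr["gene_id"]
        if site not in m_by_site or gene not in e_by_gene:
            continue
        er, mr = e_by_gene[gene], m_by_site[site]
        b_m2e, b_e2y, b_m2y = pr["b_SMR"], er["b_SMR"], mr["b_SMR"]
        consistent = (
            bool(np.sign(b_m2y) == np.sign(b_m2e * b_e2y))
            if b_m2e != 0 and b_e2y != 0 and b_m2y != 0
            else None
        )
        dist = np.nan
        if annotation is not None:
            dist = _site_gene_distance(annotation, site, gene)
        rows.append(
            {
                "site": site, "gene": gene, "trait": trait,
                "b_m2e": b_m2e, "b_e2y": b_e2y, "b_m2y": b_m2y,
                "p_m2e": pr["p_SMR"], "p_e2y": er["p_SMR"], "p_m2y": mr["p_SMR"],
                "heidi_m2e": pr["p_HEIDI"], "heidi_e2y": er["p_HEIDI"],
                "heidi_m2y": mr["p_HEIDI"],
                "consistent": consistent, "distance_bp": dist,
            }
        )
    return pd.DataFrame(rows, columns=CHAIN_COLUMNS)


def _interval_distance(pos: int, start: int, end: int) -> int:
    if start <= pos <= end:
        return 0
    return int(start - pos) if pos < start else int(pos - end)


def _site_gene_distance(annotation: pd.DataFrame, site: str, gene: str) -> float:
    ann = annotation.set_index("id")
    if site not in ann.index or gene not in ann.index:
        return np.nan
    s, g = ann.loc[site], ann.loc[gene]
    return float(_interval_distance(int(s["start"]), int(g["start"]), int(g["end"])))


def nearest_gene_distances(
    sites: pd.DataFrame | list[str],
    annotation: pd.DataFrame,
    evidence_genes: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nearest gene (minimal bp gap; 0 inside the gene body) per DNAm site.

    Ties on distance go to the gene with the smaller start coordinate.
    When ``evidence_genes`` is given, genes are partitioned by whether any
    functional evidence supports them and per-group median/quartile
    distance summaries are returned alongside the per-site table.
    """
    genes = annotation[annotation["class"] == "gene"]
    if genes.empty:
        raise ValueError("annotation contains no genes")
    site_ids = sites if isinstance(sites, list) else list(sites["site"])
    ann = annotation.set_index("id")
    gene_arr = genes.sort_values(["start", "id"]).reset_index(drop=True)
    rows = []
    for site in site_ids:
        if site not in ann.index:
            log.warning("nearest_gene_distances: site %s missing from annotation", site)
            continue
        pos = int(ann.loc[site, "start"])
        d = np.array(
            [_interval_distance(pos, int(s), int(e))
             for s, e in zip(gene_arr["start"], gene_arr["end"])]
        )
        best = int(np.argmin(d))  # argmin keeps the first = smaller start on ties
        rows.append(
            {"site": site, "nearest_gene": gene_arr["id"].iloc[best],
             "distance_bp": int(d[best])}
        )
    table = pd.DataFrame(rows, columns=["site", "nearest_gene", "distance_bp"])
    if evidence_genes is not None:
        table["has_evidence"] = table["nearest_gene"].isin(evidence_genes)
    else:
        table["has_evidence"] = True
    summary = (
        table.groupby("has_evidence")["distance_bp"]
        .describe(percentiles=[0.25, 0.5, 0.75])[["count", "25%", "50%", "75%"]]
        .rename(columns={"25%": "q1", "50%": "median", "75%": "q3"})
        .reset_index()
    )
    return table, summary
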