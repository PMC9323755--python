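"""Fisher's-exact enrichment of prioritized genes in external gene sets.

Fold change is the observed overlap divided by its hypergeometric
expectation; p-values are exact (hypergeometric tail sums, no
approximation).  The two-sided p uses the point-probability convention:
the sum of all outcome probabilities no larger than the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class FisherResult:
    name: str
    a: int  # overlap
    b: int  # prioritized only
    c: int  # set only
    d: int  # neither
    odds_ratio: float
    fold_change: float
    p_greater: float
    p_two_sided: float

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def greater_tail_p(a, n_total, n_set, n_prio):
    """P(overlap >= a) under the hypergeometric null; vectorized over a."""
    return np.minimum(stats.hypergeom.sf(np.asarray(a) - 1, n_total, n_set, n_prio), 1.0)


def two_sided_p(a: int, n_total: int, n_set: int, n_prio: int) -> float:
    """Two-sided exact p by the point-probability method: the sum of all
    outcome probabilities no larger than the observed one (the convention
    implemented here because exact two-sided tests admit several)."""
    lo = max(0, n_prio + n_set - n_total)
    hi = min(n_prio, n_set)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n_total, n_set, n_prio)
    p_obs = stats.hypergeom.pmf(a, n_total, n_set, n_prio)
    return float(min(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum(), 1.0))


def fisher_counts(a: int, b: int, c: int, d: int, name: str = "") -> FisherResult:
    """Exact enrichment statistics from 2x2 counts."""
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty universe")
    n_prio, n_set = a + b, a + c
    expected = n_prio * n_set / n
    fc = a / expected if expected > 0 else np.nan
    oddsr = (a * d) / (b * c) if b * c > 0 else np.inf
    return FisherResult(
        name=name, a=a, b=b, c=c, d=d,
        odds_ratio=float(oddsr), fold_change=float(fc),
        p_greater=float(greater_tail_p(a, n, n_set, n_prio)),
        p_two_sided=two_sided_p(a, n, n_set, n_prio),
    )


def fisher_enrichment(
    prioritized_genes, gene_set, universe, name: str = ""
) -> FisherResult:
    """Enrichment of a gene set among prioritized genes within a universe.

    Genes outside the universe are logged and clipped before counting.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    prio = set(prioritized_genes)
    gset = set(gene_set)
    for label, s in (("prioritized", prio), ("gene_set", gset)):
        extra = s - universe
        if extra:
            log.warning("fisher_enrichment: %d %s gene(s) outside universe clipped",
                        len(extra), label)
    prio &= universe
    gset &= universe
    a = len(prio & gset)
    b = len(prio - gset)
    c = len(gset - prio)
    d = len(universe) - a - b - c
    return fisher_counts(a, b, c, d, name=name)


def fisher_table(results: list[FisherResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"set": r.name, "overlap": r.a, "prioritized_only": r.b,
             "set_only": r.c, "neither": r.d, "odds_ratio": r.odds_ratio,
             "fold_change": r.fold_change, "p_greater": r.p_greater,
             "p_two_sided": r.p_two_sided}
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Drug-gene annotation
# ---------------------------------------------------------------------------

def drug_annotations(prioritized_genes, drug_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene drug interaction summary.

    ``drugged``: at least one interacting drug; ``druggable``: listed with a
    druggable-category interaction but no drug; BP flags mark interacting
    drugs indicated for hyper-/hypotension or with BP adverse effects;
    repurposing candidates are drugged genes whose drugs are all non-BP
    indicated.
    """
    rows = []
    by_gene = dict(tuple(drug_table.groupby("gene", sort=False)))
    for gene in sorted(set(prioritized_genes)):
        sub = by_gene.get(gene)
        if sub is None:
            rows.append({"gene": gene, "drugged": False, "druggable": False,
                         "drugs": "", "bp_indicated": False, "bp_adverse": False,
                         "repurposing_candidate": False})
            continue
        interactions = sub[sub["interaction_type"] != "druggable_category"]
        drugged = not interactions.empty
        druggable = (sub["interaction_type"] == "druggable_category").any()
        bp_ind = bool(interactions["indication"].isin(["hypertension", "hypotension"]).any())
        bp_adv = bool((interactions["adverse_bp"].astype(int) == 1).any())
        rows.append(
            {
                "gene": gene,
                "drugged": drugged,
                "druggable": bool(druggable),
                "drugs": ",".join(sorted(set(interactions["drug_id"]))),
                "bp_indicated": bp_ind,
                "bp_adverse": bp_adv,
                "repurposing_candidate": drugged and not bp_ind,
            }
        )
    return pd.DataFrame(rows)
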