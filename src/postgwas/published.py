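"""Bundled curated evidence tables from a large published blood-pressure
multi-omics prioritization study, with the arithmetic the package's
scoring and replication operations apply to them.

Two small tables ship with the package:

* ``highly_prioritized_evidence.tsv`` — the genes reported with their
  supporting prioritization sources (coding consequence NS, multilayer ML,
  the two TWAS engines MX and SMR, coregulation DEPICT, and methylation
  mediation 3xSMR);
* ``novel_gene_replication.tsv`` — newly identified blood-pressure genes
  with at least two evidence sources that replicated in an independent
  cohort, with their minimum replication p-value.  The replication screen
  tested :data:`NOVEL_CANDIDATES_TESTED` candidate genes in total; the
  non-replicating candidates are not individually listed.

These serve as worked demo inputs for the scoring layer and as fixed
ground truth for its arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .prioritize import score_evidence_sets

#: number of novel multi-evidence candidate genes submitted to replication
NOVEL_CANDIDATES_TESTED = 34

REPLICATION_ALPHA = 0.05


def _data(name: str) -> pd.DataFrame:
    with resources.files("postgwas.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_highly_prioritized() -> pd.DataFrame:
    """Gene x sources table of the most highly prioritized genes."""
    return _data("highly_prioritized_evidence.tsv")


def load_novel_replication() -> pd.DataFrame:
    """Replicated novel genes with their minimum replication p-values."""
    return _data("novel_gene_replication.tsv")


def high_evidence_gene_count(min_sources: int = 4) -> int:
    """Number of genes supported by >= ``min_sources`` of the six
    prioritization approaches, computed by the package's evidence-scoring
    filter from the bundled source annotations."""
    table = load_highly_prioritized()
    evidence: dict[str, set[str]] = {}
    for _, row in table.iterrows():
        for src in row["sources"].split(","):
            evidence.setdefault(src, set()).add(row["gene"])
    return len(score_evidence_sets(evidence, min_sources=min_sources))


def replication_summary(alpha: float = REPLICATION_ALPHA) -> dict:
    """Replicated-gene count and percentage among the novel candidates.

    The numerator is recomputed by thresholding the bundled per-gene
    minimum replication p-values at ``alpha``; the denominator is the size
    of the candidate set the replication screen tested.
    """
    table = load_novel_replication()
    n_replicated = int((table["min_p_rep"] < alpha).sum())
    return {
        "n_replicated": n_replicated,
        "n_candidates": NOVEL_CANDIDATES_TESTED,
        "pct_replicated": 100.0 * n_replicated / NOVEL_CANDIDATES_TESTED,
    }
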