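"""LD computation on a reference panel and r^2-based proxy expansion.

The proxy expansion ("in silico sequencing") takes a set of lead SNPs and
returns every panel SNP within a window whose squared correlation with a
lead exceeds a threshold — the standard way to carry association evidence
from a genotyped lead to ungenotyped functional variants.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .synth import Genotypes

log = logging.getLogger(__name__)

DEFAULT_R2 = 0.50
DEFAULT_WINDOW_BP = 1_000_000


class UndefinedLdError(ValueError):
    """LD requested for a zero-variance SNP."""


class LdPanel:
    """Reference genotypes with cached standardized dosages.

    Correlations are plain Pearson correlations of 0/1/2 dosage vectors;
    submatrices are computed on demand from the standardized matrix rather
    than materializing the full p x p correlation matrix.
    """

    def __init__(self, genotypes: Genotypes):
        self.genotypes = genotypes
        mat = genotypes.matrix.astype(float)
        mat = mat - mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=0)
        self._zero_var = sd == 0
        sd_safe = np.where(self._zero_var, 1.0, sd)
        self._std = mat / sd_safe
        self._n = mat.shape[0]
        self._index = {s: i for i, s in enumerate(genotypes.snps["SNP"])}

    @property
    def snps(self) -> pd.DataFrame:
        return self.genotypes.snps

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def _col(self, snp: str) -> int:
        try:
            i = self._index[snp]
        except KeyError:
            raise KeyError(f"SNP {snp!r} not in panel") from None
        if self._zero_var[i]:
            raise UndefinedLdError(f"SNP {snp!r} has zero variance in the panel")
        return i

    def r(self, snp_i: str, snp_j: str) -> float:
        """Pearson correlation of two dosage vectors."""
        a, b = self._col(snp_i), self._col(snp_j)
        return float(self._std[:, a] @ self._std[:, b] / self._n)

    def r_matrix(self, snps: list[str]) -> np.ndarray:
        """Pairwise correlation matrix for an ordered SNP list."""
        idx = [self._col(s) for s in snps]
        sub = self._std[:, idx]
        return (sub.T @ sub) / self._n

    def r_vector(self, snp: str, others: list[str]) -> np.ndarray:
        a = self._col(snp)
        idx = [self._col(s) for s in others]
        return self._std[:, idx].T @ self._std[:, a] / self._n

    def dosage_sd(self, snps: list[str]) -> np.ndarray:
        idx = [self._col(s) for s in snps]
        return self.genotypes.matrix[:, idx].astype(float).std(axis=0, ddof=0)

    def proxy_expand(
        self,
        lead_snps,
        r2_threshold: float = DEFAULT_R2,
        window_bp: int = DEFAULT_WINDOW_BP,
    ) -> pd.DataFrame:
        """All SNPs with r^2 > threshold within ``window_bp`` of a lead.

        Every lead is a member of its own proxy set (r^2 = 1).  A proxy
        linked to several leads is assigned to the one with the larger r^2,
        ties broken by smaller bp distance.  Leads absent from the panel are
        skipped with a warning.

        Returns columns ``lead_snp proxy_snp r2 distance_bp``.
        """
        snps = self.snps
        bp = snps["bp"].to_numpy()
        rows = []
        for lead in lead_snps:
            if lead not in self._index:
                log.warning("proxy_expand: lead %s absent from panel; skipped", lead)
                continue
            lead_bp = int(bp[self._index[lead]])
            in_window = np.abs(bp - lead_bp) <= window_bp
            cand = snps["SNP"].to_numpy()[in_window]
            r = self.r_vector(lead, list(cand))
            r2 = r * r
            hit = r2 > r2_threshold
            # the lead itself always qualifies (guards float fuzz at threshold 1.0)
            hit |= cand == lead
            for s, q in zip(cand[hit], r2[hit]):
                rows.append(
                    {
                        "lead_snp": lead,
                        "proxy_snp": s,
                        "r2": min(float(q), 1.0) if s != lead else 1.0,
                        "distance_bp": abs(int(bp[self._index[s]]) - lead_bp),
                    }
                )
        out = pd.DataFrame(rows, columns=["lead_snp", "proxy_snp", "r2", "distance_bp"])
        if out.empty:
            return out
        # best-lead assignment: larger r2 first, then smaller distance
        out = out.sort_values(
            ["proxy_snp", "r2", "distance_bp"], ascending=[True, False, True]
        )
        out = out.drop_duplicates("proxy_snp", keep="first")
        return out.sort_values(["lead_snp", "distance_bp"]).reset_index(drop=True)


def ld_r(panel: LdPanel, snp_i: str, snp_j: str) -> float:
    return panel.r(snp_i, snp_j)
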