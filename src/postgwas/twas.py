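"""Summary-statistic TWAS: prediction weights, gene-level Z, colocalization.

The gene-level statistic follows the S-PrediXcan construction: with
per-SNP prediction weights w_l, GWAS z-scores z_l, SNP dosage standard
deviations sigma_l from a reference panel, and the model-predicted
expression SD sigma_g (sigma_g^2 = w' Sigma w with Sigma the panel dosage
covariance of the model SNPs),

    Z_g = sum_l w_l * (sigma_l / sigma_g) * z_l.

Prediction weights are ridge regressions of expression on cis dosages,
with the penalty chosen by k-fold cross-validation and the out-of-fold
squared correlation reported as the prediction-performance R^2.

The colocalization screen is the standard approximate-Bayes-factor model
comparison over five hypotheses (H0 no association ... H4 one shared
causal variant), with per-SNP log ABFs

    log ABF = 0.5 * [ log(V / (V + W)) + z^2 * W / (V + W) ],  V = se^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from . import io as pio
from .ld import LdPanel
from .synth import Genotypes

log = logging.getLogger(__name__)

RIDGE_GRID = (0.1, 1.0, 10.0, 100.0, 1000.0)
PERF_R2_MIN = 0.01
PERF_P_MAX = 0.05
MAX_WEIGHT_LOSS = 0.5


@dataclass
class TwasModel:
    """Prediction weights for one gene's cis region."""

    gene: str
    snps: list[str]
    weights: np.ndarray
    a1: list[str]
    a2: list[str]
    cv_r2: float
    cv_p: float


@dataclass(frozen=True)
class ColocConfig:
    """Priors of the colocalization model: p1/p2 per-SNP association priors
    for each trait alone, p12 the shared-causal prior, W the prior effect
    variance on the standardized scale."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w: float = 0.15**2

    def __post_init__(self):
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.p12 > min(self.p1, self.p2):
            import warnings

            warnings.warn("p12 exceeds min(p1, p2); unusual prior ordering")


# ---------------------------------------------------------------------------
# Weight training
# ---------------------------------------------------------------------------

def _ridge_beta(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    p = X.shape[1]
    return np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ y)


def train_weights(
    genotypes: Genotypes,
    expression: np.ndarray,
    genes: list[str],
    gene_snps: dict[str, list[str]],
    k_folds: int = 5,
    grid: tuple[float, ...] = RIDGE_GRID,
    seed: int = 0,
) -> list[TwasModel]:
    """Ridge prediction weights per gene with k-fold CV penalty selection.

    ``expression`` is (individuals x genes); ``gene_snps`` maps each gene
    to its cis SNP ids (columns of the panel).  Fold assignment is
    deterministic given ``seed``.  Genes with fewer than ``2 * k_folds``
    individuals are skipped.
    """
    n = genotypes.n
    if n < 2 * k_folds:
        log.warning("train_weights: %d individuals < 2x%d folds; no models", n, k_folds)
        return []
    rng = np.random.default_rng(seed)
    fold_of = rng.permuted(np.arange(n) % k_folds)
    index = {s: i for i, s in enumerate(genotypes.snps["SNP"])}
    models = []
    for gi, gene in enumerate(genes):
        snp_ids = gene_snps.get(gene, [])
        cols = [index[s] for s in snp_ids if s in index]
        if not cols:
            continue
        X = genotypes.matrix[:, cols].astype(float)
        X = X - X.mean(axis=0)
        y = expression[:, gi] - expression[:, gi].mean()
        # out-of-fold predictions per penalty
        best = None
        for lam in grid:
            pred = np.empty(n)
            for f in range(k_folds):
                tr = fold_of != f
                beta = _ridge_beta(X[tr], y[tr], lam)
                pred[~tr] = X[~tr] @ beta
            if pred.std() == 0:
                r2 = 0.0
            else:
                r2 = float(np.corrcoef(pred, y)[0, 1] ** 2)
            if best is None or r2 > best[1]:
                best = (lam, r2, pred)
        lam, cv_r2, pred = best
        if pred.std() > 0:
            r = np.corrcoef(pred, y)[0, 1]
            tstat = r * np.sqrt((n - 2) / max(1 - r**2, 1e-12))
            cv_p = float(2 * stats.t.sf(abs(tstat), n - 2)) if r > 0 else 1.0
        else:
            cv_p = 1.0
        weights = _ridge_beta(X, y, lam)
        if not np.any(weights != 0):
            continue
        sub = genotypes.snps.iloc[cols]
        models.append(
            TwasModel(
                gene=gene,
                snps=list(sub["SNP"]),
                weights=weights,
                a1=list(sub["A1"]),
                a2=list(sub["A2"]),
                cv_r2=cv_r2,
                cv_p=cv_p,
            )
        )
    return models


def models_to_table(models: list[TwasModel]) -> pd.DataFrame:
    rows = []
    for m in models:
        for s, a1, a2, w in zip(m.snps, m.a1, m.a2, m.weights):
            rows.append(
                {"gene": m.gene, "SNP": s, "A1": a1, "A2": a2, "weight": w,
                 "cv_r2": m.cv_r2, "cv_p": m.cv_p}
            )
    return pd.DataFrame(rows, columns=["gene", "SNP", "A1", "A2", "weight", "cv_r2", "cv_p"])


def models_from_table(table: pd.DataFrame) -> list[TwasModel]:
    models = []
    for gene, grp in table.groupby("gene", sort=True):
        models.append(
            TwasModel(
                gene=gene,
                snps=list(grp["SNP"]),
                weights=grp["weight"].to_numpy(float),
                a1=list(grp["A1"]),
                a2=list(grp["A2"]),
                cv_r2=float(grp["cv_r2"].iloc[0]),
                cv_p=float(grp["cv_p"].iloc[0]),
            )
        )
    return models


# ---------------------------------------------------------------------------
# Gene-level Z
# ---------------------------------------------------------------------------

def metaxcan_z(model: TwasModel, gwas: pd.DataFrame, panel: LdPanel) -> dict | None:
    """Gene-level Z from GWAS z-scores, model weights and panel LD.

    GWAS alleles are harmonized to the model's coding (sign-flip on swap).
    Model SNPs missing from the GWAS are dropped and sigma_g recomputed
    from the remaining weights; the gene is skipped when more than half the
    absolute weight mass is lost or sigma_g degenerates to zero.
    """
    gsub = gwas[gwas["SNP"].isin(model.snps)]
    model_tab = pd.DataFrame(
        {"SNP": model.snps, "A1": model.a1, "A2": model.a2, "weight": model.weights,
         "freq": 0.5, "b": 0.0, "se": 1.0}
    )
    mh, gh = pio.harmonize_alleles(model_tab, gsub)
    if mh.empty:
        return None
    kept = set(mh["SNP"])
    total_mass = np.abs(model.weights).sum()
    kept_mask = [s in kept for s in model.snps]
    if total_mass > 0 and np.abs(model.weights[kept_mask]).sum() < MAX_WEIGHT_LOSS * total_mass:
        log.warning("metaxcan_z: gene %s lost >50%% of weight mass; skipped", model.gene)
        return None
    snps = list(mh["SNP"])
    w = mh["weight"].to_numpy(float)
    z = (gh["b"] / gh["se"]).to_numpy(float)
    in_panel = [s in panel for s in snps]
    if not all(in_panel):
        snps = [s for s, k in zip(snps, in_panel) if k]
        w = w[in_panel]
        z = z[in_panel]
        if len(snps) == 0:
            return None
    sig = panel.dosage_sd(snps)
    R = panel.r_matrix(snps)
    Sigma = R * np.outer(sig, sig)
    var_g = float(w @ Sigma @ w)
    if var_g <= 0:
        log.warning("metaxcan_z: gene %s has sigma_g = 0; skipped", model.gene)
        return None
    sigma_g = np.sqrt(var_g)
    z_g = float(np.sum(w * sig / sigma_g * z))
    return {
        "gene": model.gene,
        "zscore": z_g,
        "sigma_g": sigma_g,
        "p": float(2 * stats.norm.sf(abs(z_g))),
        "pred_perf_r2": model.cv_r2,
        "pred_perf_p": model.cv_p,
        "n_snps_used": len(snps),
    }


# ---------------------------------------------------------------------------
# Colocalization
# ---------------------------------------------------------------------------

def _log_abf(z: np.ndarray, se: np.ndarray, w: float) -> np.ndarray:
    v = se**2
    return 0.5 * (np.log(v / (v + w)) + z**2 * w / (v + w))


def coloc_abf(
    trait1: pd.DataFrame,
    trait2: pd.DataFrame,
    config: ColocConfig = ColocConfig(),
) -> dict | None:
    """Posterior probabilities PP0..PP4 for one region.

    Both tables must cover the same SNPs after harmonization (rows are
    inner-joined on SNP id with allele alignment).  Returns None when fewer
    than two shared SNPs remain (not testable).
    """
    t1, t2 = pio.harmonize_alleles(trait1, trait2)
    if len(t1) < 2:
        return None
    l1 = _log_abf((t1["b"] / t1["se"]).to_numpy(), t1["se"].to_numpy(), config.w)
    l2 = _log_abf((t2["b"] / t2["se"]).to_numpy(), t2["se"].to_numpy(), config.w)
    lsum = l1 + l2
    lh1 = logsumexp(l1)
    lh2 = logsumexp(l2)
    lh4 = logsumexp(lsum)
    # H3: distinct causal SNPs for the two traits (i != j): S1*S2 - sum_i ABF1_i*ABF2_i
    lh3, sgn = logsumexp([lh1 + lh2, lh4], b=[1.0, -1.0], return_sign=True)
    if sgn <= 0:
        lh3 = -np.inf
    logpost = np.array(
        [
            0.0,
            np.log(config.p1) - 0.0 + lh1,
            np.log(config.p2) + lh2,
            np.log(config.p1) + np.log(config.p2) + lh3,
            np.log(config.p12) + lh4,
        ]
    )
    # priors: H0 baseline 1; H1 p1 per SNP; H2 p2; H3 p1*p2 per ordered pair;
    # H4 p12 per shared SNP — the per-configuration priors multiply the ABF sums
    post = np.exp(logpost - logsumexp(logpost))
    return {f"PP{i}": float(post[i]) for i in range(5)} | {"n_snps": int(len(t1))}


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

def twas_scan(
    gwas: pd.DataFrame,
    models: list[TwasModel],
    panel: LdPanel,
    alpha: float = 0.05,
    eqtl: pd.DataFrame | None = None,
    coloc_config: ColocConfig = ColocConfig(),
    coloc_pp4_min: float = 0.5,
    perf_r2_min: float = PERF_R2_MIN,
    perf_p_max: float = PERF_P_MAX,
) -> pd.DataFrame:
    """Gene-level TWAS with performance filter, Bonferroni significance and
    (when eQTL records are supplied) the colocalization screen on the
    significant genes."""
    rows = []
    for model in models:
        res = metaxcan_z(model, gwas, panel)
        if res is not None:
            rows.append(res)
    result = pd.DataFrame(
        rows,
        columns=["gene", "zscore", "sigma_g", "p", "pred_perf_r2", "pred_perf_p",
                 "n_snps_used"],
    )
    result["pass_perf"] = (result["pred_perf_r2"] > perf_r2_min) & (
        result["pred_perf_p"] < perf_p_max
    )
    n_tested = int(result["pass_perf"].sum())
    threshold = alpha / n_tested if n_tested else np.nan
    result["pass_bonferroni"] = result["pass_perf"] & (result["p"] < threshold)
    for c in ("PP0", "PP1", "PP2", "PP3", "PP4"):
        result[c] = np.nan
    result["coloc_pass"] = pd.array([pd.NA] * len(result), dtype="boolean")
    if eqtl is not None and n_tested:
        by_gene = dict(tuple(eqtl.groupby("gene_id", sort=False)))
        for i, row in result.iterrows():
            if not row["pass_bonferroni"]:
                continue
            grp = by_gene.get(row["gene"])
            if grp is None:
                continue
            cc = coloc_abf(grp, gwas, coloc_config)
            if cc is None:
                continue
            for k in ("PP0", "PP1", "PP2", "PP3", "PP4"):
                result.loc[i, k] = cc[k]
            result.loc[i, "coloc_pass"] = cc["PP4"] >= coloc_pp4_min
    result["pass"] = result["pass_bonferroni"] & result["coloc_pass"].fillna(True)
    result.attrs["bonferroni_threshold"] = threshold
    result.attrs["n_tested"] = n_tested
    return result
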