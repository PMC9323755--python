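"""Summary-data-based Mendelian randomization (SMR) with the HEIDI filter.

Given marginal summary statistics for an exposure (cis-eQTL or cis-mQTL)
and an outcome (a trait GWAS, or another molecular phenotype), the SMR
ratio estimate at the top cis instrument is

    b_xy = b_zy / b_zx,

with the delta-method standard error, and the test statistic

    T_SMR = z_zy^2 * z_zx^2 / (z_zy^2 + z_zx^2)  ~  chi^2_1 under H0.

A significant T_SMR is compatible with causality/pleiotropy at one shared
variant, but also with two distinct variants in LD (linkage).  HEIDI
screens for the latter: it compares the ratio estimate at the top SNP with
the ratios at other significant cis SNPs, accounting for the LD-induced
covariance of the estimates, and sums the squared standardized differences
into a statistic distributed as a weighted mixture of chi^2_1 variables
under the single-variant null.  Loci with P_HEIDI < 0.01 are flagged as
linkage-confounded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from . import io as pio
from .ld import LdPanel

log = logging.getLogger(__name__)

CIS_WINDOW_BP = 2_000_000
P_INSTRUMENT = 5e-8
HEIDI_P_EXPOSURE = 1.57e-3  # ~ chi^2_1 > 10
HEIDI_R2_MIN = 0.05
HEIDI_R2_MAX = 0.9
HEIDI_MAX_SNPS = 20
HEIDI_MIN_SNPS = 3
HEIDI_PASS = 0.01


# ---------------------------------------------------------------------------
# Weighted chi-square mixture tail probability
# ---------------------------------------------------------------------------

def chi2_mixture_sf(x: float, lambdas: np.ndarray) -> float:
    """P(sum_k lambda_k * chi^2_1 > x) by Imhof's characteristic-function
    inversion, with Satterthwaite moment matching as fallback.

    The integrand is smooth and decays like exp(-c u); quad with a
    generous subdivision limit reaches ~1e-8 accuracy on well-conditioned
    eigenvalue sets.
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0 or x <= 0:
        return 1.0

    # Imhof's truncation bound: the |integrand| tail beyond U is below
    # 2 / (pi * k * U^(k/2) * prod(lam)^(1/2)); solve for U at the target
    # absolute accuracy, then integrate with a vectorized Simpson rule on a
    # grid fine enough to resolve the phase oscillation.
    k = lam.size
    tail_target = 1e-8
    log_prod = 0.5 * np.sum(np.log(lam))
    log_u = (math.log(2.0 / (math.pi * k * tail_target)) - log_prod) / (0.5 * k)
    upper = float(np.clip(np.exp(log_u), 50.0, 1e6))
    try:
        max_phase_rate = 0.5 * (lam.sum() + x)
        du = (2.0 * math.pi) / (60.0 * max_phase_rate)
        n_pts = int(np.clip(upper / du, 2_000, 4_000_000))
        if n_pts % 2 == 0:
            n_pts += 1
        u = np.linspace(0.0, upper, n_pts)[1:]  # integrand -> finite limit at 0
        with np.errstate(all="ignore"):
            lu = np.outer(u, lam)
            theta = 0.5 * np.arctan(lu).sum(axis=1) - 0.5 * x * u
            rho = np.exp(0.25 * np.log1p(lu**2).sum(axis=1))
            f = np.sin(theta) / (u * rho)
        # limit at u -> 0: theta/u -> 0.5*(sum(lam) - x), rho -> 1
        f0 = 0.5 * (lam.sum() - x)
        val = integrate.simpson(np.concatenate([[f0], f]), dx=upper / (n_pts - 1))
        if not np.isfinite(val):
            raise RuntimeError("integration failed")
        p = 0.5 + val / math.pi
    except Exception:
        p = _satterthwaite_sf(x, lam)
    return float(min(max(p, np.nextafter(0.0, 1.0)), 1.0))


def _satterthwaite_sf(x: float, lam: np.ndarray) -> float:
    """Match the first two moments with a scaled chi-square."""
    s1, s2 = lam.sum(), (lam**2).sum()
    scale = s2 / s1
    df = s1**2 / s2
    return float(stats.chi2.sf(x / scale, df))


# ---------------------------------------------------------------------------
# Core tests
# ---------------------------------------------------------------------------

def smr_test(
    b_zx: float, se_zx: float, b_zy: float, se_zy: float
) -> tuple[float, float, float, float]:
    """Ratio estimate, delta-method SE, T_SMR, P_SMR.

    Raises on a zero exposure effect (undefined ratio).
    """
    if b_zx == 0:
        raise ZeroDivisionError("undefined SMR ratio: exposure effect b_zx is zero")
    b_xy = b_zy / b_zx
    var_xy = se_zy**2 / b_zx**2 + b_zy**2 * se_zx**2 / b_zx**4
    z_x2 = (b_zx / se_zx) ** 2
    z_y2 = (b_zy / se_zy) ** 2
    denom = z_x2 + z_y2
    t_smr = (z_x2 * z_y2 / denom) if denom > 0 else 0.0
    p_smr = float(stats.chi2.sf(t_smr, 1)) if t_smr > 0 else 1.0
    return float(b_xy), float(math.sqrt(var_xy)), float(t_smr), p_smr


def select_top_instrument(
    probe_qtl: pd.DataFrame,
    cis_window: int = CIS_WINDOW_BP,
    p_instrument: float = P_INSTRUMENT,
) -> pd.Series | None:
    """Smallest-exposure-p cis SNP below the instrument threshold.

    Ties on p are broken by larger |z|, then smaller bp.  Returns None when
    no SNP qualifies (the probe is skipped, not an error).
    """
    cis = probe_qtl[
        (probe_qtl["snp_bp"] - probe_qtl["probe_bp"]).abs() <= cis_window
    ]
    eligible = cis[cis["p"] < p_instrument]
    if eligible.empty:
        return None
    ordered = eligible.assign(_absz=eligible["z"].abs()).sort_values(
        ["p", "_absz", "snp_bp"], ascending=[True, False, True]
    )
    return ordered.iloc[0].drop("_absz")


@dataclass
class HeidiResult:
    t_heidi: float | None
    p_heidi: float | None
    n_snps: int

    @property
    def testable(self) -> bool:
        return self.p_heidi is not None


def heidi_test(
    merged: pd.DataFrame,
    top_snp: str,
    panel: LdPanel,
    p_exposure: float = HEIDI_P_EXPOSURE,
    r2_range: tuple[float, float] = (HEIDI_R2_MIN, HEIDI_R2_MAX),
    max_snps: int = HEIDI_MAX_SNPS,
    min_snps: int = HEIDI_MIN_SNPS,
) -> HeidiResult:
    """Heterogeneity in dependent instruments at one probe.

    ``merged`` holds harmonized per-SNP records with exposure columns
    ``b_zx se_zx p_zx`` and outcome columns ``b_zy se_zy``.  Candidates are
    cis SNPs with exposure p below ``p_exposure`` and r^2 with the top SNP
    inside ``r2_range``, capped at the ``max_snps`` most significant;
    fewer than ``min_snps`` candidates -> not testable (probe retained
    downstream with a flag).
    """
    in_panel = merged["SNP"].map(lambda s: s in panel)
    cand = merged[in_panel & (merged["p_zx"] < p_exposure) & (merged["SNP"] != top_snp)]
    if top_snp not in panel or cand.empty:
        return HeidiResult(None, None, 0)
    r_top = panel.r_vector(top_snp, list(cand["SNP"]))
    r2 = r_top**2
    cand = cand[(r2 >= r2_range[0]) & (r2 <= r2_range[1])]
    cand = cand.sort_values("p_zx").head(max_snps)
    if len(cand) < min_snps:
        return HeidiResult(None, None, len(cand))

    snps = list(cand["SNP"]) + [top_snp]
    R = panel.r_matrix(snps)
    top = merged[merged["SNP"] == top_snp].iloc[0]
    u = np.append(cand["b_zy"].to_numpy(), top["b_zy"])  # outcome betas
    su = np.append(cand["se_zy"].to_numpy(), top["se_zy"])
    v = np.append(cand["b_zx"].to_numpy(), top["b_zx"])  # exposure betas
    sv = np.append(cand["se_zx"].to_numpy(), top["se_zx"])

    # delta-method covariance of the b_xy vector; exposure and outcome come
    # from independent cohorts so only within-trait LD covariance enters
    cov_bxy = R * np.outer(su / v, su / v) + R * np.outer(
        u * sv / v**2, u * sv / v**2
    )
    k = len(snps) - 1
    M = np.hstack([np.eye(k), -np.ones((k, 1))])
    C = M @ cov_bxy @ M.T
    d = u[:k] / v[:k] - u[k] / v[k]
    var_d = np.diag(C).copy()
    if np.any(var_d <= 0):
        C = C + 1e-6 * np.eye(k)
        var_d = np.diag(C).copy()
        log.info("heidi_test: ridge-regularized singular difference covariance")
    z_d = d / np.sqrt(var_d)
    t_heidi = float(np.sum(z_d**2))
    corr = C / np.sqrt(np.outer(var_d, var_d))
    eig = np.linalg.eigvalsh((corr + corr.T) / 2.0)
    p_heidi = chi2_mixture_sf(t_heidi, np.clip(eig, 0.0, None))
    return HeidiResult(t_heidi, p_heidi, k)


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

SMR_COLUMNS = [
    "probe", "gene_id", "topSNP", "b_SMR", "se_SMR", "t_SMR", "p_SMR",
    "p_HEIDI", "nsnp_HEIDI", "heidi_testable", "pass_bonferroni", "pass",
]


def smr_scan(
    outcome: pd.DataFrame,
    qtl: pd.DataFrame,
    panel: LdPanel,
    alpha: float = 0.05,
    cis_window: int = CIS_WINDOW_BP,
    p_instrument: float = P_INSTRUMENT,
    heidi: bool = True,
    heidi_pass: float = HEIDI_PASS,
) -> pd.DataFrame:
    """One SMR + HEIDI result per probe with an eligible instrument.

    The Bonferroni threshold is alpha divided by the number of probes
    actually tested in this run.  ``pass`` requires Bonferroni-significant
    P_SMR and P_HEIDI >= ``heidi_pass`` (probes where HEIDI is not
    testable are retained with ``heidi_testable = False``).
    """
    exposure, out_h = pio.harmonize_alleles(qtl, outcome)
    merged = exposure.rename(
        columns={"b": "b_zx", "se": "se_zx", "p": "p_zx", "z": "z_zx"}
    )
    merged["b_zy"] = out_h["b"].to_numpy()
    merged["se_zy"] = out_h["se"].to_numpy()
    merged["p_zy"] = out_h["p"].to_numpy()

    rows = []
    for probe, grp in merged.groupby("probe_id", sort=True):
        inst = select_top_instrument(
            grp.rename(columns={"p_zx": "p", "z_zx": "z"}),
            cis_window=cis_window,
            p_instrument=p_instrument,
        )
        if inst is None:
            log.debug("smr_scan: probe %s has no eligible instrument; skipped", probe)
            continue
        b_xy, se_xy, t_smr, p_smr = smr_test(
            inst["b_zx"], inst["se_zx"], inst["b_zy"], inst["se_zy"]
        )
        if heidi:
            hres = heidi_test(grp, inst["SNP"], panel)
        else:
            hres = HeidiResult(None, None, 0)
        rows.append(
            {
                "probe": probe,
                "gene_id": grp["gene_id"].iloc[0] if "gene_id" in grp else probe,
                "topSNP": inst["SNP"],
                "b_SMR": b_xy,
                "se_SMR": se_xy,
                "t_SMR": t_smr,
                "p_SMR": p_smr,
                "p_HEIDI": hres.p_heidi if hres.testable else np.nan,
                "nsnp_HEIDI": hres.n_snps,
                "heidi_testable": hres.testable,
            }
        )
    result = pd.DataFrame(rows, columns=SMR_COLUMNS[:-2])
    n_tested = len(result)
    threshold = alpha / n_tested if n_tested else np.nan
    if n_tested:
        result["pass_bonferroni"] = result["p_SMR"] < threshold
        heidi_ok = (~result["heidi_testable"]) | (result["p_HEIDI"] >= heidi_pass)
        result["pass"] = result["pass_bonferroni"] & heidi_ok
    else:
        result["pass_bonferroni"] = pd.Series(dtype=bool)
        result["pass"] = pd.Series(dtype=bool)
    result.attrs["bonferroni_threshold"] = threshold
    result.attrs["n_tested"] = n_tested
    return result
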