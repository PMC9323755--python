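"""Synthetic cohorts with planted SNP -> methylation -> expression -> trait architectures.

Generates individual-level genotypes for four non-overlapping cohorts (LD
reference, GWAS, eQTL, mQTL) drawn from one block-LD population, simulates
molecular phenotypes and a quantitative trait under per-locus causal
scenarios, and reduces everything to the marginal summary statistics the
inference modules consume.  A machine-readable truth table records the
planted mechanism per locus so downstream calls can be scored.

LD model: within each block a latent Gaussian AR(1) process with parameter
``rho`` is dichotomized twice per individual (two haplotypes) at the
MAF-quantile threshold and summed to 0/1/2 dosages.  Blocks are mutually
independent, which makes cis/trans structure explicit and analytically
checkable.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

log = logging.getLogger(__name__)

SCENARIOS = ("chain", "direct", "pleiotropy", "linkage", "null")

#: fixed allele coding of the generator: A1 (effect/counted) = "G", A2 = "A"
EFFECT_ALLELE = "G"
OTHER_ALLELE = "A"


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Effect sizes are interpreted on the scale the phenotype model uses:
    ``beta_xm``/``beta_xe``/``beta_xy`` are per-allele effects of the causal
    dosage, ``beta_me``/``beta_ey`` are per-SD effects between (unit
    variance) molecular phenotypes.  Noise variances default to the
    complement that makes each phenotype's total variance one, so the
    post-hoc column standardization is a no-op in expectation and ratio
    estimates recover the path coefficients directly.
    """

    scenarios: tuple[str, ...] = ("chain", "direct", "pleiotropy", "linkage", "null")
    n_gwas: int = 20_000
    n_eqtl: int = 5_000
    n_mqtl: int = 5_000
    n_ref: int = 2_000
    snps_per_block: int = 20
    rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_xm: float = 0.5
    beta_me: float = 0.5
    beta_ey: float = 0.3
    beta_xe: float = 0.4
    beta_xy: float = 0.12
    linkage_r: float = 0.7
    var_m_noise: float | None = None
    var_e_noise: float | None = None
    var_y_noise: float | None = None
    spacing_bp: int = 1_000
    seed: int = 0

    @property
    def n_blocks(self) -> int:
        return len(self.scenarios)

    def __post_init__(self) -> None:
        for name in ("n_gwas", "n_eqtl", "n_mqtl", "n_ref"):
            if getattr(self, name) < 30:
                raise ConfigurationError(f"{name} must be >= 30, got {getattr(self, name)}")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigurationError(f"rho must lie in [0, 1), got {self.rho}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must be within (0, 0.5], got {self.maf_range}")
        if self.snps_per_block < 1 or self.n_blocks < 1:
            raise ConfigurationError("need at least one block with at least one SNP")
        if not 0.0 <= self.linkage_r < 1.0:
            raise ConfigurationError("linkage_r must lie in [0, 1)")
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ConfigurationError(f"unknown scenario label(s): {sorted(unknown)}")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# LD primitives: latent AR(1) + double dichotomization
# ---------------------------------------------------------------------------

def dosage_correlation(latent_r: float, maf1: float, maf2: float) -> float:
    """Pearson correlation of two 0/1/2 dosages given their latent-Gaussian
    correlation and allele frequencies, in closed form.

    With thresholds t_k = Phi^{-1}(1 - f_k) per haplotype, the allele
    indicators have P11 = P(Z1 > t1, Z2 > t2) and the dosage covariance is
    2 (P11 - f1 f2).
    """
    t1 = special.ndtri(1.0 - maf1)
    t2 = special.ndtri(1.0 - maf2)
    joint = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, latent_r], [latent_r, 1.0]]
    ).cdf([t1, t2])
    p11 = 1.0 - (1.0 - maf1) - (1.0 - maf2) + joint
    cov = p11 - maf1 * maf2
    denom = np.sqrt(maf1 * (1 - maf1) * maf2 * (1 - maf2))
    return float(cov / denom)


def latent_r_for_dosage(target_r: float, maf1: float, maf2: float) -> float:
    """Invert :func:`dosage_correlation` for the latent correlation giving a
    target dosage correlation (Brent root find)."""
    if target_r <= 0:
        return 0.0
    f = lambda r: dosage_correlation(r, maf1, maf2) - target_r
    hi = 0.9999
    if f(hi) < 0:  # unreachable target: saturate
        return hi
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-10))


def _ar1_latent(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    eps = rng.standard_normal((n, p))
    if rho == 0.0 or p == 1:
        return eps
    z = np.empty_like(eps)
    z[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, p):
        z[:, j] = rho * z[:, j - 1] + scale * eps[:, j]
    return z


def _block_dosages(
    rng: np.random.Generator, n: int, mafs: np.ndarray, rho: float
) -> np.ndarray:
    """0/1/2 dosages for one block: two dichotomized AR(1) haplotypes."""
    p = len(mafs)
    thr = special.ndtri(1.0 - mafs)
    h1 = _ar1_latent(rng, n, p, rho) > thr
    h2 = _ar1_latent(rng, n, p, rho) > thr
    return (h1.astype(np.int8) + h2.astype(np.int8))


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

@dataclass
class Genotypes:
    """One cohort's dosage matrix (individuals x SNPs) with its SNP map."""

    matrix: np.ndarray
    snps: pd.DataFrame  # columns: SNP chr bp A1 A2 maf block

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class LocusPlan:
    """Per-locus causal layout decided before any cohort is drawn."""

    block: int
    scenario: str
    causal_idx: int  # column index (global) of the primary causal SNP
    causal_idx2: int | None  # second causal SNP (linkage scenario only)
    probe: str
    gene: str
    rho_block: float


def plan_loci(config: SimulationConfig) -> tuple[pd.DataFrame, list[LocusPlan]]:
    """Deterministic SNP map and per-locus causal layout.

    One synthetic chromosome, fixed ``spacing_bp`` between SNPs, 1-based
    positions.  The primary causal SNP sits at the block centre; linkage
    blocks place the second causal SNP adjacent and tune that block's latent
    AR(1) parameter so the dosage correlation of the pair hits
    ``linkage_r``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    p = config.snps_per_block
    total = p * config.n_blocks
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=total)
    plans: list[LocusPlan] = []
    mid = p // 2
    for b, scen in enumerate(config.scenarios):
        c1 = b * p + mid
        c2 = None
        rho_b = config.rho
        if scen == "linkage":
            if p < 2:
                raise ConfigurationError("linkage scenario needs >= 2 SNPs per block")
            c2 = c1 + 1 if mid + 1 < p else c1 - 1
            # matched frequencies keep the target dosage correlation reachable
            mafs[c2] = mafs[c1]
            rho_b = latent_r_for_dosage(
                config.linkage_r, mafs[c1], mafs[c2]
            )
        plans.append(
            LocusPlan(
                block=b,
                scenario=scen,
                causal_idx=c1,
                causal_idx2=c2,
                probe=f"cg{b:05d}",
                gene=f"GENE{b:04d}",
                rho_block=rho_b,
            )
        )
    snps = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(total)],
            "chr": 1,
            "bp": (np.arange(total) * config.spacing_bp) + 1,
            "A1": EFFECT_ALLELE,
            "A2": OTHER_ALLELE,
            "maf": mafs,
            "block": np.repeat(np.arange(config.n_blocks), p),
        }
    )
    return snps, plans


_COHORT_STREAM = {"ref": 1, "gwas": 2, "eqtl": 3, "mqtl": 4}


def _cohort_rng(config: SimulationConfig, cohort: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, _COHORT_STREAM[cohort], extra])
    )


def simulate_cohort_genotypes(
    config: SimulationConfig, cohort: str, snps: pd.DataFrame, plans: list[LocusPlan]
) -> Genotypes:
    sizes = {
        "ref": config.n_ref,
        "gwas": config.n_gwas,
        "eqtl": config.n_eqtl,
        "mqtl": config.n_mqtl,
    }
    n = sizes[cohort]
    rng = _cohort_rng(config, cohort)
    p = config.snps_per_block
    mat = np.empty((n, len(snps)), dtype=np.int8)
    mafs = snps["maf"].to_numpy()
    for plan in plans:
        sl = slice(plan.block * p, (plan.block + 1) * p)
        mat[:, sl] = _block_dosages(rng, n, mafs[sl], plan.rho_block)
    return Genotypes(matrix=mat, snps=snps)


def simulate_panel(config: SimulationConfig) -> dict[str, Genotypes]:
    """Four independent cohorts from the same block-LD population."""
    snps, plans = plan_loci(config)
    return {
        c: simulate_cohort_genotypes(config, c, snps, plans)
        for c in ("ref", "gwas", "eqtl", "mqtl")
    }


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------

def _auto_var(explicit: float | None, explained: float, what: str) -> float:
    if explicit is not None:
        return explicit
    resid = 1.0 - explained
    if resid < 0.1:
        warnings.warn(
            f"{what}: genetic variance {explained:.3f} leaves residual < 0.1; flooring",
            stacklevel=3,
        )
        resid = 0.1
    return resid


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return x / sd


@dataclass
class Phenotypes:
    """Standardized molecular phenotypes and trait for one cohort."""

    methylation: np.ndarray  # n x loci
    expression: np.ndarray  # n x loci
    trait: np.ndarray  # n
    probes: list[str]
    genes: list[str]


def simulate_phenotypes(
    genotypes: Genotypes, config: SimulationConfig, plans: list[LocusPlan], cohort: str
) -> Phenotypes:
    """Structural-equation phenotypes per locus scenario.

    chain:      m = bxm g + em;  e = bme m + ee;  y += bey e
    direct:     e = bxe g + ee;  y += bey e
    pleiotropy: e = bxe g + ee;  y += bxy g      (no e -> y path)
    linkage:    e = bxe g1 + ee; y += bxy g2     (corr(g1,g2) = linkage_r)
    null:       m, e pure noise; no trait contribution

    All phenotype columns are standardized to unit sample variance.  Trait
    noise defaults to the complement of the summed per-locus genetic
    variances so the trait, too, has unit variance in expectation.
    """
    n = genotypes.n
    rng = _cohort_rng(config, cohort, extra=7)
    mafs = genotypes.snps["maf"].to_numpy()
    m = np.empty((n, config.n_blocks))
    e = np.empty((n, config.n_blocks))
    y_gen = np.zeros(n)
    y_explained = 0.0
    for b, plan in enumerate(plans):
        scen = plan.scenario
        if scen not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {scen!r}")
        g = genotypes.matrix[:, plan.causal_idx].astype(float)
        vg = 2.0 * mafs[plan.causal_idx] * (1.0 - mafs[plan.causal_idx])
        if scen == "chain":
            var_em = _auto_var(config.var_m_noise, config.beta_xm**2 * vg, "methylation")
            mb = config.beta_xm * g + rng.normal(0.0, np.sqrt(var_em), n)
            var_ee = _auto_var(config.var_e_noise, config.beta_me**2, "expression")
            eb = config.beta_me * mb + rng.normal(0.0, np.sqrt(var_ee), n)
            contrib, cvar = config.beta_ey * eb, config.beta_ey**2
        elif scen == "direct":
            mb = rng.standard_normal(n)
            var_ee = _auto_var(config.var_e_noise, config.beta_xe**2 * vg, "expression")
            eb = config.beta_xe * g + rng.normal(0.0, np.sqrt(var_ee), n)
            contrib, cvar = config.beta_ey * eb, config.beta_ey**2
        elif scen == "pleiotropy":
            mb = rng.standard_normal(n)
            var_ee = _auto_var(config.var_e_noise, config.beta_xe**2 * vg, "expression")
            eb = config.beta_xe * g + rng.normal(0.0, np.sqrt(var_ee), n)
            contrib, cvar = config.beta_xy * g, config.beta_xy**2 * vg
        elif scen == "linkage":
            assert plan.causal_idx2 is not None
            g2 = genotypes.matrix[:, plan.causal_idx2].astype(float)
            vg2 = 2.0 * mafs[plan.causal_idx2] * (1.0 - mafs[plan.causal_idx2])
            mb = rng.standard_normal(n)
            var_ee = _auto_var(config.var_e_noise, config.beta_xe**2 * vg, "expression")
            eb = config.beta_xe * g + rng.normal(0.0, np.sqrt(var_ee), n)
            contrib, cvar = config.beta_xy * g2, config.beta_xy**2 * vg2
        else:  # null
            mb = rng.standard_normal(n)
            eb = rng.standard_normal(n)
            contrib, cvar = 0.0, 0.0
        if cvar > 0.10:
            warnings.warn(
                f"locus {b} ({scen}) contributes {cvar:.3f} > 10% of trait variance",
                stacklevel=2,
            )
        m[:, b] = mb
        e[:, b] = eb
        y_gen += contrib
        y_explained += cvar
    var_ey = _auto_var(config.var_y_noise, y_explained, "trait")
    y = y_gen + rng.normal(0.0, np.sqrt(var_ey), n)
    return Phenotypes(
        methylation=_standardize(m),
        expression=_standardize(e),
        trait=_standardize(y[:, None])[:, 0],
        probes=[p.probe for p in plans],
        genes=[p.gene for p in plans],
    )


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def compute_summary_stats(
    genotypes: Genotypes, phenotype: np.ndarray, columns: np.ndarray | slice | None = None
) -> pd.DataFrame:
    """Per-SNP simple-linear-regression summary statistics.

    Returns one row per SNP with the .ma columns
    ``SNP A1 A2 freq b se p N`` plus ``chr bp z``.  Zero-variance SNPs are
    dropped with a logged warning.  p comes from the t reference with n-2
    degrees of freedom, clipped away from exact zero so downstream -log10
    arithmetic stays finite.
    """
    if columns is None:
        columns = slice(None)
    snps = genotypes.snps.iloc[columns] if not isinstance(columns, slice) else genotypes.snps
    y = np.asarray(phenotype, dtype=float)
    if genotypes.matrix.shape[0] != y.shape[0]:
        raise ValueError("genotype and phenotype row counts differ")
    n = genotypes.matrix.shape[0]
    total_cols = len(snps)
    if total_cols > 2048:  # bound the float working set on large scans
        col_idx = np.arange(genotypes.matrix.shape[1])[columns]
        parts = [
            compute_summary_stats(genotypes, phenotype, col_idx[i : i + 2048])
            for i in range(0, total_cols, 2048)
        ]
        return pd.concat(parts, ignore_index=True)
    G = genotypes.matrix[:, columns].astype(float)
    xc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc * xc).sum(axis=0)
    keep = sxx > 0
    if not keep.all():
        log.warning("dropping %d zero-variance SNPs", (~keep).sum())
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = sxy / sxx
        rss = np.maximum(syy - b * sxy, 0.0)
        sigma2 = rss / max(n - 2, 1)
        se = np.sqrt(sigma2 / sxx)
        z = np.where(se > 0, b / se, np.inf)
    p = 2.0 * stats.t.sf(np.abs(z), df=n - 2)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    out = pd.DataFrame(
        {
            "SNP": snps["SNP"].to_numpy(),
            "chr": snps["chr"].to_numpy(),
            "bp": snps["bp"].to_numpy(),
            "A1": snps["A1"].to_numpy(),
            "A2": snps["A2"].to_numpy(),
            "freq": G.mean(axis=0) / 2.0,
            "b": b,
            "se": se,
            "z": z,
            "p": p,
            "n": n,
        }
    )
    return out[keep].reset_index(drop=True)


def compute_qtl_stats(
    genotypes: Genotypes,
    phen_matrix: np.ndarray,
    plans: list[LocusPlan],
    config: SimulationConfig,
    kind: str,
) -> pd.DataFrame:
    """cis-QTL summary statistics: each probe against the SNPs of its own
    LD block (blocks are independent, so all trans signal is null by
    construction and omitted)."""
    p = config.snps_per_block
    frames = []
    for b, plan in enumerate(plans):
        cols = np.arange(b * p, (b + 1) * p)
        tab = compute_summary_stats(genotypes, phen_matrix[:, b], cols)
        tab.insert(0, "probe_id", plan.probe if kind == "m" else plan.gene)
        tab.insert(1, "probe_chr", 1)
        tab.insert(2, "probe_bp", int(genotypes.snps["bp"].iloc[plan.causal_idx]))
        tab.insert(3, "gene_id", plan.gene)
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    return out.rename(columns={"chr": "snp_chr", "bp": "snp_bp"})


# ---------------------------------------------------------------------------
# Truth table and dataset emission
# ---------------------------------------------------------------------------

def truth_table(config: SimulationConfig, plans: list[LocusPlan], snps: pd.DataFrame) -> pd.DataFrame:
    """One row per locus recording the planted mechanism."""
    rows = []
    for plan in plans:
        scen = plan.scenario
        bxm = config.beta_xm if scen == "chain" else 0.0
        bme = config.beta_me if scen == "chain" else 0.0
        bey = config.beta_ey if scen in ("chain", "direct") else 0.0
        bxe = config.beta_xe if scen in ("direct", "pleiotropy", "linkage") else 0.0
        bxy = config.beta_xy if scen in ("pleiotropy", "linkage") else 0.0
        rows.append(
            {
                "locus": plan.block,
                "scenario": scen,
                "causal_snp": snps["SNP"].iloc[plan.causal_idx],
                "causal_snp2": (
                    snps["SNP"].iloc[plan.causal_idx2] if plan.causal_idx2 is not None else ""
                ),
                "probe": plan.probe,
                "gene": plan.gene,
                "beta_xm": bxm,
                "beta_me": bme,
                "beta_ey": bey,
                "beta_xe": bxe,
                "beta_xy": bxy,
                "is_chain": bxm != 0 and bme != 0 and bey != 0,
            }
        )
    return pd.DataFrame(rows)


def make_annotation(
    config: SimulationConfig, plans: list[LocusPlan], snps: pd.DataFrame
) -> pd.DataFrame:
    """Gene bodies and DNAm site coordinates on the synthetic chromosome.

    Each gene spans the central kilobases of its block; its DNAm site sits
    just upstream of the gene start (promoter-like), so nearest-gene
    assignment is unambiguous on clean data.
    """
    rows = []
    for plan in plans:
        causal_bp = int(snps["bp"].iloc[plan.causal_idx])
        start = causal_bp + 100
        end = start + 2_000
        rows.append(
            {"id": plan.gene, "chr": 1, "start": start, "end": end, "strand": "+", "class": "gene"}
        )
        rows.append(
            {
                "id": plan.probe,
                "chr": 1,
                "start": causal_bp,
                "end": causal_bp,
                "strand": "+",
                "class": "dnam_site",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class Dataset:
    """In-memory bundle of everything one simulated study produces."""

    config: SimulationConfig
    plans: list[LocusPlan]
    cohorts: dict[str, Genotypes]
    phenotypes: dict[str, Phenotypes]
    gwas: pd.DataFrame
    eqtl: pd.DataFrame
    mqtl: pd.DataFrame
    annotation: pd.DataFrame
    truth: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Run the full generative model and summarize (no files written)."""
    snps, plans = plan_loci(config)
    cohorts = {
        c: simulate_cohort_genotypes(config, c, snps, plans)
        for c in ("ref", "gwas", "eqtl", "mqtl")
    }
    phen = {
        c: simulate_phenotypes(cohorts[c], config, plans, c) for c in ("gwas", "eqtl", "mqtl")
    }
    gwas = compute_summary_stats(cohorts["gwas"], phen["gwas"].trait)
    eqtl = compute_qtl_stats(cohorts["eqtl"], phen["eqtl"].expression, plans, config, "e")
    mqtl = compute_qtl_stats(cohorts["mqtl"], phen["mqtl"].methylation, plans, config, "m")
    return Dataset(
        config=config,
        plans=plans,
        cohorts=cohorts,
        phenotypes=phen,
        gwas=gwas,
        eqtl=eqtl,
        mqtl=mqtl,
        annotation=make_annotation(config, plans, snps),
        truth=truth_table(config, plans, snps),
    )


def emit_dataset(outdir, config: SimulationConfig) -> Dataset:
    """Simulate and write every flat file the pipeline consumes.

    Re-running with the same config (and seed) reproduces byte-identical
    files.  Returns the in-memory dataset as well.
    """
    from . import io as pio  # local import to avoid a cycle at module load

    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)
    pio.write_gwas(ds.gwas, outdir / "gwas_BP.ma")
    pio.write_qtl(ds.eqtl, outdir / "eqtl.tsv")
    pio.write_qtl(ds.mqtl, outdir / "mqtl.tsv")
    pio.write_panel(ds.cohorts["ref"], outdir / "panel.txt")
    pio.write_annotation(ds.annotation, outdir / "annotation.tsv")
    pio.write_table(ds.truth, outdir / "truth.tsv")
    return ds
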