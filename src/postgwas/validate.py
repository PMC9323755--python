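"""Planted-truth evaluation experiments.

Each function runs one calibration or recovery study on synthetic data and
returns the scalar metrics it measures.  The study conditions (cohort
sizes, effect sizes, locus counts) are fixed defaults of the experiment,
chosen to represent a large GWAS (n = 20,000) instrumented with blood
molecular QTL panels (n = 5,000); replicate counts keep Monte-Carlo error
well inside the property bounds being checked.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from . import mediation, prioritize, smr, twas
from .ld import LdPanel
from .synth import (
    SimulationConfig,
    compute_qtl_stats,
    compute_summary_stats,
    plan_loci,
    simulate_cohort_genotypes,
    simulate_dataset,
    simulate_phenotypes,
)


def _sub_seed(seed: int, salt: int) -> int:
    """Stable per-experiment substream below 2^31."""
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# 1. SMR calibration under a trait-null
# ---------------------------------------------------------------------------

def smr_null_calibration(
    seed: int,
    n_probes: int = 2000,
    n_gwas: int = 20_000,
    n_eqtl: int = 5_000,
    snps_per_block: int = 5,
) -> dict:
    """P_SMR distribution when expression is heritable but the trait has no
    genetic component (pleiotropy scenario with a zero trait effect).

    Returns the empirical rejection rate at 0.05 and the KS distance of
    the P_SMR sample from U(0,1) with its 1% critical value.
    """
    config = SimulationConfig(
        scenarios=("pleiotropy",) * n_probes,
        n_gwas=n_gwas,
        n_eqtl=n_eqtl,
        n_mqtl=30,
        n_ref=1000,
        snps_per_block=snps_per_block,
        beta_xe=0.45,
        beta_xy=0.0,
        seed=_sub_seed(seed, 1),
    )
    snps, plans = plan_loci(config)
    gwas_geno = simulate_cohort_genotypes(config, "gwas", snps, plans)
    eqtl_geno = simulate_cohort_genotypes(config, "eqtl", snps, plans)
    ref_geno = simulate_cohort_genotypes(config, "ref", snps, plans)
    gwas_ph = simulate_phenotypes(gwas_geno, config, plans, "gwas")
    eqtl_ph = simulate_phenotypes(eqtl_geno, config, plans, "eqtl")
    gwas_tab = compute_summary_stats(gwas_geno, gwas_ph.trait)
    eqtl_tab = compute_qtl_stats(eqtl_geno, eqtl_ph.expression, plans, config, "e")
    result = smr.smr_scan(gwas_tab, eqtl_tab, LdPanel(ref_geno), alpha=0.05)
    p = result["p_SMR"].to_numpy()
    ks = stats.kstest(p, "uniform")
    ks_crit_1pct = 1.6276 / math.sqrt(len(p))
    return {
        "n_probes_tested": int(len(p)),
        "rejection_rate_0.05": float((p < 0.05).mean()),
        "ks_statistic": float(ks.statistic),
        "ks_critical_1pct": float(ks_crit_1pct),
        "ks_uniform_ok": bool(ks.statistic < ks_crit_1pct),
    }


# ---------------------------------------------------------------------------
# 2. SMR effect recovery under the causal chain
# ---------------------------------------------------------------------------

def smr_chain_recovery(
    seed: int,
    n_reps: int = 200,
    beta_ey: float = 0.3,
    n_gwas: int = 20_000,
    n_eqtl: int = 5_000,
) -> dict:
    """Mean SMR ratio estimate at planted chain loci vs the true
    expression -> trait effect (SD units)."""
    estimates = []
    for rep in range(n_reps):
        config = SimulationConfig(
            scenarios=("chain",),
            n_gwas=n_gwas,
            n_eqtl=n_eqtl,
            n_mqtl=30,
            n_ref=200,
            snps_per_block=10,
            beta_ey=beta_ey,
            seed=_sub_seed(seed, 100 + rep),
        )
        snps, plans = plan_loci(config)
        gwas_geno = simulate_cohort_genotypes(config, "gwas", snps, plans)
        eqtl_geno = simulate_cohort_genotypes(config, "eqtl", snps, plans)
        ref_geno = simulate_cohort_genotypes(config, "ref", snps, plans)
        gwas_ph = simulate_phenotypes(gwas_geno, config, plans, "gwas")
        eqtl_ph = simulate_phenotypes(eqtl_geno, config, plans, "eqtl")
        gwas_tab = compute_summary_stats(gwas_geno, gwas_ph.trait)
        eqtl_tab = compute_qtl_stats(eqtl_geno, eqtl_ph.expression, plans, config, "e")
        res = smr.smr_scan(gwas_tab, eqtl_tab, LdPanel(ref_geno), heidi=False)
        if len(res):
            estimates.append(float(res["b_SMR"].iloc[0]))
    estimates = np.asarray(estimates)
    return {
        "n_reps": int(len(estimates)),
        "mean_b_smr": float(estimates.mean()),
        "true_effect": beta_ey,
        "relative_bias": float(estimates.mean() / beta_ey - 1.0),
        "mc_se": float(estimates.std(ddof=1) / math.sqrt(len(estimates))),
    }


# ---------------------------------------------------------------------------
# 3. HEIDI linkage vs causal discrimination
# ---------------------------------------------------------------------------

def _heidi_rejection_rate(seed: int, scenario: str, n_reps: int, **cfg_kwargs) -> float:
    rejections, tested = 0, 0
    for rep in range(n_reps):
        config = SimulationConfig(
            scenarios=(scenario,),
            n_gwas=20_000,
            n_eqtl=5_000,
            n_mqtl=30,
            n_ref=2_000,
            snps_per_block=30,
            rho=0.85,
            seed=_sub_seed(seed, 10_000 + rep),
            **cfg_kwargs,
        )
        snps, plans = plan_loci(config)
        gwas_geno = simulate_cohort_genotypes(config, "gwas", snps, plans)
        eqtl_geno = simulate_cohort_genotypes(config, "eqtl", snps, plans)
        ref_geno = simulate_cohort_genotypes(config, "ref", snps, plans)
        gwas_ph = simulate_phenotypes(gwas_geno, config, plans, "gwas")
        eqtl_ph = simulate_phenotypes(eqtl_geno, config, plans, "eqtl")
        gwas_tab = compute_summary_stats(gwas_geno, gwas_ph.trait)
        eqtl_tab = compute_qtl_stats(eqtl_geno, eqtl_ph.expression, plans, config, "e")
        res = smr.smr_scan(gwas_tab, eqtl_tab, LdPanel(ref_geno))
        if len(res) and res["heidi_testable"].iloc[0]:
            tested += 1
            if res["p_HEIDI"].iloc[0] < 0.01:
                rejections += 1
    return rejections / tested if tested else float("nan")


def heidi_discrimination(
    seed: int, n_reps: int = 150, linkage_r: float = 0.7
) -> dict:
    """HEIDI rejection rate (P < 0.01) under linkage confounding (two
    distinct causal SNPs) vs under a true causal chain."""
    linkage_rate = _heidi_rejection_rate(
        seed, "linkage", n_reps, linkage_r=linkage_r, beta_xe=0.4, beta_xy=0.12
    )
    chain_rate = _heidi_rejection_rate(_sub_seed(seed, 2), "chain", n_reps)
    ratio = linkage_rate / chain_rate if chain_rate > 0 else float("inf")
    return {
        "linkage_rejection_rate": float(linkage_rate),
        "chain_rejection_rate": float(chain_rate),
        "discrimination_ratio": float(ratio),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# 4. Summary-TWAS vs individual-level oracle
# ---------------------------------------------------------------------------

def twas_oracle_agreement(seed: int, n_genes: int = 100) -> dict:
    """Correlation of the summary-based gene Z with the individual-level
    predicted-expression regression z in the same cohort.

    Half the loci carry a genetic expression -> trait effect, half are
    null, so the Z values span signal and noise.
    """
    scenarios = tuple(
        "direct" if i % 2 == 0 else "null" for i in range(n_genes)
    )
    config = SimulationConfig(
        scenarios=scenarios,
        n_gwas=2_000,
        n_eqtl=1_000,
        n_mqtl=30,
        n_ref=500,
        snps_per_block=10,
        beta_xe=0.4,
        beta_ey=0.1,  # 50 signal loci share the trait variance
        seed=_sub_seed(seed, 3),
    )
    snps, plans = plan_loci(config)
    gwas_geno = simulate_cohort_genotypes(config, "gwas", snps, plans)
    eqtl_geno = simulate_cohort_genotypes(config, "eqtl", snps, plans)
    gwas_ph = simulate_phenotypes(gwas_geno, config, plans, "gwas")
    eqtl_ph = simulate_phenotypes(eqtl_geno, config, plans, "eqtl")
    gwas_tab = compute_summary_stats(gwas_geno, gwas_ph.trait)

    p = config.snps_per_block
    gene_snps = {
        plan.gene: list(snps["SNP"].iloc[plan.block * p : (plan.block + 1) * p])
        for plan in plans
    }
    models = twas.train_weights(
        eqtl_geno, eqtl_ph.expression, [pl.gene for pl in plans], gene_snps,
        seed=_sub_seed(seed, 4),
    )
    # summary statistic with LD from the GWAS cohort itself, so the oracle
    # comparison isolates the summary-vs-individual algebra
    panel = LdPanel(gwas_geno)
    index = {s: i for i, s in enumerate(snps["SNP"])}
    z_summary, z_individual = [], []
    y = gwas_ph.trait
    for model in models:
        res = twas.metaxcan_z(model, gwas_tab, panel)
        if res is None:
            continue
        cols = [index[s] for s in model.snps]
        X = gwas_geno.matrix[:, cols].astype(float)
        pred = (X - X.mean(axis=0)) @ model.weights
        if pred.std() == 0:
            continue
        slope_tab = stats.linregress(pred, y)
        z_ind = slope_tab.slope / slope_tab.stderr
        z_summary.append(res["zscore"])
        z_individual.append(z_ind)
    r = float(np.corrcoef(z_summary, z_individual)[0, 1])
    return {"n_genes": len(z_summary), "pearson_r": r}


# ---------------------------------------------------------------------------
# 5. COLOC hypothesis recovery
# ---------------------------------------------------------------------------

def coloc_behavior(seed: int, n_reps: int = 100) -> dict:
    """Modal posterior hypothesis per planted locus type: one shared causal
    SNP (direct), two distinct causal SNPs in LD (linkage, r = 0.5), and a
    double null."""
    modal = {"shared": 0, "distinct": 0, "null": 0}
    for rep in range(n_reps):
        config = SimulationConfig(
            scenarios=("direct", "linkage", "null"),
            n_gwas=10_000,
            n_eqtl=5_000,
            n_mqtl=30,
            n_ref=500,
            snps_per_block=20,
            beta_xe=0.4,
            beta_ey=0.3,
            beta_xy=0.12,
            linkage_r=0.5,
            seed=_sub_seed(seed, 20_000 + rep),
        )
        snps, plans = plan_loci(config)
        gwas_geno = simulate_cohort_genotypes(config, "gwas", snps, plans)
        eqtl_geno = simulate_cohort_genotypes(config, "eqtl", snps, plans)
        gwas_ph = simulate_phenotypes(gwas_geno, config, plans, "gwas")
        eqtl_ph = simulate_phenotypes(eqtl_geno, config, plans, "eqtl")
        gwas_tab = compute_summary_stats(gwas_geno, gwas_ph.trait)
        eqtl_tab = compute_qtl_stats(eqtl_geno, eqtl_ph.expression, plans, config, "e")
        for plan, label in zip(plans, ("shared", "distinct", "null")):
            grp = eqtl_tab[eqtl_tab["probe_id"] == plan.gene]
            cc = twas.coloc_abf(grp, gwas_tab)
            if cc is None:
                continue
            pp = [cc[f"PP{i}"] for i in range(5)]
            expected = {"shared": 4, "distinct": 3, "null": 0}[label]
            if int(np.argmax(pp)) == expected:
                modal[label] += 1
    return {
        "pp4_modal_rate_shared": modal["shared"] / n_reps,
        "pp3_modal_rate_distinct": modal["distinct"] / n_reps,
        "pp0_modal_rate_null": modal["null"] / n_reps,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# 6. 3xSMR chain recovery
# ---------------------------------------------------------------------------

def chain_recovery(seed: int, n_chains: int = 10) -> dict:
    """Recall of planted methylation-mediation chains and the count of
    false chains arising from non-chain loci."""
    scenarios = (
        ("chain",) * n_chains
        + ("direct",) * 5
        + ("pleiotropy",) * 5
        + ("linkage",) * 5
        + ("null",) * 10
    )
    # effect sizes keep the summed per-locus trait variance below one so no
    # locus's signal is diluted by the unit-variance standardization
    config = SimulationConfig(
        scenarios=scenarios,
        n_gwas=20_000,
        n_eqtl=5_000,
        n_mqtl=5_000,
        n_ref=2_000,
        snps_per_block=20,
        beta_xm=0.6,
        beta_me=0.6,
        beta_ey=0.22,
        seed=_sub_seed(seed, 5),
    )
    ds = simulate_dataset(config)
    panel = LdPanel(ds.cohorts["ref"])
    esmr, msmr, m2e = mediation.run_3smr(ds.gwas, ds.eqtl, ds.mqtl, panel)
    chains = mediation.intersect_chains(esmr, msmr, m2e, annotation=ds.annotation)
    truth_chain = ds.truth[ds.truth["is_chain"]]
    planted = set(zip(truth_chain["probe"], truth_chain["gene"]))
    found = set(zip(chains["site"], chains["gene"]))
    recall = len(planted & found) / len(planted)
    false_chains = len(found - planted)
    return {
        "n_planted": len(planted),
        "n_nonchain_loci": int((~ds.truth["is_chain"]).sum()),
        "recall": float(recall),
        "false_chains": int(false_chains),
    }


# ---------------------------------------------------------------------------
# 7. Tissue prioritization with planted enrichment
# ---------------------------------------------------------------------------

def tissue_ranking(
    seed: int,
    n_reps: int = 100,
    n_tissues: int = 8,
    n_genes: int = 200,
    inflation: float = 1.5,
) -> dict:
    """Rate at which the tissue whose gene Z-scores have inflated variance
    is ranked first by the average-squared-Z criterion."""
    rng = np.random.default_rng(_sub_seed(seed, 6))
    traits = ("SBP", "DBP", "PP")
    methods = ("MX", "SMR")
    wins = 0
    for _ in range(n_reps):
        target = int(rng.integers(n_tissues))
        results = {}
        for t in range(n_tissues):
            sd = inflation if t == target else 1.0
            results[f"tissue{t:02d}"] = {
                (trait, method): rng.normal(0.0, sd, n_genes)
                for trait in traits
                for method in methods
            }
        ranked = prioritize.tissue_priority(results)
        top = ranked.loc[ranked["rank"] == 1, "tissue"].iloc[0]
        if top == f"tissue{target:02d}":
            wins += 1
    return {"top_rank_rate": wins / n_reps, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# 8. Fisher exactness vs enumeration
# ---------------------------------------------------------------------------

def fisher_exact_equivalence(max_n: int = 60) -> dict:
    """Exhaustive comparison of the hypergeometric tail computation with a
    from-scratch enumeration over all 2x2 tables with N <= max_n.

    The oracle builds each pmf from integer binomial coefficients and sums
    the tail exactly, independent of the implementation path.
    """
    from math import comb

    from .enrich import greater_tail_p, two_sided_p

    max_err_greater = 0.0
    max_err_two = 0.0
    n_tables = 0
    for n in range(1, max_n + 1):
        for k_set in range(0, n + 1):
            for n_prio in range(0, n + 1):
                lo = max(0, n_prio + k_set - n)
                hi = min(n_prio, k_set)
                denom = comb(n, n_prio)
                pmf = np.array(
                    [comb(k_set, a) * comb(n - k_set, n_prio - a) for a in range(lo, hi + 1)],
                    dtype=float,
                ) / denom
                sf_oracle = np.cumsum(pmf[::-1])[::-1]  # P(K >= a)
                a_vals = np.arange(lo, hi + 1)
                ours = greater_tail_p(a_vals, n, k_set, n_prio)
                max_err_greater = max(max_err_greater, float(np.abs(ours - sf_oracle).max()))
                # two-sided point-probability oracle at the extreme observed value
                a_obs = int(a_vals[-1])
                p_two_oracle = float(pmf[pmf <= pmf[-1] * (1.0 + 1e-12)].sum())
                max_err_two = max(
                    max_err_two, abs(two_sided_p(a_obs, n, k_set, n_prio) - p_two_oracle)
                )
                n_tables += len(a_vals)
    return {
        "n_tables": n_tables,
        "max_abs_error_greater": max_err_greater,
        "max_abs_error_two_sided": max_err_two,
    }


# ---------------------------------------------------------------------------
# 9. Bundled published-evidence arithmetic
# ---------------------------------------------------------------------------

def published_table_arithmetic() -> dict:
    from . import published

    summary = published.replication_summary()
    return {
        "high_evidence_gene_count": published.high_evidence_gene_count(min_sources=4),
        "novel_replicated_count": summary["n_replicated"],
        "novel_candidates": summary["n_candidates"],
        "pct_replicated": summary["pct_replicated"],
    }
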