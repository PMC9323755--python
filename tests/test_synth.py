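"""Generator checks: LD structure, determinism, phenotype model, summary stats."""

import numpy as np
import pytest
from scipy import special

from postgwas.synth import (
    ConfigurationError,
    SimulationConfig,
    compute_summary_stats,
    dosage_correlation,
    latent_r_for_dosage,
    plan_loci,
    simulate_cohort_genotypes,
    simulate_dataset,
    simulate_phenotypes,
)


def test_config_invariants_enforced():
    with pytest.raises(ConfigurationError):
        SimulationConfig(rho=1.0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(rho=-0.1)
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_gwas=10)
    with pytest.raises(ConfigurationError):
        SimulationConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ConfigurationError):
        SimulationConfig(scenarios=("chain", "bogus"))


def test_same_seed_reproduces_identical_outputs():
    a = simulate_dataset(SimulationConfig(scenarios=("chain", "null"), n_gwas=200,
                                          n_eqtl=100, n_mqtl=100, n_ref=50, seed=3))
    b = simulate_dataset(SimulationConfig(scenarios=("chain", "null"), n_gwas=200,
                                          n_eqtl=100, n_mqtl=100, n_ref=50, seed=3))
    for c in ("ref", "gwas", "eqtl", "mqtl"):
        assert np.array_equal(a.cohorts[c].matrix, b.cohorts[c].matrix)
    assert a.gwas.equals(b.gwas)
    assert a.truth.equals(b.truth)


def test_independent_blocks_under_rho_zero():
    cfg = SimulationConfig(scenarios=("null",) * 4, rho=0.0, n_gwas=100, n_eqtl=100,
                           n_mqtl=100, n_ref=5_000, snps_per_block=10, seed=1)
    snps, plans = plan_loci(cfg)
    geno = simulate_cohort_genotypes(cfg, "ref", snps, plans)
    G = geno.matrix.astype(float)
    G = (G - G.mean(0)) / G.std(0)
    corr = (G.T @ G) / len(G)
    off = corr[np.triu_indices_from(corr, k=1)]
    assert np.abs(off).mean() < 3 / np.sqrt(cfg.n_ref)


def test_adjacent_ld_matches_monte_carlo_oracle():
    """Empirical adjacent-SNP dosage correlation vs a brute-force latent
    Gaussian oracle pushed through the same double dichotomization."""
    rho, maf = 0.9, 0.3
    # oracle: 10^6 latent AR(1) pairs, dichotomized twice, correlated
    rng = np.random.default_rng(123)
    z1 = rng.standard_normal(10**6)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(10**6)
    w1 = rng.standard_normal(10**6)
    w2 = rho * w1 + np.sqrt(1 - rho**2) * rng.standard_normal(10**6)
    thr = special.ndtri(1 - maf)
    d1 = (z1 > thr).astype(float) + (w1 > thr)
    d2 = (z2 > thr).astype(float) + (w2 > thr)
    oracle_r = np.corrcoef(d1, d2)[0, 1]

    cfg = SimulationConfig(scenarios=("null",) * 20, rho=rho, maf_range=(maf, maf),
                           n_gwas=100, n_eqtl=100, n_mqtl=100, n_ref=5_000,
                           snps_per_block=2, seed=5)
    snps, plans = plan_loci(cfg)
    geno = simulate_cohort_genotypes(cfg, "ref", snps, plans)
    rs = [
        np.corrcoef(geno.matrix[:, 2 * b], geno.matrix[:, 2 * b + 1])[0, 1]
        for b in range(20)
    ]
    assert abs(np.mean(rs) - oracle_r) < 0.05
    # the closed form used for linkage calibration agrees with the oracle too
    assert abs(dosage_correlation(rho, maf, maf) - oracle_r) < 0.01


def test_latent_r_inversion_round_trips():
    for target in (0.3, 0.5, 0.7):
        lat = latent_r_for_dosage(target, 0.25, 0.4)
        assert abs(dosage_correlation(lat, 0.25, 0.4) - target) < 1e-8


def test_null_scenario_trait_z_calibrated():
    """SNP-trait z under the null has mean z^2 ~ 1 (chi^2_1 calibration)."""
    cfg = SimulationConfig(scenarios=("null",) * 250, n_gwas=2_000, n_eqtl=30,
                           n_mqtl=30, n_ref=30, snps_per_block=8, seed=11)
    snps, plans = plan_loci(cfg)
    geno = simulate_cohort_genotypes(cfg, "gwas", snps, plans)
    phen = simulate_phenotypes(geno, cfg, plans, "gwas")
    tab = compute_summary_stats(geno, phen.trait)
    assert len(tab) >= 2000
    assert 0.9 < (tab["z"] ** 2).mean() < 1.1


def test_broken_chain_disconnects_trait():
    cfg = SimulationConfig(scenarios=("chain",), beta_xm=0.0, n_gwas=4_000,
                           n_eqtl=30, n_mqtl=30, n_ref=30, seed=2)
    snps, plans = plan_loci(cfg)
    geno = simulate_cohort_genotypes(cfg, "gwas", snps, plans)
    phen = simulate_phenotypes(geno, cfg, plans, "gwas")
    g = geno.matrix[:, plans[0].causal_idx].astype(float)
    r = np.corrcoef(g, phen.trait)[0, 1]
    assert abs(r) < 3 / np.sqrt(cfg.n_gwas)


def test_chain_methylation_expression_correlation_closed_form():
    """Under the linear-Gaussian chain with unit phenotype variances,
    corr(m, e) equals beta_me exactly (path covariance)."""
    cfg = SimulationConfig(scenarios=("chain",) * 10, beta_me=0.5, n_gwas=30,
                           n_eqtl=20_000, n_mqtl=30, n_ref=30, seed=4)
    snps, plans = plan_loci(cfg)
    geno = simulate_cohort_genotypes(cfg, "eqtl", snps, plans)
    phen = simulate_phenotypes(geno, cfg, plans, "eqtl")
    rs = [
        np.corrcoef(phen.methylation[:, b], phen.expression[:, b])[0, 1]
        for b in range(10)
    ]
    assert abs(np.mean(rs) - 0.5) < 0.03


def test_marginal_slope_recovers_path_product():
    """The per-allele SNP-trait slope at a chain locus converges to
    beta_xm*beta_me*beta_ey (phenotypes standardized, so no extra scale)."""
    cfg = SimulationConfig(scenarios=("chain",), n_gwas=40_000, n_eqtl=30,
                           n_mqtl=30, n_ref=30, snps_per_block=3, seed=9)
    snps, plans = plan_loci(cfg)
    geno = simulate_cohort_genotypes(cfg, "gwas", snps, plans)
    phen = simulate_phenotypes(geno, cfg, plans, "gwas")
    tab = compute_summary_stats(geno, phen.trait)
    row = tab[tab["SNP"] == snps["SNP"].iloc[plans[0].causal_idx]].iloc[0]
    expected = cfg.beta_xm * cfg.beta_me * cfg.beta_ey
    assert abs(row["b"] - expected) < 2.5 * row["se"]


def test_summary_stats_match_ols_oracle():
    """Slopes equal cov(g,y)/var(g) from independent arithmetic to 1e-10."""
    cfg = SimulationConfig(scenarios=("direct",), n_gwas=500, n_eqtl=30, n_mqtl=30,
                           n_ref=30, snps_per_block=5, seed=13)
    snps, plans = plan_loci(cfg)
    geno = simulate_cohort_genotypes(cfg, "gwas", snps, plans)
    phen = simulate_phenotypes(geno, cfg, plans, "gwas")
    tab = compute_summary_stats(geno, phen.trait)
    for j, row in tab.iterrows():
        g = geno.matrix[:, j].astype(float)
        slope = np.cov(g, phen.trait, ddof=1)[0, 1] / np.var(g, ddof=1)
        assert abs(row["b"] - slope) < 1e-10


def test_perfect_association_retained_with_underflowed_p():
    cfg = SimulationConfig(scenarios=("null",), n_gwas=1_000, n_eqtl=30, n_mqtl=30,
                           n_ref=30, snps_per_block=3, seed=1)
    snps, plans = plan_loci(cfg)
    geno = simulate_cohort_genotypes(cfg, "gwas", snps, plans)
    y = geno.matrix[:, 0].astype(float)
    tab = compute_summary_stats(geno, y)
    row = tab[tab["SNP"] == "rs1"].iloc[0]
    assert row["p"] <= np.nextafter(0.0, 1.0) * 2
    assert np.isinf(row["z"]) or row["z"] > 1e6


def test_permuted_phenotype_p_uniform():
    """p-values under permutation are U(0,1): KS below the 1% critical value."""
    from scipy import stats

    cfg = SimulationConfig(scenarios=("null",) * 500, n_gwas=500, n_eqtl=30,
                           n_mqtl=30, n_ref=30, snps_per_block=10, seed=21)
    snps, plans = plan_loci(cfg)
    geno = simulate_cohort_genotypes(cfg, "gwas", snps, plans)
    rng = np.random.default_rng(0)
    y = rng.permutation(np.arange(cfg.n_gwas, dtype=float))
    tab = compute_summary_stats(geno, y)
    assert len(tab) == 5000
    ks = stats.kstest(tab["p"], "uniform").statistic
    assert ks < 1.6276 / np.sqrt(len(tab))


def test_cross_cohort_genotypes_uncorrelated():
    cfg = SimulationConfig(scenarios=("null",), n_gwas=1_000, n_eqtl=1_000,
                           n_mqtl=30, n_ref=30, snps_per_block=10, seed=6)
    snps, plans = plan_loci(cfg)
    a = simulate_cohort_genotypes(cfg, "gwas", snps, plans).matrix
    b = simulate_cohort_genotypes(cfg, "eqtl", snps, plans).matrix
    rs = [np.corrcoef(a[:, j], b[:, j])[0, 1] for j in range(10)]
    assert np.abs(rs).mean() < 3 / np.sqrt(1_000)


def test_truth_table_counts_and_chain_flags(small_dataset):
    truth = small_dataset.truth
    assert len(truth) == len(small_dataset.config.scenarios)
    assert truth["probe"].is_unique and truth["gene"].is_unique
    assert set(truth.loc[truth["is_chain"], "scenario"]) == {"chain"}
    chain = truth[truth["scenario"] == "chain"]
    assert ((chain[["beta_xm", "beta_me", "beta_ey"]] != 0).all(axis=1)).all()


def test_linkage_pair_dosage_correlation_near_target():
    cfg = SimulationConfig(scenarios=("linkage",) * 10, n_gwas=30, n_eqtl=30,
                           n_mqtl=30, n_ref=8_000, linkage_r=0.7, seed=17)
    snps, plans = plan_loci(cfg)
    geno = simulate_cohort_genotypes(cfg, "ref", snps, plans)
    rs = [
        np.corrcoef(geno.matrix[:, p.causal_idx], geno.matrix[:, p.causal_idx2])[0, 1]
        for p in plans
    ]
    assert abs(np.mean(rs) - 0.7) < 0.05
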