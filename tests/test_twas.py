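"""Prediction-weight training, summary Z statistic, colocalization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from postgwas import twas
from postgwas.ld import LdPanel
from postgwas.synth import Genotypes, SimulationConfig, plan_loci, simulate_cohort_genotypes
from postgwas.twas import ColocConfig, coloc_abf, metaxcan_z, train_weights, TwasModel
from conftest import make_assoc


def _toy_genotypes(n=300, p=6, seed=0):
    rng = np.random.default_rng(seed)
    mat = rng.integers(0, 3, size=(n, p)).astype(np.int8)
    snps = pd.DataFrame(
        {"SNP": [f"rs{i+1}" for i in range(p)], "chr": 1, "bp": np.arange(1, p + 1) * 1000,
         "A1": "G", "A2": "A"}
    )
    return Genotypes(matrix=mat, snps=snps)


def test_perfect_heritability_recovered():
    geno = _toy_genotypes()
    expr = geno.matrix[:, 2].astype(float)[:, None]
    models = train_weights(geno, expr, ["G1"], {"G1": list(geno.snps["SNP"])}, seed=1)
    m = models[0]
    assert m.cv_r2 > 0.99
    assert np.argmax(np.abs(m.weights)) == 2


def test_ridge_solution_equals_normal_equations_oracle():
    geno = _toy_genotypes(seed=3)
    rng = np.random.default_rng(4)
    expr = (0.3 * geno.matrix[:, 0] + rng.standard_normal(geno.n))[:, None]
    models = train_weights(geno, expr, ["G1"], {"G1": list(geno.snps["SNP"])},
                           grid=(1.0,), seed=1)
    X = geno.matrix.astype(float)
    X = X - X.mean(axis=0)
    y = expr[:, 0] - expr[:, 0].mean()
    oracle = np.linalg.inv(X.T @ X + 1.0 * np.eye(X.shape[1])) @ (X.T @ y)
    np.testing.assert_allclose(models[0].weights, oracle, atol=1e-8)


def test_permuted_expression_low_cv_r2():
    rng = np.random.default_rng(5)
    geno = _toy_genotypes(n=400, seed=6)
    hits = 0
    for rep in range(30):
        expr = rng.standard_normal((geno.n, 1))
        models = train_weights(geno, expr, ["G1"], {"G1": list(geno.snps["SNP"])}, seed=rep)
        m = models[0]
        if m.cv_r2 > 0.01 and m.cv_p < 0.05:
            hits += 1
    assert hits <= 6  # ~nominal 5% false-positive rate, generous binomial slack


def test_single_snp_model_z_equals_snp_z(small_dataset, small_panel):
    gwas = small_dataset.gwas
    snp = small_panel.snps["SNP"].iloc[10]
    model = TwasModel(gene="G", snps=[snp], weights=np.array([1.0]),
                      a1=["G"], a2=["A"], cv_r2=0.5, cv_p=1e-4)
    res = metaxcan_z(model, gwas, small_panel)
    z_snp = float(gwas.loc[gwas["SNP"] == snp, "z"].iloc[0])
    assert res["zscore"] == pytest.approx(z_snp, rel=1e-9)


def test_duplicate_snps_collapse():
    """Two perfectly correlated SNPs with unit weights give Z_g = z_l."""
    rng = np.random.default_rng(7)
    g = rng.integers(0, 3, size=(500, 1)).astype(np.int8)
    mat = np.hstack([g, g])
    snps = pd.DataFrame({"SNP": ["rs1", "rs2"], "chr": 1, "bp": [1000, 2000],
                         "A1": "G", "A2": "A"})
    panel = LdPanel(Genotypes(matrix=mat, snps=snps))
    gwas = pd.concat([make_assoc("rs1", a1="G", a2="A", b=0.1, se=0.02),
                      make_assoc("rs2", a1="G", a2="A", b=0.1, se=0.02)],
                     ignore_index=True)
    model = TwasModel(gene="G", snps=["rs1", "rs2"], weights=np.array([1.0, 1.0]),
                      a1=["G", "G"], a2=["A", "A"], cv_r2=0.5, cv_p=1e-4)
    res = metaxcan_z(model, gwas, panel)
    assert res["zscore"] == pytest.approx(5.0, rel=1e-9)


def test_z_invariant_under_joint_allele_flip(small_dataset, small_panel):
    gwas = small_dataset.gwas
    snp = small_panel.snps["SNP"].iloc[25]
    base = TwasModel(gene="G", snps=[snp], weights=np.array([0.7]),
                     a1=["G"], a2=["A"], cv_r2=0.3, cv_p=1e-3)
    flipped_gwas = gwas.copy()
    i = flipped_gwas["SNP"] == snp
    flipped_gwas.loc[i, ["A1", "A2"]] = ["A", "G"]
    flipped_gwas.loc[i, "b"] *= -1
    flipped_gwas.loc[i, "z"] *= -1
    flipped_gwas.loc[i, "freq"] = 1 - flipped_gwas.loc[i, "freq"]
    flipped_model = TwasModel(gene="G", snps=[snp], weights=np.array([-0.7]),
                              a1=["A"], a2=["G"], cv_r2=0.3, cv_p=1e-3)
    r1 = metaxcan_z(base, gwas, small_panel)
    r2 = metaxcan_z(flipped_model, flipped_gwas, small_panel)
    assert r1["zscore"] == pytest.approx(r2["zscore"], rel=1e-9)


def _region(zs, se=0.02, prefix="rs"):
    rows = []
    for i, z in enumerate(zs):
        rows.append({"SNP": f"{prefix}{i+1}", "A1": "G", "A2": "A", "freq": 0.3,
                     "b": z * se, "se": se, "z": z,
                     "p": 2 * stats.norm.sf(abs(z)), "n": 1000})
    return pd.DataFrame(rows)


def test_coloc_null_region_pp0():
    t1 = _region([0.1, -0.2, 0.05, 0.3, -0.1])
    t2 = _region([0.2, 0.1, -0.15, 0.0, 0.25])
    pp = coloc_abf(t1, t2)
    assert pp["PP0"] > 0.99


def test_coloc_shared_strong_signal_pp4():
    t1 = _region([8.0, 1.0, 0.5])
    t2 = _region([8.0, 0.8, 0.2])
    pp = coloc_abf(t1, t2)
    assert max(range(5), key=lambda i: pp[f"PP{i}"]) == 4


def test_coloc_distinct_signals_pp3():
    t1 = _region([8.0, 0.1, 0.3, 0.2])
    t2 = _region([0.2, 0.1, 8.0, 0.3])
    pp = coloc_abf(t1, t2)
    assert max(range(5), key=lambda i: pp[f"PP{i}"]) == 3


def test_coloc_posteriors_sum_to_one_and_single_snp_not_testable():
    t1 = _region([2.0, 1.0])
    t2 = _region([1.5, 0.5])
    pp = coloc_abf(t1, t2)
    assert sum(pp[f"PP{i}"] for i in range(5)) == pytest.approx(1.0, abs=1e-9)
    assert coloc_abf(_region([2.0]), _region([1.0])) is None


def test_coloc_pp4_monotone_in_p12():
    t1 = _region([5.0, 1.0, 0.2])
    t2 = _region([5.0, 0.8, 0.1])
    prev = -1.0
    for p12 in (1e-6, 1e-5, 1e-4):
        pp = coloc_abf(t1, t2, ColocConfig(p12=p12))
        assert pp["PP4"] >= prev
        prev = pp["PP4"]


def test_coloc_hand_computed_abf_sums():
    """Two-SNP region checked against a direct enumeration of the
    hypothesis sums computed from scratch."""
    z1, z2 = np.array([3.0, 1.0]), np.array([2.5, 0.5])
    se = 0.05
    w = 0.15**2
    t1, t2 = _region(z1, se=se), _region(z2, se=se)
    pp = coloc_abf(t1, t2)
    v = se**2
    ab1 = np.sqrt(v / (v + w)) * np.exp(z1**2 / 2 * w / (v + w))
    ab2 = np.sqrt(v / (v + w)) * np.exp(z2**2 / 2 * w / (v + w))
    p1 = p2 = 1e-4
    p12 = 1e-5
    s0 = 1.0
    s1 = p1 * ab1.sum()
    s2 = p2 * ab2.sum()
    s4 = p12 * (ab1 * ab2).sum()
    s3 = p1 * p2 * (ab1.sum() * ab2.sum() - (ab1 * ab2).sum())
    total = s0 + s1 + s2 + s3 + s4
    for i, s in enumerate([s0, s1, s2, s3, s4]):
        assert pp[f"PP{i}"] == pytest.approx(s / total, rel=1e-6)


def test_twas_scan_deterministic_and_filters(small_dataset, small_panel):
    cfg = small_dataset.config
    p = cfg.snps_per_block
    snps = small_dataset.cohorts["eqtl"].snps
    gene_snps = {
        pl.gene: list(snps["SNP"].iloc[pl.block * p : (pl.block + 1) * p])
        for pl in small_dataset.plans
    }
    models = train_weights(
        small_dataset.cohorts["eqtl"], small_dataset.phenotypes["eqtl"].expression,
        [pl.gene for pl in small_dataset.plans], gene_snps, seed=0,
    )
    r1 = twas.twas_scan(small_dataset.gwas, models, small_panel, eqtl=small_dataset.eqtl)
    r2 = twas.twas_scan(small_dataset.gwas, models, small_panel, eqtl=small_dataset.eqtl)
    pd.testing.assert_frame_equal(r1, r2)
    truth = small_dataset.truth
    direct_gene = truth.loc[truth["scenario"] == "direct", "gene"].iloc[0]
    row = r1[r1["gene"] == direct_gene].iloc[0]
    assert row["pass_bonferroni"]
    null_gene = truth.loc[truth["scenario"] == "null", "gene"].iloc[0]
    nrow = r1[r1["gene"] == null_gene]
    assert nrow.empty or not nrow["pass_bonferroni"].iloc[0]
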