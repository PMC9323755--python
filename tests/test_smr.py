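"""SMR ratio test, HEIDI heterogeneity screen, and the probe scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from postgwas import smr
from postgwas.ld import LdPanel
from postgwas.smr import chi2_mixture_sf, heidi_test, select_top_instrument, smr_test
from postgwas.synth import SimulationConfig, simulate_dataset


def test_smr_statistic_symmetric_example():
    # z_zx = z_zy = 2 -> T = 16/8 = 2
    _, _, t, p = smr_test(b_zx=0.2, se_zx=0.1, b_zy=0.02, se_zy=0.01)
    assert t == pytest.approx(2.0)
    assert p == pytest.approx(stats.chi2.sf(2.0, 1))


def test_smr_zero_outcome():
    b, se, t, p = smr_test(b_zx=0.5, se_zx=0.05, b_zy=0.0, se_zy=0.01)
    assert (b, t, p) == (0.0, 0.0, 1.0)


def test_smr_delta_method_example_and_monte_carlo():
    """Worked delta-method arithmetic plus a ratio-of-normals MC check."""
    b, se, _, _ = smr_test(b_zx=0.5, se_zx=0.05, b_zy=0.1, se_zy=0.02)
    assert b == pytest.approx(0.2)
    expected_se = np.sqrt(0.0004 / 0.25 + 0.01 * 0.0025 / 0.0625)
    assert se == pytest.approx(expected_se, rel=1e-12)
    assert se == pytest.approx(0.0447, abs=5e-4)
    rng = np.random.default_rng(0)
    ratio = rng.normal(0.1, 0.02, 400_000) / rng.normal(0.5, 0.05, 400_000)
    assert ratio.std() == pytest.approx(se, rel=0.05)


def test_smr_zero_exposure_raises():
    with pytest.raises(ZeroDivisionError):
        smr_test(b_zx=0.0, se_zx=0.05, b_zy=0.1, se_zy=0.02)


@settings(max_examples=200, deadline=None)
@given(
    zx=st.floats(-10, 10, allow_nan=False),
    zy=st.floats(-10, 10, allow_nan=False),
)
def test_smr_statistic_bounded_and_symmetric(zx, zy):
    """T_SMR <= min(z_zx^2, z_zy^2) and exchanging exposure/outcome z-scores
    leaves the statistic unchanged."""
    se = 0.1
    if abs(zx) < 1e-6:
        zx = 1.0
    _, _, t1, _ = smr_test(zx * se, se, zy * se, se)
    assert t1 <= min(zx**2, zy**2) + 1e-9
    if abs(zy) > 1e-6:
        _, _, t2, _ = smr_test(zy * se, se, zx * se, se)
        assert t1 == pytest.approx(t2, rel=1e-9, abs=1e-12)


def _probe_frame(ps, zs=None, bps=None):
    n = len(ps)
    zs = zs if zs is not None else [5.0] * n
    return pd.DataFrame(
        {
            "SNP": [f"rs{i+1}" for i in range(n)],
            "probe_bp": 5_000,
            "snp_bp": bps if bps is not None else np.arange(1, n + 1) * 1000,
            "p": ps,
            "z": zs,
        }
    )


def test_instrument_selection_tie_rules():
    single = _probe_frame([1e-9])
    assert select_top_instrument(single)["SNP"] == "rs1"
    # identical p and |z| -> smaller bp wins
    tied = _probe_frame([1e-9, 1e-9], zs=[6.0, -6.0])
    assert select_top_instrument(tied)["SNP"] == "rs1"
    # no eligible instrument -> None
    assert select_top_instrument(_probe_frame([1e-3])) is None


def test_instrument_selection_matches_bruteforce(small_dataset):
    qtl = small_dataset.eqtl
    for probe, grp in qtl.groupby("probe_id"):
        got = select_top_instrument(grp)
        eligible = grp[(grp["p"] < 5e-8)
                       & ((grp["snp_bp"] - grp["probe_bp"]).abs() <= 2_000_000)]
        if eligible.empty:
            assert got is None
        else:
            best = min(
                eligible.itertuples(),
                key=lambda r: (r.p, -abs(r.z), r.snp_bp),
            )
            assert got["SNP"] == best.SNP


def test_chi2_mixture_matches_chi2_special_cases():
    assert chi2_mixture_sf(3.84, [1.0]) == pytest.approx(stats.chi2.sf(3.84, 1), abs=1e-6)
    assert chi2_mixture_sf(7.81, [1, 1, 1]) == pytest.approx(stats.chi2.sf(7.81, 3), abs=1e-6)
    assert chi2_mixture_sf(0.0, [1, 1]) == 1.0


def test_heidi_identical_ratios_give_p_one(small_panel):
    """When every candidate carries exactly the same b_xy the heterogeneity
    statistic is zero and P_HEIDI = 1."""
    snps = [f"rs{i}" for i in range(8, 14)]
    merged = pd.DataFrame(
        {
            "SNP": snps,
            "b_zx": [0.5, 0.4, 0.45, 0.5, 0.42, 0.48],
            "se_zx": 0.02,
            "p_zx": 1e-20,
            "b_zy": [0.25, 0.2, 0.225, 0.25, 0.21, 0.24],  # all ratios = 0.5
            "se_zy": 0.01,
        }
    )
    res = heidi_test(merged, "rs10", small_panel)
    if res.testable:
        assert res.t_heidi == pytest.approx(0.0, abs=1e-9)
        assert res.p_heidi == 1.0


def test_heidi_too_few_candidates_not_testable(small_panel):
    merged = pd.DataFrame(
        {
            "SNP": ["rs10", "rs11"],
            "b_zx": [0.5, 0.4], "se_zx": 0.02, "p_zx": 1e-20,
            "b_zy": [0.25, 0.2], "se_zy": 0.01,
        }
    )
    res = heidi_test(merged, "rs10", small_panel)
    assert not res.testable
    assert res.n_snps < 3


def test_scan_recovers_planted_effect_and_keeps_pleiotropy(small_dataset, small_panel):
    res = smr.smr_scan(small_dataset.gwas, small_dataset.eqtl, small_panel)
    truth = small_dataset.truth
    by_gene = res.set_index("gene_id")
    direct_gene = truth.loc[truth["scenario"] == "direct", "gene"].iloc[0]
    assert direct_gene in by_gene.index
    assert by_gene.loc[direct_gene, "pass_bonferroni"]
    # pleiotropy passes SMR by design (the ratio test cannot separate it)
    pleio_gene = truth.loc[truth["scenario"] == "pleiotropy", "gene"].iloc[0]
    if pleio_gene in by_gene.index:
        assert by_gene.loc[pleio_gene, "p_SMR"] < 0.05
    # null gene should not appear or not pass
    null_gene = truth.loc[truth["scenario"] == "null", "gene"].iloc[0]
    if null_gene in by_gene.index:
        assert not by_gene.loc[null_gene, "pass_bonferroni"]


def test_scan_bonferroni_uses_probes_tested(small_dataset, small_panel):
    res = smr.smr_scan(small_dataset.gwas, small_dataset.eqtl, small_panel, alpha=0.05)
    assert res.attrs["bonferroni_threshold"] == pytest.approx(0.05 / res.attrs["n_tested"])


def test_smr_estimator_bias_shrinks_with_sample_size():
    """b_xy is consistent for the expression -> trait effect: the absolute
    bias at the larger n is no worse than at the smaller n (plus MC noise)."""
    from postgwas.validate import smr_chain_recovery

    small = smr_chain_recovery(3, n_reps=30, n_gwas=2_000, n_eqtl=1_000)
    large = smr_chain_recovery(3, n_reps=30, n_gwas=20_000, n_eqtl=5_000)
    tol = 2 * (small["mc_se"] + large["mc_se"])
    assert abs(large["mean_b_smr"] - 0.3) <= abs(small["mean_b_smr"] - 0.3) + tol
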