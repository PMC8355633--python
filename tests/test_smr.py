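"""The SMR statistic, chi-square test, thresholds, and gene calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from smr_integrate.smr import (
    ThresholdPolicy,
    bonferroni_threshold,
    call_risk_genes,
    log_p_smr,
    p_smr,
    run_smr_dataset,
    select_instruments,
    t_smr,
    wald_ratio,
    z_score,
)
from conftest import make_merged

finite_z = st.floats(min_value=-50, max_value=50, allow_nan=False)


def chi2_tail_by_quadrature(t: float) -> float:
    """Independent oracle: numerically integrate the df-1 chi-square density."""
    density = lambda x: np.exp(-x / 2) / np.sqrt(2 * np.pi * x)
    val, _ = integrate.quad(density, t, np.inf)
    return val


class TestZScore:
    def test_direct_quotients(self):
        assert z_score(1.0, 0.5) == pytest.approx(2.0)
        assert z_score(0.0, 0.3) == 0.0
        assert z_score(-0.42, 0.07) == pytest.approx(-6.0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            z_score(0.1, 0.0)
        with pytest.raises(ValueError):
            z_score(np.array([0.1, 0.2]), np.array([0.1, -0.1]))


class TestTSmr:
    def test_worked_values(self):
        assert t_smr(2, 2) == pytest.approx(2.0)
        assert t_smr(0, 5) == 0.0
        assert t_smr(3, 4) == pytest.approx(5.76)
        assert t_smr(0, 0) == 0.0

    @settings(max_examples=300, derandomize=True)
    @given(a=finite_z, b=finite_z)
    def test_symmetry_and_sign_invariance(self, a, b):
        t = t_smr(a, b)
        assert t == pytest.approx(t_smr(b, a))
        assert t == pytest.approx(t_smr(-a, b))
        assert t == pytest.approx(t_smr(a, -b))

    @settings(max_examples=300, derandomize=True)
    @given(a=finite_z, b=finite_z)
    def test_bounded_by_weaker_arm(self, a, b):
        assert 0 <= t_smr(a, b) <= min(a * a, b * b) + 1e-12

    @settings(max_examples=300, derandomize=True)
    @given(a=st.floats(1e-6, 50), b=st.floats(1e-6, 50),
           sa=st.sampled_from([-1, 1]), sb=st.sampled_from([-1, 1]))
    def test_equals_half_harmonic_mean_of_squares(self, a, b, sa, sb):
        harmonic = 2.0 / (1.0 / a ** 2 + 1.0 / b ** 2)
        assert t_smr(sa * a, sb * b) == pytest.approx(harmonic / 2, rel=1e-12)

    def test_monotone_in_each_arm_magnitude(self):
        grid = np.linspace(0.1, 10, 40)
        for b in (0.5, 3.0, 20.0):
            vals = t_smr(grid, np.full_like(grid, b))
            assert (np.diff(vals) >= -1e-12).all()


class TestPSmr:
    def test_zero_statistic_full_mass(self):
        assert p_smr(0.0) == 1.0

    def test_matches_quadrature_oracle_at_key_quantiles(self):
        assert p_smr(3.841459) == pytest.approx(
            chi2_tail_by_quadrature(3.841459), abs=1e-6)
        assert p_smr(3.841459) == pytest.approx(0.05, abs=1e-4)
        assert p_smr(10.8276) == pytest.approx(
            chi2_tail_by_quadrature(10.8276), abs=1e-7)
        assert p_smr(10.8276) == pytest.approx(1.0e-3, abs=1e-5)

    def test_strictly_decreasing(self):
        t = np.linspace(0, 40, 200)
        assert (np.diff(p_smr(t)) < 0).all()

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            p_smr(-0.1)

    def test_log_form_survives_underflow(self):
        t = 3200.0  # p far below the smallest positive double
        assert p_smr(t) == 0.0
        lp = log_p_smr(t)
        assert np.isfinite(lp) and lp < -1500


class TestThreshold:
    def test_probe_count_division(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 1000) == pytest.approx(5e-5)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)

    def test_policy_exposes_exact_quotient(self):
        policy = ThresholdPolicy(n_probes=28522)
        assert policy.threshold == 0.05 / 28522


class TestWaldRatio:
    def test_direct_ratio(self):
        bxy, _ = wald_ratio(0.2, 0.05, 0.4, 0.05)
        assert bxy == pytest.approx(0.5)

    def test_zero_numerator_convention(self):
        bxy, se = wald_ratio(0.0, 0.05, 0.4, 0.05)
        assert bxy == 0.0
        assert se == pytest.approx(0.125)

    def test_zero_eqtl_beta_undefined(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.2, 0.05, 0.0, 0.05)

    def test_delta_method_se(self):
        bxy, se = wald_ratio(0.2, 0.05, 0.4, 0.08)
        expected = abs(bxy) * np.sqrt((0.05 / 0.2) ** 2 + (0.08 / 0.4) ** 2)
        assert se == pytest.approx(expected, rel=1e-12)


def _random_merged(rng, n=60, n_probes=12):
    df = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in rng.integers(0, 40, size=n)],
        "probe_id": [f"p{i}" for i in rng.integers(0, n_probes, size=n)],
        "beta_gwas": rng.normal(scale=0.3, size=n),
        "se_gwas": rng.uniform(0.05, 0.2, size=n),
        "beta_eqtl": rng.normal(scale=0.6, size=n),
        "se_eqtl": rng.uniform(0.05, 0.2, size=n),
        "pvalue_eqtl": 10.0 ** rng.uniform(-12, 0, size=n),
    })
    df = df.drop_duplicates(["snp_id", "probe_id"]).reset_index(drop=True)
    df["gene_name"] = "gene_" + df["probe_id"]
    return make_merged(df, n_probes=n_probes)


class TestInstrumentSelection:
    def test_all_pairs_returns_everything(self, rng):
        ds = _random_merged(rng)
        assert len(select_instruments(ds, "all_pairs")) == ds.n_pairs

    def test_top_per_probe_argmin_under_cutoff(self):
        df = pd.DataFrame({
            "snp_id": ["rs1", "rs2"], "probe_id": ["p1", "p1"],
            "beta_gwas": [0.1, 0.1], "se_gwas": [0.1, 0.1],
            "beta_eqtl": [0.5, 0.5], "se_eqtl": [0.1, 0.1],
            "pvalue_eqtl": [1e-9, 1e-4],
        })
        sel = select_instruments(make_merged(df), "top_per_probe", p_cut=5e-8)
        assert len(sel) == 1 and sel["snp_id"].iloc[0] == "rs1"

    def test_top_per_probe_matches_bruteforce(self, rng):
        ds = _random_merged(rng, n=120)
        p_cut = 1e-3
        sel = select_instruments(ds, "top_per_probe", p_cut=p_cut)
        got = dict(zip(sel["probe_id"], sel["snp_id"]))
        expected = {}
        for probe, grp in ds.pairs.groupby("probe_id"):
            grp = grp[grp["pvalue_eqtl"] <= p_cut]
            if grp.empty:
                continue
            best = min(grp.itertuples(),
                       key=lambda r: (r.pvalue_eqtl, -abs(r.z_eqtl), r.snp_id))
            expected[probe] = best.snp_id
        assert got == expected


class TestRunSmr:
    def test_single_strong_pair_significant(self):
        df = pd.DataFrame({
            "snp_id": ["rs1"], "probe_id": ["p1"],
            "beta_gwas": [0.6], "se_gwas": [0.1],
            "beta_eqtl": [0.6], "se_eqtl": [0.1],
        })
        res = run_smr_dataset(make_merged(df, n_probes=1000))
        row = res.iloc[0]
        assert row["t_smr"] == pytest.approx(18.0)
        assert row["p_smr"] == pytest.approx(2.2e-5, abs=2e-6)
        assert row["p_smr"] == pytest.approx(
            chi2_tail_by_quadrature(18.0), rel=1e-9)
        assert row["significant"]  # threshold 5e-5

    def test_unaligned_dataset_rejected(self, rng):
        ds = _random_merged(rng)
        ds.aligned = False
        with pytest.raises(ValueError):
            run_smr_dataset(ds)

    def test_significance_flags_match_bruteforce(self, rng):
        ds = _random_merged(rng, n=200)
        policy = ThresholdPolicy(n_probes=50)
        res = run_smr_dataset(ds, policy=policy)
        recomputed = res["p_smr"] < policy.threshold
        assert (res["significant"] == recomputed).all()

    def test_results_sorted_by_p(self, rng):
        res = run_smr_dataset(_random_merged(rng, n=150))
        assert (np.diff(res["log_p_smr"]) >= -1e-12).all()

    def test_no_pair_passing_yields_no_calls(self):
        df = pd.DataFrame({
            "snp_id": ["rs1"], "probe_id": ["p1"],
            "beta_gwas": [0.01], "se_gwas": [0.1],
            "beta_eqtl": [0.5], "se_eqtl": [0.1],
        })
        res = run_smr_dataset(make_merged(df, n_probes=1000))
        assert not res["significant"].any()
        assert call_risk_genes(res).empty


class TestRiskGeneCalls:
    def _results(self, genes, sig=True):
        n = len(genes)
        return pd.DataFrame({
            "snp_id": [f"rs{i}" for i in range(n)],
            "probe_id": [f"p{i}" for i in range(n)],
            "gene_name": genes,
            "p_smr": np.linspace(1e-9, 1e-7, n),
            "log_p_smr": np.log(np.linspace(1e-9, 1e-7, n)),
            "significant": [sig] * n,
        })

    def test_no_significant_results_empty_calls(self):
        assert call_risk_genes(self._results(["A", "B"], sig=False)).empty

    def test_five_snps_one_gene(self):
        calls = call_risk_genes(self._results(["SNCA"] * 5))
        assert len(calls) == 1
        row = calls.iloc[0]
        assert row["n_snps"] == 5
        assert len(row["snp_ids"].split(",")) == 5
        assert row["best_p_smr"] == pytest.approx(1e-9)

    def test_groupby_counts(self):
        calls = call_risk_genes(self._results(["A", "A", "B"]))
        assert len(calls) == 2
        assert sorted(calls["n_snps"]) == [1, 2]

    def test_counts_match_groupby_oracle(self, rng):
        ds = _random_merged(rng, n=200)
        res = run_smr_dataset(ds, policy=ThresholdPolicy(n_probes=2))
        calls = call_risk_genes(res)
        sig = res[res["significant"]]
        oracle = sig.groupby("gene_name")["snp_id"].nunique()
        assert dict(zip(calls["gene_name"], calls["n_snps"])) == oracle.to_dict()
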