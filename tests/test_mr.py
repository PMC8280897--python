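"""Mendelian randomization: QC, harmonization, IVW, Egger, MR-PRESSO."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wbclung.mr import (
    compute_f_stat,
    egger,
    filter_instruments,
    harmonize,
    ivw,
    mr_presso,
)
from wbclung.synthetic import (
    TwoSampleSpec,
    generate_two_sample,
    scramble_outcome_coding,
)


def make_instruments(bx, by, se_x=0.01, se_y=1.0, **extra):
    n = len(bx)
    df = pd.DataFrame(
        {
            "snp": [f"rs{j}" for j in range(n)],
            "effect_allele": ["A"] * n,
            "other_allele": ["G"] * n,
            "eaf": [0.3] * n,
            "beta_exposure": bx,
            "se_exposure": np.broadcast_to(se_x, (n,)).astype(float),
            "beta_outcome": by,
            "se_outcome": np.broadcast_to(se_y, (n,)).astype(float),
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df


class TestFStat:
    def test_known_values(self):
        assert compute_f_stat(0.1, 0.01) == pytest.approx(100.0)
        assert compute_f_stat(0.0, 0.5) == 0.0

    def test_weak_subset_matches_direct_threshold(self, rng):
        bx = rng.uniform(0.01, 0.2, 33)
        se = rng.uniform(0.01, 0.05, 33)
        f = compute_f_stat(bx, se)
        weak = set(np.flatnonzero(f < 10))
        direct = {j for j in range(33) if (bx[j] / se[j]) ** 2 < 10}
        assert weak == direct


class TestFilterInstruments:
    def test_weak_instrument_removed_with_reason(self):
        df = make_instruments(
            np.array([0.2, 0.2, 0.2, 0.2, 0.02]), np.zeros(5), se_x=0.01
        )
        retained, log = filter_instruments(df)
        assert len(retained) == 4
        assert any("weak" in reason for _, reason in log)

    def test_confounder_associated_snp_removed(self):
        df = make_instruments(np.full(5, 0.2), np.zeros(5))
        conf = pd.DataFrame(
            {"snp": ["rs0", "rs1"], "confounder": ["height", "smoking"],
             "p": [1e-8, 0.5]}
        )
        retained, log = filter_instruments(df, conf)
        assert "rs0" not in set(retained["snp"])
        assert "rs1" in set(retained["snp"])

    def test_ambiguous_palindrome_removed(self):
        df = make_instruments(np.full(4, 0.2), np.zeros(4))
        df.loc[0, ["effect_allele", "other_allele"]] = ["A", "T"]
        df.loc[0, "eaf"] = 0.50
        df.loc[1, ["effect_allele", "other_allele"]] = ["C", "G"]
        df.loc[1, "eaf"] = 0.10  # orientable: frequency far from 0.5
        retained, log = filter_instruments(df)
        assert "rs0" not in set(retained["snp"])
        assert "rs1" in set(retained["snp"])

    def test_no_rule_triggered_is_identity(self):
        df = make_instruments(np.full(4, 0.2), np.zeros(4))
        retained, log = filter_instruments(df)
        assert len(retained) == 4
        assert log == []

    def test_all_excluded_raises(self):
        df = make_instruments(np.full(3, 0.001), np.zeros(3), se_x=0.01)
        with pytest.raises(ValueError, match="no IVs"):
            filter_instruments(df)


class TestHarmonize:
    @staticmethod
    def _halves(n=12, seed=5, **spec_kw):
        df, _ = generate_two_sample(TwoSampleSpec(n_snps=n, seed=seed, **spec_kw))
        return df, scramble_outcome_coding(df, seed=seed + 1)

    def test_swapped_coding_flips_outcome_beta(self):
        exp = pd.DataFrame(
            {"snp": ["rs1"], "effect_allele": ["A"], "other_allele": ["G"],
             "eaf": [0.3], "beta": [0.1], "se": [0.01], "p": [1e-9], "n": [1000]}
        )
        out = pd.DataFrame(
            {"snp": ["rs1"], "effect_allele": ["G"], "other_allele": ["A"],
             "eaf": [0.7], "beta": [5.0], "se": [1.0], "p": [0.01], "n": [500]}
        )
        h, _ = harmonize(exp, out)
        assert h["beta_outcome"].iloc[0] == pytest.approx(-5.0)

    def test_identical_coding_unchanged(self):
        exp = pd.DataFrame(
            {"snp": ["rs1"], "effect_allele": ["A"], "other_allele": ["G"],
             "eaf": [0.3], "beta": [0.1], "se": [0.01], "p": [1e-9], "n": [1000]}
        )
        out = exp.assign(beta=[5.0], se=[1.0], p=[0.1], n=[500])
        h, _ = harmonize(exp, out)
        assert h["beta_outcome"].iloc[0] == pytest.approx(5.0)

    def test_palindrome_at_half_frequency_flagged(self):
        exp = pd.DataFrame(
            {"snp": ["rs1"], "effect_allele": ["A"], "other_allele": ["T"],
             "eaf": [0.50], "beta": [0.1], "se": [0.01], "p": [1e-9], "n": [1000]}
        )
        out = exp.assign(beta=[1.0], se=[1.0], p=[0.1], n=[500])
        h, log = harmonize(exp, out)
        assert bool(h["ambiguous"].iloc[0])
        assert any("ambiguous" in r for _, r in log)

    def test_incompatible_alleles_dropped_with_log(self):
        exp = pd.DataFrame(
            {"snp": ["rs1"], "effect_allele": ["A"], "other_allele": ["G"],
             "eaf": [0.3], "beta": [0.1], "se": [0.01], "p": [1e-9], "n": [1000]}
        )
        out = pd.DataFrame(
            {"snp": ["rs1"], "effect_allele": ["A"], "other_allele": ["C"],
             "eaf": [0.3], "beta": [5.0], "se": [1.0], "p": [0.01], "n": [500]}
        )
        h, log = harmonize(exp, out)
        assert len(h) == 0
        assert any("incompatible" in r for _, r in log)

    def test_scrambled_coding_round_trip(self):
        df, (exp, out) = self._halves()
        h, _ = harmonize(exp, out)
        h = h.sort_values("snp").reset_index(drop=True)
        ref = df.sort_values("snp").reset_index(drop=True)
        assert np.allclose(h["beta_outcome"], ref["beta_outcome"])
        assert np.allclose(h["beta_exposure"], ref["beta_exposure"])


class TestIvw:
    def test_single_instrument_is_wald_ratio(self):
        df = make_instruments(np.array([0.2]), np.array([-0.1]),
                              se_x=0.02, se_y=0.05)
        res = ivw(df)
        assert res.estimate == pytest.approx(-0.5)

    def test_matches_brute_force_objective_minimizer(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.25])
        by = np.array([-4.0, -11.0, -14.0, -21.0, -24.0])
        sy = np.array([1.0, 2.0, 1.5, 1.0, 2.5])
        res = ivw(make_instruments(bx, by, se_y=sy))

        def objective(b):
            return np.sum((by - b * bx) ** 2 / sy**2)

        grid = np.arange(res.estimate - 0.5, res.estimate + 0.5, 1e-4)
        best = grid[np.argmin([objective(b) for b in grid])]
        assert abs(res.estimate - best) <= 1e-4
        assert objective(res.estimate) <= objective(best) + 1e-12

    def test_zero_exposure_beta_excluded_from_q_with_warning(self):
        df = make_instruments(np.array([0.2, 0.0, 0.1, 0.15]),
                              np.array([-1.0, 0.5, -0.4, -0.8]))
        with pytest.warns(UserWarning, match="beta_exposure = 0"):
            res = ivw(df)
        assert np.isfinite(res.q_stat)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 500), flips=st.integers(1, 2**10 - 1))
    def test_joint_sign_flip_invariance(self, seed, flips):
        df, _ = generate_two_sample(TwoSampleSpec(n_snps=10, seed=seed))
        base_ivw = ivw(df).estimate
        base_egger = egger(df).estimate
        mask = np.array([(flips >> j) & 1 for j in range(10)], dtype=bool)
        flipped = df.copy()
        flipped.loc[mask, "beta_exposure"] *= -1
        flipped.loc[mask, "beta_outcome"] *= -1
        assert ivw(flipped).estimate == pytest.approx(base_ivw, rel=1e-10)
        assert egger(flipped).estimate == pytest.approx(base_egger, rel=1e-10)


class TestEgger:
    def test_exact_line_recovered_to_1e10(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.25, 0.3])
        by = 0.1 + 0.5 * bx
        res = egger(make_instruments(bx, by))
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-10)
        assert res.estimate == pytest.approx(0.5, abs=1e-10)

    def test_matches_weighted_normal_equations_oracle(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.25, 0.3])
        by = np.array([-4.0, -11.0, -14.0, -21.0, -24.0, -30.0])
        sy = np.array([1.0, 2.0, 1.5, 1.0, 2.5, 2.0])
        res = egger(make_instruments(bx, by, se_y=sy))
        w = 1.0 / sy**2
        X = np.column_stack([np.ones(6), bx])
        coef = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * by))
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
        assert res.egger_intercept == pytest.approx(coef[0], rel=1e-10)
        assert res.estimate == pytest.approx(coef[1], rel=1e-10)
        assert res.se == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-10)

    def test_too_few_instruments_rejected(self):
        df = make_instruments(np.array([0.1, 0.2]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="3 instruments"):
            egger(df)


class TestPresso:
    def test_observed_rss_matches_direct_leave_one_out_loop(self):
        df, _ = generate_two_sample(TwoSampleSpec(n_snps=6, seed=17))
        res = mr_presso(df, n_simulations=100, seed=0)
        bx = df["beta_exposure"].to_numpy()
        by = df["beta_outcome"].to_numpy()
        w = 1.0 / df["se_outcome"].to_numpy() ** 2
        rss = 0.0
        for j in range(6):
            keep = [i for i in range(6) if i != j]
            b = np.sum(w[keep] * bx[keep] * by[keep]) / np.sum(
                w[keep] * bx[keep] ** 2
            )
            rss += w[j] * (by[j] - b * bx[j]) ** 2
        assert res.rss_observed == pytest.approx(rss, abs=1e-10)

    def test_seed_reproducibility(self):
        df, _ = generate_two_sample(TwoSampleSpec(n_snps=10, seed=23))
        a = mr_presso(df, n_simulations=200, seed=9)
        b = mr_presso(df, n_simulations=200, seed=9)
        assert a.global_p == b.global_p
        assert np.array_equal(a.outlier_p, b.outlier_p)

    def test_planted_outlier_flagged_and_removal_improves_estimate(self):
        spec = TwoSampleSpec(n_snps=21, n_outliers=1,
                             outlier_magnitude=10 * 50.0, seed=77)
        df, truth = generate_two_sample(spec)
        res = mr_presso(df, n_simulations=1000, seed=5)
        assert set(truth.outlier_indices) <= set(res.outlier_indices)
        clean = df.drop(index=list(res.outlier_indices))
        err_all = abs(ivw(df).estimate - truth.causal_effect)
        err_clean = abs(ivw(clean).estimate - truth.causal_effect)
        assert err_clean < err_all
        assert res.distortion_p is not None

    def test_insufficient_instruments_rejected(self):
        df, _ = generate_two_sample(TwoSampleSpec(n_snps=3, seed=1))
        with pytest.raises(ValueError, match="4 instruments"):
            mr_presso(df, n_simulations=100, seed=0)

    def test_degenerate_instruments_rejected(self):
        df = make_instruments(np.full(5, 0.1), np.full(5, 1.0))
        with pytest.raises(ValueError, match="degenerate"):
            mr_presso(df, n_simulations=100, seed=0)

    def test_too_few_simulations_rejected(self):
        df, _ = generate_two_sample(TwoSampleSpec(n_snps=6, seed=2))
        with pytest.raises(ValueError, match="n_simulations"):
            mr_presso(df, n_simulations=50, seed=0)
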