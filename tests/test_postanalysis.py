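"""Correlation post-analysis: pair correlations, analytic null tails,
mapping classes, eGene variance, and the correlation regression."""

import numpy as np
import pandas as pd
import pytest

from isofactor.postanalysis import (
    classify_mapping,
    egene_variance_explained,
    expected_tail_count,
    fit_correlation_model,
    null_tail_fraction,
    pair_correlations,
    sample_control_pairs,
)


class TestPairCorrelations:
    def test_identical_and_negated_columns(self):
        x = np.random.default_rng(0).normal(size=(20, 2))
        tbl = pair_correlations(np.column_stack([x[:, 0], -x[:, 1]]), x).table
        assert tbl["r"].iloc[0] == pytest.approx(1.0)
        assert tbl["r"].iloc[1] == pytest.approx(-1.0)
        assert list(tbl["tail"]) == ["strong_positive", "strong_negative"]

    def test_zero_variance_pair_dropped_with_warning(self):
        I_hat = np.ones((10, 2))
        I_hat[:, 1] = np.arange(10)
        T = np.random.default_rng(1).normal(size=(10, 2))
        with pytest.warns(UserWarning, match="zero-variance"):
            tbl = pair_correlations(I_hat, T).table
        assert len(tbl) == 1

    def test_independent_columns_rarely_exceed_tail(self):
        rng = np.random.default_rng(7)
        n, B = 103, 4000
        I_hat = rng.standard_normal((n, B))
        T = rng.standard_normal((n, B))
        tbl = pair_correlations(I_hat, T).table
        frac = (tbl["r"].abs() > 0.3).mean()
        # analytic tail is ~0.2%; allow 3 binomial SDs
        p = null_tail_fraction(n, 0.3)
        assert frac == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / B))


class TestMappingClasses:
    def test_identity_mask_all_unique(self):
        assert (classify_mapping(np.eye(4)) == "unique").all()

    def test_shared_peptide_marks_both_ambiguous(self):
        mask = np.array([[1, 1, 0], [0, 1, 1], [0, 0, 1]])
        np.testing.assert_array_equal(
            classify_mapping(mask), ["ambiguous", "ambiguous", "ambiguous"]
        )

    def test_matches_column_sum_oracle(self, rng):
        for _ in range(20):
            mask = (rng.uniform(size=(15, 25)) < 0.15).astype(int)
            got = classify_mapping(mask)
            shared = mask.sum(axis=0) >= 2
            expected = np.where(
                (mask * shared).sum(axis=1) > 0, "ambiguous", "unique"
            )
            np.testing.assert_array_equal(got, expected)

    def test_classes_partition_isoforms(self, rng):
        mask = (rng.uniform(size=(12, 20)) < 0.2).astype(int)
        classes = classify_mapping(mask)
        assert (classes == "unique").sum() + (classes == "ambiguous").sum() == 12


class TestNullTail:
    def test_matches_printed_value_at_reference_size(self):
        # n=103, |r| > 0.30 -> 0.2% to one decimal
        assert 100 * null_tail_fraction(103, 0.30) == pytest.approx(0.2, abs=0.05)

    def test_threshold_to_zero_exhausts_probability(self):
        assert null_tail_fraction(103, 1e-9) == pytest.approx(1.0)

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(11)
        n, B = 103, 200_000
        x = rng.standard_normal((B, n))
        y = rng.standard_normal((B, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        mc = (np.abs(r) > 0.30).mean()
        p = null_tail_fraction(103, 0.30)
        assert p == pytest.approx(mc, abs=3 * np.sqrt(mc * (1 - mc) / B))

    def test_strictly_decreasing_in_n_and_threshold(self):
        assert null_tail_fraction(103, 0.3) < null_tail_fraction(50, 0.3)
        assert null_tail_fraction(103, 0.4) < null_tail_fraction(103, 0.3)

    def test_expected_count_at_reference_size(self):
        # 7107 pairs at n=103: about 7 per tail
        assert expected_tail_count(7107, 103, 0.30) == pytest.approx(7.0, abs=1.0)

    def test_expected_count_linear_in_pairs(self):
        assert expected_tail_count(0, 103, 0.3) == 0.0
        assert expected_tail_count(2 * 7107, 103, 0.3) == pytest.approx(
            2 * expected_tail_count(7107, 103, 0.3)
        )


class TestEgeneVariance:
    @pytest.mark.parametrize(
        "f, b, expected", [(0.5, 1.0, 0.5), (0.0, 3.0, 0.0), (0.2, 2.0, 1.28)]
    )
    def test_direct_arithmetic(self, f, b, expected):
        assert egene_variance_explained(f, b) == pytest.approx(expected)

    def test_frequency_out_of_range_errors(self):
        with pytest.raises(ValueError):
            egene_variance_explained(1.2, 1.0)


class TestCorrelationRegression:
    def _predictors(self, n, rng):
        return pd.DataFrame(
            rng.standard_normal((n, 5)),
            columns=["d_iso", "d_tx", "age_iso", "age_tx", "egene_var"],
        )

    def test_exact_linear_outcome_gives_unit_r2(self, rng):
        X = self._predictors(40, rng)
        y = 0.5 + X @ np.array([1.0, -2.0, 0.3, 0.0, 1.5])
        fit = fit_correlation_model(y, X)
        assert fit.rsquared == pytest.approx(1.0)

    def test_independent_outcome_gives_near_zero_r2(self, rng):
        X = self._predictors(4000, rng)
        fit = fit_correlation_model(rng.standard_normal(4000), X)
        assert fit.rsquared < 0.01

    def test_matches_hand_solved_normal_equations(self):
        # two predictors, normal equations solved by hand:
        # X = [[1,0],[0,1],[1,1]] (+ intercept), y = [1, 2, 3.5]
        X = pd.DataFrame({"a": [1.0, 0.0, 1.0], "b": [0.0, 1.0, 1.0]})
        y = np.array([1.0, 2.0, 3.5])
        fit = fit_correlation_model(y, X)
        design = np.column_stack([np.ones(3), X.to_numpy()])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_collinear_predictors_named(self, rng):
        X = self._predictors(30, rng)
        X["dup"] = X["d_iso"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            fit_correlation_model(rng.standard_normal(30), X)

    def test_control_pair_sampling_is_seeded_and_bounded(self, rng):
        table = pd.DataFrame({"r": rng.uniform(-0.2, 0.2, 500)})
        out1 = sample_control_pairs(table, 50, np.random.default_rng(3))
        out2 = sample_control_pairs(table, 50, np.random.default_rng(3))
        pd.testing.assert_frame_equal(out1, out2)
        assert (out1["r"].abs() < 0.05).all()


class TestFullPipelineNullTail:
    def test_null_pair_tail_fraction_matches_analytic(self):
        """When transcripts carry no information (W=0) and the fit is
        unsupervised, estimated abundances are independent of the
        transcripts and the strong-positive pair fraction stays at the
        analytic null rate. (A supervised fit leaks the sampled conversion
        weight into the estimate and widens the null; see the methods
        notes.)"""
        from isofactor.model import IsoformAbundanceModel
        from isofactor.simulate import ScenarioConfig, simulate_difficult

        rs = []
        for seed in range(6):
            sim = simulate_difficult(
                ScenarioConfig(
                    scenario="difficult", n=103, effect=0.0, seed=seed,
                    misspecify_w_zero=True,
                )
            )
            model = IsoformAbundanceModel(
                P=sim.data.P, mask=sim.data.mask, T=None, A=sim.data.A,
                bounds="data-abs",
            )
            res = model.fit(n_iter=1200, burn_in=700, n_chains=1, seed=seed)
            tbl = pair_correlations(res.isoform_abundance, sim.data.T).table
            rs.extend(tbl["r"].tolist())
        rs = np.asarray(rs)
        frac_pos = (rs > 0.3).mean()
        p_half = null_tail_fraction(103, 0.3) / 2
        sd = np.sqrt(p_half * (1 - p_half) / rs.size)
        assert frac_pos <= p_half + 3 * sd + 1e-9
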