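"""Boosting engine: design blocks, df-matched ridge penalties, base-learner
closed form, and equivalence with a naive dense reference loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lizonc import boosting, summaries
from lizonc.boosting import BoostHyperparams, DesignBlock

from _reference import lambda_for_df, naive_boost, random_instance


def _block(codes, n_levels, name="v"):
    levels = tuple(f"L{i}" for i in range(n_levels))
    return DesignBlock(name, levels, np.asarray(codes, dtype=np.intp))


class TestDesign:
    def test_blocks_cover_every_record_once(self, escra_cohort):
        blocks = boosting.build_design(escra_cohort)
        for b in blocks:
            Z = b.indicator()
            assert Z.shape == (len(escra_cohort), b.n_levels)
            np.testing.assert_array_equal(Z.sum(axis=1), 1.0)
            np.testing.assert_array_equal(Z.sum(axis=0), b.counts)

    def test_column_sums_match_frequency_table(self, escra_cohort):
        blocks = {b.variable: b for b in boosting.build_design(escra_cohort)}
        table = summaries.frequency_table(escra_cohort, "treatment")
        counts = dict(zip(table["level"], table["count"]))
        b = blocks["treatment"]
        for level, c in zip(b.levels, b.counts):
            assert counts.get(level, 0) == c

    def test_unknown_variable_rejected(self, escra_cohort):
        with pytest.raises(KeyError):
            boosting.build_design(escra_cohort, ["not_a_field"])


class TestRidgeLambda:
    def test_full_df_means_no_penalty(self):
        b = _block([0, 1, 2, 0, 1], 3)
        assert boosting.ridge_lambda_for_df(b, 3) == 0.0

    def test_balanced_block_eigen_oracle(self):
        # 4 levels x 10 records each: trace = 4*10/(10+lam) = 2 => lam = 10
        b = _block(np.repeat(np.arange(4), 10), 4)
        lam = boosting.ridge_lambda_for_df(b, 2.0)
        assert lam == pytest.approx(10.0, abs=1e-6)

    def test_matches_dense_hat_trace(self, rng):
        codes, Ls, _ = random_instance(rng, n_max=30, max_blocks=1)
        b = _block(codes[0], Ls[0])
        for df in (1.0, 1.7, Ls[0] - 0.5):
            lam = boosting.ridge_lambda_for_df(b, df)
            ref = lambda_for_df(b.indicator(), df)
            assert lam == pytest.approx(ref, abs=1e-6)

    def test_trace_decreases_with_lambda(self, rng):
        b = _block(rng.integers(0, 4, 40), 4)
        counts = b.counts.astype(float)
        traces = [np.sum(counts / (counts + lam)) for lam in (0.0, 1.0, 10.0, 1e6)]
        assert all(a > b_ for a, b_ in zip(traces, traces[1:]))
        assert traces[-1] < 1e-3

    def test_df_beyond_rank_rejected(self):
        b = _block([0, 1, 0, 1], 2)
        with pytest.raises(ValueError):
            boosting.ridge_lambda_for_df(b, 2.5)


class TestBaseLearner:
    def test_unpenalized_balanced_gives_level_means(self):
        b = _block([0, 0, 1, 1], 2)
        r = np.array([1.0, 3.0, 10.0, 20.0])
        coef, rss = boosting.fit_base_learner(b, r, 0.0)
        np.testing.assert_allclose(coef, [2.0, 15.0])
        assert rss == pytest.approx(2.0 + 50.0)

    def test_zero_residuals(self):
        b = _block([0, 1, 2], 3)
        coef, rss = boosting.fit_base_learner(b, np.zeros(3), 1.0)
        np.testing.assert_array_equal(coef, 0.0)
        assert rss == 0.0

    def test_matches_dense_solve(self, rng):
        b = _block(rng.integers(0, 2, 6), 2)
        r = rng.normal(size=6)
        lam = 0.7
        coef, rss = boosting.fit_base_learner(b, r, lam)
        Z = b.indicator()
        ref = np.linalg.solve(Z.T @ Z + lam * np.eye(2), Z.T @ r)
        np.testing.assert_allclose(coef, ref, atol=1e-10)
        assert rss == pytest.approx(float(np.sum((r - Z @ ref) ** 2)), abs=1e-10)


class TestFitBoost:
    def test_mstop_zero(self):
        b = _block([0, 1, 0, 1], 2)
        y = np.array([0.0, 1.0, 1.0, 1.0])
        fit = boosting.fit_boost([b], y, BoostHyperparams(mstop=0))
        assert fit.intercept == pytest.approx(0.75)
        np.testing.assert_array_equal(fit.coefficients["v"], 0.0)
        assert fit.selection_path == []

    def test_constant_outcome_gives_zero_effects(self):
        b = _block([0, 1, 2, 0, 1, 2], 3)
        fit = boosting.fit_boost([b], np.ones(6), BoostHyperparams(mstop=50))
        np.testing.assert_array_equal(fit.coefficients["v"], 0.0)
        assert fit.loss_trace[-1] == 0.0

    def test_loss_trace_non_increasing(self, rng):
        codes, Ls, y = random_instance(rng)
        blocks = [_block(c, L, f"v{j}") for j, (c, L) in enumerate(zip(codes, Ls))]
        fit = boosting.fit_boost(blocks, y, BoostHyperparams(mstop=60, df=2))
        assert np.all(np.diff(fit.loss_trace) <= 1e-12)

    @settings(deadline=None, max_examples=12, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_naive_reference(self, seed):
        """Property: the closed-form engine reproduces a literal dense loop."""
        rng = np.random.default_rng(seed)
        codes, Ls, y = random_instance(rng)
        blocks = [_block(c, L, f"v{j}") for j, (c, L) in enumerate(zip(codes, Ls))]
        hp = BoostHyperparams(mstop=25, nu=0.1, df=2.0)
        fit = boosting.fit_boost(blocks, y, hp)
        _, ref_coefs, ref_path = naive_boost(
            [b.indicator() for b in blocks], y, hp.mstop, hp.nu, hp.df)
        assert fit.selection_path == [f"v{j}" for j in ref_path]
        for b, ref in zip(blocks, ref_coefs):
            np.testing.assert_allclose(fit.coefficients[b.variable], ref, atol=1e-10)

    def test_single_block_converges_to_level_means(self, rng):
        codes = np.concatenate([np.arange(3), rng.integers(0, 3, 27)])
        y = rng.integers(0, 2, 30).astype(float)
        b = _block(codes, 3)
        fit = boosting.fit_boost([b], y, BoostHyperparams(mstop=5000, nu=0.1, df=3))
        centered = y - y.mean()
        target = [centered[codes == k].mean() for k in range(3)]
        np.testing.assert_allclose(fit.coefficients["v"], target, atol=1e-3)

    def test_effects_continuous_in_nu(self, rng):
        codes, Ls, y = random_instance(rng)
        blocks = [_block(c, L, f"v{j}") for j, (c, L) in enumerate(zip(codes, Ls))]
        fits = [boosting.fit_boost(blocks, y, BoostHyperparams(mstop=40, nu=nu, df=2))
                for nu in (0.1, 0.1001)]
        for b in blocks:
            diff = np.abs(fits[0].coefficients[b.variable]
                          - fits[1].coefficients[b.variable]).max()
            assert diff < 0.05

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            boosting.fit_boost([], np.array([1.0]))


class TestMultiFit:
    def test_columns_match_independent_single_fits(self, rng):
        codes, Ls, _ = random_instance(rng)
        blocks = [_block(c, L, f"v{j}") for j, (c, L) in enumerate(zip(codes, Ls))]
        n = blocks[0].n_records
        Y = rng.integers(0, 2, (n, 6)).astype(float)
        hp = BoostHyperparams(mstop=30, nu=0.2, df=2.0)
        multi = boosting.fit_boost_multi(blocks, Y, hp)
        for col in range(Y.shape[1]):
            single = boosting.fit_boost(blocks, Y[:, col], hp)
            for b in blocks:
                np.testing.assert_allclose(
                    multi[b.variable][:, col], single.coefficients[b.variable],
                    atol=1e-12)


class TestPredictAndEffects:
    def test_mstop_zero_predicts_mean(self):
        b = _block([0, 1, 0], 2)
        y = np.array([0.0, 1.0, 1.0])
        fit = boosting.fit_boost([b], y, BoostHyperparams(mstop=0))
        np.testing.assert_allclose(boosting.predict(fit, [b]), y.mean())

    def test_fitted_rss_equals_last_loss(self, rng):
        codes, Ls, y = random_instance(rng)
        blocks = [_block(c, L, f"v{j}") for j, (c, L) in enumerate(zip(codes, Ls))]
        fit = boosting.fit_boost(blocks, y, BoostHyperparams(mstop=30, df=2))
        rss = float(np.sum((y - boosting.predict(fit, blocks)) ** 2))
        assert rss == pytest.approx(fit.loss_trace[-1], abs=1e-10)

    def test_unseen_level_is_named(self):
        b = _block([0, 1], 2)
        fit = boosting.fit_boost([b], np.array([0.0, 1.0]),
                                 BoostHyperparams(mstop=5, df=1))
        new = DesignBlock("v", ("L0", "L9"), np.array([0, 1]))
        with pytest.raises(KeyError, match="L9"):
            boosting.predict(fit, [new])

    def test_separated_levels_get_opposite_signs(self):
        codes = np.array([0] * 10 + [1] * 10)
        y = np.array([1.0] * 10 + [0.0] * 10)
        b = _block(codes, 2)
        fit = boosting.fit_boost([b], y, BoostHyperparams(mstop=200, df=1))
        table = boosting.extract_effects(fit, [b])
        eff = dict(zip(table["level"], table["effect"]))
        assert eff["L0"] > 0 > eff["L1"]
        assert dict(zip(table["level"], table["n"])) == {"L0": 10, "L1": 10}

    def test_sample_weighted_effects_sum_to_zero_single_block(self, rng):
        codes = np.concatenate([np.arange(4), rng.integers(0, 4, 36)])
        y = rng.integers(0, 2, 40).astype(float)
        b = _block(codes, 4)
        fit = boosting.fit_boost([b], y, BoostHyperparams(mstop=100, df=4))
        weighted = float(np.sum(b.counts * fit.coefficients["v"]))
        assert weighted == pytest.approx(0.0, abs=1e-10)
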