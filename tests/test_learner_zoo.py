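"""Tests for hyperparameter sampling, CV tuning, one-SE selection, evaluation."""

import numpy as np
import pytest

from specstack.learner_zoo import (CandidateModel, CVSpec, PrepConfig,
                                   candidate_from_dict, candidate_to_dict,
                                   finalize_and_evaluate, rmse_r2,
                                   sample_space, select_one_se, tune)
from specstack.preprocess import fit_preprocess, transform
from specstack.synthetic_leaf import SyntheticConfig, generate_dataset

SMALL_CV = CVSpec(folds=3, repeats=1, seed=5)
# narrow latent-dimension search keeps small-n tuning fast and well-posed
SMALL_BOUNDS = {"num_comp": (2, 12)}


@pytest.fixture(scope="module")
def linear_ds():
    cfg = SyntheticConfig(n=120, seed=21)
    ds, _ = generate_dataset(cfg)
    return ds.take(range(90)), ds.take(range(90, 120))


class TestSampleSpace:
    def test_plsr_integer_grid_in_bounds(self):
        cfgs = sample_space("pls", budget=20, seed=0)
        assert len(cfgs) == 20
        vals = [c["num_comp"] for c in cfgs]
        assert all(isinstance(v, int) and 2 <= v <= 120 for v in vals)

    def test_budget_one_midpoint(self):
        (cfg,) = sample_space("xgb", budget=1, seed=0)
        assert cfg["depth"] == round((3 + 8) / 2)
        # log-scaled dims use the geometric midpoint
        lo, hi = 10**-3.5, 10**-1.0
        assert cfg["learning_rate"] == pytest.approx(np.sqrt(lo * hi))

    def test_deterministic_under_seed(self):
        a = sample_space("lgbm", budget=8, seed=3)
        b = sample_space("lgbm", budget=8, seed=3)
        assert a == b
        c = sample_space("lgbm", budget=8, seed=4)
        assert a != c

    @pytest.mark.parametrize("family", ["pcr", "pls", "enet", "rf", "xgb",
                                        "lgbm", "gpr"])
    def test_all_samples_inside_printed_bounds(self, family):
        from specstack.learner_zoo import _BOUNDS
        for cfg in sample_space(family, budget=15, seed=1):
            for k, v in cfg.items():
                lo, hi = _BOUNDS[family][k]
                assert lo - 1e-12 <= v <= hi + 1e-12, (family, k, v)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown family"):
            sample_space("svr", budget=5, seed=0)

    def test_gpr_stage1_pins_sigma_at_log_midpoint(self):
        cfgs = sample_space("gpr", budget=5, seed=0)
        sigmas = sorted({c["sigma"] for c in cfgs})
        assert sigmas == [pytest.approx(np.sqrt(1e-3 * 10.0))]


class TestSelectOneSE:
    def _cand(self, mean, se, num_comp):
        return CandidateModel(family="pcr", params={"num_comp": num_comp},
                              cv_rmse_mean=mean, cv_rmse_se=se)

    def test_single_candidate(self):
        c = self._cand(2.0, 0.1, 5)
        assert select_one_se([c]) is c

    def test_simpler_within_one_se_preferred(self):
        a = self._cand(2.00, 0.10, 50)
        b = self._cand(2.05, 0.10, 10)  # simpler, within 2.10
        c = self._cand(2.30, 0.10, 5)   # simplest but outside the band
        assert select_one_se([a, b, c]) is b

    def test_equal_means_pick_simplest(self):
        cands = [self._cand(2.0, 0.1, k) for k in (30, 10, 20)]
        assert select_one_se(cands).params["num_comp"] == 10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_one_se([])


class TestMetrics:
    def test_hand_arithmetic(self):
        mp = rmse_r2(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]))
        assert mp.rmse == pytest.approx(np.sqrt(1 / 3))
        assert mp.r2 == pytest.approx(0.5)

    def test_perfect_and_constant(self):
        y = np.array([1.0, 2, 3, 4])
        assert rmse_r2(y, y).rmse == 0
        assert rmse_r2(y, y).r2 == 1
        assert rmse_r2(y, np.full(4, y.mean())).r2 == pytest.approx(0)


class TestTune:
    def test_fold_cover_property(self, linear_ds):
        train, _ = linear_ds
        cv = CVSpec(folds=4, repeats=2, seed=9)
        cands = tune("pcr", train, cv=cv, budget=2, bounds=SMALL_BOUNDS)
        for c in cands:
            assert c.oof_by_repeat.shape == (2, train.n)
            assert np.all(np.isfinite(c.oof_by_repeat))  # every sample once/repeat

    def test_candidates_sorted_and_ids_assigned(self, linear_ds):
        train, _ = linear_ds
        cands = tune("pcr", train, cv=SMALL_CV, budget=4, bounds=SMALL_BOUNDS)
        means = [c.cv_rmse_mean for c in cands]
        assert means == sorted(means)
        assert [c.candidate_id for c in cands] == \
            [f"pcr_{i}" for i in range(1, len(cands) + 1)]

    def test_two_fold_manual_cv_oracle(self):
        """Held-out predictions match a hand-rolled two-split OLS oracle."""
        rng = np.random.default_rng(10)
        cfg = SyntheticConfig(n=6, seed=30, mult_noise_sd=0.0,
                              add_noise_sd=0.0, baseline_wiggle_sd=0.0)
        ds, _ = generate_dataset(cfg)
        cv = CVSpec(folds=2, repeats=1, seed=17)
        cands = tune("pcr", ds, cv=cv, budget=1, bounds={"num_comp": (1, 1)})
        cand = cands[0]
        # oracle: reproduce the same folds and fit OLS on 1 PCA score
        from sklearn.model_selection import RepeatedKFold
        rkf = RepeatedKFold(n_splits=2, n_repeats=1, random_state=17)
        oof = np.full(6, np.nan)
        for tr_idx, va_idx in rkf.split(np.arange(6)):
            pm = fit_preprocess(ds.X[tr_idx], ds.spectra.grid)
            s_tr = transform(pm, ds.X[tr_idx], K=1)
            s_va = transform(pm, ds.X[va_idx], K=1)
            A = np.column_stack([np.ones(len(tr_idx)), s_tr[:, 0]])
            beta, *_ = np.linalg.lstsq(A, ds.y[tr_idx], rcond=None)
            oof[va_idx] = beta[0] + beta[1] * s_va[:, 0]
        np.testing.assert_allclose(cand.oof, oof, atol=1e-8)

    def test_pls_noise_free_linear_data_fits_exactly(self):
        cfg = SyntheticConfig(n=60, seed=31, water_noise_sd=0.0,
                              mult_noise_sd=0.0, add_noise_sd=0.0,
                              baseline_wiggle_sd=0.0)
        ds, _ = generate_dataset(cfg)
        cands = tune("pls", ds, cv=CVSpec(folds=3, repeats=1, seed=1),
                     budget=3, bounds={"num_comp": (2, 10)})
        assert cands[0].cv_rmse_mean <= 1e-6

    def test_null_mode_rmse_floor(self):
        cfg = SyntheticConfig(n=100, seed=32, mode="null")
        ds, _ = generate_dataset(cfg)
        sd = np.std(ds.y, ddof=1)
        cands = tune("pcr", ds, cv=CVSpec(folds=4, repeats=1, seed=2),
                     budget=3, bounds=SMALL_BOUNDS)
        for c in cands:
            assert c.cv_rmse_mean >= 0.9 * sd

    def test_pcr_equals_ols_on_scores(self, linear_ds):
        """PCR prediction == OLS on the first K PCA scores (equivalence)."""
        train, test = linear_ds
        cands = tune("pcr", train, cv=SMALL_CV, budget=1,
                     bounds={"num_comp": (5, 5)})
        mp = finalize_and_evaluate(cands[0], train, test)
        pm = fit_preprocess(train.X, train.spectra.grid)
        s_tr = transform(pm, train.X, K=5)
        s_te = transform(pm, test.X, K=5)
        A = np.column_stack([np.ones(train.n), s_tr])
        beta, *_ = np.linalg.lstsq(A, train.y, rcond=None)
        pred = beta[0] + s_te @ beta[1:]
        oracle = rmse_r2(test.y, pred)
        assert mp.rmse == pytest.approx(oracle.rmse, abs=1e-8)

    def test_gpr_two_stage_adds_sigma_search(self, linear_ds):
        train, _ = linear_ds
        cands = tune("gpr", train, cv=SMALL_CV, budget=3,
                     bounds={"num_comp": (2, 10)})
        sigmas = {c.params["sigma"] for c in cands}
        assert len(sigmas) > 1  # stage 2 explored the bandwidth

    def test_execution_order_independence(self, linear_ds):
        """Identical CV spec => identical candidate metrics across calls."""
        train, _ = linear_ds
        a = tune("pcr", train, cv=SMALL_CV, budget=3, bounds=SMALL_BOUNDS)
        b = tune("pcr", train, cv=SMALL_CV, budget=3, bounds=SMALL_BOUNDS)
        for ca, cb in zip(a, b):
            assert ca.params == cb.params
            assert ca.cv_rmse_mean == cb.cv_rmse_mean
            np.testing.assert_array_equal(ca.oof_by_repeat, cb.oof_by_repeat)


class TestFinalize:
    def test_test_too_small_rejected(self, linear_ds):
        train, test = linear_ds
        cands = tune("pcr", train, cv=SMALL_CV, budget=1, bounds=SMALL_BOUNDS)
        with pytest.raises(ValueError):
            finalize_and_evaluate(cands[0], train, test.take([0]))

    def test_serialization_round_trip(self, linear_ds):
        train, _ = linear_ds
        c = tune("pcr", train, cv=SMALL_CV, budget=2, bounds=SMALL_BOUNDS)[0]
        back = candidate_from_dict(candidate_to_dict(c))
        assert back.params == c.params
        assert back.cv_provenance == c.cv_provenance
        np.testing.assert_array_equal(back.oof_by_repeat, c.oof_by_repeat)
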