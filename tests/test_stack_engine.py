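"""Tests for OOF assembly and the non-negative LASSO meta-learner."""

import numpy as np
import pytest
from scipy.optimize import nnls

from specstack.learner_zoo import CandidateModel, CVSpec
from specstack.stack_engine import (OOFMatrix, assemble_oof, blend,
                                    build_candidate_library, finalize_stack,
                                    predict_stack, report_weights)
from specstack.synthetic_leaf import SyntheticConfig, generate_dataset


def pg_oracle(X, y, lam=0.0, iters=500_000, lr=None):
    """Independent projected-gradient solver for the meta-fit QP.

    min_{w>=0, b} (1/2n)||y - b - Xw||^2 + lam * sum(w)
    """
    n, p = X.shape
    w = np.zeros(p)
    b = y.mean()
    if lr is None:
        lr = 0.9 * n / (np.linalg.norm(X, 2) ** 2 + n)
    for _ in range(iters):
        r = y - b - X @ w
        gw = -X.T @ r / n + lam
        gb = -r.mean()
        w_new = np.maximum(0.0, w - lr * gw)
        b_new = b - lr * gb
        if max(np.max(np.abs(w_new - w)), abs(b_new - b)) < 1e-12:
            w, b = w_new, b_new
            break
        w, b = w_new, b_new
    return w, b


def make_candidate(family, oof_rep, cv, cid=""):
    return CandidateModel(family=family, params={"num_comp": 5},
                          cv_rmse_mean=1.0, cv_rmse_se=0.1,
                          oof_by_repeat=np.asarray(oof_rep, float),
                          cv_provenance=(cv.folds, cv.repeats, cv.seed),
                          candidate_id=cid)


class TestLibrary:
    def _cands(self, family, means):
        out = []
        for m in means:
            c = CandidateModel(family=family, params={"num_comp": int(m * 10)},
                               cv_rmse_mean=m, cv_rmse_se=0.1)
            out.append(c)
        return out

    def test_top_m_per_family_and_ids(self):
        results = {"gpr": self._cands("gpr", [2.0, 1.5, 3.0]),
                   "pcr": self._cands("pcr", [1.8])}
        lib = build_candidate_library(results, top_m=2)
        assert [c.candidate_id for c in lib] == ["gpr_1", "gpr_2", "pcr_1"]
        assert lib[0].cv_rmse_mean == 1.5  # ranked by CV RMSE

    def test_short_family_not_padded(self):
        results = {"pls": self._cands("pls", [1.0, 2.0])}
        assert len(build_candidate_library(results, top_m=20)) == 2

    def test_failed_family_skipped_with_warning(self):
        bad = CandidateModel(family="rf", params={}, failed=True)
        with pytest.warns(UserWarning, match="skipped"):
            lib = build_candidate_library({"rf": [bad],
                                           "pls": self._cands("pls", [1.0])},
                                          top_m=3)
        assert [c.family for c in lib] == ["pls"]


class TestAssembleOOF:
    def test_fold_mean_candidate_oracle(self):
        """Candidate predicting its training-fold mean: verify by hand."""
        cv = CVSpec(folds=2, repeats=1, seed=3)
        y = np.array([1.0, 2, 3, 4, 5, 6])
        from sklearn.model_selection import RepeatedKFold
        rkf = RepeatedKFold(n_splits=2, n_repeats=1, random_state=3)
        oof = np.full((1, 6), np.nan)
        for tr, va in rkf.split(np.arange(6)):
            oof[0, va] = y[tr].mean()
        cand = make_candidate("pcr", oof, cv, "pcr_1")
        mat = assemble_oof([cand], cv, [f"s{i}" for i in range(6)])
        np.testing.assert_allclose(mat.values[:, 0], oof[0])

    def test_repeat_averaging_idempotent_for_identical_repeats(self):
        cv = CVSpec(folds=2, repeats=3, seed=0)
        row = np.arange(6.0)
        cand = make_candidate("pcr", np.tile(row, (3, 1)), cv, "pcr_1")
        mat = assemble_oof([cand], cv, [f"s{i}" for i in range(6)])
        np.testing.assert_array_equal(mat.values[:, 0], row)

    def test_provenance_mismatch_is_hard_error(self):
        cv = CVSpec(folds=2, repeats=1, seed=0)
        other = CVSpec(folds=2, repeats=1, seed=1)
        good = make_candidate("pcr", np.zeros((1, 4)), cv, "pcr_1")
        bad = make_candidate("pls", np.zeros((1, 4)), other, "pls_1")
        with pytest.raises(ValueError, match="provenance"):
            assemble_oof([good, bad], cv, [f"s{i}" for i in range(4)])

    def test_constant_zero_candidate(self):
        cv = CVSpec(folds=2, repeats=2, seed=0)
        cand = make_candidate("pcr", np.zeros((2, 4)), cv, "pcr_1")
        mat = assemble_oof([cand], cv, [f"s{i}" for i in range(4)])
        np.testing.assert_array_equal(mat.values, 0)


class TestBlend:
    def test_exact_member_recovered(self):
        y = np.array([1.0, 2, 3, 4, 5])
        w, b = blend(y[:, None], y, lam=1e-6)
        assert w[0] == pytest.approx(1.0, abs=1e-4)
        assert b == pytest.approx(0.0, abs=1e-3)

    def test_anticorrelated_column_gets_zero_weight(self):
        y = np.array([1.0, 2, 3, 4, 5])
        X = (-y)[:, None]
        w, b = blend(X, y, lam=1e-6)
        assert w[0] == 0.0
        assert b == pytest.approx(y.mean(), abs=1e-6)

    def test_two_column_qp_oracle(self):
        y = np.array([1.0, 2, 3, 4])
        X = np.column_stack([[1.1, 1.9, 3.2, 3.8], [0.9, 2.1, 2.8, 4.2]])
        w, b = blend(X, y, lam=1e-6)
        w_o, b_o = pg_oracle(X, y, lam=1e-6)
        np.testing.assert_allclose(w, w_o, atol=1e-4)
        assert b == pytest.approx(b_o, abs=1e-4)

    def test_lambda_zero_matches_scipy_nnls(self):
        """At lam=0 with centered data the solution is plain NNLS."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            n, p = 40, 4
            X = rng.normal(size=(n, p)) + 2
            y = X @ rng.uniform(0, 1, p) + rng.normal(0, 0.1, n)
            w, b = blend(X, y, lam=0.0)
            # oracle: NNLS on column-centered X, intercept recovered after
            Xc = X - X.mean(axis=0)
            w_o, _ = nnls(Xc, y - y.mean())
            np.testing.assert_allclose(w, w_o, atol=1e-6)
            assert b == pytest.approx(y.mean() - X.mean(axis=0) @ w_o, abs=1e-6)

    def test_large_lambda_shuts_all_weights_off(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 30)
        w, b = blend(X, y, lam=1e6)
        np.testing.assert_array_equal(w, 0)
        assert b == pytest.approx(y.mean())

    def test_non_negativity_always(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(10, 50)
            p = rng.integers(1, 6)
            X = rng.normal(size=(n, p)) * rng.uniform(0.1, 5)
            y = rng.normal(size=n) * 10
            w, _ = blend(X, y, lam=1e-6)
            assert np.all(w >= 0)

    def test_meta_fit_dominance(self):
        """Blend RMSE on its own design <= best single column + intercept."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            n, p = 50, 5
            X = rng.normal(size=(n, p)) + rng.uniform(-2, 2, p)
            y = X @ rng.uniform(0, 1, p) + rng.normal(0, 0.5, n)
            w, b = blend(X, y, lam=1e-6)
            blend_rmse = np.sqrt(np.mean((y - b - X @ w) ** 2))
            singles = []
            for j in range(p):
                wj, bj = blend(X[:, [j]], y, lam=1e-6)
                singles.append(np.sqrt(np.mean((y - bj - X[:, [j]] @ wj) ** 2)))
            assert blend_rmse <= min(singles) + 1e-6

    def test_duplicate_columns_deterministic(self):
        y = np.array([1.0, 2, 3, 4, 5])
        X = np.column_stack([y, y])
        w1, b1 = blend(X, y, lam=1e-6)
        w2, b2 = blend(X, y, lam=1e-6)
        np.testing.assert_array_equal(w1, w2)
        assert w1.sum() == pytest.approx(1.0, abs=1e-4)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            blend(np.ones((3, 1)), np.ones(3), lam=-1.0)


class TestFinalizeAndReport:
    @pytest.fixture(scope="class")
    def small_stack(self):
        from specstack.learner_zoo import PrepConfig, tune
        cfg = SyntheticConfig(n=90, seed=40)
        ds, _ = generate_dataset(cfg)
        train, test = ds.take(range(70)), ds.take(range(70, 90))
        cv = CVSpec(folds=3, repeats=1, seed=4)
        results = {f: tune(f, train, cv=cv, budget=2,
                           bounds={"num_comp": (2, 8)}) for f in ("pcr", "pls")}
        lib = build_candidate_library(results, top_m=2)
        oof = assemble_oof(lib, cv, train.spectra.sample_ids)
        w, b = blend(oof, train.y)
        stack = finalize_stack(w, b, lib, train, PrepConfig())
        return stack, lib, w, b, train, test

    def test_single_member_stack_equals_member(self, small_stack):
        stack, lib, w, b, train, test = small_stack
        member = stack.members[0]
        solo = finalize_stack(np.array([1.0]), 0.0, [member], train)
        np.testing.assert_allclose(predict_stack(solo, test.X),
                                   member.predict(test.X), atol=1e-10)

    def test_prediction_linearity(self, small_stack):
        stack, *_ , test = small_stack
        preds = predict_stack(stack, test.X)
        manual = np.full(test.n, stack.intercept)
        for wc, m in zip(stack.weights, stack.members):
            manual += wc * m.predict(test.X)
        np.testing.assert_allclose(preds, manual, atol=1e-12)

    def test_all_zero_weights_rejected(self, small_stack):
        _, lib, *_ , train, _ = small_stack
        with pytest.raises(ValueError, match="no members"):
            finalize_stack(np.zeros(len(lib)), 0.0, lib, train)

    def test_report_aggregates_match_member_sums(self, small_stack):
        stack, *_ = small_stack
        rep = report_weights(stack)
        # independent group-sum oracle over the member table
        manual = {}
        for _, row in rep.members.iterrows():
            manual[row["Family"]] = manual.get(row["Family"], 0.0) + row["Weight"]
        for _, row in rep.family_totals.iterrows():
            assert row["Weight"] == pytest.approx(manual[row["Family"]], abs=1e-12)
        assert rep.members["Weight"].min() > 0

    def test_stack_reproducible_under_seed(self):
        from specstack.learner_zoo import PrepConfig, tune
        cfg = SyntheticConfig(n=60, seed=41)
        ds, _ = generate_dataset(cfg)
        cv = CVSpec(folds=3, repeats=1, seed=11)
        outs = []
        for _ in range(2):
            res = {"pcr": tune("pcr", ds, cv=cv, budget=2,
                               bounds={"num_comp": (2, 6)})}
            lib = build_candidate_library(res, top_m=2)
            oof = assemble_oof(lib, cv, ds.spectra.sample_ids)
            outs.append(blend(oof, ds.y))
        np.testing.assert_array_equal(outs[0][0], outs[1][0])
        assert outs[0][1] == outs[1][1]
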