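"""Tangent featurization, LDA, multi-target shrinkage and pipelines."""

import itertools

import numpy as np
import pandas as pd
import pytest

from screenfree_bci.data import EventSchedule
from screenfree_bci.decoding import (
    featurize,
    fit_lda,
    fit_pipeline,
    mts_components,
    mts_objective,
    mts_shrunk_mean,
    mts_weights,
    predict_window_scores,
    select_object,
)
from screenfree_bci.evaluation import auc
from screenfree_bci.geometry import frechet_mean
from conftest import random_spd


class TestFeaturize:
    def test_vector_length_and_pooled_centering(self, rng):
        covs = np.stack([random_spd(rng, 8) for _ in range(15)])
        ref = frechet_mean(list(covs), tol=1e-10)
        vecs = featurize(covs, ref, mode="pooled")
        assert vecs.shape == (15, 36)
        # stationarity of the Fréchet mean: tangent vectors sum to zero
        assert np.abs(vecs.sum(axis=0)).max() < 1e-5

    def test_per_subclass_centering(self, rng):
        covs = np.stack([random_spd(rng, 4) for _ in range(20)])
        sub = np.repeat([1, 2], 10)
        refs = {j: frechet_mean(list(covs[sub == j]), tol=1e-10) for j in (1, 2)}
        vecs = featurize(covs, refs, subclass_labels=sub, mode="per_subclass_centered")
        for j in (1, 2):
            assert np.abs(vecs[sub == j].sum(axis=0)).max() < 1e-5

    def test_unknown_subclass_rejected(self, rng):
        covs = np.stack([random_spd(rng, 3) for _ in range(4)])
        with pytest.raises(ValueError, match="reference"):
            featurize(
                covs, {1: np.eye(3)}, subclass_labels=np.array([1, 1, 2, 2]),
                mode="per_subclass_centered",
            )


class TestLDA:
    def test_separates_one_dimensional_classes(self, rng):
        y = np.repeat([True, False], 100)
        X = np.where(y, 1.0, -1.0)[:, None] + 0.3 * rng.standard_normal((200, 1))
        lda = fit_lda(X, y)
        assert lda.w[0] > 0
        assert lda.score(np.array([[1.0]]))[0] > lda.score(np.array([[-1.0]]))[0]

    def test_identical_means_give_chance_auc(self, rng):
        X = rng.standard_normal((400, 6))
        y = np.repeat([True, False], 200)
        lda = fit_lda(X, y)
        # score held-out data: in-sample AUC would be optimistically biased
        X_new = rng.standard_normal((400, 6))
        assert 0.4 < auc(lda.score(X_new), y) < 0.6

    def test_matches_closed_form_direction(self, rng):
        Sigma = np.array([[2.0, 0.8], [0.8, 1.0]])
        dmu = np.array([1.0, 0.5])
        L = np.linalg.cholesky(Sigma)
        n = 10_000
        X = np.vstack([
            (L @ rng.standard_normal((2, n))).T + dmu,
            (L @ rng.standard_normal((2, n))).T,
        ])
        y = np.repeat([True, False], n)
        lda = fit_lda(X, y)
        expected = np.linalg.solve(Sigma, dmu)
        cos = lda.w @ expected / np.linalg.norm(lda.w) / np.linalg.norm(expected)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5.0

    def test_singleton_class_rejected(self, rng):
        X = rng.standard_normal((3, 2))
        with pytest.raises(ValueError, match="2 members"):
            fit_lda(X, np.array([True, False, False]))

    def test_auc_invariant_under_affine_feature_maps(self, rng):
        # exact for plain LDA; approximate here because the analytic
        # shrinkage intensity is not affine-equivariant
        X = rng.standard_normal((4000, 4))
        y = np.repeat([True, False], 2000)
        X[y] += 0.8
        base = auc(fit_lda(X, y).score(X), y)
        A = rng.standard_normal((4, 4)) + 0.5 * np.eye(4)
        Xt = X @ A.T + rng.standard_normal(4)
        assert auc(fit_lda(Xt, y).score(Xt), y) == pytest.approx(base, abs=0.01)


def _grid_min(v_j, v_others, B, step=0.02):
    """Exhaustive search of the MTS objective over the constrained simplex."""
    m = len(v_others)
    grid = np.arange(0.0, 1.0 + step / 2, step)
    best = np.inf
    for combo in itertools.product(grid, repeat=m):
        a = np.asarray(combo)
        if a.sum() > 1.0 + 1e-12:
            continue
        best = min(best, mts_objective(a, v_j, v_others, B))
    return best


class TestMTS:
    def test_single_subclass_yields_empty_alpha(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.repeat([True, False], 10)
        ids, alpha = mts_weights(X, y, np.ones(20, dtype=int), 1, True)
        assert ids == [] and alpha.size == 0

    def test_distant_subclass_gets_no_weight(self, rng):
        n = 40
        X = np.vstack([rng.standard_normal((n, 4)),
                       rng.standard_normal((n, 4)) + 50.0])
        y = np.ones(2 * n, dtype=bool)
        sub = np.repeat([1, 2], n)
        ids, alpha = mts_weights(X, y, sub, 1, True)
        assert ids == [2]
        assert alpha[0] < 1e-3

    def test_iid_subclasses_shrinkage_never_hurts(self, rng):
        for _ in range(50):
            X = rng.standard_normal((60, 5))
            y = np.ones(60, dtype=bool)
            sub = np.repeat([1, 2, 3], 20)
            ids, alpha = mts_weights(X, y, sub, 1, True)
            mu_j, v_j, mus, vs = _components_for(X, y, sub, 1, ids)
            B, v_others = mts_components(mu_j, v_j, mus, vs)
            assert mts_objective(alpha, v_j, v_others, B) <= mts_objective(
                np.zeros_like(alpha), v_j, v_others, B
            ) + 1e-12

    def test_qp_matches_grid_search_oracle(self, rng):
        for _ in range(10):
            X = rng.standard_normal((90, 4))
            X[30:60] += rng.uniform(0, 2)
            X[60:] += rng.uniform(0, 4)
            y = np.ones(90, dtype=bool)
            sub = np.repeat([1, 2, 3], 30)
            ids, alpha = mts_weights(X, y, sub, 1, True)
            mu_j, v_j, mus, vs = _components_for(X, y, sub, 1, ids)
            B, v_others = mts_components(mu_j, v_j, mus, vs)
            achieved = mts_objective(alpha, v_j, v_others, B)
            assert achieved <= _grid_min(v_j, v_others, B) + 1e-6

    def test_shrunk_mean_is_convex_combination(self, rng):
        mu = rng.standard_normal(4)
        others = rng.standard_normal((2, 4))
        assert np.allclose(mts_shrunk_mean(mu, others, np.zeros(2)), mu)
        same = np.tile(mu, (2, 1))
        assert np.allclose(mts_shrunk_mean(mu, same, np.array([0.3, 0.5])), mu)
        mid = mts_shrunk_mean(mu, others[:1], np.array([0.5]))
        assert np.allclose(mid, 0.5 * (mu + others[0]))
        with pytest.raises(ValueError, match="sum"):
            mts_shrunk_mean(mu, others, np.array([0.8, 0.8]))


def _components_for(X, y, sub, j, ids):
    from screenfree_bci.decoding import _mean_and_variance

    mu_j, v_j = _mean_and_variance(X[(y) & (sub == j)])
    mus, vs = [], []
    for s in ids:
        mu, v = _mean_and_variance(X[(y) & (sub == s)])
        mus.append(mu)
        vs.append(v)
    return mu_j, v_j, np.stack(mus), np.asarray(vs)


class TestPipelines:
    def test_fit_is_deterministic(self, small_session):
        ep, _ = small_session
        m1 = fit_pipeline("ts_lda", ep)
        m2 = fit_pipeline("ts_lda", ep)
        assert np.array_equal(m1.global_lda.w, m2.global_lda.w)
        assert np.array_equal(m1.global_ref, m2.global_ref)

    def test_scores_permutation_equivariant(self, small_session, small_models):
        ep, _ = small_session
        model = small_models["cts_reg_lda"]
        test = ep.subset(np.arange(60))
        perm = np.random.default_rng(0).permutation(60)
        base = predict_window_scores(model, test)
        permuted = predict_window_scores(model, test.subset(perm))
        assert np.allclose(permuted, base[perm])

    def test_noise_free_features_fully_separable(self):
        from screenfree_bci.preprocessing import (
            bandpass_and_resample, extract_epochs,
        )
        from screenfree_bci.simulate import SessionConfig, simulate_session

        # noise far below the ERP amplitudes: classes remain separable but
        # the total covariance stays full-rank for the xDAWN eigenproblem
        cfg = SessionConfig(
            n_trials=4, rate=200.0, noise_scale=0.05, artifact_rate=0.0, seed=7
        )
        rec, sched = simulate_session(cfg)
        ep = extract_epochs(bandpass_and_resample(rec), sched)
        model = fit_pipeline("ts_lda", ep)
        scores = predict_window_scores(model, ep)
        y = ep.schedule.labels
        assert scores[y].min() > scores[~y].max()

    def test_subclass_routing_ablation(self, small_session, small_models):
        ep, _ = small_session
        import copy

        model = copy.deepcopy(small_models["cts_reg_lda"])
        test = ep.subset(np.arange(200))
        base = predict_window_scores(model, test)
        model.subclass_refs[2] = 4.0 * model.subclass_refs[2]
        changed = predict_window_scores(model, test) != base
        sub = test.schedule.subclass_labels("object")
        assert changed[sub == 2].all()
        assert not changed[sub != 2].any()

    def test_cts_with_zero_alpha_and_own_scatter_equals_sep(self, small_session):
        ep, _ = small_session
        sep = fit_pipeline("sep_ts_lda", ep)
        reduced = fit_pipeline(
            "cts_reg_lda", ep, use_mts=False, pooled_scatter=False
        )
        test = ep.subset(np.arange(150))
        assert np.allclose(
            predict_window_scores(sep, test),
            predict_window_scores(reduced, test),
            atol=1e-8,
        )

    def test_position_group_subclasses(self, small_session):
        # initial vs subsequent stimuli as the two subclasses
        ep, _ = small_session
        model = fit_pipeline("cts_reg_lda", ep, subclass_definition="position_group")
        assert set(model.subclass_refs) == {1, 2}
        scores = predict_window_scores(model, ep.subset(np.arange(96)))
        assert np.isfinite(scores).all()

    def test_subclass_missing_a_class_is_named(self, small_session):
        ep, _ = small_session
        # drop every target window of object 3
        mask = ~((ep.schedule.objects == 3) & ep.schedule.labels)
        with pytest.raises(ValueError, match="3"):
            fit_pipeline("sep_ts_lda", ep.subset(mask))

    def test_unseen_subclass_falls_back_to_pooled(self, small_session, small_models):
        ep, _ = small_session
        model = small_models["sep_ts_lda"]
        test = ep.subset(np.arange(100))
        shifted = test.schedule.frame.copy()
        shifted["object"] = shifted["object"].replace({1: 7})
        from screenfree_bci.data import EpochSet, EventSchedule

        odd = EpochSet(
            windows=test.windows, schedule=EventSchedule(shifted), rate=test.rate
        )
        with pytest.warns(RuntimeWarning, match="unseen"):
            scores = predict_window_scores(model, odd)
        pooled = predict_window_scores(small_models["ts_lda"], test)
        sub = odd.schedule.objects
        assert np.allclose(scores[sub == 7], pooled[sub == 7])


class TestSelectObject:
    def _sched(self, scores_by_object):
        rows = []
        t = 0.0
        for obj, scores in scores_by_object.items():
            for _ in scores:
                rows.append((t, obj, 1, 1, 1 if t == 0 else 2, obj == 1))
                t += 0.25
        frame = pd.DataFrame(
            rows,
            columns=[
                "onset_s", "object", "trial", "repetition", "seq_position",
                "is_target",
            ],
        )
        frame["seq_position"] = np.arange(1, len(frame) + 1)
        return EventSchedule(frame)

    def test_clear_winner_and_mean_aggregation(self):
        sched = self._sched({1: [0.2, 0.4], 2: [0.1, 0.6]})
        # object 2 wins on mean score (0.35 vs 0.30)
        assert select_object(np.array([0.2, 0.4, 0.1, 0.6]), sched, 1) == 2
        sched2 = self._sched({1: [1.0, 1.0], 2: [-1.0, -1.0], 3: [-1.0, -1.0]})
        assert select_object(np.array([1., 1., -1., -1., -1., -1.]), sched2, 1) == 1

    def test_ties_break_to_lowest_object_id(self):
        sched = self._sched({2: [0.5], 3: [0.5], 1: [0.5]})
        assert select_object(np.full(3, 0.5), sched, 1) == 1

    def test_fully_rejected_candidate_excluded(self):
        sched = self._sched({1: [0.9, 0.9], 2: [0.1, 0.1]})
        retained = np.array([False, False, True, True])
        with pytest.warns(RuntimeWarning, match="no scored windows"):
            sel = select_object(
                np.array([0.9, 0.9, 0.1, 0.1]), sched, 1, retained=retained
            )
        assert sel == 2
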