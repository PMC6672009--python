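"""Decoder correctness: LDA oracle equivalence, balancing, time generalization."""

import numpy as np
import pytest
from scipy import stats as sstats

from tonepred.decoding import (
    InfeasibleBalancingError,
    TimeGeneralizationDecoder,
    TimeGenMap,
    balance_n1n,
    cross_condition_timegen,
    crossval_timegen,
    decode_entropy,
    drop_post_omission,
    fit_lda,
    window_average,
)
from tonepred.sequences import BlockDesign, make_block
from tonepred.simulate import (
    EpochSet,
    SimulationParams,
    make_kernel,
    make_topographies,
    simulate_subject,
)
import pandas as pd


def naive_lda_predict(X_train, y_train, X_test, lam):
    """Independent brute-force evaluation of the LDA discriminant equations."""
    classes = np.unique(y_train)
    d = X_train.shape[1]
    means = {c: X_train[y_train == c].mean(axis=0) for c in classes}
    resid = np.vstack([X_train[y_train == c] - means[c] for c in classes])
    S = resid.T @ resid / (len(X_train) - len(classes))
    S = (1 - lam) * S + lam * (np.trace(S) / d) * np.eye(d)
    Sinv = np.linalg.inv(S)
    preds = []
    for x in X_test:
        best, best_score = None, -np.inf
        for c in classes:  # ties go to the lowest class index
            w = Sinv @ means[c]
            score = x @ w - 0.5 * means[c] @ w + np.log(1 / len(classes))
            if score > best_score + 1e-12:
                best, best_score = c, score
        preds.append(best)
    return np.array(preds)


class TestFitLDA:
    def test_symmetric_two_class_boundary_at_zero(self):
        X = np.array([[-1.5], [-1.0], [-0.5], [0.5], [1.0], [1.5]])
        y = np.array([0, 0, 0, 1, 1, 1])
        m = fit_lda(X, y, shrinkage=0.0)
        s = m.scores(np.array([[0.0]]))
        assert s[0, 0] == pytest.approx(s[0, 1])  # boundary exactly at 0
        assert m.predict(np.array([[-0.1]]))[0] == 0
        assert m.predict(np.array([[0.1]]))[0] == 1

    def test_full_shrinkage_gives_scaled_mean_classifier(self, rng):
        X = rng.standard_normal((80, 5))
        y = rng.integers(3, size=80)
        m = fit_lda(X, y, shrinkage=1.0)
        # sigma = (tr S / d) I, so W_k is proportional to the class mean
        for k, c in enumerate(m.classes):
            cosine = m.weights[:, k] @ m.means[k] / (
                np.linalg.norm(m.weights[:, k]) * np.linalg.norm(m.means[k]))
            assert cosine == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_problems(self, seed):
        rng = np.random.default_rng(seed)
        d, n = 6, 400
        means = rng.standard_normal((4, d))
        y = rng.integers(4, size=n)
        X = means[y] + rng.standard_normal((n, d))
        lam = float(rng.uniform(0, 0.5))
        m = fit_lda(X, y, shrinkage=lam)
        np.testing.assert_array_equal(m.predict(X),
                                      naive_lda_predict(X, y, X, lam))

    def test_bias_shift_invariance(self, rng):
        X = rng.standard_normal((60, 4))
        y = rng.integers(2, size=60)
        m = fit_lda(X, y)
        shifted = m.scores(X) + 3.7
        np.testing.assert_array_equal(m.classes[np.argmax(shifted, axis=1)],
                                      m.predict(X))

    def test_class_with_single_trial_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            fit_lda(X, np.array([0, 0, 1]))

    def test_singular_covariance_without_shrinkage_fails(self):
        X = np.zeros((8, 3))
        X[:, 0] = [0, 0, 1, 1, 0, 0, 1, 1.]
        y = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        with pytest.raises(np.linalg.LinAlgError):
            fit_lda(X, y, shrinkage=0.0)

    def test_auto_shrinkage_matches_sklearn(self, rng):
        from sklearn.covariance import ledoit_wolf_shrinkage
        X = rng.standard_normal((100, 7)) * [1, 2, 3, 1, 1, 2, 1]
        y = rng.integers(4, size=100)
        m = fit_lda(X, y, "auto")
        classes = np.unique(y)
        resid = X - np.stack([X[y == c].mean(0) for c in classes])[
            np.searchsorted(classes, y)]
        assert m.shrinkage == pytest.approx(
            float(ledoit_wolf_shrinkage(resid, assume_centered=True)))


class TestBalanceN1N:
    def test_already_balanced_keeps_everything(self, rng):
        y = np.repeat(np.arange(4), 40)
        prev = np.tile(np.repeat(np.arange(4), 10), 4)
        kept = balance_n1n(y, prev, seed=0)
        assert kept.size == 160

    def test_min_cell_rule(self, rng):
        # one target class with previous-class cell counts 10, 7, 9, 8
        y, prev = [], []
        for p, count in enumerate([10, 7, 9, 8]):
            y += [0] * count
            prev += [p] * count
        # other classes fully balanced
        for cls in (1, 2, 3):
            y += [cls] * 20
            prev += list(np.tile(np.arange(4), 5))
        kept = balance_n1n(np.array(y), np.array(prev), seed=1)
        yk, pk = np.array(y)[kept], np.array(prev)[kept]
        assert np.sum(yk == 0) == 28  # 7 per cell
        for p in range(4):
            assert np.sum((yk == 0) & (pk == p)) == 7

    def test_generated_block_bigram_exactly_uniform(self):
        # balancing is applied to the random-sequence training set, where
        # every (class, previous-class) cell is populated
        blk = make_block("RD", BlockDesign(n_stimuli=440, omission_rate=0.1),
                         seed=2)
        tones = blk.tone_classes
        y, prev = tones[1:], tones[:-1]
        kept = balance_n1n(y, prev, seed=3)
        table = np.zeros((4, 4), dtype=int)
        np.add.at(table, (y[kept], prev[kept]), 1)
        for row in table:
            assert len(set(row)) == 1  # exactly uniform per target class

    def test_ordered_block_is_structurally_infeasible(self):
        # OR forbids two of the four transitions per class (probability 0),
        # so those previous-class cells are empty and balancing must refuse
        blk = make_block("OR", BlockDesign(n_stimuli=440, omission_rate=0.1),
                         seed=2)
        tones = blk.tone_classes
        with pytest.raises(InfeasibleBalancingError, match="empty cell"):
            balance_n1n(tones[1:], tones[:-1], seed=3)

    def test_invariant_to_trial_order(self, rng):
        y = rng.integers(4, size=200)
        prev = rng.integers(4, size=200)
        kept = balance_n1n(y, prev, seed=9)
        perm = rng.permutation(200)
        kept_perm = balance_n1n(y[perm], prev[perm], seed=9)
        # same multiset of (class, prev) cells kept
        a = sorted(zip(y[kept], prev[kept]))
        b = sorted(zip(y[perm][kept_perm], prev[perm][kept_perm]))
        assert a == b

    def test_empty_cell_reported(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        prev = np.array([0, 1, 2, 3, 0, 1, 2, 2])  # (1, 3) cell empty
        with pytest.raises(InfeasibleBalancingError, match="class"):
            balance_n1n(y, prev, seed=0)


def _labelled_epochs(X, y, times=None):
    n = X.shape[0]
    labels = pd.DataFrame({
        "tone_class": y, "condition": "RD", "event_type": "sound",
        "prev_tone_class": np.zeros(n, dtype=int),
        "prev_was_omission": np.zeros(n, dtype=int), "subject_id": 0})
    t = times if times is not None else np.arange(X.shape[2]) / 100.0
    return EpochSet(X, labels, t)


class TestTimeGeneralization:
    def test_noise_only_data_is_at_chance(self, rng):
        X = rng.standard_normal((240, 8, 6))
        y = rng.integers(4, size=240)
        tg = crossval_timegen(_labelled_epochs(X, y), y, seed=0)
        # every cell within a generous binomial band around 0.25
        se = np.sqrt(0.25 * 0.75 / 240)
        assert np.all(np.abs(tg.accuracy - 0.25) < 5 * se)

    def test_separable_data_perfect_on_diagonal_window(self, rng):
        # distinct topographies active in samples 2..4, nothing elsewhere
        topo = np.eye(8)[:, :4]
        y = np.tile(np.arange(4), 30)
        X = np.zeros((120, 8, 6))
        X[np.arange(120), y, 2:5] = 5.0
        X += 0.01 * rng.standard_normal(X.shape)
        tg = crossval_timegen(_labelled_epochs(X, y), y, seed=0)
        np.testing.assert_array_equal(np.diag(tg.accuracy)[2:5], 1.0)

    def test_diagonal_equals_time_resolved_decoding(self, small_cohort):
        ep = drop_post_omission(small_cohort.subjects[0]).where(
            condition=("RD", "MM", "MP", "OR"), event_type="sound")
        cond_code = {"RD": 0, "MM": 1, "MP": 2, "OR": 3}
        y = ep.labels["condition"].map(cond_code).to_numpy()
        # restrict to a few time points to keep the full map cheap
        sub = EpochSet(ep.data[:, :, 95:110], ep.labels, ep.times[95:110])
        tg = crossval_timegen(sub, y, seed=42)
        course = decode_entropy(
            EpochSet(small_cohort.subjects[0].data[:, :, 95:110],
                     small_cohort.subjects[0].labels,
                     small_cohort.subjects[0].times[95:110]),
            "sound", seed=42)
        np.testing.assert_allclose(np.diag(tg.accuracy), course, atol=1e-12)

    def test_cross_decoding_rejects_identical_sets(self, rng):
        X = rng.standard_normal((40, 4, 3))
        y = rng.integers(4, size=40)
        ep = _labelled_epochs(X, y)
        with pytest.raises(ValueError, match="disjoint"):
            TimeGeneralizationDecoder(ep, y, test=ep, y_test=y)

    def test_label_shuffle_null_within_binomial_band(self, rng):
        # shuffled labels on structured data: mean map accuracy ~ chance
        topo = np.eye(6)[:, :4]
        y = np.tile(np.arange(4), 50)
        X = topo[:, y].T[:, :, None] * np.ones(4) + rng.standard_normal((200, 6, 4))
        y_shuf = rng.permutation(y)
        tg = crossval_timegen(_labelled_epochs(X, y_shuf), y_shuf, seed=1)
        se = np.sqrt(0.25 * 0.75 / 200)
        assert abs(tg.accuracy.mean() - 0.25) < 3 * se


class TestWindowAverage:
    def _map(self, rng):
        acc = rng.uniform(0, 1, size=(10, 7))
        return TimeGenMap(np.arange(10) / 100, np.arange(7) / 100, acc)

    def test_single_sample_window_returns_that_row(self, rng):
        tg = self._map(rng)
        np.testing.assert_array_equal(window_average(tg, (30, 30)),
                                      tg.accuracy[3])

    def test_constant_map(self):
        acc = np.full((5, 4), 0.4)
        tg = TimeGenMap(np.arange(5) / 100, np.arange(4) / 100, acc)
        np.testing.assert_allclose(window_average(tg, (0, 40)), 0.4)

    def test_matches_brute_force_row_mean(self, rng):
        tg = self._map(rng)
        lo, hi = 20, 60
        rows = [i for i, t in enumerate(tg.train_times * 1000)
                if lo <= t <= hi]
        expected = np.mean([tg.accuracy[i] for i in rows], axis=0)
        np.testing.assert_allclose(window_average(tg, (lo, hi)), expected)

    def test_empty_window_rejected(self, rng):
        with pytest.raises(ValueError):
            window_average(self._map(rng), (500, 600))


class TestRecoverySmoke:
    """End-to-end decodability of injected effects on one subject."""

    def test_anticipation_raises_preonset_accuracy_in_ordered_condition(self):
        from tonepred.decoding import sound_to_sound_maps
        design = BlockDesign(n_stimuli=240, omission_rate=0.10)
        topo = make_topographies(16, 0.3, seed=1)
        kernel = make_kernel()
        params = SimulationParams(anticipation_gain=1.2, noise_sd=0.6)
        blocks = {c: make_block(c, design, s) for s, c in
                  enumerate(("RD", "MM", "MP", "OR"))}
        ep = simulate_subject(blocks, topo, kernel, params, seed=3)
        maps = sound_to_sound_maps(ep, 1, train_window_s=(0.0, 0.3),
                                   test_window_s=(-0.3, 0.1))
        pre = lambda m: m.accuracy[:, m.test_times <= 0].mean()
        assert pre(maps["OR"]) > pre(maps["RD"]) + 0.03

    def test_omission_map_at_chance_without_effects(self, rng):
        from tonepred.decoding import sound_to_omission_maps
        design = BlockDesign(n_stimuli=240, omission_rate=0.10)
        topo = make_topographies(12, 0.3, seed=1)
        kernel = make_kernel()
        params = SimulationParams(anticipation_gain=0.0, omission_gain=0.0,
                                  entropy_signature_gain=0.0, noise_sd=1.0)
        blocks = {c: make_block(c, design, s) for s, c in
                  enumerate(("RD", "MM", "MP", "OR"))}
        ep = simulate_subject(blocks, topo, kernel, params, seed=3)
        maps = sound_to_omission_maps(ep, 1, train_window_s=(0.0, 0.2),
                                      test_window_s=(0.0, 0.2))
        # 21x21 map on 23 omission trials: generous band around chance
        acc = np.concatenate([m.accuracy.ravel() for m in maps.values()])
        assert abs(acc.mean() - 0.25) < 0.08

    def test_entropy_decoding_above_chance_with_signature(self, small_cohort):
        course = decode_entropy(small_cohort.subjects[0], "sound", seed=0)
        # course mean pools ~620 trials x 201 time points: a 1-point margin
        # above chance is many standard errors
        assert course.mean() > 0.26
        assert (course > 0.25).mean() > 0.75

    def test_entropy_decoding_deterministic(self, small_cohort):
        ep = small_cohort.subjects[1]
        sub = EpochSet(ep.data[:, :, 90:96], ep.labels, ep.times[90:96])
        a = decode_entropy(sub, "omission", seed=5)
        b = decode_entropy(sub, "omission", seed=5)
        np.testing.assert_array_equal(a, b)
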