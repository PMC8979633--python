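"""Fisher ranking, LDA, AUC and word-wise cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import errpspeller as e
from errpspeller.classify import (FeatureMatrix, _fisher_from_arrays,
                                  crossvalidate_by_word, train_lda, score_lda,
                                  predict_lda)


def fm(values, labels, word_ids=None):
    values = np.asarray(values, dtype=float)
    n, f = values.shape
    return FeatureMatrix(values=values, channel_idx=np.zeros(f, dtype=int),
                         time_idx=np.arange(f), labels=labels,
                         word_ids=word_ids if word_ids is not None
                         else np.zeros(n, dtype=int))


class TestFisherScores:
    def test_hand_computed_value(self):
        """Class means 1 and 0 with sample variances 0.5 each score
        1/sqrt(0.5+0.5) = 1.0."""
        x = np.array([[1.5], [0.5], [0.5], [-0.5]])  # means 1, 0; vars 0.5
        y = np.array([True, True, False, False])
        assert e.fisher_scores(fm(x, y))[0] == pytest.approx(1.0)

    def test_identical_distributions_score_zero(self):
        x = np.array([[1.0], [2.0], [1.0], [2.0]])
        y = np.array([True, True, False, False])
        assert e.fisher_scores(fm(x, y))[0] == pytest.approx(0.0)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((20, 3))
        y = np.arange(20) % 2 == 0
        s1 = _fisher_from_arrays(x, y)
        s2 = _fisher_from_arrays(a * x + b, y)
        np.testing.assert_allclose(s1, s2, rtol=1e-9)

    def test_single_class_rejected(self):
        x = np.ones((4, 2))
        with pytest.raises(ValueError):
            e.fisher_scores(fm(x, np.array([True] * 4)))

    def test_degenerate_zero_variance_unequal_means_capped(self):
        x = np.array([[1.0, 0.3], [1.0, 0.9], [0.0, 0.1], [0.0, 0.8]])
        y = np.array([True, True, False, False])
        with pytest.warns(UserWarning, match="zero-variance"):
            s = e.fisher_scores(fm(x, y))
        assert np.isfinite(s[0]) and s[0] > s[1]


class TestSelectTopFeatures:
    def test_all_features(self):
        idx = e.select_top_features(np.array([3.0, 1.0, 2.0]), 3)
        np.testing.assert_array_equal(idx, [0, 1, 2])

    def test_top_two(self):
        idx = e.select_top_features(np.array([3.0, 1.0, 2.0]), 2)
        np.testing.assert_array_equal(sorted(idx), [0, 2])

    def test_tie_break_earlier_time_then_channel(self):
        scores = np.array([1.0, 1.0, 1.0, 1.0])
        time_idx = np.array([3, 1, 1, 0])
        chan_idx = np.array([0, 1, 0, 2])
        idx = e.select_top_features(scores, 2, time_idx, chan_idx)
        # earliest time wins (feature 3), then time 1 / channel 0 (feature 2)
        np.testing.assert_array_equal(sorted(idx), [2, 3])

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            e.select_top_features(np.array([1.0, 2.0]), 3)


class TestLDA:
    def test_separable_clouds_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(10, 1, (30, 4))])
        y = np.array([False] * 30 + [True] * 30)
        model = train_lda(x, y)
        assert np.mean(predict_lda(model, x) == y) == 1.0

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((120, 5))
        y = rng.permutation([True, False] * 60)
        aucs = []
        for fold in range(4):
            test = np.arange(120) % 4 == fold
            m = train_lda(x[~test], y[~test])
            aucs.append(e.auc(score_lda(m, x[test]), y[test]))
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_matches_closed_form_direction(self):
        """At zero shrinkage the discriminant direction equals
        pooled-covariance^-1 (mu1 - mu0), computed by hand on 6 points."""
        x = np.array([[0.0, 0.0], [1.0, 0.5], [0.5, 1.0],
                      [3.0, 2.0], [4.0, 2.5], [3.5, 3.0]])
        y = np.array([False, False, False, True, True, True])
        model = train_lda(x, y, shrinkage=0)
        mu0, mu1 = x[~y].mean(axis=0), x[y].mean(axis=0)
        # pooled covariance: prior-weighted mean of biased class covariances
        def cov0(a):
            d = a - a.mean(axis=0)
            return d.T @ d / len(a)
        pooled = 0.5 * cov0(x[~y]) + 0.5 * cov0(x[y])
        expected = np.linalg.solve(pooled, mu1 - mu0)
        np.testing.assert_allclose(model.estimator.coef_.ravel(), expected,
                                   atol=1e-6)

    def test_too_few_epochs_rejected(self):
        with pytest.raises(ValueError):
            train_lda(np.ones((3, 2)), np.array([True, False, False]))


class TestAUC:
    def test_perfect_ordering(self):
        assert e.auc([1, 2, 3, 4], [False, False, True, True]) == 1.0

    def test_all_ties_give_half(self):
        assert e.auc([1, 1, 1, 1], [False, True, False, True]) == 0.5

    def test_small_example_equals_pairwise_count(self):
        """[0.1,0.4,0.35,0.8] with labels [0,0,1,1]: concordant pairs
        (0.35>0.1, 0.8>0.1, 0.8>0.4) and one discordant (0.35<0.4) -> 3/4."""
        assert e.auc([0.1, 0.4, 0.35, 0.8],
                     [False, False, True, True]) == pytest.approx(3 / 4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            e.auc([1, 2], [True, True])

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, data):
        """Mann-Whitney AUC equals exhaustive pairwise concordance (ties
        count 1/2) on random instances of up to 30 epochs."""
        n = data.draw(st.integers(4, 30))
        scores = data.draw(st.lists(
            st.integers(0, 10), min_size=n, max_size=n))  # ints force ties
        labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        labels = np.array(labels)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        scores = np.asarray(scores, dtype=float)
        pos, neg = scores[labels], scores[~labels]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        expected = conc / (len(pos) * len(neg))
        assert e.auc(scores, labels) == pytest.approx(expected)


def _toy_epochs(n_words=6, per_word=20, err_frac=0.25, sep=2.0, seed=0,
                n_ch=2, n_t=16):
    """Small synthetic EpochSet with a class-mean difference `sep`."""
    rng = np.random.default_rng(seed)
    n = n_words * per_word
    is_error = np.zeros(n, dtype=bool)
    for w in range(n_words):
        k = max(1, int(err_frac * per_word))
        idx = w * per_word + rng.choice(per_word, size=k, replace=False)
        is_error[idx] = True
    data = rng.standard_normal((n, n_ch, n_t))
    data[is_error, :, 4:8] += sep
    return e.EpochSet(
        data=data, rate=64.0, window=(0.0, n_t / 64.0), is_error=is_error,
        word_ids=np.repeat(np.arange(n_words), per_word),
        shifts=np.zeros(n), channels=tuple(f"ch{i}" for i in range(n_ch)),
    )


class TestCrossValidateByWord:
    def test_six_words_six_folds(self):
        cv = crossvalidate_by_word(_toy_epochs(), k_features=8, realign=False)
        assert cv.n_folds == 6

    def test_no_leakage_fold_reproducible_from_public_pieces(self):
        """An independent re-implementation of one fold (train on the other
        words, Fisher-rank, LDA) reproduces the fold's AUC exactly, and
        flipping the held-out labels flips the AUC to its complement —
        the trained model cannot depend on test labels."""
        ep = _toy_epochs(seed=3)
        cv = crossvalidate_by_word(ep, k_features=8, realign=False)

        w = 0
        train = ep.select_epochs(ep.word_ids != w)
        test = ep.select_epochs(ep.word_ids == w)
        fm_train = FeatureMatrix.from_epochs(train)
        scores = e.fisher_scores(fm_train)
        sel = e.select_top_features(scores, 8, fm_train.time_idx,
                                    fm_train.channel_idx)
        model = train_lda(fm_train.values[:, sel], fm_train.labels)
        fm_test = FeatureMatrix.from_epochs(test)
        s = score_lda(model, fm_test.values[:, sel])
        assert cv.per_fold[0].auc == pytest.approx(e.auc(s, fm_test.labels))
        assert e.auc(s, ~fm_test.labels) == pytest.approx(
            1.0 - cv.per_fold[0].auc)

    def test_separable_data_high_auc(self):
        cv = crossvalidate_by_word(_toy_epochs(sep=4.0), k_features=8,
                                   realign=False)
        assert cv.mean_auc > 0.95

    def test_single_class_word_merged(self, caplog):
        ep = _toy_epochs(n_words=4, seed=1)
        # strip errors from word 2
        mask = ~((ep.word_ids == 2) & ep.is_error)
        ep2 = ep.select_epochs(mask)
        with caplog.at_level("INFO", logger="errpspeller.classify"):
            cv = crossvalidate_by_word(ep2, k_features=8, realign=False)
        assert cv.n_folds == 3
        assert any("merging" in r.message for r in caplog.records)

    def test_too_few_folds_rejected(self):
        ep = _toy_epochs(n_words=1)
        with pytest.raises(ValueError):
            crossvalidate_by_word(ep, k_features=8, realign=False)

    def test_per_class_recalls_reported(self):
        cv = crossvalidate_by_word(_toy_epochs(sep=4.0), k_features=8,
                                   realign=False)
        for m in cv.per_fold.values():
            assert 0.0 <= m.recall_error <= 1.0
            assert 0.0 <= m.recall_correct <= 1.0

    def test_fisher_map_peaks_at_template_and_midline(self):
        """On near-noiseless generated data the Fisher map's maximum sits at
        the positivity latency on a midline channel."""
        sub = e.simulate_subject(
            seed=5, words=("ace", "bed"),
            errp=e.ErrPTemplateParams(jitter_sd=0.0, amplitude_cv=0.2),
            noise=e.NoiseParams(noise_sd=0.5),
        )
        ep = e.preprocess_session(sub.recording, sub.events)
        f = FeatureMatrix.from_epochs(ep)
        s = e.fisher_scores(f).reshape(ep.n_channels, ep.n_times)
        ch, t = np.unravel_index(np.argmax(s), s.shape)
        assert ep.channels[ch] in ("FCz", "Cz", "CPz", "FC1", "FC2",
                                   "CP1", "CP2")
        t_peak = ep.times[t]
        assert 0.2 <= t_peak <= 0.55  # at one of the two deflections
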