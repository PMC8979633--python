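"""MI decoding chain: Laplacian, Welch features, classifiers, accumulation."""

import numpy as np
import pytest

import errpspeller as e
from errpspeller.midecoder import (DecoderConfig, EvidenceState, welch_psd,
                                   openloop_mi_accuracy)
from errpspeller.synth import ContinuousRecording


class TestLaplacian:
    def test_spatially_constant_signal_cancelled(self, layout):
        data = np.tile(np.sin(np.linspace(0, 20, 1000)), (len(layout), 1))
        rec = ContinuousRecording(data, 512.0, layout)
        out = e.laplacian_filter(rec)
        nbrs = layout.neighbor_sets()
        for i, nbr in enumerate(nbrs):
            if nbr:
                np.testing.assert_allclose(out.data[i], 0.0, atol=1e-12)
            else:
                np.testing.assert_array_equal(out.data[i], data[i])

    def test_single_active_channel_spreads_negatively(self, layout):
        """A lone active channel leaves -1/n_neighbours of its signal on
        each neighbour (hand computation on the montage cross)."""
        data = np.zeros((len(layout), 100))
        cz = layout.index("Cz")
        data[cz] = 1.0
        rec = ContinuousRecording(data, 512.0, layout)
        out = e.laplacian_filter(rec)
        nbrs = layout.neighbor_sets()
        for i, nbr in enumerate(nbrs):
            if i == cz:
                continue
            if cz in nbr:
                np.testing.assert_allclose(out.data[i], -1.0 / len(nbr))
            else:
                np.testing.assert_allclose(out.data[i], 0.0)

    def test_zero_in_zero_out(self, layout):
        rec = ContinuousRecording(np.zeros((len(layout), 100)), 512.0, layout)
        assert np.all(e.laplacian_filter(rec).data == 0.0)

    def test_common_offset_invariance(self, layout):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((len(layout), 500))
        rec1 = ContinuousRecording(data, 512.0, layout)
        rec2 = ContinuousRecording(data + 42.0, 512.0, layout)
        o1, o2 = e.laplacian_filter(rec1), e.laplacian_filter(rec2)
        nbrs = layout.neighbor_sets()
        with_nbrs = [i for i, nb in enumerate(nbrs) if nb]
        np.testing.assert_allclose(o1.data[with_nbrs], o2.data[with_nbrs],
                                   atol=1e-9)


def _mi_events(times, intended, durations, word_ids=None):
    n = len(times)
    return e.EventLog(
        time_s=times, intended=intended, delivered=intended,
        correct=[True] * n,
        word_id=word_ids if word_ids is not None else list(range(n)),
        condition=["FBoff"] * n, duration_s=durations,
    )


class TestWelchFeatures:
    def test_sinusoid_peaks_in_its_bin(self, layout):
        rate = 512.0
        t = np.arange(int(30 * rate)) / rate
        data = np.tile(np.sin(2 * np.pi * 12.0 * t), (len(layout), 1))
        rec = ContinuousRecording(data, rate, layout)
        ev = _mi_events([25.0], ["left"], [20.0])
        cfg = DecoderConfig()
        feats = e.welch_psd_features(rec, cfg, ev)
        row = feats.values[0]
        ch0 = feats.channel_idx == 0
        best = feats.bin_freqs[ch0][np.argmax(row[ch0])]
        assert abs(best - 12.0) <= cfg.bin_width

    def test_white_noise_spectrum_roughly_flat(self, layout):
        rng = np.random.default_rng(0)
        rate = 512.0
        rec = ContinuousRecording(rng.standard_normal((len(layout),
                                                       int(70 * rate))),
                                  rate, layout)
        ev = _mi_events([65.0], ["left"], [60.0])
        cfg = DecoderConfig(psd_window=2.0, window_step=2.0)
        feats = e.welch_psd_features(rec, cfg, ev)
        ch0 = feats.channel_idx == 0
        power = 10 ** feats.values[:, ch0].mean(axis=0)
        assert power.max() / power.min() < 3.0

    def test_amplitude_doubling_adds_log_four(self, layout):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((len(layout), int(30 * 512)))
        ev = _mi_events([25.0], ["left"], [20.0])
        cfg = DecoderConfig()
        f1 = e.welch_psd_features(ContinuousRecording(base, 512.0, layout),
                                  cfg, ev)
        f2 = e.welch_psd_features(ContinuousRecording(2 * base, 512.0, layout),
                                  cfg, ev)
        np.testing.assert_allclose(f2.values - f1.values, np.log10(4.0),
                                   atol=1e-9)

    def test_band_beyond_nyquist_rejected(self, layout):
        rec = ContinuousRecording(np.zeros((len(layout), 1000)), 100.0, layout)
        ev = _mi_events([5.0], ["left"], [4.0])
        with pytest.raises(ValueError, match="Nyquist"):
            e.welch_psd_features(rec, DecoderConfig(band_range=(4, 60)), ev)

    def test_parseval_total_power_matches_variance(self):
        """Integrated Welch PSD approximates time-domain variance within 10%
        for broadband input."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal(512 * 60)
        f, p = welch_psd(x, 512.0, DecoderConfig())
        total = np.trapezoid(p, f)
        assert total == pytest.approx(x.var(), rel=0.10)


class TestMIClassifier:
    def test_symmetric_classes_posterior_half(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(-1, 1, (50, 3)), rng.normal(1, 1, (50, 3))])
        y = np.array([False] * 50 + [True] * 50)
        m = e.train_mi_classifier(x, y, DecoderConfig(n_features=3))
        p = e.posterior(m, np.zeros(3) + x.mean(axis=0))
        assert p[0] == pytest.approx(0.5, abs=0.15)
        assert p[0] + p[1] == pytest.approx(1.0)

    def test_prototype_point_near_certainty(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(-5, 0.5, (50, 2)),
                       rng.normal(5, 0.5, (50, 2))])
        y = np.array([False] * 50 + [True] * 50)
        m = e.train_mi_classifier(x, y, DecoderConfig(n_features=2))
        assert e.posterior(m, np.array([5.0, 5.0]))[1] > 0.99

    def test_one_dimensional_bayes_closed_form(self):
        """Posterior matches the two-Gaussian Bayes formula within 1e-9."""
        x0 = np.array([-1.0, -1.5, -0.5, -1.2, -0.8])
        x1 = np.array([2.0, 2.5, 1.5, 2.2, 1.8])
        x = np.concatenate([x0, x1])[:, None]
        y = np.array([False] * 5 + [True] * 5)
        m = e.train_mi_classifier(x, y, DecoderConfig(n_features=1),
                                  kind="gaussian")
        q = 0.3
        mu = np.array([x0.mean(), x1.mean()])
        var = np.array([x0.var(), x1.var()])
        lik = np.exp(-0.5 * ((q - mu) ** 2 / var)) / np.sqrt(2 * np.pi * var)
        post = lik * 0.5 / np.sum(lik * 0.5)
        got = e.posterior(m, np.array([q]))
        assert got[0] == pytest.approx(post[0], abs=1e-9)
        assert got[1] == pytest.approx(post[1], abs=1e-9)

    def test_lda_kind_produces_valid_posteriors(self):
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(-1, 1, (30, 4)), rng.normal(1, 1, (30, 4))])
        y = np.array([False] * 30 + [True] * 30)
        m = e.train_mi_classifier(x, y, DecoderConfig(n_features=4), kind="lda")
        p = e.posterior(m, x[0])
        assert 0.0 <= p[1] <= 1.0 and p[0] + p[1] == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            e.train_mi_classifier(np.ones((4, 2)), np.array([True] * 4),
                                  DecoderConfig())


class TestAccumulateEvidence:
    def test_hand_iterated_recurrence(self):
        """Constant posterior 1.0 with alpha 0.7 from 0.5: the sequence is
        0.65, 0.755, 0.8285, 0.87995, crossing threshold 0.85 on step 4."""
        cfg = DecoderConfig(alpha=0.7, decision_threshold=0.85)
        state = EvidenceState()
        expected = [0.65, 0.755, 0.8285, 0.87995]
        for i, want in enumerate(expected, start=1):
            state, decision = e.accumulate_evidence(state, 1.0, cfg)
            assert state.history[-1] == pytest.approx(want, abs=1e-10)
            if i < 4:
                assert decision is None
            else:
                assert decision == "right"
        assert state.p == 0.5  # reset after the decision

    def test_rejection_band_freezes_state(self):
        cfg = DecoderConfig()
        state = EvidenceState()
        for _ in range(50):
            state, decision = e.accumulate_evidence(state, 0.52, cfg)
            assert decision is None
        assert state.p == 0.5

    def test_alpha_one_never_moves(self):
        cfg = DecoderConfig(alpha=1.0)
        state = EvidenceState()
        for _ in range(10):
            state, decision = e.accumulate_evidence(state, 1.0, cfg)
        assert state.p == 0.5 and decision is None

    def test_geometric_convergence_to_constant_input(self):
        """With constant input q outside the rejection band, p - q decays by
        factor alpha per step and stays in [0, 1]."""
        cfg = DecoderConfig(alpha=0.9, decision_threshold=0.999)
        q = 0.8
        state = EvidenceState()
        prev_gap = 0.5 - q
        for _ in range(30):
            state, _ = e.accumulate_evidence(state, q, cfg)
            assert 0.0 <= state.p <= 1.0
            gap = state.p - q
            assert gap == pytest.approx(prev_gap * cfg.alpha, abs=1e-12)
            prev_gap = gap

    def test_left_decision_mirror(self):
        cfg = DecoderConfig(alpha=0.5, decision_threshold=0.8)
        state = EvidenceState()
        decision = None
        for _ in range(10):
            state, decision = e.accumulate_evidence(state, 0.0, cfg)
            if decision:
                break
        assert decision == "left"


class TestOpenLoopAccuracy:
    @staticmethod
    def _session(seed, erd):
        words = ("az", "by")  # each word mixes left- and right-bound letters
        sub = e.simulate_subject(
            seed=seed, words=words,
            smr=e.SMRParams(erd_depth=erd, lateralization=1.0),
            noise=e.NoiseParams(noise_sd=6.0),
        )
        return sub

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_clear_erd_decodable(self, seed):
        """With 50% ERD the cross-validated trial accuracy exceeds 0.7."""
        sub = self._session(seed, erd=0.5)
        res = openloop_mi_accuracy(sub.recording, sub.events)
        assert res.trial_accuracy > 0.7

    def test_no_erd_is_chance(self):
        """erd_depth 0 leaves no class information: accuracy within a
        3-sigma binomial band of 0.5."""
        sub = self._session(4, erd=0.0)
        res = openloop_mi_accuracy(sub.recording, sub.events)
        sd = np.sqrt(0.25 / res.n_trials)
        assert abs(res.trial_accuracy - 0.5) <= 4 * sd

    def test_label_permutation_is_chance(self):
        """Shuffling trial labels destroys decodability."""
        sub = self._session(5, erd=0.5)
        ev = sub.events
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ev))
        shuffled = e.EventLog(
            time_s=ev.time_s, intended=ev.intended[perm],
            delivered=ev.intended[perm], correct=[True] * len(ev),
            word_id=ev.word_id, condition=ev.condition,
            duration_s=ev.duration_s,
        )
        res = openloop_mi_accuracy(sub.recording, shuffled)
        sd = np.sqrt(0.25 / res.n_trials)
        assert abs(res.trial_accuracy - 0.5) <= 4 * sd
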