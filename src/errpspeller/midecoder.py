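"""Motor-imagery decoding chain.

The standard SMR-BCI pipeline used both to drive the playback controller and
for open-loop sanity analysis: surface Laplacian spatial filtering, Welch
power-spectral-density features over the mu/beta range, discriminant-power
(Fisher-score) feature ranking, a Gaussian or LDA classifier emitting
posterior probabilities, sample rejection near chance, exponential evidence
accumulation and decision thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .classify import _fisher_from_arrays, train_lda
from .events import EventLog
from .layout import ChannelLayout
from .synth import ContinuousRecording

__all__ = [
    "DecoderConfig", "EvidenceState", "MIModel",
    "laplacian_filter", "welch_psd_features", "MIFeatureSet",
    "train_mi_classifier", "posterior", "accumulate_evidence",
    "openloop_mi_accuracy",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DecoderConfig:
    """Tunable parameters of the MI chain.

    ``alpha`` is the exponential-smoothing coefficient applied once per
    analysis step (62.5 ms at the default window hop); ``decision_threshold``
    is the accumulated-probability level that triggers a command;
    ``rejection_band`` discards single-sample posteriors too close to 0.5.
    """

    psd_window: float = 1.0            # s, analysis window (Welch over it)
    psd_overlap: float = 0.5           # fraction, Welch segment overlap
    band_range: tuple[float, float] = (4.0, 30.0)  # Hz
    bin_width: float = 2.0             # Hz
    n_features: int = 10
    alpha: float = 0.96
    decision_threshold: float = 0.8
    rejection_band: tuple[float, float] = (0.45, 0.55)
    window_step: float = 0.0625        # s, hop between analysis windows

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.5 < self.decision_threshold <= 1.0:
            raise ValueError("decision_threshold must be in (0.5, 1]")
        lo, hi = self.rejection_band
        if not (0.0 < lo < hi < 1.0) or abs((lo + hi) / 2.0 - 0.5) > 1e-9:
            raise ValueError("rejection_band must sit inside (0,1), symmetric "
                             "around 0.5")
        if not 0 < self.band_range[0] < self.band_range[1]:
            raise ValueError("band_range edges must be ordered and positive")
        if not 0.0 <= self.psd_overlap < 1.0:
            raise ValueError("psd_overlap must be in [0, 1)")


@dataclass
class EvidenceState:
    """Accumulated probability of the 'right' class, with its history."""

    p: float = 0.5
    history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")


def laplacian_filter(rec: ContinuousRecording,
                     layout: ChannelLayout | None = None,
                     radius: float = 0.22) -> ContinuousRecording:
    """Surface Laplacian: each channel minus the mean of its spatial
    neighbours (nearest-neighbour set within ``radius`` on the unit disc).
    Channels without neighbours pass through unchanged, logged."""
    layout = layout or rec.layout
    neighbors = layout.neighbor_sets(radius)
    out = rec.data.copy()
    lonely = []
    for i, nbr in enumerate(neighbors):
        if nbr:
            out[i] = rec.data[i] - rec.data[nbr].mean(axis=0)
        else:
            lonely.append(layout.names[i])
    if lonely:
        logger.info("laplacian_filter: no neighbours for %s; passed through",
                    lonely)
    return ContinuousRecording(data=out, rate=rec.rate, layout=rec.layout,
                               start_time=rec.start_time)


def welch_psd(x: np.ndarray, rate: float, cfg: DecoderConfig
              ) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD along the last axis: Hann-tapered segments of half the
    analysis window, overlapping by ``cfg.psd_overlap``. Returns
    (freqs, psd)."""
    n = x.shape[-1]
    nperseg = min(n, max(8, int(round(cfg.psd_window * rate / 2))))
    noverlap = int(nperseg * cfg.psd_overlap)
    return signal.welch(x, fs=rate, window="hann", nperseg=nperseg,
                        noverlap=noverlap, axis=-1)


@dataclass
class MIFeatureSet:
    """Per-analysis-window log-power features with trial bookkeeping."""

    values: np.ndarray          # windows x (channels * bins)
    channel_idx: np.ndarray
    bin_freqs: np.ndarray       # Hz centre of each feature's bin
    labels: np.ndarray          # True = 'right' MI class
    trial_ids: np.ndarray       # event index the window belongs to
    word_ids: np.ndarray
    times: np.ndarray           # window end times, seconds


def welch_psd_features(rec: ContinuousRecording, cfg: DecoderConfig,
                       events: EventLog) -> MIFeatureSet:
    """Log band-power features for sliding windows inside each MI period.

    Every event's MI period ``[time - duration, time]`` is tiled with
    ``cfg.psd_window``-long windows hopping by ``cfg.window_step``; each
    window yields, per channel, Welch PSD power averaged into
    ``cfg.bin_width``-wide bins across ``cfg.band_range``, log10-transformed.
    The window label is the event's intended MI class.
    """
    lo, hi = cfg.band_range
    if hi > rec.rate / 2:
        raise ValueError(f"band edge {hi:g} Hz exceeds Nyquist {rec.rate / 2:g} Hz")
    win_n = int(round(cfg.psd_window * rec.rate))
    step_n = max(1, int(round(cfg.window_step * rec.rate)))
    edges = np.arange(lo, hi + 1e-9, cfg.bin_width)
    if len(edges) < 2:
        raise ValueError("band_range narrower than one bin")
    centers = (edges[:-1] + edges[1:]) / 2.0

    # averaging matrix mapping Welch frequency bins onto band-power bins
    nperseg = min(win_n, max(8, int(round(cfg.psd_window * rec.rate / 2))))
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / rec.rate)
    avg = np.zeros((len(centers), len(freqs)))
    for b, (a_lo, a_hi) in enumerate(zip(edges[:-1], edges[1:])):
        sel = (freqs >= a_lo) & (freqs < a_hi)
        if not sel.any():
            raise ValueError("bin_width finer than the Welch resolution")
        avg[b, sel] = 1.0 / sel.sum()

    rows, labels, trial_ids, word_ids, times = [], [], [], [], []
    for ev in range(len(events)):
        t1 = events.time_s[ev]
        t0 = max(rec.start_time, t1 - events.duration_s[ev])
        s0 = int(round((t0 - rec.start_time) * rec.rate))
        s1 = int(round((t1 - rec.start_time) * rec.rate))
        if s1 - s0 < win_n:
            logger.info("MI period of event %d shorter than the PSD window; "
                        "skipped", ev)
            continue
        for start in range(s0, s1 - win_n + 1, step_n):
            seg = rec.data[:, start:start + win_n]
            _, psd = welch_psd(seg, rec.rate, cfg)  # (n_ch, n_freqs)
            binned = psd @ avg.T
            rows.append(np.log10(np.maximum(binned, 1e-20)).ravel())
            labels.append(events.intended[ev] == "right")
            trial_ids.append(ev)
            word_ids.append(events.word_id[ev])
            times.append(rec.start_time + (start + win_n) / rec.rate)
    if not rows:
        raise ValueError("no MI analysis window fits inside any trial")

    n_ch = rec.data.shape[0]
    n_bins = len(centers)
    return MIFeatureSet(
        values=np.asarray(rows),
        channel_idx=np.repeat(np.arange(n_ch), n_bins),
        bin_freqs=np.tile(centers, n_ch),
        labels=np.asarray(labels, dtype=bool),
        trial_ids=np.asarray(trial_ids, dtype=int),
        word_ids=np.asarray(word_ids, dtype=int),
        times=np.asarray(times, dtype=float),
    )


@dataclass
class MIModel:
    """Trained MI classifier over the top discriminant-power features.

    ``kind='gaussian'``: one prototype per class with diagonal covariance,
    posteriors by Bayes rule with training-frequency priors.
    ``kind='lda'``: shrinkage LDA posteriors (the offline analysis default).
    """

    kind: str
    feature_idx: np.ndarray
    means: np.ndarray | None = None       # 2 x k (left, right)
    variances: np.ndarray | None = None   # 2 x k
    log_priors: np.ndarray | None = None  # 2
    lda = None


def train_mi_classifier(values: np.ndarray, labels: np.ndarray,
                        cfg: DecoderConfig, kind: str = "gaussian") -> MIModel:
    """Rank features by discriminant power (Fisher score), keep the top
    ``cfg.n_features``, and fit the requested classifier. ``labels`` is
    boolean with True = 'right'."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both MI classes required")
    values = np.asarray(values, dtype=float)
    scores = _fisher_from_arrays(values, labels)
    k = min(cfg.n_features, values.shape[1])
    idx = np.sort(np.argsort(-scores, kind="stable")[:k])
    x = values[:, idx]

    if kind == "lda":
        model = MIModel(kind="lda", feature_idx=idx)
        model.lda = train_lda(x, labels)
        return model
    if kind != "gaussian":
        raise ValueError("kind must be 'gaussian' or 'lda'")

    means = np.stack([x[~labels].mean(axis=0), x[labels].mean(axis=0)])
    var = np.stack([x[~labels].var(axis=0), x[labels].var(axis=0)])
    floor = 1e-6 * max(float(var.max()), 1e-12)
    if np.any(var < floor):
        logger.info("flooring %d degenerate variances", int((var < floor).sum()))
        var = np.maximum(var, floor)
    priors = np.array([float((~labels).mean()), float(labels.mean())])
    return MIModel(kind="gaussian", feature_idx=idx, means=means,
                   variances=var, log_priors=np.log(priors))


def posterior(model: MIModel, feature_vector: np.ndarray) -> tuple[float, float]:
    """Posterior probability pair (p_left, p_right), summing to 1."""
    x = np.asarray(feature_vector, dtype=float)[model.feature_idx]
    if model.kind == "lda":
        proba = model.lda.estimator.predict_proba(x[None, :])[0]
        return float(proba[0]), float(proba[1])
    log_lik = -0.5 * np.sum(
        np.log(2 * np.pi * model.variances)
        + (x[None, :] - model.means) ** 2 / model.variances, axis=1,
    ) + model.log_priors
    log_lik -= log_lik.max()
    w = np.exp(log_lik)
    w /= w.sum()
    return float(w[0]), float(w[1])


def _posterior_right_batch(model: MIModel, values: np.ndarray) -> np.ndarray:
    """Vectorised p(right) for many feature rows (same maths as
    :func:`posterior`)."""
    x = np.asarray(values, dtype=float)[:, model.feature_idx]
    if model.kind == "lda":
        return model.lda.estimator.predict_proba(x)[:, 1]
    log_lik = -0.5 * np.sum(
        np.log(2 * np.pi * model.variances)[None, :, :]
        + (x[:, None, :] - model.means[None, :, :]) ** 2
        / model.variances[None, :, :], axis=2,
    ) + model.log_priors[None, :]
    log_lik -= log_lik.max(axis=1, keepdims=True)
    w = np.exp(log_lik)
    return w[:, 1] / w.sum(axis=1)


def accumulate_evidence(state: EvidenceState, posterior_t: float,
                        cfg: DecoderConfig) -> tuple[EvidenceState, str | None]:
    """One evidence-accumulation step.

    ``posterior_t`` is the single-sample probability of the 'right' class.
    Samples inside the rejection band leave the state untouched; otherwise
    ``p <- alpha * p + (1 - alpha) * posterior_t``. A decision fires when
    ``p`` reaches the threshold ('right') or its mirror ('left'); the state
    then resets to 0.5.
    """
    if not 0.0 <= posterior_t <= 1.0:
        raise ValueError("posterior_t must be in [0, 1]")
    lo, hi = cfg.rejection_band
    if lo < posterior_t < hi:
        new_p = state.p
    else:
        new_p = cfg.alpha * state.p + (1.0 - cfg.alpha) * posterior_t
    history = state.history + [new_p]
    decision = None
    if new_p >= cfg.decision_threshold:
        decision = "right"
    elif new_p <= 1.0 - cfg.decision_threshold:
        decision = "left"
    if decision is not None:
        return EvidenceState(p=0.5, history=history), decision
    return EvidenceState(p=new_p, history=history), None


def _trial_decision(posteriors: np.ndarray, cfg: DecoderConfig) -> str:
    """Run accumulation over a trial's window posteriors; if no threshold
    crossing occurs, fall back to the side of the final accumulated p."""
    state = EvidenceState()
    last_p = 0.5
    for q in posteriors:
        state, decision = accumulate_evidence(state, float(q), cfg)
        if decision is not None:
            return decision
        last_p = state.p
    return "right" if last_p >= 0.5 else "left"


@dataclass
class OpenLoopResult:
    sample_accuracy: float
    trial_accuracy: float
    per_fold_sample: np.ndarray
    per_fold_trial: np.ndarray
    n_trials: int


def openloop_mi_accuracy(rec: ContinuousRecording, events: EventLog,
                         cfg: DecoderConfig | None = None,
                         kind: str = "lda") -> OpenLoopResult:
    """Word-wise cross-validated MI decoding of a session's MI periods.

    Single-sample accuracy scores each analysis window against the trial's
    intended class; trial accuracy feeds each held-out trial's window
    posteriors through evidence accumulation and scores the decision.
    """
    cfg = cfg or DecoderConfig()
    lap = laplacian_filter(rec)
    feats = welch_psd_features(lap, cfg, events)
    words = sorted(set(feats.word_ids.tolist()))
    if len(words) < 2:
        raise ValueError("need at least 2 words for cross-validation")

    fold_sample, fold_trial = [], []
    n_trials = 0
    for w in words:
        test = feats.word_ids == w
        y_tr = feats.labels[~test]
        if y_tr.all() or not y_tr.any():
            logger.info("fold %s skipped: training data single-class", w)
            continue
        model = train_mi_classifier(feats.values[~test], y_tr, cfg, kind)
        post_right = _posterior_right_batch(model, feats.values[test])
        y_te = feats.labels[test]
        fold_sample.append(float(np.mean((post_right >= 0.5) == y_te)))
        correct_trials = []
        for trial in np.unique(feats.trial_ids[test]):
            sel = feats.trial_ids[test] == trial
            order = np.argsort(feats.times[test][sel])
            q = post_right[sel][order]
            decision = _trial_decision(q, cfg)
            truth = "right" if feats.labels[test][sel][0] else "left"
            correct_trials.append(decision == truth)
        fold_trial.append(float(np.mean(correct_trials)))
        n_trials += len(correct_trials)
    if len(fold_sample) < 2:
        raise ValueError("fewer than 2 usable folds")
    return OpenLoopResult(
        sample_accuracy=float(np.mean(fold_sample)),
        trial_accuracy=float(np.mean(fold_trial)),
        per_fold_sample=np.asarray(fold_sample),
        per_fold_trial=np.asarray(fold_trial),
        n_trials=n_trials,
    )
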