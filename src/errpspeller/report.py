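"""Figure and table rendering for a completed analysis run.

Produces the customary ErrP-study artefacts: per-subject AUC/accuracy bars
with fold-SD errorbars and dashed chance lines, grand-average waveforms
before/after realignment with standard-deviation bands, a wrong-minus-
correct scalp topography averaged over the negativity and positivity
windows, Fisher-score channel x time maps, and a machine-readable TSV
summary.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classify import CVResult
from .layout import ChannelLayout
from .preprocess import EpochSet
from .realign import RealignResult, grand_average
from .stats import binomial_chance_threshold

__all__ = ["render_report", "SUMMARY_COLUMNS", "TOPO_WINDOWS"]

SUMMARY_COLUMNS = ("subject", "condition", "fold", "auc", "accuracy",
                   "balanced_accuracy", "recall_error", "recall_correct",
                   "n_test")

#: Averaging windows (s) for the difference topographies: the fronto-central
#: negativity and the later positivity.
TOPO_WINDOWS = {"negativity": (0.20, 0.30), "positivity": (0.45, 0.55)}


def _bar_chart(results: dict, out: Path) -> None:
    subjects = sorted(results)
    conds = ("FBon", "FBoff")
    fig, axes = plt.subplots(2, 1, figsize=(1.2 * len(subjects) + 3, 6),
                             sharex=True)
    width = 0.38
    xs = np.arange(len(subjects))
    for ax, attr, chance_of in (
        (axes[0], "auc", lambda cv: 0.5),
        (axes[1], "accuracy",
         lambda cv: binomial_chance_threshold(cv.n_test_total)),
    ):
        for j, cond in enumerate(conds):
            means = [getattr(results[s][cond], f"mean_{attr}") for s in subjects]
            sds = [getattr(results[s][cond], f"sd_{attr}") for s in subjects]
            ax.bar(xs + (j - 0.5) * width, means, width, yerr=sds,
                   capsize=3, label=cond)
        chance = np.mean([chance_of(results[s][conds[1]]) for s in subjects])
        ax.axhline(chance, color="red", linestyle="--", linewidth=1,
                   label="chance")
        ax.set_ylabel(attr.upper() if attr == "auc" else "Accuracy")
        ax.set_ylim(0, 1)
        ax.legend(fontsize=8)
    axes[1].set_xticks(xs, subjects)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def _grand_average_plot(epochs: EpochSet, aligned: EpochSet, channel: str,
                        out: Path) -> None:
    ci = epochs.channel_index(channel)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
    for ax, eps, title in ((axes[0], epochs, "before realignment"),
                           (axes[1], aligned, "after realignment")):
        t = eps.times * 1e3
        for label, color in (("correct", "tab:blue"), ("error", "tab:red")):
            mask = eps.is_error if label == "error" else ~eps.is_error
            if not mask.any():
                continue
            ga = grand_average(eps, label)[ci]
            sd = eps.data[mask, ci, :].std(axis=0)
            ax.plot(t, ga, color=color, label=label)
            ax.fill_between(t, ga - sd, ga + sd, color=color, alpha=0.2)
        ax.axvline(0, color="k", linewidth=0.5)
        ax.set_title(f"{channel}, {title}")
        ax.set_xlabel("time after command (ms)")
    axes[0].set_ylabel("amplitude (uV)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def _topography(epochs: EpochSet, layout: ChannelLayout, out: Path) -> None:
    diff = grand_average(epochs, "error") - grand_average(epochs, "correct")
    t = epochs.times
    fig, axes = plt.subplots(1, len(TOPO_WINDOWS), figsize=(8, 3.5))
    idx = [layout.index(c) for c in epochs.channels]
    pos = layout.positions[idx]
    for ax, (name, (w0, w1)) in zip(np.atleast_1d(axes), TOPO_WINDOWS.items()):
        sel = (t >= w0) & (t <= w1)
        vals = diff[:, sel].mean(axis=1)
        vmax = np.abs(vals).max() or 1.0
        sc = ax.scatter(pos[:, 0], pos[:, 1], c=vals, s=400, cmap="RdBu_r",
                        vmin=-vmax, vmax=vmax, edgecolors="k")
        for (x, y), ch in zip(pos, epochs.channels):
            ax.annotate(ch, (x, y), ha="center", va="center", fontsize=6)
        circle = plt.Circle((0, 0), 1.0, fill=False, color="k", linewidth=0.8)
        ax.add_patch(circle)
        ax.set_xlim(-1.1, 1.1)
        ax.set_ylim(-1.1, 1.1)
        ax.set_aspect("equal")
        ax.set_axis_off()
        ax.set_title(f"wrong - correct, {name} [{w0:.2f}, {w1:.2f}] s")
        fig.colorbar(sc, ax=ax, shrink=0.7, label="uV")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def _fisher_map(scores: np.ndarray, epochs: EpochSet, out: Path) -> None:
    grid = scores.reshape(epochs.n_channels, epochs.n_times)
    fig, ax = plt.subplots(figsize=(6, 3.2))
    extent = (epochs.times[0] * 1e3, epochs.times[-1] * 1e3,
              epochs.n_channels - 0.5, -0.5)
    im = ax.imshow(grid, aspect="auto", extent=extent, cmap="viridis")
    ax.set_yticks(range(epochs.n_channels), epochs.channels, fontsize=7)
    ax.set_xlabel("time after command (ms)")
    fig.colorbar(im, ax=ax, label="Fisher score")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def render_report(results: dict, epochs: EpochSet | None = None,
                  realign_result: RealignResult | None = None,
                  fisher: np.ndarray | None = None,
                  layout: ChannelLayout | None = None,
                  out_dir=None, channel: str = "CPz") -> list[Path]:
    """Write the run's figures and summary table into ``out_dir``.

    ``results`` maps subject -> condition -> :class:`CVResult`. The epoch-
    level figures (grand averages, topography, Fisher map) are drawn for the
    optionally supplied example subject's data. Returns the written paths.
    """
    if out_dir is None:
        raise ValueError("out_dir is required")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"output directory {out_dir} is not writable") from exc

    written: list[Path] = []

    rows = []
    for subject, conds in sorted(results.items()):
        for cond, cv in sorted(conds.items()):
            for fold, m in cv.per_fold.items():
                rows.append((subject, cond, fold, m.auc, m.accuracy,
                             m.balanced_accuracy, m.recall_error,
                             m.recall_correct, m.n_test))
    summary = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    path = out_dir / "summary.tsv"
    summary.to_csv(path, sep="\t", index=False)
    written.append(path)

    path = out_dir / "detection_performance.png"
    _bar_chart(results, path)
    written.append(path)

    if epochs is not None and realign_result is not None:
        path = out_dir / "grand_averages.png"
        _grand_average_plot(epochs, realign_result.aligned, channel, path)
        written.append(path)
    if epochs is not None and layout is not None:
        path = out_dir / "topography_difference.png"
        _topography(epochs, layout, path)
        written.append(path)
    if fisher is not None and epochs is not None:
        path = out_dir / "fisher_map.png"
        _fisher_map(fisher, epochs, path)
        written.append(path)
    return written
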