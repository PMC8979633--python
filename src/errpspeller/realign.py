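"""Woody-style latency realignment of ErrP epochs.

Single-trial ErrPs jitter in latency, which smears the grand average and
dilutes time-domain features. The classic remedy iterates: compute the
grand average of the error class, shift every error epoch to the lag that
maximises its correlation with that template, recompute the template, and
repeat until the shifts settle.

Conventions (used everywhere in this package):

* the stored shift is the *correction applied to the epoch* — positive means
  the epoch content was moved later in time; an epoch whose response arrived
  3 samples late therefore receives a shift of -3 samples;
* correlation is Pearson correlation after per-channel mean removal, summed
  across channels;
* shifted epochs are edge-padded by repeating the boundary sample (no
  zero-fill transients);
* only error epochs drive and receive training-time realignment (the ErrP
  carries the latency structure); at test time shifts are applied
  label-blind against the frozen training template, so no label leaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .preprocess import EpochSet

__all__ = ["RealignResult", "grand_average", "best_shift", "realign_epochs",
           "apply_template_shifts", "shift_epoch", "realigned_data"]


@dataclass
class RealignResult:
    """Outcome of iterative realignment.

    ``aligned`` has per-epoch ``shifts`` populated (seconds); ``template`` is
    the error-class grand average at convergence; ``objective_trace`` records
    the mean epoch-template correlation per iteration (non-decreasing).
    """

    aligned: EpochSet
    template: np.ndarray
    iterations: int
    objective_trace: np.ndarray
    converged: bool


def shift_epoch(epoch: np.ndarray, shift: int) -> np.ndarray:
    """Move a (channels x time) epoch ``shift`` samples later (positive) or
    earlier (negative), repeating the boundary sample to fill the edge."""
    if shift == 0:
        return epoch.copy()
    out = np.empty_like(epoch)
    if shift > 0:
        out[:, shift:] = epoch[:, :-shift]
        out[:, :shift] = epoch[:, :1]
    else:
        out[:, :shift] = epoch[:, -shift:]
        out[:, shift:] = epoch[:, -1:]
    return out


def realigned_data(epochs: EpochSet) -> np.ndarray:
    """The epoch tensor with each epoch's stored shift correction applied.

    ``EpochSet.data`` always holds the raw cut; shifts live in metadata and
    are applied here (and inside :func:`grand_average` and the feature
    builder) so that re-estimating shifts never compounds.
    """
    shifts_samp = np.round(epochs.shifts * epochs.rate).astype(int)
    if not np.any(shifts_samp):
        return epochs.data.copy()
    return np.stack([shift_epoch(epochs.data[i], shifts_samp[i])
                     for i in range(len(epochs))])


def _pooled_correlation(epoch: np.ndarray, template: np.ndarray) -> float:
    """Sum over channels of Pearson correlation; zero-variance channels
    contribute 0 (so a flat epoch scores 0 at every lag)."""
    e = epoch - epoch.mean(axis=1, keepdims=True)
    t = template - template.mean(axis=1, keepdims=True)
    num = np.sum(e * t, axis=1)
    den = np.sqrt(np.sum(e ** 2, axis=1) * np.sum(t ** 2, axis=1))
    valid = den > 0
    return float(np.sum(num[valid] / den[valid]))


def grand_average(epochs: EpochSet, label: str = "error") -> np.ndarray:
    """Pointwise mean (channels x time) over epochs of one class, with any
    stored shifts applied first."""
    if label not in ("error", "correct"):
        raise ValueError("label must be 'error' or 'correct'")
    mask = epochs.is_error if label == "error" else ~epochs.is_error
    if not np.any(mask):
        raise ValueError(f"no {label!r} epochs to average")
    shifts_samp = np.round(epochs.shifts * epochs.rate).astype(int)
    acc = np.zeros(epochs.data.shape[1:])
    for i in np.nonzero(mask)[0]:
        acc += shift_epoch(epochs.data[i], shifts_samp[i])
    return acc / int(np.sum(mask))


def best_shift(epoch: np.ndarray, template: np.ndarray, max_shift: int) -> int:
    """Lag in [-max_shift, +max_shift] samples whose applied correction
    maximises the pooled epoch-template correlation.

    Ties break toward the smallest absolute lag, then toward the negative
    lag; a flat epoch therefore returns 0.
    """
    n_t = epoch.shape[1]
    if max_shift >= n_t / 2:
        raise ValueError("max_shift must be below half the window length")
    best_lag, best_score = 0, -np.inf
    for mag in range(max_shift + 1):
        lags = (0,) if mag == 0 else (-mag, mag)
        for lag in lags:
            score = _pooled_correlation(shift_epoch(epoch, lag), template)
            if score > best_score + 1e-12:
                best_lag, best_score = lag, score
    return best_lag


def realign_epochs(epochs: EpochSet, max_shift: float = 0.075,
                   max_iter: int = 20, tol: int = 1) -> RealignResult:
    """Iteratively realign the error-class epochs to their grand average.

    ``max_shift`` is in seconds; ``tol`` is the per-iteration shift change
    (samples) below which the loop stops. Correct-class epochs are never
    shifted. If the objective would decrease after a template update the
    previous shifts are kept and iteration stops, so ``objective_trace`` is
    non-decreasing. Hitting ``max_iter`` returns a result flagged
    ``converged=False`` with a warning rather than raising.
    """
    err_idx = np.nonzero(epochs.is_error)[0]
    if len(err_idx) < 2:
        raise ValueError("need at least 2 error epochs to realign")
    m = int(round(max_shift * epochs.rate))
    shifts = np.round(epochs.shifts * epochs.rate).astype(int)

    def template_and_objective(cur: np.ndarray) -> tuple[np.ndarray, float]:
        shifted = [shift_epoch(epochs.data[i], cur[i]) for i in err_idx]
        tpl = np.mean(shifted, axis=0)
        obj = float(np.mean([_pooled_correlation(s, tpl) for s in shifted]))
        return tpl, obj

    template, objective = template_and_objective(shifts)
    trace = [objective]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        new_shifts = shifts.copy()
        for i in err_idx:
            new_shifts[i] = best_shift(epochs.data[i], template, m)
        max_change = int(np.max(np.abs(new_shifts - shifts))) if len(err_idx) else 0
        new_template, new_objective = template_and_objective(new_shifts)
        if new_objective < objective - 1e-12:
            iterations -= 1  # the rejected update does not count
            converged = True
            break
        shifts, template, objective = new_shifts, new_template, new_objective
        trace.append(objective)
        if max_change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"realignment did not converge within {max_iter} iterations",
            stacklevel=2)

    aligned = replace(epochs, data=epochs.data.copy(),
                      shifts=shifts / epochs.rate)
    return RealignResult(aligned=aligned, template=template,
                         iterations=iterations,
                         objective_trace=np.asarray(trace), converged=converged)


def apply_template_shifts(test_epochs: EpochSet, template: np.ndarray,
                          max_shift: float = 0.075) -> EpochSet:
    """Shift every test epoch (label-blind) to best match a training-fold
    error template; the resulting ``shifts`` are bounded by ``max_shift``."""
    m = int(round(max_shift * test_epochs.rate))
    shifts = np.array([
        best_shift(test_epochs.data[i], template, m)
        for i in range(len(test_epochs))
    ], dtype=float)
    return replace(test_epochs, data=test_epochs.data.copy(),
                   shifts=shifts / test_epochs.rate)
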