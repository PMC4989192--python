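"""Epoching, artifact rejection, averaging, smoothing and baselines.

The processing chain mirrors standard ERP practice for slow preparatory
components: continuous EEG is segmented into 2000 ms epochs (1100 ms
before to 900 ms after stimulus onset by default), epochs with any sample
exceeding +/-120 uV on any channel are rejected, retained epochs are
averaged per condition, averages are low-pass filtered with a zero-phase
4th-order Butterworth at 25 Hz, and the baseline is the mean voltage over
the initial 200 ms of the epoch (two alternative schemes are provided for
control analyses).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ContinuousRecording", "EpochSet", "Evoked",
    "segment", "reject_artifacts", "average", "smooth", "baseline_correct",
    "build_condition_evokeds", "build_control_evokeds", "BASELINE_SCHEMES",
]


@dataclass
class ContinuousRecording:
    """Multichannel voltage matrix (channels x samples, microvolts)."""

    data: np.ndarray
    channels: tuple[str, ...]
    sfreq_hz: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sfreq_hz * 1000.0

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"unknown channel label {name!r}") from None


def n_epoch_samples(start_ms: float, end_ms: float, sfreq_hz: float) -> int:
    """Number of samples in an epoch window, both endpoints included."""
    return int(round((end_ms - start_ms) / 1000.0 * sfreq_hz)) + 1


@dataclass
class EpochSet:
    """Per-trial segments: epochs x channels x samples, with metadata."""

    data: np.ndarray
    channels: tuple[str, ...]
    sfreq_hz: float
    lock: str
    start_ms: float
    end_ms: float
    trial_index: np.ndarray
    conditions: np.ndarray            # str labels, "" when unlabelled
    rejected: np.ndarray = field(default=None)  # bool mask
    n_dropped: int = 0                # epochs outside the recording span

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(len(self.data), dtype=bool)

    @property
    def n_epochs(self) -> int:
        return len(self.data)

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.start_ms + np.arange(n) * 1000.0 / self.sfreq_hz

    @property
    def retained(self) -> np.ndarray:
        return ~self.rejected

    def retained_counts(self) -> dict[str, int]:
        """Retained-epoch count per condition label."""
        out: dict[str, int] = {}
        for cond in np.unique(self.conditions):
            out[str(cond)] = int(np.sum(self.retained
                                        & (self.conditions == cond)))
        return out

    def subset(self, mask: np.ndarray) -> "EpochSet":
        return replace(self, data=self.data[mask],
                       trial_index=self.trial_index[mask],
                       conditions=self.conditions[mask],
                       rejected=self.rejected[mask])


@dataclass
class Evoked:
    """Across-trial average for one condition (channels x samples, uV)."""

    data: np.ndarray
    channels: tuple[str, ...]
    sfreq_hz: float
    start_ms: float
    n_epochs: int
    condition: str = ""
    baseline: tuple[float, float] | None = None

    @property
    def times_ms(self) -> np.ndarray:
        return self.start_ms + np.arange(self.data.shape[1]) * 1000.0 / self.sfreq_hz

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"unknown channel label {name!r}") from None


def segment(recording: ContinuousRecording,
            events: pd.DataFrame,
            lock: str = "stimulus",
            window: tuple[float, float] = (-1100.0, 900.0),
            condition_filter: Callable[[pd.DataFrame], np.ndarray] | np.ndarray | None = None,
            conditions: np.ndarray | None = None) -> EpochSet:
    """Cut one epoch per selected event from the continuous recording.

    ``lock='stimulus'`` centers epochs on ``onset_ms``; ``lock='response'``
    on ``onset_ms + rt_ms`` and silently restricts to responded trials.
    ``condition_filter`` may be a boolean mask over event rows or a
    callable producing one.  ``conditions`` attaches a per-epoch label
    (aligned with the filtered events).  Epochs that would extend past
    either end of the recording are dropped and counted, not an error.
    """
    start_ms, end_ms = window
    if start_ms > end_ms:
        raise ValueError("epoch window must have start <= end")
    sel = events
    if condition_filter is not None:
        mask = (condition_filter(events) if callable(condition_filter)
                else np.asarray(condition_filter, dtype=bool))
        sel = events.loc[mask]
    if lock == "stimulus":
        lock_ms = sel["onset_ms"].to_numpy(dtype=float)
        keep = np.ones(len(sel), dtype=bool)
    elif lock == "response":
        rt = sel["rt_ms"].to_numpy(dtype=float)
        keep = np.isfinite(rt) & (sel["response"].to_numpy() == 1)
        lock_ms = sel["onset_ms"].to_numpy(dtype=float) + rt
    else:
        raise ValueError(f"unknown lock {lock!r}")

    sel = sel.loc[keep]
    lock_ms = lock_ms[keep]
    if conditions is None:
        cond = np.array([""] * len(sel), dtype=object)
    else:
        cond = np.asarray(conditions, dtype=object)[keep]

    sf = recording.sfreq_hz
    n = n_epoch_samples(start_ms, end_ms, sf)
    lock_sample = np.round(lock_ms / 1000.0 * sf).astype(np.int64)
    first = lock_sample + int(round(start_ms / 1000.0 * sf))
    in_bounds = (first >= 0) & (first + n <= recording.n_samples)
    n_dropped = int(np.sum(~in_bounds))

    first = first[in_bounds]
    idx = first[:, None] + np.arange(n)[None, :]
    data = recording.data[:, idx]              # ch x ep x n
    data = np.ascontiguousarray(np.moveaxis(data, 0, 1))

    return EpochSet(
        data=data, channels=recording.channels, sfreq_hz=sf, lock=lock,
        start_ms=start_ms, end_ms=end_ms,
        trial_index=sel.index.to_numpy()[in_bounds],
        conditions=cond[in_bounds], n_dropped=n_dropped,
    )


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 120.0) -> EpochSet:
    """Mark epochs whose absolute voltage strictly exceeds the threshold.

    The rule is per-epoch and order-independent: an epoch is rejected iff
    any sample on any channel has |v| > threshold; |v| equal to the
    threshold is retained.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    peak = np.max(np.abs(epochs.data), axis=(1, 2))
    return replace(epochs, rejected=peak > threshold_uv)


def average(epochs: EpochSet, condition: str | None = None) -> Evoked:
    """Pointwise mean over retained epochs (optionally of one condition)."""
    mask = epochs.retained.copy()
    if condition is not None:
        mask &= epochs.conditions == condition
    k = int(np.sum(mask))
    if k == 0:
        raise ValueError(
            f"no retained epochs{f' for condition {condition!r}' if condition else ''}")
    return Evoked(
        data=epochs.data[mask].mean(axis=0), channels=epochs.channels,
        sfreq_hz=epochs.sfreq_hz, start_ms=epochs.start_ms, n_epochs=k,
        condition=condition or "",
    )


def smooth(evoked: Evoked, cutoff_hz: float = 25.0, order: int = 4) -> Evoked:
    """Zero-phase Butterworth low-pass on the average waveform.

    A 4th-order filter (24 dB/octave) applied forward and backward via
    ``filtfilt`` so component latencies are not delayed; the two passes
    double the stopband attenuation.
    """
    if cutoff_hz >= evoked.sfreq_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(order, cutoff_hz, btype="low",
                        fs=evoked.sfreq_hz, output="sos")
    out = signal.sosfiltfilt(sos, evoked.data, axis=-1)
    return replace(evoked, data=out)


#: named baseline schemes -> interval in epoch time (ms); the default
#: scheme resolves against the epoch start at call time
BASELINE_SCHEMES = ("epoch_initial_200ms", "interval_-1500_-1300",
                    "prestim_100ms")


def _baseline_interval(scheme: str, start_ms: float) -> tuple[float, float]:
    if scheme == "epoch_initial_200ms":
        return (start_ms, start_ms + 200.0)
    if scheme == "interval_-1500_-1300":
        return (-1500.0, -1300.0)
    if scheme == "prestim_100ms":
        return (-100.0, 0.0)
    raise ValueError(f"unknown baseline scheme {scheme!r}")


def baseline_correct(evoked: Evoked, scheme: str = "epoch_initial_200ms") -> Evoked:
    """Subtract the per-channel mean voltage over the scheme's interval."""
    lo, hi = _baseline_interval(scheme, evoked.start_ms)
    t = evoked.times_ms
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not mask.any():
        raise ValueError(
            f"baseline interval ({lo}, {hi}) ms lies outside the epoch")
    base = evoked.data[:, mask].mean(axis=1, keepdims=True)
    return replace(evoked, data=evoked.data - base, baseline=(lo, hi))


def build_condition_evokeds(
        recording: ContinuousRecording,
        events: pd.DataFrame,
        labels: pd.DataFrame,
        window: tuple[float, float] = (-1100.0, 900.0),
        threshold_uv: float = 120.0,
        cutoff_hz: float = 25.0,
        baseline_scheme: str = "epoch_initial_200ms",
) -> tuple[dict[str, Evoked], EpochSet]:
    """Stimulus-locked condition averages: post_error, post_correct, error.

    ``labels`` is the per-trial context table from
    :func:`posterp.behavior.classify_trials` (aligned with ``events``).
    Current Go and No-go trials are pooled within each context; the
    ``error`` condition is the false-alarm trials themselves.  A condition
    with zero retained epochs is absent from the result.  Returns the
    evokeds and the rejected-marked epoch set (whose per-condition counts
    feed the inclusion decision).
    """
    cond = np.array([""] * len(events), dtype=object)
    cond[labels["post_correct"].to_numpy(dtype=bool)] = "post_correct"
    cond[labels["post_error"].to_numpy(dtype=bool)] = "post_error"
    # the error condition is segmented separately so an FA trial can
    # contribute both as an error and as a post_* current trial
    epochs = segment(recording, events, "stimulus", window, conditions=cond)
    epochs = reject_artifacts(epochs, threshold_uv)

    is_fa = (labels["outcome"] == "false_alarm").to_numpy()
    err = segment(recording, events, "stimulus", window,
                  condition_filter=is_fa,
                  conditions=np.array(["error"] * int(is_fa.sum()), dtype=object))
    err = reject_artifacts(err, threshold_uv)

    evokeds: dict[str, Evoked] = {}
    for name, eps in (("post_error", epochs), ("post_correct", epochs),
                      ("error", err)):
        try:
            ev = average(eps, name)
        except ValueError:
            continue
        ev = smooth(ev, cutoff_hz)
        evokeds[name] = baseline_correct(ev, baseline_scheme)
    return evokeds, err


def build_control_evokeds(
        recording: ContinuousRecording,
        events: pd.DataFrame,
        labels: pd.DataFrame,
        threshold_uv: float = 120.0,
        cutoff_hz: float = 25.0,
) -> dict[str, dict[str, Evoked]]:
    """The three alternative segmentation/baseline control schemes.

    ``response_locked``: error vs correct-hit trials locked to the button
    press, long window, -1500/-1300 ms baseline — separates the error
    complex from next-trial preparation in response time.
    ``stimulus_locked_previous``: the same trials locked to their own
    stimulus with a traditional 100 ms pre-stimulus baseline.
    ``expanded_epoch``: post-error vs post-correct trials in a window
    expanded to 2000 ms before onset, with the -1500/-1300 ms baseline,
    exposing the previous trial's activity inside the epoch.
    """
    out: dict[str, dict[str, Evoked]] = {}
    outcome = labels["outcome"].to_numpy()
    prev_cond = np.array([""] * len(events), dtype=object)
    prev_cond[outcome == "false_alarm"] = "error"
    prev_cond[outcome == "hit"] = "correct"

    def _conditions(epochs: EpochSet, cutoff: float,
                    scheme: str) -> dict[str, Evoked]:
        res = {}
        for name in ("error", "correct", "post_error", "post_correct"):
            try:
                ev = average(epochs, name)
            except ValueError:
                continue
            res[name] = baseline_correct(smooth(ev, cutoff), scheme)
        return res

    eps = segment(recording, events, "response", (-1600.0, 1600.0),
                  conditions=prev_cond)
    eps = reject_artifacts(eps, threshold_uv)
    out["response_locked"] = _conditions(eps, cutoff_hz, "interval_-1500_-1300")

    eps = segment(recording, events, "stimulus", (-1600.0, 1600.0),
                  conditions=prev_cond)
    eps = reject_artifacts(eps, threshold_uv)
    out["stimulus_locked_previous"] = _conditions(eps, cutoff_hz,
                                                  "prestim_100ms")

    cond = np.array([""] * len(events), dtype=object)
    cond[labels["post_correct"].to_numpy(dtype=bool)] = "post_correct"
    cond[labels["post_error"].to_numpy(dtype=bool)] = "post_error"
    eps = segment(recording, events, "stimulus", (-2000.0, 900.0),
                  conditions=cond)
    eps = reject_artifacts(eps, threshold_uv)
    out["expanded_epoch"] = _conditions(eps, cutoff_hz, "interval_-1500_-1300")
    return out
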