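"""Window discovery and quantification of ERP components.

Slow preparatory components (the prefrontal negativity pN and the
Bereitschaftspotential BP) are quantified as the mean amplitude over a
fixed pre-stimulus window per channel; the visual P1 and N1 as the
extremum amplitude and its latency inside a post-stimulus search window.
Analysis windows can also be discovered from the data: a sample-by-sample
paired t-test between conditions across subjects, followed by selection
of the longest run of consecutively significant samples lasting at least
40 ms (a guard against isolated-sample false positives).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ComponentWindowSpec
from .erp import Evoked

__all__ = [
    "SignificanceMask", "ComponentWindow",
    "samplewise_paired_ttest", "select_window",
    "mean_amplitude", "peak_measure", "measure_components",
]


@dataclass
class SignificanceMask:
    """Per channel x sample paired-t statistics between two conditions."""

    channels: tuple[str, ...]
    times_ms: np.ndarray
    t: np.ndarray          # channels x samples
    p: np.ndarray
    significant: np.ndarray
    alpha: float
    n_subjects: int

    def for_channel(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = self.channels.index(name)
        return self.t[i], self.p[i], self.significant[i]


@dataclass
class ComponentWindow:
    component: str
    channels: tuple[str, ...]
    start_ms: float
    end_ms: float


def samplewise_paired_ttest(subject_evokeds: Sequence[Mapping[str, Evoked]],
                            cond_a: str, cond_b: str,
                            channels: Sequence[str],
                            alpha: float = 0.05) -> SignificanceMask:
    """Two-tailed paired t across subjects at every sample of every channel.

    Subjects missing either condition are dropped pairwise.  At least
    three complete subjects are required.
    """
    pairs = [s for s in subject_evokeds if cond_a in s and cond_b in s]
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need >=3 subjects with both conditions, got {n}")
    ref = pairs[0][cond_a]
    diffs = np.stack([
        np.stack([s[cond_a].channel(ch) - s[cond_b].channel(ch)
                  for ch in channels])
        for s in pairs
    ])  # subjects x channels x samples
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(np.isfinite(t), t, np.where(mean != 0, np.inf, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    return SignificanceMask(channels=tuple(channels), times_ms=ref.times_ms,
                            t=t, p=p, significant=p < alpha, alpha=alpha,
                            n_subjects=n)


def select_window(mask: SignificanceMask, channel: str,
                  search: tuple[float, float],
                  min_duration_ms: float = 40.0,
                  component: str = "") -> ComponentWindow | None:
    """Longest run of consecutively significant samples within the search
    range, if it lasts at least ``min_duration_ms`` (a run of k samples
    covers k / rate seconds).  Returns None when no run qualifies."""
    t = mask.times_ms
    in_range = (t >= search[0] - 1e-9) & (t <= search[1] + 1e-9)
    if not in_range.any():
        raise ValueError("mask does not cover the search range")
    _, _, sig = mask.for_channel(channel)
    sig = sig & in_range

    dt_ms = float(np.mean(np.diff(t)))  # sample period
    best_len, best_start = 0, None
    run_len, run_start = 0, None
    for i, s in enumerate(sig):
        if s:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len = 0
    if best_len * dt_ms < min_duration_ms or best_start is None:
        return None
    return ComponentWindow(component=component, channels=(channel,),
                           start_ms=float(t[best_start]),
                           end_ms=float(t[best_start + best_len - 1]))


def mean_amplitude(evoked: Evoked, channel: str,
                   window: tuple[float, float]) -> float:
    """Arithmetic mean of the channel's samples with times in [start, end]."""
    start, end = window
    t = evoked.times_ms
    if start < t[0] - 1e-9 or end > t[-1] + 1e-9:
        raise ValueError(f"window ({start}, {end}) ms outside the epoch span")
    m = (t >= start - 1e-9) & (t <= end + 1e-9)
    return float(evoked.channel(channel)[m].mean())


def peak_measure(evoked: Evoked, channel: str,
                 search_window: tuple[float, float],
                 polarity: str = "positive") -> tuple[float, float]:
    """Extremum amplitude (uV) and latency (ms) inside the search window.

    Polarity 'positive' takes the maximum, 'negative' the minimum; ties
    break toward the earliest sample.  A peak on a window edge triggers a
    warning (the true extremum may lie outside the window).
    """
    start, end = search_window
    t = evoked.times_ms
    if start < t[0] - 1e-9 or end > t[-1] + 1e-9:
        raise ValueError("search window outside the epoch span")
    m = (t >= start - 1e-9) & (t <= end + 1e-9)
    x = evoked.channel(channel)[m]
    tt = t[m]
    if polarity == "positive":
        i = int(np.argmax(x))
    elif polarity == "negative":
        i = int(np.argmin(x))
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    if i in (0, len(x) - 1):
        warnings.warn(
            f"extremum at the {'start' if i == 0 else 'end'} of the search "
            f"window on {channel}; waveform may be monotone there",
            stacklevel=2)
    return float(x[i]), float(tt[i])


def measure_components(evokeds: Mapping[str, Evoked],
                       windows: Sequence[ComponentWindowSpec],
                       subject: object = None) -> pd.DataFrame:
    """Tidy per-condition component measures for one subject.

    Columns: subject, condition, component, channel, value_uv,
    latency_ms (NaN for window means).
    """
    rows = []
    for cond in ("post_error", "post_correct"):
        if cond not in evokeds:
            continue
        ev = evokeds[cond]
        for spec in windows:
            for ch in spec.channels:
                if spec.measure == "mean":
                    val = mean_amplitude(ev, ch, (spec.start_ms, spec.end_ms))
                    lat = np.nan
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        val, lat = peak_measure(
                            ev, ch, (spec.start_ms, spec.end_ms),
                            spec.polarity)
                rows.append((subject, cond, spec.component, ch, val, lat))
    return pd.DataFrame(rows, columns=["subject", "condition", "component",
                                       "channel", "value_uv", "latency_ms"])
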