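"""Synthetic Go/No-go cohorts with known ground truth.

The generator has three layers:

1. :func:`generate_event_sequence` — the task schedule and the behavioral
   outcomes.  Stimulus categories are exactly balanced (400 Go / 400
   No-go by default) and shuffled within blocks; onsets advance by a
   uniform stimulus-onset asynchrony on [1000, 2000] ms.  Responses
   follow a first-order sequential rule: the false-alarm probability on a
   No-go trial depends on whether the previous trial was an error, and
   hit RT medians shift after an error (post-error slowing).
2. :func:`render_recording` — a linear forward model: a noise
   realization plus, for every trial, each applicable ERP template placed
   at its lock time (stimulus onset, or the button press for the
   response-locked error complex) and scaled by the trial's sequential
   context.
3. :func:`generate_cohort` / :func:`iter_cohort` — independent subjects
   with between-subject jitter of the behavioral and amplitude
   parameters, each stored next to its ground truth.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import replace
from typing import Iterator

import numpy as np
import pandas as pd
import scipy.fft as sfft

from .config import (BehaviorProfile, ComponentTemplate, GroundTruth,
                     NoiseModel, PipelineConfig, ProfileJitter, TaskConfig,
                     default_templates, ANALYSIS_MONTAGE)
from .erp import ContinuousRecording

__all__ = [
    "generate_event_sequence", "render_recording", "generate_cohort",
    "iter_cohort", "sample_subject", "simulate_subject",
]

#: responses are attributed to the preceding stimulus only inside this
#: window (ms after onset); the generator keeps RTs inside it
RESPONSE_WINDOW_MS = (100.0, 1000.0)

#: silence before the first stimulus and after the last epoch, so every
#: epoch window fits inside the recording
_EDGE_MARGIN_MS = 2200.0


def _draw_rt(rng: np.random.Generator, median_ms: float,
             spread_ms: float, size: int = 1) -> np.ndarray:
    """Log-normal RTs parameterized by median and spread (~SD in ms)."""
    sigma = spread_ms / median_ms
    rt = median_ms * np.exp(sigma * rng.standard_normal(size))
    lo, hi = RESPONSE_WINDOW_MS
    return np.clip(rt, lo, hi - 1.0)


def _block_categories(task: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Stimulus identities for one block, exactly balanced then shuffled."""
    base, extra = divmod(task.trials_per_block, task.n_categories)
    ids = np.repeat(np.arange(task.n_categories), base)
    if extra:
        ids = np.concatenate([ids, rng.choice(task.n_categories, extra,
                                              replace=False)])
    return rng.permutation(ids)


def generate_event_sequence(task: TaskConfig | None = None,
                            profile: BehaviorProfile | None = None,
                            seed: int | np.random.Generator = 0,
                            ) -> pd.DataFrame:
    """Simulate one subject's event log.

    Returns a DataFrame with one row per stimulus: ``onset_ms`` (from
    recording start), ``block``, ``trial`` (0-based within block),
    ``category`` ('go'/'nogo'), ``stim_id``, ``response`` (0/1) and
    ``rt_ms`` (NaN when no response).
    """
    task = task or TaskConfig()
    profile = profile or BehaviorProfile()
    task.validate()
    profile.validate()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    n_go_ids = int(round(task.n_categories * task.go_fraction))
    rows = []
    t = _EDGE_MARGIN_MS
    for block in range(task.n_blocks):
        ids = _block_categories(task, rng)
        soa = rng.uniform(task.soa_min_ms, task.soa_max_ms,
                          task.trials_per_block)
        prev_outcome = None  # block-initial trial: treated as after-correct
        for trial in range(task.trials_per_block):
            stim_id = int(ids[trial])
            is_go = stim_id < n_go_ids
            response, rt = 0, math.nan
            if is_go:
                if rng.random() >= profile.p_miss:
                    response = 1
                    median = (profile.rt_hit_post_error_ms
                              if prev_outcome == "false_alarm"
                              else profile.rt_hit_pre_error_ms)
                    rt = float(_draw_rt(rng, median, profile.rt_spread_ms)[0])
                    outcome = "hit"
                else:
                    outcome = "miss"
            else:
                p_fa = (profile.p_fa_after_error
                        if prev_outcome == "false_alarm"
                        else profile.p_fa_after_correct)
                if rng.random() < p_fa:
                    response = 1
                    rt = float(_draw_rt(rng, profile.rt_fa_ms,
                                        profile.rt_spread_ms)[0])
                    outcome = "false_alarm"
                else:
                    outcome = "correct_rejection"
            rows.append((t, block, trial, "go" if is_go else "nogo",
                         stim_id, response, rt))
            prev_outcome = outcome
            t += soa[trial]
        t += task.inter_block_gap_ms
    return pd.DataFrame(rows, columns=["onset_ms", "block", "trial",
                                       "category", "stim_id", "response",
                                       "rt_ms"])


def _shaped_noise(rng: np.random.Generator, n: int, sd: float,
                  exponent: float) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent and SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    if exponent == 0:
        return rng.normal(0.0, sd, n)
    m = sfft.next_fast_len(n)       # pad for FFT speed, then truncate
    white = rng.standard_normal(m)
    spec = sfft.rfft(white)
    f = sfft.rfftfreq(m)
    with np.errstate(divide="ignore"):
        gain = np.where(f > 0, f ** (-exponent / 2.0), 0.0)
    x = sfft.irfft(spec * gain, m)[:n]
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _trial_conditions(events: pd.DataFrame) -> np.ndarray:
    """Sequential context of every trial, for template scaling."""
    from .behavior import classify_trials
    labels = classify_trials(events)
    cond = np.array([""] * len(events), dtype=object)
    cond[labels["post_correct"].to_numpy(dtype=bool)] = "post_correct"
    cond[labels["post_error"].to_numpy(dtype=bool)] = "post_error"
    return cond, labels["outcome"].to_numpy()


def render_recording(events: pd.DataFrame,
                     templates: list[ComponentTemplate] | None = None,
                     noise: NoiseModel | None = None,
                     montage: tuple[str, ...] = ANALYSIS_MONTAGE,
                     sfreq_hz: float = 250.0,
                     seed: int | np.random.Generator = 0,
                     ) -> ContinuousRecording:
    """Render continuous EEG (channels x samples, uV) for an event log."""
    templates = default_templates() if templates is None else templates
    noise = NoiseModel() if noise is None else noise
    noise.validate()
    for tpl in templates:
        tpl.validate()
        unknown = set(tpl.channel_weights) - set(montage)
        if unknown:
            raise KeyError(f"template {tpl.name!r} uses unknown channel "
                           f"labels {sorted(unknown)}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    last = float(events["onset_ms"].max()) if len(events) else 0.0
    n_samples = int(math.ceil((last + _EDGE_MARGIN_MS) / 1000.0 * sfreq_hz))
    data = np.zeros((len(montage), n_samples))
    ch_index = {ch: i for i, ch in enumerate(montage)}

    # --- background noise -------------------------------------------------
    for i in range(len(montage)):
        data[i] += _shaped_noise(rng, n_samples, noise.broadband_sd_uv,
                                 noise.one_over_f_exponent)
        if noise.alpha_band_amplitude_uv > 0:
            phase = rng.uniform(0, 2 * np.pi)
            t = np.arange(n_samples) / sfreq_hz
            data[i] += noise.alpha_band_amplitude_uv * np.sin(
                2 * np.pi * noise.alpha_freq_hz * t + phase)

    # --- deterministic template placement ---------------------------------
    conditions, outcomes = _trial_conditions(events)
    onset_samp = np.round(events["onset_ms"].to_numpy() / 1000.0
                          * sfreq_hz).astype(np.int64)
    rt = events["rt_ms"].to_numpy(dtype=float)
    responded = (events["response"].to_numpy() == 1) & np.isfinite(rt)
    resp_samp = np.round(
        (events["onset_ms"].to_numpy() + np.nan_to_num(rt)) / 1000.0
        * sfreq_hz).astype(np.int64)

    for tpl in templates:
        k0 = int(math.floor(tpl.onset_ms / 1000.0 * sfreq_hz))
        k1 = int(math.ceil(tpl.offset_ms / 1000.0 * sfreq_hz))
        offs = np.arange(k0, k1 + 1)
        shape = tpl.waveform(offs * 1000.0 / sfreq_hz)
        if tpl.lock == "response":
            sel = responded.copy()
            if tpl.error_only:
                sel &= outcomes == "false_alarm"
            centers = resp_samp[sel]
        else:
            sel = np.ones(len(events), dtype=bool)
            centers = onset_samp[sel]
        gains = np.array([tpl.gain(c) for c in conditions[sel]])
        active = gains != 0.0
        centers, gains = centers[active], gains[active]
        if len(centers) == 0:
            continue
        if centers.max() >= n_samples or centers.min() < 0:
            raise ValueError("event lies beyond the recording span")
        pos = (centers[:, None] + offs[None, :]).ravel()
        vals = (gains[:, None] * shape[None, :]).ravel()
        ok = (pos >= 0) & (pos < n_samples)
        for ch, w in tpl.channel_weights.items():
            np.add.at(data[ch_index[ch]], pos[ok], w * vals[ok])

    # --- injected artifacts ------------------------------------------------
    if noise.artifact_rate > 0 and len(events):
        width = int(round(noise.artifact_duration_ms / 1000.0 * sfreq_hz))
        pulse = noise.artifact_amplitude_uv * (
            1.0 - np.abs(np.linspace(-1, 1, width)))
        hit = rng.random(len(events)) < noise.artifact_rate
        for i in np.flatnonzero(hit):
            lo = onset_samp[i] + int(round(-1100.0 / 1000.0 * sfreq_hz))
            hi = onset_samp[i] + int(round(900.0 / 1000.0 * sfreq_hz)) - width
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            ch = int(rng.integers(0, len(montage)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            seg = slice(max(start, 0), min(start + width, n_samples))
            data[ch, seg] += sign * pulse[: seg.stop - seg.start]

    return ContinuousRecording(data=data, channels=montage, sfreq_hz=sfreq_hz)


def sample_subject(profile: BehaviorProfile, jitter: ProfileJitter,
                   templates: list[ComponentTemplate],
                   rng: np.random.Generator,
                   ) -> tuple[BehaviorProfile, list[ComponentTemplate], float, float]:
    """Draw one subject's profile and condition gains around the population
    values (truncated Gaussian perturbations)."""
    bp_dev = rng.normal(0.0, jitter.sd_bp_gain) if jitter.sd_bp_gain else 0.0
    pn_dev = rng.normal(0.0, jitter.sd_pn_gain) if jitter.sd_pn_gain else 0.0

    def _n(x, sd, lo, hi):
        return float(np.clip(x + (rng.normal(0.0, sd) if sd else 0.0), lo, hi))

    prof = replace(
        profile,
        p_fa_after_correct=_n(profile.p_fa_after_correct,
                              jitter.sd_p_fa_correct, 0.04, 0.4),
        p_fa_after_error=_n(profile.p_fa_after_error,
                            jitter.sd_p_fa_error, 0.005, 0.4),
        p_miss=_n(profile.p_miss, jitter.sd_p_miss, 0.0, 0.1),
        rt_hit_pre_error_ms=_n(profile.rt_hit_pre_error_ms,
                               jitter.sd_rt_ms, 200.0, 800.0),
        rt_hit_post_error_ms=float(np.clip(
            profile.rt_hit_post_error_ms
            + (rng.normal(0.0, jitter.sd_rt_ms) if jitter.sd_rt_ms else 0.0)
            - jitter.rt_bp_coupling_ms_per_gain * bp_dev, 200.0, 900.0)),
        rt_fa_ms=_n(profile.rt_fa_ms, jitter.sd_rt_ms, 200.0, 800.0),
    )

    pn_gain = bp_gain = math.nan
    subj_templates = []
    for tpl in templates:
        scaling = dict(tpl.condition_scaling)
        if tpl.name == "pN" and "post_error" in scaling:
            scaling["post_error"] = float(np.clip(
                scaling["post_error"] + pn_dev, 0.1, 6.0))
            pn_gain = scaling["post_error"]
        if tpl.name == "BP" and "post_error" in scaling:
            scaling["post_error"] = float(np.clip(
                scaling["post_error"] + bp_dev, 0.02, 2.0))
            bp_gain = scaling["post_error"]
        subj_templates.append(dataclasses.replace(tpl,
                                                  condition_scaling=scaling))
    return prof, subj_templates, pn_gain, bp_gain


def simulate_subject(cfg: PipelineConfig, rng: np.random.Generator,
                     ) -> tuple[ContinuousRecording, pd.DataFrame, GroundTruth]:
    """One subject: jittered profile -> events -> rendered recording."""
    prof, templates, pn_gain, bp_gain = sample_subject(
        cfg.profile, cfg.jitter, cfg.templates, rng)
    events = generate_event_sequence(cfg.task, prof, rng)
    recording = render_recording(events, templates, cfg.noise, cfg.montage,
                                 cfg.task.sampling_rate_hz, rng)
    from .behavior import classify_trials
    outcomes = classify_trials(events)["outcome"].tolist()
    truth = GroundTruth(profile=prof, pn_gain_post_error=pn_gain,
                        bp_gain_post_error=bp_gain, outcomes=outcomes)
    return recording, events, truth


def iter_cohort(cfg: PipelineConfig, seed: int | None = None,
                n_subjects: int | None = None,
                ) -> Iterator[tuple[ContinuousRecording, pd.DataFrame, GroundTruth]]:
    """Yield independent subjects; per-subject seeds are spawned from the
    master seed so any prefix of the cohort is reproducible."""
    cfg.validate()
    master = cfg.seed if seed is None else seed
    n = cfg.n_subjects if n_subjects is None else n_subjects
    if n < 1:
        raise ValueError("need at least one subject")
    for child in np.random.SeedSequence(master).spawn(n):
        yield simulate_subject(cfg, np.random.default_rng(child))


def generate_cohort(cfg: PipelineConfig | None = None,
                    seed: int | None = None, n_subjects: int | None = None,
                    ) -> list[tuple[ContinuousRecording, pd.DataFrame, GroundTruth]]:
    """Materialized cohort (prefer :func:`iter_cohort` for large runs)."""
    cfg = cfg or PipelineConfig()
    return list(iter_cohort(cfg, seed=seed, n_subjects=n_subjects))
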