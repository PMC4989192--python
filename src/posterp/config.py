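"""Domain types and configuration for the Go/No-go post-error pipeline.

Every default here reproduces the study design the package emulates: an
equiprobable four-stimulus Go/No-go task (10 blocks x 80 trials, 260 ms
stimuli, 1000-2000 ms stimulus-onset asynchrony, 250 Hz EEG), a behavioral
profile with post-error slowing and post-error improvement of accuracy, and
ERP component templates for the prefrontal negativity (pN), the
Bereitschaftspotential (BP), the visual P1/N1, and the response-locked
error complex (Ne/Pe).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

#: channels the analysis touches, plus one EOG-like noise channel
ANALYSIS_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "C1", "Cz", "C2", "PO7", "PO8", "VEOG",
)

CONDITIONS = ("post_error", "post_correct", "error")


@dataclass
class TaskConfig:
    """Stimulus schedule of the equiprobable Go/No-go task."""

    n_blocks: int = 10
    trials_per_block: int = 80
    n_categories: int = 4
    category_probability: float = 0.25
    go_fraction: float = 0.5
    stimulus_duration_ms: float = 260.0
    soa_min_ms: float = 1000.0
    soa_max_ms: float = 2000.0
    sampling_rate_hz: float = 250.0
    inter_block_gap_ms: float = 4000.0

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def validate(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("need at least one block and one trial per block")
        if not np.isclose(self.n_categories * self.category_probability, 1.0):
            raise ValueError("category probabilities must sum to 1")
        if not 0.0 < self.go_fraction < 1.0:
            raise ValueError("go_fraction must be in (0, 1)")
        if self.soa_min_ms > self.soa_max_ms:
            raise ValueError("soa_min_ms must not exceed soa_max_ms")
        if self.soa_min_ms < self.stimulus_duration_ms:
            raise ValueError("soa_min_ms must be >= stimulus duration")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")


@dataclass
class BehaviorProfile:
    """Generative behavioral parameters of one subject (or the population).

    Response times follow a log-normal family parameterized by its median
    (in ms) and a multiplicative spread; ``rt_spread_ms`` is the
    approximate RT standard deviation in ms, converted internally to the
    log-scale sigma as spread/median.
    """

    p_fa_after_correct: float = 0.111
    p_fa_after_error: float = 0.0404
    p_miss: float = 0.01
    rt_hit_pre_error_ms: float = 408.0
    rt_hit_post_error_ms: float = 445.0
    rt_fa_ms: float = 395.0
    rt_spread_ms: float = 70.0
    rt_family: str = "lognormal"

    def validate(self) -> None:
        for name in ("p_fa_after_correct", "p_fa_after_error", "p_miss"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("rt_hit_pre_error_ms", "rt_hit_post_error_ms",
                     "rt_fa_ms", "rt_spread_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rt_family != "lognormal":
            raise ValueError(f"unknown RT family {self.rt_family!r}")

    @property
    def true_pes_ms(self) -> float:
        """Injected post-error slowing (difference of RT medians)."""
        return self.rt_hit_post_error_ms - self.rt_hit_pre_error_ms

    @property
    def true_pia(self) -> float:
        """Injected post-error improvement of accuracy."""
        return self.p_fa_after_correct - self.p_fa_after_error


@dataclass
class ComponentTemplate:
    """Piecewise-linear ERP component waveform in a forward model.

    The time course rises linearly from zero at ``onset_ms`` to
    ``amplitude_uv`` at ``peak_ms`` and returns linearly to zero at
    ``offset_ms``.  Stimulus-locked templates are placed at stimulus
    onset; response-locked ones at the button-press time and only on
    trials that carry a response (the error complex is restricted to
    false-alarm trials).  ``condition_scaling`` multiplies the amplitude
    according to the trial's sequential context; missing conditions scale
    by 1.
    """

    name: str
    lock: str  # "stimulus" | "response"
    channel_weights: dict[str, float]
    onset_ms: float
    peak_ms: float
    amplitude_uv: float
    offset_ms: float
    condition_scaling: dict[str, float] = field(default_factory=dict)
    error_only: bool = False

    def validate(self) -> None:
        if self.lock not in ("stimulus", "response"):
            raise ValueError(f"unknown lock {self.lock!r}")
        if not self.onset_ms <= self.peak_ms <= self.offset_ms:
            raise ValueError("require onset <= peak <= offset")
        if not self.channel_weights:
            raise ValueError("template needs at least one channel weight")

    def gain(self, condition: str) -> float:
        return self.condition_scaling.get(condition, 1.0)

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        """Evaluate the unit-gain time course at times ``t_ms`` (ms)."""
        t = np.asarray(t_ms, dtype=float)
        out = np.zeros_like(t)
        if self.peak_ms > self.onset_ms:
            rise = (t >= self.onset_ms) & (t < self.peak_ms)
            out[rise] = (t[rise] - self.onset_ms) / (self.peak_ms - self.onset_ms)
        if self.offset_ms > self.peak_ms:
            fall = (t >= self.peak_ms) & (t <= self.offset_ms)
            out[fall] = (self.offset_ms - t[fall]) / (self.offset_ms - self.peak_ms)
        else:
            out[t == self.peak_ms] = 1.0
        return out * self.amplitude_uv


def default_templates() -> list[ComponentTemplate]:
    """Templates calibrated to the reported condition means.

    The pre-stimulus ramps are triangular, so their mean over the
    measurement window (onset to 0 ms) is half the peak amplitude: peaks
    of -2.8 uV (pN) and -3.6 uV (BP) yield post-correct window means of
    -1.4 and -1.8 uV, and the post-error gains 2.14 and 0.44 yield -3.0
    and -0.8 uV — the reported group means.  Channel weights encode the
    reported laterality (right > left for pN, C2 > C1/Cz for BP).  The
    preparation ramps terminate at stimulus onset: a stylized sharp
    resolution that keeps the previous trial's preparation out of the
    epoch-initial baseline window, which in real recordings the SOA
    jitter only attenuates.
    """
    return [
        ComponentTemplate(
            name="pN", lock="stimulus",
            channel_weights={"Fp1": 0.86, "Fp2": 1.14},
            onset_ms=-600.0, peak_ms=0.0, amplitude_uv=-2.8, offset_ms=0.0,
            condition_scaling={"post_error": 2.14, "post_correct": 1.0},
        ),
        ComponentTemplate(
            name="BP", lock="stimulus",
            channel_weights={"C1": 0.9, "Cz": 0.9, "C2": 1.2},
            onset_ms=-500.0, peak_ms=0.0, amplitude_uv=-3.6, offset_ms=0.0,
            condition_scaling={"post_error": 0.44, "post_correct": 1.0},
        ),
        ComponentTemplate(
            name="P1", lock="stimulus",
            channel_weights={"PO8": 1.0, "PO7": 0.6},
            onset_ms=70.0, peak_ms=120.0, amplitude_uv=5.0, offset_ms=200.0,
        ),
        ComponentTemplate(
            name="N1", lock="stimulus",
            channel_weights={"PO7": 1.0, "PO8": 0.6},
            onset_ms=110.0, peak_ms=170.0, amplitude_uv=-6.0, offset_ms=260.0,
        ),
        # The error complex is rendered as a compact triphasic transient:
        # Ne, Pe, and the Pe's late negative rebound (two segments
        # sharing the Pe label).  Its net area and first moment are both
        # zero, i.e. it carries no slow-frequency content, so it leaves
        # neither a plateau nor a drift in the SOA-jittered average of
        # the following trial — the temporal segregation between
        # error-related activity and next-trial preparation that the
        # jittered design is meant to provide.
        ComponentTemplate(
            name="Ne", lock="response", error_only=True,
            channel_weights={"C1": 1.0, "Cz": 1.1, "C2": 1.0,
                             "Fp1": 0.4, "Fp2": 0.4},
            onset_ms=0.0, peak_ms=50.0, amplitude_uv=-5.0, offset_ms=100.0,
        ),
        ComponentTemplate(
            name="Pe", lock="response", error_only=True,
            channel_weights={"C1": 1.0, "Cz": 1.1, "C2": 1.0,
                             "Fp1": 0.4, "Fp2": 0.4},
            onset_ms=100.0, peak_ms=200.0, amplitude_uv=4.375,
            offset_ms=300.0,
        ),
        ComponentTemplate(
            name="Pe", lock="response", error_only=True,
            channel_weights={"C1": 1.0, "Cz": 1.1, "C2": 1.0,
                             "Fp1": 0.4, "Fp2": 0.4},
            onset_ms=300.0, peak_ms=400.0, amplitude_uv=-1.875,
            offset_ms=500.0,
        ),
    ]


def null_templates() -> list[ComponentTemplate]:
    """Condition-blind forward model for null calibration.

    All condition gains are 1 and the response-locked error complex is
    removed: Ne/Pe occur only on error trials, so they are themselves
    condition-dependent signal and have no place in a null in which the
    two sequential contexts must be statistically exchangeable.
    """
    out = []
    for tpl in default_templates():
        if tpl.error_only:
            continue
        out.append(dataclasses.replace(tpl, condition_scaling={}))
    return out


@dataclass
class NoiseModel:
    """Additive EEG background noise.

    A spectrally shaped Gaussian process (power ~ 1/f**exponent, total
    standard deviation ``broadband_sd_uv``; exponent 0 is white), an
    alpha-band sinusoid with random phase per channel, and sporadic
    large-amplitude artifacts injected per trial at a rate
    ``artifact_rate`` with amplitude above the rejection threshold so they
    are rejectable by design.
    """

    broadband_sd_uv: float = 10.0
    one_over_f_exponent: float = 1.0
    alpha_band_amplitude_uv: float = 4.0
    alpha_freq_hz: float = 10.0
    artifact_rate: float = 0.05
    artifact_amplitude_uv: float = 200.0
    artifact_duration_ms: float = 200.0

    def validate(self) -> None:
        for name in ("broadband_sd_uv", "alpha_band_amplitude_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")
        if self.artifact_rate > 0 and self.artifact_amplitude_uv <= 120.0:
            raise ValueError("artifact_amplitude_uv must exceed 120 uV")


@dataclass
class ProfileJitter:
    """Between-subject variation: independent Gaussian perturbations of
    the population profile, truncated to valid ranges.

    ``rt_bp_coupling_ms_per_gain`` couples a subject's BP post-error gain
    deviation to their post-error RT median (smaller BP -> slower RTs),
    inducing the amplitude-RT correlation the analysis probes.
    """

    sd_p_fa_correct: float = 0.03
    sd_p_fa_error: float = 0.015
    sd_p_miss: float = 0.005
    sd_rt_ms: float = 15.0
    sd_pn_gain: float = 0.40
    sd_bp_gain: float = 0.12
    rt_bp_coupling_ms_per_gain: float = 150.0

    @classmethod
    def none(cls) -> "ProfileJitter":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class GroundTruth:
    """Per-subject latent truth stored alongside each simulated subject."""

    profile: BehaviorProfile
    pn_gain_post_error: float
    bp_gain_post_error: float
    outcomes: list[str] = field(default_factory=list)

    @property
    def true_pes_ms(self) -> float:
        return self.profile.true_pes_ms

    @property
    def true_pia(self) -> float:
        return self.profile.true_pia


@dataclass
class ComponentWindowSpec:
    """Fixed measurement window for one ERP component."""

    component: str
    channels: tuple[str, ...]
    start_ms: float
    end_ms: float
    measure: str = "mean"          # "mean" | "peak"
    polarity: str = "negative"     # used by peak measures only


def default_windows() -> list[ComponentWindowSpec]:
    return [
        ComponentWindowSpec("pN", ("Fp1", "Fp2"), -600.0, 0.0),
        ComponentWindowSpec("BP", ("C1", "Cz", "C2"), -500.0, 0.0),
        ComponentWindowSpec("P1", ("PO8",), 60.0, 160.0, "peak", "positive"),
        ComponentWindowSpec("N1", ("PO7",), 100.0, 220.0, "peak", "negative"),
    ]


@dataclass
class PipelineConfig:
    """Everything one run needs: task, generative model, preprocessing,
    measurement windows, statistics options and the master seed."""

    task: TaskConfig = field(default_factory=TaskConfig)
    profile: BehaviorProfile = field(default_factory=BehaviorProfile)
    jitter: ProfileJitter = field(default_factory=ProfileJitter)
    noise: NoiseModel = field(default_factory=NoiseModel)
    templates: list[ComponentTemplate] = field(default_factory=default_templates)
    windows: list[ComponentWindowSpec] = field(default_factory=default_windows)
    montage: tuple[str, ...] = ANALYSIS_MONTAGE
    n_subjects: int = 36
    epoch_start_ms: float = -1100.0
    epoch_end_ms: float = 900.0
    rejection_threshold_uv: float = 120.0
    smoothing_cutoff_hz: float = 25.0
    baseline_scheme: str = "epoch_initial_200ms"
    min_clean_fa: int = 20
    alpha: float = 0.05
    discover_windows: bool = False
    min_run_ms: float = 40.0
    seed: int = 0

    def validate(self) -> None:
        self.task.validate()
        self.profile.validate()
        self.noise.validate()
        for tpl in self.templates:
            tpl.validate()
            unknown = set(tpl.channel_weights) - set(self.montage)
            if unknown:
                raise ValueError(
                    f"template {tpl.name!r} references channels not in the "
                    f"montage: {sorted(unknown)}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.epoch_start_ms >= self.epoch_end_ms:
            raise ValueError("epoch window must have positive length")
        if self.rejection_threshold_uv <= 0:
            raise ValueError("rejection threshold must be positive")
        if self.smoothing_cutoff_hz * 2 >= self.task.sampling_rate_hz:
            raise ValueError("smoothing cutoff must be below Nyquist")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["montage"] = list(self.montage)
        for w in d["windows"]:
            w["channels"] = list(w["channels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["task"] = TaskConfig(**d.get("task", {}))
        d["profile"] = BehaviorProfile(**d.get("profile", {}))
        d["jitter"] = ProfileJitter(**d.get("jitter", {}))
        d["noise"] = NoiseModel(**d.get("noise", {}))
        d["templates"] = [ComponentTemplate(**t) for t in d.get("templates", [])]
        d["windows"] = [
            ComponentWindowSpec(**{**w, "channels": tuple(w["channels"])})
            for w in d.get("windows", [])
        ]
        d["montage"] = tuple(d.get("montage", ANALYSIS_MONTAGE))
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- canned study conditions ------------------------------------------
    @classmethod
    def null(cls, n_subjects: int = 12,
             montage: Sequence[str] = ("Fp1", "Fp2")) -> "PipelineConfig":
        """Condition-blind configuration for null calibration: equal RT
        medians, equal false-alarm probabilities, all gains 1, no error
        complex."""
        profile = BehaviorProfile(
            p_fa_after_correct=0.111, p_fa_after_error=0.111,
            rt_hit_post_error_ms=408.0,
        )
        montage = tuple(montage)
        templates = [t for t in null_templates()
                     if set(t.channel_weights) & set(montage)]
        for t in templates:
            t.channel_weights = {
                ch: w for ch, w in t.channel_weights.items() if ch in montage}
        windows = [ComponentWindowSpec("pN", ("Fp1", "Fp2"), -600.0, 0.0)]
        return cls(profile=profile, templates=templates, montage=montage,
                   windows=windows, n_subjects=n_subjects,
                   jitter=ProfileJitter(sd_pn_gain=0.0, sd_bp_gain=0.0,
                                        rt_bp_coupling_ms_per_gain=0.0))
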