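"""Epoching, rejection, averaging, smoothing and baseline contracts."""
import numpy as np
import pandas as pd
import pytest

from posterp import (ContinuousRecording, NoiseModel, TaskConfig,
                     average, baseline_correct, build_condition_evokeds,
                     classify_trials, default_templates,
                     generate_event_sequence, reject_artifacts,
                     render_recording, segment, smooth)
from posterp.erp import Evoked, n_epoch_samples


def _recording(n_samples=5000, n_ch=2, sfreq=250.0, fill=0.0):
    data = np.full((n_ch, n_samples), fill, dtype=float)
    return ContinuousRecording(data, tuple(f"ch{i}" for i in range(n_ch)),
                               sfreq)


def _events(onsets_ms, rts=None):
    n = len(onsets_ms)
    rts = rts if rts is not None else [np.nan] * n
    return pd.DataFrame({
        "onset_ms": onsets_ms, "block": [0] * n, "trial": range(n),
        "category": ["go" if np.isfinite(r) else "nogo" for r in rts],
        "stim_id": [0] * n,
        "response": [1 if np.isfinite(r) else 0 for r in rts],
        "rt_ms": rts})


def test_default_window_has_501_samples():
    assert n_epoch_samples(-1100.0, 900.0, 250.0) == 501
    rec = _recording(2000)
    eps = segment(rec, _events([4000.0]), "stimulus", (-1100.0, 900.0))
    assert eps.data.shape == (1, 2, 501)
    t = eps.times_ms
    assert t[0] == pytest.approx(-1100.0) and t[-1] == pytest.approx(900.0)
    # the lock sample sits at index round(-start / 1000 * rate)
    assert t[275] == pytest.approx(0.0)


def test_zero_length_window_picks_the_lock_sample():
    rec = _recording(2000)
    rec.data[:, 1000] = 7.5
    eps = segment(rec, _events([4000.0]), "stimulus", (0.0, 0.0))
    assert eps.data.shape == (1, 2, 1)
    assert eps.data[0, 0, 0] == pytest.approx(7.5)


def test_out_of_bounds_epochs_dropped_not_crashed():
    rec = _recording(1000)   # 4 s of data
    eps = segment(rec, _events([200.0, 2000.0]), "stimulus",
                  (-1100.0, 900.0))
    assert eps.n_epochs == 1
    assert eps.n_dropped == 1


def test_response_locked_equals_stimulus_locked_shifted(quiet_noise):
    """On noiseless data the response-locked epoch of a trial is the
    stimulus-locked epoch shifted by the trial's RT (in samples)."""
    tpls = default_templates()
    ev = _events([5000.0], rts=[444.0])
    ev.loc[0, "category"] = "nogo"   # make the press a false alarm
    rec = render_recording(ev, tpls, quiet_noise, seed=0)
    sf = rec.sfreq_hz
    stim = segment(rec, ev, "stimulus", (-1100.0, 900.0))
    resp = segment(rec, ev, "response", (-200.0, 200.0))
    k = (int(round((5000.0 + 444.0) / 1000.0 * sf))
         - int(round(5000.0 / 1000.0 * sf)))
    # time t in the response frame = stimulus-frame index of t + k
    i0 = int(round((-200.0 + 1100.0) / 1000.0 * sf)) + k
    np.testing.assert_allclose(resp.data[0], stim.data[0][:, i0:i0 + 101],
                               atol=1e-12)


def test_rejection_threshold_is_strict():
    rec = _recording(3000)
    eps = segment(rec, _events([3000.0, 6000.0, 9000.0]), "stimulus",
                  (-1100.0, 900.0))
    eps.data[0, 0, 10] = 121.0     # just above
    eps.data[1, 1, 10] = 120.0     # exactly at the boundary: retained
    eps.data[2, 0, 10] = -121.0    # rejection is two-sided
    out = reject_artifacts(eps, 120.0)
    assert out.rejected.tolist() == [True, False, True]
    assert out.retained_counts()[""] == 1


def test_injected_artifact_rate_drives_rejections():
    """With disjoint epochs (SOA > epoch length) the rejected-epoch count
    is binomial at the injection rate."""
    task = TaskConfig(n_blocks=13, trials_per_block=80, soa_min_ms=2500.0,
                      soa_max_ms=2500.0)
    noise = NoiseModel(broadband_sd_uv=0.0, alpha_band_amplitude_uv=0.0,
                       artifact_rate=0.1, artifact_amplitude_uv=200.0)
    ev = generate_event_sequence(task, seed=3)
    rec = render_recording(ev, [], noise, seed=3)
    eps = reject_artifacts(
        segment(rec, ev, "stimulus", (-1100.0, 900.0)), 120.0)
    n = eps.n_epochs
    k = int(eps.rejected.sum())
    se = np.sqrt(n * 0.1 * 0.9)
    assert abs(k - 0.1 * n) < 3 * se, (k, n)


def test_average_of_identical_and_opposite_epochs():
    rec = _recording(3000)
    ev = _events([3000.0, 6000.0])
    eps = segment(rec, ev, "stimulus", (-100.0, 100.0))
    eps.data[0] = 1.0
    eps.data[1] = 1.0
    assert np.all(average(eps).data == 1.0)
    eps.data[1] = -1.0
    assert np.all(average(eps).data == 0.0)
    eps.rejected[:] = True
    with pytest.raises(ValueError):
        average(eps)


def test_noiseless_average_reproduces_template(quiet_noise):
    """With widely spaced trials the unsmoothed average equals the
    injected template exactly at every sample."""
    pn = [t for t in default_templates() if t.name == "pN"][0]
    onsets = [5000.0 + 3000.0 * i for i in range(10)]
    ev = _events(onsets)
    rec = render_recording(ev, [pn], quiet_noise, seed=0)
    eps = segment(rec, ev, "stimulus", (-1100.0, 900.0))
    evo = average(eps)
    expected = (pn.waveform(evo.times_ms) * pn.channel_weights["Fp2"])
    np.testing.assert_allclose(evo.channel("Fp2"), expected, atol=1e-12)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _tone(freq, sfreq=250.0, n=4001):
    t = np.arange(n) / sfreq
    return Evoked(np.sin(2 * np.pi * freq * t)[None, :], ("x",), sfreq,
                  0.0, 1)


def test_smoothing_preserves_dc():
    ev = Evoked(np.full((1, 1000), 3.3), ("x",), 250.0, 0.0, 1)
    out = smooth(ev)
    np.testing.assert_allclose(out.data, 3.3, rtol=1e-9)


def test_smoothing_passband_and_stopband_match_butterworth():
    """Two-pass 4th-order Butterworth at 25 Hz: < 1% loss at 5 Hz and
    >= 24 dB attenuation at 50 Hz (one octave up).

    The oracle is the analytic Butterworth magnitude |H|^2 =
    1 / (1 + r^8) applied twice, with r the bilinear-warped frequency
    ratio tan(pi f / fs) / tan(pi fc / fs) of the digital design.
    """
    fs = 250.0
    for freq, check in ((5.0, "pass"), (50.0, "stop")):
        out = smooth(_tone(freq)).data[0]
        mid = out[1000:3000]                       # away from the edges
        amp = np.sqrt(2.0) * np.sqrt(np.mean(mid ** 2))
        r = np.tan(np.pi * freq / fs) / np.tan(np.pi * 25.0 / fs)
        analytic = 1.0 / (1.0 + r ** 8)            # two passes
        if check == "pass":
            assert amp > 0.99
            assert amp == pytest.approx(analytic, abs=1e-3)
        else:
            assert 20 * np.log10(amp) <= -24.0
            assert amp == pytest.approx(analytic, rel=0.05)


def test_smoothing_rejects_cutoff_at_nyquist():
    with pytest.raises(ValueError):
        smooth(_tone(5.0), cutoff_hz=125.0)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def test_baseline_schemes_zero_their_interval():
    rng = np.random.default_rng(0)
    data = rng.normal(0, 5, (2, 501))
    ev = Evoked(data, ("a", "b"), 250.0, -1100.0, 10)
    for scheme, (lo, hi) in (("epoch_initial_200ms", (-1100.0, -900.0)),
                             ("prestim_100ms", (-100.0, 0.0))):
        out = baseline_correct(ev, scheme)
        t = out.times_ms
        m = (t >= lo) & (t <= hi)
        np.testing.assert_allclose(out.data[:, m].mean(axis=1), 0.0,
                                   atol=1e-12)
        assert out.baseline == (lo, hi)


def test_constant_waveform_zeroed_by_any_scheme():
    ev = Evoked(np.full((1, 501), 5.0), ("x",), 250.0, -2000.0, 1)
    for scheme in ("epoch_initial_200ms", "interval_-1500_-1300"):
        assert np.all(baseline_correct(ev, scheme).data == 0.0)


def test_zero_mean_baseline_is_untouched():
    data = np.zeros((1, 501))
    data[0, 300:] = 4.0
    ev = Evoked(data, ("x",), 250.0, -1100.0, 1)
    out = baseline_correct(ev, "epoch_initial_200ms")
    np.testing.assert_allclose(out.data, data, atol=1e-12)


def test_baseline_outside_window_raises():
    ev = Evoked(np.zeros((1, 100)), ("x",), 250.0, -100.0, 1)
    with pytest.raises(ValueError):
        baseline_correct(ev, "interval_-1500_-1300")


def test_average_and_baseline_commute():
    """Baseline-correcting each epoch then averaging equals averaging
    then baseline-correcting (linearity)."""
    rng = np.random.default_rng(1)
    rec = _recording(6000)
    rec.data[:] = rng.normal(0, 10, rec.data.shape)
    ev = _events([4000.0, 9000.0, 14000.0])
    eps = segment(rec, ev, "stimulus", (-1100.0, 900.0))
    evo = baseline_correct(average(eps), "epoch_initial_200ms")
    t = eps.times_ms
    m = (t >= -1100.0) & (t <= -900.0)
    per_epoch = eps.data - eps.data[:, :, m].mean(axis=2, keepdims=True)
    np.testing.assert_allclose(evo.data, per_epoch.mean(axis=0), atol=1e-12)


# ---------------------------------------------------------------------------
# condition evokeds
# ---------------------------------------------------------------------------

def test_condition_evokeds_from_noiseless_forward_model(quiet_noise):
    """The post-error evoked's pre-stimulus ramp equals the pN/BP
    templates scaled by the post-error gains (checked mid-ramp, away
    from the smoothing-affected kinks).

    The SOA is stretched beyond the epoch length so neighbouring trials
    contribute nothing and the forward-model oracle is exact.
    """
    task = TaskConfig(n_blocks=12, soa_min_ms=2500.0, soa_max_ms=2600.0)
    ev = generate_event_sequence(task, seed=9)
    tpls = default_templates()
    rec = render_recording(ev, tpls, quiet_noise, seed=9)
    lab = classify_trials(ev)
    evokeds, err = build_condition_evokeds(rec, ev, lab)
    assert set(evokeds) == {"post_error", "post_correct", "error"}
    assert evokeds["error"].n_epochs == int(err.retained.sum())

    pn = [t for t in tpls if t.name == "pN"][0]
    t = evokeds["post_error"].times_ms
    mid = (t >= -450.0) & (t <= -150.0)
    for cond, gain in (("post_error", 2.14), ("post_correct", 1.0)):
        got = evokeds[cond].channel("Fp2")[mid]
        want = pn.waveform(t[mid]) * pn.channel_weights["Fp2"] * gain
        np.testing.assert_allclose(got, want, atol=0.01)


def test_zero_fa_subject_has_no_error_conditions(quiet_noise):
    from posterp import BehaviorProfile
    prof = BehaviorProfile(p_fa_after_correct=0.0, p_fa_after_error=0.0)
    task = TaskConfig(n_blocks=2)
    ev = generate_event_sequence(task, prof, seed=1)
    rec = render_recording(ev, default_templates(), quiet_noise, seed=1)
    lab = classify_trials(ev)
    evokeds, err = build_condition_evokeds(rec, ev, lab)
    assert "post_error" not in evokeds and "error" not in evokeds
    assert "post_correct" in evokeds
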