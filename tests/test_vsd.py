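"""VSD processing: bleach correction, mapping, oversampling, filtering."""

import numpy as np
import pytest

from axonwave.vsd import (EphysReference, VSDStack, activity_map,
                          bleach_correct, lowpass_two_step, segment_average,
                          shift_and_mean, vsd_ap_area)


def flat_stack(T=500, h=6, w=6, value=1000.0, events=(20.0,)):
    frames = np.full((T, h, w), value)
    return VSDStack(frames=frames, event_times_ms=np.array(events))


def test_bleach_correct_is_identity_on_flat_stack():
    st = flat_stack()
    cor = bleach_correct(st)
    np.testing.assert_allclose(cor.frames, st.frames, rtol=1e-3)


def test_bleach_correct_flattens_double_exponential_decay():
    T = 2000
    t = np.arange(T) * 0.1
    bleach = 0.6 + 0.15 * np.exp(-t / 50) + 0.25 * np.exp(-t / 500)
    rng = np.random.default_rng(1)
    f0 = rng.uniform(500, 2000, (6, 6))
    st = VSDStack(frames=f0[None] * bleach[:, None, None],
                  event_times_ms=np.array([100.0]))
    cor = bleach_correct(st)
    trace = cor.frames[:, 2, 2]
    assert np.abs(trace / trace.mean() - 1).max() < 0.005


def test_bleach_correct_preserves_injected_transient():
    T = 2000
    t = np.arange(T) * 0.1
    bleach = 0.6 + 0.15 * np.exp(-t / 50) + 0.25 * np.exp(-t / 500)
    sig = np.zeros(T)
    k = 1000
    sig[k - 2: k + 3] = 0.01            # 1% AP-locked transient
    f0 = np.full((4, 4), 1500.0)
    frames = f0[None] * bleach[:, None, None] * (1 + sig[:, None, None])
    st = VSDStack(frames=frames, event_times_ms=np.array([100.0]))
    cor = bleach_correct(st)
    tr = cor.frames[:, 1, 1]
    base = np.median(tr)
    amp = (tr[k] - base) / base
    assert amp == pytest.approx(0.01, rel=0.05)


def test_activity_map_step_and_silence():
    T = 400
    frames = np.full((T, 4, 4), 1000.0)
    k = 300                              # event at 30 ms (0.1 ms frames)
    frames[k - 2: k + 3, 1, 1] *= 1.10   # +10% at the event
    st = VSDStack(frames=frames, event_times_ms=np.array([30.0]))
    am = activity_map(st, peak_halfwidth_ms=0.2)
    assert am[1, 1] == pytest.approx(0.10, abs=0.005)
    assert abs(am[2, 2]) < 1e-9
    with pytest.raises(ValueError):
        activity_map(flat_stack(events=()))


def test_segment_average_partition_and_uniformity():
    h, w = 4, 16
    frames = np.full((100, h, w), 7.0)
    pos = np.full((h, w), np.nan)
    mask = np.zeros((h, w), dtype=bool)
    pos[2, :] = np.arange(w) * 0.79      # 12.6 um of axon
    mask[2, :] = True
    st = VSDStack(frames=frames, event_times_ms=np.array([5.0]), mask=mask,
                  path_position_um=pos)
    segs = segment_average(st, max_extent_um=5.0)
    assert len(segs) == 3
    for s in segs:
        assert s.path_end_um - s.path_start_um <= 5.0 + 1e-9
        np.testing.assert_allclose(s.trace, 7.0)
    assert sum(s.n_pixels for s in segs) == w


def test_segment_average_snr_gain():
    rng = np.random.default_rng(0)
    h, w, T = 4, 16, 400
    signal = np.sin(np.arange(T) / 20.0)
    frames = 100.0 + signal[:, None, None] + rng.normal(0, 1.0, (T, h, w))
    pos = np.full((h, w), np.nan)
    mask = np.zeros((h, w), dtype=bool)
    pos[2, :] = np.arange(w) * 0.3
    mask[2, :] = True
    st = VSDStack(frames=np.maximum(frames, 0),
                  event_times_ms=np.array([5.0]),
                  mask=mask, path_position_um=pos)
    seg = segment_average(st, max_extent_um=5.0)[0]
    noise_seg = np.std(seg.trace - 100.0 - signal)
    noise_pix = np.std(frames[:, 2, 3] - 100.0 - signal)
    assert noise_seg < noise_pix


def _jittered_trials(n_trials, rng, dtf=0.1, nfr=100):
    def gt(tt):
        return np.exp(-(tt / 0.15) ** 2)
    trials, refs = [], []
    for _ in range(n_trials):
        tpk = 5.0 + rng.uniform(0, dtf)
        trials.append(gt(np.arange(nfr) * dtf - tpk))
        refs.append(EphysReference(time=np.arange(0, 10, 0.004),
                                   v=np.zeros(2500),
                                   peak_times=np.array([tpk])))
    return trials, refs, gt


def test_shift_and_mean_zero_jitter_identity():
    def gt(tt):
        return np.exp(-(tt / 0.2) ** 2)
    dtf = 0.1
    trace = gt(np.arange(100) * dtf - 5.0)
    refs = [EphysReference(time=np.arange(0, 10, 0.004), v=np.zeros(2500),
                           peak_times=np.array([5.0]))] * 4
    times, wave, rate, used = shift_and_mean([trace] * 4, refs,
                                             resample_factor=4)
    assert used == 4
    np.testing.assert_allclose(wave, gt(times), atol=1e-12)


def test_shift_and_mean_beats_naive_averaging():
    rng = np.random.default_rng(3)
    trials, refs, gt = _jittered_trials(20, rng)
    times, wave, rate, used = shift_and_mean(trials, refs)
    rmse_sm = np.sqrt(np.mean((wave - gt(times)) ** 2))
    naive = np.mean(trials, axis=0)
    tn = np.arange(100) * 0.1 - 5.05     # mean AP phase
    rmse_naive = np.sqrt(np.mean((naive - gt(tn)) ** 2))
    assert rmse_sm < rmse_naive


def test_shift_and_mean_effective_rate_band():
    """20-22 pooled 10 kHz trials block-averaged by 8 -> 24.5-27.5 kHz."""
    rng = np.random.default_rng(7)
    for n in (20, 21, 22):
        trials, refs, _ = _jittered_trials(n, rng)
        _, _, rate, _ = shift_and_mean(trials, refs, resample_factor=8)
        assert 24.5 <= rate <= 27.5


def test_shift_and_mean_converges_with_trial_count():
    rng = np.random.default_rng(11)
    errs = {}
    for n in (10, 40):
        trials, refs, gt = _jittered_trials(n, rng)
        times, wave, _, _ = shift_and_mean(trials, refs)
        errs[n] = np.sqrt(np.mean((wave - gt(times)) ** 2))
    assert errs[40] < 0.5 * errs[10]


def test_shift_and_mean_drops_trials_without_reference():
    rng = np.random.default_rng(0)
    trials, refs, _ = _jittered_trials(5, rng)
    refs[2] = EphysReference(time=refs[2].time, v=refs[2].v,
                             peak_times=np.zeros(0))
    _, _, _, used = shift_and_mean(trials, refs)
    assert used == 4


def test_lowpass_dc_preserved_and_tone_attenuated():
    rate = 25.0                                    # kHz
    t = np.arange(0, 40, 1 / rate)
    dc = np.full(t.size, 3.0)
    out, skipped = lowpass_two_step(t, dc, cutoffs_khz=(2.0, 10.0))
    np.testing.assert_allclose(out, 3.0, atol=1e-9)
    # a 8 kHz tone under a 2 kHz cutoff: > 20 dB down
    tone = np.sin(2 * np.pi * 8.0 * t)
    out, _ = lowpass_two_step(t, tone, cutoffs_khz=(2.0, 10.0))
    mid = slice(t.size // 4, 3 * t.size // 4)
    assert np.std(out[mid]) < 0.1 * np.std(tone[mid])
    # cutoffs above Nyquist are skipped, logged
    _, skipped = lowpass_two_step(t, tone, cutoffs_khz=(100.0, 200.0))
    assert skipped == [100.0, 200.0]


def test_lowpass_near_idempotent_on_passband_signal():
    rate = 25.0
    t = np.arange(0, 40, 1 / rate)
    x = np.exp(-((t - 20.0) / 0.5) ** 2)      # ~0.3 kHz bandwidth pulse
    once, _ = lowpass_two_step(t, x, cutoffs_khz=(2.0, 10.0))
    twice, _ = lowpass_two_step(t, once, cutoffs_khz=(2.0, 10.0))
    assert np.sqrt(np.mean((twice - once) ** 2)) < 0.01 * np.std(once)


def test_vsd_ap_area_closed_form_and_invariance():
    # normalized exponential decay tau = 0.3 ms from the peak
    tau = 0.3
    t = np.arange(-5.0, 5.0, 0.01)
    wave = np.where(t >= 0, np.exp(-t / tau), 0.0)
    wave[t < 0] = 0.0
    expected = tau * (np.exp(-0.05 / tau) - np.exp(-0.65 / tau))
    area = vsd_ap_area(t, wave, start_offset_ms=0.05)
    assert area == pytest.approx(expected, rel=0.01)
    # amplitude rescaling leaves the normalized area unchanged
    area2 = vsd_ap_area(t, 37.0 * wave, start_offset_ms=0.05)
    assert area2 == pytest.approx(area, rel=1e-9)
    # flat-zero decay after the peak integrates to zero
    pulse = np.zeros_like(t)
    pulse[np.argmin(np.abs(t))] = 1.0
    assert vsd_ap_area(t, pulse, start_offset_ms=0.05) == pytest.approx(
        0.0, abs=1e-9)
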