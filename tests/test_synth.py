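"""Synthetic-data generators: determinism and statistical contracts."""

import numpy as np
import pytest

from axonwave.ap_metrics import APWaveform, repol_area
from axonwave.cable import SimConfig, Stimulus, run
from axonwave.channels import ActiveDensities, PassiveParams
from axonwave.morphology import discretize, write_swc
from axonwave.synth import (AxonSpec, VSDRenderSpec, make_axon,
                            make_recording, make_vsd_dataset,
                            render_vsd_trial, two_compartment_transient)
from axonwave.vsd import activity_map, shift_and_mean


def test_make_axon_deterministic(tmp_path):
    spec = AxonSpec(seed=42)
    a = make_axon(spec)
    b = make_axon(spec)
    pa, pb = tmp_path / "a.swc", tmp_path / "b.swc"
    write_swc(a, pa)
    write_swc(b, pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_make_axon_diameter_bounds_and_bouton_count():
    for seed in range(5):
        spec = AxonSpec(seed=seed)
        m = make_axon(spec)
        radii = np.array([n.radius for n in m.nodes])
        assert np.all(radii * 2 >= 0.1 - 1e-9)
        assert np.all(radii * 2 <= 5.0 + 1e-9)
        assert len(m.metadata["bouton_centers_um"]) == \
            spec.n_boutons + spec.n_giant
        diams = np.array(m.metadata["bouton_diameters_um"])
        assert (diams >= 2.0).sum() >= spec.n_giant


def test_make_axon_infeasible_spacing_raises():
    with pytest.raises(ValueError, match="cannot place"):
        make_axon(AxonSpec(seed=0, length=200, edge_margin=50,
                           n_boutons=20, n_giant=2, min_spacing=15))


def test_two_caliber_populations_and_capacitance_ordering():
    """Generated boutons show small and giant modes; capacitance grows
    with diameter while input resistance falls."""
    m = make_axon(AxonSpec(seed=1))
    diams = np.array(m.metadata["bouton_diameters_um"])
    assert (diams < 2.0).any() and (diams > 2.5).any()
    grid = discretize(m, 1.0)
    caps = grid.area * 0.01
    order = np.argsort(grid.diameter)
    assert caps[order[-1]] > caps[order[0]]


def test_make_recording_noise_statistics():
    m = make_axon(AxonSpec(seed=2, length=120, edge_margin=30, n_boutons=2,
                           n_giant=1, min_spacing=15))
    t, clean, noisy = make_recording(m, "single_ap", seed=3, noise_sd=0.5,
                                     dt=0.02)
    resid = noisy - clean
    assert abs(resid.std() - 0.5) / 0.5 < 0.1
    t2, clean2, noisy2 = make_recording(m, "single_ap", seed=3, noise_sd=0.0,
                                        dt=0.02)
    np.testing.assert_array_equal(clean2, noisy2)
    # seeded determinism
    t3, _, noisy3 = make_recording(m, "single_ap", seed=3, noise_sd=0.5,
                                   dt=0.02)
    np.testing.assert_array_equal(noisy, noisy3)
    with pytest.raises(ValueError):
        make_recording(m, "nonsense")


@pytest.fixture(scope="module")
def vsd_sim():
    spec = AxonSpec(seed=1)
    grid = discretize(make_axon(spec), 1.0)
    cfg = SimConfig(dt=0.004, duration=18.0,
                    stimuli=(Stimulus("current_step", 0.0, 0.3,
                                      onset=1.0, width=0.5),),
                    settle=20.0)
    res = run(grid, PassiveParams(), ActiveDensities(), None, cfg)
    return grid, res


def test_zero_sensitivity_stack_has_no_ap_signal(vsd_sim):
    grid, res = vsd_sim
    spec = VSDRenderSpec(seed=0, n_trials=1, sensitivity_per_100mv=0.0,
                         read_noise_sd=0.0, shot_noise_scale=0.0,
                         bleach_amplitudes=(0.0, 0.0))
    st, ref, _ = render_vsd_trial(spec, grid, res.time, res.v, 270.0,
                                  np.random.default_rng(0))
    am = activity_map(st, peak_halfwidth_ms=0.2)
    assert np.abs(am).max() < 1e-9


def test_vsd_dataset_render_consistency_with_voltage(vsd_sim):
    """Ground-truth VSD area matches the voltage-side repolarization area
    measured on the same normalized waveform within 5%."""
    grid, res = vsd_sim
    spec = VSDRenderSpec(seed=5, n_trials=2)
    data = make_vsd_dataset(spec, grid, res.time, res.v, 270.0)
    clean = data["ground_truth"]
    h = clean.frames.shape[1] // 2
    f = clean.frames[:, h, 32]          # center column pixel
    t = clean.times
    # normalized fluorescence transient vs normalized voltage transient
    base = np.median(f[t < 4.0])
    fl = (f - base)
    fl /= fl.max()
    center = grid.index_at(270.0 + 32.5 * 0.79)
    v = res.v[:, center]
    t_ap = clean.event_times_ms[0]
    tv = res.time - res.time[np.argmax(v)] + t_ap
    vn = (v - v[0]) / (v.max() - v[0])
    vi = np.interp(t, tv, vn)
    # compare the areas of the two normalized waveforms above 0 after peak
    sel = (t > t_ap) & (t < t_ap + 1.0)
    a_f = np.trapezoid(np.clip(fl[sel], 0, None), t[sel])
    a_v = np.trapezoid(np.clip(vi[sel], 0, None), t[sel])
    assert a_f == pytest.approx(a_v, rel=0.05)


def test_zero_jitter_shift_and_mean_equals_naive(vsd_sim):
    grid, res = vsd_sim
    spec = VSDRenderSpec(seed=9, n_trials=4, read_noise_sd=0.0,
                         shot_noise_scale=0.0, bleach_amplitudes=(0.0, 0.0),
                         detection_jitter_ms=0.0)
    # force identical AP phase by reusing one rng draw per trial
    rng = np.random.default_rng(1)
    stacks, refs = [], []
    class FixedRng:
        def uniform(self, lo, hi):
            return 0.5 * (lo + hi)
        def normal(self, mu, sd, size=None):
            return np.zeros(size) if size else 0.0
    for _ in range(4):
        st, ref, _ = render_vsd_trial(spec, grid, res.time, res.v, 270.0,
                                      FixedRng(), noiseless=True)
        stacks.append(st)
        refs.append(ref)
    h = stacks[0].frames.shape[1] // 2
    traces = [s.frames[:, h, :].mean(axis=1) for s in stacks]
    times, wave, rate, used = shift_and_mean(traces, refs, resample_factor=4)
    # identical trials: block means reproduce the single-trial samples
    single = traces[0]
    tpk = refs[0].peak_times[0]
    tt = np.arange(single.size) * 0.1 - tpk
    sel = (tt >= -2.0) & (tt <= 3.0)
    np.testing.assert_allclose(np.sort(wave), np.sort(single[sel]),
                               atol=1e-9)


def test_two_compartment_transient_is_biexponential():
    t, i, info = two_compartment_transient()
    assert len(info["taus"]) == 2 and info["taus"][0] < info["taus"][1]
    # noise determinism
    _, a, _ = two_compartment_transient(noise_sd=0.01, seed=5)
    _, b, _ = two_compartment_transient(noise_sd=0.01, seed=5)
    np.testing.assert_array_equal(a, b)
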