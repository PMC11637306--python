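"""Cable solver: analytic oracles, stability, clamp and train protocols."""

import math

import numpy as np
import pytest

from axonwave.cable import (SimConfig, Stimulus, detect_spikes, run,
                            train_protocol, voltage_clamp)
from axonwave.channels import ActiveDensities, PassiveParams
from axonwave.morphology import Morphology, Node, discretize
from tests.conftest import cylinder

PASSIVE = ActiveDensities(g_na=0.0, g_k=0.0)


def finite_cable_input_resistance_center(length_um, d_um, passive):
    """Closed form: two sealed half-cables in parallel, R = Rinf*coth(l/lam)/2."""
    d_cm = d_um * 1e-4
    lam = math.sqrt((passive.rm * 1e3 / passive.ra) * d_cm / 4)  # cm
    rinf = passive.ra * lam / (math.pi * (d_cm / 2) ** 2)        # Ohm
    l_half = length_um / 2 * 1e-4
    return rinf / math.tanh(l_half / lam) / 2 / 1e6              # MOhm


def test_passive_input_resistance_matches_finite_cable_formula(
        cylinder_grid, passive):
    cfg = SimConfig(dt=0.004, duration=250.0,
                    stimuli=(Stimulus("current_step", 50.0, 0.01,
                                      onset=2.0, width=248.0),),
                    settle=0.0)
    res = run(cylinder_grid, passive, PASSIVE, None, cfg)
    mid = cylinder_grid.index_at(50.0)
    rin_sim = (res.v[-1, mid] - res.v[0, mid]) / 0.01
    rin_true = finite_cable_input_resistance_center(100.0, 1.0, passive)
    assert abs(rin_sim - rin_true) / rin_true < 0.01


def test_single_compartment_rc_charging(passive):
    m = Morphology([Node(1, None, 0, 0, 0, 5.0), Node(2, 1, 10, 0, 0, 5.0)])
    g = discretize(m, 20.0)
    assert g.n == 1
    cfg = SimConfig(dt=0.01, duration=300.0,
                    stimuli=(Stimulus("current_step", 0.0, 0.005,
                                      onset=0.0, width=300.0),),
                    settle=0.0)
    res = run(g, passive, PASSIVE, None, cfg)
    tau = passive.tau_m                               # rm*cm = 50 ms
    r_mohm = passive.rm * 1e5 / g.area[0]             # kOhm*cm^2 / um^2
    v_inf = res.v[0, 0] + 0.005 * r_mohm              # I[nA]*R[MOhm] in mV
    v_model = v_inf + (res.v[0, 0] - v_inf) * np.exp(-res.time / tau)
    np.testing.assert_allclose(res.v[:, 0], v_model, atol=0.05)


def test_ap_translation_invariance_on_uniform_cylinder(long_cylinder_ap,
                                                       long_cylinder_grid):
    """Waveform sampled far from either end is translation invariant."""
    from tests.conftest import peak_aligned_window
    waves = []
    for pos in (300.0, 400.0, 500.0):
        v = long_cylinder_ap.v[:, long_cylinder_grid.index_at(pos)]
        waves.append(peak_aligned_window(long_cylinder_ap.time, v))
    for a in waves:
        for b in waves:
            rms = np.sqrt(np.mean((a - b) ** 2))
            assert rms < 0.5


def test_charge_bookkeeping_in_passive_run(cylinder_grid, passive):
    cfg = SimConfig(dt=0.004, duration=40.0,
                    stimuli=(Stimulus("current_step", 50.0, 0.02,
                                      onset=1.0, width=30.0),),
                    settle=0.0)
    res = run(cylinder_grid, passive, PASSIVE, None, cfg)
    dt = 0.004
    q_inj = np.trapezoid(res.injected, dx=dt)                     # nA*ms = pC
    cap = passive.cm * cylinder_grid.area * 1e-5                  # nF
    q_cap = float(np.sum(cap * (res.v[-1] - res.v[0])))           # nF*mV = pC
    g_leak = passive.g_leak * cylinder_grid.area * 1e-5           # uS
    i_leak = (res.v - passive.e_leak) * g_leak[None, :]           # nA
    q_leak = float(np.trapezoid(i_leak.sum(axis=1), dx=dt))
    assert abs(q_inj - (q_cap + q_leak)) / q_inj < 1e-3


def test_convergence_under_dt_and_dx_halving(passive, densities):
    def ap_wave(dt, seg):
        g = discretize(cylinder(100, 1.0), seg)
        cfg = SimConfig(dt=dt, duration=8.0,
                        stimuli=(Stimulus("current_step", 0.0, 0.3,
                                          onset=1.0, width=0.5),),
                        settle=20.0)
        res = run(g, passive, densities, None, cfg)
        v = res.v[:, g.index_at(50.0)]
        # resample to the coarse grid for comparison
        t = res.time
        return np.interp(np.arange(0, 8.0, 0.004), t, v)

    base = ap_wave(0.004, 1.0)
    fine = ap_wave(0.002, 0.5)
    amp = base.max() - base.min()
    assert np.sqrt(np.mean((base - fine) ** 2)) / amp < 0.01


def test_instability_flagged():
    g = discretize(cylinder(20, 1.0), 1.0)
    cfg = SimConfig(dt=0.004, duration=5.0,
                    stimuli=(Stimulus("current_step", 0.0, 1000.0,
                                      onset=0.0, width=5.0),),
                    settle=0.0)
    res = run(g, PassiveParams(), PASSIVE, None, cfg)
    assert res.unstable


def test_voltage_clamp_rc_transient_and_charge(passive):
    m = Morphology([Node(1, None, 0, 0, 0, 5.0), Node(2, 1, 10, 0, 0, 5.0)])
    g = discretize(m, 20.0)
    cap_nf = passive.cm * g.area[0] * 1e-5
    cfg = SimConfig(dt=0.002, duration=60.0,
                    stimuli=(Stimulus("voltage_step", 0.0, -90.0,
                                      onset=10.0, width=45.0),),
                    v_init=-70.0, settle=30.0)
    res = voltage_clamp(g, passive, PASSIVE, cfg, access_resistance=0.0)
    i = res.clamp_current
    t = res.time
    sel = (t >= 10.0) & (t < 40.0)
    q = np.trapezoid(i[sel] - i[sel][-1], dx=0.002)  # nA*ms = pC
    assert q == pytest.approx(cap_nf * -20.0, rel=0.02)


def test_voltage_clamp_series_resistance_time_constant(passive):
    # rm-dominated single compartment, C ~ 10 pF, access 50 MOhm:
    # transient tau ~ Rs*C
    area_needed = 10.0 / (passive.cm * 0.01)          # um^2 for 10 pF
    d = math.sqrt(area_needed / math.pi)
    m = Morphology([Node(1, None, 0, 0, 0, d / 2), Node(2, 1, d, 0, 0, d / 2)])
    g = discretize(m, 2 * d)
    cap_nf = passive.cm * g.area[0] * 1e-5
    rs = 50.0
    cfg = SimConfig(dt=0.002, duration=30.0,
                    stimuli=(Stimulus("voltage_step", 0.0, -90.0,
                                      onset=5.0, width=22.0),),
                    v_init=-70.0, settle=30.0)
    res = voltage_clamp(g, passive, PASSIVE, cfg, access_resistance=rs)
    t, i = res.time, res.clamp_current
    sel = (t >= 5.0) & (t <= 15.0)
    y = i[sel] - i[sel][-1]
    ts = t[sel] - 5.0
    # fit log-linear over the first 2 tau
    tau_true = rs * cap_nf  # MOhm*nF = ms
    fit_sel = (ts > 0.01) & (ts < 2 * tau_true) & (np.abs(y) > 1e-6)
    slope = np.polyfit(ts[fit_sel], np.log(np.abs(y[fit_sel])), 1)[0]
    assert -1.0 / slope == pytest.approx(tau_true, rel=0.02)


def test_voltage_clamp_two_compartment_biexponential(passive):
    """Bouton + lumped axon stub: fast-charge capacitance within 5%."""
    from axonwave.morphology import CompartmentGrid
    from axonwave.passive_probe import (TransientRecord, fit_exponentials,
                                        structure_capacitance)
    # two iso-potential compartments: 50 um^2 bouton, 3000 um^2 remote
    # arbor, coupled through ~425 MOhm of thin axon
    g = CompartmentGrid(parent=np.array([-1, 0]),
                        position=np.array([0.0, 50.0]),
                        length=np.array([4.0, 100.0]),
                        diameter=np.array([4.0, 9.5]),
                        area=np.array([50.0, 3000.0]),
                        r_half=np.array([25.0, 400.0]),
                        label=["bouton", "axon"])
    c_local = passive.cm * 50.0 * 0.01   # pF
    cfg = SimConfig(dt=0.004, duration=160.0,
                    stimuli=(Stimulus("voltage_step", 0.0, -90.0,
                                      onset=10.0, width=145.0),),
                    v_init=-70.0, settle=80.0)
    res = voltage_clamp(g, passive, PASSIVE, cfg, access_resistance=100.0)
    rec = TransientRecord(time=res.time, current=res.clamp_current,
                          dv=-20.0, step_onset=10.0)
    fit = fit_exponentials(rec, 2, window=(0.0, 120.0))
    cap, _ = structure_capacitance(fit)
    assert cap == pytest.approx(c_local, rel=0.05)


def test_train_protocol_bookkeeping(passive, densities):
    g = discretize(cylinder(60, 1.0), 1.0)
    res, aps, ok = train_protocol(g, passive, densities, n_aps=10,
                                  frequency=20.0, amplitude=0.25,
                                  site_um=30.0, dt=0.008)
    assert ok and len(aps) == 10
    np.testing.assert_allclose(np.diff(aps), 50.0, atol=0.5)
    # subthreshold: no APs, flagged
    res, aps, ok = train_protocol(g, passive, densities, n_aps=3,
                                  frequency=20.0, amplitude=0.005,
                                  site_um=30.0, dt=0.008)
    assert not ok and len(aps) == 0 and res.meta["ap_failures"] == 3


def test_train_broadening_with_slow_k_inactivation(passive):
    from axonwave.ap_metrics import APWaveform, half_width
    g = discretize(cylinder(60, 1.0), 1.0)
    den = ActiveDensities(slow_k_inactivation=True)
    res, aps, ok = train_protocol(g, passive, den, n_aps=5, frequency=40.0,
                                  amplitude=0.25, site_um=30.0, dt=0.008,
                                  pulse_width=1.5)
    assert ok
    mi = g.index_at(30.0)
    hws = []
    for ta in aps:
        sel = (res.time >= ta - 1.5) & (res.time <= ta + 6.0)
        hws.append(half_width(APWaveform(res.time[sel], res.v[sel, mi])))
    ratios = np.array(hws) / hws[0]
    assert np.all(np.diff(ratios) >= -1e-9)
    assert ratios[-1] > 1.05


def test_stimulus_site_validation(cylinder_grid, passive):
    cfg = SimConfig(duration=1.0, stimuli=(Stimulus(
        "current_step", 1e5, 0.1, onset=0.0, width=1.0),), settle=0.0)
    with pytest.raises(ValueError, match="site"):
        run(cylinder_grid, passive, PASSIVE, None, cfg)
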