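"""Implicit cable-equation simulation of axonal action potentials.

Solves C dV/dt = -I_ion + I_axial + I_inj per compartment with backward
Euler on the voltage, staggered exact-exponential (Rush-Larsen) gate
updates, and an exact tree-structured linear solve per step (Hines
ordering).  Unconditionally stable at the default 250 kHz resolution
(dt = 4 us).

Stimulus sites are addressed by path distance from the root (um) so that
results do not depend on the discretization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from .channels import (
    ActiveDensities,
    CaChannelMixture,
    PassiveParams,
    FARADAY,
    GAS_R,
    comp_gate_inf_tau,
    ca_gate_inf_tau,
    gate_steady_state,
)
from .morphology import CompartmentGrid

__all__ = [
    "Stimulus",
    "SimConfig",
    "SimulationResult",
    "Circuit",
    "assemble",
    "run",
    "voltage_clamp",
    "train_protocol",
]

SPECIES = ("i_na", "i_k", "i_k_comp", "i_ca", "i_leak")
V_LIMIT = 150.0  # |V| beyond this flags the run unstable


@dataclass(frozen=True)
class Stimulus:
    """One stimulus at a path position (um from root).

    ``amplitude`` is nA for current kinds, absolute mV for voltage_step.
    """

    kind: str                      # current_step | current_train | voltage_step
    site_um: float
    amplitude: float
    onset: float                   # ms
    width: float                   # ms (per pulse for trains)
    frequency: float = 0.0         # Hz, trains only
    n_pulses: int = 1

    def waveform(self, dt: float, nsteps: int) -> np.ndarray:
        t = np.arange(nsteps) * dt
        if self.kind == "current_step":
            return np.where((t >= self.onset) & (t < self.onset + self.width),
                            self.amplitude, 0.0)
        if self.kind == "current_train":
            if self.frequency <= 0 or self.n_pulses < 1:
                raise ValueError("train needs positive frequency and n_pulses")
            period = 1000.0 / self.frequency
            wave = np.zeros(nsteps)
            for k in range(self.n_pulses):
                on = self.onset + k * period
                wave[(t >= on) & (t < on + self.width)] = self.amplitude
            return wave
        raise ValueError(f"not a current stimulus: {self.kind!r}")


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.004             # ms (250 kHz)
    duration: float = 15.0        # ms
    stimuli: tuple[Stimulus, ...] = ()
    v_init: float = -80.0         # mV
    settle: float = 20.0          # ms integrated before t = 0, not recorded
    record_currents_at: tuple[float, ...] | str | None = None  # um or "all"
    record_ca: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("need dt > 0 and duration >= dt")


@dataclass
class SimulationResult:
    time: np.ndarray                       # (T,) ms
    v: np.ndarray                          # (T, n) mV
    currents: dict[str, np.ndarray]        # species -> (T, nrec) nA
    rec_positions: np.ndarray              # (nrec,) um
    i_ca: np.ndarray | None                # (T, n) nA, if recorded
    injected: np.ndarray                   # (T,) nA summed over sites
    clamp_current: np.ndarray | None       # (T,) nA, clamp runs
    unstable: bool = False
    meta: dict = field(default_factory=dict)

    def trace(self, index: int) -> np.ndarray:
        return self.v[:, index]


@dataclass
class Circuit:
    """Node-level arrays ready for the kernel; instrument models extend these."""

    parent: np.ndarray
    g_pair: np.ndarray        # uS coupling to parent (0 at root)
    cap: np.ndarray           # nF
    g_leak: np.ndarray        # uS
    e_leak: np.ndarray        # mV per node
    g_na: np.ndarray          # uS
    g_k: np.ndarray
    g_kc: np.ndarray
    ca_coef: np.ndarray       # (n_subtypes, n) nA per unit GHK density
    densities: ActiveDensities
    mixture: CaChannelMixture | None
    passive: PassiveParams
    n_membrane: int           # nodes that belong to the morphology proper

    @property
    def n(self) -> int:
        return self.parent.size


def assemble(grid: CompartmentGrid, passive: PassiveParams,
             densities: ActiveDensities,
             mixture: CaChannelMixture | None = None) -> Circuit:
    """Build node-level circuit arrays from a compartment grid."""
    n = grid.n
    area = grid.area                      # um^2
    cap = passive.cm * area * 1e-5        # nF
    g_leak = passive.g_leak * area * 1e-5  # uS
    e_leak = np.full(n, passive.e_leak)
    g_na = np.full(n, densities.g_na) * area * 1e-5
    g_k = np.full(n, densities.g_k) * area * 1e-5
    gkc_density = np.broadcast_to(np.asarray(densities.g_k_comp, dtype=float), (n,))
    g_kc = gkc_density * area * 1e-5
    # coupling conductance to parent: series of the two half-resistances
    g_pair = np.zeros(n)
    for i in range(1, n):
        p = grid.parent[i]
        if p >= 0:
            g_pair[i] = 1.0 / (grid.r_half[i] + grid.r_half[p])
    if mixture is not None:
        perms = mixture.permeabilities
        ca_coef = perms[:, None] * area[None, :] * 0.01  # nA per mA/cm^2
    else:
        ca_coef = np.zeros((0, n))
    return Circuit(parent=grid.parent.astype(np.int64), g_pair=g_pair,
                   cap=cap, g_leak=g_leak, e_leak=e_leak,
                   g_na=g_na, g_k=g_k, g_kc=g_kc, ca_coef=ca_coef,
                   densities=densities, mixture=mixture, passive=passive,
                   n_membrane=n)


def _initial_state(circuit: Circuit, v0: float):
    n = circuit.n
    d = circuit.densities
    v = np.full(n, float(v0))
    m = np.full(n, float(gate_steady_state(v0, "m", d.shift_na)))
    h = np.full(n, float(gate_steady_state(v0, "h", d.shift_h)))
    nn = np.full(n, float(gate_steady_state(v0, "n", d.shift_k)))
    if d.slow_k_inactivation:
        sinf = d.slow_k_floor + (1 - d.slow_k_floor) / (
            1 + np.exp((v0 - d.slow_k_vhalf) / d.slow_k_slope))
        ks = np.full(n, float(sinf))
    else:
        ks = np.ones(n)
    kc = np.full(n, float(comp_gate_inf_tau(v0)[0]))
    mix = circuit.mixture
    if mix is not None:
        cg = np.stack([np.full(n, float(ca_gate_inf_tau(v0, s)[0]))
                       for s in mix.subtypes])
    else:
        cg = np.zeros((0, n))
    return v, m, h, nn, ks, kc, cg


def _ca_scalars(mix: CaChannelMixture | None):
    if mix is None:
        z = np.zeros(0)
        return z, z, z, z, 1.0, 0.0, 0.0, 0.0, 0.0
    vh = np.array([s.vhalf for s in mix.subtypes])
    sl = np.array([s.slope for s in mix.subtypes])
    tmin = np.array([s.tau_min for s in mix.subtypes])
    tamp = np.array([s.tau_amp for s in mix.subtypes])
    T = mix.temperature_kelvin
    u_coef = 2 * FARADAY * 1e-3 / (GAS_R * T)       # per mV
    zf3 = 2 * FARADAY * 1e3                          # mA/cm^2 per (mol/cm^3 * cm/s)
    return vh, sl, tmin, tamp, mix.rate_factor, u_coef, mix.ca_in * 1e-6, \
        mix.ca_out * 1e-6, zf3


def _integrate(circuit: Circuit, state, stim_sites, stim_wave,
               clamp_site, g_clamp, clamp_v, rec_idx,
               record_currents, record_ca, dt, nsteps, store):
    d = circuit.densities
    vh, sl, tmin, tamp, rate_factor, u_coef, ci, co, zf3 = _ca_scalars(circuit.mixture)
    v, m, h, nn, ks, kc, cg = state
    return _kernel.integrate(
        circuit.parent, circuit.g_pair, circuit.cap, circuit.g_leak,
        circuit.e_leak, circuit.g_na, circuit.g_k, circuit.g_kc,
        circuit.ca_coef,
        v, m, h, nn, ks, kc, cg,
        d.e_na, d.e_k,
        d.shift_na, d.shift_h, d.shift_k,
        d.rate_scale_na, d.rate_scale_h, d.rate_scale_k,
        d.slow_k_inactivation, d.slow_k_tau, d.slow_k_tau_depol,
        d.slow_k_vhalf, d.slow_k_slope, d.slow_k_floor,
        -30.0, 8.0, 0.2, 1.0,
        vh, sl, tmin, tamp, rate_factor,
        u_coef, ci, co, zf3,
        stim_sites, stim_wave,
        clamp_site, g_clamp, clamp_v,
        rec_idx, record_currents, record_ca,
        dt, nsteps, store)


def _resolve_rec_idx(grid: CompartmentGrid, config: SimConfig):
    spec = config.record_currents_at
    if spec is None:
        return np.zeros(0, dtype=np.int64), False
    if isinstance(spec, str) and spec == "all":
        return np.arange(grid.n, dtype=np.int64), True
    idx = np.array(sorted({grid.index_at(p) for p in spec}), dtype=np.int64)
    return idx, True


def _simulate(circuit: Circuit, grid: CompartmentGrid, config: SimConfig,
              clamp_site=-1, g_clamp=0.0, clamp_wave=None,
              site_lookup=None) -> SimulationResult:
    """Shared driver: settle phase, stimulus build, main run."""
    lookup = site_lookup or grid.index_at
    nsteps = int(round(config.duration / config.dt))
    stims = [s for s in config.stimuli if s.kind != "voltage_step"]
    if stims:
        stim_sites = np.array([lookup(s.site_um) for s in stims], dtype=np.int64)
        stim_wave = np.stack([s.waveform(config.dt, nsteps) for s in stims])
    else:
        stim_sites = np.zeros(0, dtype=np.int64)
        stim_wave = np.zeros((0, nsteps))
    rec_idx, record_currents = _resolve_rec_idx(grid, config)

    state = _initial_state(circuit, config.v_init)

    if config.settle > 0:
        settle_steps = int(round(config.settle / config.dt))
        hold = np.full(settle_steps, config.v_init) if clamp_site >= 0 \
            else np.zeros(1)
        _integrate(circuit, state,
                   np.zeros(0, dtype=np.int64), np.zeros((0, settle_steps)),
                   clamp_site, g_clamp, hold,
                   np.zeros(0, dtype=np.int64), False, False,
                   config.dt, settle_steps, False)

    cv = clamp_wave if clamp_wave is not None else np.zeros(1)
    v_out, cur_out, ica_out, clamp_current, vmax = _integrate(
        circuit, state, stim_sites, stim_wave,
        clamp_site, g_clamp, cv, rec_idx, record_currents, config.record_ca,
        config.dt, nsteps, True)

    time = np.arange(nsteps + 1) * config.dt
    currents = {}
    if record_currents:
        for k, name in enumerate(SPECIES):
            currents[name] = cur_out[k]
    injected = np.zeros(nsteps + 1)
    if stims:
        injected[1:] = stim_wave.sum(axis=0)
    rec_pos = grid.position[rec_idx] if record_currents and rec_idx.size \
        else np.zeros(0)
    return SimulationResult(
        time=time, v=v_out[:, :circuit.n_membrane],
        currents=currents, rec_positions=rec_pos,
        i_ca=ica_out[:, :circuit.n_membrane] if config.record_ca else None,
        injected=injected,
        clamp_current=clamp_current if clamp_site >= 0 else None,
        unstable=bool(vmax > V_LIMIT),
        meta={"dt": config.dt, "vmax_abs": float(vmax)},
    )


def run(grid: CompartmentGrid, passive: PassiveParams,
        densities: ActiveDensities, mixture: CaChannelMixture | None = None,
        config: SimConfig | None = None) -> SimulationResult:
    """Current-clamp simulation on a compartment grid."""
    config = config or SimConfig()
    for s in config.stimuli:
        if not (0.0 <= s.site_um <= grid.position[-1] + grid.length[-1]):
            raise ValueError(f"stimulus site {s.site_um} um outside morphology")
    circuit = assemble(grid, passive, densities, mixture)
    return _simulate(circuit, grid, config)


def voltage_clamp(grid: CompartmentGrid, passive: PassiveParams,
                  densities: ActiveDensities, config: SimConfig,
                  access_resistance: float = 0.0,
                  mixture: CaChannelMixture | None = None,
                  seal_resistance: float = np.inf) -> SimulationResult:
    """Voltage-clamp via an ideal source in series with the access resistance.

    The (single) ``voltage_step`` stimulus in ``config`` defines the command:
    held at ``config.v_init`` outside [onset, onset+width], stepped to
    ``amplitude`` mV inside.  ``access_resistance`` in MOhm (0 = ideal clamp,
    implemented as a 1 kOhm series resistance).  ``seal_resistance`` (GOhm)
    adds a leak to bath (0 mV) at the clamp site.  The returned
    ``clamp_current`` is the pipette current in nA.
    """
    if access_resistance < 0:
        raise ValueError("access resistance must be >= 0")
    steps = [s for s in config.stimuli if s.kind == "voltage_step"]
    if len(steps) != 1:
        raise ValueError("voltage_clamp needs exactly one voltage_step stimulus")
    vstep = steps[0]
    nsteps = int(round(config.duration / config.dt))
    t = np.arange(nsteps) * config.dt
    clamp_wave = np.where((t >= vstep.onset) & (t < vstep.onset + vstep.width),
                          vstep.amplitude, config.v_init)
    clamp_site = grid.index_at(vstep.site_um)
    rs = max(access_resistance, 1e-3)  # MOhm
    circuit = assemble(grid, passive, densities, mixture)
    if np.isfinite(seal_resistance):
        # fold seal leak (reversal 0 mV) into the clamp node's leak
        g_seal = 1e-3 / seal_resistance  # uS (GOhm -> 1/(1e3 MOhm))
        g0 = circuit.g_leak[clamp_site]
        e0 = circuit.e_leak[clamp_site]
        circuit.g_leak[clamp_site] = g0 + g_seal
        circuit.e_leak[clamp_site] = (g0 * e0) / (g0 + g_seal)
    return _simulate(circuit, grid, config, clamp_site=clamp_site,
                     g_clamp=1.0 / rs, clamp_wave=clamp_wave)


def detect_spikes(trace: np.ndarray, dt: float, level: float = -20.0):
    """Times (ms) of upward crossings of ``level``; linear interpolation."""
    above = trace >= level
    idx = np.flatnonzero(~above[:-1] & above[1:])
    out = []
    for i in idx:
        f = (level - trace[i]) / (trace[i + 1] - trace[i])
        out.append((i + f) * dt)
    return np.asarray(out)


def train_protocol(grid: CompartmentGrid, passive: PassiveParams,
                   densities: ActiveDensities, n_aps: int, frequency: float,
                   pulse_width: float = 3.0, amplitude: float = 0.5,
                   site_um: float = 0.0, measure_um: float | None = None,
                   mixture: CaChannelMixture | None = None,
                   dt: float = 0.004, onset: float = 1.0,
                   settle: float = 20.0):
    """Deliver ``n_aps`` current pulses; verify one AP per pulse.

    Returns (result, ap_times, ok) where ``ok`` is False if any pulse failed
    to elicit exactly one AP (the failure count goes to ``result.meta``).
    """
    if frequency <= 0 or n_aps < 1:
        raise ValueError("frequency and n_aps must be positive")
    period = 1000.0 / frequency
    duration = onset + n_aps * period + 5.0
    stim = Stimulus("current_train", site_um, amplitude, onset, pulse_width,
                    frequency=frequency, n_pulses=n_aps)
    config = SimConfig(dt=dt, duration=duration, stimuli=(stim,),
                       settle=settle)
    result = run(grid, passive, densities, mixture, config)
    mi = grid.index_at(measure_um if measure_um is not None else site_um)
    ap_times = detect_spikes(result.v[:, mi], dt)
    failures = 0
    for k in range(n_aps):
        lo = onset + k * period
        n_in = int(np.sum((ap_times >= lo) & (ap_times < lo + period)))
        if n_in != 1:
            failures += 1
    result.meta["ap_failures"] = failures
    result.meta["ap_times"] = ap_times
    return result, ap_times, failures == 0
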