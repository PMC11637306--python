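"""Seeded generators for every synthetic input the analyses consume.

The generators emulate the study system: an unmyelinated, varicose
mossy-fiber-like axon (thin shaft of ~0.3 um bearing en passant boutons of
0.5-1.5 um and occasional giant boutons of 2-5 um), whole-cell/cell-attached
voltage-clamp transients through a pipette, current-clamp AP trains, and
voltage-sensitive-dye (VSD) image stacks at 10 kHz paired with 250 kHz
electrical reference traces.

Every generator is a pure function of its spec: the same seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cable import SimConfig, Stimulus, run, voltage_clamp
from .channels import ActiveDensities, CaChannelMixture, PassiveParams
from .morphology import CompartmentGrid, Morphology, Node, discretize
from .vsd import EphysReference, VSDStack

__all__ = [
    "AxonSpec",
    "VSDRenderSpec",
    "make_axon",
    "make_recording",
    "make_vsd_dataset",
    "two_compartment_transient",
]


@dataclass(frozen=True)
class AxonSpec:
    """Parameters of the synthetic varicose axon.

    Bouton diameters are log-normal (small en passant mode near 1 um) with a
    separate giant-bouton population at 2-5 um, reflecting the two caliber
    populations of mossy fibers; all diameters clipped to [0.1, 5] um.
    """

    seed: int = 0
    length: float = 600.0            # um, includes a 150 um run-in each end
    shaft_diameter: float = 0.3      # um
    node_spacing: float = 1.0        # um
    n_boutons: int = 14
    n_giant: int = 4
    bouton_diameter_median: float = 1.0   # um, log-normal median
    bouton_diameter_sigma: float = 0.35   # log-sd
    giant_diameter_range: tuple[float, float] = (2.5, 4.5)  # um
    min_spacing: float = 15.0        # um between bouton centers
    edge_margin: float = 150.0       # um kept bouton-free at both ends


def _draw_positions(rng: np.random.Generator, spec: AxonSpec, n: int):
    """Stratified bouton centers: one per equal slot, jittered within it."""
    lo = spec.edge_margin
    hi = spec.length - spec.edge_margin
    span = hi - lo
    slot = span / n
    if slot < spec.min_spacing:
        raise ValueError(
            f"cannot place {n} boutons {spec.min_spacing} um apart in {span} um")
    jitter = (slot - spec.min_spacing) / 2.0
    base = lo + (np.arange(n) + 0.5) * slot
    return base + rng.uniform(-jitter, jitter, size=n)


def make_axon(spec: AxonSpec = AxonSpec()) -> Morphology:
    """Generate an unbranched varicose axon with labelled boutons.

    The diameter profile is the shaft diameter plus a Gaussian bump per
    bouton (width tied to the bouton diameter), sampled at ``node_spacing``;
    nodes where a bump dominates are labelled ``bouton``.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_boutons + spec.n_giant
    centers = _draw_positions(rng, spec, n_total)
    giant_idx = rng.choice(n_total, size=spec.n_giant, replace=False)
    diams = np.exp(rng.normal(np.log(spec.bouton_diameter_median),
                              spec.bouton_diameter_sigma, size=n_total))
    lo, hi = spec.giant_diameter_range
    diams[giant_idx] = rng.uniform(lo, hi, size=spec.n_giant)
    diams = np.clip(diams, 0.1, 5.0)

    x = np.arange(0.0, spec.length + 1e-9, spec.node_spacing)
    d = np.full_like(x, spec.shaft_diameter)
    for c, db in zip(centers, diams):
        w = max(db / 2.0, 0.75)
        d += (db - spec.shaft_diameter) * np.exp(-((x - c) / w) ** 2)
    d = np.clip(d, 0.1, 5.0)
    is_bouton = d > 1.5 * spec.shaft_diameter

    nodes = [Node(id=1, parent_id=None, x=0.0, y=0.0, z=0.0,
                  radius=d[0] / 2, label="axon")]
    for i in range(1, x.size):
        nodes.append(Node(id=i + 1, parent_id=i, x=float(x[i]), y=0.0, z=0.0,
                          radius=float(d[i] / 2),
                          label="bouton" if is_bouton[i] else "axon"))
    meta = {
        "generator": "axonwave.synth.make_axon",
        "seed": spec.seed,
        "bouton_centers_um": [float(c) for c in centers],
        "bouton_diameters_um": [float(v) for v in diams],
    }
    return Morphology(nodes=nodes, metadata=meta)


# ---------------------------------------------------------------------------
# electrophysiology fixtures


def make_recording(morph: Morphology, protocol: str, seed: int = 0,
                   noise_sd: float = 0.0, passive: PassiveParams | None = None,
                   densities: ActiveDensities | None = None,
                   site_um: float | None = None, dt: float = 0.004):
    """Synthetic current/voltage-clamp recording on a morphology.

    ``protocol`` is one of ``seal_test`` (100 ms, -70 to -90 mV voltage
    clamp), ``single_ap`` or ``ap_train`` (3 ms current pulses).  Returns
    ``(time, clean, noisy)`` traces; the noisy trace adds white Gaussian
    noise of ``noise_sd`` (nA for clamp current, mV for voltage).
    """
    rng = np.random.default_rng(seed)
    passive = passive or PassiveParams()
    densities = densities or ActiveDensities()
    grid = discretize(morph, 1.0, ra=passive.ra)
    site = site_um if site_um is not None else float(grid.position[grid.n // 2])
    if protocol == "seal_test":
        stim = Stimulus("voltage_step", site, -90.0, onset=10.0, width=100.0)
        cfg = SimConfig(dt=dt, duration=120.0, stimuli=(stim,), v_init=-70.0,
                        settle=50.0)
        res = voltage_clamp(grid, passive, densities.with_(g_na=0.0, g_k=0.0),
                            cfg, access_resistance=15.0)
        clean = res.clamp_current
    elif protocol in ("single_ap", "ap_train"):
        n = 1 if protocol == "single_ap" else 10
        stim = Stimulus("current_train", site, 0.5, onset=2.0, width=3.0,
                        frequency=40.0, n_pulses=n)
        duration = 2.0 + n * 25.0 + 5.0
        cfg = SimConfig(dt=dt, duration=duration, stimuli=(stim,))
        res = run(grid, passive, densities, None, cfg)
        clean = res.v[:, grid.index_at(site)]
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    return res.time, clean, noisy


def two_compartment_transient(c_local: float = 5.0, c_remote: float = 60.0,
                              r_axial: float = 800.0, r_access: float = 100.0,
                              r_m_local: float = 1e4, r_m_remote: float = 450.0,
                              dv: float = -20.0, duration: float = 80.0,
                              dt: float = 0.004, onset: float = 5.0,
                              seal_gohm: float = np.inf,
                              noise_sd: float = 0.0, seed: int = 0):
    """Closed-form capacitive transient of the two-compartment probe circuit.

    Pipette (access resistance ``r_access`` MOhm) into a local compartment
    (``c_local`` pF, membrane resistance ``r_m_local`` MOhm) coupled through
    ``r_axial`` MOhm to a remote compartment (``c_remote`` pF,
    ``r_m_remote`` MOhm).  A voltage step of ``dv`` mV at ``onset``; the
    exact biexponential pipette current comes from the 2x2 linear-circuit
    eigendecomposition.  Optional seal leak to bath and Gaussian noise.

    Returns ``(t, current_nA, info)`` with the eigen time constants in
    ``info`` (ms, ascending).
    """
    c1, c2 = c_local * 1e-3, c_remote * 1e-3    # nF
    g_s = 1.0 / r_access                         # uS
    g_a = 1.0 / r_axial
    g1, g2 = 1.0 / r_m_local, 1.0 / r_m_remote

    # x = [v1, v2] relative to holding; C dx/dt = A x + b(t), pipette at u(t)
    A = np.array([[-(g_s + g1 + g_a) / c1, g_a / c1],
                  [g_a / c2, -(g_a + g2) / c2]])
    evals, evecs = np.linalg.eig(A)
    taus = np.sort(-1.0 / evals.real)

    t = np.arange(0.0, duration + dt / 2, dt)
    u = np.where(t >= onset, dv, 0.0)
    v_pre = np.linalg.solve(A, -np.array([0.0, 0.0]))
    v_post = np.linalg.solve(A, -np.array([g_s * dv / c1, 0.0]))
    coef = np.linalg.solve(evecs, v_pre - v_post)
    tp = np.clip(t - onset, 0.0, None)
    v1 = np.where(
        t >= onset,
        (v_post[0]
         + (evecs[0, :] * coef)[None, :] @ np.exp(np.outer(evals, tp))).ravel().real,
        v_pre[0])
    current = g_s * (u - v1)                     # uS * mV = nA
    if np.isfinite(seal_gohm):
        current = current + u / (seal_gohm * 1e3)  # seal leak, GOhm -> MOhm
    rng = np.random.default_rng(seed)
    noisy = current + rng.normal(0.0, noise_sd, size=current.shape)
    info = {"taus": taus, "onset": onset, "dv": dv}
    return t, noisy, info


# ---------------------------------------------------------------------------
# VSD rendering


@dataclass(frozen=True)
class VSDRenderSpec:
    """Parameters of the synthetic VSD imaging model.

    Fluorescence per pixel: F(t) = F0 * bleach(t) * (1 + s*(V - V_rest)/100)
    plus shot noise (Gaussian with variance proportional to F) and Gaussian
    read noise; ``s`` is the fractional sensitivity per 100 mV.  Each trial's
    frame clock is jittered uniformly within one frame period against the
    electrical clock, plus a small Gaussian detection error on the reference
    peak.
    """

    seed: int = 0
    n_trials: int = 20
    frame_rate_khz: float = 10.0
    shape: tuple[int, int] = (46, 64)     # rows x cols; axon runs along cols
    pixel_size_um: float = 0.79
    sensitivity_per_100mv: float = 0.08
    f0_axon: float = 2000.0               # counts at baseline on the axon
    f0_background: float = 300.0
    axon_rows: int = 2
    read_noise_sd: float = 10.0
    shot_noise_scale: float = 1.0         # 0 disables shot noise
    bleach_amplitudes: tuple[float, float] = (0.15, 0.25)
    bleach_taus_ms: tuple[float, float] = (50.0, 500.0)
    duration_ms: float = 12.0
    detection_jitter_ms: float = 0.004    # electrical peak-time error SD


def render_vsd_trial(spec: VSDRenderSpec, grid: CompartmentGrid,
                     sim_time: np.ndarray, v: np.ndarray, x0_um: float,
                     rng: np.random.Generator, ap_time_in_trial: float = 5.0,
                     noiseless: bool = False):
    """Render one VSD trial from simulated voltage.

    ``v`` is the (T, n) compartment voltage array; the imaged field of view
    starts at path position ``x0_um`` (axon along image columns).  Returns
    ``(VSDStack, EphysReference, frame_offset_ms)``.
    """
    h, wdt = spec.shape
    dt_f = 1.0 / spec.frame_rate_khz
    n_frames = int(round(spec.duration_ms / dt_f))
    # frames sit on the shared acquisition clock; the AP lands at a random
    # phase within one frame period (the imaging clock never resolves it)
    frame_times = np.arange(n_frames) * dt_f
    offset = float(rng.uniform(0.0, dt_f))
    t_ap = ap_time_in_trial + offset

    # true AP peak (electrical time base) at the field-of-view center
    center_idx = grid.index_at(x0_um + 0.5 * wdt * spec.pixel_size_um)
    vc = v[:, center_idx]
    t_peak_sim = float(sim_time[np.argmax(vc)])
    # place the simulated AP peak at t_ap on the trial clock
    t_shift = t_ap - t_peak_sim
    v_rest = float(vc[0])

    rows = h // 2 + np.arange(spec.axon_rows) - spec.axon_rows // 2
    f0 = np.full((h, wdt), spec.f0_background)
    path_pos = np.full((h, wdt), np.nan)
    mask = np.zeros((h, wdt), dtype=bool)
    comp_of_col = np.array([grid.index_at(x0_um + (j + 0.5) * spec.pixel_size_um)
                            for j in range(wdt)])
    # baseline fluorescence scales with local membrane (diameter)
    diam = grid.diameter[comp_of_col]
    for r in rows:
        f0[r, :] = spec.f0_axon * diam / diam.mean()
        path_pos[r, :] = x0_um + (np.arange(wdt) + 0.5) * spec.pixel_size_um
        mask[r, :] = True

    a1, a2 = spec.bleach_amplitudes
    t1, t2 = spec.bleach_taus_ms
    bleach = (1 - a1 - a2) + a1 * np.exp(-frame_times / t1) \
        + a2 * np.exp(-frame_times / t2)

    s = spec.sensitivity_per_100mv
    frames = np.empty((n_frames, h, wdt))
    v_cols = np.empty((n_frames, wdt))
    for j in range(wdt):
        v_cols[:, j] = np.interp(frame_times - t_shift, sim_time,
                                 v[:, comp_of_col[j]],
                                 left=v_rest, right=v_rest)
    signal = 1.0 + s * (v_cols - v_rest) / 100.0
    for k in range(n_frames):
        img = f0 * bleach[k]
        img[rows[0]:rows[-1] + 1, :] = (f0[rows[0]:rows[-1] + 1, :]
                                        * bleach[k] * signal[k][None, :])
        frames[k] = img
    if not noiseless:
        if spec.shot_noise_scale > 0:
            frames = frames + rng.normal(0.0, 1.0, frames.shape) \
                * np.sqrt(np.maximum(frames, 0.0)) * spec.shot_noise_scale
        if spec.read_noise_sd > 0:
            frames = frames + rng.normal(0.0, spec.read_noise_sd, frames.shape)
    frames = np.maximum(frames, 0.0)

    # 250 kHz electrical reference on the same clock
    dt_e = 0.004
    te = np.arange(0.0, spec.duration_ms, dt_e)
    ve = np.interp(te - t_shift, sim_time, vc, left=v_rest, right=v_rest)
    peak = t_ap + float(rng.normal(0.0, spec.detection_jitter_ms))
    ref = EphysReference(time=te, v=ve, peak_times=np.array([peak]))

    stack = VSDStack(frames=frames, frame_rate_khz=spec.frame_rate_khz,
                     pixel_size_um=spec.pixel_size_um,
                     event_times_ms=np.array([t_ap]),
                     mask=mask, path_position_um=path_pos,
                     meta={"ap_phase_ms": offset, "x0_um": x0_um})
    return stack, ref, offset


def make_vsd_dataset(spec: VSDRenderSpec, grid: CompartmentGrid,
                     sim_time: np.ndarray, v: np.ndarray, x0_um: float):
    """Render a full multi-trial VSD dataset with per-trial clock jitter.

    Returns a dict with ``stacks``, ``references``, ``mask``,
    ``path_position``, and the noiseless ground truth (stack of the first
    trial geometry rendered without noise and without bleaching).
    """
    rng = np.random.default_rng(spec.seed)
    stacks, refs = [], []
    for _ in range(spec.n_trials):
        st, ref, _ = render_vsd_trial(spec, grid, sim_time, v, x0_um, rng)
        stacks.append(st)
        refs.append(ref)
    clean_spec = VSDRenderSpec(
        seed=spec.seed, n_trials=1, frame_rate_khz=spec.frame_rate_khz,
        shape=spec.shape, pixel_size_um=spec.pixel_size_um,
        sensitivity_per_100mv=spec.sensitivity_per_100mv,
        f0_axon=spec.f0_axon, f0_background=spec.f0_background,
        axon_rows=spec.axon_rows, read_noise_sd=0.0, shot_noise_scale=0.0,
        bleach_amplitudes=(0.0, 0.0), bleach_taus_ms=spec.bleach_taus_ms,
        duration_ms=spec.duration_ms,
        detection_jitter_ms=0.0)
    rng0 = np.random.default_rng(spec.seed + 1)
    clean, clean_ref, _ = render_vsd_trial(clean_spec, grid, sim_time, v,
                                           x0_um, rng0, noiseless=True)
    return {"stacks": stacks, "references": refs,
            "mask": stacks[0].mask, "path_position": stacks[0].path_position_um,
            "ground_truth": clean, "ground_truth_reference": clean_ref}
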