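"""Local passive biophysics from seal-test transients.

The measurement pipeline used on patched axonal structures: a -20 mV
voltage-clamp step (-70 to -90 mV) drives a capacitive current transient;
after subtracting the averaged cell-attached trace (residual instrumental
capacitance), the transient is fitted with sums of 1-3 exponentials in a
window anchored at the transient peak.  A two-compartment equivalent
circuit is the adequate representation of a patched axon: the fast
component reflects the local membrane at the recording site, the slow one
the composite arbor.  The structure capacitance follows from the fast
component's charge, C = |A_fast * tau_fast| / dV, with the amplitude
back-extrapolated from the fit-window start to the step onset and a
circuit-exact correction for the voltage division across the access
resistance (see :func:`structure_capacitance`).  The window must be long
enough to resolve the slow component against the offset; the default spans
0-60 ms after the peak and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TransientRecord",
    "ExpFit",
    "PassiveEstimate",
    "subtract_cell_attached",
    "fit_exponentials",
    "select_model",
    "structure_capacitance",
    "input_resistance",
    "membrane_time_constant",
]


@dataclass(frozen=True)
class TransientRecord:
    """A capacitive current transient from a voltage-clamp step."""

    time: np.ndarray          # ms
    current: np.ndarray       # nA
    dv: float = -20.0         # mV step (-70 -> -90)
    step_onset: float = 0.0   # ms
    mode: str = "whole_cell"  # whole_cell | cell_attached
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class ExpFit:
    """Least-squares fit of sum(A_i exp(-t/tau_i)) + offset after the peak."""

    n_exp: int
    amplitudes: np.ndarray    # nA, at the fit-window start
    taus: np.ndarray          # ms, ascending
    offset: float             # nA
    sse: float                # nA^2
    window: tuple[float, float]   # ms after the transient peak
    t_window_start: float     # absolute time of the window start, ms
    peak_time: float          # absolute time of the transient peak, ms
    step_onset: float         # absolute time of the step, ms
    dv: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.taus) > 0):
            raise ValueError("taus must be strictly increasing")


@dataclass(frozen=True)
class PassiveEstimate:
    """Local biophysics of a patched structure."""

    structure_capacitance_pf: float
    input_resistance_mohm: float
    membrane_time_constant_ms: float

    def __post_init__(self) -> None:
        if min(self.structure_capacitance_pf, self.input_resistance_mohm,
               self.membrane_time_constant_ms) <= 0:
            raise ValueError("passive estimates must be positive")


def subtract_cell_attached(whole_cell: TransientRecord,
                           cell_attached_avg: TransientRecord) -> TransientRecord:
    """Remove residual uncompensated instrumental capacitance."""
    if whole_cell.time.shape != cell_attached_avg.time.shape or \
            not np.allclose(whole_cell.time, cell_attached_avg.time):
        raise ValueError("time bases do not match")
    if abs(whole_cell.step_onset - cell_attached_avg.step_onset) > 1e-9:
        raise ValueError("step onsets do not match")
    meta = dict(whole_cell.meta)
    meta["cell_attached_subtracted"] = True
    return replace(whole_cell,
                   current=whole_cell.current - cell_attached_avg.current,
                   meta=meta)


def _model(t, amps, taus, offset):
    return offset + sum(a * np.exp(-t / tau) for a, tau in zip(amps, taus))


def fit_exponentials(record: TransientRecord, n_exp: int,
                     window: tuple[float, float] = (0.0, 60.0),
                     n_starts: int = 5, seed: int = 0,
                     start_hint: ExpFit | None = None) -> ExpFit:
    """Multi-start least-squares multiexponential fit after the peak.

    The window is expressed relative to the transient peak (the first
    extremum after the step onset).  ``n_starts`` log-spaced tau
    initializations are tried (plus, if ``start_hint`` is given, a start
    derived from a lower-order fit, which guarantees nested-model SSE
    ordering); the best-SSE solution wins.  Deterministic for a given seed.
    """
    if n_exp not in (1, 2, 3):
        raise ValueError("n_exp must be 1, 2 or 3")
    t = record.time
    i = record.current
    after = t >= record.step_onset
    ipeak = int(np.argmax(np.abs(i - i[after][-1]) * after))
    t_peak = float(t[ipeak])
    lo, hi = window
    sel = (t >= t_peak + lo) & (t <= t_peak + hi)
    if sel.sum() < 3 * n_exp + 2:
        raise ValueError("fit window too short for the requested model")
    ts = t[sel] - (t_peak + lo)
    ys = i[sel]
    rng = np.random.default_rng(seed)
    # a decay faster than a few samples is unresolvable, not a component
    log_tau_min = float(np.log(3.0 * record.dt))

    def pack(amps, taus, offset):
        return np.concatenate([amps, np.log(taus), [offset]])

    def unpack(p):
        log_tau = np.clip(p[n_exp:2 * n_exp], log_tau_min, 8.0)
        return p[:n_exp], np.exp(log_tau), p[-1]

    def resid(p):
        a, tau, off = unpack(p)
        return _model(ts, a, tau, off) - ys

    span = hi - lo
    amp0 = ys[0] - ys[-1]
    starts = []
    for k in range(n_starts):
        taus0 = np.sort(np.exp(rng.uniform(np.log(span / 50), np.log(4 * span),
                                           size=n_exp)))
        amps0 = np.full(n_exp, amp0 / n_exp)
        starts.append(pack(amps0, taus0, ys[-1]))
    if start_hint is not None and start_hint.n_exp < n_exp:
        k = n_exp - start_hint.n_exp
        hint_amps = np.concatenate([start_hint.amplitudes, np.zeros(k)])
        hint_taus = np.concatenate([start_hint.taus,
                                    start_hint.taus[-1] * (2.0 + np.arange(k))])
        starts.append(pack(hint_amps, np.sort(hint_taus), start_hint.offset))

    best = None
    for p0 in starts:
        try:
            sol = least_squares(resid, p0, method="lm", max_nfev=4000)
        except Exception:
            continue
        sse = float(np.sum(sol.fun ** 2))
        if best is None or sse < best[0]:
            best = (sse, sol.x)
    if best is None:
        raise RuntimeError("multiexponential fit failed from every start")
    sse, p = best
    amps, taus, offset = unpack(p)
    order = np.argsort(taus)
    # guard against degenerate equal taus produced by the optimizer
    taus = taus[order]
    for j in range(1, taus.size):
        if taus[j] <= taus[j - 1]:
            taus[j] = taus[j - 1] * (1 + 1e-9)
    return ExpFit(n_exp=n_exp, amplitudes=amps[order], taus=taus,
                  offset=float(offset), sse=sse, window=window,
                  t_window_start=t_peak + lo, peak_time=t_peak,
                  step_onset=record.step_onset, dv=record.dv)


def select_model(fits: dict[int, ExpFit], tri_gain: float = 0.10,
                 mono_margin: float = 0.10) -> int:
    """Pick the number of exponentials: 2 by default.

    Chooses the bi-exponential (two-compartment) model unless the
    tri-exponential improves its SSE by more than ``tri_gain`` of the
    bi-exponential SSE, or the mono-exponential is within ``mono_margin`` of
    the bi-exponential (then the extra compartment is unsupported).
    """
    if set(fits) != {1, 2, 3}:
        raise ValueError("need fits for n_exp = 1, 2 and 3")
    s1, s2, s3 = fits[1].sse, fits[2].sse, fits[3].sse
    if s1 <= s2 * (1 + mono_margin):
        return 1
    if s3 < s2 * (1 - tri_gain):
        return 3
    return 2


def structure_capacitance(fit: ExpFit, dv: float | None = None,
                          tau_ratio_warn: float = 3.0,
                          baseline: float = 0.0):
    """Local membrane capacitance from the fast fit component, pF.

    The fast-component charge gives C = |A0 * tau_fast / dV| with A0
    back-extrapolated from the fit-window start to the step onset along the
    fitted exponential.  Because part of the clamp step drops across the
    access resistance and the axial path, the raw fast charge underestimates
    the local capacitance by the square of the voltage-division ratio
    v_local/v_pipette = A0_fast / I0, where I0 (the total step current at
    onset) is available from the fit itself as sum(A0_i) + offset; the
    returned value applies this circuit-exact correction, which reduces to
    the plain fast-charge formula for an ideal clamp.  nA*ms/mV = nF, hence
    the 1e3 factor to pF.  Returns ``(capacitance_pF, degenerate_flag)``;
    the flag is set when the tau separation is below ``tau_ratio_warn``.
    """
    if fit.n_exp < 2:
        raise ValueError("structure capacitance needs a >= 2-exponential fit")
    dv = fit.dv if dv is None else dv
    if dv == 0:
        raise ValueError("dv must be nonzero")
    taus = np.asarray(fit.taus, dtype=float)
    back = fit.t_window_start - fit.step_onset
    a0 = np.asarray(fit.amplitudes, dtype=float) * np.exp(back / taus)
    tau_fast = float(taus[0])
    cap_raw = abs(a0[0] * tau_fast / dv) * 1e3
    i0 = float(a0.sum() + fit.offset - baseline)
    division = a0[0] / i0 if i0 != 0 else 1.0
    cap_pf = cap_raw / division ** 2 if division != 0 else cap_raw
    degenerate = bool(taus[1] / tau_fast < tau_ratio_warn)
    return float(cap_pf), degenerate


def input_resistance(record: TransientRecord, baseline_frac: float = 0.2,
                     steady_frac: float = 0.2) -> float:
    """R_in = dV / dI_ss from the voltage-clamp step, MOhm (leak-subtracted).

    The steady-state current is the mean over the last ``steady_frac`` of
    the step; the baseline is the mean over the last ``baseline_frac`` of
    the pre-step period.
    """
    t = record.time
    i = record.current
    pre = t < record.step_onset
    post = t >= record.step_onset
    if pre.sum() < 2 or post.sum() < 10:
        raise ValueError("step too short to reach steady state")
    t_pre = t[pre]
    base = i[pre][t_pre >= t_pre[0] + (1 - baseline_frac) * (t_pre[-1] - t_pre[0])]
    t_post = t[post]
    ss = i[post][t_post >= t_post[0] + (1 - steady_frac) * (t_post[-1] - t_post[0])]
    di = float(ss.mean() - base.mean())
    if di == 0:
        raise ValueError("no steady-state current change")
    return abs(record.dv / di)


def membrane_time_constant(time: np.ndarray, v: np.ndarray,
                           step_onset: float, late_frac: float = 0.8,
                           seed: int = 0) -> float:
    """Slow time constant of a current-clamp voltage relaxation, ms.

    Fits a single exponential to the late phase (last ``late_frac``) of the
    post-step relaxation, where the fast redistribution components have
    decayed and the slow membrane component dominates.
    """
    t = np.asarray(time, dtype=float)
    v = np.asarray(v, dtype=float)
    post = t >= step_onset
    tp = t[post] - step_onset
    vp = v[post]
    v_inf = vp[int(0.9 * vp.size):].mean()
    sel = tp >= (1 - late_frac) * tp[-1]
    y = vp - v_inf
    rec = TransientRecord(time=tp[sel], current=y[sel], dv=1.0,
                          step_onset=float(tp[sel][0]))
    fit = fit_exponentials(rec, 1, window=(0.0, float(tp[sel][-1] - tp[sel][0])),
                           seed=seed)
    return float(fit.taus[0])
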