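"""Action-potential waveform metrics.

Works on any uniformly sampled single-AP trace (simulation, patch recording,
or normalized voltage-imaging signal).  Conventions follow axonal
electrophysiology practice: the AP onset is the point where the upstroke
velocity first reaches 100 mV/ms; the AP area integrates v minus the onset
voltage from onset to the first post-peak return to the onset voltage; the
repolarization-only area integrates the same reference from the peak (this
avoids contaminating the measurement with rise-phase effects); duration can
be quantified as the width at an absolute level (-20 mV for propagating
simulated APs) or at half the onset-to-peak amplitude.  All crossing times
are refined by linear sub-sample interpolation, which removes the leading
dt-dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "APWaveform",
    "APMetrics",
    "NotAnAPError",
    "detect_onset",
    "ap_area",
    "repol_area",
    "width_at_level",
    "half_width",
    "broadening",
    "measure",
]


class NotAnAPError(ValueError):
    """The trace does not contain a detectable action potential."""


@dataclass(frozen=True)
class APWaveform:
    """A uniformly sampled waveform containing one dominant AP."""

    time: np.ndarray   # ms
    v: np.ndarray      # mV (or normalized fluorescence)
    source: str = "sim"   # ephys | sim | vsd

    def __post_init__(self) -> None:
        t = np.asarray(self.time)
        if t.ndim != 1 or t.size != np.asarray(self.v).size or t.size < 3:
            raise ValueError("time and v must be 1-D, equal length, >= 3 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("waveform must be uniformly sampled")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def sample_rate_khz(self) -> float:
        return 1.0 / self.dt


@dataclass(frozen=True)
class APMetrics:
    onset_time: float
    onset_voltage: float
    peak_time: float
    amplitude: float        # onset-to-peak, mV
    area: float             # mV*ms
    repol_area: float       # mV*ms
    half_width: float       # ms
    width_at_minus20: float  # ms; nan if peak below -20 mV
    max_rise: float         # mV/ms
    max_decay: float        # mV/ms (negative)


def _crossing_time(t0, t1, y0, y1, level):
    """Linear interpolation of the crossing of ``level`` between two samples."""
    return t0 + (level - y0) / (y1 - y0) * (t1 - t0)


def detect_onset(wave: APWaveform, slope_threshold: float = 100.0):
    """First pre-peak crossing of dV/dt above ``slope_threshold`` (mV/ms).

    Returns ``(time, voltage)`` with sub-sample interpolation of both.
    Raises :class:`NotAnAPError` when the upstroke never reaches the
    threshold before the peak.
    """
    v = np.asarray(wave.v, dtype=float)
    t = np.asarray(wave.time, dtype=float)
    dvdt = np.gradient(v, wave.dt)
    ipeak = int(np.argmax(v))
    pre = dvdt[: ipeak + 1]
    above = np.flatnonzero(pre >= slope_threshold)
    if above.size == 0:
        raise NotAnAPError(
            f"upstroke velocity never reached {slope_threshold} mV/ms")
    i = int(above[0])
    if i == 0:
        return float(t[0]), float(v[0])
    tc = _crossing_time(t[i - 1], t[i], dvdt[i - 1], dvdt[i], slope_threshold)
    vc = np.interp(tc, t, v)
    return float(tc), float(vc)


def _return_index(v, t, ipeak, vref):
    """First post-peak sub-sample crossing of vref; truncation error if none."""
    post = v[ipeak:]
    below = np.flatnonzero(post <= vref)
    if below.size == 0:
        raise NotAnAPError("trace ends before returning to the reference voltage")
    j = ipeak + int(below[0])
    if j == ipeak:
        return float(t[j])
    return _crossing_time(t[j - 1], t[j], v[j - 1], v[j], vref)


def _area_between(t, v, t_start, t_end, vref):
    """Trapezoid integral of (v - vref) over [t_start, t_end], sub-sampled."""
    inside = (t > t_start) & (t < t_end)
    ts = np.concatenate(([t_start], t[inside], [t_end]))
    vs = np.concatenate(([np.interp(t_start, t, v)], v[inside],
                         [np.interp(t_end, t, v)]))
    return float(np.trapezoid(vs - vref, ts))


def ap_area(wave: APWaveform, onset: tuple[float, float] | None = None) -> float:
    """Integral of (v - onset voltage) from onset to first return, mV*ms."""
    if onset is None:
        onset = detect_onset(wave)
    t_on, v_on = onset
    v = np.asarray(wave.v, dtype=float)
    t = np.asarray(wave.time, dtype=float)
    ipeak = int(np.argmax(v))
    t_ret = _return_index(v, t, ipeak, v_on)
    return _area_between(t, v, t_on, t_ret, v_on)


def repol_area(wave: APWaveform, reference: float | None = None) -> float:
    """Integral of (v - reference) from the peak to return-to-reference.

    ``reference`` defaults to the onset voltage for ephys/sim waveforms and
    to the pre-peak baseline (first sample) for VSD waveforms.
    """
    v = np.asarray(wave.v, dtype=float)
    t = np.asarray(wave.time, dtype=float)
    ipeak = int(np.argmax(v))
    if reference is None:
        if wave.source == "vsd":
            reference = float(v[0])
        else:
            reference = detect_onset(wave)[1]
    t_ret = _return_index(v, t, ipeak, reference)
    return _area_between(t, v, float(t[ipeak]), t_ret, reference)


def width_at_level(wave: APWaveform, level: float = -20.0) -> float:
    """Time between the up- and down-crossings of ``level`` around the peak."""
    v = np.asarray(wave.v, dtype=float)
    t = np.asarray(wave.time, dtype=float)
    ipeak = int(np.argmax(v))
    if v[ipeak] <= level:
        raise NotAnAPError(f"peak {v[ipeak]:.1f} mV is below the level {level}")
    pre = np.flatnonzero(v[: ipeak + 1] <= level)
    post = np.flatnonzero(v[ipeak:] <= level)
    if pre.size == 0 or post.size == 0:
        raise NotAnAPError("trace does not bracket the level on both flanks")
    i = int(pre[-1])           # last sample at/below level before peak
    j = ipeak + int(post[0])   # first sample at/below level after peak
    t_up = _crossing_time(t[i], t[i + 1], v[i], v[i + 1], level)
    t_dn = _crossing_time(t[j - 1], t[j], v[j - 1], v[j], level)
    return float(t_dn - t_up)


def half_width(wave: APWaveform, onset: tuple[float, float] | None = None) -> float:
    """Width at 50% of the onset-to-peak amplitude, ms."""
    if onset is None:
        onset = detect_onset(wave)
    v_on = onset[1]
    vpk = float(np.max(wave.v))
    return width_at_level(wave, v_on + 0.5 * (vpk - v_on))


def broadening(train_waves: list[APWaveform]) -> np.ndarray:
    """Half-width of each AP in a train normalized to the first AP."""
    if not train_waves:
        raise ValueError("empty train")
    hws = np.array([half_width(w) for w in train_waves])
    return hws / hws[0]


def measure(wave: APWaveform, slope_threshold: float = 100.0) -> APMetrics:
    """All metrics of one AP in a single pass."""
    t_on, v_on = detect_onset(wave, slope_threshold)
    v = np.asarray(wave.v, dtype=float)
    ipeak = int(np.argmax(v))
    dvdt = np.gradient(v, wave.dt)
    try:
        w20 = width_at_level(wave, -20.0)
    except NotAnAPError:
        w20 = float("nan")
    return APMetrics(
        onset_time=t_on,
        onset_voltage=v_on,
        peak_time=float(wave.time[ipeak]),
        amplitude=float(v[ipeak] - v_on),
        area=ap_area(wave, (t_on, v_on)),
        repol_area=repol_area(wave, v_on),
        half_width=half_width(wave, (t_on, v_on)),
        width_at_minus20=w20,
        max_rise=float(np.max(dvdt)),
        max_decay=float(np.min(dvdt[ipeak:])) if ipeak < v.size - 1 else float("nan"),
    )
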