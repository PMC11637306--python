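"""Voltage-sensitive-dye (VSD) signal processing.

Pipeline for 10 kHz frame-rate imaging of axonal APs paired with 250 kHz
electrical reference traces: per-pixel photobleaching correction (pixels
clustered into intensity bins, a double exponential fitted per bin with AP
windows excluded), dF/F0 activity mapping around AP peaks, averaging over
short (<5 um) axonal segments, spike-locked shift-and-mean temporal
oversampling across trials, two-step zero-phase Butterworth filtering, and
the peak-normalized VSD AP-area metric.  VSD amplitudes depend on
background intensity and are not comparable across structures, so metrics
operate on peak-normalized signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import least_squares

__all__ = [
    "VSDStack",
    "EphysReference",
    "SegmentTrace",
    "bleach_correct",
    "activity_map",
    "segment_average",
    "shift_and_mean",
    "lowpass_two_step",
    "vsd_ap_area",
    "save_stack",
    "load_stack",
]


@dataclass
class VSDStack:
    """Image stack (frames x H x W) with acquisition metadata."""

    frames: np.ndarray                 # counts, >= 0
    frame_rate_khz: float = 10.0
    pixel_size_um: float = 0.79
    event_times_ms: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mask: np.ndarray | None = None     # bool (H, W), axon pixels
    path_position_um: np.ndarray | None = None  # (H, W) path position, nan off-axon
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_rate_khz <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame rate and pixel size must be positive")
        if np.any(self.frames < 0):
            raise ValueError("fluorescence counts must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate_khz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass(frozen=True)
class EphysReference:
    """High-rate electrical trace paired with an imaging trial."""

    time: np.ndarray       # ms
    v: np.ndarray          # mV
    peak_times: np.ndarray  # ms, AP peaks at the electrical resolution

    @property
    def rate_khz(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


@dataclass
class SegmentTrace:
    segment_id: int
    path_start_um: float
    path_end_um: float
    trace: np.ndarray
    n_pixels: int


def _event_mask(times: np.ndarray, events: np.ndarray, half_width: float):
    m = np.zeros(times.size, dtype=bool)
    for e in events:
        m |= np.abs(times - e) <= half_width
    return m


def _double_exp(t, p):
    a1, lt1, a2, lt2, c = p
    t1 = np.exp(np.clip(lt1, -6.0, 12.0))
    t2 = np.exp(np.clip(lt2, -6.0, 12.0))
    return a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2) + c


def bleach_correct(stack: VSDStack, n_bins: int = 8,
                   event_halfwidth_ms: float = 1.0):
    """Divide out per-pixel photobleaching.

    Pixels are clustered into ``n_bins`` mean-intensity bins; for each bin a
    double exponential plus offset is fitted to the bin-average time course
    with AP event windows excluded, and each pixel is divided by the bin's
    bleach curve normalized to its initial value (so the pixel keeps its own
    baseline).  Falls back to a mono-exponential for bins where the double
    exponential fails; fallback bins are listed in the returned stack's
    ``meta['bleach_fallback_bins']``.
    """
    f = stack.frames.astype(float)
    T = stack.n_frames
    n_event = int(np.sum(_event_mask(stack.times, stack.event_times_ms,
                                     event_halfwidth_ms)))
    if n_event and T < 10 * n_event:
        raise ValueError("stack too short relative to the AP windows")
    mean_img = f.mean(axis=0)
    if stack.mask is not None:
        pix = np.argwhere(stack.mask)
    else:
        pix = np.argwhere(np.ones_like(mean_img, dtype=bool))
    intensities = mean_img[pix[:, 0], pix[:, 1]]
    edges = np.quantile(intensities, np.linspace(0, 1, n_bins + 1))
    bin_of = np.clip(np.searchsorted(edges, intensities, side="right") - 1,
                     0, n_bins - 1)
    t = stack.times
    keep = ~_event_mask(t, stack.event_times_ms, event_halfwidth_ms)
    corrected = f.copy()
    fallback = []
    for b in range(n_bins):
        rows = pix[bin_of == b]
        if rows.size == 0:
            continue
        trace = f[:, rows[:, 0], rows[:, 1]].mean(axis=1)
        y = trace[keep]
        tk = t[keep]
        scale = y.mean()
        p0 = np.array([0.3 * scale, np.log(t[-1] / 10), 0.3 * scale,
                       np.log(t[-1]), 0.4 * scale])
        curve = None
        try:
            sol = least_squares(lambda p: _double_exp(tk, p) - y, p0,
                                max_nfev=2000)
            if sol.success or sol.cost < np.sum((y - y.mean()) ** 2):
                curve = _double_exp(t, sol.x)
        except Exception:
            curve = None
        if curve is None or np.any(curve <= 0):
            fallback.append(b)
            try:
                sol = least_squares(
                    lambda p: p[0] * np.exp(-tk / np.exp(p[1])) + p[2] - y,
                    np.array([0.5 * scale, np.log(t[-1]), 0.5 * scale]),
                    max_nfev=2000)
                curve = sol.x[0] * np.exp(-t / np.exp(sol.x[1])) + sol.x[2]
            except Exception as exc:
                raise RuntimeError(f"bleach fit failed in bin {b}") from exc
        rel = curve / curve[0]
        corrected[:, rows[:, 0], rows[:, 1]] /= rel[:, None]
    out = VSDStack(frames=corrected, frame_rate_khz=stack.frame_rate_khz,
                   pixel_size_um=stack.pixel_size_um,
                   event_times_ms=stack.event_times_ms, mask=stack.mask,
                   path_position_um=stack.path_position_um,
                   meta={**stack.meta, "bleach_corrected": True,
                         "bleach_fallback_bins": fallback})
    return out


def activity_map(stack: VSDStack, peak_halfwidth_ms: float = 0.2,
                 baseline_ms: float | None = None) -> np.ndarray:
    """dF/F0 image: (mean around AP peaks - baseline) / baseline per pixel.

    The baseline is the pre-event mean (frames before the first event minus
    a guard interval); ``baseline_ms`` limits it to the given duration.
    """
    if stack.event_times_ms.size == 0:
        raise ValueError("no AP event times in the stack")
    t = stack.times
    peak = _event_mask(t, stack.event_times_ms, peak_halfwidth_ms)
    first = float(np.min(stack.event_times_ms))
    base_sel = t < first - 5 * peak_halfwidth_ms
    if baseline_ms is not None:
        base_sel &= t >= first - 5 * peak_halfwidth_ms - baseline_ms
    if base_sel.sum() < 3 or peak.sum() == 0:
        raise ValueError("not enough frames for baseline or peak windows")
    f = stack.frames.astype(float)
    f0 = f[base_sel].mean(axis=0)
    fp = f[peak].mean(axis=0)
    return (fp - f0) / f0


def segment_average(stack: VSDStack, max_extent_um: float = 5.0):
    """Average pixel traces in contiguous path segments of <= 5 um."""
    if stack.path_position_um is None:
        raise ValueError("stack has no pixel path positions")
    pos = stack.path_position_um
    valid = np.isfinite(pos)
    if stack.mask is not None:
        valid &= stack.mask
    if not valid.any():
        raise ValueError("empty axon mask")
    pvals = pos[valid]
    lo, hi = float(pvals.min()), float(pvals.max())
    n_seg = max(1, int(np.ceil((hi - lo) / max_extent_um - 1e-9)))
    edges = lo + np.arange(n_seg + 1) * (hi - lo) / n_seg
    f = stack.frames.astype(float)
    out = []
    for s in range(n_seg):
        sel = valid & (pos >= edges[s]) & (pos <= edges[s + 1]
                                           if s == n_seg - 1
                                           else pos < edges[s + 1])
        if not sel.any():
            continue
        rows = np.argwhere(sel)
        trace = f[:, rows[:, 0], rows[:, 1]].mean(axis=1)
        out.append(SegmentTrace(segment_id=s, path_start_um=float(edges[s]),
                                path_end_um=float(edges[s + 1]), trace=trace,
                                n_pixels=int(sel.sum())))
    return out


def shift_and_mean(trial_traces: list[np.ndarray],
                   references: list[EphysReference],
                   frame_rate_khz: float = 10.0,
                   resample_factor: int = 8,
                   window_ms: tuple[float, float] = (-2.0, 3.0)):
    """Spike-locked temporal oversampling across trials.

    Each trial's frame samples are aligned by subtracting the trial's
    electrical AP peak time, pooled over trials, sorted by aligned time and
    block-averaged in fixed groups of ``resample_factor`` samples.  Returns
    ``(times, waveform, effective_rate_khz, n_used)``; trials without a
    reference peak are dropped.
    """
    dt = 1.0 / frame_rate_khz
    pooled_t = []
    pooled_y = []
    n_used = 0
    for trace, ref in zip(trial_traces, references):
        if ref.peak_times.size == 0:
            continue
        peak = float(ref.peak_times[0])
        t = np.arange(len(trace)) * dt - peak
        sel = (t >= window_ms[0]) & (t < window_ms[1])  # half-open window
        pooled_t.append(t[sel])
        pooled_y.append(np.asarray(trace, dtype=float)[sel])
        n_used += 1
    if n_used == 0:
        raise ValueError("no trial had a usable reference peak")
    t = np.concatenate(pooled_t)
    y = np.concatenate(pooled_y)
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    n_blocks = t.size // resample_factor
    tb = t[: n_blocks * resample_factor].reshape(n_blocks, resample_factor)
    yb = y[: n_blocks * resample_factor].reshape(n_blocks, resample_factor)
    times = tb.mean(axis=1)
    wave = yb.mean(axis=1)
    # output points per covered time span (the alignment window)
    span = float(window_ms[1] - window_ms[0])
    eff_rate = n_blocks / span if span > 0 else float("nan")
    return times, wave, eff_rate, n_used


def lowpass_two_step(times: np.ndarray, wave: np.ndarray,
                     cutoffs_khz: tuple[float, float] = (10.0, 100.0),
                     order: int = 4):
    """Two sequential zero-phase Butterworth low-pass filters.

    Cutoffs at or above the Nyquist frequency of the (possibly irregular,
    block-averaged) waveform are skipped; skipped cutoffs are returned.
    """
    wave = np.asarray(wave, dtype=float)
    rate = (times.size - 1) / float(times[-1] - times[0])
    skipped = []
    out = wave
    for fc in cutoffs_khz:
        if fc >= rate / 2:
            skipped.append(fc)
            continue
        b, a = sps.butter(order, fc / (rate / 2))
        padlen = min(3 * max(len(a), len(b)), out.size - 1)
        out = sps.filtfilt(b, a, out, padlen=padlen)
    return out, skipped


def vsd_ap_area(times: np.ndarray, wave: np.ndarray,
                start_offset_ms: float = 0.05,
                window_ms: float = 0.6) -> float:
    """Normalized VSD AP area.

    The waveform is peak-normalized (VSD amplitudes are not comparable
    across structures), then integrated over
    [peak + start_offset, peak + start_offset + window].
    """
    times = np.asarray(times, dtype=float)
    wave = np.asarray(wave, dtype=float)
    base = np.median(wave[times < times[wave.argmax()] - 1.0]) \
        if np.any(times < times[wave.argmax()] - 1.0) else 0.0
    y = wave - base
    peak = float(np.max(y))
    if peak <= 0:
        raise ValueError("waveform has no positive peak")
    y = y / peak
    t_peak = float(times[np.argmax(y)])
    lo = t_peak + start_offset_ms
    hi = lo + window_ms
    if hi > times[-1] + 1e-9:
        raise ValueError("integration window exceeds the trace")
    grid = np.linspace(lo, hi, 241)
    vals = np.interp(grid, times, y)
    return float(np.trapezoid(vals, grid))


def save_stack(stack: VSDStack, path) -> None:
    """Write the stack as a multi-page TIFF (frames as pages)."""
    import tifffile
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     metadata={"frame_rate_khz": stack.frame_rate_khz,
                               "pixel_size_um": stack.pixel_size_um})


def load_stack(path, frame_rate_khz: float = 10.0,
               pixel_size_um: float = 0.79) -> VSDStack:
    import tifffile
    frames = tifffile.imread(path)
    return VSDStack(frames=np.asarray(frames, dtype=float),
                    frame_rate_khz=frame_rate_khz, pixel_size_um=pixel_size_um)
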