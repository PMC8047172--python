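"""Acoustic measurement layer: call detection, level measurement, TDOA.

All operations work on band-passed signals (default 20-80 kHz, spanning the
first harmonic of big-brown-bat FM calls).  Detection runs independently
per channel and detections are then associated across channels by
propagation-consistent arrival times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .geometry import MicArray

__all__ = [
    "DetectorParams", "Detection", "TdoaSet",
    "detect_calls", "measure_level", "tdoa_pair", "associate_detections",
    "bandpass",
]

DEFAULT_BAND_HZ = (20_000.0, 80_000.0)


@dataclass(frozen=True)
class DetectorParams:
    """Energy-envelope detector configuration."""

    band_hz: tuple[float, float] = DEFAULT_BAND_HZ
    threshold_db: float = 10.0        # onset threshold above the noise floor
    min_gap_ms: float = 5.0           # merge detections closer than this
    envelope_ms: float = 0.5          # RMS-envelope smoothing window
    hysteresis_db: float = 4.0        # release threshold = threshold - hysteresis


@dataclass(frozen=True)
class Detection:
    """One above-threshold acoustic event on one channel."""

    mic_id: int
    onset_time_s: float
    peak_time_s: float
    rms_level_db: float     # dB re full scale over the event
    snr_db: float           # peak envelope above the estimated noise floor
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ

    def __post_init__(self) -> None:
        if self.onset_time_s > self.peak_time_s + 1e-12:
            raise ValueError("onset must not follow the peak")


@dataclass
class TdoaSet:
    """Per-call TDOAs of every usable channel against a reference mic."""

    call_index: int
    reference_mic_id: int
    mic_ids: np.ndarray       # channels with a usable TDOA (includes reference)
    tdoas_s: np.ndarray       # same order; 0 for the reference
    cc_peak: np.ndarray       # normalized correlation peak per channel
    levels_db: np.ndarray | None = None   # per-channel received level (optional)

    def __post_init__(self) -> None:
        ref = self.tdoas_s[np.nonzero(self.mic_ids == self.reference_mic_id)[0]]
        if len(ref) != 1 or abs(float(ref[0])) > 1e-12:
            raise ValueError("reference mic must be present with zero tdoa")


def bandpass(x: np.ndarray, fs_hz: float, band_hz=DEFAULT_BAND_HZ, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    sos = signal.butter(order, band_hz, btype="bandpass", fs=fs_hz, output="sos")
    return signal.sosfiltfilt(sos, x)


def _envelope_db(xb: np.ndarray, fs_hz: float, envelope_ms: float) -> np.ndarray:
    """Short-time RMS envelope in dB re full scale."""
    n = max(3, int(envelope_ms / 1000.0 * fs_hz) | 1)
    from scipy.ndimage import uniform_filter1d

    p = uniform_filter1d(xb ** 2, n, mode="nearest")
    return 10.0 * np.log10(np.maximum(p, 1e-20))


def detect_calls(waveform: np.ndarray, fs_hz: float,
                 params: DetectorParams = DetectorParams(),
                 mic_id: int = 0) -> list[Detection]:
    """Detect calls on one channel.

    Band-pass filter, short-time RMS envelope in dB, threshold crossing
    (``threshold_db`` above the median-estimated noise floor) with
    hysteresis; events closer than ``min_gap_ms`` are merged; the onset is
    refined to the last point at least 10 dB below the event peak before it.
    """
    x = np.asarray(waveform, float)
    if x.size == 0:
        return []
    if fs_hz <= 2 * params.band_hz[1]:
        raise ValueError("sample rate too low for the detection band")
    xb = bandpass(x, fs_hz, params.band_hz)
    env = _envelope_db(xb, fs_hz, params.envelope_ms)
    floor = float(np.median(env))
    if params.threshold_db < 3.0:
        warnings.warn("detection threshold within 3 dB of the noise floor")
    return detect_from_envelope(env, xb, fs_hz, params, floor, mic_id)


def detect_from_envelope(env: np.ndarray, xb: np.ndarray, fs_hz: float,
                         params: DetectorParams, floor: float,
                         mic_id: int) -> list[Detection]:
    """Threshold-with-hysteresis detection on a precomputed dB envelope.

    Split out from :func:`detect_calls` so multichannel pipelines can filter
    each channel once and reuse the envelope.
    """
    on_thresh = floor + params.threshold_db
    off_thresh = on_thresh - params.hysteresis_db
    above = env >= on_thresh
    if not np.any(above):
        return []
    # hysteresis: extend each above-threshold region until env < off_thresh
    starts = np.nonzero(above & ~np.roll(above, 1))[0]
    ends = np.nonzero(above & ~np.roll(above, -1))[0]
    if above[0]:
        starts = np.concatenate([[0], starts[starts != 0]])
    if above[-1]:
        ends = np.concatenate([ends[ends != len(env) - 1], [len(env) - 1]])
    regions = []
    below_off = env < off_thresh
    for s, e in zip(starts, ends):
        while e + 1 < len(env) and not below_off[e + 1]:
            e += 1
        while s - 1 >= 0 and not below_off[s - 1]:
            s -= 1
        regions.append([s, e])
    # merge regions separated by < min_gap
    gap = int(params.min_gap_ms / 1000.0 * fs_hz)
    merged = [regions[0]]
    for s, e in regions[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    out = []
    for s, e in merged:
        seg = env[s:e + 1]
        pk = s + int(np.argmax(seg))
        peak_db = env[pk]
        # onset: last sample before the peak at least 10 dB below it
        pre = env[s:pk + 1]
        lower = np.nonzero(pre <= peak_db - 10.0)[0]
        onset = s + (int(lower[-1]) if len(lower) else 0)
        rms_db = 10.0 * np.log10(np.mean(xb[s:e + 1] ** 2) + 1e-20)
        out.append(Detection(
            mic_id=mic_id,
            onset_time_s=onset / fs_hz,
            peak_time_s=pk / fs_hz,
            rms_level_db=float(rms_db),
            snr_db=float(peak_db - floor),
            band_hz=params.band_hz,
        ))
    return out


def measure_level(waveform: np.ndarray, window: tuple[float, float],
                  band_hz=DEFAULT_BAND_HZ, fs_hz: float = 250_000.0,
                  prefiltered: bool = False) -> float:
    """Band-limited RMS level (dB re full scale) over a time window.

    The window must be long enough to ride out the band-pass transient
    (three filter time constants of the low band edge).
    """
    t0, t1 = window
    i0, i1 = int(round(t0 * fs_hz)), int(round(t1 * fs_hz))
    if i0 < 0 or i1 > len(waveform) or i1 <= i0:
        raise ValueError("window outside waveform")
    min_len = int(3 * fs_hz / band_hz[0])
    if i1 - i0 < min_len:
        raise ValueError("window shorter than 3 filter transients")
    seg = np.asarray(waveform[i0:i1], float)
    seg = seg - seg.mean()
    if not prefiltered:
        seg = bandpass(seg, fs_hz, band_hz)
    return float(10.0 * np.log10(np.mean(seg ** 2) + 1e-20))


def tdoa_pair(sig_a: np.ndarray, sig_b: np.ndarray, fs_hz: float,
              max_lag_s: float, method: str = "cc") -> tuple[float, float]:
    """Time difference of arrival of one event on two channels.

    Positive result means ``sig_b`` lags ``sig_a``.  The peak of the
    (generalized) cross-correlation within plus/minus ``max_lag_s`` is
    refined by 3-point parabolic interpolation to sub-sample precision.
    ``method`` is ``"cc"`` (plain normalized cross-correlation, default) or
    ``"gcc_phat"``.
    """
    a = np.asarray(sig_a, float)
    b = np.asarray(sig_b, float)
    if len(a) != len(b):
        raise ValueError("signals must have equal length")
    ea, eb = np.sum(a ** 2), np.sum(b ** 2)
    if ea == 0 or eb == 0:
        raise ValueError("correlation undefined for an all-zero signal")
    if method == "cc":
        cc = signal.correlate(b, a, mode="full", method="fft")
        cc = cc / np.sqrt(ea * eb)
    elif method == "gcc_phat":
        n = 2 * len(a)
        A = np.fft.rfft(a, n)
        B = np.fft.rfft(b, n)
        S = B * np.conj(A)
        S = S / np.maximum(np.abs(S), 1e-20)
        r = np.fft.irfft(S, n)
        cc = np.concatenate([r[-(len(a) - 1):], r[:len(a)]])
    else:
        raise ValueError(f"unknown method {method!r}")
    lags = np.arange(-(len(a) - 1), len(a))
    max_lag = int(np.floor(max_lag_s * fs_hz))
    ok = np.abs(lags) <= max_lag
    cc_w, lags_w = cc[ok], lags[ok]
    k = int(np.argmax(cc_w))
    peak = float(cc_w[k])
    lag = float(lags_w[k])
    if 0 < k < len(cc_w) - 1:
        y0, y1, y2 = cc_w[k - 1], cc_w[k], cc_w[k + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-20:
            lag += 0.5 * (y0 - y2) / denom
    return lag / fs_hz, peak


def associate_detections(per_mic: dict[int, list[Detection]], mics: MicArray,
                         c_mps: float = 344.0, min_channels: int = 4,
                         window_s: float | None = 0.012,
                         ) -> tuple[list[dict[int, Detection]], list[Detection]]:
    """Group single-channel detections into multichannel call candidates.

    Detections on different channels belong to one call when their peak
    times are consistent with a single source somewhere in the array: the
    arrival spread of one call is bounded by the range spread over the
    room, itself at most the maximum inter-mic distance over c.
    ``window_s`` may tighten that bound (the default 12 ms suits sources
    inside a perimeter array, where range spread stays well below the full
    baseline; pass ``None`` for the loose geometric bound, e.g. with calls
    sparser than the array transit time).  Greedy in time order; one
    detection per channel per call (the earliest — direct paths precede
    clutter echoes); calls need at least ``min_channels`` channels.
    Returns ``(groups, residual)`` where the residual holds unassociated
    detections.
    """
    geo = mics.max_baseline_m / c_mps + 2e-3
    tol = geo if window_s is None else min(window_s, geo)
    all_det = sorted(
        (d for dets in per_mic.values() for d in dets),
        key=lambda d: d.peak_time_s,
    )
    groups: list[dict[int, Detection]] = []
    residual: list[Detection] = []
    used = [False] * len(all_det)
    for i, d in enumerate(all_det):
        if used[i]:
            continue
        cand = {d.mic_id: d}
        used[i] = True
        t_anchor = d.peak_time_s
        for j in range(i + 1, len(all_det)):
            dj = all_det[j]
            if dj.peak_time_s - t_anchor > tol:
                break
            if used[j] or dj.mic_id in cand:
                continue
            cand[dj.mic_id] = dj
            used[j] = True
        if len(cand) >= min_channels:
            groups.append(cand)
        else:
            residual.extend(cand.values())
    return groups, residual
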