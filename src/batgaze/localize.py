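"""Per-call localization, flight kinematics, and beam-aim reconstruction.

The measurement chain: hyperbolic multilateration of each call from its
time differences of arrival, per-call received levels corrected for
spherical spreading and atmospheric absorption, and a grid-plus-refinement
fit of the beam-pattern azimuth to the corrected levels.  Downstream
statistics (10-cm binned beam aim, the two coarse flightpath segments,
shift onset, first-versus-last-day regressions) live here too.

Segment and bin boundaries are half-open intervals measured from the turn:
``[lower, upper)`` in centimetres, so 150.0 cm belongs to beam 1 and 0 cm
is the turn plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .beam import BeamModel
from .frontend import Detection, DetectorParams, TdoaSet, _envelope_db, bandpass, \
    associate_detections, detect_from_envelope, tdoa_pair
from .geometry import FlightRoomConfig, MicArray, Trajectory, distance_to_turn, \
    signed_beam_angle, wrap_angle_deg
from .propagation import Environment

__all__ = [
    "BeamSegmentStats", "BinnedBeam", "Segment",
    "multilaterate", "estimate_heading", "flight_speed", "estimate_beam_aim",
    "bin_beam", "segment_stats", "shift_onset", "firstlast_day_regression",
    "analyze_flight", "RegressionComparison",
]

#: Coarse flightpath segments, half-open [lower, upper) cm from the turn.
SEGMENTS_CM = {
    "BEAM1": (150.0, 300.0),
    "BEAM2": (0.0, 150.0),
    "SPEED1": (100.0, 250.0),
    "SPEED2": (0.0, 100.0),
}
Segment = str


# ---------------------------------------------------------------------------
# Multilateration
# ---------------------------------------------------------------------------

def multilaterate(tdoas: TdoaSet, mics: MicArray, c_mps: float = 344.0,
                  source_height_m: float = 1.2) -> tuple[np.ndarray, float]:
    """Planar least-squares hyperbolic localization of one call.

    Solves for the horizontal source position at a fixed flight height
    (microphone z enters through the 3-D ranges).  A linearized closed-form
    solution (unknowns x, y and the reference range) initializes an
    iterative nonlinear least-squares refinement.  Returns
    ``(xy, residual_rms)`` with the residual in metres of range.
    """
    idx = np.array([mics.index_of(m) for m in tdoas.mic_ids])
    if len(idx) < 4:
        raise ValueError("need at least 4 usable channels for 2-D multilateration")
    pos = mics.mic_positions[idx]
    xy = pos[:, :2]
    if np.linalg.matrix_rank(xy - xy.mean(0), tol=1e-9) < 2:
        raise ValueError("usable microphones are collinear")
    ref = int(np.nonzero(tdoas.mic_ids == tdoas.reference_mic_id)[0][0])
    tau = np.asarray(tdoas.tdoas_s, float)
    z = source_height_m

    others = [i for i in range(len(idx)) if i != ref]
    mref = pos[ref]
    A = np.zeros((len(others), 3))
    b = np.zeros(len(others))
    for row, i in enumerate(others):
        mi = pos[i]
        ct = c_mps * (tau[i] - tau[ref])
        A[row, :2] = -2.0 * (mi[:2] - mref[:2])
        A[row, 2] = -2.0 * ct
        b[row] = ct ** 2 - np.dot(mi, mi) + np.dot(mref, mref) \
            + 2.0 * z * (mi[2] - mref[2])
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    x0 = sol[:2]

    def resid(p):
        r = np.sqrt(np.sum((pos - np.array([p[0], p[1], z])) ** 2, axis=1))
        return (r - r[ref]) - c_mps * (tau - tau[ref])

    fit = optimize.least_squares(resid, x0, method="lm", max_nfev=100)
    rms = float(np.sqrt(np.mean(fit.fun[np.arange(len(tau)) != ref] ** 2)))
    return fit.x, rms


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def estimate_heading(times_s: np.ndarray, positions_xy: np.ndarray,
                     room: FlightRoomConfig, smooth_window: int = 5,
                     min_speed_mps: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample heading (signed degrees re midline) from ordered positions.

    Positions are smoothed with a centred moving average, velocities taken
    by central differences (one-sided at the ends).  Stationary samples
    (< ``min_speed_mps``) carry the previous heading forward and are
    flagged.  Returns ``(heading_deg, stationary_flag)``.
    """
    t = np.asarray(times_s, float)
    p = np.asarray(positions_xy, float)
    if len(t) < 2:
        raise ValueError("need at least 2 positions")
    k = max(1, min(smooth_window, len(t)) | 1)
    kern = np.ones(k) / k
    sm = np.column_stack([
        np.convolve(np.pad(p[:, j], (k // 2, k // 2), mode="edge"), kern, mode="valid")
        for j in range(2)
    ])
    v = np.gradient(sm, t, axis=0)
    speed = np.hypot(v[:, 0], v[:, 1])
    heading = np.full(len(t), np.nan)
    flag = speed < min_speed_mps
    last = None
    for i in range(len(t)):
        if not flag[i]:
            heading[i] = signed_beam_angle(v[i], room)
            last = heading[i]
        elif last is not None:
            heading[i] = last
    # leading stationary samples: back-fill from the first moving one
    if np.any(~flag):
        first = np.nonzero(~flag)[0][0]
        heading[:first] = heading[first]
    return heading, flag


def flight_speed(trajectory: Trajectory, segment: Segment,
                 room: FlightRoomConfig) -> float:
    """Median finite-difference flight speed over one path segment.

    ``segment`` is ``"SPEED1"`` (250-100 cm before the turn) or
    ``"SPEED2"`` (100-0 cm).
    """
    lo, hi = SEGMENTS_CM[segment]
    d = np.array([distance_to_turn(p, room).distance_to_turn_cm
                  for p in trajectory.xy_m])
    sel = (d >= lo) & (d < hi)
    if not np.any(sel):
        raise ValueError(f"trajectory has no samples in segment {segment}")
    return float(np.median(trajectory.speeds_mps()[sel]))


# ---------------------------------------------------------------------------
# Beam-aim estimation
# ---------------------------------------------------------------------------

def estimate_beam_aim(levels_db: np.ndarray, mic_ids: np.ndarray,
                      position_xy: np.ndarray, mics: MicArray,
                      beam: BeamModel, env: Environment,
                      room: FlightRoomConfig,
                      absorption_freq_hz: float = 35_000.0,
                      source_height_m: float = 1.2,
                      grid_step_deg: float = 0.5,
                      min_span_deg: float = 10.0) -> tuple[float, float]:
    """Fit the beam-axis azimuth to per-microphone received levels.

    Levels are corrected for spherical spreading and atmospheric absorption
    (at a representative in-band frequency) back to the source reference
    distance; the aim is the azimuth minimizing the squared mismatch
    between corrected levels and the beam pattern evaluated at each
    microphone's off-axis angle, with the unknown source level profiled
    out.  Grid search at ``grid_step_deg`` over (-180, 180], then local
    quadratic refinement.  Returns ``(beam_aim_deg, fit_quality)`` where
    the fit quality is the residual RMS in dB (lower is better).

    Microphones far down the pattern are down-weighted (logistic roll-off
    starting ``dynamic_range_db`` below the strongest corrected level):
    near the pattern floor the level is dominated by noise and by model
    side-lobe detail, so those channels carry little aim information.
    """
    levels = np.asarray(levels_db, float)
    if len(levels) < 5:
        raise ValueError("need at least 5 microphones with valid levels")
    idx = np.array([mics.index_of(m) for m in mic_ids])
    pos = mics.mic_positions[idx]
    src = np.array([position_xy[0], position_xy[1], source_height_m])
    d = pos - src
    r = np.sqrt(np.sum(d * d, axis=1))
    mx, my = room.midline_direction
    az = -np.degrees(np.arctan2(mx * d[:, 1] - my * d[:, 0],
                                mx * d[:, 0] + my * d[:, 1]))
    if np.ptp(az) < min_span_deg:
        raise ValueError("microphone azimuth span too small; aim unconstrained")
    alpha = float(env.absorption_db_per_m(absorption_freq_hz))
    corrected = levels - mics.calibration_db[idx] \
        + 20.0 * np.log10(r / env.ref_distance_m) + alpha * r
    dynamic_range_db = 35.0
    w = 1.0 / (1.0 + 10.0 ** (-(corrected - (corrected.max() - dynamic_range_db)) / 10.0))
    w = w / w.sum()

    def wvar(resid):
        resid = np.atleast_2d(resid)
        mu = resid @ w                       # weighted source level profiled out
        out = ((resid - mu[:, None]) ** 2) @ w
        return out if len(out) > 1 else float(out[0])

    aims = np.arange(-180.0 + grid_step_deg, 180.0 + 1e-9, grid_step_deg)
    off = (az[None, :] - aims[:, None] + 180.0) % 360.0 - 180.0
    G = beam.gain_db(off.ravel()).reshape(off.shape)
    loss = wvar(corrected[None, :] - G)
    k = int(np.argmin(loss))

    def loss_at(a):
        o = (az - a + 180.0) % 360.0 - 180.0
        return float(wvar(corrected - beam.gain_db(o)))

    lo, hi = aims[k] - grid_step_deg, aims[k] + grid_step_deg
    res = optimize.minimize_scalar(loss_at, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-3})
    aim = wrap_angle_deg(float(res.x))
    return aim, float(np.sqrt(res.fun))


# ---------------------------------------------------------------------------
# Beam statistics along the flightpath
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamSegmentStats:
    """Beam-aim summary over one coarse flightpath segment."""

    segment: Segment
    n_calls: int
    mean_deg: float
    sd_deg: float
    single_call: bool = False     # SD undefined, reported as 0

    def __post_init__(self) -> None:
        if self.n_calls < 1:
            raise ValueError("segment must contain at least one call")


@dataclass(frozen=True)
class BinnedBeam:
    """Beam aim in 10-cm distance bins tiling [0, 300) cm."""

    bin_lower_cm: np.ndarray
    bin_centers_cm: np.ndarray
    mean_deg: np.ndarray       # NaN where the bin is empty
    sd_deg: np.ndarray
    n: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lower_cm": self.bin_lower_cm,
            "bin_center_cm": self.bin_centers_cm,
            "mean_deg": self.mean_deg,
            "sd_deg": self.sd_deg,
            "n": self.n,
        })


def bin_beam(calls: pd.DataFrame, bin_cm: float = 10.0,
             path_extent_cm: float = 300.0) -> BinnedBeam:
    """Per-bin mean, SD and count of beam aim over the flightpath.

    Bins are half-open ``[k*bin_cm, (k+1)*bin_cm)`` from the turn; empty
    bins are reported as NaN, never zero-filled.
    """
    edges = np.arange(0.0, path_extent_cm + bin_cm / 2, bin_cm)
    lowers = edges[:-1]
    d = calls["distance_to_turn_cm"].to_numpy(float)
    a = calls["beam_aim_deg"].to_numpy(float)
    which = np.floor(d / bin_cm).astype(int)
    mean = np.full(len(lowers), np.nan)
    sd = np.full(len(lowers), np.nan)
    n = np.zeros(len(lowers), int)
    for k in range(len(lowers)):
        vals = a[(which == k) & (d >= 0) & (d < path_extent_cm)]
        if len(vals):
            n[k] = len(vals)
            mean[k] = vals.mean()
            sd[k] = vals.std(ddof=1) if len(vals) > 1 else 0.0
    return BinnedBeam(bin_lower_cm=lowers, bin_centers_cm=lowers + bin_cm / 2,
                      mean_deg=mean, sd_deg=sd, n=n)


def segment_stats(calls: pd.DataFrame, segment: Segment) -> BeamSegmentStats:
    """Beam-aim N / mean / SD over one coarse segment (BEAM1 or BEAM2)."""
    lo, hi = SEGMENTS_CM[segment]
    d = calls["distance_to_turn_cm"].to_numpy(float)
    vals = calls["beam_aim_deg"].to_numpy(float)[(d >= lo) & (d < hi)]
    if len(vals) == 0:
        raise ValueError(f"no calls in segment {segment}")
    if len(vals) == 1:
        return BeamSegmentStats(segment, 1, float(vals[0]), 0.0, single_call=True)
    return BeamSegmentStats(segment, len(vals), float(vals.mean()),
                            float(vals.std(ddof=1)))


def shift_onset(binned: BinnedBeam, beam1: BeamSegmentStats,
                turn_direction: str) -> float | None:
    """Distance at which the beam first commits to the turn.

    Scans the beam-2 bins from 150 cm toward 0 cm and returns the centre of
    the first bin whose mean deviates from the beam-1 mean by more than one
    beam-1 SD *in the turn direction* (``"right"`` or ``"left"``); ``None``
    if no bin ever does.
    """
    sign = {"right": 1.0, "left": -1.0}[turn_direction]
    order = np.argsort(binned.bin_lower_cm)[::-1]
    for k in order:
        if binned.bin_lower_cm[k] >= SEGMENTS_CM["BEAM2"][1]:
            continue
        m = binned.mean_deg[k]
        if np.isnan(m):
            continue
        if sign * (m - beam1.mean_deg) > beam1.sd_deg:
            return float(binned.bin_centers_cm[k])
    return None


# ---------------------------------------------------------------------------
# First-vs-last-day regression comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionComparison:
    """Per-day OLS fits of beam aim vs distance plus a slope-difference test."""

    slope_first: float
    intercept_first: float
    slope_last: float
    intercept_last: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    alpha: float = 0.004

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def firstlast_day_regression(calls_first: pd.DataFrame, calls_last: pd.DataFrame,
                             alpha: float = 0.004) -> RegressionComparison:
    """Compare beam-aim-vs-distance regressions between two day sets.

    Ordinary least squares of beam angle on distance to turn for each day
    over the 150-0 cm segment; the slope difference is tested by the
    day-by-distance interaction F-test in the pooled model, judged at the
    multiple-comparison-corrected ``alpha`` (default 0.004).
    """
    import statsmodels.api as sm

    frames = []
    for day, df in ((0, calls_first), (1, calls_last)):
        lo, hi = SEGMENTS_CM["BEAM2"]
        d = df["distance_to_turn_cm"].to_numpy(float)
        sel = (d >= lo) & (d < hi)
        if sel.sum() < 3:
            raise ValueError("need at least 3 calls in each day set")
        frames.append(pd.DataFrame({
            "beam": df["beam_aim_deg"].to_numpy(float)[sel],
            "dist": d[sel], "day": day,
        }))
    pooled = pd.concat(frames, ignore_index=True)

    per_day = []
    for day in (0, 1):
        sub = pooled[pooled["day"] == day]
        X = sm.add_constant(sub["dist"].to_numpy())
        fit = sm.OLS(sub["beam"].to_numpy(), X).fit()
        per_day.append((float(fit.params[1]), float(fit.params[0])))

    X = np.column_stack([
        np.ones(len(pooled)), pooled["dist"], pooled["day"],
        pooled["dist"] * pooled["day"],
    ])
    fit = sm.OLS(pooled["beam"].to_numpy(), X).fit()
    t = fit.tvalues[3]
    f = float(t ** 2)
    p = float(fit.pvalues[3])
    if not np.isfinite(f):       # identical day sets: no slope difference
        f, p = 0.0, 1.0
    return RegressionComparison(
        slope_first=per_day[0][0], intercept_first=per_day[0][1],
        slope_last=per_day[1][0], intercept_last=per_day[1][1],
        f_stat=f, df_num=1, df_den=int(fit.df_resid), p_value=p, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Per-flight analysis pipeline
# ---------------------------------------------------------------------------

def analyze_flight(waveform: np.ndarray, mics: MicArray, room: FlightRoomConfig,
                   beam: BeamModel | None = None,
                   env: Environment | None = None,
                   detector: DetectorParams | None = None,
                   external_trajectory: Trajectory | None = None,
                   flight_height_m: float = 1.2,
                   residual_max_m: float = 0.10,
                   tdoa_method: str = "cc",
                   level_min_above_floor_db: float = 3.0) -> pd.DataFrame:
    """Reconstruct per-call position and beam aim from one array recording.

    Runs detection on every channel, associates detections into calls,
    estimates TDOAs against the strongest channel, multilaterates each
    call, measures per-channel received levels, and fits the beam aim.
    When ``external_trajectory`` is given (e.g. a video-derived track) it
    supersedes acoustic positions for kinematics; acoustic positions are
    kept as diagnostics.

    Returns a call table with one row per retained call; calls failing
    quality gates carry a nonempty ``flags`` string but are only dropped
    when localization itself is impossible.
    """
    beam = beam or BeamModel.calibrated()
    env = env or Environment()
    detector = detector or DetectorParams()
    fs = mics.sample_rate_hz
    c = env.c_mps

    filtered = [bandpass(ch, fs, detector.band_hz) for ch in waveform]
    envs = [_envelope_db(ch, fs, detector.envelope_ms) for ch in filtered]
    floors = np.array([np.median(e) for e in envs])

    per_mic: dict[int, list[Detection]] = {}
    for i, mid in enumerate(mics.mic_ids):
        per_mic[int(mid)] = detect_from_envelope(
            envs[i], filtered[i], fs, detector, float(floors[i]), int(mid))
    groups, _residual = associate_detections(per_mic, mics, c)

    win_s = 0.004           # level/correlation window around each arrival
    rows = []
    for gi, group in enumerate(groups):
        dets = sorted(group.values(), key=lambda d: -d.snr_db)
        ref = dets[0]
        ref_i = mics.index_of(ref.mic_id)
        mic_ids, taus, peaks, levels = [ref.mic_id], [0.0], [1.0], []
        seg_ref = _extract(filtered[ref_i], fs, ref.peak_time_s, win_s)
        for det in dets[1:]:
            i = mics.index_of(det.mic_id)
            seg = _extract(filtered[i], fs, det.peak_time_s, win_s)
            if seg is None or seg_ref is None:
                continue
            try:
                fine, q = tdoa_pair(seg_ref, seg, fs, 1.5e-3, method=tdoa_method)
            except ValueError:
                continue
            mic_ids.append(det.mic_id)
            taus.append((det.peak_time_s - ref.peak_time_s) + fine)
            peaks.append(q)
        if len(mic_ids) < 4:
            continue
        tset = TdoaSet(call_index=gi, reference_mic_id=ref.mic_id,
                       mic_ids=np.array(mic_ids), tdoas_s=np.array(taus),
                       cc_peak=np.array(peaks))
        try:
            xy, rms = multilaterate(tset, mics, c, flight_height_m)
        except ValueError:
            continue
        flags = []
        if rms > residual_max_m:
            flags.append("high_residual")
        if not room.in_room(xy):
            flags.append("outside_room")
            xy = np.clip(xy, [0.05, 0.05],
                         [room.room_length_m - 0.05, room.room_width_m - 0.05])

        src = np.array([xy[0], xy[1], flight_height_m])
        rr = np.sqrt(np.sum((mics.mic_positions - src) ** 2, axis=1))
        t_emit = ref.onset_time_s - rr[ref_i] / c
        lvl_ids, lvls = [], []
        for i, mid in enumerate(mics.mic_ids):
            det = group.get(int(mid))
            t_arr = det.peak_time_s if det is not None else \
                t_emit + rr[i] / c + win_s / 2
            seg = _extract(filtered[i], fs, t_arr, win_s)
            if seg is None:
                continue
            lvl = 10.0 * np.log10(np.mean(seg ** 2) + 1e-20)
            if lvl > floors[i] + level_min_above_floor_db:
                lvl_ids.append(int(mid))
                lvls.append(lvl)
        try:
            aim, quality = estimate_beam_aim(
                np.array(lvls), np.array(lvl_ids), xy, mics, beam, env, room,
                source_height_m=flight_height_m)
        except ValueError:
            aim, quality = np.nan, np.nan
            flags.append("beam_fit_failed")

        coord = distance_to_turn(np.clip(xy, [0.0, 0.0],
                                         [room.room_length_m, room.room_width_m]), room)
        rows.append({
            "call_index": gi, "emission_time_s": t_emit,
            "x_m": xy[0], "y_m": xy[1],
            "distance_to_turn_cm": coord.distance_to_turn_cm,
            "lateral_offset_cm": coord.lateral_offset_cm,
            "beam_aim_deg": aim, "residual_rms_m": rms,
            "fit_quality": quality, "n_channels": len(mic_ids),
            "flags": ",".join(flags),
        })

    calls = pd.DataFrame(rows).sort_values("emission_time_s").reset_index(drop=True)
    if len(calls) >= 2:
        if external_trajectory is not None:
            pos = external_trajectory.position_at(calls["emission_time_s"].to_numpy())
            calls["x_ext_m"], calls["y_ext_m"] = pos[:, 0], pos[:, 1]
            coords = [distance_to_turn(p, room) for p in pos]
            calls["distance_to_turn_cm"] = [cc.distance_to_turn_cm for cc in coords]
            heading, stat = estimate_heading(calls["emission_time_s"].to_numpy(),
                                             pos, room)
        else:
            heading, stat = estimate_heading(
                calls["emission_time_s"].to_numpy(),
                calls[["x_m", "y_m"]].to_numpy(), room)
        calls["heading_deg"] = heading
        calls["beam_aim_re_heading_deg"] = [
            wrap_angle_deg(a - h) if np.isfinite(a) else np.nan
            for a, h in zip(calls["beam_aim_deg"], heading)]
    calls["call_index"] = np.arange(len(calls))
    return calls


def _extract(x, fs, center_s, win_s):
    i0 = int(round((center_s - win_s / 2) * fs))
    i1 = i0 + int(round(win_s * fs))
    if i0 < 0 or i1 > len(x):
        return None
    return x[i0:i1]
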