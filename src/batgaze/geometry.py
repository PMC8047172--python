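"""Flight-room geometry, coordinate conventions, and trial domain types.

Coordinate conventions used throughout the package:

* Room coordinates are metric, right-handed, viewed from above: ``x`` runs
  along the straight corridor segment (the approach), ``y`` across it,
  ``z`` up.  The bat flies at an approximately constant height.
* Path coordinates are centimetres of arc length measured *to* the turn
  point along the corridor midline: the turn is at 0 cm and the beginning
  of the measured flightpath is at 300 cm.
* Signed azimuths are measured against the corridor midline direction and
  are **positive toward the bat's right** when flying toward the turn
  (so a right turn produces positive beam aims).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Condition",
    "FlightRoomConfig",
    "MicArray",
    "TrialRecord",
    "PathCoordinate",
    "distance_to_turn",
    "signed_beam_angle",
    "default_room",
    "default_mic_array",
    "load_room_config",
    "save_room_config",
    "load_mic_table",
    "save_mic_table",
]


class Condition(str, enum.Enum):
    """Corridor layout / task condition."""

    STRAIGHT = "STRAIGHT"
    RIGHT_TURN = "RIGHT_TURN"
    LEFT_TURN = "LEFT_TURN"
    REVERSED_RIGHT_TURN = "REVERSED_RIGHT_TURN"

    @property
    def reward_wall(self) -> str:
        """Wall the bat is rewarded for landing on in this condition."""
        return _REWARD_WALL[self]

    @property
    def turn_sign(self) -> int:
        """Sign of the beam-aim shift the turn demands (+1 right, -1 left, 0 none)."""
        return {"STRAIGHT": 0, "RIGHT_TURN": 1, "LEFT_TURN": -1, "REVERSED_RIGHT_TURN": 1}[self.value]


# Straight flights land on the far wall (B); a right turn leads to wall C,
# a left turn to wall A; the reversed right turn is flown from wall B and
# ends on wall A.
_REWARD_WALL = {
    Condition.STRAIGHT: "B",
    Condition.RIGHT_TURN: "C",
    Condition.LEFT_TURN: "A",
    Condition.REVERSED_RIGHT_TURN: "A",
}


@dataclass(frozen=True)
class PathCoordinate:
    """Position expressed in corridor path coordinates (centimetres).

    ``distance_to_turn_cm`` is 0 at the turn and increases toward the
    release point; ``lateral_offset_cm`` is signed, positive to the right
    of the midline (flying toward the turn).  ``off_corridor`` flags
    positions whose lateral offset exceeds the corridor envelope plus the
    configured slack; such positions are flagged, never clamped.
    """

    distance_to_turn_cm: float
    lateral_offset_cm: float
    off_corridor: bool = False


@dataclass(frozen=True)
class FlightRoomConfig:
    """Flight room, chain array and corridor layout for one condition.

    The default geometry (:func:`default_room`) is an *approximate*
    reconstruction of the study flight room — the exact room and corridor
    coordinates are not tabulated — and is a configuration input: no
    algorithm hard-codes it.
    """

    room_length_m: float
    room_width_m: float
    release_point: tuple[float, float]
    turn_point: tuple[float, float]
    midline_direction: tuple[float, float]
    condition: Condition
    corridor_width_m: float = 0.40
    chain_spacing_m: float = 0.20
    chain_positions: tuple[tuple[float, float], ...] = ()
    flightpath_length_m: float = 3.0
    turn_radius_m: float = 0.30
    off_corridor_slack_m: float = 0.10

    def __post_init__(self) -> None:
        if self.corridor_width_m <= 0:
            raise ValueError("corridor_width_m must be positive")
        m = np.asarray(self.midline_direction, float)
        n = np.hypot(*m)
        if n == 0:
            raise ValueError("midline_direction must be nonzero")
        object.__setattr__(self, "midline_direction", (float(m[0] / n), float(m[1] / n)))
        object.__setattr__(self, "condition", Condition(self.condition))
        if self.chain_positions:
            self._check_chain_grid()

    def _check_chain_grid(self) -> None:
        pts = np.asarray(self.chain_positions, float)
        for axis in (0, 1):
            vals = np.unique(np.round(pts[:, axis] / self.chain_spacing_m))
            recon = vals * self.chain_spacing_m
            got = np.round(pts[:, axis] / self.chain_spacing_m) * self.chain_spacing_m
            if not np.allclose(got, pts[:, axis], atol=1e-9):
                raise ValueError("chain positions do not lie on the chain grid")
            del recon

    @property
    def reward_wall(self) -> str:
        return self.condition.reward_wall

    @property
    def exit_direction(self) -> tuple[float, float]:
        """Unit direction of the corridor after the turn (midline for straight)."""
        mx, my = self.midline_direction
        s = self.condition.turn_sign
        if s == 0:
            return (mx, my)
        # rotate midline by 90 deg toward the turn: right = clockwise (viewed
        # from above with z up), i.e. (x, y) -> (y, -x)
        if s > 0:
            return (my, -mx)
        return (-my, mx)

    def midline_polyline(self) -> np.ndarray:
        """Corridor midline as an (N, 2) polyline from release to landing wall.

        Turn conditions have a single 90-degree vertex at the turn point.
        """
        rel = np.asarray(self.release_point, float)
        turn = np.asarray(self.turn_point, float)
        if self.condition.turn_sign == 0:
            # extend straight past the "equivalent turn point" to the far wall
            d = np.asarray(self.midline_direction, float)
            end = turn + d * self._distance_to_wall(turn, d)
            return np.vstack([rel, turn, end])
        e = np.asarray(self.exit_direction, float)
        end = turn + e * self._distance_to_wall(turn, e)
        return np.vstack([rel, turn, end])

    def _distance_to_wall(self, origin: np.ndarray, direction: np.ndarray) -> float:
        """Distance from origin to the first room wall along direction."""
        lo = np.array([0.0, 0.0])
        hi = np.array([self.room_length_m, self.room_width_m])
        ts = []
        for ax in (0, 1):
            if abs(direction[ax]) > 1e-12:
                for bound in (lo[ax], hi[ax]):
                    t = (bound - origin[ax]) / direction[ax]
                    if t > 1e-9:
                        ts.append(t)
        if not ts:
            raise ValueError("direction does not reach a wall")
        return min(ts)

    def in_room(self, position) -> bool:
        x, y = position
        return 0.0 <= x <= self.room_length_m and 0.0 <= y <= self.room_width_m


@dataclass(frozen=True)
class MicArray:
    """Microphone array geometry and acquisition parameters."""

    mic_positions: np.ndarray          # (N, 3) metres
    mic_ids: np.ndarray                # (N,) integer ids
    sample_rate_hz: float
    calibration_db: np.ndarray = None  # (N,) per-mic gain offsets, dB

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.mic_positions, float))
        if pos.shape[1] != 3:
            raise ValueError("mic_positions must be (N, 3)")
        object.__setattr__(self, "mic_positions", pos)
        ids = np.asarray(self.mic_ids, int)
        if len(ids) != len(pos) or len(np.unique(ids)) != len(ids):
            raise ValueError("mic_ids must be unique and match mic_positions")
        object.__setattr__(self, "mic_ids", ids)
        cal = self.calibration_db
        cal = np.zeros(len(pos)) if cal is None else np.asarray(cal, float)
        if len(cal) != len(pos):
            raise ValueError("calibration_db length mismatch")
        object.__setattr__(self, "calibration_db", cal)
        if len(pos) < 3:
            raise ValueError("need at least 3 microphones")
        # planar (x, y) degeneracy check: 2-D multilateration needs >= 3
        # non-collinear mics
        xy = pos[:, :2] - pos[:, :2].mean(0)
        if np.linalg.matrix_rank(xy, tol=1e-9) < 2:
            raise ValueError("microphones are collinear in the horizontal plane")

    def __len__(self) -> int:
        return len(self.mic_ids)

    @property
    def max_baseline_m(self) -> float:
        from scipy.spatial.distance import pdist

        return float(pdist(self.mic_positions).max())

    def index_of(self, mic_id: int) -> int:
        idx = np.nonzero(self.mic_ids == mic_id)[0]
        if len(idx) == 0:
            raise KeyError(f"unknown mic id {mic_id}")
        return int(idx[0])


@dataclass(frozen=True)
class TrialRecord:
    """One flight trial: identity, schedule position and outcome.

    ``success`` means the bat flew the entire corridor length to the
    appropriate wall without turning around, exiting through the chains,
    landing on a chain, or falling to the floor.
    """

    bat_id: str
    day_index: int
    trial_index: int
    condition: Condition
    success: bool
    prior_experience: bool = False

    def __post_init__(self) -> None:
        if self.day_index < 1 or self.trial_index < 1:
            raise ValueError("day_index and trial_index are 1-based")
        object.__setattr__(self, "condition", Condition(self.condition))


# ---------------------------------------------------------------------------
# Path-coordinate operations
# ---------------------------------------------------------------------------

def _project_to_polyline(point: np.ndarray, poly: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Project a 2-D point onto a polyline.

    Returns ``(s, lateral, tangent)``: arc length from the polyline start to
    the foot of the projection, the signed perpendicular offset (positive to
    the right of the local tangent), and the local tangent unit vector.
    """
    best = None
    s_acc = 0.0
    for a, b in zip(poly[:-1], poly[1:]):
        seg = b - a
        L = float(np.hypot(*seg))
        if L == 0:
            continue
        t = seg / L
        u = float(np.clip(np.dot(point - a, t), 0.0, L))
        foot = a + u * t
        d2 = float(np.sum((point - foot) ** 2))
        if best is None or d2 < best[0] - 1e-15:
            # signed lateral: positive to the right of travel = clockwise side
            rel = point - a
            lat = -float(t[0] * rel[1] - t[1] * rel[0])
            best = (d2, s_acc + u, lat, t)
        s_acc += L
    assert best is not None
    return best[1], best[2], best[3]


def distance_to_turn(position, room: FlightRoomConfig) -> PathCoordinate:
    """Express a room position in corridor path coordinates.

    The distance is arc length along the corridor midline polyline, measured
    toward the turn point: 0 at the turn, increasing toward the release point,
    negative past the turn.  Positions laterally outside the corridor
    envelope (half-width plus the configured slack) are flagged
    ``off_corridor`` rather than clamped.
    """
    p = np.asarray(position, float)
    if not room.in_room(p):
        raise ValueError(f"position {position} outside room bounds")
    poly = room.midline_polyline()
    s, lat, _t = _project_to_polyline(p, poly)
    s_turn, _, _ = _project_to_polyline(np.asarray(room.turn_point, float), poly)
    dist_m = s_turn - s
    limit = room.corridor_width_m / 2 + room.off_corridor_slack_m
    return PathCoordinate(
        distance_to_turn_cm=float(dist_m * 100.0),
        lateral_offset_cm=float(lat * 100.0),
        off_corridor=bool(abs(lat) > limit),
    )


def signed_beam_angle(beam_vector, room: FlightRoomConfig) -> float:
    """Signed azimuth of a 2-D direction relative to the corridor midline.

    Positive angles point toward the bat's right when flying toward the
    turn; the result lies in (-180, 180] degrees.
    """
    v = np.asarray(beam_vector, float)
    if np.hypot(*v) == 0:
        raise ValueError("beam vector must be nonzero")
    m = np.asarray(room.midline_direction, float)
    # CCW-positive angle from midline to v, then negate: right = clockwise
    ang = -math.degrees(math.atan2(m[0] * v[1] - m[1] * v[0], float(np.dot(m, v))))
    if ang <= -180.0:
        ang += 360.0
    return ang


def wrap_angle_deg(angle: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped planar bat positions at constant flight height."""

    t_s: np.ndarray          # (N,) strictly increasing times
    xy_m: np.ndarray         # (N, 2) positions
    height_m: float = 1.2

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, float)
        xy = np.asarray(self.xy_m, float)
        if t.ndim != 1 or xy.shape != (len(t), 2):
            raise ValueError("t_s must be (N,), xy_m must be (N, 2)")
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "xy_m", xy)

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    def speeds_mps(self) -> np.ndarray:
        """Finite-difference speed at each sample (central, one-sided ends)."""
        v = np.gradient(self.xy_m, self.t_s, axis=0)
        return np.hypot(v[:, 0], v[:, 1])

    def headings_deg(self, room: "FlightRoomConfig") -> np.ndarray:
        """Velocity direction per sample as a signed angle re the midline."""
        v = np.gradient(self.xy_m, self.t_s, axis=0)
        return np.array([signed_beam_angle(vi, room) if np.hypot(*vi) > 0 else np.nan
                         for vi in v])

    def position_at(self, t) -> np.ndarray:
        """Linearly interpolated position(s) at time(s) t."""
        t = np.asarray(t, float)
        x = np.interp(t, self.t_s, self.xy_m[:, 0])
        y = np.interp(t, self.t_s, self.xy_m[:, 1])
        return np.stack([x, y], axis=-1)

    def path_length_m(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.xy_m, axis=0).T)))


# ---------------------------------------------------------------------------
# Default (approximate) study geometry
# ---------------------------------------------------------------------------

def _chain_grid(room_length_m, room_width_m, spacing, midline_y, corridor_hw, condition):
    """Chain grid on a regular lattice with the corridor cut out (approximate)."""
    xs = np.arange(spacing, room_length_m - spacing / 2, spacing)
    ys = np.arange(spacing, room_width_m - spacing / 2, spacing)
    pts = []
    for x in xs:
        for y in ys:
            if 0.6 <= x <= 4.6 and abs(y - midline_y) <= corridor_hw + 1e-9:
                continue  # straight corridor cut-out
            if not (0.4 <= x <= 4.8 and abs(y - midline_y) <= 1.0 + 1e-9):
                continue  # chains only flank the corridor region
            pts.append((round(x / spacing) * spacing, round(y / spacing) * spacing))
    return tuple(pts)


def default_room(condition: Condition | str = Condition.STRAIGHT, *, with_chains: bool = False) -> FlightRoomConfig:
    """Approximate flight-room layout for a given condition.

    Room 5.5 m x 4.8 m; the bat is released at x = 0.7 m on the corridor
    midline (y = 2.4 m) and flies in +x; the (equivalent) turn point is
    3.5 m down-corridor, so the measured 300-cm flightpath spans
    x in [0.7, 3.7] ... [4.2].  Exact study coordinates are not tabulated;
    these values are an approximation and purely configuration.
    """
    condition = Condition(condition)
    chains = _chain_grid(5.5, 4.8, 0.20, 2.4, 0.20, condition) if with_chains else ()
    if condition is Condition.REVERSED_RIGHT_TURN:
        # flown from the far wall back toward the release wall, turning right
        return FlightRoomConfig(
            room_length_m=5.5, room_width_m=4.8,
            release_point=(4.9, 2.4), turn_point=(1.4, 2.4),
            midline_direction=(-1.0, 0.0), condition=condition,
            chain_positions=chains,
        )
    return FlightRoomConfig(
        room_length_m=5.5, room_width_m=4.8,
        release_point=(0.7, 2.4), turn_point=(4.2, 2.4),
        midline_direction=(1.0, 0.0), condition=condition,
        chain_positions=chains,
    )


def default_mic_array(sample_rate_hz: float = 250_000.0) -> MicArray:
    """Fourteen perimeter microphones (approximate positions, metres)."""
    pos = np.array([
        # along wall y = 0 (bat's right when flying +x)
        (0.8, 0.0, 1.0), (1.8, 0.0, 1.2), (2.8, 0.0, 0.9),
        (3.8, 0.0, 1.1), (4.8, 0.0, 1.0),
        # along wall y = 4.8 (bat's left)
        (0.8, 4.8, 1.1), (1.8, 4.8, 0.9), (2.8, 4.8, 1.2),
        (3.8, 4.8, 1.0), (4.8, 4.8, 1.1),
        # far wall x = 5.5 (wall B)
        (5.5, 1.6, 1.0), (5.5, 3.2, 1.2),
        # release wall x = 0
        (0.0, 1.6, 1.1), (0.0, 3.2, 0.9),
    ])
    return MicArray(mic_positions=pos, mic_ids=np.arange(1, 15), sample_rate_hz=sample_rate_hz)


# ---------------------------------------------------------------------------
# Config file I/O
# ---------------------------------------------------------------------------

def save_room_config(room: FlightRoomConfig, path: str | Path) -> None:
    doc = {
        "room_length_m": room.room_length_m,
        "room_width_m": room.room_width_m,
        "release_point": list(room.release_point),
        "turn_point": list(room.turn_point),
        "midline_direction": list(room.midline_direction),
        "condition": room.condition.value,
        "corridor_width_m": room.corridor_width_m,
        "chain_spacing_m": room.chain_spacing_m,
        "chain_positions": [list(p) for p in room.chain_positions],
        "flightpath_length_m": room.flightpath_length_m,
        "turn_radius_m": room.turn_radius_m,
        "off_corridor_slack_m": room.off_corridor_slack_m,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_room_config(path: str | Path) -> FlightRoomConfig:
    doc = yaml.safe_load(Path(path).read_text())
    doc["release_point"] = tuple(doc["release_point"])
    doc["turn_point"] = tuple(doc["turn_point"])
    doc["midline_direction"] = tuple(doc["midline_direction"])
    doc["chain_positions"] = tuple(tuple(p) for p in doc.get("chain_positions", ()))
    return FlightRoomConfig(**doc)


def save_mic_table(mics: MicArray, path: str | Path) -> None:
    df = pd.DataFrame({
        "mic_id": mics.mic_ids,
        "x": mics.mic_positions[:, 0],
        "y": mics.mic_positions[:, 1],
        "z": mics.mic_positions[:, 2],
        "calibration_db": mics.calibration_db,
    })
    df.to_csv(path, index=False)


def load_mic_table(path: str | Path, sample_rate_hz: float = 250_000.0) -> MicArray:
    df = pd.read_csv(path)
    return MicArray(
        mic_positions=df[["x", "y", "z"]].to_numpy(float),
        mic_ids=df["mic_id"].to_numpy(int),
        sample_rate_hz=sample_rate_hz,
        calibration_db=df["calibration_db"].to_numpy(float) if "calibration_db" in df else None,
    )
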