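"""End-to-end orchestration: dataset simulation, analysis, validation.

A *dataset* is a directory with a fixed layout (the reference schema; the
synthetic generator writes it and the analysis reads it):

.. code-block:: text

    dataset/
      room_<condition>.yaml     flight-room config per condition
      mics.csv                  mic_id,x,y,z,calibration_db
      manifest.csv              flight_id,bat,condition,day,trial,success,
                                wav,truth,n_calls,seed
      params.json               generator parameters + root seed
      flights/<id>.wav          multichannel recording (channels = mic order)
      flights/<id>_truth.csv    ground-truth call table (+ .json sidecar)

Readers for other layouts (e.g. an external data deposit) can adapt to
this schema via :class:`DatasetReader`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from . import stats as bstats
from .beam import BeamModel
from .frontend import DetectorParams
from .geometry import Condition, FlightRoomConfig, MicArray, Trajectory, TrialRecord, \
    default_mic_array, default_room, load_mic_table, load_room_config, \
    save_mic_table, save_room_config
from .lmm import IPIApproachModel, IPIDaysModel
from .localize import analyze_flight, bin_beam, firstlast_day_regression, \
    segment_stats, shift_onset, SEGMENTS_CM
from .propagation import Environment
from .simulate import GazeModel, default_gaze_model, default_speed_profile, \
    default_timing_model, simulate_flight
from .timing import SSGParams, classify_ssgs, compute_ipis, fingerprint, \
    grouped_vs_single_counts, ssg_proportions

__all__ = ["SimConfig", "run_simulate", "run_analysis", "validate_dataset",
           "DatasetReader", "load_dataset"]

log = logging.getLogger("batgaze")


@dataclass
class SimConfig:
    """Synthetic-dataset generation parameters."""

    out_dir: str | Path = "dataset"
    conditions: tuple = (Condition.STRAIGHT, Condition.RIGHT_TURN, Condition.LEFT_TURN)
    n_bats: int = 2
    n_days: int = 2
    n_trials: int = 2
    seed: int = 0
    sample_rate_hz: float = 250_000.0
    noise_db: float = -65.0
    success_rates: dict = field(default_factory=lambda: {
        "STRAIGHT": 0.94, "RIGHT_TURN": 0.87, "LEFT_TURN": 0.85,
        "REVERSED_RIGHT_TURN": 0.80})
    clutter_reflection_db: float | None = None

    def to_json(self) -> str:
        d = {**self.__dict__, "out_dir": str(self.out_dir),
             "conditions": [Condition(c).value for c in self.conditions]}
        return json.dumps(d, indent=1, sort_keys=True)


def config_hash(obj) -> str:
    s = obj if isinstance(obj, str) else json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(s.encode()).hexdigest()[:12]


def run_simulate(config: SimConfig) -> Path:
    """Generate a synthetic dataset directory; deterministic under the seed."""
    out = Path(config.out_dir)
    (out / "flights").mkdir(parents=True, exist_ok=True)
    mics = default_mic_array(config.sample_rate_hz)
    save_mic_table(mics, out / "mics.csv")
    env = Environment(noise_db=config.noise_db)
    root = np.random.SeedSequence(config.seed)

    rows = []
    fid = 0
    for cond in config.conditions:
        cond = Condition(cond)
        room = default_room(cond, with_chains=config.clutter_reflection_db is not None)
        save_room_config(room, out / f"room_{cond.value}.yaml")
        for b in range(1, config.n_bats + 1):
            for day in range(1, config.n_days + 1):
                for trial in range(1, config.n_trials + 1):
                    ss = root.spawn(1)[0]
                    meta_rng = np.random.default_rng(ss.spawn(1)[0])
                    success = bool(meta_rng.random() <
                                   config.success_rates.get(cond.value, 0.9))
                    trialrec = TrialRecord(f"bat{b}", day, trial, cond, success)
                    wave, truth = simulate_flight(
                        room, mics, trial=trialrec, env=env, seed=ss,
                        clutter_reflection_db=config.clutter_reflection_db)
                    name = f"flight_{fid:04d}"
                    wavfile.write(out / "flights" / f"{name}.wav",
                                  int(config.sample_rate_hz),
                                  wave.astype(np.float32).T)
                    truth.save(out / "flights" / f"{name}_truth.csv")
                    rows.append({
                        "flight_id": name, "bat": f"bat{b}",
                        "condition": cond.value, "day": day, "trial": trial,
                        "success": success,
                        "wav": f"flights/{name}.wav",
                        "truth": f"flights/{name}_truth.csv",
                        "n_calls": truth.n_calls,
                        "seed": int(np.random.default_rng(ss).integers(2 ** 31)),
                    })
                    fid += 1
                    log.info("simulated %s (%s, %s day %d trial %d, %d calls)",
                             name, cond.value, f"bat{b}", day, trial, truth.n_calls)
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    (out / "params.json").write_text(config.to_json())
    return out


# ---------------------------------------------------------------------------
# Dataset reading
# ---------------------------------------------------------------------------

class DatasetReader:
    """Reader for the reference dataset layout.

    Subclass and override :meth:`load_manifest` / :meth:`load_flight` to
    adapt other on-disk layouts (e.g. an external archive) to the same
    in-memory interface.
    """

    def __init__(self, root: str | Path):
        self.root = Path(root)

    def load_manifest(self) -> pd.DataFrame:
        return pd.read_csv(self.root / "manifest.csv")

    def load_mics(self) -> MicArray:
        fs = json.loads((self.root / "params.json").read_text()).get(
            "sample_rate_hz", 250_000.0) if (self.root / "params.json").exists() \
            else 250_000.0
        return load_mic_table(self.root / "mics.csv", fs)

    def load_room(self, condition: str) -> FlightRoomConfig:
        return load_room_config(self.root / f"room_{condition}.yaml")

    def load_flight(self, row) -> tuple[np.ndarray, pd.DataFrame | None]:
        fs, data = wavfile.read(self.root / row.wav)
        wave = data.T.astype(float)
        truth_path = self.root / row.truth if isinstance(row.truth, str) else None
        truth = pd.read_csv(truth_path) if truth_path and truth_path.exists() else None
        return wave, truth


def load_dataset(path: str | Path) -> DatasetReader:
    return DatasetReader(path)


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------

def run_analysis(dataset_dir: str | Path, out_dir: str | Path,
                 ssg_params: SSGParams = SSGParams(),
                 detector: DetectorParams | None = None,
                 fit_lmms: bool = True, make_figures: bool = True,
                 use_truth_positions: bool = False) -> Path:
    """Run the full analysis over a dataset directory.

    Writes per-call tables, binned/segment beam statistics, shift onsets,
    SSG labels and proportions, a stats JSON, and (optionally) figures.
    Every table carries the bat/day/trial/condition keys and the config
    hash.  Calls on failed flights are processed identically but flagged.
    """
    reader = load_dataset(dataset_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = reader.load_manifest()
    if len(manifest) == 0:
        raise ValueError("dataset manifest is empty")
    mics = reader.load_mics()
    beam = BeamModel.calibrated()
    env = Environment()
    chash = config_hash({"ssg": ssg_params.__dict__,
                         "detector": (detector or DetectorParams()).__dict__})

    rooms = {c: reader.load_room(c) for c in manifest["condition"].unique()}
    all_calls = []
    for row in manifest.itertuples(index=False):
        wave, truth = reader.load_flight(row)
        room = rooms[row.condition]
        ext = None
        if use_truth_positions and truth is not None:
            ext = Trajectory(t_s=truth["emission_time_s"].to_numpy(),
                             xy_m=truth[["x_m", "y_m"]].to_numpy())
        calls = analyze_flight(wave, mics, room, beam=beam, env=env,
                               detector=detector, external_trajectory=ext)
        for key in ("flight_id", "bat", "condition", "day", "trial", "success"):
            calls[key] = getattr(row, key)
        all_calls.append(calls)
        log.info("analyzed %s: %d calls", row.flight_id, len(calls))
    calls = pd.concat(all_calls, ignore_index=True)
    calls["config_hash"] = chash
    calls.to_csv(out / "calls.csv", index=False)

    results = {"config_hash": chash, "n_flights": len(manifest),
               "n_calls": int(len(calls))}
    ok = calls[calls["success"] & np.isfinite(calls["beam_aim_deg"])]

    # --- beam statistics -------------------------------------------------
    seg_rows, bin_rows, onset_rows = [], [], []
    for (bat, cond), sub in ok.groupby(["bat", "condition"], observed=True):
        binned = bin_beam(sub)
        bf = binned.as_frame()
        bf["bat"], bf["condition"], bf["config_hash"] = bat, cond, chash
        bin_rows.append(bf)
        try:
            s1 = segment_stats(sub, "BEAM1")
            s2 = segment_stats(sub, "BEAM2")
        except ValueError:
            continue
        for s in (s1, s2):
            seg_rows.append({"bat": bat, "condition": cond, "segment": s.segment,
                             "n": s.n_calls, "mean_deg": s.mean_deg,
                             "sd_deg": s.sd_deg, "config_hash": chash})
        sign = Condition(cond).turn_sign
        if sign != 0:
            onset = shift_onset(binned, s1, "right" if sign > 0 else "left")
            onset_rows.append({"bat": bat, "condition": cond,
                               "shift_onset_cm": onset, "config_hash": chash})
    if seg_rows:
        pd.DataFrame(seg_rows).to_csv(out / "segment_stats.csv", index=False)
    if bin_rows:
        pd.concat(bin_rows).to_csv(out / "binned_beam.csv", index=False)
    if onset_rows:
        pd.DataFrame(onset_rows).to_csv(out / "shift_onset.csv", index=False)

    # --- flight speed ----------------------------------------------------
    speed_rows = []
    for (fid, cond), sub in calls.groupby(["flight_id", "condition"], observed=True):
        if len(sub) < 5 or not sub["success"].iloc[0]:
            continue
        traj = Trajectory(t_s=sub["emission_time_s"].to_numpy(),
                          xy_m=sub[["x_m", "y_m"]].to_numpy())
        room = rooms[cond]
        from .localize import flight_speed

        row = {"flight_id": fid, "condition": cond, "config_hash": chash}
        for seg in ("SPEED1", "SPEED2"):
            try:
                row[seg.lower() + "_mps"] = flight_speed(traj, seg, room)
            except ValueError:
                row[seg.lower() + "_mps"] = np.nan
        speed_rows.append(row)
    speeds = pd.DataFrame(speed_rows)
    if len(speeds):
        speeds.to_csv(out / "flight_speeds.csv", index=False)
        conds = [c for c in speeds["condition"].unique()]
        if len(conds) >= 2:
            a = speeds[speeds["condition"] == conds[0]]["speed2_mps"].dropna()
            b = speeds[speeds["condition"] == conds[1]]["speed2_mps"].dropna()
            if len(a) >= 5 and len(b) >= 5:
                d, p = bstats.speed_distribution_test(a, b)
                results["speed_ks"] = {"conditions": conds[:2], "D": d, "p": p}

    # --- call timing ------------------------------------------------------
    label_rows, ipi_rows = [], []
    for (fid,), sub in calls.groupby(["flight_id"], observed=True):
        sub = sub.sort_values("emission_time_s")
        if len(sub) < 2:
            continue
        recs = compute_ipis(sub["emission_time_s"].to_numpy())
        labels = classify_ssgs(recs, ssg_params)
        sizes = np.empty(len(sub), int)
        gids = np.empty(len(sub), int)
        for lab in labels:
            for m in lab.member_call_indices:
                sizes[m], gids[m] = lab.group_size, lab.group_id
        lab_df = sub[["flight_id", "bat", "condition", "day", "trial",
                      "success", "call_index"]].copy()
        lab_df["ssg_size"], lab_df["ssg_group_id"] = sizes, gids
        lab_df["pre_ipi_ms"] = [r.pre_ipi_ms for r in recs]
        lab_df["post_ipi_ms"] = [r.post_ipi_ms for r in recs]
        label_rows.append(lab_df)
    if label_rows:
        labels_df = pd.concat(label_rows, ignore_index=True)
        labels_df["config_hash"] = chash
        labels_df.to_csv(out / "ssg_labels.csv", index=False)

        prop_rows = []
        for (bat, cond), sub in labels_df[labels_df["success"]].groupby(
                ["bat", "condition"], observed=True):
            heads = sub.drop_duplicates(["flight_id", "ssg_group_id"])
            from .timing import SSGLabel

            labs = [SSGLabel(i, int(s), tuple(range(int(s))))
                    for i, s in enumerate(heads["ssg_size"])]
            props = ssg_proportions(labs)
            for size, p in props.items():
                prop_rows.append({"bat": bat, "condition": cond, "ssg_size": size,
                                  "proportion_of_calls": p, "config_hash": chash,
                                  "ssg_params": json.dumps(ssg_params.__dict__)})
        pd.DataFrame(prop_rows).to_csv(out / "ssg_proportions.csv", index=False)

        chi_rows = []
        for bat, sub in labels_df[labels_df["success"]].groupby("bat", observed=True):
            conds = sub["condition"].unique()
            straight = sub[sub["condition"] == "STRAIGHT"]
            for cond in conds:
                if cond == "STRAIGHT" or len(straight) == 0:
                    continue
                other = sub[sub["condition"] == cond]
                ga = int((straight["ssg_size"] >= 2).sum())
                sa = int((straight["ssg_size"] == 1).sum())
                gb = int((other["ssg_size"] >= 2).sum())
                sb = int((other["ssg_size"] == 1).sum())
                try:
                    chi2, p = bstats.ssg_proportion_test(ga, sa, gb, sb)
                except ValueError:
                    continue
                chi_rows.append({"bat": bat, "condition_a": "STRAIGHT",
                                 "condition_b": cond, "chi2": chi2, "p": p,
                                 "n": ga + sa + gb + sb})
        results["ssg_chi2"] = chi_rows

    # --- performance ------------------------------------------------------
    trials = manifest[["bat", "condition", "day", "success"]]
    daily = bstats.daily_success_table(trials)
    daily.to_csv(out / "daily_success.csv", index=False)
    if daily["condition"].nunique() >= 2 and len(daily) > daily["condition"].nunique():
        an = bstats.performance_anova(daily)
        results["performance_anova"] = {
            "F": an.f_stat, "df": [an.df_between, an.df_within], "p": an.p_value,
            "group_means": an.group_means.to_dict()}

    # --- LMMs -------------------------------------------------------------
    if fit_lmms and label_rows:
        lmm_data = _lmm_rows(labels_df, calls)
        if len(lmm_data) >= 200 and lmm_data["condition"].nunique() >= 2:
            try:
                res = IPIApproachModel(lmm_data).fit()
                results["ipi_approach_lmm"] = _lmm_json(res)
            except Exception as exc:        # singular tiny datasets
                log.warning("approach LMM failed: %s", exc)
        days_data = lmm_data.rename(columns={"day": "day_number"})
        days_data["day"] = days_data["day_number"]
        if len(days_data) >= 200 and days_data["day_number"].nunique() >= 2 \
                and days_data["condition"].nunique() >= 2:
            try:
                res = IPIDaysModel(days_data).fit()
                results["ipi_days_lmm"] = _lmm_json(res)
            except Exception as exc:
                log.warning("days LMM failed: %s", exc)

    (out / "stats.json").write_text(json.dumps(results, indent=1, default=float))

    if make_figures:
        _figures(out, ok, labels_df if label_rows else None, rooms)
    return out


def _lmm_rows(labels_df: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Call-level LMM input: successful flights, calls before the turn."""
    merged = labels_df.merge(
        calls[["flight_id", "call_index", "distance_to_turn_cm"]],
        on=["flight_id", "call_index"], how="left")
    merged = merged[merged["success"] & (merged["distance_to_turn_cm"] > 0)
                    & merged["post_ipi_ms"].notna()]
    out_rows = []
    for fid, sub in merged.groupby("flight_id", observed=True):
        sub = sub.sort_values("call_index").copy()
        sub["calls_to_turn"] = np.arange(len(sub))[::-1]
        out_rows.append(sub)
    return pd.concat(out_rows, ignore_index=True) if out_rows else pd.DataFrame()


def _lmm_json(res) -> dict:
    return {
        "estimates": res.params.to_dict(),
        "ci_low": res.conf_int_low.to_dict(),
        "ci_high": res.conf_int_high.to_dict(),
        "p": res.pvalues.to_dict(),
        "variance_components": res.variance_components.to_dict(),
        "n_observations": res.n_observations,
        "derived_slopes": res.derived_slopes().to_dict(),
    }


def _figures(out: Path, ok: pd.DataFrame, labels_df: pd.DataFrame | None, rooms):
    from . import plots
    from .timing import IPIRecord

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    for (bat, cond), sub in ok.groupby(["bat", "condition"], observed=True):
        if len(sub) < 5:
            continue
        plots.plot_binned_beam(bin_beam(sub), f"{bat} {cond}",
                               figdir / f"beam_{bat}_{cond}.svg")
    if labels_df is not None:
        for (bat, cond), sub in labels_df[labels_df["success"]].groupby(
                ["bat", "condition"], observed=True):
            recs = [IPIRecord(i, pre, post) for i, (pre, post) in enumerate(
                zip(sub["pre_ipi_ms"], sub["post_ipi_ms"]))]
            interior = [r for r in recs if r.pre_ipi_ms is not None
                        and r.post_ipi_ms is not None]
            if len(interior) < 5:
                continue
            h, pe, po, _ = fingerprint(recs)
            plots.plot_fingerprint(h, pe, po, f"{bat} {cond}",
                                   figdir / f"fingerprint_{bat}_{cond}.svg")
        wide = None
        props = pd.read_csv(out / "ssg_proportions.csv") \
            if (out / "ssg_proportions.csv").exists() else None
        if props is not None and len(props):
            for bat, sub in props.groupby("bat", observed=True):
                wide = sub.pivot_table(index="ssg_size", columns="condition",
                                       values="proportion_of_calls", observed=True)
                plots.plot_ssg_proportions(wide, str(bat),
                                           figdir / f"ssg_{bat}.svg")

    # first-vs-last-day regression panels
    for (bat, cond), sub in ok.groupby(["bat", "condition"], observed=True):
        days = sorted(sub["day"].unique())
        if len(days) < 2:
            continue
        first = sub[sub["day"] == days[0]]
        last = sub[sub["day"] == days[-1]]
        try:
            comp = firstlast_day_regression(first, last)
        except ValueError:
            continue
        from . import plots as _p

        _p.plot_day_regressions(first, last, comp, f"{bat} {cond}",
                                figdir / f"days_{bat}_{cond}.svg")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_dataset(path: str | Path) -> list[dict]:
    """Schema / geometry / monotonicity checks on a dataset directory.

    Returns a list of violations, each ``{"rule": id, "detail": text}``;
    an empty list means the dataset is pristine.
    """
    root = Path(path)
    violations: list[dict] = []

    def bad(rule, detail):
        violations.append({"rule": rule, "detail": str(detail)})

    if not (root / "manifest.csv").exists():
        bad("manifest_missing", root / "manifest.csv")
        return violations
    manifest = pd.read_csv(root / "manifest.csv")
    required = {"flight_id", "bat", "condition", "day", "trial", "success", "wav"}
    missing = required - set(manifest.columns)
    if missing:
        bad("manifest_columns", f"missing {sorted(missing)}")
        return violations
    if not (root / "mics.csv").exists():
        bad("mics_missing", root / "mics.csv")
        return violations
    mics_df = pd.read_csv(root / "mics.csv")
    for cond in manifest["condition"].unique():
        room_path = root / f"room_{cond}.yaml"
        if not room_path.exists():
            bad("room_missing", room_path)
            continue
        room = load_room_config(room_path)
        for _, m in mics_df.iterrows():
            if not (0 <= m.x <= room.room_length_m and 0 <= m.y <= room.room_width_m):
                bad("mic_outside_room", f"mic {int(m.mic_id)} at ({m.x}, {m.y})")
    for row in manifest.itertuples(index=False):
        wav_path = root / row.wav
        if not wav_path.exists():
            bad("wav_missing", wav_path)
            continue
        _, data = wavfile.read(wav_path)
        n_ch = 1 if data.ndim == 1 else data.shape[1]
        if n_ch != len(mics_df):
            bad("channel_count", f"{row.flight_id}: {n_ch} channels vs "
                f"{len(mics_df)} mics")
        truth_path = root / row.truth if isinstance(getattr(row, "truth", None), str) \
            else None
        if truth_path and truth_path.exists():
            truth = pd.read_csv(truth_path)
            t = truth["emission_time_s"].to_numpy()
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                bad("nonmonotone_times", row.flight_id)
            if hasattr(row, "n_calls") and len(truth) != row.n_calls:
                bad("call_count_mismatch",
                    f"{row.flight_id}: truth {len(truth)} vs manifest {row.n_calls}")
    return violations
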