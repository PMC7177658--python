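"""Reading NGSIM-style trajectory tables and extracting car-following episodes.

An episode is a maximal uninterrupted run of frames over which a follower
stays in an allowed lane behind the same leader, with both vehicles present
at every frame. Internally everything is SI (m, s); NGSIM's US-customary
feet are converted on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryRecord",
    "CarFollowingEpisode",
    "SchemaError",
    "read_trajectory_table",
    "extract_episodes",
    "write_episode_archive",
    "read_episode_archive",
]

FT_TO_M = 0.3048

#: NGSIM I-80 column names -> canonical field names.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "vehicle_id": "vehicle_id",
    "frame_id": "frame_index",
    "lane_id": "lane_id",
    "preceding": "preceding_id",
    "local_y": "position",
    "v_vel": "speed",
    "v_acc": "acceleration",
    "space_headway": "space_headway",
    "v_length": "vehicle_length",
}

_LENGTH_FIELDS = ("position", "space_headway", "vehicle_length")
_SPEED_FIELDS = ("speed",)
_ACCEL_FIELDS = ("acceleration",)


class SchemaError(ValueError):
    """A mandatory column is missing or unresolvable."""


@dataclass(frozen=True)
class TrajectoryRecord:
    """One vehicle at one 0.1 s frame, SI units."""

    vehicle_id: int
    frame_index: int
    lane_id: int
    preceding_id: int  # 0 = no leader
    position: float  # m along roadway
    speed: float  # m/s
    acceleration: float  # m/s^2
    space_headway: float  # m, front bumper to front bumper
    vehicle_length: float  # m


@dataclass
class CarFollowingEpisode:
    """Aligned leader/follower series for one uninterrupted pair.

    ``d`` is the bumper-to-bumper gap (space headway minus leader length,
    clamped at zero), the physically meaningful collision distance.
    """

    follower_id: int
    leader_id: int
    dt: float
    t: np.ndarray  # s, from 0
    v_l: np.ndarray  # m/s
    v_f: np.ndarray  # m/s
    a_f: np.ndarray  # m/s^2
    d: np.ndarray  # m
    start_frame: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        n = len(self.t)
        for name in ("v_l", "v_f", "a_f", "d"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if len(arr) != n:
                raise ValueError(f"series {name} length {len(arr)} != {n}")

    @property
    def duration(self) -> float:
        """(N - 1) * dt, s."""
        return (len(self.t) - 1) * self.dt

    def __len__(self) -> int:
        return len(self.t)


def _resolve_columns(
    header: Sequence[str], column_map: Mapping[str, str]
) -> dict[str, str]:
    lower = {c.lower().strip(): c for c in header}
    resolved: dict[str, str] = {}
    for src, field_name in column_map.items():
        if src.lower() in lower:
            resolved[field_name] = lower[src.lower()]
    missing = set(column_map.values()) - set(resolved)
    if missing:
        raise SchemaError(
            "missing mandatory column(s): " + ", ".join(sorted(missing))
        )
    return resolved


def read_trajectory_table(
    path: str | Path,
    unit_system: str = "us_customary",
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[TrajectoryRecord]:
    """Read an NGSIM-style CSV into SI-unit records sorted by (vehicle, frame).

    Parameters
    ----------
    unit_system : ``"metric"`` (m, m/s) or ``"us_customary"`` (ft, ft/s);
        NGSIM ships feet.
    column_map : source-column -> canonical-field mapping; case-insensitive
        on the source side. Defaults to the NGSIM I-80 schema.
    """
    if unit_system not in ("metric", "us_customary"):
        raise ValueError(f"unknown unit_system {unit_system!r}")
    cmap = column_map or DEFAULT_COLUMN_MAP
    df = pd.read_csv(path, delimiter=delimiter)
    resolved = _resolve_columns(df.columns, cmap)
    df = df[[resolved[f] for f in resolved]].copy()
    df.columns = list(resolved)

    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value in column {col!r} at data row {row}"
            )
        df[col] = coerced
    if df.isna().any().any():
        col = df.columns[df.isna().any().to_numpy()][0]
        row = int(np.flatnonzero(df[col].isna().to_numpy())[0])
        raise ValueError(f"missing value in column {col!r} at data row {row}")

    factor = FT_TO_M if unit_system == "us_customary" else 1.0
    for f in _LENGTH_FIELDS + _SPEED_FIELDS + _ACCEL_FIELDS:
        df[f] = df[f] * factor

    df = df.sort_values(["vehicle_id", "frame_index"], kind="mergesort")
    return [
        TrajectoryRecord(
            vehicle_id=int(r.vehicle_id),
            frame_index=int(r.frame_index),
            lane_id=int(r.lane_id),
            preceding_id=int(r.preceding_id),
            position=float(r.position),
            speed=float(r.speed),
            acceleration=float(r.acceleration),
            space_headway=float(r.space_headway),
            vehicle_length=float(r.vehicle_length),
        )
        for r in df.itertuples(index=False)
    ]


def extract_episodes(
    records: Iterable[TrajectoryRecord],
    min_duration: float = 10.0,
    lane_ids: set[int] | None = None,
    dt: float = 0.1,
) -> list[CarFollowingEpisode]:
    """Cut maximal car-following runs out of a record table.

    A run breaks when the follower changes lane (if ``lane_ids`` given,
    leaves the allowed set), changes or loses its leader, skips a frame,
    or the leader has no record at that frame. Runs shorter than
    ``min_duration`` seconds — duration (N-1)*dt — are discarded.
    """
    if min_duration <= 0:
        raise ValueError("min_duration must be positive")
    records = sorted(records, key=lambda r: (r.vehicle_id, r.frame_index))
    by_vehicle_frame = {(r.vehicle_id, r.frame_index): r for r in records}
    by_vehicle: dict[int, list[TrajectoryRecord]] = {}
    for r in records:
        by_vehicle.setdefault(r.vehicle_id, []).append(r)

    min_frames = int(round(min_duration / dt)) + 1
    episodes: list[CarFollowingEpisode] = []

    for fid, recs in by_vehicle.items():
        run: list[tuple[TrajectoryRecord, TrajectoryRecord]] = []

        def flush() -> None:
            if len(run) >= min_frames:
                f0 = run[0][0].frame_index
                v_l = np.array([lr.speed for _, lr in run])
                v_f = np.array([fr.speed for fr, _ in run])
                a_f = np.array([fr.acceleration for fr, _ in run])
                d = np.maximum(
                    np.array(
                        [fr.space_headway - lr.vehicle_length for fr, lr in run]
                    ),
                    0.0,
                )
                episodes.append(
                    CarFollowingEpisode(
                        follower_id=fid,
                        leader_id=run[0][0].preceding_id,
                        dt=dt,
                        t=np.arange(len(run)) * dt,
                        v_l=v_l,
                        v_f=v_f,
                        a_f=a_f,
                        d=d,
                        start_frame=f0,
                    )
                )
            run.clear()

        prev_frame = None
        prev_leader = None
        for rec in recs:
            leader = rec.preceding_id
            lane_ok = lane_ids is None or rec.lane_id in lane_ids
            lead_rec = (
                by_vehicle_frame.get((leader, rec.frame_index))
                if leader != 0
                else None
            )
            contiguous = prev_frame is not None and rec.frame_index == prev_frame + 1
            same_leader = leader == prev_leader
            if not (lane_ok and leader != 0 and lead_rec is not None):
                flush()
                prev_frame, prev_leader = None, None
                continue
            if run and not (contiguous and same_leader):
                flush()
            run.append((rec, lead_rec))
            prev_frame, prev_leader = rec.frame_index, leader
        flush()

    episodes.sort(key=lambda e: (e.follower_id, e.start_frame))
    return episodes


def write_episode_archive(episodes, outdir: str | Path) -> Path:
    """One CSV per episode plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, ep in enumerate(episodes):
        name = f"episode_{i:04d}.csv"
        pd.DataFrame(
            {"t": ep.t, "v_l": ep.v_l, "v_f": ep.v_f, "a_f": ep.a_f, "d": ep.d}
        ).to_csv(outdir / name, index=False)  # shortest-repr floats round-trip
        manifest.append(
            {
                "file": name,
                "follower_id": ep.follower_id,
                "leader_id": ep.leader_id,
                "start_frame": ep.start_frame,
                "n": len(ep),
                "dt": ep.dt,
            }
        )
    mpath = outdir / "manifest.csv"
    pd.DataFrame(manifest).to_csv(mpath, index=False)
    return mpath


def read_episode_archive(outdir: str | Path) -> list[CarFollowingEpisode]:
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    episodes = []
    for row in manifest.itertuples(index=False):
        df = pd.read_csv(outdir / row.file, float_precision="round_trip")
        episodes.append(
            CarFollowingEpisode(
                follower_id=int(row.follower_id),
                leader_id=int(row.leader_id),
                dt=float(row.dt),
                t=df["t"].to_numpy(),
                v_l=df["v_l"].to_numpy(),
                v_f=df["v_f"].to_numpy(),
                a_f=df["a_f"].to_numpy(),
                d=df["d"].to_numpy(),
                start_frame=int(row.start_frame),
            )
        )
    return episodes
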