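"""Particle-track kinematics in the left-right organizer.

Native particles tracked in midplane movies of the zebrafish LRO are
converted into polar kinematic samples about the organizer center:
instantaneous angular velocity (signed, counterclockwise positive),
tangential/radial velocity components, sector summaries of the angular
velocity field, and displacement-directionality distributions.

Axis convention: after rotating the image frame by the recorded anterior
axis angle, +y points anterior (PA) and +x points to the embryo's right
(LR); angles are standard counterclockwise radians with theta = pi/2 at
anterior.  Normalized lr/pa coordinates are Cartesian position over the
LRO radius, clipped to [-1, 1].  Angular sectors (8 for field summaries,
12 thirty-degree sectors for directionality) start at the anterior
direction and proceed counterclockwise; the origin is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

__all__ = [
    "ParticleTrack",
    "LROFrameGeometry",
    "to_polar",
    "exclude_core",
    "angular_velocity",
    "velocity_components",
    "sector_summary",
    "directionality",
    "compare_directionality",
    "track_summaries",
    "tracks_from_frame",
    "read_tracks_csv",
    "read_metadata_csv",
]

log = logging.getLogger(__name__)

SAMPLE_COLUMNS = [
    "embryo_id", "track_id", "step", "r", "theta", "dtheta", "aav",
    "v_tan", "v_rad", "lr", "pa", "r_next", "dx", "dy", "stage",
]


@dataclass(frozen=True)
class ParticleTrack:
    """One tracked particle: ordered (frame, x_um, y_um) points."""

    embryo_id: str
    track_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    stage: int | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a track needs at least 2 points")
        if not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x, y must have equal length")


@dataclass(frozen=True)
class LROFrameGeometry:
    """Polar reference frame of one embryo's LRO at one somite stage."""

    center: tuple[float, float]
    radius: float
    anterior_axis_angle: float = np.pi / 2
    stage: int = 6
    dt: float = 0.2

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def _wrap_pi(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]; ties at pi go positive."""
    out = -((-a + np.pi) % (2 * np.pi) - np.pi)
    return out


def to_polar(track: ParticleTrack, geom: LROFrameGeometry) -> pd.DataFrame:
    """Convert one track to per-step kinematic samples.

    One row per consecutive frame pair.  Coordinates are rotated so the
    anterior axis maps to +y; dtheta is the wrapped angle change of the
    step, aav = dtheta / dt with counterclockwise positive.
    """
    rot = np.pi / 2 - geom.anterior_axis_angle
    c, s = np.cos(rot), np.sin(rot)
    dx0, dy0 = track.x - geom.center[0], track.y - geom.center[1]
    x = c * dx0 - s * dy0
    y = s * dx0 + c * dy0

    r = np.hypot(x, y)
    theta = np.mod(np.arctan2(y, x), 2 * np.pi)
    nstep = len(x) - 1
    dframes = np.diff(track.frames)
    dt_step = dframes * geom.dt
    dtheta = _wrap_pi(np.diff(theta))
    dx, dy = np.diff(x), np.diff(y)

    # tangential/radial projection at the step's first point
    with np.errstate(invalid="ignore", divide="ignore"):
        ur_x, ur_y = x[:-1] / r[:-1], y[:-1] / r[:-1]
    ut_x, ut_y = -ur_y, ur_x  # counterclockwise tangent
    v_rad = (dx * ur_x + dy * ur_y) / dt_step
    v_tan = (dx * ut_x + dy * ut_y) / dt_step

    return pd.DataFrame(
        {
            "embryo_id": track.embryo_id,
            "track_id": track.track_id,
            "step": np.arange(nstep),
            "r": r[:-1],
            "theta": theta[:-1],
            "dtheta": dtheta,
            "aav": dtheta / dt_step,
            "v_tan": v_tan,
            "v_rad": v_rad,
            "lr": np.clip(x[:-1] / geom.radius, -1, 1),
            "pa": np.clip(y[:-1] / geom.radius, -1, 1),
            "r_next": r[1:],
            "dx": dx,
            "dy": dy,
            "stage": geom.stage,
        }
    )


def exclude_core(samples: pd.DataFrame, geom: LROFrameGeometry) -> pd.DataFrame:
    """Drop samples near the rotation axis, where angles are ill defined.

    A step survives only if both endpoints lie at or beyond half the LRO
    radius (boundary inclusive).
    """
    half = geom.radius / 2.0
    keep = (samples["r"] >= half) & (samples["r_next"] >= half)
    dropped = int((~keep).sum())
    if dropped:
        log.info("core exclusion dropped %d of %d samples", dropped, len(samples))
    return samples.loc[keep].reset_index(drop=True)


def angular_velocity(samples: pd.DataFrame, dt: float) -> np.ndarray:
    """Instantaneous angular velocity (rad/s): angle change over dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return samples["dtheta"].to_numpy() / dt


def velocity_components(samples: pd.DataFrame) -> pd.DataFrame:
    """Tangential (counterclockwise +) and radial (outward +) velocities."""
    return samples[["v_tan", "v_rad"]].copy()


def _sector_index(theta: np.ndarray, n_sectors: int, origin: float) -> np.ndarray:
    width = 2 * np.pi / n_sectors
    return (np.mod(theta - origin, 2 * np.pi) // width).astype(int)


def sector_summary(
    samples: pd.DataFrame,
    n_sectors: int = 8,
    statistic: str = "median",
    value: str = "aav",
    origin: float = np.pi / 2,
) -> pd.DataFrame:
    """Per-sector summary of a kinematic quantity.

    Equal-width angular sectors starting at the anterior direction
    (``origin``), counterclockwise.  Returns one row per sector with the
    pooled summary, the per-embryo summaries as a dict column, and the
    sample count; empty sectors report NaN, not zero.
    """
    if n_sectors < 1:
        raise ValueError("n_sectors must be >= 1")
    df = samples.copy()
    df["sector"] = _sector_index(df["theta"].to_numpy(), n_sectors, origin)
    rows = []
    for k in range(n_sectors):
        sub = df[df["sector"] == k]
        pooled = getattr(sub[value], statistic)() if len(sub) else np.nan
        per_embryo = (
            sub.groupby("embryo_id")[value].agg(statistic).to_dict() if len(sub) else {}
        )
        rows.append(
            {"sector": k, "n": len(sub), statistic: pooled, "per_embryo": per_embryo}
        )
    return pd.DataFrame(rows)


def directionality(samples: pd.DataFrame, origin: float = np.pi / 2) -> pd.DataFrame:
    """Displacement direction of each step in its local radial frame.

    The direction is the angle of the step's displacement vector measured
    from the outward radial direction at the step's first point, mapped to
    [0, 2*pi); a purely counterclockwise-tangential step reads pi/2, a
    purely outward step reads 0.  Steps with zero displacement are skipped
    (direction undefined).  ``sector`` is the 30-degree sector (0-11) of
    the first point, counted counterclockwise from the anterior direction.
    """
    disp = np.hypot(samples["dx"], samples["dy"])
    moving = samples.loc[disp > 0].copy()
    # angle of displacement minus angle of the outward radial unit vector
    disp_angle = np.arctan2(moving["dy"], moving["dx"])
    direction = np.mod(disp_angle - moving["theta"], 2 * np.pi)
    moving["direction"] = direction
    moving["sector"] = _sector_index(moving["theta"].to_numpy(), 12, origin)
    return moving[["embryo_id", "track_id", "step", "sector", "direction"]].reset_index(
        drop=True
    )


def compare_directionality(directions_a, directions_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on directionality distributions."""
    a = np.asarray(directions_a, dtype=float)
    b = np.asarray(directions_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def track_summaries(
    tracks: list[ParticleTrack],
    geoms: dict,
    group_of: dict | None = None,
    apply_core_exclusion: bool = True,
) -> pd.DataFrame:
    """One observation row per track: the unit fed to the flow regression.

    ``geoms`` maps (embryo_id, stage) or embryo_id to an LROFrameGeometry.
    Each row carries the track's median angular velocity and mean
    normalized lr/pa position; tracks that fall entirely inside the
    excluded core are dropped (counted in the log).
    """
    rows, dropped = [], 0
    for tr in tracks:
        if isinstance(geoms, LROFrameGeometry):
            geom = geoms
        else:
            key = (tr.embryo_id, tr.stage) if tr.stage is not None else tr.embryo_id
            if key not in geoms:
                raise KeyError(f"no geometry for {key!r}")
            geom = geoms[key]
        samples = to_polar(tr, geom)
        if apply_core_exclusion:
            samples = exclude_core(samples, geom)
        if samples.empty:
            dropped += 1
            continue
        rows.append(
            {
                "embryo_id": tr.embryo_id,
                "track_id": tr.track_id,
                "aav": float(samples["aav"].median()),
                "lr": float(samples["lr"].mean()),
                "pa": float(samples["pa"].mean()),
                "stage": geom.stage,
                "group": group_of.get(tr.embryo_id) if group_of else None,
            }
        )
    if dropped:
        log.info("%d tracks fell entirely inside the excluded core", dropped)
    return pd.DataFrame(rows)


def samples_from_frame(tracks: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Vectorized kinematic samples for a whole tidy track table.

    Equivalent to running :func:`to_polar` on every track (one row per
    consecutive frame pair within a track) but computed in bulk; the
    metadata table supplies per-(embryo, stage) geometry.
    """
    df = tracks.merge(
        meta[["embryo_id", "stage", "center_x", "center_y", "radius",
              "anterior_axis_deg", "dt_s"]],
        on=["embryo_id", "stage"], how="left", validate="many_to_one",
    )
    if df["radius"].isna().any():
        missing = df.loc[df["radius"].isna(), ["embryo_id", "stage"]].drop_duplicates()
        raise KeyError(f"no geometry for {missing.to_records(index=False).tolist()}")
    df = df.sort_values(["embryo_id", "stage", "track_id", "frame"], kind="stable")

    rot = np.pi / 2 - np.deg2rad(df["anterior_axis_deg"].to_numpy())
    c, s = np.cos(rot), np.sin(rot)
    dx0 = df["x_um"].to_numpy() - df["center_x"].to_numpy()
    dy0 = df["y_um"].to_numpy() - df["center_y"].to_numpy()
    x = c * dx0 - s * dy0
    y = s * dx0 + c * dy0
    r = np.hypot(x, y)
    theta = np.mod(np.arctan2(y, x), 2 * np.pi)

    same = (
        (df["embryo_id"].to_numpy()[1:] == df["embryo_id"].to_numpy()[:-1])
        & (df["track_id"].to_numpy()[1:] == df["track_id"].to_numpy()[:-1])
        & (df["stage"].to_numpy()[1:] == df["stage"].to_numpy()[:-1])
    )
    dt_step = np.diff(df["frame"].to_numpy()) * df["dt_s"].to_numpy()[:-1]
    dtheta = _wrap_pi(np.diff(theta))
    dx, dy = np.diff(x), np.diff(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        ur_x, ur_y = x[:-1] / r[:-1], y[:-1] / r[:-1]
    radius = df["radius"].to_numpy()[:-1]
    out = pd.DataFrame(
        {
            "embryo_id": df["embryo_id"].to_numpy()[:-1],
            "track_id": df["track_id"].to_numpy()[:-1],
            "r": r[:-1],
            "theta": theta[:-1],
            "dtheta": dtheta,
            "aav": dtheta / dt_step,
            "v_tan": (dx * -ur_y + dy * ur_x) / dt_step,
            "v_rad": (dx * ur_x + dy * ur_y) / dt_step,
            "lr": np.clip(x[:-1] / radius, -1, 1),
            "pa": np.clip(y[:-1] / radius, -1, 1),
            "r_next": r[1:],
            "dx": dx,
            "dy": dy,
            "stage": df["stage"].to_numpy()[:-1],
            "radius": radius,
        }
    )
    return out.loc[same].reset_index(drop=True)


def observations_from_frames(
    tracks: pd.DataFrame,
    meta: pd.DataFrame,
    apply_core_exclusion: bool = True,
) -> pd.DataFrame:
    """Per-track observation rows (vectorized): the flow-regression input.

    Matches :func:`track_summaries` on the same data.
    """
    samples = samples_from_frame(tracks, meta)
    if apply_core_exclusion:
        keep = (samples["r"] >= samples["radius"] / 2) & (
            samples["r_next"] >= samples["radius"] / 2
        )
        dropped = int((~keep).sum())
        if dropped:
            log.info("core exclusion dropped %d of %d samples", dropped, len(samples))
        samples = samples.loc[keep]
    obs = (
        samples.groupby(["embryo_id", "stage", "track_id"], as_index=False)
        .agg(aav=("aav", "median"), lr=("lr", "mean"), pa=("pa", "mean"))
    )
    group_of = meta.drop_duplicates("embryo_id").set_index("embryo_id")["group"]
    obs["group"] = obs["embryo_id"].map(group_of)
    return obs[["embryo_id", "track_id", "aav", "lr", "pa", "stage", "group"]]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def tracks_from_frame(df: pd.DataFrame) -> list[ParticleTrack]:
    """Build ParticleTrack objects from a tidy table.

    Expects columns embryo_id, track_id, frame, x_um, y_um (and optionally
    stage, in which case tracks are split per stage and track ids suffixed).
    """
    has_stage = "stage" in df.columns
    keys = ["embryo_id", "track_id"] + (["stage"] if has_stage else [])
    out = []
    for key, sub in df.groupby(keys, sort=False):
        sub = sub.sort_values("frame")
        out.append(
            ParticleTrack(
                embryo_id=str(key[0]),
                track_id=str(key[1]),
                frames=sub["frame"].to_numpy(),
                x=sub["x_um"].to_numpy(dtype=float),
                y=sub["y_um"].to_numpy(dtype=float),
                stage=int(key[2]) if has_stage else None,
            )
        )
    return out


def read_tracks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"embryo_id", "track_id", "frame", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    return df


def read_metadata_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"embryo_id", "stage", "group", "center_x", "center_y", "radius",
                "anterior_axis_deg", "dt_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    return df


def geometries_from_metadata(meta: pd.DataFrame) -> dict:
    """(embryo_id, stage) -> LROFrameGeometry from a metadata table."""
    out = {}
    for _, row in meta.iterrows():
        out[(str(row["embryo_id"]), int(row["stage"]))] = LROFrameGeometry(
            center=(float(row["center_x"]), float(row["center_y"])),
            radius=float(row["radius"]),
            anterior_axis_angle=np.deg2rad(float(row["anterior_axis_deg"])),
            stage=int(row["stage"]),
            dt=float(row["dt_s"]),
        )
    return out
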