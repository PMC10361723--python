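"""Synthetic particle tracks and outcome series with known ground truth.

The track generator emulates the counterclockwise rotational flow of the
zebrafish LRO: each particle performs a rigid rotation about the organizer
center at a local angular velocity

    omega(LR, PA) = omega0 + b_embryo + group offsets + grad_pa * PA
                    + grad_lr * LR + stage slope * (stage - time origin)

plus i.i.d. Gaussian positional jitter.  Rigid rotation is the minimal
process for which angular velocity is well defined and exactly
recoverable; the local omega is evaluated at the track's angular midpoint
so that per-track mean position (the downstream regressor) matches the
generative covariate to first order in the arc length.

Defaults mirror the fitted flow field of the fluid-extraction study:
baseline 0.25 rad/s, anterior-dominance gradient 0.16 rad/s per unit
normalized PA, negligible LR gradient, +0.021 rad/s per somite stage,
frames 0.2 s apart, stages 6-8.  The positional jitter SD (0.2 um) and
between-embryo SD (0.05 rad/s) are fixture choices; no noise model is
reported for the real tracking data.

The outcome generator draws per-embryo AAV trajectories from the stage
models, integrates the signal, and assigns situs by the 50%/90% threshold
rule, yielding series of normal/abnormal counts at known stage weights for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aav import InterventionScenario, sample_trajectories
from .kinematics import LROFrameGeometry, ParticleTrack
from .symmetry import ExperimentSeries, StageWeights

__all__ = [
    "GroupEffects",
    "SyntheticFlowConfig",
    "SyntheticOutcomeConfig",
    "generate_tracks",
    "generate_outcome_series",
    "stage_scan_scenarios",
]


def stage_scan_scenarios() -> tuple[InterventionScenario, ...]:
    """Single-stage interventions at 3-8 ss: the stage-scan design.

    Ablating the flow from each candidate stage in turn is the design that
    identifies per-stage sensitivity weights; without late-stage
    interventions the likelihood is flat along trades between early and
    late weights.
    """
    return tuple(InterventionScenario(f"{s}ss", (s,)) for s in range(3, 9))


@dataclass(frozen=True)
class GroupEffects:
    """Fixed-effect offsets of one experimental group relative to sham."""

    intercept: float = 0.0
    pa: float = 0.0
    lr: float = 0.0
    time: float = 0.0


@dataclass(frozen=True)
class SyntheticFlowConfig:
    """Generative parameters for synthetic LRO particle tracks."""

    omega0: float = 0.25
    grad_pa: float = 0.16
    grad_lr: float = 0.004
    time_slope: float = 0.021
    embryo_sd: float = 0.05
    jitter_sd: float = 0.2
    radius: float = 25.0
    n_tracks: int = 30
    n_frames: int = 6
    dt: float = 0.2
    stages: tuple[int, ...] = (6, 7, 8)
    time_origin: float = 6.0
    include_core: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if min(self.embryo_sd, self.jitter_sd) < 0:
            raise ValueError("SDs must be non-negative")


def _local_omega(cfg, eff, b, theta_mid, r_norm, time):
    lr = r_norm * np.cos(theta_mid)
    pa = r_norm * np.sin(theta_mid)
    return (
        cfg.omega0 + b + eff.intercept
        + (cfg.grad_pa + eff.pa) * pa
        + (cfg.grad_lr + eff.lr) * lr
        + (cfg.time_slope + eff.time) * time
    )


def generate_tracks(
    config: SyntheticFlowConfig,
    group_spec: dict[str, GroupEffects] | None = None,
    n_embryos: int = 20,
):
    """Simulate tracks for ``n_embryos`` embryos cycling through the groups.

    Returns ``(tracks, meta, truth)``: a tidy track table (embryo_id,
    track_id, stage, frame, x_um, y_um), a per-embryo/stage metadata table
    in the dialect the kinematics reader expects, and a ground-truth dict
    recording every drawn effect.
    """
    if group_spec is None:
        group_spec = {"Sham": GroupEffects()}
    labels = list(group_spec)
    root = np.random.SeedSequence(config.seed)
    embryo_seeds = root.spawn(n_embryos)

    track_rows, meta_rows = [], []
    truth = {"config": config, "embryos": {}}
    t_rel = np.arange(config.n_frames) * config.dt
    arc_half = (config.n_frames - 1) * config.dt / 2.0

    for i in range(n_embryos):
        rng = np.random.default_rng(embryo_seeds[i])
        embryo = f"E{i:03d}"
        group = labels[i % len(labels)]
        eff = group_spec[group]
        b = rng.normal(0.0, config.embryo_sd) if config.embryo_sd > 0 else 0.0
        truth["embryos"][embryo] = {"group": group, "intercept_re": float(b)}
        for stage in config.stages:
            time = stage - config.time_origin
            meta_rows.append(
                {
                    "embryo_id": embryo, "stage": stage, "group": group,
                    "center_x": 0.0, "center_y": 0.0, "radius": config.radius,
                    "anterior_axis_deg": 90.0, "dt_s": config.dt,
                }
            )
            # start radii on [R/2, R] so all points survive core exclusion;
            # include_core samples the full disc to exercise the filter
            lo = 0.02 if config.include_core else 0.5
            r = rng.uniform(lo * config.radius, config.radius, size=config.n_tracks)
            theta0 = rng.uniform(0.0, 2 * np.pi, size=config.n_tracks)
            for j in range(config.n_tracks):
                # fixed point for omega at the arc midpoint (gradients are small)
                omega = _local_omega(config, eff, b, theta0[j], r[j] / config.radius, time)
                for _ in range(3):
                    theta_mid = theta0[j] + omega * arc_half
                    omega = _local_omega(
                        config, eff, b, theta_mid, r[j] / config.radius, time
                    )
                theta_t = theta0[j] + omega * t_rel
                x = r[j] * np.cos(theta_t)
                y = r[j] * np.sin(theta_t)
                if config.jitter_sd > 0:
                    x = x + rng.normal(0, config.jitter_sd, size=config.n_frames)
                    y = y + rng.normal(0, config.jitter_sd, size=config.n_frames)
                tid = f"{embryo}_s{stage}_t{j:03d}"
                for k in range(config.n_frames):
                    track_rows.append(
                        {
                            "embryo_id": embryo, "track_id": tid, "stage": stage,
                            "frame": k, "x_um": x[k], "y_um": y[k],
                        }
                    )
                truth["embryos"][embryo].setdefault("tracks", {})[tid] = float(omega)

    return pd.DataFrame(track_rows), pd.DataFrame(meta_rows), truth


@dataclass(frozen=True)
class SyntheticOutcomeConfig:
    """Generative parameters for synthetic situs-outcome series."""

    true_weights: StageWeights = field(default_factory=StageWeights)
    scenarios: tuple[InterventionScenario, ...] = (
        InterventionScenario("sham"),
        InterventionScenario("3ss", (3,)),
        InterventionScenario("4ss", (4,)),
        InterventionScenario("5ss", (5,)),
        InterventionScenario("6ss", (6,)),
        InterventionScenario("5ss+7ss", (5, 7)),
    )
    n_per_series: int = 40
    n_virtual: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_series < 1 or self.n_virtual < 1:
            raise ValueError("n_per_series and n_virtual must be >= 1")


def generate_outcome_series(config: SyntheticOutcomeConfig) -> list[ExperimentSeries]:
    """Draw observed normal/abnormal counts for each scenario.

    Each embryo's AAV trajectory is sampled from the stage models, the
    signal S integrated against the true weights, and situs drawn normal
    with probability 0.9 (S above threshold) or 0.5 (otherwise).
    """
    w = config.true_weights
    root = np.random.SeedSequence(config.seed)
    out = []
    for scen, child in zip(config.scenarios, root.spawn(len(config.scenarios))):
        rng = np.random.default_rng(child)
        traj = sample_trajectories(scen, config.n_per_series, rng)
        S = traj @ w.as_array()
        p_normal = np.where(S > w.threshold, w.p_high, w.p_base)
        abnormal = int(np.sum(rng.random(config.n_per_series) >= p_normal))
        out.append(ExperimentSeries(scen, config.n_per_series, abnormal))
    return out
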