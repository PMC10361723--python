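import numpy as np
import pytest

import kupfferflow as kf


@pytest.fixture(scope="session")
def suction_groups():
    """Group effect offsets mirroring the fluid-extraction experiment."""
    return {
        "Sham": kf.GroupEffects(),
        "NoDefects": kf.GroupEffects(intercept=-0.03, lr=0.027, pa=0.034, time=0.027),
        "Defects": kf.GroupEffects(intercept=-0.13, lr=-0.003, pa=-0.041, time=0.013),
    }


@pytest.fixture()
def noiseless_config():
    """Deterministic rigid rotation: no jitter, no gradients, no random effects."""
    return kf.SyntheticFlowConfig(
        omega0=0.25, grad_pa=0.0, grad_lr=0.0, time_slope=0.0,
        embryo_sd=0.0, jitter_sd=0.0, n_tracks=10, n_frames=5, seed=7,
    )


@pytest.fixture(scope="session")
def rigid_rotation_samples():
    """Kinematic samples from a single exact rigid rotation at 0.3 rad/s."""
    omega, dt, r = 0.3, 0.2, 15.0
    t = np.arange(12) * dt
    theta = 0.4 + omega * t
    track = kf.ParticleTrack(
        "E0", "T0", frames=np.arange(12), x=r * np.cos(theta), y=r * np.sin(theta)
    )
    geom = kf.LROFrameGeometry(center=(0.0, 0.0), radius=20.0)
    return kf.to_polar(track, geom)
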