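"""Polar conversion, core exclusion, velocity decomposition, directionality."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kupfferflow as kf
from kupfferflow.kinematics import (
    _wrap_pi,
    observations_from_frames,
    samples_from_frame,
    sector_summary,
)


def make_track(points, embryo="E0", tid="T0"):
    pts = np.asarray(points, dtype=float)
    return kf.ParticleTrack(embryo, tid, np.arange(len(pts)), pts[:, 0], pts[:, 1])


GEOM = kf.LROFrameGeometry(center=(0.0, 0.0), radius=20.0)


class TestToPolar:
    def test_anterior_point_has_pa_one(self):
        # anterior axis at +x in image coordinates; a point along it is pure PA
        geom = kf.LROFrameGeometry(center=(0.0, 0.0), radius=20.0, anterior_axis_angle=0.0)
        s = kf.to_polar(make_track([(20.0, 0.0), (19.0, 0.0)]), geom)
        assert s["pa"].iloc[0] == pytest.approx(1.0)
        assert s["lr"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert s["theta"].iloc[0] == pytest.approx(np.pi / 2)

    def test_wrap_across_zero_gives_small_positive_dtheta(self):
        r = 15.0
        a0, a1 = 2 * np.pi - 0.1, 0.1
        s = kf.to_polar(
            make_track([(r * np.cos(a0), r * np.sin(a0)), (r * np.cos(a1), r * np.sin(a1))]),
            GEOM,
        )
        assert s["dtheta"].iloc[0] == pytest.approx(0.2)
        assert s["aav"].iloc[0] == pytest.approx(1.0)

    def test_rigid_rotation_recovers_omega(self, rigid_rotation_samples):
        assert np.allclose(rigid_rotation_samples["aav"], 0.3, atol=1e-9)

    def test_clockwise_step_negative(self):
        r = 15.0
        s = kf.to_polar(
            make_track([(r, 0.0), (r * np.cos(-0.05), r * np.sin(-0.05))]), GEOM
        )
        assert s["aav"].iloc[0] < 0

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            make_track([(1.0, 0.0)])

    def test_rotation_equivariance(self):
        """Rotating coordinates and the anterior axis together changes nothing."""
        rng = np.random.default_rng(5)
        pts = rng.uniform(-15, 15, size=(6, 2))
        base = kf.to_polar(make_track(pts), GEOM)
        phi = 1.234
        c, s = np.cos(phi), np.sin(phi)
        rot_pts = pts @ np.array([[c, -s], [s, c]]).T  # rotation by phi
        geom2 = kf.LROFrameGeometry(
            center=(0.0, 0.0), radius=20.0,
            anterior_axis_angle=GEOM.anterior_axis_angle + phi,
        )
        rot = kf.to_polar(make_track(rot_pts), geom2)
        for col in ["aav", "v_tan", "v_rad", "lr", "pa", "r"]:
            assert np.allclose(base[col], rot[col], atol=1e-9), col


class TestCoreExclusion:
    @pytest.mark.parametrize(
        "r_frac,kept", [(0.49, False), (0.5, True), (0.9, True)]
    )
    def test_half_radius_rule(self, r_frac, kept):
        r = r_frac * GEOM.radius
        s = kf.to_polar(
            make_track([(r, 0.0), (r * np.cos(0.05), r * np.sin(0.05))]), GEOM
        )
        out = kf.exclude_core(s, GEOM)
        assert (len(out) == 1) is kept

    def test_outer_set_unchanged(self, rigid_rotation_samples):
        out = kf.exclude_core(rigid_rotation_samples, GEOM)
        assert len(out) == len(rigid_rotation_samples)


class TestVelocities:
    def test_pure_rotation_components(self, rigid_rotation_samples):
        s = rigid_rotation_samples
        # a finite chord has an inward radial component of order r*omega^2*dt/2
        chord_bound = s["r"] * 0.3**2 * 0.2 / 2 + 1e-9
        assert (s["v_rad"].abs() <= chord_bound).all()
        assert np.allclose(s["v_tan"], s["r"] * 0.3, rtol=2e-3)

    def test_pure_radial_step(self):
        s = kf.to_polar(make_track([(10.0, 0.0), (12.0, 0.0)]), GEOM)
        assert s["v_tan"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert s["v_rad"].iloc[0] == pytest.approx(2.0 / 0.2)

    def test_pythagorean_identity_random_steps(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-18, 18, size=(30, 2))
        s = kf.to_polar(make_track(pts), GEOM)
        speed2 = (s["dx"] ** 2 + s["dy"] ** 2) / GEOM.dt**2
        assert np.allclose(s["v_tan"] ** 2 + s["v_rad"] ** 2, speed2, rtol=1e-9)

    def test_dt_must_be_positive(self):
        with pytest.raises(ValueError):
            kf.angular_velocity(pd.DataFrame({"dtheta": [0.1]}), dt=0.0)


class TestSectorSummary:
    def test_uniform_field_uniform_medians(self, rigid_rotation_samples):
        out = sector_summary(rigid_rotation_samples, n_sectors=8)
        filled = out.dropna(subset=["median"])
        assert np.allclose(filled["median"], 0.3, atol=1e-9)

    def test_empty_sector_is_nan(self):
        s = kf.to_polar(make_track([(15.0, 0.0), (15.0, 0.5)]), GEOM)
        out = sector_summary(s, n_sectors=8)
        assert out["median"].isna().sum() == 7

    def test_anterior_gradient_ordering(self):
        cfg = kf.SyntheticFlowConfig(
            grad_pa=0.16, jitter_sd=0.0, embryo_sd=0.0, time_slope=0.0,
            n_tracks=200, stages=(6,), seed=3,
        )
        tracks, meta, _ = kf.generate_tracks(cfg, n_embryos=1)
        samples = samples_from_frame(tracks, meta)
        out = sector_summary(samples, n_sectors=8)
        # sector 0 starts at anterior; sectors 0 and 7 flank the anterior pole,
        # sectors 3 and 4 the posterior pole
        anterior = np.nanmean([out["median"][0], out["median"][7]])
        posterior = np.nanmean([out["median"][3], out["median"][4]])
        assert anterior > posterior


class TestDirectionality:
    def test_tangential_step_reads_half_pi(self, rigid_rotation_samples):
        d = kf.directionality(rigid_rotation_samples)
        # rotation steps are tangential up to chord curvature
        assert np.allclose(d["direction"], np.pi / 2, atol=0.05)

    def test_outward_step_reads_zero(self):
        s = kf.to_polar(make_track([(10.0, 0.0), (12.0, 0.0)]), GEOM)
        d = kf.directionality(s)
        assert d["direction"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_displacement_skipped(self):
        s = kf.to_polar(make_track([(10.0, 0.0), (10.0, 0.0)]), GEOM)
        assert len(kf.directionality(s)) == 0

    def test_range_and_sectors(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-18, 18, size=(50, 2))
        d = kf.directionality(kf.to_polar(make_track(pts), GEOM))
        assert ((d["direction"] >= 0) & (d["direction"] < 2 * np.pi)).all()
        assert d["sector"].between(0, 11).all()

    def test_ks_identical_and_disjoint(self):
        a = np.linspace(0.1, 3.0, 100)
        stat, p = kf.compare_directionality(a, a)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        stat, _ = kf.compare_directionality(
            np.linspace(0.0, 3.0, 50), np.linspace(3.3, 6.2, 50)
        )
        assert stat == pytest.approx(1.0)
        with pytest.raises(ValueError):
            kf.compare_directionality([], a)


class TestTrackSummaries:
    def test_single_step_track_row_equals_step(self):
        tr = make_track([(15.0, 0.0), (15.0 * np.cos(0.05), 15.0 * np.sin(0.05))])
        obs = kf.track_summaries([tr], GEOM)
        s = kf.to_polar(tr, GEOM)
        assert obs["aav"].iloc[0] == pytest.approx(s["aav"].iloc[0])
        assert obs["lr"].iloc[0] == pytest.approx(s["lr"].iloc[0])

    def test_core_track_dropped(self):
        inner = make_track([(2.0, 0.0), (0.0, 2.0)])
        outer = make_track([(15.0, 0.0), (0.0, 15.0)], tid="T1")
        obs = kf.track_summaries([inner, outer], GEOM)
        assert list(obs["track_id"]) == ["T1"]

    def test_constant_field_constant_medians(self, noiseless_config):
        tracks, meta, _ = kf.generate_tracks(noiseless_config, n_embryos=2)
        obs = observations_from_frames(tracks, meta)
        assert np.allclose(obs["aav"], 0.25, atol=1e-9)

    def test_vectorized_matches_per_track(self):
        cfg = kf.SyntheticFlowConfig(n_tracks=8, seed=1, stages=(6, 7))
        tracks, meta, _ = kf.generate_tracks(cfg, n_embryos=3)
        from kupfferflow.kinematics import geometries_from_metadata

        slow = kf.track_summaries(
            kf.tracks_from_frame(tracks),
            geometries_from_metadata(meta),
            dict(zip(meta["embryo_id"], meta["group"])),
        )
        fast = observations_from_frames(tracks, meta)
        key = ["embryo_id", "stage", "track_id"]
        a = slow.sort_values(key).reset_index(drop=True)
        b = fast.sort_values(key).reset_index(drop=True)
        assert np.allclose(a[["aav", "lr", "pa"]], b[["aav", "lr", "pa"]])


@settings(derandomize=True, max_examples=200)
@given(st.floats(min_value=-50, max_value=50, allow_nan=False))
def test_wrap_pi_range_and_identity(angle):
    w = _wrap_pi(np.array([angle]))[0]
    assert -np.pi < w <= np.pi
    assert np.cos(w) == pytest.approx(np.cos(angle), abs=1e-9)
    assert np.sin(w) == pytest.approx(np.sin(angle), abs=1e-9)
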