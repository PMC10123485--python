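"""Boundaries, domain confinement, synthetic SPT, and domain reconstruction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from prebcr.landscape import (
    DomainMap,
    LandscapeError,
    SptTrajectorySet,
    confine_step,
    domain_recovery_score,
    generate_synthetic_domains,
    generate_synthetic_spt,
    reconstruct_domains,
    reflect_z,
    wrap_periodic,
)

BOX = (1.5, 1.5)


class TestBoundaries:
    @pytest.mark.parametrize("x,expected", [
        (1.6, 0.1), (-0.2, 1.3), (0.7, 0.7),
    ])
    def test_wrap_examples(self, x, expected):
        assert wrap_periodic((x, 0.5), BOX)[0] == pytest.approx(expected)

    @given(x=st.floats(-10, 10), y=st.floats(-10, 10))
    def test_wrap_lands_in_box_and_is_idempotent(self, x, y):
        p = wrap_periodic((x, y), BOX)
        assert 0 <= p[0] < 1.5 and 0 <= p[1] < 1.5
        assert np.allclose(wrap_periodic(p, BOX), p)

    @pytest.mark.parametrize("z,expected", [
        (-0.1, 0.1), (0.6, 0.4), (0.25, 0.25), (1.3, 0.3),
    ])
    def test_reflect_examples(self, z, expected):
        assert reflect_z(z, 0.5) == pytest.approx(expected)

    @given(z=st.floats(-0.49, 0.0))
    def test_reflect_preserves_overshoot_distance(self, z):
        # a small undershoot below the z=0 face mirrors to the same distance
        assert reflect_z(z, 0.5) == pytest.approx(abs(z))

    def test_nonfinite_rejected(self):
        with pytest.raises(LandscapeError):
            wrap_periodic((np.nan, 0.0), BOX)
        with pytest.raises(LandscapeError):
            reflect_z(np.inf, 0.5)


def _one_disk(exit_probability, radius=0.2, center=(0.75, 0.75)):
    theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    poly = np.column_stack([center[0] + radius * np.cos(theta),
                            center[1] + radius * np.sin(theta)])
    return DomainMap(contours=[poly], exit_probability=exit_probability)


class TestConfineStep:
    def test_zero_exit_probability_never_escapes(self, rng):
        dm = _one_disk(0.0)
        pos = np.array([0.75, 0.75])
        rms = np.sqrt(2 * 0.16 * 1e-3)
        for _ in range(3000):
            pos = confine_step(pos, rms * rng.standard_normal(2), dm, rng, BOX)
        assert dm.locate(pos[0], pos[1]) == 0

    def test_exit_probability_one_is_free_diffusion(self, rng):
        # statistically identical to free diffusion: MSD matches 4 D t
        dm = _one_disk(1.0)
        d, dt, n = 0.16, 1e-3, 400
        disp = []
        for _ in range(200):
            start = np.array([0.75, 0.75])
            pos = start.copy()
            for _ in range(n):
                j = np.sqrt(2 * d * dt) * rng.standard_normal(2)
                new = confine_step(pos, j, dm, rng, BOX)
                step_vec = new - pos
                step_vec -= np.round(step_vec / 1.5) * 1.5
                disp.append(step_vec)
                pos = new
        msd = np.mean(np.sum(np.square(disp), axis=1))
        expected = 4 * d * dt
        se = np.std(np.sum(np.square(disp), axis=1)) / np.sqrt(len(disp))
        assert abs(msd - expected) < 3 * se

    def test_start_outside_box_rejected(self, rng):
        with pytest.raises(LandscapeError):
            confine_step((2.0, 0.5), (0.0, 0.0), _one_disk(0.2), rng, BOX)


class TestSyntheticDomains:
    def test_empty_map(self):
        dm = generate_synthetic_domains(BOX, 0, (0.05, 0.1), seed=1)
        assert len(dm) == 0

    def test_deterministic_for_seed(self):
        a = generate_synthetic_domains(BOX, 5, (0.05, 0.1), seed=7)
        b = generate_synthetic_domains(BOX, 5, (0.05, 0.1), seed=7)
        for ca, cb in zip(a.contours, b.contours):
            assert np.array_equal(ca, cb)

    def test_ten_disjoint_inbox_polygons(self):
        dm = generate_synthetic_domains(BOX, 10, (0.05, 0.1), seed=3)
        assert len(dm) == 10
        dm.validate(box=BOX)  # simple, disjoint, inside the box

    def test_impossible_placement_raises(self):
        with pytest.raises(LandscapeError):
            generate_synthetic_domains(BOX, 60, (0.2, 0.2), seed=1,
                                       max_tries=200)

    def test_serialization_round_trip(self, tmp_path):
        dm = generate_synthetic_domains(BOX, 4, (0.05, 0.1), seed=9)
        path = tmp_path / "domains.txt"
        dm.save(path)
        back = DomainMap.load(path)
        assert back.exit_probability == dm.exit_probability
        assert len(back) == len(dm)
        for ca, cb in zip(dm.contours, back.contours):
            assert np.allclose(ca, cb, atol=1e-8)


class TestSyntheticSpt:
    def test_free_diffusion_msd_linear_in_lag(self):
        # large box so reflective-fold bias is far below statistical noise
        d_free = 0.16
        frame_dt = 0.01
        spt = generate_synthetic_spt(DomainMap(), d_free, n_tracks=60,
                                     frames=120, frame_dt=frame_dt, seed=5,
                                     box=(10.0, 10.0))
        for lag in (1, 2):
            sq = []
            for _, g in spt.frame.groupby("track_id"):
                xy = g[["x", "y"]].to_numpy()[::lag]  # non-overlapping jumps
                sq.append(np.sum((xy[1:] - xy[:-1]) ** 2, axis=1))
            sq = np.concatenate(sq)
            expected = 4 * d_free * lag * frame_dt
            se = sq.std() / np.sqrt(len(sq))
            assert abs(sq.mean() - expected) < 3 * se

    def test_deterministic_for_seed(self):
        dm = generate_synthetic_domains(BOX, 3, (0.1, 0.2), seed=2)
        a = generate_synthetic_spt(dm, 0.16, 5, 50, 0.02, seed=11)
        b = generate_synthetic_spt(dm, 0.16, 5, 50, 0.02, seed=11)
        assert a.frame.equals(b.frame)

    def test_zero_exit_probability_traps_tracks(self):
        dm = _one_disk(0.0, radius=0.25)
        spt = generate_synthetic_spt(dm, 0.16, n_tracks=40, frames=80,
                                     frame_dt=0.02, seed=13)
        started_inside = False
        for tid, g in spt.frame.groupby("track_id"):
            idx = g.index.to_numpy()
            if spt.in_domain[idx[0]] == 0:
                started_inside = True
                assert np.all(spt.in_domain[idx] == 0)
        assert started_inside  # fixture must actually exercise the trap

    def test_invalid_parameters(self):
        with pytest.raises(LandscapeError):
            generate_synthetic_spt(DomainMap(), 0.0, 1, 10, 0.02, seed=1)


class TestReconstruction:
    def test_planted_disks_recovered(self):
        truth = DomainMap(contours=[
            _one_disk(0.2, 0.15, (0.4, 0.4)).contours[0],
            _one_disk(0.2, 0.15, (1.1, 1.1)).contours[0],
        ], exit_probability=0.02)
        spt = generate_synthetic_spt(truth, 0.16, n_tracks=40, frames=200,
                                     frame_dt=0.1, seed=17)
        rec = reconstruct_domains(spt, L=0.1, slow_threshold=0.35,
                                  min_cluster_size=30)
        scores = domain_recovery_score(rec, truth)
        assert len(rec) >= 2
        assert all(s > 0.5 for s in scores)

    def test_free_diffusion_gives_near_chance_recovery(self):
        spt = generate_synthetic_spt(DomainMap(), 0.16, n_tracks=40,
                                     frames=200, frame_dt=0.1, seed=19)
        rec = reconstruct_domains(spt, L=0.1, slow_threshold=0.2,
                                  min_cluster_size=20)
        # no confinement: any contours that do appear are small and sparse
        probe = generate_synthetic_domains(BOX, 2, (0.2, 0.22), seed=23)
        scores = domain_recovery_score(rec, probe)
        assert all(s < 0.3 for s in scores)

    def test_stationary_track_does_not_crash(self):
        import pandas as pd
        df = pd.DataFrame({
            "track_id": [0] * 20,
            "t": np.arange(20) * 0.02,
            "x": [0.5] * 20,
            "y": [0.5] * 20,
        })
        rec = reconstruct_domains(SptTrajectorySet(frame=df), L=0.1,
                                  min_cluster_size=5)
        assert len(rec) == 0  # fewer than 3 distinct points: no contour

    def test_empty_trajectories_rejected(self):
        import pandas as pd
        df = pd.DataFrame({"track_id": [], "t": [], "x": [], "y": []})
        with pytest.raises(LandscapeError):
            reconstruct_domains(SptTrajectorySet(frame=df), L=0.1)
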