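"""Ends-ratio statistic, curvature maps, supercoil calling, apex finding."""

import numpy as np
import pytest

from curvafm.curvature import (
    apex_position,
    call_supercoils,
    curvature_map,
    ends_ratio,
    trajectory_ends_ratio,
)
from curvafm.sequence import GenomicSequence
from curvafm.synthetic import SequenceDesign, gen_phased_sequence, path_bent
from curvafm.trajectory import StepTable, build_trajectory


def brute_force_ends_ratio(points, w):
    """Independent re-computation from raw coordinates, one window at a
    time with explicit python loops."""
    out = []
    for s in range(len(points) - w + 1):
        contour = 0.0
        for i in range(s, s + w - 1):
            contour += float(np.linalg.norm(points[i + 1] - points[i]))
        chord = float(np.linalg.norm(points[s + w - 1] - points[s]))
        out.append(contour / chord)
    return np.array(out)


class TestEndsRatio:
    def test_collinear_points_give_exactly_one(self):
        pts = np.column_stack([np.arange(300) * 0.34, np.zeros(300), np.zeros(300)])
        prof = ends_ratio(pts, window_len=150)
        assert np.allclose(prof.values, 1.0, atol=1e-12)

    def test_semicircular_window_gives_half_pi(self):
        phi = np.linspace(0.0, np.pi, 401)
        arc = np.column_stack([np.cos(phi), np.sin(phi)])
        prof = ends_ratio(arc, window_len=401)
        assert len(prof) == 1
        assert prof.values[0] == pytest.approx(np.pi / 2, abs=1e-4)

    def test_matches_brute_force_oracle(self, step_table, random_sequence):
        traj = build_trajectory(random_sequence(n=400, seed=6), step_table)
        prof = ends_ratio(traj.points, window_len=150)
        expected = brute_force_ends_ratio(traj.points, 150)
        assert np.max(np.abs(prof.values - expected)) < 1e-9

    def test_rigid_motion_and_scale_invariance(self, step_table, random_sequence):
        from scipy.spatial.transform import Rotation

        traj = build_trajectory(random_sequence(n=300, seed=8), step_table)
        base = ends_ratio(traj.points, window_len=150).values
        rng = np.random.default_rng(0)
        for _ in range(5):
            R = Rotation.random(random_state=rng).as_matrix()
            moved = 3.7 * traj.points @ R.T + rng.normal(size=3)
            assert np.allclose(
                ends_ratio(moved, window_len=150).values, base, atol=1e-9
            )

    def test_larger_window_on_arc_never_less_curved(self):
        """Arc/chord of a circular arc grows with the subtended angle, so
        the maximum Ends ratio is monotone in window length."""
        phi = np.linspace(0.0, 1.5 * np.pi, 2000)
        arc = np.column_stack([np.cos(phi), np.sin(phi)])
        maxima = [
            ends_ratio(arc, window_len=w).values.max() for w in (100, 400, 800, 1500)
        ]
        assert all(b >= a for a, b in zip(maxima, maxima[1:]))

    def test_window_longer_than_molecule_warns_empty(self):
        pts = np.zeros((10, 2))
        pts[:, 0] = np.arange(10)
        with pytest.warns(UserWarning, match="longer than molecule"):
            prof = ends_ratio(pts, window_len=50)
        assert len(prof) == 0


class TestCurvatureMap:
    def test_canonical_row_equals_direct_profile_at_native_repeat(
        self, step_table, random_sequence
    ):
        seq = random_sequence(n=1000, seed=12)
        native = step_table.helical_repeat
        cmap = curvature_map(seq, step_table, pitches=np.array([native]))
        direct = trajectory_ends_ratio(build_trajectory(seq, step_table))
        assert np.allclose(cmap.values[0], direct.values, atol=1e-12)

    def test_deterministic_and_order_independent(self, step_table, random_sequence):
        seq = random_sequence(n=400, seed=13)
        p1 = np.array([6.0, 9.0, 12.0])
        m1 = curvature_map(seq, step_table, pitches=p1)
        m2 = curvature_map(seq, step_table, pitches=p1[::-1])
        assert np.allclose(m1.values, m2.values[::-1])

    def test_phased_tracts_peak_at_their_period(self, step_table):
        seq, truth = gen_phased_sequence(
            SequenceDesign(length=600, phasing_period=8.0,
                           tract_region=(150, 450), seed=1)
        )
        cmap = curvature_map(seq, step_table)
        spectrum = cmap.values.max(axis=1)
        assert cmap.pitches[int(np.argmax(spectrum))] <= 9.0


class TestSupercoilCalls:
    def test_straight_map_gives_no_calls(self, step_table, random_sequence):
        straight = StepTable(
            roll={d: 0.0 for d in step_table.roll},
            tilt={d: 0.0 for d in step_table.tilt},
            twist=dict(step_table.twist),
        )
        cmap = curvature_map(random_sequence(n=400, seed=2), straight)
        assert call_supercoils(cmap) == []

    @pytest.mark.parametrize(
        "period,hand", [(8.0, "left"), (13.0, "right")]
    )
    def test_phased_supercoil_handedness(self, step_table, period, hand):
        seq, truth = gen_phased_sequence(
            SequenceDesign(length=600, phasing_period=period,
                           tract_region=(150, 450), seed=3)
        )
        calls = call_supercoils(curvature_map(seq, step_table))
        region = truth["region"]
        in_region = [
            c for c in calls
            if c.interval[1] >= region[0] and c.interval[0] <= region[1]
        ]
        assert len(in_region) == 1
        assert in_region[0].handedness == hand
        assert abs(in_region[0].peak_pitch - period) <= 0.5

    def test_canonical_phasing_is_planar_not_supercoiled(self, step_table):
        seq, _ = gen_phased_sequence(
            SequenceDesign(length=600, phasing_period=10.5,
                           tract_region=(150, 450), seed=3)
        )
        cmap = curvature_map(seq, step_table)
        assert call_supercoils(cmap) == []
        # but the planar curvature is strong at the canonical pitch itself
        assert cmap.profile(10.5).values.max() > 1.3


class TestApex:
    def test_unique_maximum(self):
        from curvafm.curvature import EndsRatioProfile

        prof = EndsRatioProfile(
            150, 1, np.array([-60, -50, -40, -30]), np.array([1.0, 1.1, 1.4, 1.2])
        )
        assert apex_position(prof) == -40

    def test_flat_profile_ties_break_three_prime(self):
        from curvafm.curvature import EndsRatioProfile

        prof = EndsRatioProfile(150, 1, np.array([-10, 5, 20]), np.ones(3))
        assert apex_position(prof) == 20

    def test_moving_bend_shifts_apex(self):
        """Shifting a planted bend by +30 bp moves the profile apex by
        +30 within a tenth of the window."""
        bp_per_point = 0.5 / 0.36  # paths are sampled every 0.5 nm
        a1 = ends_ratio(path_bent(600, 250.0), window_len=150,
                        bp_per_point=bp_per_point)
        a2 = ends_ratio(path_bent(600, 280.0), window_len=150,
                        bp_per_point=bp_per_point)
        shift = (apex_position(a2) - apex_position(a1)) * bp_per_point
        assert shift == pytest.approx(30.0, abs=15.0)
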