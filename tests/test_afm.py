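"""AFM image quantification: flattening, tracing, orientation, positioning."""

import numpy as np
import pytest

from curvafm.afm import (
    AFMImage,
    detect_loop,
    flatten,
    map_nucleosome,
    map_protein,
    measure_nucleosome,
    model_height_profile,
    orient_molecule,
    skeletonize_molecule,
    trace_ends_ratio,
    track_apex,
)
from curvafm.synthetic import (
    ImageDesign,
    MoleculeSpec,
    center_path,
    path_arc,
    path_rod,
    path_teardrop,
    render_afm_image,
)


def _rot(deg):
    th = np.radians(deg)
    return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])


def _render(path, shape=(192, 192), noise=0.3, seed=0, **spec_kw):
    design = ImageDesign(
        shape=shape, pixel_size=2.0,
        molecules=[MoleculeSpec(path_nm=path, **spec_kw)],
        noise_sd=noise, seed=seed,
    )
    return render_afm_image(design)


class TestFlatten:
    def test_pure_per_line_quadratic_removed_exactly(self):
        x = np.arange(128.0)
        img = AFMImage(
            np.array([0.4 + 0.01 * x + 3e-4 * (x - 40) ** 2 for _ in range(64)]),
            pixel_size=2.0,
        )
        flat = flatten(img)
        assert np.abs(flat.heights).max() < 1e-9

    def test_rod_height_preserved_over_background(self):
        x = np.arange(192.0)
        bg = np.array([0.2 + 5e-4 * (x - 90) ** 2 for _ in range(192)])
        path = center_path(path_rod(200.0, 30.0), (192, 192), 2.0)
        img, _ = _render(path, noise=0.0)
        combined = AFMImage(img.heights + bg, 2.0)
        flat = flatten(combined)
        assert flat.heights.max() == pytest.approx(img.heights.max(), rel=0.02)

    def test_second_pass_removes_almost_nothing(self):
        rng = np.random.default_rng(5)
        img = AFMImage(rng.normal(0.1, 0.3, (96, 96)), 2.0)
        once = flatten(img)
        twice = flatten(once)
        residual = twice.heights - once.heights
        assert np.sqrt((residual**2).mean()) < 0.1 * 0.3

    def test_order_validated(self):
        with pytest.raises(ValueError):
            flatten(AFMImage(np.zeros((8, 8)), 1.0), polynomial_order=5)


class TestSkeletonize:
    def test_rod_contour_within_five_percent(self):
        path = center_path(path_rod(200.0, 25.0), (192, 192), 2.0)
        img, _ = _render(path, seed=3)
        traces = skeletonize_molecule(img)
        assert len(traces) == 1
        assert traces[0].contour_length == pytest.approx(200.0, rel=0.05)
        assert traces[0].bp_length * 0.36 == pytest.approx(
            traces[0].contour_length
        )

    def test_two_disjoint_molecules_two_traces(self):
        p1 = path_rod(120.0, 15.0) + np.array([40.0, 60.0])
        p2 = path_rod(150.0, 100.0) + np.array([240.0, 120.0])
        design = ImageDesign(
            shape=(192, 192), pixel_size=2.0,
            molecules=[MoleculeSpec(path_nm=p1), MoleculeSpec(path_nm=p2)],
            noise_sd=0.3, seed=4,
        )
        img, _ = render_afm_image(design)
        assert len(skeletonize_molecule(img)) == 2

    def test_blank_noise_image_gives_nothing(self):
        rng = np.random.default_rng(6)
        img = AFMImage(rng.normal(0.0, 0.3, (128, 128)), 2.0)
        assert skeletonize_molecule(img) == []


class TestOrientation:
    def test_exact_profile_orients_forward(self, random_sequence):
        seq = random_sequence(n=500, seed=30)
        model = model_height_profile(seq)
        from curvafm.afm import MoleculeTrace

        path = np.column_stack([np.arange(500) * 0.36, np.zeros(500)])
        trace = MoleculeTrace(path=path, heights=model.copy(), pixel_size=2.0)
        res = orient_molecule(trace, model, smooth_bp=0)
        assert res.oriented and res.direction == 1
        assert res.r_forward == pytest.approx(1.0, abs=1e-6)

    def test_reversed_profile_orients_backward(self, random_sequence):
        seq = random_sequence(n=500, seed=30)
        model = model_height_profile(seq)
        from curvafm.afm import MoleculeTrace

        path = np.column_stack([np.arange(500) * 0.36, np.zeros(500)])
        trace = MoleculeTrace(path=path, heights=model[::-1].copy(), pixel_size=2.0)
        res = orient_molecule(trace, model, smooth_bp=0)
        assert res.oriented and res.direction == -1

    def test_length_mismatch_refused_with_reason(self, random_sequence):
        seq = random_sequence(n=500, seed=30)
        model = model_height_profile(seq)
        from curvafm.afm import MoleculeTrace

        path = np.column_stack([np.arange(300) * 0.36, np.zeros(300)])
        trace = MoleculeTrace(path=path, heights=np.ones(300), pixel_size=2.0)
        res = orient_molecule(trace, model)
        assert not res.oriented
        assert "tolerance" in res.reason


class TestNucleosome:
    def test_dyad_arithmetic_matches_printed_formula(self):
        call = map_nucleosome(898, 500, 250)
        assert call.extra["Lc"] == pytest.approx(148)
        assert call.position == pytest.approx(574)

    def test_equal_arms_put_dyad_at_center(self):
        call = map_nucleosome(898, 300, 300)
        assert call.position == pytest.approx(449)

    def test_dyad_consistency_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            L = float(rng.uniform(400, 1200))
            lc = float(rng.uniform(50, 200))
            lp = float(rng.uniform((L - lc) / 2, L - lc))
            lm = L - lc - lp
            call = map_nucleosome(L, lp, lm)
            assert lp + call.extra["Lc"] / 2 + (lm + call.extra["Lc"] / 2) == (
                pytest.approx(L)
            )

    def test_no_wrapped_segment_rejected(self):
        with pytest.raises(ValueError, match="Lc"):
            map_nucleosome(500, 300, 250)
        with pytest.raises(ValueError):
            map_nucleosome(500, 100, 200)

    def test_rendered_nucleosome_recovered(self):
        L, d_true = 898, 600.0
        contour = L * 0.36
        path = center_path(path_arc(contour, radius_nm=contour / 2.2), (192, 192), 2.0)
        img, _ = _render(path, noise=0.0, particles=[(d_true, 2.2, 12.0)])
        call = measure_nucleosome(img, L_bp=L)
        assert call.position == pytest.approx(d_true, abs=10)
        assert call.height > 1.5


class TestProtein:
    def _trace(self, particles, seed=0, noise=0.0):
        L = 563
        contour = L * 0.36
        path = center_path(
            path_arc(contour, radius_nm=contour / 1.8) @ _rot(20).T, (160, 160), 2.0
        )
        img, _ = _render(path, shape=(160, 160), noise=noise, seed=seed,
                         particles=particles)
        traces = skeletonize_molecule(img)
        assert len(traces) == 1
        return traces[0]

    def test_bare_dna_gives_no_call(self):
        assert map_protein(self._trace([], noise=0.25)) is None

    def test_bump_position_recovered(self):
        trace = self._trace([(430.0, 1.8, 8.0)])
        call = map_protein(trace)
        assert call is not None
        pos = call.position
        if abs(pos - (trace.bp_length - 430)) < abs(pos - 430):
            pos = trace.bp_length - pos
        assert pos == pytest.approx(430, abs=15)

    def test_two_bumps_most_prominent_wins_and_verbose_lists_both(self):
        trace = self._trace([(180.0, 1.6, 8.0), (430.0, 2.2, 8.0)])
        best = map_protein(trace)
        both = map_protein(trace, verbose=True)
        assert len(both) >= 2
        assert best.height == pytest.approx(max(c.height for c in both))


class TestLoop:
    def _loop_image(self, seed=0, noise=0.25, height_profile=None):
        path, truth = path_teardrop(total_bp=900, loop_bp=260, crossing_bp=350)
        path = center_path(path @ _rot(25).T, (192, 192), 2.0)
        img, _ = _render(path, noise=noise, seed=seed,
                         height_profile=height_profile)
        return img, truth, path

    def test_loop_length_and_midpoint(self):
        img, truth, path = self._loop_image(noise=0.0)
        trace = skeletonize_molecule(img)[0]
        if np.linalg.norm(trace.path[0] - path[0]) > np.linalg.norm(
            trace.path[-1] - path[0]
        ):
            trace = trace.reversed()
        call, crossing = detect_loop(trace, img)
        assert call.extra["loop_bp"] == pytest.approx(260, rel=0.10)
        assert call.position == pytest.approx(truth["loop_mid_bp"], abs=20)
        # the summit must exceed the single-strand height; its absolute
        # value is resolution-limited at 2 nm/px
        branch = np.median(trace.heights)
        assert branch < crossing.summit_height <= 1.7

    def test_over_strand_follows_branch_heights(self):
        profile = np.where(np.arange(900) < 450, 1.4, 0.9)
        img, truth, path = self._loop_image(noise=0.2, height_profile=profile)
        trace = skeletonize_molecule(img)[0]
        if np.linalg.norm(trace.path[0] - path[0]) > np.linalg.norm(
            trace.path[-1] - path[0]
        ):
            trace = trace.reversed()
        result = detect_loop(trace, img)
        assert result is not None
        _, crossing = result
        assert crossing.over_strand == "first"

    def test_bent_but_uncrossed_molecule_gives_no_call(self):
        contour = 700 * 0.36
        path = center_path(path_arc(contour, radius_nm=contour / 2.0), (192, 192), 2.0)
        img, _ = _render(path, noise=0.25, seed=9)
        trace = skeletonize_molecule(img)[0]
        assert detect_loop(trace, img) is None


class TestTraceEndsRatio:
    def test_arc_profile_matches_closed_form(self):
        radius = 40.0
        contour = 600 * 0.36
        path = center_path(path_arc(contour, radius_nm=radius), (192, 192), 2.0)
        img, _ = _render(path, noise=0.0)
        trace = skeletonize_molecule(img)[0]
        prof = trace_ends_ratio(trace, window_len=150)
        phi = 150 * 0.36 / radius
        expected = (phi / 2) / np.sin(phi / 2)
        interior = prof.values[20:-20]
        assert np.median(interior) == pytest.approx(expected, rel=0.03)


class TestTrackApex:
    def _frame(self, bend_bp, seed, t):
        from curvafm.synthetic import path_bent

        path = center_path(path_bent(800, bend_bp, bend_angle_deg=80) @ _rot(35).T,
                           (192, 192), 2.0)
        design = ImageDesign(
            shape=(192, 192), pixel_size=2.0,
            molecules=[MoleculeSpec(path_nm=path)], noise_sd=0.25, seed=seed,
            frame_time=t,
        )
        img, _ = render_afm_image(design)
        trace = skeletonize_molecule(img)[0]
        if np.linalg.norm(trace.path[0] - path[0]) > np.linalg.norm(
            trace.path[-1] - path[0]
        ):
            trace = trace.reversed()
        trace.oriented = True
        return trace

    def test_identical_frames_no_displacement(self):
        t = self._frame(250.0, seed=1, t=0.0)
        t2 = self._frame(250.0, seed=1, t=37.0)
        track = track_apex([t, t2])
        assert track.displacement_bp == pytest.approx(0.0, abs=1e-9)
        assert track.times == [0.0, 37.0]

    def test_moving_bend_recovered(self):
        frames = [
            self._frame(250.0 + 30 * k, seed=40 + k, t=37.0 * k) for k in range(4)
        ]
        track = track_apex(frames)
        assert track.times == [0.0, 37.0, 74.0, 111.0]
        assert track.displacement_bp == pytest.approx(90.0, abs=15.0)

    def test_unoriented_frames_dropped_with_warning(self):
        a = self._frame(250.0, seed=1, t=0.0)
        b = self._frame(250.0, seed=2, t=37.0)
        c = self._frame(250.0, seed=3, t=74.0)
        b.oriented = False
        with pytest.warns(UserWarning, match="not oriented"):
            track = track_apex([a, b, c])
        assert len(track.apexes_bp) == 2
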