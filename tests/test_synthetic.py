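"""Generators: phased sequences, worm-like chains, image rendering."""

import numpy as np
import pytest

from curvafm.afm import measure_nucleosome
from curvafm.synthetic import (
    ImageDesign,
    MoleculeSpec,
    SequenceDesign,
    center_path,
    estimate_persistence,
    gen_control_sequence,
    gen_phased_sequence,
    gen_promoter_like,
    path_arc,
    path_rod,
    render_afm_image,
    sample_open_wlc,
    sample_wlc_2d,
)


class TestSequenceGenerators:
    def test_same_seed_same_sequence(self):
        a = gen_control_sequence(300, seed=42)
        b = gen_control_sequence(300, seed=42)
        assert a.bases == b.bases

    def test_gc_zero_is_all_at(self):
        seq = gen_control_sequence(200, gc=0.0, seed=1)
        assert set(seq.bases) <= {"A", "T"}

    def test_phased_tracts_planted_at_period(self):
        seq, truth = gen_phased_sequence(
            SequenceDesign(length=400, phasing_period=10.5,
                           tract_region=(100, 300), seed=7)
        )
        starts = [seq.to_offset(s) for s in truth["tract_starts"]]
        gaps = np.diff(starts)
        assert np.mean(gaps) == pytest.approx(10.5, abs=0.1)
        for s in starts:
            assert seq.bases[s : s + truth["tract_len"]] == "A" * truth["tract_len"]

    def test_region_too_small_rejected(self):
        with pytest.raises(ValueError):
            gen_phased_sequence(
                SequenceDesign(length=100, phasing_period=10.5,
                               tract_region=(40, 50))
            )

    def test_promoter_like_architecture(self):
        from curvafm.sequence import find_at_tracts

        seq, truth = gen_promoter_like(seed=0)
        region = seq.subsequence(*truth["region"])
        tracts = find_at_tracts(region, min_len=5)
        assert len(tracts) == 3
        assert max(t.length for t in tracts) == 19


class TestWormLikeChain:
    def test_infinite_stiffness_is_straight(self):
        pts = sample_wlc_2d(500, persistence_nm=1e9, seed=0)
        chord = np.linalg.norm(pts[-1] - pts[0])
        contour = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert chord == pytest.approx(contour, rel=1e-6)

    def test_tangent_correlation_decay(self):
        """<cos dtheta(s)> follows exp(-s / (2 P)) in the 2D convention."""
        P = 50.0
        chains = [sample_wlc_2d(1290, P, seed=s) for s in range(300)]
        corrs = []
        for pts in chains:
            d = np.diff(pts, axis=0)
            theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
            corrs.append(
                [np.mean(np.cos(theta[k:] - theta[:-k])) for k in (50, 150, 250)]
            )
        mean_corr = np.mean(corrs, axis=0)
        for k, c in zip((50, 150, 250), mean_corr):
            expected = np.exp(-k * 0.36 / (2 * P))
            assert c == pytest.approx(expected, rel=0.10)

    def test_persistence_recovery(self):
        rng = np.random.default_rng(3)
        chains = [sample_wlc_2d(1290, 50.0, seed=rng) for _ in range(200)]
        assert estimate_persistence(chains) == pytest.approx(50.0, abs=5.0)

    def test_open_chain_avoids_itself(self):
        from scipy.spatial import cKDTree

        pts = sample_open_wlc(1290, 50.0, seed=0, min_separation_nm=7.0)
        tree = cKDTree(pts)
        pairs = tree.query_pairs(7.0 - 1e-9, output_type="ndarray")
        if len(pairs):
            assert (np.abs(pairs[:, 0] - pairs[:, 1]) * 0.36 < 20 * 0.36 * 2.5).all()


class TestRendering:
    def test_noiseless_rod_height(self):
        path = center_path(path_rod(150.0, 30.0), (160, 160), 2.0)
        img, truth = render_afm_image(
            ImageDesign(shape=(160, 160), pixel_size=2.0,
                        molecules=[MoleculeSpec(path_nm=path)], noise_sd=0.0)
        )
        assert img.heights.max() == pytest.approx(1.0, abs=0.01)
        assert truth["molecules"][0]["contour_nm"] == pytest.approx(150.0, abs=0.5)

    def test_crossing_summit_capped_in_range(self):
        p1 = center_path(path_rod(150.0, 20.0), (160, 160), 2.0)
        p2 = center_path(path_rod(150.0, 110.0), (160, 160), 2.0)
        img, _ = render_afm_image(
            ImageDesign(shape=(160, 160), pixel_size=2.0,
                        molecules=[MoleculeSpec(path_nm=p1), MoleculeSpec(path_nm=p2)],
                        noise_sd=0.0)
        )
        assert 1.5 <= img.heights.max() <= 1.6 + 1e-9

    def test_molecule_exceeding_frame_rejected(self):
        path = path_rod(400.0, 0.0)  # longer than a 320 nm frame
        with pytest.raises(ValueError, match="frame"):
            render_afm_image(
                ImageDesign(shape=(160, 160), pixel_size=2.0,
                            molecules=[MoleculeSpec(path_nm=path)])
            )

    def test_seeded_noise_is_reproducible(self):
        path = center_path(path_rod(100.0, 45.0), (128, 128), 2.0)
        design = ImageDesign(shape=(128, 128), pixel_size=2.0,
                             molecules=[MoleculeSpec(path_nm=path)], seed=11)
        a, _ = render_afm_image(design)
        b, _ = render_afm_image(design)
        assert np.array_equal(a.heights, b.heights)

    def test_end_to_end_nucleosome_recovery(self):
        """Render a mononucleosome at a planned dyad and recover it through
        the full image-analysis pipeline."""
        L, dyad = 898, 600.0
        contour = L * 0.36
        path = center_path(path_arc(contour, radius_nm=contour / 2.2),
                           (192, 192), 2.0)
        img, _ = render_afm_image(
            ImageDesign(shape=(192, 192), pixel_size=2.0,
                        molecules=[MoleculeSpec(path_nm=path,
                                                particles=[(dyad, 2.2, 12.0)])],
                        noise_sd=0.0)
        )
        call = measure_nucleosome(img, L_bp=L)
        assert call.position == pytest.approx(dyad, abs=10)
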