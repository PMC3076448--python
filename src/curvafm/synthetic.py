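"""Synthetic sequences and AFM-like images with known ground truth.

Sequence generators produce promoter-like fragments whose phased A/T-tracts
encode planar curvature (phasing period at the canonical helical repeat) or
intrinsic supercoils (period below/above it), plus i.i.d. control fragments.
Image generators render worm-like-chain or designed paths as ridges of
double-helix height (0.8-1.2 nm), with optional bound-particle bumps,
self-crossings (summit = sum of ridges capped at 1.6 nm), Gaussian tip
broadening, and additive height noise (SD ~0.3 nm) -- the features the
image-analysis stages rely on, with every planned position recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .afm import NM_PER_BP, AFMImage
from .sequence import GenomicSequence

#: default persistence length of B-DNA, nm
PERSISTENCE_NM = 50.0


# ------------------------------------------------------------- sequences

@dataclass
class SequenceDesign:
    """Plan for a phased A/T-tract fragment."""

    length: int = 600
    tract_len: int = 5
    phasing_period: float = 10.5
    tract_region: tuple[int, int] = (150, 450)   # 0-based offsets, half-open
    gc: float = 0.5
    origin: int = 1
    seed: int = 0


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=n, p=p)


def _cap_w_runs(bases: np.ndarray, max_run: int, rng: np.random.Generator) -> None:
    """Break accidental A/T runs longer than ``max_run`` in place."""
    run = 0
    for i, b in enumerate(bases):
        if b in "AT":
            run += 1
            if run > max_run:
                bases[i] = rng.choice(np.array(list("GC")))
                run = 0
        else:
            run = 0


def gen_phased_sequence(
    design: SequenceDesign,
) -> tuple[GenomicSequence, dict]:
    """A-tracts of ``tract_len`` placed every ``phasing_period`` bp inside
    ``tract_region`` on a seeded random background.

    Background W-runs are capped below ``tract_len`` so the planned tracts
    are the only phased signal.  Returns the sequence and a ground-truth
    annotation (planned period, region, tract starts).
    """
    rng = np.random.default_rng(design.seed)
    lo, hi = design.tract_region
    if hi - lo < design.phasing_period + design.tract_len:
        raise ValueError("tract_region too small for one phasing period")
    if hi > design.length:
        raise ValueError("tract_region outside sequence")
    bases = _random_bases(rng, design.length, design.gc)
    _cap_w_runs(bases, max_run=design.tract_len - 1, rng=rng)
    starts = []
    k = 0
    while True:
        s = lo + int(round(k * design.phasing_period))
        if s + design.tract_len > hi:
            break
        bases[s : s + design.tract_len] = "A"
        # guard: keep tracts maximal by forcing S flanks
        if s > 0 and bases[s - 1] in "AT":
            bases[s - 1] = "G"
        e = s + design.tract_len
        if e < design.length and bases[e] in "AT":
            bases[e] = "C"
        starts.append(s)
        k += 1
    seq = GenomicSequence("".join(bases), origin=design.origin)
    truth = {
        "period": design.phasing_period,
        "region": (seq.to_promoter(lo), seq.to_promoter(hi - 1)),
        "tract_starts": [seq.to_promoter(s) for s in starts],
        "tract_len": design.tract_len,
    }
    return seq, truth


def gen_control_sequence(length: int = 976, gc: float = 0.5, seed: int = 0) -> GenomicSequence:
    """i.i.d. bases at the given GC fraction (plasmid-like control)."""
    rng = np.random.default_rng(seed)
    return GenomicSequence("".join(_random_bases(rng, length, gc)), origin=1)


def gen_promoter_like(
    seed: int = 0,
    origin: int = -300,
    length: int = 500,
    tract_lens: tuple[int, int, int] = (10, 13, 19),
    spacers: tuple[int, int] = (6, 7),
    region_start: int = -137,
) -> tuple[GenomicSequence, dict]:
    """A fragment emulating the regulatory-region architecture the package
    targets: three A/T-tracts separated by short G/C spacers (6 and 7 bp),
    the longest tract last, embedded in a background free of long W-runs.

    Synthetic stand-in for the real promoter accession (which the user may
    supply as FASTA instead).
    """
    rng = np.random.default_rng(seed)
    bases = _random_bases(rng, length, 0.55)
    _cap_w_runs(bases, max_run=4, rng=rng)
    seq0 = GenomicSequence("".join(bases), origin=origin)
    off = seq0.to_offset(region_start)
    pos = off
    tract_spans = []
    for i, tl in enumerate(tract_lens):
        w = rng.choice(np.array(list("AT")), size=tl, p=[0.7, 0.3])
        bases[pos : pos + tl] = w
        tract_spans.append((pos, pos + tl))
        pos += tl
        if i < len(spacers):
            bases[pos : pos + spacers[i]] = rng.choice(
                np.array(list("GC")), size=spacers[i]
            )
            pos += spacers[i]
    # strict maximality: S flanks around the whole block
    if off > 0:
        bases[off - 1] = "G"
    if pos < length:
        bases[pos] = "C"
    seq = GenomicSequence("".join(bases), origin=origin)
    truth = {
        "tract_lens": list(tract_lens),
        "spacers": list(spacers),
        "region": (region_start, seq.to_promoter(pos - 1)),
    }
    return seq, truth


# ------------------------------------------------------------- WLC paths

def sample_wlc_2d(
    length_bp: int,
    persistence_nm: float = PERSISTENCE_NM,
    seed: int | np.random.Generator = 0,
    segment_nm: float = NM_PER_BP,
) -> np.ndarray:
    """Discrete 2D-equilibrated worm-like chain.

    Successive segment headings differ by Gaussian angles of variance
    (segment length / persistence length) -- the 2D convention, under which
    the tangent autocorrelation decays as exp(-s / (2 * persistence)).
    Returns (length_bp, 2) points in nm; persistence -> infinity gives a
    straight path.
    """
    if persistence_nm <= 0:
        raise ValueError("persistence_nm must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_seg = length_bp - 1
    sigma = np.sqrt(segment_nm / persistence_nm)
    theta = np.cumsum(np.concatenate([[0.0], rng.normal(0.0, sigma, n_seg - 1)]))
    steps = segment_nm * np.column_stack([np.cos(theta), np.sin(theta)])
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


def sample_open_wlc(
    length_bp: int,
    persistence_nm: float = PERSISTENCE_NM,
    seed: int = 0,
    min_separation_nm: float = 7.0,
    segment_nm: float = NM_PER_BP,
    max_restarts: int = 50,
) -> np.ndarray:
    """A self-avoiding worm-like chain (surface excluded volume).

    Grows the chain step by step, resampling a bend angle when the new
    point would come within ``min_separation_nm`` of a contour-distant
    part of the chain -- the well-spread 2D-equilibrated molecules one
    selects for tracing and orientation.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(segment_nm / persistence_nm)
    cell = min_separation_nm
    excl = int(np.ceil(2.5 * min_separation_nm / segment_nm))  # neighbors along contour
    for _ in range(max_restarts):
        pts = np.empty((length_bp, 2))
        pts[0] = 0.0
        theta = 0.0
        grid: dict[tuple[int, int], list[int]] = {(0, 0): [0]}
        ok = True
        for i in range(1, length_bp):
            for _try in range(30):
                cand_theta = theta + (rng.normal(0.0, sigma) if i > 1 else 0.0)
                cand = pts[i - 1] + segment_nm * np.array(
                    [np.cos(cand_theta), np.sin(cand_theta)]
                )
                cx, cy = int(cand[0] // cell), int(cand[1] // cell)
                clash = False
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for j in grid.get((cx + dx, cy + dy), ()):
                            if i - j > excl and (
                                np.hypot(*(cand - pts[j])) < min_separation_nm
                            ):
                                clash = True
                                break
                        if clash:
                            break
                    if clash:
                        break
                if not clash:
                    break
            else:
                ok = False
                break
            pts[i] = cand
            theta = cand_theta
            grid.setdefault((cx, cy), []).append(i)
        if ok:
            return pts
    raise RuntimeError("could not grow an open conformation; relax parameters")


def estimate_persistence(
    chains: list[np.ndarray], max_lag_nm: float = 100.0
) -> float:
    """Persistence length from the ensemble tangent autocorrelation.

    Fits -log<cos(theta(s) - theta(0))> = s / (2P) by least squares over
    separations up to ``max_lag_nm`` (2D convention)."""
    seg_len = float(np.linalg.norm(chains[0][1] - chains[0][0]))
    max_lag = int(max_lag_nm / seg_len)
    corrs = []
    for pts in chains:
        d = np.diff(pts, axis=0)
        theta = np.arctan2(d[:, 1], d[:, 0])
        theta = np.unwrap(theta)
        corrs.append(
            [np.mean(np.cos(theta[k:] - theta[:-k])) for k in range(1, max_lag + 1)]
        )
    c = np.mean(corrs, axis=0)
    lags = np.arange(1, max_lag + 1) * seg_len
    ok = c > 0.2
    slope = np.polyfit(lags[ok], -np.log(c[ok]), 1)[0]
    return 1.0 / (2.0 * slope)


# --------------------------------------------------------- designed paths

def path_rod(length_nm: float, angle_deg: float = 0.0, spacing_nm: float = 0.5) -> np.ndarray:
    n = max(2, int(round(length_nm / spacing_nm)) + 1)
    s = np.linspace(0.0, length_nm, n)
    a = np.radians(angle_deg)
    return np.column_stack([s * np.cos(a), s * np.sin(a)])


def path_arc(length_nm: float, radius_nm: float, spacing_nm: float = 0.5) -> np.ndarray:
    """Circular arc of the given contour length and radius."""
    n = max(2, int(round(length_nm / spacing_nm)) + 1)
    phi = np.linspace(0.0, length_nm / radius_nm, n)
    return np.column_stack([radius_nm * np.sin(phi), radius_nm * (1 - np.cos(phi))])


def path_bent(
    total_bp: float,
    bend_center_bp: float,
    bend_angle_deg: float = 70.0,
    bend_span_bp: float = 100.0,
    spacing_nm: float = 0.5,
) -> np.ndarray:
    """A molecule with one localized circular bend, straight elsewhere.

    The bend (total turn ``bend_angle_deg`` spread over ``bend_span_bp``)
    is centered at contour position ``bend_center_bp``; the curvature
    apex of the traced molecule should recover that position.
    """
    total_nm = total_bp * NM_PER_BP
    span_nm = bend_span_bp * NM_PER_BP
    c_nm = bend_center_bp * NM_PER_BP
    if not span_nm / 2 < c_nm < total_nm - span_nm / 2:
        raise ValueError("bend does not fit inside the molecule")
    n = max(4, int(round(total_nm / spacing_nm)))
    s = np.linspace(0.0, total_nm, n + 1)
    kappa = np.zeros_like(s)
    inside = np.abs(s - c_nm) <= span_nm / 2
    kappa[inside] = np.radians(bend_angle_deg) / span_nm
    theta = np.concatenate([[0.0], np.cumsum(0.5 * (kappa[1:] + kappa[:-1]) * np.diff(s))])
    steps = np.diff(s)[:, None] * np.column_stack([np.cos(theta[1:]), np.sin(theta[1:])])
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


_TEARDROP_LOOP_FACTOR = 2.0 + 1.5 * np.pi  # stub + 270 deg arc + stub, per R


def path_teardrop(
    total_bp: float,
    loop_bp: float,
    crossing_bp: float,
    spacing_nm: float = 0.5,
) -> tuple[np.ndarray, dict]:
    """A self-crossing path: straight tail in, a loop closed by a
    270-degree arc between two straight stubs, straight tail out.

    The two passages cross at 90 degrees and no two non-consecutive
    strand stretches run parallel within tip-broadening distance, so the
    crossing thins to a clean X.  The first passage sits at contour
    position ``crossing_bp``; the second at ``crossing_bp + loop_bp``.
    Returns the path (nm) and ground truth with the passage positions and
    the loop midpoint.
    """
    total_nm = total_bp * NM_PER_BP
    loop_nm = loop_bp * NM_PER_BP
    s1_nm = crossing_bp * NM_PER_BP
    s2_nm = s1_nm + loop_nm
    if s1_nm < 15 or total_nm < s2_nm + 15:
        raise ValueError("crossing too close to a molecule end for this loop")
    R = loop_nm / _TEARDROP_LOOP_FACTOR

    # incoming tail heading +y, ending at the crossing C = (0, 0)
    n_in = max(2, int(round(s1_nm / spacing_nm)))
    t_in = np.linspace(-s1_nm, 0.0, n_in + 1)
    pts = [np.column_stack([np.zeros_like(t_in), t_in])]
    # loop: stub C->(0,R), 270 deg arc about (-R, R), stub (-R,0)->C
    n_s = max(2, int(round(R / spacing_nm)))
    t = np.linspace(0.0, R, n_s + 1)[1:]
    pts.append(np.column_stack([np.zeros_like(t), t]))
    n_arc = max(8, int(round(1.5 * np.pi * R / spacing_nm)))
    phi = np.linspace(0.0, 1.5 * np.pi, n_arc + 1)[1:]
    pts.append(np.column_stack([-R + R * np.cos(phi), R + R * np.sin(phi)]))
    t = np.linspace(-R, 0.0, n_s + 1)[1:]
    pts.append(np.column_stack([t, np.zeros_like(t)]))
    # outgoing tail heading +x
    out_len = total_nm - s2_nm
    n_out = max(2, int(round(out_len / spacing_nm)))
    t = np.linspace(0.0, out_len, n_out + 1)[1:]
    pts.append(np.column_stack([t, np.zeros_like(t)]))
    path = np.vstack(pts)
    truth = {
        "crossing_bp": (crossing_bp, crossing_bp + loop_bp),
        "loop_bp": loop_bp,
        "loop_mid_bp": crossing_bp + loop_bp / 2.0,
        "crossing_xy_nm": (0.0, 0.0),
    }
    return path, truth


# ------------------------------------------------------------- rendering

@dataclass
class MoleculeSpec:
    """One molecule to render: its path and height (possibly modulated)."""

    path_nm: np.ndarray                       # (n, 2), frame coordinates
    height_nm: float = 1.0
    height_profile: np.ndarray | None = None  # absolute nm per path point
    particles: list[tuple[float, float, float]] = field(default_factory=list)
    # particles: (position_bp along path, height nm, width FWHM nm)


@dataclass
class ImageDesign:
    """Plan for one synthetic AFM frame.

    ``tip_radius_nm`` models tip broadening as a parabolic-tip grey
    dilation: strands widen to the tip contact width but keep their
    height, as in real topography (0 disables it).
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 2.0              # nm/px
    molecules: list[MoleculeSpec] = field(default_factory=list)
    noise_sd: float = 0.3                # nm
    tip_radius_nm: float = 8.0           # parabolic tip broadening
    ridge_sigma_nm: float = 1.0          # ridge cross-section (sigma)
    crossing_cap_nm: float = 1.6         # summit cap where strands overlap
    frame_time: float | None = None
    seed: int = 0


def _resample_path(path: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    grid = np.arange(0.0, cum[-1] + spacing / 2, spacing)
    x = np.interp(grid, cum, path[:, 0])
    y = np.interp(grid, cum, path[:, 1])
    return np.column_stack([x, y]), grid


def _render_molecule(
    spec: MoleculeSpec, design: ImageDesign
) -> np.ndarray:
    """Ridge layer for one molecule; contributions of contour-distinct
    passages add (capped later), along-strand neighbors do not."""
    H, W = design.shape
    px = design.pixel_size
    sigma = design.ridge_sigma_nm
    reach = 3.0 * sigma
    margin = reach + design.tip_radius_nm + 2.0
    samples, s_nm = _resample_path(spec.path_nm, spacing=0.5)
    if (samples.min() < margin or samples[:, 0].max() > W * px - margin
            or samples[:, 1].max() > H * px - margin):
        raise ValueError("molecule path exceeds the frame (margin included)")
    if spec.height_profile is not None:
        prof = np.asarray(spec.height_profile, dtype=float)
        pos = np.linspace(0.0, s_nm[-1], len(prof))
        h_s = np.interp(s_nm, pos, prof)
    else:
        h_s = np.full(len(samples), spec.height_nm)

    tree = cKDTree(samples)
    cols = np.round(samples[:, 0] / px).astype(int)
    rows = np.round(samples[:, 1] / px).astype(int)
    mask = np.zeros(design.shape, dtype=bool)
    mask[np.clip(rows, 0, H - 1), np.clip(cols, 0, W - 1)] = True
    r_px = int(np.ceil(reach / px)) + 1
    mask = ndimage.binary_dilation(mask, iterations=r_px)
    rr, cc = np.nonzero(mask)
    centers = np.column_stack([cc * px, rr * px])

    layer = np.zeros(design.shape)
    gap_nm = 4.0 * sigma  # contour separation that defines a distinct passage
    gap_idx = int(np.ceil(gap_nm / 0.5))
    neighbor_lists = tree.query_ball_point(centers, reach)
    for (r, c), neigh in zip(zip(rr, cc), neighbor_lists):
        if not neigh:
            continue
        idx = np.sort(np.asarray(neigh))
        breaks = np.nonzero(np.diff(idx) > gap_idx)[0]
        total = 0.0
        point = np.array([c * px, r * px])
        for grp in np.split(idx, breaks + 1):
            d2 = np.sum((samples[grp] - point) ** 2, axis=1)
            j = int(np.argmin(d2))
            total += h_s[grp[j]] * np.exp(-d2[j] / (2 * sigma**2))
        layer[r, c] = total
    return layer


def _particle_layer(spec: MoleculeSpec, design: ImageDesign) -> np.ndarray:
    H, W = design.shape
    px = design.pixel_size
    layer = np.zeros(design.shape)
    if not spec.particles:
        return layer
    samples, s_nm = _resample_path(spec.path_nm, spacing=0.5)
    yy, xx = np.mgrid[0:H, 0:W]
    for pos_bp, height, width in spec.particles:
        s = pos_bp * NM_PER_BP
        j = int(np.argmin(np.abs(s_nm - s)))
        cx, cy = samples[j]
        sig = width / 2.355
        bump = height * np.exp(
            -((xx * px - cx) ** 2 + (yy * px - cy) ** 2) / (2 * sig**2)
        )
        layer = np.maximum(layer, bump)
    return layer


def render_afm_image(design: ImageDesign) -> tuple[AFMImage, dict]:
    """Rasterize an :class:`ImageDesign` into a noisy height image.

    Ridges have Gaussian cross-section; overlapping passages (crossings)
    add and are capped at ``crossing_cap_nm`` (the summit range seen over
    supercoil crossings); particles are Gaussian bumps combined by
    maximum; parabolic-tip dilation and additive Gaussian noise follow.
    Returns the image and the ground-truth plan.
    """
    rng = np.random.default_rng(design.seed)
    ridges = np.zeros(design.shape)
    particles = np.zeros(design.shape)
    truth_mols = []
    for spec in design.molecules:
        ridges = ridges + _render_molecule(spec, design)
        particles = np.maximum(particles, _particle_layer(spec, design))
        seg = np.linalg.norm(np.diff(spec.path_nm, axis=0), axis=1).sum()
        truth_mols.append(
            {
                "contour_nm": float(seg),
                "contour_bp": float(seg / NM_PER_BP),
                "particles": list(spec.particles),
            }
        )
    img = np.minimum(ridges, design.crossing_cap_nm)
    img = np.maximum(img, particles)
    if design.tip_radius_nm > 0:
        img = _tip_dilate(img, design.tip_radius_nm, design.pixel_size)
    if design.noise_sd > 0:
        img = img + rng.normal(0.0, design.noise_sd, design.shape)
    return (
        AFMImage(img, design.pixel_size, design.frame_time),
        {"molecules": truth_mols, "seed": design.seed},
    )


def _tip_dilate(img: np.ndarray, tip_radius_nm: float, px: float) -> np.ndarray:
    """Parabolic-tip contact broadening: grey dilation with the inverted
    tip apex, which widens features without lowering their summits."""
    r_px = max(1, int(np.ceil(np.sqrt(2 * tip_radius_nm * img.max() + 1e-9) / px)))
    ax = np.arange(-r_px, r_px + 1) * px
    d2 = ax[None, :] ** 2 + ax[:, None] ** 2
    tip = -d2 / (2.0 * tip_radius_nm)
    return ndimage.grey_dilation(img, structure=tip)


def center_path(
    path: np.ndarray, shape: tuple[int, int], pixel_size: float
) -> np.ndarray:
    """Translate a path so its bounding box is centered in the frame."""
    H, W = shape
    mid_frame = np.array([W * pixel_size / 2.0, H * pixel_size / 2.0])
    lo, hi = path.min(axis=0), path.max(axis=0)
    return path - (lo + hi) / 2.0 + mid_frame
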