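"""Quantification of AFM height images of single DNA molecules.

Pipeline: line-by-line background flattening, thresholding, morphological
thinning to one-pixel paths, graph-based ordering (with crossing/loop
resolution), sub-pixel refinement, and length/height measurement.  Lengths
in nm convert to bp with the B-DNA rise on mica, 0.36 nm/bp.  Oriented
molecules can then be scored for nucleosome dyads (arm-length arithmetic),
bound proteins (height maxima), loops (self-crossings), and time-lapse
curvature-apex movement.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.stats import pearsonr
from skimage import morphology

from . import _skeleton
from .curvature import EndsRatioProfile, apex_position, ends_ratio
from .sequence import GenomicSequence
from .trajectory import StepTable, default_step_table

#: nm of contour per base pair for molecules adsorbed on mica
NM_PER_BP = 0.36

#: default height threshold above the flattened background, nm
#: (between the noise level ~0.3 nm and the double-helix height 0.8-1.2 nm)
HEIGHT_THRESHOLD_NM = 0.5


@dataclass
class AFMImage:
    """A height raster in nm with its physical pixel size."""

    heights: np.ndarray
    pixel_size: float                 # nm per pixel
    frame_time: float | None = None   # seconds, for time-lapse series

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights contain non-finite values")


def read_image(path: str | Path, pixel_size: float | None = None) -> AFMImage:
    """Read a TIFF or whitespace-delimited text raster; a sidecar
    ``<name>.json`` may provide ``pixel_size_nm`` and ``frame_time_s``."""
    path = Path(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        heights = tifffile.imread(str(path)).astype(float)
    else:
        heights = np.loadtxt(str(path))
    px = pixel_size or meta.get("pixel_size_nm")
    if px is None:
        raise ValueError("pixel size not given and no sidecar JSON found")
    return AFMImage(heights, float(px), meta.get("frame_time_s"))


@dataclass
class MoleculeTrace:
    """Ordered sub-pixel path along one molecule, with per-point heights."""

    path: np.ndarray                   # (n, 2) nm, (x, y)
    heights: np.ndarray                # nm per point
    pixel_size: float = 1.0
    loop_span: tuple[int, int] | None = None
    frame_time: float | None = None
    oriented: bool = False
    origin_end: str = "unknown"        # "5prime", "3prime", "unknown"

    @property
    def contour_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.path, axis=0), axis=1).sum())

    @property
    def bp_length(self) -> float:
        return self.contour_length / NM_PER_BP

    def arclength(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.path, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def reversed(self) -> "MoleculeTrace":
        n = len(self.path)
        span = self.loop_span
        if span is not None:
            span = (n - 1 - span[1], n - 1 - span[0])
        return MoleculeTrace(
            path=self.path[::-1].copy(),
            heights=self.heights[::-1].copy(),
            pixel_size=self.pixel_size,
            loop_span=span,
            frame_time=self.frame_time,
            oriented=self.oriented,
            origin_end=self.origin_end,
        )

    def resample_per_bp(self) -> tuple[np.ndarray, np.ndarray]:
        """Path points and heights at 1-bp (0.36 nm) arc-length spacing."""
        cum = self.arclength()
        m = int(np.floor(cum[-1] / NM_PER_BP)) + 1
        grid = np.arange(m) * NM_PER_BP
        x = np.interp(grid, cum, self.path[:, 0])
        y = np.interp(grid, cum, self.path[:, 1])
        h = np.interp(grid, cum, self.heights)
        return np.column_stack([x, y]), h

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("index\tx\ty\theight\n")
            for i, ((x, y), h) in enumerate(zip(self.path, self.heights)):
                fh.write(f"{i}\t{x:.4f}\t{y:.4f}\t{h:.4f}\n")


@dataclass
class PlacementCall:
    """A positioned object on an oriented molecule, in bp along the path."""

    kind: str                          # nucleosome_dyad | protein | loop_midpoint
    position: float
    height: float | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class CrossingCall:
    """A self-crossing: where, which passage is on top, summit height."""

    location: tuple[float, float]      # nm
    over_strand: str                   # "first" or "second" contour passage
    summit_height: float


# ----------------------------------------------------------------- flattening

def flatten(
    image: AFMImage,
    polynomial_order: int = 2,
    mask_threshold: float | None = None,
    iterations: int = 4,
    exclude: np.ndarray | None = None,
) -> AFMImage:
    """Line-by-line polynomial background subtraction.

    Each scan line is fitted iteratively: after every fit, pixels well
    above it (the molecules) are excluded and the line refitted, so the
    background estimate is not pulled up by DNA even where a molecule
    runs along the scan direction.  By default the exclusion level adapts
    to the line's own noise (from the lower quantiles, which molecules --
    being strictly positive relief -- leave clean); ``mask_threshold``
    fixes it in nm instead.  ``exclude`` marks known molecule pixels to
    drop from every fit (see :func:`flatten_two_pass`).  A line whose fit
    would be left with too few pixels falls back to fitting all of them.
    """
    if polynomial_order > 3:
        raise ValueError("polynomial_order must be <= 3")
    h = image.heights
    out = np.empty_like(h)
    x = np.arange(h.shape[1], dtype=float)
    pfit = np.polynomial.polynomial.polyfit
    pval = np.polynomial.polynomial.polyval
    for i, line in enumerate(h):
        allowed = np.ones(len(line), bool) if exclude is None else ~exclude[i]
        if allowed.sum() <= polynomial_order + 1:
            allowed = np.ones(len(line), bool)
        ref = line[allowed]
        q05, q25 = np.quantile(ref, [0.05, 0.25])
        sigma0 = max((q25 - q05) / 0.9704, 1e-3)
        cut = 2.0 * sigma0 if mask_threshold is None else mask_threshold
        bg = np.full_like(line, q25 + 0.674 * sigma0)
        for _ in range(iterations):
            resid = line - bg
            keep = allowed & (resid <= cut)
            if keep.sum() <= polynomial_order + 1:
                break
            coef = pfit(x[keep], line[keep], polynomial_order)
            new_bg = pval(x, coef)
            if np.abs(new_bg - bg).max() < 1e-6:
                bg = new_bg
                break
            bg = new_bg
        out[i] = line - bg
    return AFMImage(out, image.pixel_size, image.frame_time)


def flatten_two_pass(
    image: AFMImage,
    polynomial_order: int = 2,
    height_threshold: float = HEIGHT_THRESHOLD_NM,
) -> AFMImage:
    """Flatten, threshold a 2D molecule mask, then flatten again with the
    molecules excluded from every line fit.

    A dim strand running along the scan direction survives this where a
    single pass would partially subtract it: the first pass only needs to
    reveal the strand well enough to mask it.
    """
    first = flatten(image, polynomial_order)
    smooth = ndimage.gaussian_filter(first.heights, 2.0 / image.pixel_size)
    molecules = ndimage.binary_dilation(
        smooth > 0.5 * height_threshold, iterations=2
    )
    return flatten(image, polynomial_order, exclude=molecules)


# -------------------------------------------------------------- skeleton trace

def _sample(heights: np.ndarray, rc: np.ndarray) -> np.ndarray:
    """Bilinear height lookup at fractional (row, col) positions."""
    return ndimage.map_coordinates(heights, rc.T, order=1, mode="nearest")


def _tangents(path_rc: np.ndarray) -> np.ndarray:
    d = np.gradient(path_rc, axis=0)
    n = np.linalg.norm(d, axis=1, keepdims=True)
    return d / np.maximum(n, 1e-12)


def _refine_subpixel(
    path_rc: np.ndarray,
    heights: np.ndarray,
    reach_px: float = 2.0,
    freeze: np.ndarray | None = None,
) -> np.ndarray:
    """Shift each point to the height-weighted centroid along the local
    normal, recovering the sub-pixel ridge axis.

    ``freeze`` marks points to leave in place (near a crossing the normal
    samples catch the other strand and would drag the path sideways).
    """
    t = _tangents(path_rc)
    normal = np.column_stack([-t[:, 1], t[:, 0]])
    offsets = np.linspace(-reach_px, reach_px, 9)
    samples = np.stack(
        [_sample(heights, path_rc + o * normal) for o in offsets], axis=1
    )
    w = np.clip(samples, 0.0, None) ** 2
    wsum = w.sum(axis=1)
    shift = np.where(wsum > 1e-9, (w * offsets).sum(axis=1) / np.maximum(wsum, 1e-9), 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    if freeze is not None:
        shift = np.where(freeze, 0.0, shift)
    return path_rc + shift[:, None] * normal


def _smooth_path(
    path_rc: np.ndarray, sigma: float = 1.0, freeze: np.ndarray | None = None
) -> np.ndarray:
    if len(path_rc) < 5:
        return path_rc
    out = np.column_stack(
        [
            ndimage.gaussian_filter1d(path_rc[:, 0], sigma, mode="nearest"),
            ndimage.gaussian_filter1d(path_rc[:, 1], sigma, mode="nearest"),
        ]
    )
    out[0], out[-1] = path_rc[0], path_rc[-1]
    if freeze is not None:
        out[freeze] = path_rc[freeze]
    return out


def _extend_end(
    path_rc: np.ndarray,
    heights: np.ndarray,
    threshold: float,
    at_start: bool,
    max_px: float = 4.0,
    step_px: float = 0.25,
) -> np.ndarray:
    """Walk a path end outward along its tangent while the image stays
    above threshold (thinning erodes molecule tips by ~the ridge width)."""
    pts = path_rc[::-1] if at_start else path_rc
    k = min(6, len(pts) - 1)
    direction = pts[-1] - pts[-1 - k]
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        return path_rc
    direction = direction / norm
    added = []
    pos = pts[-1].copy()
    travelled = 0.0
    while travelled < max_px:
        cand = pos + step_px * direction
        if _sample(heights, cand[None, :])[0] <= threshold:
            break
        if not (0 <= cand[0] <= heights.shape[0] - 1
                and 0 <= cand[1] <= heights.shape[1] - 1):
            break
        added.append(cand.copy())
        pos = cand
        travelled += step_px
    if not added:
        return path_rc
    added = np.array(added)
    if at_start:
        return np.vstack([added[::-1], path_rc])
    return np.vstack([path_rc, added])


def skeletonize_molecule(
    image: AFMImage,
    height_threshold: float = HEIGHT_THRESHOLD_NM,
    min_contour_nm: float = 30.0,
    flatten_first: bool = True,
    prune_px: int = 5,
    smooth_nm: float = 2.0,
    path_smooth_sigma: float = 1.5,
    end_extension_px: float = 0.0,
) -> list[MoleculeTrace]:
    """Trace every molecule in an image.

    Flattens, lightly smooths (``smooth_nm``), thresholds with hysteresis
    (a noisy ridge must not fragment where the noise dips), thins each
    connected region to a one-pixel path, prunes branch whiskers, orders
    the pixels (resolving self-crossings into a loop span), refines the
    axis to sub-pixel precision by height-weighted centroids, and smooths
    the final path (``path_smooth_sigma``, in points) to keep noise jitter
    from inflating contour lengths.  ``end_extension_px`` walks eroded
    tips outward along the tangent -- useful for imagery without tip
    broadening, off by default since broadened strands already reach past
    the true molecule ends.  Traces shorter than ``min_contour_nm`` are
    discarded; an empty image yields an empty list.
    """
    from skimage import filters

    img = flatten_two_pass(image, height_threshold=height_threshold) if flatten_first else image
    px = img.pixel_size
    h = ndimage.gaussian_filter(img.heights, smooth_nm / px)
    # heights are measured on a lightly smoothed copy: the heavier mask
    # smoothing would attenuate particle bumps and height modulation
    h_meas = ndimage.gaussian_filter(img.heights, 1.0 / px)
    mask = filters.apply_hysteresis_threshold(
        h, 0.5 * height_threshold, 0.8 * height_threshold
    )
    mask = _drop_small(mask, min_px=max(8, int(10 / px)))
    if not mask.any():
        return []
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3)))
    traces: list[MoleculeTrace] = []
    for lab in range(1, n_lab + 1):
        region = labels == lab
        skel = morphology.skeletonize(region)
        if skel.sum() < 4:
            continue
        try:
            path_rc, loop_span = _skeleton.trace_component(skel, prune_px=prune_px)
        except ValueError:
            continue
        freeze = None
        if loop_span is not None:
            # points within the crossing blob: refinement and smoothing
            # there would cut both passages short
            idx = np.arange(len(path_rc))
            r_cross = max(3, int(round(6.0 / px)))
            freeze = (np.abs(idx - loop_span[0]) <= r_cross) | (
                np.abs(idx - loop_span[1]) <= r_cross
            )
        path_rc = _smooth_path(path_rc, sigma=1.0, freeze=freeze)
        path_rc = _refine_subpixel(path_rc, h, freeze=freeze)
        path_rc = _smooth_path(path_rc, sigma=path_smooth_sigma, freeze=freeze)
        if end_extension_px > 0:
            path_rc = _extend_end(path_rc, h, height_threshold,
                                  at_start=False, max_px=end_extension_px)
            n_after_tail = len(path_rc)
            path_rc = _extend_end(path_rc, h, height_threshold,
                                  at_start=True, max_px=end_extension_px)
            prepended = len(path_rc) - n_after_tail
            if loop_span is not None and prepended:
                loop_span = (loop_span[0] + prepended, loop_span[1] + prepended)
        trace = _build_trace(path_rc, h_meas, px, loop_span, img.frame_time)
        if trace.contour_length >= min_contour_nm:
            traces.append(trace)
    traces.sort(key=lambda t: -t.contour_length)
    return traces


def _drop_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = counts[1:] >= min_px
    return keep[labels]


def _build_trace(
    path_rc: np.ndarray,
    heights: np.ndarray,
    px: float,
    loop_span: tuple[int, int] | None,
    frame_time: float | None,
) -> MoleculeTrace:
    h = _sample(heights, path_rc)
    path_nm = np.column_stack([path_rc[:, 1] * px, path_rc[:, 0] * px])
    return MoleculeTrace(
        path=path_nm,
        heights=h,
        pixel_size=px,
        loop_span=loop_span,
        frame_time=frame_time,
    )


# -------------------------------------------------------------- orientation

@dataclass
class OrientationResult:
    direction: int                     # +1 forward, -1 reverse, 0 undecided
    r_forward: float
    r_reverse: float
    oriented: bool
    reason: str = ""

    @property
    def r_best(self) -> float:
        return max(abs(self.r_forward), abs(self.r_reverse))


def model_height_profile(
    seq: GenomicSequence,
    table: StepTable | None = None,
    smooth_bp: float = 10.0,
) -> np.ndarray:
    """Per-bp model signal used to orient measured molecules: the local
    helical pitch (360/twist) along the sequence, smoothed and z-scored.
    AFM height modulation along a molecule correlates with this pattern."""
    if table is None:
        table = default_step_table()
    bases = seq.bases
    step_pitch = np.array(
        [360.0 / table.twist[bases[i : i + 2]] for i in range(len(bases) - 1)]
    )
    per_bp = np.concatenate([step_pitch[:1], (step_pitch[1:] + step_pitch[:-1]) / 2,
                             step_pitch[-1:]])
    sm = ndimage.gaussian_filter1d(per_bp, smooth_bp, mode="nearest")
    sd = sm.std()
    return (sm - sm.mean()) / (sd if sd > 1e-12 else 1.0)


def orient_molecule(
    trace: MoleculeTrace,
    model_profile: np.ndarray,
    margin: float = 0.1,
    length_tol: float = 0.15,
    smooth_bp: float = 10.0,
) -> OrientationResult:
    """Compare the measured height profile with the sequence model in both
    orientations; accept only if the correlation gap exceeds ``margin``.

    The measured profile is resampled to the model length and smoothed
    over ``smooth_bp`` to match the model's bandwidth.  The trace must be
    within ``length_tol`` of the model length (in bp).
    """
    m = len(model_profile)
    if abs(trace.bp_length - m) > length_tol * m:
        return OrientationResult(
            0, np.nan, np.nan, False,
            reason=f"length {trace.bp_length:.0f} bp vs model {m} bp "
                   f"exceeds {length_tol:.0%} tolerance",
        )
    _, h = trace.resample_per_bp()
    if smooth_bp > 0 and len(h) > 8:
        h = ndimage.gaussian_filter1d(h, smooth_bp, mode="nearest")
    pos = np.linspace(0, 1, len(h))
    target = np.linspace(0, 1, m)
    meas = np.interp(target, pos, h)
    if np.std(meas) < 1e-12:
        return OrientationResult(0, np.nan, np.nan, False, reason="flat profile")
    r_fwd = float(pearsonr(meas, model_profile)[0])
    r_rev = float(pearsonr(meas[::-1], model_profile)[0])
    direction = 1 if abs(r_fwd) >= abs(r_rev) else -1
    gap = abs(abs(r_fwd) - abs(r_rev))
    oriented = gap >= margin
    return OrientationResult(
        direction if oriented else 0, r_fwd, r_rev, oriented,
        reason="" if oriented else f"correlation gap {gap:.3f} < margin {margin}",
    )


# -------------------------------------------------------------- positioning

def map_nucleosome(L: float, L_plus: float, L_minus: float) -> PlacementCall:
    """Dyad position from total length and the two free-arm lengths (bp).

    The wrapped length is Lc = L - (L+ + L-); the dyad sits Lc/2 beyond the
    long arm, i.e. at L+ + Lc/2 measured from the long-arm end.  The same
    point is L - (L- + Lc/2) from the other end.
    """
    if not (L_plus >= L_minus >= 0):
        raise ValueError("need L_plus >= L_minus >= 0")
    Lc = L - (L_plus + L_minus)
    if Lc <= 0:
        raise ValueError(f"no wrapped segment: Lc = {Lc:.1f} <= 0")
    dyad = L_plus + Lc / 2.0
    assert abs((L - (L_minus + Lc / 2.0)) - dyad) < 1e-9
    return PlacementCall(
        kind="nucleosome_dyad", position=dyad, extra={"Lc": Lc, "L": L}
    )


def measure_nucleosome(
    image: AFMImage,
    L_bp: float,
    particle_threshold: float = 1.5,
    height_threshold: float = HEIGHT_THRESHOLD_NM,
    mask_margin_nm: float = 8.0,
) -> PlacementCall:
    """Locate a nucleosome on a single-molecule image and position its dyad.

    The particle is the largest region above ``particle_threshold``; the
    two free DNA arms are traced after masking the particle plus a margin
    (wide enough that the particle's skirt cannot tether the arm tips),
    and the dyad follows from :func:`map_nucleosome` with the known total
    length ``L_bp``.  Position is measured from the long-arm end.  The
    margin is widened once if the arms come out implausibly long.
    """
    img = flatten_two_pass(image, height_threshold=height_threshold)
    h = img.heights
    px = img.pixel_size
    blob = h > particle_threshold
    if not blob.any():
        raise ValueError("no particle above threshold")
    labels, _ = ndimage.label(blob)
    sizes = ndimage.sum_labels(blob, labels, range(1, labels.max() + 1))
    blob = labels == (1 + int(np.argmax(sizes)))
    last_error = None
    for margin in (mask_margin_nm, 1.5 * mask_margin_nm):
        grown = morphology.dilation(
            blob, morphology.disk(max(1, int(round(margin / px))))
        )
        masked = h.copy()
        masked[grown] = 0.0
        arms = skeletonize_molecule(
            AFMImage(masked, px), height_threshold=height_threshold,
            min_contour_nm=8.0, flatten_first=False,
        )
        if len(arms) < 2:
            last_error = f"expected 2 free arms, traced {len(arms)}"
            continue
        l1, l2 = arms[0].bp_length, arms[1].bp_length
        try:
            call = map_nucleosome(L_bp, max(l1, l2), min(l1, l2))
        except ValueError as exc:
            last_error = str(exc)
            continue
        call.height = float(h[blob].max())
        return call
    raise ValueError(last_error or "nucleosome arms not measurable")


def map_protein(
    trace: MoleculeTrace,
    margin: float = 0.4,
    smooth_points: float = 1.0,
    verbose: bool = False,
):
    """Bound protein as the most prominent height maximum along the path.

    Peaks must exceed the DNA baseline (median height) by ``margin`` nm.
    Returns ``None`` (or an empty list with ``verbose``) for bare DNA.
    """
    h = ndimage.gaussian_filter1d(trace.heights, smooth_points, mode="nearest")
    baseline = float(np.median(h))
    idx, props = find_peaks(h, height=baseline + margin, prominence=margin / 2)
    cum = trace.arclength()
    calls = [
        PlacementCall(
            kind="protein",
            position=float(cum[i] / NM_PER_BP),
            height=float(trace.heights[i]),
            extra={"prominence": float(p)},
        )
        for i, p in zip(idx, props["prominences"])
    ]
    calls.sort(key=lambda c: -c.extra["prominence"])
    if verbose:
        return calls
    return calls[0] if calls else None


def detect_loop(
    trace: MoleculeTrace,
    image: AFMImage | None = None,
    proximity_nm: float = 4.0,
    min_loop_bp: float = 50.0,
):
    """Loop call from a self-crossing molecule.

    Uses the loop span recorded during skeleton tracing when present,
    otherwise searches for two contour-distant path points that approach
    each other below ``proximity_nm``.  Reports the loop contour length,
    its middle point (contour midpoint between the two crossing passages),
    and a :class:`CrossingCall` whose over-strand is the passage with the
    higher flanking heights.  Returns ``None`` when there is no crossing.
    """
    cum = trace.arclength()
    if trace.loop_span is not None:
        i0, i1 = trace.loop_span
    else:
        pair = _closest_self_approach(trace, proximity_nm, min_loop_bp)
        if pair is None:
            return None
        i0, i1 = pair
    s0, s1 = cum[i0], cum[i1]
    loop_bp = (s1 - s0) / NM_PER_BP
    if loop_bp < min_loop_bp:
        return None
    mid_bp = ((s0 + s1) / 2.0) / NM_PER_BP
    loc = tuple(((trace.path[i0] + trace.path[i1]) / 2.0).tolist())

    k_in = max(2, int(round(2.0 / max(trace.pixel_size, 1e-6))))
    k_out = 4 * k_in
    h1 = trace.heights[max(0, i0 - k_out) : max(1, i0 - k_in)]
    h2 = trace.heights[min(len(trace.heights) - 1, i1 + k_in) :
                       min(len(trace.heights), i1 + k_out)]
    m1 = float(np.mean(h1)) if len(h1) else float(trace.heights[i0])
    m2 = float(np.mean(h2)) if len(h2) else float(trace.heights[i1])
    over = "first" if m1 >= m2 else "second"
    near = trace.heights[[i0, i1]]
    summit = float(np.max(near))
    if image is not None:
        # noise-suppressed summit: smooth before taking the patch maximum,
        # else the reading is the noise extreme rather than the topography
        flat = flatten_two_pass(image)
        smooth = ndimage.gaussian_filter(flat.heights, 1.0 / image.pixel_size)
        r = int(np.ceil(3.0 / image.pixel_size))
        cx, cy = loc[0] / image.pixel_size, loc[1] / image.pixel_size
        y0, y1 = int(max(0, cy - r)), int(min(smooth.shape[0], cy + r + 1))
        x0, x1 = int(max(0, cx - r)), int(min(smooth.shape[1], cx + r + 1))
        if y1 > y0 and x1 > x0:
            summit = float(smooth[y0:y1, x0:x1].max())
    call = PlacementCall(
        kind="loop_midpoint", position=float(mid_bp),
        extra={"loop_bp": float(loop_bp)},
    )
    return call, CrossingCall(location=loc, over_strand=over, summit_height=summit)


def _closest_self_approach(
    trace: MoleculeTrace, proximity_nm: float, min_loop_bp: float
) -> tuple[int, int] | None:
    from scipy.spatial import cKDTree

    pts = trace.path
    cum = trace.arclength()
    tree = cKDTree(pts)
    pairs = tree.query_pairs(proximity_nm, output_type="ndarray")
    if len(pairs) == 0:
        return None
    sep = np.abs(cum[pairs[:, 0]] - cum[pairs[:, 1]])
    ok = sep > min_loop_bp * NM_PER_BP
    if not ok.any():
        return None
    pairs = pairs[ok]
    d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    i, j = pairs[int(np.argmin(d))]
    return (int(min(i, j)), int(max(i, j)))


# ------------------------------------------------------------- ends ratio

def trace_ends_ratio(
    trace: MoleculeTrace, window_len: int = 150, step: int = 1
) -> EndsRatioProfile:
    """Ends-ratio profile along a traced molecule (2D chords), centers in
    bp along the path."""
    pts, _ = trace.resample_per_bp()
    return ends_ratio(pts, window_len=window_len, step=step, bp_per_point=1.0)


@dataclass
class ApexTrack:
    times: list[float]
    apexes_bp: list[float]
    displacement_bp: float


def track_apex(
    traces: list[MoleculeTrace], window_len: int = 150
) -> ApexTrack:
    """Curvature-apex position per time-lapse frame plus net displacement.

    Frames must be consistently oriented; unoriented frames are dropped
    with a warning.  Times come from ``frame_time`` (frame index when
    absent).
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 frames")
    kept = []
    for k, t in enumerate(traces):
        if not t.oriented:
            warnings.warn(f"frame {k} not oriented; dropped", stacklevel=2)
            continue
        kept.append((k, t))
    if len(kept) < 2:
        raise ValueError("fewer than 2 oriented frames")
    times, apexes = [], []
    for k, t in kept:
        prof = trace_ends_ratio(t, window_len=window_len)
        if len(prof) == 0:
            warnings.warn(f"frame {k} shorter than window; dropped", stacklevel=2)
            continue
        apexes.append(float(apex_position(prof)))
        times.append(float(t.frame_time) if t.frame_time is not None else float(k))
    return ApexTrack(
        times=times, apexes_bp=apexes,
        displacement_bp=float(apexes[-1] - apexes[0]),
    )
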