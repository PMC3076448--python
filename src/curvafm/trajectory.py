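"""Sequence-encoded 3D helix-axis trajectory from a dinucleotide step table.

The DNA path is reconstructed step by step: at each dinucleotide the local
frame advances by the rise along its helix axis and is then rotated by the
step's tilt (about local x), roll (about local y) and twist (about local z),
in that order.  Signs follow the Cambridge convention (positive roll opens
toward the major groove).  Phased deviations from straightness accumulate
into planar curvature when their period matches the helical repeat, and
into a 3D superhelix otherwise; the supercoil scan makes the latter visible
by uniformly rescaling the twists to impose a different phasing pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .sequence import GenomicSequence

#: B-DNA rise per base-pair step used for model trajectories, nm
MODEL_RISE_NM = 0.34

_DINUCS = [a + b for a in "ACGT" for b in "ACGT"]


@dataclass(frozen=True)
class StepTable:
    """Roll/tilt/twist (degrees) for each of the 16 dinucleotide steps."""

    roll: dict[str, float]
    tilt: dict[str, float]
    twist: dict[str, float]
    rise: float = MODEL_RISE_NM

    def __post_init__(self) -> None:
        missing = [d for d in _DINUCS if d not in self.twist]
        if missing:
            raise ValueError(f"step table missing dinucleotides: {missing}")
        for d in _DINUCS:
            if not 0.0 < self.twist[d] < 90.0:
                raise ValueError(f"twist[{d}] = {self.twist[d]} outside (0, 90) deg")

    @property
    def mean_twist(self) -> float:
        return float(np.mean([self.twist[d] for d in _DINUCS]))

    @property
    def helical_repeat(self) -> float:
        """Native mean phasing pitch, bp per turn (360 / mean twist)."""
        return 360.0 / self.mean_twist

    @classmethod
    def from_tsv(cls, path: str | Path, rise: float = MODEL_RISE_NM) -> "StepTable":
        roll, tilt, twist = {}, {}, {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("dinucleotide"):
                    continue
                d, r, t, w = line.split("\t")
                roll[d], tilt[d], twist[d] = float(r), float(t), float(w)
        return cls(roll=roll, tilt=tilt, twist=twist, rise=rise)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("dinucleotide\troll\ttilt\ttwist\n")
            for d in _DINUCS:
                fh.write(f"{d}\t{self.roll[d]:.6f}\t{self.tilt[d]:.6f}\t{self.twist[d]:.6f}\n")


def default_step_table() -> StepTable:
    """The wedge-angle coding table shipped with the package."""
    with resources.as_file(
        resources.files("curvafm.data").joinpath("wedge_steps.tsv")
    ) as p:
        return StepTable.from_tsv(p)


def rescale_twist(table: StepTable, target_pitch: float) -> StepTable:
    """Impose a phasing pitch by uniformly rescaling all twist angles.

    Every twist is multiplied by the single factor
    ``(360/target_pitch) / mean(native twist)``, so the sequence-dependent
    twist modulation is preserved and the rescaled mean helical repeat is
    exactly ``target_pitch``.  Roll and tilt are unchanged.  A decreased
    pitch over-twists the molecule, an increased pitch under-twists it.
    """
    if target_pitch <= 0:
        raise ValueError("target_pitch must be positive")
    factor = (360.0 / target_pitch) / table.mean_twist
    return StepTable(
        roll=dict(table.roll),
        tilt=dict(table.tilt),
        twist={d: v * factor for d, v in table.twist.items()},
        rise=table.rise,
    )


@dataclass
class Trajectory3D:
    """Helix-axis path: one 3D point (nm) per base pair plus per-step frames."""

    points: np.ndarray          # (n, 3) nm
    frames: np.ndarray          # (n, 3, 3); frames[i] maps local -> lab axes
    pitch_used: float | str = "native"
    coords: list[int] | None = field(default=None, repr=False)  # promoter coords

    @property
    def contour_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("index\tx\ty\tz\n")
            for i, (x, y, z) in enumerate(self.points):
                fh.write(f"{i}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def _step_matrix(tilt: float, roll: float, twist: float) -> np.ndarray:
    """Symmetric wedge-step rotation: Rz(twist/2) . bend . Rz(twist/2).

    The bend is a single rotation about the in-plane wedge axis (rotation
    vector (roll, tilt, 0) in degrees, i.e. wedge magnitude sqrt(roll^2 +
    tilt^2) at the tabulated direction).  Splitting the twist around the
    bend -- rather than composing tilt/roll/twist sequentially -- makes
    the step generator exactly complement-symmetric: the trajectory read
    from the other strand superimposes on the reversed trajectory.
    """
    from scipy.spatial.transform import Rotation

    half_tw = Rotation.from_euler("z", twist / 2.0, degrees=True).as_matrix()
    bend = Rotation.from_rotvec(np.radians([roll, tilt, 0.0])).as_matrix()
    return half_tw @ bend @ half_tw


def _half_matrix(m: np.ndarray) -> np.ndarray:
    """Rotation square root (half-angle about the same axis)."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(
        Rotation.from_matrix(m).as_rotvec() / 2.0
    ).as_matrix()


def build_trajectory(
    seq: GenomicSequence,
    table: StepTable | None = None,
    pitch: float | None = None,
) -> Trajectory3D:
    """Deterministic helix-axis trajectory of ``seq``.

    Starts at the origin with the identity frame.  Each step rotates the
    frame by half the dinucleotide's tilt/roll/twist, advances by the rise
    along the mid-step helix axis, then applies the second half of the
    rotation -- the symmetric splitting that makes the trajectory of the
    reverse complement an exact mirror image for a complement-symmetric
    table.  ``pitch`` (bp per turn, in [4, 20]) applies
    :func:`rescale_twist` first; ``None`` keeps the native table.
    """
    if table is None:
        table = default_step_table()
    pitch_used: float | str = "native"
    if pitch is not None:
        if not 4.0 <= pitch <= 20.0:
            raise ValueError(f"pitch {pitch} outside [4, 20] bp/turn")
        table = rescale_twist(table, pitch)
        pitch_used = pitch

    bases = seq.bases
    n = len(bases)
    halves = {
        d: _half_matrix(_step_matrix(table.tilt[d], table.roll[d], table.twist[d]))
        for d in _DINUCS
    }
    points = np.zeros((n, 3))
    frames = np.zeros((n, 3, 3))
    frame = np.eye(3)
    frames[0] = frame
    p = np.zeros(3)
    for i in range(n - 1):
        d = bases[i : i + 2]
        try:
            h = halves[d]
        except KeyError:  # unreachable for validated GenomicSequence input
            raise ValueError(f"unknown dinucleotide {d!r} at offset {i}") from None
        mid = frame @ h
        p = p + table.rise * mid[:, 2]
        frame = mid @ h
        points[i + 1] = p
        frames[i + 1] = frame
    return Trajectory3D(points=points, frames=frames, pitch_used=pitch_used,
                        coords=seq.coordinates())
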