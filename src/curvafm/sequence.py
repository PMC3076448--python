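"""Sequence handling in promoter coordinates.

Promoter coordinates are 1-based on each side of the transcription start
site (TSS, position +1) and skip zero: ... -2, -1, +1, +2 ...  A fragment
spanning -869..+421 therefore contains exactly 869 + 421 = 1290 bases.
All public APIs speak promoter coordinates (closed intervals); internal
arrays are 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

_VALID = re.compile(r"^[ACGT]+$")

#: canonical IL2RA promoter features, promoter coordinates (closed intervals)
DEFAULT_FEATURES = [
    ("PRRI", -289, -216),
    ("PRRII", -137, -64),
    ("TATA", -51, -44),
    ("TSS", 1, 1),
]


class CoordinateError(ValueError):
    """Invalid promoter coordinate (zero, or outside the fragment span)."""


def _axis(pos: int) -> int:
    """Map a skip-zero promoter coordinate onto a continuous integer axis."""
    if pos == 0:
        raise CoordinateError(
            "promoter coordinate 0 does not exist: the convention is "
            "... -2, -1, +1, +2 ... around the TSS (+1)"
        )
    return pos + 1 if pos < 0 else pos


def promoter_to_offset(pos: int, origin: int, length: int | None = None) -> int:
    """0-based array offset of promoter coordinate ``pos`` in a fragment
    whose first base sits at promoter coordinate ``origin``.

    Offsets are monotone in ``pos`` and the offsets of -1 and +1 are
    adjacent.  Raises :class:`CoordinateError` for ``pos == 0`` or for a
    position outside the span when ``length`` is given.
    """
    off = _axis(pos) - _axis(origin)
    if off < 0 or (length is not None and off >= length):
        raise CoordinateError(
            f"position {pos:+d} outside fragment starting at {origin:+d}"
            + (f" (length {length})" if length is not None else "")
        )
    return off


def offset_to_promoter(offset: int, origin: int) -> int:
    """Inverse of :func:`promoter_to_offset`."""
    a = _axis(origin) + int(offset)
    return a - 1 if a <= 0 else a


def span_length(start: int, end: int) -> int:
    """Number of bases in the closed promoter-coordinate interval start..end."""
    return _axis(end) - _axis(start) + 1


@dataclass
class GenomicSequence:
    """A DNA fragment anchored in promoter coordinates.

    Parameters
    ----------
    bases:
        Uppercase string over {A, C, G, T}.
    origin:
        Promoter coordinate of the first base (never 0).
    features:
        ``(name, start, end)`` triples in promoter coordinates.
    """

    bases: str
    origin: int = 1
    features: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        if len(self.bases) < 2:
            raise ValueError("sequence must contain at least 2 bases")
        if not _VALID.match(self.bases):
            bad = sorted(set(self.bases) - set("ACGT"))
            raise ValueError(
                f"unsupported symbols {bad}: only A/C/G/T accepted "
                "(IUPAC ambiguity codes are not resolved)"
            )
        _axis(self.origin)  # reject origin 0

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def end(self) -> int:
        """Promoter coordinate of the last base."""
        return offset_to_promoter(len(self.bases) - 1, self.origin)

    def to_offset(self, pos: int) -> int:
        return promoter_to_offset(pos, self.origin, len(self.bases))

    def to_promoter(self, offset: int) -> int:
        if not 0 <= offset < len(self.bases):
            raise CoordinateError(f"offset {offset} outside [0, {len(self.bases)})")
        return offset_to_promoter(offset, self.origin)

    def coordinates(self) -> list[int]:
        """Promoter coordinate of every base, in order."""
        return [offset_to_promoter(i, self.origin) for i in range(len(self.bases))]

    def subsequence(self, start: int, end: int) -> "GenomicSequence":
        """Closed-interval promoter-coordinate slice, features carried over."""
        i, j = self.to_offset(start), self.to_offset(end)
        if j < i:
            raise CoordinateError(f"empty interval {start:+d}..{end:+d}")
        feats = [
            (n, s, e)
            for (n, s, e) in self.features
            if _axis(s) <= _axis(end) and _axis(e) >= _axis(start)
        ]
        return GenomicSequence(self.bases[i : j + 1], origin=start, features=feats)

    def reverse_complement(self) -> "GenomicSequence":
        """Reverse complement; coordinates are mirrored so that the new
        origin is the (negated) old end.  Involution up to feature order."""
        rc = str(Seq(self.bases).reverse_complement())
        new_origin = _mirror(self.end)
        feats = [(n, _mirror(e), _mirror(s)) for (n, s, e) in self.features]
        return GenomicSequence(rc, origin=new_origin, features=feats)

    def feature(self, name: str) -> tuple[int, int]:
        for n, s, e in self.features:
            if n == name:
                return (s, e)
        raise KeyError(name)


def _mirror(pos: int) -> int:
    """Reflect a promoter coordinate through the TSS (swap strand sense)."""
    return -pos


@dataclass(frozen=True)
class ATTract:
    """A maximal run of A/T (a W-run) in promoter coordinates."""

    start: int
    end: int
    length: int
    composition: float = 1.0


def find_at_tracts(seq: GenomicSequence, min_len: int = 5) -> list[ATTract]:
    """Maximal A/T runs of length >= ``min_len``, sorted by start.

    A tract may not contain any G or C (strict W-run); the bases flanking a
    tract are G/C or the sequence ends, so tracts never overlap.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    tracts = []
    for m in re.finditer(r"[AT]+", seq.bases):
        if m.end() - m.start() >= min_len:
            tracts.append(
                ATTract(
                    start=seq.to_promoter(m.start()),
                    end=seq.to_promoter(m.end() - 1),
                    length=m.end() - m.start(),
                )
            )
    return tracts


def read_fasta(path: str | Path, origin: int = 1,
               features: Iterable[tuple[str, int, int]] | None = None) -> GenomicSequence:
    """First record of a FASTA file as a :class:`GenomicSequence`.

    Non-ACGT symbols (including IUPAC ambiguity codes) are rejected because
    the downstream dinucleotide tables are defined only for A/C/G/T.
    """
    record = next(SeqIO.parse(str(path), "fasta"))
    return GenomicSequence(str(record.seq).upper(), origin=origin,
                           features=list(features or []))


def write_fasta(seq: GenomicSequence, path: str | Path, name: str = "fragment") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name} origin={seq.origin:+d} end={seq.end:+d}\n")
        for i in range(0, len(seq.bases), 70):
            fh.write(seq.bases[i : i + 70] + "\n")


def read_features_tsv(path: str | Path) -> list[tuple[str, int, int]]:
    """BED-like TSV: name, start, end in promoter coordinates."""
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, s, e = line.split("\t")[:3]
            feats.append((name, int(s), int(e)))
    return feats


def tracts_to_tsv(tracts: list[ATTract], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tlength\tcomposition\n")
        for t in tracts:
            fh.write(f"{t.start:+d}\t{t.end:+d}\t{t.length}\t{t.composition:.2f}\n")
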