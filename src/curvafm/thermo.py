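"""Sliding-window DNA duplex-stability profiles from nearest-neighbor
thermodynamics.

Duplex stability is evaluated as the nearest-neighbor free energy of helix
formation at 25 C and 1 M NaCl, dG = dH - T*dS, from the 10 unique
Watson-Crick steps (the other 6 dinucleotides follow by complement
symmetry).  Less negative dG marks DNA that is easier to melt.  The window
statistic is the per-step mean (windows of different length stay
comparable); the window sum is available via ``statistic="sum"``.
Initiation terms are stored but not applied inside windows: a sliding
window is an interior excerpt of a long duplex, not an isolated oligomer.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .sequence import GenomicSequence

#: evaluation temperature, K (25 C)
T_KELVIN = 298.15

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(d: str) -> str:
    return d.translate(_COMP)[::-1]


@dataclass(frozen=True)
class NNParameterSet:
    """dH (kcal/mol) and dS (cal/(mol*K)) per unique Watson-Crick step,
    at the 1 M NaCl, pH 7 reference condition."""

    dH: dict[str, float]
    dS: dict[str, float]
    init_dH: dict[str, float]
    init_dS: dict[str, float]

    def dG(self, dinuc: str, temperature: float = T_KELVIN) -> float:
        """Free energy of one step, kcal/mol, at the given temperature."""
        d = dinuc if dinuc in self.dH else _revcomp(dinuc)
        try:
            return self.dH[d] - temperature * self.dS[d] / 1000.0
        except KeyError:
            raise ValueError(f"not a Watson-Crick DNA step: {dinuc!r}") from None

    def step_dG_table(self, temperature: float = T_KELVIN) -> dict[str, float]:
        """dG for all 16 dinucleotides (complement-symmetric by design)."""
        return {
            a + b: self.dG(a + b, temperature) for a in "ACGT" for b in "ACGT"
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NNParameterSet":
        dH, dS, idH, idS = {}, {}, {}, {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("step"):
                    continue
                key, h, s = line.split("\t")
                if key.startswith("init"):
                    idH[key], idS[key] = float(h), float(s)
                else:
                    dH[key], dS[key] = float(h), float(s)
        if len(dH) != 10:
            raise ValueError(f"expected 10 unique steps, found {len(dH)}")
        return cls(dH=dH, dS=dS, init_dH=idH, init_dS=idS)


def default_nn_parameters() -> NNParameterSet:
    with resources.as_file(
        resources.files("curvafm.data").joinpath("nn_duplex.tsv")
    ) as p:
        return NNParameterSet.from_tsv(p)


@dataclass
class DeltaGProfile:
    """Sliding-window duplex stability, kcal/mol per base step."""

    window_len: int
    step: int
    centers: np.ndarray
    values: np.ndarray
    global_mean: float

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# global_mean\t{self.global_mean:.6f}\n")
            fh.write("center\tdG\n")
            for c, v in zip(self.centers, self.values):
                fh.write(f"{int(c)}\t{v:.6f}\n")


def window_dG(
    window: str,
    params: NNParameterSet | None = None,
    statistic: str = "mean",
) -> float:
    """Duplex stability of one sequence window, kcal/mol.

    ``statistic="mean"`` (default) averages the (w-1) step free energies;
    ``"sum"`` totals them.
    """
    if params is None:
        params = default_nn_parameters()
    if len(window) < 2:
        raise ValueError("window must contain at least one dinucleotide step")
    table = params.step_dG_table()
    try:
        vals = [table[window[i : i + 2]] for i in range(len(window) - 1)]
    except KeyError as exc:
        raise ValueError(f"non-ACGT step in window: {exc}") from None
    total = float(np.sum(vals))
    return total / (len(window) - 1) if statistic == "mean" else total


def dG_profile(
    seq: GenomicSequence,
    window_len: int = 150,
    step: int = 1,
    params: NNParameterSet | None = None,
    statistic: str = "mean",
) -> DeltaGProfile:
    """Sliding-window dG profile plus the whole-sequence mean.

    The global mean is the per-step mean over the entire sequence (the
    horizontal reference line of a stability plot).
    """
    if params is None:
        params = default_nn_parameters()
    bases = seq.bases
    n = len(bases)
    if n < window_len:
        raise ValueError(f"sequence ({n} bp) shorter than window ({window_len} bp)")
    table = params.step_dG_table()
    step_dG = np.array([table[bases[i : i + 2]] for i in range(n - 1)])
    cum = np.concatenate([[0.0], np.cumsum(step_dG)])
    starts = np.arange(0, n - window_len + 1, step)
    ends = starts + window_len - 1          # window covers bases [s, e]
    totals = cum[ends] - cum[starts]        # sum of (window_len - 1) steps
    values = totals / (window_len - 1) if statistic == "mean" else totals
    coords = np.array(seq.coordinates())
    centers = coords[(starts + ends) // 2]
    return DeltaGProfile(
        window_len=window_len,
        step=step,
        centers=centers,
        values=values,
        global_mean=float(step_dG.mean()),
    )
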