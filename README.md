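# curvafm

Structural analysis of promoter DNA from sequence and from AFM images of
single molecules.

Eukaryotic promoters can encode their own mechanics: runs of A/T
("A-tracts") bend the double helix, and when those bends repeat with a
period different from the helical repeat (~10.5 bp/turn) the molecule
folds into an intrinsic 3D superhelix instead of a planar curve — a
left-handed (negative) supercoil when the period is shorter, right-handed
(positive) when longer.  Such structures position nucleosomes and
architectural transcription factors and help direct where the duplex
melts at transcription start.  `curvafm` implements the complete desk
side of this analysis for molecular biophysicists:

* **Sequence → 3D trajectory.**  A dinucleotide wedge-angle model
  (roll/tilt/twist per step) reconstructs the helix-axis path of any
  sequence, in a promoter coordinate system anchored at the TSS
  (+1, no position 0; a fragment spanning −869..+421 is exactly 1290 bp).
* **Curvature and supercoil detection.**  The *Ends ratio* of a sliding
  window — contour length divided by the end-to-end chord,
  `ER = L_contour / |r(s+w) − r(s)|` ≥ 1 — is scanned over an imposed
  *phasing pitch* (5–15 bp/turn).  A superhelix that is invisible at the
  canonical pitch flattens into detectable planar curvature at its
  resonant pitch; peaks below/above 10.5 bp/turn are called as
  left-/right-handed intrinsic supercoils, with a false-positive rate
  calibrated on an i.i.d. sequence null.
* **Duplex stability.**  Sliding-window ΔG of helix formation from the
  10 unique Watson–Crick nearest-neighbor steps, ΔG = ΔH − T·ΔS at 25 °C
  and 1 M NaCl, in kcal/mol per base step; less negative = easier to melt.
* **AFM image quantification.**  Height images (nm, known nm/px) are
  flattened line by line, thresholded, thinned and ordered into sub-pixel
  molecule traces — including through self-crossings, which are resolved
  into loops.  Contours convert to bp at 0.36 nm/bp.  On oriented
  molecules the package maps nucleosome dyads (from the free-arm lengths
  L₊ and L₋: L_c = L − (L₊+L₋), dyad at L₊ + L_c/2), bound proteins
  (height maxima), loop midpoints, and time-lapse movement of the
  curvature apex.
* **Synthetic ground truth.**  Generators for phased-tract sequences,
  2D worm-like chains (persistence length ~50 nm), and rendered AFM
  frames (0.8–1.2 nm strands, capped 1.5–1.6 nm crossing summits,
  parabolic-tip broadening, 0.3 nm noise) make every stage testable
  without instrument data.

## Worked example

Generate a fragment with A-tracts phased at 8 bp — a period below the
canonical repeat, which encodes a left-handed supercoil — and analyze it:

```
$ curvafm simulate --kind phased --period 8 -o phased8.fa
37 tracts, period 8 -> phased8.fa
$ curvafm curvemap phased8.fa -o map.tsv --calls calls.tsv
map (21, 451) -> map.tsv
supercoil left: pitch 8 bp/turn, +181..+424, amplitude 3.24
```

The curvature map (Ends ratio over window center × pitch) peaks at the
planted 8 bp phasing period, and the caller reports one left-handed
supercoil spanning the tract region with peak Ends ratio 3.24 — far
above the 1.4 amplitude threshold set by the random-sequence null.

The same analyses from Python, on a synthetic fragment with the
regulatory-region architecture (three A/T-tracts separated by 6 and 7 bp,
the longest 19 bp):

```python
import curvafm as cf
from curvafm import sequence, synthetic, thermo

seq, truth = synthetic.gen_promoter_like(seed=0)
region = seq.subsequence(*truth["region"])
for t in sequence.find_at_tracts(region, min_len=5):
    print(t.start, t.end, t.length)
# -137 -128 10
# -121 -109 13
# -101 -83 19
prof = thermo.dG_profile(seq)
print(round(prof.global_mean, 3))   # -1.705  (kcal/mol per step)
```

The three tracts sit at −137..−128, −121..−109 and −101..−83 in promoter
coordinates; the ΔG profile's global mean (−1.705 kcal/mol/step) is the
horizontal reference against which melting-prone windows are read.

For AFM data, `curvafm afm image.txt --pixel-size 2 -o out` traces every
molecule in a raster and reports contour lengths in nm and bp;
`curvafm report -o outdir` runs all stages on packaged synthetic data and
writes TSV outputs with a checksummed manifest.

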