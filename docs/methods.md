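# Methods

This note documents the models implemented in `curvafm`, the parameters
that matter, the synthetic data the tests run on, and the limitations of
both.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Promoter coordinates

Positions are 1-based on each side of the transcription start site and
skip zero: … −2, −1, +1, +2 …  All public APIs speak these coordinates
(closed intervals); internal arrays are 0-based.  The convention is
forced by arithmetic: a fragment printed as spanning −869..+421 contains
1290 bases only if there is no position 0.  A/T-tracts are maximal runs
over {A, T} (strict W-runs, no G/C allowed inside) with a default length
floor of 5 bp; the floor is an analysis choice — short W-runs carry
little phased-bending signal — and is exposed as a parameter.

## Helix-axis trajectory (wedge model)

Each dinucleotide step contributes three rotations — roll, tilt, twist —
and one translation (rise 0.34 nm) to the helix axis.  The shipped table
(`data/wedge_steps.tsv`) is the classic wedge-angle set expressed as
roll = wedge·cos(direction), tilt = wedge·sin(direction); its mean twist
gives a native repeat of 10.61 bp/turn.  The 0.36 nm/bp figure is *not*
used here: it is the empirical rise of molecules adsorbed on mica and is
reserved for AFM length conversion.

The step generator is the symmetric composition

    M = Rz(twist/2) · R_wedge(roll, tilt) · Rz(twist/2),

with the bend applied as a single rotation about the in-plane wedge
axis, and the translation applied along the mid-step helix axis (frame
advanced by the half-step rotation before translating).  This choice is
forced by a physical invariant: the trajectory read from the complementary
strand must superimpose exactly on the reversed forward trajectory
(same molecule).  A sequential tilt-then-roll-then-twist Euler
composition cannot satisfy this for any strand flip (numerical residuals
0.08–0.28 across the 16 steps); the symmetric form satisfies it to
machine precision, which the test suite asserts (RMSD < 1e-6 nm after
optimal superposition).  Curvature magnitudes agree with the sequential
form to first order in the wedge angles.

**Phasing-pitch override.**  Scanning for supercoils rebuilds the
trajectory with every twist multiplied by one factor,
(360/pitch)/mean(native twist), so sequence-dependent twist modulation is
preserved and the rescaled mean repeat equals the requested pitch
exactly.  At the native repeat the factor is 1 and the trajectory is
bit-identical — the regression test for the override.  The alternative
(replacing twist by 360/pitch uniformly) discards twist modulation and
was not adopted; peak pitches read from the map may shift by a few
tenths of a bp between the two conventions.

## Ends ratio, curvature map, supercoil calls

The Ends ratio of a window is contour length over end-to-end chord:
1 for a straight segment, π/2 for a semicircle.  Windows are 150 bp at
1 bp steps by default, reported at window centers with no edge padding;
model trajectories use 3D chords, AFM traces 2D.  The curvature map
stacks profiles over a pitch grid of 5–15 bp/turn at 0.5 bp resolution —
finer than integer stepping so that a resonance near 7.5 bp/turn is
representable.

**Calling.**  The pitch spectrum (per-pitch maximum Ends ratio) is
searched for peaks.  Three filters make the call specific to intrinsic
supercoils:

1. *Canonical exclusion* (±1 bp/turn around 10.5): planar curvature, not
   supercoiling.
2. *Canonical subharmonic exclusion* (±0.5 around 5.25): a bend pattern
   phased at the canonical repeat also resonates at half the repeat, so
   a peak there is the same planar curvature echoed.
3. *Echo suppression*: a weaker peak at 1/2 or 1/3 of an accepted peak's
   pitch is the same structure resonating at a subharmonic (tracts
   spaced d bp resonate at every pitch d/k).

The amplitude threshold (default 1.4) is the 95th percentile of the
off-harmonic peak amplitude over a committed null ensemble — 100 i.i.d.
976 bp sequences at GC 0.5 (seeds 0..99) — so random DNA is called in
≤ ~5% of cases by construction.  With the wedge table the null is far
from flat (median spectrum maximum ≈ 1.5 before peak filtering): random
sequence accumulates substantial static bending, and any fixed threshold
below the null's bulk would flag everything.  Prominence ≥ 0.05
(configurable) rejects plateau noise.  Handedness is left below the
canonical pitch, right above.  No smoothing is applied to profiles
before peak reading.

The curvature apex of a profile is the window center of the global
maximum; exact ties break toward the 3′ end (deterministic, documented).

## Duplex stability

ΔG of helix formation per step, ΔH − T·ΔS at T = 298.15 K, from the 10
unique Watson–Crick nearest-neighbor parameters of the unified set
(1 M NaCl reference; shipped as `data/nn_duplex.tsv`, complement
symmetry supplies the other 6 dinucleotides).  The window statistic is
the mean over the (w−1) steps — windows of different length stay
comparable — with the sum available via a flag.  Initiation terms are
stored but never applied inside windows: a sliding window is an interior
excerpt of a long duplex, not an isolated oligomer.  No salt or pH
correction is applied (the stated condition equals the table's reference
condition).  The profile's `global_mean` is the per-step mean over the
whole sequence, the horizontal reference line of a stability plot.

## AFM image analysis

Pipeline per frame (heights in nm, pixel size known):

1. **Two-pass line flattening.**  Each scan line gets an iterative
   robust polynomial fit (order ≤ 3, default 2).  Noise scale comes from
   the line's lower quantiles (molecules are strictly positive relief,
   so q05/q25 stay clean even under heavy coverage); pixels more than
   2σ above the fit are excluded and the line refitted.  A first pass
   reveals the molecules; a second pass refits with a dilated 2D
   molecule mask excluded, which preserves dim strands that run along
   the scan direction.
2. **Masking.**  Hysteresis thresholding (low/high = 0.5/0.8 of the
   height threshold, default threshold 0.5 nm — between the 0.3 nm noise
   level and the 0.8–1.2 nm strand height) on a 2 nm-smoothed copy;
   heights are measured on a separate 1 nm-smoothed copy so particle
   bumps and height modulation are not attenuated by the mask smoothing.
3. **Thinning and ordering.**  `skimage` skeletonization, then a pixel
   graph (8-connectivity, redundant diagonals dropped).  Whisker spurs
   < 5 px are pruned; junction clusters bridged by ≤ 2 px are fused (an
   X crossing thins into two 3-degree pixels plus a bridge that belongs
   to both passages).  Segments between junctions form a multigraph; the
   molecule is the minimum-length walk between the two free ends, and a
   leftover cycle attached to a cluster on that walk — found as an
   Eulerian circuit, so a noise nub splitting the ring is tolerated — is
   inserted there as the loop, with its index span recorded.
4. **Sub-pixel refinement.**  Height-weighted centroid shifts along the
   local normal recover the ridge axis to sub-pixel precision; points
   within ~6 nm of a crossing are frozen (the normal samples would catch
   the other strand and drag both passages inward).  A final Gaussian
   smoothing of the path (σ = 1.5 points) keeps pixel-noise jitter from
   inflating contour lengths; end extension exists for imagery without
   tip broadening but is off by default, since broadened strands already
   reach past the true molecule ends.
5. **Measurement.**  Contours convert to bp at exactly 0.36 nm/bp
   (global constant, not per-molecule).  Traces shorter than 30 nm are
   discarded.

**Orientation.**  The model signal is the local helical pitch
(360/twist) per bp, smoothed over 10 bp and z-scored; measured height
profiles are resampled to the model length, smoothed to the same
bandwidth, and correlated in both orientations.  A molecule is oriented
only when the trace length is within 15% of the model and the gap
between |r| of the two orientations is ≥ 0.1; unoriented molecules are
excluded from positioning statistics.

**Positioning.**  Nucleosome dyads use the arm-length identity
L_c = L − (L₊ + L₋), dyad at L₊ + L_c/2 from the long-arm end (the
identity L − (L₋ + L_c/2) giving the same point is asserted on every
call).  On images, the particle is the largest region above 1.5 nm; arms
are traced with the particle plus an 8 nm margin masked (wide enough
that the particle's skirt cannot tether the arm tips; widened 1.5× and
retried once if the arms come out implausibly long).  Proteins are the
most prominent height maximum ≥ 0.4 nm above the trace's median height.
Loops use the recorded crossing span (or, lacking one, the closest
contour-distant self-approach); the reported position is the contour
midpoint between the two passages, and the over-strand is the passage
with higher flanking heights.  Time-lapse apex tracking reports the
Ends-ratio apex per oriented frame and the net displacement.

## Synthetic data

The generator produces the study conditions the analyses assume, with
full ground truth:

* **Sequences.**  Phased A-tracts (default 5 bp) placed every *p* bp on
  i.i.d. backgrounds whose accidental W-runs are capped below the tract
  length; period 10.5 encodes planar curvature, periods below/above
  encode left/right supercoils.  A promoter-like construct carries three
  A/T-tracts separated by 6 and 7 bp, the longest 19 bp.  Controls are
  i.i.d. at a given GC.
* **Chains.**  2D-equilibrated worm-like chains: successive headings
  differ by Gaussian angles of variance (segment/persistence), under
  which the tangent autocorrelation decays as exp(−s/2P).  Persistence
  defaults to 50 nm.  A self-avoiding variant grows the chain with a
  7 nm excluded-volume distance — the well-spread molecules one selects
  for tracing; the plain variant is used for persistence estimation.
* **Images.**  Paths rasterize as ridges of Gaussian cross-section
  (σ 1 nm) at heights 0.8–1.2 nm; contour-distant passages add and are
  capped at 1.6 nm (the crossing-summit range; true tip physics is out
  of scope).  Bound particles are Gaussian bumps combined by maximum.
  Tip broadening is a grey dilation with a parabolic tip (default
  radius 8 nm), which widens strands to the contact width without
  lowering them — the correct first-order contact geometry, and the
  reason strands are 3–4 px wide at the default 2 nm/px.  Additive
  Gaussian noise (SD 0.3 nm) comes last.

What the synthetic data does **not** emulate: scanner drift and creep,
line-to-line registration errors, tip asymmetry and double-tip
artifacts, molecule–molecule overlap, surface contamination, and the
true electrostatics of DNA–mica adsorption.  Passing the recovery tests
therefore demonstrates the correctness of the algorithms under the
stated geometry and noise, not robustness to every instrument artifact.

## Study sizes and recovery statistics

The committed campaigns (fixed seed lists, `curvafm.studies`): 34/33/33
rendered images for dyad/protein/loop-midpoint mapping (|median error|
is compared against one pixel-equivalent, 2 nm ≈ 5.6 bp), 100 rendered
self-avoiding chains for orientation, 1000 chains of 1290 bp for
persistence recovery, and 100 control sequences for the false-positive
rate.  These sizes put the median standard error well below the pixel
scale while keeping a full run in tens of seconds; the acceptance script
re-runs all of them from scratch.

## Known limitations

* A long molecule lying along the scan direction and covering most of a
  line defeats line-wise flattening (the background estimate has too few
  clean pixels); real practice scans frames much larger than the
  molecule, and the generators draw random orientations.
* Strand stretches of two different molecule parts closer than the
  tip-broadened width (~7 nm) merge in the mask; crossings at shallow
  angles or tangential contacts are traced with a shortcut.  Loop
  detection succeeds on ~100% of the committed campaign's 90°-crossing
  geometry but will miss tangential loops.
* Absolute summit heights at 2 nm/px are resolution-limited: the
  crossing plateau is ~2 px, so smoothed readouts sit slightly below the
  rendered cap.
* Sequence-directed orientation succeeds in ~83% of fresh campaigns
  (88% on the committed list) at 0.3 nm noise; the margin criterion
  (Δ|r| ≥ 0.1) trades coverage for a low wrong-orientation rate.
* The wedge-angle and nearest-neighbor tables are editable TSVs;
  conclusions inherit their calibration.  All thresholds above are
  package defaults, exposed as parameters.
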