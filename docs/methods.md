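# Methods

## Problem and model

The package answers a single structural question from pose tables alone:
when dimers of a protein decorate the outside of a microtubule, are they
arranged as rings around the tube, as helices along it, and how long are
the oligomers? The observable is a set of subtomogram poses (position +
orientation per particle) attached to traced filament backbones. Three
derived statistics carry the answer:

1. the helical angle θ between each close pair's displacement vector and
   the local filament tangent (ring ⇒ θ ≈ 90°, right-handed helix ⇒
   θ ≈ helix angle, e.g. 33°);
2. the chain-length histogram of connected groups of perpendicular
   pairs, in dimer units;
3. decoration coverage, particles per nm of traced filament.

θ is reported on [0°, 180°] without folding. Folding to [0°, 90°] would
be correct only if filament polarity were known; traces are ordered
arbitrarily, so a helix angle α and its mirror 180° − α are
indistinguishable and both must remain visible in the histogram.

## Geometry

**Frames.** Filament traces are resampled equidistantly by arc length on
the piecewise-linear interpolant (both endpoints kept; the final gap may
be short). Tangents are unit central differences, one-sided at the ends —
stable on equidistant nodes and exact for straight segments. Normals are
propagated by parallel transport (the minimal rotation carrying tangent
i−1 onto tangent i), which prevents the frame flips that a fixed
reference vector produces near vertical tangents.

**Rotations.** Two Euler dialects are implemented, zxz (Dynamo-style)
and zyz (RELION-style), both intrinsic, active, column-vector, composed
R = Rz(z1)·Rmid(x)·Rz(z2). The underlying ecosystems do not document a
single shared handedness, so the package fixes this one choice,
documents it with worked examples, and verifies it in tests against an
independent quaternion-composition oracle; round trips are exact to
1e-8. Gimbal-locked matrices (tilt 0 or 180°) decompose with z2 = 0 so
written tables are deterministic.

**Picking grid.** One ring of candidate positions per resampled node, in
the node's normal plane, evenly spaced in azimuth. Defaults — 23 nm
radius, 7 nm ring spacing, 18 subunits per ring, 36 nm box (metadata) —
follow the picking protocol used for LRRK2 on microtubules. Azimuth
origin is the transported normal; rings are not staggered between layers
(a flag exists). Particle orientations put local +z outward (radial) and
local +y along the tangent.

## Cleaning filters

* **Azimuth randomization**: each orientation is post-multiplied by a
  rotation about its own outward axis, uniform on [0°, 360°), to
  decorrelate in-plane orientations from the missing wedge. Positions
  are untouched.
* **Duplicate removal**: greedy by ascending particle id — a particle is
  dropped if within `min_distance` (default 4 nm, configurable) of an
  already-kept one. Greedy-by-id is deterministic and idempotent; the
  survivor set has minimum pairwise distance ≥ the threshold.
* **CC filter**: keep score ≥ 0.32. The rule removes particles *lower
  than* 0.32, so the boundary is inclusive.
* **Polarity flips** are declared per filament id (180° about the
  outward axis); detecting tubulin skew from density is out of scope.

## Pair analysis defaults

The neighbor window is [5, 12] nm, bracketing the ≈ 8 nm azimuthal pitch
implied by the picking geometry (2π·23/18 ≈ 8.0 nm); the window is a
parameter, not a claim about biology. Classification bands are ±30°
around 90° (perpendicular) and around 0/180° (parallel); the two pair
populations are well separated in practice, so the bands are documented
defaults and validated only on synthetic data. θ
histograms use 5° bins with centres on multiples of the bin width; a
`center_on` option aligns one bin centre on a target angle (needed when
the expected angle, e.g. 33°, falls on a default bin edge). Modal-bin
ties break toward the lower bin for determinism.

## Chain grouping

"Overlapping" pairs are pairs sharing a particle id — the only reading
that is well defined after duplicate removal; a distance-based merge
(< 2 nm centroids) exists behind a flag for over-picked data. Chains are
connected components (networkx; verified against a hand-written BFS
oracle). Singletons count as size-1 chains because isolated dimers are a
real, frequent species; note the edge caveat that a chain-terminal
monomer contributing weakly to alignment can shorten an observed chain
by one — this is logged as a limitation, not modeled. Components are not
split at branch points.

## Synthetic generator

The generator plants what the analysis is supposed to measure, nothing
more:

* **Lattice**: tubulin subunits on the 1-start helix — rise 0.94 nm,
  twist −360°/n_pf (−27.69° at 13 protofilaments, printing as −27.7°),
  tube diameter 30 nm. Decorations are planted relative to the filament
  *axis*, not snapped to lattice subunits, because θ is defined against
  the axis; a snap option exists for realism.
* **Decoration**: chains seed at axial sites spaced `neighbor_spacing`
  (default 8 nm ≈ the picking pitch) with probability `occupancy`
  (default 0.3, sub-stoichiometric), uniform random azimuth, and sizes
  drawn from a 1–6 distribution weighted toward single dimers. Within a
  chain, each step moves `neighbor_spacing` in 3-D on the
  `binding_radius` (23 nm) cylinder at angle θ to the tangent — purely
  azimuthal for rings, right-handed azimuthal+axial for helices (azimuth
  increases with height). A candidate chain closer than
  `min_chain_separation` (16 nm = 2× spacing) to placed particles is
  rejected, keeping distinct oligomers resolvable by the pair window;
  chains running off the filament end are truncated and logged.
* **Noise**: `pos_noise_sigma` displaces positions isotropically
  (Gaussian per axis, nm). `ang_noise_sigma` does two things: it jitters
  each placement step's θ (so the planted θ *distribution* has the
  stated width — θ is computed from positions, so orientation noise
  alone would leave it exact) and wobbles orientations by a random-axis
  rotation of Gaussian angle. Sigma 0 is an exact identity.
* **Scores and decoys**: planted particles draw CC from N(0.6, 0.1),
  decoys — scattered uniformly on the picking cylinder with truth id −1
  — from N(0.2, 0.08), both clipped to [−1, 1], so the CC filter has
  signal to act on.
* **Scale**: filaments are straight, randomly oriented segments of
  2000 nm by default — the few-micron scale of traced microtubules —
  giving ≈ 1700 analysis pairs over 20 filaments at occupancy 0.3. At
  this size the modal θ bin is a stable estimator under the default
  noise (pair-level θ spread ≈ 7°); short test fixtures use dozens of
  nm where only exact geometry matters.

What the generator does **not** emulate: curved filaments in the
decorated region (paths may curve, but chains step using local frames
and are only validated on straight axes), missing-wedge anisotropy of
positional error, alignment-driven correlation between CC score and
pose error, and lattice defects. Passing tests therefore demonstrate
correctness of the geometry and statistics pipeline, not robustness to
every pathology of real tomograms.

## Numerical choices

* acos arguments are clamped to [−1, 1]; zero vectors are errors, not
  NaNs.
* Resampling keeps both endpoints; the last gap may be shorter than the
  spacing (consistency between a path's spacing and a grid spec is
  checked to 1e-9 nm).
* Duplicate removal uses an incrementally rebuilt k-d tree; results are
  identical to the O(n²) greedy oracle.
* Table round trips are lossless to 1e-6 nm in position and 1e-8 in the
  rotation matrix; absent CC / truth fields use out-of-range sentinels
  (2.0 and −999) because STAR rows are whitespace-delimited and cannot
  hold empty cells.
* All stochastic steps take explicit seeds (numpy `default_rng`); every
  filter stage logs input/output counts.

## Known limitations

* Filament polarity is never inferred; θ stays unfolded and the helix
  handedness of *observed* data is not determined (the generator's
  right-handedness is a planted convention).
* The chain statistic counts picked dimer units; a terminal monomer
  missed at a chain edge biases observed lengths short by construction
  of the picking unit, as noted above.
* `neighbor_spacing` of planted oligomers is a free parameter of the
  simulation, not a measured biological constant.
* The Dynamo `.tbl` dialect honors a documented subset of the 35
  columns (tag, shifts, Euler triple, CC, tomogram/filament indices,
  coordinates); remaining columns are written as zeros.
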