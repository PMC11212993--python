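# tomolattice

Geometric analysis of protein oligomers decorating microtubules in
cryo-electron tomography, working purely from subtomogram pose tables —
no density volumes required.

When a protein such as LRRK2 binds the outside of a microtubule, the
arrangement of bound copies carries mechanistic information: active-like
LRRK2 wraps microtubules in long right-handed helices (pair-to-axis angle
θ ≈ 33°), while the autoinhibited form makes short ring-like oligomers
(θ ≈ 90°) of 1–6 dimers. `tomolattice` implements the full geometric
pipeline used to make that distinction from subtomogram coordinates:

* **picking** — oversampled cylindrical picking grids around traced
  filaments (default: radius 23 nm, ring spacing 7 nm, 18 subunits per
  ring), azimuth randomization, greedy distance-based duplicate removal,
  and a cross-correlation cutoff (keep CC ≥ 0.32);
* **pair analysis** — same-filament neighbor pairs in a distance window
  (default 5–12 nm), the helical angle θ between each pair's displacement
  vector and the local microtubule axis, pair classification
  (perpendicular / parallel / other), and θ histograms with modal-bin
  reporting;
* **oligomer chains** — grouping of perpendicular pairs that share a
  particle into chains (connected components), chain-length histograms in
  dimer units, and per-filament coverage (particles per nm);
* **lattice_synth** — a synthetic generator of decorated microtubules
  with planted ground truth (lattice geometry, decoration mode, θ, chain
  sizes, occupancy, noise, CC scores, decoys), so every stage is testable
  end to end;
* **io_tables** — STAR, Dynamo-style 35-column `.tbl` and TSV particle
  tables, IMOD-style point-list traces, YAML configuration. All unit
  conversion (pixels/Å → nm) happens here and nowhere else.

## The θ statistic

For two bound dimers *a*, *b* on the same microtubule with displacement
**d** = **x**_b − **x**_a and local unit tangent **t** at the pair
midpoint,

θ = arccos( **d**·**t** / |**d**| ) ∈ [0°, 180°].

θ is deliberately *not* folded to [0°, 90°]: microtubule polarity is
unknown per filament, so the sign of **t** is arbitrary and the full
range must be kept. Ring-like oligomers give a θ distribution peaked at
90°; helical filaments peak near their helix angle (33° or the 147°
mirror). Chains are connected components of the graph whose edges are
perpendicular-class pairs; a chain's size counts its dimers.

## Conventions

* Internal units: nanometres and 3×3 proper rotation matrices.
* Euler dialects: `"zxz-dynamo"` (R = Rz(z1)·Rx(x)·Rz(z2)) and
  `"zyz-relion"` (R = Rz(z1)·Ry(x)·Rz(z2)), intrinsic, active, acting on
  column vectors; positive = counter-clockwise by the right-hand rule.
  Worked example: (90°, 0, 0) in either dialect maps unit-x to unit-y.
  Gimbal-locked decompositions are canonicalized to z2 = 0.
* Microtubule lattice: subunits on the 1-start helix with rise 0.94 nm
  and twist −360°/n_pf per subunit (−27.7° for 13 protofilaments), tube
  diameter 30 nm.

## Worked example

Simulate 20 ring-decorated microtubules under realistic noise and run
the analysis:

```python
from tomolattice import DecorationSpec, make_synthetic_dataset, analyze_decoration

spec = DecorationSpec(mode="ring", occupancy=0.3,
                      ang_noise_sigma=5.0, pos_noise_sigma=0.5)
ds = make_synthetic_dataset(n_filaments=20, decoration_spec=spec, seed=1)
print(f"particles: {len(ds.particles)}")
res = analyze_decoration(ds.particles, ds.paths)
print(f"pairs in [5, 12] nm window: {len(res.pairs)}")
print(f"theta modal bin centre: {res.theta_mode:.1f} deg")
print(f"chain-length histogram: {res.chain_histogram}")
print(f"decoration density: {res.coverage_totals.particles_per_nm:.3f} particles/nm")
```

prints

```
particles: 3013
pairs in [5, 12] nm window: 1687
theta modal bin centre: 90.0 deg
chain-length histogram: {1: 509, 2: 349, 3: 236, 4: 116, 5: 62, 6: 54}
decoration density: 0.075 particles/nm
```

The θ histogram peaks in the bin centred on 90° — the ring-like
signature — and the recovered chain-length histogram spans single dimers
through 6-dimer oligomers, matching the planted truth (`ds.truth`)
exactly in the noiseless case. The density (0.075 dimers per nm of
filament, summed over all filaments) quantifies how sparse the
decoration is.

The same pipeline is scriptable from a shell:

```sh
tomolattice simulate --mode helix --theta 33 --n-filaments 20 --seed 1 --out-dir sim/
tomolattice pick     --traces sim/traces.txt --out grid.star
tomolattice filter   --particles sim/particles.star --out clean.star
tomolattice analyze  --particles clean.star --traces sim/traces.txt --out-dir analysis/
tomolattice report   --chains analysis/chains.tsv --sim-truth sim/truth.tsv
```

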