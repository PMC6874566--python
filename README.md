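# hookjoint

Geometric analysis of supercoiled helical polymer assemblies, built around
the bacterial flagellar hook — the short, supercoiled tube of FlgE subunits
that works as the flagellum's universal joint.

The hook is an 11-protofilament tubular lattice: consecutive subunits along
the 1-start helix advance by Δφ ≈ 65.45° in azimuth and Δz ≈ 4.15 Å along
the tube axis, so subunits k and k+11 stack axially within one
protofilament at a straight-form repeat of d₀ = 45.6 Å. When the tube
supercoils, each protofilament compresses or extends according to the
elastic-bending law

    d(ρ, φ) = d₀ · (1 − κ·ρ·cos(φ − φc)),

where κ is the centerline curvature, ρ the radial position of a residue
and φc the azimuth of the bend center; the supercoil's radius R and pitch
P follow from the centerline curvature and torsion by the inverse Frenet
relations R = κ/(κ²+τ²), P = 2π|τ|/(κ²+τ²), with left-handedness ⇔ τ < 0.

`hookjoint` measures all of this from atomic coordinates:

- **structure_io** — mmCIF/PDB input (via gemmi), domain definitions,
  CSV/JSON output with metadata sidecars;
- **lattice** — tube-axis estimation, 1-start lattice indexing, −5/6/11-start
  neighbor maps, protofilament assignment and the extended=1 / compressed=6,7
  numbering convention;
- **protofilament** — per-residue axial Cα spacing maps, per-domain
  compression/extension statistics, elastic-bending consistency;
- **domain_motion** — Kabsch superposition, the 11 per-protofilament
  conformation classes, inner-domain-referenced tilts and axial shifts,
  subunit length extension;
- **supercoil** — discrete curvature/torsion of the centerline,
  least-squares helix fitting (with a coiled-tube refinement that fits the
  full lattice deformation field), extension of a segment to one supercoil
  pitch;
- **contacts** — residue-level interfaces along the three lattice
  directions, constant vs switching classification across the 11
  protofilament contexts, per-residue neighbor-distance variability, the
  inter-domain triangle gap;
- **synthetic** — a coarse-grained generator of straight and supercoiled
  assemblies with full ground truth, so every stage is verifiable by
  parameter recovery;
- **pipeline / cli** — end-to-end orchestration (`hookjoint analyze`,
  `synth`, `recover`, `report`).

## Worked example

Generate a synthetic assembly at the native supercoil geometry
(pitch 1290 Å, diameter 330 Å, left-handed, 26 subunits) and analyze it:

```sh
hookjoint synth --preset native --seed 3 --out hook.pdb
echo '{"D0c": [[1,30]], "D1": [[31,70]], "D2": [[71,105]]}' > domains.json
hookjoint analyze hook.pdb --cutoff 18 --domains domains.json --outdir out
hookjoint report out/summary.json
```

prints

```
subunits: 26  protofilaments: 11  conformation classes: 11
axial spacing: min 37.1 Å (pf 7), max 54.1 Å (pf 1), reference d0 45.6 Å
supercoil: left-handed, pitch 129.0 nm, diameter 33.0 nm
domain motion (compressed → extended): D0c: tilt 0.0°, shift -0.0 Å,
D1: tilt 1.3°, shift 0.1 Å, D2: tilt 1.5°, shift 0.1 Å;
subunit length extension 3.6 Å
```

Reading the output: the lattice indexing found all 11 protofilaments and
one conformation class per protofilament; the most extended protofilament
(labeled 1) runs along the outside of the bend and the most compressed
(6–7) along the inside, with the spacing extremes symmetric about the
straight-form 45.6 Å — the signature of pure elastic bending. The
centerline analysis recovers the generator's left-handed supercoil with
pitch 129 nm and diameter 33 nm, and the residual inter-domain tilts
reflect the bending-induced conformational gradient around the
circumference.

The same `analyze` command accepts any mmCIF/PDB helical assembly; for a
real hook model, use the default contact cutoff (4 Å heavy-atom) and the
built-in FlgE domain ranges.

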