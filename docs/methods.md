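# Methods

This note documents the models, conventions and numerical choices behind
memglyco, and what the synthetic generators do and do not emulate.

## Conventions

Coordinates are in Å throughout. The bilayer normal is the +z axis and
z = 0 is the membrane centre of mass; systems are assumed pre-oriented (no
per-frame normal refitting). Residue numbering is 1-based; atom indices are
0-based. Energies are kcal/mol, temperatures K, times ps (configs take the
time step in fs).

The peptide fixture is a 21-residue Cα-bead ideal α-helix (rise 1.5 Å,
twist 100°, radius 2.3 Å — canonical α-helix values) with one glycan bead
3 Å radially outward of residue 7's Cα. Only the residue identities that
are documented for the sequence are encoded (Thr1, Arg3, Val4, Glu5, Arg6,
Asn7+glycan, Gly8, His9, Phe12, Tyr13, Ala14, Pro15, Tyr16, Trp18, Lys21);
the remaining positions are alanine placeholders and are flagged as such by
`csf114_sequence()`, so the package never silently invents sequence.

## Contact collective variable

`s(r) = [1 − (r/r0)^n] / [1 − (r/r0)^m]`, defaults r0 = 5 Å, n = 8,
m = 16. The removable singularity at r = r0 is handled analytically
(returns n/m exactly); for r/r0 below ≈0.5 the deviation from 1 underflows
double precision, so strict monotonicity is only resolvable beyond that.
Distances use the minimum-image convention when a frame carries an
orthorhombic box, plain Euclidean otherwise. The pair sum is evaluated with
a vectorised all-pairs distance matrix; tests pin it to an explicit double
loop at 1e-10 relative.

**Normalization.** The bound threshold (s > 0.5) is an absolute number, so
the scale of s matters. The default divides the raw pair sum by the size of
the peptide-side selection, making "one ideal contact per tracked atom"
give s ≈ 1 regardless of how many atoms a face contains; the raw sum is
available for sensitivity analysis. Whether published per-face contact
traces are normalized is generally not stated, which is why this is
configuration rather than a fixed claim.

**Helix faces.** Side 1 defaults to the Cα atoms of residues {3, 6, 7, 18}
(the glycosylated face: the arginines, the glycosylated asparagine and the
interfacial tryptophan); Side 2 to {1, 12, 16}. The face lists are fully
overridable in the config: exact per-atom lists are a property of a
particular study, not of the method. Trp18 is reported to engage the
membrane in both binding modes; it is assigned to Side 1 because the two
side selections must be disjoint for the per-side series to be meaningful.

## Funnel restraint

Boundary radius r(z) = Rcyl + max(0, Zcc − z)·tan(α) — a cone with its
wide end at the membrane narrowing to a cylinder toward the solvent;
defaults α = 0.8 rad, Rcyl = 1 Å, Zcc = 35 Å. The wall is a one-sided
(flat-bottom) harmonic in the radial excess, the standard form in the
funnelled-sampling literature; stiffness defaults to 10 kcal mol⁻¹ Å⁻²
(rarely stated in applications, hence configurable). An optional top wall
closes the cylinder at z_max (default 45 Å, 10 Å beyond Zcc, mirroring a
35 Å initial peptide–membrane separation). Points exactly on the boundary
are unbiased (closed interior) so the frame-exclusion flag of the
measure-zero boundary case is deterministic. Frame flags test the wall
energy at the unweighted geometric centre of the tracked selection
(whether a published protocol restrained the centre of mass or all atoms is
typically unstated; the tracked selection is configurable).

## Pose clustering

Pairwise superposition-minimised RMSD over the helix-core Cα atoms
(residues 5–12; 8 atoms) via Kabsch SVD with the proper-rotation sign fix;
the pair matrix uses batched 3×3 SVDs that tests pin to the scalar path.
Agglomeration is unweighted average linkage (Lance–Williams update). Ties
on the minimal inter-cluster distance are broken toward the smallest
(i, j) pair of active cluster ids in lexicographic condensed order, making
merge trees identical across platforms. The tree is cut at a fixed family
count (default 10, matching the convention of reporting ten families per
binding mode); an insufficient number of bound frames yields an empty
cluster table rather than an error. The cluster average structure is an
iterative mean: members are re-superposed onto the running mean until it
moves < 1e-6 Å; the representative is the member with the lowest core-Cα
RMSD to that average (ties → lowest frame index). For very long bound
segments the pipeline thins frames deterministically (evenly spaced,
default cap 800) before building the O(k²) matrix.

## Order parameters

S_CD(k) = ⟨(3cos²θ − 1)/2⟩ over hydrogens × lipids × retained frames, with
θ against the fixed +z normal; both leaflets are pooled by default (a
per-leaflet breakdown is available; mirror symmetry makes pooling exact for
the synthetic bilayer). The signed quantity is reported alongside |S_CD|,
since plots conventionally show the magnitude while the definition is
signed. Uncertainty is the standard error over 5 contiguous frame blocks.
Explicit hydrogens are used when present; otherwise two tetrahedral
methylene H directions are reconstructed from the two chain-neighbour
carbons (terminal carbons, including the C14 methyl, are excluded from
reconstruction). Profile comparison flags a carbon when |ΔS_CD| exceeds
2× the combined standard error plus a 1e-6 absolute floor (the floor
guards the zero-variance fixed-angle fixtures) and reports the deepest
flagged carbon per chain.

## Synthetic generators

**Binding simulator.** A rigid Cα-bead helix (no internal degrees of
freedom — mirroring protocols that restrain the helical backbone during
funnelled sampling) undergoes rigid-body Langevin dynamics at 300 K:
BAOAB splitting for translation, with free-rotor propagation by a
symmetric per-principal-axis (NO_SQUISH-style) factorisation and an
Ornstein–Uhlenbeck thermostat on the body-frame angular momentum. With
friction and noise disabled the integrator conserves energy with the
expected O(dt²) drift (tested by halving dt). The default time step is
10 fs at friction 0.2 ps⁻¹ with 110 g/mol per bead.

The membrane is implicit: each bead feels a Gaussian attraction of width
1.2 Å centred at the surface (z = 18 Å) with class-dependent depth —
glycan 2.5, basic (Arg/Lys/His) 1.2, aromatic (Trp/Tyr/Phe) 0.15,
other 0.03 kcal/mol — plus a per-bead harmonic repulsion below
z_surface − 1.5 Å (2 kcal mol⁻¹ Å⁻²) representing the impenetrable bilayer
interior. The repulsion matters structurally: a purely Gaussian well is
mirror-symmetric about the surface plane, so no face preference could
exist without it. Depths were chosen by a Boltzmann average of the
(orientation × height) energy surface to give a clear Side-1 preference
(equilibrium Side-1 probability ≈ 0.97) at a binding depth of
≈ −7 kcal/mol; the ordering encodes glycan H-bonding > arginine salt
bridges > interfacial aromatics > weak backbone contacts. A static square
lattice of phosphate markers (4 Å spacing) at the surface makes the contact
CV computable on emitted frames. Beads get 0.15 Å Gaussian jitter on
output only (thermal fluctuation of a restrained backbone; dynamics are
unaffected), which keeps the pose-clustering stage non-degenerate.

Ground truth is recomputed from the emitted frames by fixed rules: bound
iff the peptide-bead centre of mass is below 25.4 Å — the height at which
a flat-lying helix's per-atom contact CV over the default lattice crosses
the 0.5 threshold, so the distance rule and the contact rule label the
same physical state — and the side label from the sign of the Side-1 face's
mean height relative to the helix axis. Labels are therefore exactly
reproducible from any stored trajectory (`recompute_ground_truth`).

Diagnostic modes: `harmonic_trap` (translation-only, for the
⟨x²⟩ = k_BT/k equipartition check) and `com_well` (the membrane well acting
on the centre of mass only, orientation-independent, so the bound fraction
has a closed numeric Boltzmann oracle via a 2-D (z, ρ) integral).

**What the simulator does not emulate:** explicit lipids, water,
electrostatics, peptide flexibility, or the specific bound geometries of
any real peptide. Passing tests show the *analysis* stages are correct and
internally consistent on systems with known truth; they do not validate
force-field-level claims about real membranes.

**Bilayer generator.** DMPC-like all-trans zig-zag chains (c1 = sn-1,
c2 = sn-2, carbons 2–14, two leaflets mirrored in z) with explicit
hydrogens drawn at the fixed polar angle θ* = arccos(√((2S*+1)/3)) and
uniform azimuth, which realises any target S* ∈ (−0.5, 1] exactly (the
azimuth does not change cos θ); a noisy mode adds Gaussian angular spread.
It emulates prescribed per-carbon order, not lipid conformational
statistics.

**Cluster fixture.** Frames drawn from reference Cα conformations with
isotropic Gaussian noise and random rigid moves, labels recorded.

All generators are pure functions of (seed, parameters); identical seeds
give bitwise-identical output. Each operation draws from its own named
`numpy` Generator seeded from the config; there is no global random state.

## Problem sizes used in the shipped checks

The packaged verification runs are desk-scale by design: 2 ns (200k steps)
for the end-to-end binding analysis, 10⁶ steps for equipartition, 3 ns for
the two-state occupancy check, 200 random matrices (k ≤ 6) for the
clustering oracle, 10⁵ samples for the isotropic order-parameter null, and
16-lipid bilayers for profile comparisons. These sizes give the statistical
resolution the assertions need (e.g. ≈2% on ⟨x²⟩, exact recovery where the
construction is exact) while keeping the whole suite in minutes.

## Known limitations

- The funnel wall stiffness, top-wall placement and tracked point are
  conventions with documented defaults, not universally published values.
- Average linkage at the default cap (800 frames) is O(k³) in the worst
  case; thinning is deterministic but discards within-segment detail.
- The bilayer generator's chains are static skeletons; only C–H
  orientations fluctuate, so it cannot test normal-refitting or
  chain-packing effects.
- Side labels for a tilted, barely-bound helix are a hard classification
  of a continuous orientation; frames near the threshold legitimately
  disagree with the contact rule at the percent level, which is why
  bound-fraction comparisons are made at block-averaged statistical
  resolution.
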