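# memglyco

Analysis toolkit for peptide–membrane binding simulations, built around the
workflow used to characterise how an N-glucosylated 21-residue α-helical
peptide (CSF114(Glc), a multiple-sclerosis antibody biomarker candidate)
binds a DMPC bilayer: funnel-restrained sampling geometry, a
switching-function contact collective variable, bound-pose classification
and clustering, and lipid acyl-chain order parameters. A synthetic-data
module generates coarse-grained Langevin binding trajectories and bilayer
frames with known ground truth, so every analysis stage is testable end to
end.

Intended users: simulation practitioners who want a reproducible, tested
pipeline for "did the peptide bind, with which helical face, in which pose
families, and what did it do to the membrane?" questions on their own
trajectories or on the bundled synthetic systems.

## The quantities computed

**Contact collective variable.** The degree of peptide–membrane contact in
a frame is a smooth pair count over a peptide selection *A* (e.g. the Cα
atoms of one helix face) and the membrane phosphate groups *B*:

```
s = (1/|A|) Σ_{i∈A} Σ_{j∈B} [1 − (r_ij/r0)^n] / [1 − (r_ij/r0)^m]
```

with r0 = 5 Å, n = 8, m = 16 by default. Each term decays smoothly from 1
(contact) to 0 (far), taking the analytic value n/m = 0.5 at r = r0. A
frame is a **bound pose** when s > 0.5 (strict). Two opposite helix faces
are tracked: Side 1 carries the glycosylated residue, Side 2 is the
complementary face.

**Funnel restraint.** A cone of half-angle α = 0.8 rad whose wide end
embraces the membrane narrows to a cylinder of radius Rcyl = 1 Å at
Zcc = 35 Å above the membrane centre, with a one-sided harmonic wall
(default 10 kcal mol⁻¹ Å⁻²). Frames in which the tracked selection feels
the wall are excluded from all statistics.

**Pose clustering.** Bound frames are compared by superposition-minimised
RMSD over the helix-core Cα atoms (residues 5–12), agglomerated by
unweighted average linkage, cut to a configurable number of families
(default 10); each family is reported with its population and the member
closest to the family's iteratively superposed average structure.

**Chain order parameters.** Per carbon k of the sn-1 (c1) and sn-2 (c2)
acyl chains (carbons 2–14 for a DMPC-like myristoyl chain):

```
S_CD(k) = ⟨ (3 cos²θ − 1) / 2 ⟩
```

where θ is the angle between a C–H bond vector and the bilayer normal;
+1 means aligned, −0.5 perpendicular, 0 isotropic. Profiles of two systems
(e.g. bilayer with and without peptide) are compared per carbon with
block-averaged uncertainties, reporting how deep into the chain the
perturbation reaches.

## Worked example

Simulate a funnel-restrained binding trajectory of the glycopeptide at
300 K (2 ns of coarse Langevin dynamics, frames every 2 ps) and run the
full binding analysis:

```python
from memglyco import (SimulationConfig, csf114_helix,
                      simulate_funnel_langevin, run_binding_analysis)

topology, frame = csf114_helix()
config = SimulationConfig(n_steps=200_000, stride=200, seed=1)
trajectory, truth = simulate_funnel_langevin(topology, frame, config)
report = run_binding_analysis({}, trajectory=trajectory)
```

Output (printed from the report object):

```
frames: 1001 (31 excluded by the funnel wall)
mean contact CV  Side1: 4.695  Side2: 3.208
bound fraction: 0.988 (ground truth 0.976)
 cluster  population  fraction  representative_frame
       0         773   0.96625                   783
       2           5   0.00625                   493
       3           4   0.00500                   126
top cluster Side1 purity: 0.920
```

Reading this: 31 of 1001 frames touched the funnel wall and were dropped;
the glycosylated face (Side 1) shows a higher mean contact CV than the
opposite face; 98.8% of retained frames are bound (the generator's own
distance-rule labels say 97.6%); the dominant pose family holds 97% of the
clustered bound frames and is 92% ground-truth Side 1 — the pipeline
recovers the generator's built-in preference for binding through the
glycosylated face.

The same stages are available as a CLI (`memglyco synth simulate`,
`memglyco funnel-check`, `memglyco contacts`, `memglyco cluster`,
`memglyco scd`, `memglyco run`, `memglyco validate`), all driven by one
YAML config whose defaults are the parameter set above.

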