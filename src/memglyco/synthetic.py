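"""Synthetic systems with known ground truth.

Everything the analysis stages consume can be generated here with labels
attached: an ideal rigid α-helix peptide (Cα beads plus one glycan bead)
diffusing, binding and unbinding at an implicit planar bilayer inside a
funnel restraint; bilayer frames whose acyl-chain C-H orientations realise a
prescribed per-carbon order parameter exactly; and pose-family fixtures for
the clustering stage.

The binding simulator is a rigid-body Langevin (BAOAB) integrator at 300 K:
translation of the centre of mass plus rotation about it (NO_SQUISH free-
rotor splitting on the principal axes).  The membrane is an implicit smooth
well: each bead feels a Gaussian attraction of class-dependent depth centred
at the membrane surface, so the glycosylated/basic face ("Side 1") binds
more strongly than the opposite face — the behaviour the analysis pipeline
is meant to detect.  Explicit lipid coordinates appear only in the bilayer
generator; the binding trajectories carry a static phosphate lattice so the
contact CV is computable.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .contacts import SIDE1_DEFAULT_RESIDUES, SwitchingParams, switch
from .errors import IntegrationError, StructureError
from .funnel import FunnelGeometry, bias_energy, bias_force
from .model_io import (Frame, Topology, Trajectory, csf114_sequence,
                       CSF114_GLYCAN_RESIDUE)

__all__ = ["SimulationConfig", "GroundTruth", "build_ideal_helix",
           "simulate_funnel_langevin", "gen_bilayer_frames",
           "make_cluster_fixture", "recompute_ground_truth",
           "build_phosphate_lattice", "csf114_helix"]

KB = 0.0019872041          # kcal/mol/K
KCAL = 418.4               # (g/mol)(A/ps)^2 per kcal/mol

BASIC_RESIDUES = {"ARG", "LYS", "HIS"}
AROMATIC_RESIDUES = {"TRP", "TYR", "PHE"}

# COM height (A) at which the per-atom contact CV of a flat-lying helix over
# the default phosphate lattice crosses the 0.5 bound threshold; the
# ground-truth distance rule uses this so both rules label the same state.
DEFAULT_BOUND_Z_CUTOFF = 25.4


# ---------------------------------------------------------------------------
# Ideal helix
# ---------------------------------------------------------------------------

def build_ideal_helix(sequence: list[str], rise: float = 1.5,
                      twist_deg: float = 100.0, radius: float = 2.3,
                      glycan_residue: int | None = None,
                      ) -> tuple[Topology, Frame]:
    """Cα-only ideal α-helix along +x, centred at the origin.

    Canonical α-helix parameters: 1.5 A rise and 100 degrees twist per
    residue on a 2.3 A radius, so the helix faces point along ±z when the
    peptide lies on the membrane.  If ``glycan_residue`` is given, one extra
    glycan bead is placed 3 A radially outward from that residue's Cα.
    """
    n = len(sequence)
    if n < 5:
        raise ValueError(f"sequence too short ({n} residues; need >= 5)")
    i = np.arange(n)
    theta = np.deg2rad(twist_deg) * i
    coords = np.column_stack([
        (i - (n - 1) / 2.0) * rise,
        radius * np.cos(theta),
        radius * np.sin(theta),
    ])
    names = ["CA"] * n
    elements = ["C"] * n
    res_ids = list(range(1, n + 1))
    res_names = [s.upper() for s in sequence]
    hetero = [False] * n
    if glycan_residue is not None:
        if not (1 <= glycan_residue <= n):
            raise ValueError(f"glycan residue {glycan_residue} outside 1..{n}")
        gi = glycan_residue - 1
        direction = np.array([0.0, np.cos(theta[gi]), np.sin(theta[gi])])
        coords = np.vstack([coords, coords[gi] + 3.0 * direction])
        names.append("GLC")
        elements.append("C")
        res_ids.append(glycan_residue)
        res_names.append("GLC")
        hetero.append(True)
    topology = Topology(
        names=np.array(names), elements=np.array(elements),
        res_ids=np.array(res_ids), res_names=np.array(res_names),
        chain_ids=np.array(["P"] * len(names)),
        hetero=np.array(hetero))
    return topology, Frame(coordinates=coords)


def csf114_helix() -> tuple[Topology, Frame]:
    """The bundled 21-residue glycopeptide fixture (glycan bead on residue 7)."""
    codes, _ = csf114_sequence()
    return build_ideal_helix(codes, glycan_residue=CSF114_GLYCAN_RESIDUE)


def _bead_classes(topology: Topology) -> np.ndarray:
    classes = []
    for name, res_name, het in zip(topology.names, topology.res_names,
                                   topology.hetero):
        if het or name == "GLC":
            classes.append("glycan")
        elif res_name in BASIC_RESIDUES:
            classes.append("basic")
        elif res_name in AROMATIC_RESIDUES:
            classes.append("aromatic")
        else:
            classes.append("other")
    return np.array(classes)


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the coarse binding simulator.

    The physical set-point mirrors the production simulations of the study:
    300 K Langevin dynamics inside the funnel with alpha = 0.8 rad,
    Rcyl = 1 A, Zcc = 35 A.  Well depths are per bead class (kcal/mol) so
    the glycan/basic face binds more strongly.
    """

    temperature: float = 300.0          # K
    friction: float = 0.2               # ps^-1
    dt_fs: float = 10.0                 # fs
    n_steps: int = 500_000
    stride: int = 250                   # store every `stride` steps
    seed: int = 0
    well_depths: dict = field(default_factory=lambda: {
        "glycan": 2.5, "basic": 1.2, "aromatic": 0.15, "other": 0.03})
    well_width: float = 1.2             # A, Gaussian width of the surface well
    z_surface: float = 18.0             # A, membrane surface above the centre
    bound_z_cutoff: float = DEFAULT_BOUND_Z_CUTOFF
    funnel: FunnelGeometry = field(default_factory=FunnelGeometry)
    mass_per_bead: float = 110.0        # g/mol
    mode: str = "membrane"              # membrane | com_well | harmonic_trap
    com_well_depth: float = 1.2         # kcal/mol (com_well mode)
    trap_k: float = 1.0                 # kcal/mol/A^2 (harmonic_trap mode)
    jitter_sigma: float = 0.15          # A, thermal bead jitter on output
    bottom_wall_z: float = 12.0         # A, COM repulsion below this height
    k_bottom: float = 10.0              # kcal/mol/A^2
    core_offset: float = 1.5            # A, beads repelled below z_surface - offset
    k_core: float = 2.0                 # kcal/mol/A^2, per-bead core stiffness
    start_z: float = 35.0               # A, initial COM height
    phosphate_spacing: float = 4.0      # A
    phosphate_halfwidth: float = 28.0   # A

    def __post_init__(self):
        if self.dt_fs <= 0 or self.temperature <= 0:
            raise ValueError("dt and temperature must be positive")
        if self.mode not in ("membrane", "com_well", "harmonic_trap"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class GroundTruth:
    """Per-frame labels emitted with every simulated trajectory."""

    bound: np.ndarray                 # (n_frames,) bool
    side: np.ndarray                  # (n_frames,) 'Side1' | 'Side2' | 'none'
    events: list[tuple[int, str]]     # (frame index, 'bind'|'unbind')
    bound_fraction: float
    seed: int


def build_phosphate_lattice(config: SimulationConfig) -> tuple[Topology, np.ndarray]:
    """Static square lattice of phosphate markers at the membrane surface."""
    hw, a = config.phosphate_halfwidth, config.phosphate_spacing
    ticks = np.arange(-hw, hw + 0.5 * a, a)
    xx, yy = np.meshgrid(ticks, ticks, indexing="ij")
    coords = np.column_stack([xx.ravel(), yy.ravel(),
                              np.full(xx.size, config.z_surface)])
    n = len(coords)
    topology = Topology(
        names=np.array(["P"] * n), elements=np.array(["P"] * n),
        res_ids=np.arange(1, n + 1), res_names=np.array(["PO4"] * n),
        chain_ids=np.array(["M"] * n), hetero=np.zeros(n, dtype=bool))
    return topology, coords


def _merge_topologies(pep: Topology, mem: Topology) -> Topology:
    return Topology(
        names=np.concatenate([pep.names, mem.names]),
        elements=np.concatenate([pep.elements, mem.elements]),
        res_ids=np.concatenate([pep.res_ids, mem.res_ids]),
        res_names=np.concatenate([pep.res_names, mem.res_names]),
        chain_ids=np.concatenate([pep.chain_ids, mem.chain_ids]),
        hetero=np.concatenate([pep.hetero, mem.hetero]))


# ---------------------------------------------------------------------------
# Rigid-body Langevin integrator
# ---------------------------------------------------------------------------

def _free_rotor(rot: np.ndarray, l_body: np.ndarray, inertia: np.ndarray,
                h: float) -> tuple[np.ndarray, np.ndarray]:
    """NO_SQUISH-style free rigid-body propagation for time h.

    Symmetric Trotter splitting of the free-rotor Hamiltonian into the three
    principal-axis terms; each factor rotates the orientation and the other
    two angular-momentum components about one principal axis.
    """
    def axis_rotation(k, dt):
        nonlocal rot, l_body
        phi = dt * l_body[k] / inertia[k]
        c, s = np.cos(phi), np.sin(phi)
        i, j = (k + 1) % 3, (k + 2) % 3
        li, lj = l_body[i], l_body[j]
        l_body = l_body.copy()
        l_body[i] = c * li - s * lj
        l_body[j] = s * li + c * lj
        axis_rot = np.eye(3)
        axis_rot[i, i] = c; axis_rot[i, j] = -s
        axis_rot[j, i] = s; axis_rot[j, j] = c
        rot = rot @ axis_rot

    axis_rotation(0, h / 2)
    axis_rotation(1, h / 2)
    axis_rotation(2, h)
    axis_rotation(1, h / 2)
    axis_rotation(0, h / 2)
    return rot, l_body


def _forces(q: np.ndarray, rot: np.ndarray, body: np.ndarray,
            classes_eps: np.ndarray, config: SimulationConfig
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """Total force on the COM (kcal/mol/A), body-frame torque and potential."""
    force = np.zeros(3)
    torque_lab = np.zeros(3)
    potential = 0.0
    if config.mode == "harmonic_trap":
        force -= config.trap_k * q
        potential += 0.5 * config.trap_k * float(q @ q)
        return force, torque_lab, potential
    if config.mode == "membrane":
        pos = q + body @ rot.T
        dz = pos[:, 2] - config.z_surface
        gauss = np.exp(-dz ** 2 / (2.0 * config.well_width ** 2))
        potential += float(-(classes_eps * gauss).sum())
        fz = -classes_eps * gauss * dz / config.well_width ** 2
        # per-bead repulsive core below the headgroup region: beads cannot
        # sink into the bilayer interior; this breaks the mirror symmetry of
        # the Gaussian well so face preference can exist at all
        core_z = config.z_surface - config.core_offset
        depth = np.maximum(0.0, core_z - pos[:, 2])
        potential += float(0.5 * config.k_core * (depth ** 2).sum())
        fz = fz + config.k_core * depth
        bead_forces = np.zeros_like(pos)
        bead_forces[:, 2] = fz
        force += bead_forces.sum(axis=0)
        rel = pos - q
        # torque = sum rel x F with F purely along z
        torque_lab += np.array([
            float(rel[:, 1] @ fz), float(-(rel[:, 0] @ fz)), 0.0])
    else:  # com_well
        dz = q[2] - config.z_surface
        gauss = np.exp(-dz ** 2 / (2.0 * config.well_width ** 2))
        potential += -config.com_well_depth * gauss
        force[2] += -config.com_well_depth * gauss * dz / config.well_width ** 2
    # repulsive core below the surface region (the bilayer interior)
    if q[2] < config.bottom_wall_z:
        d = config.bottom_wall_z - q[2]
        potential += 0.5 * config.k_bottom * d ** 2
        force[2] += config.k_bottom * d
    # funnel wall on the COM
    potential += bias_energy(q, config.funnel)
    force += bias_force(q, config.funnel)
    return force, rot.T @ torque_lab, potential


def simulate_funnel_langevin(helix_topology: Topology, helix_frame: Frame,
                             config: SimulationConfig,
                             return_energies: bool = False):
    """Rigid-body Langevin dynamics of the helix in the funnel.

    Returns ``(Trajectory, GroundTruth)`` (plus an ``(n_frames, 2)`` array of
    kinetic/potential energies in kcal/mol when ``return_energies`` is set).
    The same seed always yields a bitwise-identical trajectory.
    """
    rng_dyn = np.random.default_rng([config.seed, 1])
    rng_jitter = np.random.default_rng([config.seed, 2])
    body_raw = helix_frame.coordinates - helix_frame.coordinates.mean(axis=0)
    n_beads = len(body_raw)
    mass = config.mass_per_bead
    total_mass = mass * n_beads
    # principal body frame: diagonal inertia
    inertia_tensor = mass * ((body_raw ** 2).sum() * np.eye(3)
                             - body_raw.T @ body_raw)
    inertia, axes = np.linalg.eigh(inertia_tensor)
    body = body_raw @ axes  # coordinates in the principal frame
    classes = _bead_classes(helix_topology)
    classes_eps = np.array([config.well_depths.get(c, 0.0) for c in classes])

    dt = config.dt_fs * 1e-3  # ps
    kt = KB * config.temperature * KCAL  # (g/mol)(A/ps)^2
    gamma = config.friction
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    translation_only = config.mode == "harmonic_trap"

    q = np.array([0.0, 0.0, config.start_z])
    rot = np.eye(3)
    v = rng_dyn.normal(0.0, np.sqrt(kt / total_mass), 3)
    l_body = rng_dyn.normal(0.0, np.sqrt(kt * inertia), 3)

    force, torque, potential = _forces(q, rot, body, classes_eps, config)
    frames: list[Frame] = []
    energies: list[tuple[float, float]] = []

    mem_topology, mem_coords = (None, None)
    if config.mode == "membrane":
        mem_topology, mem_coords = build_phosphate_lattice(config)

    def record():
        pep = q + body @ rot.T
        if config.jitter_sigma > 0:
            pep = pep + rng_jitter.normal(0.0, config.jitter_sigma, pep.shape)
        coords = pep if mem_coords is None else np.vstack([pep, mem_coords])
        frames.append(Frame(coordinates=coords,
                            time=len(frames) * config.stride * dt))
        if return_energies:
            ke = 0.5 * total_mass * float(v @ v)
            if not translation_only:
                ke += 0.5 * float((l_body ** 2 / inertia).sum())
            energies.append((ke / KCAL, potential))

    record()
    for step in range(1, config.n_steps + 1):
        half_kick = 0.5 * dt * KCAL
        v = v + half_kick * force / total_mass
        if not translation_only:
            l_body = l_body + 0.5 * dt * torque * KCAL
        q = q + 0.5 * dt * v
        if not translation_only:
            rot, l_body = _free_rotor(rot, l_body, inertia, 0.5 * dt)
        if gamma > 0.0:
            v = c1 * v + c2 * np.sqrt(kt / total_mass) * rng_dyn.normal(size=3)
            if not translation_only:
                l_body = (c1 * l_body
                          + c2 * np.sqrt(kt * inertia) * rng_dyn.normal(size=3))
        q = q + 0.5 * dt * v
        if not translation_only:
            rot, l_body = _free_rotor(rot, l_body, inertia, 0.5 * dt)
        force, torque, potential = _forces(q, rot, body, classes_eps, config)
        v = v + half_kick * force / total_mass
        if not translation_only:
            l_body = l_body + 0.5 * dt * torque * KCAL
        if not np.isfinite(q).all() or abs(q).max() > 1e4:
            raise IntegrationError("coordinate overflow; reduce the time step",
                                   step=step)
        if step % config.stride == 0:
            record()

    topology = (helix_topology if mem_topology is None
                else _merge_topologies(helix_topology, mem_topology))
    trajectory = Trajectory(topology=topology, frames=frames,
                            stride_ps=config.stride * dt)
    truth = recompute_ground_truth(trajectory, config)
    if return_energies:
        return trajectory, truth, np.array(energies)
    return trajectory, truth


def recompute_ground_truth(trajectory: Trajectory, config: SimulationConfig,
                           side1_residues=SIDE1_DEFAULT_RESIDUES) -> GroundTruth:
    """Reapply the labelling rules to an emitted trajectory.

    Bound iff the peptide-bead COM height is below ``bound_z_cutoff``; the
    side of a bound frame is Side1 when the Side1 face (mean of its Cα
    beads) points below the helix axis, Side2 otherwise.
    """
    top = trajectory.topology
    pep_idx = np.flatnonzero(top.peptide_mask())
    ca_mask = (top.names[pep_idx] == "CA")
    ca_idx = pep_idx[ca_mask]
    side1_idx = ca_idx[np.isin(top.res_ids[ca_idx], list(side1_residues))]
    bound = np.empty(trajectory.n_frames, dtype=bool)
    side = np.empty(trajectory.n_frames, dtype="U5")
    for k, frame in enumerate(trajectory.frames):
        com_z = frame.coordinates[pep_idx, 2].mean()
        bound[k] = com_z < config.bound_z_cutoff
        if bound[k]:
            d1z = (frame.coordinates[side1_idx, 2].mean()
                   - frame.coordinates[ca_idx, 2].mean())
            side[k] = "Side1" if d1z < 0 else "Side2"
        else:
            side[k] = "none"
    events: list[tuple[int, str]] = []
    for k in range(1, len(bound)):
        if bound[k] and not bound[k - 1]:
            events.append((k, "bind"))
        elif bound[k - 1] and not bound[k]:
            events.append((k, "unbind"))
    return GroundTruth(bound=bound, side=side, events=events,
                       bound_fraction=float(bound.mean()), seed=config.seed)


def calibrate_bound_cutoff(config: SimulationConfig | None = None,
                           params: SwitchingParams = SwitchingParams(),
                           threshold: float = 0.5) -> float:
    """COM height at which a flat-lying helix's per-atom contact CV over the
    phosphate lattice equals the bound threshold (bisection).

    This defines the ground-truth distance cutoff so the distance rule and
    the contact rule describe the same physical state.
    """
    from .contacts import SIDE2_DEFAULT_RESIDUES
    config = config or SimulationConfig()
    topology, frame = csf114_helix()
    _, lattice = build_phosphate_lattice(config)
    ca = np.flatnonzero(topology.names == "CA")
    body = frame.coordinates - frame.coordinates.mean(axis=0)

    def crossing(sel: np.ndarray, flip: float) -> float:
        def mean_s(com_z: float) -> float:
            coords = body.copy()
            coords[:, 2] *= flip
            coords[:, 2] += com_z
            d = np.sqrt(((coords[sel][:, None, :] - lattice[None]) ** 2
                         ).sum(-1))
            return float(switch(d, params).sum()) / len(sel)

        lo, hi = config.z_surface, config.z_surface + 22.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if mean_s(mid) > threshold:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # each face in its membrane-facing orientation (Side1 down / Side2 down)
    side1 = ca[np.isin(topology.res_ids[ca], list(SIDE1_DEFAULT_RESIDUES))]
    side2 = ca[np.isin(topology.res_ids[ca], list(SIDE2_DEFAULT_RESIDUES))]
    return 0.5 * (crossing(side1, 1.0) + crossing(side2, -1.0))


# ---------------------------------------------------------------------------
# Bilayer generator
# ---------------------------------------------------------------------------

def _order_to_angle(s_target: float) -> float:
    if not (-0.5 < s_target <= 1.0):
        raise ValueError(f"target order {s_target} outside (-0.5, 1]")
    return float(np.arccos(np.sqrt((2.0 * s_target + 1.0) / 3.0)))


def _expand_targets(target, carbons) -> dict[int, float]:
    if np.isscalar(target):
        return {k: float(target) for k in carbons}
    if isinstance(target, dict):
        return {int(k): float(v) for k, v in target.items()}
    arr = np.asarray(target, dtype=float)
    if len(arr) != len(carbons):
        raise ValueError("per-carbon target length mismatch")
    return dict(zip(carbons, arr))


def gen_bilayer_frames(n_lipids: int, n_frames: int, target_order,
                       mode: str = "fixed-angle", seed: int = 0,
                       noise_deg: float = 10.0,
                       carbons=range(2, 15)) -> Trajectory:
    """DMPC-like bilayer frames with prescribed per-carbon chain order.

    C-H unit vectors are drawn at the fixed polar angle
    theta* = arccos(sqrt((2 S* + 1)/3)) with uniform azimuth, so in
    ``fixed-angle`` mode :func:`memglyco.order.scd_profile` recovers S*
    exactly; ``noisy`` adds Gaussian angular noise.  ``target_order`` may be
    a scalar, a {carbon: S*} map, a per-carbon sequence, or a
    {"c1": ..., "c2": ...} map of any of those.  Leaflets are mirror
    symmetric; ``n_lipids`` must be even.
    """
    if n_lipids % 2:
        raise ValueError("n_lipids must be even (two leaflets)")
    if mode not in ("fixed-angle", "noisy"):
        raise ValueError(f"unknown mode {mode!r}")
    carbons = list(carbons)
    if isinstance(target_order, dict) and set(target_order) <= {"c1", "c2"}:
        per_chain = {c: _expand_targets(target_order[c], carbons)
                     for c in ("c1", "c2")}
    else:
        shared = _expand_targets(target_order, carbons)
        per_chain = {"c1": shared, "c2": shared}
    angles = {c: {k: _order_to_angle(s) for k, s in per_chain[c].items()}
              for c in ("c1", "c2")}
    rng = np.random.default_rng([seed, 3])

    # static skeleton: all-trans zig-zag chains along z, heads outward
    names, elements, res_ids, res_names = [], [], [], []
    base_coords = []
    carbon_slots = []  # (atom offset of C, chain, carbon, lipid row, sign)
    per_side = n_lipids // 2
    grid = int(np.ceil(np.sqrt(per_side)))
    for lip in range(n_lipids):
        upper = lip < per_side
        sgn = 1.0 if upper else -1.0
        g = lip % per_side
        x0, y0 = (g % grid) * 8.0, (g // grid) * 8.0
        rid = lip + 1

        def add(name, xyz):
            names.append(name)
            elements.append(name[0])
            res_ids.append(rid)
            res_names.append("DMP")
            base_coords.append(xyz)

        add("P", np.array([x0, y0, sgn * 18.0]))
        add("N", np.array([x0, y0 + 1.0, sgn * 20.0]))
        for chain, prefix, xoff in (("c1", "C3", -1.5), ("c2", "C2", 1.5)):
            for k in carbons:
                z = sgn * (16.0 - (k - 2) * 1.25)
                x = x0 + xoff + (0.44 if k % 2 else -0.44)
                carbon_slots.append((len(names), chain, k, lip, sgn))
                add(f"{prefix}{k}", np.array([x, y0, z]))
                hp = ("HX", "HY") if chain == "c1" else ("HR", "HS")
                add(f"{hp[0]}{k}", np.zeros(3))  # filled per frame
                add(f"{hp[1]}{k}", np.zeros(3))
    base_coords = np.array(base_coords)
    topology = Topology(
        names=np.array(names), elements=np.array(elements),
        res_ids=np.array(res_ids), res_names=np.array(res_names),
        chain_ids=np.array(["M"] * len(names)),
        hetero=np.zeros(len(names), dtype=bool))

    frames = []
    bond = 1.09
    for _ in range(n_frames):
        coords = base_coords.copy()
        for c_at, chain, k, lip, sgn in carbon_slots:
            theta = angles[chain][k]
            if mode == "noisy":
                theta = abs(theta + rng.normal(0.0, np.deg2rad(noise_deg)))
            for h_off in (1, 2):
                phi = rng.uniform(0.0, 2.0 * np.pi)
                u = np.array([np.sin(theta) * np.cos(phi),
                              np.sin(theta) * np.sin(phi),
                              sgn * np.cos(theta)])
                coords[c_at + h_off] = coords[c_at] + bond * u
        frames.append(Frame(coordinates=coords))
    return Trajectory(topology=topology, frames=frames)


# ---------------------------------------------------------------------------
# Clustering fixture
# ---------------------------------------------------------------------------

def make_cluster_fixture(n_frames: int, mode_references: list[np.ndarray],
                         noise_sigma: float, weights, seed: int = 0,
                         rigid_moves: bool = True
                         ) -> tuple[Trajectory, np.ndarray]:
    """Frames drawn from reference Cα conformations with Gaussian noise and
    random rigid moves; returns the trajectory and the true mode labels."""
    refs = [np.asarray(r, dtype=float) for r in mode_references]
    n_atoms = refs[0].shape[0]
    if any(r.shape != (n_atoms, 3) for r in refs):
        raise StructureError("mode references have mismatched sizes")
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(refs) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must match reference count and sum to 1")
    rng = np.random.default_rng([seed, 4])
    labels = rng.choice(len(refs), size=n_frames, p=weights)
    frames = []
    for lbl in labels:
        coords = refs[lbl] + rng.normal(0.0, noise_sigma, (n_atoms, 3))
        if rigid_moves:
            rot = Rotation.random(rng=rng).as_matrix()
            trans = rng.uniform(-10.0, 10.0, 3)
            coords = coords @ rot.T + trans
        frames.append(Frame(coordinates=coords))
    topology = Topology(
        names=np.array(["CA"] * n_atoms), elements=np.array(["C"] * n_atoms),
        res_ids=np.arange(1, n_atoms + 1), res_names=np.array(["ALA"] * n_atoms),
        chain_ids=np.array(["P"] * n_atoms), hetero=np.zeros(n_atoms, dtype=bool))
    return Trajectory(topology=topology, frames=frames), labels
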