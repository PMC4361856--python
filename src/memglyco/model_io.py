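"""Domain types and file I/O for peptide-membrane trajectories.

Conventions used throughout the package:

* coordinates are in Angstrom; the bilayer normal is +z and z = 0 sits at the
  membrane centre of mass;
* residue numbering is 1-based (Thr1 ... Lys21), atom indices are 0-based;
* multi-model PDB is the primary container (MODEL/ENDMDL delimited, chain ID
  ``P`` for the peptide, ``M`` for lipids, glycan beads as HETATM records
  attached to their carrier residue); a plain XYZ dialect with per-frame
  blocks is supported for coordinate-only data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import ParseError, SelectionError, StructureError

__all__ = [
    "AtomSelection",
    "Frame",
    "Lipid",
    "MembraneTopology",
    "PeptideTopology",
    "Topology",
    "Trajectory",
    "build_selection",
    "csf114_sequence",
    "read_structure",
    "write_trajectory",
]

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
GLYCAN_RESNAMES = {"GLC", "NAG", "BGC"}
LIPID_RESNAMES = {"DMP", "DMPC", "POPC", "LIP", "PO4", "PO4L"}
BACKBONE_NAMES = {"N", "C", "O", "OXT"}

# Residue identities of CSF114(Glc) that are stated explicitly in the
# literature; unstated positions are alanine placeholders (flagged) so the
# fixture never silently invents sequence.
CSF114_KNOWN_RESIDUES = {
    1: "THR", 3: "ARG", 4: "VAL", 5: "GLU", 6: "ARG", 7: "ASN", 8: "GLY",
    9: "HIS", 12: "PHE", 13: "TYR", 14: "ALA", 15: "PRO", 16: "TYR",
    18: "TRP", 21: "LYS",
}
CSF114_LENGTH = 21
CSF114_GLYCAN_RESIDUE = 7


def csf114_sequence() -> tuple[list[str], list[bool]]:
    """Return the 21-residue CSF114 fixture sequence.

    Returns (codes, placeholder) where ``placeholder[i]`` is True for
    positions whose identity is not documented and was filled with alanine.
    """
    codes, placeholder = [], []
    for i in range(1, CSF114_LENGTH + 1):
        known = CSF114_KNOWN_RESIDUES.get(i)
        codes.append(known if known else "ALA")
        placeholder.append(known is None)
    return codes, placeholder


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Frame:
    """A single snapshot: per-atom coordinates plus optional box and time."""

    coordinates: np.ndarray  # (n_atoms, 3) float64, Angstrom
    box: np.ndarray | None = None  # (3,) orthorhombic box lengths, Angstrom
    time: float | None = None  # ps

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise StructureError(f"coordinates must be (n, 3), got {coords.shape}")
        if not np.isfinite(coords).all():
            raise StructureError("non-finite coordinates in frame")
        object.__setattr__(self, "coordinates", coords)
        if self.box is not None:
            box = np.asarray(self.box, dtype=float).reshape(3)
            if not (np.isfinite(box).all() and (box > 0).all()):
                raise StructureError("box lengths must be finite and positive")
            object.__setattr__(self, "box", box)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Topology:
    """Flat per-atom attribute table for the whole system."""

    names: np.ndarray        # str
    elements: np.ndarray     # str
    res_ids: np.ndarray      # int, 1-based
    res_names: np.ndarray    # str
    chain_ids: np.ndarray    # str, 'P' peptide / 'M' membrane
    hetero: np.ndarray       # bool

    def __post_init__(self):
        n = len(self.names)
        for attr in ("elements", "res_ids", "res_names", "chain_ids", "hetero"):
            if len(getattr(self, attr)) != n:
                raise StructureError(f"topology attribute '{attr}' length mismatch")
        self.names = np.asarray(self.names, dtype="U6")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype="U4")
        self.chain_ids = np.asarray(self.chain_ids, dtype="U2")
        self.hetero = np.asarray(self.hetero, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def peptide_mask(self) -> np.ndarray:
        by_chain = self.chain_ids == "P"
        if by_chain.any():
            return by_chain
        return np.isin(self.res_names, list(AMINO_ACIDS | GLYCAN_RESNAMES))

    def membrane_mask(self) -> np.ndarray:
        by_chain = self.chain_ids == "M"
        if by_chain.any():
            return by_chain
        return np.isin(self.res_names, list(LIPID_RESNAMES))

    def peptide(self, glycan_residue: int | None = None,
                helix_core: tuple[int, int] = (5, 12)) -> "PeptideTopology":
        return PeptideTopology.from_topology(self, glycan_residue=glycan_residue,
                                             helix_core=helix_core)

    def membrane(self, reference: Frame | None = None) -> "MembraneTopology":
        return MembraneTopology.from_topology(self, reference=reference)


def _infer_peptide_role(name: str, res_name: str, hetero: bool) -> str:
    if hetero or res_name in GLYCAN_RESNAMES or name == "GLC":
        return "glycan"
    if name == "CA":
        return "CA"
    if name in BACKBONE_NAMES:
        return "backbone"
    return "sidechain"


@dataclass
class PeptideTopology:
    """Peptide residues plus per-residue atoms with roles.

    ``atoms`` maps each residue index to a list of
    (global atom index, atom name, element, role); role is one of
    ``backbone``, ``CA``, ``sidechain``, ``glycan``.
    """

    residues: list[tuple[int, str]]
    atoms: dict[int, list[tuple[int, str, str, str]]]
    glycan_residue: int | None = None
    helix_core: tuple[int, int] = (5, 12)

    def __post_init__(self):
        ids = [i for i, _ in self.residues]
        if ids != list(range(1, len(ids) + 1)):
            raise StructureError("residue indices must be contiguous and start at 1")
        for rid, _ in self.residues:
            n_ca = sum(1 for _, _, _, role in self.atoms.get(rid, []) if role == "CA")
            if n_ca != 1:
                raise StructureError(f"residue {rid} has {n_ca} CA atoms (exactly 1 required)")
        lo, hi = self.helix_core
        if not (1 <= lo <= hi <= len(ids)):
            raise StructureError(f"helix core {self.helix_core} outside residue range 1..{len(ids)}")
        if self.glycan_residue is not None and self.glycan_residue not in dict(self.residues):
            raise StructureError(f"glycan residue {self.glycan_residue} not in topology")

    @classmethod
    def from_topology(cls, topology: Topology, glycan_residue: int | None = None,
                      helix_core: tuple[int, int] = (5, 12)) -> "PeptideTopology":
        mask = topology.peptide_mask()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise StructureError("topology contains no peptide atoms")
        residues: dict[int, str] = {}
        atoms: dict[int, list[tuple[int, str, str, str]]] = {}
        inferred_glycan = glycan_residue
        for i in idx:
            rid = int(topology.res_ids[i])
            name = str(topology.names[i])
            res_name = str(topology.res_names[i])
            het = bool(topology.hetero[i])
            role = _infer_peptide_role(name, res_name, het)
            if role != "glycan":
                residues.setdefault(rid, res_name)
            elif inferred_glycan is None:
                inferred_glycan = rid
            atoms.setdefault(rid, []).append((int(i), name, str(topology.elements[i]), role))
        res_list = sorted(residues.items())
        n_res = len(res_list)
        lo, hi = helix_core
        if n_res and hi > n_res:  # clamp the default core for short peptides
            lo, hi = min(lo, n_res), n_res
        return cls(residues=res_list, atoms=atoms, glycan_residue=inferred_glycan,
                   helix_core=(lo, hi))

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def ca_index(self, res_id: int) -> int:
        for gidx, _, _, role in self.atoms.get(res_id, []):
            if role == "CA":
                return gidx
        raise SelectionError(f"residue {res_id} has no CA atom")

    def ca_indices(self, res_ids: Iterable[int] | None = None) -> list[int]:
        if res_ids is None:
            res_ids = [i for i, _ in self.residues]
        return [self.ca_index(r) for r in res_ids]

    def glycan_indices(self) -> list[int]:
        out = []
        for entries in self.atoms.values():
            out.extend(g for g, _, _, role in entries if role == "glycan")
        return sorted(out)


_C2_RE = re.compile(r"^C2(\d+)$")   # sn-2 ("c2") chain carbons
_C3_RE = re.compile(r"^C3(\d+)$")   # sn-1 ("c1") chain carbons
_H2_RE = re.compile(r"^H[RS](\d+)$")
_H1_RE = re.compile(r"^H[XY](\d+)$")


@dataclass
class Lipid:
    lipid_id: int
    type_label: str
    leaflet: str  # 'upper' | 'lower'
    phosphate: list[int] = field(default_factory=list)
    choline_n: int | None = None
    c1: dict[int, int] = field(default_factory=dict)   # carbon index -> atom index
    c2: dict[int, int] = field(default_factory=dict)
    h1: dict[int, list[int]] = field(default_factory=dict)
    h2: dict[int, list[int]] = field(default_factory=dict)

    def chain(self, which: str) -> dict[int, int]:
        if which == "c1":
            return self.c1
        if which == "c2":
            return self.c2
        raise SelectionError(f"unknown chain {which!r} (expected 'c1' or 'c2')")

    def hydrogens(self, which: str) -> dict[int, list[int]]:
        return self.h1 if which == "c1" else self.h2


@dataclass
class MembraneTopology:
    """Lipids with role maps: phosphate markers, choline N, acyl-chain carbons
    (c1 = sn-1, c2 = sn-2, carbons 2..14) and their attached hydrogens."""

    lipids: list[Lipid]

    def __post_init__(self):
        if not self.lipids:
            raise StructureError("membrane topology with no lipids")
        for lip in self.lipids:
            if lip.leaflet not in ("upper", "lower"):
                raise StructureError(f"lipid {lip.lipid_id}: bad leaflet {lip.leaflet!r}")

    @classmethod
    def from_topology(cls, topology: Topology,
                      reference: Frame | None = None) -> "MembraneTopology":
        mask = topology.membrane_mask()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise StructureError("topology contains no membrane atoms")
        lipids: dict[int, Lipid] = {}
        for i in idx:
            rid = int(topology.res_ids[i])
            name = str(topology.names[i])
            lip = lipids.get(rid)
            if lip is None:
                lip = Lipid(lipid_id=rid, type_label=str(topology.res_names[i]),
                            leaflet="upper")
                lipids[rid] = lip
            if name in ("P", "P1", "PO4"):
                lip.phosphate.append(int(i))
            elif name == "N":
                lip.choline_n = int(i)
            elif (m := _C3_RE.match(name)):
                k = int(m.group(1))
                if k in lip.c1:
                    raise StructureError(f"lipid {rid}: duplicate c1 carbon {k}")
                lip.c1[k] = int(i)
            elif (m := _C2_RE.match(name)):
                k = int(m.group(1))
                if k in lip.c2:
                    raise StructureError(f"lipid {rid}: duplicate c2 carbon {k}")
                lip.c2[k] = int(i)
            elif (m := _H1_RE.match(name)):
                lip.h1.setdefault(int(m.group(1)), []).append(int(i))
            elif (m := _H2_RE.match(name)):
                lip.h2.setdefault(int(m.group(1)), []).append(int(i))
        result = sorted(lipids.values(), key=lambda l: l.lipid_id)
        if reference is not None:
            for lip in result:
                marker = lip.phosphate[0] if lip.phosphate else next(
                    iter(lip.c1.values()), next(iter(lip.c2.values()), None))
                if marker is not None:
                    z = reference.coordinates[marker, 2]
                    lip.leaflet = "upper" if z >= 0 else "lower"
        return cls(lipids=result)

    def phosphate_indices(self) -> list[int]:
        out: list[int] = []
        for lip in self.lipids:
            out.extend(lip.phosphate)
        return sorted(out)


@dataclass
class Trajectory:
    """Ordered frames bound to a topology."""

    topology: Topology
    frames: list[Frame]
    stride_ps: float | None = None  # time between stored frames

    def __post_init__(self):
        if not self.frames:
            raise StructureError("trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for k, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise StructureError(
                    f"frame {k} has {f.n_atoms} atoms, topology has {n}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate array."""
        return np.stack([f.coordinates for f in self.frames])


@dataclass(frozen=True)
class AtomSelection:
    """Named, sorted, duplicate-free set of 0-based atom indices."""

    name: str
    indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise SelectionError("selection indices must be one-dimensional")
        if idx.size and (np.unique(idx).size != idx.size):
            raise SelectionError(f"selection {self.name!r} contains duplicate indices")
        object.__setattr__(self, "indices", np.sort(idx))

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, topology: Topology, allow_empty: bool = False) -> "AtomSelection":
        if len(self) == 0 and not allow_empty:
            raise SelectionError(f"selection {self.name!r} is empty")
        if len(self) and (self.indices[0] < 0 or self.indices[-1] >= topology.n_atoms):
            raise SelectionError(
                f"selection {self.name!r} has indices outside 0..{topology.n_atoms - 1}")
        return self


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_RES_RANGE_RE = re.compile(
    r"^peptide\s+ca(?:\s+residues\s+(\d+)\s*[-–]\s*(\d+))?$")


def build_selection(topology: Topology, spec, name: str | None = None,
                    allow_empty: bool = False) -> AtomSelection:
    """Resolve a selection rule against a topology.

    ``spec`` may be an explicit index list, a string rule
    (``"peptide ca"``, ``"peptide ca residues 5-12"``,
    ``"membrane phosphate atoms"``, ``"membrane choline"``, ``"glycan"``)
    or a tuple ``("peptide_ca", [res_ids...])``.
    Deterministic: the result is a pure function of (topology, spec).
    """
    if isinstance(spec, (list, tuple, np.ndarray)) and not (
            isinstance(spec, tuple) and len(spec) == 2 and isinstance(spec[0], str)):
        sel = AtomSelection(name or "explicit", np.asarray(spec, dtype=int))
        return sel.validate(topology, allow_empty=allow_empty)

    if isinstance(spec, tuple):
        kind, res_ids = spec
        if kind not in ("peptide_ca", "peptide ca"):
            raise SelectionError(f"unknown selection rule {kind!r}")
        pep = topology.peptide()
        sel = AtomSelection(name or f"peptide_ca:{sorted(res_ids)}",
                            pep.ca_indices(sorted(res_ids)))
        return sel.validate(topology, allow_empty=allow_empty)

    rule = " ".join(str(spec).lower().split())
    if (m := _RES_RANGE_RE.match(rule)):
        pep = topology.peptide()
        if m.group(1) is not None:
            lo, hi = int(m.group(1)), int(m.group(2))
            if not (1 <= lo <= hi <= pep.n_residues):
                raise SelectionError(
                    f"residue range {lo}-{hi} outside 1..{pep.n_residues}")
            res_ids = range(lo, hi + 1)
        else:
            res_ids = None
        sel = AtomSelection(name or rule, pep.ca_indices(res_ids))
    elif rule in ("membrane phosphate atoms", "membrane phosphate"):
        mem = topology.membrane()
        sel = AtomSelection(name or rule, mem.phosphate_indices())
    elif rule in ("membrane choline", "membrane choline n"):
        mem = topology.membrane()
        idx = [l.choline_n for l in mem.lipids if l.choline_n is not None]
        sel = AtomSelection(name or rule, idx)
    elif rule == "glycan":
        pep = topology.peptide()
        sel = AtomSelection(name or rule, pep.glycan_indices())
    elif rule == "peptide all":
        sel = AtomSelection(name or rule, np.flatnonzero(topology.peptide_mask()))
    else:
        raise SelectionError(f"unknown selection rule {spec!r}")
    return sel.validate(topology, allow_empty=allow_empty)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> None:
    """Cheap validation pass: coordinate fields must parse and every model
    must contain the same number of atom records."""
    counts: list[int] = []
    current = 0
    in_model = False
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                rec = line[:6].strip()
                if rec == "MODEL":
                    in_model = True
                    current = 0
                elif rec == "ENDMDL":
                    counts.append(current)
                    in_model = False
                elif rec in ("ATOM", "HETATM"):
                    if len(line.rstrip("\n")) < 54:
                        raise ParseError("truncated ATOM/HETATM record", lineno)
                    try:
                        float(line[30:38]); float(line[38:46]); float(line[46:54])
                    except ValueError:
                        raise ParseError("malformed coordinate field",
                                         lineno) from None
                    current += 1
    except UnicodeDecodeError as exc:
        raise ParseError(f"not a text PDB file: {exc}") from None
    if in_model:
        counts.append(current)
    if not counts:
        counts.append(current)
    if max(counts, default=0) == 0 and current == 0:
        raise ParseError("no ATOM/HETATM records found", 1)
    if len(set(c for c in counts if c > 0)) > 1:
        raise StructureError(
            f"atom-count mismatch between models: {sorted(set(counts))}")


def _read_pdb(path: Path) -> tuple[Topology, Trajectory]:
    _prescan_pdb(path)
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises its own hierarchy
        raise ParseError(f"could not parse PDB {path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    elements = stack.element if "element" in stack.get_annotation_categories() else None
    names = stack.atom_name
    if elements is None or all(e == "" for e in elements):
        elements = np.array([_element_from_name(n) for n in names])
    topology = Topology(
        names=names,
        elements=elements,
        res_ids=stack.res_id,
        res_names=stack.res_name,
        chain_ids=stack.chain_id,
        hetero=stack.hetero,
    )
    box = None
    if stack.box is not None:
        # orthorhombic assumption: diagonal of the box vectors
        box = np.diagonal(stack.box[0])
        if not (box > 0).all():
            box = None
    frames = [Frame(coordinates=np.array(stack.coord[i], dtype=float), box=box)
              for i in range(stack.stack_depth())]
    return topology, Trajectory(topology=topology, frames=frames)


def _element_from_name(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():
        stripped = stripped.lstrip("0123456789")
    return stripped[0].upper() if stripped else ""


def _read_xyz(path: Path) -> tuple[Topology, Trajectory]:
    frames: list[Frame] = []
    names: list[str] | None = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError("expected atom count", i + 1) from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        time = None
        if (m := re.search(r"time=([-\d.eE+]+)", comment)):
            time = float(m.group(1))
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ParseError(f"truncated frame: expected {n} atom lines", len(lines))
        fnames, coords = [], []
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError("malformed XYZ atom line", i + 3 + j)
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise ParseError("malformed XYZ coordinate", i + 3 + j) from None
            fnames.append(parts[0])
        if names is None:
            names = fnames
        elif fnames != names:
            raise StructureError("atom names differ between XYZ frames")
        frames.append(Frame(coordinates=np.array(coords), time=time))
        i += 2 + n
        lineno = i
    if names is None:
        raise ParseError("empty XYZ file", lineno or 1)
    n_at = len(names)
    topology = Topology(
        names=np.array(names), elements=np.array([_element_from_name(x) for x in names]),
        res_ids=np.ones(n_at, dtype=int), res_names=np.array(["XXX"] * n_at),
        chain_ids=np.array(["X"] * n_at), hetero=np.zeros(n_at, dtype=bool))
    return topology, Trajectory(topology=topology, frames=frames)


def read_structure(path, format: str | None = None) -> tuple[Topology, Trajectory]:
    """Read a multi-model PDB or frame-block XYZ file.

    Returns ``(topology, trajectory)`` with one frame per model/frame block
    and atom order preserved. ``format`` defaults to the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("pdb", "multi-model-pdb"):
        return _read_pdb(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unsupported format {fmt!r} (expected 'pdb' or 'xyz')")


def _to_atom_array(topology: Topology, frame: Frame) -> struc.AtomArray:
    arr = struc.AtomArray(topology.n_atoms)
    arr.coord = np.asarray(frame.coordinates, dtype=np.float32)
    arr.atom_name = topology.names
    arr.element = topology.elements
    arr.res_id = topology.res_ids
    arr.res_name = topology.res_names
    arr.chain_id = topology.chain_ids
    arr.hetero = topology.hetero
    if frame.box is not None:
        arr.box = np.diag(frame.box).astype(np.float32)
    return arr


def write_trajectory(trajectory: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory as multi-model PDB or frame-block XYZ.

    Output is re-readable by :func:`read_structure` with coordinates equal to
    the input at format precision (1e-3 A for PDB).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("pdb", "multi-model-pdb"):
        arrays = [_to_atom_array(trajectory.topology, f) for f in trajectory.frames]
        stack = struc.stack(arrays)
        if trajectory.frames[0].box is not None:
            stack.box = np.stack([np.diag(f.box if f.box is not None
                                          else trajectory.frames[0].box)
                                  for f in trajectory.frames]).astype(np.float32)
        pdb = PDBFile()
        pdb.set_structure(stack)
        # single-model files are still MODEL/ENDMDL delimited in this dialect
        if len(trajectory.frames) == 1 and not any(
                l.startswith("MODEL") for l in pdb.lines):
            body = [l for l in pdb.lines if l.startswith(("ATOM", "HETATM"))]
            head = [l for l in pdb.lines
                    if not l.startswith(("ATOM", "HETATM"))]
            pdb.lines = head + ["MODEL        1"] + body + ["ENDMDL"]
        pdb.write(str(path))
    elif fmt == "xyz":
        with open(path, "w") as fh:
            for k, f in enumerate(trajectory.frames):
                fh.write(f"{f.n_atoms}\n")
                t = f" time={f.time:g}" if f.time is not None else ""
                fh.write(f"frame={k}{t}\n")
                for name, xyz in zip(trajectory.topology.names, f.coordinates):
                    fh.write(f"{name} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
    else:
        raise ValueError(f"unsupported format {fmt!r} (expected 'pdb' or 'xyz')")
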