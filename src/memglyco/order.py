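"""Lipid acyl-chain order parameters.

The deuterium order parameter of a chain carbon is

    S_CD = < (3 cos^2(theta) - 1) / 2 >,

with theta the angle between a C-H bond vector and the bilayer normal,
averaged over hydrogens, lipids and retained frames.  S_CD is +1 for bonds
along the normal, -0.5 perpendicular to it and 0 for an isotropic
distribution; higher values mean more ordered, more compact chains.  Chains
are labelled c1 (sn-1) and c2 (sn-2); for a DMPC-like myristoyl chain the
carbons run 2..14.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SelectionError
from .model_io import Frame, Lipid, MembraneTopology, Trajectory

__all__ = ["OrderProfile", "ch_vectors", "scd_profile", "profile_compare"]

_TETRA_HALF = np.deg2rad(109.471220634 / 2.0)  # half the H-C-H angle


@dataclass
class OrderProfile:
    """Per-carbon S_CD profile of one chain, with block-averaged errors."""

    chain: str                 # 'c1' | 'c2'
    carbons: np.ndarray        # strictly increasing carbon indices
    scd: np.ndarray            # signed mean S_CD
    se: np.ndarray             # standard error from block averaging
    n_samples: np.ndarray      # hydrogens x lipids x frames actually used

    def __post_init__(self):
        self.carbons = np.asarray(self.carbons, dtype=int)
        self.scd = np.asarray(self.scd, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.n_samples = np.asarray(self.n_samples, dtype=int)
        if not (np.diff(self.carbons) > 0).all():
            raise ValueError("carbon indices must be strictly increasing")
        if ((self.scd < -0.5 - 1e-12) | (self.scd > 1.0 + 1e-12)).any():
            raise ValueError("S_CD outside [-0.5, 1]")

    @property
    def abs_scd(self) -> np.ndarray:
        return np.abs(self.scd)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chain": self.chain, "carbon": self.carbons, "scd": self.scd,
            "abs_scd": self.abs_scd, "se": self.se, "n_samples": self.n_samples,
        })


def _reconstructed_ch(c: np.ndarray, prev_c: np.ndarray, next_c: np.ndarray
                      ) -> list[np.ndarray]:
    """Two tetrahedral methylene C-H directions from the carbon and its two
    chain neighbours (standard united-atom H reconstruction)."""
    na = prev_c - c
    nb = next_c - c
    na = na / np.linalg.norm(na)
    nb = nb / np.linalg.norm(nb)
    bisector = -(na + nb)
    norm_b = np.linalg.norm(bisector)
    plane = np.cross(na, nb)
    norm_p = np.linalg.norm(plane)
    if norm_b < 1e-10 or norm_p < 1e-10:
        raise SelectionError("collinear chain neighbours; cannot reconstruct H")
    bisector /= norm_b
    plane /= norm_p
    h1 = np.cos(_TETRA_HALF) * bisector + np.sin(_TETRA_HALF) * plane
    h2 = np.cos(_TETRA_HALF) * bisector - np.sin(_TETRA_HALF) * plane
    return [h1 / np.linalg.norm(h1), h2 / np.linalg.norm(h2)]


def ch_vectors(frame: Frame, lipid: Lipid, chain: str, carbon: int,
               h_mode: str = "explicit") -> list[np.ndarray]:
    """Unit C-H vectors of one chain carbon in one frame.

    ``explicit`` uses hydrogens present in the topology; ``reconstructed``
    builds two tetrahedral directions from the two chain-neighbour carbons
    (terminal carbons, including the methyl, have no such pair and raise).
    """
    carbons = lipid.chain(chain)
    if carbon not in carbons:
        raise SelectionError(f"lipid {lipid.lipid_id}: no {chain} carbon {carbon}")
    c_xyz = frame.coordinates[carbons[carbon]]
    if h_mode == "explicit":
        h_idx = lipid.hydrogens(chain).get(carbon, [])
        if not h_idx:
            raise SelectionError(
                f"lipid {lipid.lipid_id}: {chain} carbon {carbon} has no hydrogens")
        vecs = []
        for h in h_idx:
            v = frame.coordinates[h] - c_xyz
            norm = np.linalg.norm(v)
            if norm < 1e-10:
                raise SelectionError("zero-length C-H vector")
            vecs.append(v / norm)
        return vecs
    if h_mode == "reconstructed":
        if (carbon - 1) not in carbons or (carbon + 1) not in carbons:
            raise SelectionError(
                f"carbon {carbon} lacks both chain neighbours; terminal carbons "
                "are excluded from reconstruction")
        return _reconstructed_ch(c_xyz, frame.coordinates[carbons[carbon - 1]],
                                 frame.coordinates[carbons[carbon + 1]])
    raise ValueError(f"unknown h_mode {h_mode!r}")


def _p2(cos_theta: np.ndarray) -> np.ndarray:
    return 0.5 * (3.0 * cos_theta ** 2 - 1.0)


def scd_profile(trajectory: Trajectory, membrane: MembraneTopology | None = None,
                chain: str = "c1", normal: np.ndarray = np.array([0.0, 0.0, 1.0]),
                h_mode: str = "explicit", excluded: np.ndarray | None = None,
                n_blocks: int = 5, leaflet: str | None = None) -> OrderProfile:
    """Per-carbon S_CD profile of one chain, both leaflets pooled by default.

    The bilayer normal is fixed (+z unless overridden); the uncertainty is
    the standard error of ``n_blocks`` contiguous frame-block means.
    """
    membrane = membrane if membrane is not None else trajectory.topology.membrane(
        reference=trajectory.frames[0])
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    n = trajectory.n_frames
    if excluded is None:
        excluded = np.zeros(n, dtype=bool)
    excluded = np.asarray(excluded, dtype=bool)
    kept = np.flatnonzero(~excluded)
    if kept.size == 0:
        raise InsufficientDataError("no retained frames")
    lipids = [l for l in membrane.lipids
              if (leaflet is None or l.leaflet == leaflet) and l.chain(chain)]
    if not lipids:
        raise SelectionError(f"chain {chain!r} absent from membrane topology")
    carbon_set = sorted({k for l in lipids for k in l.chain(chain)})
    if h_mode == "reconstructed":
        carbon_set = [k for k in carbon_set
                      if any((k - 1) in l.chain(chain) and (k + 1) in l.chain(chain)
                             for l in lipids)]
    per_frame = {k: np.full(kept.size, np.nan) for k in carbon_set}
    counts = {k: 0 for k in carbon_set}
    for fi, frame_no in enumerate(kept):
        frame = trajectory.frames[frame_no]
        for k in carbon_set:
            acc, m = 0.0, 0
            for lip in lipids:
                if k not in lip.chain(chain):
                    continue
                if h_mode == "reconstructed" and (
                        (k - 1) not in lip.chain(chain) or (k + 1) not in lip.chain(chain)):
                    continue
                for v in ch_vectors(frame, lip, chain, k, h_mode=h_mode):
                    acc += _p2(abs(float(v @ normal)))
                    m += 1
            if m:
                per_frame[k][fi] = acc / m
                counts[k] += m
    carbons, scd, se, n_samples = [], [], [], []
    for k in carbon_set:
        vals = per_frame[k]
        good = ~np.isnan(vals)
        if not good.any():
            continue
        v = vals[good]
        carbons.append(k)
        scd.append(float(v.mean()))
        blocks = np.array_split(v, min(n_blocks, len(v)))
        bm = np.array([b.mean() for b in blocks if len(b)])
        se.append(float(bm.std(ddof=1) / np.sqrt(len(bm))) if len(bm) > 1 else 0.0)
        n_samples.append(counts[k])
    return OrderProfile(chain=chain, carbons=np.array(carbons),
                        scd=np.array(scd), se=np.array(se),
                        n_samples=np.array(n_samples))


def profile_compare(profile_a: OrderProfile, profile_b: OrderProfile,
                    n_sigma: float = 2.0, atol: float = 1e-6) -> pd.DataFrame:
    """Per-carbon difference a - b with combined uncertainty.

    A carbon is flagged perturbed when |delta| exceeds ``n_sigma`` times the
    combined standard error plus a small absolute floor (``atol``, guarding
    against zero-variance profiles); the deepest flagged carbon index
    summarises how far down the chain the perturbation reaches.
    """
    if profile_a.chain != profile_b.chain:
        raise ValueError(f"chain mismatch: {profile_a.chain} vs {profile_b.chain}")
    if not np.array_equal(profile_a.carbons, profile_b.carbons):
        raise ValueError("carbon ranges differ between profiles")
    delta = profile_a.scd - profile_b.scd
    se = np.sqrt(profile_a.se ** 2 + profile_b.se ** 2)
    flagged = np.abs(delta) > n_sigma * se + atol
    df = pd.DataFrame({
        "chain": profile_a.chain, "carbon": profile_a.carbons,
        "delta_scd": delta, "combined_se": se, "perturbed": flagged,
    })
    df.attrs["deepest_perturbed_carbon"] = (
        int(profile_a.carbons[flagged].max()) if flagged.any() else None)
    return df
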