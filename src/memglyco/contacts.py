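"""Switching-function contact collective variable.

The contact CV *s* is a smooth count of peptide-membrane atom pairs built
from the rational switching function

    s(r) = [1 - (r/r0)^n] / [1 - (r/r0)^m],    n < m (both even),

which decays from 1 at contact to 0 at large separation and takes the
removable-singularity value n/m at r = r0.  Defaults r0 = 5 A, n = 8,
m = 16, so s(r0) = 0.5.  A frame counts as a bound pose when its CV exceeds
a threshold (default 0.5, strict inequality).

Two opposite faces of the helix ("Side 1", carrying the glycosylated
residue, and "Side 2") are tracked as separate CVs against the membrane
phosphate groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import SelectionError
from .model_io import AtomSelection, Frame, Trajectory

__all__ = ["SwitchingParams", "ContactSeries", "switch", "contact_value",
           "per_side_series", "classify_bound",
           "SIDE1_DEFAULT_RESIDUES", "SIDE2_DEFAULT_RESIDUES"]

# Default helix faces: residues observed to anchor each binding mode.
# Side 1 is the glycosylated face (Arg3, Arg6, Asn7(Glc), Trp18); Side 2 the
# opposite face (Thr1, Phe12, Tyr16).  Fully overridable in configuration.
SIDE1_DEFAULT_RESIDUES = (3, 6, 7, 18)
SIDE2_DEFAULT_RESIDUES = (1, 12, 16)


@dataclass(frozen=True)
class SwitchingParams:
    r0: float = 5.0
    n: int = 8
    m: int = 16

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not (0 < self.n < self.m):
            raise ValueError("need 0 < n < m")
        if self.n % 2 or self.m % 2:
            raise ValueError("n and m must be even")


def switch(r, params: SwitchingParams = SwitchingParams()):
    """Rational switching function; accepts scalars or arrays.

    Value in (0, 1]; strictly decreasing; s(0) = 1, s(r0) = n/m (analytic
    limit), s -> 0 as r -> inf.  Negative distances are a domain error.
    """
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ValueError("distance must be non-negative")
    x = r / params.r0
    xn = x ** params.n
    xm = x ** params.m
    denom = 1.0 - xm
    # analytic removable singularity at r = r0
    near = np.isclose(x, 1.0, rtol=0.0, atol=1e-12)
    safe_denom = np.where(near, 1.0, denom)
    value = np.where(near, params.n / params.m, (1.0 - xn) / safe_denom)
    return float(value) if value.ndim == 0 else value


def _pair_distances(coords_a: np.ndarray, coords_b: np.ndarray,
                    box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return cdist(coords_a, coords_b)
    # minimum-image convention for an orthorhombic box
    delta = coords_a[:, None, :] - coords_b[None, :, :]
    delta -= box * np.round(delta / box)
    return np.sqrt((delta ** 2).sum(axis=-1))


def contact_value(frame: Frame, group_a: AtomSelection, group_b: AtomSelection,
                  params: SwitchingParams = SwitchingParams(),
                  normalization: str = "per-group-atom") -> float:
    """Contact CV of one frame: sum of switch(r_ij) over all (a, b) pairs.

    Under ``per-group-atom`` normalization the raw sum is divided by
    ``len(group_a)`` (the peptide-side selection), so one ideal contact per
    tracked atom gives s of order 1; ``raw-sum`` returns the bare sum.
    Selections must be non-empty and disjoint.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise SelectionError("contact groups must be non-empty")
    if np.intersect1d(group_a.indices, group_b.indices).size:
        raise SelectionError("contact groups overlap")
    if normalization not in ("per-group-atom", "raw-sum"):
        raise ValueError(f"unknown normalization {normalization!r}")
    dists = _pair_distances(frame.coordinates[group_a.indices],
                            frame.coordinates[group_b.indices], frame.box)
    total = float(switch(dists, params).sum())
    if normalization == "per-group-atom":
        total /= len(group_a)
    return total


@dataclass
class ContactSeries:
    """Per-frame contact CV values for one helix side."""

    side: str                       # 'Side1' | 'Side2' | custom label
    values: np.ndarray              # (n_frames,) dimensionless, >= 0
    params: SwitchingParams
    normalization: str
    excluded: np.ndarray            # (n_frames,) bool; True = biased frame

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.values.shape != self.excluded.shape:
            raise ValueError("values and excluded mask lengths differ")
        if (self.values < 0).any():
            raise ValueError("contact CV values must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def retained(self) -> np.ndarray:
        return self.values[~self.excluded]

    def mean(self) -> float:
        """Mean CV over retained (unbiased) frames."""
        vals = self.retained
        return float(vals.mean()) if vals.size else float("nan")


def per_side_series(trajectory: Trajectory, side1: AtomSelection,
                    side2: AtomSelection, phosphate: AtomSelection,
                    params: SwitchingParams = SwitchingParams(),
                    excluded: np.ndarray | None = None,
                    normalization: str = "per-group-atom",
                    ) -> tuple[ContactSeries, ContactSeries]:
    """Contact CV time series for the two helix sides against the phosphates.

    Frames flagged in ``excluded`` keep their values but are omitted from
    every summary statistic.  The side selections must not overlap.
    """
    if np.intersect1d(side1.indices, side2.indices).size:
        raise SelectionError("side selections overlap")
    n = trajectory.n_frames
    if excluded is None:
        excluded = np.zeros(n, dtype=bool)
    excluded = np.asarray(excluded, dtype=bool)
    if excluded.shape != (n,):
        raise ValueError(f"excluded mask length {excluded.shape} != frame count {n}")
    out = []
    for label, sel in (("Side1", side1), ("Side2", side2)):
        vals = np.array([contact_value(f, sel, phosphate, params, normalization)
                         for f in trajectory.frames])
        out.append(ContactSeries(side=label, values=vals, params=params,
                                 normalization=normalization, excluded=excluded))
    return out[0], out[1]


def classify_bound(series: ContactSeries, threshold: float = 0.5
                   ) -> tuple[np.ndarray, float]:
    """Bound-pose mask: frames with s strictly greater than the threshold.

    Excluded (biased) frames are never bound.  Returns ``(mask,
    bound_fraction)`` where the fraction is taken over retained frames only.
    """
    mask = (series.values > threshold) & ~series.excluded
    n_retained = int((~series.excluded).sum())
    fraction = float(mask.sum() / n_retained) if n_retained else 0.0
    return mask, fraction
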