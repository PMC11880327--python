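"""Anchor-based superposition and backbone distances between CDR loops.

The distance between two loop conformations is measured by first
least-squares superposing the mobile loop's *anchor* backbone atoms onto
the reference's (Kabsch, proper rotation only) and then taking the RMSD
over loop backbone atoms (N, CA, C, O) without any re-fitting — loop atoms
never influence the superposition. Loops of unequal length are compared by
resampling each backbone trace with a natural cubic spline at a common
number of points; the sampling grid is chosen so that the result is
*exactly* the plain RMSD whenever lengths agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .model import BACKBONE_ATOMS, ImgtResidue, LoopStructure, StructureError

logger = logging.getLogger(__name__)

ATOL = 1e-9  # internal absolute tolerance for floating-point ties


class GeometryError(StructureError):
    """Base class for geometry errors."""


class UnderdeterminedError(GeometryError):
    """Fewer than three common anchor atoms: superposition is ill-posed."""


class LoopLengthError(GeometryError):
    """Equal-length RMSD requested for loops of different residue counts."""


@dataclass
class Superposition:
    """A rigid transform ``x -> rotation @ x + translation`` (Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray
    anchor_rmsd: float
    n_atoms_used: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class LoopDistance:
    value: float
    kind: str  # "rmsd_equal_length" or "spline_upsampled"
    n_points: int


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with item identifiers."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise GeometryError("distance matrix shape does not match ids")

    def validate(self) -> None:
        if np.any(self.values < -ATOL):
            raise GeometryError("negative distances")
        if not np.allclose(self.values, self.values.T, atol=ATOL):
            raise GeometryError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=ATOL):
            raise GeometryError("distance matrix diagonal not zero")

    def __len__(self) -> int:
        return len(self.ids)

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        # default float formatting is the shortest round-trip repr, so the
        # matrix re-reads bit-exactly
        frame.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(ids=[str(i) for i in frame.index], values=frame.to_numpy(float))

    def save_npz(self, path: str | Path) -> None:
        np.savez_compressed(path, ids=np.array(self.ids), values=self.values)

    @classmethod
    def load_npz(cls, path: str | Path) -> "DistanceMatrix":
        data = np.load(path, allow_pickle=False)
        return cls(ids=[str(i) for i in data["ids"]], values=data["values"])


def _atom_table(residues: Sequence[ImgtResidue]) -> dict[tuple[int, str, str], np.ndarray]:
    table = {}
    for res in residues:
        for atom in BACKBONE_ATOMS:
            coord = res.backbone.get(atom)
            if coord is not None:
                table[(res.imgt_number, res.insertion_code, atom)] = coord
    return table


def _matched_coords(
    a: Sequence[ImgtResidue], b: Sequence[ImgtResidue]
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of atoms present in both residue sets, matched by
    (IMGT number, insertion code, atom name); absent atoms drop pairwise."""
    ta, tb = _atom_table(a), _atom_table(b)
    keys = [k for k in ta if k in tb]
    if not keys:
        return np.empty((0, 3)), np.empty((0, 3))
    return np.array([ta[k] for k in keys]), np.array([tb[k] for k in keys])


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform (proper rotation R, translation t)
    minimising ``|| R @ mobile + t - reference ||``; returns (R, t, rmsd)."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise UnderdeterminedError(
            f"need >= 3 matched atoms for superposition, got {mobile.shape[0]}"
        )
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = cr - rotation @ cm
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rotation, translation, rmsd


def superpose_by_anchors(mobile: LoopStructure, reference: LoopStructure) -> Superposition:
    """Fit the mobile loop's anchors onto the reference's anchors."""
    if mobile.region_name != reference.region_name:
        raise GeometryError(
            f"region mismatch: {mobile.region_name} vs {reference.region_name}"
        )
    pm, pr = _matched_coords(mobile.anchor_residues, reference.anchor_residues)
    if len(pm) < 3:
        raise UnderdeterminedError(
            f"only {len(pm)} common anchor atoms between "
            f"{mobile.loop_id} and {reference.loop_id}"
        )
    rotation, translation, rmsd = kabsch(pm, pr)
    return Superposition(rotation, translation, rmsd, len(pm))


def loop_rmsd(a: LoopStructure, b: LoopStructure) -> LoopDistance:
    """Backbone RMSD over loop atoms after anchor superposition.

    Requires equal residue counts; unequal-length loops must go through
    :func:`upsampled_distance`.
    """
    if a.loop_length != b.loop_length:
        raise LoopLengthError(
            f"loop lengths differ ({a.loop_length} vs {b.loop_length}); "
            "use upsampled_distance"
        )
    sup = superpose_by_anchors(a, b)
    pa, pb = _matched_coords(a.loop_residues, b.loop_residues)
    if len(pa) == 0:
        raise GeometryError(f"no matched loop atoms for {a.loop_id} vs {b.loop_id}")
    moved = sup.apply(pa)
    value = float(np.sqrt(np.mean(np.sum((moved - pb) ** 2, axis=1))))
    return LoopDistance(value=value, kind="rmsd_equal_length", n_points=len(pa))


def _backbone_trace(loop: LoopStructure) -> np.ndarray:
    """Ordered (4L, 3) backbone trace N, CA, C, O per residue."""
    coords = []
    for res in loop.loop_residues:
        for atom in BACKBONE_ATOMS:
            coord = res.backbone.get(atom)
            if coord is None:
                raise GeometryError(
                    f"{loop.loop_id}: residue {res.key_str()} missing backbone "
                    f"atom {atom}; spline up-sampling needs complete backbones"
                )
            coords.append(coord)
    return np.array(coords)


def _resample_trace(trace: np.ndarray, n_samples: int) -> np.ndarray:
    """Natural cubic spline through the trace, knots at atoms, parameter
    normalised to [0, 1]; evaluated at ``n_samples`` uniform parameters.

    When ``n_samples`` equals the number of knots the uniform grid
    coincides with the knots and the spline returns them exactly, which is
    what makes the up-sampled distance degenerate to plain RMSD at equal
    lengths.
    """
    n_knots = trace.shape[0]
    knots = np.linspace(0.0, 1.0, n_knots)
    spline = CubicSpline(knots, trace, bc_type="natural", axis=0)
    return spline(np.linspace(0.0, 1.0, n_samples))


def upsampled_distance(a: LoopStructure, b: LoopStructure) -> LoopDistance:
    """Spline up-sampled backbone distance for loops of any two lengths.

    Both backbone traces are resampled at ``M = 4 * max(L_a, L_b)`` points
    and the RMS point-to-point distance is taken after anchor
    superposition. For equal lengths the value equals :func:`loop_rmsd`.
    """
    if a.loop_length < 2 or b.loop_length < 2:
        raise GeometryError("spline up-sampling needs loops of >= 2 residues")
    sup = superpose_by_anchors(a, b)
    trace_a = sup.apply(_backbone_trace(a))
    trace_b = _backbone_trace(b)
    n_samples = 4 * max(a.loop_length, b.loop_length)
    sa = _resample_trace(trace_a, n_samples)
    sb = _resample_trace(trace_b, n_samples)
    value = float(np.sqrt(np.mean(np.sum((sa - sb) ** 2, axis=1))))
    return LoopDistance(value=value, kind="spline_upsampled", n_points=n_samples)


def loop_distance(a: LoopStructure, b: LoopStructure) -> LoopDistance:
    """RMSD when lengths agree, spline up-sampled distance otherwise."""
    if a.loop_length == b.loop_length:
        return loop_rmsd(a, b)
    return upsampled_distance(a, b)


def pairwise_distance_matrix(
    loops: Sequence[LoopStructure],
    ids: Optional[Sequence[str]] = None,
) -> DistanceMatrix:
    """Symmetric all-against-all loop distance matrix.

    Plain RMSD where loop lengths match, spline up-sampled distance where
    they differ. All loops must share region and chain kind.
    """
    if not loops:
        raise GeometryError("no loops given")
    region = loops[0].region_name
    chain = loops[0].chain_kind
    for loop in loops:
        if loop.region_name != region or loop.chain_kind != chain:
            raise GeometryError("all loops must share region_name and chain_kind")
    if ids is None:
        ids = [loop.loop_id for loop in loops]
    n = len(loops)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dist = loop_distance(loops[i], loops[j])
            except GeometryError as exc:
                raise GeometryError(f"pair ({ids[i]}, {ids[j]}): {exc}") from exc
            values[i, j] = values[j, i] = dist.value
    return DistanceMatrix(ids=list(ids), values=values)
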