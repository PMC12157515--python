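"""Superposition, helix-RMSD metrics, 6D helix vectors and spatial binning.

The metrics here quantify how much the reshaped loop-helix-loop (LHL)
geometry of one backbone differs from another:

* ``pairwise_helix_rmsd`` aligns two structures on their beta-sheet
  residues and measures RMSD over the matched reshaped helices, trimming
  unequal-length helices to their longest common central window.
* ``lhl_rmsd`` aligns a prediction to a design model on everything outside
  the reshaped LHLs and measures RMSD over the LHL residues — the quantity
  behind the standard "< 1.5 A to the design model" prediction filter.
* ``helix_vector``/``bin_index``/``bin_occupancy`` summarise a helix as a
  6D descriptor (centroid + N-to-C direction) and count occupied bins
  (2 A cubic voxels x direction octants) as a diversity measure.
* ``bias_statistics`` measures the systematic pull of predictions toward an
  idealized reference geometry rather than the design model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import (
    BACKBONE_ATOMS,
    BackboneStructure,
    SegmentAnnotation,
    PredictionEnsemble,
    StructureError,
)

__all__ = [
    "RigidTransform", "HelixVector", "BinSpec", "ShellSpec",
    "superpose", "helix_vector", "trim_to_common", "pairwise_helix_rmsd",
    "lhl_rmsd", "ensemble_lhl_rmsd", "bias_statistics", "bin_index",
    "bin_occupancy", "sheet_face", "shell_residues",
    "min_helix_length_filter",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, applied as ``x @ R.T + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3, translation length-3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-8):
            raise ValueError("rotation has determinant != +1 (reflection?)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class HelixVector:
    """6D helix descriptor: backbone-atom centroid + unit N-to-C direction."""

    centroid: np.ndarray
    direction: np.ndarray
    helix_range: tuple[int, int]
    n_residues: int

    def __post_init__(self) -> None:
        c = np.asarray(self.centroid, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        if not math.isclose(float(np.linalg.norm(d)), 1.0, abs_tol=1e-8):
            raise ValueError("direction must be a unit vector")
        if self.n_residues != self.helix_range[1] - self.helix_range[0] + 1:
            raise ValueError("n_residues inconsistent with helix_range")
        object.__setattr__(self, "centroid", c)
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class BinSpec:
    """Cubic voxel grid for helix centroids; octants for directions."""

    cube_edge: float = 2.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.cube_edge <= 0:
            raise ValueError("cube_edge must be positive")


@dataclass(frozen=True)
class ShellSpec:
    """CA-CA cutoffs for the two environment shells around reshaped LHLs."""

    shell1_distance: float = 10.0
    shell2_distance: float = 8.0

    def __post_init__(self) -> None:
        if self.shell1_distance <= 0 or self.shell2_distance <= 0:
            raise ValueError("shell distances must be positive")


# ---------------------------------------------------------------------------
# Superposition (Kabsch)
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, target: np.ndarray
              ) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the optimal proper-rotation transform and the minimized RMSD.
    Reflections are excluded by sign-correcting the smallest singular
    vector (Kabsch).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    transform = RigidTransform(R, t)
    diff = transform.apply(P) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return transform, rmsd


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a, float) - np.asarray(b, float)
    return float(np.sqrt((d ** 2).sum() / len(d)))


# ---------------------------------------------------------------------------
# Helix vectors
# ---------------------------------------------------------------------------

def helix_vector(s: BackboneStructure, helix_range: tuple[int, int]
                 ) -> HelixVector:
    """6D descriptor of one helix.

    Centroid: mean over all N, CA, C, O atoms in the range.  Direction:
    normalized mean of per-residue unit C->O vectors, sign-flipped if
    needed so it points N-to-C along the helix (positive dot product with
    CA_last - CA_first).
    """
    a, b = helix_range
    indices = list(range(a, b + 1))
    atoms = s.atoms(indices)  # raises on missing residues/atoms
    centroid = atoms.mean(axis=0)
    co = []
    for i in indices:
        r = s.residue(i)
        v = r.coords["O"] - r.coords["C"]
        co.append(v / np.linalg.norm(v))
    direction = np.mean(co, axis=0)
    n = np.linalg.norm(direction)
    if n < 1e-12:
        raise StructureError(f"degenerate C->O mean direction for {helix_range}")
    direction = direction / n
    axis_nc = s.ca(b) - s.ca(a)
    if float(direction @ axis_nc) < 0:
        direction = -direction
    return HelixVector(
        centroid=centroid,
        direction=direction,
        helix_range=(a, b),
        n_residues=b - a + 1,
    )


# ---------------------------------------------------------------------------
# Helix trimming and RMSD metrics
# ---------------------------------------------------------------------------

def trim_to_common(range_a: tuple[int, int], range_b: tuple[int, int]
                   ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Trim the longer of two inclusive ranges to the shorter's length.

    The longer range keeps its central window; when the total trim is odd
    the extra kept residue is N-terminal (floor(d/2) residues removed from
    the N side, ceil(d/2) from the C side).
    """
    la = range_a[1] - range_a[0] + 1
    lb = range_b[1] - range_b[0] + 1
    if la <= 0 or lb <= 0:
        raise ValueError("ranges must be non-empty")
    if la == lb:
        return range_a, range_b
    if la > lb:
        d = la - lb
        a0 = range_a[0] + d // 2
        return (a0, a0 + lb - 1), range_b
    d = lb - la
    b0 = range_b[0] + d // 2
    return range_a, (b0, b0 + la - 1)


def _expand(rng: tuple[int, int]) -> list[int]:
    return list(range(rng[0], rng[1] + 1))


def pairwise_helix_rmsd(
    a: BackboneStructure, ann_a: SegmentAnnotation,
    b: BackboneStructure, ann_b: SegmentAnnotation,
    helix: int | None = None,
    ca_only: bool = False,
) -> float:
    """Sheet-aligned RMSD over matched (trimmed) reshaped helices.

    ``b`` is superposed onto ``a`` using the position-matched sheet
    residues' backbone atoms; RMSD is then taken over the concatenated
    backbone atoms of all matched helix pairs without re-superposition.
    ``helix`` restricts the measurement to one matched helix (0-based).
    """
    atoms = ("CA",) if ca_only else BACKBONE_ATOMS
    sheet_a = sorted(ann_a.sheet_residues)
    sheet_b = sorted(ann_b.sheet_residues)
    if len(sheet_a) != len(sheet_b):
        raise StructureError(
            f"sheet size mismatch: {len(sheet_a)} vs {len(sheet_b)}"
        )
    if len(ann_a.helices) != len(ann_b.helices):
        raise StructureError(
            f"helix count mismatch: {len(ann_a.helices)} vs {len(ann_b.helices)}"
        )
    transform, _ = superpose(
        b.atoms(sheet_b, atoms), a.atoms(sheet_a, atoms)
    )
    pairs = list(zip(ann_a.helices, ann_b.helices))
    if helix is not None:
        pairs = [pairs[helix]]
    pts_a, pts_b = [], []
    for ha, hb in pairs:
        ta, tb = trim_to_common(ha, hb)
        pts_a.append(a.atoms(_expand(ta), atoms))
        pts_b.append(transform.apply(b.atoms(_expand(tb), atoms)))
    return _rmsd(np.vstack(pts_a), np.vstack(pts_b))


def lhl_rmsd(
    prediction: BackboneStructure,
    design: BackboneStructure,
    annotation: SegmentAnnotation,
    ca_only: bool = False,
) -> float:
    """RMSD over reshaped-LHL backbone atoms after superposing on all
    residues outside every reshaped LHL range."""
    if len(prediction) != len(design):
        raise StructureError(
            f"residue count mismatch: {len(prediction)} vs {len(design)}"
        )
    atoms = ("CA",) if ca_only else BACKBONE_ATOMS
    lhl = annotation.lhl_residues
    frame = [i for i in design.indices if i not in lhl]
    moving = [i for i in design.indices if i in lhl]
    if not frame or not moving:
        raise StructureError("annotation leaves no frame or no LHL residues")
    transform, _ = superpose(
        prediction.atoms(frame, atoms), design.atoms(frame, atoms)
    )
    return _rmsd(
        transform.apply(prediction.atoms(moving, atoms)),
        design.atoms(moving, atoms),
    )


def ensemble_lhl_rmsd(
    ensemble: PredictionEnsemble,
    design: BackboneStructure,
    annotation: SegmentAnnotation,
    selector: str = "lowest",
) -> float:
    """LHL RMSD of a prediction ensemble against the design model.

    ``"lowest"`` takes the minimum over members; ``"rank1"`` takes the
    member with highest pLDDT (ties: first in member order).
    """
    if selector == "lowest":
        return min(
            lhl_rmsd(member, design, annotation)
            for member, _ in ensemble.members
        )
    if selector == "rank1":
        best = max(
            range(len(ensemble.members)),
            key=lambda i: (ensemble.members[i][1], -i),
        )
        return lhl_rmsd(ensemble.members[best][0], design, annotation)
    raise ValueError(f"unknown selector {selector!r}")


def bias_statistics(
    designs: list[tuple[BackboneStructure, SegmentAnnotation]],
    predictions: list[tuple[BackboneStructure, SegmentAnnotation]],
    reference: tuple[BackboneStructure, SegmentAnnotation],
    margin: float = 1.0,
) -> tuple[float, float]:
    """Fraction of predictions closer (and > ``margin`` A closer) to an
    idealized reference than to their own design model.

    For each index-aligned (design, prediction) pair the sheet-aligned
    helix RMSD of the prediction is computed to the reference and to the
    design; a tie counts as not closer.  Returns
    ``(frac_closer_to_ref, frac_margin_closer)``.
    """
    if len(designs) != len(predictions):
        raise ValueError("designs and predictions must be index-aligned")
    ref_s, ref_ann = reference
    closer = margin_closer = 0
    for (d_s, d_ann), (p_s, p_ann) in zip(designs, predictions):
        d_ref = pairwise_helix_rmsd(p_s, p_ann, ref_s, ref_ann)
        d_design = pairwise_helix_rmsd(p_s, p_ann, d_s, d_ann)
        if d_ref < d_design:
            closer += 1
        if d_design - d_ref > margin:
            margin_closer += 1
    n = len(designs)
    return closer / n, margin_closer / n


# ---------------------------------------------------------------------------
# Geometry bins
# ---------------------------------------------------------------------------

def bin_index(v: HelixVector, spec: BinSpec = BinSpec()
              ) -> tuple[int, int, int, str, str, str]:
    """6D bin key: voxel indices (floor convention) + direction octant.

    A direction component exactly 0 maps to '+'.
    """
    origin = np.asarray(spec.origin, dtype=float)
    idx = np.floor((v.centroid - origin) / spec.cube_edge).astype(int)
    signs = tuple("+" if c >= 0 else "-" for c in v.direction)
    return (int(idx[0]), int(idx[1]), int(idx[2]), *signs)


def bin_occupancy(subset, universe, spec: BinSpec = BinSpec()) -> float:
    """Fraction of bins occupied by ``universe`` that ``subset`` occupies."""
    universe_bins = {bin_index(v, spec) for v in universe}
    if not universe_bins:
        raise ValueError("empty universe")
    subset_bins = {bin_index(v, spec) for v in subset}
    return len(subset_bins) / len(universe_bins)


# ---------------------------------------------------------------------------
# Sheet face and shells
# ---------------------------------------------------------------------------

def _sheet_plane(s: BackboneStructure, sheet_residues) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit plane of the sheet CAs: (centroid, oriented unit normal).

    The normal's sign is fixed by requiring a positive dot product with the
    cross product of the first two non-collinear inter-CA vectors, so the
    result is reproducible for a given residue ordering.
    """
    idx = sorted(sheet_residues)
    if len(idx) < 4:
        raise StructureError("need >= 4 sheet residues")
    cas = np.array([s.ca(i) for i in idx])
    centroid = cas.mean(axis=0)
    centered = cas - centroid
    _, svals, Vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-6:
        raise StructureError("collinear sheet CAs: no plane defined")
    normal = Vt[2]
    ref = None
    v0 = cas[1] - cas[0]
    for k in range(2, len(cas)):
        cr = np.cross(v0, cas[k] - cas[0])
        if np.linalg.norm(cr) > 1e-6:
            ref = cr
            break
    if ref is None:
        raise StructureError("degenerate sheet geometry")
    if float(normal @ ref) < 0:
        normal = -normal
    return centroid, normal / np.linalg.norm(normal)


def sheet_face(s: BackboneStructure, helix_range: tuple[int, int],
               sheet_residues) -> int:
    """Which face of the beta sheet a helix sits on: +1 or -1.

    Sign of the dot product between the sheet's oriented best-fit-plane
    normal and (helix centroid - sheet CA centroid); exactly in-plane maps
    to +1.
    """
    centroid, normal = _sheet_plane(s, sheet_residues)
    hv = helix_vector(s, helix_range)
    return 1 if float(normal @ (hv.centroid - centroid)) >= 0 else -1


_TET = 0.9128709  # sin/cos factors for an ideal tetrahedral CB below


def virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal-geometry CB position from backbone N, CA, C (used for Gly)."""
    b = ca - n
    cvec = c - ca
    a = np.cross(b, cvec)
    # standard construction: -0.58273431*a + 0.56802827*b - 0.54067466*c + CA
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cvec + ca


def _cb(residue) -> np.ndarray:
    if "CB" in residue.coords:
        return residue.coords["CB"]
    return virtual_cb(residue.coords["N"], residue.coords["CA"],
                      residue.coords["C"])


def _points_toward(s: BackboneStructure, i: int, j: int) -> bool:
    """Residue i points toward residue j when the angle between
    (CB_i - CA_i) and (CA_j - CA_i) is < 90 degrees."""
    ri = s.residue(i)
    side = _cb(ri) - ri.coords["CA"]
    to_j = s.ca(j) - ri.coords["CA"]
    return float(side @ to_j) > 0


def shell_residues(
    s: BackboneStructure,
    annotation: SegmentAnnotation,
    spec: ShellSpec = ShellSpec(),
    shell: int = 1,
) -> frozenset[int]:
    """Environment shells around the reshaped LHLs.

    Shell 1: all reshaped-LHL residues, plus any residue within
    ``shell1_distance`` (CA-CA) of an LHL residue that also points toward
    some LHL residue.  Shell 2: shell 1 plus any residue within
    ``shell2_distance`` of a shell-1 residue that points toward some
    shell-1 residue.
    """
    if shell not in (1, 2):
        raise ValueError("shell must be 1 or 2")
    lhl = set(annotation.lhl_residues)

    def grow(core: set[int], cutoff: float) -> frozenset[int]:
        out = set(core)
        core_idx = sorted(core)
        core_cas = np.array([s.ca(i) for i in core_idx])
        for r in s.residues:
            if r.index in core:
                continue
            dists = np.linalg.norm(core_cas - r.coords["CA"], axis=1)
            if dists.min() > cutoff:
                continue
            if any(_points_toward(s, r.index, j) for j in core_idx):
                out.add(r.index)
        return frozenset(out)

    shell1 = grow(lhl, spec.shell1_distance)
    if shell == 1:
        return shell1
    return grow(set(shell1), spec.shell2_distance)


def min_helix_length_filter(annotation: SegmentAnnotation,
                            min_len: int = 7) -> bool:
    """Pass iff every reshaped LHL contains >= ``min_len`` helical residues.

    Helices are matched to LHL units by containment; an LHL with no
    assigned helix fails.
    """
    for a, b in annotation.reshaped_lhls:
        n_helical = sum(
            hb - ha + 1
            for ha, hb in annotation.helices
            if ha >= a and hb <= b
        )
        if n_helical < min_len:
            return False
    return True
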