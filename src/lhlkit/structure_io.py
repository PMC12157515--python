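"""Backbone structure containers, PDB input/output and helix assignment.

The unit of all geometry in this package is a :class:`BackboneStructure`: an
ordered list of residues, each carrying the four backbone heavy atoms
(N, CA, C, O; CB optional).  Segment annotations (sheet residues, helix
ranges, reshaped loop-helix-loop ranges, linker identifiers) travel
separately as :class:`SegmentAnnotation` so that the same coordinates can be
interpreted under different labellings.

Only ATOM records are parsed; designed and predicted models never carry
insertion codes, so those are rejected rather than silently renumbered.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureError(ValueError):
    """Raised for malformed structures or annotation/coordinate mismatches."""


@dataclass
class Residue:
    index: int                       # 1-based author numbering
    aa: str                          # one-letter code, 'X' for non-standard
    coords: dict[str, np.ndarray]    # atom name -> (3,) array, Angstrom

    def __post_init__(self) -> None:
        for name in BACKBONE_ATOMS:
            if name not in self.coords:
                raise StructureError(
                    f"residue {self.index} missing backbone atom {name}"
                )
        for name, xyz in self.coords.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise StructureError(
                    f"residue {self.index} atom {name}: bad coordinates"
                )
            self.coords[name] = xyz


@dataclass
class BackboneStructure:
    id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise StructureError(f"structure {self.id!r} has no residues")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError(
                f"structure {self.id!r}: residue indices not strictly increasing"
            )
        self._by_index = {r.index: r for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, index: int) -> Residue:
        try:
            return self._by_index[index]
        except KeyError:
            raise StructureError(
                f"structure {self.id!r} has no residue {index}"
            ) from None

    @property
    def indices(self) -> list[int]:
        return [r.index for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def atoms(self, indices=None, atom_names=BACKBONE_ATOMS) -> np.ndarray:
        """Stacked coordinates, residue-major then atom-name order."""
        if indices is None:
            residues = self.residues
        else:
            residues = [self.residue(i) for i in indices]
        rows = [r.coords[a] for r in residues for a in atom_names]
        return np.array(rows, dtype=float)

    def ca(self, index: int) -> np.ndarray:
        return self.residue(index).coords["CA"]


@dataclass
class SegmentAnnotation:
    """Sheet/helix/LHL labelling for one structure.

    Ranges are inclusive 1-based ``(first, last)`` pairs, matching the
    field's "residues 31-51" convention.
    """

    structure_id: str
    sheet_residues: frozenset[int] = field(default_factory=frozenset)
    helices: list[tuple[int, int]] = field(default_factory=list)
    reshaped_lhls: list[tuple[int, int]] = field(default_factory=list)
    linker_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.sheet_residues = frozenset(int(i) for i in self.sheet_residues)
        self.helices = [(int(a), int(b)) for a, b in self.helices]
        self.reshaped_lhls = [(int(a), int(b)) for a, b in self.reshaped_lhls]
        for group in (self.helices, self.reshaped_lhls):
            for a, b in group:
                if b < a:
                    raise StructureError(f"empty range ({a}, {b})")
            spans = sorted(group)
            for (_, b1), (a2, _) in zip(spans, spans[1:]):
                if a2 <= b1:
                    raise StructureError(f"overlapping ranges in {group}")
        if self.linker_ids is not None and len(self.linker_ids) != len(
            self.reshaped_lhls
        ):
            raise StructureError("one linker_id per reshaped LHL required")

    @property
    def lhl_residues(self) -> frozenset[int]:
        out: set[int] = set()
        for a, b in self.reshaped_lhls:
            out.update(range(a, b + 1))
        return frozenset(out)

    def to_json(self) -> str:
        payload = {
            "structure_id": self.structure_id,
            "sheet_residues": sorted(self.sheet_residues),
            "helices": [list(r) for r in self.helices],
            "reshaped_lhls": [list(r) for r in self.reshaped_lhls],
        }
        if self.linker_ids is not None:
            payload["linker_ids"] = list(self.linker_ids)
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SegmentAnnotation":
        d = json.loads(text)
        return cls(
            structure_id=d["structure_id"],
            sheet_residues=frozenset(d.get("sheet_residues", ())),
            helices=[tuple(r) for r in d.get("helices", ())],
            reshaped_lhls=[tuple(r) for r in d.get("reshaped_lhls", ())],
            linker_ids=d.get("linker_ids"),
        )


@dataclass
class PredictionEnsemble:
    """A set of predicted models for one design, each with a global pLDDT."""

    design_id: str
    members: list[tuple[BackboneStructure, float]]

    def __post_init__(self) -> None:
        if not self.members:
            raise StructureError("empty prediction ensemble")
        for _, plddt in self.members:
            if not math.isfinite(plddt):
                raise StructureError("non-finite pLDDT")


# ---------------------------------------------------------------------------
# PDB parsing / writing (ATOM records only)
# ---------------------------------------------------------------------------

def read_backbone(pdb_text: str, chain: str | None = None,
                  structure_id: str = "structure") -> BackboneStructure:
    """Parse ATOM records of a PDB text into a :class:`BackboneStructure`.

    Only the requested chain is read (default: the first chain seen).
    Altloc blank or 'A' is kept; insertion codes are rejected.  Every
    residue must provide N, CA, C and O.
    """
    residues: list[Residue] = []
    current_key: tuple[str, int] | None = None
    current_coords: dict[str, np.ndarray] = {}
    current_aa = "X"
    picked_chain = chain

    def flush() -> None:
        nonlocal current_key, current_coords, current_aa
        if current_key is None:
            return
        residues.append(
            Residue(index=current_key[1], aa=current_aa, coords=current_coords)
        )
        current_key, current_coords = None, {}

    for line in pdb_text.splitlines():
        if not line.startswith("ATOM"):
            if line.startswith("TER") and current_key is not None and (
                picked_chain is not None
            ):
                # end of the chosen chain
                break
            continue
        atom_name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain_id = line[21]
        icode = line[26]
        if picked_chain is None:
            picked_chain = chain_id
        if chain_id != picked_chain:
            continue
        if altloc not in (" ", "A"):
            continue
        if icode != " ":
            raise StructureError(
                f"insertion code {icode!r} at residue {line[22:26].strip()} "
                "not supported"
            )
        resseq = int(line[22:26])
        key = (chain_id, resseq)
        if key != current_key:
            flush()
            current_key = key
            current_aa = THREE_TO_ONE.get(resname, "X")
        if atom_name in ("N", "CA", "C", "O", "CB") and atom_name not in current_coords:
            xyz = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
            current_coords[atom_name] = xyz
    flush()
    if not residues:
        raise StructureError(
            f"no ATOM records for chain {picked_chain!r}" if picked_chain
            else "no ATOM records found"
        )
    return BackboneStructure(id=structure_id, residues=residues)


_ATOM_FMT = (
    "ATOM  {serial:5d} {name:<4s}{altloc}{resname:>3s} {chain}{resseq:4d}{icode}"
    "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}\n"
)


def write_backbone(s: BackboneStructure, chain: str = "A") -> str:
    """Render a structure as standard fixed-column ATOM records."""
    lines = []
    serial = 0
    for r in s.residues:
        names = [a for a in ("N", "CA", "C", "O", "CB") if a in r.coords]
        for name in names:
            serial += 1
            x, y, z = r.coords[name]
            lines.append(_ATOM_FMT.format(
                serial=serial,
                name=f" {name}" if len(name) < 4 else name,
                altloc=" ",
                resname=ONE_TO_THREE.get(r.aa, "UNK"),
                chain=chain,
                resseq=r.index,
                icode=" ",
                x=x, y=y, z=z, occ=1.0, b=0.0,
                element=name[0],
            ))
    lines.append("TER\nEND\n")
    return "".join(lines)


# ---------------------------------------------------------------------------
# Dihedral-window helix assignment
# ---------------------------------------------------------------------------

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return math.degrees(math.atan2(y, x))


def phi_psi(s: BackboneStructure) -> list[tuple[float | None, float | None]]:
    """Per-residue (phi, psi) in degrees; ``None`` where undefined.

    Dihedrals are only computed between residues consecutive in author
    numbering, so chain breaks (index gaps) terminate phi/psi runs.
    """
    out: list[tuple[float | None, float | None]] = []
    res = s.residues
    for i, r in enumerate(res):
        prev_r = res[i - 1] if i > 0 and res[i - 1].index == r.index - 1 else None
        next_r = (
            res[i + 1]
            if i + 1 < len(res) and res[i + 1].index == r.index + 1
            else None
        )
        phi = psi = None
        if prev_r is not None:
            phi = dihedral(prev_r.coords["C"], r.coords["N"],
                           r.coords["CA"], r.coords["C"])
        if next_r is not None:
            psi = dihedral(r.coords["N"], r.coords["CA"],
                           r.coords["C"], next_r.coords["N"])
        out.append((phi, psi))
    return out


# Alpha-helical Ramachandran window used when no annotation is supplied.
PHI_WINDOW = (-100.0, -30.0)
PSI_WINDOW = (-80.0, 5.0)


def assign_helices(s: BackboneStructure, min_length: int = 4
                   ) -> list[tuple[int, int]]:
    """Maximal runs of >= ``min_length`` residues with helical (phi, psi).

    A residue counts as helical when both dihedrals are defined and fall in
    phi in [-100, -30] and psi in [-80, +5] degrees.  Terminal residues lack
    one dihedral and therefore never count, so a planted L-residue ideal
    helix is recovered as at least its L-2 interior residues.
    """
    if len(s) < 3:
        raise StructureError("need at least 3 residues to assign helices")
    angles = phi_psi(s)
    helical = []
    for (phi, psi) in angles:
        ok = (
            phi is not None and psi is not None
            and PHI_WINDOW[0] <= phi <= PHI_WINDOW[1]
            and PSI_WINDOW[0] <= psi <= PSI_WINDOW[1]
        )
        helical.append(ok)
    ranges: list[tuple[int, int]] = []
    run_start: int | None = None
    for pos, flag in enumerate(helical + [False]):
        if flag and run_start is None:
            run_start = pos
        elif not flag and run_start is not None:
            if pos - run_start >= min_length:
                ranges.append(
                    (s.residues[run_start].index, s.residues[pos - 1].index)
                )
            run_start = None
    return ranges
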