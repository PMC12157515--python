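"""Synthetic backbones, prediction ensembles, metric tables and assay data.

Every input the analysis pipeline consumes can be generated here with
known ground truth:

* an idealized antiparallel beta-sheet scaffold (stand-in for a fixed
  Rossmann-like sheet);
* loop-helix-loop (LHL) variants placing ideal alpha-helices at requested
  centroids/axes against that scaffold, with geometric (not physical)
  connecting loops and per-LHL linker identifiers;
* prediction ensembles displacing only the reshaped LHL atoms to planted
  LHL-RMSD targets;
* metric tables with independent planted per-metric pass rates;
* a forward proteolysis-selection simulator emitting EC50 tables (and
  optionally per-round read sets) with a planted stable/unstable
  separation against scramble controls.

Helix internal geometry uses textbook ideal-alpha-helix constants
(1.5 A rise/residue, 100 deg twist/residue, 2.3 A CA radius emerge from
phi = -57 deg, psi = -47 deg); loops are smooth interpolations sufficient
for coordinate bookkeeping but not physically valid backbones — no
in-scope operation evaluates loop physics.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from .selection import AF2_METRICS, DesignMetricRecord, ROSETTA_METRICS
from .stability import EC50Record
from .structure_io import (
    BackboneStructure,
    PredictionEnsemble,
    Residue,
    SegmentAnnotation,
    StructureError,
)

# ---------------------------------------------------------------------------
# Internal-coordinate backbone builder (NeRF)
# ---------------------------------------------------------------------------

# Engh-Huber-like bond lengths (A) and angles (deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5

ALPHA_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-139.0, 135.0)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF atom placement: position d with |cd| = bond, angle(b,c,d) and
    torsion(a,b,c,d) as requested."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        -bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain(phi_psi_list: list[tuple[float, float]]
                ) -> list[dict[str, np.ndarray]]:
    """Backbone (N, CA, C, O) coordinates for a chain with the given
    per-residue (phi, psi), omega fixed at 180 deg."""
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, len(phi_psi_list)):
        prev = coords[-1]
        psi_prev = phi_psi_list[i - 1][1]
        n = _place(prev["N"], prev["CA"], prev["C"],
                   _B_C_N, _A_CA_C_N, psi_prev)
        ca = _place(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, 180.0)
        c = _place(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi_psi_list[i][0])
        coords.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: torsion N-CA-C-O = psi - 180
    for i, atom in enumerate(coords):
        if i + 1 < len(coords):
            psi = phi_psi_list[i][1]
        else:
            psi = phi_psi_list[i][1]
        atom["O"] = _place(atom["N"], atom["CA"], atom["C"],
                           _B_C_O, _A_CA_C_O, psi - 180.0)
    return coords


def ideal_helix(n_residues: int) -> list[dict[str, np.ndarray]]:
    return build_chain([ALPHA_PHI_PSI] * n_residues)


def extended_chain(n_residues: int,
                   phi_psi: tuple[float, float] = (180.0, 180.0)
                   ) -> list[dict[str, np.ndarray]]:
    return build_chain([phi_psi] * n_residues)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis perpendicular to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _chain_axis(coords: list[dict[str, np.ndarray]]) -> np.ndarray:
    """Principal CA axis, oriented N-to-C."""
    cas = np.array([c["CA"] for c in coords])
    centered = cas - cas.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    axis = Vt[0]
    if float(axis @ (cas[-1] - cas[0])) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _backbone_centroid(coords: list[dict[str, np.ndarray]]) -> np.ndarray:
    pts = np.array([c[a] for c in coords for a in ("N", "CA", "C", "O")])
    return pts.mean(axis=0)


# ---------------------------------------------------------------------------
# Scaffold and LHL variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LhlSpec:
    """One reshaped LHL: helix size/placement plus flanking loop lengths."""

    helix_length: int
    centroid: tuple[float, float, float]
    axis: tuple[float, float, float]
    loop_lengths: tuple[int, int] = (2, 2)

    def __post_init__(self) -> None:
        if self.helix_length < 4:
            raise ValueError("helix_length must be >= 4")
        if min(self.loop_lengths) < 1:
            raise ValueError("loop lengths must be >= 1")
        a = np.asarray(self.axis, float)
        if not math.isclose(float(np.linalg.norm(a)), 1.0, rel_tol=1e-6):
            raise ValueError("axis must be a unit vector")


@dataclass(frozen=True)
class LhlVariantSpec:
    scaffold_id: str
    lhls: tuple[LhlSpec, ...]
    seed: int = 0


def make_scaffold(n_strands: int = 4, strand_length: int = 5,
                  scaffold_id: str = "scaffold"
                  ) -> tuple[BackboneStructure, SegmentAnnotation]:
    """Idealized antiparallel beta sheet in the z = 0 plane.

    Strands run along +/- x alternately at 4.8 A spacing in y.  All
    residues are annotated as sheet residues.  Deterministic.
    """
    if n_strands < 2:
        raise ValueError("need >= 2 strands")
    template = extended_chain(strand_length, EXTENDED_PHI_PSI)
    # center and flatten the template strand onto its principal axis frame
    axis = _chain_axis(template)
    center = _backbone_centroid(template)
    R = _rotation_between(axis, np.array([1.0, 0.0, 0.0]))
    residues: list[Residue] = []
    idx = 0
    for strand in range(n_strands):
        flip = (
            np.diag([-1.0, -1.0, 1.0]) if strand % 2 else np.eye(3)
        )  # antiparallel: rotate odd strands 180 deg about z
        offset = np.array([0.0, 4.8 * strand, 0.0])
        for atom_set in template:
            idx += 1
            coords = {
                name: flip @ (R @ (xyz - center)) + offset
                for name, xyz in atom_set.items()
            }
            residues.append(Residue(index=idx, aa="V", coords=coords))
    structure = BackboneStructure(id=scaffold_id, residues=residues)
    annotation = SegmentAnnotation(
        structure_id=scaffold_id,
        sheet_residues=frozenset(structure.indices),
    )
    return structure, annotation


def _loop_coords(start: np.ndarray, end: np.ndarray, n: int,
                 bulge: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Geometric loop: CAs along a bulged arc, N/C/O from local tangents."""
    out = []
    for k in range(n):
        t = (k + 1) / (n + 1)
        ca = (1 - t) * start + t * end + math.sin(math.pi * t) * bulge
        tangent = end - start
        tn = tangent / max(np.linalg.norm(tangent), 1e-9)
        up = np.array([0.0, 0.0, 1.0])
        if abs(float(tn @ up)) > 0.95:
            up = np.array([0.0, 1.0, 0.0])
        out.append({
            "N": ca - 0.75 * tn,
            "CA": ca,
            "C": ca + 0.75 * tn,
            "O": ca + 0.75 * tn + 0.6 * up,
        })
    return out


def _linker_id(lhl: LhlSpec) -> str:
    key = (
        lhl.loop_lengths,
        lhl.helix_length,
        tuple(round(c, 3) for c in lhl.centroid),
        tuple(round(a, 4) for a in lhl.axis),
    )
    return hashlib.sha1(repr(key).encode()).hexdigest()[:12]


def make_lhl_variant(
    scaffold: BackboneStructure,
    scaffold_annotation: SegmentAnnotation,
    spec: LhlVariantSpec,
    variant_id: str | None = None,
    min_clearance: float = 3.0,
) -> tuple[BackboneStructure, SegmentAnnotation, list]:
    """Place ideal helices (plus geometric loops) against the scaffold.

    Returns (structure, annotation, ground-truth HelixVector list).  The
    planted centroid/axis are exact by construction; a variant whose LHL
    comes within ``min_clearance`` (CA-CA) of the sheet raises
    StructureError.
    """
    from .geometry import HelixVector  # local import to avoid a cycle

    residues = list(scaffold.residues)
    next_idx = residues[-1].index + 1
    helices: list[tuple[int, int]] = []
    lhl_ranges: list[tuple[int, int]] = []
    linkers: list[str] = []
    truths = []
    sheet_cas = np.array([r.coords["CA"] for r in scaffold.residues])
    anchor = sheet_cas.mean(axis=0)

    for lhl in spec.lhls:
        centroid = np.asarray(lhl.centroid, float)
        axis = np.asarray(lhl.axis, float)
        axis = axis / np.linalg.norm(axis)
        helix = ideal_helix(lhl.helix_length)
        R = _rotation_between(_chain_axis(helix), axis)
        shift = centroid - R @ _backbone_centroid(helix)
        helix = [
            {name: R @ xyz + shift for name, xyz in atom_set.items()}
            for atom_set in helix
        ]
        half = 0.5 * lhl.helix_length * 1.5
        n_start = centroid - half * axis
        c_end = centroid + half * axis
        bulge = 1.5 * np.array([0.0, 0.0, 1.0])
        loop_in = _loop_coords(anchor, n_start, lhl.loop_lengths[0], bulge)
        loop_out = _loop_coords(c_end, anchor, lhl.loop_lengths[1], bulge)

        lhl_start = next_idx
        for atom_set in loop_in:
            residues.append(Residue(index=next_idx, aa="G", coords=atom_set))
            next_idx += 1
        helix_start = next_idx
        for atom_set in helix:
            residues.append(Residue(index=next_idx, aa="A", coords=atom_set))
            next_idx += 1
        helix_end = next_idx - 1
        for atom_set in loop_out:
            residues.append(Residue(index=next_idx, aa="G", coords=atom_set))
            next_idx += 1
        lhl_end = next_idx - 1

        lhl_cas = np.array(
            [r.coords["CA"] for r in residues
             if lhl_start <= r.index <= lhl_end]
        )
        dmin = np.linalg.norm(
            sheet_cas[:, None, :] - lhl_cas[None, :, :], axis=2
        ).min()
        if dmin < min_clearance:
            raise StructureError(
                f"LHL at {tuple(np.round(centroid, 2))} clashes with the "
                f"scaffold (min CA-CA {dmin:.2f} A)"
            )
        helices.append((helix_start, helix_end))
        lhl_ranges.append((lhl_start, lhl_end))
        linkers.append(_linker_id(lhl))
        truths.append(HelixVector(
            centroid=centroid, direction=axis,
            helix_range=(helix_start, helix_end),
            n_residues=lhl.helix_length,
        ))

    vid = variant_id or f"{spec.scaffold_id}_v{spec.seed}"
    structure = BackboneStructure(id=vid, residues=residues)
    annotation = SegmentAnnotation(
        structure_id=vid,
        sheet_residues=scaffold_annotation.sheet_residues,
        helices=helices,
        reshaped_lhls=lhl_ranges,
        linker_ids=linkers,
    )
    return structure, annotation, truths


def random_variant_spec(
    rng: np.random.Generator,
    scaffold_id: str = "scaffold",
    n_lhls: int = 2,
    helix_length_range: tuple[int, int] = (8, 14),
    z_range: tuple[float, float] = (8.0, 14.0),
) -> LhlVariantSpec:
    """Random LHL placement above the sheet plane (diverse regime)."""
    lhls = []
    for k in range(n_lhls):
        length = int(rng.integers(*helix_length_range, endpoint=True))
        centroid = (
            float(rng.uniform(-2.0, 10.0)),
            float(rng.uniform(2.0 + 10.0 * k, 8.0 + 10.0 * k)),
            float(rng.uniform(*z_range)),
        )
        axis = rng.normal(size=3)
        axis[2] *= 0.3  # keep helices broadly parallel to the sheet plane
        axis /= np.linalg.norm(axis)
        lhls.append(LhlSpec(
            helix_length=length, centroid=centroid,
            axis=tuple(axis),
        ))
    return LhlVariantSpec(
        scaffold_id=scaffold_id, lhls=tuple(lhls),
        seed=int(rng.integers(2 ** 31)),
    )


def regular_variant_spec(
    rng: np.random.Generator,
    scaffold_id: str = "scaffold",
    n_lhls: int = 2,
    jitter: float = 0.4,
) -> LhlVariantSpec:
    """Near-idealized LHL placement (regular regime): helices parallel to
    the strands with only small positional jitter, emulating a generator
    that reproduces one idealized geometry."""
    lhls = []
    for k in range(n_lhls):
        centroid = (
            4.0 + float(rng.normal(0, jitter)),
            5.0 + 10.0 * k + float(rng.normal(0, jitter)),
            10.0 + float(rng.normal(0, jitter)),
        )
        axis = np.array([1.0, 0.0, 0.0]) + rng.normal(0, 0.05, size=3)
        axis /= np.linalg.norm(axis)
        lhls.append(LhlSpec(
            helix_length=10, centroid=centroid, axis=tuple(axis),
        ))
    return LhlVariantSpec(
        scaffold_id=scaffold_id, lhls=tuple(lhls),
        seed=int(rng.integers(2 ** 31)),
    )


# ---------------------------------------------------------------------------
# Prediction ensembles
# ---------------------------------------------------------------------------

def make_prediction_ensemble(
    design: BackboneStructure,
    annotation: SegmentAnnotation,
    target_rmsds: list[float],
    plddts: list[float],
    seed: int = 0,
) -> PredictionEnsemble:
    """Members perturb only reshaped-LHL atoms by a rigid translation
    scaled so the LHL RMSD equals each target (verified to within 5%)."""
    from .geometry import lhl_rmsd

    if len(target_rmsds) != len(plddts):
        raise ValueError("target_rmsds and plddts must be equal length")
    rng = np.random.default_rng(seed)
    lhl = annotation.lhl_residues
    members = []
    for target, plddt in zip(target_rmsds, plddts):
        if target < 0:
            raise ValueError(f"unreachable target RMSD {target}")
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift = target * direction
        residues = [
            Residue(
                index=r.index, aa=r.aa,
                coords={
                    name: xyz + shift if r.index in lhl else xyz.copy()
                    for name, xyz in r.coords.items()
                },
            )
            for r in design.residues
        ]
        member = BackboneStructure(
            id=f"{design.id}_pred{len(members)}", residues=residues
        )
        if target > 0:
            achieved = lhl_rmsd(member, design, annotation)
            if abs(achieved - target) > 0.05 * target:  # pragma: no cover
                scale = target / achieved
                for r, r0 in zip(member.residues, design.residues):
                    if r.index in lhl:
                        for name in r.coords:
                            r.coords[name] = r0.coords[name] + scale * shift
        members.append((member, float(plddt)))
    return PredictionEnsemble(design_id=design.id, members=members)


# ---------------------------------------------------------------------------
# Metric tables
# ---------------------------------------------------------------------------

_PASS_DRAW = {
    "fragment_quality_A": ((0.3, 0.95), (1.05, 2.0)),
    "holes_shell2": ((-2.0, -0.05), (0.05, 2.0)),
    "helix_complementarity": ((0.65, 0.95), (0.1, 0.55)),
    "hydrophobic_sasa_ratio_shell2": ((0.35, 0.55), (0.61, 0.8)),
    "best_plddt_reshaped": ((86.0, 99.0), (50.0, 84.0)),
    "min_lhl_rmsd_A": ((0.2, 1.4), (1.6, 6.0)),
}
_NON_CYS = "ADEFGHIKLMNPQRSTVWY"


def simulate_metrics(
    n: int,
    pass_rates: dict[str, float] | None = None,
    seed: int = 0,
    designs_per_backbone: int = 1,
    sequence_length: int = 80,
) -> list[DesignMetricRecord]:
    """Metric table with independent planted per-metric pass rates.

    Each metric is drawn strictly inside its pass region with the planted
    probability, strictly outside otherwise, so realized pass rates are
    binomial around the planted marginals.
    """
    rates = {m: 0.5 for m in (*ROSETTA_METRICS, *AF2_METRICS)}
    if pass_rates:
        unknown = set(pass_rates) - set(rates)
        if unknown:
            raise KeyError(f"unknown metrics: {sorted(unknown)}")
        rates.update(pass_rates)
    for m, p in rates.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"pass rate for {m} outside [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        values: dict[str, float] = {}
        for metric in (*ROSETTA_METRICS, *AF2_METRICS):
            ok = rng.random() < rates[metric]
            if metric == "buried_unsat_count":
                values[metric] = int(rng.integers(0, 2)) if ok else int(
                    rng.integers(2, 5)
                )
            elif metric == "oversaturated_hbonds":
                values[metric] = 0 if ok else int(rng.integers(1, 3))
            else:
                lo, hi = _PASS_DRAW[metric][0 if ok else 1]
                values[metric] = float(rng.uniform(lo, hi))
        seq = "".join(rng.choice(list(_NON_CYS), size=sequence_length))
        records.append(DesignMetricRecord(
            design_id=f"d{i:06d}",
            backbone_id=f"bb{i // designs_per_backbone:06d}",
            sequence=seq,
            rosetta={m: values[m] for m in ROSETTA_METRICS},
            af2={m: values[m] for m in AF2_METRICS},
        ))
    return records


# ---------------------------------------------------------------------------
# Proteolysis-selection forward simulator
# ---------------------------------------------------------------------------

# Protease concentration schedule (uM), highest of each round feeding the
# next round's input population.
TRYPSIN_ROUNDS = ((0.07, 0.21), (0.64, 1.93), (5.78, 17.33, 51.99))
CHYMOTRYPSIN_ROUNDS = ((0.08, 0.25), (0.74, 2.22), (6.67, 20.0))


@dataclass(frozen=True)
class AssaySimSpec:
    n_designs: int = 2000
    stable_fraction: float = 0.6
    n_full_scrambles: int = 190
    n_patterned_scrambles: int = 190
    # log-normal (median, sigma of ln) EC50 distributions, assay units
    stable_ec50: tuple[float, float] = (12.0, 0.5)
    unstable_ec50: tuple[float, float] = (0.2, 0.5)
    scramble_ec50: tuple[float, float] = (0.2, 0.5)
    ci_width: tuple[float, float] = (0.8, 0.4)
    concentrations: dict = field(default_factory=lambda: {
        "trypsin": TRYPSIN_ROUNDS, "chymotrypsin": CHYMOTRYPSIN_ROUNDS,
    })
    read_depth: int = 50_000
    protein_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.stable_fraction <= 1:
            raise ValueError("stable_fraction must be in [0, 1]")
        for rounds in self.concentrations.values():
            flat = [c for rnd in rounds for c in rnd]
            if any(b <= a for a, b in zip(flat, flat[1:])):
                raise ValueError("concentrations must increase across rounds")


def survival(ec50: float, concentration: float) -> float:
    """Pseudo-first-order proteolysis survival: exp(-k c) with the rate
    constant set so survival is 1/2 at c = EC50."""
    return float(np.exp(-math.log(2.0) * concentration / ec50))


_CODON = {  # one codon per residue; enough to build countable reads
    "A": "GCT", "R": "AGA", "N": "AAC", "D": "GAC", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAC", "I": "ATC",
    "L": "TTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCA",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAC", "V": "GTT",
}


def reverse_translate(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein)


def simulate_assay(
    spec: AssaySimSpec = AssaySimSpec(),
    with_reads: bool = False,
):
    """Forward proteolysis-selection simulation.

    Returns ``(records, truth)`` or, with reads,
    ``(records, truth, designs, reads)``:

    * ``records``: list of EC50Record (designs + both scramble types) with
      reported EC50 = planted EC50 under multiplicative log-normal noise
      whose sigma is tied to the drawn credible-interval width;
    * ``truth``: design_id -> planted-stable flag (exactly
      round(n * stable_fraction) stable designs);
    * ``designs``: design_id -> (coding_dna, protein) for read counting;
    * ``reads``: (protease, round_idx, concentration) -> list of read
      strings (flank5 + coding + flank3) multinomially sampled from the
      surviving population at ``read_depth``.
    """
    rng = np.random.default_rng(spec.seed)
    n_stable = int(round(spec.n_designs * spec.stable_fraction))
    stable_flags = np.zeros(spec.n_designs, dtype=bool)
    stable_flags[:n_stable] = True
    rng.shuffle(stable_flags)

    def draw_ec50(params: tuple[float, float]) -> float:
        median, sigma = params
        return float(median * np.exp(rng.normal(0.0, sigma)))

    records: list[EC50Record] = []
    truth: dict[str, bool] = {}
    planted: dict[str, dict[str, float]] = {}

    def add(design_id: str, category: str, params: tuple[float, float],
            correlated: bool) -> None:
        ec50, ci = {}, {}
        shared = draw_ec50(params) if correlated else None
        for protease in spec.concentrations:
            true_val = shared if shared is not None else draw_ec50(params)
            width = draw_ec50(spec.ci_width)
            noise_sigma = width / (2 * 1.96)
            ec50[protease] = float(
                true_val * np.exp(rng.normal(0.0, noise_sigma))
            )
            ci[protease] = width
            planted.setdefault(design_id, {})[protease] = true_val
        records.append(EC50Record(
            design_id=design_id, category=category, ec50=ec50, ci95=ci,
        ))

    for i in range(spec.n_designs):
        did = f"d{i:06d}"
        params = spec.stable_ec50 if stable_flags[i] else spec.unstable_ec50
        # stable designs share one underlying stability across proteases;
        # unstable ones fluctuate independently like scrambles
        add(did, "design", params, correlated=bool(stable_flags[i]))
        truth[did] = bool(stable_flags[i])
    for i in range(spec.n_full_scrambles):
        add(f"fs{i:05d}", "full_scramble", spec.scramble_ec50, correlated=False)
    for i in range(spec.n_patterned_scrambles):
        add(f"ps{i:05d}", "patterned_scramble", spec.scramble_ec50,
            correlated=False)

    if not with_reads:
        return records, truth

    aas = np.array(list(_CODON))
    designs: dict[str, tuple[str, str]] = {}
    for r in records:
        protein = "".join(rng.choice(aas, size=spec.protein_length))
        while protein in {p for _, p in designs.values()}:  # pragma: no cover
            protein = "".join(rng.choice(aas, size=spec.protein_length))
        designs[r.design_id] = (reverse_translate(protein), protein)

    ids = [r.design_id for r in records]
    reads: dict[tuple[str, int, float], list[str]] = {}
    for protease, rounds in spec.concentrations.items():
        carried = np.ones(len(ids))  # survival through previous rounds
        for round_idx, concentrations in enumerate(rounds):
            for conc in concentrations:
                weights = carried * np.array([
                    survival(planted[i][protease], conc) for i in ids
                ])
                total = weights.sum()
                if total <= 0:  # pragma: no cover
                    continue
                counts = rng.multinomial(spec.read_depth, weights / total)
                batch = []
                for design_id, count in zip(ids, counts):
                    if count == 0:
                        continue
                    coding, _ = designs[design_id]
                    read = "TCAATG" + coding + "CTCGAG"
                    batch.extend([read] * int(count))
                reads[(protease, round_idx, conc)] = batch
            carried *= np.array([
                survival(planted[i][protease], max(concentrations))
                for i in ids
            ])
    return records, truth, designs, reads
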