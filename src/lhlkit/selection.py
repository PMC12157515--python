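"""Experimental design-selection pipeline.

Designed sequences are screened for orderability (oligo-pool length
arithmetic and a no-cysteine rule), divided into four quadrants by whether
they pass a set of Rosetta-style physics metrics and a set of
structure-prediction metrics, reduced to at most one design per unique
backbone by a staged priority algorithm, and finally sampled per quadrant
for experimental testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROSETTA_METRICS = (
    "fragment_quality_A",
    "holes_shell2",
    "helix_complementarity",
    "buried_unsat_count",
    "oversaturated_hbonds",
    "hydrophobic_sasa_ratio_shell2",
)
AF2_METRICS = ("best_plddt_reshaped", "min_lhl_rmsd_A")

QUADRANTS = ("RP-AP", "RP-AF", "RF-AP", "RF-AF")


@dataclass
class DesignMetricRecord:
    """Per-design metric table row; metrics are consumed, never computed."""

    design_id: str
    backbone_id: str
    sequence: str
    rosetta: dict[str, float]
    af2: dict[str, float]

    def __post_init__(self) -> None:
        plddt = self.af2.get("best_plddt_reshaped")
        if plddt is not None and not (0.0 <= plddt <= 100.0):
            raise ValueError(f"{self.design_id}: pLDDT {plddt} outside [0, 100]")
        rmsd = self.af2.get("min_lhl_rmsd_A")
        if rmsd is not None and rmsd < 0:
            raise ValueError(f"{self.design_id}: negative RMSD")


@dataclass(frozen=True)
class OligoSpec:
    """Oligo-pool synthesis constraints.

    A design is encoded as primer + variable region + primer on an oligo of
    at most ``oligo_max_nt`` bases; the reverse primer encodes the first
    ``fixed_cterm_in_primer`` of ``fixed_cterm_residues`` C-terminal
    residues shared by all designs (the rest live on the vector), so the
    orderable protein is longer than the variable region alone.
    """

    oligo_max_nt: int = 300
    primer_nt: int = 21
    fixed_cterm_residues: int = 17
    fixed_cterm_in_primer: int = 7

    def __post_init__(self) -> None:
        if self.oligo_max_nt < 2 * self.primer_nt:
            raise ValueError("oligo shorter than its two primers")
        if self.fixed_cterm_in_primer * 3 != self.primer_nt:
            raise ValueError("reverse primer must encode fixed_cterm_in_primer residues")
        if self.fixed_cterm_in_primer > self.fixed_cterm_residues:
            raise ValueError("primer-encoded residues exceed fixed C-terminal stretch")


# Default pass thresholds; all comparisons strict.
DEFAULT_THRESHOLDS = {
    "fragment_quality_A": ("<", 1.0),
    "holes_shell2": ("<", 0.0),
    "helix_complementarity": (">", 0.6),
    "buried_unsat_count": ("<", 2),
    "oversaturated_hbonds": ("==", 0),
    "hydrophobic_sasa_ratio_shell2": ("<", 0.58),
    "best_plddt_reshaped": (">", 85.0),
    "min_lhl_rmsd_A": ("<", 1.5),
}


def max_lengths(spec: OligoSpec = OligoSpec()) -> tuple[int, int, int]:
    """(variable nucleotides, variable residues, total orderable residues)."""
    variable_nt = spec.oligo_max_nt - 2 * spec.primer_nt
    variable_aa = variable_nt // 3
    total_aa = variable_aa + spec.fixed_cterm_residues
    return variable_nt, variable_aa, total_aa


def orderability_filter(
    seq: str,
    spec: OligoSpec = OligoSpec(),
    forbid: frozenset[str] = frozenset("C"),
) -> tuple[bool, list[str]]:
    """Length and forbidden-residue screen; returns (pass, reasons)."""
    _, _, total_aa = max_lengths(spec)
    reasons = []
    if len(seq) > total_aa:
        reasons.append(f"length {len(seq)} exceeds {total_aa} residues")
    hits = sorted(set(seq) & set(forbid))
    if hits:
        reasons.append(f"contains forbidden residue(s) {''.join(hits)}")
    return not reasons, reasons


def _passes(value: float, rule: tuple[str, float]) -> bool:
    op, threshold = rule
    if op == "<":
        return value < threshold
    if op == ">":
        return value > threshold
    if op == "==":
        return value == threshold
    raise ValueError(f"unknown comparison {op!r}")


def quadrant_assign(
    record: DesignMetricRecord,
    thresholds: dict[str, tuple[str, float]] | None = None,
) -> str:
    """Quadrant label from the Rosetta-pass and AF2-pass flags."""
    rules = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        rules.update(thresholds)
    for name in ROSETTA_METRICS:
        if name not in record.rosetta:
            raise KeyError(f"{record.design_id}: missing Rosetta metric {name}")
    for name in AF2_METRICS:
        if name not in record.af2:
            raise KeyError(f"{record.design_id}: missing AF2 metric {name}")
    rosetta_pass = all(
        _passes(record.rosetta[m], rules[m]) for m in ROSETTA_METRICS
    )
    af2_pass = all(_passes(record.af2[m], rules[m]) for m in AF2_METRICS)
    return f"{'RP' if rosetta_pass else 'RF'}-{'AP' if af2_pass else 'AF'}"


def populate_quadrants(
    records: list[DesignMetricRecord],
    seed: int = 0,
    thresholds: dict[str, tuple[str, float]] | None = None,
) -> dict[str, tuple[str, str]]:
    """Reduce multi-design backbones to one design per backbone, quadrant-wise.

    Staged priority (the two Rosetta-Pass quadrants are scarcer and are
    populated first):

    1. backbones with designs in both RP-AP and RP-AF are evenly split
       between those two quadrants (seeded shuffle, alternating
       assignment), discarding their other designs;
    2. remaining backbones with any RP-AP or RP-AF design go to that
       quadrant;
    3. remaining backbones with an RF-AP design go to RF-AP;
    4. everything left goes to RF-AF.

    Returns backbone_id -> (chosen design_id, quadrant).
    """
    rng = np.random.default_rng(seed)
    by_backbone: dict[str, dict[str, list[str]]] = {}
    for r in records:
        q = quadrant_assign(r, thresholds)
        by_backbone.setdefault(r.backbone_id, {}).setdefault(q, []).append(
            r.design_id
        )
    for quads in by_backbone.values():
        for designs in quads.values():
            designs.sort()

    assignment: dict[str, tuple[str, str]] = {}

    def take(backbone: str, quadrant: str) -> None:
        assignment[backbone] = (by_backbone[backbone][quadrant][0], quadrant)

    # stage 1: backbones straddling the two Rosetta-Pass quadrants
    both = sorted(
        b for b, quads in by_backbone.items()
        if "RP-AP" in quads and "RP-AF" in quads
    )
    rng.shuffle(both)
    for pos, backbone in enumerate(both):
        take(backbone, "RP-AP" if pos % 2 == 0 else "RP-AF")
    # stage 2: remaining Rosetta-Pass backbones
    for quadrant in ("RP-AP", "RP-AF"):
        for backbone in sorted(by_backbone):
            if backbone not in assignment and quadrant in by_backbone[backbone]:
                take(backbone, quadrant)
    # stage 3: Rosetta-Fail / AF2-Pass
    for backbone in sorted(by_backbone):
        if backbone not in assignment and "RF-AP" in by_backbone[backbone]:
            take(backbone, "RF-AP")
    # stage 4: everything else
    for backbone in sorted(by_backbone):
        if backbone not in assignment:
            take(backbone, "RF-AF")
    return assignment


def sample_quadrants(
    assignment: dict[str, tuple[str, str]],
    per_quadrant: int = 2500,
    seed: int = 0,
) -> list[str]:
    """Seeded sampling without replacement of designs from each quadrant."""
    rng = np.random.default_rng(seed)
    by_quadrant: dict[str, list[str]] = {q: [] for q in QUADRANTS}
    for design_id, quadrant in assignment.values():
        by_quadrant[quadrant].append(design_id)
    chosen: list[str] = []
    for quadrant in QUADRANTS:
        pool = sorted(by_quadrant[quadrant])
        if len(pool) < per_quadrant:
            raise ValueError(
                f"quadrant {quadrant} holds {len(pool)} designs, "
                f"fewer than the requested {per_quadrant}"
            )
        picked = rng.choice(len(pool), size=per_quadrant, replace=False)
        chosen.extend(pool[i] for i in sorted(picked))
    return chosen


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

def records_to_frame(records: list[DesignMetricRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"design_id": r.design_id, "backbone_id": r.backbone_id,
               "sequence": r.sequence}
        row.update(r.rosetta)
        row.update(r.af2)
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[DesignMetricRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(DesignMetricRecord(
            design_id=str(row["design_id"]),
            backbone_id=str(row["backbone_id"]),
            sequence=str(row.get("sequence", "")),
            rosetta={m: row[m] for m in ROSETTA_METRICS},
            af2={m: row[m] for m in AF2_METRICS},
        ))
    return records
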