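"""Protease-resistance stability analysis.

A yeast-display proteolysis assay reports, per design and per protease
(trypsin and chymotrypsin), an EC50 — the protease concentration at which
half the displayed protein is cleaved — with a 95% credible-interval
width.  A design is called stable when its EC50 for *both* proteases
exceeds the 95th percentile of the patterned-scramble negative controls,
which preserve hydrophobic/polar patterning and therefore bound what an
unfolded chain of design-like composition can resist.

This module also implements the read-counting rule that maps merged
amplicon reads to designs: a read counts for a design when the coding
region between fixed flanking hexamers translates to exactly the design's
protein sequence (synonymous nucleotide changes therefore still count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

PROTEASES = ("trypsin", "chymotrypsin")


@dataclass
class EC50Record:
    design_id: str
    category: str  # "design" | "full_scramble" | "patterned_scramble"
    ec50: dict[str, float]        # protease -> EC50
    ci95: dict[str, float]        # protease -> credible-interval width

    def __post_init__(self) -> None:
        if self.category not in ("design", "full_scramble", "patterned_scramble"):
            raise ValueError(f"unknown category {self.category!r}")
        for protease, value in self.ec50.items():
            if not np.isfinite(value):
                raise ValueError(f"{self.design_id}: non-finite EC50 ({protease})")
        for protease, width in self.ci95.items():
            if width < 0:
                raise ValueError(f"{self.design_id}: negative CI width ({protease})")


@dataclass(frozen=True)
class StabilityCall:
    design_id: str
    stable: bool
    thresholds_used: dict[str, float]


# ---------------------------------------------------------------------------
# Read counting
# ---------------------------------------------------------------------------

def _translate(dna: str) -> str | None:
    if len(dna) == 0 or len(dna) % 3 != 0:
        return None
    protein = str(Seq(dna).translate())
    if "*" in protein:
        return None
    return protein


def count_reads(
    merged_reads,
    designs: dict[str, tuple[str, str]],
    flank5: str = "TCAATG",
    flank3: str = "CTCGAG",
) -> dict[str, int]:
    """Count merged reads per design by flank-delimited protein identity.

    ``merged_reads``: iterable of read sequences (strings) or Biopython
    SeqRecords.  ``designs``: design_id -> (coding_dna, protein); the
    protein is the matching key, so synonymous reads still count.  Both
    strands of each read are scanned.  Designs sharing a protein sequence
    are reported once and merged under the lexicographically first id.
    """
    protein_to_id: dict[str, str] = {}
    for design_id in sorted(designs):
        coding, protein = designs[design_id]
        expected = _translate(coding)
        if expected is None or expected != protein:
            raise ValueError(
                f"design {design_id}: coding sequence does not translate to "
                "its protein"
            )
        if protein in protein_to_id:
            warnings.warn(
                f"designs {protein_to_id[protein]} and {design_id} share a "
                "protein sequence; counts merged under the former",
                stacklevel=2,
            )
        else:
            protein_to_id[protein] = design_id

    counts = {design_id: 0 for design_id in designs}

    def match(seq: str) -> str | None:
        i = seq.find(flank5)
        if i < 0:
            return None
        j = seq.find(flank3, i + len(flank5))
        if j < 0:
            return None
        protein = _translate(seq[i + len(flank5):j])
        if protein is None:
            return None
        return protein_to_id.get(protein)

    for read in merged_reads:
        seq = str(read.seq) if hasattr(read, "seq") else str(read)
        seq = seq.upper()
        hit = match(seq) or match(str(Seq(seq).reverse_complement()))
        if hit is not None:
            counts[hit] += 1
    return counts


# ---------------------------------------------------------------------------
# EC50 filtering, thresholds and classification
# ---------------------------------------------------------------------------

def credible_filter(records: list[EC50Record], max_ci: float = 2.0
                    ) -> list[EC50Record]:
    """Retain records with credible-interval width strictly below ``max_ci``
    for every protease present."""
    return [
        r for r in records
        if all(r.ci95[p] < max_ci for p in r.ci95)
    ]


def scramble_thresholds(
    records: list[EC50Record],
    percentile: float = 95.0,
    include_full: bool = False,
) -> dict[str, float]:
    """Per-protease EC50 percentile of the patterned-scramble controls.

    Linear interpolation between order statistics.  Full scrambles are
    excluded unless ``include_full`` pools both control types.
    """
    categories = {"patterned_scramble"}
    if include_full:
        categories.add("full_scramble")
    thresholds = {}
    for protease in PROTEASES:
        values = [
            r.ec50[protease] for r in records
            if r.category in categories and protease in r.ec50
        ]
        if len(values) < 2:
            raise ValueError(
                f"need >= 2 patterned-scramble EC50s for {protease}"
            )
        thresholds[protease] = float(np.percentile(values, percentile))
    return thresholds


def classify_stable(record: EC50Record, thresholds: dict[str, float]
                    ) -> StabilityCall:
    """Stable iff the EC50 strictly exceeds the threshold for every protease."""
    for protease in thresholds:
        if protease not in record.ec50:
            raise KeyError(f"{record.design_id}: missing EC50 for {protease}")
    stable = all(
        record.ec50[p] > thresholds[p] for p in thresholds
    )
    return StabilityCall(
        design_id=record.design_id, stable=stable,
        thresholds_used=dict(thresholds),
    )


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

_COLUMNS = ["design_id", "category", "trypsin_ec50", "trypsin_ci95",
            "chymotrypsin_ec50", "chymotrypsin_ci95"]


def records_to_frame(records: list[EC50Record]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "design_id": r.design_id,
            "category": r.category,
            "trypsin_ec50": r.ec50.get("trypsin", np.nan),
            "trypsin_ci95": r.ci95.get("trypsin", np.nan),
            "chymotrypsin_ec50": r.ec50.get("chymotrypsin", np.nan),
            "chymotrypsin_ci95": r.ci95.get("chymotrypsin", np.nan),
        })
    return pd.DataFrame(rows, columns=_COLUMNS)


def records_from_frame(df: pd.DataFrame) -> list[EC50Record]:
    records = []
    for _, row in df.iterrows():
        records.append(EC50Record(
            design_id=str(row["design_id"]),
            category=str(row["category"]),
            ec50={"trypsin": float(row["trypsin_ec50"]),
                  "chymotrypsin": float(row["chymotrypsin_ec50"])},
            ci95={"trypsin": float(row["trypsin_ci95"]),
                  "chymotrypsin": float(row["chymotrypsin_ci95"])},
        ))
    return records
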