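"""Scramble negative-control generation and control-source allocation.

Two kinds of unfolded-control sequences accompany a design library: full
scrambles (a uniform permutation of all residues) and patterned scrambles,
which keep the hydrophobic/polar pattern of the design — so the control is
compositionally design-like but should not fold — by shuffling identities
only within the hydrophobic class and within the polar class, with Gly and
Pro fixed in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STANDARD_AAS = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Default hydrophobic class; C is absent because design libraries here are
# cysteine-free.  The partition is configurable and recorded in output
# metadata — it is this package's convention, not a universal one.
DEFAULT_HYDROPHOBIC = frozenset("AVLIMFWY")


@dataclass(frozen=True)
class HPClassification:
    hydrophobic: frozenset[str] = DEFAULT_HYDROPHOBIC
    fixed: frozenset[str] = frozenset("GP")

    def __post_init__(self) -> None:
        hydrophobic = frozenset(self.hydrophobic)
        fixed = frozenset(self.fixed)
        if hydrophobic & fixed:
            raise ValueError("hydrophobic and fixed classes overlap")
        if not (hydrophobic | fixed) <= STANDARD_AAS:
            raise ValueError("classes must contain standard amino acids only")
        object.__setattr__(self, "hydrophobic", hydrophobic)
        object.__setattr__(self, "fixed", fixed)

    def classify(self, aa: str) -> str:
        if aa in self.fixed:
            return "fixed"
        return "hydrophobic" if aa in self.hydrophobic else "polar"


def _check_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = sorted(set(seq) - STANDARD_AAS)
    if bad:
        raise ValueError(f"non-standard residue(s): {''.join(bad)}")


def full_scramble(seq: str, seed: int) -> str:
    """Seeded uniform permutation of all residues (Fisher-Yates via
    numpy's PCG64 generator, reproducible across platforms)."""
    _check_sequence(seq)
    rng = np.random.default_rng(seed)
    letters = list(seq)
    rng.shuffle(letters)
    return "".join(letters)


def patterned_scramble(seq: str, hp: HPClassification = HPClassification(),
                       seed: int = 0) -> str:
    """Shuffle within the hydrophobic and polar classes separately,
    leaving fixed (Gly/Pro by default) positions untouched."""
    _check_sequence(seq)
    rng = np.random.default_rng(seed)
    out = list(seq)
    for cls in ("hydrophobic", "polar"):
        positions = [i for i, aa in enumerate(seq) if hp.classify(aa) == cls]
        letters = [seq[i] for i in positions]
        rng.shuffle(letters)
        for i, aa in zip(positions, letters):
            out[i] = aa
    return "".join(out)


def allocate_control_sources(
    quadrant_of: dict[str, str],
    counts: dict[str, int],
    seed: int = 0,
) -> list[str]:
    """Seeded per-quadrant sampling of designs to serve as scramble sources.

    Each selected source later yields one full and one patterned scramble,
    so the control library holds twice this many sequences.
    """
    rng = np.random.default_rng(seed)
    by_quadrant: dict[str, list[str]] = {}
    for design_id in sorted(quadrant_of):
        by_quadrant.setdefault(quadrant_of[design_id], []).append(design_id)
    chosen: list[str] = []
    for quadrant in sorted(counts):
        want = counts[quadrant]
        pool = by_quadrant.get(quadrant, [])
        if want > len(pool):
            raise ValueError(
                f"quadrant {quadrant} holds {len(pool)} designs, "
                f"cannot sample {want}"
            )
        picked = rng.choice(len(pool), size=want, replace=False)
        chosen.extend(pool[i] for i in sorted(picked))
    return chosen
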