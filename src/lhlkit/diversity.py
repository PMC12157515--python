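"""Group-level diversity statistics and score aggregation.

Average pairwise helix RMSD within a group of backbones is the headline
diversity measure: a generator producing near-identical helix placements
scores low, one spanning many positions and orientations scores high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import pairwise_helix_rmsd

_METRICS = {"overall": None, "helix1": 0, "helix2": 1}


@dataclass
class RmsdMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, Angstrom

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T, atol=1e-6):
            raise ValueError("matrix not symmetric")
        if np.any(v < 0) or not np.allclose(np.diag(v), 0):
            raise ValueError("distances must be non-negative with zero diagonal")
        self.values = v

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "RmsdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(float))


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n_pairs: int
    mean: float
    median: float
    quartiles: tuple[float, float]
    whiskers: tuple[float, float]


def pairwise_matrix(group, metric: str = "overall") -> RmsdMatrix:
    """All-by-all sheet-aligned helix RMSD within a group.

    ``group``: list of (id, BackboneStructure, SegmentAnnotation).
    ``metric``: "overall" concatenates both matched helices; "helix1" /
    "helix2" restrict to a single matched helix.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if len(group) < 2:
        raise ValueError("need >= 2 structures")
    helix = _METRICS[metric]
    n = len(group)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, si, ai = group[i]
            _, sj, aj = group[j]
            d = pairwise_helix_rmsd(si, ai, sj, aj, helix=helix)
            values[i, j] = values[j, i] = d
    return RmsdMatrix(ids=[g[0] for g in group], values=values)


def summarize_group(m: RmsdMatrix, label: str) -> GroupSummary:
    """Box-plot statistics over the n(n-1)/2 pairwise distances.

    Quartiles use linear interpolation between order statistics; whiskers
    extend to the most extreme values within 1.5 interquartile ranges of
    the quartiles.
    """
    values = m.upper_triangle()
    if len(values) < 1:
        raise ValueError("need >= 2 structures")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    in_lo = values[values >= q1 - 1.5 * iqr]
    in_hi = values[values <= q3 + 1.5 * iqr]
    return GroupSummary(
        group=label,
        n_pairs=len(values),
        mean=float(values.mean()),
        median=float(med),
        quartiles=(float(q1), float(q3)),
        whiskers=(float(in_lo.min()), float(in_hi.max())),
    )


def even_interval_sample(structures, reference, k: int):
    """k structures spanning the helix-RMSD range to a reference.

    Structures are sorted ascending by sheet-aligned helix RMSD to the
    reference and picked at indices round(j*(n-1)/(k-1)); k = 1 yields the
    median element, and k >= 2 always includes the minimum and maximum.
    ``structures``: list of (id, BackboneStructure, SegmentAnnotation);
    ``reference``: (BackboneStructure, SegmentAnnotation).
    """
    n = len(structures)
    if not 1 <= k <= n:
        raise ValueError(f"k = {k} outside [1, {n}]")
    ref_s, ref_ann = reference
    rmsds = [
        pairwise_helix_rmsd(s, ann, ref_s, ref_ann)
        for _, s, ann in structures
    ]
    order = np.argsort(rmsds, kind="stable")
    if k == 1:
        return [structures[order[(n - 1) // 2]]]
    picks = [int(round(j * (n - 1) / (k - 1))) for j in range(k)]
    return [structures[order[p]] for p in picks]


def neg_pll(per_position_probs: dict[int, float], positions) -> float:
    """Negative pseudo-log-likelihood: sum of -ln p over the requested
    positions (natural log)."""
    total = 0.0
    for i in positions:
        if i not in per_position_probs:
            raise KeyError(f"no probability for position {i}")
        p = per_position_probs[i]
        if not 0.0 < p <= 1.0:
            raise ValueError(f"probability {p} at position {i} outside (0, 1]")
        total -= np.log(p)
    return float(total)


def bin_scores_by_rmsd(scores, rmsds, edges) -> pd.DataFrame:
    """Per-bin score summaries with half-open bins [e_k, e_{k+1}).

    Values >= the last edge fall into a final overflow bin.  Returns a
    DataFrame with bin bounds, count, median and quartiles.
    """
    scores = np.asarray(scores, dtype=float)
    rmsds = np.asarray(rmsds, dtype=float)
    if scores.shape != rmsds.shape:
        raise ValueError("scores and rmsds must be index-aligned")
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    bounds = list(zip(edges, edges[1:])) + [(edges[-1], np.inf)]
    rows = []
    for lo, hi in bounds:
        mask = (rmsds >= lo) & (rmsds < hi)
        sel = scores[mask]
        if len(sel):
            q1, med, q3 = np.percentile(sel, [25, 50, 75])
        else:
            q1 = med = q3 = np.nan
        rows.append({"lo": lo, "hi": hi, "count": int(mask.sum()),
                     "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(rows)


def group_ttest(a, b) -> tuple[float, float]:
    """Two-sided two-sample t-test helper; returns (statistic, p-value)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)
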