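"""Structure-based train/test splitting.

To keep a held-out test set structurally distinct from training data, the
designs are spectrally clustered on their all-by-all helix RMSDs, many
random cluster bipartitions are scored, and the best split is pruned until
no cross-split pair is closer than a leakage threshold in *either*
reshaped helix and no cross-split pair shares a linker backbone.

The search is exhaustive over ``n_cluster_seeds`` k-means seeds times
``n_bipartitions_per_seed`` random bipartitions; all randomness derives
from a single master seed, so a split is byte-for-byte reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .diversity import RmsdMatrix


class SplitInfeasibleError(RuntimeError):
    """Raised when pruning removes every example or empties one side."""


@dataclass(frozen=True)
class SplitSpec:
    n_clusters: int = 25
    n_cluster_seeds: int = 1000
    n_bipartitions_per_seed: int = 1000
    leakage_threshold: float = 2.0
    target_train_fraction: float = 0.9
    master_seed: int = 0
    score_lambda: float = 10.0  # A of cross-split margin per unit ratio error

    def __post_init__(self) -> None:
        if min(self.n_clusters, self.n_cluster_seeds,
               self.n_bipartitions_per_seed) < 1:
            raise ValueError("counts must be >= 1")
        if not 0 < self.target_train_fraction < 1:
            raise ValueError("target_train_fraction must be in (0, 1)")
        if self.leakage_threshold <= 0:
            raise ValueError("leakage_threshold must be positive")


@dataclass
class SplitResult:
    train_ids: list[str]
    test_ids: list[str]
    removed_ids: list[str]
    provenance: dict = field(default_factory=dict)


def affinity_from_rmsd(m: RmsdMatrix, sigma: float | str = "knn-median"
                       ) -> np.ndarray:
    """Gaussian affinity A_ij = exp(-d_ij^2 / (2 sigma^2)), zero diagonal.

    ``sigma="median"`` uses the median off-diagonal distance;
    ``sigma="knn-median"`` (default) uses the median over points of the
    distance to their ceil(log2 n)-th nearest neighbour.  The local scale
    keeps the graph contrastive when the distance distribution is bimodal
    (tight structural families separated by large gaps), where the global
    median sits in the between-family mode and washes out the block
    structure.
    """
    d = m.values
    n = len(m.ids)
    if sigma == "median":
        off = d[np.triu_indices(n, k=1)]
        sigma = float(np.median(off))
    elif sigma == "knn-median":
        k = max(1, int(np.ceil(np.log2(max(n, 2)))))
        sorted_rows = np.sort(d, axis=1)  # column 0 is the zero diagonal
        sigma = float(np.median(sorted_rows[:, min(k, n - 1)]))
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    A = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    np.fill_diagonal(A, 0.0)
    return A


def spectral_cluster(affinity: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Normalized spectral clustering: embed on the k eigenvectors of the
    symmetric normalized graph Laplacian with smallest eigenvalues, then
    seeded k-means.  Deterministic for a fixed seed."""
    A = np.asarray(affinity, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("affinity must be square and symmetric")
    if np.any(A < 0):
        raise ValueError("affinity must be non-negative")
    if k > n:
        raise ValueError(f"k = {k} exceeds n = {n}")
    degree = A.sum(axis=1)
    if np.any(degree <= 0):
        raise ValueError(
            "disconnected graph: some node has zero affinity to all others"
        )
    d_inv_sqrt = 1.0 / np.sqrt(degree)
    L = np.eye(n) - d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    _, vectors = eigh(L, subset_by_index=(0, k - 1))
    # row-normalize the embedding (Ng-Jordan-Weiss)
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    embedding = vectors / norms
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(embedding)


def _cross_min(values: np.ndarray, train_mask: np.ndarray) -> float:
    sub = values[np.ix_(train_mask, ~train_mask)]
    return float(sub.min()) if sub.size else np.inf


def _greedy_prune(
    ids: list[str],
    side: dict[str, int],  # id -> 0 train / 1 test
    pairwise_bad,          # callable(id_a, id_b) -> bool (cross pair violates)
    target: float,
) -> tuple[set[str], dict[str, int]]:
    """Iteratively remove the example in the most violating cross pairs.

    Ties are broken by which removal leaves the train fraction closest to
    ``target``, then by removing from the larger side (preserving the
    smaller set), then lexicographically.
    """
    removed: set[str] = set()
    active = dict(side)
    while True:
        counts: dict[str, int] = {}
        id_list = sorted(active)
        for a_pos, a in enumerate(id_list):
            for b in id_list[a_pos + 1:]:
                if active[a] != active[b] and pairwise_bad(a, b):
                    counts[a] = counts.get(a, 0) + 1
                    counts[b] = counts.get(b, 0) + 1
        if not counts:
            return removed, active
        max_count = max(counts.values())
        candidates = [i for i, c in counts.items() if c == max_count]
        n_train = sum(1 for v in active.values() if v == 0)
        n_test = len(active) - n_train
        sizes = {0: n_train, 1: n_test}

        def key(i: str):
            s = active[i]
            new_train = n_train - (1 if s == 0 else 0)
            new_total = len(active) - 1
            frac = new_train / new_total if new_total else 0.0
            return (abs(frac - target), -sizes[s], i)

        victim = min(candidates, key=key)
        removed.add(victim)
        del active[victim]
        if not active or len(set(active.values())) < 2:
            raise SplitInfeasibleError(
                "pruning removed every example from one side of the split"
            )


def search_split(
    ids: list[str],
    helix1_m: RmsdMatrix,
    helix2_m: RmsdMatrix,
    overall_m: RmsdMatrix,
    spec: SplitSpec = SplitSpec(),
    linker_ids: dict[str, list[str]] | None = None,
) -> SplitResult:
    """Best-scoring cluster bipartition, then leakage and linker pruning.

    Scoring of a candidate bipartition (maximized):
    ``min cross-split min(helix1, helix2) RMSD
    - score_lambda * |train_fraction - target_train_fraction|``.
    Exactly ``n_cluster_seeds * n_bipartitions_per_seed`` candidates are
    scored; the count is recorded in the provenance.
    """
    for m in (helix1_m, helix2_m, overall_m):
        if m.ids != list(ids):
            raise ValueError("matrices must be index-aligned with ids")
    n = len(ids)
    pair_min = np.minimum(helix1_m.values, helix2_m.values)
    affinity = affinity_from_rmsd(overall_m)

    best = None  # (score, seed_idx, bip_idx, train_mask)
    n_scored = 0
    for seed_idx in range(spec.n_cluster_seeds):
        labels = spectral_cluster(
            affinity, spec.n_clusters, seed=spec.master_seed + seed_idx
        )
        cluster_ids = np.unique(labels)
        bip_rng = np.random.default_rng(
            (spec.master_seed + 100_003 * (seed_idx + 1)) % (2 ** 31)
        )
        for bip_idx in range(spec.n_bipartitions_per_seed):
            group_a = bip_rng.random(len(cluster_ids)) < 0.5
            if group_a.all() or not group_a.any():
                # degenerate draw: force a non-trivial bipartition
                group_a[bip_rng.integers(len(cluster_ids))] = not group_a[0]
                if group_a.all() or not group_a.any():
                    group_a[0] = ~group_a[0]
            in_a = group_a[np.searchsorted(cluster_ids, labels)]
            frac_a = in_a.sum() / n
            # the side closer to the target fraction is train
            train_mask = (
                in_a if abs(frac_a - spec.target_train_fraction)
                <= abs((1 - frac_a) - spec.target_train_fraction)
                else ~in_a
            )
            frac = train_mask.sum() / n
            score = (
                _cross_min(pair_min, train_mask)
                - spec.score_lambda * abs(frac - spec.target_train_fraction)
            )
            n_scored += 1
            if best is None or score > best[0]:
                best = (score, seed_idx, bip_idx, train_mask.copy())
    assert best is not None
    score, seed_idx, bip_idx, train_mask = best

    side = {i: (0 if train_mask[pos] else 1) for pos, i in enumerate(ids)}
    index_of = {i: pos for pos, i in enumerate(ids)}

    def leaky(a: str, b: str) -> bool:
        return pair_min[index_of[a], index_of[b]] < spec.leakage_threshold

    removed, active = _greedy_prune(
        ids, side, leaky, spec.target_train_fraction
    )

    if linker_ids:
        def shared_linker(a: str, b: str) -> bool:
            la = set(linker_ids.get(a, ()))
            lb = set(linker_ids.get(b, ()))
            return bool(la & lb)

        removed2, active = _greedy_prune(
            sorted(active), active, shared_linker, spec.target_train_fraction
        )
        removed |= removed2

    train = [i for i in ids if active.get(i) == 0]
    test = [i for i in ids if active.get(i) == 1]
    return SplitResult(
        train_ids=train,
        test_ids=test,
        removed_ids=[i for i in ids if i in removed],
        provenance={
            "winning_seed_index": seed_idx,
            "winning_seed": spec.master_seed + seed_idx,
            "winning_bipartition": bip_idx,
            "score": float(score),
            "candidates_scored": n_scored,
            "master_seed": spec.master_seed,
        },
    )


def check_split(
    result: SplitResult,
    helix1_m: RmsdMatrix,
    helix2_m: RmsdMatrix,
    threshold: float,
    linker_ids: dict[str, list[str]] | None = None,
) -> None:
    """Independent re-scan of the matrices asserting the split contract:
    partition, leakage-free, linker-disjoint.  Raises AssertionError."""
    ids = helix1_m.ids
    train, test, removed = (
        set(result.train_ids), set(result.test_ids), set(result.removed_ids)
    )
    assert not train & test, "train and test overlap"
    assert train | test | removed == set(ids), "ids lost or invented"
    pos = {i: p for p, i in enumerate(ids)}
    for a in train:
        for b in test:
            h1 = helix1_m.values[pos[a], pos[b]]
            h2 = helix2_m.values[pos[a], pos[b]]
            assert min(h1, h2) >= threshold, f"leaky pair ({a}, {b})"
            if linker_ids:
                assert not (
                    set(linker_ids.get(a, ())) & set(linker_ids.get(b, ()))
                ), f"shared linker across split ({a}, {b})"


def validation_split(ids: list[str], fraction: float = 0.1, seed: int = 0
                     ) -> tuple[list[str], list[str]]:
    """Random train/validation split; validation size is
    round-half-up(n * fraction), at least 1.  Deterministic per seed."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(ids)
    if n < 2:
        raise ValueError("need >= 2 ids")
    n_val = max(1, int(np.floor(n * fraction + 0.5)))
    rng = np.random.default_rng(seed)
    picked = set(rng.choice(n, size=n_val, replace=False).tolist())
    validation = [ids[i] for i in range(n) if i in picked]
    train = [ids[i] for i in range(n) if i not in picked]
    return train, validation
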