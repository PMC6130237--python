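"""Assemblage diversity and similarity across habitats.

Shannon diversity of species assemblages, the classic (qualitative) Jaccard
index, UPGMA clustering of habitats on Jaccard distances, and bootstrap
support for dendrogram nodes obtained by resampling species with
replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .matrix import InteractionMatrix, WebValidationError

__all__ = [
    "PresenceTable",
    "Dendrogram",
    "shannon_diversity",
    "jaccard_classic",
    "jaccard_distance_matrix",
    "upgma",
    "bootstrap_support",
]


def shannon_diversity(weights: Sequence[float] | np.ndarray) -> float:
    """Shannon index H' = -sum p_k ln p_k (natural log), zero weights ignored.

    With presence data (all weights equal) this reduces to ln S, which is how
    assemblage diversity per habitat is scored throughout the package.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or np.any(w < 0):
        raise ValueError("weights must be a 1-D non-negative vector")
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("at least one positive weight required")
    return float(entropy(w))  # scipy normalises and uses natural log


def jaccard_classic(setA: Iterable, setB: Iterable) -> float:
    """Classic qualitative Jaccard similarity |A n B| / |A u B|."""
    A, B = set(setA), set(setB)
    union = A | B
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(A & B) / len(union)


@dataclass(frozen=True)
class PresenceTable:
    """Binary habitat x species incidence table."""

    habitat_labels: tuple[str, ...]
    species_labels: tuple[str, ...]
    presence: np.ndarray  # (H, S) in {0, 1}

    def __post_init__(self) -> None:
        arr = (np.asarray(self.presence) > 0).astype(np.int64)
        if arr.shape != (len(self.habitat_labels), len(self.species_labels)):
            raise WebValidationError("presence shape does not match labels")
        if len(set(self.habitat_labels)) != len(self.habitat_labels):
            raise WebValidationError("duplicate habitat labels")
        if len(set(self.species_labels)) != len(self.species_labels):
            raise WebValidationError("duplicate species labels")
        arr.setflags(write=False)
        object.__setattr__(self, "presence", arr)

    @classmethod
    def from_matrices(
        cls, webs: Mapping[str, InteractionMatrix], guild: str = "higher"
    ) -> "PresenceTable":
        """Presence of one guild's species (default: the visitors) per habitat."""
        habitats = tuple(sorted(webs))
        pools = {
            h: set(webs[h].col_labels if guild == "higher" else webs[h].row_labels)
            for h in habitats
        }
        species = tuple(sorted(set().union(*pools.values())))
        arr = np.array(
            [[1 if s in pools[h] else 0 for s in species] for h in habitats]
        )
        return cls(habitats, species, arr)

    def species_set(self, habitat: str) -> frozenset:
        i = self.habitat_labels.index(habitat)
        return frozenset(
            s for s, p in zip(self.species_labels, self.presence[i]) if p
        )

    def richness(self) -> pd.Series:
        return pd.Series(
            self.presence.sum(axis=1), index=list(self.habitat_labels), name="S"
        )


def _jaccard_distances_from_binary(P: np.ndarray) -> np.ndarray:
    """1 - Jaccard for all habitat pairs of a binary (H, S) array.

    Columns may be duplicated (bootstrap replicates): each column instance
    counts separately in intersection and union.
    """
    inter = (P @ P.T).astype(float)
    sizes = P.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        D = 1.0 - inter / union
    np.fill_diagonal(D, 0.0)
    return D


def jaccard_distance_matrix(P: PresenceTable) -> pd.DataFrame:
    """Symmetric habitat x habitat matrix of 1 - J_clas distances."""
    if len(P.habitat_labels) < 2:
        raise ValueError("need at least two habitats")
    empty = [h for h, row in zip(P.habitat_labels, P.presence) if row.sum() == 0]
    if empty:
        raise WebValidationError(f"habitats with no species: {empty}")
    D = _jaccard_distances_from_binary(P.presence)
    return pd.DataFrame(D, index=list(P.habitat_labels), columns=list(P.habitat_labels))


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class Dendrogram:
    """UPGMA tree over habitats.

    ``merges`` lists (left, right, height) with scipy-style ids: leaves are
    0..n-1 in ``leaf_labels`` order, internal node k is id n+k.  Heights are
    half the between-cluster distance at the merge and are non-decreasing.
    ``support`` optionally maps internal node ids to bootstrap percentages.
    """

    leaf_labels: tuple[str, ...]
    merges: list[tuple[int, int, float]]
    support: dict[int, float] = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def clusters(self) -> dict[int, frozenset]:
        """Leaf-label set of every node (leaves and internal)."""
        out = {i: frozenset([l]) for i, l in enumerate(self.leaf_labels)}
        for k, (a, b, _h) in enumerate(self.merges):
            out[self.n_leaves + k] = out[a] | out[b]
        return out

    def internal_clusters(self) -> dict[int, frozenset]:
        n = self.n_leaves
        return {i: c for i, c in self.clusters().items() if i >= n}

    def node_height(self, node: int) -> float:
        if node < self.n_leaves:
            return 0.0
        return self.merges[node - self.n_leaves][2]

    def to_newick(self, digits: int = 6) -> str:
        """Newick string with branch lengths; internal labels carry bootstrap
        support percentages when present."""

        def fmt(node: int, parent_height: float) -> str:
            bl = parent_height - self.node_height(node)
            if node < self.n_leaves:
                return f"{self.leaf_labels[node]}:{bl:.{digits}f}"
            a, b, h = self.merges[node - self.n_leaves]
            inner = f"({fmt(a, h)},{fmt(b, h)})"
            label = ""
            if node in self.support:
                label = f"{self.support[node]:.0f}"
            return f"{inner}{label}:{bl:.{digits}f}"

        root = self.n_leaves + len(self.merges) - 1
        a, b, h = self.merges[-1]
        label = f"{self.support[root]:.0f}" if root in self.support else ""
        return f"({fmt(a, h)},{fmt(b, h)}){label};"


def upgma(D: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    At every step the closest pair of clusters merges at height d/2; the
    distance from the merged cluster to any other is the size-weighted mean
    of its parts' distances.  Ties on the minimal distance are broken by the
    lexicographically smallest merged label set, so trees are deterministic.
    """
    if isinstance(D, pd.DataFrame):
        labels = tuple(map(str, D.index))
        arr = D.to_numpy(dtype=float)
    else:
        arr = np.asarray(D, dtype=float)
        if labels is None:
            raise ValueError("labels required with a bare array")
        labels = tuple(map(str, labels))
    n = len(labels)
    if arr.shape != (n, n) or not np.allclose(arr, arr.T) or np.any(arr < 0):
        raise ValueError("distance matrix must be square, symmetric, non-negative")

    # active cluster state: id -> (size, sorted label tuple)
    sizes = {i: 1 for i in range(n)}
    members = {i: (labels[i],) for i in range(n)}
    dist = {(i, j): float(arr[i, j]) for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(sizes) > 1:
        dmin = min(dist.values())
        ties = [k for k, v in dist.items() if v <= dmin + 1e-12]
        a, b = min(ties, key=lambda k: tuple(sorted(members[k[0]] + members[k[1]])))
        merges.append((a, b, dmin / 2.0))
        new = next_id
        next_id += 1
        na, nb = sizes[a], sizes[b]
        for other in list(sizes):
            if other in (a, b):
                continue
            da = dist.pop((min(a, other), max(a, other)))
            db = dist.pop((min(b, other), max(b, other)))
            dist[(min(new, other), max(new, other))] = (na * da + nb * db) / (na + nb)
        dist.pop((a, b))
        sizes[new] = na + nb
        members[new] = tuple(sorted(members.pop(a) + members.pop(b)))
        del sizes[a], sizes[b]
    return Dendrogram(labels, merges)


def bootstrap_support(
    P: PresenceTable,
    n_rep: int = 9999,
    seed: int | None = 0,
    max_redraws: int = 100,
) -> Dendrogram:
    """UPGMA tree of the presence table with per-node bootstrap support.

    Each replicate resamples species (columns) with replacement to the
    original species count, recomputes Jaccard distances and the UPGMA tree;
    a reference node is supported when its exact leaf set reappears as a
    cluster.  Replicates that strip some habitat of all species are redrawn
    up to ``max_redraws`` times and then counted as unsupported.  The root
    is supported by construction, so its support is always 100.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    ref = upgma(jaccard_distance_matrix(P))
    targets = ref.internal_clusters()
    hits = {node: 0 for node in targets}
    rng = np.random.default_rng(seed)
    H, S = P.presence.shape
    for _ in range(n_rep):
        ok = False
        for _attempt in range(max_redraws):
            cols = rng.integers(0, S, size=S)
            B = P.presence[:, cols]
            if np.all(B.sum(axis=1) > 0):
                ok = True
                break
        if not ok:
            continue  # degenerate replicate counts against every node
        D = _jaccard_distances_from_binary(B)
        rep = upgma(D, labels=P.habitat_labels)
        found = set(rep.internal_clusters().values())
        for node, cluster in targets.items():
            if cluster in found:
                hits[node] += 1
    ref.support = {node: 100.0 * k / n_rep for node, k in hits.items()}
    return ref
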