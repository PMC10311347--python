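"""Clustering, cluster-disjoint splitting, and balanced sub-sampling.

Near-duplicate analogs of the same chemical series must not straddle the
train/test boundary, or test performance is inflated. Compounds are therefore
Butina-clustered on ECFP4 Tanimoto similarity (cutoff 0.8) and whole clusters
are assigned to one partition. Controlled low-data experiments then draw
balanced subsets (equal actives and inactives) of fixed even sizes from the
training partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .curation import ACTIVE, LabeledCompound
from .errors import SamplingError, SplitError
from .features import Fingerprint, tanimoto

DEFAULT_CUTOFF = 0.8
DEFAULT_TEST_FRACTION = 1 / 6
DEFAULT_SIZES = (2, 6, 12, 48, 96, 400, 1000, 4000)


@dataclass
class ClusterAssignment:
    """compound_id -> cluster index, plus each cluster's centroid compound."""

    assignment: dict[str, int]
    centroids: dict[int, str]

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def members(self, cluster: int) -> list[str]:
        return [cid for cid, c in self.assignment.items() if c == cluster]


@dataclass(frozen=True)
class DatasetSplit:
    """Cluster-disjoint train/test id partition."""

    train_ids: frozenset[str]
    test_ids: frozenset[str]
    seed: int = 0
    test_fraction: float = DEFAULT_TEST_FRACTION

    def __post_init__(self) -> None:
        if self.train_ids & self.test_ids:
            raise SplitError("train and test partitions overlap")


@dataclass(frozen=True)
class SubsetSpec:
    """The controlled training-set sizes: balanced draws, several seeded repeats."""

    sizes: tuple[int, ...] = DEFAULT_SIZES
    balanced: bool = True
    repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 2 or s % 2 for s in self.sizes):
            raise ValueError("all subset sizes must be even and >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be positive")


def butina_cluster(
    fingerprints: Mapping[str, Fingerprint], cutoff: float = DEFAULT_CUTOFF
) -> ClusterAssignment:
    """Leader-style (Butina) clustering at a Tanimoto similarity cutoff.

    Compounds are visited in descending neighbor-count order (neighbor counts
    computed once, on the full set); each still-unassigned compound visited
    becomes a centroid and absorbs all its unassigned neighbors with
    similarity >= cutoff. Ties in neighbor count break on ascending compound
    id, making the outcome deterministic across platforms.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must lie in (0, 1]")
    ids = sorted(fingerprints)
    neighbors: dict[str, list[str]] = {cid: [] for cid in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if tanimoto(fingerprints[a], fingerprints[b]) >= cutoff:
                neighbors[a].append(b)
                neighbors[b].append(a)
    order = sorted(ids, key=lambda cid: (-len(neighbors[cid]), cid))
    assignment: dict[str, int] = {}
    centroids: dict[int, str] = {}
    cluster = 0
    for cid in order:
        if cid in assignment:
            continue
        centroids[cluster] = cid
        assignment[cid] = cluster
        for nb in neighbors[cid]:
            if nb not in assignment:
                assignment[nb] = cluster
        cluster += 1
    return ClusterAssignment(assignment=assignment, centroids=centroids)


def cluster_split(
    compound_ids: Sequence[str],
    clusters: ClusterAssignment,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    seed: int = 0,
) -> DatasetSplit:
    """Assign whole clusters to the test partition until it reaches the target size.

    Clusters go to test greedily from the largest down (seeded shuffle among
    equal sizes); overshoot past ``test_fraction * N`` is tolerated rather than
    splitting a cluster. A single cluster covering everything is an error.
    """
    ids = [str(c) for c in compound_ids]
    missing = [c for c in ids if c not in clusters.assignment]
    if missing:
        raise SplitError(f"unclustered compounds: {missing[:5]}")
    members: dict[int, list[str]] = {}
    for cid in ids:
        members.setdefault(clusters.assignment[cid], []).append(cid)
    if len(members) == 1 and len(ids) > 0:
        raise SplitError("all compounds fall in a single cluster; "
                         "a cluster-disjoint nonempty split is impossible")
    rng = np.random.default_rng(seed)
    cluster_ids = list(members)
    rng.shuffle(cluster_ids)  # seeded tie-break among equal-sized clusters
    cluster_ids.sort(key=lambda c: -len(members[c]))
    target = test_fraction * len(ids)
    test: set[str] = set()
    for c in cluster_ids:
        if len(test) >= target:
            break
        test.update(members[c])
    train = set(ids) - test
    if not train:
        raise SplitError("test assignment consumed every cluster; no train data left")
    return DatasetSplit(train_ids=frozenset(train), test_ids=frozenset(test),
                        seed=seed, test_fraction=test_fraction)


def balanced_indices(labels: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw size/2 active (1) and size/2 inactive (0) indices without replacement."""
    if size < 2 or size % 2:
        raise SamplingError("subset size must be even and >= 2")
    labels = np.asarray(labels).ravel()
    half = size // 2
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) < half or len(neg) < half:
        raise SamplingError(
            f"need {half} of each class, have {len(pos)} active / {len(neg)} inactive"
        )
    chosen = np.concatenate([rng.choice(pos, size=half, replace=False),
                             rng.choice(neg, size=half, replace=False)])
    return np.sort(chosen)


def balanced_subset(
    train: Sequence[LabeledCompound], size: int, seed: int = 0
) -> list[LabeledCompound]:
    """Seeded uniform draw of a balanced subset of curated compounds."""
    labels = np.array([1 if c.label == ACTIVE else 0 for c in train])
    idx = balanced_indices(labels, size, np.random.default_rng(seed))
    return [train[i] for i in idx]
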