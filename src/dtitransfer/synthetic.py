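"""Synthetic multi-family datasets with controllable cross-family relatedness.

The transfer machinery only ever sees 300-dimensional real vectors, so the
generator aims for statistical rather than chemical realism: each protein
family f gets a unit decision direction w_f = normalize(sqrt(rho) * w0 +
sqrt(1 - rho) * u_f), where w0 is shared across families and u_f is
family-specific. The overlap rho in [0, 1] controls how related the families'
decision rules are (rho = 1: identical tasks; rho = 0: unrelated). Features
are standard normal; labels are the sign of the projection onto w_f, flipped
with probability epsilon (label noise). Transfer from one family to another
is therefore provably useful exactly when rho is high — which is what the
benchmark must be able to demonstrate.

Also provided: a fixed 12-row toy activity table exercising every curation
filter, and pseudo-fingerprints with planted cluster structure for exercising
Butina clustering and cluster-disjoint splitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import Fingerprint
from .io import ActivityRecord
from .models import LabeledVectors

DESK_SCALE = {
    "n_source": 5000,
    "n_target_train": 2000,
    "n_target_test": 1000,
    "overlap": 0.8,
    "label_noise": 0.1,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the linear-threshold family generator."""

    families: tuple[str, ...] = ("source", "target")
    n_per_family: int = 2000
    dimension: int = 300
    overlap: float = 0.8
    signal: float = 1.0
    label_noise: float = 0.1
    n_clusters: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError("overlap must lie in [0, 1]")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.signal <= 0:
            raise ValueError("signal must be positive")


@dataclass
class SyntheticFamily:
    """One generated family: ids, feature matrix, labels, ground-truth direction."""

    family: str
    ids: list[str]
    X: np.ndarray  # (n, d) float32
    y: np.ndarray  # (n,) int 0/1
    w: np.ndarray  # (d,) ground-truth unit direction
    fingerprints: dict[str, Fingerprint] | None = None

    def as_vectors(self) -> LabeledVectors:
        return LabeledVectors(X=self.X, y=self.y, family=self.family)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_families(config: SyntheticConfig) -> dict[str, SyntheticFamily]:
    """Draw every family's direction, features and noisy threshold labels (seeded)."""
    root = np.random.SeedSequence(config.seed)
    rng_dirs = np.random.default_rng(root.spawn(1)[0])
    w0 = _unit(rng_dirs.standard_normal(config.dimension))
    out: dict[str, SyntheticFamily] = {}
    for fi, family in enumerate(config.families):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(1, fi))
        )
        u = _unit(rng.standard_normal(config.dimension))
        w = _unit(np.sqrt(config.overlap) * w0 + np.sqrt(1.0 - config.overlap) * u)
        X = rng.standard_normal((config.n_per_family, config.dimension)).astype(np.float32)
        margin = X @ w.astype(np.float32)
        if config.signal != 1.0:
            # Stretch each point along w: widens (signal > 1) or shrinks the margin.
            X = X + np.float32(config.signal - 1.0) * np.outer(margin, w.astype(np.float32))
        y = (margin > 0).astype(np.int64)
        flips = rng.random(config.n_per_family) < config.label_noise
        y[flips] ^= 1
        ids = [f"{family}_{i:06d}" for i in range(config.n_per_family)]
        fam = SyntheticFamily(family=family, ids=ids, X=X, y=y, w=w)
        if config.n_clusters >= 1:
            fps, _ = generate_pseudo_fingerprints(
                n_clusters=config.n_clusters,
                cluster_size=max(1, config.n_per_family // config.n_clusters),
                seed=int(np.random.SeedSequence(entropy=config.seed,
                                                spawn_key=(2, fi)).generate_state(1)[0]),
                id_prefix=f"{family}_",
            )
            fam.fingerprints = fps
        out[family] = fam
    return out


def make_benchmark_data(
    seed: int,
    overlap: float = DESK_SCALE["overlap"],
    label_noise: float = DESK_SCALE["label_noise"],
    n_source: int = DESK_SCALE["n_source"],
    n_target_train: int = DESK_SCALE["n_target_train"],
    n_target_test: int = DESK_SCALE["n_target_test"],
    dimension: int = 300,
    signal: float = 1.0,
) -> tuple[LabeledVectors, LabeledVectors, LabeledVectors]:
    """The desk-scale benchmark triple: source train, target train, target test.

    Source and target are two related families (shared-direction fraction
    ``overlap``); the target family is split i.i.d. into train and test pools.
    """
    n = max(n_source, n_target_train + n_target_test)
    fams = generate_families(
        SyntheticConfig(families=("source", "target"), n_per_family=n,
                        dimension=dimension, overlap=overlap, signal=signal,
                        label_noise=label_noise, seed=seed)
    )
    src = fams["source"]
    tgt = fams["target"]
    source_train = LabeledVectors(src.X[:n_source], src.y[:n_source], "source")
    target_train = LabeledVectors(tgt.X[:n_target_train], tgt.y[:n_target_train], "target")
    target_test = LabeledVectors(
        tgt.X[n_target_train : n_target_train + n_target_test],
        tgt.y[n_target_train : n_target_train + n_target_test],
        "target",
    )
    return source_train, target_train, target_test


def generate_toy_activity_table(seed: int = 0) -> list[ActivityRecord]:
    """A fixed 12-row activity table exercising every curation rule.

    Eight rows pass all filters; among them one (compound, target) pair is
    measured twice with pChEMBL 6.0 and 8.0, so curation yields 7 labeled
    compounds and the duplicated pair's median 7.0 is labeled active under the
    >=-threshold convention. The four violating rows are: a functional assay,
    a non-human organism, a missing pChEMBL value, and a disallowed standard
    type (AUC). Values are fixed; ``seed`` is accepted for interface symmetry
    but does not influence the output.
    """
    del seed
    ok = dict(target_type="SINGLE PROTEIN", taxonomy="human",
              assay_type="binding", family="kinase")
    return [
        # duplicated pair: same compound & target, two measurements
        ActivityRecord("TOY_C1", "CCO", "T1", standard_type="IC50", pchembl=6.0, **ok),
        ActivityRecord("TOY_C1", "CCO", "T1", standard_type="Ki", pchembl=8.0, **ok),
        ActivityRecord("TOY_C2", "CCN", "T1", standard_type="IC50", pchembl=7.5, **ok),
        ActivityRecord("TOY_C3", "CCC", "T1", standard_type="EC50", pchembl=6.5, **ok),
        ActivityRecord("TOY_C4", "CCCl", "T1", standard_type="Kd", pchembl=7.0, **ok),
        ActivityRecord("TOY_C5", "c1ccccc1", "T1", standard_type="AC50", pchembl=8.2, **ok),
        ActivityRecord("TOY_C6", "CC(=O)O", "T1", standard_type="Potency", pchembl=5.0, **ok),
        ActivityRecord("TOY_C7", "CCOC", "T1", standard_type="IC50", pchembl=6.9, **ok),
        # violations, one per filter rule
        ActivityRecord("TOY_C8", "CCS", "T1", target_type="SINGLE PROTEIN",
                       taxonomy="human", assay_type="functional",
                       standard_type="IC50", pchembl=7.7, family="kinase"),
        ActivityRecord("TOY_C9", "CCBr", "T1", target_type="SINGLE PROTEIN",
                       taxonomy="rat", assay_type="binding",
                       standard_type="IC50", pchembl=7.7, family="kinase"),
        ActivityRecord("TOY_C10", "CCI", "T1", target_type="SINGLE PROTEIN",
                       taxonomy="human", assay_type="binding",
                       standard_type="IC50", pchembl=None, family="kinase"),
        ActivityRecord("TOY_C11", "CCF", "T1", target_type="SINGLE PROTEIN",
                       taxonomy="human", assay_type="binding",
                       standard_type="AUC", pchembl=7.7, family="kinase"),
    ]


def generate_pseudo_fingerprints(
    n_clusters: int,
    cluster_size: int,
    nbits: int = 2048,
    n_on_bits: int = 64,
    flip_bits: int = 3,
    seed: int = 0,
    id_prefix: str = "",
) -> tuple[dict[str, Fingerprint], dict[str, int]]:
    """Pseudo-fingerprints with planted cluster structure.

    Each cluster has a random ``n_on_bits``-bit centroid pattern; members copy
    it with ``flip_bits`` on-bits swapped for random off-bits. With the
    defaults any two members of a cluster share Tanimoto >= (64-6)/(64+6) ≈
    0.83 while inter-cluster similarity is near zero, so Butina clustering at
    cutoff 0.8 recovers the planted partition. ``flip_bits = 0`` makes all
    intra-cluster similarities exactly 1.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if 2 * flip_bits >= n_on_bits:
        raise ValueError("flip_bits too large for the centroid pattern")
    rng = np.random.default_rng(seed)
    fps: dict[str, Fingerprint] = {}
    planted: dict[str, int] = {}
    for c in range(n_clusters):
        centroid = set(rng.choice(nbits, size=n_on_bits, replace=False).tolist())
        for m in range(cluster_size):
            bits = set(centroid)
            if flip_bits and m > 0:  # member 0 is the exact centroid pattern
                drop = rng.choice(sorted(bits), size=flip_bits, replace=False)
                bits -= set(int(b) for b in drop)
                candidates = np.setdiff1d(np.arange(nbits), sorted(centroid))
                add = rng.choice(candidates, size=flip_bits, replace=False)
                bits |= set(int(b) for b in add)
            cid = f"{id_prefix}c{c}_m{m}"
            fps[cid] = Fingerprint(bits=frozenset(bits), nbits=nbits)
            planted[cid] = c
    return fps, planted
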