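"""Seeded synthetic ontologies, proteomes, and planted annotation tasks.

The generator emulates the data regime the predictor is built for, with
no downloads:

* a rooted single-namespace DAG whose non-root terms attach to one or
  more earlier terms (is_a, occasionally part_of), with template
  definitions that embed lineage tokens so related terms share
  vocabulary — giving the text provider and label encoder real signal;
* a planted proteome: each leaf term owns a Gaussian prototype in
  feature space; a protein samples 1-3 leaves under a Zipf popularity
  law (so rare terms with few annotations exist, the few-shot regime),
  and its feature vector is the mean of its leaves' prototypes plus
  Gaussian noise.  Annotations are the sampled leaves closed under the
  true-path rule, with evidence codes drawn from the experimental list.

With zero noise the task is separable by nearest prototype, which makes
it a calibration point for the whole learning pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ontology import (
    EXPERIMENTAL_EVIDENCE_CODES,
    AnnotationSet,
    OntologyGraph,
    propagate_annotations,
)

_NAMESPACE_LONG = {"MF": "molecular_function", "CC": "cellular_component", "BP": "biological_process"}


@dataclass
class SyntheticConfig:
    """Study conditions for the planted benchmark.

    Defaults follow the desk-scale regime the package is exercised at:
    60 terms, 500 proteins, 64-dimensional features, noise sigma 0.5,
    Zipf exponent 1.5 (heavy-tailed popularity so that a rare-term
    stratum with <= 10 annotations exists).
    """

    n_terms: int = 60
    n_proteins: int = 500
    max_parents: int = 2
    zipf_exponent: float = 1.5
    noise_sigma: float = 0.5
    feature_dim: int = 64
    seed: int = 0
    namespace: str = "MF"
    max_leaves_per_protein: int = 3
    part_of_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.namespace not in _NAMESPACE_LONG:
            raise ValueError(f"unknown namespace {self.namespace!r}")


@dataclass
class PlantedModel:
    """Ground truth of the generator: prototypes and leaf assignments."""

    leaf_terms: list[str]
    prototypes: np.ndarray  # (n_leaves, feature_dim)
    assignments: dict[str, list[str]]  # protein -> sampled leaves
    popularity: np.ndarray  # sampling weights over leaf_terms


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def generate_ontology(config: SyntheticConfig) -> OntologyGraph:
    """Rooted DAG with lineage-token definitions, deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    terms = [_term_id(i) for i in range(config.n_terms)]
    edges: list[tuple[str, str, str]] = []
    parents_of: dict[int, list[int]] = {0: []}
    for i in range(1, config.n_terms):
        n_par = int(rng.integers(1, config.max_parents + 1))
        n_par = min(n_par, i)
        chosen = rng.choice(i, size=n_par, replace=False)
        parents_of[i] = sorted(int(c) for c in chosen)
        for p in parents_of[i]:
            rel = "part_of" if rng.random() < config.part_of_fraction else "is_a"
            edges.append((terms[i], terms[p], rel))

    # lineage tokens: each definition mentions its own token plus every
    # ancestor's token, so related terms share vocabulary
    tokens = [f"term{i:04d}" for i in range(config.n_terms)]
    anc_tokens: dict[int, list[str]] = {0: [tokens[0]]}
    for i in range(1, config.n_terms):
        seen: dict[str, None] = {}
        for p in parents_of[i]:
            for tok in anc_tokens[p]:
                seen.setdefault(tok)
        anc_tokens[i] = [tokens[i], *seen]
    definitions = {
        terms[i]: (
            f"A synthetic {_NAMESPACE_LONG[config.namespace]} activity {tokens[i]} "
            + ("that specializes " + " and ".join(anc_tokens[i][1:]) if i else "at the root")
            + "."
        )
        for i in range(config.n_terms)
    }
    return OntologyGraph(
        terms=terms,
        namespace={t: config.namespace for t in terms},
        edges=sorted(edges),
        definitions=definitions,
    )


def generate_proteome(
    graph: OntologyGraph, config: SyntheticConfig
) -> tuple[list[str], np.ndarray, AnnotationSet, PlantedModel]:
    """Planted proteins: features, closed annotations, and the ground truth.

    Returns (protein ids, feature matrix, ancestor-closed annotations,
    planted model).
    """
    rng = np.random.default_rng(config.seed + 1)
    leaves = graph.leaves(config.namespace)
    prototypes = rng.standard_normal((len(leaves), config.feature_dim))
    ranks = rng.permutation(len(leaves)) + 1
    weights = ranks.astype(float) ** (-config.zipf_exponent)
    popularity = weights / weights.sum()
    codes = sorted(EXPERIMENTAL_EVIDENCE_CODES)

    protein_ids = [f"P{i + 1:05d}" for i in range(config.n_proteins)]
    features = np.zeros((config.n_proteins, config.feature_dim))
    records: list[tuple[str, str, str]] = []
    assignments: dict[str, list[str]] = {}
    leaf_index = {t: i for i, t in enumerate(leaves)}
    for i, pid in enumerate(protein_ids):
        k = int(rng.integers(1, config.max_leaves_per_protein + 1))
        k = min(k, len(leaves))
        chosen = rng.choice(len(leaves), size=k, replace=False, p=popularity)
        chosen_terms = [leaves[int(c)] for c in chosen]
        assignments[pid] = chosen_terms
        proto_mean = prototypes[[leaf_index[t] for t in chosen_terms]].mean(axis=0)
        noise = rng.standard_normal(config.feature_dim) * config.noise_sigma
        features[i] = proto_mean + noise
        for t in chosen_terms:
            records.append((pid, t, codes[int(rng.integers(len(codes)))]))

    anns = propagate_annotations(graph, AnnotationSet(records=records, closed=False))
    planted = PlantedModel(
        leaf_terms=list(leaves),
        prototypes=prototypes,
        assignments=assignments,
        popularity=popularity,
    )
    return protein_ids, features, anns, planted


def split_dataset(
    protein_ids: Sequence[str],
    fractions: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Seeded disjoint, exhaustive train/validation/test split."""
    fractions = tuple(fractions)
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be nonnegative")
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("need three fractions summing to 1")
    ids = list(protein_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n = len(ids)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    shuffled = [ids[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


def leaf_holdout_split(
    planted: PlantedModel,
    holdout_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Cluster-style holdout: all proteins of some leaves become the test set.

    A stand-in for sequence-identity clustering on real data: proteins
    whose first sampled leaf falls into the held-out leaf set are novel
    with respect to the training distribution.
    """
    rng = np.random.default_rng(seed)
    leaves = list(planted.leaf_terms)
    n_hold = max(1, int(round(holdout_fraction * len(leaves))))
    held = set(rng.choice(len(leaves), size=n_hold, replace=False))
    held_terms = {leaves[i] for i in held}
    test = [p for p, ls in planted.assignments.items() if ls[0] in held_terms]
    train = [p for p in planted.assignments if p not in set(test)]
    return train, test


def naive_predictor(train_truth: np.ndarray, n_proteins: int) -> np.ndarray:
    """Frequency-prior baseline: every protein scores term t at its
    training annotation frequency."""
    prior = np.asarray(train_truth, float).mean(axis=0)
    return np.tile(prior, (n_proteins, 1))


def nearest_prototype_accuracy(
    features: np.ndarray,
    planted: PlantedModel,
    protein_ids: Sequence[str],
) -> float:
    """Fraction of proteins whose nearest prototype is one of their leaves.

    With zero feature noise and a single leaf per protein this is 1.0 by
    construction; it is the separability oracle for the planted task.
    """
    d2 = (
        (features**2).sum(axis=1, keepdims=True)
        - 2 * features @ planted.prototypes.T
        + (planted.prototypes**2).sum(axis=1)
    )
    nearest = np.argmin(d2, axis=1)
    hits = sum(
        planted.leaf_terms[nearest[i]] in planted.assignments[pid]
        for i, pid in enumerate(protein_ids)
    )
    return hits / len(protein_ids)
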