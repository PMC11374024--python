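"""High-level orchestration shared by the command line and scripts.

These functions glue the modules together at the granularity a run
actually needs: pretrain the label encoder on an ontology, assemble the
label matrix for a protein split, train the joint model, and checkpoint
or restore everything from a single file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .joint_model import JointModel, JointTrainConfig, train_joint
from .label_encoder import (
    GAEConfig,
    HashTextProvider,
    LabelEmbedding,
    text_embed,
    train_gae,
)
from .metrics import MetricReport, evaluate_predictions
from .ontology import (
    AnnotationSet,
    OntologyGraph,
    annotation_matrix,
    build_adjacency,
    filter_evidence,
    propagate_annotations,
)
from .query_processor import DEFAULT_PARTITIONS, TermPartition, partition_terms

CHECKPOINT_VERSION = 1


def pretrain_label_encoder(
    graph: OntologyGraph,
    namespace: str,
    text_dim: int = 64,
    embed_dim: int = 64,
    hidden: int | None = None,
    epochs: int = 500,
    lr: float = 0.01,
    seed: int = 0,
):
    """Text-embed definitions and pretrain the graph autoencoder.

    Returns the GAE training result; the frozen embedding lives in
    ``result.embedding`` with rows in the namespace's term order.
    """
    terms = graph.namespace_terms(namespace)
    provider = HashTextProvider(dim=text_dim, seed=seed)
    X = text_embed({t: graph.definitions[t] for t in terms}, provider, terms=terms)
    A = build_adjacency(graph, namespace)
    config = GAEConfig(embed_dim=embed_dim, hidden=hidden, lr=lr, epochs=epochs, seed=seed)
    result = train_gae(X, A, config)
    result.embedding.terms = terms
    return result


def training_partition(
    graph: OntologyGraph,
    anns: AnnotationSet,
    namespace: str,
    train_ids: Sequence[str] | None = None,
    n: int | None = None,
    thresholds: Sequence[int] | None = None,
) -> TermPartition:
    """Frequency partition of a namespace from (closed) training counts."""
    if not anns.closed:
        anns = propagate_annotations(graph, anns)
    terms = graph.namespace_terms(namespace)
    train_set = set(train_ids) if train_ids is not None else None
    counts: dict[str, int] = {t: 0 for t in terms}
    for p, t, _c in anns.records:
        if t in counts and (train_set is None or p in train_set):
            counts[t] += 1
    if n is None or thresholds is None:
        default_n, default_thr = DEFAULT_PARTITIONS[namespace]
        n = n or default_n
        thresholds = thresholds if thresholds is not None else default_thr
    return partition_terms(counts, n, thresholds)


def dataset_matrices(
    graph: OntologyGraph,
    anns: AnnotationSet,
    namespace: str,
    protein_ids: Sequence[str],
    features: np.ndarray,
    splits: dict[str, list[str]],
):
    """Closed, evidence-filtered binary label matrices per split."""
    anns = filter_evidence(anns)
    if not anns.closed:
        anns = propagate_annotations(graph, anns)
    terms = graph.namespace_terms(namespace)
    index = {p: i for i, p in enumerate(protein_ids)}
    out = {}
    for name, ids in splits.items():
        rows = [index[p] for p in ids]
        sub = AnnotationSet(
            records=[r for r in anns.records if r[0] in set(ids)], closed=True
        )
        out[name] = {
            "ids": list(ids),
            "features": features[rows],
            "truth": annotation_matrix(sub, ids, terms),
        }
    return out, terms


def save_checkpoint(
    path: str | Path,
    model: JointModel,
    label_embedding: LabelEmbedding,
    extra_config: dict | None = None,
) -> None:
    """Single-file archive: config, partition, provider names, weights."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "train_config": asdict(model.config),
        "partition": {
            "groups": model.partition.groups,
            "n": model.partition.n,
            "thresholds": list(model.partition.frequency_thresholds),
            "terms": model.partition.terms,
        },
        "d_in": model.query.d_in,
        "extra": extra_config or {},
    }
    arrays = {f"state::{k}": v for k, v in model.get_state().items()}
    arrays["label_embedding"] = np.asarray(label_embedding.Z)
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> tuple[JointModel, LabelEmbedding]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        Z = LabelEmbedding(Z=data["label_embedding"].copy()).freeze()
        part = TermPartition(
            groups=[list(g) for g in meta["partition"]["groups"]],
            n=meta["partition"]["n"],
            frequency_thresholds=tuple(meta["partition"]["thresholds"]),
            terms=list(meta["partition"]["terms"]),
        )
        config = JointTrainConfig(**meta["train_config"])
        model = JointModel(meta["d_in"], part, Z, config)
        state = {k.split("::", 1)[1]: data[k] for k in data.files if k.startswith("state::")}
        model.set_state(state)
    return model, Z


def fit_joint_model(
    features_by_split: dict,
    label_embedding: LabelEmbedding,
    partition: TermPartition,
    config: JointTrainConfig,
) -> JointModel:
    """Train with the explicit validation split from the dataset."""
    return train_joint(
        features_by_split["train"]["features"],
        features_by_split["train"]["truth"],
        label_embedding,
        partition,
        config,
        val_features=features_by_split["val"]["features"],
        val_truth=features_by_split["val"]["truth"],
    )


def evaluate_split(
    model: JointModel,
    split: dict,
    train_truth: np.ndarray,
    terms: Sequence[str],
    A: np.ndarray,
) -> MetricReport:
    """Predict a split and evaluate against its closed truth.

    Term frequencies (for IC and the rare-term bins) come from the
    training split, as they would in a real benchmark.
    """
    scores = model.predict(split["features"])
    counts = {t: int(c) for t, c in zip(terms, train_truth.sum(axis=0))}
    return evaluate_predictions(
        scores,
        split["truth"],
        counts,
        terms,
        n_proteins_for_ic=train_truth.shape[0],
        A=A,
    )
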