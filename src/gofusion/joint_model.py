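"""Joint feature-label embedding network with cross attention.

The query representation q (one logit per term, from the expert MLPs) is
projected into a shared space, u = Wq^T q; the frozen label embedding Z
provides keys K = Z Wk and values V = Z Wv.  Scaled dot-product cross
attention

    o = softmax(u K^T / sqrt(d_k)) V,   d_k = Dm

attends from the protein over all term embeddings, and the prediction
head applies a residual combination followed by a logistic output map:

    y = sigmoid(Wo (o + u) + b).

Everything except Z is trained end-to-end (query processor included) by
minimizing binary cross-entropy against the ancestor-closed labels; the
label encoder's weights stay fixed, so the label semantics learned by
self-supervision survive joint training.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .label_encoder import LabelEmbedding
from .query_processor import QueryProcessor, TermPartition

BCE_EPS = 1e-7


@dataclass
class JointParams:
    """Projection matrices of the cross-attention head."""

    Wq: np.ndarray  # (Dc, Dm)
    Wk: np.ndarray  # (D_e, Dm)
    Wv: np.ndarray  # (D_e, Dm)
    Wo: np.ndarray  # (Dm, Dc)
    bo: np.ndarray  # (Dc,)

    @property
    def dm(self) -> int:
        return self.Wq.shape[1]


@dataclass
class PredictionMatrix:
    """Proteins x terms scores in [0, 1]."""

    scores: np.ndarray
    protein_ids: list[str]
    terms: list[str]


def project_query(q: np.ndarray, Wq: np.ndarray) -> np.ndarray:
    """u = Wq^T q (batched: row-wise)."""
    q = np.asarray(q, float)
    if q.shape[-1] != Wq.shape[0]:
        raise ValueError(f"query length {q.shape[-1]} != Wq input dimension {Wq.shape[0]}")
    return q @ Wq


def cross_attention(
    u: np.ndarray,
    Z: LabelEmbedding | np.ndarray,
    Wk: np.ndarray,
    Wv: np.ndarray,
    return_weights: bool = False,
):
    """Scaled dot-product attention of u over the term embeddings.

    The attention weights form a probability distribution over the Dc
    terms; the output is the weight-averaged row of V.
    """
    Zm = Z.Z if isinstance(Z, LabelEmbedding) else np.asarray(Z, float)
    if Zm.shape[0] == 0:
        raise ValueError("attention over zero terms is undefined")
    u = np.asarray(u, float)
    d_k = Wk.shape[1]
    K = Zm @ Wk
    V = Zm @ Wv
    scores = u @ K.T / np.sqrt(d_k)
    weights = nn.softmax(scores, axis=-1)
    o = weights @ V
    return (o, weights) if return_weights else o


def predict_protein(
    q: np.ndarray, Z: LabelEmbedding | np.ndarray, params: JointParams
) -> np.ndarray:
    """Per-term probabilities for one protein (or a batch of rows)."""
    u = project_query(q, params.Wq)
    o = cross_attention(u, Z, params.Wk, params.Wv)
    return nn.sigmoid((o + u) @ params.Wo + params.bo)


def bce_loss(scores: np.ndarray | PredictionMatrix, truth: np.ndarray) -> float:
    """Mean binary cross-entropy over all (protein, term) cells."""
    s = scores.scores if isinstance(scores, PredictionMatrix) else np.asarray(scores, float)
    t = np.asarray(truth, float)
    if s.shape != t.shape:
        raise ValueError(f"shape mismatch: scores {s.shape} vs truth {t.shape}")
    s = np.clip(s, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(t * np.log(s) + (1.0 - t) * np.log(1.0 - s)))


class JointHead:
    """Trainable cross-attention head (Z itself is frozen, not a Param)."""

    def __init__(self, dc: int, d_e: int, dm: int, rng: np.random.Generator) -> None:
        self.dm = dm
        self.Wq = nn.Param(rng.normal(0.0, np.sqrt(1.0 / dc), size=(dc, dm)), "head.Wq")
        self.Wk = nn.Param(rng.normal(0.0, np.sqrt(1.0 / d_e), size=(d_e, dm)), "head.Wk")
        self.Wv = nn.Param(rng.normal(0.0, np.sqrt(1.0 / d_e), size=(d_e, dm)), "head.Wv")
        self.Wo = nn.Param(rng.normal(0.0, np.sqrt(1.0 / dm), size=(dm, dc)), "head.Wo")
        self.bo = nn.Param(np.zeros(dc), "head.bo")
        self._cache: tuple | None = None

    def params(self) -> list[nn.Param]:
        return [self.Wq, self.Wk, self.Wv, self.Wo, self.bo]

    def as_joint_params(self) -> JointParams:
        return JointParams(
            Wq=self.Wq.value, Wk=self.Wk.value, Wv=self.Wv.value,
            Wo=self.Wo.value, bo=self.bo.value,
        )

    def forward(self, q: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """Return pre-sigmoid logits for a batch of query representations."""
        u = q @ self.Wq.value
        K = Z @ self.Wk.value
        V = Z @ self.Wv.value
        scale = 1.0 / np.sqrt(self.dm)
        S = u @ K.T * scale
        W = nn.softmax(S, axis=-1)
        o = W @ V
        h = o + u
        logits = h @ self.Wo.value + self.bo.value
        self._cache = (q, Z, u, K, V, W, h, scale)
        return logits

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        q, Z, u, K, V, W, h, scale = self._cache
        self.Wo.grad += h.T @ dlogits
        self.bo.grad += dlogits.sum(axis=0)
        dh = dlogits @ self.Wo.value.T
        do = dh
        du = dh.copy()
        dW = do @ V.T
        dV = W.T @ do
        dS = W * (dW - (dW * W).sum(axis=-1, keepdims=True))
        du += dS @ K * scale
        dK = dS.T @ u * scale
        self.Wk.grad += Z.T @ dK
        self.Wv.grad += Z.T @ dV
        self.Wq.grad += q.T @ du
        return du @ self.Wq.value.T


@dataclass
class JointTrainConfig:
    """Optimization settings for the end-to-end model.

    ``aux_weight`` adds per-group auxiliary supervision — binary
    cross-entropy on the logistic of the raw query logits q against the
    same labels — which keeps each expert predictive on its own group;
    setting ``use_joint_head=False`` turns the model into the standalone
    expert-MLP ablation (scores = sigmoid(q)).
    """

    dm: int = 512
    expert_depth: int = 2
    expert_hidden: int | None = None
    lr: float = 1e-3
    epochs: int = 200
    batch_size: int = 32
    patience: int = 20
    val_fraction: float = 0.1
    aux_weight: float = 1.0
    use_joint_head: bool = True
    seed: int = 0


class JointModel:
    """Query processor + cross-attention head over a frozen label embedding."""

    def __init__(
        self,
        d_in: int,
        partition: TermPartition,
        label_embedding: LabelEmbedding,
        config: JointTrainConfig,
    ) -> None:
        if not label_embedding.frozen:
            raise ValueError("label embedding must be frozen before joint training")
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.partition = partition
        self.label_embedding = label_embedding
        self.query = QueryProcessor(
            d_in, partition, rng, depth=config.expert_depth, hidden=config.expert_hidden
        )
        self.head = (
            JointHead(partition.dc, label_embedding.dim, config.dm, rng)
            if config.use_joint_head
            else None
        )
        self.train_history: list[dict[str, float]] = []

    def params(self) -> list[nn.Param]:
        ps = self.query.params()
        if self.head is not None:
            ps += self.head.params()
        return ps

    def _forward(self, X: np.ndarray, train: bool) -> tuple[np.ndarray, np.ndarray]:
        q = self.query.forward(X, train=train)
        logits = q if self.head is None else self.head.forward(q, self.label_embedding.Z)
        return q, logits

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic eval-mode scores in [0, 1] for a feature batch."""
        if X.shape[1] != self.query.d_in:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model input {self.query.d_in}"
            )
        if X.shape[0] == 0:
            return np.zeros((0, self.partition.dc))
        _q, logits = self._forward(X, train=False)
        return nn.sigmoid(logits)

    def get_state(self) -> dict[str, np.ndarray]:
        state = nn.state_dict(self.params())
        for k, v in self.query.norm_buffers().items():
            state[f"buffer.{k}"] = v.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        nn.load_state(self.params(), state)
        for k, v in self.query.norm_buffers().items():
            v[...] = state[f"buffer.{k}"]


def label_embedding_digest(Z: LabelEmbedding) -> str:
    """Byte-level hash of the label matrix, used to assert frozenness."""
    return hashlib.sha256(np.ascontiguousarray(Z.Z).tobytes()).hexdigest()


def train_joint(
    features: np.ndarray,
    truth: np.ndarray,
    Z: LabelEmbedding,
    partition: TermPartition,
    config: JointTrainConfig | None = None,
    val_features: np.ndarray | None = None,
    val_truth: np.ndarray | None = None,
) -> JointModel:
    """Train the query processor and joint head; Z stays fixed.

    The best parameter snapshot by validation loss is restored at the
    end; early stopping after ``patience`` epochs without improvement.
    If no validation split is supplied, a seeded fraction of the training
    proteins is held out internally.
    """
    config = config or JointTrainConfig()
    features = np.asarray(features, float)
    truth = np.asarray(truth, float)
    if features.shape[0] != truth.shape[0]:
        raise ValueError("features and truth must cover the same proteins")
    z_digest_before = label_embedding_digest(Z)

    rng = np.random.default_rng(config.seed + 1)
    if val_features is None:
        n = features.shape[0]
        n_val = max(1, int(round(config.val_fraction * n)))
        order = rng.permutation(n)
        val_idx, train_idx = order[:n_val], order[n_val:]
        val_features, val_truth = features[val_idx], truth[val_idx]
        features, truth = features[train_idx], truth[train_idx]

    model = JointModel(features.shape[1], partition, Z, config)
    opt = nn.Adam(model.params(), lr=config.lr)
    n = features.shape[0]
    n_cells = truth.size

    best_val = np.inf
    best_state: dict[str, np.ndarray] | None = None
    stale = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, tb = features[idx], truth[idx]
            opt.zero_grad()
            q, logits = model._forward(xb, train=True)
            y = nn.sigmoid(logits)
            batch_cells = tb.size
            loss = bce_loss(y, tb)
            dlogits = (y - tb) / batch_cells
            if model.head is not None:
                dq = model.head.backward(dlogits)
                if config.aux_weight > 0.0:
                    yq = nn.sigmoid(q)
                    loss += config.aux_weight * bce_loss(yq, tb)
                    dq = dq + config.aux_weight * (yq - tb) / batch_cells
            else:
                dq = dlogits
            model.query.backward(dq)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            opt.step()
            epoch_loss += loss * len(idx)
        val_scores = model.predict(val_features)
        val_loss = bce_loss(val_scores, val_truth)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        model.train_history.append(
            {"epoch": epoch, "train_loss": epoch_loss / n, "val_loss": val_loss}
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.get_state()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_state is not None:
        model.set_state(best_state)
    model.best_val_loss = best_val

    if label_embedding_digest(Z) != z_digest_before:
        raise RuntimeError("label embedding was mutated during joint training")
    return model


def predict_batch(
    features: np.ndarray,
    model: JointModel,
    protein_ids: Sequence[str] | None = None,
) -> PredictionMatrix:
    """Score a feature table; one row of probabilities per protein."""
    features = np.asarray(features, float)
    scores = model.predict(features)
    ids = list(protein_ids) if protein_ids is not None else [f"P{i}" for i in range(len(scores))]
    return PredictionMatrix(scores=scores, protein_ids=ids, terms=list(model.partition.terms))
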