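"""Label-side encoder: a GCN graph autoencoder over the ontology.

Each function term carries two kinds of information: its textual
definition and its position in the ontology DAG.  A two-layer graph
convolutional encoder

    Z = A_norm . ReLU(A_norm . X . W0) . W1

fuses per-term definition embeddings X with the symmetrically normalized
ancestor-closure matrix A_norm, and an inner-product decoder

    A_hat = sigmoid(Z . Z^T)

reconstructs the closure.  The autoencoder is pretrained self-supervised
to reconstruct A and the bottleneck Z is then frozen as the label
embedding consumed by the joint cross-attention head.  Because related
terms share graph neighbourhood and definition vocabulary, rare terms
inherit usable structure from their frequent relatives — the point of
the label encoder.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np

from .nn import sigmoid
from .ontology import AdjacencyMatrix, normalize_adjacency

#: Reference biomedical text encoder output width.
REFERENCE_TEXT_DIM = 768
#: Reference label-embedding width.
REFERENCE_LABEL_DIM = 1024


@dataclass
class TermTextEmbedding:
    """Per-term definition embeddings, rows in global term order."""

    X: np.ndarray
    terms: list[str]
    provider_name: str = ""


class TextProvider(Protocol):
    name: str
    dim: int

    def embed_text(self, text: str) -> np.ndarray: ...


class HashTextProvider:
    """Seeded hash-based random projection of token counts.

    Each lowercase token deterministically seeds a random direction (via
    a stable digest of the token), and a text maps to the normalized sum
    of its tokens' directions.  Texts sharing vocabulary — e.g. ontology
    definitions that mention their lineage — therefore get correlated
    vectors, which is the property the label encoder needs.
    """

    def __init__(self, dim: int = 64, seed: int = 0) -> None:
        self.dim = dim
        self.seed = seed
        self.name = f"hash-text-{dim}"
        self._cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.md5(f"{self.seed}:{token}".encode()).digest()
            rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
            vec = rng.standard_normal(self.dim)
            self._cache[token] = vec
        return vec

    def embed_text(self, text: str) -> np.ndarray:
        tokens = re.findall(r"[a-z0-9]+", text.lower())
        if not tokens:
            raise ValueError("cannot embed empty text")
        acc = np.zeros(self.dim)
        for tok in tokens:
            acc += self._token_vector(tok)
        return acc / np.sqrt(len(tokens))


def text_embed(
    definitions: Mapping[str, str], provider: TextProvider, terms: Sequence[str] | None = None
) -> TermTextEmbedding:
    """Embed every term's definition text; rows follow global term order."""
    terms = sorted(definitions) if terms is None else list(terms)
    missing = [t for t in terms if not definitions.get(t, "").strip()]
    if missing:
        raise ValueError(f"missing definitions for terms: {', '.join(missing)}")
    X = np.stack([provider.embed_text(definitions[t]) for t in terms])
    return TermTextEmbedding(X=X, terms=terms, provider_name=provider.name)


@dataclass
class GAEParams:
    """Weights of the two-layer GCN encoder (X -> hidden -> Z)."""

    W0: np.ndarray
    W1: np.ndarray

    @property
    def hidden(self) -> int:
        return self.W0.shape[1]

    @property
    def embed_dim(self) -> int:
        return self.W1.shape[1]


@dataclass
class LabelEmbedding:
    """The matrix Z of per-term semantic vectors (rows = term order)."""

    Z: np.ndarray
    terms: list[str] | None = None
    frozen: bool = False

    def freeze(self) -> "LabelEmbedding":
        self.frozen = True
        self.Z.setflags(write=False)
        return self

    @property
    def dim(self) -> int:
        return self.Z.shape[1]


def gcn_encode(
    X: TermTextEmbedding | np.ndarray,
    A_norm: np.ndarray,
    params: GAEParams,
) -> LabelEmbedding:
    """Two-layer GCN: Z = A_norm . ReLU(A_norm . X . W0) . W1 (unfrozen)."""
    terms = X.terms if isinstance(X, TermTextEmbedding) else None
    Xm = X.X if isinstance(X, TermTextEmbedding) else np.asarray(X, float)
    if Xm.shape[0] != A_norm.shape[0]:
        raise ValueError("X row count must equal adjacency dimension")
    if Xm.shape[1] != params.W0.shape[0]:
        raise ValueError("X width must equal W0 input dimension")
    H = np.maximum(A_norm @ Xm @ params.W0, 0.0)
    Z = A_norm @ H @ params.W1
    return LabelEmbedding(Z=Z, terms=terms, frozen=False)


def decode(Z: LabelEmbedding | np.ndarray) -> np.ndarray:
    """Inner-product decoder: A_hat = sigmoid(Z Z^T), symmetric."""
    Zm = Z.Z if isinstance(Z, LabelEmbedding) else np.asarray(Z, float)
    if not np.all(np.isfinite(Zm)):
        raise ValueError("label embedding contains non-finite entries")
    return sigmoid(Zm @ Zm.T)


@dataclass
class GAEConfig:
    """Training settings for the graph autoencoder.

    ``embed_dim`` is the label-embedding width D_e (reference 1024);
    the hidden width defaults to 2 * D_e.  The reconstruction loss is
    binary cross-entropy over all closure entries with the positive class
    re-weighted by (#zeros / #ones) to counter sparsity.  Definition
    features are standardized per column and the learning rate follows a
    cosine decay — both stabilize the full-batch Adam run on the badly
    scaled inner-product logits.
    """

    embed_dim: int = REFERENCE_LABEL_DIM
    hidden: int | None = None
    lr: float = 0.01
    epochs: int = 500
    seed: int = 0
    standardize: bool = True
    cosine_lr: bool = True
    auc_every: int = 10


@dataclass
class GAETrainResult:
    params: GAEParams
    embedding: LabelEmbedding
    loss_history: list[float] = field(default_factory=list)
    auc_history: list[tuple[int, float]] = field(default_factory=list)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def train_gae(
    X: TermTextEmbedding,
    A: AdjacencyMatrix | np.ndarray,
    config: GAEConfig | None = None,
) -> GAETrainResult:
    """Pretrain the autoencoder to reconstruct the ancestor closure.

    Full-batch Adam on the re-weighted reconstruction cross-entropy;
    seeded and reproducible.  Returns the encoder weights and the frozen
    bottleneck embedding Z.
    """
    config = config or GAEConfig()
    Am = A.A if isinstance(A, AdjacencyMatrix) else np.asarray(A, float)
    if X.X.shape[0] != Am.shape[0]:
        raise ValueError("X row count must equal adjacency dimension")
    A_norm = normalize_adjacency(Am)
    dc, d_t = X.X.shape
    hidden = config.hidden or 2 * config.embed_dim
    rng = np.random.default_rng(config.seed)
    W0 = rng.normal(0.0, np.sqrt(1.0 / d_t), size=(d_t, hidden))
    W1 = rng.normal(0.0, np.sqrt(1.0 / hidden), size=(hidden, config.embed_dim))

    n_ones = Am.sum()
    n_zeros = Am.size - n_ones
    pos_weight = (n_zeros / n_ones) if (n_ones and n_zeros) else 1.0

    # Adam state
    ms = [np.zeros_like(W0), np.zeros_like(W1)]
    vs = [np.zeros_like(W0), np.zeros_like(W1)]
    b1, b2, eps = 0.9, 0.999, 1e-8
    Xm = X.X
    if config.standardize and dc > 1:
        Xm = (Xm - Xm.mean(axis=0)) / (Xm.std(axis=0) + 1e-8)
    AX = A_norm @ Xm
    off_diag = ~np.eye(dc, dtype=bool)
    loss_history: list[float] = []
    auc_history: list[tuple[int, float]] = []
    for epoch in range(config.epochs):
        Hpre = AX @ W0
        H = np.maximum(Hpre, 0.0)
        AH = A_norm @ H
        Z = AH @ W1
        M = Z @ Z.T
        # weighted BCE on logits M vs targets A
        loss = float(
            np.mean(pos_weight * Am * _softplus(-M) + (1.0 - Am) * _softplus(M))
        )
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite reconstruction loss at epoch {epoch}")
        loss_history.append(loss)
        track = config.auc_every and (epoch % config.auc_every == 0 or epoch == config.epochs - 1)
        if track and dc > 1 and 0 < Am[off_diag].sum() < off_diag.sum():
            from sklearn.metrics import roc_auc_score

            auc_history.append(
                (epoch, float(roc_auc_score(Am[off_diag].ravel(), sigmoid(M[off_diag]).ravel())))
            )

        S = sigmoid(M)
        dM = (pos_weight * Am * (S - 1.0) + (1.0 - Am) * S) / Am.size
        dZ = (dM + dM.T) @ Z
        dW1 = AH.T @ dZ
        dH = (A_norm.T @ dZ) @ W1.T
        dHpre = dH * (Hpre > 0)
        dW0 = AX.T @ dHpre

        lr = config.lr
        if config.cosine_lr:
            lr *= 0.5 * (1.0 + np.cos(np.pi * epoch / config.epochs))
        t = epoch + 1
        for W, g, m, v in ((W0, dW0, ms[0], vs[0]), (W1, dW1, ms[1], vs[1])):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            W -= lr * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps)

    params = GAEParams(W0=W0, W1=W1)
    X_used = TermTextEmbedding(X=Xm, terms=X.terms, provider_name=X.provider_name)
    embedding = gcn_encode(X_used, A_norm, params).freeze()
    return GAETrainResult(
        params=params, embedding=embedding,
        loss_history=loss_history, auc_history=auc_history,
    )


def random_label_embedding(dc: int, d_e: int, seed: int) -> LabelEmbedding:
    """Seeded standard-normal label matrix, the ablation control for Z."""
    if dc < 1 or d_e < 1:
        raise ValueError("dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    return LabelEmbedding(Z=rng.standard_normal((dc, d_e)), frozen=False).freeze()


def reconstruction_auc(A: AdjacencyMatrix | np.ndarray, Z: LabelEmbedding) -> float:
    """Off-diagonal ROC AUC of decoded scores against the true closure."""
    from sklearn.metrics import roc_auc_score

    Am = A.A if isinstance(A, AdjacencyMatrix) else np.asarray(A, float)
    Ahat = decode(Z)
    mask = ~np.eye(Am.shape[0], dtype=bool)
    return float(roc_auc_score(Am[mask].ravel(), Ahat[mask].ravel()))
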