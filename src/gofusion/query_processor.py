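"""Sequence-side encoder: frequency-partitioned expert MLPs with scatter.

Function terms have wildly different annotation frequencies, and a single
head over all terms lets common terms dominate the rare ones.  The query
processor therefore partitions one namespace's terms into ``n``
frequency bands (rare -> common) and assigns one residual MLP "expert"
per band.  All experts read the same pooled sequence embedding; their
per-group logit vectors are scattered back into the global term order to
form the query representation ``q`` (one logit per term).

By default biological process uses three groups and molecular function /
cellular component two, with boundaries at log-spaced annotation counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np

from . import nn

#: Residue chunk length accepted by the reference protein language model.
CHUNK_LENGTH = 1022

#: Reference provider (large protein language model, last-layer mean pool).
REFERENCE_FEATURE_DIM = 5120

AMINO_ACID_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZUO")

#: Default per-namespace (n_groups, thresholds) frequency partitions.
DEFAULT_PARTITIONS: dict[str, tuple[int, tuple[int, ...]]] = {
    "MF": (2, (100,)),
    "CC": (2, (100,)),
    "BP": (3, (30, 100)),
}


@dataclass
class TermPartition:
    """Ordered split of a namespace's terms into frequency groups.

    ``scatter_index`` maps each slot of the concatenated group outputs to
    its position in the global term order; it is a bijection onto
    ``range(dc)``.
    """

    groups: list[list[str]]
    n: int
    frequency_thresholds: tuple[int, ...]
    terms: list[str]
    scatter_index: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pos = {t: i for i, t in enumerate(self.terms)}
        self.scatter_index = np.array(
            [pos[t] for group in self.groups for t in group], dtype=int
        )

    @property
    def dc(self) -> int:
        return len(self.terms)

    @property
    def group_sizes(self) -> list[int]:
        return [len(g) for g in self.groups]


def partition_terms(
    frequencies: Mapping[str, int],
    n: int,
    thresholds: Sequence[int],
) -> TermPartition:
    """Assign each term to its frequency band (rare bands first).

    Band *i* holds terms with ``thresholds[i-1] < count <= thresholds[i]``;
    the last band is unbounded above.  Within a band, terms keep the
    global (lexicographic) order.
    """
    if n < 1:
        raise ValueError("group count must be >= 1")
    thresholds = tuple(thresholds)
    if len(thresholds) != n - 1:
        raise ValueError(f"need {n - 1} thresholds for {n} groups, got {len(thresholds)}")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    terms = sorted(frequencies)
    bounds = (*thresholds, np.inf)
    groups: list[list[str]] = [[] for _ in range(n)]
    for t in terms:
        count = frequencies[t]
        for i, upper in enumerate(bounds):
            if count <= upper:
                groups[i].append(t)
                break
    return TermPartition(groups=groups, n=n, frequency_thresholds=thresholds, terms=terms)


@dataclass
class SequenceFeature:
    """Mean-pooled per-residue embedding of one protein."""

    protein_id: str
    vector: np.ndarray


class EmbeddingProvider(Protocol):
    """Yields a per-residue embedding matrix for a (chunk of a) sequence."""

    name: str
    dim: int

    def embed_residues(self, sequence: str) -> np.ndarray: ...


class HashResidueProvider:
    """Deterministic per-residue embeddings from seeded per-letter vectors.

    A lightweight, dependency-free stand-in with the same interface shape
    as a protein language model: each residue letter maps to a fixed
    random vector (seeded), so the pooled protein embedding is the
    residue-composition profile projected into ``dim`` dimensions.
    """

    def __init__(self, dim: int = 64, seed: int = 0) -> None:
        self.name = f"hash-residue-{dim}"
        self.dim = dim
        rng = np.random.default_rng(seed)
        letters = sorted(AMINO_ACID_ALPHABET)
        self._table = {aa: rng.standard_normal(dim) for aa in letters}

    def embed_residues(self, sequence: str) -> np.ndarray:
        return np.stack([self._table[aa] for aa in sequence])


class ConstantProvider:
    """Every residue maps to the same vector; useful to test pooling."""

    def __init__(self, vector: np.ndarray) -> None:
        self.vector = np.asarray(vector, dtype=float)
        self.dim = self.vector.shape[0]
        self.name = f"constant-{self.dim}"

    def embed_residues(self, sequence: str) -> np.ndarray:
        return np.tile(self.vector, (len(sequence), 1))


class MSAProvider:
    """Interface stub for multiple-sequence-alignment features."""

    name = "msa"
    dim = 0

    def embed_residues(self, sequence: str) -> np.ndarray:
        raise NotImplementedError("MSA feature provider is an interface stub")


class InterProProvider:
    """Interface stub for protein-domain-annotation features."""

    name = "interpro"
    dim = 0

    def embed_residues(self, sequence: str) -> np.ndarray:
        raise NotImplementedError("domain-annotation provider is an interface stub")


def chunk_lengths(length: int, chunk: int = CHUNK_LENGTH) -> list[int]:
    """Lengths of the consecutive chunks a sequence is split into."""
    if length <= 0:
        raise ValueError("sequence length must be positive")
    out = [chunk] * (length // chunk)
    if length % chunk:
        out.append(length % chunk)
    return out


def embed_sequence(
    sequence: str,
    provider: EmbeddingProvider,
    protein_id: str = "",
    chunk: int = CHUNK_LENGTH,
) -> SequenceFeature:
    """Mean-pooled protein embedding, chunking long sequences.

    Sequences longer than the provider's limit are split into consecutive
    chunks (last one shorter); per-chunk per-residue embeddings are
    concatenated along the sequence before the mean, so the result is the
    residue-count-weighted mean over chunks and is invariant to the
    chunking for any provider that treats residues independently.
    """
    if not sequence:
        raise ValueError(f"empty sequence for protein {protein_id!r}")
    bad = set(sequence) - AMINO_ACID_ALPHABET
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)} in protein {protein_id!r}")
    try:
        pieces = [
            provider.embed_residues(sequence[i : i + chunk])
            for i in range(0, len(sequence), chunk)
        ]
    except NotImplementedError:
        raise
    except Exception as exc:
        raise RuntimeError(f"embedding provider failed for protein {protein_id!r}: {exc}") from exc
    per_residue = np.concatenate(pieces, axis=0)
    return SequenceFeature(protein_id=protein_id, vector=per_residue.mean(axis=0))


class QueryExpert:
    """Residual MLP for one frequency group.

    ``depth`` hidden blocks of linear -> batch norm -> GELU with identity
    skips, followed by a plain linear layer emitting raw logits of width
    ``group_size``.  Applying the logistic function to the logits gives
    standalone per-term probabilities.
    """

    def __init__(
        self,
        d_in: int,
        group_size: int,
        rng: np.random.Generator,
        depth: int = 2,
        hidden: int | None = None,
        name: str = "expert",
    ) -> None:
        if hidden is None:
            hidden = min(1024, d_in)
        self.blocks: list[nn.MLPBlock] = []
        d = d_in
        for k in range(depth):
            self.blocks.append(
                nn.MLPBlock(d, hidden, rng, skip=True, use_norm=True, name=f"{name}.block{k}")
            )
            d = hidden
        self.out = nn.Linear(d, group_size, rng, name=f"{name}.out")

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for b in self.blocks:
            ps += b.params()
        return ps + self.out.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        for b in self.blocks:
            h = b.forward(h, train)
        return self.out.forward(h, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.out.backward(dy)
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        return dh

    def norm_buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for k, b in enumerate(self.blocks):
            if b.norm is not None:
                out[f"block{k}.running_mean"] = b.norm.running_mean
                out[f"block{k}.running_var"] = b.norm.running_var
        return out


def mlp_forward(x: np.ndarray, expert: QueryExpert, mode: str = "eval") -> np.ndarray:
    """Run one expert on a feature batch (or single vector)."""
    if mode not in ("train", "eval"):
        raise ValueError(f"unknown mode {mode!r}")
    single = x.ndim == 1
    xb = x[None, :] if single else x
    y = expert.forward(xb, train=(mode == "train"))
    return y[0] if single else y


def scatter_combine(
    group_outputs: Sequence[np.ndarray], partition: TermPartition
) -> np.ndarray:
    """Place each group's logits at their global term positions.

    Accepts vectors (one protein) or batches (rows = proteins); every
    global slot is written exactly once because the scatter index is a
    bijection.
    """
    sizes = partition.group_sizes
    if len(group_outputs) != partition.n:
        raise ValueError(f"expected {partition.n} group outputs, got {len(group_outputs)}")
    for out, size in zip(group_outputs, sizes):
        if out.shape[-1] != size:
            raise ValueError(f"group output width {out.shape[-1]} != group size {size}")
    concat = np.concatenate(group_outputs, axis=-1)
    q = np.empty_like(concat)
    q[..., partition.scatter_index] = concat
    return q


def gather_split(q: np.ndarray, partition: TermPartition) -> list[np.ndarray]:
    """Inverse of :func:`scatter_combine`."""
    concat = q[..., partition.scatter_index]
    return list(np.split(concat, np.cumsum(partition.group_sizes)[:-1], axis=-1))


class QueryProcessor:
    """All experts of one namespace plus the scatter recombination."""

    def __init__(
        self,
        d_in: int,
        partition: TermPartition,
        rng: np.random.Generator,
        depth: int = 2,
        hidden: int | None = None,
    ) -> None:
        self.partition = partition
        self.d_in = d_in
        self.experts = [
            QueryExpert(d_in, size, rng, depth=depth, hidden=hidden, name=f"expert{i}")
            for i, size in enumerate(partition.group_sizes)
        ]

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for e in self.experts:
            ps += e.params()
        return ps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        outs = [e.forward(x, train) for e in self.experts]
        return scatter_combine(outs, self.partition)

    def backward(self, dq: np.ndarray) -> np.ndarray:
        dgroups = gather_split(dq, self.partition)
        dx = np.zeros((dq.shape[0], self.d_in))
        for e, dg in zip(self.experts, dgroups):
            dx += e.backward(dg)
        return dx

    def norm_buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for i, e in enumerate(self.experts):
            for k, v in e.norm_buffers().items():
                out[f"expert{i}.{k}"] = v
        return out


def query_representation(
    feature: SequenceFeature | np.ndarray,
    experts: Sequence[QueryExpert],
    partition: TermPartition,
) -> np.ndarray:
    """Run every expert on one shared feature vector and scatter-combine."""
    if len(experts) != partition.n:
        raise ValueError("one expert per partition group is required")
    x = feature.vector if isinstance(feature, SequenceFeature) else np.asarray(feature, float)
    outs = [mlp_forward(x, e, mode="eval") for e in experts]
    return scatter_combine(outs, partition)
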