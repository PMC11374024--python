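"""Gene Ontology handling: parsing, ancestor closure, annotation propagation.

The ontology is a rooted DAG of function terms in three namespaces
(molecular function, cellular component, biological process).  Ancestry
follows both ``is_a`` (inheritance) and ``part_of`` (composition) edges;
other relation types are ignored.  The *true-path rule* states that a
protein annotated with a term implicitly carries all of that term's
ancestors, which motivates the ancestor closure applied to annotation
sets before training and evaluation.

All matrices and partitions in the package share a single stable term
order: lexicographic by GO identifier, 0-based.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import obonet

logger = logging.getLogger(__name__)

#: OBO namespace names -> short codes used throughout the package.
NAMESPACE_CODES = {
    "molecular_function": "MF",
    "cellular_component": "CC",
    "biological_process": "BP",
}

#: The 13 experimentally grounded evidence codes retained by default,
#: following the CAFA convention (electronic IEA annotations are dropped).
EXPERIMENTAL_EVIDENCE_CODES = frozenset(
    {
        "EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC",
        "HTP", "HDA", "HMP", "HGI", "HEP",
    }
)

#: Edge (relation) types that define ancestry.
ANCESTRY_RELATIONS = ("is_a", "part_of")


class OboParseError(ValueError):
    """Raised when an OBO document cannot be parsed or validated."""


@dataclass
class OntologyGraph:
    """A rooted DAG of function terms with typed child->parent edges.

    ``terms`` is sorted lexicographically and contains only non-obsolete
    primary identifiers; ``alt_ids`` maps alias identifiers onto their
    primary term.
    """

    terms: list[str]
    namespace: dict[str, str]
    edges: list[tuple[str, str, str]]  # (child, parent, relation type)
    definitions: dict[str, str]
    alt_ids: dict[str, str] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)
    n_dropped_cross_namespace: int = 0

    def __post_init__(self) -> None:
        self._parents: dict[str, set[str]] = {t: set() for t in self.terms}
        self._children: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, parent, _rel in self.edges:
            self._parents[child].add(parent)
            self._children[parent].add(child)
        self._index = {t: i for i, t in enumerate(self.terms)}

    def resolve(self, term: str) -> str:
        """Map an alt_id alias onto its primary identifier."""
        return self.alt_ids.get(term, term)

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) in self._index

    def parents(self, term: str) -> set[str]:
        return set(self._parents[self.resolve(term)])

    def children(self, term: str) -> set[str]:
        return set(self._children[self.resolve(term)])

    def namespace_terms(self, namespace: str) -> list[str]:
        """All terms of one namespace, in the global (lexicographic) order."""
        return [t for t in self.terms if self.namespace[t] == namespace]

    def leaves(self, namespace: str | None = None) -> list[str]:
        """Terms with no children (optionally restricted to a namespace)."""
        out = [t for t in self.terms if not self._children[t]]
        if namespace is not None:
            out = [t for t in out if self.namespace[t] == namespace]
        return out

    def roots(self, namespace: str | None = None) -> list[str]:
        out = [t for t in self.terms if not self._parents[t]]
        if namespace is not None:
            out = [t for t in out if self.namespace[t] == namespace]
        return out

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for t in self.terms:
            g.add_node(t, namespace=self.namespace[t], definition=self.definitions.get(t, ""))
        for child, parent, rel in self.edges:
            g.add_edge(child, parent, key=rel)
        return g


@dataclass
class AdjacencyMatrix:
    """Ancestor-closure matrix of one namespace.

    ``A[i, j] == 1`` iff term *i* is an ancestor of term *j* or ``i == j``,
    in the namespace's stable term order; hence the diagonal is all ones
    and the relation encoded is transitively closed.
    """

    A: np.ndarray
    terms: list[str]

    @property
    def dc(self) -> int:
        return len(self.terms)


@dataclass
class AnnotationSet:
    """(protein, term, evidence code) triples, optionally ancestor-closed."""

    records: list[tuple[str, str, str]]
    closed: bool = False
    n_dropped: int = 0

    def proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for p, _t, _c in self.records:
            seen.setdefault(p)
        return list(seen)

    def by_protein(self) -> dict[str, dict[str, str]]:
        out: dict[str, dict[str, str]] = {}
        for p, t, c in self.records:
            out.setdefault(p, {})[t] = c
        return out

    def term_counts(self) -> dict[str, int]:
        """Number of distinct proteins annotated to each term."""
        counts: dict[str, int] = {}
        for _p, t, _c in self.records:
            counts[t] = counts.get(t, 0) + 1
        return counts


def _validate_obo_lines(obo_text: str) -> None:
    in_stanza = False
    for lineno, raw in enumerate(obo_text.splitlines(), start=1):
        line = raw.split("!")[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            in_stanza = True
            continue
        if ":" not in line:
            where = "stanza" if in_stanza else "header"
            raise OboParseError(f"malformed OBO {where} line {lineno}: {raw!r}")


def parse_obo(obo_text: str) -> OntologyGraph:
    """Parse OBO flat-file content into an :class:`OntologyGraph`.

    Non-obsolete ``[Term]`` stanzas become nodes; ``is_a`` and
    ``relationship: part_of`` lines become typed edges.  ``alt_id``
    identifiers are aliased to their primary term.  Edges whose endpoints
    lie in different namespaces are dropped (with a logged count), so each
    namespace is a self-contained DAG.

    Raises
    ------
    OboParseError
        On a malformed line (reported with its line number) or on an edge
        referencing a term with no ``[Term]`` stanza.
    """
    _validate_obo_lines(obo_text)
    try:
        multigraph = obonet.read_obo(io.StringIO(obo_text))
    except ValueError as exc:  # pragma: no cover - obonet internal failure
        raise OboParseError(f"could not parse OBO document: {exc}") from exc

    unknown = sorted(
        n for n, attrs in multigraph.nodes(data=True) if "namespace" not in attrs and "name" not in attrs
    )
    if unknown:
        raise OboParseError(
            "edges reference terms with no stanza: " + ", ".join(unknown)
        )

    namespace: dict[str, str] = {}
    definitions: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for node, attrs in multigraph.nodes(data=True):
        ns_long = attrs.get("namespace", "molecular_function")
        if ns_long not in NAMESPACE_CODES:
            raise OboParseError(f"term {node} has unknown namespace {ns_long!r}")
        namespace[node] = NAMESPACE_CODES[ns_long]
        raw_def = attrs.get("def", "")
        definitions[node] = raw_def.split('" [')[0].strip('"') if raw_def else attrs.get("name", "")
        for alias in attrs.get("alt_id", []):
            alt_ids[alias] = node

    terms = sorted(multigraph.nodes)
    edges: list[tuple[str, str, str]] = []
    n_cross = 0
    for child, parent, rel in multigraph.edges(keys=True):
        if rel not in ANCESTRY_RELATIONS:
            continue
        if namespace[child] != namespace[parent]:
            n_cross += 1
            continue
        edges.append((child, parent, rel))
    if n_cross:
        logger.info("dropped %d cross-namespace edges", n_cross)

    graph = OntologyGraph(
        terms=terms,
        namespace=namespace,
        edges=sorted(edges),
        definitions=definitions,
        alt_ids=alt_ids,
        n_dropped_cross_namespace=n_cross,
    )
    _check_acyclic(graph)
    return graph


def _check_acyclic(graph: OntologyGraph) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(graph.terms)
    g.add_edges_from((c, p) for c, p, _ in graph.edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OboParseError(f"ontology contains a cycle: {cycle}")


def ancestors(graph: OntologyGraph, term: str) -> set[str]:
    """All terms reachable upward from ``term`` via is_a/part_of edges.

    Excludes ``term`` itself; restricted to the term's namespace by
    construction (cross-namespace edges are dropped at parse time).
    """
    term = graph.resolve(term)
    if term not in graph:
        raise KeyError(f"unknown term {term!r}")
    out: set[str] = set()
    frontier = list(graph.parents(term))
    while frontier:
        t = frontier.pop()
        if t not in out:
            out.add(t)
            frontier.extend(graph.parents(t))
    return out


def build_adjacency(graph: OntologyGraph, namespace: str) -> AdjacencyMatrix:
    """Ancestor-closure adjacency matrix of one namespace.

    Row *i*, column *j* is 1 iff term *i* is an ancestor of *j* or equals
    *j*; the matrix is upper-triangular-like under the stable term order
    only when identifiers happen to sort topologically, so no such
    structure is assumed downstream.
    """
    terms = graph.namespace_terms(namespace)
    if not terms:
        raise ValueError(f"namespace {namespace!r} has no terms")
    index = {t: i for i, t in enumerate(terms)}
    A = np.eye(len(terms))
    for j, t in enumerate(terms):
        for anc in ancestors(graph, t):
            A[index[anc], j] = 1.0
    return AdjacencyMatrix(A=A, terms=terms)


def normalize_adjacency(A: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    """Symmetric degree normalization D^(-1/2) A D^(-1/2).

    Degrees are row sums of A; with the self-entries guaranteed by the
    ancestor closure every degree is >= 1.
    """
    mat = A.A if isinstance(A, AdjacencyMatrix) else np.asarray(A, dtype=float)
    deg = mat.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("adjacency has a zero-degree row")
    inv_sqrt = 1.0 / np.sqrt(deg)
    return mat * np.outer(inv_sqrt, inv_sqrt)


def propagate_annotations(graph: OntologyGraph, anns: AnnotationSet) -> AnnotationSet:
    """Close an annotation set under the true-path rule.

    Every (protein, term) pair gains (protein, ancestor) pairs for all
    ancestors of the term.  The evidence code of a propagated pair is
    inherited from the most specific originating record (deepest term;
    ties broken by stable term order).  Records on unknown or obsolete
    terms are dropped with a warning and counted in ``n_dropped``.
    """
    depth = {t: len(ancestors(graph, t)) for t in graph.terms}
    closed: dict[str, dict[str, tuple[int, int, str]]] = {}
    n_dropped = 0
    order = {t: i for i, t in enumerate(graph.terms)}
    for p, t, code in anns.records:
        t = graph.resolve(t)
        if t not in graph or t in graph.obsolete:
            logger.warning("dropping annotation to unknown/obsolete term %s", t)
            n_dropped += 1
            continue
        rows = closed.setdefault(p, {})
        # candidate priority: deeper originating term wins, then term order
        prio = (-depth[t], order[t])
        for target in {t} | ancestors(graph, t):
            if target not in rows or prio < rows[target][:2]:
                rows[target] = (*prio, code)
    records = [
        (p, t, code)
        for p in anns.proteins()
        if p in closed
        for t, (_d, _o, code) in sorted(closed[p].items())
    ]
    return AnnotationSet(records=records, closed=True, n_dropped=anns.n_dropped + n_dropped)


def filter_evidence(
    anns: AnnotationSet, allowed: Iterable[str] = EXPERIMENTAL_EVIDENCE_CODES
) -> AnnotationSet:
    """Keep only records whose evidence code is in ``allowed``."""
    allowed = frozenset(allowed)
    return AnnotationSet(
        records=[r for r in anns.records if r[2] in allowed],
        closed=anns.closed,
        n_dropped=anns.n_dropped,
    )


def annotation_matrix(
    anns: AnnotationSet, protein_ids: Sequence[str], terms: Sequence[str]
) -> np.ndarray:
    """Binary proteins x terms matrix in the given orders."""
    t_index = {t: j for j, t in enumerate(terms)}
    p_index = {p: i for i, p in enumerate(protein_ids)}
    Y = np.zeros((len(protein_ids), len(terms)))
    for p, t, _c in anns.records:
        i = p_index.get(p)
        j = t_index.get(t)
        if i is not None and j is not None:
            Y[i, j] = 1.0
    return Y
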