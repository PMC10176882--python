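"""GO ontology handling, overlap classes, Wang/ABM semantic similarity, depth.

The ontology is a DAG of terms connected by ``is_a`` and ``part_of``
edges within three namespaces (BP, MF, CC).  Similarity between two
terms follows Wang's topological measure: each term induces a sub-DAG of
its ancestors, every ancestor receives an S-value equal to the best
(max) product of edge weights along any path from the term, and the
similarity is the summed S-values over shared ancestors normalized by
both terms' totals.  Gene-level similarity aggregates term pairs by
Average-Best-Match: every term is matched to its best counterpart in the
other set and the matches are averaged over both directions.

Term *depth* is the longest ``is_a`` path from the namespace root
(matching the convention of the common GO toolkits); *level* (shortest
path) is exposed alongside for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Classic Wang edge weights.  The similarity engine accepts any mapping
#: relation -> factor, or a callable, so alternative weight schemes (e.g.
#: child-count-dependent ones) can be plugged in without further changes.
DEFAULT_EDGE_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}

_NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}

OVERLAP_CLASSES = ("identical", "partial", "disjoint", "not_comparable")


class OboFormatError(ValueError):
    """Structurally invalid ontology file (e.g. a cycle)."""


@dataclass(frozen=True)
class GoTerm:
    term_id: str
    name: str
    namespace: str  # BP | MF | CC
    parents: tuple[tuple[str, str], ...] = ()  # (parent_id, relation)


@dataclass
class GoOntology:
    """DAG of GO terms with is_a/part_of edges, alt-id map, obsolete set."""

    terms: dict[str, GoTerm] = field(default_factory=dict)
    alt_ids: dict[str, str] = field(default_factory=dict)
    obsolete: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent_id, _relation in term.parents:
                graph.add_edge(term.term_id, parent_id)
        if not nx.is_directed_acyclic_graph(graph):
            member = nx.find_cycle(graph)[0][0]
            raise OboFormatError(f"ontology contains a cycle through {member}")
        self._depth_cache: dict[str, int] = {}
        self._level_cache: dict[str, int] = {}

    # -- lookup -----------------------------------------------------------

    def resolve(self, term_id: str) -> str:
        """Map an id (possibly an alt_id) to its primary term id."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_ids:
            return self.alt_ids[term_id]
        if term_id in self.obsolete:
            return term_id
        raise KeyError(f"unknown GO term {term_id}")

    def namespace(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].namespace

    def parents(self, term_id: str, relations: Iterable[str]) -> list[tuple[str, str]]:
        wanted = set(relations)
        return [
            (pid, rel)
            for pid, rel in self.terms[term_id].parents
            if rel in wanted and pid in self.terms
        ]

    # -- S-values and similarity ------------------------------------------

    def s_values(
        self,
        term_id: str,
        weights: Mapping[str, float] | Callable[[str, str, str], float] = None,
    ) -> dict[str, float]:
        """Wang S-values over the term's ancestor sub-DAG.

        ``S(term) = 1``; for any ancestor ``t``, ``S(t)`` is the maximum
        over in-sub-DAG children ``c`` of ``w(edge) * S(c)`` — i.e. the
        best path product from the term.  Edges whose relation has no
        weight are excluded from the sub-DAG.
        """
        if weights is None:
            weights = DEFAULT_EDGE_WEIGHTS
        if callable(weights):
            weight_of = weights
        else:
            table = dict(weights)

            def weight_of(child: str, parent: str, relation: str) -> Optional[float]:
                return table.get(relation)

        term_id = self.resolve(term_id)
        svalues = {term_id: 1.0}
        stack = [term_id]
        # max-product relaxation; weights < 1 on a DAG, so this terminates
        # with each ancestor holding its best path product
        while stack:
            current = stack.pop()
            for parent_id, relation in self.terms[current].parents:
                if parent_id not in self.terms:
                    continue
                w = weight_of(current, parent_id, relation)
                if w is None:
                    continue
                candidate = svalues[current] * w
                if candidate > svalues.get(parent_id, 0.0):
                    svalues[parent_id] = candidate
                    stack.append(parent_id)
        return svalues

    # -- depth / level -----------------------------------------------------

    def depth(self, term_id: str) -> int:
        """Longest is_a path from the namespace root (root -> 0)."""
        term_id = self.resolve(term_id)
        if term_id not in self._depth_cache:
            parents = self.parents(term_id, ("is_a",))
            self._depth_cache[term_id] = (
                0
                if not parents
                else 1 + max(self.depth(pid) for pid, _ in parents)
            )
        return self._depth_cache[term_id]

    def level(self, term_id: str) -> int:
        """Shortest is_a path from the namespace root."""
        term_id = self.resolve(term_id)
        if term_id not in self._level_cache:
            parents = self.parents(term_id, ("is_a",))
            self._level_cache[term_id] = (
                0
                if not parents
                else 1 + min(self.level(pid) for pid, _ in parents)
            )
        return self._level_cache[term_id]


def parse_obo(path: str | Path) -> GoOntology:
    """Parse an OBO 1.2 flat file into a :class:`GoOntology`.

    Only ``is_a`` and ``relationship: part_of`` edges enter the DAG;
    obsolete stanzas are recorded but excluded.  A cycle raises
    :class:`OboFormatError` naming one of its members.
    """
    graph = obonet.read_obo(path, ignore_obsolete=False)
    terms: dict[str, GoTerm] = {}
    alt_ids: dict[str, str] = {}
    obsolete: set[str] = set()
    for node, data in graph.nodes(data=True):
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(node)
            continue
        namespace = _NAMESPACE_CODES.get(data.get("namespace", ""), "BP")
        parents: list[tuple[str, str]] = []
        for _child, parent, relation in graph.out_edges(node, keys=True):
            if relation in ("is_a", "part_of"):
                parents.append((parent, relation))
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
        terms[node] = GoTerm(
            term_id=node,
            name=data.get("name", node),
            namespace=namespace,
            parents=tuple(sorted(parents)),
        )
    # drop edges into obsolete terms
    cleaned = {
        tid: GoTerm(
            term_id=t.term_id,
            name=t.name,
            namespace=t.namespace,
            parents=tuple(p for p in t.parents if p[0] in terms),
        )
        for tid, t in terms.items()
    }
    return GoOntology(terms=cleaned, alt_ids=alt_ids, obsolete=frozenset(obsolete))


def overlap_class(a: Iterable[str], b: Iterable[str]) -> str:
    """Direct (raw-set) overlap class of two GO annotation sets."""
    a, b = set(a), set(b)
    if not a or not b:
        return "not_comparable"
    if a == b:
        return "identical"
    if a & b:
        return "partial"
    return "disjoint"


def wang_similarity(
    t1: str,
    t2: str,
    onto: GoOntology,
    weights: Mapping[str, float] | Callable[[str, str, str], float] = None,
) -> float:
    """Wang topological semantic similarity of two terms in (0, 1]."""
    t1, t2 = onto.resolve(t1), onto.resolve(t2)
    if onto.namespace(t1) != onto.namespace(t2):
        raise ValueError(
            f"{t1} ({onto.namespace(t1)}) and {t2} ({onto.namespace(t2)}) "
            "are in different namespaces"
        )
    s1 = onto.s_values(t1, weights)
    s2 = onto.s_values(t2, weights)
    common = set(s1) & set(s2)
    numerator = sum(s1[t] + s2[t] for t in common)
    return numerator / (sum(s1.values()) + sum(s2.values()))


def abm_similarity(
    set_a: Iterable[str],
    set_b: Iterable[str],
    onto: GoOntology,
    weights: Mapping[str, float] | Callable[[str, str, str], float] = None,
) -> Optional[float]:
    """Average-Best-Match similarity of two term sets.

    Every term in A is matched to its most similar term in B and vice
    versa; the matches are averaged:
    ``(sum_a max_b sim + sum_b max_a sim) / (|A| + |B|)``.
    Returns ``None`` if either set is empty.
    """
    set_a, set_b = sorted(set(set_a)), sorted(set(set_b))
    if not set_a or not set_b:
        return None
    cache: dict[tuple[str, str], float] = {}

    def sim(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        if key not in cache:
            cache[key] = wang_similarity(x, y, onto, weights)
        return cache[key]

    forward = sum(max(sim(a, b) for b in set_b) for a in set_a)
    backward = sum(max(sim(a, b) for a in set_a) for b in set_b)
    return (forward + backward) / (len(set_a) + len(set_b))


def term_depth(term_id: str, onto: GoOntology) -> int:
    """Longest is_a path from the namespace root to the term."""
    return onto.depth(term_id)


def resolve_annotation_set(
    onto: GoOntology, term_ids: Iterable[str], protein_id: str = "?"
) -> set[str]:
    """Resolve alt_ids to primary ids and drop obsolete terms (warning)."""
    resolved: set[str] = set()
    for tid in term_ids:
        primary = onto.resolve(tid)
        if primary in onto.obsolete:
            logger.warning(
                "%s: dropping obsolete GO term %s", protein_id, tid
            )
            continue
        resolved.add(primary)
    return resolved


def read_go_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a TSV of (protein_id, comma-separated GO ids)."""
    annotations: dict[str, set[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            protein = parts[0]
            terms = (
                {t.strip() for t in parts[1].split(",") if t.strip()}
                if len(parts) > 1
                else set()
            )
            annotations[protein] = terms
    return annotations


@dataclass(frozen=True)
class GoComparison:
    """Per-protein outcome of a sequence-vs-structure GO comparison."""

    protein_id: str
    overlap: str
    abm: Optional[float]
    matched_depths: tuple[int, ...]
    unmatched_depths: tuple[int, ...]


def compare_annotation_sets(
    onto: GoOntology,
    protein_id: str,
    set_a: Iterable[str],
    set_b: Iterable[str],
    namespace: Optional[str] = None,
    weights: Mapping[str, float] | Callable[[str, str, str], float] = None,
) -> GoComparison:
    """Overlap class, ABM similarity and depth summary for one protein."""
    a = resolve_annotation_set(onto, set_a, protein_id)
    b = resolve_annotation_set(onto, set_b, protein_id)
    if namespace is not None:
        a = {t for t in a if onto.namespace(t) == namespace}
        b = {t for t in b if onto.namespace(t) == namespace}
    matched = a & b
    unmatched = (a | b) - matched
    # ABM is defined within a namespace; without a namespace restriction,
    # average the per-namespace scores over namespaces populated on both sides
    per_ns = []
    for ns in ("BP", "MF", "CC"):
        a_ns = {t for t in a if onto.namespace(t) == ns}
        b_ns = {t for t in b if onto.namespace(t) == ns}
        score = abm_similarity(a_ns, b_ns, onto, weights) if a_ns and b_ns else None
        if score is not None:
            per_ns.append(score)
    abm = sum(per_ns) / len(per_ns) if per_ns else None
    return GoComparison(
        protein_id=protein_id,
        overlap=overlap_class(a, b),
        abm=abm,
        matched_depths=tuple(sorted(onto.depth(t) for t in matched)),
        unmatched_depths=tuple(sorted(onto.depth(t) for t in unmatched)),
    )
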