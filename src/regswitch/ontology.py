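"""GO DAG handling: annotation propagation, information content, and the
Schlicker Relevance (SimRel) semantic similarity.

The similarity of two terms t1, t2 is

    sim(t1, t2) = [2 * IC(MICA) / (IC(t1) + IC(t2))] * (1 - p(MICA))

where IC(t) = -ln p(t), p(t) is the annotation frequency of t in the
corpus after true-path propagation, and MICA is the common ancestor with
maximal IC. The (1 - p(MICA)) factor down-weights pairs whose only shared
ancestry is near the root, which is what makes the measure usable both for
redundancy reduction (REVIGO-style) and for scoring how *contrasting* a
healthy/disease term pair is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import log as ln
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

log = logging.getLogger(__name__)

DEFAULT_NAMESPACE = "biological_process"
DEFAULT_SIM_CUTOFF = 0.5


@dataclass
class OntologyGraph:
    """A GO DAG (edges child → parent) with propagated annotation counts."""

    graph: nx.DiGraph
    alt_ids: dict[str, str] = field(default_factory=dict)
    gene_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    total_annotated: int = 0

    # -- structure ---------------------------------------------------------

    def canonical(self, term: str) -> str:
        return self.alt_ids.get(term, term)

    def __contains__(self, term: str) -> bool:
        return self.canonical(term) in self.graph

    def name_of(self, term: str) -> str:
        return self.graph.nodes[self.canonical(term)].get("name", "")

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including itself (true-path closure)."""
        term = self.canonical(term)
        return frozenset(nx.descendants(self.graph, term)) | {term}

    # -- annotation --------------------------------------------------------

    @property
    def annotated(self) -> bool:
        return self.total_annotated > 0

    def annotation_count(self, term: str) -> int:
        return len(self.gene_sets.get(self.canonical(term), frozenset()))

    def p(self, term: str) -> float:
        if not self.annotated:
            raise ValueError("ontology has no annotations; propagate first")
        return self.annotation_count(term) / self.total_annotated

    def ic(self, term: str) -> float:
        return information_content(self, term)


def parse_obo(
    path: str | Path,
    namespace: str | None = DEFAULT_NAMESPACE,
    include_part_of: bool = True,
) -> OntologyGraph:
    """Parse an OBO 1.2 file into an unannotated :class:`OntologyGraph`.

    Obsolete terms are dropped, ``alt_id`` entries are mapped onto their
    canonical id, and only ``is_a`` (plus, by default, ``part_of``) edges
    are retained. A cycle is an error.
    """
    multigraph = obonet.read_obo(str(path), ignore_obsolete=True)
    keep_relations = {"is_a"} | ({"part_of"} if include_part_of else set())
    g = nx.DiGraph()
    alt_ids: dict[str, str] = {}
    for node, data in multigraph.nodes(data=True):
        if namespace and data.get("namespace", namespace) != namespace:
            continue
        g.add_node(node, name=data.get("name", ""),
                   namespace=data.get("namespace", ""))
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    for child, parent, key in multigraph.edges(keys=True):
        if key in keep_relations and child in g and parent in g:
            g.add_edge(child, parent, relation=key)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    return OntologyGraph(graph=g, alt_ids=alt_ids)


def propagate_annotations(
    onto: OntologyGraph,
    gene_term_pairs: Iterable[tuple[str, str]] | Mapping[str, Iterable[str]],
) -> OntologyGraph:
    """Apply the true-path rule: a gene annotated to t counts for t and all
    its ancestors, each distinct gene once per term.

    Annotations to unknown terms are skipped with a warning. Returns the
    same graph object, annotated in place.
    """
    if isinstance(gene_term_pairs, Mapping):
        pairs = [(g, t) for g, ts in gene_term_pairs.items() for t in ts]
    else:
        pairs = list(gene_term_pairs)
    sets: dict[str, set[str]] = {}
    genes: set[str] = set()
    n_skipped = 0
    for gene, term in pairs:
        term = onto.canonical(term)
        if term not in onto.graph:
            n_skipped += 1
            continue
        genes.add(gene)
        for anc in onto.ancestors(term):
            sets.setdefault(anc, set()).add(gene)
    if n_skipped:
        log.warning("skipped %d annotation(s) to unknown terms", n_skipped)
    onto.gene_sets = {t: frozenset(s) for t, s in sets.items()}
    onto.total_annotated = len(genes)
    return onto


def information_content(onto: OntologyGraph, term: str) -> float:
    """IC(t) = -ln(annotation frequency); 0 at the root, larger = more specific."""
    term = onto.canonical(term)
    count = onto.annotation_count(term)
    if count == 0:
        raise ValueError(f"term {term} has no annotations; IC undefined")
    if count == onto.total_annotated:
        return 0.0  # avoid -0.0 from -ln(1)
    return -ln(count / onto.total_annotated)


@dataclass(frozen=True)
class TermSimilarity:
    term_a: str
    term_b: str
    score: float


def relevance_similarity(onto: OntologyGraph, t1: str, t2: str) -> TermSimilarity:
    """Schlicker Relevance / SimRel similarity of two annotated terms."""
    a, b = onto.canonical(t1), onto.canonical(t2)
    common = onto.ancestors(a) & onto.ancestors(b)
    common = {t for t in common if onto.annotation_count(t) > 0}
    if not common:
        return TermSimilarity(t1, t2, 0.0)
    mica = max(common, key=lambda t: (onto.ic(t), t))
    denom = onto.ic(a) + onto.ic(b)
    if denom == 0:
        return TermSimilarity(t1, t2, 0.0)
    score = (2.0 * onto.ic(mica) / denom) * (1.0 - onto.p(mica))
    return TermSimilarity(t1, t2, score + 0.0)


def reduce_redundancy(
    onto: OntologyGraph,
    terms: Iterable[str],
    cutoff: float = DEFAULT_SIM_CUTOFF,
) -> tuple[list[str], dict[str, str]]:
    """Greedy REVIGO-style redundancy reduction of a term list.

    Repeatedly takes the remaining pair with the highest Relevance score
    >= ``cutoff`` and removes the member with the lower IC (ties remove the
    lexicographically larger id), recording removed → surviving
    representative. Survivors end up with all pairwise scores < cutoff.
    Deterministic given the input set (order-independent).
    """
    unique = sorted(set(onto.canonical(t) for t in terms))
    removed_to_rep: dict[str, str] = {}
    # duplicates in the input collapse onto their canonical/unique form
    for t in terms:
        ct = onto.canonical(t)
        if ct != t:
            removed_to_rep[t] = ct
    sims = {
        (a, b): relevance_similarity(onto, a, b).score
        for i, a in enumerate(unique) for b in unique[i + 1:]
    }
    alive = set(unique)
    while True:
        candidates = [
            (s, a, b) for (a, b), s in sims.items()
            if s >= cutoff and a in alive and b in alive
        ]
        if not candidates:
            break
        s, a, b = max(candidates, key=lambda c: (c[0], c[1], c[2]))
        ic_a, ic_b = onto.ic(a), onto.ic(b)
        if ic_a > ic_b:
            keep, drop = a, b
        elif ic_b > ic_a:
            keep, drop = b, a
        else:  # equal IC: remove the lexicographically larger id
            keep, drop = min(a, b), max(a, b)
        alive.discard(drop)
        removed_to_rep[drop] = keep
    # chase chains so every removed term maps to a surviving representative
    def resolve(t: str) -> str:
        while t in removed_to_rep:
            t = removed_to_rep[t]
        return t

    removed_to_rep = {t: resolve(rep) for t, rep in removed_to_rep.items()}
    survivors = sorted(alive)
    return survivors, removed_to_rep
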