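"""Gene Ontology handling and topological-clustering semantic similarity.

Interacting proteins tend to share cellular component, biological process
and molecular function annotations.  The similarity measure implemented
here first normalizes the ontology topology: every term gets a *topology*
information content ICT(t) = -ln(|descendants(t) + t| / |namespace|), and
the namespace DAG is cut at the frontier of terms whose ICT meets a
per-ontology cutoff.  Each frontier term roots a sub-graph of its
descendants; the frontier terms together with everything above them form
a meta-graph.  Within each (sub- or meta-) graph, terms are scored by
annotation-frequency information content normalized by the graph maximum,
so scores are comparable between general and specific regions of the
ontology.  The similarity of two terms is the normalized IC of their most
informative common ancestor, evaluated in a sub-graph containing both
when one exists and otherwise in the meta-graph via the terms' sub-graph
roots.  The protein-pair score aggregates over the annotated term pairs
(maximum by default).

The per-ontology cutoffs used for the cellular component, biological
process and molecular function scores are 2.4, 3.5 and 3.3 respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .errors import EmptyOntology, MissingAnnotation, UnknownTerm

#: Topology-IC cutoffs per namespace: cellular_component, biological_process,
#: molecular_function.
DEFAULT_CUTOFFS = {
    "cellular_component": 2.4,
    "biological_process": 3.5,
    "molecular_function": 3.3,
}


@dataclass
class GoDag:
    """A directed acyclic graph of ontology terms.

    ``edges`` are child -> parent links; ``is_a`` and ``part_of`` are
    treated identically.  Each namespace is a rooted DAG and namespaces
    share no edges.
    """

    graph: nx.DiGraph
    namespace: dict           # term -> namespace name
    roots: dict               # namespace name -> root term

    @classmethod
    def from_edges(cls, terms, edges, namespace):
        """Build and validate a DAG.

        Parameters
        ----------
        terms : iterable of term ids
        edges : iterable of (child, parent)
        namespace : mapping term -> namespace name
        """
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        for child, parent in edges:
            if namespace[child] != namespace[parent]:
                raise ValueError(
                    f"cross-namespace edge {child} -> {parent}"
                )
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology graph contains a cycle")
        roots = {}
        for t in g.nodes:
            if g.out_degree(t) == 0:
                ns = namespace[t]
                if ns in roots:
                    raise ValueError(f"namespace {ns} has multiple roots")
                roots[ns] = t
        for t in g.nodes:
            ns = namespace[t]
            if t != roots[ns] and not nx.has_path(g, t, roots[ns]):
                raise ValueError(f"term {t} does not reach root of {ns}")
        return cls(graph=g, namespace=dict(namespace), roots=roots)

    def terms_in_namespace(self, ns):
        return {t for t in self.graph.nodes if self.namespace[t] == ns}

    def ancestors(self, term):
        """Term plus all its ancestors (towards the root)."""
        return {term} | nx.descendants(self.graph, term)

    def descendants(self, term):
        """Term plus all its descendants (towards the leaves)."""
        return {term} | nx.ancestors(self.graph, term)


@dataclass
class AnnotationSet:
    """Direct protein -> term annotations.

    Propagation to ancestors happens inside the similarity computation
    (the true-path rule), never in storage.
    """

    by_protein: dict = field(default_factory=dict)  # protein -> set of terms

    def add(self, protein, term):
        self.by_protein.setdefault(protein, set()).add(term)

    def terms_for(self, protein, dag: GoDag, ns):
        terms = self.by_protein.get(protein, set())
        return {t for t in terms if dag.namespace.get(t) == ns}

    def proteins(self):
        return set(self.by_protein)


def topology_information_content(dag: GoDag, ns) -> dict:
    """ICT(t) = -ln(|descendants(t) union {t}| / |namespace terms|).

    The root scores 0 (everything descends from it); leaves score the
    namespace maximum ln(|namespace|).
    """
    terms = dag.terms_in_namespace(ns)
    if not terms:
        raise EmptyOntology(f"namespace {ns!r} has no terms")
    total = len(terms)
    return {t: -math.log(len(dag.descendants(t)) / total) for t in terms}


class TcssScorer:
    """Precomputed similarity scorer for one namespace and cutoff.

    Builds the topology cut, the annotation-count propagation and the
    per-graph normalized IC tables once; ``similarity(a, b)`` then only
    looks up term pairs.
    """

    def __init__(self, dag: GoDag, annotations: AnnotationSet, ns,
                 cutoff: float, aggregate: str = "max"):
        if cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if aggregate not in ("max", "bma"):
            raise ValueError("aggregate must be 'max' or 'bma'")
        self.dag = dag
        self.annotations = annotations
        self.ns = ns
        self.cutoff = cutoff
        self.aggregate = aggregate
        self._build()

    # --- construction ----------------------------------------------------

    def _build(self):
        dag, ns = self.dag, self.ns
        terms = dag.terms_in_namespace(ns)
        ict = topology_information_content(dag, ns)

        # frontier: terms meeting the cutoff with no ancestor meeting it
        frontier = set()
        for t in terms:
            if ict[t] < self.cutoff:
                continue
            above = dag.ancestors(t) - {t}
            if all(ict[u] < self.cutoff for u in above):
                frontier.add(t)
        # a term below the frontier belongs to the sub-graph of every
        # frontier ancestor (overlaps are allowed; scoring takes the max)
        self.subgraphs = {r: dag.descendants(r) & terms for r in frontier}
        self.meta_terms = {t for t in terms if ict[t] < self.cutoff} | frontier
        self.roots_of = {}
        for t in terms:
            anc = dag.ancestors(t)
            self.roots_of[t] = {r for r in frontier if r in anc}

        # annotation counts propagated by the true-path rule
        counts = {t: 0 for t in terms}
        annotated_proteins = 0
        for protein in self.annotations.proteins():
            direct = self.annotations.terms_for(protein, dag, ns)
            if not direct:
                continue
            annotated_proteins += 1
            covered = set()
            for t in direct:
                covered |= dag.ancestors(t)
            for t in covered & terms:
                counts[t] += 1
        if annotated_proteins == 0:
            raise MissingAnnotation(f"no protein annotated in {ns}")
        self.counts = counts
        self.total = annotated_proteins
        self.ic = {
            t: -math.log(counts[t] / annotated_proteins)
            for t in terms if counts[t] > 0
        }

        # per-graph normalization tables
        self._norm = {}
        for root, members in self.subgraphs.items():
            self._norm[root] = self._normalize(members)
        self._norm["__meta__"] = self._normalize(self.meta_terms)

    def _normalize(self, members):
        ics = {t: self.ic[t] for t in members if t in self.ic}
        if not ics:
            return {}
        mx = max(ics.values())
        if mx <= 0:
            return {t: 0.0 for t in ics}
        return {t: v / mx for t, v in ics.items()}

    # --- term-pair similarity --------------------------------------------

    def term_similarity(self, t1, t2) -> float:
        dag = self.dag
        for t in (t1, t2):
            if t not in dag.graph:
                raise UnknownTerm(f"term {t!r} absent from ontology")
        common = dag.ancestors(t1) & dag.ancestors(t2)

        # graphs containing both terms
        best = None
        for root, members in self.subgraphs.items():
            if t1 in members and t2 in members:
                table = self._norm[root]
                vals = [table[a] for a in common & members if a in table]
                if vals:
                    v = max(vals)
                    best = v if best is None else max(best, v)
        if best is not None:
            return min(best, 1.0)

        # fall back to the meta-graph through the sub-graph roots
        reps1 = (self.roots_of[t1] or {t1}) & self.meta_terms or {t1}
        reps2 = (self.roots_of[t2] or {t2}) & self.meta_terms or {t2}
        table = self._norm["__meta__"]
        best = 0.0
        for r1 in reps1:
            for r2 in reps2:
                common_meta = (dag.ancestors(r1) & dag.ancestors(r2)
                               & self.meta_terms)
                vals = [table[a] for a in common_meta if a in table]
                if vals:
                    best = max(best, max(vals))
        return min(best, 1.0)

    # --- protein-pair similarity ------------------------------------------

    def similarity(self, a, b) -> float:
        terms_a = self.annotations.terms_for(a, self.dag, self.ns)
        terms_b = self.annotations.terms_for(b, self.dag, self.ns)
        if not terms_a or not terms_b:
            raise MissingAnnotation(
                f"{a if not terms_a else b} has no {self.ns} annotation"
            )
        sims = {
            (t1, t2): self.term_similarity(t1, t2)
            for t1 in terms_a for t2 in terms_b
        }
        if self.aggregate == "max":
            return max(sims.values())
        # best-match average, symmetrized
        row = sum(max(sims[(t1, t2)] for t2 in terms_b) for t1 in terms_a)
        col = sum(max(sims[(t1, t2)] for t1 in terms_a) for t2 in terms_b)
        return (row / len(terms_a) + col / len(terms_b)) / 2


def tcss_similarity(a, b, dag: GoDag, annotations: AnnotationSet, ns,
                    cutoff: float, aggregate: str = "max") -> float:
    """Semantic similarity of two proteins in one namespace (see module
    docstring).  Convenience wrapper building a :class:`TcssScorer` per
    call; reuse the scorer for batch work."""
    return TcssScorer(dag, annotations, ns, cutoff, aggregate).similarity(a, b)
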