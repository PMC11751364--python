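"""Gene Ontology handling: DAG parsing, annotation propagation, label
vocabularies, information content, and hierarchical score consistency.

The GO graph is reduced to its ``is_a`` skeleton: annotation propagation
and parent/child score consistency both operate on ``is_a`` edges only,
within a single namespace (BP, CC or MF). The three namespace roots are
treated specially — they are removed from propagated annotation sets on
request and never enter a label vocabulary, following CAFA assessment
practice.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: canonical namespace root terms of the Gene Ontology
NAMESPACE_ROOTS = {
    "biological_process": "GO:0008150",
    "cellular_component": "GO:0005575",
    "molecular_function": "GO:0003674",
}

#: short namespace codes used throughout the package
NAMESPACE_CODES = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}
CODE_TO_NAMESPACE = {v: k for k, v in NAMESPACE_CODES.items()}


class OboParseError(ValueError):
    """Raised when an OBO document is malformed."""


class OntologyValidationError(ValueError):
    """Raised when a parsed graph violates GO structural invariants."""


@dataclass
class GoDag:
    """The ``is_a`` skeleton of the Gene Ontology.

    Attributes
    ----------
    terms:
        All primary (non-obsolete) term identifiers.
    is_a_parents:
        Map from term to its direct ``is_a`` parents. Roots map to the
        empty set.
    namespace:
        Map from term to its namespace code (``BP``/``CC``/``MF``).
    roots:
        The namespace root terms present in this DAG.
    alt_ids:
        Map from secondary (alt) identifier to primary identifier.
    """

    terms: Set[str]
    is_a_parents: Dict[str, Set[str]]
    namespace: Dict[str, str]
    roots: Set[str]
    alt_ids: Dict[str, str] = field(default_factory=dict)
    _children: Optional[Dict[str, Set[str]]] = field(default=None, repr=False)

    def resolve(self, term: str) -> str:
        """Map an alt_id to its primary id; primary ids pass through."""
        if term in self.terms:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise KeyError(f"unknown GO term: {term}")

    def __contains__(self, term: str) -> bool:
        return term in self.terms or term in self.alt_ids

    def parents(self, term: str) -> Set[str]:
        return self.is_a_parents.get(term, set())

    def children_map(self) -> Dict[str, Set[str]]:
        """Direct ``is_a`` children of every term (cached)."""
        if self._children is None:
            children: Dict[str, Set[str]] = {t: set() for t in self.terms}
            for child, parents in self.is_a_parents.items():
                for p in parents:
                    children[p].add(child)
            self._children = children
        return self._children

    def ancestors(self, term: str) -> Set[str]:
        """All ``is_a`` ancestors of ``term`` (excluding the term itself)."""
        term = self.resolve(term)
        out: Set[str] = set()
        stack = list(self.is_a_parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.is_a_parents.get(t, ()))
        return out


@dataclass
class AnnotationSet:
    """Protein → GO-term assignments, optionally closed under ``is_a``."""

    assignments: Dict[str, Set[str]]
    propagated: bool = False
    roots_excluded: bool = False

    def proteins(self) -> List[str]:
        return list(self.assignments)

    def restrict_namespace(self, dag: GoDag, code: str) -> "AnnotationSet":
        """Keep only terms of one namespace (by code, e.g. ``MF``)."""
        sub = {
            p: {t for t in ts if dag.namespace.get(t) == code}
            for p, ts in self.assignments.items()
        }
        return AnnotationSet(sub, self.propagated, self.roots_excluded)


@dataclass
class LabelVocabulary:
    """Ordered label set of one namespace, the model's output columns."""

    ontology: str
    terms: List[str]
    index: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.terms:
                fh.write(t + "\n")

    @classmethod
    def load(cls, path, ontology: str) -> "LabelVocabulary":
        with open(path) as fh:
            terms = [line.strip() for line in fh if line.strip()]
        return cls(ontology=ontology, terms=terms)


# ---------------------------------------------------------------------------
# OBO parsing
# ---------------------------------------------------------------------------

def _prescan_obo(text: str) -> None:
    """Line-level sanity scan giving the diagnostics obonet does not.

    Every non-blank line must be a stanza header ``[Name]`` or a
    ``key: value`` tag line.
    """
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("!"):
            continue
        if s.startswith("[") and s.endswith("]"):
            continue
        if ":" not in s:
            raise OboParseError(
                f"malformed OBO line {lineno}: expected 'key: value', got {line!r}"
            )


def parse_obo(obo_text: str) -> GoDag:
    """Parse an OBO 1.2/1.4 document into a :class:`GoDag`.

    Only ``is_a`` edges are retained; other relationship types
    (``part_of``, ``regulates`` ...) are dropped. Obsolete terms are
    removed and ``alt_id`` aliases are recorded so lookups of secondary
    ids resolve to the primary term.

    Raises
    ------
    OboParseError
        If a line is not a stanza header or tag line (the message names
        the line number).
    OntologyValidationError
        If the retained ``is_a`` graph contains a cycle.
    """
    _prescan_obo(obo_text)
    graph = obonet.read_obo(io.StringIO(obo_text))

    terms: Set[str] = set()
    parents: Dict[str, Set[str]] = {}
    namespace: Dict[str, str] = {}
    alt_ids: Dict[str, str] = {}

    for node, data in graph.nodes(data=True):
        terms.add(node)
        parents[node] = set()
        ns = data.get("namespace")
        if ns in NAMESPACE_CODES:
            namespace[node] = NAMESPACE_CODES[ns]
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node

    # obonet edges run child -> parent keyed by relationship type
    isa = nx.DiGraph()
    isa.add_nodes_from(terms)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
            isa.add_edge(child, parent)

    if not nx.is_directed_acyclic_graph(isa):
        cycle = nx.find_cycle(isa)
        raise OntologyValidationError(f"cyclic is_a relationship: {cycle}")

    roots = {t for t in terms if t in NAMESPACE_ROOTS.values()}
    # terms without parents that are not canonical roots still act as
    # local roots of their namespace (common in sub-ontology extracts)
    return GoDag(
        terms=terms,
        is_a_parents=parents,
        namespace=namespace,
        roots=roots,
        alt_ids=alt_ids,
    )


# ---------------------------------------------------------------------------
# Annotation propagation
# ---------------------------------------------------------------------------

def propagate(
    annos: AnnotationSet, dag: GoDag, exclude_roots: bool = True
) -> AnnotationSet:
    """Close every protein's annotation set under ``is_a`` ancestry.

    Annotating a term implies all of its more general ancestors. When
    ``exclude_roots`` the three namespace roots are removed from the
    closed sets (CAFA practice). The operation is idempotent.

    Raises
    ------
    KeyError
        If any annotated term (after alt_id resolution) is absent from
        the DAG; the message lists the offending ids.
    """
    unknown = sorted(
        {t for ts in annos.assignments.values() for t in ts if t not in dag}
    )
    if unknown:
        raise KeyError(f"annotated terms absent from the ontology: {unknown}")

    closure_cache: Dict[str, Set[str]] = {}

    def closure(term: str) -> Set[str]:
        term = dag.resolve(term)
        if term not in closure_cache:
            closure_cache[term] = {term} | dag.ancestors(term)
        return closure_cache[term]

    out: Dict[str, Set[str]] = {}
    for protein, ts in annos.assignments.items():
        closed: Set[str] = set()
        for t in ts:
            closed |= closure(t)
        if exclude_roots:
            closed -= dag.roots
        out[protein] = closed
    return AnnotationSet(out, propagated=True, roots_excluded=exclude_roots)


def build_vocabulary(
    train_annos: AnnotationSet,
    dag: GoDag,
    ontology: str,
    min_count: int = 200,
) -> LabelVocabulary:
    """Build the label vocabulary of one namespace from training data.

    Keeps the terms of the requested namespace annotating at least
    ``min_count`` training proteins (boundary inclusive), excludes the
    namespace roots, and orders terms lexicographically by GO id so the
    model's output columns are reproducible.
    """
    if not train_annos.propagated:
        raise ValueError("build_vocabulary requires propagated annotations")
    counts: Dict[str, int] = {}
    for ts in train_annos.assignments.values():
        for t in ts:
            counts[t] = counts.get(t, 0) + 1
    kept = sorted(
        t
        for t, c in counts.items()
        if c >= min_count
        and dag.namespace.get(t) == ontology
        and t not in dag.roots
    )
    if not kept:
        raise ValueError(
            f"empty {ontology} vocabulary at min_count={min_count}; "
            "lower min_count or add training annotations"
        )
    return LabelVocabulary(ontology=ontology, terms=kept)


def information_content(term: str, train_annos: AnnotationSet) -> float:
    """Information content of a term: −log2 of its training frequency.

    The frequency f(l) is the fraction of training proteins annotated
    with ``l``; rarer terms carry more information. Undefined (raises)
    when no training protein carries the term.
    """
    n = len(train_annos.assignments)
    if n == 0:
        raise ValueError("empty annotation set")
    k = sum(1 for ts in train_annos.assignments.values() if term in ts)
    if k == 0:
        raise ValueError(f"term {term} annotates no training protein; IC undefined")
    return -math.log2(k / n)


def up_propagate_scores(scores, dag: GoDag):
    """Enforce parent ≥ child on prediction scores within the vocabulary.

    Each term's score is raised to the maximum over itself and all of its
    in-vocabulary ``is_a`` descendants (computed bottom-up to the fixed
    point). Scores only ever increase; the operation is idempotent.

    Parameters
    ----------
    scores:
        A :class:`~contextgo.context_model.ScoreMatrix`.
    dag:
        The full ontology; vocabulary terms must form a sub-DAG of it.
    """
    import numpy as np

    vocab = scores.terms
    m = len(vocab)
    # direct is_a edges restricted to the vocabulary
    child_cols: List[List[int]] = [[] for _ in range(m)]
    for j, term in enumerate(vocab.terms):
        for c in dag.children_map().get(term, ()):
            if c in vocab:
                child_cols[j].append(vocab.index[c])

    # topological order of the vocabulary sub-DAG, leaves first
    sub = nx.DiGraph()
    sub.add_nodes_from(range(m))
    for j, cols in enumerate(child_cols):
        for c in cols:
            sub.add_edge(c, j)  # child -> parent
    order = list(nx.topological_sort(sub))

    mat = scores.scores.copy()
    for j in order:
        if child_cols[j]:
            best_child = np.max(mat[:, child_cols[j]], axis=1)
            np.maximum(mat[:, j], best_child, out=mat[:, j])
    return scores.with_scores(mat)


def read_annotations(path_or_text, dag: Optional[GoDag] = None) -> AnnotationSet:
    """Read a 2-column TSV (protein_id, GO id); '#' comment lines allowed.

    When a DAG is given, alt_ids are resolved to primary ids.
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        try:
            with open(path_or_text) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = str(path_or_text)
    assignments: Dict[str, Set[str]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split("\t")
        if len(parts) < 2:
            raise ValueError(
                f"annotation line {lineno}: expected 'protein<TAB>GO id', got {line!r}"
            )
        protein, term = parts[0], parts[1]
        if term == "go_term" and protein == "protein_id":
            continue  # header
        if dag is not None and term in dag:
            term = dag.resolve(term)
        assignments.setdefault(protein, set()).add(term)
    return AnnotationSet(assignments)


def write_annotations(annos: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tgo_term\n")
        for protein in sorted(annos.assignments):
            for term in sorted(annos.assignments[protein]):
                fh.write(f"{protein}\t{term}\n")
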