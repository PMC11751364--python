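"""Dataset construction: genus filtering by annotation rate, an
all-vs-all protein similarity graph, Markov clustering, and a
leakage-aware train/validation/test split.

Putting whole sequence-similarity clusters on one side of the
train/held-out boundary prevents near-duplicate proteins from leaking
between training and evaluation. The held-out pool is then halved into
validation and test while balancing per-GO-term protein counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .hybrid import DiamondHitTable
from .ontology import AnnotationSet

logger = logging.getLogger(__name__)


@dataclass
class GenusTable:
    """Genus → genomes → ordered proteins membership tables."""

    genus_genomes: Dict[str, List[str]]
    genome_proteins: Dict[str, List[str]]

    def proteins_of_genus(self, genus: str) -> List[str]:
        out: List[str] = []
        for g in self.genus_genomes[genus]:
            out.extend(self.genome_proteins[g])
        return out


@dataclass
class SplitAssignment:
    """protein_id → one of {train, validation, test}."""

    subset: Dict[str, str]

    def members(self, name: str) -> Set[str]:
        return {p for p, s in self.subset.items() if s == name}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_id\tsubset\n")
            for p in sorted(self.subset):
                fh.write(f"{p}\t{self.subset[p]}\n")


# ---------------------------------------------------------------------------
# Annotation-rate genus selection
# ---------------------------------------------------------------------------

def annotation_rate(
    genome_proteins: Sequence[str], annos: AnnotationSet
) -> float:
    """Fraction of a genome's proteins carrying at least one GO term."""
    if not genome_proteins:
        raise ValueError("empty genome")
    annotated = sum(
        1 for p in genome_proteins if annos.assignments.get(p)
    )
    return annotated / len(genome_proteins)


def select_genera(
    table: GenusTable,
    annos: AnnotationSet,
    threshold: float,
) -> List[str]:
    """Genera whose mean genome annotation rate reaches the threshold.

    Single-genome genera are excluded regardless of rate (too little
    material to train on); the threshold is inclusive (logged).
    """
    logger.info(
        "genus selection: mean annotation rate >= %.2f (inclusive), "
        "single-genome genera excluded",
        threshold,
    )
    kept = []
    for genus, genomes in table.genus_genomes.items():
        if len(genomes) < 2:
            continue
        rates = [
            annotation_rate(table.genome_proteins[g], annos) for g in genomes
        ]
        if float(np.mean(rates)) >= threshold:
            kept.append(genus)
    return sorted(kept)


# ---------------------------------------------------------------------------
# Similarity graph
# ---------------------------------------------------------------------------

def build_graph(
    hits: DiamondHitTable, max_evalue: float = 0.001
) -> nx.Graph:
    """Undirected similarity graph from an all-vs-all hit table.

    Self-hits are dropped, the e-value filter is applied, and a pair
    aligned in both directions gets the maximum of the two bitscores as
    its edge weight (logged convention).
    """
    df = hits.table
    df = df[(df["evalue"] <= max_evalue) & (df["qseqid"] != df["sseqid"])]
    graph = nx.Graph()
    graph.add_nodes_from(hits.table["qseqid"].unique())
    graph.add_nodes_from(hits.table["sseqid"].unique())
    for q, s, bit in zip(df["qseqid"], df["sseqid"], df["bitscore"]):
        if graph.has_edge(q, s):
            if bit > graph[q][s]["weight"]:
                graph[q][s]["weight"] = float(bit)
        else:
            graph.add_edge(q, s, weight=float(bit))
    logger.info(
        "similarity graph: %d nodes, %d edges (max-bitscore symmetrisation)",
        graph.number_of_nodes(),
        graph.number_of_edges(),
    )
    return graph


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    self_loop: str = "max",
    prune: float = 1e-9,
) -> List[Set[str]]:
    """Markov clustering of a weighted graph.

    The column-stochastic transition matrix alternates *expansion*
    (matrix power, simulating random-walk flow) and *inflation*
    (elementwise power then column renormalisation, sharpening strong
    flows) until the matrix changes by less than ``tol`` or ``max_iter``
    rounds elapse. Clusters are read from the limit matrix: attractor
    rows with positive mass define overlapping node sets that are merged
    into a partition; singletons are allowed.

    Self-loops are added before normalisation (``max``: the node's
    maximum incident edge weight; isolated nodes get weight 1), the
    standard regularisation keeping the iteration well-behaved.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes())
    n = len(nodes)
    if n == 0:
        return []
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        M[idx[u], idx[v]] = w
        M[idx[v], idx[u]] = w
    if self_loop == "max":
        diag = M.max(axis=0)
        diag[diag == 0] = 1.0
        np.fill_diagonal(M, diag)
    M = M / M.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        last = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.abs(M - last).max() < tol:
            break

    # attractors: rows with positive diagonal mass; each attractor row
    # claims the columns it feeds; overlapping claims merge
    support = nx.Graph()
    support.add_nodes_from(range(n))
    attractors = [i for i in range(n) if M[i, i] > tol]
    for i in attractors:
        for j in np.nonzero(M[i] > tol)[0]:
            support.add_edge(i, j)
    clusters = [
        {nodes[i] for i in comp} for comp in nx.connected_components(support)
    ]
    clusters.sort(key=lambda c: sorted(c)[0])
    return clusters


# ---------------------------------------------------------------------------
# Leakage-aware split
# ---------------------------------------------------------------------------

def split(
    clusters: Sequence[Set[str]],
    annos: Optional[AnnotationSet] = None,
    target_train_fraction: float = 0.8,
    seed: int = 0,
) -> SplitAssignment:
    """Cluster-level train/validation/test split.

    Clusters are drawn in seeded random order into the training set
    until the cumulative protein count reaches the target fraction
    (stopping as soon as cumulative ≥ target, so train ≥ target is
    guaranteed while the held-out pool stays nonempty whenever the
    boundary allows; logged convention). Remaining proteins are halved
    into validation and test: proteins are grouped by their exact
    annotation signature and alternately assigned within each group, in
    seeded order, so per-term counts stay balanced.
    """
    clusters = [set(c) for c in clusters]
    if len(clusters) < 3:
        raise ValueError("need at least 3 clusters to form 3 disjoint sets")
    total = sum(len(c) for c in clusters)
    target = target_train_fraction * total
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clusters))

    logger.info(
        "split: adding clusters until cumulative count >= %.0f%% of %d "
        "proteins (inclusive stop)",
        100 * target_train_fraction,
        total,
    )
    assignment: Dict[str, str] = {}
    cum = 0
    heldout: List[str] = []
    for k, ci in enumerate(order):
        if cum >= target:
            heldout.extend(sorted(clusters[ci]))
            continue
        for p in clusters[ci]:
            assignment[p] = "train"
        cum += len(clusters[ci])
    if not heldout:
        raise ValueError(
            "no proteins left for validation/test; lower "
            "target_train_fraction or refine clustering"
        )

    # greedy per-signature alternating halving of the held-out pool
    groups: Dict[Tuple[str, ...], List[str]] = {}
    for p in heldout:
        sig: Tuple[str, ...] = ()
        if annos is not None:
            sig = tuple(sorted(annos.assignments.get(p, ())))
        groups.setdefault(sig, []).append(p)
    flip = 0
    for sig in sorted(groups):
        members = groups[sig]
        rng.shuffle(members)
        for i, p in enumerate(members):
            assignment[p] = "validation" if (i + flip) % 2 == 0 else "test"
        flip += len(members)  # keep overall sizes balanced across groups
    return SplitAssignment(assignment)


def check_no_leakage(
    clusters: Sequence[Set[str]], assignment: SplitAssignment
) -> bool:
    """True iff no cluster spans train and the held-out pool."""
    for c in clusters:
        sides = {
            "train" if assignment.subset[p] == "train" else "heldout"
            for p in c
        }
        if len(sides) > 1:
            return False
    return True
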