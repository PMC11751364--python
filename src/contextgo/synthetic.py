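"""Self-contained synthetic corpus with a planted genomic-context signal.

The generator emulates the statistical structure the real pipeline
consumes: a small GO DAG with ``is_a`` edges and imbalanced term
frequencies; genera of genomes that share a conserved function order
(phage genomes of one genus keep their gene arrangement); pooled
protein vectors drawn around per-function centroids; and — the planted
signal — a κ-fraction of proteins whose own vector is an uninformative
background draw while their true function is determined by their
position in the genus's conserved order, hence recoverable only from
the neighbouring proteins. A single-protein classifier is blind to
these; a context model is not.

All randomness flows from one seed through named child generators, so a
corpus is bitwise reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .context_model import GenomeSentence
from .ontology import (
    NAMESPACE_ROOTS,
    AnnotationSet,
    GoDag,
    propagate,
    write_annotations,
)

logger = logging.getLogger(__name__)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic corpus.

    ``context_strength`` κ is the fraction of protein slots per genome
    whose vector is uninformative background; ``label_imbalance`` is the
    power-law exponent of the class frequency distribution (0 → uniform);
    ``noise_sigma`` is the per-coordinate Gaussian noise around class
    centroids.
    """

    n_genera: int = 6
    genomes_per_genus: int = 10
    proteins_per_genome: int = 10
    d_e: int = 32
    n_terms: int = 12
    dag_depth: int = 3
    context_strength: float = 0.5
    label_imbalance: float = 1.0
    noise_sigma: float = 0.25
    shuffle_prob: float = 0.05
    namespace: str = "MF"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.context_strength <= 1.0:
            raise ValueError("context_strength must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if min(
            self.n_genera,
            self.genomes_per_genus,
            self.proteins_per_genome,
            self.d_e,
            self.n_terms,
        ) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_terms < self.dag_depth:
            raise ValueError("n_terms must be >= dag_depth")


def _term_id(k: int) -> str:
    return f"GO:9{k:06d}"


def make_dag(config: SyntheticConfig) -> Tuple[GoDag, Dict[str, float]]:
    """Random layered DAG plus power-law class frequency targets.

    ``n_terms`` terms are spread over ``dag_depth`` layers under the
    configured namespace root; each term gets one or two parents from
    the layer above. The terms of the deepest layer are the *classes*
    proteins are drawn from; their target frequencies follow
    f(c) ∝ (c+1)^(−label_imbalance).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 101]).generate_state(1)[0]
    )
    ns_code = config.namespace
    ns_long = {v: k for k, v in {
        "biological_process": "BP",
        "cellular_component": "CC",
        "molecular_function": "MF",
    }.items()}[ns_code]
    root = NAMESPACE_ROOTS[ns_long]

    depth = config.dag_depth
    base, extra = divmod(config.n_terms, depth)
    layer_sizes = [base + (1 if i < extra else 0) for i in range(depth)]
    if any(s == 0 for s in layer_sizes):
        raise ValueError("infeasible layering: a layer would be empty")

    terms: Set[str] = set(NAMESPACE_ROOTS.values())
    parents: Dict[str, Set[str]] = {t: set() for t in terms}
    namespace: Dict[str, str] = {
        NAMESPACE_ROOTS["biological_process"]: "BP",
        NAMESPACE_ROOTS["cellular_component"]: "CC",
        NAMESPACE_ROOTS["molecular_function"]: "MF",
    }

    layers: List[List[str]] = []
    k = 0
    for li, size in enumerate(layer_sizes):
        layer = []
        above = layers[li - 1] if li > 0 else [root]
        for _ in range(size):
            t = _term_id(k)
            k += 1
            n_par = 1 if len(above) == 1 else int(rng.integers(1, 3))
            chosen = rng.choice(len(above), size=min(n_par, len(above)), replace=False)
            parents[t] = {above[int(c)] for c in chosen}
            namespace[t] = ns_code
            terms.add(t)
            layer.append(t)
        layers.append(layer)

    classes = layers[-1]
    ranks = np.arange(1, len(classes) + 1, dtype=float)
    w = ranks ** (-config.label_imbalance)
    freqs = {c: float(x) for c, x in zip(classes, w / w.sum())}
    dag = GoDag(
        terms=terms,
        is_a_parents=parents,
        namespace=namespace,
        roots=set(NAMESPACE_ROOTS.values()),
    )
    return dag, freqs


@dataclass
class SyntheticCorpus:
    """A generated corpus: everything the pipeline consumes, in memory."""

    config: SyntheticConfig
    dag: GoDag
    class_terms: List[str]
    class_freqs: np.ndarray
    sentences: List[GenomeSentence]
    order: Dict[str, Tuple[str, int]]
    annotations: AnnotationSet  # propagated, roots excluded
    embeddings: Dict[str, np.ndarray]
    protein_class: Dict[str, int]
    context_only: Set[str]
    genus_of_genome: Dict[str, str]
    sequences: Dict[str, str] = field(default_factory=dict)

    def genomes_of_genus(self, genus: str) -> List[str]:
        return [g for g, gn in self.genus_of_genome.items() if gn == genus]

    def write(self, outdir) -> None:
        """FASTA + order TSV + annotation TSV + OBO, the CLI input set."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .cli_io import write_fasta, write_order_tsv

        write_fasta(
            [(p, self.sequences[p]) for p in sorted(self.sequences)],
            outdir / "proteins.faa",
        )
        write_order_tsv(self.order, outdir / "order.tsv")
        write_annotations(self.annotations, outdir / "annotations.tsv")
        write_obo(self.dag, outdir / "ontology.obo")
        np.savez(
            outdir / "embeddings.npz",
            **{p: v for p, v in self.embeddings.items()},
        )


def _pick_context_slots(
    L: int, count: int, rng: np.random.Generator
) -> List[int]:
    """Seeded choice of context-only slots, avoiding slot 0 and, when
    feasible, adjacency (so most context-only proteins keep an
    informative left neighbour)."""
    candidates = list(range(1, L))
    rng.shuffle(candidates)
    chosen: List[int] = []
    for c in candidates:
        if len(chosen) == count:
            break
        if all(abs(c - x) > 1 for x in chosen):
            chosen.append(c)
    for c in candidates:  # relax adjacency if needed
        if len(chosen) == count:
            break
        if c not in chosen:
            chosen.append(c)
    return sorted(chosen)


def make_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate a corpus under the configured study conditions.

    Each genus draws a canonical function order — ``proteins_per_genome``
    class indices sampled i.i.d. from the power-law distribution — and
    every genome of the genus realises that order, with rare adjacent
    swaps. Informative proteins get ``centroid[class] + N(0, σ²)``
    vectors; context-only proteins (a κ-fraction of slots, conserved
    within the genus) get background ``N(0, σ²)`` vectors while keeping the class
    of their canonical slot, so their label is recoverable only from the
    conserved neighbourhood.
    """
    cfg = config
    ss = np.random.SeedSequence([cfg.seed, 202])
    dag, freq_map = make_dag(cfg)
    class_terms = sorted(freq_map)
    freqs = np.array([freq_map[c] for c in class_terms])
    K = len(class_terms)

    rng_centroid, rng_order, rng_noise, rng_seq = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    centroids = rng_centroid.standard_normal((K, cfg.d_e))

    sentences: List[GenomeSentence] = []
    order: Dict[str, Tuple[str, int]] = {}
    embeddings: Dict[str, np.ndarray] = {}
    protein_class: Dict[str, int] = {}
    context_only: Set[str] = set()
    genus_of_genome: Dict[str, str] = {}
    raw_assignments: Dict[str, Set[str]] = {}
    sequences: Dict[str, str] = {}

    L = cfg.proteins_per_genome
    n_ctx = int(round(cfg.context_strength * L))
    n_ctx = min(n_ctx, L - 1) if L > 1 else 0

    for gi in range(cfg.n_genera):
        genus = f"genus{gi:02d}"
        canonical = rng_order.choice(K, size=L, p=freqs)
        # context-only loci are conserved within a genus, like the
        # recurrently unannotatable loci of real phage genera
        ctx_slots = set(_pick_context_slots(L, n_ctx, rng_order))
        for mi in range(cfg.genomes_per_genus):
            genome = f"{genus}_g{mi:02d}"
            genus_of_genome[genome] = genus
            classes = list(canonical)
            slots = list(range(L))
            # rare adjacent swaps: genus order conserved, not exact
            for i in range(L - 1):
                if rng_order.random() < cfg.shuffle_prob:
                    slots[i], slots[i + 1] = slots[i + 1], slots[i]
            pids = []
            for pos, slot in enumerate(slots):
                pid = f"{genome}_p{pos:02d}"
                cls = int(classes[slot])
                pids.append(pid)
                order[pid] = (genome, pos)
                protein_class[pid] = cls
                noise = cfg.noise_sigma * rng_noise.standard_normal(cfg.d_e)
                if slot in ctx_slots:
                    context_only.add(pid)
                    embeddings[pid] = noise  # background, class-blind
                else:
                    embeddings[pid] = centroids[cls] + noise
                raw_assignments[pid] = {class_terms[cls]}
                length = int(rng_seq.integers(60, 121))
                sequences[pid] = "".join(
                    _AA[i] for i in rng_seq.integers(0, len(_AA), size=length)
                )
            sentences.append(GenomeSentence(genome, pids))

    annos = propagate(
        AnnotationSet(raw_assignments), dag, exclude_roots=True
    )
    return SyntheticCorpus(
        config=cfg,
        dag=dag,
        class_terms=class_terms,
        class_freqs=freqs,
        sentences=sentences,
        order=order,
        annotations=annos,
        embeddings=embeddings,
        protein_class=protein_class,
        context_only=context_only,
        genus_of_genome=genus_of_genome,
        sequences=sequences,
    )


def expected_term_frequencies(corpus: SyntheticCorpus) -> Dict[str, float]:
    """Configured target frequency of every vocabulary term.

    A term's target is the summed class frequency of the classes whose
    propagated annotation contains it.
    """
    targets: Dict[str, float] = {}
    for cls_idx, cls_term in enumerate(corpus.class_terms):
        closure = {cls_term} | corpus.dag.ancestors(cls_term)
        closure -= corpus.dag.roots
        for t in closure:
            targets[t] = targets.get(t, 0.0) + float(
                corpus.class_freqs[cls_idx]
            )
    return {t: min(1.0, p) for t, p in targets.items()}


def run_context_recovery(
    corpus_seed: int = 1,
    model_seed: int = 7,
    context_lengths: Sequence[int] = (1, 2, 10),
    config: SyntheticConfig | None = None,
    epochs: int = 150,
    learning_rate: float = 1e-2,
) -> Dict[int, float]:
    """Desk-scale context-recovery experiment.

    Generates the default corpus (6 genera × 10 genomes × 10 proteins,
    d_e = 32, 12 terms, κ = 0.5), holds out the last two genomes of
    every genus, trains the context model at several maximum context
    lengths under identical hyperparameters, and returns the held-out
    term-centric AUPR per context length. Window length 1 is the
    single-protein ablation; the full sentence length uses the entire
    genome as context.
    """
    from .context_model import ModelConfig, predict, train
    from .metrics import term_centric_aupr
    from .ontology import build_vocabulary

    cfg = config or SyntheticConfig(seed=corpus_seed)
    corpus = make_corpus(cfg)
    vocab = build_vocabulary(corpus.annotations, corpus.dag,
                             cfg.namespace, min_count=1)
    heldout = set()
    for genus in sorted(set(corpus.genus_of_genome.values())):
        heldout.update(sorted(corpus.genomes_of_genus(genus))[-2:])
    train_sents = [s for s in corpus.sentences if s.genome_id not in heldout]
    test_sents = [s for s in corpus.sentences if s.genome_id in heldout]

    results: Dict[int, float] = {}
    for max_len in context_lengths:
        mc = ModelConfig(
            d_e=cfg.d_e,
            n_heads=4,
            n_layers=2,
            max_sentence_len=max_len,
            window_overlap=max(0, min(1, max_len - 1)),
            learning_rate=learning_rate,
            epochs=epochs,
            batch_size=16,
            seed=model_seed,
            ontology=cfg.namespace,
        )
        model, _ = train(
            train_sents, corpus.embeddings, corpus.annotations, vocab, mc
        )
        scores = predict(test_sents, model, corpus.embeddings)
        results[max_len] = term_centric_aupr(scores, corpus.annotations)
    return results


def write_obo(dag: GoDag, path) -> None:
    """Serialise a DAG to a minimal OBO 1.2 document."""
    long_ns = {
        "BP": "biological_process",
        "CC": "cellular_component",
        "MF": "molecular_function",
    }
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for t in sorted(dag.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {t}\n")
            fh.write(f"name: synthetic term {t}\n")
            ns = dag.namespace.get(t)
            if ns:
                fh.write(f"namespace: {long_ns[ns]}\n")
            for p in sorted(dag.is_a_parents.get(t, ())):
                fh.write(f"is_a: {p} ! parent\n")
            fh.write("\n")
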