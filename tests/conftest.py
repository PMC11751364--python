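import numpy as np
import pytest

from contextgo.ontology import AnnotationSet, GoDag, parse_obo
from contextgo.synthetic import SyntheticConfig, make_corpus

CHAIN_OBO = """format-version: 1.2

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0000002
name: b
namespace: molecular_function
is_a: GO:0003674 ! molecular_function

[Term]
id: GO:0000003
name: c
namespace: molecular_function
is_a: GO:0000002 ! b
"""


@pytest.fixture
def chain_dag() -> GoDag:
    """c is_a b is_a root, single namespace."""
    return parse_obo(CHAIN_OBO)


def random_dag(rng: np.random.Generator, n_terms: int) -> GoDag:
    """Random single-namespace DAG rooted at the MF root."""
    root = "GO:0003674"
    terms = {root}
    parents = {root: set()}
    namespace = {root: "MF"}
    ids = [f"GO:{1000 + k:07d}" for k in range(n_terms)]
    pool = [root]
    for t in ids:
        k = int(rng.integers(1, min(3, len(pool)) + 1))
        chosen = rng.choice(len(pool), size=k, replace=False)
        parents[t] = {pool[int(c)] for c in chosen}
        namespace[t] = "MF"
        terms.add(t)
        pool.append(t)
    return GoDag(
        terms=terms,
        is_a_parents=parents,
        namespace=namespace,
        roots={root},
    )


def random_annotations(
    rng: np.random.Generator, dag: GoDag, n_proteins: int
) -> AnnotationSet:
    terms = sorted(dag.terms - dag.roots)
    out = {}
    for i in range(n_proteins):
        k = int(rng.integers(1, 4))
        out[f"p{i}"] = set(
            rng.choice(terms, size=min(k, len(terms)), replace=False)
        )
    return AnnotationSet(out)


@pytest.fixture(scope="session")
def small_corpus():
    """Small seeded corpus shared by read-only tests."""
    return make_corpus(
        SyntheticConfig(
            n_genera=3,
            genomes_per_genus=4,
            proteins_per_genome=6,
            d_e=16,
            n_terms=9,
            seed=11,
        )
    )
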