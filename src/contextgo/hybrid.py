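"""Alignment-based DiamondScore and the convex model/alignment hybrid.

DiamondScore transfers GO annotations from alignment hits: for a query
protein with hits h against annotated training proteins, the score of
term t is the bitscore-weighted fraction of hits whose subject carries
t. The hybrid blends the context model's scores with DiamondScore via a
convex combination S⁺ = β·S_model + (1−β)·S_diamond, with β tuned per
ontology on validation data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .context_model import ScoreMatrix
from .ontology import AnnotationSet, LabelVocabulary

logger = logging.getLogger(__name__)

#: default column order of DIAMOND/BLAST outfmt-6 tabular output
OUTFMT6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass
class DiamondHitTable:
    """Query → subject alignment hits with identity/e-value/bitscore."""

    table: pd.DataFrame  # columns: at least qseqid, sseqid, pident, evalue, bitscore

    def __post_init__(self) -> None:
        needed = {"qseqid", "sseqid", "pident", "evalue", "bitscore"}
        missing = needed - set(self.table.columns)
        if missing:
            raise ValueError(f"hit table missing columns: {sorted(missing)}")
        if (self.table["bitscore"] <= 0).any():
            raise ValueError("bitscore must be positive")
        if (self.table["evalue"] < 0).any():
            raise ValueError("e-value must be non-negative")

    @classmethod
    def read(
        cls,
        path,
        columns: Optional[Sequence[str]] = None,
        max_evalue: Optional[float] = 0.001,
    ) -> "DiamondHitTable":
        """Read a DIAMOND/BLAST tabular file (configurable column order)."""
        cols = list(columns) if columns is not None else OUTFMT6_COLUMNS
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
        if max_evalue is not None:
            df = df[df["evalue"] <= max_evalue].reset_index(drop=True)
        return cls(df)

    def filter_evalue(self, max_evalue: float = 0.001) -> "DiamondHitTable":
        return DiamondHitTable(
            self.table[self.table["evalue"] <= max_evalue].reset_index(
                drop=True
            )
        )

    def best_identity(self) -> Dict[str, float]:
        """Best-hit percent identity per query."""
        if self.table.empty:
            return {}
        return self.table.groupby("qseqid")["pident"].max().to_dict()


def diamond_score(
    hits: DiamondHitTable,
    train_annos: AnnotationSet,
    vocab: LabelVocabulary,
    query_ids: Optional[Sequence[str]] = None,
) -> ScoreMatrix:
    """Bitscore-normalised annotation transfer from alignment hits.

    score(query, t) = Σ_h bitscore(h)·1[t ∈ annos(subject(h))]
                      / Σ_h bitscore(h)

    over the query's hits against annotated training proteins. Hits to
    subjects absent from the training annotations are skipped with a
    warning; queries with no usable hits get an all-zero row.
    """
    if not train_annos.propagated:
        raise ValueError("diamond_score requires propagated training annotations")
    df = hits.table
    known = df["sseqid"].isin(train_annos.assignments.keys())
    n_skipped = int((~known).sum())
    if n_skipped:
        logger.warning(
            "%d hits to subjects without training annotations skipped",
            n_skipped,
        )
    df = df[known]
    if query_ids is None:
        query_ids = sorted(df["qseqid"].unique())
    m = len(vocab)
    scores = np.zeros((len(query_ids), m))
    row_of = {q: i for i, q in enumerate(query_ids)}
    for q, group in df.groupby("qseqid"):
        i = row_of.get(q)
        if i is None:
            continue
        total = group["bitscore"].sum()
        for sseq, bit in zip(group["sseqid"], group["bitscore"]):
            for t in train_annos.assignments[sseq]:
                j = vocab.index.get(t)
                if j is not None:
                    scores[i, j] += bit
        scores[i] /= total
    return ScoreMatrix(list(query_ids), vocab, scores)


def combine(
    s_model: ScoreMatrix, s_diamond: ScoreMatrix, beta: float
) -> ScoreMatrix:
    """Convex combination β·S_model + (1−β)·S_diamond, elementwise."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    if s_model.terms.terms != s_diamond.terms.terms:
        raise ValueError("vocabulary mismatch between score matrices")
    if s_model.protein_ids != s_diamond.protein_ids:
        raise ValueError("protein index mismatch between score matrices")
    return s_model.with_scores(
        beta * s_model.scores + (1.0 - beta) * s_diamond.scores
    )


def tune_beta(
    s_model_val: ScoreMatrix,
    s_diamond_val: ScoreMatrix,
    val_annos: AnnotationSet,
    metric: Optional[Callable[[ScoreMatrix, AnnotationSet], float]] = None,
    grid_step: float = 0.01,
) -> float:
    """Grid-search β on validation data; ties resolve to the smallest β.

    The default criterion is the protein-centric Fmax of the blended
    scores against the validation annotations.
    """
    if not val_annos.assignments:
        raise ValueError("empty validation annotation set")
    if metric is None:
        from .metrics import protein_centric_fmax

        metric = lambda s, a: protein_centric_fmax(s, a)[0]  # noqa: E731
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    best_beta, best_val = 0.0, -np.inf
    for beta in grid:
        val = metric(combine(s_model_val, s_diamond_val, float(beta)), val_annos)
        if val > best_val + 1e-12:
            best_val, best_beta = val, float(beta)
    logger.info("tuned beta = %.2f (validation metric %.4f)", best_beta, best_val)
    return best_beta
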