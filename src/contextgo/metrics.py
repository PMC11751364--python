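"""CAFA-style evaluation: protein-centric and term-centric Fmax and AUPR,
plus stratified reporting by information content and by sequence identity.

Conventions (all logged where exercised):

* a term is "predicted" for a protein at threshold t when its score ≥ t;
* protein-centric precision at t averages only over the n_t proteins
  with at least one prediction; recall averages over all evaluable
  proteins (those with a nonempty truth set);
* micro AUPR concatenates all (protein, term) pairs into one binary
  problem; macro AUPR averages per-label areas, skipping labels with no
  positive;
* term-centric Fmax is the mean of per-label Fmax values over evaluated
  labels (labels without positives are skipped with a warning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import average_precision_score

from .context_model import ScoreMatrix
from .hybrid import DiamondHitTable
from .ontology import AnnotationSet, LabelVocabulary, information_content

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = np.round(np.arange(0.01, 1.001, 0.01), 2)


@dataclass
class EvalReport:
    """Bundle of protein- and term-centric metrics for one ontology."""

    ontology: str
    protein_centric: Dict[str, float] = field(default_factory=dict)
    term_centric: Dict[str, float] = field(default_factory=dict)
    strata: List[Tuple[str, Dict[str, float]]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ontology": self.ontology,
            "protein_centric": self.protein_centric,
            "term_centric": self.term_centric,
            "strata": [
                {"stratum": name, **vals} for name, vals in self.strata
            ],
        }


def _truth_matrix(scores: ScoreMatrix, truth: AnnotationSet) -> np.ndarray:
    """Binary truth matrix aligned to the score matrix's axes."""
    m = len(scores.terms)
    Y = np.zeros((len(scores.protein_ids), m))
    for i, pid in enumerate(scores.protein_ids):
        for t in truth.assignments.get(pid, ()):
            j = scores.terms.index.get(t)
            if j is not None:
                Y[i, j] = 1.0
    return Y


# ---------------------------------------------------------------------------
# Protein-centric metrics
# ---------------------------------------------------------------------------

def protein_centric_fmax(
    scores: ScoreMatrix,
    truth: AnnotationSet,
    thresholds: Optional[Sequence[float]] = None,
) -> Tuple[float, float]:
    """Maximum protein-centric F1 over a threshold sweep.

    At each threshold t, per-protein precision is |P∩T|/|P| and recall
    is |P∩T|/|T|; precision is averaged over the n_t proteins with ≥1
    prediction, recall over all evaluable proteins. Returns
    (fmax, best_threshold); fmax is 0 when no threshold yields any
    prediction (convention, logged).
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    S = scores.scores
    Y = _truth_matrix(scores, truth)
    has_truth = Y.sum(axis=1) > 0
    n_skipped = int((~has_truth).sum())
    if n_skipped:
        logger.warning(
            "%d proteins with empty truth excluded from recall averaging",
            n_skipped,
        )
    if not has_truth.any():
        raise ValueError("no protein with a nonempty truth set")

    fmax, best_t = 0.0, 0.0
    for t in thresholds:
        P = S >= t
        n_pred = P.sum(axis=1)
        covered = n_pred > 0
        n_t = int(covered.sum())
        if n_t == 0:
            continue
        tp = (P & (Y > 0)).sum(axis=1)
        avg_pre = float((tp[covered] / n_pred[covered]).mean())
        avg_rec = float(
            (tp[has_truth] / Y[has_truth].sum(axis=1)).mean()
        )
        if avg_pre + avg_rec > 0:
            f1 = 2 * avg_pre * avg_rec / (avg_pre + avg_rec)
            if f1 > fmax:
                fmax, best_t = f1, float(t)
    if fmax == 0.0:
        logger.warning("no threshold produced predictions; Fmax = 0 by convention")
    return fmax, best_t


def protein_centric_aupr(scores: ScoreMatrix, truth: AnnotationSet) -> float:
    """Micro-averaged AUPR over concatenated (protein, term) pairs."""
    S = scores.scores.ravel()
    Y = _truth_matrix(scores, truth).ravel()
    if Y.sum() == 0:
        raise ValueError("no positive (protein, term) pair in the truth")
    return float(average_precision_score(Y, S))


# ---------------------------------------------------------------------------
# Term-centric metrics
# ---------------------------------------------------------------------------

def term_centric_fmax(
    scores: ScoreMatrix,
    truth: AnnotationSet,
    thresholds: Optional[Sequence[float]] = None,
) -> float:
    """Mean over labels of the per-label maximum F1.

    Per label l and threshold t: precision = TP/(predicted positives),
    recall = TP/(truth positives); the per-label maximum F1 over the
    sweep is averaged over labels with at least one truth positive.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    S = scores.scores
    Y = _truth_matrix(scores, truth)
    fmaxes = []
    skipped = 0
    for j in range(S.shape[1]):
        pos = Y[:, j] > 0
        if not pos.any():
            skipped += 1
            continue
        best = 0.0
        for t in thresholds:
            pred = S[:, j] >= t
            tp = int((pred & pos).sum())
            npred = int(pred.sum())
            if npred == 0:
                continue
            pre = tp / npred
            rec = tp / int(pos.sum())
            if pre + rec > 0:
                best = max(best, 2 * pre * rec / (pre + rec))
        fmaxes.append(best)
    if skipped:
        logger.warning("%d labels without truth positives skipped", skipped)
    if not fmaxes:
        raise ValueError("every label lacks truth positives")
    return float(np.mean(fmaxes))


def term_centric_aupr(scores: ScoreMatrix, truth: AnnotationSet) -> float:
    """Macro-averaged AUPR: mean of per-label PR areas."""
    S = scores.scores
    Y = _truth_matrix(scores, truth)
    areas = []
    for j in range(S.shape[1]):
        if Y[:, j].sum() == 0:
            continue
        areas.append(float(average_precision_score(Y[:, j], S[:, j])))
    if not areas:
        raise ValueError("every label lacks truth positives")
    return float(np.mean(areas))


def evaluate(
    scores: ScoreMatrix,
    truth: AnnotationSet,
    thresholds: Optional[Sequence[float]] = None,
) -> EvalReport:
    """All four headline metrics for one ontology."""
    fmax, best_t = protein_centric_fmax(scores, truth, thresholds)
    report = EvalReport(ontology=scores.terms.ontology)
    report.protein_centric = {
        "fmax": fmax,
        "best_threshold": best_t,
        "aupr": protein_centric_aupr(scores, truth),
    }
    report.term_centric = {
        "fmax": term_centric_fmax(scores, truth, thresholds),
        "aupr": term_centric_aupr(scores, truth),
    }
    return report


# ---------------------------------------------------------------------------
# Stratified reporting
# ---------------------------------------------------------------------------

def stratify_by_ic(
    vocab: LabelVocabulary,
    train_annos: AnnotationSet,
    n_groups: int = 3,
) -> List[List[str]]:
    """Split the vocabulary into IC groups of near-equal size.

    Labels are sorted by ascending information content (frequent →
    rare), ties broken by GO id, and cut into ``n_groups`` contiguous
    blocks whose sizes differ by at most one.
    """
    keyed = sorted(
        (information_content(t, train_annos), t) for t in vocab.terms
    )
    ordered = [t for _, t in keyed]
    return [list(part) for part in np.array_split(ordered, n_groups)]


def stratify_by_identity(
    test_hits_vs_train: DiamondHitTable,
    protein_ids: Sequence[str],
    boundary: float = 40.0,
) -> Dict[str, List[str]]:
    """Bin test proteins by their best-hit identity against training.

    Groups: ``no-alignment`` (no hit at all), ``min-40%`` (best percent
    identity below the boundary), ``40-100%`` (boundary inclusive —
    exactly 40.0 goes to the upper bin).
    """
    best = test_hits_vs_train.best_identity()
    logger.info(
        "identity binning: boundary %.1f%% assigned to the upper bin",
        boundary,
    )
    groups: Dict[str, List[str]] = {
        "no-alignment": [],
        "min-40%": [],
        "40-100%": [],
    }
    for pid in protein_ids:
        ident = best.get(pid)
        if ident is None:
            groups["no-alignment"].append(pid)
        elif ident < boundary:
            groups["min-40%"].append(pid)
        else:
            groups["40-100%"].append(pid)
    return groups


def evaluate_strata(
    scores: ScoreMatrix,
    truth: AnnotationSet,
    protein_groups: Mapping[str, Sequence[str]],
) -> List[Tuple[str, Dict[str, float]]]:
    """Term-centric metrics restricted to each protein stratum."""
    out = []
    index = {p: i for i, p in enumerate(scores.protein_ids)}
    for name, pids in protein_groups.items():
        rows = [index[p] for p in pids if p in index]
        if not rows:
            continue
        sub = ScoreMatrix(
            [scores.protein_ids[i] for i in rows],
            scores.terms,
            scores.scores[rows],
        )
        try:
            vals = {
                "aupr": term_centric_aupr(sub, truth),
                "fmax": term_centric_fmax(sub, truth),
                "n_proteins": float(len(rows)),
            }
        except ValueError:
            continue
        out.append((name, vals))
    return out
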