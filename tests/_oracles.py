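"""Independent brute-force oracles used by the test suite.

Everything here is written straight from the metric/algorithm
definitions with plain loops, deliberately sharing no code with the
package implementations it checks.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set

import numpy as np
import scipy.sparse as sp


# ---------------------------------------------------------------------------
# Protein-centric metrics, literal formulas
# ---------------------------------------------------------------------------

def fmax_protein_bruteforce(
    S: np.ndarray, Y: np.ndarray, thresholds: Sequence[float]
) -> float:
    """max_t 2·AvgPre·AvgRecall/(AvgPre+AvgRecall) with per-protein
    pre_i = |P∩T|/|P| averaged over proteins with predictions and
    recall_i = |P∩T|/|T| averaged over proteins with nonempty truth."""
    best = 0.0
    n_prot, m = S.shape
    for t in thresholds:
        pres, recs = [], []
        for i in range(n_prot):
            P = {j for j in range(m) if S[i, j] >= t}
            T = {j for j in range(m) if Y[i, j] > 0}
            if P:
                pres.append(len(P & T) / len(P))
            if T:
                recs.append(len(P & T) / len(T))
        if not pres or not recs:
            continue
        avg_pre = sum(pres) / len(pres)
        avg_rec = sum(recs) / len(recs)
        if avg_pre + avg_rec > 0:
            best = max(best, 2 * avg_pre * avg_rec / (avg_pre + avg_rec))
    return best


def average_precision_bruteforce(y: np.ndarray, s: np.ndarray) -> float:
    """Step-wise PR area: AP = Σ_k (R_k − R_{k−1})·P_k over the unique
    score thresholds in descending order (ties grouped)."""
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    npos = int(y.sum())
    ap, tp, fp, prev_r = 0.0, 0, 0, 0.0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        fp += (j - i) - int(y[i:j].sum())
        r = tp / npos
        p = tp / (tp + fp)
        ap += (r - prev_r) * p
        prev_r = r
        i = j
    return ap


def aupr_micro_bruteforce(S: np.ndarray, Y: np.ndarray) -> float:
    return average_precision_bruteforce(Y.ravel(), S.ravel())


def fmax_term_bruteforce(
    S: np.ndarray, Y: np.ndarray, thresholds: Sequence[float]
) -> float:
    """Mean over labels with positives of the per-label max F1."""
    per_label = []
    n, m = S.shape
    for j in range(m):
        npos = int((Y[:, j] > 0).sum())
        if npos == 0:
            continue
        best = 0.0
        for t in thresholds:
            tp = sum(1 for i in range(n) if S[i, j] >= t and Y[i, j] > 0)
            npred = sum(1 for i in range(n) if S[i, j] >= t)
            if npred == 0:
                continue
            pre, rec = tp / npred, tp / npos
            if pre + rec > 0:
                best = max(best, 2 * pre * rec / (pre + rec))
        per_label.append(best)
    return sum(per_label) / len(per_label)


def aupr_macro_bruteforce(S: np.ndarray, Y: np.ndarray) -> float:
    areas = [
        average_precision_bruteforce(Y[:, j], S[:, j])
        for j in range(S.shape[1])
        if Y[:, j].sum() > 0
    ]
    return sum(areas) / len(areas)


# ---------------------------------------------------------------------------
# Ontology oracles
# ---------------------------------------------------------------------------

def descendant_max_bruteforce(
    scores: np.ndarray,
    vocab_terms: List[str],
    parents: Dict[str, Set[str]],
) -> np.ndarray:
    """Each column raised to the max over its transitive in-vocabulary
    descendants, found by exhaustive path enumeration."""
    idx = {t: i for i, t in enumerate(vocab_terms)}

    def descendants(term: str) -> Set[str]:
        out = set()
        frontier = [term]
        while frontier:
            t = frontier.pop()
            for c, ps in parents.items():
                if t in ps and c not in out:
                    out.add(c)
                    frontier.append(c)
        return out

    out = scores.copy()
    for t in vocab_terms:
        cols = [idx[d] for d in descendants(t) if d in idx]
        if cols:
            out[:, idx[t]] = np.maximum(
                scores[:, idx[t]], scores[:, cols].max(axis=1)
            )
    return out


# ---------------------------------------------------------------------------
# Markov clustering, independent sparse implementation
# ---------------------------------------------------------------------------

def mcl_reference(
    adjacency: np.ndarray,
    nodes: List[str],
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> List[Set[str]]:
    """Expansion/inflation loop on a scipy.sparse column-stochastic
    matrix; clusters from connected components of the limit support."""
    A = adjacency.astype(float).copy()
    diag = A.max(axis=0)
    diag[diag == 0] = 1.0
    np.fill_diagonal(A, diag)
    M = sp.csc_matrix(A / A.sum(axis=0, keepdims=True))
    for _ in range(max_iter):
        last = M.toarray()
        M = M @ M
        M = M.power(inflation)
        M.data[M.data < 1e-9] = 0.0
        M.eliminate_zeros()
        colsum = np.asarray(M.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        M = M @ sp.diags(1.0 / colsum)
        M = sp.csc_matrix(M)
        if np.abs(M.toarray() - last).max() < tol:
            break
    L = M.toarray()
    n = len(nodes)
    support = sp.lil_matrix((n, n))
    for i in range(n):
        if L[i, i] > tol:
            for j in np.nonzero(L[i] > tol)[0]:
                support[i, j] = 1
                support[j, i] = 1
    n_comp, labels = sp.csgraph.connected_components(
        sp.csr_matrix(support), directed=False
    )
    clusters = [
        {nodes[i] for i in range(n) if labels[i] == c} for c in range(n_comp)
    ]
    clusters.sort(key=lambda c: sorted(c)[0])
    return clusters
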