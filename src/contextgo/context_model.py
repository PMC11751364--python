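"""The genomic-context Transformer for multi-label GO prediction.

Each phage contig is treated as a *sentence* whose tokens are the pooled
embeddings of its proteins in genomic-coordinate order. Learned position
embeddings are added, a stack of multi-head self-attention blocks with
feed-forward layers mixes information between neighbouring proteins, and
a sigmoid output head assigns each protein a score in (0,1) for every
term of the label vocabulary. Training minimises the multi-label binary
cross-entropy; one model is trained per ontology (BP, CC, MF).

The network is implemented directly in NumPy with hand-written reverse-
mode gradients; at the scale this package targets (embedding widths of
tens to hundreds, sentences of tens of proteins) a CPU handles training
in seconds and the implementation stays fully transparent and
dependency-light.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .ontology import AnnotationSet, LabelVocabulary

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Sentences
# ---------------------------------------------------------------------------

@dataclass
class GenomeSentence:
    """Ordered protein tokens of one contig."""

    genome_id: str
    protein_ids: List[str]

    def __len__(self) -> int:
        return len(self.protein_ids)


def build_sentences(
    order: Mapping[str, Tuple[str, int]]
) -> List[GenomeSentence]:
    """Group proteins into per-contig sentences sorted by gene index.

    ``order`` maps protein_id → (genome_id, gene_index). Indices within a
    genome need not be contiguous but must be unique.
    """
    per_genome: Dict[str, List[Tuple[int, str]]] = {}
    seen: Dict[Tuple[str, int], str] = {}
    for pid, (gid, idx) in order.items():
        key = (gid, int(idx))
        if key in seen:
            raise ValueError(
                f"duplicate gene position {key}: {seen[key]!r} and {pid!r}"
            )
        seen[key] = pid
        per_genome.setdefault(gid, []).append((int(idx), pid))
    sentences = []
    for gid in sorted(per_genome):
        entries = sorted(per_genome[gid])
        sentences.append(GenomeSentence(gid, [p for _, p in entries]))
    return sentences


def window_spans(n: int, max_len: int, overlap: int) -> List[Tuple[int, int]]:
    """Start offsets of overlapping windows covering ``n`` positions.

    Windows have length ``max_len`` and stride ``max_len − overlap``; the
    final window is shifted left so it is full-length and reaches the end.
    """
    if n <= max_len:
        return [(0, n)]
    if max_len <= overlap:
        raise ValueError("overlap must be smaller than max_len")
    stride = max_len - overlap
    starts = list(range(0, n - max_len, stride))
    starts.append(n - max_len)
    return [(s, s + max_len) for s in starts]


def assign_owner_windows(
    spans: Sequence[Tuple[int, int]], n: int
) -> List[int]:
    """For each position, the window whose centre is nearest (ties → first).

    A protein appearing in several overlapping windows takes its
    prediction from the window where it sits most centrally.
    """
    owners = []
    for i in range(n):
        best, best_d = None, None
        for w, (s, e) in enumerate(spans):
            if s <= i < e:
                d = abs(i - (s + e - 1) / 2.0)
                if best is None or d < best_d:
                    best, best_d = w, d
        owners.append(best)
    return owners


# ---------------------------------------------------------------------------
# Config and score container
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Hyperparameters of the context model.

    ``d_e`` must be divisible by ``n_heads``; ``d_k = d_e / n_heads`` is
    the per-head width used in the attention scaling. Position
    embeddings are learned vectors indexed 0..max_sentence_len−1 (one per
    slot of a window).
    """

    d_e: int = 1280
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 0  # 0 → 2 * d_e
    max_sentence_len: int = 128
    window_overlap: int = 32
    dropout: float = 0.0
    learning_rate: float = 1e-4
    epochs: int = 20
    batch_size: int = 16
    seed: int = 0
    ontology: str = "MF"
    use_position_embeddings: bool = True
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.d_e % self.n_heads:
            raise ValueError(
                f"d_e={self.d_e} not divisible by n_heads={self.n_heads}"
            )
        if self.max_sentence_len < 1:
            raise ValueError("max_sentence_len must be >= 1")
        if self.d_ff == 0:
            self.d_ff = 2 * self.d_e

    @property
    def d_k(self) -> int:
        return self.d_e // self.n_heads


@dataclass
class ScoreMatrix:
    """Proteins × vocabulary prediction scores in [0, 1]."""

    protein_ids: List[str]
    terms: LabelVocabulary
    scores: np.ndarray  # (n_proteins, m)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.protein_ids), len(self.terms)):
            raise ValueError("score matrix shape mismatch")

    def with_scores(self, scores: np.ndarray) -> "ScoreMatrix":
        return ScoreMatrix(self.protein_ids, self.terms, scores)

    def row(self, protein_id: str) -> np.ndarray:
        return self.scores[self.protein_ids.index(protein_id)]

    def reorder_like(self, other: "ScoreMatrix") -> "ScoreMatrix":
        """Reindex rows to another matrix's protein order (same vocab)."""
        if self.terms.terms != other.terms.terms:
            raise ValueError("vocabulary mismatch")
        idx = {p: i for i, p in enumerate(self.protein_ids)}
        rows = [idx[p] for p in other.protein_ids]
        return ScoreMatrix(
            list(other.protein_ids), self.terms, self.scores[rows]
        )


# ---------------------------------------------------------------------------
# Core maths: attention and multi-head attention
# ---------------------------------------------------------------------------

def _softmax_last(x: np.ndarray) -> np.ndarray:
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


def attention(
    Q: np.ndarray,
    K: np.ndarray,
    V: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention: softmax(QKᵀ/√d_k)·V.

    ``mask`` marks valid *key* positions (True = attend); masked
    positions receive zero weight. Returns (output, attention weights);
    weight rows sum to 1 over the unmasked positions.
    """
    d_k = Q.shape[-1]
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if not m.any(axis=-1).all():
            raise ValueError("a query row has all key positions masked")
        while m.ndim < scores.ndim:  # broadcast over heads / query axis
            m = np.expand_dims(m, -2)
        scores = np.where(m, scores, -np.inf)
    weights = _softmax_last(scores)
    return weights @ V, weights


def split_heads(x: np.ndarray, n_heads: int) -> np.ndarray:
    """(B, n, d_e) → (B, h, n, d_k)."""
    B, n, d = x.shape
    return x.reshape(B, n, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def merge_heads(x: np.ndarray) -> np.ndarray:
    """(B, h, n, d_k) → (B, n, d_e); heads concatenated in order."""
    B, h, n, dk = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, n, h * dk)


def multi_head(
    X3: np.ndarray,
    layer_params: Mapping[str, np.ndarray],
    n_heads: int,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Multi-head self-attention of one layer (no residual).

    Q, K, V come from three independent linear maps of ``X3``; per-head
    attention outputs are concatenated and passed through the output map
    ``W^M`` (``Wo``/``bo``).
    """
    p = layer_params
    Q = split_heads(X3 @ p["Wq"] + p["bq"], n_heads)
    K = split_heads(X3 @ p["Wk"] + p["bk"], n_heads)
    V = split_heads(X3 @ p["Wv"] + p["bv"], n_heads)
    heads, _ = attention(Q, K, V, mask)
    return merge_heads(heads) @ p["Wo"] + p["bo"]


def bce_loss(scores: np.ndarray, targets: np.ndarray) -> float:
    """Multi-label binary cross-entropy.

    Mean over proteins of the per-label cross-entropy summed over the
    vocabulary: L = −(1/N)·Σ_i Σ_j [y·log ŷ + (1−y)·log(1−ŷ)].
    """
    scores = np.asarray(scores, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if scores.shape != targets.shape:
        raise ValueError(
            f"shape mismatch: scores {scores.shape} vs targets {targets.shape}"
        )
    eps = 1e-12
    s = np.clip(scores, eps, 1.0 - eps)
    per_protein = -(targets * np.log(s) + (1 - targets) * np.log(1 - s)).sum(
        axis=-1
    )
    return float(per_protein.mean())


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class ContextTransformer:
    """Transformer over genome sentences with a sigmoid multi-label head.

    Parameters are plain NumPy arrays; forward caches intermediates for
    the hand-written backward pass. Residual connections wrap the
    attention and feed-forward sub-blocks.
    """

    def __init__(self, config: ModelConfig, vocab: LabelVocabulary) -> None:
        self.config = config
        self.vocab = vocab
        self.params: Dict[str, np.ndarray] = {}
        self._init_params()
        # optional jointly-trained fc-pooler weights over residue positions
        self.pooler_weights: Optional[np.ndarray] = None

    # -- parameters ---------------------------------------------------------

    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        d, dff, m = cfg.d_e, cfg.d_ff, len(self.vocab)

        def lin(rows, cols):
            return rng.standard_normal((rows, cols)) / np.sqrt(rows)

        p: Dict[str, np.ndarray] = {}
        if cfg.use_position_embeddings:
            # unit-scale init: position must compete with token vectors
            # of norm ~sqrt(d_e) in a network without layer normalisation
            p["pos"] = rng.standard_normal((cfg.max_sentence_len, d))
        for l in range(cfg.n_layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"{l}.{name}"] = lin(d, d)
            for name in ("bq", "bk", "bv", "bo"):
                p[f"{l}.{name}"] = np.zeros(d)
            p[f"{l}.W1"] = lin(d, dff)
            p[f"{l}.b1"] = np.zeros(dff)
            p[f"{l}.W2"] = lin(dff, d)
            p[f"{l}.b2"] = np.zeros(d)
        p["Wout"] = lin(d, m)
        p["bout"] = np.zeros(m)
        self.params = p

    def zero_params(self) -> None:
        """All-zero weights: the sigmoid head then outputs 0.5 everywhere."""
        for k in self.params:
            self.params[k] = np.zeros_like(self.params[k])

    # -- forward ------------------------------------------------------------

    def forward(
        self,
        tokens: np.ndarray,
        mask: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tuple[np.ndarray, dict]:
        """Scores (B, n, m) in (0,1) plus the backward cache.

        ``tokens``: (B, n, d_e) pooled protein vectors; ``mask``: (B, n)
        boolean, True on real (unpadded) token slots.
        """
        cfg = self.config
        p = self.params
        B, n, d = tokens.shape
        if d != cfg.d_e:
            raise ValueError(f"token width {d} != model d_e {cfg.d_e}")
        if n > cfg.max_sentence_len:
            raise ValueError(
                f"sentence length {n} exceeds max_sentence_len "
                f"{cfg.max_sentence_len}; window it first"
            )
        cache: dict = {"mask": mask, "layers": [], "drop": []}
        X = tokens
        if cfg.use_position_embeddings:
            X = X + p["pos"][:n][None, :, :]
        cache["X0"] = X
        keep = 1.0 - cfg.dropout if train and cfg.dropout > 0 else None
        for l in range(cfg.n_layers):
            lc: dict = {"Xin": X}
            Q = split_heads(X @ p[f"{l}.Wq"] + p[f"{l}.bq"], cfg.n_heads)
            K = split_heads(X @ p[f"{l}.Wk"] + p[f"{l}.bk"], cfg.n_heads)
            V = split_heads(X @ p[f"{l}.Wv"] + p[f"{l}.bv"], cfg.n_heads)
            H, W = attention(Q, K, V, mask)
            Hm = merge_heads(H)
            M = Hm @ p[f"{l}.Wo"] + p[f"{l}.bo"]
            if keep is not None:
                dm = (rng.random(M.shape) < keep) / keep
                M = M * dm
                lc["drop_attn"] = dm
            X = X + M
            lc.update(Q=Q, K=K, V=V, W=W, Hm=Hm, Xmid=X)
            F1p = X @ p[f"{l}.W1"] + p[f"{l}.b1"]
            F1 = np.maximum(F1p, 0.0)
            F2 = F1 @ p[f"{l}.W2"] + p[f"{l}.b2"]
            if keep is not None:
                df = (rng.random(F2.shape) < keep) / keep
                F2 = F2 * df
                lc["drop_ffn"] = df
            X = X + F2
            lc.update(F1p=F1p, F1=F1)
            cache["layers"].append(lc)
        cache["Xfinal"] = X
        logits = X @ p["Wout"] + p["bout"]
        scores = 0.5 * (1.0 + np.tanh(0.5 * logits))  # overflow-safe sigmoid
        return scores, cache

    # -- backward -----------------------------------------------------------

    def backward(
        self, cache: dict, dlogits: np.ndarray
    ) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
        """Gradients of all parameters plus the gradient w.r.t. tokens."""
        cfg = self.config
        p = self.params
        grads: Dict[str, np.ndarray] = {
            k: np.zeros_like(v) for k, v in p.items()
        }
        mask = cache["mask"]

        def lin_back(dY, Xin, Wname, bname):
            grads[Wname] += np.einsum("bnd,bnm->dm", Xin, dY)
            grads[bname] += dY.sum(axis=(0, 1))
            return dY @ p[Wname].T

        X = cache["Xfinal"]
        grads["Wout"] += np.einsum("bnd,bnm->dm", X, dlogits)
        grads["bout"] += dlogits.sum(axis=(0, 1))
        dX = dlogits @ p["Wout"].T

        for l in reversed(range(cfg.n_layers)):
            lc = cache["layers"][l]
            # feed-forward block (residual)
            dF2 = dX.copy()
            if "drop_ffn" in lc:
                dF2 = dF2 * lc["drop_ffn"]
            dF1 = lin_back(dF2, lc["F1"], f"{l}.W2", f"{l}.b2")
            dF1p = dF1 * (lc["F1p"] > 0)
            dXmid = dX + lin_back(dF1p, lc["Xmid"], f"{l}.W1", f"{l}.b1")
            # attention block (residual)
            dM = dXmid.copy()
            if "drop_attn" in lc:
                dM = dM * lc["drop_attn"]
            dHm = lin_back(dM, lc["Hm"], f"{l}.Wo", f"{l}.bo")
            dH = split_heads(dHm, cfg.n_heads)
            W, Q, K, V = lc["W"], lc["Q"], lc["K"], lc["V"]
            dW = dH @ np.swapaxes(V, -1, -2)
            dV = np.swapaxes(W, -1, -2) @ dH
            dS = W * (dW - (dW * W).sum(axis=-1, keepdims=True))
            scale = 1.0 / np.sqrt(cfg.d_k)
            dQ = dS @ K * scale
            dK = np.swapaxes(dS, -1, -2) @ Q * scale
            Xin = lc["Xin"]
            dXin = dXmid
            dXin = dXin + lin_back(merge_heads(dQ), Xin, f"{l}.Wq", f"{l}.bq")
            dXin = dXin + lin_back(merge_heads(dK), Xin, f"{l}.Wk", f"{l}.bk")
            dXin = dXin + lin_back(merge_heads(dV), Xin, f"{l}.Wv", f"{l}.bv")
            dX = dXin

        if cfg.use_position_embeddings:
            n = dX.shape[1]
            grads["pos"][:n] += (dX * mask[..., None]).sum(axis=0)
        dtokens = dX * mask[..., None]
        return grads, dtokens

    def loss_and_grads(
        self,
        tokens: np.ndarray,
        mask: np.ndarray,
        targets: np.ndarray,
        train: bool = True,
        rng: Optional[np.random.Generator] = None,
    ) -> Tuple[float, Dict[str, np.ndarray], np.ndarray]:
        """BCE over real tokens and its parameter gradients."""
        scores, cache = self.forward(tokens, mask, train=train, rng=rng)
        N = int(mask.sum())
        real = mask[..., None]
        eps = 1e-12
        s = np.clip(scores, eps, 1 - eps)
        loss = float(
            -(
                (targets * np.log(s) + (1 - targets) * np.log(1 - s)) * real
            ).sum()
            / N
        )
        dlogits = (scores - targets) * real / N
        grads, dtokens = self.backward(cache, dlogits)
        return loss, grads, dtokens


# ---------------------------------------------------------------------------
# Batching, training, prediction
# ---------------------------------------------------------------------------

def _sentence_windows(
    sentence: GenomeSentence, cfg: ModelConfig
) -> Tuple[List[List[str]], Dict[str, int]]:
    """Window one sentence; map each protein to its owning window."""
    n = len(sentence)
    spans = window_spans(n, cfg.max_sentence_len, cfg.window_overlap)
    owners = assign_owner_windows(spans, n)
    windows = [sentence.protein_ids[s:e] for s, e in spans]
    owner_of = {
        sentence.protein_ids[i]: owners[i] for i in range(n)
    }
    return windows, owner_of


def _make_batch(
    windows: List[List[str]],
    embeddings: Mapping[str, np.ndarray],
    targets: Optional[Mapping[str, np.ndarray]],
    d_e: int,
    m: int,
) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    B = len(windows)
    n_max = max(len(w) for w in windows)
    tokens = np.zeros((B, n_max, d_e))
    mask = np.zeros((B, n_max), dtype=bool)
    Y = np.zeros((B, n_max, m)) if targets is not None else None
    for b, w in enumerate(windows):
        for i, pid in enumerate(w):
            tokens[b, i] = embeddings[pid]
            mask[b, i] = True
            if targets is not None:
                Y[b, i] = targets[pid]
    return tokens, mask, Y


class AdamOptimizer:
    """Adam with bias correction; state keyed like the parameter dict."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainHistory:
    epochs: List[int] = field(default_factory=list)
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    best_epoch: int = -1


def _targets_from_annos(
    protein_ids: Iterable[str], annos: AnnotationSet, vocab: LabelVocabulary
) -> Dict[str, np.ndarray]:
    m = len(vocab)
    out = {}
    for pid in protein_ids:
        y = np.zeros(m)
        for t in annos.assignments.get(pid, ()):
            j = vocab.index.get(t)
            if j is not None:
                y[j] = 1.0
        out[pid] = y
    return out


def train(
    sentences: Sequence[GenomeSentence],
    embeddings: Mapping[str, np.ndarray],
    annos: AnnotationSet,
    vocab: LabelVocabulary,
    config: ModelConfig,
    val_sentences: Optional[Sequence[GenomeSentence]] = None,
) -> Tuple[ContextTransformer, TrainHistory]:
    """Train one per-ontology context model with Adam and early selection.

    Sentences are windowed to ``max_sentence_len``, batched, and shuffled
    each epoch with a seeded generator; the checkpoint with the lowest
    validation loss is retained. When no explicit validation sentences
    are given, a seeded ``val_fraction`` split of the input is used.
    """
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    sentences = list(sentences)
    if not sentences:
        raise ValueError("empty corpus")
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    if val_sentences is None:
        order = rng.permutation(len(sentences))
        n_val = max(1, int(round(cfg.val_fraction * len(sentences)))) if len(
            sentences
        ) > 1 else 0
        val_idx = set(order[:n_val].tolist())
        val_sentences = [sentences[i] for i in sorted(val_idx)]
        train_sentences = [
            s for i, s in enumerate(sentences) if i not in val_idx
        ]
    else:
        train_sentences = sentences
        val_sentences = list(val_sentences)

    all_pids = {
        p for s in list(train_sentences) + list(val_sentences)
        for p in s.protein_ids
    }
    missing = sorted(p for p in all_pids if p not in embeddings)
    if missing:
        raise KeyError(f"proteins without embeddings: {missing[:10]}")
    targets = _targets_from_annos(all_pids, annos, vocab)

    model = ContextTransformer(cfg, vocab)
    opt = AdamOptimizer(model.params, lr=cfg.learning_rate)
    m = len(vocab)

    def windows_of(sents):
        out = []
        for s in sents:
            ws, _ = _sentence_windows(s, cfg)
            out.extend(ws)
        return out

    train_windows = windows_of(train_sentences)
    val_windows = windows_of(val_sentences)

    def eval_loss(windows) -> float:
        if not windows:
            return float("nan")
        total, count = 0.0, 0
        for start in range(0, len(windows), cfg.batch_size):
            chunk = windows[start : start + cfg.batch_size]
            tokens, mask, Y = _make_batch(
                chunk, embeddings, targets, cfg.d_e, m
            )
            scores, _ = model.forward(tokens, mask, train=False)
            N = int(mask.sum())
            eps = 1e-12
            s = np.clip(scores, eps, 1 - eps)
            total += float(
                -(
                    (Y * np.log(s) + (1 - Y) * np.log(1 - s))
                    * mask[..., None]
                ).sum()
            )
            count += N
        return total / count

    history = TrainHistory()
    best_val = np.inf
    best_params = copy.deepcopy(model.params)
    drop_rng = np.random.default_rng(cfg.seed + 1)

    for epoch in range(1, cfg.epochs + 1):
        perm = rng.permutation(len(train_windows))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(perm), cfg.batch_size):
            chunk = [train_windows[i] for i in perm[start : start + cfg.batch_size]]
            tokens, mask, Y = _make_batch(
                chunk, embeddings, targets, cfg.d_e, m
            )
            loss, grads, _ = model.loss_and_grads(
                tokens, mask, Y, train=True, rng=drop_rng
            )
            opt.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1
        val = eval_loss(val_windows)
        history.epochs.append(epoch)
        history.train_loss.append(epoch_loss / max(n_batches, 1))
        history.val_loss.append(val)
        if np.isnan(val) or val < best_val:
            best_val = val if not np.isnan(val) else best_val
            best_params = copy.deepcopy(model.params)
            history.best_epoch = epoch
    model.params = best_params
    return model, history


def predict(
    sentences: Sequence[GenomeSentence],
    model: ContextTransformer,
    embeddings: Mapping[str, np.ndarray],
) -> ScoreMatrix:
    """Score every protein of every sentence with a trained model.

    Long sentences are split into overlapping windows; each protein's
    scores come from the window in which it is most central. The result
    is deterministic.
    """
    cfg = model.config
    all_pids: List[str] = []
    for s in sentences:
        all_pids.extend(s.protein_ids)
    missing = sorted(p for p in set(all_pids) if p not in embeddings)
    if missing:
        raise KeyError(f"proteins without embeddings: {missing[:10]}")
    m = len(model.vocab)
    rows: Dict[str, np.ndarray] = {}
    for s in sentences:
        windows, owner_of = _sentence_windows(s, cfg)
        tokens, mask, _ = _make_batch(windows, embeddings, None, cfg.d_e, m)
        scores, _ = model.forward(tokens, mask, train=False)
        for i, pid in enumerate(s.protein_ids):
            w = owner_of[pid]
            pos_in_window = i - (
                window_spans(len(s), cfg.max_sentence_len, cfg.window_overlap)[
                    w
                ][0]
            )
            rows[pid] = scores[w, pos_in_window]
    ordered = list(dict.fromkeys(all_pids))
    return ScoreMatrix(
        ordered, model.vocab, np.stack([rows[p] for p in ordered])
    )


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: ContextTransformer, path) -> None:
    """Self-describing archive: weights (npz) + config + vocabulary."""
    path = Path(path)
    meta = {
        "config": asdict(model.config),
        "vocabulary": model.vocab.terms,
        "ontology": model.vocab.ontology,
    }
    arrays = dict(model.params)
    if model.pooler_weights is not None:
        arrays["__pooler__"] = model.pooler_weights
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path) -> ContextTransformer:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig(**meta["config"])
    vocab = LabelVocabulary(meta["ontology"], meta["vocabulary"])
    model = ContextTransformer(cfg, vocab)
    with np.load(path.with_suffix(".npz")) as npz:
        arrays = {k: npz[k] for k in npz.files}
    model.pooler_weights = arrays.pop("__pooler__", None)
    model.params = arrays
    return model
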