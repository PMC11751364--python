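"""Per-protein embeddings: pluggable per-residue backends and pooling.

A backend turns an amino-acid sequence into an ``L × d_e`` per-residue
matrix; a pooler collapses that matrix to a single ``d_e`` vector per
protein. Sequences are capped at 1024 residues (N-terminal prefix kept),
matching the context window of the ESM2 family.

Three backends are registered:

``plm-large``
    ESM2 with 33 layers, d_e = 1280 — the full-scale model. Requires the
    optional ``esm``/``torch`` stack at run time.
``plm-base``
    ESM2 with 12 layers, d_e = 480 — the lightweight variant.
``synthetic``
    A deterministic hash-seeded random projection, always available;
    used for offline testing and by the synthetic corpus.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Optional

import numpy as np

logger = logging.getLogger(__name__)

MAX_RESIDUES = 1024
#: 20 standard residues plus X (unknown)
AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ResidueEmbedding:
    """Zero-padded per-residue embedding matrix of one protein."""

    protein_id: str
    matrix: np.ndarray  # (L_max, d_e); rows >= true_length are zero
    true_length: int

    def __post_init__(self) -> None:
        if self.true_length > self.matrix.shape[0]:
            raise ValueError("true_length exceeds matrix rows")


@dataclass
class ProteinVector:
    """Pooled fixed-dimension embedding of one protein."""

    protein_id: str
    vector: np.ndarray  # (d_e,)


class BackendUnavailableError(RuntimeError):
    """Raised when a real-PLM backend's runtime stack is missing."""


def truncate(sequence: str, max_residues: int = MAX_RESIDUES) -> str:
    """Cap a sequence at ``max_residues`` keeping the N-terminal prefix."""
    if not sequence:
        raise ValueError("empty protein sequence")
    return sequence[:max_residues]


def validate_sequence(sequence: str) -> str:
    """Upper-case, strip stop characters, and check the residue alphabet."""
    seq = sequence.upper().replace("*", "")
    if not seq:
        raise ValueError("empty protein sequence")
    bad = sorted(set(seq) - AMINO_ALPHABET)
    if bad:
        raise ValueError(f"unknown residue characters: {''.join(bad)}")
    return seq


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

class EmbeddingBackend:
    """Interface: per-residue embedding of a validated, capped sequence."""

    backend_id: str
    d_e: int

    def embed(self, protein_id: str, sequence: str) -> ResidueEmbedding:
        raise NotImplementedError


class SyntheticBackend(EmbeddingBackend):
    """Deterministic hash-seeded embedding, a stand-in for a real PLM.

    Each (sequence, seed) pair maps to a fixed random matrix: rows are
    drawn from a per-residue-type Gaussian codebook plus positional
    noise, so identical sequences embed identically and different
    sequences differ with overwhelming probability.
    """

    def __init__(self, d_e: int = 64, seed: int = 0) -> None:
        self.backend_id = f"synthetic-d{d_e}-s{seed}"
        self.d_e = d_e
        self.seed = seed

    def _seq_seed(self, sequence: str) -> int:
        h = hashlib.blake2b(
            f"{self.seed}:{sequence}".encode(), digest_size=4
        ).digest()
        return int.from_bytes(h, "big") % (2**31)

    def embed(self, protein_id: str, sequence: str) -> ResidueEmbedding:
        seq = truncate(validate_sequence(sequence))
        rng = np.random.default_rng(self._seq_seed(seq))
        mat = np.zeros((MAX_RESIDUES, self.d_e))
        mat[: len(seq)] = rng.standard_normal((len(seq), self.d_e))
        return ResidueEmbedding(protein_id, mat, len(seq))


class _EsmBackend(EmbeddingBackend):
    """Real ESM2 backend; imports torch/esm lazily."""

    def __init__(self, backend_id: str, model_name: str, d_e: int) -> None:
        self.backend_id = backend_id
        self._model_name = model_name
        self.d_e = d_e
        self._model = None

    def _load(self):
        try:
            import esm  # type: ignore
            import torch  # noqa: F401
        except ImportError as exc:
            raise BackendUnavailableError(
                f"backend {self.backend_id!r} needs the 'esm' and 'torch' "
                "packages; install them or use backend='synthetic'"
            ) from exc
        model, alphabet = getattr(esm.pretrained, self._model_name)()
        model.eval()
        self._model = (model, alphabet)

    def embed(self, protein_id: str, sequence: str) -> ResidueEmbedding:
        if self._model is None:
            self._load()
        import torch

        model, alphabet = self._model
        seq = truncate(validate_sequence(sequence))
        batch_converter = alphabet.get_batch_converter()
        _, _, tokens = batch_converter([(protein_id, seq)])
        with torch.no_grad():
            layer = model.num_layers
            out = model(tokens, repr_layers=[layer])
        reps = out["representations"][layer][0, 1 : len(seq) + 1].numpy()
        mat = np.zeros((MAX_RESIDUES, self.d_e))
        mat[: len(seq)] = reps
        return ResidueEmbedding(protein_id, mat, len(seq))


_REGISTRY: Dict[str, Callable[..., EmbeddingBackend]] = {
    "synthetic": SyntheticBackend,
    "plm-large": lambda **kw: _EsmBackend(
        "plm-large", "esm2_t33_650M_UR50D", 1280
    ),
    "plm-base": lambda **kw: _EsmBackend("plm-base", "esm2_t12_35M_UR50D", 480),
}


def get_backend(name: str, **kwargs) -> EmbeddingBackend:
    """Instantiate a registered backend by name."""
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown backend {name!r}; available: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name](**kwargs)


def embed_residues(
    sequence: str, backend: EmbeddingBackend, protein_id: str = ""
) -> ResidueEmbedding:
    """Per-residue embedding of one (validated, capped) sequence."""
    return backend.embed(protein_id, sequence)


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------

def pool(
    residue_emb: ResidueEmbedding,
    pooler: str = "mean",
    fc_weights: Optional[np.ndarray] = None,
) -> ProteinVector:
    """Collapse a per-residue matrix to one ``d_e`` vector.

    ``mean`` and ``max`` act over the ``true_length`` unpadded rows.
    ``fc`` applies one learned weight per residue position (padded
    positions masked): ``x2 = Σ_{i<L} w_i · X1[i]``. With all weights
    equal to 1/L this reduces to the masked mean. The fc weights are
    normally trained jointly with the context model; here they may be
    supplied explicitly.
    """
    L = residue_emb.true_length
    if L == 0:
        raise ValueError("cannot pool a zero-length protein")
    rows = residue_emb.matrix[:L]
    if pooler == "mean":
        vec = rows.mean(axis=0)
    elif pooler == "max":
        vec = rows.max(axis=0)
    elif pooler == "fc":
        if fc_weights is None:
            raise ValueError("fc pooling requires fc_weights")
        vec = fc_weights[:L] @ rows
    else:
        raise ValueError(f"unknown pooler {pooler!r}; use fc, mean or max")
    return ProteinVector(residue_emb.protein_id, vec)


# ---------------------------------------------------------------------------
# On-disk cache
# ---------------------------------------------------------------------------

class EmbeddingCache:
    """Directory cache of pooled vectors keyed by backend, id and sequence.

    Layout: one ``.npy`` per protein plus a JSON manifest mapping the
    cache key to the file and recording d_e.
    """

    def __init__(self, directory) -> None:
        self.dir = Path(directory)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.dir / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {}

    @staticmethod
    def key(backend_id: str, protein_id: str, sequence: str) -> str:
        h = hashlib.blake2b(sequence.encode(), digest_size=8).hexdigest()
        return f"{backend_id}:{protein_id}:{h}"

    def get(self, backend_id, protein_id, sequence) -> Optional[np.ndarray]:
        entry = self.manifest.get(self.key(backend_id, protein_id, sequence))
        if entry is None:
            return None
        return np.load(self.dir / entry["file"])

    def put(self, backend_id, protein_id, sequence, vector: np.ndarray) -> None:
        k = self.key(backend_id, protein_id, sequence)
        fname = hashlib.blake2b(k.encode(), digest_size=12).hexdigest() + ".npy"
        np.save(self.dir / fname, vector)
        self.manifest[k] = {"file": fname, "d_e": int(vector.shape[0])}
        self.manifest_path.write_text(json.dumps(self.manifest, indent=0))


def embed_corpus(
    sequences: Dict[str, str],
    backend: EmbeddingBackend,
    pooler: str = "mean",
    fc_weights: Optional[np.ndarray] = None,
    cache: Optional[EmbeddingCache] = None,
) -> Dict[str, np.ndarray]:
    """Pooled vectors for a whole corpus, with optional disk caching."""
    out: Dict[str, np.ndarray] = {}
    for pid, seq in sequences.items():
        if cache is not None:
            hit = cache.get(backend.backend_id, pid, seq)
            if hit is not None:
                out[pid] = hit
                continue
        vec = pool(embed_residues(seq, backend, pid), pooler, fc_weights).vector
        if cache is not None:
            cache.put(backend.backend_id, pid, seq, vec)
        out[pid] = vec
    return out
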