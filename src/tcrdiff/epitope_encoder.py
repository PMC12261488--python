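"""Epitope peptide → 1024-dimensional conditioning vector.

Every denoiser layer and the binding predictor consume a fixed (1, 1024)
embedding of the epitope. The default encoder is a deterministic, weight-free
featurization: hashed k-mer counts (k = 1..3) plus sinusoidal positional
features folded into 1024 bins, unit-normalized. Any callable mapping a
peptide to a 1024-vector deterministically can be plugged in instead — a
pre-trained protein language model adapter is provided behind the same
interface for environments that have `transformers` installed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .seq_codec import STANDARD_AA

__all__ = ["EMBED_DIM", "EpitopeEmbedding", "HashedKmerEncoder", "ProtT5Encoder",
           "default_encode", "embed"]

EMBED_DIM = 1024


@dataclass(frozen=True)
class EpitopeEmbedding:
    vector: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=np.float64)
        if v.shape != (EMBED_DIM,):
            raise ValueError(f"embedding must have shape ({EMBED_DIM},), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("embedding must be finite")
        object.__setattr__(self, "vector", v)


def _validate(epitope: str) -> None:
    if not epitope:
        raise ValueError("empty epitope")
    bad = set(epitope) - set(STANDARD_AA)
    if bad:
        raise ValueError(f"invalid residue(s) in epitope: {sorted(bad)}")


def _bucket(key: str) -> int:
    """Stable hash → bin index (independent of PYTHONHASHSEED)."""
    h = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(h, "little") % EMBED_DIM


class HashedKmerEncoder:
    """Deterministic weight-free epitope featurization (the default encoder).

    Counts of k-mers for k = 1..3 are folded into 1024 bins by a stable hash;
    sinusoidal features of each (residue, position) pair are added so that
    permuted peptides map to distinct vectors. The result is unit-normalized.
    """

    def __init__(self):
        self._cache: dict[str, np.ndarray] = {}

    def __call__(self, epitope: str) -> np.ndarray:
        _validate(epitope)
        cached = self._cache.get(epitope)
        if cached is not None:
            return cached
        v = np.zeros(EMBED_DIM)
        n = len(epitope)
        for k in (1, 2, 3):
            for i in range(n - k + 1):
                v[_bucket(f"kmer{k}:{epitope[i:i + k]}")] += 1.0
        for i, aa in enumerate(epitope):
            j = _bucket(f"pos:{aa}")
            v[j] += np.sin((i + 1) / 10.0)
            v[(j + 1) % EMBED_DIM] += np.cos((i + 1) / 10.0)
        v /= np.linalg.norm(v)
        self._cache[epitope] = v
        return v


class ProtT5Encoder:
    """Adapter for a pre-trained ProtT5-XL protein language model.

    Mean-pools the per-residue hidden states and truncates/projects to 1024
    dimensions. Requires the optional `transformers` + `sentencepiece`
    dependencies and downloaded weights; never used by the test suite.
    """

    def __init__(self, model_name: str = "Rostlab/prot_t5_xl_half_uniref50-enc"):
        try:
            from transformers import T5EncoderModel, T5Tokenizer  # noqa: F401
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "ProtT5Encoder requires the optional 'transformers' and "
                "'sentencepiece' packages; install them or use the default "
                "HashedKmerEncoder"
            ) from exc
        self._tok = T5Tokenizer.from_pretrained(model_name)  # pragma: no cover
        self._model = T5EncoderModel.from_pretrained(model_name)  # pragma: no cover

    def __call__(self, epitope: str) -> np.ndarray:  # pragma: no cover
        _validate(epitope)
        import torch

        spaced = " ".join(epitope)
        ids = self._tok(spaced, return_tensors="pt")
        with torch.no_grad():
            states = self._model(**ids).last_hidden_state[0, : len(epitope)]
        v = states.mean(dim=0).float().numpy()
        v = v[:EMBED_DIM] if v.size >= EMBED_DIM else np.pad(v, (0, EMBED_DIM - v.size))
        return v / np.linalg.norm(v)


_default = HashedKmerEncoder()


def default_encode(epitope: str) -> EpitopeEmbedding:
    """Embed with the deterministic hashed-feature encoder."""
    return EpitopeEmbedding(_default(epitope))


def embed(epitope: str, encoder=None) -> EpitopeEmbedding:
    """Embed a peptide with any 1024-dim deterministic encoder callable."""
    encoder = encoder or _default
    return EpitopeEmbedding(np.asarray(encoder(epitope), dtype=np.float64))
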