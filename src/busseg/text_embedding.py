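"""Text-encoder contract, the deterministic offline stand-in, and projection.

The model only requires an object satisfying :class:`TextEncoder`: a frozen
map from a prompt string to a fixed-length vector.  A production deployment
would adapt a pretrained contrastive text encoder behind this contract; the
shipped :class:`HashingTextEncoder` is a fully deterministic stand-in (hashed
bag-of-words through a fixed Gaussian projection) that needs no downloads and
is reproducible across processes.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from . import autodiff as ad
from .layers import Linear, Module, Parameter

__all__ = [
    "PromptEmbedding",
    "ProjectedEmbedding",
    "TextEncoder",
    "HashingTextEncoder",
    "EmbeddingProjector",
    "encode_text",
    "project_embedding",
]


@dataclass(frozen=True)
class PromptEmbedding:
    """A fixed-length prompt embedding and the id of the encoder that made it."""

    vector: np.ndarray
    encoder_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=np.float32)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise ValueError("embedding must be a finite 1-D vector")
        object.__setattr__(self, "vector", v)


@dataclass(frozen=True)
class ProjectedEmbedding:
    """Embedding after the learned affine projection to the conditioning width d."""

    vector: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=np.float32)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise ValueError("projected embedding must be a finite 1-D vector")
        object.__setattr__(self, "vector", v)


@runtime_checkable
class TextEncoder(Protocol):
    """Frozen text encoder contract: ``encode(text) -> vector(embed_dim)``."""

    embed_dim: int
    encoder_id: str

    def encode(self, text: str) -> np.ndarray: ...


_TOKEN_RE = re.compile(r"[a-z0-9-]+")


def _stable_token_index(token: str, vocab_size: int) -> int:
    digest = hashlib.md5(token.encode()).digest()
    return int.from_bytes(digest[:8], "little") % vocab_size


class HashingTextEncoder:
    """Deterministic bag-of-words stand-in encoder.

    Lowercased word tokens are hashed (MD5, process-independent) to indices
    in a fixed vocabulary; the count vector is multiplied by a seeded Gaussian
    matrix to ``embed_dim`` and L2-normalized.
    """

    def __init__(self, embed_dim: int = 64, vocab_size: int = 4096, seed: int = 0):
        self.embed_dim = int(embed_dim)
        self.vocab_size = int(vocab_size)
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, vocab_size, embed_dim]))
        self._proj = rng.standard_normal((vocab_size, embed_dim)).astype(np.float32)
        self._proj /= np.sqrt(embed_dim)
        self.encoder_id = f"hash-bow-{embed_dim}-v{vocab_size}-s{seed}"

    def encode(self, text: str) -> np.ndarray:
        if not text:
            raise ValueError("cannot encode an empty prompt")
        counts = np.zeros(self.vocab_size, dtype=np.float32)
        for token in _TOKEN_RE.findall(text.lower()):
            counts[_stable_token_index(token, self.vocab_size)] += 1.0
        vec = counts @ self._proj
        norm = float(np.linalg.norm(vec))
        return vec / norm if norm > 0 else vec


def encode_text(prompt: str, encoder: TextEncoder) -> PromptEmbedding:
    """Encode one prompt with a frozen encoder."""
    if not prompt:
        raise ValueError("cannot encode an empty prompt")
    vec = np.asarray(encoder.encode(prompt), dtype=np.float32)
    if vec.shape != (encoder.embed_dim,):
        raise ValueError(
            f"encoder {encoder.encoder_id} returned length {vec.shape}, "
            f"declared {encoder.embed_dim}")
    return PromptEmbedding(vector=vec, encoder_id=encoder.encoder_id)


def encode_batch(prompts: list[str], encoder: TextEncoder) -> np.ndarray:
    """Encode a list of prompts into a (B, e) float32 array."""
    return np.stack([encode_text(p, encoder).vector for p in prompts])


class EmbeddingProjector(Module):
    """Trainable affine map from encoder width e to conditioning width d."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 init: str = "random", dtype=np.float32):
        self.linear = Linear(in_dim, out_dim, rng, dtype=dtype)
        if init == "identity":
            if in_dim != out_dim:
                raise ValueError("identity init requires a square projector")
            self.linear.weight = Parameter(np.eye(in_dim, dtype=dtype))
        elif init == "zero":
            self.linear.weight = Parameter(np.zeros((in_dim, out_dim), dtype=dtype))
        elif init != "random":
            raise ValueError(f"unknown init {init!r}")
        self.in_dim = in_dim
        self.out_dim = out_dim

    def forward(self, emb: ad.Tensor | np.ndarray) -> ad.Tensor:
        emb = ad.as_tensor(emb)
        if emb.shape[-1] != self.in_dim:
            raise ValueError(
                f"projector expects width {self.in_dim}, got {emb.shape[-1]}")
        return self.linear(emb)


def project_embedding(embedding: PromptEmbedding, projector: EmbeddingProjector) -> ProjectedEmbedding:
    """Project a single embedding (non-training convenience path)."""
    out = projector(embedding.vector[None, :])
    return ProjectedEmbedding(vector=out.data[0])
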