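"""Latent-representation layer.

Real deployments plug in latent vectors from a pretrained molecular
autoencoder (CDDD-style translation models, variational or adversarial
autoencoders) as a precomputed CSV matrix keyed by canonical SMILES.  For
everything testable on a desk the package ships a deterministic toy
sequence encoder: each (token, position) pair owns a fixed pseudo-random
vector derived from the seed, and a sequence maps to the mean of its
(token, position) vectors.

The basis vectors are *position-localized and sparse*: the vector for
(token, position) has a single nonzero coordinate inside the block of
latent dimensions assigned to that position, with a seed-derived
pseudo-random value of magnitude >= 1.  This emulates two properties of
pretrained sequence-to-sequence latents that the whole modelling approach
presumes: the fixed-length vector retains positional structure of the
input string, and it is already feature-ready — no generic decoding stage
remains to be learned downstream.  Convolution windows can thus read token
information (local, composition features) directly, while integrating
position-weighted information (global, arrangement features) is left to
models that traverse the latent as an ordered sequence.  Two sequences
with the same token multiset but different order map to different vectors
(almost surely), which is what lets permutation "isomers" be distinguished
at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .data_io import LatentMatrix
from .errors import MissingEmbeddingError

_MAX_CACHE = 64


class EncoderKind(str, Enum):
    toy = "toy"
    external_matrix = "external_matrix"


@dataclass
class EncoderSpec:
    latent_dim: int = 512
    kind: EncoderKind = EncoderKind.toy
    seed: int = 0
    max_len: int = 120
    # canonical SMILES -> vector, for kind == external_matrix
    table: dict = field(default=None, repr=False)

    def __post_init__(self):
        self.kind = EncoderKind(self.kind)
        if self.latent_dim < 8:
            raise ValueError("latent_dim must be >= 8")


# one basis table per (seed, latent_dim, max_len); vocab dimension grows lazily
_basis_cache: dict = {}


def _basis(spec: EncoderSpec, token: int, position: int) -> np.ndarray:
    key = (spec.seed, spec.latent_dim, spec.max_len, token, position)
    vec = _basis_cache.get(key)
    if vec is None:
        n_segments = min(spec.max_len, spec.latent_dim)
        width = spec.latent_dim // n_segments
        start = (position % n_segments) * width
        rng = np.random.default_rng([spec.seed, token, position])
        value = rng.standard_normal()
        vec = np.zeros(spec.latent_dim)
        # magnitude kept >= 1 so no (token, position) signal ever vanishes
        vec[start + token % width] = value + np.copysign(1.0, value)
        if len(_basis_cache) > _MAX_CACHE * 4096:
            _basis_cache.clear()
        _basis_cache[key] = vec
    return vec


def toy_encode_sequence(tokens, spec: EncoderSpec) -> np.ndarray:
    """Deterministic embedding of an integer token sequence.

    The (token, position) basis vectors are summed and divided by the
    sequence length, so the embedding scale is length-independent.
    """
    tokens = list(tokens)
    if not 1 <= len(tokens) <= spec.max_len:
        raise ValueError(
            f"sequence length must be in [1, {spec.max_len}], got {len(tokens)}")
    acc = np.zeros(spec.latent_dim)
    for pos, tok in enumerate(tokens):
        acc += _basis(spec, int(tok), pos)
    return acc / len(tokens)


def encode_sequences(sequences, spec: EncoderSpec) -> LatentMatrix:
    """Encode a list of integer token sequences into an n x latent_dim matrix."""
    return LatentMatrix(np.stack([toy_encode_sequence(s, spec) for s in sequences]))


def smiles_tokens(smiles: str) -> list:
    """Character-level tokenization; the toy encoder is sequence- not chemistry-aware."""
    return [ord(c) for c in smiles]


def load_external_table(path) -> dict:
    """Load an external embedding CSV: first column canonical SMILES, rest the vector."""
    import pandas as pd

    df = pd.read_csv(path, header=None)
    return {str(row.iloc[0]): row.iloc[1:].to_numpy(dtype=float)
            for _, row in df.iterrows()}


def encode(spec: EncoderSpec, smiles_list) -> LatentMatrix:
    """Encode SMILES spellings into latent vectors.

    The toy encoder consumes the spelling as given (not re-canonicalized),
    so different enumerations of one molecule produce different vectors —
    the property SMILES-enumeration augmentation relies on.  The external
    encoder looks spellings up by canonical form, since pretrained matrices
    are keyed that way.
    """
    if spec.kind is EncoderKind.toy:
        return encode_sequences([smiles_tokens(s) for s in smiles_list], spec)
    if spec.table is None:
        raise MissingEmbeddingError("external encoder requires a loaded table")
    from .smiles_aug import canonicalize

    rows = []
    for s in smiles_list:
        key = canonicalize(s)
        if key not in spec.table:
            raise MissingEmbeddingError(f"no embedding for molecule {key!r}")
        rows.append(spec.table[key])
    return LatentMatrix(np.stack(rows))
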