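"""Per-residue embedding providers.

Real deployments inject embeddings from a pretrained protein language
model (ProtT5-class models emit 1024-dimensional rows).  Transformer
inference is outside this package; two providers cover the contract:

* :class:`ReferenceEmbedder` — a deterministic, seeded featurizer used
  for testing and synthetic experiments.  Each residue's row is a fixed
  random projection of its one-hot identity concatenated with hashed
  features of the +/-2-residue context window, so rows are
  context-sensitive yet fully reproducible.
* :class:`PrecomputedEmbedder` — serves L x d matrices precomputed
  offline (e.g. by a real language model) from an .npz container keyed
  by sequence id or by the sequence itself.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure_io import STANDARD_AA

_ALPHABET = STANDARD_AA + "X"
_AA_TO_IDX = {aa: i for i, aa in enumerate(_ALPHABET)}

#: context half-width of the reference embedder
CONTEXT_WINDOW = 2


@dataclass(frozen=True)
class EmbedderSpec:
    name: str = "reference"
    dim: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError("embedding dimension must be >= 1")


class ReferenceEmbedder:
    """Deterministic context-window embedder.

    The input feature of residue i is the concatenation of the one-hot
    vectors of positions i-2..i+2 (out-of-range positions use a padding
    symbol), hashed to a stable integer and projected through a seeded
    Gaussian matrix.  Residues with identical +/-2 context windows get
    identical rows.
    """

    def __init__(self, spec: EmbedderSpec | None = None, *,
                 dim: int | None = None, seed: int | None = None):
        if spec is None:
            spec = EmbedderSpec(dim=dim if dim is not None else 32,
                                seed=seed if seed is not None else 0)
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        n_ctx = 2 * CONTEXT_WINDOW + 1
        # projection from the stacked context one-hots (22 symbols incl. pad)
        self._proj = rng.standard_normal((n_ctx * (len(_ALPHABET) + 1),
                                          spec.dim)) / np.sqrt(n_ctx)

    @property
    def dim(self) -> int:
        return self.spec.dim

    def embed(self, sequence: str) -> np.ndarray:
        if not sequence:
            raise ValueError("cannot embed an empty sequence")
        L = len(sequence)
        pad_idx = len(_ALPHABET)  # padding symbol index
        n_sym = len(_ALPHABET) + 1
        n_ctx = 2 * CONTEXT_WINDOW + 1
        ctx = np.zeros((L, n_ctx * n_sym))
        for i in range(L):
            for w in range(-CONTEXT_WINDOW, CONTEXT_WINDOW + 1):
                j = i + w
                sym = _AA_TO_IDX[sequence[j]] if 0 <= j < L else pad_idx
                ctx[i, (w + CONTEXT_WINDOW) * n_sym + sym] = 1.0
        # hash-derived per-window phase makes rows depend on the exact
        # window content beyond the linear projection
        phases = np.array([self._window_phase(sequence, i) for i in range(L)])
        return ctx @ self._proj + 0.1 * np.sin(phases)[:, None]

    def _window_phase(self, sequence: str, i: int) -> float:
        lo = max(0, i - CONTEXT_WINDOW)
        hi = min(len(sequence), i + CONTEXT_WINDOW + 1)
        pad_left = CONTEXT_WINDOW - (i - lo)
        pad_right = CONTEXT_WINDOW - (hi - 1 - i)
        window = "^" * pad_left + sequence[lo:hi] + "$" * pad_right
        digest = hashlib.sha256(
            f"{self.spec.seed}:{window}".encode()).digest()
        return int.from_bytes(digest[:4], "little") / 2**32 * 2 * np.pi


class PrecomputedEmbedder:
    """Serve embeddings computed offline, keyed by id or sequence.

    The container is a single .npz whose arrays are the L x d matrices;
    the array names are the keys.  When ``key_by_sequence`` is true the
    sha256 hex digest of the sequence is used as the key, which lets a
    caller store embeddings without tracking chain identifiers.
    """

    def __init__(self, path: str | Path, dim: int,
                 key_by_sequence: bool = True):
        self._store = np.load(Path(path), allow_pickle=False)
        self._dim = dim
        self._key_by_sequence = key_by_sequence

    @property
    def dim(self) -> int:
        return self._dim

    def embed(self, sequence: str, key: str | None = None) -> np.ndarray:
        if key is None:
            if not self._key_by_sequence:
                raise KeyError("this store requires an explicit key")
            key = hashlib.sha256(sequence.encode()).hexdigest()
        E = np.asarray(self._store[key], dtype=np.float64)
        if E.shape != (len(sequence), self._dim):
            raise ValueError(f"stored embedding for {key} has shape "
                             f"{E.shape}, expected ({len(sequence)}, {self._dim})")
        return E

    @staticmethod
    def save(path: str | Path, embeddings: dict[str, np.ndarray]) -> None:
        np.savez(Path(path), **embeddings)

    @staticmethod
    def sequence_key(sequence: str) -> str:
        return hashlib.sha256(sequence.encode()).hexdigest()


def embed_sequence(sequence: str, spec: EmbedderSpec) -> np.ndarray:
    """Embed one sequence with the reference embedder described by spec."""
    return ReferenceEmbedder(spec).embed(sequence)
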