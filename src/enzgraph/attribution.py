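"""Gradient-based residue attribution (saliency mapping).

For a chosen class, the gradient of the model's output probability with
respect to every entry of the node input H0 = [X | E] is computed by
backpropagation.  Per residue, the absolute gradient entries (Saliency)
or absolute gradient-times-input entries (InputXGradient) are summed
across feature dimensions and min-max normalized to [0, 1]; the top
fraction of residues (10% by default) are reported as putative
catalytic sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff import Tensor
from .graphs import ProteinGraph
from .model import ModelConfig, _forward_t

DEFAULT_TOP_FRACTION = 0.10


class AttributionMethod(str, Enum):
    SALIENCY = "saliency"
    INPUT_X_GRADIENT = "input_x_gradient"


@dataclass
class SaliencyMap:
    chain_ref: str
    target_class: int
    scores: np.ndarray              # (L,), min-max normalized to [0, 1]
    method: AttributionMethod

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if np.any((s < 0) | (s > 1)):
            raise ValueError("scores must lie in [0, 1]")
        self.scores = s

    def __len__(self) -> int:
        return len(self.scores)


def _normalize(raw: np.ndarray) -> np.ndarray:
    """Min-max normalize; an all-constant map becomes all zeros."""
    lo, hi = raw.min(), raw.max()
    if hi - lo == 0:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def input_gradient(graph: ProteinGraph, params: dict[str, Tensor],
                   config: ModelConfig, target_class: int) -> np.ndarray:
    """d p[target_class] / d H0, shape (L, input_dim)."""
    if not 0 <= target_class < config.n_classes:
        raise IndexError(f"target class {target_class} out of range")
    H0 = Tensor(graph.node_input, requires_grad=True)
    probs = _forward_t(H0, graph.adjacency, params, config)
    probs[target_class].backward()
    return np.zeros_like(H0.value) if H0.grad is None else H0.grad


def node_saliency(graph: ProteinGraph, params: dict[str, Tensor],
                  config: ModelConfig, target_class: int) -> SaliencyMap:
    """Per-residue saliency: summed absolute input gradients, normalized."""
    grad = input_gradient(graph, params, config, target_class)
    raw = np.abs(grad).sum(axis=1)
    return SaliencyMap(chain_ref=graph.chain_ref, target_class=target_class,
                       scores=_normalize(raw),
                       method=AttributionMethod.SALIENCY)


def node_input_x_gradient(graph: ProteinGraph, params: dict[str, Tensor],
                          config: ModelConfig, target_class: int
                          ) -> SaliencyMap:
    """Per-residue attribution from gradient x input, normalized."""
    grad = input_gradient(graph, params, config, target_class)
    raw = np.abs(grad * graph.node_input).sum(axis=1)
    return SaliencyMap(chain_ref=graph.chain_ref, target_class=target_class,
                       scores=_normalize(raw),
                       method=AttributionMethod.INPUT_X_GRADIENT)


def top_fraction_residues(saliency: SaliencyMap,
                          fraction: float = DEFAULT_TOP_FRACTION
                          ) -> list[int]:
    """1-based positions of the ceil(fraction * L) highest-scoring residues.

    Ties are broken toward the lower residue position; output is sorted
    ascending.  At least one residue is always returned.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    L = len(saliency)
    if L == 0:
        raise ValueError("empty saliency map")
    k = math.ceil(fraction * L)
    # stable sort on -score keeps lower positions first among ties
    order = np.argsort(-saliency.scores, kind="stable")
    return sorted(int(i) + 1 for i in order[:k])


def write_score_table(maps: list[SaliencyMap], sequences: dict[str, str],
                      path: str | Path,
                      fraction: float = DEFAULT_TOP_FRACTION) -> None:
    """Per-residue score track as TSV, flagging the top-fraction residues."""
    rows = []
    for smap in maps:
        selected = set(top_fraction_residues(smap, fraction))
        seq = sequences.get(smap.chain_ref, "")
        for pos, score in enumerate(smap.scores, start=1):
            rows.append({"chain": smap.chain_ref, "position": pos,
                         "aa": seq[pos - 1] if pos <= len(seq) else "?",
                         "score": score,
                         "selected": int(pos in selected),
                         "class": smap.target_class,
                         "method": smap.method.value})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")
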