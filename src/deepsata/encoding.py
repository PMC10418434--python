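"""The 1000 x 4 x (N+1) input tensor.

Layer 1 is the one-hot encoding of the window sequence with channel order
A, T, C, G ([1,0,0,0] = A, [0,1,0,0] = T, [0,0,1,0] = C, [0,0,0,1] = G; an
N or padded base is the all-zero row).  Layers 2..N+1 are TF
binding-affinity layers: at each predicted binding site of the layer's
motif the sub-matrix is populated with the motif's position-probability
rows, everything else is 0.  A reverse-strand site is written with the
reverse-complemented PPM so every row always describes forward-strand base
probabilities.  Positions covered by several sites of the same motif take
the element-wise maximum.

A flattened ablation variant (`build_flat_tensor`) carries, instead of a
4-channel plane per TF, a single extra column per TF holding the PPM
probability of the realized base at covered positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .motifs import BASE_INDEX, Motif, MotifHit

WINDOW_SIZE = 1000

_ONE_HOT_LUT = np.zeros((5, 4), dtype=np.float32)
for _b in range(4):
    _ONE_HOT_LUT[_b, _b] = 1.0  # row 4 (N) stays all-zero


@dataclass
class EncodedExample:
    """A window encoded as a (window, 4, N+1) tensor plus its TF layer order."""

    tensor: np.ndarray
    tf_order: list[str]
    bin_ref: str = ""

    def __post_init__(self) -> None:
        if self.tensor.ndim != 3 or self.tensor.shape[1] != 4:
            raise ValueError(f"tensor must be (window, 4, N+1), got {self.tensor.shape}")
        if self.tensor.shape[2] != len(self.tf_order) + 1:
            raise ValueError("third axis must have extent len(tf_order) + 1")


def _indices(seq: str) -> np.ndarray:
    try:
        return np.array([BASE_INDEX[b] for b in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"illegal character {exc.args[0]!r} in sequence") from exc


def one_hot(seq: str, window_len: int = WINDOW_SIZE) -> np.ndarray:
    """(window_len, 4) one-hot matrix in A,T,C,G channel order; N -> zeros."""
    if len(seq) != window_len:
        raise ValueError(f"sequence length {len(seq)} != {window_len}")
    return _ONE_HOT_LUT[_indices(seq.upper())].copy()


def encode_tf_layer(
    window_len: int,
    hits: Sequence[MotifHit],
    motif: Motif,
) -> np.ndarray:
    """One TF binding-affinity layer: PPM rows at predicted sites, 0 elsewhere.

    Overlapping sites of the motif are combined by element-wise maximum.
    """
    layer = np.zeros((window_len, 4), dtype=np.float32)
    L = len(motif)
    fwd = motif.ppm.astype(np.float32)
    rev = motif.reverse_complement().ppm.astype(np.float32)
    for h in hits:
        if h.start < 0 or h.start + L > window_len:
            raise ValueError(
                f"hit at {h.start} (+{L}) extends past the {window_len} bp window"
            )
        block = fwd if h.strand == "+" else rev
        region = layer[h.start : h.start + L]
        np.maximum(region, block, out=region)
    return layer


def build_tensor(
    seq: str,
    hits_by_motif: Mapping[str, Sequence[MotifHit]],
    tf_order: Sequence[str],
    motifs: Mapping[str, Motif],
    bin_ref: str = "",
) -> EncodedExample:
    """Assemble the full (window, 4, N+1) tensor for one window."""
    window_len = len(seq)
    tensor = np.zeros((window_len, 4, len(tf_order) + 1), dtype=np.float32)
    tensor[:, :, 0] = one_hot(seq, window_len)
    for k, mid in enumerate(tf_order):
        tensor[:, :, k + 1] = encode_tf_layer(
            window_len, hits_by_motif.get(mid, ()), motifs[mid]
        )
    return EncodedExample(tensor, list(tf_order), bin_ref)


def build_flat_tensor(
    seq: str,
    hits_by_motif: Mapping[str, Sequence[MotifHit]],
    tf_order: Sequence[str],
    motifs: Mapping[str, Motif],
) -> np.ndarray:
    """Flattened ablation encoding: (window, 4 + N) matrix.

    Columns 1..4 are the one-hot sequence; column 4+k carries, at positions
    covered by a site of motif ``tf_order[k]``, the PPM probability of the
    realized (forward-strand) base there — the dot product of the one-hot
    row with the corresponding 3-D TF-layer row — and 0 elsewhere.
    """
    window_len = len(seq)
    oh = one_hot(seq, window_len)
    cols = [oh]
    for mid in tf_order:
        layer = encode_tf_layer(window_len, hits_by_motif.get(mid, ()), motifs[mid])
        cols.append((layer * oh).sum(axis=1, keepdims=True))
    return np.concatenate(cols, axis=1)


def encode_windows(
    windows: Sequence[str],
    hits_per_window: Sequence[Mapping[str, Sequence[MotifHit]]],
    tf_order: Sequence[str],
    motifs: Mapping[str, Motif],
    flat: bool = False,
) -> np.ndarray:
    """Batch encoding: (n, window, 4, N+1) tensors or (n, window, 4+N) flats."""
    if flat:
        return np.stack(
            [build_flat_tensor(w, h, tf_order, motifs)
             for w, h in zip(windows, hits_per_window)]
        )
    return np.stack(
        [build_tensor(w, h, tf_order, motifs).tensor
         for w, h in zip(windows, hits_per_window)]
    )
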