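"""Orthogonal wavelet-packet decomposition with periodized boundaries.

The pipeline compresses each motion channel by walking the repeated low-pass
(approximation) path of a full wavelet-packet tree: one level halves the
length, so level 2 turns a 49,000-sample channel into 12,250 coefficients.
High-pass (detail) nodes are computed but discarded by the pipeline — the
high-frequency content of rider motion is sparse and carries little class
information.

Boundary handling is periodization ("wrap-around" correlation), the only
convention under which lengths halve exactly. The filter-alignment phase is
fixed so that every node agrees with PyWavelets' ``periodization`` mode:
``approx[m] = sum_k h[k] x[(2m + k + 1 - L/2) mod n]`` for a length-L filter,
with odd-length inputs first extended by repeating their last sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaveletFilterPair",
    "PacketNode",
    "PacketTree",
    "get_filters",
    "packet_step",
    "decompose",
    "select_node",
    "compress_recording",
    "compress_matrix",
]

_SQRT3 = np.sqrt(3.0)

#: Orthogonal scaling (low-pass) filters. The high-pass mate follows from the
#: quadrature-mirror relation g[k] = (-1)^k h[2N-1-k].
_SCALING_FILTERS: dict[str, tuple[float, ...]] = {
    "haar": (1 / np.sqrt(2), 1 / np.sqrt(2)),
    "db2": (
        (1 + _SQRT3) / (4 * np.sqrt(2)),
        (3 + _SQRT3) / (4 * np.sqrt(2)),
        (3 - _SQRT3) / (4 * np.sqrt(2)),
        (1 - _SQRT3) / (4 * np.sqrt(2)),
    ),
}


@dataclass(frozen=True)
class WaveletFilterPair:
    """An orthogonal analysis filter pair (h low-pass, g high-pass)."""

    h: np.ndarray
    g: np.ndarray
    name: str

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if h.shape != g.shape or h.ndim != 1 or len(h) % 2:
            raise ValueError("h and g must be 1-D, equal even length")
        n = len(h)
        qmr = np.array([(-1) ** k * h[n - 1 - k] for k in range(n)])
        if not np.allclose(g, qmr, atol=1e-12):
            raise ValueError("g violates the quadrature-mirror relation")
        if abs(h.sum() - np.sqrt(2)) > 1e-12:
            raise ValueError("sum(h) must equal sqrt(2)")
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "g", g)


def get_filters(name: str) -> WaveletFilterPair:
    """Return the named orthogonal filter pair (``haar`` or ``db2``)."""
    try:
        h = np.asarray(_SCALING_FILTERS[name], dtype=float)
    except KeyError:
        raise ValueError(
            f"unknown wavelet {name!r}; available: {sorted(_SCALING_FILTERS)}"
        ) from None
    n = len(h)
    g = np.array([(-1) ** k * h[n - 1 - k] for k in range(n)])
    return WaveletFilterPair(h=h, g=g, name=name)


@dataclass(frozen=True)
class PacketNode:
    """Node W_{level,index} of the packet tree and its coefficients."""

    level: int
    index: int
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        if self.index >= 2**self.level:
            raise ValueError("index must be < 2**level")


@dataclass(frozen=True)
class PacketTree:
    """A fully decomposed wavelet-packet tree down to ``levels``."""

    root_length: int
    levels: int
    nodes: dict[tuple[int, int], PacketNode]
    filter_name: str


def _periodized_halfband(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Correlate periodically with ``filt`` and downsample by 2 (pywt phase)."""
    if len(x) % 2:
        x = np.concatenate([x, x[-1:]])
    n, L = len(x), len(filt)
    shift = 1 - L // 2
    # gather x[(2m + k + shift) mod n] for m rows, k columns
    m = np.arange(n // 2)[:, None]
    k = np.arange(L)[None, :]
    return np.asarray((x[(2 * m + k + shift) % n] * filt).sum(axis=1))


def packet_step(
    coefficients: np.ndarray, filters: WaveletFilterPair
) -> tuple[np.ndarray, np.ndarray]:
    """One analysis step: split a sequence into approximation and detail.

    Discrete analogue of the two-scale recursions
    ``W_{2n}(x) = sqrt(2) sum_k h(k) W_n(2x - k)`` and its high-pass mate:
    periodized correlation with h (resp. g) followed by downsampling by two.
    Output lengths are ``ceil(len(input) / 2)``.
    """
    x = np.asarray(coefficients, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if x.size < 2:
        raise ValueError("packet step needs at least 2 samples")
    return _periodized_halfband(x, filters.h), _periodized_halfband(x, filters.g)


def decompose(
    signal: np.ndarray, filters: WaveletFilterPair, levels: int
) -> PacketTree:
    """Build the full packet tree of depth ``levels`` for a 1-D signal.

    Node (L, n) holds W_{L,n}; (L, 0) is the L-fold low-pass path whose
    coefficients are the compressed signal used downstream.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if len(x) < 2**levels:
        raise ValueError(
            f"too many levels: need len(signal) >= 2**levels = {2**levels}"
        )
    nodes = {(0, 0): PacketNode(0, 0, x)}
    for level in range(levels):
        for index in range(2**level):
            parent = nodes[(level, index)]
            approx, detail = packet_step(parent.coefficients, filters)
            nodes[(level + 1, 2 * index)] = PacketNode(level + 1, 2 * index, approx)
            nodes[(level + 1, 2 * index + 1)] = PacketNode(
                level + 1, 2 * index + 1, detail
            )
    return PacketTree(
        root_length=len(x), levels=levels, nodes=nodes, filter_name=filters.name
    )


def select_node(tree: PacketTree, level: int, index: int) -> np.ndarray:
    """Return the coefficients of W_{level,index}; (2, 0) is the default "A2"."""
    try:
        return tree.nodes[(level, index)].coefficients
    except KeyError:
        raise KeyError(f"node ({level}, {index}) not in tree") from None


def compress_matrix(
    values: np.ndarray, filters: WaveletFilterPair, level: int = 2
) -> np.ndarray:
    """Compress each column of a frames x channels matrix to its level-``level``
    approximation node. ``level=0`` is the identity."""
    values = np.asarray(values, dtype=float)
    if level == 0:
        return values.copy()
    cols = [
        select_node(decompose(values[:, j], filters, level), level, 0)
        for j in range(values.shape[1])
    ]
    return np.column_stack(cols)


def compress_recording(recording, filters: WaveletFilterPair, level: int = 2):
    """Compress all 8 channels of a :class:`~gaitstack.synth.MotionRecording`.

    Returns a new recording with the same label/seed and the level-``level``
    approximation coefficients as values (length ceil(n / 2**level)).
    """
    from .synth import MotionRecording

    compressed = compress_matrix(recording.values, filters, level)
    return MotionRecording(
        values=compressed, gait_label=recording.gait_label, seed=recording.seed
    )
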