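"""Wavelet-packet decomposition and reduced feature matrices.

A wavelet packet splits *both* the approximation and the detail branch at
every level, so depth ``n`` yields ``2^n`` subband nodes per layer
(indexed ``[layer, k]`` in natural filter-bank order) while downsampling
keeps the total coefficient count roughly constant.  The plain wavelet
transform is the ``[j, 0]`` approximation path of this tree.

For 100-frame gait windows with the default Haar wavelet the per-node
length cascade is 100 -> 50 -> 25 -> 13, so the layer-2 approximation
node turns a 100 x N dataset into the 25 x N feature block used by the
classifier.

The decomposition itself is delegated to PyWavelets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pywt

from .dataset import GaitDataset

__all__ = [
    "DEFAULT_WAVELET",
    "WPNode",
    "FeatureMatrix",
    "wp_decompose",
    "wp_reconstruct",
    "count_nodes",
    "node_length_cascade",
    "wp_layer_features",
    "write_features",
    "read_features",
]

#: Haar (db1): filter length 2 reproduces the 100/50/25/13 cascade exactly.
DEFAULT_WAVELET = "haar"

#: Half-point symmetric extension; the conventional default whose
#: coefficient lengths follow floor((n + L - 1) / 2).
_MODE = "symmetric"


@dataclass
class WPNode:
    """One subband ``[layer, index]`` of the packet tree.

    ``coefficients`` is a vector for a single-signal tree or a
    node_length x samples matrix for a dataset-level feature block.
    """

    layer: int
    index: int
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        if not (0 <= self.index < 2**self.layer):
            raise IndexError(
                f"node index {self.index} out of range for layer {self.layer}"
            )
        self.coefficients = np.asarray(self.coefficients, dtype=float)


@dataclass
class FeatureMatrix:
    """Reduced feature block with provenance (wavelet, layer, node)."""

    features: np.ndarray
    wavelet: str
    layer: int
    node: int | str  # subband index, or "all" for a whole layer

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))

    @property
    def n_samples(self) -> int:
        return self.features.shape[1]


def _node_path(index: int, layer: int) -> str:
    """Natural-order path string for subband ``index`` at ``layer``
    (binary digits, a=0 / d=1)."""
    if layer == 0:
        return ""
    bits = format(index, f"0{layer}b")
    return bits.replace("0", "a").replace("1", "d")


def wp_decompose(
    signal: np.ndarray, depth: int, wavelet: str = DEFAULT_WAVELET
) -> dict[tuple[int, int], WPNode]:
    """Full wavelet-packet tree of one signal down to ``depth``.

    Returns a mapping ``(layer, index) -> WPNode`` covering every node of
    layers 0..depth; layer 0 node ``[0, 0]`` is the input signal itself.

    Raises
    ------
    ValueError
        If ``depth < 1`` or the signal is shorter than ``2**depth``.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if signal.size < 2**depth:
        raise ValueError(
            f"signal of length {signal.size} too short for depth {depth}"
        )
    wp = pywt.WaveletPacket(
        data=signal, wavelet=wavelet, mode=_MODE, maxlevel=depth
    )
    nodes: dict[tuple[int, int], WPNode] = {
        (0, 0): WPNode(0, 0, signal.copy())
    }
    for layer in range(1, depth + 1):
        for k in range(2**layer):
            data = wp[_node_path(k, layer)].data
            nodes[(layer, k)] = WPNode(layer, k, np.asarray(data, dtype=float))
    return nodes


def wp_reconstruct(
    nodes: dict[tuple[int, int], WPNode],
    layer: int,
    length: int,
    wavelet: str = DEFAULT_WAVELET,
) -> np.ndarray:
    """Inverse transform from all subbands of one layer back to the signal."""
    wp = pywt.WaveletPacket(
        data=None, wavelet=wavelet, mode=_MODE, maxlevel=layer
    )
    for k in range(2**layer):
        wp[_node_path(k, layer)] = nodes[(layer, k)].coefficients
    return np.asarray(wp.reconstruct(update=False), dtype=float)[:length]


def count_nodes(depth: int) -> tuple[list[int], int]:
    """Subband counts per layer and the total over layers 1..depth.

    Layer ``j`` holds ``2**j`` nodes; for depth 3 the decomposed layers
    contribute 2 + 4 + 8 = 14 subbands.  ``depth == 0`` counts the single
    root node.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    counts = [2**j for j in range(depth + 1)]
    total = sum(counts[1:]) if depth >= 1 else 1
    return counts, total


def node_length_cascade(
    n: int, depth: int, wavelet: str = DEFAULT_WAVELET
) -> list[int]:
    """Per-layer coefficient lengths for an ``n``-sample signal,
    floor((n + L - 1)/2) at each split (100 -> 50 -> 25 -> 13 for Haar)."""
    filt_len = pywt.Wavelet(wavelet).dec_len
    lengths = [n]
    for _ in range(depth):
        lengths.append(pywt.dwt_coeff_len(lengths[-1], filt_len, mode=_MODE))
    return lengths


def wp_layer_features(
    data: GaitDataset,
    layer: int,
    wavelet: str = DEFAULT_WAVELET,
    node: int | str = 0,
) -> FeatureMatrix:
    """Per-sample wavelet-packet features at one layer.

    Each signal column is decomposed and the chosen subband's coefficients
    become the feature column.  ``node=0`` (the approximation path) is the
    default reduction: a 100 x 160 dataset at layer 2 becomes 25 x 160.
    ``node="all"`` concatenates the layer's ``2**layer`` subbands row-wise.
    ``layer=0`` is the identity (features = signals).
    """
    if layer < 0:
        raise ValueError("layer must be >= 0")
    if layer == 0:
        return FeatureMatrix(data.signals.copy(), wavelet, 0, 0)
    if node != "all":
        node = int(node)
        if not 0 <= node < 2**layer:
            raise IndexError(
                f"node index {node} out of range for layer {layer} "
                f"(0..{2**layer - 1})"
            )
    cols = []
    for i in range(data.n_samples):
        nodes = wp_decompose(data.signals[:, i], depth=layer, wavelet=wavelet)
        if node == "all":
            col = np.concatenate(
                [nodes[(layer, k)].coefficients for k in range(2**layer)]
            )
        else:
            col = nodes[(layer, node)].coefficients
        cols.append(col)
    return FeatureMatrix(np.column_stack(cols), wavelet, layer, node)


def write_features(fm: FeatureMatrix, path: str | Path,
                   delimiter: str = ",") -> None:
    """Delimited text export with a provenance comment line."""
    with open(path, "w") as fh:
        fh.write(f"# wavelet={fm.wavelet} layer={fm.layer} node={fm.node}\n")
        for row in fm.features:
            fh.write(delimiter.join(f"{v:.17g}" for v in row) + "\n")


def read_features(path: str | Path, delimiter: str = ",") -> FeatureMatrix:
    """Read a feature matrix written by :func:`write_features`."""
    wavelet, layer, node = DEFAULT_WAVELET, 0, 0
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                parts = dict(
                    kv.split("=") for kv in line.lstrip("# ").split()
                )
                wavelet = parts.get("wavelet", wavelet)
                layer = int(parts.get("layer", layer))
                node_s = parts.get("node", node)
                node = node_s if node_s == "all" else int(node_s)
                continue
            if line:
                rows.append([float(v) for v in line.split(delimiter)])
    return FeatureMatrix(np.array(rows, dtype=float), wavelet, layer, node)
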