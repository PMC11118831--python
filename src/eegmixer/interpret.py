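"""Diagnostics of learned representations: per-layer activation maps and
t-SNE embeddings of first/last layer features.

"First layer" means the post-patch-embedding activations and "last layer"
the output of the final mixer block (pre-pooling); both are exposed by
index so intermediate blocks can be inspected too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .model import ConvMixerECA, ForwardTrace

__all__ = ["EmbeddingResult", "layer_features", "tsne_embed", "activation_maps"]


@dataclass
class EmbeddingResult:
    """2-D embedding of one layer's features, one point per input epoch."""

    points: np.ndarray
    layer_tag: str
    seed: int
    perplexity: float
    silhouette: float | None = None


def layer_features(model: ConvMixerECA, x: np.ndarray, layer_index: int,
                   batch_size: int = 64) -> np.ndarray:
    """Flattened activations of one trace layer for every epoch.

    Layer 0 is the patch embedding; layers 1..depth are mixer-block
    outputs (``-1`` addresses the last block).  Batching is deterministic
    and has no effect on the result because the network has no cross-batch
    state.
    """
    n_layers = model.config.depth + 1
    if not -n_layers <= layer_index < n_layers:
        valid = ", ".join(str(i) for i in range(n_layers))
        raise IndexError(
            f"layer_index {layer_index} out of range; valid layers: {valid}"
        )
    x = np.asarray(x)
    rows = []
    for lo in range(0, x.shape[0], batch_size):
        _, tr = model.forward(x[lo : lo + batch_size], trace=True)
        act = tr.activations[layer_index]
        rows.append(act.reshape(act.shape[0], -1))
    return np.concatenate(rows, axis=0)


def tsne_embed(features: np.ndarray, labels: np.ndarray | None = None,
               perplexity: float = 30.0, iters: int = 1000, seed: int = 0,
               layer_tag: str = "", pca_dims: int = 50) -> EmbeddingResult:
    """Seeded t-SNE to 2-D, with PCA pre-reduction above ``pca_dims`` dims.

    When labels are given, the silhouette score of the embedding against
    them is attached as a separation summary.
    """
    features = np.asarray(features, dtype=np.float64)
    n = features.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"need more than 3*perplexity={3 * perplexity:.0f} points, got {n}"
        )
    if features.shape[1] > pca_dims:
        features = PCA(n_components=pca_dims, random_state=seed).fit_transform(features)
    points = TSNE(
        n_components=2, perplexity=perplexity, max_iter=iters,
        random_state=seed, init="pca",
    ).fit_transform(features)
    sil = None
    if labels is not None:
        labels = np.asarray(labels)
        if len(np.unique(labels)) > 1:
            sil = float(silhouette_score(points, labels))
    return EmbeddingResult(
        points=points, layer_tag=layer_tag, seed=seed,
        perplexity=perplexity, silhouette=sil,
    )


def activation_maps(trace: ForwardTrace, threshold: float = 0.1
                    ) -> tuple[list[np.ndarray], list[float]]:
    """Mean-over-batch magnitude maps per layer plus a sparsity summary.

    Each map is [hidden_dim x positions]; the sparsity statistic is the
    fraction of map entries below ``threshold`` times the layer maximum,
    quantifying how coarse/sparse deeper layers become.
    """
    if not trace.activations:
        raise ValueError("trace has no activations; run forward(..., trace=True)")
    maps, sparsity = [], []
    for act in trace.activations:
        m = np.abs(act).mean(axis=0)
        maps.append(m)
        peak = m.max()
        sparsity.append(float((m < threshold * peak).mean()) if peak > 0 else 0.0)
    return maps, sparsity
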