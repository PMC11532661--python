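"""Two-stage fusion of the four latents, k-means clustering, and metrics.

Fusion averages within each group (Z_ad¹ = (Z¹+Z²)/2, Z_ad² = (Z³+Z⁴)/2) and
concatenates the two group means column-wise into Z_cat ∈ R^{n×2c}.  An
optional multilayer-perceptron projection of Z_cat is provided for interface
completeness, but the default final representation is Z_cat itself: no term
of the training objective touches the projected output, so a randomly
initialized projection would only add untrained noise (see docs/methods.md).

Clustering is Lloyd's k-means with k-means++ seeding and multiple restarts.
Agreement with ground truth is reported as ACC (Hungarian-matched accuracy),
NMI (arithmetic-mean normalization), ARI, and FMI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn import metrics as skm
from sklearn.cluster import KMeans

from .network import LatentSet


@dataclass
class MetricsReport:
    acc: float
    nmi: float
    ari: float
    fmi: float

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "nmi": self.nmi, "ari": self.ari, "fmi": self.fmi}


@dataclass
class ClusterResult:
    z_final: np.ndarray
    labels: np.ndarray
    c: int
    metrics: MetricsReport | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape[0] != self.z_final.shape[0]:
            raise ValueError("labels and embedding must cover the same cells")
        if len(np.unique(self.labels)) > self.c:
            raise ValueError("more distinct labels than clusters")


def fuse(ls: LatentSet) -> np.ndarray:
    """Group-wise means concatenated: [ (z1+z2)/2 | (z3+z4)/2 ], shape (n, 2c)."""
    z_ad1 = (ls.z1 + ls.z2) / 2.0
    z_ad2 = (ls.z3 + ls.z4) / 2.0
    return np.hstack([z_ad1, z_ad2])


def project_final(
    z_cat: np.ndarray,
    mode: str = "identity",
    layers: int = 2,
    seed: int = 0,
    width: int | None = None,
) -> np.ndarray:
    """Optional projection of the fused features.

    ``mode="identity"`` (default) returns ``z_cat`` unchanged.  ``mode="mlp"``
    applies a seed-initialized, untrained perceptron with ``layers`` layers of
    Glorot-uniform weights and ReLU between them; ``width`` sets the output
    dimension (defaults to the input width).
    """
    z_cat = np.asarray(z_cat, dtype=np.float64)
    if mode == "identity":
        return z_cat
    if mode != "mlp":
        raise ValueError(f"unknown projection mode {mode!r}")
    if layers < 1:
        raise ValueError("mlp projection needs at least one layer")
    rng = np.random.default_rng(seed)
    out_dim = z_cat.shape[1] if width is None else int(width)
    h = z_cat
    for layer in range(layers):
        fan_in = h.shape[1]
        fan_out = out_dim
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        h = h @ w
        if layer < layers - 1:
            h = np.maximum(h, 0.0)
    return h


def kmeans_cluster(z: np.ndarray, c: int, seed: int = 0, n_init: int = 20) -> np.ndarray:
    """k-means labels on the embedding; deterministic for a fixed seed."""
    z = np.asarray(z, dtype=np.float64)
    if c > z.shape[0]:
        raise ValueError("cannot form more clusters than cells")
    if c < 1:
        raise ValueError("cluster count must be positive")
    km = KMeans(n_clusters=c, n_init=n_init, max_iter=300, random_state=seed % (2**32))
    return km.fit_predict(z).astype(np.int64)


def clustering_accuracy(labels: np.ndarray, truth: np.ndarray) -> float:
    """Fraction matched under the optimal one-to-one cluster↔class assignment."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    pred_codes, pred_inv = np.unique(labels, return_inverse=True)
    true_codes, true_inv = np.unique(truth, return_inverse=True)
    w = np.zeros((len(pred_codes), len(true_codes)), dtype=np.int64)
    np.add.at(w, (pred_inv, true_inv), 1)
    rows, cols = linear_sum_assignment(w, maximize=True)
    return float(w[rows, cols].sum()) / labels.size


def evaluate(labels: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """ACC / NMI / ARI / FMI between a predicted and a reference partition."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    return MetricsReport(
        acc=clustering_accuracy(labels, truth),
        nmi=float(skm.normalized_mutual_info_score(truth, labels, average_method="arithmetic")),
        ari=float(skm.adjusted_rand_score(truth, labels)),
        fmi=float(skm.fowlkes_mallows_score(truth, labels)),
    )
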