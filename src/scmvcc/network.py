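"""Shared GCN encoder and the contrastive / structural loss families.

The encoder is a two-layer graph convolutional network applied with one
shared parameter set to all four views:

    Z = softmax( Ân · ReLU( Ân · F · W1 ) · W2 ),   Ân = D̂^{-1/2}(A + I)D̂^{-1/2}

with output dimension equal to the cluster count c, so each latent column
corresponds to a cluster.  Rows of Z are then L2-normalized.

Three loss families drive training:

* **group contrastive** — an NT-Xent contrast over the c latent *columns*
  between the two views of a group, pulling matched cluster columns of the
  paired views together (cosine similarity, temperature τ);
* **structural consistency** — a squared-error push of the cross-view cell
  similarity matrix S = Z^a (Z^b)ᵀ toward the self-loop adjacency Â
  (edges → 1, non-edges → 0), averaged over all n² entries;
* **cross-view similarity contrast** — the same NT-Xent contrast applied to
  the n *rows* (cells) of the two similarity matrices S^(1,2) and S^(3,4).

The total objective is  α·l_s + β·l_con + γ·l_cell.

Public functions accept plain numpy arrays and return floats; the
``*_t`` functions operate on :class:`~scmvcc.autodiff.Tensor` and form the
differentiable graph used by :mod:`scmvcc.training`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, exp, log, relu, transpose, tsum
from .preprocess import DegenerateInputError
from .views import AffinityGraph, normalized_adjacency

_EPS = 1e-12


@dataclass
class EncoderParams:
    """Weights of the shared two-layer GCN encoder."""

    w1: np.ndarray  # (m', hidden_dim)
    w2: np.ndarray  # (hidden_dim, c)

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=np.float64)
        self.w2 = np.asarray(self.w2, dtype=np.float64)
        if self.w1.ndim != 2 or self.w2.ndim != 2 or self.w1.shape[1] != self.w2.shape[0]:
            raise ValueError("w1 and w2 have incompatible shapes")

    @property
    def hidden_dim(self) -> int:
        return self.w1.shape[1]

    @property
    def output_dim(self) -> int:
        return self.w2.shape[1]


def save_checkpoint(p: EncoderParams, path, config: dict | None = None) -> None:
    """Serialize encoder weights to one JSON checkpoint with a header."""
    import json

    payload = {
        "header": {
            "n_features": p.w1.shape[0],
            "hidden_dim": p.hidden_dim,
            "output_dim": p.output_dim,
            "config": config or {},
        },
        "w1": p.w1.tolist(),
        "w2": p.w2.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> tuple[EncoderParams, dict]:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    params = EncoderParams(w1=np.array(payload["w1"]), w2=np.array(payload["w2"]))
    return params, payload["header"]


def init_encoder(n_features: int, hidden_dim: int, n_clusters: int, rng: np.random.Generator) -> EncoderParams:
    """Glorot-uniform initialization of both layers."""

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return EncoderParams(w1=glorot(n_features, hidden_dim), w2=glorot(hidden_dim, n_clusters))


@dataclass
class LossWeights:
    """Weights of the three loss terms and the contrast temperature."""

    alpha: float = 1.0  # structural consistency
    beta: float = 1.0  # group contrastive
    gamma: float = 0.5  # cross-view similarity contrast
    tau: float = 0.5  # NT-Xent temperature

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.tau <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class LatentSet:
    """The four row-normalized latents plus the two cross-view similarities."""

    z1: np.ndarray
    z2: np.ndarray
    z3: np.ndarray
    z4: np.ndarray
    s12: np.ndarray = field(default=None)  # type: ignore[assignment]
    s34: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        zs = [np.asarray(z, dtype=np.float64) for z in (self.z1, self.z2, self.z3, self.z4)]
        self.z1, self.z2, self.z3, self.z4 = zs
        if len({z.shape for z in zs}) != 1:
            raise ValueError("latents must share one shape")
        for z in zs:
            norms = np.linalg.norm(z, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("latent rows must be L2-normalized")
        if self.s12 is None:
            self.s12 = self.z1 @ self.z2.T
        if self.s34 is None:
            self.s34 = self.z3 @ self.z4.T

    @property
    def n(self) -> int:
        return self.z1.shape[0]

    @property
    def c(self) -> int:
        return self.z1.shape[1]


# --------------------------------------------------------------------------
# differentiable building blocks
# --------------------------------------------------------------------------


def softmax_rows_t(x: Tensor) -> Tensor:
    shift = Tensor(x.data.max(axis=1, keepdims=True))  # constant: keeps exp bounded
    e = exp(x - shift)
    return e / tsum(e, axis=1, keepdims=True)


def l2_normalize_rows_t(x: Tensor, eps: float = _EPS) -> Tensor:
    norms = (tsum(x * x, axis=1, keepdims=True) + eps) ** 0.5
    return x / norms


def gcn_forward_t(an_f: Tensor | np.ndarray, an: Tensor | np.ndarray, w1: Tensor, w2: Tensor) -> Tensor:
    """Forward pass given the precomputed constant product Ân·F and Ân itself."""
    an_f = an_f if isinstance(an_f, Tensor) else Tensor(an_f)
    an = an if isinstance(an, Tensor) else Tensor(an)
    hidden = relu(an_f @ w1)
    logits = (an @ hidden) @ w2
    return softmax_rows_t(logits)


def column_ntxent_t(za: Tensor, zb: Tensor, tau: float) -> Tensor:
    """NT-Xent contrast over the c columns of (za, zb); asymmetric in its arguments.

    Per column i:

        l_i = -log  e^{φ(zaᵢ, zbᵢ)/τ} /
                    ( Σ_{j≠i} e^{φ(zaᵢ, zaⱼ)/τ} + Σ_j e^{φ(zaᵢ, zbⱼ)/τ} )

    with φ the cosine similarity of columns; returns the mean over columns.
    """
    c = za.shape[1]
    if c < 2:
        raise ValueError("need at least two columns to contrast")
    a = l2_normalize_rows_t(transpose(za))  # (c, n) unit rows = unit columns of za
    b = l2_normalize_rows_t(transpose(zb))
    saa = a @ transpose(a)  # (c, c) cosine similarities, entries in [-1, 1]
    sab = a @ transpose(b)
    off_diag = Tensor(1.0 - np.eye(c))
    eye = Tensor(np.eye(c))
    denom = tsum(exp(saa / tau) * off_diag, axis=1) + tsum(exp(sab / tau), axis=1)
    pos = tsum(sab * eye, axis=1) / tau  # φ(zaᵢ, zbᵢ)/τ
    losses = log(denom) - pos
    return tsum(losses) / float(c)


def group_contrastive_loss_t(z1: Tensor, z2: Tensor, z3: Tensor, z4: Tensor, tau: float) -> Tensor:
    half = 0.5
    l1 = (column_ntxent_t(z1, z2, tau) + column_ntxent_t(z2, z1, tau)) * half
    l2 = (column_ntxent_t(z3, z4, tau) + column_ntxent_t(z4, z3, tau)) * half
    return l1 + l2


def structural_consistency_loss_t(s12: Tensor, s34: Tensor, a_hat1: np.ndarray, a_hat2: np.ndarray) -> Tensor:
    """(1/n²)‖S − Â‖_F² summed over both groups.

    Because Â is 0/1, the Frobenius form equals the indicator split
    Σ_{â=1}(s−1)² + Σ_{â=0}s².
    """
    n = s12.shape[0]
    d1 = s12 - Tensor(a_hat1)
    d2 = s34 - Tensor(a_hat2)
    return (tsum(d1 * d1) + tsum(d2 * d2)) / float(n * n)


def cross_similarity_loss_t(s12: Tensor, s34: Tensor, tau: float) -> Tensor:
    """NT-Xent contrast over the n rows (cells) of the two similarity matrices."""
    if s12.shape[0] < 2:
        raise ValueError("need at least two cells to contrast")
    # row contrast of S == column contrast of Sᵀ
    return column_ntxent_t(transpose(s12), transpose(s34), tau) + column_ntxent_t(
        transpose(s34), transpose(s12), tau
    )


# --------------------------------------------------------------------------
# numpy-facing wrappers
# --------------------------------------------------------------------------


def _hat(a: AffinityGraph | np.ndarray) -> np.ndarray:
    """Coerce to a self-loop adjacency array Â = A + I."""
    if isinstance(a, AffinityGraph):
        return a.with_self_loops().a
    a = np.asarray(a, dtype=np.float64)
    if np.all(np.diag(a) == 0):
        return a + np.eye(a.shape[0])
    return a


def gcn_forward(a: AffinityGraph | np.ndarray, f: np.ndarray, p: EncoderParams) -> np.ndarray:
    """Two-layer GCN forward pass; rows of the output sum to 1."""
    adj = a.a if isinstance(a, AffinityGraph) else np.asarray(a, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    if adj.shape[0] != f.shape[0]:
        raise ValueError("adjacency and features must cover the same cells")
    if f.shape[1] != p.w1.shape[0]:
        raise ValueError("feature dimension does not match w1")
    an = normalized_adjacency(adj)
    return gcn_forward_t(an @ f, an, Tensor(p.w1), Tensor(p.w2)).data


def l2_normalize_rows(z: np.ndarray) -> np.ndarray:
    """Divide each row by its Euclidean norm; errors on all-zero rows."""
    z = np.asarray(z, dtype=np.float64)
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise DegenerateInputError("cannot L2-normalize an all-zero row")
    return z / norms


def column_ntxent(za: np.ndarray, zb: np.ndarray, tau: float) -> float:
    za, zb = np.asarray(za, float), np.asarray(zb, float)
    if za.shape != zb.shape:
        raise ValueError("za and zb must share a shape")
    return float(column_ntxent_t(Tensor(za), Tensor(zb), tau).data)


def group_contrastive_loss(ls: LatentSet, tau: float) -> float:
    return float(
        group_contrastive_loss_t(Tensor(ls.z1), Tensor(ls.z2), Tensor(ls.z3), Tensor(ls.z4), tau).data
    )


def structural_consistency_loss(
    s12: np.ndarray,
    s34: np.ndarray,
    a_hat1: AffinityGraph | np.ndarray,
    a_hat2: AffinityGraph | np.ndarray,
) -> float:
    s12, s34 = np.asarray(s12, float), np.asarray(s34, float)
    h1, h2 = _hat(a_hat1), _hat(a_hat2)
    if s12.shape != h1.shape or s34.shape != h2.shape:
        raise ValueError("similarity and adjacency shapes do not match")
    return float(structural_consistency_loss_t(Tensor(s12), Tensor(s34), h1, h2).data)


def cross_similarity_loss(s12: np.ndarray, s34: np.ndarray, tau: float) -> float:
    s12, s34 = np.asarray(s12, float), np.asarray(s34, float)
    if s12.shape != s34.shape:
        raise ValueError("similarity matrices must share a shape")
    return float(cross_similarity_loss_t(Tensor(s12), Tensor(s34), tau).data)


def total_loss(ls_val: float, lcon_val: float, lcell_val: float, w: LossWeights) -> float:
    """α·l_s + β·l_con + γ·l_cell."""
    for v in (ls_val, lcon_val, lcell_val):
        if not np.isfinite(v):
            raise ValueError("loss components must be finite")
    return w.alpha * ls_val + w.beta * lcon_val + w.gamma * lcell_val
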