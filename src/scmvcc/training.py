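"""Full-batch training of the shared encoder on the four views.

All cells participate in every loss term (the graph losses couple the whole
similarity matrix), so training is full-batch gradient descent with the Adam
update rule.  Runs are bit-reproducible on CPU for a fixed seed.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, transpose
from .network import (
    EncoderParams,
    LatentSet,
    LossWeights,
    cross_similarity_loss_t,
    gcn_forward_t,
    group_contrastive_loss_t,
    init_encoder,
    l2_normalize_rows_t,
    structural_consistency_loss_t,
)
from .views import ViewBundle, normalized_adjacency

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Hyperparameters of the optimization."""

    learning_rate: float = 0.01
    epochs: int = 200
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    hidden_dim: int = 256
    device: str = "cpu"
    encoder: str = "gcn"  # "mlp" replaces graph aggregation with the identity
    per_group_encoders: bool = False  # separate weights for the two view groups
    cell_contrast_axis: str = "rows"  # instance axis of the similarity contrast
    log_every: int = 0  # 0 = silent
    early_stop: bool = False  # stop on a loss plateau
    patience: int = 20
    min_delta: float = 1e-5

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be a positive integer")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.device != "cpu":
            raise ValueError("only cpu training is supported")
        if self.encoder not in ("gcn", "mlp"):
            raise ValueError("encoder must be 'gcn' or 'mlp'")
        if self.cell_contrast_axis not in ("rows", "columns"):
            raise ValueError("cell_contrast_axis must be 'rows' or 'columns'")


@dataclass
class TrainTrace:
    """Per-epoch loss records plus run metadata."""

    records: list[dict[str, float]]
    seed: int

    @property
    def first_total(self) -> float:
        return self.records[0]["total"]

    @property
    def final_total(self) -> float:
        return self.records[-1]["total"]


class Adam:
    """Adam update rule with library-default moment decay."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def set_global_seed(seed: int) -> None:
    """Seed every random source the package touches."""
    random.seed(seed)
    np.random.seed(seed % (2**32))


def _epoch_losses(
    w1: Tensor,
    w2: Tensor,
    an_fs: list[np.ndarray],
    ans: list[np.ndarray],
    a_hat1: np.ndarray,
    a_hat2: np.ndarray,
    weights: LossWeights,
    w1b: Tensor | None = None,
    w2b: Tensor | None = None,
    cell_contrast_axis: str = "rows",
) -> tuple[Tensor, Tensor, Tensor, Tensor, list[Tensor]]:
    """Build the differentiable loss graph for one full-batch epoch.

    ``w1b``/``w2b``, when given, encode the second view group with their own
    parameters (otherwise one shared set encodes all four views).
    """
    w1s = [w1, w1, w1b or w1, w1b or w1]
    w2s = [w2, w2, w2b or w2, w2b or w2]
    zs = [
        l2_normalize_rows_t(gcn_forward_t(an_f, an, wa, wb))
        for an_f, an, wa, wb in zip(an_fs, ans, w1s, w2s)
    ]
    s12 = zs[0] @ transpose(zs[1])
    s34 = zs[2] @ transpose(zs[3])
    l_s = structural_consistency_loss_t(s12, s34, a_hat1, a_hat2)
    l_con = group_contrastive_loss_t(zs[0], zs[1], zs[2], zs[3], weights.tau)
    if cell_contrast_axis == "rows":
        l_cell = cross_similarity_loss_t(s12, s34, weights.tau)
    else:  # columns of S as instances
        l_cell = cross_similarity_loss_t(transpose(s12), transpose(s34), weights.tau)
    total = weights.alpha * l_s + weights.beta * l_con + weights.gamma * l_cell
    return l_s, l_con, l_cell, total, zs


def train(bundle: ViewBundle, n_clusters: int, cfg: TrainConfig) -> tuple[EncoderParams, LatentSet, TrainTrace]:
    """Optimize the shared encoder on the four views; return final latents.

    Raises
    ------
    RuntimeError
        If any loss term becomes non-finite, naming the offending term.
    """
    if n_clusters < 2:
        raise ValueError("need at least two clusters")
    rng = np.random.default_rng(cfg.seed)
    n_features = bundle.views[0][1].shape[1]
    params = init_encoder(n_features, cfg.hidden_dim, n_clusters, rng)
    w1 = Tensor(params.w1, requires_grad=True)
    w2 = Tensor(params.w2, requires_grad=True)
    w1b = w2b = None
    trainable = [w1, w2]
    if cfg.per_group_encoders:
        params_b = init_encoder(n_features, cfg.hidden_dim, n_clusters, rng)
        w1b = Tensor(params_b.w1, requires_grad=True)
        w2b = Tensor(params_b.w2, requires_grad=True)
        trainable += [w1b, w2b]

    if cfg.encoder == "gcn":
        ans = [normalized_adjacency(g.a) for g, _ in bundle.views]
    else:  # "mlp": identity aggregation, the graph plays no role in the encoder
        ans = [np.eye(bundle.n) for _ in bundle.views]
    an_fs = [an @ f for (g, f), an in zip(bundle.views, ans)]
    a_hat1 = bundle.a_knn.with_self_loops().a
    a_hat2 = bundle.a_dm.with_self_loops().a

    opt = Adam(trainable, lr=cfg.learning_rate)
    records: list[dict[str, float]] = []
    best_total, stale = np.inf, 0
    for epoch in range(cfg.epochs):
        opt.zero_grad()
        l_s, l_con, l_cell, total, _ = _epoch_losses(
            w1, w2, an_fs, ans, a_hat1, a_hat2, cfg.loss_weights,
            w1b=w1b, w2b=w2b, cell_contrast_axis=cfg.cell_contrast_axis,
        )
        rec = {
            "epoch": float(epoch),
            "l_s": float(l_s.data),
            "l_con": float(l_con.data),
            "l_cell": float(l_cell.data),
            "total": float(total.data),
        }
        for name in ("l_s", "l_con", "l_cell", "total"):
            if not np.isfinite(rec[name]):
                raise RuntimeError(f"non-finite loss term {name!r} at epoch {epoch}")
        records.append(rec)
        if cfg.early_stop:
            if rec["total"] < best_total - cfg.min_delta:
                best_total, stale = rec["total"], 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        total.backward()
        opt.step()
        if cfg.log_every and epoch % cfg.log_every == 0:
            logger.info(
                "epoch %d: total=%.6f l_s=%.6f l_con=%.6f l_cell=%.6f",
                epoch, rec["total"], rec["l_s"], rec["l_con"], rec["l_cell"],
            )

    # final forward with the updated parameters, outside the gradient tape
    _, _, _, _, zs = _epoch_losses(
        Tensor(w1.data), Tensor(w2.data), an_fs, ans, a_hat1, a_hat2, cfg.loss_weights,
        w1b=Tensor(w1b.data) if w1b is not None else None,
        w2b=Tensor(w2b.data) if w2b is not None else None,
        cell_contrast_axis=cfg.cell_contrast_axis,
    )
    z1, z2, z3, z4 = (z.data for z in zs)
    latents = LatentSet(z1=z1, z2=z2, z3=z3, z4=z4)
    final_params = EncoderParams(w1=w1.data.copy(), w2=w2.data.copy())
    return final_params, latents, TrainTrace(records=records, seed=cfg.seed)
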