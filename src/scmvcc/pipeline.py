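"""End-to-end orchestration: preprocess → views → train → fuse → cluster."""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import preprocess as pp
from . import views as vw
from .fusion_cluster import ClusterResult, evaluate, fuse, kmeans_cluster, project_final
from .training import TrainConfig, TrainTrace, train

#: ablation presets, named after what they remove
ABLATIONS = {
    "no-graph": "encoder aggregates over the identity instead of the cell graph",
    "no-structural": "structural consistency loss off (alpha = 0)",
    "no-group": "group contrastive loss off (beta = 0)",
    "no-cell": "cross-view similarity loss off (gamma = 0)",
    "single-view": "all four slots carry view G1 (single-view model)",
    "fusion-mlp": "project the fused features through the untrained 2-layer MLP",
}


@dataclass
class PipelineConfig:
    """Every knob of the pipeline with the defaults used throughout."""

    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    target_sum: float = 1e4
    n_top_genes: int = 2000
    hvg_criterion: str = "dispersion"
    scale_genes: bool = True
    k_knn: int = 15
    k_dm: int = 15
    k_bw: int = 15
    glf_layers: int = 4
    dm_squared_distance: bool = False
    bandwidth_mode: str = "knn_dist"
    train: TrainConfig = field(default_factory=TrainConfig)
    fusion_mode: str = "identity"
    mlp_layers: int = 2
    kmeans_restarts: int = 20
    ablation: str | None = None

    def resolved(self) -> "PipelineConfig":
        """Apply the ablation preset, returning an equivalent explicit config."""
        cfg = self
        if cfg.ablation is None:
            return cfg
        if cfg.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {cfg.ablation!r}; choose from {sorted(ABLATIONS)}")
        tr = cfg.train
        if cfg.ablation == "no-graph":
            cfg = replace(cfg, train=replace(tr, encoder="mlp"))
        elif cfg.ablation == "no-structural":
            cfg = replace(cfg, train=replace(tr, loss_weights=replace(tr.loss_weights, alpha=0.0)))
        elif cfg.ablation == "no-group":
            cfg = replace(cfg, train=replace(tr, loss_weights=replace(tr.loss_weights, beta=0.0)))
        elif cfg.ablation == "no-cell":
            cfg = replace(cfg, train=replace(tr, loss_weights=replace(tr.loss_weights, gamma=0.0)))
        elif cfg.ablation == "fusion-mlp":
            cfg = replace(cfg, fusion_mode="mlp")
        return cfg

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    result: ClusterResult
    trace: TrainTrace
    cell_ids: list[str]
    truth: np.ndarray | None
    timings: dict[str, float]
    config: PipelineConfig


def run_pipeline(
    x: pp.ExpressionMatrix,
    n_clusters: int,
    config: PipelineConfig | None = None,
    truth: np.ndarray | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full clustering pipeline on a raw counts matrix.

    ``truth`` (optional, aligned with ``x``'s cells) is subset alongside any
    cells removed by filtering and used to fill the metrics report.
    ``seed`` overrides ``config.train.seed`` for every stochastic stage.
    """
    cfg = (config or PipelineConfig()).resolved()
    if seed is not None:
        cfg = replace(cfg, train=replace(cfg.train, seed=int(seed)))
    run_seed = cfg.train.seed
    if truth is not None:
        truth = np.asarray(truth)
        if truth.shape[0] != x.n_cells:
            raise ValueError("truth labels must align with the input cells")
    timings: dict[str, float] = {}

    tic = time.perf_counter()
    filtered = pp.filter_cells_genes(
        x, min_genes_per_cell=cfg.min_genes_per_cell, min_cells_per_gene=cfg.min_cells_per_gene
    )
    if truth is not None:
        keep = {c: i for i, c in enumerate(x.cell_ids)}
        truth = truth[[keep[c] for c in filtered.cell_ids]]
    normed = pp.normalize_log(filtered, target_sum=cfg.target_sum)
    selected = pp.select_top_genes(normed, n_top=cfg.n_top_genes, criterion=cfg.hvg_criterion)
    if cfg.scale_genes:
        selected = pp.scale_genes(selected)
    timings["preprocess"] = time.perf_counter() - tic

    tic = time.perf_counter()
    dist = vw.pairwise_distances(selected)
    a_knn = vw.build_knn_adjacency(dist, k=cfg.k_knn)
    affinity = vw.dm_affinity(
        dist, k_bw=cfg.k_bw, squared_distance=cfg.dm_squared_distance, bandwidth_mode=cfg.bandwidth_mode
    )
    a_dm = vw.build_dm_adjacency(affinity, k=cfg.k_dm)
    if cfg.ablation == "single-view":
        bundle = vw.single_view_bundle(a_knn, selected, t=cfg.glf_layers)
    else:
        bundle = vw.assemble_views(a_knn, a_dm, selected, t=cfg.glf_layers)
    timings["views"] = time.perf_counter() - tic

    tic = time.perf_counter()
    _, latents, trace = train(bundle, n_clusters, cfg.train)
    timings["train"] = time.perf_counter() - tic

    tic = time.perf_counter()
    z_cat = fuse(latents)
    z_final = project_final(z_cat, mode=cfg.fusion_mode, layers=cfg.mlp_layers, seed=run_seed)
    labels = kmeans_cluster(z_final, n_clusters, seed=run_seed, n_init=cfg.kmeans_restarts)
    metrics = evaluate(labels, truth) if truth is not None else None
    timings["cluster"] = time.perf_counter() - tic

    result = ClusterResult(z_final=z_final, labels=labels, c=n_clusters, metrics=metrics)
    return PipelineResult(
        result=result,
        trace=trace,
        cell_ids=list(selected.cell_ids),
        truth=truth,
        timings=timings,
        config=cfg,
    )
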