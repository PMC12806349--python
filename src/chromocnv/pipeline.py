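"""End-to-end helpers chaining simulation, embedding, and GCN training."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import EmbeddingMatrix, node2vec_embed
from .gcn import GCNParams, TrainConfig, train_gcn
from .graph import build_graph
from .hic_io import ContactMatrix
from .linear import SplitSpec
from .metrics import MetricsReport


@dataclass
class PipelineResult:
    """Everything produced by one node2vec + GCN run on a chromosome."""

    params: GCNParams = field(repr=False)
    report: MetricsReport
    losses: list[float] = field(repr=False)
    embeddings: EmbeddingMatrix = field(repr=False)
    graph: object = field(repr=False)


def run_gcn_pipeline(
    matrix: ContactMatrix,
    labels: np.ndarray,
    d: int = 64,
    walk_length: int = 100,
    num_walks: int = 10,
    window: int = 10,
    p: float = 1.0,
    q: float = 1.0,
    embed_epochs: int = 3,
    train_config: TrainConfig | None = None,
    embeddings: EmbeddingMatrix | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Contact matrix -> graph -> node2vec features -> trained GCN.

    Precomputed ``embeddings`` may be passed when only the labels changed
    (label perturbations leave the graph untouched).
    """
    graph = build_graph(matrix)
    if embeddings is None:
        embeddings = node2vec_embed(
            graph,
            d=d,
            walk_length=walk_length,
            num_walks=num_walks,
            window=window,
            p=p,
            q=q,
            epochs=embed_epochs,
            seed=seed,
        )
    if train_config is None:
        train_config = TrainConfig(split=SplitSpec(train_fraction=0.6, seed=seed), seed=seed)
    params, report, losses = train_gcn(graph, embeddings, labels, train_config)
    return PipelineResult(
        params=params, report=report, losses=losses, embeddings=embeddings, graph=graph
    )
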