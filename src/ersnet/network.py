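"""Weighted-network and community-partition containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class WeightedNetwork:
    """Symmetric signed weighted network over labelled nodes.

    ``weights`` is a p x p real matrix with exact symmetry and a zero
    diagonal.  For partial-correlation networks (``estimator_tag ==
    "ebic_glasso"``) all weights lie in [-1, 1].  Mixed-graphical-model fits
    additionally carry the training statistics needed to simulate from the
    nodewise conditionals: per-node mean, standard deviation and residual
    standard deviation (the latter on the standardized scale).
    """

    node_ids: list[str]
    weights: np.ndarray
    estimator_tag: str  # ebic_glasso | mgm
    kinds: list[str] | None = None  # continuous_strategy | ordinal_symptom
    groups: dict[str, str] | None = None  # node_id -> ER | depression | anxiety
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    residual_sd: np.ndarray | None = None
    sign_conflicts: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        p = len(self.node_ids)
        if self.weights.shape != (p, p):
            raise ValueError(f"weights shape {self.weights.shape} != ({p}, {p})")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        self.weights = (self.weights + self.weights.T) / 2.0
        np.fill_diagonal(self.weights, 0.0)
        if self.estimator_tag == "ebic_glasso" and np.abs(self.weights).max(initial=0) > 1 + 1e-9:
            raise ValueError("partial correlations must lie in [-1, 1]")

    @property
    def p(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_frame(self) -> pd.DataFrame:
        """Long-format edge list (nonzero upper triangle)."""
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.weights[i, j]
                if w != 0.0:
                    rows.append((self.node_ids[i], self.node_ids[j], w, self.estimator_tag))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "estimator_tag"])

    def index_of(self, node_id: str) -> int:
        return self.node_ids.index(node_id)


@dataclass
class CommunityPartition:
    """Node -> community assignment with contiguous community indices."""

    assignment: dict[str, int]

    def __post_init__(self) -> None:
        labels = sorted(set(self.assignment.values()))
        if labels != list(range(len(labels))):
            relabel = {old: new for new, old in enumerate(labels)}
            self.assignment = {k: relabel[v] for k, v in self.assignment.items()}

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def labels(self, node_ids: list[str]) -> np.ndarray:
        return np.array([self.assignment[n] for n in node_ids])


def partition_from_labels(node_ids: list[str], labels) -> CommunityPartition:
    return CommunityPartition(dict(zip(node_ids, (int(v) for v in labels))))
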