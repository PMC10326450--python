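"""Pairwise spatial information between genes and gene clustering.

The single-gene score generalizes directly to ordered gene pairs: near pairs
take gene a's expression at walk starts and gene b's at walk ends; far pairs
apply one cell permutation to both genes before indexing (preserving
within-cell coupling while destroying spatial structure).  The resulting
matrix I is symmetrized, transformed to a distance D = (1 + I~)^(-s) with
s = 0.5 by default, and clustered with complete linkage.

Because pairwise cost grows quadratically, genes are pre-filtered by their
auto-information score (e.g. keeping scores above a threshold, or the top
few dozen genes) before computing all pairs.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .core import (
    ClassifierParams,
    TrainConfig,
    _objective_and_grad,
    classify_pair,
    normalize_scores,
)
from .graph import SpatialGraph, build_graph, sample_walks
from .io import SpatialDataset
from .uncertainty import GeneExpressionSampler, SamplerConfig, default_size_factors
from scipy.special import log_expit


def train_pair(
    sampler_a: GeneExpressionSampler,
    sampler_b: GeneExpressionSampler,
    graph: SpatialGraph,
    coords: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> float:
    """Spatial information with gene a at walk starts, gene b at walk ends.

    Returns the normalized (per-cell summed) score.  Degenerate constant
    genes score 0.
    """
    if sampler_a.is_constant() or sampler_b.is_constant():
        return 0.0
    n = graph.n_cells
    pilot = sample_walks(graph, coords, cfg.walk_k, rng)
    theta_v = ClassifierParams.initial(float(pilot.dist.mean()), cfg.init_weight).as_vector()
    m = np.zeros(5)
    v = np.zeros(5)
    history: list[float] = []
    xa = xb = None
    resample_every = sampler_a.cfg.resample_every
    for it in range(cfg.max_iters):
        if xa is None or it % resample_every == 0:
            xa = sampler_a.draw(rng)
            xb = sampler_b.draw(rng)
        walks = sample_walks(graph, coords, cfg.walk_k, rng)
        perm = rng.permutation(n)
        xas, xbs = xa[perm], xb[perm]
        obj, grad = _objective_and_grad(
            theta_v,
            xa[walks.start_idx], xb[walks.end_idx],
            xas[walks.start_idx], xbs[walks.end_idx],
            walks.dist,
        )
        m = cfg.beta1 * m + (1 - cfg.beta1) * grad
        v = cfg.beta2 * v + (1 - cfg.beta2) * grad**2
        t = it + 1
        mhat = m / (1 - cfg.beta1**t)
        vhat = v / (1 - cfg.beta2**t)
        theta_v = theta_v + cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.adam_eps)
        history.append(obj)
        if cfg.early_stop and len(history) >= 2 * cfg.convergence_window:
            window = float(np.mean(history[-cfg.convergence_window:]))
            prev = float(np.mean(history[-2 * cfg.convergence_window : -cfg.convergence_window]))
            if (window - prev) / max(abs(prev), 1e-12) < cfg.convergence_rtol:
                break
    theta = ClassifierParams.from_vector(theta_v)
    cell_scores = np.zeros(n)
    for _ in range(cfg.eval_rounds):
        xa = sampler_a.draw(rng)
        xb = sampler_b.draw(rng)
        walks = sample_walks(graph, coords, cfg.walk_k, rng)
        perm = rng.permutation(n)
        f_near = classify_pair(theta, xa[walks.start_idx], xb[walks.end_idx], walks.dist)
        f_far = classify_pair(
            theta, xa[perm][walks.start_idx], xb[perm][walks.end_idx], walks.dist
        )
        cell_scores += log_expit(f_near) + log_expit(-f_far)
    cell_scores /= cfg.eval_rounds
    _, normalized = normalize_scores(cell_scores)
    return normalized


def info_to_distance(I_tilde: np.ndarray, s: float = 0.5) -> np.ndarray:
    """D = (1 + I~)^(-s); strictly decreasing in I~.  Small negative I~
    (Monte-Carlo noise) are clipped to 0 so D <= 1."""
    I_tilde = np.clip(np.asarray(I_tilde, dtype=float), 0.0, None)
    return (1.0 + I_tilde) ** (-s)


def cluster_genes(D: np.ndarray, gene_ids: Sequence[str]) -> tuple[str, pd.DataFrame]:
    """Complete-linkage clustering of the gene distance matrix.

    Returns a Newick string (branch lengths from merge heights) and the
    merge table (scipy linkage format columns: left, right, height, size).
    The diagonal is forced to zero before condensing.
    """
    D = np.asarray(D, dtype=float).copy()
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite values")
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = linkage(squareform(D, checks=False), method="complete")
    merge = pd.DataFrame(Z, columns=["left", "right", "height", "size"])
    newick = _to_newick(Z, list(gene_ids))
    return newick, merge


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


class PairwiseSpatialInformation:
    """Model computing spatial information between all pairs of a gene subset.

    Parameters mirror :class:`SpatialInformationModel` (unbinned level only);
    ``genes`` is the pre-filtered subset (at least 2), typically genes whose
    auto-information exceeds a threshold.
    """

    def __init__(
        self,
        dataset: SpatialDataset,
        genes: Sequence[str],
        graph_method: str = "delaunay",
        epsilon: Optional[float] = None,
        knn_m: int = 6,
        uncertainty="gamma_poisson",
        train_config: Optional[TrainConfig] = None,
        scale_exponent: float = 0.5,
    ) -> None:
        if len(genes) < 2:
            raise ValueError("pairwise information requires at least 2 genes")
        missing = [g for g in genes if g not in dataset.gene_ids]
        if missing:
            raise ValueError(f"genes not in dataset: {missing}")
        self.dataset = dataset
        self.genes = list(genes)
        self.graph_method = graph_method
        self.epsilon = epsilon
        self.knn_m = knn_m
        self.sampler_config = (
            uncertainty if isinstance(uncertainty, SamplerConfig) else SamplerConfig(model=str(uncertainty))
        )
        self.train_config = train_config or TrainConfig()
        self.scale_exponent = scale_exponent

    @classmethod
    def from_scores(
        cls,
        dataset: SpatialDataset,
        scores: pd.DataFrame,
        min_auto_info: Optional[float] = None,
        top: int = 50,
        **kwargs,
    ) -> "PairwiseSpatialInformation":
        """Select genes from an auto-information score table: either all genes
        with normalized_score above ``min_auto_info``, or the ``top`` genes."""
        ranked = scores.sort_values("normalized_score", ascending=False)
        if min_auto_info is not None:
            genes = ranked.loc[ranked.normalized_score > min_auto_info, "gene_id"].tolist()
        else:
            genes = ranked.gene_id.head(top).tolist()
        return cls(dataset, genes, **kwargs)

    def fit(self, seed: int = 0) -> "PairwiseInfoResults":
        ds = self.dataset
        import scipy.sparse as sp

        counts = ds.counts.toarray() if sp.issparse(ds.counts) else np.asarray(ds.counts)
        graph = build_graph(ds.coords, self.graph_method, epsilon=self.epsilon, knn_m=self.knn_m)
        totals = counts.sum(axis=1)
        sf = default_size_factors(totals)
        samplers = {}
        for g in self.genes:
            j = ds.gene_ids.index(g)
            samplers[g] = GeneExpressionSampler(
                counts=counts[:, j],
                cfg=self.sampler_config,
                size_factors=sf,
                cell_totals=totals,
                n_genes=ds.n_genes,
                posterior_mean=None if ds.posterior_mean is None else ds.posterior_mean[:, j],
                posterior_sd=None if ds.posterior_sd is None else ds.posterior_sd[:, j],
            )
        g = len(self.genes)
        I = np.zeros((g, g))
        for a in range(g):
            for b in range(g):
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(seed), 15485863, a, b])
                )
                I[a, b] = train_pair(
                    samplers[self.genes[a]],
                    samplers[self.genes[b]],
                    graph,
                    ds.coords,
                    self.train_config,
                    rng,
                )
        return PairwiseInfoResults(self, I, seed)


class PairwiseInfoResults:
    """Pairwise information matrix, its distance transform and clustering."""

    def __init__(self, model: PairwiseSpatialInformation, I: np.ndarray, seed: int):
        self.model = model
        self.gene_ids = model.genes
        self.I = I
        self.I_tilde = (I + I.T) / 2.0
        self.D = info_to_distance(self.I_tilde, model.scale_exponent)
        self.seed = seed
        self._newick: Optional[str] = None
        self._merge: Optional[pd.DataFrame] = None

    def cluster(self) -> tuple[str, pd.DataFrame]:
        if self._newick is None:
            self._newick, self._merge = cluster_genes(self.D, self.gene_ids)
        return self._newick, self._merge

    def to_newick(self) -> str:
        return self.cluster()[0]

    def summary(self) -> str:
        nz = self.I_tilde[np.triu_indices_from(self.I_tilde, k=1)]
        lines = [
            "Pairwise spatial information",
            "=" * 48,
            f"genes: {len(self.gene_ids)}    seed: {self.seed}",
            f"symmetrized info: median {np.median(nz):.3f}, max {nz.max():.3f}",
        ]
        return "\n".join(lines)

    def write(self, out_prefix) -> dict:
        from pathlib import Path

        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, mat in (("info", self.I_tilde), ("distance", self.D)):
            p = out_prefix.with_name(f"{out_prefix.name}.{name}.csv")
            pd.DataFrame(mat, index=self.gene_ids, columns=self.gene_ids).to_csv(p)
            paths[name] = p
        newick, merge = self.cluster()
        p = out_prefix.with_name(out_prefix.name + ".dendrogram.nwk")
        p.write_text(newick + "\n")
        paths["newick"] = p
        p = out_prefix.with_name(out_prefix.name + ".merges.csv")
        merge.to_csv(p, index=False)
        paths["merges"] = p
        return paths
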