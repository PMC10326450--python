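"""Model/Results interface for per-gene spatial information scoring.

Usage::

    model = SpatialInformationModel(dataset, walk_k=10, bin_sizes=(4, 8, 16))
    res = model.fit(seed=0)
    print(res.summary())
    res.scores                  # tidy per-gene DataFrame
    res.saliency("Gpx3")        # per-cell saliency vector

The model holds the data and configuration; ``fit`` trains one small
classifier per gene (independent random substreams per gene, so results do
not depend on execution order) and returns a results object carrying scores,
p/q values, saliency vectors and fitted classifier parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .binning import BinLevel, build_bin_stack
from .core import (
    GeneScoreResult,
    TrainConfig,
    _LevelState,
    adjust_pvalues,
    train_gene,
)
from .graph import SpatialGraph, build_graph
from .io import SpatialDataset, write_results
from .uncertainty import GeneExpressionSampler, SamplerConfig, default_size_factors

logger = logging.getLogger(__name__)


def _gene_rng(seed: int, gene_idx: int) -> np.random.Generator:
    """Independent, order-insensitive substream for one gene."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), 104729 + int(gene_idx)]))


@dataclass
class _Level:
    """Internal: one resolution level shared across genes."""

    weight: float
    counts: np.ndarray
    coords: np.ndarray
    graph: SpatialGraph
    size_factors: np.ndarray
    totals: np.ndarray
    posterior_mean: Optional[np.ndarray] = None
    posterior_sd: Optional[np.ndarray] = None
    bin_level: Optional[BinLevel] = None


class SpatialInformationModel:
    """Scores each gene's spatial coherence in a spatial expression dataset.

    Parameters
    ----------
    dataset : SpatialDataset
    graph_method : {"delaunay", "radius", "knn", "grid"}
        Spatial neighborhood graph construction (default Delaunay).
    walk_k : int
        Random-walk length defining the neighborhood scale (default 10).
    bin_sizes : sequence of int
        Exact-k binning resolutions trained jointly with the unbinned data
        (default (4, 8, 16)); empty disables binning.
    uncertainty : str or SamplerConfig
        Count-posterior resampling model; "gamma_poisson" (default),
        "dirichlet_multinomial", "gaussian" or "none".
    """

    def __init__(
        self,
        dataset: SpatialDataset,
        graph_method: str = "delaunay",
        epsilon: Optional[float] = None,
        knn_m: int = 6,
        walk_k: int = 10,
        bin_sizes: Sequence[int] = (4, 8, 16),
        uncertainty="gamma_poisson",
        train_config: Optional[TrainConfig] = None,
        **train_kwargs,
    ) -> None:
        self.dataset = dataset
        self.graph_method = graph_method
        self.epsilon = epsilon
        self.knn_m = knn_m
        self.bin_sizes = tuple(bin_sizes)
        if isinstance(uncertainty, SamplerConfig):
            self.sampler_config = uncertainty
        else:
            self.sampler_config = SamplerConfig(model=str(uncertainty))
        if self.sampler_config.model == "gaussian" and dataset.posterior_sd is None:
            raise ValueError("gaussian uncertainty requires dataset posterior_mean/sd")
        cfg = train_config or TrainConfig()
        if train_kwargs or walk_k != cfg.walk_k:
            cfg = replace(cfg, walk_k=walk_k, **train_kwargs)
        self.train_config = cfg
        self._levels: Optional[list[_Level]] = None

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, coord_cols: Sequence[str] = ("x", "y"), **kwargs
    ) -> "SpatialInformationModel":
        """Build from a tidy table: coordinate columns plus one column per gene."""
        coords = df[list(coord_cols)].to_numpy(dtype=float)
        id_col = next((c for c in ("cell_id", "barcode") if c in df.columns), None)
        gene_cols = [c for c in df.columns if c not in coord_cols and c != id_col]
        ds = SpatialDataset(
            counts=df[gene_cols].to_numpy(dtype=float),
            coords=coords,
            gene_ids=gene_cols,
            cell_ids=df[id_col].astype(str).tolist() if id_col else [],
        )
        return cls(ds, **kwargs)

    @classmethod
    def from_anndata(cls, adata, spatial_key: str = "spatial", **kwargs):
        from .io import dataset_from_anndata

        return cls(dataset_from_anndata(adata, spatial_key), **kwargs)

    # -- level construction ----------------------------------------------

    def _build_levels(self, seed: int) -> list[_Level]:
        ds = self.dataset
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7919]))
        counts = ds.counts.toarray() if sp.issparse(ds.counts) else np.asarray(ds.counts)
        stack = build_bin_stack(counts, ds.coords, self.bin_sizes, rng)
        levels: list[_Level] = []
        for sl in stack:
            graph = build_graph(
                sl.coords, self.graph_method, epsilon=self.epsilon, knn_m=self.knn_m
            )
            totals = sl.counts.sum(axis=1)
            pm = psd = None
            if self.sampler_config.model == "gaussian":
                if sl.bin_level is None:
                    pm, psd = ds.posterior_mean, ds.posterior_sd
                else:
                    pm, psd = _aggregate_gaussian(ds, sl.bin_level)
            levels.append(
                _Level(
                    weight=sl.weight,
                    counts=sl.counts,
                    coords=sl.coords,
                    graph=graph,
                    size_factors=default_size_factors(totals),
                    totals=totals,
                    posterior_mean=pm,
                    posterior_sd=psd,
                    bin_level=sl.bin_level,
                )
            )
        return levels

    def _gene_states(self, levels: list[_Level], j: int) -> list[_LevelState]:
        cfg = self.sampler_config
        states = []
        for lv in levels:
            sampler = GeneExpressionSampler(
                counts=lv.counts[:, j],
                cfg=cfg,
                size_factors=lv.size_factors,
                cell_totals=lv.totals,
                n_genes=self.dataset.n_genes,
                posterior_mean=None if lv.posterior_mean is None else lv.posterior_mean[:, j],
                posterior_sd=None if lv.posterior_sd is None else lv.posterior_sd[:, j],
            )
            states.append(_LevelState(sampler, lv.graph, lv.coords, lv.weight))
        return states

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        seed: int = 0,
        genes: Optional[Sequence[str]] = None,
        progress: bool = False,
    ) -> "SpatialInformationResults":
        """Train the per-gene classifiers and score every gene.

        ``genes`` restricts fitting to a subset of gene ids (BH adjustment is
        then over that subset).  The master ``seed`` derives one substream per
        gene, so scores are reproducible and independent of iteration order.
        """
        ds = self.dataset
        levels = self._build_levels(seed)
        self._levels = levels
        gene_idx = (
            range(ds.n_genes)
            if genes is None
            else [ds.gene_ids.index(g) for g in genes]
        )
        results: list[GeneScoreResult] = []
        for count_done, j in enumerate(gene_idx):
            rng = _gene_rng(seed, j)
            states = self._gene_states(levels, j)
            _, res = train_gene(
                ds.gene_ids[j], states, self.train_config, rng, cell_ids=ds.cell_ids
            )
            results.append(res)
            if progress and (count_done + 1) % 100 == 0:
                logger.info(
                    "scored %d genes (last objective %.4f)",
                    count_done + 1,
                    res.raw_score,
                )
        q = adjust_pvalues(np.array([r.p_value for r in results]))
        for r, qv in zip(results, q):
            r.q_value = float(qv)
        return SpatialInformationResults(self, results, seed)


def _aggregate_gaussian(ds: SpatialDataset, bl: BinLevel):
    """Binned Gaussian posteriors: sum of means, variance-additive sd."""
    pm = np.zeros((bl.n_bins, ds.n_genes))
    var = np.zeros_like(pm)
    for b in range(bl.n_bins):
        mem = bl.members(b)
        pm[b] = ds.posterior_mean[mem].sum(axis=0)
        var[b] = (ds.posterior_sd[mem] ** 2).sum(axis=0)
    return pm, np.sqrt(var)


class SpatialInformationResults:
    """Fitted per-gene spatial information scores.

    Attributes
    ----------
    scores : DataFrame
        One row per gene: raw_score, normalized_score, accuracy, n_trials,
        p_value, q_value, n_iters, skipped; input gene order.
    """

    def __init__(self, model: SpatialInformationModel, results: list[GeneScoreResult], seed: int):
        self.model = model
        self.gene_results = results
        self.seed = seed
        self.scores = pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in results],
                "raw_score": [r.raw_score for r in results],
                "normalized_score": [r.normalized_score for r in results],
                "accuracy": [r.accuracy for r in results],
                "n_trials": [r.n_trials for r in results],
                "p_value": [r.p_value for r in results],
                "q_value": [r.q_value for r in results],
                "n_iters": [r.n_iters for r in results],
                "skipped": [r.skipped for r in results],
            }
        )

    def __getitem__(self, gene_id: str) -> GeneScoreResult:
        for r in self.gene_results:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)

    def saliency(self, gene_id: str) -> np.ndarray:
        """Per-cell saliency vector (in [0, 1]) for one gene."""
        return self[gene_id].saliency

    def saliency_frame(self, genes: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Cells x genes saliency matrix as a DataFrame."""
        genes = list(genes) if genes is not None else [r.gene_id for r in self.gene_results]
        data = {g: self[g].saliency for g in genes}
        return pd.DataFrame(data, index=self.model.dataset.cell_ids)

    def top_genes(self, n: int = 10) -> pd.DataFrame:
        return self.scores.sort_values("normalized_score", ascending=False).head(n)

    def summary(self, top: int = 10) -> str:
        """Readable summary: run settings and the highest-scoring genes."""
        ds = self.model.dataset
        cfg = self.model.train_config
        lines = [
            "Spatial information score results",
            "=" * 64,
            f"cells: {ds.n_cells}    genes scored: {len(self.gene_results)}",
            f"graph: {self.model.graph_method}    walk length: {cfg.walk_k}    "
            f"bin sizes: {self.model.bin_sizes or 'none'}",
            f"uncertainty model: {self.model.sampler_config.model}    seed: {self.seed}",
            f"significant at q<0.05: {(self.scores.q_value < 0.05).sum()}",
            "-" * 64,
            f"{'gene':<16}{'score':>10}{'accuracy':>10}{'p':>12}{'q':>12}",
        ]
        for _, row in self.top_genes(top).iterrows():
            lines.append(
                f"{row.gene_id:<16}{row.normalized_score:>10.2f}"
                f"{row.accuracy:>10.3f}{row.p_value:>12.3g}{row.q_value:>12.3g}"
            )
        return "\n".join(lines)

    def write(self, out_prefix, saliency_genes: Optional[Sequence[str]] = None) -> dict:
        """Write score table (sorted by score) and optional saliency CSVs."""
        return write_results(self.gene_results, out_prefix, saliency_genes)

    def plot_saliency(self, gene_id: str, ax=None, s: float = 6.0):
        """Scatter cells at their coordinates colored by saliency."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        coords = self.model.dataset.coords
        pts = ax.scatter(
            coords[:, 0], coords[:, 1], c=self.saliency(gene_id), s=s, cmap="viridis"
        )
        ax.set_title(f"{gene_id} saliency")
        ax.set_aspect("equal")
        plt.colorbar(pts, ax=ax, label="saliency")
        return ax
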