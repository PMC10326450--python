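"""Reading and writing spatial expression datasets and result tables.

The central container is :class:`SpatialDataset`: a cells-by-genes count (or
expression) matrix together with 2-D spatial coordinates.  Coordinates are
kept in whatever Euclidean units they arrive in (pixels, grid indices,
micrometers); the model's learned distance-decay parameter absorbs the scale,
so no rescaling is applied on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


@dataclass
class SpatialDataset:
    """A cells x genes expression matrix with per-cell 2-D coordinates.

    Parameters
    ----------
    counts : ndarray or sparse matrix, shape (n_cells, n_genes)
        Non-negative expression values; integers when they are raw counts.
    coords : ndarray, shape (n_cells, 2)
        Spatial positions, arbitrary Euclidean units.
    gene_ids, cell_ids : sequences of str
        Row/column identifiers.  Generated (``gene0001`` ...) when omitted.
    posterior_mean, posterior_sd : ndarray, optional
        Per-cell-per-gene Gaussian posterior summaries, for running the model
        on the output of an external normalisation/denoising method.
    cell_labels : sequence of str, optional
        Cell type or region annotation.
    """

    counts: np.ndarray
    coords: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)
    posterior_mean: Optional[np.ndarray] = None
    posterior_sd: Optional[np.ndarray] = None
    cell_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if sp.issparse(self.counts):
            self.counts = sp.csr_matrix(self.counts)
        else:
            self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        n, g = self.counts.shape
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n_cells, 2) array")
        if self.coords.shape[0] != n:
            raise ValueError(
                f"count matrix has {n} cells but coordinates have "
                f"{self.coords.shape[0]} rows ({n} vs {self.coords.shape[0]})"
            )
        if not np.all(np.isfinite(self.coords)):
            bad = int(np.where(~np.isfinite(self.coords).all(axis=1))[0][0])
            raise ValueError(f"non-finite coordinate at row {bad}")
        if self.counts_min() < 0:
            raise ValueError("counts must be non-negative")
        if not self.gene_ids:
            width = len(str(g))
            self.gene_ids = [f"gene{i:0{width}d}" for i in range(g)]
        if not self.cell_ids:
            width = len(str(n))
            self.cell_ids = [f"cell{i:0{width}d}" for i in range(n)]
        self.gene_ids = [str(x) for x in self.gene_ids]
        self.cell_ids = [str(x) for x in self.cell_ids]
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} gene columns")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} cell rows")
        for name in ("posterior_mean", "posterior_sd"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=float)
                if m.shape != (n, g):
                    raise ValueError(f"{name} shape {m.shape} != counts shape {(n, g)}")
                setattr(self, name, m)
        if self.posterior_sd is not None and not np.all(self.posterior_sd > 0):
            raise ValueError("posterior_sd must be strictly positive")
        if self.cell_labels is not None:
            self.cell_labels = np.asarray(self.cell_labels)
            if len(self.cell_labels) != n:
                raise ValueError("cell_labels length mismatch")

    # -- basic properties -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def counts_min(self) -> float:
        if sp.issparse(self.counts):
            return float(self.counts.data.min()) if self.counts.nnz else 0.0
        return float(self.counts.min()) if self.counts.size else 0.0

    def gene_column(self, j: int) -> np.ndarray:
        """Dense expression vector for gene column ``j``."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts[:, j].todense()).ravel().astype(float)
        return np.asarray(self.counts[:, j], dtype=float)

    def total_counts(self) -> np.ndarray:
        """Per-cell library sizes."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.sum(axis=1)).ravel().astype(float)
        return self.counts.sum(axis=1).astype(float)

    def zero_genes(self) -> np.ndarray:
        """Boolean flag per gene: all-zero expression (kept, but flagged)."""
        if sp.issparse(self.counts):
            nz = np.asarray((self.counts != 0).sum(axis=0)).ravel()
        else:
            nz = (self.counts != 0).sum(axis=0)
        return nz == 0


def read_dataset(
    path_spec,
    mode: str = "table",
    coord_cols: Sequence = ("x", "y"),
    transpose_mtx: bool = False,
) -> SpatialDataset:
    """Read a :class:`SpatialDataset` from disk.

    Parameters
    ----------
    path_spec : str | Path | dict
        ``table`` mode: a single delimited file with coordinate columns plus
        one column per gene.  ``mtx`` mode: a dict with keys ``matrix``,
        ``features``, ``barcodes``, ``coords`` (or a directory containing
        ``matrix.mtx``, ``features.tsv``, ``barcodes.tsv``, ``coords.csv``).
        ``gaussian`` mode: a dict with ``mean``, ``sd``, ``coords`` CSV paths.
    mode : {"table", "mtx", "gaussian"}
    coord_cols : names (or integer indices) of the two coordinate columns.
    transpose_mtx : set when the MatrixMarket file is genes x cells.
    """
    if mode == "table":
        return _read_table(Path(path_spec), coord_cols)
    if mode == "mtx":
        return _read_mtx(path_spec, transpose_mtx)
    if mode == "gaussian":
        return _read_gaussian(path_spec, coord_cols)
    raise ValueError(f"unknown mode {mode!r}")


def _read_delim(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def _read_table(path: Path, coord_cols: Sequence) -> SpatialDataset:
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = _read_delim(path)
    cols = list(df.columns)
    cnames = [cols[c] if isinstance(c, int) else c for c in coord_cols]
    for c in cnames:
        if c not in cols:
            raise ValueError(f"coordinate column {c!r} not found in {path}")
    coords = df[cnames].to_numpy()
    for ax, c in enumerate(cnames):
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any():
            raise ValueError(
                f"non-numeric coordinate in column {c!r} at row "
                f"{int(col.isna().idxmax())}"
            )
    id_col = None
    for cand in ("cell_id", "barcode", "cell"):
        if cand in cols:
            id_col = cand
            break
    gene_cols = [c for c in cols if c not in cnames and c != id_col]
    counts = df[gene_cols].to_numpy(dtype=float)
    cell_ids = df[id_col].astype(str).tolist() if id_col else []
    return SpatialDataset(counts=counts, coords=coords, gene_ids=gene_cols, cell_ids=cell_ids)


def _resolve_mtx_paths(path_spec) -> dict:
    if isinstance(path_spec, dict):
        return {k: Path(v) for k, v in path_spec.items()}
    d = Path(path_spec)
    return {
        "matrix": d / "matrix.mtx",
        "features": d / "features.tsv",
        "barcodes": d / "barcodes.tsv",
        "coords": d / "coords.csv",
    }


def _read_mtx(path_spec, transpose: bool) -> SpatialDataset:
    paths = _resolve_mtx_paths(path_spec)
    for k, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"{k} file not found: {p}")
    mat = sp.csr_matrix(scipy.io.mmread(paths["matrix"]))
    if transpose:
        mat = mat.T.tocsr()
    gene_ids = [line.split("\t")[0] for line in paths["features"].read_text().splitlines() if line]
    cell_ids = [line.split("\t")[0] for line in paths["barcodes"].read_text().splitlines() if line]
    cdf = pd.read_csv(paths["coords"])
    coord_cols = [c for c in ("x", "y") if c in cdf.columns]
    if len(coord_cols) != 2:
        coord_cols = list(cdf.columns[-2:])
    coords = cdf[coord_cols].to_numpy(dtype=float)
    if mat.shape[0] != coords.shape[0]:
        raise ValueError(
            f"matrix has {mat.shape[0]} cells but coordinates have "
            f"{coords.shape[0]} rows ({mat.shape[0]} vs {coords.shape[0]})"
        )
    if "cell_id" in cdf.columns and not cell_ids:
        cell_ids = cdf["cell_id"].astype(str).tolist()
    return SpatialDataset(counts=mat, coords=coords, gene_ids=gene_ids, cell_ids=cell_ids)


def _read_gaussian(path_spec, coord_cols) -> SpatialDataset:
    if not isinstance(path_spec, dict) or not {"mean", "sd", "coords"} <= set(path_spec):
        raise ValueError("gaussian mode requires dict with 'mean', 'sd', 'coords' paths")
    mean_df = _read_delim(Path(path_spec["mean"]))
    sd_path = path_spec.get("sd")
    if sd_path is None or not Path(sd_path).exists():
        raise FileNotFoundError("gaussian mode requires a posterior sd matrix file")
    sd_df = _read_delim(Path(sd_path))
    cdf = _read_delim(Path(path_spec["coords"]))
    cnames = [c for c in ("x", "y") if c in cdf.columns] or list(cdf.columns[-2:])
    coords = cdf[cnames].to_numpy(dtype=float)
    gene_ids = [c for c in mean_df.columns if c not in ("cell_id",)]
    mean = mean_df[gene_ids].to_numpy(dtype=float)
    sd = sd_df[gene_ids].to_numpy(dtype=float)
    cell_ids = cdf["cell_id"].astype(str).tolist() if "cell_id" in cdf.columns else []
    return SpatialDataset(
        counts=np.clip(mean, 0.0, None),
        coords=coords,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        posterior_mean=mean,
        posterior_sd=sd,
    )


def write_results(results, out_prefix, saliency_genes: Optional[Sequence[str]] = None) -> dict:
    """Write gene-level scores (and optionally per-cell saliency) as CSV.

    ``results`` is a sequence of :class:`spatialinfo.core.GeneScoreResult`.
    The gene table is sorted by normalized score, descending.  Saliency is
    written long-format (cell_id, gene_id, saliency) for the requested genes
    (all genes when ``saliency_genes`` is None and saliency vectors exist).

    Returns a dict of written paths.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to write")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "gene_id": r.gene_id,
            "raw_score": r.raw_score,
            "normalized_score": r.normalized_score,
            "accuracy": r.accuracy,
            "p_value": r.p_value,
            "q_value": r.q_value,
        }
        for r in results
    ]
    table = pd.DataFrame(rows).sort_values(
        "normalized_score", ascending=False, kind="stable"
    )
    gene_path = out_prefix.with_name(out_prefix.name + ".scores.csv")
    table.to_csv(gene_path, index=False, float_format="%.6g")
    written = {"scores": gene_path}

    if saliency_genes is None:
        saliency_genes = [r.gene_id for r in results if r.saliency is not None]
    if saliency_genes:
        by_id = {r.gene_id: r for r in results}
        recs = []
        for gid in saliency_genes:
            r = by_id[gid]
            if r.saliency is None:
                continue
            cell_ids = r.cell_ids if r.cell_ids is not None else range(len(r.saliency))
            for cid, s in zip(cell_ids, r.saliency):
                recs.append({"cell_id": cid, "gene_id": gid, "saliency": s})
        if recs:
            sal_path = out_prefix.with_name(out_prefix.name + ".saliency.csv")
            pd.DataFrame(recs).to_csv(sal_path, index=False, float_format="%.6g")
            written["saliency"] = sal_path
    return written


def write_dataset_table(ds: SpatialDataset, path) -> Path:
    """Write a dataset as a single dense CSV (cell_id, x, y, one column per gene)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    counts = ds.counts.toarray() if sp.issparse(ds.counts) else ds.counts
    df = pd.DataFrame(counts, columns=ds.gene_ids)
    df.insert(0, "y", ds.coords[:, 1])
    df.insert(0, "x", ds.coords[:, 0])
    df.insert(0, "cell_id", ds.cell_ids)
    df.to_csv(path, index=False)
    return path


def dataset_from_anndata(adata, spatial_key: str = "spatial") -> SpatialDataset:
    """Convenience constructor from an AnnData with coords in ``obsm[spatial_key]``."""
    coords = np.asarray(adata.obsm[spatial_key])[:, :2]
    return SpatialDataset(
        counts=adata.X.copy() if sp.issparse(adata.X) else np.asarray(adata.X),
        coords=coords,
        gene_ids=list(map(str, adata.var_names)),
        cell_ids=list(map(str, adata.obs_names)),
    )
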