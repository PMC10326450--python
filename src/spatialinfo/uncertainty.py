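"""Expression resampling from count posteriors.

Raw counts are noisy measurements of expression.  Rather than training the
classifier on fixed (transformed) counts, expression is redrawn from a
per-cell-per-gene posterior at each optimizer iteration, so the fitted score
reflects an expectation over plausible expression values and resists
overfitting sparse counts.

Three posteriors are supported:

* Gamma-Poisson — counts measure absolute expression; the conjugate posterior
  of the rate is Gamma(a0 + x, b0 + size_factor).
* Dirichlet-Multinomial — counts measure proportional expression; posterior
  proportions per cell are Dirichlet(a0d + x).
* Gaussian — posterior mean/sd matrices from an external model.

``none`` disables resampling (deterministic transform of the counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


@dataclass
class SamplerConfig:
    model: str = "gamma_poisson"  # gamma_poisson | dirichlet_multinomial | gaussian | none
    prior_shape: float = 0.1  # a0, Gamma prior shape
    prior_rate: float = 0.1  # b0, Gamma prior rate
    dirichlet_prior: float = 0.01  # a0d, symmetric Dirichlet concentration
    resample_every: int = 1
    transform: str | None = None  # default depends on model

    def __post_init__(self) -> None:
        if self.resample_every < 1:
            raise ValueError("resample_every must be >= 1")
        if self.model not in {"gamma_poisson", "dirichlet_multinomial", "gaussian", "none"}:
            raise ValueError(f"unknown uncertainty model {self.model!r}")
        if self.transform is None:
            # log is safe on the strictly positive posterior draws; raw counts
            # (none mode) contain zeros so use log1p there.
            self.transform = {"none": "log1p", "gaussian": "identity"}.get(self.model, "log")


def _apply_transform(x: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log":
        return np.log(x)
    if transform == "log1p":
        return np.log1p(x)
    if transform == "identity":
        return x
    raise ValueError(f"unknown transform {transform!r}")


def _check_integral(counts: np.ndarray) -> None:
    data = counts.data if sp.issparse(counts) else counts
    if not np.allclose(data, np.round(data)):
        raise ValueError("count-posterior models require integral counts")


def default_size_factors(total_counts: np.ndarray) -> np.ndarray:
    """Library size over median library size; cells with zero counts get 1."""
    total = np.asarray(total_counts, dtype=float)
    med = np.median(total[total > 0]) if np.any(total > 0) else 1.0
    sf = total / med
    sf[sf <= 0] = 1.0
    return sf


def sample_expression_gp(
    counts: np.ndarray,
    size_factors: np.ndarray,
    cfg: SamplerConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw rates from the conjugate Gamma posterior, then transform.

    lambda_cg ~ Gamma(shape = a0 + x_cg, rate = b0 + s_c); E[lambda] is the
    usual shrunken normalized-expression estimate (a0 + x) / (b0 + s).
    """
    if sp.issparse(counts):
        counts = counts.toarray()
    counts = np.asarray(counts, dtype=float)
    _check_integral(counts)
    size_factors = np.asarray(size_factors, dtype=float)
    if np.any(size_factors <= 0):
        raise ValueError("size factors must be positive")
    shape = cfg.prior_shape + counts
    rate = cfg.prior_rate + size_factors[:, None]
    lam = rng.gamma(shape, 1.0 / rate)
    return _apply_transform(lam, cfg.transform)


def sample_expression_dm(
    counts: np.ndarray,
    cfg: SamplerConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw per-cell proportions from the Dirichlet posterior, then transform.

    Output proportions are scaled to counts-per-10k before the transform so
    log values sit on a familiar normalized-expression scale.
    """
    if sp.issparse(counts):
        counts = counts.toarray()
    counts = np.asarray(counts, dtype=float)
    _check_integral(counts)
    totals = counts.sum(axis=1)
    if np.any(totals < 1):
        warnings.warn("cells with zero total counts: proportions drawn from the prior alone")
    # Dirichlet via normalized Gammas, vectorized over cells.
    g = rng.gamma(cfg.dirichlet_prior + counts, 1.0)
    p = g / g.sum(axis=1, keepdims=True)
    return _apply_transform(p * 1e4, cfg.transform)


def sample_expression_gaussian(
    posterior_mean: np.ndarray,
    posterior_sd: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent Normal(mean, sd) draws (identity transform)."""
    if posterior_sd is None:
        raise ValueError("gaussian uncertainty model requires a posterior sd matrix")
    mean = np.asarray(posterior_mean, dtype=float)
    sd = np.asarray(posterior_sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("posterior sd must be non-negative")
    return mean + sd * rng.standard_normal(mean.shape)


class GeneExpressionSampler:
    """Per-gene resampler used inside the training loop.

    Holds one gene's counts (or posterior summaries) for one level of the
    binning stack and produces a fresh standardized expression vector on each
    ``draw``.  Standardization (zero mean, unit variance across cells,
    recomputed per draw) is an affine change absorbed by the classifier's
    weights and shift, kept purely for optimizer conditioning.

    In dirichlet_multinomial mode the gene's marginal posterior proportion is
    Beta(a0d + x_g, (G-1)a0d + total - x_g) — the exact Dirichlet marginal —
    so single-gene draws avoid materializing the full simplex.
    """

    def __init__(
        self,
        counts: np.ndarray,
        cfg: SamplerConfig,
        size_factors: np.ndarray | None = None,
        cell_totals: np.ndarray | None = None,
        n_genes: int = 1,
        posterior_mean: np.ndarray | None = None,
        posterior_sd: np.ndarray | None = None,
        standardize: bool = True,
    ) -> None:
        self.cfg = cfg
        self.counts = np.asarray(counts, dtype=float)
        self.size_factors = size_factors
        self.cell_totals = cell_totals
        self.n_genes = n_genes
        self.posterior_mean = posterior_mean
        self.posterior_sd = posterior_sd
        self.standardize = standardize
        if cfg.model == "gamma_poisson":
            if size_factors is None:
                raise ValueError("gamma_poisson sampler needs size factors")
            _check_integral(self.counts)
            self._shape = cfg.prior_shape + self.counts
            self._rate = cfg.prior_rate + np.asarray(size_factors, dtype=float)
        elif cfg.model == "dirichlet_multinomial":
            if cell_totals is None:
                raise ValueError("dirichlet_multinomial sampler needs per-cell totals")
            _check_integral(self.counts)
            self._a = cfg.dirichlet_prior + self.counts
            self._b = (n_genes - 1) * cfg.dirichlet_prior + (
                np.asarray(cell_totals, dtype=float) - self.counts
            )
        elif cfg.model == "gaussian":
            if posterior_mean is None or posterior_sd is None:
                raise ValueError("gaussian sampler needs posterior mean and sd")
        # cached deterministic vector for 'none'
        self._fixed: np.ndarray | None = None

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        if not self.standardize:
            return x
        mu = x.mean()
        sd = x.std()
        if sd == 0 or not np.isfinite(sd):
            return np.zeros_like(x)
        return (x - mu) / sd

    def is_constant(self) -> bool:
        """True when the observed signal carries no variation across cells."""
        if self.cfg.model == "gaussian":
            return bool(np.ptp(self.posterior_mean) == 0 and np.ptp(self.posterior_sd) == 0)
        return bool(np.ptp(self.counts) == 0)

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        m = self.cfg.model
        if m == "none":
            if self._fixed is None:
                self._fixed = self._standardize(
                    _apply_transform(self.counts, self.cfg.transform)
                )
            return self._fixed
        if m == "gamma_poisson":
            lam = rng.gamma(self._shape, 1.0 / self._rate)
            return self._standardize(_apply_transform(lam, self.cfg.transform))
        if m == "dirichlet_multinomial":
            p = rng.beta(self._a, self._b)
            return self._standardize(_apply_transform(p * 1e4, self.cfg.transform))
        x = self.posterior_mean + self.posterior_sd * rng.standard_normal(self.counts.shape)
        return self._standardize(x)
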