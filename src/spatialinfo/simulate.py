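"""Labeled synthetic spatial transcriptomics data.

Two generators produce datasets with known ground-truth spatially varying
genes (SVGs):

* :func:`simulate_potts` — a cellular Potts model on a square lattice.  Cells
  are site sets evolving by Metropolis copy attempts under a Hamiltonian with
  (i) contact adhesion between adjacent sites of different cells, with a
  random symmetric cell-type affinity matrix J, (ii) a quadratic area
  constraint, and (iii) an actin-inspired protrusion term: sites carry an
  activity memory that decays from ``max_act`` after a successful copy, and
  copies from high-activity into low-activity regions receive an energy bonus,
  driving persistent migration.  Cell types are initialized in ordered bands
  from a sum of sine waves over the lattice, so spatial order is high at
  iteration 0 and decays (while remaining patterned through differential
  adhesion) as Monte-Carlo steps accumulate.  Expression is negative binomial
  per gene; SVG genes receive per-type multiplicative perturbations of the
  mean, so their expression tracks the (spatially organized) type layout.

* :func:`simulate_geo` — cells uniform on the unit square with SVG expression
  elevated in a vertical band ("streak") or central disk ("hotspot").

One iteration of the Potts model is one Monte-Carlo step sweep (L^2 copy
attempts).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .io import SpatialDataset, write_dataset_table


@dataclass
class PottsConfig:
    """Cellular Potts simulation settings.

    Defaults target the standard benchmark condition: 2,000 cells on a
    200 x 200 lattice, 4 cell types, with adhesion/activity/temperature
    chosen so that default-config cells visibly migrate and type order
    decays gradually over ~1,000 sweeps.  All values are recorded in the
    simulation's params.json.
    """

    lattice_size: int = 200
    n_cells: int = 2000
    n_types: int = 4
    target_area: int = 16
    adhesion_range: tuple[float, float] = (5.0, 15.0)
    lambda_area: float = 25.0
    lambda_act: float = 100.0
    max_act: float = 20.0
    temperature: float = 15.0
    iterations: int = 1000
    sine_periods: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells * self.target_area > self.lattice_size**2:
            raise ValueError(
                f"lattice {self.lattice_size}^2 too small for "
                f"{self.n_cells} cells of area {self.target_area}"
            )
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


@dataclass
class ExprConfig:
    """Negative binomial expression settings.

    ``n_svg`` of the ``n_genes`` genes are perturbed across cell types with
    per-type log-fold effects of standard deviation ``effect_size``.  Baseline
    gene means are log-normal and rescaled so the expected per-cell library
    size is ``target_library_size`` counts (a sparse in-situ-like regime).
    """

    n_genes: int = 8000
    n_svg: int = 1000
    nb_dispersion: float = 4.0  # r, in the benchmark range [3, 6]
    mean_log_sigma: float = 1.0
    target_library_size: float = 200.0
    effect_size: float = 0.5  # sigma_e, sd of per-type log-fold perturbation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_svg > self.n_genes:
            raise ValueError("n_svg cannot exceed n_genes")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class SimTruth:
    """Simulator output: dataset, ground-truth SVG labels, parameters."""

    dataset: SpatialDataset
    is_svg: np.ndarray
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# cellular Potts machinery
# ---------------------------------------------------------------------------


@njit(cache=True)
def _site_activity_gm(activity, spin, x, y, L):
    """Geometric mean of activity over the site and same-cell 4-neighbors."""
    s = spin[x, y]
    if s == 0:
        return 0.0
    log_sum = 0.0
    count = 0
    for dx, dy in ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)):
        xc, yc = x + dx, y + dy
        if 0 <= xc < L and 0 <= yc < L and spin[xc, yc] == s:
            a = activity[xc, yc]
            if a <= 0.0:
                return 0.0
            log_sum += np.log(a)
            count += 1
    return np.exp(log_sum / count)


@njit(cache=True)
def _run_mcs(spin, ctype, J, area, activity, A, lam_area, lam_act, max_act, temp, n_mcs, seed):
    """Run n_mcs Monte-Carlo step sweeps (L^2 copy attempts each) in place.

    Copy attempts that would annihilate a cell's last site are rejected, so
    the number of cells is conserved.  Returns the number of accepted copies.
    """
    np.random.seed(seed)
    L = spin.shape[0]
    accepted = 0
    for _ in range(n_mcs):
        for _ in range(L * L):
            xa = np.random.randint(0, L)
            ya = np.random.randint(0, L)
            d = np.random.randint(0, 4)
            xb, yb = xa, ya
            if d == 0:
                xb += 1
            elif d == 1:
                xb -= 1
            elif d == 2:
                yb += 1
            else:
                yb -= 1
            if xb < 0 or xb >= L or yb < 0 or yb >= L:
                continue
            sa = spin[xa, ya]
            sb = spin[xb, yb]
            if sa == sb:
                continue
            if sb != 0 and area[sb] == 1:
                continue  # never annihilate a cell
            dH = 0.0
            ta = ctype[sa]
            tb = ctype[sb]
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                xc, yc = xb + dx, yb + dy
                if xc < 0 or xc >= L or yc < 0 or yc >= L:
                    continue
                sc = spin[xc, yc]
                tc = ctype[sc]
                if sc != sa:
                    dH += J[ta, tc]
                if sc != sb:
                    dH -= J[tb, tc]
            if sb != 0:
                dH += lam_area * ((area[sb] - 1 - A) ** 2 - (area[sb] - A) ** 2)
            if sa != 0:
                dH += lam_area * ((area[sa] + 1 - A) ** 2 - (area[sa] - A) ** 2)
            if lam_act > 0.0 and max_act > 0.0:
                gm_a = _site_activity_gm(activity, spin, xa, ya, L)
                gm_b = _site_activity_gm(activity, spin, xb, yb, L)
                dH -= lam_act / max_act * (gm_a - gm_b)
            if dH > 0.0:
                if temp <= 0.0 or np.random.random() >= np.exp(-dH / temp):
                    continue
            if sb != 0:
                area[sb] -= 1
            if sa != 0:
                area[sa] += 1
            spin[xb, yb] = sa
            activity[xb, yb] = max_act if sa != 0 else 0.0
            accepted += 1
        # activity memory decays by one per sweep
        for x in range(L):
            for y in range(L):
                if activity[x, y] > 0.0:
                    activity[x, y] -= 1.0
    return accepted


def _sine_band_types(coords: np.ndarray, L: int, periods, n_types: int) -> np.ndarray:
    """Assign types by discretizing a sum of per-axis sine waves into
    equal-probability bands (balanced type frequencies)."""
    px, py = periods
    val = np.sin(2 * np.pi * px * coords[:, 0] / L) + np.sin(2 * np.pi * py * coords[:, 1] / L)
    qs = np.quantile(val, np.linspace(0, 1, n_types + 1)[1:-1])
    return np.searchsorted(qs, val, side="right").astype(np.int64)


def _seed_cells(cfg: PottsConfig, rng: np.random.Generator) -> np.ndarray:
    """Single-site cells on a jittered grid; returns (n_cells, 2) int sites."""
    L, n = cfg.lattice_size, cfg.n_cells
    g = int(np.ceil(np.sqrt(n)))
    spacing = L / g
    slots = [(i, j) for i in range(g) for j in range(g)]
    chosen = rng.permutation(len(slots))[:n]
    sites = np.empty((n, 2), dtype=np.int64)
    occupied = set()
    for c, slot_idx in enumerate(chosen):
        i, j = slots[slot_idx]
        jitter = rng.uniform(-spacing / 4, spacing / 4, size=2)
        x = int(np.clip(round((i + 0.5) * spacing + jitter[0]), 0, L - 1))
        y = int(np.clip(round((j + 0.5) * spacing + jitter[1]), 0, L - 1))
        while (x, y) in occupied:  # rare collision: probe right/up
            x = (x + 1) % L
            if (x, y) in occupied:
                y = (y + 1) % L
        occupied.add((x, y))
        sites[c] = (x, y)
    return sites


def _grow_cells(spin: np.ndarray, area: np.ndarray, A: int, rng: np.random.Generator) -> None:
    """Grow single-site cells toward the target area by claiming random
    adjacent empty sites, in randomized cell order per round."""
    L = spin.shape[0]
    n_cells = len(area) - 1
    sites: list[list[tuple[int, int]]] = [[] for _ in range(n_cells + 1)]
    xs, ys = np.nonzero(spin)
    for x, y in zip(xs, ys):
        sites[spin[x, y]].append((int(x), int(y)))
    for _ in range(A - 1):
        order = rng.permutation(n_cells) + 1
        grew = False
        for c in order:
            if area[c] >= A:
                continue
            frontier = []
            for (x, y) in sites[c]:
                for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    xb, yb = x + dx, y + dy
                    if 0 <= xb < L and 0 <= yb < L and spin[xb, yb] == 0:
                        frontier.append((xb, yb))
            if not frontier:
                continue
            xb, yb = frontier[rng.integers(len(frontier))]
            spin[xb, yb] = c
            sites[c].append((xb, yb))
            area[c] += 1
            grew = True
        if not grew:
            break


def _centroids(spin: np.ndarray, n_cells: int) -> np.ndarray:
    xs, ys = np.nonzero(spin)
    ids = spin[xs, ys]
    out = np.zeros((n_cells + 1, 2))
    cnt = np.zeros(n_cells + 1)
    np.add.at(out[:, 0], ids, xs)
    np.add.at(out[:, 1], ids, ys)
    np.add.at(cnt, ids, 1.0)
    return (out[1:] / cnt[1:, None]), cnt[1:]


class PottsState:
    """Lattice state of a cellular Potts run (exposed for inspection/tests)."""

    def __init__(self, cfg: PottsConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        L, n, T = cfg.lattice_size, cfg.n_cells, cfg.n_types
        seeds = _seed_cells(cfg, rng)
        types = _sine_band_types(seeds.astype(float), L, cfg.sine_periods, T)
        self.initial_types = types
        self.spin = np.zeros((L, L), dtype=np.int64)
        self.spin[seeds[:, 0], seeds[:, 1]] = np.arange(1, n + 1)
        self.ctype = np.zeros(n + 1, dtype=np.int64)
        self.ctype[1:] = types + 1  # 0 reserved for medium
        jmin, jmax = cfg.adhesion_range
        Jm = rng.uniform(jmin, jmax, size=(T + 1, T + 1))
        self.J = (Jm + Jm.T) / 2.0
        self.area = np.zeros(n + 1, dtype=np.int64)
        self.area[1:] = 1
        _grow_cells(self.spin, self.area, cfg.target_area, rng)
        self.activity = np.zeros((L, L), dtype=np.float64)
        self._mcs_done = 0
        self._seg = 0

    def run(self, n_mcs: int) -> int:
        """Advance the simulation by ``n_mcs`` sweeps; returns accepted copies."""
        if n_mcs == 0:
            return 0
        cfg = self.cfg
        kernel_seed = (cfg.seed * 1000003 + 7 * self._seg + 13) % (2**31 - 1)
        self._seg += 1
        acc = _run_mcs(
            self.spin,
            self.ctype,
            self.J,
            self.area,
            self.activity,
            cfg.target_area,
            cfg.lambda_area,
            cfg.lambda_act,
            cfg.max_act,
            cfg.temperature,
            n_mcs,
            kernel_seed,
        )
        self._mcs_done += n_mcs
        return int(acc)

    def total_energy(self) -> float:
        """Adhesion + area energy of the current lattice (activity excluded)."""
        spin, J, ctype = self.spin, self.J, self.ctype
        L = spin.shape[0]
        e = 0.0
        right = (spin[:-1, :], spin[1:, :])
        up = (spin[:, :-1], spin[:, 1:])
        for a, b in (right, up):
            diff = a != b
            e += J[ctype[a[diff]], ctype[b[diff]]].sum()
        e += self.cfg.lambda_area * ((self.area[1:] - self.cfg.target_area) ** 2).sum()
        return float(e)

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        return _centroids(self.spin, self.cfg.n_cells)

    @property
    def cell_types(self) -> np.ndarray:
        return self.ctype[1:] - 1

    @property
    def n_cells_alive(self) -> int:
        return int((self.area[1:] > 0).sum())


def draw_expression(
    types: np.ndarray, expr_cfg: ExprConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Negative binomial counts (cells x genes) with per-type SVG effects.

    Gene means are log-normal, rescaled to the target library size; the first
    ``n_svg`` genes (after a random shuffle of labels) get multiplicative
    per-type effects exp(N(0, effect_size^2)) on the mean.  Counts are
    NB(r, p) with mean mu and variance mu + mu^2 / r.
    """
    n_cells = len(types)
    G, r = expr_cfg.n_genes, expr_cfg.nb_dispersion
    base = rng.lognormal(0.0, expr_cfg.mean_log_sigma, size=G)
    base *= expr_cfg.target_library_size / base.sum()
    is_svg = np.zeros(G, dtype=bool)
    svg_idx = rng.permutation(G)[: expr_cfg.n_svg]
    is_svg[svg_idx] = True
    n_types = int(types.max()) + 1 if n_cells else 1
    mult = np.ones((G, n_types))
    mult[svg_idx] = np.exp(rng.normal(0.0, expr_cfg.effect_size, size=(expr_cfg.n_svg, n_types)))
    mu = base[None, :] * mult[:, types].T  # cells x genes
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    params = {"base_mean_sum": float(base.sum()), "n_svg": int(expr_cfg.n_svg)}
    return counts, is_svg, params


def simulate_potts(potts_cfg: Optional[PottsConfig] = None,
                   expr_cfg: Optional[ExprConfig] = None) -> SimTruth:
    """Run the cellular Potts simulation and draw expression at cell centroids."""
    potts_cfg = potts_cfg or PottsConfig()
    expr_cfg = expr_cfg or ExprConfig()
    state = PottsState(potts_cfg)
    state.run(potts_cfg.iterations)
    coords, areas = state.centroids()
    if np.any(areas == 0):
        raise RuntimeError("a cell vanished; annihilation guard failed")
    types = state.cell_types
    rng = np.random.default_rng(np.random.SeedSequence([expr_cfg.seed, 27644437]))
    counts, is_svg, expr_params = draw_expression(types, expr_cfg, rng)
    ds = SpatialDataset(
        counts=counts,
        coords=coords,
        cell_labels=np.array([f"type{t}" for t in types]),
    )
    params = {"potts": asdict(potts_cfg), "expr": asdict(expr_cfg), **expr_params}
    return SimTruth(dataset=ds, is_svg=is_svg, params=params)


def simulate_geo(
    n_cells: int = 5000,
    pattern: str = "streak",
    region_fraction: float = 0.2,
    fold_change: float = 3.0,
    nb_params: Optional[dict] = None,
    n_genes: int = 1000,
    n_svg: int = 100,
    seed: int = 0,
) -> SimTruth:
    """Uniform cells on the unit square with SVGs elevated in a region.

    ``streak``: vertical band centered at x = 0.5 of width ``region_fraction``
    (covering that fraction of the area).  ``hotspot``: central disk of
    radius sqrt(region_fraction / pi).  SVG genes have their NB mean
    multiplied by ``fold_change`` inside the region.
    """
    if not 0 < region_fraction < 1:
        raise ValueError("region_fraction must lie in (0, 1)")
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    nb_params = {"mean": 2.0, "dispersion": 4.0, "mean_log_sigma": 1.0, **(nb_params or {})}
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1.0, size=(n_cells, 2))
    if pattern == "streak":
        inside = np.abs(coords[:, 0] - 0.5) <= region_fraction / 2.0
    elif pattern == "hotspot":
        radius = np.sqrt(region_fraction / np.pi)
        inside = np.linalg.norm(coords - 0.5, axis=1) <= radius
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    r = float(nb_params["dispersion"])
    base = rng.lognormal(np.log(float(nb_params["mean"])), float(nb_params["mean_log_sigma"]), size=n_genes)
    is_svg = np.zeros(n_genes, dtype=bool)
    is_svg[rng.permutation(n_genes)[:n_svg]] = True
    mu = np.tile(base, (n_cells, 1))
    mu[np.ix_(inside, is_svg)] *= fold_change
    counts = rng.negative_binomial(r, r / (r + mu))
    ds = SpatialDataset(counts=counts, coords=coords,
                        cell_labels=np.where(inside, "inside", "outside"))
    params = {
        "pattern": pattern,
        "n_cells": n_cells,
        "region_fraction": region_fraction,
        "fold_change": fold_change,
        "nb_params": nb_params,
        "n_genes": n_genes,
        "n_svg": n_svg,
        "seed": seed,
    }
    return SimTruth(dataset=ds, is_svg=is_svg, params=params)


def type_homophily(coords: np.ndarray, types: np.ndarray) -> float:
    """Fraction of Delaunay-adjacent cell pairs sharing a type."""
    from .graph import build_graph

    g = build_graph(np.asarray(coords, dtype=float), "delaunay")
    same = total = 0
    for i, j in g.edge_set():
        total += 1
        same += int(types[i] == types[j])
    return same / total if total else float("nan")


def write_sim(sim: SimTruth, out_prefix) -> dict:
    """Write dataset table, truth.csv (gene_id, is_svg) and params.json."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {"dataset": write_dataset_table(sim.dataset, out_prefix.with_name(out_prefix.name + ".dataset.csv"))}
    import pandas as pd

    truth = pd.DataFrame({"gene_id": sim.dataset.gene_ids, "is_svg": sim.is_svg.astype(int)})
    tpath = out_prefix.with_name(out_prefix.name + ".truth.csv")
    truth.to_csv(tpath, index=False)
    paths["truth"] = tpath
    ppath = out_prefix.with_name(out_prefix.name + ".params.json")
    ppath.write_text(json.dumps(sim.params, indent=2, default=str))
    paths["params"] = ppath
    return paths
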