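import numpy as np
import pytest

from spatialinfo.simulate import (
    ExprConfig,
    PottsConfig,
    PottsState,
    draw_expression,
    simulate_geo,
    simulate_potts,
    type_homophily,
    write_sim,
)

SMALL = dict(lattice_size=60, n_cells=200, n_types=4, target_area=8)


class TestPottsInit:
    def test_iteration_zero_matches_sine_bands(self):
        st = PottsState(PottsConfig(seed=5, iterations=0, **SMALL))
        np.testing.assert_array_equal(st.cell_types, st.initial_types)
        # balanced type frequencies from quantile bands
        counts = np.bincount(st.cell_types, minlength=4)
        assert counts.max() - counts.min() <= 2

    def test_initial_order_is_high(self):
        st = PottsState(PottsConfig(seed=5, iterations=0, **SMALL))
        coords, _ = st.centroids()
        assert type_homophily(coords, st.cell_types) > 0.6

    def test_lattice_too_small_error(self):
        with pytest.raises(ValueError):
            PottsConfig(lattice_size=10, n_cells=50, target_area=10)

    def test_cells_grow_to_target_area(self):
        st = PottsState(PottsConfig(seed=1, iterations=0, **SMALL))
        assert st.area[1:].min() >= 1
        assert st.area[1:].max() <= SMALL["target_area"]
        assert np.median(st.area[1:]) == SMALL["target_area"]


class TestPottsDynamics:
    def test_cell_count_conserved(self):
        st = PottsState(PottsConfig(seed=2, **SMALL))
        st.run(100)
        assert st.n_cells_alive == SMALL["n_cells"]
        assert st.area[1:].min() >= 1

    def test_energy_decreases_at_low_temperature(self):
        cfg = PottsConfig(seed=3, temperature=0.1, lambda_act=0.0, **SMALL)
        st = PottsState(cfg)
        e0 = st.total_energy()
        st.run(20)
        assert st.total_energy() < e0

    def test_order_decays_with_iterations(self):
        st = PottsState(PottsConfig(seed=4, **SMALL))
        st.run(10)
        c10, _ = st.centroids()
        h10 = type_homophily(c10, st.cell_types)
        st.run(990)
        c1k, _ = st.centroids()
        h1k = type_homophily(c1k, st.cell_types)
        assert h10 >= h1k

    def test_deterministic_given_seed(self):
        runs = []
        for _ in range(2):
            st = PottsState(PottsConfig(seed=6, **SMALL))
            st.run(10)
            runs.append(st.spin.copy())
        np.testing.assert_array_equal(runs[0], runs[1])


class TestExpression:
    def test_default_svg_count(self):
        cfg = ExprConfig()
        assert cfg.n_genes == 8000 and cfg.n_svg == 1000
        rng = np.random.default_rng(0)
        types = rng.integers(0, 4, 300)
        _, is_svg, _ = draw_expression(types, cfg, rng)
        assert is_svg.sum() == 1000

    def test_nb_moments(self):
        # a non-SVG gene has NB(mu, r) counts: variance mu + mu^2/r
        cfg = ExprConfig(n_genes=20, n_svg=0, nb_dispersion=4.0, seed=1)
        rng = np.random.default_rng(1)
        types = np.zeros(20_000, dtype=int)
        counts, _, _ = draw_expression(types, cfg, rng)
        for j in range(3):
            mu = counts[:, j].mean()
            expected_var = mu + mu**2 / 4.0
            assert counts[:, j].var() == pytest.approx(expected_var, rel=0.1)

    def test_svg_genes_vary_by_type(self):
        cfg = ExprConfig(n_genes=50, n_svg=25, effect_size=1.0, seed=2,
                         target_library_size=500)
        rng = np.random.default_rng(2)
        types = np.repeat([0, 1], 2000)
        counts, is_svg, _ = draw_expression(types, cfg, rng)
        lfc = np.abs(
            np.log1p(counts[types == 0].mean(axis=0))
            - np.log1p(counts[types == 1].mean(axis=0))
        )
        assert lfc[is_svg].mean() > lfc[~is_svg].mean()


class TestSimulatePotts:
    def test_end_to_end_small(self):
        sim = simulate_potts(
            PottsConfig(seed=0, iterations=5, **SMALL),
            ExprConfig(n_genes=40, n_svg=10, seed=0),
        )
        assert sim.dataset.n_cells == SMALL["n_cells"]
        assert sim.dataset.n_genes == 40
        assert sim.is_svg.sum() == 10
        assert sim.dataset.cell_labels is not None


class TestSimulateGeo:
    def test_region_fraction_coverage(self):
        sim = simulate_geo(n_cells=10_000, pattern="streak", region_fraction=0.2,
                           n_genes=5, n_svg=1, seed=0)
        inside = sim.dataset.cell_labels == "inside"
        assert inside.mean() == pytest.approx(0.2, abs=0.012)

    def test_hotspot_disk_geometry(self):
        frac = 0.15
        sim = simulate_geo(n_cells=20_000, pattern="hotspot", region_fraction=frac,
                           n_genes=5, n_svg=1, seed=1)
        radius = np.sqrt(frac / np.pi)
        r = np.linalg.norm(sim.dataset.coords - 0.5, axis=1)
        inside = sim.dataset.cell_labels == "inside"
        assert np.all(r[inside] <= radius + 1e-12)
        assert np.all(r[~inside] > radius)
        assert inside.mean() == pytest.approx(frac, abs=0.01)

    def test_fold_change_one_is_null(self):
        sim = simulate_geo(n_cells=4000, fold_change=1.0, n_genes=20, n_svg=10, seed=2)
        inside = sim.dataset.cell_labels == "inside"
        svg_means_in = sim.dataset.counts[inside][:, sim.is_svg].mean()
        svg_means_out = sim.dataset.counts[~inside][:, sim.is_svg].mean()
        assert svg_means_in == pytest.approx(svg_means_out, rel=0.1)

    def test_svg_elevated_inside_region(self):
        sim = simulate_geo(n_cells=4000, fold_change=4.0, n_genes=20, n_svg=10, seed=3)
        inside = sim.dataset.cell_labels == "inside"
        ratio = (
            sim.dataset.counts[inside][:, sim.is_svg].mean()
            / sim.dataset.counts[~inside][:, sim.is_svg].mean()
        )
        assert ratio == pytest.approx(4.0, rel=0.2)


class TestWriteSim:
    def test_round_trip_and_truth(self, tmp_path):
        from spatialinfo import read_dataset

        sim = simulate_geo(n_cells=50, n_genes=8, n_svg=2, seed=4)
        paths = write_sim(sim, tmp_path / "sim")
        ds2 = read_dataset(paths["dataset"], mode="table")
        np.testing.assert_array_equal(np.asarray(sim.dataset.counts), ds2.counts)
        import pandas as pd

        truth = pd.read_csv(paths["truth"])
        assert len(truth) == 8
        assert truth.is_svg.sum() == 2

    def test_params_replay_identical(self, tmp_path):
        import json

        sim = simulate_geo(n_cells=30, n_genes=5, n_svg=1, seed=9)
        paths = write_sim(sim, tmp_path / "sim")
        params = json.loads(paths["params"].read_text())
        sim2 = simulate_geo(
            n_cells=params["n_cells"], pattern=params["pattern"],
            region_fraction=params["region_fraction"], fold_change=params["fold_change"],
            n_genes=params["n_genes"], n_svg=params["n_svg"], seed=params["seed"],
        )
        np.testing.assert_array_equal(np.asarray(sim.dataset.counts), np.asarray(sim2.dataset.counts))
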