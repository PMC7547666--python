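"""GA selector: fitness semantics, evolution integrity, ensemble statistics."""

import numpy as np
import pytest

import specselect.ga as ga_mod
from specselect.dataset import SpectraDataset
from specselect.ga import (
    GAConfig,
    ensemble_from_chromosomes,
    ensemble_ga,
    fitness,
    run_ga,
    select_by_probability,
    synchronous_2d_correlation,
)


def _small_problem(seed=0, n=30, p=25, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X[:, 4] - X[:, 5] + noise * rng.normal(size=n)
    return X, np.abs(y - y.min())


_FAST = dict(
    population_size=16,
    generations=8,
    fitness_mccv_iters=10,
    holdout_n_v=4,
    n_components=2,
    init_density=0.3,
)


class TestFitness:
    def test_exact_linear_chromosome_is_perfect(self):
        # rank-1 informative pair: one component fits y without residual
        # while the chromosome still satisfies the >= c + 1 size rule
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 10))
        X[:, 9] = X[:, 0]
        y = 2.0 * X[:, 0]
        chrom = np.zeros(10, dtype=bool)
        chrom[[0, 9]] = True
        cfg = GAConfig(n_components=1, fitness_mccv_iters=10, fitness_n_v=4)
        assert fitness(chrom, X, y, cfg, seed=0) < 1e-16

    def test_undersized_chromosome_gets_sentinel(self):
        X, y = _small_problem()
        cfg = GAConfig(n_components=3, fitness_mccv_iters=5, fitness_n_v=4)
        small = np.zeros(25, dtype=bool)
        small[:3] = True  # 3 selected < n_components + 1
        assert fitness(small, X, y, cfg, seed=0) == np.inf

    def test_empty_chromosome_gets_sentinel_not_exception(self):
        X, y = _small_problem()
        cfg = GAConfig(n_components=2, fitness_mccv_iters=5, fitness_n_v=4)
        assert fitness(np.zeros(25, dtype=bool), X, y, cfg, seed=0) == np.inf

    def test_superset_of_signal_beats_noise_only(self):
        X, y = _small_problem(seed=2)
        cfg = GAConfig(n_components=2, fitness_mccv_iters=20, fitness_n_v=5)
        rng = np.random.default_rng(3)
        noise_only = np.zeros(25, dtype=bool)
        noise_only[rng.choice([i for i in range(25) if i not in (4, 5)], 8, replace=False)] = True
        superset = noise_only.copy()
        superset[[4, 5]] = True
        assert fitness(superset, X, y, cfg, seed=7) <= fitness(noise_only, X, y, cfg, seed=7)


class TestRunGa:
    def test_boundary_single_generation(self):
        X, y = _small_problem(seed=4)
        cfg = GAConfig(population_size=2, generations=1, fitness_mccv_iters=4,
                       holdout_n_v=4, n_components=2, init_density=0.4)
        res = run_ga(X, y, cfg, run_seed=0)
        assert res.fitness_history.shape == (1,)
        assert res.rmsev_history.shape == (1,)

    def test_elitism_makes_best_fitness_non_increasing(self):
        X, y = _small_problem(seed=5)
        res = run_ga(X, y, GAConfig(**_FAST), run_seed=1)
        finite = res.fitness_history[np.isfinite(res.fitness_history)]
        assert np.all(np.diff(finite) <= 1e-15)

    def test_deterministic_given_run_seed(self):
        X, y = _small_problem(seed=6)
        a = run_ga(X, y, GAConfig(**_FAST), run_seed=3)
        b = run_ga(X, y, GAConfig(**_FAST), run_seed=3)
        np.testing.assert_array_equal(a.best_chromosome, b.best_chromosome)
        np.testing.assert_array_equal(a.fitness_history, b.fitness_history)
        assert a.holdout_rmsev == b.holdout_rmsev

    def test_holdout_isolation_no_leakage(self, monkeypatch):
        # instrument the fitness evaluator: every design matrix it sees must
        # be built exclusively from evolution-set rows
        X, y = _small_problem(seed=7)
        seen: list[np.ndarray] = []
        original = ga_mod._mccv_errors

        def spy(Xs, ys, c, splits, **kw):
            seen.append(np.asarray(ys))
            return original(Xs, ys, c, splits, **kw)

        monkeypatch.setattr(ga_mod, "_mccv_errors", spy)
        res = run_ga(X, y, GAConfig(**_FAST), run_seed=5)
        holdout_y = set(np.round(y[res.holdout_indices], 12).tolist())
        assert seen, "fitness evaluator was never exercised"
        for ys in seen:
            assert not holdout_y & set(np.round(ys, 12).tolist())

    def test_chromosome_history_tracking(self):
        X, y = _small_problem(seed=8)
        cfg = GAConfig(track_chromosomes=True, **_FAST)
        res = run_ga(X, y, cfg, run_seed=2)
        assert res.chromosome_history.shape == (cfg.generations, 25)
        np.testing.assert_array_equal(res.chromosome_history[-1], res.best_chromosome)


class TestEnsemble:
    def test_bit_identical_under_fixed_seed(self):
        X, y = _small_problem(seed=9)
        cfg = GAConfig(n_runs=4, seed=11, **_FAST)
        a = ensemble_ga(X, y, cfg)
        b = ensemble_ga(X, y, cfg)
        np.testing.assert_array_equal(a.G, b.G)
        np.testing.assert_array_equal(a.H, b.H)
        np.testing.assert_array_equal(a.p_ga, b.p_ga)

    def test_h_matrix_identities_and_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        G_rows = rng.random((7, 20)) < 0.4
        ens = ensemble_from_chromosomes(list(G_rows), n_runs_total=7)
        H = ens.H
        assert np.array_equal(H, H.T)
        assert np.all(np.diag(H)[:, None] >= H)
        assert H.max() <= 7 and H.min() >= 0
        # brute force double loop
        for i in range(20):
            for j in range(20):
                count = sum(1 for r in G_rows if r[i] and r[j])
                assert H[i, j] == count
        np.testing.assert_array_equal(np.diag(H), G_rows.sum(axis=0))

    def test_hand_arithmetic_case(self):
        ens = ensemble_from_chromosomes(
            [np.array([1, 1, 0], dtype=bool), np.array([0, 1, 0], dtype=bool)],
            n_runs_total=2,
        )
        np.testing.assert_array_equal(ens.H, [[1, 1, 0], [1, 2, 0], [0, 0, 0]])
        np.testing.assert_allclose(ens.p_ga, [0.5, 1.0, 0.0])

    def test_all_ones_identity(self):
        ens = ensemble_from_chromosomes([np.ones(4, dtype=bool)] * 3, n_runs_total=3)
        assert np.all(ens.H == 3)
        np.testing.assert_allclose(ens.p_ga, 1.0)


class TestSelectByProbability:
    def _ens(self):
        return ensemble_from_chromosomes(
            [np.array([1, 1, 0], dtype=bool), np.array([0, 1, 0], dtype=bool)],
            n_runs_total=4,
        )

    def test_threshold_zero_selects_everything(self):
        assert select_by_probability(self._ens(), 0.0).mask.all()

    def test_out_of_range_threshold(self):
        with pytest.raises(ValueError):
            select_by_probability(self._ens(), 1.0 + 1e-9)

    def test_hand_case_at_default_threshold(self):
        sel = select_by_probability(self._ens(), 0.6)
        np.testing.assert_array_equal(sel.mask, [False, True, False])

    def test_total_denominator_switch(self):
        sel = select_by_probability(self._ens(), 0.6, denominator="total")
        # counts (1, 2, 0) over 4 total runs -> (0.25, 0.5, 0)
        np.testing.assert_allclose(sel.score, [0.25, 0.5, 0.0])
        assert not sel.mask.any()


def test_ensemble_serialization_round_trip(tmp_path):
    ens = ensemble_from_chromosomes(
        [np.array([1, 1, 0], dtype=bool), np.array([0, 1, 0], dtype=bool)],
        n_runs_total=2,
    )
    ens.save(tmp_path, wavenumbers=[1000.0, 1001.0, 1002.0], config=GAConfig(n_runs=2))
    G_back = np.loadtxt(tmp_path / "G.tsv", dtype=int)
    H_back = np.loadtxt(tmp_path / "H.tsv", dtype=int)
    np.testing.assert_array_equal(G_back, ens.G)
    np.testing.assert_array_equal(H_back, ens.H)
    lines = (tmp_path / "p_ga.tsv").read_text().strip().splitlines()
    assert lines[0] == "wavenumber\tp_ga" and len(lines) == 4
    assert (tmp_path / "ensemble.yaml").exists()


class TestSynchronous2DCorrelation:
    def test_symmetry_and_variance_diagonal(self):
        X = np.random.default_rng(0).normal(size=(12, 6))
        phi = synchronous_2d_correlation(X)
        np.testing.assert_allclose(phi, phi.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(phi), X.var(axis=0, ddof=1), rtol=1e-12)

    def test_perfectly_correlated_columns(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=20)
        X = np.column_stack([a, 3.0 * a])
        phi = synchronous_2d_correlation(X)
        expected = np.sqrt(phi[0, 0] * phi[1, 1])
        assert phi[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_orthogonal_centered_columns(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        phi = synchronous_2d_correlation(np.column_stack([a, b]))
        assert phi[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_needs_two_spectra(self):
        with pytest.raises(ValueError):
            synchronous_2d_correlation(np.ones((1, 5)))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"crossover_rate": 1.5},
            {"init_density": -0.1},
            {"acceptance_factor": 0.0},
            {"population_size": 0},
            {"mutation_rate": 2.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GAConfig(**kwargs)
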