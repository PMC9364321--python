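"""Optimizer baselines: Tanimoto GP correctness against a dense oracle,
GA contracts, token-string robustness, BO plumbing, similarity search."""

import numpy as np
import pytest
from rdkit import Chem

from dockbench import benchmarks as bm
from dockbench import docking as dk
from dockbench import fixtures as fx
from dockbench.chemspace import fingerprint, fingerprint_array, tanimoto_matrix
from dockbench.optimizers import (Acquisition, BOConfig, GAConfig,
                                  GPHyperparams, ScoredMolecule,
                                  TanimotoGPState, bo_select_batch,
                                  bo_training_subset, crossover,
                                  expected_improvement, fss_rank, gp_fit,
                                  gp_predict, graph_ga_generation,
                                  log_marginal_likelihood, mutate,
                                  mutate_tokens, random_baseline,
                                  run_optimizer, selfies_ga_generation, ucb)
from dockbench.optimizers import selfies_lite as sl


def _random_fps(rng, n, nbits=64, density=0.3):
    return (rng.random((n, nbits)) < density).astype(np.float32)


def _oracle_posterior(params, train_arr, y, query_arr):
    """Textbook GP posterior with explicit matrix inversion (independent of
    the package's Cholesky path)."""
    K = params.amplitude * tanimoto_matrix(train_arr, train_arr)
    K = K + (params.noise + 1e-8) * np.eye(len(y))
    Ks = params.amplitude * tanimoto_matrix(train_arr, query_arr)
    Kinv = np.linalg.inv(K)
    r = np.asarray(y) - params.constant_mean
    mean = params.constant_mean + Ks.T @ Kinv @ r
    var = params.amplitude - np.einsum("ij,ik,kj->j", Ks, Kinv, Ks)
    return mean, np.maximum(var, 0)


class TestGP:
    @pytest.mark.parametrize("n,q,seed", [(5, 2, 0), (20, 7, 1), (50, 10, 2)])
    def test_posterior_matches_dense_oracle(self, n, q, seed):
        rng = np.random.default_rng(seed)
        params = GPHyperparams(amplitude=1.7, noise=0.2, constant_mean=-8.0)
        train = _random_fps(rng, n)
        query = _random_fps(rng, q)
        y = rng.normal(-8, 1, size=n)
        mean, var = gp_predict(params, (train, y), query)
        omean, ovar = _oracle_posterior(params, train, y, query)
        assert np.allclose(mean, omean, atol=1e-8)
        assert np.allclose(var, ovar, atol=1e-8)

    def test_interpolation_limit(self):
        rng = np.random.default_rng(5)
        train = _random_fps(rng, 8)
        y = rng.normal(size=8)
        params = GPHyperparams(amplitude=1.0, noise=1e-9, constant_mean=0.0)
        mean, _ = gp_predict(params, (train, y), train)
        assert np.allclose(mean, y, atol=1e-4)

    def test_prior_reversion_for_dissimilar_query(self):
        params = GPHyperparams(amplitude=2.0, noise=0.1, constant_mean=-7.5)
        train = np.zeros((4, 32), dtype=np.float32)
        train[:, :8] = 1.0
        query = np.zeros((1, 32), dtype=np.float32)
        query[:, 20:] = 1.0  # zero Tanimoto overlap with every training point
        mean, var = gp_predict(params, (train, [1.0, 2.0, 0.5, 1.5]), query)
        assert mean[0] == pytest.approx(-7.5)
        assert var[0] == pytest.approx(2.0)

    def test_fit_never_below_init_likelihood(self, small_library):
        fps = fingerprint_array([fingerprint(s) for s in small_library[:40]])
        rng = np.random.default_rng(0)
        y = rng.normal(-8, 1, size=40)
        init = GPHyperparams(amplitude=1.0, noise=0.5, constant_mean=0.0)
        fitted = gp_fit(fps, y, init)
        assert (log_marginal_likelihood(fitted, fps, y)
                >= log_marginal_likelihood(init, fps, y))

    def test_parameter_recovery_from_simulated_data(self, small_library):
        """Data simulated from a known Tanimoto GP: both amplitude and noise
        recovered within 50% relative error at n = 200."""
        fps = fingerprint_array([fingerprint(s) for s in small_library[:200]])
        true = GPHyperparams(amplitude=2.0, noise=1.0, constant_mean=-8.0)
        K = true.amplitude * tanimoto_matrix(fps, fps) + true.noise * np.eye(200)
        rng = np.random.default_rng(0)
        y = true.constant_mean + np.linalg.cholesky(
            K + 1e-10 * np.eye(200)) @ rng.standard_normal(200)
        fitted = gp_fit(fps, y, GPHyperparams(amplitude=1.0, noise=0.5,
                                              constant_mean=0.0))
        assert abs(fitted.amplitude - true.amplitude) / true.amplitude <= 0.5
        assert abs(fitted.noise - true.noise) / true.noise <= 0.5

    def test_incremental_update_equals_rebuild(self):
        rng = np.random.default_rng(9)
        params = GPHyperparams(amplitude=1.3, noise=0.15, constant_mean=-8.0)
        A, yA = _random_fps(rng, 20), rng.normal(size=20)
        B, yB = _random_fps(rng, 6), rng.normal(size=6)
        state = TanimotoGPState(params, A, yA)
        state.add(B, yB)
        rebuilt = TanimotoGPState(params, np.vstack([A, B]),
                                  np.concatenate([yA, yB]))
        Q = _random_fps(rng, 5)
        m1, v1 = state.predict(Q)
        m2, v2 = rebuilt.predict(Q)
        assert np.allclose(m1, m2, atol=1e-8)
        assert np.allclose(v1, v2, atol=1e-8)

    def test_invalid_hyperparams(self):
        with pytest.raises(ValueError):
            GPHyperparams(amplitude=0.0)
        with pytest.raises(ValueError):
            GPHyperparams(noise=-0.1)


class TestAcquisition:
    def test_ucb_formula(self):
        mu, sd = np.array([1.0, 2.0]), np.array([0.5, 0.1])
        assert np.allclose(ucb(mu, sd, beta=10), [6.0, 3.0])

    def test_ei_zero_when_certain_and_worse(self):
        ei = expected_improvement(np.array([0.0]), np.array([1e-14]), best=1.0)
        assert ei[0] == pytest.approx(0.0, abs=1e-10)

    def test_ei_matches_monte_carlo(self):
        rng = np.random.default_rng(2)
        mu, sd, best = 0.3, 0.8, 0.5
        samples = rng.normal(mu, sd, size=400_000)
        mc = np.maximum(samples - best, 0).mean()
        ei = expected_improvement(np.array([mu]), np.array([sd]), best)[0]
        assert ei == pytest.approx(mc, rel=0.02)

    def test_ucb_argmax_matches_enumeration_over_pool(self, small_library):
        """On a fixed candidate pool, the acquisition ranking used by batch
        selection agrees with exhaustive evaluation of mu + beta * sigma."""
        fps = fingerprint_array([fingerprint(s) for s in small_library[:30]])
        rng = np.random.default_rng(1)
        y = rng.normal(size=30)
        params = GPHyperparams(amplitude=1.0, noise=0.1, constant_mean=0.0)
        state = TanimotoGPState(params, fps[:20], y[:20])
        pool = fps[20:]
        mean, var = state.predict(pool)
        values = ucb(mean, np.sqrt(var), beta=10.0)
        brute = [ucb(state.predict(pool[i:i + 1])[0],
                     np.sqrt(state.predict(pool[i:i + 1])[1]), 10.0)[0]
                 for i in range(len(pool))]
        assert np.allclose(values, brute, atol=1e-10)
        assert int(np.argmax(values)) == int(np.argmax(brute))


@pytest.fixture(scope="module")
def objective(mini_target):
    backend = dk.MockBackend()
    return lambda smi: backend.score_smiles(mini_target, smi)


class TestGraphGA:

    def test_population_size_after_step_is_250(self, library_2000, objective):
        config = GAConfig(seed=0)
        population = [ScoredMolecule(s, objective(s)) for s in library_2000[:250]]
        new = graph_ga_generation(population, config, objective)
        assert len(new) == 250

    def test_elitism_best_never_worsens(self, small_library, objective):
        config = GAConfig(population_size=50, offspring_size=10, seed=1)
        population = [ScoredMolecule(s, objective(s)) for s in small_library[:50]]
        rng = np.random.default_rng(1)
        best = min(m.value for m in population)
        for _ in range(5):
            population = graph_ga_generation(population, config, objective, rng)
            new_best = min(m.value for m in population)
            assert new_best <= best + 1e-12
            best = new_best

    def test_all_emitted_smiles_valid(self, small_library, objective):
        config = GAConfig(population_size=30, offspring_size=20, seed=2)
        population = [ScoredMolecule(s, objective(s)) for s in small_library[:30]]
        rng = np.random.default_rng(2)
        for _ in range(5):
            population = graph_ga_generation(population, config, objective, rng)
            for m in population:
                assert Chem.MolFromSmiles(m.smiles) is not None

    def test_variation_operators_validity_sweep(self, small_library):
        rng = np.random.default_rng(4)
        mols = [Chem.MolFromSmiles(s) for s in small_library[:40]]
        produced = 0
        for _ in range(100):
            i, j = rng.integers(len(mols), size=2)
            child = crossover(mols[i], mols[j], rng)
            if child is None:
                child = mutate(mols[i], rng)
            if child is not None:
                assert Chem.MolFromSmiles(Chem.MolToSmiles(child)) is not None
                produced += 1
        assert produced >= 80


class TestSelfiesGA:
    def test_round_trip_on_library(self, small_library):
        ok = 0
        for smi in small_library[:100]:
            try:
                tokens = sl.encode(smi)
            except sl.EncodingError:
                continue
            assert sl.decode(tokens) == Chem.CanonSmiles(smi)
            ok += 1
        assert ok >= 90

    def test_thousand_random_edits_always_decode(self, small_library):
        rng = np.random.default_rng(0)
        encodable = []
        for smi in small_library:
            try:
                encodable.append(sl.encode(smi))
            except sl.EncodingError:
                continue
            if len(encodable) >= 50:
                break
        for i in range(1000):
            tokens = encodable[i % len(encodable)]
            child = sl.decode(mutate_tokens(tokens, rng))
            if child is not None:
                assert Chem.MolFromSmiles(child) is not None

    def test_single_token_edit_distance(self):
        rng = np.random.default_rng(6)
        tokens = sl.encode("CC(=O)Nc1ccc(O)cc1")
        for _ in range(100):
            edited = mutate_tokens(tokens, rng)
            assert abs(len(edited) - len(tokens)) <= 1
            if len(edited) == len(tokens):
                assert sum(a != b for a, b in zip(edited, tokens)) == 1

    def test_same_seed_same_edit_sequence(self):
        tokens = sl.encode("c1ccc(CCN)cc1")
        seq_a = [mutate_tokens(tokens, np.random.default_rng(42)) for _ in range(1)]
        seq_b = [mutate_tokens(tokens, np.random.default_rng(42)) for _ in range(1)]
        assert seq_a == seq_b

    def test_generation_step(self, small_library, mini_target):
        backend = dk.MockBackend()
        objective = lambda smi: backend.score_smiles(mini_target, smi)  # noqa: E731
        config = GAConfig(population_size=30, offspring_size=15, seed=3)
        population = [ScoredMolecule(s, objective(s)) for s in small_library[:30]]
        new = selfies_ga_generation(population, config, objective,
                                    np.random.default_rng(3))
        assert len(new) == 30
        assert min(m.value for m in new) <= min(m.value for m in population)


class TestBOPlumbing:
    def test_training_subset_composition(self):
        rng = np.random.default_rng(0)
        values = list(rng.normal(size=200))
        smiles = [f"M{i}" for i in range(200)]
        config = BOConfig(n_best_train=20, n_random_train=30, seed=0)
        subset = bo_training_subset(smiles, values, config)
        assert len(subset) == 50
        assert len(set(subset)) == 50
        assert int(np.argmin(values)) in subset
        best20 = set(np.argsort(values)[:20])
        assert best20.issubset(subset)

    def test_training_subset_fallback_for_small_dataset(self):
        config = BOConfig(n_best_train=2000, n_random_train=3000)
        subset = bo_training_subset([f"M{i}" for i in range(100)],
                                    list(range(100)), config)
        assert subset == list(range(100))

    def test_defaults_as_published(self):
        config = BOConfig()
        assert config.beta == 10
        assert config.batch_size == 5
        assert config.n_best_train == 2000
        assert config.n_random_train == 3000
        assert config.inner_ga_offspring == 1000
        assert config.inner_ga_generations == 25
        ga = GAConfig()
        assert (ga.population_size, ga.offspring_size, ga.mutation_rate) == (250, 25, 0.01)

    def test_select_batch_size_and_novelty(self, small_library):
        fps = fingerprint_array([fingerprint(s) for s in small_library[:60]])
        rng = np.random.default_rng(0)
        y = rng.normal(size=60)
        params = GPHyperparams(amplitude=1.0, noise=0.1, constant_mean=0.0)
        state = TanimotoGPState(params, fps, y)
        evaluated = set(small_library[:60])
        seed_pop = [(s, float(v)) for s, v in zip(small_library[:20], y[:20])]
        config = BOConfig(batch_size=5, inner_ga_offspring=30,
                          inner_ga_generations=3, seed=0)
        batch = bo_select_batch(state, evaluated, seed_pop, config, rng)
        assert len(batch) == 5
        assert len(set(batch)) == 5
        assert not set(batch) & evaluated


class TestFSS:
    def test_identical_active_reference_ranked_first(self, small_library):
        refs = small_library[:20]
        flags = [True] * 20
        library = [small_library[25], refs[3], small_library[30]]
        lib_fps = [fingerprint(s) for s in library]
        ref_fps = [fingerprint(s) for s in refs]
        ranked = fss_rank(lib_fps, ref_fps, flags, top_k=10)
        assert ranked[0] == 1  # the molecule identical to an active reference

    def test_inactive_nearest_reference_discarded(self):
        refs = ["CCCCCCCC", "c1ccc2ccccc2c1"]
        flags = [True, False]
        library = ["CCCCCCCCC", "Cc1ccc2ccccc2c1"]
        ranked = fss_rank([fingerprint(s) for s in library],
                          [fingerprint(s) for s in refs], flags)
        assert ranked == [0]

    def test_output_capped_at_top_k(self, small_library):
        lib_fps = [fingerprint(s) for s in small_library[:100]]
        ref_fps = [fingerprint(s) for s in small_library[100:120]]
        ranked = fss_rank(lib_fps, ref_fps, [True] * 20, top_k=7)
        assert len(ranked) <= 7

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            fss_rank([fingerprint("CCO")], [], [])


class TestRandomBaseline:
    def test_full_library(self):
        lib = [f"M{i}" for i in range(10)]
        assert sorted(random_baseline(lib, 10, seed=0)) == sorted(lib)

    def test_deterministic_and_seed_sensitive(self):
        lib = [f"M{i}" for i in range(500)]
        assert random_baseline(lib, 50, seed=1) == random_baseline(lib, 50, seed=1)
        assert random_baseline(lib, 50, seed=1) != random_baseline(lib, 50, seed=2)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            random_baseline(["CCO"], 2)


class TestBudgetCompliance:
    @pytest.mark.parametrize("name", ["random", "graph_ga", "selfies_ga"])
    def test_halts_under_budget_on_failing_objective(self, small_library, name):
        def always_fails(smiles: str) -> float:
            raise ValueError("simulated preparation failure")

        dataset = (small_library[:100], [0.0] * 100)
        result = run_optimizer(name, dataset, always_fails, budget=30, seed=0,
                               ga_config=GAConfig(population_size=20,
                                                  offspring_size=10, seed=0))
        assert result["ledger"].unique_calls <= 30

    def test_gp_bo_respects_budget(self, small_library, mini_target):
        backend = dk.MockBackend()
        objective = lambda smi: backend.score_smiles(mini_target, smi)  # noqa: E731
        lib = small_library[:150]
        values = [objective(s) for s in lib]
        config = BOConfig(seed=0, n_best_train=30, n_random_train=40,
                          inner_ga_offspring=20, inner_ga_generations=2,
                          batch_size=5)
        result = run_optimizer("gp_bo_ucb", (lib, values), objective,
                               budget=20, seed=0, bo_config=config)
        assert result["ledger"].unique_calls <= 20
        assert result["best"] <= min(values) + 5.0  # produced sane values
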