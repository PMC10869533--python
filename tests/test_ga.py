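import numpy as np
import pytest

from galambda.datamodel import FeatureTable, RunConfig
from galambda.ga import (
    ExcellentGeneSchedule,
    Individual,
    build_screen,
    crossover,
    dynamic_gene_count,
    evaluate_fitness,
    evolve,
    initialize_population,
    screen_excellent_genes,
    standard_ga_select,
    univariate_r2,
)
from galambda.lasso import LassoFit


def _fit(B, mse=None):
    B = np.asarray(B, dtype=float)
    nl = B.shape[1]
    lambdas = np.linspace(0.1, 0.1 * nl, nl)
    if mse is None:
        mse = np.linspace(1.0, 2.0, nl)
    mse = np.asarray(mse, dtype=float)
    return LassoFit(
        B=B, intercepts=np.zeros(nl), lambdas=lambdas,
        mse=mse, index_min_mse=int(np.argmin(mse)),
    )


class TestUnivariateR2:
    def test_hand_computed_four_points(self):
        """x=[0,1,2,3], y=[0,0,1,1]: closed-form least squares gives 0.8."""
        assert univariate_r2([0, 1, 2, 3], [0, 0, 1, 1]) == pytest.approx(0.8)

    def test_perfect_affine_relation(self):
        x = np.array([-1.0, -1.0, 1.0, 1.0])
        y = np.array([0, 0, 1, 1])
        assert univariate_r2(x, y) == pytest.approx(1.0)

    def test_equals_squared_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        y = rng.integers(0, 2, 50)
        r = np.corrcoef(x, y)[0, 1]
        assert univariate_r2(x, y) == pytest.approx(r * r, abs=1e-12)

    def test_independent_feature_near_zero(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(1000)
            y = rng.integers(0, 2, 1000)
            if univariate_r2(x, y) < 0.01:
                ok += 1
        assert ok >= 19

    def test_constant_predictor_warns_zero(self):
        assert univariate_r2(np.ones(10), np.r_[np.ones(5), np.zeros(5)]) == 0.0


class TestInitialization:
    def _table(self, n=60, p=12, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        y = (X[:, 0] + 0.5 * rng.standard_normal(n) > 0).astype(int)
        return FeatureTable(
            X, tuple(f"f{i}" for i in range(p)), y, tuple(f"s{i}" for i in range(n))
        )

    def test_tied_r2_gives_midpoint_probability(self):
        rng = np.random.default_rng(1)
        X = np.tile(rng.standard_normal(30)[:, None], (1, 4))
        X = X + 0  # identical columns -> identical R^2
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        t = FeatureTable(
            X + rng.standard_normal((30, 4)) * 0,  # keep exact ties
            ("a", "b", "c", "d"), y, tuple(f"s{i}" for i in range(30)),
        )
        screen = build_screen(t, 0.2, 0.8)
        np.testing.assert_allclose(screen.init_probability, 0.5)

    def test_top_feature_well_represented(self):
        t = self._table()
        screen = build_screen(t, 0.2, 0.8)
        top = int(np.argmax(screen.r_squared))
        assert screen.init_probability[top] == pytest.approx(0.8)
        pop = initialize_population(screen, 50, seed=0)
        frac = np.mean([ind.genes[top] for ind in pop])
        assert frac >= 0.7  # binomial(50, 0.8): P(<0.7) < 4%

    def test_population_contract(self):
        t = self._table()
        pop = initialize_population(build_screen(t), 10, seed=2)
        assert len(pop) == 10
        assert all(ind.genes.any() for ind in pop)

    def test_odd_population_rejected(self):
        t = self._table()
        with pytest.raises(ValueError):
            initialize_population(build_screen(t), 7, seed=0)


class TestScreenExcellentGenes:
    def test_max_lambda_column_single(self):
        """Highest-penalty column [0, 0.5, 0, 0] with n=1 -> index 1."""
        B = np.zeros((4, 3))
        B[1, 2] = 0.5  # last column = largest lambda
        B[:, 0] = [0.3, 0.5, 0.0, -0.1]
        B[:, 1] = [0.0, 0.4, 0.0, -0.05]
        np.testing.assert_array_equal(screen_excellent_genes(B, 1), [1])

    def test_descends_to_column_with_enough_nonzeros(self):
        """n=2 skips the sparse high-penalty columns and returns the two
        largest |coefficients| of the first qualifying column."""
        B = np.zeros((4, 3))
        B[1, 2] = 0.5
        B[:, 1] = [0.3, 0.5, 0.0, -0.1]  # middle column: 3 nonzeros
        np.testing.assert_array_equal(screen_excellent_genes(B, 2), [1, 0])

    def test_exhaustion_fallback(self):
        """n beyond every column's df: all nonzeros of the smallest-lambda
        column are returned."""
        B = np.zeros((4, 3))
        B[:, 0] = [0.3, 0.0, 0.0, -0.1]
        B[1, 2] = 0.5
        np.testing.assert_array_equal(
            np.sort(screen_excellent_genes(B, 3)), [0, 3]
        )

    def test_all_zero_matrix(self):
        assert screen_excellent_genes(np.zeros((3, 2)), 1).size == 0

    def test_tie_breaks_deterministic(self):
        B = np.zeros((3, 1))
        B[:, 0] = [0.5, 0.5, 0.2]
        np.testing.assert_array_equal(screen_excellent_genes(B, 2), [0, 1])


class TestDynamicGeneCount:
    SCHEDULE = ExcellentGeneSchedule(nums=(2, 4, 6), mses=(0.10, 0.15, 0.20))

    def test_below_first_breakpoint(self):
        fit = _fit(np.zeros((2, 3)), mse=[0.09, 0.5, 0.5])
        assert dynamic_gene_count(fit, self.SCHEDULE) == 2

    def test_between_breakpoints(self):
        fit = _fit(np.zeros((2, 3)), mse=[0.13, 0.5, 0.5])
        assert dynamic_gene_count(fit, self.SCHEDULE) == 4

    def test_above_all_defaults_to_one(self):
        fit = _fit(np.zeros((2, 3)), mse=[0.9, 0.95, 1.0])
        assert dynamic_gene_count(fit, self.SCHEDULE) == 1

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            ExcellentGeneSchedule(nums=(1, 2), mses=(0.1,))
        with pytest.raises(ValueError):
            ExcellentGeneSchedule(nums=(1, 2), mses=(0.2, 0.1))


def _evaluated_individual(genes, B, mse):
    """Construct an Individual with a hand-built lasso fit over its
    subspace (B rows = subspace features, in subspace order)."""
    ind = Individual(genes=np.asarray(genes, dtype=bool))
    ind.lasso_fit = _fit(B, mse=mse)
    ind.final_features = ind.subspace
    ind.fitness = 0.3
    return ind


class TestCrossover:
    SCHEDULE = ExcellentGeneSchedule(nums=(3, 2, 1), mses=(0.1, 0.2, 0.3))

    def test_excellent_union_forced_on(self):
        """Excellent genes of both parents appear in the offspring.

        Hand trace: parent a's subspace is {1, 2, 5} with path rows in
        that order; the largest-lambda column [0, 0.3, 0] keeps subspace
        row 1 = global feature 2.  Parent b's subspace is {2, 6} with
        largest-lambda column [0, 0.5] keeping global feature 6.  Both
        parents' minMSE = 0.25 <= 0.3 grants quota 1, so the forced union
        is {2, 6}."""
        a = _evaluated_individual(
            [0, 1, 1, 0, 0, 1, 0, 0],
            np.array([[0.4, 0.0], [0.6, 0.3], [0.2, 0.0]]),
            mse=[0.25, 0.5],
        )
        b = _evaluated_individual(
            [0, 0, 1, 0, 0, 0, 1, 0],
            np.array([[0.1, 0.0], [0.7, 0.5]]),
            mse=[0.25, 0.5],
        )
        child = crossover(a, b, self.SCHEDULE, seed=0)
        assert child.genes[2] and child.genes[6]

    def test_identical_parents_closure(self):
        a = _evaluated_individual(
            [1, 0, 1, 0], np.array([[0.5, 0.3], [0.2, 0.0]]), mse=[0.25, 0.5]
        )
        b = _evaluated_individual(
            [1, 0, 1, 0], np.array([[0.5, 0.3], [0.2, 0.0]]), mse=[0.25, 0.5]
        )
        child = crossover(a, b, self.SCHEDULE, seed=1)
        gene_set = set(np.flatnonzero(child.genes).tolist())
        assert gene_set <= {0, 2}
        assert 0 in gene_set  # the excellent gene

    def test_no_spontaneous_genes(self):
        """A locus that is 0 in both parents and not excellent stays 0."""
        a = _evaluated_individual(
            [1, 0, 0, 0, 0], np.array([[0.5, 0.3]]), mse=[0.25, 0.5]
        )
        b = _evaluated_individual(
            [0, 1, 0, 0, 0], np.array([[0.5, 0.3]]), mse=[0.25, 0.5]
        )
        for seed in range(20):
            child = crossover(a, b, self.SCHEDULE, seed=seed)
            assert not child.genes[2] and not child.genes[3] and not child.genes[4]

    def test_unevaluated_parent_rejected(self):
        a = Individual(genes=np.array([True, False]))
        b = Individual(genes=np.array([False, True]))
        with pytest.raises(ValueError, match="evaluated"):
            crossover(a, b, self.SCHEDULE, seed=0)

    @pytest.mark.parametrize("trial", range(10))
    def test_heritability_and_allele_source_fuzz(self, trial):
        """Over random evaluated parents: (a) both parents' screened
        excellent genes are 1 in the offspring; (b) every other offspring
        allele comes from one of the parents."""
        rng = np.random.default_rng(trial)
        nvars = 20
        rounds = 100
        for _ in range(rounds):
            parents = []
            for _p in range(2):
                genes = rng.random(nvars) < 0.4
                if not genes.any():
                    genes[rng.integers(nvars)] = True
                k = genes.sum()
                B = rng.standard_normal((k, 4)) * (rng.random((k, 4)) < 0.5)
                ind = _evaluated_individual(genes, B, mse=rng.random(4) + 0.05)
                parents.append(ind)
            a, b = parents
            sched = ExcellentGeneSchedule(
                nums=(3, 2, 1), mses=tuple(np.sort(rng.random(3)))
            )
            child = crossover(a, b, sched, rng)
            na = dynamic_gene_count(a.lasso_fit, sched)
            nb = dynamic_gene_count(b.lasso_fit, sched)
            exc = np.union1d(
                screen_excellent_genes(a.global_coef_matrix(), na),
                screen_excellent_genes(b.global_coef_matrix(), nb),
            ).astype(int)
            assert child.genes[exc].all()
            other = np.setdiff1d(np.arange(nvars), exc)
            ok = (
                (child.genes[other] == a.genes[other])
                | (child.genes[other] == b.genes[other])
            )
            assert ok.all()


class TestEvaluateFitness:
    def _table(self, seed=0, n=80, p=12, separating=True):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        if separating:
            y = (X[:, 0] > 0).astype(int)
        else:
            y = rng.integers(0, 2, n)
        return FeatureTable(
            X, tuple(f"f{i}" for i in range(p)), y, tuple(f"s{i}" for i in range(n))
        )

    def test_separating_feature_near_zero_fitness(self):
        t = self._table(separating=True)
        ind = Individual(genes=np.ones(12, dtype=bool))
        evaluate_fitness(ind, t, folds=5, df_max=8)
        assert ind.fitness < 0.05
        assert 0 in ind.final_features

    def test_noise_fitness_near_half(self):
        vals = []
        for seed in range(10):
            t = self._table(seed=seed, separating=False)
            ind = Individual(genes=np.ones(12, dtype=bool))
            evaluate_fitness(ind, t, folds=5, df_max=8, lasso_seed=seed)
            vals.append(ind.fitness)
        assert 0.3 < np.mean(vals) < 0.7

    def test_fitness_in_unit_interval_and_deterministic(self):
        t = self._table()
        ind1 = Individual(genes=np.ones(12, dtype=bool))
        ind2 = Individual(genes=np.ones(12, dtype=bool))
        evaluate_fitness(ind1, t, folds=4, df_max=6, lasso_seed=3, eval_seed=5)
        evaluate_fitness(ind2, t, folds=4, df_max=6, lasso_seed=3, eval_seed=5)
        assert 0.0 <= ind1.fitness <= 1.0
        assert ind1.fitness == ind2.fitness


@pytest.fixture(scope="module")
def planted():
    from galambda.synthetic import SyntheticSpec, generate_feature_table

    return generate_feature_table(
        SyntheticSpec(
            n_samples=150, n_features=120, n_informative=5,
            effect_sizes=(2.5, -2.5, 2.5, -2.5, 2.5), seed=21,
        )
    )


class TestEvolve:
    def _config(self, seed=0):
        return RunConfig(
            population_size=12, generations=8, stagnation_window=8,
            nlambdas=40, seed=seed,
        )

    def test_recovers_planted_features(self, planted):
        table, informative = planted
        hits = 0
        for seed in range(3):
            best, _ = evolve(table, self._config(seed))
            found = len(np.intersect1d(best.final_features, informative))
            hits += found >= 4
        assert hits >= 2

    def test_history_nonincreasing(self, planted):
        table, _ = planted
        _, state = evolve(table, self._config(1))
        h = state.best_fitness_history
        assert all(h[i + 1] <= h[i] + 1e-15 for i in range(len(h) - 1))

    def test_seed_determinism(self, planted):
        table, _ = planted
        b1, s1 = evolve(table, self._config(2))
        b2, s2 = evolve(table, self._config(2))
        np.testing.assert_array_equal(b1.genes, b2.genes)
        np.testing.assert_array_equal(b1.final_features, b2.final_features)
        assert s1.best_fitness_history == s2.best_fitness_history


class TestBaselines:
    def test_standard_ga_finds_separating_feature(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((80, 10))
        y = (X[:, 3] > 0).astype(int)
        t = FeatureTable(
            X, tuple(f"f{i}" for i in range(10)), y,
            tuple(f"s{i}" for i in range(80)),
        )
        cfg = RunConfig(
            population_size=8, generations=5, stagnation_window=5,
            nlambdas=30, seed=0, alpha=0.05, rho=0.95,
        )
        sel = standard_ga_select(t, cfg)
        assert 3 in sel

    def test_standard_ga_deterministic(self, small_table):
        table, _ = small_table
        cfg = RunConfig(
            population_size=8, generations=3, stagnation_window=3,
            nlambdas=30, seed=4,
        )
        s1 = standard_ga_select(table, cfg)
        s2 = standard_ga_select(table, cfg)
        np.testing.assert_array_equal(s1, s2)

    def test_conventional_empty_preselection(self):
        from galambda.ga import conventional_lasso_select

        rng = np.random.default_rng(6)
        X = rng.standard_normal((60, 8))
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        t = FeatureTable(
            X, tuple(f"f{i}" for i in range(8)), y,
            tuple(f"s{i}" for i in range(60)),
        )
        sel = conventional_lasso_select(t, alpha=1e-9, rho=0.8)
        assert sel.size == 0

    def test_conventional_strong_recovery_and_cap(self, small_table):
        from galambda.ga import conventional_lasso_select

        table, informative = small_table
        ok = 0
        for seed in range(5):
            sel = conventional_lasso_select(table, df_max=12, seed=seed)
            assert len(sel) <= 12
            if set(informative.tolist()) <= set(sel.tolist()):
                ok += 1
        assert ok >= 4


class TestReports:
    def test_selection_report_contents(self, planted, tmp_path):
        from galambda.ga import write_selection_report

        table, _ = planted
        cfg = RunConfig(
            population_size=8, generations=3, stagnation_window=3,
            nlambdas=30, seed=6,
        )
        best, state = evolve(table, cfg)
        assert len(state.mean_fitness_history) == len(state.best_fitness_history)
        out = tmp_path / "report.txt"
        write_selection_report(best, state, cfg, table.feature_names, out)
        text = out.read_text()
        assert "# selected features" in text and "population_size=8" in text
        for i in best.final_features:
            assert table.feature_names[i] in text

    def test_preselection_report(self, planted, tmp_path):
        import pandas as pd

        from galambda.preselection import preselect, write_report

        table, _ = planted
        res = preselect(table, 0.05, 0.8)
        out = tmp_path / "pres.csv"
        write_report(res, table.feature_names, out)
        df = pd.read_csv(out)
        assert len(df) == table.n_features
        assert set(df["fate"]) <= {
            "kept", "dropped_by_test", "dropped_by_correlation"
        }
        assert (df[df.fate == "kept"]["p_value"] < 0.05).all()
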