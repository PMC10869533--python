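"""GALambda: genetic feature-combination search driven by high-penalty LASSO.

The search operates on binary gene vectors over the preselected candidate
features; a 1 means the feature belongs to the individual's feature
SUBSPACE (not yet the final selection).  Fitness of an individual is
``1 - CV AUC`` of a logistic model on the features that a cross-validated
lasso picks *within* that subspace, so the GA explores subspaces while the
lasso does the within-subspace combination search.

The distinguishing operator is the crossover: before mixing parental
genes, each parent's lasso path is read from the HIGH-penalty end, and the
features whose coefficients survive strong shrinkage — the "excellent
genes" — are copied into the offspring unconditionally.  How many genes
count as excellent is set dynamically from the parent's CV error: a
parent whose subspace fits well (low minimum CV MSE) donates more
excellent genes.  All remaining loci are inherited from the parents, half
from each.

Two baselines share the representation and fitness: a standard GA with
plain uniform crossover (no excellent-gene preservation), and the
conventional single-shot lasso selection on all candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .datamodel import FeatureTable, RunConfig
from .evaluation import cv_logistic_auc
from .lasso import LassoFit, cv_lasso, selected_features
from .preselection import preselect

logger = logging.getLogger("galambda")

__all__ = [
    "Individual",
    "ExcellentGeneSchedule",
    "GAState",
    "UnivariateScreen",
    "univariate_r2",
    "build_screen",
    "initialize_population",
    "evaluate_fitness",
    "screen_excellent_genes",
    "dynamic_gene_count",
    "crossover",
    "evolve",
    "standard_ga_select",
    "conventional_lasso_select",
]


@dataclass
class Individual:
    """One candidate feature subspace with its evaluation artifacts."""

    genes: np.ndarray  # bool, length nvars (candidate space)
    fitness: float | None = None
    lasso_fit: LassoFit | None = None
    final_features: np.ndarray | None = None  # indices into the candidate space
    excellent: np.ndarray | None = None  # loci forced by crossover

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=bool)
        if not self.genes.any():
            raise ValueError("an individual must select at least one gene")

    @property
    def subspace(self) -> np.ndarray:
        return np.flatnonzero(self.genes)

    def global_coef_matrix(self) -> np.ndarray:
        """Lasso coefficients embedded in the full candidate space
        (``nvars x nlambdas``; rows outside the subspace are zero)."""
        if self.lasso_fit is None:
            raise ValueError("individual has not been evaluated")
        B = np.zeros((len(self.genes), self.lasso_fit.B.shape[1]))
        B[self.subspace] = self.lasso_fit.B
        return B

    def key(self) -> bytes:
        return np.packbits(self.genes).tobytes()


@dataclass(frozen=True)
class ExcellentGeneSchedule:
    """Mapping from a parent's CV error to its excellent-gene quota.

    ``mses`` is ascending; a parent with minimum CV MSE at or below
    ``mses[i]`` (smallest such i) donates ``nums[i]`` excellent genes; a
    parent above every breakpoint donates the default of 1.  The default
    schedule grants MORE genes to better-fitting parents, so ``nums`` is
    typically descending.
    """

    nums: tuple[int, ...]
    mses: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.nums) != len(self.mses):
            raise ValueError("nums and mses must have equal length")
        if any(n < 1 for n in self.nums):
            raise ValueError("nums must be positive")
        if np.any(np.diff(self.mses) < 0):
            raise ValueError("mses must be sorted ascending")


@dataclass
class GAState:
    population: list[Individual]
    generation: int
    best_fitness_history: list[float]
    seed: int
    mean_fitness_history: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class UnivariateScreen:
    r_squared: np.ndarray
    init_probability: np.ndarray


def univariate_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination of the least-squares fit of y on x
    (with intercept): R^2 = 1 - sum(yhat - y_i)^2 / sum(y_i - ybar)^2.

    For a univariate fit this equals the squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("y must contain both classes")
    if np.ptp(x) == 0:
        logger.warning("constant predictor: R^2 set to 0")
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def build_screen(
    table: FeatureTable, p_lo: float = 0.2, p_hi: float = 0.8
) -> UnivariateScreen:
    """Per-feature univariate R^2, rank-mapped to gene probabilities.

    Ranks (average for ties) are mapped affinely onto [p_lo, p_hi]; the
    top-R^2 feature gets p_hi, the bottom p_lo, and full ties all get the
    midpoint.  A deterministic greater/less-than-0.5 reading would make
    every individual identical, so a stochastic map is used.
    """
    r2 = np.array(
        [
            univariate_r2(table.values[:, j], table.labels)
            if np.ptp(table.values[:, j]) > 0
            else 0.0
            for j in range(table.n_features)
        ]
    )
    ranks = _stats.rankdata(r2, method="average")
    nvars = table.n_features
    if nvars > 1:
        prob = p_lo + (ranks - 1.0) / (nvars - 1.0) * (p_hi - p_lo)
    else:
        prob = np.full(1, 0.5 * (p_lo + p_hi))
    return UnivariateScreen(r_squared=r2, init_probability=prob)


def initialize_population(
    screen: UnivariateScreen, pop_size: int, seed: int | np.random.Generator
) -> list[Individual]:
    """Draw each gene Bernoulli(init_probability[j]) per individual;
    all-zero draws are redrawn."""
    if pop_size < 4 or pop_size % 2:
        raise ValueError("pop_size must be even and >= 4")
    nvars = len(screen.init_probability)
    if nvars == 0:
        raise ValueError("no candidate features")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    population = []
    for _ in range(pop_size):
        genes = rng.random(nvars) < screen.init_probability
        while not genes.any():
            genes = rng.random(nvars) < screen.init_probability
        population.append(Individual(genes=genes))
    return population


def evaluate_fitness(
    ind: Individual,
    table: FeatureTable,
    folds: int = 5,
    df_max: int | None = None,
    lasso_seed: int = 0,
    eval_seed: int = 0,
    nlambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> Individual:
    """Fitness = 1 - CV AUC of the logistic model on the subspace's
    lasso-selected features.

    The lasso path with k-fold CV runs on the subspace columns; the
    features with nonzero coefficients at the MSE-minimizing lambda are
    the individual's final selection.  An empty selection scores chance
    level (fitness 0.5)."""
    sub = ind.subspace
    fit = cv_lasso(
        table.values[:, sub],
        table.labels,
        folds=folds,
        seed=lasso_seed,
        df_max=df_max,
        nlambdas=nlambdas,
        lambda_min_ratio=lambda_min_ratio,
    )
    local_sel = selected_features(fit, "min_mse")
    final = sub[local_sel]
    if len(final) == 0:
        logger.warning("empty lasso selection in subspace of size %d", len(sub))
        ind.fitness = 0.5
    else:
        auc = cv_logistic_auc(
            table.values, table.labels, final, folds=folds, seed=eval_seed
        )
        ind.fitness = 1.0 - auc
    ind.lasso_fit = fit
    ind.final_features = final
    return ind


def screen_excellent_genes(B: np.ndarray, n: int) -> np.ndarray:
    """Features surviving the highest penalty at which >= n survive.

    ``B`` is ``nvars x nlambdas`` with lambda ASCENDING across columns.
    Columns are scanned from the last (largest lambda) downward; at the
    first column with at least ``n`` nonzero coefficients, the indices of
    the ``n`` largest |coefficients| are returned (ties -> lower index).
    If no column ever reaches ``n`` nonzeros, all nonzeros of the
    smallest-lambda column are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    B = np.asarray(B, dtype=float)
    for j in range(B.shape[1] - 1, -1, -1):
        v = np.abs(B[:, j])
        nz = np.flatnonzero(v)
        if len(nz) >= n:
            order = nz[np.lexsort((nz, -v[nz]))]  # |coef| desc, index asc
            return order[:n]
    nz = np.flatnonzero(B[:, 0])
    if len(nz) == 0:
        logger.warning("all-zero coefficient matrix: no excellent genes")
    return nz


def dynamic_gene_count(fit: LassoFit, schedule: ExcellentGeneSchedule) -> int:
    """Excellent-gene quota from the CV error: smallest breakpoint at or
    above the fit's minimum CV MSE decides; above all breakpoints -> 1."""
    m = fit.min_mse
    for num, mse in zip(schedule.nums, schedule.mses):
        if m <= mse:
            return int(num)
    return 1


def crossover(
    parent_a: Individual,
    parent_b: Individual,
    schedule: ExcellentGeneSchedule,
    seed: int | np.random.Generator,
) -> Individual:
    """Excellent-gene-preserving crossover.

    Each parent's quota (na, nb) comes from its own CV error via the
    schedule; its excellent genes are read off its own lasso path.  The
    union of both excellent sets is forced to 1 in the offspring; every
    remaining locus is inherited from a parent, the loci being randomly
    split half/half between the two parents.
    """
    if parent_a.lasso_fit is None or parent_b.lasso_fit is None:
        raise ValueError("both parents must be evaluated before crossover")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    na = dynamic_gene_count(parent_a.lasso_fit, schedule)
    nb = dynamic_gene_count(parent_b.lasso_fit, schedule)
    exc_a = screen_excellent_genes(parent_a.global_coef_matrix(), na)
    exc_b = screen_excellent_genes(parent_b.global_coef_matrix(), nb)
    excellent = np.union1d(exc_a, exc_b).astype(int)

    nvars = len(parent_a.genes)
    genes = np.zeros(nvars, dtype=bool)
    genes[excellent] = True
    others = np.setdiff1d(np.arange(nvars), excellent)
    perm = rng.permutation(others)
    half = len(perm) // 2
    from_a, from_b = perm[:half], perm[half:]
    genes[from_a] = parent_a.genes[from_a]
    genes[from_b] = parent_b.genes[from_b]
    if not genes.any():
        # degenerate: both parents contributed nothing and no excellent
        # genes exist; seed one locus from the parental union (or anywhere)
        pool = np.flatnonzero(parent_a.genes | parent_b.genes)
        if len(pool) == 0:
            pool = np.arange(nvars)
        genes[rng.choice(pool)] = True
    return Individual(genes=genes, excellent=excellent)


def _mutate(
    ind: Individual, rate: float, rng: np.random.Generator, exempt: np.ndarray | None
) -> Individual:
    flips = rng.random(len(ind.genes)) < rate
    if exempt is not None and len(exempt):
        flips[exempt] = False
    genes = ind.genes ^ flips
    if not genes.any():
        genes = ind.genes.copy()
    return Individual(genes=genes, excellent=ind.excellent)


def _resolve_schedule(
    population: list[Individual], config: RunConfig
) -> ExcellentGeneSchedule:
    """Default schedule: MSE breakpoints at quantiles of the first
    generation's minimum CV errors, quotas descending so better-fitting
    parents donate more excellent genes."""
    min_mses = np.array([ind.lasso_fit.min_mse for ind in population])
    mses = tuple(
        float(np.quantile(min_mses, q)) for q in config.excellent_mse_quantiles
    )
    return ExcellentGeneSchedule(nums=tuple(config.excellent_nums), mses=mses)


class _FitnessCache:
    """Memoize fitness by gene vector; identical subspaces re-use their
    evaluation (the lasso and folds are deterministic given the seeds)."""

    def __init__(self) -> None:
        self._store: dict[bytes, tuple[float, LassoFit, np.ndarray]] = {}
        self.hits = 0
        self.misses = 0

    def evaluate(self, ind: Individual, **kwargs) -> Individual:
        k = ind.key()
        if k in self._store:
            self.hits += 1
            ind.fitness, ind.lasso_fit, ind.final_features = self._store[k]
            return ind
        self.misses += 1
        evaluate_fitness(ind, **kwargs)
        self._store[k] = (ind.fitness, ind.lasso_fit, ind.final_features)
        return ind


def _tournament(
    population: list[Individual], rng: np.random.Generator, size: int = 2
) -> Individual:
    picks = rng.integers(len(population), size=size)
    best = min(picks, key=lambda i: population[i].fitness)
    return population[best]


def _ga_loop(
    table: FeatureTable,
    config: RunConfig,
    use_excellent_crossover: bool,
) -> tuple[Individual, GAState]:
    """Shared generational loop for GALambda and the standard GA."""
    rng = np.random.default_rng(config.stage_seed("ga"))
    df_max = config.df_max(table.n_samples)
    eval_kwargs = dict(
        table=table,
        folds=config.cv_folds,
        df_max=df_max,
        lasso_seed=config.stage_seed("lasso"),
        eval_seed=config.stage_seed("evaluation"),
        nlambdas=config.nlambdas,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    cache = _FitnessCache()
    screen = build_screen(table, config.init_p_lo, config.init_p_hi)
    population = initialize_population(screen, config.population_size, rng)
    for ind in population:
        cache.evaluate(ind, **eval_kwargs)

    schedule = _resolve_schedule(population, config) if use_excellent_crossover else None
    mut_rate = (
        config.mutation_rate
        if config.mutation_rate is not None
        else 1.0 / table.n_features
    )

    best = min(population, key=lambda i: i.fitness)
    history = [best.fitness]
    mean_history = [float(np.mean([i.fitness for i in population]))]
    stagnant = 0
    generation = 0
    for generation in range(1, config.generations + 1):
        new_pop = [best]  # elitism
        while len(new_pop) < config.population_size:
            pa = _tournament(population, rng)
            pb = _tournament(population, rng)
            if use_excellent_crossover:
                child = crossover(pa, pb, schedule, rng)
                exempt = child.excellent
            else:
                mask = rng.random(table.n_features) < 0.5
                genes = np.where(mask, pa.genes, pb.genes)
                if not genes.any():
                    genes[rng.integers(table.n_features)] = True
                child = Individual(genes=genes)
                exempt = None
            if mut_rate > 0:
                child = _mutate(child, mut_rate, rng, exempt)
            cache.evaluate(child, **eval_kwargs)
            new_pop.append(child)
        population = new_pop
        gen_best = min(population, key=lambda i: i.fitness)
        if gen_best.fitness < best.fitness:
            best = gen_best
            stagnant = 0
        else:
            stagnant += 1
        history.append(best.fitness)
        mean_history.append(float(np.mean([i.fitness for i in population])))
        if stagnant >= config.stagnation_window:
            logger.info("stopping: %d stagnant generations", stagnant)
            break
    logger.info(
        "GA done: gen=%d best_fitness=%.4f cache hits/misses=%d/%d",
        generation, best.fitness, cache.hits, cache.misses,
    )
    state = GAState(
        population=population,
        generation=generation,
        best_fitness_history=history,
        seed=config.stage_seed("ga"),
        mean_fitness_history=mean_history,
    )
    return best, state


def evolve(
    table: FeatureTable,
    config: RunConfig | None = None,
    candidates: np.ndarray | None = None,
) -> tuple[Individual, GAState]:
    """Run GALambda on a training table.

    If ``candidates`` is None, preselection (U test + correlation pruning
    at the config thresholds) is applied first; the GA then searches the
    candidate space.  The returned best individual's ``final_features``
    are indices into the ORIGINAL table's columns.
    """
    config = config or RunConfig()
    if candidates is None:
        candidates = np.asarray(preselect(table, config.alpha, config.rho).kept_indices)
    candidates = np.asarray(candidates, dtype=int)
    if len(candidates) == 0:
        raise ValueError("no candidate features after preselection")
    sub_table = table.subset_columns(candidates)
    best, state = _ga_loop(sub_table, config, use_excellent_crossover=True)
    best.final_features = candidates[best.final_features]
    return best, state


def standard_ga_select(
    table: FeatureTable,
    config: RunConfig | None = None,
    candidates: np.ndarray | None = None,
) -> np.ndarray:
    """Baseline: same representation and fitness, plain uniform crossover.

    The selected set is the gene set of the best individual (the standard
    GA has no within-crossover lasso to thin it out)."""
    config = config or RunConfig()
    if candidates is None:
        candidates = np.asarray(preselect(table, config.alpha, config.rho).kept_indices)
    candidates = np.asarray(candidates, dtype=int)
    if len(candidates) == 0:
        raise ValueError("no candidate features after preselection")
    sub_table = table.subset_columns(candidates)
    best, _ = _ga_loop(sub_table, config, use_excellent_crossover=False)
    return candidates[best.subspace]


def conventional_lasso_select(
    table: FeatureTable,
    alpha: float = 0.05,
    rho: float = 0.8,
    folds: int = 5,
    df_max: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Baseline: preselection then one cross-validated lasso over ALL
    candidates; the selection is the nonzero set at the MSE-minimizing
    lambda."""
    pres = preselect(table, alpha, rho)
    cand = np.asarray(pres.kept_indices, dtype=int)
    if len(cand) == 0:
        logger.warning("conventional lasso: empty preselection")
        return np.empty(0, dtype=int)
    fit = cv_lasso(
        table.values[:, cand], table.labels, folds=folds, seed=seed, df_max=df_max
    )
    return cand[selected_features(fit, "min_mse")]


def write_selection_report(
    best: Individual,
    state: GAState,
    config: RunConfig,
    feature_names: tuple[str, ...],
    path,
) -> None:
    """Text report: selected feature names, per-generation best/mean
    fitness, and every resolved configuration value."""
    import dataclasses

    lines = ["# selected features"]
    lines += [feature_names[i] for i in best.final_features]
    lines.append("")
    lines.append("# generation\tbest_fitness\tmean_fitness")
    for g, (b, m) in enumerate(
        zip(state.best_fitness_history, state.mean_fitness_history)
    ):
        lines.append(f"{g}\t{b:.6f}\t{m:.6f}")
    lines.append("")
    lines.append("# config")
    for f in dataclasses.fields(config):
        lines.append(f"{f.name}={getattr(config, f.name)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
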