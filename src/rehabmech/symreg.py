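"""Multi-objective genetic-programming symbolic regression.

Evolves algebraic expression trees over the activity features to predict
end-point bone volume, trading off accuracy (fitness ``1 - R^2``) against
*expressional complexity* (visitation length: the sum of node counts over
all subtrees).  Ten independent evolutions are merged into a deduplicated
Pareto archive; the "knee" of the accuracy-complexity front is selected by
strict thresholds on both axes, and the resulting model ensemble drives
variable-presence analysis and response-surface prediction with an
explicit uncertainty envelope.

The operator set is purely algebraic: ``+``, ``-``, ``*``, protected ``/``
(a denominator of magnitude below 1e-12 yields a configured constant), and
integer powers 2 and 3.  Every evaluated tree is linearly scaled
(``y ~ a*f(x) + b`` with ``a, b`` from least squares) before scoring, and
the scaling constants are folded back into the stored tree.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ExpressionModel",
    "ParetoArchive",
    "ModelEnsemble",
    "GPConfig",
    "eval_tree",
    "node_count",
    "complexity",
    "canonical",
    "variables_in",
    "fit_model",
    "evolve",
    "refit_with_features",
    "select_knee",
    "pareto_front",
    "variable_presence",
    "variable_combinations",
    "ensemble_predict",
    "response_surface",
    "robust_filter",
]

PROTECTED_DIV_EPS = 1e-12
PROTECTED_DIV_VALUE = 1.0
_CLIP = 1e12
_BINARY_OPS = ("add", "sub", "mul", "div")


# ---------------------------------------------------------------------------
# Expression trees

def eval_tree(tree: tuple, X: np.ndarray) -> np.ndarray:
    """Evaluate an expression tree on a feature matrix ``X (n, p)``.

    Results are clipped to ``±1e12`` and NaNs from degenerate operations
    are replaced by 0 so that evolution never crashes on a pathological
    expression.
    """
    op = tree[0]
    if op == "var":
        return X[:, tree[1]].astype(float)
    if op == "const":
        return np.full(X.shape[0], float(tree[1]))
    with np.errstate(all="ignore"):
        if op == "pow":
            a = eval_tree(tree[1], X)
            r = a ** int(tree[2])
        else:
            a = eval_tree(tree[1], X)
            b = eval_tree(tree[2], X)
            if op == "add":
                r = a + b
            elif op == "sub":
                r = a - b
            elif op == "mul":
                r = a * b
            elif op == "div":
                small = np.abs(b) < PROTECTED_DIV_EPS
                r = np.where(small, PROTECTED_DIV_VALUE,
                             a / np.where(small, 1.0, b))
            else:
                raise ValueError(f"malformed tree: unknown op {op!r}")
    return np.clip(np.nan_to_num(r, nan=0.0, posinf=_CLIP, neginf=-_CLIP),
                   -_CLIP, _CLIP)


def node_count(tree: tuple) -> int:
    op = tree[0]
    if op in ("var", "const"):
        return 1
    if op == "pow":
        return 2 + node_count(tree[1])  # exponent counts as a leaf
    return 1 + node_count(tree[1]) + node_count(tree[2])


def complexity(tree: tuple) -> int:
    """Visitation length: sum of node counts over all subtrees."""
    op = tree[0]
    if op in ("var", "const"):
        return 1
    if op == "pow":
        return node_count(tree) + complexity(tree[1]) + 1
    return (
        node_count(tree) + complexity(tree[1]) + complexity(tree[2])
    )


def variables_in(tree: tuple) -> frozenset[int]:
    op = tree[0]
    if op == "var":
        return frozenset((tree[1],))
    if op == "const":
        return frozenset()
    if op == "pow":
        return variables_in(tree[1])
    return variables_in(tree[1]) | variables_in(tree[2])


def _sig6(c: float) -> str:
    if c == 0 or not math.isfinite(c):
        return repr(float(c))
    return f"{c:.6g}"


def canonical(tree: tuple) -> str:
    """Canonical string form: constants rounded to 6 significant digits,
    commutative operands sorted."""
    op = tree[0]
    if op == "var":
        return f"x{tree[1]}"
    if op == "const":
        return _sig6(float(tree[1]))
    if op == "pow":
        return f"(pow {canonical(tree[1])} {int(tree[2])})"
    a, b = canonical(tree[1]), canonical(tree[2])
    if op in ("add", "mul") and b < a:
        a, b = b, a
    return f"({op} {a} {b})"


# ---------------------------------------------------------------------------
# Models and archives


@dataclass(frozen=True)
class ExpressionModel:
    """A scored expression: folded tree, fitness ``1 - R^2`` (clamped to
    [0, 1]), visitation-length complexity, and the variables it reads."""

    tree: tuple
    fitness: float
    complexity: int
    variables_used: frozenset[int]
    run_index: int = -1
    y_constant: bool = False
    base_tree: tuple = None
    scale: tuple[float, float] = (1.0, 0.0)
    x_mean: tuple | None = None  # feature standardization folded into
    x_std: tuple | None = None  # prediction when set

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self.x_mean is None:
            return X
        return (X - np.asarray(self.x_mean)) / np.asarray(self.x_std)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return eval_tree(self.tree, self._standardize(X))

    @property
    def key(self) -> str:
        return canonical(self.tree)


def _fold_linear(tree: tuple, a: float, b: float) -> tuple:
    if abs(a) < 1e-12:
        return ("const", b)
    out = tree
    if abs(a - 1.0) > 1e-12:
        out = ("mul", ("const", a), out)
    if abs(b) > 1e-12:
        out = ("add", out, ("const", b))
    return out


def fit_model(
    tree: tuple, X: np.ndarray, y: np.ndarray, run_index: int = -1
) -> ExpressionModel:
    """Score a raw tree: linear-scale its output to ``y`` by least squares,
    fold the scaling into the tree, and compute fitness and complexity."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    ss_tot = float(((y - y.mean()) ** 2).sum())
    z = eval_tree(tree, X)
    if ss_tot <= 0.0:
        folded = ("const", float(y.mean()))
        return ExpressionModel(
            tree=folded, fitness=0.0, complexity=1,
            variables_used=frozenset(), run_index=run_index,
            y_constant=True, base_tree=tree, scale=(0.0, float(y.mean())),
        )
    zc = z - z.mean()
    denom = float((zc**2).sum())
    if denom < 1e-12 or not np.all(np.isfinite(z)):
        a, b = 0.0, float(y.mean())
    else:
        a = float((zc * (y - y.mean())).sum() / denom)
        b = float(y.mean() - a * z.mean())
    pred = a * z + b
    fitness = float(np.clip(((y - pred) ** 2).sum() / ss_tot, 0.0, 1.0))
    folded = _fold_linear(tree, a, b)
    return ExpressionModel(
        tree=folded,
        fitness=fitness,
        complexity=complexity(folded),
        variables_used=variables_in(folded),
        run_index=run_index,
        base_tree=tree,
        scale=(a, b),
    )


def _dominates(m1: ExpressionModel, m2: ExpressionModel) -> bool:
    return (
        m1.fitness <= m2.fitness
        and m1.complexity <= m2.complexity
        and (m1.fitness < m2.fitness or m1.complexity < m2.complexity)
    )


def pareto_front(models: Sequence[ExpressionModel]) -> list[ExpressionModel]:
    """Nondominated subset w.r.t. (fitness, complexity), via a sorted
    sweep (equivalent to the O(n^2) domination scan)."""
    order = sorted(
        range(len(models)),
        key=lambda i: (models[i].fitness, models[i].complexity),
    )
    front: list[ExpressionModel] = []
    min_c = math.inf
    f_at_min_c = math.inf
    for i in order:
        m = models[i]
        if m.complexity < min_c:
            front.append(m)
            min_c = m.complexity
            f_at_min_c = m.fitness
        elif m.complexity == min_c and m.fitness == f_at_min_c:
            front.append(m)  # exact metric tie: mutually nondominated
    return front


@dataclass
class ParetoArchive:
    """Deduplicated model archive across evolution runs.

    Keeps every nondominated model plus dominated ones up to ``cap``
    (best-fitness first).  Deduplication key is the canonical tree form.
    """

    models: list[ExpressionModel] = field(default_factory=list)
    cap: int = 2000
    flags: list[str] = field(default_factory=list)
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def add(self, model: ExpressionModel) -> None:
        k = model.key
        i = self._index.get(k)
        if i is None:
            self._index[k] = len(self.models)
            self.models.append(model)
        elif model.fitness < self.models[i].fitness:
            self.models[i] = model

    def update(self, models: Iterable[ExpressionModel]) -> None:
        for m in models:
            self.add(m)

    def nondominated(self) -> list[ExpressionModel]:
        return pareto_front(self.models)

    def prune(self) -> None:
        """Enforce the dominated-model cap."""
        front = pareto_front(self.models)
        front_keys = {m.key for m in front}
        dominated = sorted(
            (m for m in self.models if m.key not in front_keys),
            key=lambda m: (m.fitness, m.complexity, m.key),
        )[: self.cap]
        self.models = front + dominated
        self._index = {m.key: i for i, m in enumerate(self.models)}

    def __len__(self) -> int:
        return len(self.models)


def select_knee(
    archive: ParetoArchive | Sequence[ExpressionModel],
    max_complexity: float = 100,
    max_fitness: float = 0.2,
) -> list[ExpressionModel]:
    """Knee-of-the-front selection: strict thresholds on both axes,
    returned sorted by fitness."""
    models = archive.models if isinstance(archive, ParetoArchive) else archive
    picked = [
        m
        for m in models
        if m.complexity < max_complexity and m.fitness < max_fitness
    ]
    return sorted(picked, key=lambda m: (m.fitness, m.complexity, m.key))


def select_knee_relative(
    archive: ParetoArchive | Sequence[ExpressionModel],
    max_fitness: float = 0.2,
    max_models: int = 100,
) -> list[ExpressionModel]:
    """Knee selection with a complexity cap relative to the archive.

    The absolute complexity threshold of interactive tools does not
    transfer across complexity metrics; here every model passing the
    fitness cap competes and the ``max_models`` most accurate are kept
    (complexity breaking ties), which bounds the ensemble size the way
    the absolute cap bounds the knee.
    """
    models = archive.models if isinstance(archive, ParetoArchive) else archive
    good = sorted(
        (m for m in models if m.fitness < max_fitness),
        key=lambda m: (m.fitness, m.complexity, m.key),
    )
    return good[:max_models]


def variable_presence(
    models: Sequence[ExpressionModel],
    n_features: int | None = None,
    feature_names: Sequence[str] | None = None,
) -> dict:
    """Fraction of models whose expression uses each variable."""
    if not models:
        raise ValueError("empty model list")
    if n_features is None:
        used = frozenset().union(*(m.variables_used for m in models))
        n_features = (max(used) + 1) if used else 0
    counts = np.zeros(n_features)
    for m in models:
        for v in m.variables_used:
            counts[v] += 1
    frac = counts / len(models)
    if feature_names is not None:
        return {feature_names[j]: float(frac[j]) for j in range(n_features)}
    return {j: float(frac[j]) for j in range(n_features)}


def variable_combinations(
    models: Sequence[ExpressionModel],
    feature_names: Sequence[str] | None = None,
) -> Counter:
    """Counts of models keyed by the exact variable set they use."""
    if not models:
        raise ValueError("empty model list")
    out: Counter = Counter()
    for m in models:
        key = m.variables_used
        if feature_names is not None:
            key = frozenset(feature_names[j] for j in key)
        out[key] += 1
    return out


# ---------------------------------------------------------------------------
# Evolution


@dataclass(frozen=True)
class GPConfig:
    """Evolution settings.  ``generations`` replaces the wall-clock budget
    of interactive tools so runs are reproducible."""

    n_runs: int = 10
    population: int = 300
    generations: int = 60
    seed: int = 0
    max_nodes: int = 40
    init_depth: tuple[int, int] = (1, 4)
    p_crossover: float = 0.7
    p_subtree_mutation: float = 0.15
    p_const_mutation: float = 0.15
    tournament_size: int = 4
    n_const_refit: int = 12
    archive_cap: int = 2000
    standardize: bool = True
    feature_subset: tuple[int, ...] | None = None
    robust: bool = False
    robust_holdout: float = 0.2
    robust_max_degradation: float = 0.05


def _random_tree(rng, depth: int, variables: Sequence[int], full: bool):
    if depth <= 0 or (not full and rng.random() < 0.3):
        if rng.random() < 0.75:
            return ("var", int(rng.choice(variables)))
        return ("const", float(np.round(rng.uniform(-5.0, 5.0), 4)))
    op = _BINARY_OPS[rng.integers(0, 4)] if rng.random() < 0.85 else "pow"
    if op == "pow":
        return ("pow", _random_tree(rng, depth - 1, variables, full),
                int(rng.integers(2, 4)))
    return (
        op,
        _random_tree(rng, depth - 1, variables, full),
        _random_tree(rng, depth - 1, variables, full),
    )


def _subtree_slots(tree: tuple) -> int:
    """Number of crossover points (the pow exponent is not a slot)."""
    op = tree[0]
    if op in ("var", "const"):
        return 1
    if op == "pow":
        return 1 + _subtree_slots(tree[1])
    return 1 + _subtree_slots(tree[1]) + _subtree_slots(tree[2])


def _get_subtree(tree: tuple, idx: int) -> tuple:
    if idx == 0:
        return tree
    op = tree[0]
    if op == "pow":
        return _get_subtree(tree[1], idx - 1)
    n_left = _subtree_slots(tree[1])
    if idx - 1 < n_left:
        return _get_subtree(tree[1], idx - 1)
    return _get_subtree(tree[2], idx - 1 - n_left)


def _replace_subtree(tree: tuple, idx: int, new: tuple) -> tuple:
    if idx == 0:
        return new
    op = tree[0]
    if op == "pow":
        return ("pow", _replace_subtree(tree[1], idx - 1, new), tree[2])
    n_left = _subtree_slots(tree[1])
    if idx - 1 < n_left:
        return (op, _replace_subtree(tree[1], idx - 1, new), tree[2])
    return (op, tree[1], _replace_subtree(tree[2], idx - 1 - n_left, new))


def _tree_constants(tree: tuple) -> list[float]:
    op = tree[0]
    if op == "const":
        return [float(tree[1])]
    if op == "var":
        return []
    if op == "pow":
        return _tree_constants(tree[1])
    return _tree_constants(tree[1]) + _tree_constants(tree[2])


def _with_constants(tree: tuple, values) -> tuple:
    op = tree[0]
    if op == "const":
        return ("const", float(next(values)))
    if op == "var":
        return tree
    if op == "pow":
        return ("pow", _with_constants(tree[1], values), tree[2])
    return (
        op,
        _with_constants(tree[1], values),
        _with_constants(tree[2], values),
    )


def refit_constants(
    tree: tuple, X: np.ndarray, y: np.ndarray, max_nfev: int = 40
) -> tuple:
    """Local least-squares refit of a tree's scalar coefficients.

    Inner constants are optimized by Levenberg-Marquardt on the residual
    after the (analytically optimal) outer linear scaling — a variable
    projection.  Trees without constants are returned unchanged.
    """
    from scipy.optimize import least_squares

    consts = _tree_constants(tree)
    if not consts:
        return tree
    y = np.asarray(y, dtype=float).ravel()
    ym = y.mean()

    def resid(c):
        t = _with_constants(tree, iter(c))
        z = eval_tree(t, X)
        zc = z - z.mean()
        den = float((zc**2).sum())
        if den < 1e-12:
            a, b = 0.0, ym
        else:
            a = float((zc * (y - ym)).sum() / den)
            b = ym - a * z.mean()
        return np.nan_to_num(y - (a * z + b), nan=1e6,
                             posinf=1e6, neginf=-1e6)

    try:
        res = least_squares(
            resid, np.asarray(consts), method="lm", max_nfev=max_nfev
        )
        if np.all(np.isfinite(res.x)):
            return _with_constants(tree, iter(res.x))
    except Exception:
        pass
    return tree


def _mutate_consts(tree: tuple, rng) -> tuple:
    op = tree[0]
    if op == "const":
        return ("const", float(tree[1] + rng.normal(0.0, 0.5)))
    if op == "var":
        return tree
    if op == "pow":
        k = int(tree[2])
        if rng.random() < 0.2:
            k = int(rng.integers(2, 4))
        return ("pow", _mutate_consts(tree[1], rng), k)
    return (op, _mutate_consts(tree[1], rng), _mutate_consts(tree[2], rng))


def _tournament(pop, ranks, rng, k: int):
    """k-way tournament.  Most tournaments compare raw fitness (accuracy
    pressure); the rest compare Pareto rank then complexity (parsimony
    pressure), which keeps the low-complexity end of the front alive."""
    by_fitness = rng.random() < 0.7
    best = None
    for _ in range(k):
        i = int(rng.integers(0, len(pop)))
        if best is None:
            best = i
            continue
        a, b = pop[i], pop[best]
        if by_fitness:
            key_a = (a.fitness, a.complexity)
            key_b = (b.fitness, b.complexity)
        else:
            key_a = (ranks[i], a.complexity, a.fitness)
            key_b = (ranks[best], b.complexity, b.fitness)
        if key_a < key_b:
            best = i
    return pop[best]


def _pareto_ranks(models: Sequence[ExpressionModel]) -> list[int]:
    """Successive-front ranks over (fitness, complexity)."""
    remaining = list(range(len(models)))
    ranks = [0] * len(models)
    rank = 0
    while remaining:
        sub = [models[i] for i in remaining]
        fs = {id(m) for m in pareto_front(sub)}
        next_remaining = []
        for i in remaining:
            if id(models[i]) in fs:
                ranks[i] = rank
            else:
                next_remaining.append(i)
        remaining = next_remaining
        rank += 1
    return ranks


def _single_evolution(
    X: np.ndarray,
    y: np.ndarray,
    config: GPConfig,
    variables: Sequence[int],
    seed,
    run_index: int,
    archive: ParetoArchive,
) -> None:
    rng = np.random.default_rng(seed)
    lo, hi = config.init_depth
    pop: list[ExpressionModel] = []
    # Seed with every bare variable, each square, and each pairwise
    # product (building blocks for interaction terms), then ramped
    # half-and-half.
    for v in variables:
        pop.append(fit_model(("var", int(v)), X, y, run_index))
        pop.append(fit_model(("pow", ("var", int(v)), 2), X, y, run_index))
    for i, v in enumerate(variables):
        for w in variables[i + 1:]:
            if len(pop) >= config.population:
                break
            pop.append(
                fit_model(
                    ("mul", ("var", int(v)), ("var", int(w))),
                    X, y, run_index,
                )
            )
    while len(pop) < config.population:
        depth = int(rng.integers(lo, hi + 1))
        tree = _random_tree(rng, depth, variables, full=rng.random() < 0.5)
        pop.append(fit_model(tree, X, y, run_index))
    archive.update(pop)

    for _gen in range(config.generations):
        ranks = _pareto_ranks(pop)
        offspring: list[ExpressionModel] = []
        while len(offspring) < config.population:
            p1 = _tournament(pop, ranks, rng, config.tournament_size)
            u = rng.random()
            if u < config.p_crossover:
                p2 = _tournament(pop, ranks, rng, config.tournament_size)
                t1, t2 = p1.base_tree, p2.base_tree
                i1 = int(rng.integers(0, _subtree_slots(t1)))
                i2 = int(rng.integers(0, _subtree_slots(t2)))
                child = _replace_subtree(t1, i1, _get_subtree(t2, i2))
            elif u < config.p_crossover + config.p_subtree_mutation:
                t1 = p1.base_tree
                i1 = int(rng.integers(0, _subtree_slots(t1)))
                child = _replace_subtree(
                    t1, i1, _random_tree(rng, 2, variables, full=False)
                )
            else:
                child = _mutate_consts(p1.base_tree, rng)
            if node_count(child) > config.max_nodes:
                continue
            offspring.append(fit_model(child, X, y, run_index))
        # Local least-squares refit of scalar coefficients for the most
        # accurate offspring.
        if config.n_const_refit > 0:
            top = sorted(
                range(len(offspring)),
                key=lambda i: offspring[i].fitness,
            )[: config.n_const_refit]
            for i in top:
                t = refit_constants(offspring[i].base_tree, X, y)
                refit = fit_model(t, X, y, run_index)
                if refit.fitness < offspring[i].fitness:
                    offspring[i] = refit
        archive.update(offspring)
        combined = pop + offspring
        ranks_c = _pareto_ranks(combined)
        order = sorted(
            range(len(combined)),
            key=lambda i: (
                ranks_c[i],
                combined[i].fitness,
                combined[i].complexity,
                combined[i].key,
            ),
        )
        pop = [combined[i] for i in order[: config.population]]


def evolve(X: np.ndarray, y: np.ndarray, config: GPConfig | None = None
           ) -> ParetoArchive:
    """Run ``config.n_runs`` independent evolutions and merge their models
    into a deduplicated Pareto archive.

    A constant response (zero total sum of squares) short-circuits to an
    archive holding only the flagged constant model.
    """
    config = config or GPConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    if config.generations <= 0 or config.population <= 0:
        raise ValueError("budget (generations, population) must be positive")
    variables = (
        tuple(config.feature_subset)
        if config.feature_subset is not None
        else tuple(range(X.shape[1]))
    )
    if not variables:
        raise ValueError("feature subset is empty")
    archive = ParetoArchive(cap=config.archive_cap)
    if float(((y - y.mean()) ** 2).sum()) <= 0.0:
        archive.add(fit_model(("const", float(y.mean())), X, y, 0))
        archive.flags.append("constant response: R^2 undefined")
        return archive
    if config.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        Xs = (X - mu) / sd
        scaling = (tuple(mu), tuple(sd))
    else:
        Xs, scaling = X, (None, None)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    for run, seed in enumerate(seeds):
        _single_evolution(Xs, y, config, variables, seed, run, archive)
    # Final polish: a deeper least-squares refit of the scalar
    # coefficients of the most accurate merged models.
    if config.n_const_refit > 0:
        top = sorted(
            archive.models, key=lambda m: (m.fitness, m.complexity, m.key)
        )[: 4 * config.n_const_refit]
        for m in top:
            t = refit_constants(m.base_tree, Xs, y, max_nfev=120)
            refit = fit_model(t, Xs, y, m.run_index)
            if refit.fitness < m.fitness:
                archive.add(refit)
    if scaling[0] is not None:
        archive.models = [
            dc_replace(m, x_mean=scaling[0], x_std=scaling[1])
            for m in archive.models
        ]
        archive._index = {
            m.key: i for i, m in enumerate(archive.models)
        }
    archive.prune()
    if config.robust:
        kept = robust_filter(
            archive.models, X, y,
            holdout=config.robust_holdout,
            max_degradation=config.robust_max_degradation,
            seed=config.seed,
        )
        archive.models = kept
        archive._index = {m.key: i for i, m in enumerate(kept)}
    return archive


def refit_with_features(
    X: np.ndarray,
    y: np.ndarray,
    feature_subset: Sequence[int],
    config: GPConfig | None = None,
) -> ParetoArchive:
    """Re-run the evolutions with variable leaves restricted to
    ``feature_subset`` (column indices of ``X``)."""
    subset = tuple(feature_subset)
    if not subset:
        raise ValueError("feature subset is empty")
    config = config or GPConfig()
    return evolve(X, y, dc_replace(config, feature_subset=subset))


def robust_filter(
    models: Sequence[ExpressionModel],
    X: np.ndarray,
    y: np.ndarray,
    holdout: float = 0.2,
    max_degradation: float = 0.05,
    seed: int = 0,
) -> list[ExpressionModel]:
    """Discard models whose fitness degrades by more than
    ``max_degradation`` when their scaling constants are refit on a random
    ``1 - holdout`` subset and re-evaluated on the full data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    keep: list[ExpressionModel] = []
    for m in models:
        idx = rng.permutation(n)[: max(3, int(round((1 - holdout) * n)))]
        Xm = m._standardize(X)
        refit = fit_model(m.base_tree, Xm[idx], y[idx], m.run_index)
        a, b = refit.scale
        z = eval_tree(m.base_tree, Xm)
        pred = a * z + b
        ss_tot = float(((y - y.mean()) ** 2).sum())
        fit_full = float(np.clip(((y - pred) ** 2).sum() / ss_tot, 0.0, 1.0))
        if fit_full - m.fitness <= max_degradation:
            keep.append(m)
    return keep


# ---------------------------------------------------------------------------
# Ensembles and response surfaces


@dataclass
class ModelEnsemble:
    """A selected set of models queried jointly: the center is the member
    median and the spread is the interdecile (10th-90th percentile) range."""

    members: list[ExpressionModel]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must have at least one member")
        self.n_excluded = 0


def ensemble_predict(
    ensemble: ModelEnsemble, X_query: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-query (center, spread) of the member predictions.

    Members whose evaluation is non-finite at a query point are excluded
    at that point; the exclusion count is recorded on the ensemble.
    """
    Xq = np.atleast_2d(np.asarray(X_query, dtype=float))
    preds = np.stack([m.predict(Xq) for m in ensemble.members])
    bad = ~np.isfinite(preds)
    ensemble.n_excluded = int(bad.sum())
    preds = np.where(bad, np.nan, preds)
    center = np.nanmedian(preds, axis=0)
    # Nearest-observation percentiles keep the spread meaningful for
    # small ensembles (two members {1, 3} span 2, not an interpolate).
    hi = np.nanpercentile(preds, 90, axis=0, method="closest_observation")
    lo = np.nanpercentile(preds, 10, axis=0, method="closest_observation")
    return center, hi - lo


def response_profile(
    ensemble: ModelEnsemble,
    var: int,
    X_train: np.ndarray,
    n_points: int = 15,
    quantiles: tuple[float, float] = (0.05, 0.95),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """1-D ensemble response in one variable, others at training medians.

    The grid spans the central data-supported quantile range of the
    training values; predictions outside it are extrapolations the
    ensemble does not support.  Returns (grid, center, spread).
    """
    X_train = np.asarray(X_train, dtype=float)
    lo, hi = np.quantile(X_train[:, var], quantiles)
    grid = np.linspace(lo, hi, n_points)
    med = np.median(X_train, axis=0)
    Xq = np.tile(med, (n_points, 1))
    Xq[:, var] = grid
    center, spread = ensemble_predict(ensemble, Xq)
    return grid, center, spread


def count_direction_changes(profile: np.ndarray, rtol: float = 1e-9
                            ) -> int:
    """Sign changes of the first difference, ignoring near-zero steps."""
    profile = np.asarray(profile, dtype=float)
    d = np.diff(profile)
    scale = max(float(np.ptp(profile)), 1e-12)
    signs = np.sign(d[np.abs(d) > rtol * scale])
    if signs.size < 2:
        return 0
    return int(np.sum(signs[1:] * signs[:-1] < 0))


def response_surface(
    ensemble: ModelEnsemble,
    var_x: int,
    var_y: int,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    X_train: np.ndarray,
    spread_fraction: float = 0.5,
    support_radius: float = 1.0,
) -> dict[str, np.ndarray]:
    """Ensemble response over a 2-D grid with support flags.

    Non-varied features are fixed at training medians.  A grid cell is
    *unsupported* (the open/white region of the surface plot) when either
    the ensemble spread exceeds ``spread_fraction`` of the center's range
    over the grid, or the nearest training point — in standardized space
    over the two varied features — is farther than ``support_radius``.
    """
    if var_x == var_y:
        raise ValueError("var_x and var_y must differ")
    X_train = np.asarray(X_train, dtype=float)
    med = np.median(X_train, axis=0)
    gx, gy = np.meshgrid(grid_x, grid_y, indexing="ij")
    nq = gx.size
    Xq = np.tile(med, (nq, 1))
    Xq[:, var_x] = gx.ravel()
    Xq[:, var_y] = gy.ravel()
    center, spread = ensemble_predict(ensemble, Xq)

    mu = X_train[:, [var_x, var_y]].mean(axis=0)
    sd = X_train[:, [var_x, var_y]].std(axis=0, ddof=1)
    sd = np.where(sd < 1e-12, 1.0, sd)
    train_std = (X_train[:, [var_x, var_y]] - mu) / sd
    query_std = (Xq[:, [var_x, var_y]] - mu) / sd
    d2 = (
        (query_std[:, None, :] - train_std[None, :, :]) ** 2
    ).sum(axis=2)
    nearest = np.sqrt(d2.min(axis=1))

    center_range = float(center.max() - center.min())
    if center_range < 1e-12:
        center_range = 1.0
    supported = (spread <= spread_fraction * center_range) & (
        nearest <= support_radius
    )
    shape = gx.shape
    return {
        "center": center.reshape(shape),
        "spread": spread.reshape(shape),
        "supported": supported.reshape(shape),
        "nearest_distance": nearest.reshape(shape),
    }
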