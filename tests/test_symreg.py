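"""Expression trees, Pareto archives, evolution, ensembles."""

import numpy as np
import pytest

from rehabmech import symreg as sr


# Independent recursive oracle for visitation length.
def oracle_nodes(tree):
    op = tree[0]
    if op in ("var", "const"):
        return [tree]
    if op == "pow":
        return [tree] + oracle_nodes(tree[1]) + [("const", tree[2])]
    return [tree] + oracle_nodes(tree[1]) + oracle_nodes(tree[2])


def oracle_complexity(tree):
    def count(t):
        op = t[0]
        if op in ("var", "const"):
            return 1
        if op == "pow":
            return 1 + count(t[1]) + 1
        return 1 + count(t[1]) + count(t[2])

    def subtrees(t):
        op = t[0]
        if op in ("var", "const"):
            return [t]
        if op == "pow":
            return [t] + subtrees(t[1]) + [("const", t[2])]
        return [t] + subtrees(t[1]) + subtrees(t[2])

    return sum(count(s) for s in subtrees(tree))


def brute_force_front(models):
    out = []
    for m in models:
        dominated = any(
            (o.fitness <= m.fitness and o.complexity <= m.complexity)
            and (o.fitness < m.fitness or o.complexity < m.complexity)
            for o in models
        )
        if not dominated:
            out.append(m)
    return out


def make_models(pairs):
    return [
        sr.ExpressionModel(
            tree=("const", float(i)),
            fitness=f,
            complexity=c,
            variables_used=frozenset(),
        )
        for i, (c, f) in enumerate(pairs)
    ]


class TestComplexity:
    @pytest.mark.parametrize(
        "tree,expected",
        [
            (("var", 0), 1),
            (("const", 3.0), 1),
            (("add", ("var", 0), ("var", 1)), 5),
            (("mul", ("add", ("var", 0), ("var", 1)), ("const", 2.0)), 11),
            (("pow", ("var", 0), 2), 5),
        ],
    )
    def test_examples(self, tree, expected):
        assert sr.complexity(tree) == expected
        assert oracle_complexity(tree) == expected

    def test_matches_recursive_oracle_on_random_trees(self, rng):
        for _ in range(50):
            tree = sr._random_tree(rng, int(rng.integers(1, 5)),
                                   [0, 1, 2], full=False)
            assert sr.complexity(tree) == oracle_complexity(tree)


class TestEval:
    def test_protected_division_is_finite(self):
        X = np.array([[0.0], [1e-13], [2.0]])
        t = ("div", ("const", 1.0), ("var", 0))
        out = sr.eval_tree(t, X)
        assert np.all(np.isfinite(out))
        assert out[0] == sr.PROTECTED_DIV_VALUE
        assert out[1] == sr.PROTECTED_DIV_VALUE
        assert out[2] == pytest.approx(0.5)

    def test_canonical_sorts_commutative_operands(self):
        a = ("add", ("var", 1), ("var", 0))
        b = ("add", ("var", 0), ("var", 1))
        assert sr.canonical(a) == sr.canonical(b)
        assert sr.canonical(("sub", ("var", 1), ("var", 0))) != sr.canonical(
            ("sub", ("var", 0), ("var", 1))
        )

    def test_fitness_matches_recomputation(self, goldilocks_xy):
        X, y = goldilocks_xy
        arch = sr.evolve(
            X, y, sr.GPConfig(n_runs=1, population=40, generations=3, seed=0)
        )
        rng = np.random.default_rng(0)
        ss_tot = ((y - y.mean()) ** 2).sum()
        for m in rng.choice(arch.models, size=20, replace=False):
            pred = m.predict(X)
            fit = np.clip(((y - pred) ** 2).sum() / ss_tot, 0.0, 1.0)
            assert m.fitness == pytest.approx(float(fit), abs=1e-10)


class TestPareto:
    def test_front_matches_brute_force_on_random_archives(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 60))
            pairs = list(
                zip(
                    rng.integers(1, 30, n).tolist(),
                    np.round(rng.random(n), 3).tolist(),
                )
            )
            models = make_models(pairs)
            got = {(m.complexity, m.fitness) for m in sr.pareto_front(models)}
            want = {
                (m.complexity, m.fitness) for m in brute_force_front(models)
            }
            assert got == want

    def test_knee_filter_is_strict_on_both_axes(self):
        models = make_models(
            [(50, 0.1), (100, 0.1), (50, 0.2), (99, 0.19)]
        )
        picked = sr.select_knee(models, max_complexity=100, max_fitness=0.2)
        assert {(m.complexity, m.fitness) for m in picked} == {
            (50, 0.1),
            (99, 0.19),
        }

    def test_knee_on_empty_or_all_failing(self):
        assert sr.select_knee([], 100, 0.2) == []
        models = make_models([(200, 0.5), (150, 0.9)])
        assert sr.select_knee(models, 100, 0.2) == []


class TestVariableAnalysis:
    def test_presence_fractions(self):
        models = [
            sr.ExpressionModel(("var", 0), 0.1, 1, frozenset(v))
            for v in ({0, 1}, {0}, {0, 2})
        ]
        pres = sr.variable_presence(models, n_features=3)
        assert pres == {0: 1.0, 1: pytest.approx(1 / 3),
                        2: pytest.approx(1 / 3)}

    def test_single_model_presence(self):
        models = [sr.ExpressionModel(("var", 1), 0.0, 1, frozenset({1}))]
        pres = sr.variable_presence(models, n_features=3)
        assert pres == {0: 0.0, 1: 1.0, 2: 0.0}

    def test_combinations_keyed_by_exact_set(self):
        models = [
            sr.ExpressionModel(("var", 0), 0.1, 1, frozenset(v))
            for v in ({0, 1}, {0}, {0, 1})
        ]
        combos = sr.variable_combinations(models)
        assert combos[frozenset({0, 1})] == 2
        assert combos[frozenset({0})] == 1

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError):
            sr.variable_presence([])


class TestEvolve:
    def test_planted_linear_law_recovered(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-3, 3, (200, 4))
        y = 2.0 * X[:, 0] + 3.0
        arch = sr.evolve(
            X, y,
            sr.GPConfig(n_runs=2, population=50, generations=4, seed=2),
        )
        good = [
            m for m in arch.models
            if m.fitness < 1e-6 and m.complexity <= 11
        ]
        assert good, "no compact exact model found"
        m = good[0]
        np.testing.assert_allclose(m.predict(X), y, atol=1e-5)

    def test_constant_response_flagged(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        arch = sr.evolve(X, np.full(10, 5.0))
        assert len(arch.models) == 1
        assert arch.models[0].y_constant
        assert arch.flags

    def test_same_seed_identical_archive(self, goldilocks_xy):
        X, y = goldilocks_xy
        cfg = sr.GPConfig(n_runs=2, population=40, generations=3, seed=9)
        a = sr.evolve(X, y, cfg)
        b = sr.evolve(X, y, cfg)
        assert [m.key for m in a.models] == [m.key for m in b.models]
        assert [m.fitness for m in a.models] == [m.fitness for m in b.models]

    def test_subset_restriction(self, goldilocks_xy):
        X, y = goldilocks_xy
        cfg = sr.GPConfig(n_runs=1, population=40, generations=4, seed=1)
        arch = sr.refit_with_features(X, y, [0, 5], cfg)
        for m in arch.models:
            assert m.variables_used <= {0, 5}
        with pytest.raises(ValueError):
            sr.refit_with_features(X, y, [], cfg)

    def test_distance_only_fits_worse_than_distance_and_rest(
        self, goldilocks_xy
    ):
        X, y = goldilocks_xy
        cfg = sr.GPConfig(n_runs=2, population=80, generations=10, seed=3)
        best_d = min(
            m.fitness for m in sr.refit_with_features(X, y, [0], cfg).models
        )
        best_dr = min(
            m.fitness
            for m in sr.refit_with_features(X, y, [0, 5], cfg).models
        )
        assert best_dr < best_d


class TestEnsemble:
    def _const_model(self, v):
        return sr.ExpressionModel(("const", float(v)), 0.0, 1, frozenset())

    def test_identical_members_have_zero_spread(self):
        ens = sr.ModelEnsemble([self._const_model(2.0)] * 5)
        center, spread = sr.ensemble_predict(ens, np.zeros((3, 2)))
        assert np.all(center == 2.0)
        assert np.all(spread == 0.0)

    def test_two_constant_members(self):
        ens = sr.ModelEnsemble([self._const_model(1.0),
                                self._const_model(3.0)])
        center, spread = sr.ensemble_predict(ens, np.zeros((1, 2)))
        assert center[0] == pytest.approx(2.0)
        assert spread[0] == pytest.approx(2.0)

    def test_center_bounded_by_member_range(self, rng):
        members = [
            sr.fit_model(sr._random_tree(rng, 3, [0, 1], full=False),
                         rng.normal(size=(30, 2)), rng.normal(size=30))
            for _ in range(7)
        ]
        ens = sr.ModelEnsemble(members)
        Xq = rng.normal(size=(1000, 2))
        center, _ = sr.ensemble_predict(ens, Xq)
        preds = np.stack([m.predict(Xq) for m in members])
        assert np.all(center >= preds.min(axis=0) - 1e-12)
        assert np.all(center <= preds.max(axis=0) + 1e-12)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            sr.ModelEnsemble([])


class TestResponseSurface:
    def test_support_flags(self, rng):
        X_train = rng.uniform(0, 1, size=(30, 3))
        member = sr.fit_model(("var", 0), X_train, X_train[:, 0])
        ens = sr.ModelEnsemble([member])
        # grid covering the data plus a far corner
        gx = np.array([X_train[0, 0], 50.0])
        gy = np.array([X_train[0, 1], 50.0])
        surf = sr.response_surface(ens, 0, 1, gx, gy, X_train)
        assert surf["supported"][0, 0]  # coincident with a training point
        assert not surf["supported"][1, 1]  # far corner
        # single-model ensemble: spread identically zero
        assert np.all(surf["spread"] == 0.0)

    def test_same_variable_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        ens = sr.ModelEnsemble([sr.fit_model(("var", 0), X, X[:, 0])])
        with pytest.raises(ValueError):
            sr.response_surface(ens, 1, 1, np.arange(3.0), np.arange(3.0), X)


class TestDirectionChanges:
    @pytest.mark.parametrize(
        "profile,expected",
        [
            ([1, 2, 3, 2, 1], 1),
            ([1, 2, 3, 4], 0),
            ([3, 2, 1], 0),
            ([1, 2, 1, 2], 2),
            ([1, 1, 1], 0),
        ],
    )
    def test_counts(self, profile, expected):
        assert sr.count_direction_changes(np.array(profile, float)) == expected
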