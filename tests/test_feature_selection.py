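import itertools

import numpy as np
import pytest

from essprot.feature_selection import (
    LinearSvmRfe,
    SubcellularFeatureSpec,
    SvmConfig,
    kkt_residual,
    rank_localization_terms,
    read_ranking,
    rfe_rank,
    select_top_communities,
    subcellular_features,
    train_linear_svm,
    write_ranking,
)
from essprot.io import LocalizationTable


class TestLinearSvm:
    def test_separable_1d(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        model = train_linear_svm(X, y, SvmConfig(C=1.0, lam=0.0))
        assert model.w[0] > 0
        assert (np.sign(X @ model.w + model.bias) == y).all()
        assert kkt_residual(model, X, y, SvmConfig(C=1.0, lam=0.0)) <= 1e-6

    def test_constant_column_gets_zero_weight(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.repeat(1.0, 20), rng.normal(size=20)])
        y = np.where(X[:, 1] > 0, 1.0, -1.0)
        model = train_linear_svm(X, y)
        # a feature identical across classes cannot separate: weight ~ 0
        # (w_0 = sum alpha_k y_k * 1 = 0 by the equality constraint)
        assert abs(model.w[0]) <= 1e-6

    def test_margin_matches_support_pair_oracle(self):
        # brute-force maximum margin over candidate support-vector pairs
        rng = np.random.default_rng(4)
        pos = rng.normal(loc=[2.5, 2.5], scale=0.5, size=(4, 2))
        neg = rng.normal(loc=[-2.5, -2.5], scale=0.5, size=(4, 2))
        X = np.vstack([pos, neg])
        y = np.array([1.0] * 4 + [-1.0] * 4)
        model = train_linear_svm(X, y, SvmConfig(C=1e3, lam=0.0))
        margin = 2.0 / np.linalg.norm(model.w)
        # hard-margin oracle: the optimal margin is attained either between a
        # closest opposite pair or at a point-to-segment distance
        best = np.inf
        for i, j in itertools.product(range(4), range(4, 8)):
            best = min(best, np.linalg.norm(X[i] - X[j]))
        for a, b, c in itertools.permutations(range(8), 3):
            if y[a] == y[b] != y[c]:
                seg = X[b] - X[a]
                t = np.clip(np.dot(X[c] - X[a], seg) / np.dot(seg, seg), 0, 1)
                best = min(best, np.linalg.norm(X[c] - (X[a] + t * seg)))
        assert margin == pytest.approx(best, abs=1e-6)

    def test_kkt_satisfied_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        cfg = SvmConfig()
        for _ in range(20):
            n, d = int(rng.integers(10, 40)), int(rng.integers(2, 6))
            X = rng.normal(size=(n, d))
            y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
            if len(set(y)) < 2:
                continue
            model = train_linear_svm(X, y, cfg)
            assert kkt_residual(model, X, y, cfg) <= 1e-6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_svm(np.ones((4, 1)), np.ones(4))


class TestRfe:
    def test_single_feature(self):
        X = np.array([[1.0], [0.0], [1.0], [0.0]])
        y = np.array([1, 0, 1, 0])
        assert rfe_rank(X, y).ranked == (0,)

    def test_zero_column_removed_first(self):
        rng = np.random.default_rng(1)
        y = np.array([1, 1, 1, 0, 0, 0, 1, 0, 1, 0])
        X = np.column_stack([y.astype(float), np.zeros(10)])
        ranking = rfe_rank(X, y)
        assert ranking.ranked == (0, 1)
        # criterion of the zero column at its removal is exactly 0
        assert ranking.removal_criteria[0] == 0.0

    def test_copy_noise_zero_ordering(self):
        rng = np.random.default_rng(2)
        y = np.array([1, 0] * 10)
        noise = rng.normal(size=20)  # uninformative but nonzero-weight column
        X = np.column_stack([y.astype(float), noise, np.zeros(20)])
        ranking = rfe_rank(X, y)
        assert ranking.ranked[0] == 0  # the exact label copy ranks best
        assert ranking.ranked[-1] == 2  # the zero column is removed first
        assert ranking.removal_criteria[0] == 0.0

    def test_ranked_is_permutation(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 7))
        y = np.where(rng.random(30) < 0.5, 1, 0)
        ranking = rfe_rank(X, y)
        assert sorted(ranking.ranked) == list(range(7))
        assert len(ranking.surviving_trace) == 7

    def test_informative_features_rank_high(self):
        # 5 planted informative + 20 noise features; informative in top 10
        # in at least 90% of seeded runs
        hits = 0
        n_runs = 50
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(120, 25))
            coef = np.zeros(25)
            coef[:5] = 2.0
            y = (X @ coef + rng.normal(scale=0.5, size=120) > 0).astype(int)
            if len(set(y)) < 2:
                continue
            ranking = rfe_rank(X, y)
            if set(range(5)) <= set(ranking.ranked[:10]):
                hits += 1
        assert hits >= 0.9 * n_runs

    def test_training_failure_names_round(self):
        X = np.ones((4, 2))
        y = np.ones(4)
        with pytest.raises(ValueError):
            rfe_rank(X, y)

    def test_estimator_get_params_round_trip(self):
        est = LinearSvmRfe(C=2.0, lam=1e-5)
        params = est.get_params()
        est2 = LinearSvmRfe(**params)
        assert est2.get_params() == params


class TestSelectTop:
    def make_ranking(self, n):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, n))
        y = np.where(rng.random(40) < 0.5, 1, 0)
        return rfe_rank(X, y)

    def test_selects_k(self):
        ranking = self.make_ranking(10)
        assert len(select_top_communities(ranking, 4)) == 4

    def test_saturation_warns(self):
        ranking = self.make_ranking(5)
        with pytest.warns(UserWarning):
            out = select_top_communities(ranking, 64)
        assert sorted(out) == list(range(5))

    def test_zero_k_rejected(self):
        ranking = self.make_ranking(3)
        with pytest.raises(ValueError):
            select_top_communities(ranking, 0)

    def test_returned_in_column_order(self):
        ranking = self.make_ranking(10)
        out = select_top_communities(ranking, 6)
        assert out == sorted(out)
        assert set(out) == set(ranking.ranked[:6])


class TestSubcellular:
    def make_table(self, n_terms, per_term_counts=None):
        records = set()
        for j in range(n_terms):
            count = per_term_counts[j] if per_term_counts else (j % 7) + 1
            for i in range(count):
                records.add((f"P{i:04d}", f"term{j:04d}"))
        return LocalizationTable(records=frozenset(records))

    def test_970_columns_when_enough_terms(self):
        table = self.make_table(1500)
        proteins = sorted({p for p, _ in table.records})
        mat, terms = subcellular_features(table, proteins)
        assert len(terms) == 970
        assert mat.shape == (len(proteins), 970)

    def test_term_order_count_desc_ties_lexicographic(self):
        table = LocalizationTable(
            records=frozenset(
                {(f"P{i}", "zeta") for i in range(9)}
                | {(f"P{i}", "beta") for i in range(7)}
                | {(f"P{i}", "alpha") for i in range(7)}
                | {(f"P{i}", "gamma") for i in range(3)}
                | {("P0", "delta")}
            )
        )
        proteins = sorted({p for p, _ in table.records})
        order = rank_localization_terms(table, proteins)
        assert order == ["zeta", "alpha", "beta", "gamma", "delta"]

    def test_unannotated_protein_all_zero(self):
        table = self.make_table(5)
        mat, _ = subcellular_features(table, ["ZZZZ"])
        assert not mat.any()

    def test_column_count_formula(self):
        spec = SubcellularFeatureSpec()
        for n_terms in (5, 10, 11, 40, 64, 65, 200, 1024, 1500):
            table = self.make_table(n_terms)
            proteins = sorted({p for p, _ in table.records})
            _, terms = subcellular_features(table, proteins, spec)
            in_band = len([r for r in range(11, 65) if r <= min(n_terms, 1024)])
            assert len(terms) == min(n_terms, 1024) - in_band


def test_ranking_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    X = rng.normal(size=(30, 5))
    y = np.where(rng.random(30) < 0.5, 1, 0)
    ranking = rfe_rank(X, y)
    p = tmp_path / "ranking.tsv"
    with open(p, "w") as fh:
        write_ranking(ranking, fh)
    with open(p) as fh:
        back = read_ranking(fh)
    assert back.ranked == ranking.ranked
    assert np.allclose(back.removal_criteria, ranking.removal_criteria)
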