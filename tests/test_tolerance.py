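"""Membership/PCA/D-value pipeline against hand computations and oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import coldkit as ck
from coldkit.tolerance import (
    CompositeResult,
    classify_tolerance,
    cluster_cultivars,
    component_weights,
    d_value,
    membership,
    pca_composites,
    select_components,
    standardize_table,
)


class TestMembership:
    @pytest.mark.parametrize(
        "x,lo,hi,expected",
        [(0.0, 0.0, 10.0, 0.0), (10.0, 0.0, 10.0, 1.0), (5.0, 0.0, 10.0, 0.5),
         (2.5, 2.0, 4.0, 0.25)],
    )
    def test_values(self, x, lo, hi, expected):
        assert membership(x, lo, hi) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_and_out_of_range(self):
        with pytest.raises(ValueError, match="degenerate"):
            membership(1.0, 2.0, 2.0)
        with pytest.raises(ValueError):
            membership(11.0, 0.0, 10.0)


class TestStandardize:
    def test_column_mapping(self):
        table = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [1.0, 0.0, 0.5]},
                             index=["c1", "c2", "c3"])
        std = standardize_table(table)
        assert std["a"].tolist() == [0.0, 0.5, 1.0]
        assert std["b"].tolist() == [1.0, 0.0, 0.5]

    def test_idempotent_on_unit_spanning(self):
        table = pd.DataFrame({"a": [0.0, 0.3, 1.0], "b": [1.0, 0.0, 0.6]})
        pd.testing.assert_frame_equal(standardize_table(standardize_table(table)),
                                      standardize_table(table))

    def test_constant_column_names_variable(self):
        table = pd.DataFrame({"SOD": [1.0, 1.0, 1.0], "MDA": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="SOD"):
            standardize_table(table)

    def test_single_cultivar_rejected(self):
        with pytest.raises(ValueError):
            standardize_table(pd.DataFrame({"a": [1.0]}))


class TestPCA:
    def test_matches_sklearn_oracle(self):
        """Eigenvalues/contributions/|loadings| agree with an independent SVD
        PCA on a random 14 x 5 fixture."""
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            rng.uniform(size=(14, 5)),
            columns=["SOD", "POD", "soluble_sugar", "soluble_protein", "MDA"],
        )
        std = standardize_table(table)
        res = pca_composites(std)
        ref = PCA(n_components=5).fit(std.to_numpy())
        assert np.allclose(res.eigenvalues, ref.explained_variance_, atol=1e-8)
        assert np.allclose(res.contribution_rates, ref.explained_variance_ratio_, atol=1e-8)
        assert np.allclose(np.abs(res.loadings.to_numpy()), np.abs(ref.components_.T),
                           atol=1e-8)
        assert res.contribution_rates.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_covariance(self):
        table = pd.DataFrame({"a": [0.0, 0.5, 1.0], "b": [0.0, 0.5, 1.0]})
        res = pca_composites(table, directions={"a": 1, "b": 1})
        assert res.contribution_rates[0] == pytest.approx(1.0)

    def test_orientation_rule(self):
        """Direction-weighted loading sums are non-negative for every
        component, and D-relevant scores are orientation-stable under global
        sign flips of the input."""
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        dirs = {"a": 1, "b": 1, "c": -1, "d": 1}
        res = pca_composites(standardize_table(table), directions=dirs)
        dvec = np.array([dirs[c] for c in res.loadings.index])
        for j in range(res.loadings.shape[1]):
            assert dvec @ res.loadings.iloc[:, j].to_numpy() >= -1e-12


class TestSelectionAndWeights:
    @pytest.mark.parametrize(
        "contributions,expected_k",
        [((0.9, 0.1), 1), ((0.5, 0.3, 0.15, 0.05), 3), ((1.0,), 1),
         ((0.85, 0.15), 2)],  # strictly-greater rule: 0.85 is not > 0.85
    )
    def test_prefix_rule(self, contributions, expected_k):
        res = CompositeResult(
            loadings=pd.DataFrame(), scores=pd.DataFrame(),
            eigenvalues=np.asarray(contributions),
            contribution_rates=np.asarray(contributions),
        )
        select_components(res, 0.85)
        assert res.retained == list(range(expected_k))

    def test_weights(self):
        res = CompositeResult(
            loadings=pd.DataFrame(), scores=pd.DataFrame(),
            eigenvalues=np.array([0.6, 0.3, 0.1]),
            contribution_rates=np.array([0.6, 0.3, 0.1]),
        )
        res.retained = [0, 1]
        w = component_weights(res)
        assert np.allclose(w, [2 / 3, 1 / 3])
        assert w.sum() == pytest.approx(1.0, abs=1e-9)


class TestDValue:
    def test_hand_computed_three_cultivar_fixture(self):
        """Two perfectly correlated benefit variables collapse to one
        component; D is then the membership of that component's score, i.e.
        0, 1/2, 1 for an equally spaced fixture."""
        table = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [20.0, 40.0, 60.0]},
                             index=["c1", "c2", "c3"])
        scores, res = ck.score_cultivars(table, directions={"a": 1, "b": 1})
        assert res.retained == [0]
        ds = {s.cultivar: s.d_value for s in scores}
        assert ds["c1"] == pytest.approx(0.0, abs=1e-12)
        assert ds["c2"] == pytest.approx(0.5, abs=1e-12)
        assert ds["c3"] == pytest.approx(1.0, abs=1e-12)

    def test_best_cultivar_gets_one(self, physio_noiseless):
        table, truth = physio_noiseless
        scores, _ = ck.score_cultivars(ck.aggregate_indicators(table))
        best = max(scores, key=lambda s: s.d_value)
        assert best.d_value == pytest.approx(1.0)
        assert all(0.0 <= s.d_value <= 1.0 for s in scores)

    def test_noiseless_ranking_matches_theta(self, physio_noiseless):
        table, truth = physio_noiseless
        scores, _ = ck.score_cultivars(ck.aggregate_indicators(table))
        d = np.array([s.d_value for s in scores])
        theta = np.array([c.theta for c in truth.latent_cultivars])
        assert (np.argsort(d) == np.argsort(theta)).all()

    def test_affine_rescaling_invariance(self, physio_noiseless):
        """Rescaling any input variable (positive scale + shift) leaves D
        unchanged: the membership function removes location and scale."""
        table, _ = physio_noiseless
        agg = ck.aggregate_indicators(table)
        base, _ = ck.score_cultivars(agg)
        rescaled = agg.copy()
        rescaled["POD"] = rescaled["POD"] * 3.7 + 11.0
        alt, _ = ck.score_cultivars(rescaled)
        assert np.allclose([s.d_value for s in base], [s.d_value for s in alt], atol=1e-9)


class TestClassification:
    @pytest.mark.parametrize(
        "d,expected",
        [(0.916, "strong"), (0.142, "weak"), (0.40, "moderate"), (0.70, "strong"),
         (0.399, "weak"), (0.0, "weak"), (1.0, "strong")],
    )
    def test_thresholds(self, d, expected):
        assert classify_tolerance(d) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_tolerance(1.2)


def _brute_force_three_partition(values):
    """Minimal within-group sum of squares over all contiguous 3-partitions
    of the sorted values (optimal 1-D clustering is contiguous in sorted
    order)."""
    import itertools

    order = np.argsort(values)[::-1]
    n = len(order)
    best, best_groups = np.inf, None
    vals = np.asarray(values, dtype=float)
    for i, j in itertools.combinations(range(1, n), 2):
        groups = [order[:i], order[i:j], order[j:]]
        ss = sum(vals[g].var() * len(g) for g in groups)
        if ss < best - 1e-12:
            best, best_groups = ss, groups
    return [set(g.tolist()) for g in best_groups]


class TestClustering:
    def test_matches_brute_force_partition(self):
        d = np.array([0.9, 0.88, 0.5, 0.48, 0.1])
        scores = [ck.tolerance.ToleranceScore(f"c{i}", np.array([v]), v,
                                              classify_tolerance(v))
                  for i, v in enumerate(d)]
        df = cluster_cultivars(scores, k=3)
        got = {frozenset(df.index[df.group == g]) for g in df.group.unique()}
        expected = _brute_force_three_partition(d)
        assert got == {frozenset(s) for s in expected}
        # labels follow descending mean D
        assert set(df.loc[df.d_value > 0.8, "group"]) == {"strong"}
        assert set(df.loc[df.d_value < 0.2, "group"]) == {"weak"}

    def test_k1_single_group(self):
        scores = [ck.tolerance.ToleranceScore(f"c{i}", np.array([v]), v, "weak")
                  for i, v in enumerate([0.1, 0.2, 0.3])]
        df = cluster_cultivars(scores, k=1)
        assert df.group.nunique() == 1

    def test_k_too_large(self):
        scores = [ck.tolerance.ToleranceScore("c", np.array([0.5]), 0.5, "moderate")]
        with pytest.raises(ValueError):
            cluster_cultivars(scores, k=2)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=3, max_size=8))
def test_membership_bounds_property(values):
    lo, hi = min(values), max(values)
    if hi > lo:
        for v in values:
            assert 0.0 <= membership(v, lo, hi) <= 1.0
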