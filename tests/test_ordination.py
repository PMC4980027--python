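import numpy as np
import pandas as pd
import pytest

from ecostatus import (
    IndicatorMatrix,
    independence_screen,
    pca,
    rda,
    select_indicators,
)
from ecostatus.ordination import (
    GreedyIndicatorSelector,
    PartialCorrelationScreen,
    RedundancyAnalysis,
    standardize,
)


def make_matrix(values, ids=None):
    values = np.asarray(values, float)
    ids = ids or tuple(f"V{j}" for j in range(values.shape[1]))
    return IndicatorMatrix(
        times=tuple(range(2000, 2000 + values.shape[0])),
        indicator_ids=tuple(ids),
        values=values,
    )


def eigen_oracle(values):
    """Brute-force PCA oracle: eigen-decompose the sample correlation matrix."""
    corr = np.corrcoef(values, rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
    return eig / eig.sum()


def regression_oracle(values, cidx):
    """Hand-rolled RDA share: per-response OLS R^2, variance-weighted."""
    z = (values - values.mean(0)) / values.std(0, ddof=1)
    X = z[:, cidx]
    ridx = [j for j in range(z.shape[1]) if j not in set(cidx)]
    ss_fit = ss_tot = 0.0
    for j in ridx:
        beta = np.linalg.lstsq(X, z[:, j], rcond=None)[0]
        ss_fit += np.sum((X @ beta) ** 2)
        ss_tot += np.sum(z[:, j] ** 2)
    return ss_fit / ss_tot


class TestIndicatorMatrix:
    def test_interior_gaps_interpolated_edge_rows_dropped(self):
        df = pd.DataFrame(
            {"a": [1.0, np.nan, 3.0, 4.0], "b": [np.nan, 2.0, 3.0, 4.0]},
            index=[2000, 2001, 2002, 2003],
        )
        m = IndicatorMatrix.from_dataframe(df)
        assert m.times == (2001, 2002, 2003)  # 2000 not extrapolable
        assert m.values[0, 0] == pytest.approx(2.0)  # interior gap filled

    def test_shape_and_uniqueness_validated(self):
        with pytest.raises(ValueError, match="unique"):
            make_matrix(np.ones((3, 2)), ids=("a", "a"))
        with pytest.raises(ValueError, match="missing"):
            make_matrix([[1.0, np.nan], [2.0, 1.0], [3.0, 2.0]])


class TestPCA:
    def test_matches_eigen_oracle(self, random_matrix):
        res = pca(random_matrix)
        assert res.variance_share == pytest.approx(
            eigen_oracle(random_matrix.values), abs=1e-8
        )
        assert res.variance_share.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_loadings_orthonormal(self, random_matrix):
        L = pca(random_matrix).loadings
        assert L.T @ L == pytest.approx(np.eye(L.shape[1]), abs=1e-8)

    def test_uncorrelated_columns_share_evenly(self, rng):
        m = make_matrix(rng.standard_normal((4000, 2)))
        assert pca(m).variance_share == pytest.approx([0.5, 0.5], abs=0.05)

    def test_perfectly_correlated_columns_collapse_to_one_axis(self):
        x = np.arange(10.0) + np.sin(np.arange(10.0))
        m = make_matrix(np.column_stack([x, 2 * x + 1]))
        assert pca(m).variance_share[0] == pytest.approx(1.0, abs=1e-10)

    def test_constant_column_error_names_indicator(self):
        m = make_matrix(np.column_stack([np.ones(5), np.arange(5.0)]), ids=("flat", "ok"))
        with pytest.raises(ValueError, match="flat"):
            pca(m)


class TestRDA:
    def test_matches_regression_oracle(self, random_matrix):
        res = rda(random_matrix, ["V1", "V4"])
        oracle = regression_oracle(random_matrix.values, [1, 4])
        assert res.constrained_share == pytest.approx(oracle, abs=1e-8)

    def test_matches_scikit_bio(self, random_matrix):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        _, z = standardize(random_matrix)
        cidx = [0, 3]
        ridx = [j for j in range(6) if j not in cidx]
        out = skbio_ord.rda(
            pd.DataFrame(z[:, ridx]), pd.DataFrame(z[:, cidx]), scaling=1
        )
        # skbio stores singular values in eigvals; variances are their squares
        sv = out.eigvals.to_numpy() ** 2
        skbio_share = float(sv[: len(cidx)].sum() / sv.sum())
        res = rda(random_matrix, ["V0", "V3"])
        assert res.constrained_share == pytest.approx(skbio_share, abs=1e-8)

    def test_spanning_constraints_explain_everything(self, rng):
        X = rng.standard_normal((20, 2))
        responses = X @ rng.standard_normal((2, 3))
        m = make_matrix(np.column_stack([X, responses]))
        assert rda(m, ["V0", "V1"]).constrained_share == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_constraint_explains_nothing(self):
        # constraint exactly uncorrelated with the single response
        c = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        r = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0]) + np.arange(6) * 0
        r = r - r.mean()
        c_orth = c - (c @ r) / (r @ r) * r
        m = make_matrix(np.column_stack([c_orth, r]))
        assert rda(m, ["V0"]).constrained_share == pytest.approx(0.0, abs=1e-8)

    def test_collinear_constraints_rejected(self):
        x = np.arange(8.0)
        m = make_matrix(np.column_stack([x, 2 * x, np.random.default_rng(0).standard_normal(8)]))
        with pytest.raises(ValueError, match="collinear"):
            rda(m, ["V0", "V1"])

    def test_all_columns_as_constraints_is_fully_self_represented(self, random_matrix):
        res = rda(random_matrix, list(random_matrix.indicator_ids))
        assert res.constrained_share == 1.0 and res.explained_share == 1.0

    def test_explained_share_monotone_in_constraint_set(self, random_matrix):
        shares = [
            rda(random_matrix, ids).explained_share
            for ids in (["V0"], ["V0", "V2"], ["V0", "V2", "V5"])
        ]
        assert shares == sorted(shares)


class TestSelectIndicators:
    def test_trajectory_monotone_and_complete_selection_reaches_one(self, random_matrix):
        res = select_indicators(random_matrix, k_max=6)
        traj = list(res["trajectory"])
        assert traj == sorted(traj)
        assert traj[-1] == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_column_has_zero_marginal_gain(self, rng):
        base = rng.standard_normal((30, 3))
        values = np.column_stack([base, base[:, 0] * 2.0 + 1.0])  # V3 duplicates V0
        m = make_matrix(values)
        res = select_indicators(m, k_max=3)
        first_two = set(res["selected"][:2])
        assert not {"V0", "V3"} <= first_two  # twin never follows its duplicate early
        # explicit marginal-gain oracle (twin is collinear, so allow it)
        with_twin = RedundancyAnalysis(["V0", "V3"], allow_collinear=True).fit(m).explained_share_
        without = rda(m, ["V0"]).explained_share
        assert with_twin == pytest.approx(without, abs=1e-10)

    def test_greedy_matches_exhaustive_on_small_matrix(self, random_matrix):
        greedy = GreedyIndicatorSelector(k_max=1).fit(random_matrix)
        exhaustive = GreedyIndicatorSelector(k_max=1, strategy="exhaustive").fit(random_matrix)
        assert greedy.selected_ids_ == exhaustive.selected_ids_
        assert greedy.share_trajectory_[0] == pytest.approx(
            exhaustive.share_trajectory_[0], abs=1e-12
        )

    def test_k_max_capped_with_warning(self, random_matrix, caplog):
        res = select_indicators(random_matrix, k_max=99)
        assert len(res["selected"]) == random_matrix.n_indicators

    def test_goal_share_stops_early(self, random_matrix):
        res = select_indicators(random_matrix, k_max=6, goal_share=0.2)
        assert len(res["selected"]) < 6


class TestIndependenceScreen:
    def test_independent_noise_not_flagged(self, rng):
        m = make_matrix(rng.standard_normal((500, 2)))
        assert independence_screen(m, threshold=0.5) == ()

    def test_near_duplicate_flagged(self, rng):
        x = rng.standard_normal(200)
        m = make_matrix(np.column_stack([x, x + 0.05 * rng.standard_normal(200),
                                         rng.standard_normal(200)]))
        flagged = independence_screen(m, threshold=0.5)
        assert [(a, b) for a, b, _ in flagged] == [("V0", "V1")]

    def test_chain_mediation_not_flagged(self, rng):
        # X -> Z -> Y: marginal corr(X, Y) is strong but vanishes given Z
        x = rng.standard_normal(800)
        z = x + 0.4 * rng.standard_normal(800)
        y = z + 0.4 * rng.standard_normal(800)
        m = make_matrix(np.column_stack([x, z, y]), ids=("X", "Z", "Y"))
        assert abs(np.corrcoef(x, y)[0, 1]) > 0.5
        flagged = independence_screen(m, threshold=0.5)
        assert ("X", "Y") not in [(a, b) for a, b, _ in flagged]

    def test_matches_pingouin_partial_correlations(self, rng):
        pingouin = pytest.importorskip("pingouin")
        values = rng.standard_normal((60, 4)) @ rng.standard_normal((4, 4))
        m = make_matrix(values)
        screen = PartialCorrelationScreen(threshold=0.99).fit(m)
        oracle = pingouin.pcorr(pd.DataFrame(values)).to_numpy()
        assert screen.partial_correlations_ == pytest.approx(oracle, abs=1e-8)

    def test_more_columns_than_rows_uses_shrinkage(self, rng):
        m = make_matrix(rng.standard_normal((8, 10)))
        screen = PartialCorrelationScreen(threshold=0.9).fit(m)
        assert screen.regularized_ is True
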