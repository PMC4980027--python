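"""A posteriori indicator selection by analysis of indicator space.

Rather than fixing an indicator list in advance, the indicator space (a
years x indicators observation matrix) is analysed to find a small subset of
independent indicators that represents as much ecosystem variability as
possible:

* PCA of the correlation matrix shows how much variability a few latent
  axes carry (incommensurable units force the correlation, i.e. z-scored,
  form);
* redundancy analysis (RDA) measures the share of variance in the remaining
  indicators that a chosen constraint subset explains through least-squares
  regression;
* greedy forward selection builds the subset, tracking the explained share;
* a partial-correlation screen flags indicator pairs that remain dependent
  given all other indicators, since the Bayesian aggregation assumes
  conditionally independent evidence.

The unexplained complement of the selected subset's share is the error term
of the assessment: utility the ecosystem would have revealed through
unmonitored or unselected information.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.covariance import LedoitWolf
from sklearn.decomposition import PCA as _SkPCA

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndicatorMatrix:
    """Years x indicators observation matrix for ordination.

    ``values[t, j]`` is indicator ``indicator_ids[j]`` in year ``times[t]``.
    Use :meth:`from_dataframe` / :meth:`complete` for construction with gap
    handling: interior gaps are linearly interpolated per column (no
    extrapolation) and rows that remain incomplete are dropped.
    """

    times: tuple[int, ...]
    indicator_ids: tuple[str, ...]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (years x indicators)")
        if v.shape != (len(self.times), len(self.indicator_ids)):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"{len(self.times)} years x {len(self.indicator_ids)} indicators"
            )
        if len(set(self.indicator_ids)) != len(self.indicator_ids):
            raise ValueError("indicator ids must be unique")
        if np.any(~np.isfinite(v)):
            raise ValueError("matrix contains missing cells; call complete() first")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, standardized: bool = False) -> "IndicatorMatrix":
        """Build from a wide DataFrame (index = years, columns = indicators)."""
        clean = _complete_frame(df)
        return cls(
            times=tuple(int(t) for t in clean.index),
            indicator_ids=tuple(str(c) for c in clean.columns),
            values=clean.to_numpy(dtype=float),
            standardized=standardized,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.times), columns=list(self.indicator_ids))

    @property
    def n_years(self) -> int:
        return self.values.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.values.shape[1]

    def column_index(self, ids: Sequence[str]) -> np.ndarray:
        try:
            return np.asarray([self.indicator_ids.index(i) for i in ids], dtype=int)
        except ValueError:
            missing = [i for i in ids if i not in self.indicator_ids]
            raise KeyError(f"indicators not in matrix: {missing}")


def _complete_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Interior linear interpolation per column, then drop incomplete rows."""
    filled = df.astype(float).interpolate(method="linear", limit_area="inside", axis=0)
    dropped = filled.index[filled.isna().any(axis=1)]
    if len(dropped):
        logger.warning("dropping %d incomplete rows after interpolation: %s",
                       len(dropped), list(dropped))
    return filled.dropna(axis=0)


def standardize(m: IndicatorMatrix) -> tuple[IndicatorMatrix, np.ndarray]:
    """z-score each column (n-1 SD); errors on a constant column by name."""
    if m.standardized:
        return m, m.values
    sd = m.values.std(axis=0, ddof=1)
    bad = np.flatnonzero((sd == 0) | ~np.isfinite(sd))
    if bad.size:
        names = [m.indicator_ids[j] for j in bad]
        raise ValueError(f"constant indicator column(s), cannot standardize: {names}")
    z = (m.values - m.values.mean(axis=0)) / sd
    return IndicatorMatrix(m.times, m.indicator_ids, z, standardized=True), z


@dataclass(frozen=True)
class OrdinationResult:
    """Eigen-structure of an (optionally constrained) ordination."""

    eigenvalues: np.ndarray            # non-increasing, >= 0
    variance_share: np.ndarray         # per axis, sums to 1 for plain PCA
    loadings: np.ndarray               # variables x axes
    scores: np.ndarray                 # years x axes
    variable_ids: tuple[str, ...]
    constrained_share: float | None = None   # RDA: fitted / response variance
    explained_share: float | None = None     # RDA: inclusive, over all columns
    constraint_ids: tuple[str, ...] = ()


class CorrelationPCA(BaseEstimator):
    """PCA of the correlation matrix of an indicator matrix.

    Indicator units are incommensurable, so each column is z-scored before
    the eigen-decomposition; eigenvalues are those of the sample correlation
    matrix and ``variance_share_`` = eigenvalue / total variance.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, m: IndicatorMatrix):
        if m.n_years < 3 or m.n_indicators < 2:
            raise ValueError("ordination needs >= 3 years and >= 2 indicators")
        _, z = standardize(m)
        pca = _SkPCA(n_components=self.n_components).fit(z)
        total = float(m.n_indicators)  # correlation matrix trace
        self.eigenvalues_ = pca.explained_variance_
        self.variance_share_ = pca.explained_variance_ / total
        self.loadings_ = pca.components_.T
        self.scores_ = pca.transform(z)
        self.variable_ids_ = m.indicator_ids
        return self

    def to_result(self) -> OrdinationResult:
        return OrdinationResult(
            eigenvalues=self.eigenvalues_,
            variance_share=self.variance_share_,
            loadings=self.loadings_,
            scores=self.scores_,
            variable_ids=self.variable_ids_,
        )


def pca(m: IndicatorMatrix, n_components: int | None = None) -> OrdinationResult:
    """Correlation-matrix PCA of the indicator space."""
    return CorrelationPCA(n_components=n_components).fit(m).to_result()


class RedundancyAnalysis(BaseEstimator):
    """RDA: how much of the indicator space a constraint subset explains.

    Every column is z-scored; the response columns (all columns except the
    constraints) are regressed on the constraint columns by least squares,
    and the PCA of the fitted values gives the constrained axes.

    Two variance accountings are exposed:

    ``constrained_share_``
        fitted variance / total response variance — the share of the
        *remaining* indicators' variability the constraints reproduce.
    ``explained_share_``
        (constraints' own variance + fitted response variance) / total
        variance of *all* columns. Each selected indicator trivially
        represents itself, so this share is monotone non-decreasing in the
        constraint set and reaches 1 when every column is selected; it is
        the quantity greedy selection tracks.
    """

    def __init__(self, constraints: Sequence[str] = (), allow_collinear: bool = False):
        self.constraints = constraints
        self.allow_collinear = allow_collinear

    def fit(self, m: IndicatorMatrix):
        ids = list(self.constraints)
        if not ids:
            raise ValueError("RDA requires at least one constraint indicator")
        cidx = m.column_index(ids)
        if m.n_years < len(ids) + 2:
            raise ValueError(
                f"RDA needs at least {len(ids) + 2} years for {len(ids)} constraints"
            )
        _, z = standardize(m)
        n, p = z.shape
        X = z[:, cidx]
        if not self.allow_collinear and np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"collinear constraint columns: {ids}")
        ridx = np.asarray([j for j in range(p) if j not in set(cidx)], dtype=int)
        self.constraint_ids_ = tuple(ids)
        self.response_ids_ = tuple(m.indicator_ids[j] for j in ridx)

        if ridx.size == 0:
            # every column is a constraint: the space is fully self-represented
            self.constrained_share_ = 1.0
            self.explained_share_ = 1.0
            self.eigenvalues_ = np.zeros(0)
            self.variance_share_ = np.zeros(0)
            self.loadings_ = np.zeros((0, 0))
            self.scores_ = np.zeros((n, 0))
            return self

        Y = z[:, ridx]
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        fitted = X @ beta
        ss_fit = float(np.sum(fitted**2))
        ss_tot = float(np.sum(Y**2))            # z-scored: (n-1) per column
        self.constrained_share_ = ss_fit / ss_tot
        self.explained_share_ = (len(ids) * (n - 1) + ss_fit) / ((n - 1) * p)

        n_axes = min(len(ids), ridx.size)
        axes = _SkPCA(n_components=n_axes).fit(fitted)
        self.eigenvalues_ = axes.explained_variance_
        self.variance_share_ = axes.explained_variance_ / float(ridx.size)
        self.loadings_ = axes.components_.T
        self.scores_ = axes.transform(fitted)
        return self

    def to_result(self) -> OrdinationResult:
        return OrdinationResult(
            eigenvalues=self.eigenvalues_,
            variance_share=self.variance_share_,
            loadings=self.loadings_,
            scores=self.scores_,
            variable_ids=self.response_ids_,
            constrained_share=self.constrained_share_,
            explained_share=self.explained_share_,
            constraint_ids=self.constraint_ids_,
        )


def rda(m: IndicatorMatrix, constraints: Sequence[str]) -> OrdinationResult:
    """Redundancy analysis with the named indicators as constraints."""
    return RedundancyAnalysis(constraints=constraints).fit(m).to_result()


class GreedyIndicatorSelector(BaseEstimator):
    """Forward selection of indicators by inclusive RDA explained share.

    At each step the indicator whose addition maximizes
    ``explained_share`` (see :class:`RedundancyAnalysis`) joins the
    constraint set; ties break toward the earlier column. Selection stops
    at ``k_max`` indicators or once ``goal_share`` is reached. With
    ``strategy="exhaustive"`` (feasible up to ~12 columns) every subset of
    each size is scored instead, as a certificate for the greedy path.
    """

    def __init__(self, k_max: int = 2, goal_share: float | None = None,
                 strategy: str = "greedy"):
        self.k_max = k_max
        self.goal_share = goal_share
        self.strategy = strategy

    def fit(self, m: IndicatorMatrix):
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.strategy not in ("greedy", "exhaustive"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        k_max = self.k_max
        if k_max > m.n_indicators:
            logger.warning("k_max=%d capped at %d indicators", k_max, m.n_indicators)
            k_max = m.n_indicators
        if self.strategy == "exhaustive" and m.n_indicators > 12:
            raise ValueError("exhaustive search is limited to 12 indicators")

        zm, _ = standardize(m)
        selected: list[str] = []
        trajectory: list[float] = []
        remaining = list(zm.indicator_ids)
        while len(selected) < k_max:
            if self.strategy == "greedy":
                best_ids, best_share = None, -np.inf
                for cand in remaining:
                    share = (
                        RedundancyAnalysis(selected + [cand], allow_collinear=True)
                        .fit(zm).explained_share_
                    )
                    if share > best_share + 1e-12:  # ties keep earlier column
                        best_ids, best_share = selected + [cand], share
            else:
                k = len(selected) + 1
                best_ids, best_share = None, -np.inf
                for combo in itertools.combinations(zm.indicator_ids, k):
                    share = (
                        RedundancyAnalysis(list(combo), allow_collinear=True)
                        .fit(zm).explained_share_
                    )
                    if share > best_share + 1e-12:
                        best_ids, best_share = list(combo), share
            selected = best_ids
            remaining = [i for i in zm.indicator_ids if i not in selected]
            trajectory.append(float(best_share))
            if self.goal_share is not None and best_share >= self.goal_share:
                break
        self.selected_ids_ = tuple(selected)
        self.share_trajectory_ = tuple(trajectory)
        self.explained_share_ = trajectory[-1]
        return self

    def get_support(self, m: IndicatorMatrix) -> np.ndarray:
        mask = np.zeros(m.n_indicators, dtype=bool)
        mask[m.column_index(self.selected_ids_)] = True
        return mask


def select_indicators(
    m: IndicatorMatrix,
    k_max: int,
    goal_share: float | None = None,
    strategy: str = "greedy",
) -> dict:
    """Greedy (or exhaustive) forward indicator selection.

    Returns ``{"selected": ids, "trajectory": inclusive explained-variance
    share after each addition}``.
    """
    sel = GreedyIndicatorSelector(k_max=k_max, goal_share=goal_share,
                                  strategy=strategy).fit(m)
    return {"selected": sel.selected_ids_, "trajectory": sel.share_trajectory_}


class PartialCorrelationScreen(BaseEstimator):
    """Flag indicator pairs that are conditionally dependent.

    The additive Bayesian aggregation assumes indicators carry independent
    evidence; a nonzero partial correlation between two indicators given all
    the others says their information overlaps. Partial correlations come
    from the precision matrix of the correlation matrix,
    ``r_ij = -P_ij / sqrt(P_ii P_jj)``; with fewer years than indicators
    the correlation matrix is rank-deficient, so a Ledoit-Wolf shrinkage
    estimate replaces the sample matrix.
    """

    def __init__(self, threshold: float = 0.5):
        self.threshold = threshold

    def fit(self, m: IndicatorMatrix):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        _, z = standardize(m)
        n, p = z.shape
        if n > p:
            corr = np.corrcoef(z, rowvar=False)
            if np.linalg.matrix_rank(corr) < p:
                raise ValueError(
                    "singular correlation matrix; remove redundant indicator columns"
                )
            precision = np.linalg.inv(corr)
            self.regularized_ = False
        else:
            logger.warning(
                "%d years <= %d indicators: using Ledoit-Wolf shrinkage precision",
                n, p,
            )
            precision = LedoitWolf().fit(z).precision_
            self.regularized_ = True
        d = np.sqrt(np.diag(precision))
        pcorr = -precision / np.outer(d, d)
        np.fill_diagonal(pcorr, 1.0)
        self.partial_correlations_ = pcorr
        flags = []
        for i in range(p):
            for j in range(i + 1, p):
                if abs(pcorr[i, j]) > self.threshold:
                    flags.append(
                        (m.indicator_ids[i], m.indicator_ids[j], float(pcorr[i, j]))
                    )
        self.flagged_pairs_ = tuple(flags)
        return self


def independence_screen(m: IndicatorMatrix, threshold: float = 0.5) -> tuple:
    """Pairs flagged DEPENDENT with their partial correlations."""
    return PartialCorrelationScreen(threshold=threshold).fit(m).flagged_pairs_
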