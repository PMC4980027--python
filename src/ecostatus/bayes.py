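"""Sequential Bayesian aggregation of indicator likelihoods into P(GES).

The assessment treats good environmental status (GES) and non-GES as the two
exclusive states of the ecosystem. In a given year each indicator i
contributes a pass probability p_i (its censored likelihood of GES); under
independence the year's evidence is

    L(data | GES)     = prod_i p_i
    L(data | non-GES) = prod_i (1 - p_i)

and Bayes' rule gives the posterior

    P(GES | data) = L(data|GES) * prior / (L(data|GES) * prior
                                          + L(data|non-GES) * (1 - prior)).

Chaining the posterior of one assessment period into the prior of the next
makes the index trend-sensitive: it remembers the former state, buffers
single-year variability, and converts a persistent run of weak evidence into
a steadily drifting probability. Equivalently, in log-odds the update is

    logit(posterior_t) = logit(prior_t) + sum_i logit(p_{i,t}),

which is the numerically stable form used here.

An indicator that consistently under- or over-scores while the aggregate
stays moderate signals a persistent change in one ecosystem component; the
early-warning scan flags such runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .aggregation import AggregationConfig, EarlyWarningConfig
from .indicators import IndicatorSet
from .likelihood import clip_probability, likelihood_profile

logger = logging.getLogger(__name__)


def posterior_ges(p: Sequence[float], prior: float) -> float:
    """Two-state Bayes posterior of GES from per-indicator pass probabilities.

    Parameters
    ----------
    p : sequence of float in [0, 1]
        Pass probabilities; callers aggregating many indicators should clip
        them away from exact 0/1 first (see `likelihood.clip_probability`).
    prior : float in (0, 1)
        Prior probability of GES.

    Returns
    -------
    float in [0, 1]. An empty ``p`` returns the prior unchanged (no
    evidence). The result is symmetric in the indicators (the product is
    associative and commutative), strictly increasing in every ``p_i`` and
    in the prior, and equals the prior whenever every ``p_i`` is 0.5.
    """
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior must be in (0, 1), got {prior}")
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return float(prior)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("pass probabilities must lie in [0, 1]")
    if np.any(p == 0.0) and np.any(p == 1.0):
        raise ValueError(
            "conflicting certain evidence (p=0 and p=1); clip likelihoods first"
        )
    log_odds = logit(prior) + np.sum(logit(p))
    return float(expit(log_odds))


@dataclass(frozen=True)
class EarlyWarning:
    """A maximal run of extreme likelihoods for one indicator."""

    indicator_id: str
    start: int
    end: int
    side: Literal["low", "high"]
    mean_p: float

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class GESAssessment:
    """Result of a sequential assessment over the common years of a set.

    ``likelihoods`` is a (years x indicators) matrix of pass probabilities;
    ``prior_chain[t]`` is the prior in force at year t (``prior_chain[0]``
    is the configured initial prior; with chaining, ``prior_chain[t+1]``
    equals ``posterior[t]``). ``explained_variance`` is the share of
    ecosystem variability the indicator set represents (from ordination, if
    supplied); its complement is the unexplained error term of the
    assessment.
    """

    times: tuple[int, ...]
    indicator_ids: tuple[str, ...]
    posterior: tuple[float, ...]
    prior_chain: tuple[float, ...]
    likelihoods: np.ndarray
    warnings: tuple[EarlyWarning, ...] = ()
    explained_variance: float | None = None
    config: AggregationConfig = field(default_factory=AggregationConfig)


class GESBayesAssessor(BaseEstimator):
    """Sequential two-state Bayes aggregator over a likelihood matrix.

    A scikit-learn-style estimator: ``fit(X)`` consumes a
    (n_years, n_indicators) matrix of per-indicator pass probabilities in
    chronological row order and exposes the assessment as fitted attributes.

    Parameters
    ----------
    prior0 : float in (0, 1), default 0.5
        Initial prior probability of GES (0.5 is uninformative).
    chain : bool, default True
        Feed each year's posterior into the next year's prior (trend
        memory). With ``chain=False`` every year restarts from ``prior0``.
    discount : float in [0, 1], default 1.0
        Optional prior relaxation between periods,
        ``prior_{t+1} = discount * posterior_t + (1 - discount) * 0.5``;
        1.0 is the plain posterior-to-prior chain.
    clip_eps : float, default 1e-9
        Likelihoods are clipped into [clip_eps, 1 - clip_eps] so no single
        year can absorb the chain at certainty.
    warning_threshold, warning_k :
        An indicator whose likelihood stays below ``warning_threshold`` (or
        above its complement) for ``warning_k`` consecutive years is flagged.

    Attributes
    ----------
    posterior_ : ndarray of shape (n_years,)
    prior_chain_ : ndarray of shape (n_years,)
    likelihoods_ : ndarray of shape (n_years, n_indicators)
        The clipped matrix actually aggregated.
    warnings_ : tuple of EarlyWarning
    """

    def __init__(
        self,
        prior0: float = 0.5,
        chain: bool = True,
        discount: float = 1.0,
        clip_eps: float = 1e-9,
        warning_threshold: float = 0.25,
        warning_k: int = 3,
    ):
        self.prior0 = prior0
        self.chain = chain
        self.discount = discount
        self.clip_eps = clip_eps
        self.warning_threshold = warning_threshold
        self.warning_k = warning_k

    def fit(self, X, y=None, *, times=None, indicator_ids=None):
        """Run the sequential update over the rows (years) of X."""
        if not 0.0 < self.prior0 < 1.0:
            raise ValueError(f"prior0 must be in (0, 1), got {self.prior0}")
        if not 0.0 <= self.discount <= 1.0:
            raise ValueError("discount must be in [0, 1]")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a (n_years, n_indicators) matrix")
        if np.any(~np.isfinite(X)) or np.any((X < 0) | (X > 1)):
            raise ValueError("likelihoods must be finite and in [0, 1]")
        n_years, n_ind = X.shape
        self.times_ = tuple(range(n_years)) if times is None else tuple(times)
        if len(self.times_) != n_years:
            raise ValueError("times length must match rows of X")
        self.indicator_ids_ = (
            tuple(f"X{i + 1}" for i in range(n_ind))
            if indicator_ids is None
            else tuple(indicator_ids)
        )
        self.likelihoods_ = clip_probability(X, self.clip_eps)

        posterior = np.empty(n_years)
        prior_chain = np.empty(n_years)
        prior = self.prior0
        for t in range(n_years):
            prior_chain[t] = prior
            posterior[t] = posterior_ges(self.likelihoods_[t], prior)
            if self.chain:
                prior = self.discount * posterior[t] + (1.0 - self.discount) * 0.5
                # keep the chained prior strictly inside (0, 1)
                eps = max(self.clip_eps, np.finfo(float).tiny)
                prior = float(np.clip(prior, eps, 1.0 - eps))
            else:
                prior = self.prior0
        self.posterior_ = posterior
        self.prior_chain_ = prior_chain
        self.warnings_ = scan_warnings(
            self.likelihoods_,
            self.times_,
            self.indicator_ids_,
            threshold=self.warning_threshold,
            k=self.warning_k,
        )
        return self

    def predict_proba(self, X=None) -> np.ndarray:
        """Posterior P(GES) per fitted year (ignores X; sequential model)."""
        return self.posterior_

    def to_assessment(
        self,
        config: AggregationConfig | None = None,
        explained_variance: float | None = None,
    ) -> GESAssessment:
        return GESAssessment(
            times=self.times_,
            indicator_ids=self.indicator_ids_,
            posterior=tuple(float(x) for x in self.posterior_),
            prior_chain=tuple(float(x) for x in self.prior_chain_),
            likelihoods=self.likelihoods_,
            warnings=self.warnings_,
            explained_variance=explained_variance,
            config=config if config is not None else AggregationConfig(
                prior0=self.prior0, clip_eps=self.clip_eps, discount=self.discount,
                early_warning=EarlyWarningConfig(self.warning_threshold, self.warning_k),
            ),
        )


def scan_warnings(
    likelihoods: np.ndarray,
    times: Sequence[int],
    indicator_ids: Sequence[str],
    threshold: float = 0.25,
    k: int = 3,
) -> tuple[EarlyWarning, ...]:
    """Flag maximal runs of >= k years with p < threshold or p > 1-threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    L = np.asarray(likelihoods, dtype=float)
    n_years = L.shape[0]
    if k > n_years:
        logger.info(
            "early-warning run length k=%d exceeds the %d assessed years; no flags",
            k, n_years,
        )
        return ()
    times = list(times)
    flags: list[EarlyWarning] = []
    for j, ind in enumerate(indicator_ids):
        for side, mask in (
            ("low", L[:, j] < threshold),
            ("high", L[:, j] > 1.0 - threshold),
        ):
            start = None
            for t in range(n_years + 1):
                active = t < n_years and mask[t]
                if active and start is None:
                    start = t
                elif not active and start is not None:
                    if t - start >= k:
                        flags.append(
                            EarlyWarning(
                                indicator_id=ind,
                                start=times[start],
                                end=times[t - 1],
                                side=side,
                                mean_p=float(np.mean(L[start:t, j])),
                            )
                        )
                    start = None
    flags.sort(key=lambda w: (w.start, w.indicator_id))
    return tuple(flags)


def early_warning(
    assessment: GESAssessment,
    threshold: float = 0.25,
    k: int = 3,
) -> tuple[EarlyWarning, ...]:
    """Re-scan a computed assessment's likelihood matrix for warning runs."""
    return scan_warnings(
        assessment.likelihoods, assessment.times, assessment.indicator_ids,
        threshold=threshold, k=k,
    )


def assess(
    indicator_set: IndicatorSet,
    config: AggregationConfig | None = None,
    *,
    years: Literal["common", "union"] = "common",
    explained_variance: float | None = None,
) -> GESAssessment:
    """Assess an indicator set: likelihoods, chained Bayes posterior, warnings.

    For each assessment year (the intersection of years available in every
    series by default) the per-indicator pass probabilities are computed
    from the annual means, SDs and targets, then aggregated with the
    chained-prior posterior. ``years="union"`` assesses every observed year
    instead; an indicator missing in a year contributes no factor that year
    (equivalent to uninformative evidence p=0.5) and is logged.
    """
    if config is None:
        config = AggregationConfig()
    if len(indicator_set) == 0:
        raise ValueError("indicator set is empty")
    for s in indicator_set:
        if s.target is None:
            raise ValueError(f"indicator {s.id!r} has no target; derive one first")

    assess_years = (
        indicator_set.common_times if years == "common" else indicator_set.all_times
    )
    if len(assess_years) == 0:
        raise ValueError("no common assessment years across indicators")

    profiles = {
        s.id: likelihood_profile(s, config.distribution, config.precaution)
        for s in indicator_set
    }
    n_years, n_ind = len(assess_years), len(indicator_set)
    L = np.full((n_years, n_ind), 0.5)
    for j, s in enumerate(indicator_set):
        prof = profiles[s.id]
        lookup = dict(zip(prof.times, prof.p_ges))
        for t, year in enumerate(assess_years):
            if year in lookup:
                L[t, j] = lookup[year]
            else:
                logger.warning(
                    "indicator %r has no observation in %d; contributes no evidence",
                    s.id, year,
                )

    est = GESBayesAssessor(
        prior0=config.prior0,
        discount=config.discount,
        clip_eps=config.clip_eps,
        warning_threshold=config.early_warning.threshold,
        warning_k=config.early_warning.k,
    ).fit(L, times=assess_years, indicator_ids=indicator_set.ids)
    return est.to_assessment(config=config, explained_variance=explained_variance)
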