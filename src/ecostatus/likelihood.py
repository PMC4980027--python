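"""Per-indicator, per-year probability of passing the target.

Because the assessment question is censored — an indicator either passes or
fails its target — the likelihood of good status uses the cumulative
distribution function of the sampling distribution of the annual mean, not
the density: the likelihood of GES contributed by one indicator in one year
is the probability mass on the good side of the target. A mean sitting
exactly on the target under a symmetric sampling distribution contributes
probability 0.5, i.e. no evidence either way.

Precautionary target setting is implemented as a shift of the effective
target by a multiple of the sampling SD toward the bad side, so that passing
requires stronger evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import norm

from .indicators import Direction, IndicatorSeries

Distribution = Literal["normal", "lognormal", "degenerate"]

#: Default clipping bound keeping likelihoods away from 0/1 so that the
#: Bayes recursion can never be absorbed at certainty by a single year.
CLIP_EPS = 1e-9


def clip_probability(p, eps: float = CLIP_EPS):
    """Clip probabilities into [eps, 1-eps] before aggregation."""
    return np.clip(p, eps, 1.0 - eps)


def ges_likelihood(
    mean: float,
    sd: float,
    target: float,
    direction: Direction = "higher_is_better",
    distribution: Distribution = "normal",
) -> float:
    """Probability that the indicator is on the good side of its target.

    Parameters
    ----------
    mean, sd : float
        Annual mean and its sampling standard deviation. ``sd=0`` collapses
        the sampling distribution to a point: the result is 1 if the mean is
        strictly on the good side, 0 on the bad side, and 0.5 exactly at the
        target (the no-evidence convention).
    target : float
        Target value S in indicator units.
    direction : {"higher_is_better", "lower_is_better"}
    distribution : {"normal", "lognormal", "degenerate"}
        Sampling distribution of the mean. ``lognormal`` (for positive,
        concentration-type indicators) treats the log value as
        Normal(log mean, sd/mean), preserving the 50%-at-target property.

    Returns
    -------
    float in [0, 1]
    """
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if not np.isfinite(mean) or not np.isfinite(target):
        raise ValueError("mean and target must be finite")
    if direction not in ("higher_is_better", "lower_is_better"):
        raise ValueError(f"unknown direction {direction!r}")

    if distribution == "lognormal":
        if mean <= 0 or target <= 0:
            raise ValueError("lognormal requires mean > 0 and target > 0")
        # delta method: CV of the mean becomes the SD on the log scale
        z_num, z_den = np.log(mean) - np.log(target), sd / mean
    elif distribution in ("normal", "degenerate"):
        z_num, z_den = mean - target, sd
    else:
        raise ValueError(f"unknown distribution {distribution!r}")

    if direction == "lower_is_better":
        z_num = -z_num

    if z_den == 0.0 or distribution == "degenerate":
        return 0.5 if z_num == 0.0 else (1.0 if z_num > 0 else 0.0)
    return float(norm.cdf(z_num / z_den))


@dataclass(frozen=True)
class LikelihoodProfile:
    """Per-year pass probabilities for one indicator."""

    indicator_id: str
    times: tuple[int, ...]
    p_ges: tuple[float, ...]
    distribution: Distribution = "normal"

    def __post_init__(self) -> None:
        if len(self.times) != len(self.p_ges):
            raise ValueError("times and p_ges lengths differ")
        if any(not 0.0 <= p <= 1.0 for p in self.p_ges):
            raise ValueError("p_ges values must lie in [0, 1]")


def likelihood_profile(
    series: IndicatorSeries,
    distribution: Distribution = "normal",
    precaution: float = 0.0,
    target: float | None = None,
) -> LikelihoodProfile:
    """Per-year pass probabilities for an indicator series.

    ``precaution`` (>= 0, in units of each year's sampling SD) shifts the
    effective target toward the bad side — upward for lower-is-better
    indicators, downward shifts never occur for the good side — so that
    ``precaution=1`` at mean==target yields Phi(-1) ~ 0.159 instead of 0.5.
    ``precaution=0`` reproduces :func:`ges_likelihood` verbatim.
    """
    if precaution < 0:
        raise ValueError(f"precaution must be >= 0, got {precaution}")
    t = series.target if target is None else target
    if t is None:
        raise ValueError(f"indicator {series.id!r} has no target")
    sign = 1.0 if series.direction == "higher_is_better" else -1.0
    ps = []
    for mean, sd in zip(series.means, series.sds):
        eff_target = t + sign * precaution * sd
        ps.append(ges_likelihood(mean, sd, eff_target, series.direction, distribution))
    return LikelihoodProfile(
        indicator_id=series.id,
        times=series.times,
        p_ges=tuple(ps),
        distribution=distribution,
    )
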