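"""Alternative aggregation rules and normalization transforms.

These exist for method comparison against the Bayesian index:

* one-out-all-out (OOAO) — the exclusive rule used in several European
  water-policy assessments: overall status fails if any single indicator
  fails. Its statistical cost is that the joint probability of confirming a
  genuinely good state is the *product* of the per-indicator pass
  probabilities, which decays geometrically with the number of indicators
  (an inflated type-II error).
* weighted additive utility — a normalized weighted mean of per-indicator
  value functions; requires commensurable inputs and a weighting judgment.
* element-wise normalization (z-score, ecological quality ratio, range) —
  with diagnostics, because these transforms change the statistical
  properties of the inputs (scale differences vanish, distributions change
  shape) in ways that matter for downstream aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .likelihood import CLIP_EPS, Distribution

AggregationMethod = Literal["bayes_additive", "ooao", "weighted_additive"]


@dataclass(frozen=True)
class EarlyWarningConfig:
    threshold: float = 0.25
    k: int = 3

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("early-warning threshold must be in (0, 1)")
        if self.k < 1:
            raise ValueError("early-warning run length k must be >= 1")


@dataclass(frozen=True)
class AggregationConfig:
    """Settings shared by the assessment pipeline.

    ``prior0`` is the initial prior probability of good status before any
    evidence; ``discount`` (lambda) optionally relaxes the chained prior
    toward 0.5 between assessment periods (lambda=1 keeps the plain
    posterior-to-prior chain). ``weights`` apply only to the
    weighted-additive comparison method; the Bayesian index applies none.
    """

    method: AggregationMethod = "bayes_additive"
    prior0: float = 0.5
    clip_eps: float = CLIP_EPS
    precaution: float = 0.0
    distribution: Distribution = "normal"
    discount: float = 1.0
    early_warning: EarlyWarningConfig = field(default_factory=EarlyWarningConfig)
    weights: dict[str, float] | None = None

    def __post_init__(self):
        if not 0.0 < self.prior0 < 1.0:
            raise ValueError(f"prior0 must be in (0, 1), got {self.prior0}")
        if not 0.0 <= self.clip_eps < 0.5:
            raise ValueError("clip_eps must be in [0, 0.5)")
        if self.precaution < 0:
            raise ValueError("precaution must be >= 0")
        if not 0.0 <= self.discount <= 1.0:
            raise ValueError("discount must be in [0, 1]")
        if self.weights is not None and any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be positive")


@dataclass(frozen=True)
class OOAOResult:
    verdict: bool
    joint_pass_probability: float


def ooao_verdict(p: Sequence[float]) -> OOAOResult:
    """One-out-all-out verdict and its joint pass probability.

    The verdict is deterministic mean-vs-target (pass only if every
    indicator's mean is on the good side, i.e. every ``p_i > 0.5``); the
    joint probability ``prod(p_i)`` quantifies the statistical cost of
    demanding that all indicators pass simultaneously.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("ooao_verdict requires at least one indicator")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("pass probabilities must lie in [0, 1]")
    return OOAOResult(verdict=bool(np.all(p > 0.5)), joint_pass_probability=float(np.prod(p)))


def type2_curve(n_max: int, p_each: float) -> np.ndarray:
    """Joint pass probability ``p_each**n`` for n = 1..n_max.

    Illustrates how the probability of confirming a true good state under
    the exclusive rule decays as indicators are added (type-II error
    inflation): strictly decreasing for ``p_each < 1``.
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    if not 0.0 < p_each <= 1.0:
        raise ValueError(f"p_each must be in (0, 1], got {p_each}")
    return p_each ** np.arange(1, n_max + 1, dtype=float)


def weighted_additive(
    values: Sequence[float],
    weights: Sequence[float] | None = None,
    value_functions: Sequence[Callable[[float], float]] | None = None,
) -> float:
    """Weight-normalized additive utility sum(w_i u_i(x_i)) / sum(w_i).

    ``value_functions`` map each raw indicator value onto a common [0, 1]
    utility scale; if omitted, ``values`` are assumed to already be
    utilities in [0, 1]. Equal (or omitted) weights reduce to the
    arithmetic mean.
    """
    values = list(values)
    n = len(values)
    if n == 0:
        raise ValueError("weighted_additive requires at least one indicator")
    if value_functions is not None:
        if len(value_functions) != n:
            raise ValueError("value_functions length must match values")
        values = [f(x) for f, x in zip(value_functions, values)]
    u = np.asarray(values, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("utilities must lie in [0, 1]; supply value_functions")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights length must match values")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    return float(np.sum(w * u) / np.sum(w))


@dataclass(frozen=True)
class NormalizationResult:
    values: np.ndarray
    method: str
    diagnostics: dict


def normalize(
    x: Sequence[float],
    method: Literal["zscore", "eqr", "range"],
    reference: float | None = None,
) -> NormalizationResult:
    """Normalize a series and report how the transform changed it.

    * ``zscore``: (x - mean)/sd with the n-1 sample SD; output has sample
      mean 0 and SD 1, which erases any scale difference between series.
    * ``eqr``: x/reference (ecological-quality-ratio style); the reference
      value maps to exactly 1 and the data become ratio-scaled.
    * ``range``: (x - min)/(max - min) onto [0, 1]; compresses the
      distribution toward uniform over the observed span.

    Diagnostics record pre/post mean and SD plus a note on the shape change,
    because normalization manufactures new data properties that downstream
    additive aggregation will inherit.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("normalize expects a non-empty 1-D series")
    pre_mean = float(np.mean(x))
    pre_sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    if method == "zscore":
        if x.size < 2 or np.all(x == x[0]):
            raise ValueError("zscore needs >= 2 distinct values")
        out = (x - pre_mean) / pre_sd
        note = "scale and location removed; series on different scales become identical"
    elif method == "eqr":
        if reference is None or reference == 0:
            raise ValueError("eqr needs a nonzero reference value")
        out = x / float(reference)
        note = "interval scale changed to ratio scale; reference maps to 1"
    elif method == "range":
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi == lo:
            raise ValueError("range normalization needs non-constant values")
        out = (x - lo) / (hi - lo)
        note = "distribution compressed toward uniform on [0, 1]"
    else:
        raise ValueError(f"unknown normalization method {method!r}")

    post_sd = float(np.std(out, ddof=1)) if out.size > 1 else 0.0
    return NormalizationResult(
        values=out,
        method=method,
        diagnostics={
            "pre_mean": pre_mean,
            "pre_sd": pre_sd,
            "post_mean": float(np.mean(out)),
            "post_sd": post_sd,
            "shape_note": note,
        },
    )
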