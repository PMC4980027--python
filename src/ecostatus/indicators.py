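"""Indicator time series, indicator sets, and target-setting procedures.

An indicator is a monitored ecosystem variable (a contaminant concentration,
a fish-community metric, a breeding-success rate, ...) observed as a time
series of annual means with a sampling standard deviation, together with a
policy target and a direction stating which side of the target is "good".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Direction = Literal["higher_is_better", "lower_is_better"]
TargetBasis = Literal["fixed", "percentile", "proxy"]

_DIRECTIONS = ("higher_is_better", "lower_is_better")


@dataclass(frozen=True)
class IndicatorSeries:
    """One monitored indicator: annual means with sampling SDs and a target.

    Parameters
    ----------
    id : str
        Short unique identifier (e.g. ``"LFI"``).
    times : sequence of int
        Strictly increasing observation years.
    means : sequence of float
        Mean indicator value per year, in indicator units.
    sds : sequence of float
        Sampling standard deviation of each mean (same units); 0 means the
        mean is known exactly and the pass/fail likelihood degenerates to a
        step function.
    direction : {"higher_is_better", "lower_is_better"}
        Which side of the target counts as good status.
    target : float, optional
        Target value S in indicator units; may be set later via
        :func:`derive_target`.
    target_basis : {"fixed", "percentile", "proxy"}
        How the target was obtained. Proxy targets (converted from a related
        substance's target) are accepted only as user-supplied fixed values.
    """

    id: str
    times: tuple[int, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    direction: Direction = "higher_is_better"
    target: float | None = None
    target_basis: TargetBasis = "fixed"
    label: str = ""
    group: str = ""
    unit: str = ""

    def __post_init__(self) -> None:
        times = tuple(int(t) for t in self.times)
        means = tuple(float(m) for m in self.means)
        sds = tuple(float(s) for s in self.sds)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        if not self.id:
            raise ValueError("indicator id must be non-empty")
        if not (len(times) == len(means) == len(sds)):
            raise ValueError(
                f"indicator {self.id!r}: times/means/sds lengths differ "
                f"({len(times)}/{len(means)}/{len(sds)})"
            )
        if len(times) == 0:
            raise ValueError(f"indicator {self.id!r}: empty series")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"indicator {self.id!r}: times must be strictly increasing")
        if not all(np.isfinite(means)):
            raise ValueError(f"indicator {self.id!r}: non-finite mean")
        if any(s < 0 or not np.isfinite(s) for s in sds):
            raise ValueError(f"indicator {self.id!r}: sds must be finite and >= 0")
        if self.direction not in _DIRECTIONS:
            raise ValueError(
                f"indicator {self.id!r}: direction must be one of {_DIRECTIONS}"
            )
        if self.target is not None and not np.isfinite(self.target):
            raise ValueError(f"indicator {self.id!r}: target must be finite")

    def __len__(self) -> int:
        return len(self.times)

    def at(self, year: int) -> tuple[float, float]:
        """Return ``(mean, sd)`` observed in *year*."""
        try:
            i = self.times.index(int(year))
        except ValueError:
            raise KeyError(f"indicator {self.id!r} has no observation for year {year}")
        return self.means[i], self.sds[i]

    def with_target(self, target: float, basis: TargetBasis = "fixed") -> "IndicatorSeries":
        return replace(self, target=float(target), target_basis=basis)


@dataclass(frozen=True)
class IndicatorSet:
    """An ordered collection of indicator series with unique ids."""

    series: tuple[IndicatorSeries, ...]

    def __post_init__(self) -> None:
        series = tuple(self.series)
        object.__setattr__(self, "series", series)
        ids = [s.id for s in series]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate indicator ids: {dupes}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.series)

    @property
    def common_times(self) -> tuple[int, ...]:
        """Years present in every series (sorted ascending)."""
        if not self.series:
            return ()
        common = set(self.series[0].times)
        for s in self.series[1:]:
            common &= set(s.times)
        return tuple(sorted(common))

    @property
    def all_times(self) -> tuple[int, ...]:
        """Union of years over all series (sorted ascending)."""
        years: set[int] = set()
        for s in self.series:
            years.update(s.times)
        return tuple(sorted(years))

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    def __getitem__(self, indicator_id: str) -> IndicatorSeries:
        for s in self.series:
            if s.id == indicator_id:
                return s
        raise KeyError(indicator_id)


def derive_target(
    series: IndicatorSeries,
    method: Literal["percentile", "fixed"] = "percentile",
    *,
    percentile_q: float = 0.5,
    fixed_value: float | None = None,
) -> float:
    """Derive a target value S for an indicator series.

    ``method="percentile"`` takes a percentile of the observed means (linear
    interpolation between order statistics), a pragmatic target-setting
    convention for series without an externally mandated objective. The
    percentile is taken on the raw value scale regardless of direction.
    ``method="fixed"`` passes ``fixed_value`` through (e.g. the LFI EcoQO
    target 0.485).

    Returns the target in indicator units; does not modify *series*.
    """
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("method='fixed' requires fixed_value")
        if not np.isfinite(fixed_value):
            raise ValueError("fixed_value must be finite")
        return float(fixed_value)
    if method != "percentile":
        raise ValueError(f"unknown target method {method!r}")
    if not 0.0 < percentile_q < 1.0:
        raise ValueError(f"percentile_q must be in (0, 1), got {percentile_q}")
    if len(series) < 2:
        raise ValueError(
            f"indicator {series.id!r}: percentile target needs >= 2 time points"
        )
    return float(np.quantile(np.asarray(series.means), percentile_q))


def build_series(
    id: str,
    times: Iterable[int],
    means: Sequence[float],
    sds: Sequence[float] | float,
    **kwargs,
) -> IndicatorSeries:
    """Convenience constructor; a scalar ``sds`` is broadcast to all years."""
    means = tuple(float(m) for m in means)
    if np.isscalar(sds):
        sds = (float(sds),) * len(means)
    return IndicatorSeries(id=id, times=tuple(times), means=means, sds=tuple(sds), **kwargs)
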