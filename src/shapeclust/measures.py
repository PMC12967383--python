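"""Shape-based proximity between yearly incidence-rate curves.

The core dissimilarity between two series X = [x_1, ..., x_k] and
Y = [y_1, ..., y_k] observed on the same yearly axis is

    D(X, Y) = (1/k) * sum_i [ d(x_i, y_i) - d(T(X), T(Y)) ],

a Riemann-sum discretization of the analogous integral over curves.  With
the default kernels -- squared distance d(a, b) = (a - b)^2 and the mean as
location T -- this equals the population variance of the pointwise
difference series x - y, so it is non-negative, symmetric, and exactly zero
whenever Y = X + b for any constant b (vertical-shift invariance).

Standardizing each series to zero mean and unit population SD before
computing D extends the invariance to Y = aX + b with a > 0, so that
clustering reflects the *shape* of an incidence trend rather than how
common the cancer is.  On standardized input D reduces to 2(1 - r) with r
the Pearson correlation of the raw curves; that identity is exploited only
as an independent test oracle, never as the implementation.

Alternative kernels (absolute distance, median location, MAD scatter) are
supported but carry no non-negativity guarantee; a negative proximity is
returned unmodified with a warning.

Scatter uses the *population* convention (divide by k, not k - 1)
throughout.  This differs from numpy/pandas ``std`` defaults elsewhere
(``ddof=0`` here, always).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import (
    AxisMismatchError,
    ConstantSeriesError,
    UnknownLabelError,
)

__all__ = [
    "TimeSeries",
    "StandardizedSeries",
    "KernelConfig",
    "DEFAULT_KERNEL",
    "SeriesPanel",
    "standardize",
    "shape_distance",
    "pairwise_distance_matrix",
]

#: relative tolerance below which a scatter value counts as zero
ZERO_SCATTER_RTOL = 1e-12


@dataclass(frozen=True)
class TimeSeries:
    """One site's yearly rate curve: values per 100,000 person-years on a
    strictly consecutive integer year axis (k >= 2 points)."""

    site: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or values.ndim != 1:
            raise ValueError("years and values must be one-dimensional")
        if len(years) != len(values):
            raise ValueError(
                f"series {self.site!r}: {len(years)} years but {len(values)} values"
            )
        if len(years) < 2:
            raise ValueError(f"series {self.site!r}: need at least 2 points")
        if not np.all(np.diff(years) == 1):
            raise ValueError(
                f"series {self.site!r}: years must be strictly consecutive"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"series {self.site!r}: values must be finite")

    @property
    def k(self) -> int:
        return len(self.values)

    def same_axis(self, other: "TimeSeries") -> bool:
        return self.k == other.k and bool(np.array_equal(self.years, other.years))

    def shifted(self, b: float) -> "TimeSeries":
        return TimeSeries(self.site, self.years, self.values + b)


@dataclass(frozen=True)
class StandardizedSeries(TimeSeries):
    """A :class:`TimeSeries` after location/scale standardization.

    ``source_mean`` and ``source_scatter`` record the location T(X) and
    scatter s(X) of the raw series, so the raw curve is recoverable as
    ``values * source_scatter + source_mean``.
    """

    source_mean: float = 0.0
    source_scatter: float = 1.0


Distance = Literal["squared", "absolute"]
Location = Literal["mean", "median"]
Scatter = Literal["sd_population", "mad"]


@dataclass(frozen=True)
class KernelConfig:
    """Choice of the one-dimensional distance d, location T and scatter s.

    The default (squared, mean, sd_population) is the combination whose
    shift/scale invariance properties are proven; alternatives are provided
    for robustness experiments and carry no such guarantee.
    """

    distance: Distance = "squared"
    location: Location = "mean"
    scatter: Scatter = "sd_population"

    def __post_init__(self):
        if self.distance not in ("squared", "absolute"):
            raise ValueError(f"unknown distance kernel {self.distance!r}")
        if self.location not in ("mean", "median"):
            raise ValueError(f"unknown location kernel {self.location!r}")
        if self.scatter not in ("sd_population", "mad"):
            raise ValueError(f"unknown scatter kernel {self.scatter!r}")

    @property
    def is_default(self) -> bool:
        return (self.distance, self.location, self.scatter) == (
            "squared",
            "mean",
            "sd_population",
        )

    def d(self, a: np.ndarray | float, b: np.ndarray | float):
        if self.distance == "squared":
            return (np.asarray(a) - np.asarray(b)) ** 2
        return np.abs(np.asarray(a) - np.asarray(b))

    def T(self, x: np.ndarray) -> float:
        return float(np.mean(x)) if self.location == "mean" else float(np.median(x))

    def s(self, x: np.ndarray) -> float:
        if self.scatter == "sd_population":
            return float(np.std(x, ddof=0))
        return float(np.median(np.abs(x - np.median(x))))


DEFAULT_KERNEL = KernelConfig()


@dataclass
class SeriesPanel:
    """The curves of one sex x age-group subgroup on a common year axis."""

    members: list[TimeSeries]
    sex: str | None = None
    age_group: str | None = None
    years: np.ndarray = field(init=False)

    def __post_init__(self):
        if not self.members:
            raise ValueError("panel needs at least one series")
        axis = self.members[0].years
        for ts in self.members[1:]:
            if not np.array_equal(ts.years, axis):
                raise AxisMismatchError(
                    f"series {ts.site!r} is not on the panel's year axis"
                )
        sites = [ts.site for ts in self.members]
        if len(set(sites)) != len(sites):
            raise ValueError("panel sites must be unique")
        self.years = axis

    @property
    def sites(self) -> list[str]:
        return [ts.site for ts in self.members]

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def get(self, site: str) -> TimeSeries:
        for ts in self.members:
            if ts.site == site:
                return ts
        raise UnknownLabelError(f"site {site!r} not in panel")


def standardize(
    series: TimeSeries, kernel: KernelConfig = DEFAULT_KERNEL
) -> StandardizedSeries:
    """Standardize a series to x̂_i = (x_i - T(X)) / s(X).

    With the default kernel this yields zero mean and unit *population*
    variance.  Raises :class:`ConstantSeriesError` when s(X) is numerically
    zero (the series carries no shape information at this scale).
    """
    loc = kernel.T(series.values)
    sca = kernel.s(series.values)
    if sca < ZERO_SCATTER_RTOL * max(1.0, abs(loc)):
        raise ConstantSeriesError(series.site, sca)
    return StandardizedSeries(
        site=series.site,
        years=series.years,
        values=(series.values - loc) / sca,
        source_mean=loc,
        source_scatter=sca,
    )


def shape_distance(
    x: TimeSeries, y: TimeSeries, kernel: KernelConfig = DEFAULT_KERNEL
) -> float:
    """Proximity D(X, Y) = (1/k) Σ_i [d(x_i, y_i) - d(T(X), T(Y))].

    Requires an identical year axis (no implicit alignment).  With the
    default kernel the value is >= 0 and symmetric; with non-default
    kernels a negative value can occur and is returned as-is with a
    :class:`UserWarning`.
    """
    if not x.same_axis(y):
        raise AxisMismatchError(
            f"series {x.site!r} and {y.site!r} have different year axes; "
            "align them before computing a distance"
        )
    pointwise = kernel.d(x.values, y.values)
    center = float(kernel.d(kernel.T(x.values), kernel.T(y.values)))
    value = float(np.mean(pointwise) - center)
    if value < 0 and not kernel.is_default:
        warnings.warn(
            f"negative proximity {value:.6g} between {x.site!r} and {y.site!r} "
            f"under kernel {kernel}; non-default kernels do not guarantee "
            "non-negativity",
            stacklevel=2,
        )
    return value


def pairwise_distance_matrix(
    panel: SeriesPanel | Sequence[TimeSeries] | Iterable[TimeSeries],
    kernel: KernelConfig = DEFAULT_KERNEL,
    standardized: bool = False,
):
    """All pairwise shape distances over a panel, as a DistanceMatrix.

    When ``standardized`` is true every series is standardized (per series,
    over its full span) first; a constant series aborts the whole matrix
    with :class:`ConstantSeriesError` naming the site.
    """
    from .clustering import DistanceMatrix  # local import avoids a cycle

    members = list(panel.members if isinstance(panel, SeriesPanel) else panel)
    if standardized:
        members = [standardize(ts, kernel) for ts in members]
    n = len(members)
    values = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            dij = shape_distance(members[i], members[j], kernel)
            values[i, j] = values[j, i] = dij
    return DistanceMatrix(labels=[ts.site for ts in members], values=values)
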