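"""Structure function computation and scaling-exponent fitting.

The temporal structure function of order q at scale tau is

    S_q(tau) = < |I_t - I_{t+tau}|^q >,

the average of the absolute lag-tau increments raised to the power q.
Exactly n - tau differences enter the average at each scale. When
S_q(tau) follows a power law tau^zeta(q), the exponent zeta is the slope
of the log-log regression of S against tau.

Scales are integer lags in sample counts: for an ISI series, tau counts
intervals, not physical time. By convention S(tau) is normalized by its
value at the smallest scale, so every normalized function starts at
S(1) = 1 when tau_min = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import (
    DegenerateSignalError,
    InsufficientDataError,
    ParameterError,
    ScaleRangeError,
    ValidationError,
)
from .signal_io import TimeSeries

__all__ = [
    "ScaleRange",
    "OrderRange",
    "StructureFunction",
    "ScalingFit",
    "default_scale_range",
    "structure_function",
    "structure_function_multi",
    "normalize_sf",
    "fit_scaling_exponent",
]


@dataclass(frozen=True)
class ScaleRange:
    """Inclusive range of integer scales [tau_min, tau_max], in samples."""

    tau_min: int
    tau_max: int

    def __post_init__(self):
        if int(self.tau_min) != self.tau_min or int(self.tau_max) != self.tau_max:
            raise ParameterError("scales must be integers")
        object.__setattr__(self, "tau_min", int(self.tau_min))
        object.__setattr__(self, "tau_max", int(self.tau_max))
        if not (1 <= self.tau_min <= self.tau_max):
            raise ParameterError(
                f"need 1 <= tau_min <= tau_max, got [{self.tau_min}, {self.tau_max}]"
            )

    def taus(self) -> np.ndarray:
        return np.arange(self.tau_min, self.tau_max + 1)

    def __contains__(self, tau) -> bool:
        return self.tau_min <= tau <= self.tau_max


@dataclass(frozen=True)
class OrderRange:
    """Range of structure-function orders [q_min, q_max] with a step."""

    q_min: float
    q_max: float
    q_step: float = 1.0

    def __post_init__(self):
        if self.q_min <= 0 or self.q_max < self.q_min:
            raise ParameterError("need 0 < q_min <= q_max")
        if self.q_step <= 0:
            raise ParameterError("q_step must be positive")

    def orders(self) -> np.ndarray:
        n = int(np.floor((self.q_max - self.q_min) / self.q_step + 1e-9)) + 1
        return self.q_min + self.q_step * np.arange(n)


@dataclass(frozen=True)
class StructureFunction:
    """S_q(tau) on an increasing integer scale grid for one order q."""

    taus: np.ndarray
    values: np.ndarray
    order: float
    normalized: bool
    n_diffs: np.ndarray  # number of differences averaged at each scale: n - tau
    label: str = ""

    def __post_init__(self):
        taus = np.asarray(self.taus, dtype=int)
        values = np.asarray(self.values, dtype=float)
        n_diffs = np.asarray(self.n_diffs, dtype=int)
        object.__setattr__(self, "taus", taus)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "n_diffs", n_diffs)
        if not (taus.shape == values.shape == n_diffs.shape):
            raise ValidationError("taus, values and n_diffs must have equal length")
        if taus.size and np.any(np.diff(taus) <= 0):
            raise ValidationError("scales must be strictly increasing")
        if np.any(values < 0):
            raise ValidationError("structure-function values must be non-negative")

    @property
    def tau_min(self) -> int:
        return int(self.taus[0])

    @property
    def tau_max(self) -> int:
        return int(self.taus[-1])

    def value_at(self, tau: int) -> float:
        idx = np.searchsorted(self.taus, tau)
        if idx >= self.taus.size or self.taus[idx] != tau:
            raise ScaleRangeError(f"scale {tau} not on the computed grid")
        return float(self.values[idx])


@dataclass(frozen=True)
class ScalingFit:
    """Result of a slope fit to S(tau) vs tau.

    ``zeta`` is the scaling exponent when ``space == "log"`` (slope of
    log10 S against log10 tau); with ``space == "linear"`` it is the raw
    linear-regression slope of S against tau.
    """

    zeta: float
    intercept: float
    fit_range: ScaleRange
    r_squared: float
    space: str = "log"


def _as_values(series) -> np.ndarray:
    if isinstance(series, TimeSeries):
        return series.values
    return np.asarray(series, dtype=float)


def default_scale_range(n: int, tau_max_cap: int = 1000) -> ScaleRange:
    """Default scales tau in [1, min(cap, n // 10)].

    Large scale ranges (up to ~1000) are of interest to capture both short
    and long term dynamics; the n/10 cap keeps at least 90% of the pairs
    contributing at every scale.
    """
    tau_max = min(tau_max_cap, n // 10)
    if tau_max < 1:
        raise InsufficientDataError(f"series of length {n} too short for any scale")
    return ScaleRange(1, tau_max)


def structure_function(series, scales: ScaleRange | None = None,
                       order: float = 1.0) -> StructureFunction:
    """Compute the (un-normalized) structure function S_q(tau).

    For each scale tau in ``scales``, averages |I_t - I_{t+tau}|^q over the
    n - tau available pairs. Default order is q = 1; default scales are
    :func:`default_scale_range` of the series length.

    Parameters
    ----------
    series
        A :class:`~tempsf.signal_io.TimeSeries` or 1-d array.
    scales
        Integer scale range; ``tau_max`` must be smaller than the series
        length so at least one difference exists per scale.
    order
        Positive moment order q.
    """
    values = _as_values(series)
    n = values.size
    if n < 2:
        raise InsufficientDataError("need at least 2 samples")
    if scales is None:
        scales = default_scale_range(n)
    if scales.tau_max >= n:
        raise ScaleRangeError(
            f"tau_max={scales.tau_max} must be < series length n={n}"
        )
    if order <= 0:
        raise ParameterError(f"order q must be positive, got {order}")

    taus = scales.taus()
    s = np.empty(taus.size)
    for i, tau in enumerate(taus):
        diffs = np.abs(values[: n - tau] - values[tau:])
        if order != 1.0:
            diffs = diffs ** order
        s[i] = diffs.mean()
    label = series.label if isinstance(series, TimeSeries) else ""
    return StructureFunction(taus=taus, values=s, order=float(order),
                             normalized=False, n_diffs=n - taus, label=label)


def structure_function_multi(series, scales: ScaleRange | None = None,
                             orders: OrderRange | None = None
                             ) -> list[StructureFunction]:
    """Structure functions for a range of orders on one shared scale grid."""
    if orders is None:
        orders = OrderRange(1.0, 1.0)
    return [structure_function(series, scales=scales, order=q)
            for q in orders.orders()]


def normalize_sf(sf: StructureFunction) -> StructureFunction:
    """Divide S(tau) by its value at the smallest scale, so it starts at 1.

    Raises :class:`DegenerateSignalError` when the initial value is zero
    (a constant series) and :class:`ValidationError` when the input is
    already normalized — double normalization is almost always a bug.
    """
    if sf.normalized:
        raise ValidationError("structure function is already normalized")
    s0 = sf.values[0]
    if s0 == 0:
        raise DegenerateSignalError(
            "S at the smallest scale is zero; the signal is constant at lag "
            f"{sf.tau_min} and cannot be normalized"
        )
    return replace(sf, values=sf.values / s0, normalized=True)


def fit_scaling_exponent(sf: StructureFunction,
                         fit_range: ScaleRange | None = None,
                         space: str = "log",
                         drop_zeros: bool = False) -> ScalingFit:
    """Fit the slope of the structure function over a scale sub-range.

    With ``space="log"`` (default) this is the ordinary least-squares fit
    of log10 S against log10 tau, whose slope is the scaling exponent
    zeta(q). ``space="linear"`` fits S against tau directly — the
    convention under which the mean slope of random and oscillatory
    signals sits numerically at zero.

    Zero S values are an error in log space (they signal degenerate
    input) unless ``drop_zeros`` explicitly excludes them.
    """
    if fit_range is None:
        fit_range = ScaleRange(sf.tau_min, sf.tau_max)
    mask = (sf.taus >= fit_range.tau_min) & (sf.taus <= fit_range.tau_max)
    taus = sf.taus[mask].astype(float)
    s = sf.values[mask]
    if space not in ("log", "linear"):
        raise ParameterError(f"space must be 'log' or 'linear', got {space!r}")
    if space == "log":
        if np.any(s == 0):
            if drop_zeros:
                keep = s > 0
                taus, s = taus[keep], s[keep]
            else:
                raise DegenerateSignalError(
                    "S(tau)=0 inside the fit range; zeros are excluded only "
                    "when drop_zeros=True"
                )
        x, y = np.log10(taus), np.log10(s)
    else:
        x, y = taus, s
    if x.size < 3:
        raise InsufficientDataError(
            f"need at least 3 points for a slope fit, got {x.size}"
        )
    res = stats.linregress(x, y)
    r2 = float(res.rvalue ** 2) if np.std(y) > 0 else 1.0
    return ScalingFit(zeta=float(res.slope), intercept=float(res.intercept),
                      fit_range=fit_range, r_squared=r2, space=space)
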