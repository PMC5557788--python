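"""Interpretive statistics of a normalized structure function.

Three shapes matter in practice. A flat (zero-slope) S(tau) at every
scale indicates randomness: the ordering of the samples carries no
information beyond their amplitude distribution. A bounded, oscillating
S(tau) reflects a periodic component, whose frequency can be recovered
when the sampling rate is known. A positive slope at small scales that
breaks into a plateau is the signature of nonlinear temporal
organization: the breakpoint tau_1 marks the memory limit of the system,
and the plateau height S_p tracks the power of the random component
(additive noise lowers the normalized plateau but leaves tau_1 in place).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    InsufficientDataError,
    IncompatibilityError,
    ParameterError,
    ScaleRangeError,
    ValidationError,
)
from .sfcore import (
    ScaleRange,
    ScalingFit,
    StructureFunction,
    fit_scaling_exponent,
)

__all__ = [
    "BreakpointResult",
    "PlateauSummary",
    "OscillationResult",
    "SignalCharacterization",
    "ClassifierThresholds",
    "DEFAULT_SP_WINDOW",
    "detect_breakpoint",
    "plateau_height",
    "plateau_delta",
    "estimate_oscillation",
    "classify_signal",
]

#: Plateau window 100 < tau < 200 (open interval, integer scales 101..199).
DEFAULT_SP_WINDOW = ScaleRange(100, 200)


@dataclass(frozen=True)
class BreakpointResult:
    """Outcome of the two-segment (rise, then plateau) breakpoint search.

    ``tau1`` is None when no breakpoint was accepted; the remaining fields
    then describe the best candidate, for diagnostics. ``slope_post`` is
    zero by construction: the post-breakpoint segment is a plateau.
    """

    tau1: int | None
    slope_pre: float
    slope_post: float
    sse: float
    sse_single: float
    r2_pre: float

    @property
    def present(self) -> bool:
        return self.tau1 is not None


@dataclass(frozen=True)
class PlateauSummary:
    """Plateau height S_p: mean normalized S over an open scale window."""

    sp: float
    window: ScaleRange


@dataclass(frozen=True)
class OscillationResult:
    """Dominant periodicity of S(tau).

    ``omega_sf`` is in cycles per unit scale; when the spectral peak is
    significant, the original signal frequency is recovered as
    ``omega_signal = omega_sf * samp`` (the structure function oscillates
    ``samp`` times slower than the signal, in scale units).
    """

    omega_sf: float
    omega_signal: float | None
    samp: float
    significant: bool
    peak_power: float
    median_power: float


@dataclass(frozen=True)
class ClassifierThresholds:
    """Tunable thresholds of the random/oscillatory/nonlinear decision rule.

    Defaults are calibrated so the three reference toy systems (Gaussian
    noise, noisy sinusoid, Lorenz x-variable) classify correctly.
    """

    slope_pre_min: float = 0.05     # minimum pre-breakpoint log-log slope
    r2_pre_min: float = 0.8         # minimum R^2 of the rising segment
    zeta_random_max: float = 0.02   # |zeta| below which a flat SF reads random
    bp_sse_ratio: float = 0.9       # segmented SSE must beat this x single-line SSE
    osc_power_factor: float = 50.0  # peak power must exceed this x median power


@dataclass(frozen=True)
class SignalCharacterization:
    """Bundle of all SF statistics plus a primary class label.

    The label is one of ``random``, ``oscillatory`` or ``nonlinear``; the
    ``flags`` record each feature independently, since real neurons can
    show more than one (an oscillating SF on top of a rising trend, say).
    """

    label: str
    breakpoint: BreakpointResult
    plateau: PlateauSummary | None
    oscillation: OscillationResult
    mean_slope: ScalingFit
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-friendly summary of the characterization."""
        return {
            "label": self.label,
            "tau1": self.breakpoint.tau1,
            "slope_pre": self.breakpoint.slope_pre,
            "sp": None if self.plateau is None else self.plateau.sp,
            "sp_window": None if self.plateau is None
            else [self.plateau.window.tau_min, self.plateau.window.tau_max],
            "omega_signal": self.oscillation.omega_signal,
            "mean_zeta": self.mean_slope.zeta,
            "flags": dict(self.flags),
        }


def _require_normalized(sf: StructureFunction, op: str) -> None:
    if not sf.normalized:
        raise ValidationError(f"{op} expects a normalized structure function")


def _ascent_end(x: np.ndarray, y: np.ndarray, plateau_slope: float,
                n_grid: int, smooth_window: int) -> float | None:
    """Scale (not log) where the first ascent of S ends: the smoothed
    log-log slope decays below ``plateau_slope`` for the first time after
    first exceeding it.

    The curve is resampled on a uniform log grid and differentiated with
    a quadratic Savitzky-Golay filter; the crossing is interpolated
    between grid points. Anchoring on the first ascent, rather than on
    the global slope maximum, keeps the estimate on the initial rise even
    when post-plateau oscillations or filter edge effects produce larger
    slopes at late scales. Returns None when the slope never rises or
    never decays below the threshold.
    """
    xg = np.linspace(x[0], x[-1], n_grid)
    yg = np.interp(xg, x, y)
    dx = xg[1] - xg[0]
    dy = savgol_filter(yg, smooth_window, 2, deriv=1, delta=dx)
    above = np.flatnonzero(dy > plateau_slope)
    if above.size == 0:
        return None
    rise = int(above[0])
    below = np.flatnonzero(dy[rise:] < plateau_slope)
    if below.size == 0:
        return None
    j = rise + below[0]
    frac = 0.0
    if dy[j - 1] != dy[j]:
        frac = (dy[j - 1] - plateau_slope) / (dy[j - 1] - dy[j])
    return float(10 ** (xg[j - 1] + frac * dx))


def detect_breakpoint(sf: StructureFunction, margin: int = 5,
                      sse_ratio: float = 0.9, method: str = "slope",
                      plateau_slope: float = 0.1, n_grid: int = 300,
                      smooth_window: int = 21) -> BreakpointResult:
    """Locate the scale tau_1 where a rising S(tau) breaks into a plateau.

    Whether a breakpoint exists at all is decided by a continuous
    two-segment least-squares fit in (log10 tau, log10 S) — a free slope
    below the breakpoint, a zero slope (plateau) above it — searched
    exhaustively over all scales in ``[tau_min + margin, tau_max -
    margin]``. The segmented morphology is accepted only when its total
    squared error is below ``sse_ratio`` times that of a single straight
    line; otherwise no breakpoint is reported (a pure power law or a flat
    function has no interior slope change to find). The pre-breakpoint
    slope and its segment R^2 always come from this fit.

    Where tau_1 is placed once a breakpoint is accepted depends on
    ``method``:

    * ``"slope"`` (default) — the scale where the smoothed local log-log
      slope of S, after peaking, first decays below ``plateau_slope``:
      the end of the ascending phase. This locator barely moves when
      noise is added to the signal, matching the known noise robustness
      of the breakpoint, because it is referenced to where the curve
      actually flattens rather than to a global fit. Its resolution is
      set by the derivative smoothing window (about 0.07 decades in tau
      at the defaults), so a perfectly sharp corner is reported slightly
      late — within that window.
    * ``"hinge"`` — the corner of the best two-segment fit itself. Exact
      on idealized sharp-corner functions, but it drifts to larger
      scales when additive noise flattens the small-scale portion of the
      curve.
    """
    _require_normalized(sf, "detect_breakpoint")
    if sf.taus.size < 20:
        raise InsufficientDataError(
            f"breakpoint detection needs >= 20 scales, got {sf.taus.size}"
        )
    if np.any(sf.values <= 0):
        raise ValidationError("breakpoint detection requires strictly positive S")
    if method not in ("slope", "hinge"):
        raise ParameterError(f"method must be 'slope' or 'hinge', got {method!r}")

    x = np.log10(sf.taus.astype(float))
    y = np.log10(sf.values)
    m = x.size

    # single-line reference fit
    X = np.column_stack([np.ones(m), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse_single = float(np.sum((y - X @ coef) ** 2))

    lo = sf.tau_min + margin
    hi = sf.tau_max - margin
    cand = np.flatnonzero((sf.taus >= lo) & (sf.taus <= hi))
    if cand.size == 0:
        raise InsufficientDataError("margin leaves no candidate breakpoints")

    idx = np.arange(m)
    best = None
    for k in cand:
        # hinge regressor: (x - x_k) below the breakpoint, 0 above it
        u = np.where(idx <= k, x - x[k], 0.0)
        ub = u.mean()
        yb = y.mean()
        denom = np.sum((u - ub) ** 2)
        if denom == 0:
            continue
        b = np.sum((u - ub) * (y - yb)) / denom
        a = yb - b * ub
        sse = float(np.sum((y - a - b * u) ** 2))
        if best is None or sse < best[0]:
            best = (sse, k, b, a)

    sse, k, slope_pre, level = best
    pre = slice(0, k + 1)
    resid_pre = y[pre] - (level + slope_pre * (x[pre] - x[k]))
    sst_pre = float(np.sum((y[pre] - y[pre].mean()) ** 2))
    r2_pre = 1.0 if sst_pre == 0 else 1.0 - float(np.sum(resid_pre ** 2)) / sst_pre

    accepted = sse_single > 0 and sse < sse_ratio * sse_single
    tau1 = None
    if accepted:
        tau1 = int(sf.taus[k])
        if method == "slope":
            cross = _ascent_end(x, y, plateau_slope, n_grid, smooth_window)
            if cross is not None:
                tau1 = int(np.clip(round(cross), sf.tau_min, sf.tau_max))
    return BreakpointResult(tau1=tau1, slope_pre=float(slope_pre),
                            slope_post=0.0, sse=sse, sse_single=sse_single,
                            r2_pre=r2_pre)


def plateau_height(sf: StructureFunction,
                   window: ScaleRange = DEFAULT_SP_WINDOW) -> PlateauSummary:
    """Plateau height S_p: mean normalized S over window.tau_min < tau < window.tau_max.

    The default window is the open interval (100, 200), a scale range
    where nonlinear signals have typically reached their plateau. S_p is
    defined on the normalized SF: it is a relative quantity, meant to be
    compared within a recording (via :func:`plateau_delta`), not across
    recording conditions.
    """
    _require_normalized(sf, "plateau_height")
    if window.tau_min < sf.tau_min or window.tau_max > sf.tau_max:
        raise ScaleRangeError(
            f"plateau window ({window.tau_min}, {window.tau_max}) outside "
            f"computed scales [{sf.tau_min}, {sf.tau_max}]"
        )
    mask = (sf.taus > window.tau_min) & (sf.taus < window.tau_max)
    if not mask.any():
        raise ScaleRangeError("no scales strictly inside the plateau window")
    return PlateauSummary(sp=float(sf.values[mask].mean()), window=window)


def plateau_delta(sp_a: PlateauSummary, sp_b: PlateauSummary) -> float:
    """Difference of plateau heights, later state minus earlier: sp_b - sp_a.

    Both summaries must come from the same scale window; comparing S_p
    over different windows is meaningless.
    """
    if (sp_a.window.tau_min, sp_a.window.tau_max) != \
            (sp_b.window.tau_min, sp_b.window.tau_max):
        raise IncompatibilityError(
            f"plateau windows differ: ({sp_a.window.tau_min}, {sp_a.window.tau_max})"
            f" vs ({sp_b.window.tau_min}, {sp_b.window.tau_max})"
        )
    return sp_b.sp - sp_a.sp


def estimate_oscillation(sf: StructureFunction, samp: float = 1.0,
                         power_factor: float = 50.0,
                         min_freq_bins: int = 3) -> OscillationResult:
    """Recover the dominant oscillation frequency from S(tau).

    A periodic component of frequency f in a signal sampled at ``samp``
    samples per unit time appears in the structure function as an
    oscillation of frequency f / samp cycles per scale unit. The SF is
    linearly detrended, Hann-windowed and Fourier transformed; the peak
    of the power spectrum is deemed significant when it exceeds
    ``power_factor`` times the median spectral power. The first
    ``min_freq_bins`` frequency bins are excluded from the peak search:
    they carry residual trend, not oscillation. Frequency resolution is
    1 / (number of scales) — a hard limit of the scale grid length.
    """
    if samp <= 0:
        raise ParameterError("samp must be positive")
    if np.any(np.diff(sf.taus) != 1):
        raise ValidationError("oscillation estimate needs a contiguous scale grid")
    m = sf.taus.size
    if m < 2 * min_freq_bins + 2:
        raise InsufficientDataError("too few scales for a spectral estimate")

    y = sf.values - np.polyval(np.polyfit(sf.taus, sf.values, 1), sf.taus)
    window = np.hanning(m)
    power = np.abs(np.fft.rfft(y * window)) ** 2
    freqs = np.fft.rfftfreq(m, d=1.0)

    searchable = power[min_freq_bins:]
    peak_idx = int(np.argmax(searchable)) + min_freq_bins
    peak_power = float(power[peak_idx])
    median_power = float(np.median(power[1:]))
    significant = median_power > 0 and peak_power > power_factor * median_power
    omega_sf = float(freqs[peak_idx])
    omega_signal = omega_sf * samp if significant else None
    return OscillationResult(omega_sf=omega_sf, omega_signal=omega_signal,
                             samp=samp, significant=significant,
                             peak_power=peak_power, median_power=median_power)


def classify_signal(sf: StructureFunction, samp: float = 1.0,
                    thresholds: ClassifierThresholds | None = None,
                    sp_window: ScaleRange = DEFAULT_SP_WINDOW
                    ) -> SignalCharacterization:
    """Label a normalized SF as random, oscillatory or nonlinear.

    Decision rule, applied in order:

    1. A breakpoint is present with a clearly rising pre-segment
       (slope above ``slope_pre_min``, segment R^2 above ``r2_pre_min``)
       -> ``nonlinear``.
    2. Otherwise, a significant spectral peak -> ``oscillatory``.
    3. Otherwise, |zeta| over the full range below ``zeta_random_max``
       -> ``random``.
    4. Otherwise -> ``nonlinear`` (weakly correlated: a persistent trend
       without a clean breakpoint).

    The features are not mutually exclusive; each is also reported as a
    boolean flag alongside the primary label.
    """
    t = thresholds or ClassifierThresholds()
    _require_normalized(sf, "classify_signal")

    bp = detect_breakpoint(sf, sse_ratio=t.bp_sse_ratio)
    osc = estimate_oscillation(sf, samp=samp, power_factor=t.osc_power_factor)
    zeta = fit_scaling_exponent(sf, space="log")
    plateau = None
    if sp_window.tau_min >= sf.tau_min and sp_window.tau_max <= sf.tau_max:
        plateau = plateau_height(sf, window=sp_window)

    nonlinear_flag = (bp.present and bp.slope_pre > t.slope_pre_min
                      and bp.r2_pre > t.r2_pre_min)
    oscillatory_flag = osc.significant
    random_flag = abs(zeta.zeta) < t.zeta_random_max

    if nonlinear_flag:
        label = "nonlinear"
    elif oscillatory_flag:
        label = "oscillatory"
    elif random_flag:
        label = "random"
    else:
        label = "nonlinear"

    flags = {"nonlinear": bool(nonlinear_flag),
             "oscillatory": bool(oscillatory_flag),
             "random": bool(random_flag)}
    return SignalCharacterization(label=label, breakpoint=bp, plateau=plateau,
                                  oscillation=osc, mean_slope=zeta, flags=flags)
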