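"""Toy-signal generators: the reference systems that calibrate SF shapes.

Three systems with known dynamics span the behaviors seen in neuronal
data: i.i.d. Gaussian noise (random), a sinusoid (oscillatory) and the
x-variable of the chaotic Lorenz attractor (nonlinear, short-range
correlated). Noise-injection treatments add scaled standard-normal noise
to probe robustness. All generators are bit-reproducible under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InstabilityError, ParameterError
from .signal_io import TimeSeries

__all__ = [
    "LorenzParams",
    "NoiseSpec",
    "gen_random_normal",
    "gen_sinusoid",
    "add_scaled_noise",
    "lowpass_filter",
    "simulate_lorenz",
]


@dataclass(frozen=True)
class LorenzParams:
    """Parameters of the forward-Euler Lorenz integration.

    Defaults are the classical chaotic parameters (sigma=10, rho=28,
    beta=8/3) with dt=0.01, 10^3 transient steps discarded and 10^4
    samples retained. The initial state (1,1,1) receives a small seeded
    jitter ~N(0, 1e-3) so replicate runs sample different stretches of
    the attractor while staying reproducible.
    """

    sigma: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    dt: float = 0.01
    n_steps: int = 11_000
    transient: int = 1_000
    initial_state: tuple[float, float, float] = (1.0, 1.0, 1.0)
    jitter_sd: float = 1e-3
    seed: int | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if not (self.n_steps > self.transient >= 0):
            raise ParameterError("need n_steps > transient >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive standard-normal noise scaled by ``factor``."""

    factor: float
    seed: int | None = None

    def __post_init__(self):
        if self.factor < 0:
            raise ParameterError("noise factor must be non-negative")


def gen_random_normal(n: int, mean: float = 1.0, sd: float = 0.1,
                      seed: int | None = None) -> TimeSeries:
    """i.i.d. normal series; the reference random signal is N(1, 0.1^2), n=10^4.

    ``sd=0`` is allowed as the degenerate limit (a constant series, whose
    structure function cannot be normalized).
    """
    if n < 2:
        raise ParameterError(f"need n >= 2, got {n}")
    if sd < 0:
        raise ParameterError(f"need sd >= 0, got {sd}")
    rng = np.random.default_rng(seed)
    return TimeSeries(values=rng.normal(mean, sd, size=n), label="random-normal")


def gen_sinusoid(n: int, freq: float = 1.0, samp: float = 100.0) -> TimeSeries:
    """Sinusoid I_t = sin(2*pi*freq*t/samp), t = 0..n-1.

    ``freq`` is in cycles per unit time and ``samp`` in samples per unit
    time, so the period is samp/freq samples. Frequencies at or above the
    Nyquist rate samp/2 alias and are rejected.
    """
    if n < 2:
        raise ParameterError(f"need n >= 2, got {n}")
    if not (0 < freq < samp / 2):
        raise ParameterError(
            f"need 0 < freq < samp/2 (Nyquist); got freq={freq}, samp={samp}"
        )
    t = np.arange(n)
    return TimeSeries(values=np.sin(2 * np.pi * freq * t / samp), label="sinusoid")


def add_scaled_noise(series: TimeSeries, spec: NoiseSpec) -> TimeSeries:
    """Add factor-scaled standard-normal noise to a copy of the series."""
    rng = np.random.default_rng(spec.seed)
    noisy = series.values + spec.factor * rng.standard_normal(series.n)
    return series.with_values(noisy)


def lowpass_filter(series: TimeSeries, window: int = 5) -> TimeSeries:
    """Centered moving-average low-pass filter.

    ``window`` must be odd so the average is centered; near the edges the
    window shrinks symmetrically, keeping the output the same length as
    the input. A constant series passes through unchanged.
    """
    n = series.n
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be an odd integer >= 3, got {window}")
    if window >= n:
        raise ParameterError(f"window {window} must be smaller than series length {n}")
    h = window // 2
    csum = np.concatenate([[0.0], np.cumsum(series.values)])
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - h)
        hi = min(n, i + h + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return series.with_values(out)


def simulate_lorenz(params: LorenzParams | None = None) -> TimeSeries:
    """Integrate the Lorenz system with the Euler method; return x(t).

        dx/dt = sigma (y - x)
        dy/dt = x (rho - z) - y
        dz/dt = x y - beta z

    The first ``transient`` steps are discarded so the retained samples
    lie on the attractor. Forward Euler is only first-order accurate, but
    the structure-function statistics of interest (breakpoint band,
    plateau) are stable under step-size refinement. Divergence beyond
    |state| = 10^6 raises :class:`InstabilityError` — reduce dt.
    """
    p = params or LorenzParams()
    state = np.asarray(p.initial_state, dtype=float)
    if p.seed is not None and p.jitter_sd > 0:
        rng = np.random.default_rng(p.seed)
        state = state + rng.normal(0.0, p.jitter_sd, size=3)

    x_out = np.empty(p.n_steps - p.transient)
    sx, rho, beta, dt = p.sigma, p.rho, p.beta, p.dt
    x, y, z = state
    for i in range(p.n_steps):
        dx = sx * (y - x)
        dy = x * (rho - z) - y
        dz = x * y - beta * z
        x, y, z = x + dt * dx, y + dt * dy, z + dt * dz
        if abs(x) > 1e6 or abs(y) > 1e6 or abs(z) > 1e6:
            raise InstabilityError(
                f"Lorenz integration diverged at step {i}; use a smaller dt"
            )
        if i >= p.transient:
            x_out[i - p.transient] = x
    return TimeSeries(values=x_out, label="lorenz-x")
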