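"""Benchmark signal generators.

Deterministic maps (logistic, Hénon, Ikeda), the Rössler flow, and stochastic
processes (AR(3), white noise, 1/f noise) used as prototypical inputs for the
temporal-network analyses, plus observational-noise injection at a prescribed
signal-to-noise ratio.

Default lengths follow the study conditions used throughout the package:
n = 2x10^4 retained samples after a 4000-sample transient for the maps.
Every generator is reproducible: identical parameters and seed give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "DivergenceError",
    "DIVERGENCE_BOUND",
    "HENON_CHAOTIC",
    "HENON_PERIODIC",
    "gen_logistic",
    "gen_henon",
    "gen_ikeda",
    "gen_rossler",
    "gen_ar3",
    "gen_white_noise",
    "gen_pink_noise",
    "add_noise_snr",
    "rk4_step",
]

#: Any coordinate exceeding this magnitude aborts generation.
DIVERGENCE_BOUND = 1e6

#: Canonical chaotic Hénon parameters.
HENON_CHAOTIC = {"a": 1.4, "b": 0.3}

#: Parameters inside a stable periodic window (period 4).  Chosen as a
#: convenient periodic-regime preset; not tied to any published experiment.
HENON_PERIODIC = {"a": 1.0, "b": 0.3}


class DivergenceError(RuntimeError):
    """Raised when an orbit leaves the admissible region of state space."""


@dataclass
class TimeSeries:
    """A uniformly sampled scalar or vector time series.

    Parameters
    ----------
    values : ndarray, shape (n,) or (n, d)
        Samples; scalar series are 1-D, vector series one row per sample.
    dt : float
        Sampling interval in model time units (1 for maps).
    meta : dict
        Generator name, parameter record and seed, for provenance.
    """

    values: np.ndarray
    dt: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise DivergenceError("time series contains non-finite samples")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def is_scalar(self) -> bool:
        return self.values.ndim == 1

    @property
    def dim(self) -> int:
        return 1 if self.is_scalar else self.values.shape[1]


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_bound(state: Sequence[float], step: int, name: str) -> None:
    for coord in state:
        if not math.isfinite(coord) or abs(coord) > DIVERGENCE_BOUND:
            raise DivergenceError(
                f"{name} orbit diverged at iterate {step}: state {tuple(state)}"
            )


def gen_logistic(
    mu: float = 4.0,
    n: int = 20_000,
    n_transient: int = 4000,
    x0: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> TimeSeries:
    """Iterate the logistic map ``x_{n+1} = mu * x_n * (1 - x_n)``.

    The first ``n_transient`` iterates are discarded.  ``x0`` must lie strictly
    inside (0, 1); if omitted it is drawn uniformly from that interval using
    ``seed``.  For mu <= 4 the orbit stays in [0, 1]; leaving it (possible only
    for mu > 4) raises :class:`DivergenceError`.
    """
    if not 0 < mu <= 4 + 1e-12:
        # mu > 4 is allowed formally but almost surely diverges; reject mu <= 0.
        if mu <= 0:
            raise ValueError("mu must be positive")
    if n < 0 or n_transient < 0:
        raise ValueError("n and n_transient must be non-negative")
    rng = _rng(seed)
    if x0 is None:
        x0 = float(rng.uniform(1e-6, 1 - 1e-6))
    if not 0.0 < x0 < 1.0:
        raise ValueError(f"x0 must lie strictly inside (0, 1), got {x0}")

    x = x0
    out = np.empty(n)
    for i in range(n_transient + n):
        if i >= n_transient:
            out[i - n_transient] = x
        x = mu * x * (1.0 - x)
        if not 0.0 <= x <= 1.0:
            raise DivergenceError(
                f"logistic orbit left [0, 1] at iterate {i + 1} (mu={mu})"
            )
    return TimeSeries(out, dt=1.0, meta={"system": "logistic", "mu": mu, "x0": x0})


def gen_henon(
    a: float = 1.4,
    b: float = 0.3,
    n: int = 20_000,
    n_transient: int = 4000,
    init: tuple[float, float] | None = None,
    seed: int | np.random.Generator | None = None,
) -> TimeSeries:
    """Iterate the Hénon map ``x' = 1 - a x^2 + y``, ``y' = b x``.

    Defaults (a=1.4, b=0.3) are the canonical chaotic parameters; see
    :data:`HENON_PERIODIC` for a stable period-4 preset.  ``init=None`` draws a
    random point near the origin (inside the attractor basin).
    """
    rng = _rng(seed)
    if init is None:
        init = tuple(rng.uniform(-0.1, 0.1, size=2))
    x, y = float(init[0]), float(init[1])
    out = np.empty((n, 2))
    for i in range(n_transient + n):
        if i >= n_transient:
            out[i - n_transient] = (x, y)
        x, y = 1.0 - a * x * x + y, b * x
        _check_bound((x, y), i + 1, "Henon")
    return TimeSeries(
        out, dt=1.0, meta={"system": "henon", "a": a, "b": b, "init": init}
    )


def gen_ikeda(
    n: int = 20_000,
    n_transient: int = 4000,
    init: tuple[float, float] | None = None,
    u: float = 0.9,
    seed: int | np.random.Generator | None = None,
) -> TimeSeries:
    """Iterate the Ikeda map with dissipation parameter ``u`` (default 0.9).

    x' = 1 + u (x cos t - y sin t),  y' = u (x sin t + y cos t),
    with phase t = 0.4 - 6 / (1 + x^2 + y^2).
    """
    rng = _rng(seed)
    if init is None:
        init = tuple(rng.uniform(-0.1, 0.1, size=2))
    x, y = float(init[0]), float(init[1])
    out = np.empty((n, 2))
    for i in range(n_transient + n):
        if i >= n_transient:
            out[i - n_transient] = (x, y)
        t = 0.4 - 6.0 / (1.0 + x * x + y * y)
        c, s = math.cos(t), math.sin(t)
        x, y = 1.0 + u * (x * c - y * s), u * (x * s + y * c)
        _check_bound((x, y), i + 1, "Ikeda")
    return TimeSeries(out, dt=1.0, meta={"system": "ikeda", "u": u, "init": init})


def rk4_step(
    f: Callable[[np.ndarray], np.ndarray], y: np.ndarray, h: float
) -> np.ndarray:
    """One classical 4th-order Runge-Kutta step of size ``h`` for ``y' = f(y)``."""
    k1 = f(y)
    k2 = f(y + 0.5 * h * k1)
    k3 = f(y + 0.5 * h * k2)
    k4 = f(y + h * k3)
    return y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def gen_rossler(
    n_samples: int = 20_000,
    sample_stride: float = 1.0,
    integrator_step: float = 0.01,
    n_transient_time: float = 500.0,
    init: tuple[float, float, float] = (1.0, 1.0, 0.0),
    a: float = 0.2,
    b: float = 0.2,
    c: float = 5.7,
) -> TimeSeries:
    """Integrate the Rössler system with fixed-step RK4 and subsample.

    dx/dt = -(y + z),  dy/dt = x + a y,  dz/dt = b + z (x - c).

    The trajectory is advanced with step ``integrator_step`` and recorded every
    ``sample_stride`` time units after discarding ``n_transient_time`` time
    units of transient.  ``sample_stride`` must be an (approximate) integer
    multiple of ``integrator_step``.
    """
    if integrator_step <= 0 or sample_stride <= 0:
        raise ValueError("steps must be positive")
    steps_per_sample = round(sample_stride / integrator_step)
    if steps_per_sample < 1 or abs(steps_per_sample * integrator_step - sample_stride) > 1e-9:
        raise ValueError("sample_stride must be an integer multiple of integrator_step")
    n_transient_steps = round(n_transient_time / integrator_step)

    h = integrator_step
    x, y, z = (float(v) for v in init)

    def advance(x: float, y: float, z: float) -> tuple[float, float, float]:
        # RK4 unrolled on scalars for speed in long integrations.
        k1x = -(y + z); k1y = x + a * y; k1z = b + z * (x - c)
        x2, y2, z2 = x + 0.5 * h * k1x, y + 0.5 * h * k1y, z + 0.5 * h * k1z
        k2x = -(y2 + z2); k2y = x2 + a * y2; k2z = b + z2 * (x2 - c)
        x3, y3, z3 = x + 0.5 * h * k2x, y + 0.5 * h * k2y, z + 0.5 * h * k2z
        k3x = -(y3 + z3); k3y = x3 + a * y3; k3z = b + z3 * (x3 - c)
        x4, y4, z4 = x + h * k3x, y + h * k3y, z + h * k3z
        k4x = -(y4 + z4); k4y = x4 + a * y4; k4z = b + z4 * (x4 - c)
        return (
            x + (h / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x),
            y + (h / 6.0) * (k1y + 2 * k2y + 2 * k3y + k4y),
            z + (h / 6.0) * (k1z + 2 * k2z + 2 * k3z + k4z),
        )

    for i in range(n_transient_steps):
        x, y, z = advance(x, y, z)
        if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
            raise DivergenceError(f"Rossler trajectory diverged during transient step {i}")

    out = np.empty((n_samples, 3))
    for i in range(n_samples):
        out[i] = (x, y, z)
        for _ in range(steps_per_sample):
            x, y, z = advance(x, y, z)
        _check_bound((x, y, z), i, "Rossler")
    return TimeSeries(
        out,
        dt=sample_stride,
        meta={"system": "rossler", "a": a, "b": b, "c": c, "init": init,
              "integrator_step": integrator_step},
    )


def gen_ar3(
    n: int = 20_000,
    n_transient: int = 4000,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator | None = None,
    coeffs: tuple[float, float, float] = (0.8, -0.5, 0.7),
) -> TimeSeries:
    """Simulate the AR(3) process ``s_n = 0.8 s_{n-1} - 0.5 s_{n-2} + 0.7 s_{n-3} + eps_n``.

    ``eps_n`` is i.i.d. Gaussian with standard deviation ``noise_sd``.  Note
    the default coefficients place a root on the unit circle, so the process
    wanders; the transient merely detaches the output from the zero start.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _rng(seed)
    c1, c2, c3 = coeffs
    eps = rng.normal(0.0, noise_sd, size=n_transient + n) if noise_sd > 0 else np.zeros(
        n_transient + n
    )
    s1 = s2 = s3 = 0.0
    out = np.empty(n)
    for i in range(n_transient + n):
        s = c1 * s1 + c2 * s2 + c3 * s3 + eps[i]
        if abs(s) > DIVERGENCE_BOUND:
            raise DivergenceError(f"AR(3) series diverged at step {i}")
        if i >= n_transient:
            out[i - n_transient] = s
        s1, s2, s3 = s, s1, s2
    return TimeSeries(
        out, dt=1.0, meta={"system": "ar3", "coeffs": coeffs, "noise_sd": noise_sd}
    )


def gen_white_noise(
    n: int = 20_000, seed: int | np.random.Generator | None = None
) -> TimeSeries:
    """I.i.d. standard Gaussian samples."""
    rng = _rng(seed)
    return TimeSeries(rng.standard_normal(n), dt=1.0, meta={"system": "white"})


def gen_pink_noise(
    n: int = 20_000, seed: int | np.random.Generator | None = None
) -> TimeSeries:
    """1/f noise by spectral synthesis.

    Fourier amplitudes scale as f^(-1/2) (power spectrum ~ 1/f) with uniform
    random phases; the zero-frequency bin is set to 0 and the result is
    normalised to unit variance.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = _rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n=n)
    x /= x.std()
    return TimeSeries(x, dt=1.0, meta={"system": "pink"})


def add_noise_snr(
    series: TimeSeries,
    snr_db: float,
    seed: int | np.random.Generator | None = None,
) -> TimeSeries:
    """Add i.i.d. Gaussian observational noise at the given SNR (dB).

    SNR is defined as ``10 log10(var_signal / var_noise)``; the noise variance
    is ``var(signal) / 10^(snr_db/10)`` per coordinate.  ``snr_db = inf``
    returns an identical copy.
    """
    values = series.values
    if math.isinf(snr_db) and snr_db > 0:
        return TimeSeries(values.copy(), dt=series.dt, meta=dict(series.meta))
    var = np.var(values, axis=0)
    if np.any(var <= 0):
        raise ValueError("cannot set an SNR on a zero-variance signal")
    rng = _rng(seed)
    noise_sd = np.sqrt(var / 10.0 ** (snr_db / 10.0))
    noisy = values + rng.standard_normal(values.shape) * noise_sd
    meta = dict(series.meta)
    meta["snr_db"] = snr_db
    return TimeSeries(noisy, dt=series.dt, meta=meta)
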