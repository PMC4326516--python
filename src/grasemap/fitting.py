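"""Per-pixel and whole-image T2 estimation from multi-echo magnitudes.

The estimator of record is a two-parameter maximum-likelihood fit of
``(S0, T2)`` under the noncentral-chi magnitude noise model — the same
principle used for on-scanner map generation from phased-array magnitude
data.  Log-linear and nonlinear least-squares fits are provided as
baselines; at low SNR they are biased upward by the magnitude noise
floor, which is precisely what the ML fit corrects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .noise import NoiseModel, log_likelihood
from .protocols import GraSEProtocol

__all__ = [
    "MultiEchoStack",
    "T2MapResult",
    "fit_pixel_mle",
    "fit_pixel_lsq",
    "fit_map",
    "T2_MIN",
    "T2_MAX",
]

T2_MIN = 1.0  # ms, lower search bound
T2_MAX = 1000.0  # ms, physical/display ceiling; 0 marks non-fitted pixels


@dataclass
class MultiEchoStack:
    """Echo-indexed stack of 2-D magnitude images with echo times.

    ``volumes`` has shape ``(n_echoes, ny, nx)`` and is aligned with
    ``echo_times`` (ms).  Start-up echoes are never part of the stack.
    """

    volumes: np.ndarray
    echo_times: np.ndarray
    noise: NoiseModel | None = None
    protocol: GraSEProtocol | None = None

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.volumes.ndim != 3:
            raise ValueError("volumes must be (n_echoes, ny, nx)")
        if self.volumes.shape[0] != self.echo_times.size:
            raise ValueError("one echo time per volume required")
        if np.any(self.volumes < 0):
            raise ValueError("magnitude images must be non-negative")
        if self.protocol is not None and self.protocol.n_echoes != self.echo_times.size:
            raise ValueError("stack size does not match protocol.n_echoes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.volumes.shape[1:]


@dataclass
class T2MapResult:
    """Per-pixel T2/S0 estimates with fit status.

    ``t2_map`` is in ms, clipped to ``[T2_MIN, T2_MAX]`` where converged
    and 0 where not fitted; ``converged_mask`` marks pixels with a valid
    fit.  ``meta`` records method, noise parameters and protocol name.
    """

    t2_map: np.ndarray
    s0_map: np.ndarray
    converged_mask: np.ndarray
    method: str
    meta: dict = field(default_factory=dict)


def _loglin_init(series: np.ndarray, te: np.ndarray, floor: float) -> tuple[float, float]:
    """Log-linear least-squares (S0, T2) with magnitudes floored."""
    y = np.log(np.maximum(series, floor))
    t_mean = te.mean()
    y_mean = y.mean()
    denom = np.sum((te - t_mean) ** 2)
    slope = np.sum((te - t_mean) * (y - y_mean)) / denom
    intercept = y_mean - slope * t_mean
    t2 = np.inf if slope >= 0 else -1.0 / slope
    return float(np.exp(intercept)), float(np.clip(t2, T2_MIN, T2_MAX))


def fit_pixel_lsq(series, echo_times, mode: str = "nonlinear") -> tuple[float, float]:
    """Least-squares mono-exponential fit of one magnitude series.

    ``mode="log"`` regresses ``ln(m)`` on TE (unweighted; requires all
    magnitudes positive).  ``mode="nonlinear"`` minimizes the squared
    residual of ``S0 * exp(-TE/T2)`` starting from the log-linear
    solution.  Returns ``(s0, t2)`` with t2 clipped to [T2_MIN, T2_MAX].
    """
    m = np.asarray(series, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    if m.size != te.size or m.size < 2:
        raise ValueError("need matching series/echo_times with >= 2 echoes")
    if mode == "log":
        if np.any(m <= 0):
            raise ValueError("log mode requires strictly positive magnitudes")
        return _loglin_init(m, te, floor=0.0)
    if mode != "nonlinear":
        raise ValueError("mode must be 'log' or 'nonlinear'")
    if np.all(m <= 0):
        raise ValueError("all-zero series cannot be fitted")
    s0_0, t2_0 = _loglin_init(m, te, floor=max(m.max() * 1e-6, 1e-12))

    def resid(theta):
        s0, t2 = theta
        return s0 * np.exp(-te / t2) - m

    res = optimize.least_squares(
        resid,
        x0=[max(s0_0, 1e-9), t2_0],
        bounds=([0.0, T2_MIN], [np.inf, T2_MAX]),
        method="trf",
    )
    return float(res.x[0]), float(res.x[1])


def fit_pixel_mle(
    series, echo_times, noise: NoiseModel
) -> tuple[float, float, bool]:
    """Maximum-likelihood ``(s0, t2)`` for one pixel's echo series.

    Maximizes the noncentral-chi log-likelihood over ``(S0, T2)`` with T2
    bounded in [T2_MIN, T2_MAX] ms, starting from a log-linear fit with
    magnitudes floored at ``sigma / 2``.  The returned flag is False for
    degenerate input (all-zero series), in which case ``(0, 0)`` is
    returned rather than raising — map completeness over exceptions.
    """
    m = np.asarray(series, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    if m.size != te.size or m.size < 2:
        raise ValueError("need matching series/echo_times with >= 2 echoes")
    if np.all(m == 0):
        return 0.0, 0.0, False

    s0_0, t2_0 = _loglin_init(m, te, floor=noise.sigma / 2.0)
    s0_hi = max(2.0 * m.max(), 4.0 * noise.sigma)
    x0 = np.array([np.clip(s0_0, 1e-6, s0_hi), np.clip(t2_0, T2_MIN, T2_MAX)])

    def nll(theta):
        s0, t2 = theta
        return -log_likelihood(m, te, s0, t2, noise)

    f0 = nll(x0)
    with np.errstate(invalid="ignore", over="ignore"):
        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, s0_hi), (T2_MIN, T2_MAX)],
        )
    # never return a point worse than the (always valid) initializer
    if not np.isfinite(res.fun) or res.fun > f0 + 1e-12:
        return float(x0[0]), float(x0[1]), bool(np.isfinite(f0))
    return float(res.x[0]), float(res.x[1]), True


def fit_map(
    stack: MultiEchoStack,
    mask: np.ndarray | None = None,
    method: str = "mle",
    noise: NoiseModel | None = None,
) -> T2MapResult:
    """Fit every (masked) pixel of a multi-echo stack.

    ``method`` is ``"mle"`` (requires a noise model, taken from the stack
    if not given), ``"lsq_log"`` or ``"lsq_nonlinear"``.  Pixels outside
    the mask, and pixels whose fit fails, carry ``t2 = 0`` and are
    excluded from ``converged_mask``.  Fitting is deterministic — there
    is no randomness in the estimator.
    """
    if method not in ("mle", "lsq_log", "lsq_nonlinear"):
        raise ValueError("method must be 'mle', 'lsq_log' or 'lsq_nonlinear'")
    noise = noise or stack.noise
    if method == "mle" and noise is None:
        raise ValueError("MLE fitting needs a NoiseModel (stack.noise or noise=)")
    shape = stack.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} does not match image {shape}")

    t2_map = np.zeros(shape)
    s0_map = np.zeros(shape)
    conv = np.zeros(shape, dtype=bool)
    te = stack.echo_times
    for iy, ix in zip(*np.nonzero(mask)):
        series = stack.volumes[:, iy, ix]
        try:
            if method == "mle":
                s0, t2, ok = fit_pixel_mle(series, te, noise)
            else:
                s0, t2 = fit_pixel_lsq(series, te, mode=method.removeprefix("lsq_"))
                ok = True
        except ValueError:
            # non-positive magnitudes in log mode, all-zero series, ...
            try:
                s0, t2 = fit_pixel_lsq(series, te, mode="nonlinear")
                ok = False  # flagged: fell back from the requested method
            except ValueError:
                s0, t2, ok = 0.0, 0.0, False
        t2_map[iy, ix], s0_map[iy, ix], conv[iy, ix] = t2, s0, ok

    meta = {
        "method": method,
        "t2_bounds_ms": [T2_MIN, T2_MAX],
        "nonfitted_value": 0.0,
    }
    if noise is not None:
        meta["sigma"] = noise.sigma
        meta["n_channels"] = noise.n_channels
    if stack.protocol is not None:
        meta["protocol"] = stack.protocol.name
    return T2MapResult(t2_map, s0_map, conv, method, meta)
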