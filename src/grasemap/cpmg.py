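"""Gold-standard CPMG reference fits and method agreement.

A Carr-Purcell-Meiboom-Gill acquisition with ideal 180-degree refocusing
and dense echo sampling is the reference standard for T2 measurement.
This module fits such dense trains and quantifies how well GraSE-derived
T2 values track the reference across compartments (correlation and the
calibration line).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .fitting import fit_pixel_lsq, fit_pixel_mle
from .noise import NoiseModel

__all__ = ["cpmg_echo_times", "fit_cpmg", "method_agreement"]

#: Default dense reference sampling: 32 echoes spaced 10 ms apart.
CPMG_N_ECHOES = 32
CPMG_DELTA_TE = 10.0


def cpmg_echo_times(n_echoes: int = CPMG_N_ECHOES, delta_te: float = CPMG_DELTA_TE) -> np.ndarray:
    """Echo times (ms) of the dense CPMG reference train."""
    return delta_te * np.arange(1, n_echoes + 1)


def fit_cpmg(
    series, echo_times, noise: NoiseModel | None = None
) -> float:
    """Mono-exponential T2 (ms) from a densely sampled CPMG series.

    Nonlinear least squares by default; passing a noise model switches to
    the maximum-likelihood fit.  Requires at least 8 echoes — the point
    of the reference is dense sampling of the decay.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 8:
        raise ValueError("CPMG reference fitting expects >= 8 echoes")
    if noise is not None:
        _, t2, _ = fit_pixel_mle(series, echo_times, noise)
        return t2
    _, t2 = fit_pixel_lsq(series, echo_times, mode="nonlinear")
    return t2


def method_agreement(grase_t2, reference_t2) -> tuple[float, float, float]:
    """Pearson R and calibration line of GraSE vs reference T2.

    Returns ``(pearson_r, slope, intercept)`` of the ordinary
    least-squares line ``grase = slope * reference + intercept``.  A
    slope above 1 with high R indicates systematic overestimation that
    grows with T2 (e.g. stimulated-echo contamination).
    """
    g = np.asarray(grase_t2, dtype=float)
    r = np.asarray(reference_t2, dtype=float)
    if g.size != r.size or g.size < 3:
        raise ValueError("need equal-length lists of >= 3 paired T2 values")
    if np.std(g) == 0 or np.std(r) == 0:
        raise ValueError("zero-variance input: correlation is undefined")
    fit = stats.linregress(r, g)
    return float(fit.rvalue), float(fit.slope), float(fit.intercept)
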