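"""Independent brute-force oracles used to validate the implementation.

The isochromat simulator integrates the Bloch rotation equations for an
ensemble of uniformly dephased spins; it shares no code with the EPG
recursion it checks.  With spins on a uniform 2*pi dephasing grid the
ensemble average annihilates every nonzero configuration order exactly,
so the two must agree to numerical precision for small pulse trains.
"""

import numpy as np


def isochromat_echo_amplitudes(
    t2: float,
    t1: float,
    delta_te: float,
    n_pulses: int,
    flip_deg: float,
    n_spins: int = 500,
) -> np.ndarray:
    """Echo magnitudes from brute-force Bloch simulation.

    90 degrees about y puts the magnetization along x; refocusing pulses
    rotate about x (CPMG condition).  Each half-interval applies
    relaxation and a spin-specific dephasing rotation about z.
    """
    theta = 2.0 * np.pi * np.arange(n_spins) / n_spins
    M = np.zeros((n_spins, 3))
    M[:, 0] = 1.0
    e2 = np.exp(-0.5 * delta_te / t2)
    e1 = np.exp(-0.5 * delta_te / t1)
    a = np.deg2rad(flip_deg)
    rx = np.array(
        [[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
    )
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    def half_interval(M):
        M[:, 0] *= e2
        M[:, 1] *= e2
        M[:, 2] = M[:, 2] * e1 + (1.0 - e1)
        x = cos_t * M[:, 0] - sin_t * M[:, 1]
        y = sin_t * M[:, 0] + cos_t * M[:, 1]
        M[:, 0], M[:, 1] = x, y
        return M

    echoes = np.empty(n_pulses)
    for k in range(n_pulses):
        M = half_interval(M)
        M = M @ rx.T
        M = half_interval(M)
        echoes[k] = np.hypot(M[:, 0].mean(), M[:, 1].mean())
    return echoes


def grid_search_mle(series, echo_times, noise, t2_step=0.25, s0_step=0.25):
    """Exhaustive (s0, t2) grid maximization of the magnitude likelihood."""
    from grasemap.noise import nc_chi_logpdf

    series = np.asarray(series, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    t2_grid = np.arange(1.0, 1000.0 + t2_step, t2_step)
    s0_grid = np.arange(s0_step, 2.0 * series.max() + s0_step, s0_step)
    decay = np.exp(-te[None, :] / t2_grid[:, None])  # (T, E)
    ll = np.zeros((s0_grid.size, t2_grid.size))
    for k in range(te.size):
        ll += nc_chi_logpdf(series[k], np.outer(s0_grid, decay[:, k]), noise)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return float(s0_grid[i]), float(t2_grid[j])
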