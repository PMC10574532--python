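"""Polyexponential impulse-response kernels and exact convolution primitives.

The disposition kernel is a sum of <= 3 exponentials, c(t) = sum_i A_i
exp(-lambda_i t) per unit dose.  Convolution of a piecewise-constant input
rate with such a kernel has a closed form per segment, which both the
plasma-curve generator and the IVIVC convolution/deconvolution engine use;
no quadrature grids are involved.
"""

from __future__ import annotations

import numpy as np


def polyexp(terms, t):
    """Evaluate sum_i A_i * exp(-lambda_i * t); 0 for t < 0.

    ``terms`` is a sequence of (A_i, lambda_i) pairs.
    """
    t_arr = np.asarray(t, dtype=float)
    out = np.zeros_like(t_arr)
    pos = t_arr >= 0
    for a, lam in terms:
        out[pos] += a * np.exp(-lam * t_arr[pos])
    return float(out) if np.ndim(t) == 0 else out


def segment_response(terms, a, b, t):
    """Response at times ``t`` to a unit-rate input on the interval [a, b].

    Closed form: integral over tau in [a, min(b, t)] of kernel(t - tau).
    Vectorized over ``t``; zero for t <= a.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    active = t_arr > a
    if np.any(active):
        ta = t_arr[active]
        upper = np.minimum(ta, b)
        for amp, lam in terms:
            out[active] += (amp / lam) * (
                np.exp(-lam * (ta - upper)) - np.exp(-lam * (ta - a))
            )
    return out if np.ndim(t) else float(out[0])


def convolve_pwc_rate(breaks, rates, terms, t_eval):
    """Convolve a piecewise-constant rate with the kernel, exactly.

    ``breaks`` are the n+1 interval edges, ``rates`` the n constant rates.
    Returns the response sampled at ``t_eval``.
    """
    breaks = np.asarray(breaks, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if breaks.size != rates.size + 1:
        raise ValueError("need len(breaks) == len(rates) + 1")
    t_arr = np.atleast_1d(np.asarray(t_eval, dtype=float))
    out = np.zeros_like(t_arr)
    for j in range(rates.size):
        if rates[j] != 0.0:
            out += rates[j] * segment_response(terms, breaks[j], breaks[j + 1], t_arr)
    return out if np.ndim(t_eval) else float(out[0])


def convolve_pwl_cumulative(times, cumulative, terms, t_eval, scale=1.0):
    """Convolve d/dt(scale * cumulative) with the kernel.

    ``cumulative`` is a piecewise-linear non-decreasing amount profile
    sampled at ``times`` (its derivative is the piecewise-constant input
    rate).  A jump at times[0] > 0 is not modelled; prepend (0, 0) upstream
    if needed.  Exact per segment.
    """
    times = np.asarray(times, dtype=float)
    cum = np.asarray(cumulative, dtype=float) * scale
    if times.size != cum.size:
        raise ValueError("times and cumulative must have equal length")
    dt = np.diff(times)
    rates = np.diff(cum) / dt
    return convolve_pwc_rate(times, rates, terms, t_eval)


def response_matrix(obs_times, terms):
    """Design matrix M with M[i, j] = response at obs_times[i] of a unit
    rate on (edge_{j-1}, edge_j], where the edges are 0 plus obs_times.

    Used by the staircase-input deconvolution least squares.
    """
    obs = np.asarray(obs_times, dtype=float)
    edges = np.concatenate(([0.0], obs)) if obs[0] > 0 else obs
    n_int = edges.size - 1
    m = np.zeros((obs.size, n_int))
    for j in range(n_int):
        m[:, j] = segment_response(terms, edges[j], edges[j + 1], obs)
    return m, edges
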