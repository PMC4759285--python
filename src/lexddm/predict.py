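"""Condition-level model predictions.

Integrates the single-trial Wiener kernel over across-trial variability —
normal drift variability (``eta``, Gauss–Hermite, 20 nodes), uniform
starting-point variability (``sz``, Gauss–Legendre, 10 nodes) and uniform
non-decision-time variability (``st``, Gauss–Legendre, 10 nodes) — and
mixes the result with the contaminant distribution at weight ``p0``.

Contaminant convention: a contaminant trial has RT uniform on the analysis
window (0.25–1.5 s) and the same accuracy as the diffusion process, so
contaminants perturb RT distributions but not predicted accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .params import CONTAMINANT_WINDOW, CORRECT_SIDE, DiffusionParams, ResponseSide
from .wiener import (
    _MAX_TERMS,
    SERIES_TOL,
    NumericalAccuracyError,
    _n_terms_large,
    _p_lower_norm,
)

N_HERMITE = 20
N_LEGENDRE = 10

DEFAULT_QUANTILE_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)


@lru_cache(maxsize=8)
def _hermegauss(n: int):
    x, w = np.polynomial.hermite_e.hermegauss(n)
    return x, w / np.sqrt(2.0 * np.pi)


@lru_cache(maxsize=8)
def _leggauss(n: int):
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w / 2.0


def _drift_start_nodes(params: DiffusionParams):
    """Joint quadrature nodes over (drift, start), on the normalised scale.

    Returns ``mu`` (drift * a / s^2), ``w`` (relative start) and weights,
    flattened over the eta x sz product grid, for the *lower*-boundary
    orientation.
    """
    if params.eta > 0:
        x, wv = _hermegauss(N_HERMITE)
        vs = params.v + params.eta * x
    else:
        vs, wv = np.array([params.v]), np.array([1.0])
    if params.sz > 0:
        x, wz = _leggauss(N_LEGENDRE)
        zs = params.z + 0.5 * params.sz * x
    else:
        zs, wz = np.array([params.z]), np.array([1.0])
    mu = (vs[:, None] * params.a / params.s**2 * np.ones_like(zs)[None, :]).ravel()
    w = (np.ones_like(vs)[:, None] * (zs / params.a)[None, :]).ravel()
    wt = (wv[:, None] * wz[None, :]).ravel()
    return mu, w, wt


def _ndt_nodes(params: DiffusionParams):
    if params.st > 0:
        x, wu = _leggauss(N_LEGENDRE)
        return params.t_er + 0.5 * params.st * x, wu
    return np.array([params.t_er]), np.array([1.0])


def _side_nodes(mu, w, side: ResponseSide):
    if side is ResponseSide.UPPER:
        return -mu, 1.0 - w
    return mu, w


def _cdf_norm_grid(tau, mu, w, tol=SERIES_TOL):
    """Defective lower-boundary CDF on a (time x node) grid.

    ``tau``: (T,) normalised decision times (may include non-positive
    entries, mapped to 0); ``mu``, ``w``: (J,) node arrays.  Returns (T, J).
    The spectral series factorises as exp(-mu^2 tau/2) * [E @ C] with
    ``E[t,k] = exp(-k^2 pi^2 tau_t / 2)`` shared across nodes, so the node
    dimension costs one matrix product.
    """
    tau = np.asarray(tau, dtype=float)
    mu = np.asarray(mu, dtype=float)
    w = np.asarray(w, dtype=float)
    p_low = _p_lower_norm(mu, w)
    out = np.zeros((tau.size, mu.size))
    tau_floor = -2.0 * np.log(tol) / (np.pi**2 * _MAX_TERMS**2)
    live = tau > tau_floor
    if not np.any(live):
        return out
    tt = tau[live]
    n = _n_terms_large(float(np.min(tt)), tol)
    if n > _MAX_TERMS:
        raise NumericalAccuracyError(f"CDF series needs {n} terms (cap {_MAX_TERMS})")
    kk = np.arange(1, n + 1, dtype=float)
    lam = mu[:, None] ** 2 + kk[None, :] ** 2 * np.pi**2  # (J, K)
    coef = 2.0 * np.pi * kk[None, :] * np.sin(kk[None, :] * np.pi * w[:, None])
    coef = coef * np.exp(-mu[:, None] * w[:, None]) / lam
    ek = np.exp(-(kk[None, :] ** 2) * np.pi**2 * tt[:, None] / 2.0)  # (T, K)
    tail = ek @ coef.T  # (T, J)
    tail = tail * np.exp(-(mu[None, :] ** 2) * tt[:, None] / 2.0)
    out[live] = np.clip(p_low[None, :] - tail, 0.0, p_low[None, :])
    return out


def response_probability(params: DiffusionParams, side: ResponseSide) -> float:
    """P(respond at ``side``) after integrating drift and start variability.

    Invariant to ``t_er``, ``st`` and (by the contaminant convention) ``p0``.
    """
    mu, w, wt = _drift_start_nodes(params)
    mu_s, w_s = _side_nodes(mu, w, side)
    return float(np.sum(wt * _p_lower_norm(mu_s, w_s)))


def predicted_accuracy(params: DiffusionParams, lexicality: str) -> float:
    """P(correct response) for a condition of the given lexicality."""
    return response_probability(params, CORRECT_SIDE[lexicality])


def defective_cdf(t, params: DiffusionParams, side: ResponseSide):
    """Defective RT CDF at ``side`` for the full model (variability + contaminants).

    ``t`` is total RT in seconds (decision + non-decision time).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    mu, w, wt = _drift_start_nodes(params)
    mu_s, w_s = _side_nodes(mu, w, side)
    u, wu = _ndt_nodes(params)
    tscale = params.s**2 / params.a**2
    tau = ((t_arr[:, None] - u[None, :]) * tscale).ravel()
    grid = _cdf_norm_grid(tau, mu_s, w_s)  # (T*L, J)
    grid = grid.reshape(t_arr.size, u.size, mu_s.size)
    diffusion = np.einsum("tlj,l,j->t", grid, wu, wt)
    p_side = float(np.sum(wt * _p_lower_norm(mu_s, w_s)))
    lo, hi = CONTAMINANT_WINDOW
    contaminant = p_side * np.clip((t_arr - lo) / (hi - lo), 0.0, 1.0)
    g = (1.0 - params.p0) * diffusion + params.p0 * contaminant
    return float(g[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else g


@dataclass
class ConditionPrediction:
    """Predicted accuracy and defective RT quantiles for one condition."""

    accuracy: float
    p_response: Mapping[ResponseSide, float]
    quantile_probs: tuple
    quantiles: Mapping[ResponseSide, np.ndarray] = field(repr=False)

    def quantiles_ms(self, side: ResponseSide) -> np.ndarray:
        return self.quantiles[side] * 1000.0


def predict_condition(
    params: DiffusionParams,
    lexicality: str,
    quantile_probs: Sequence[float] = DEFAULT_QUANTILE_PROBS,
) -> ConditionPrediction:
    """Predicted accuracy and per-side RT quantiles for one condition.

    Quantiles are conditional on the response side (each side's defective
    distribution rescaled to 1).  ``quantile_probs`` must be strictly
    increasing within (0, 1).
    """
    qp = np.asarray(quantile_probs, dtype=float)
    if qp.size and (np.any(qp <= 0) or np.any(qp >= 1) or np.any(np.diff(qp) <= 0)):
        raise ValueError("quantile_probs must be strictly increasing in (0, 1)")
    p_resp = {side: response_probability(params, side) for side in ResponseSide}
    quantiles = {}
    for side in ResponseSide:
        p_side = p_resp[side]
        qs = np.empty(qp.size)
        t_max = 4.0
        for i, p in enumerate(qp):
            target = p * p_side

            def g(t):
                return defective_cdf(t, params, side) - target

            hi = t_max
            while g(hi) < 0 and hi < 512.0:
                hi *= 2.0
            if g(hi) < 0:
                raise NumericalAccuracyError("quantile bracket expansion failed")
            qs[i] = brentq(g, 1e-6, hi, xtol=1e-7)
        quantiles[side] = qs
    correct = CORRECT_SIDE[lexicality]
    return ConditionPrediction(
        accuracy=p_resp[correct],
        p_response=p_resp,
        quantile_probs=tuple(qp),
        quantiles=quantiles,
    )
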