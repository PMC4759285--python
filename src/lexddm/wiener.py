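"""Single-trial Wiener first-passage kernel for two absorbing boundaries.

Everything here treats the *single-trial* process: fixed drift ``v``,
boundaries at 0 and ``a``, start ``z = zr * a``, within-trial diffusion
coefficient ``s``.  Across-trial variability and contaminants are handled
one level up (:mod:`lexddm.predict`) by integrating these kernels.

Internally the process is normalised to unit diffusion and unit boundary
separation (``w = zr``, ``mu = v * a / s**2``, ``tau = t * s**2 / a**2``),
which is the scale on which the classical series expansions of the
first-passage density are written.  The density uses both the small-time
(image/reflection) and large-time (spectral) expansions, switching by a
per-time-point precision criterion; each series is truncated when the bound
on the next term drops below ``SERIES_TOL``.
"""

from __future__ import annotations

import numpy as np

from .params import DiffusionParams, ResponseSide

#: truncation tolerance for the series expansions (on the normalised scale)
SERIES_TOL = 1e-9

_MAX_TERMS = 4096


class NumericalAccuracyError(RuntimeError):
    """A series expansion could not reach tolerance within the term cap."""


def _normalise(params: DiffusionParams, side: ResponseSide):
    """Map to unit-diffusion, unit-boundary coordinates for ``side``.

    The upper boundary is handled through the mirror identity
    ``f_upper(t | mu, w) = f_lower(t | -mu, 1 - w)``.
    """
    mu = params.v * params.a / params.s**2
    w = params.zr
    if side is ResponseSide.UPPER:
        mu, w = -mu, 1.0 - w
    tscale = params.s**2 / params.a**2  # tau = t * tscale
    return mu, w, tscale


def _p_lower_norm(mu, w):
    """P(absorb at lower boundary) on the normalised scale, stable in mu."""
    mu = np.asarray(mu, dtype=float)
    w = np.asarray(w, dtype=float)
    x = 2.0 * mu
    small = np.abs(x) < 1e-10
    xs = np.where(small, 1.0, x)
    p = np.exp(-xs * w) * np.expm1(-xs * (1.0 - w)) / np.expm1(-xs)
    return np.where(small, 1.0 - w, p)


def _n_terms_large(tau_min: float, tol: float) -> int:
    """Terms needed for the spectral (large-time) series at the smallest tau."""
    k = int(np.ceil(np.sqrt(max(-2.0 * np.log(tol) / tau_min, 1.0)) / np.pi)) + 1
    return max(k, 2)


def _density_norm(tau, mu, w):
    """Defective first-passage density at the lower boundary, normalised scale.

    Vectorised over ``tau``; ``mu`` and ``w`` are scalars.  Chooses the
    cheaper of the two expansions per time point, following the standard
    term-count bounds.
    """
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    if not np.any(pos):
        return out
    tt = tau[pos]
    err = SERIES_TOL

    # term counts per time point
    with np.errstate(invalid="ignore"):
        ok = 2.0 * np.sqrt(2.0 * np.pi * tt) * err < 1.0
        ks = np.where(
            ok,
            2.0 + np.sqrt(np.maximum(-2.0 * tt * np.log(2.0 * err * np.sqrt(2.0 * np.pi * tt)), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(tt) + 1.0)
        kl = np.where(
            np.pi * tt * err < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(np.pi * tt * err), 0.0) / (np.pi**2 * tt)),
            0.0,
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(tt)))

    use_small = ks < kl
    dens = np.empty_like(tt)

    if np.any(use_small):
        t_s = tt[use_small]
        n = int(np.ceil(np.max(ks[use_small])))
        if n > _MAX_TERMS:
            raise NumericalAccuracyError(f"small-time series needs {n} terms (cap {_MAX_TERMS})")
        kk = np.arange(-((n - 1) // 2), ((n - 1) // 2) + (n - 1) % 2 + 1, dtype=float)
        arg = w + 2.0 * kk[None, :]
        p = np.sum(arg * np.exp(-(arg**2) / (2.0 * t_s[:, None])), axis=1)
        dens[use_small] = p / np.sqrt(2.0 * np.pi * t_s**3)

    if np.any(~use_small):
        t_l = tt[~use_small]
        n = int(np.ceil(np.max(kl[~use_small])))
        if n > _MAX_TERMS:
            raise NumericalAccuracyError(f"large-time series needs {n} terms (cap {_MAX_TERMS})")
        kk = np.arange(1, n + 1, dtype=float)
        p = np.sum(
            kk[None, :]
            * np.sin(kk[None, :] * np.pi * w)
            * np.exp(-(kk[None, :] ** 2) * np.pi**2 * t_l[:, None] / 2.0),
            axis=1,
        )
        dens[~use_small] = p * np.pi

    dens = dens * np.exp(-mu * w - mu**2 * tt / 2.0)
    out[pos] = np.maximum(dens, 0.0)
    return out


def _cdf_norm(tau, mu, w, tol=SERIES_TOL):
    """Defective first-passage CDF at the lower boundary, normalised scale.

    Uses the term-wise integral of the spectral series
    ``F(tau) = P_lower - 2*pi*e^{-mu w} sum_k k sin(k pi w)
    e^{-(mu^2 + k^2 pi^2) tau / 2} / (mu^2 + k^2 pi^2)``.
    Below the tau at which the term cap would be exceeded the mass is
    far beyond double-precision zero, so the CDF is returned as 0 there.
    """
    tau = np.asarray(tau, dtype=float)
    p_low = float(_p_lower_norm(mu, w))
    tau_floor = -2.0 * np.log(tol) / (np.pi**2 * _MAX_TERMS**2)
    out = np.zeros_like(tau)
    live = tau > tau_floor
    if not np.any(live):
        return out
    tt = tau[live]
    n = _n_terms_large(float(np.min(tt)), tol)
    kk = np.arange(1, n + 1, dtype=float)
    lam = mu**2 + kk**2 * np.pi**2
    coef = 2.0 * np.pi * kk * np.sin(kk * np.pi * w) * np.exp(-mu * w) / lam
    tail = np.exp(-lam[None, :] * tt[:, None] / 2.0) @ coef
    out[live] = np.clip(p_low - tail, 0.0, p_low)
    return out


# -- public single-trial API -------------------------------------------------

def absorption_probability(params: DiffusionParams, side: ResponseSide) -> float:
    """P(absorb at ``side``) for the single-trial kernel.

    Variability parameters (``eta``, ``sz``, ``st``) and the contaminant
    rate are ignored here; for ``v = 0`` the drift-free limit
    ``P(lower) = 1 - zr`` applies.
    """
    mu, w, _ = _normalise(params, side)
    return float(_p_lower_norm(mu, w))


def fpt_density(t, params: DiffusionParams, side: ResponseSide):
    """Defective first-passage density (per second) at ``side``.

    Integrates over ``t`` in (0, inf) to ``absorption_probability(side)``.
    Raises for non-positive ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("first-passage density is defined for t > 0 only")
    mu, w, tscale = _normalise(params, side)
    dens = _density_norm(t_arr * tscale, mu, w) * tscale
    return float(dens) if np.isscalar(t) or t_arr.ndim == 0 else dens


def fpt_cdf(t, params: DiffusionParams, side: ResponseSide):
    """Defective first-passage CDF at ``side``; 0 at t=0, -> P(side) as t -> inf."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("first-passage CDF is defined for t >= 0")
    mu, w, tscale = _normalise(params, side)
    cdf = _cdf_norm(t_arr * tscale, mu, w)
    return float(cdf) if np.isscalar(t) or t_arr.ndim == 0 else cdf
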