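"""Pixelwise mono-exponential T1ρ mapping.

The signal model is S(TSL) = s0 · exp(−TSL / T1ρ).  Fitting is done by
nonlinear least squares in linear signal space — magnitude (Rician) noise
breaks the homoscedasticity that log-space regression assumes — seeded by
the log-linear closed-form estimate.  The log-linear fit is retained as an
initializer and as an independent oracle for noiseless data.

T1ρ is constrained to [1, 1000] ms; a pixel whose fit lands outside the
bounds, fails to decay, or has no positive signal is marked invalid with a
reason, never silently clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .phantom import TSLSeries

T1RHO_BOUNDS_MS = (1.0, 1000.0)
_INVALID = np.nan


@dataclass(frozen=True)
class PixelFit:
    t1rho: float
    s0: float
    r_squared: float
    valid: bool
    reason: str = ""


@dataclass
class T1rhoMap:
    """Fitted relaxation map: per-pixel T1ρ (ms), amplitude, goodness of fit.

    Invalid pixels (outside the mask or failed fits) carry NaN in the float
    maps and False in ``valid``.
    """

    t1rho: np.ndarray
    s0: np.ndarray
    r_squared: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if not (self.t1rho.shape == self.s0.shape
                == self.r_squared.shape == self.valid.shape):
            raise ValueError("map component shapes differ")


@dataclass(frozen=True)
class RegionStats:
    """Summary of fitted T1ρ within a named region (valid pixels only)."""

    region: str
    mean: float
    sd: float
    median: float
    n_pixels: int
    n_excluded: int = 0


def _loglinear_estimate(signal: np.ndarray, tsl: np.ndarray) -> tuple[float, float]:
    """Closed-form (s0, t1rho) from unweighted regression of ln S on TSL.

    Uses only strictly positive samples; returns t1rho = inf when the signal
    does not decay (non-negative slope).
    """
    pos = signal > 0
    t, y = tsl[pos], np.log(signal[pos])
    if len(t) < 2 or np.ptp(t) == 0:
        return np.nan, np.nan
    slope, intercept = np.polyfit(t, y, 1)
    if slope >= 0:
        return float(np.exp(intercept)), np.inf
    return float(np.exp(intercept)), float(-1.0 / slope)


def fit_monoexp_pixel(signal: np.ndarray, tsl_ms: np.ndarray) -> PixelFit:
    """Fit one pixel's decay curve by bounded nonlinear least squares.

    Returns an invalid result (with a reason) when the signal is nowhere
    positive, does not decay, or the fitted T1ρ escapes [1, 1000] ms.
    """
    signal = np.asarray(signal, dtype=float)
    tsl = np.asarray(tsl_ms, dtype=float)
    if signal.shape != tsl.shape:
        raise ValueError(
            f"signal length {signal.shape} != tsl length {tsl.shape}"
        )
    if len(np.unique(tsl)) < 2:
        raise ValueError("need >= 2 distinct spin-lock durations")
    if not np.any(signal > 0):
        return PixelFit(_INVALID, _INVALID, _INVALID, False,
                        "non-positive signal")

    s0_init, t1rho_init = _loglinear_estimate(signal, tsl)
    if not np.isfinite(t1rho_init):
        return PixelFit(_INVALID, _INVALID, _INVALID, False, "no decay")
    lo, hi = T1RHO_BOUNDS_MS
    x0 = np.array([max(s0_init, 1e-12), np.clip(t1rho_init, lo, hi)])

    def residual(p):
        return p[0] * np.exp(-tsl / p[1]) - signal

    sol = optimize.least_squares(
        residual, x0, bounds=([0.0, lo], [np.inf, hi]), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    s0_fit, t1rho_fit = sol.x
    at_bound = np.isclose(t1rho_fit, lo) or np.isclose(t1rho_fit, hi)
    ss_res = float(np.sum(sol.fun ** 2))
    ss_tot = float(np.sum((signal - signal.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else _INVALID
    if at_bound:
        return PixelFit(_INVALID, _INVALID, _INVALID, False,
                        "t1rho at bounds")
    if not np.isfinite(r2) or r2 < 0:
        return PixelFit(_INVALID, _INVALID, _INVALID, False, "poor fit")
    return PixelFit(float(t1rho_fit), float(s0_fit), float(min(r2, 1.0)), True)


def _fit_monoexp_batch(signals: np.ndarray, tsl: np.ndarray,
                       n_iter: int = 30) -> tuple[np.ndarray, ...]:
    """Vectorized Gauss–Newton mono-exponential fit over many pixels.

    signals : (P, K) magnitudes; tsl : (K,) ms.  Returns per-pixel
    (t1rho, s0, r_squared, valid_mask).  Levenberg damping keeps steps
    stable for pixels whose log-linear initialization is poor.
    """
    P, K = signals.shape
    lo, hi = T1RHO_BOUNDS_MS

    any_pos = np.any(signals > 0, axis=1)
    # log-linear init per pixel on clipped signals (exact for noiseless data)
    eps = np.maximum(signals.max(axis=1, keepdims=True) * 1e-9, 1e-300)
    logs = np.log(np.maximum(signals, eps))
    t_mean = tsl.mean()
    slope = ((tsl - t_mean) @ (logs - logs.mean(axis=1, keepdims=True)).T
             ) / np.sum((tsl - t_mean) ** 2)
    decaying = slope < 0
    with np.errstate(divide="ignore"):
        rate = np.where(decaying, -slope, 1.0 / hi)  # 1/ms
    rate = np.clip(rate, 1.0 / hi, 1.0 / lo)
    s0 = np.exp(logs.mean(axis=1) + rate * t_mean)

    lam = np.full(P, 1e-8)
    cost = np.full(P, np.inf)
    for _ in range(n_iter):
        model = s0[:, None] * np.exp(-np.outer(rate, tsl))
        resid = model - signals
        new_cost = np.sum(resid ** 2, axis=1)
        worse = new_cost > cost + 1e-15
        lam = np.where(worse, lam * 10, np.maximum(lam * 0.3, 1e-12))
        cost = np.minimum(cost, new_cost)
        # Jacobian wrt (s0, rate)
        j_s0 = model / np.maximum(s0[:, None], 1e-300)
        j_rate = -model * tsl[None, :]
        a11 = np.sum(j_s0 * j_s0, axis=1) * (1 + lam)
        a12 = np.sum(j_s0 * j_rate, axis=1)
        a22 = np.sum(j_rate * j_rate, axis=1) * (1 + lam)
        b1 = -np.sum(j_s0 * resid, axis=1)
        b2 = -np.sum(j_rate * resid, axis=1)
        det = a11 * a22 - a12 ** 2
        det = np.where(np.abs(det) < 1e-300, 1.0, det)
        ds0 = (b1 * a22 - b2 * a12) / det
        drate = (a11 * b2 - a12 * b1) / det
        s0 = np.maximum(s0 + ds0, 0.0)
        rate = np.clip(rate + drate, 1.0 / hi, 1.0 / lo)

    t1rho = 1.0 / rate
    model = s0[:, None] * np.exp(-np.outer(rate, tsl))
    ss_res = np.sum((model - signals) ** 2, axis=1)
    ss_tot = np.sum((signals - signals.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    interior = (t1rho > lo * (1 + 1e-6)) & (t1rho < hi * (1 - 1e-6))
    valid = any_pos & decaying & interior & np.isfinite(r2) & (r2 >= 0)
    r2 = np.minimum(r2, 1.0)
    return t1rho, s0, r2, valid


def fit_map(series: TSLSeries, mask: np.ndarray) -> T1rhoMap:
    """Fit the mono-exponential model at every masked pixel of the stack.

    ``mask`` is a boolean (n_slices, ny, nx) volume (a 2-D mask is broadcast
    to every slice).  Pixels outside the mask are invalid.
    """
    data = series.data
    if mask.ndim == 2:
        mask = np.broadcast_to(mask, data.shape[:3])
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match stack {data.shape[:3]}"
        )
    if not mask.any():
        raise ValueError("empty mask: nothing to fit")

    tsl = np.asarray(series.tsl_ms, dtype=float)
    signals = data[mask]  # (P, K)
    t1rho_v, s0_v, r2_v, valid_v = _fit_monoexp_batch(signals, tsl)

    shape = data.shape[:3]
    t1rho = np.full(shape, _INVALID)
    s0 = np.full(shape, _INVALID)
    r2 = np.full(shape, _INVALID)
    valid = np.zeros(shape, dtype=bool)
    t1rho[mask] = np.where(valid_v, t1rho_v, _INVALID)
    s0[mask] = np.where(valid_v, s0_v, _INVALID)
    r2[mask] = np.where(valid_v, r2_v, _INVALID)
    valid[mask] = valid_v
    return T1rhoMap(t1rho=t1rho, s0=s0, r_squared=r2, valid=valid)


def region_t1rho(t1rho_map: T1rhoMap, region_mask: np.ndarray,
                 region: str = "region") -> RegionStats:
    """Mean/SD/median of fitted T1ρ over the valid pixels of a region."""
    if region_mask.shape != t1rho_map.t1rho.shape:
        raise ValueError("region mask shape does not match map")
    in_region = region_mask.astype(bool)
    sel = in_region & t1rho_map.valid
    n_excluded = int(in_region.sum() - sel.sum())
    if not sel.any():
        raise ValueError(f"region {region!r} contains no valid pixels")
    values = t1rho_map.t1rho[sel]
    return RegionStats(
        region=region,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        median=float(np.median(values)),
        n_pixels=int(len(values)),
        n_excluded=n_excluded,
    )
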