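"""Compartment-model parameter estimation by nonlinear least squares.

Given an AIF and a tissue curve on a shared grid, the four parameters
(ktrans, kep, vp, delta_t) of the compartment model are estimated by
Levenberg-Marquardt-style least squares (scipy's trust-region reflective
solver, which handles the box bounds).  ktrans is the quantity of
interest downstream: it is proportional to myocardial blood flow, and
its fitted value inherits any amplitude bias of the AIF reciprocally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .grid import ConcentrationCurve, TimeGrid
from .tissue_kinetics import PKParams, shift_curve, tissue_response

__all__ = ["FitResult", "DEFAULT_BOUNDS", "DEFAULT_INIT", "fit_pk", "ktrans_errors"]

#: Box bounds bracketing every generator range with margin:
#: ktrans [0,5], kep [0,20], vp [0,0.2], delta_t [0,0.1] (minutes).
DEFAULT_BOUNDS = (np.array([0.0, 0.0, 0.0, 0.0]), np.array([5.0, 20.0, 0.2, 0.1]))
DEFAULT_INIT = PKParams(ktrans=0.5, kep=2.0, vp=0.02, delta_t=0.02)

# Fixed alternative starting points guard against the occasional local
# minimum in (kep, delta_t); lowest-residual solution wins.
_EXTRA_INITS = (
    np.array([1.5, 6.0, 0.01, 0.0]),
    np.array([0.8, 10.0, 0.04, 0.05]),
)


def _conv_trapezoid(shifted: np.ndarray, kernel: np.ndarray, dt: float) -> np.ndarray:
    n = shifted.size
    conv = np.convolve(shifted, kernel)[:n]
    return dt * (conv - 0.5 * (shifted * kernel[0] + shifted[0] * kernel))


def _model_jacobian(aif_values: np.ndarray, grid: TimeGrid, x: np.ndarray) -> np.ndarray:
    """Jacobian of the forward model: analytic in (ktrans, kep, vp),
    central finite difference in the arrival delay (the shift enters
    through interpolation and is not smooth in closed form)."""
    ktrans, kep, vp, delta_t = x
    t = grid.values
    shifted = shift_curve(aif_values, grid, delta_t)
    ek = np.exp(-kep * t)
    d_ktrans = _conv_trapezoid(shifted, ek, grid.dt)
    d_kep = _conv_trapezoid(shifted, -ktrans * t * ek, grid.dt)
    d_vp = shifted
    h = 1e-4
    up = tissue_response(aif_values, grid, ktrans, kep, vp, delta_t + h)
    dn = tissue_response(aif_values, grid, ktrans, kep, vp, max(delta_t - h, 0.0))
    d_delay = (up - dn) / (delta_t + h - max(delta_t - h, 0.0))
    return np.column_stack([d_ktrans, d_kep, d_vp, d_delay])


@dataclass
class FitResult:
    pk: PKParams
    residual_norm: float
    converged: bool
    n_iterations: int

    def to_dict(self) -> dict:
        return {
            "pk": self.pk.to_dict(),
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
        }


def fit_pk(
    aif: ConcentrationCurve,
    tissue: ConcentrationCurve,
    init: PKParams = DEFAULT_INIT,
    bounds: tuple[np.ndarray, np.ndarray] = DEFAULT_BOUNDS,
    multi_start: bool = True,
) -> FitResult:
    """Fit the four compartment-model parameters of one tissue curve.

    The fit is deterministic: the default start plus two fixed alternates
    are tried and the lowest-residual solution kept.
    """
    if aif.grid != tissue.grid:
        raise ValueError("AIF and tissue curve must share a time grid")
    aif_values = aif.values
    if not np.any(aif_values > 0):
        raise ValueError("degenerate all-zero AIF cannot drive a fit")
    grid = aif.grid
    target = tissue.values

    def residuals(x):
        return tissue_response(aif_values, grid, x[0], x[1], x[2], x[3]) - target

    def jacobian(x):
        return _model_jacobian(aif_values, grid, x)

    lo, hi = bounds
    starts = [np.clip(init.to_array(), lo, hi)]
    if multi_start:
        starts += [np.clip(s, lo, hi) for s in _EXTRA_INITS]

    best = None
    for x0 in starts:
        sol = least_squares(
            residuals,
            x0,
            jac=jacobian,
            bounds=bounds,
            method="trf",
            x_scale=[1.0, 5.0, 0.05, 0.02],
            ftol=1e-5,
            xtol=1e-5,
            gtol=1e-5,
            max_nfev=200,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    pk = PKParams.from_array(best.x)
    return FitResult(
        pk=pk,
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(best.success),
        n_iterations=int(best.nfev),
    )


def ktrans_errors(
    est_aif: ConcentrationCurve,
    tissue_curves: list[ConcentrationCurve],
    true_ktrans_list: list[float],
    multi_start: bool = True,
) -> np.ndarray:
    """Percent errors of fitted vs. true ktrans for each tissue curve.

    Each tissue curve is fitted against the estimated AIF; the error is
    100 * (fitted - true) / true per curve.
    """
    if len(tissue_curves) != len(true_ktrans_list):
        raise ValueError("tissue curves and true ktrans values must align")
    errors = np.empty(len(tissue_curves))
    for i, (tiss, true_kt) in enumerate(zip(tissue_curves, true_ktrans_list)):
        fit = fit_pk(est_aif, tiss, multi_start=multi_start)
        errors[i] = 100.0 * (fit.pk.ktrans - true_kt) / true_kt
    return errors
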