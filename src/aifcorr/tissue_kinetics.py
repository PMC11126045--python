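"""Four-parameter compartment model for myocardial tissue curves.

Tissue enhancement follows the extended-Tofts-type model

    C_tiss(t) = C_AIF(t - dt) (x) ktrans * exp(-kep * t) + vp * C_AIF(t - dt)

where (x) is causal convolution, ktrans (min^-1) is the transfer constant
(proportional to myocardial blood flow), kep = ktrans / ve (min^-1) the
efflux rate, vp the plasma volume fraction and dt the bolus arrival delay
between blood pool and myocardium.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .grid import ConcentrationCurve, TimeGrid

__all__ = [
    "PKParams",
    "VeRange",
    "PK_PARAM_RANGES",
    "LADDER_KTRANS_STEP",
    "tissue_curve",
    "tissue_response",
    "shift_curve",
    "sample_pk_params",
    "ladder_pk_set",
]

#: Uniform sampling ranges of the random pharmacokinetic sampler.
PK_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "ktrans": (0.3, 1.1),
    "kep": (1.0, 5.0),
    "vp": (0.0, 0.05),
    "delta_t": (0.0, 0.05),
}

LADDER_KTRANS_START = 0.3
LADDER_KTRANS_STEP = 0.2
LADDER_MAX_CURVES = 11  # ktrans 0.3 .. 2.3


@dataclass(frozen=True)
class PKParams:
    """Compartment-model parameters: ktrans, kep in min^-1; vp, delta_t as above."""

    ktrans: float
    kep: float
    vp: float
    delta_t: float

    def __post_init__(self) -> None:
        if self.ktrans < 0 or self.kep < 0:
            raise ValueError("rate constants must be non-negative")
        if not 0.0 <= self.vp <= 1.0:
            raise ValueError("vp is a volume fraction in [0, 1]")
        if self.delta_t < 0:
            raise ValueError("arrival delay must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array([self.ktrans, self.kep, self.vp, self.delta_t])

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_array(cls, a) -> "PKParams":
        return cls(ktrans=float(a[0]), kep=float(a[1]), vp=float(a[2]), delta_t=float(a[3]))


@dataclass(frozen=True)
class VeRange:
    """Bounds on the extravascular-extracellular volume fraction ve."""

    lo: float = 0.2
    hi: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.lo <= self.hi < 1.0):
            raise ValueError("need 0 < lo <= hi < 1 for a ve range")


def shift_curve(values: np.ndarray, grid: TimeGrid, delay: float) -> np.ndarray:
    """Delay a sampled curve by ``delay`` minutes with linear interpolation.

    Sub-sample delays are supported; the curve is zero before t = 0.
    """
    if delay == 0.0:
        return np.asarray(values, dtype=float).copy()
    t = grid.values
    return np.interp(t - delay, t, values, left=0.0, right=values[-1])


def tissue_response(
    aif_values: np.ndarray, grid: TimeGrid, ktrans: float, kep: float, vp: float, delta_t: float
) -> np.ndarray:
    """Vectorised forward model on raw arrays (used by fitting and losses).

    Causal convolution uses trapezoid quadrature at the native grid step.
    """
    dt = grid.dt
    shifted = shift_curve(aif_values, grid, delta_t)
    n = grid.n_points
    kernel = ktrans * np.exp(-kep * grid.values)
    conv = np.convolve(shifted, kernel)[:n]
    # trapezoid end-point correction: half weight at lag 0 and lag i
    conv = conv - 0.5 * (shifted * kernel[0] + shifted[0] * kernel)
    return conv * dt + vp * shifted


def tissue_curve(aif: ConcentrationCurve, pk: PKParams) -> ConcentrationCurve:
    """Generate a tissue concentration curve from an AIF and PK parameters."""
    values = tissue_response(aif.values, aif.grid, pk.ktrans, pk.kep, pk.vp, pk.delta_t)
    return ConcentrationCurve(aif.grid, values)


def sample_pk_params(rng: np.random.Generator) -> PKParams:
    """Independent uniform draws over the random pharmacokinetic ranges."""
    draws = {name: rng.uniform(lo, hi) for name, (lo, hi) in PK_PARAM_RANGES.items()}
    return PKParams(**draws)


def ladder_pk_set(
    n_curves: int, ve_range: VeRange | None = None, rng: np.random.Generator | None = None
) -> list[PKParams]:
    """Fixed-ktrans ladder used for network input tissue curves.

    Curve ``i`` gets ktrans = 0.3 + 0.2 i; kep is tied to ktrans via a
    per-curve ve drawn from ``ve_range`` (kep = ktrans / ve); vp and the
    arrival delay come from the random sampler ranges.
    """
    if not 1 <= n_curves <= LADDER_MAX_CURVES:
        raise ValueError(
            f"ladder supports 1..{LADDER_MAX_CURVES} curves (ktrans 0.3..2.3), got {n_curves}"
        )
    ve_range = ve_range or VeRange()
    rng = rng if rng is not None else np.random.default_rng()
    out = []
    for i in range(n_curves):
        ktrans = LADDER_KTRANS_START + LADDER_KTRANS_STEP * i
        ve = rng.uniform(ve_range.lo, ve_range.hi)
        vp = rng.uniform(*PK_PARAM_RANGES["vp"])
        delta_t = rng.uniform(*PK_PARAM_RANGES["delta_t"])
        out.append(PKParams(ktrans=ktrans, kep=ktrans / ve, vp=vp, delta_t=delta_t))
    return out
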