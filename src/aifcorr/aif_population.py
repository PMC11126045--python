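"""Population model of the arterial input function (AIF).

The true (unsaturated) AIF is modelled as the sum of three gamma-variate
bolus passes and one sigmoidal washout term,

    C_AIF(t) = A1 G(l1, tau1, d1) + A2 G(l2, tau2, d1 + d2)
             + A3 G(l2, tau2, d1 + d3) + A4 S(l2, tau3, d1 + d3, T),

with tau3 tied to tau2 so that twelve parameters remain free.  The first
gamma variate is the first pass of the bolus through the left ventricle,
the second and third model recirculation peaks, and the sigmoid captures
the slow equilibration and renal elimination of the agent.

Each gamma variate is normalised to unit peak, so the amplitudes ``A_k``
are directly peak concentrations in mM; realistic first-pass peaks for a
standard contrast dose fall in the 3-9 mM range used by the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import gammainc

from .grid import ConcentrationCurve, TimeGrid

__all__ = [
    "AIFParams",
    "AIF_PARAM_RANGES",
    "gamma_variate",
    "sigmoid_washout",
    "sample_aif_params",
    "evaluate_aif",
]

#: Uniform sampling ranges of the population model (times in minutes).
AIF_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "A1": (3.0, 9.0),
    "lambda1": (5.0, 13.0),
    "tau1": (0.015, 0.025),
    "delta1": (0.1, 0.15),
    "A2": (0.75, 1.25),
    "lambda2": (5.0, 7.0),
    "tau2": (0.15, 0.25),
    "delta2": (0.04, 0.05),
    "A3": (0.35, 0.55),
    "delta3": (0.56, 0.76),
    "A4": (2.5, 3.5),
    "T": (0.35, 0.55),
}


@dataclass(frozen=True)
class AIFParams:
    """The twelve free parameters of the AIF population model.

    Amplitudes ``A1..A4`` are dimensionless scalings (mM once multiplied
    into the unit-peak basis functions); ``lambda*`` are shape parameters,
    ``tau*`` widths in minutes, ``delta*`` delays in minutes and ``T`` the
    elimination time constant in minutes.
    """

    A1: float
    lambda1: float
    tau1: float
    delta1: float
    A2: float
    lambda2: float
    tau2: float
    delta2: float
    A3: float
    delta3: float
    A4: float
    T: float

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"AIF parameter {name} must be positive, got {value}")

    @property
    def tau3(self) -> float:
        """Width of the sigmoid term, tied to the recirculation width."""
        return self.tau2

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "AIFParams":
        return cls(**{k: float(d[k]) for k in AIF_PARAM_RANGES})


def gamma_variate(grid: TimeGrid, lam: float, tau: float, delta: float) -> np.ndarray:
    """Unit-peak gamma variate ``g(t)``.

    ``g(t) = ((t-delta)/(lam*tau))**lam * exp(lam - (t-delta)/tau)`` for
    ``t > delta`` and 0 before; the peak value is exactly 1 at
    ``t = delta + lam*tau``.
    """
    if lam <= 0 or tau <= 0:
        raise ValueError("gamma-variate shape and width must be positive")
    if delta < 0:
        raise ValueError("delay must be non-negative")
    t = grid.values - delta
    out = np.zeros(grid.n_points)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(lam * np.log(tp / (lam * tau)) + lam - tp / tau)
    return out


def sigmoid_washout(
    grid: TimeGrid, lam: float, tau: float, delta: float, T: float
) -> np.ndarray:
    """Sigmoidal rise times exponential elimination.

    ``s(t) = P(lam, (t-delta)/tau) * exp(-(t-delta)/T)`` for ``t > delta``,
    where ``P`` is the regularised lower incomplete gamma function.  The
    rise saturates at 1 and the exponential models elimination from the
    blood pool with time constant ``T``.
    """
    if lam <= 0 or tau <= 0 or T <= 0:
        raise ValueError("sigmoid shape, width and elimination constant must be positive")
    t = grid.values - delta
    out = np.zeros(grid.n_points)
    pos = t > 0
    tp = t[pos]
    out[pos] = gammainc(lam, tp / tau) * np.exp(-tp / T)
    return out


def sample_aif_params(rng: np.random.Generator) -> AIFParams:
    """Draw one parameter set, each field uniform over its population range."""
    draws = {name: rng.uniform(lo, hi) for name, (lo, hi) in AIF_PARAM_RANGES.items()}
    return AIFParams(**draws)


def evaluate_aif(params: AIFParams, grid: TimeGrid) -> ConcentrationCurve:
    """Evaluate the population model on a time grid."""
    p = params
    values = (
        p.A1 * gamma_variate(grid, p.lambda1, p.tau1, p.delta1)
        + p.A2 * gamma_variate(grid, p.lambda2, p.tau2, p.delta1 + p.delta2)
        + p.A3 * gamma_variate(grid, p.lambda2, p.tau2, p.delta1 + p.delta3)
        + p.A4 * sigmoid_washout(grid, p.lambda2, p.tau3, p.delta1 + p.delta3, p.T)
    )
    return ConcentrationCurve(grid, values)
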