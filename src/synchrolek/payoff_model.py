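"""Strategy functions and the individual payoff.

The benefit an individual draws from a group display factorizes as
``b_i = g(R) * f(theta_i - phi)``: a group term ``g(R)`` (how many mates
the collective signal attracts, an increasing function of the order
parameter) times an individual *strategy function* ``f`` evaluated at the
individual's deviation ``dtheta`` from the group mean phase.  ``f`` is
itself the product of a mate-attraction factor (minimized in sync --
deviants stand out to mates) and a policing *tolerance* factor
(maximized in sync -- deviants stand out to enforcers).  Net payoff is
``p_i = b_i - beta * c_i`` with ``c_i`` the control-effort cost.

Shipped strategy shapes (all 2*pi-periodic, nonnegative):

``binary_baseline`` / ``no_policing``
    ``1 - cos(dtheta)``: attraction only, maximal at antiphase.
``symmetric_policing``
    ``cos(4*(dtheta - pi/4)) + 1 = 1 - cos(4*dtheta)`` on
    ``|dtheta| < pi/2``, zero outside: twin peaks at +-pi/4, so a
    *moderate* lead or lag pays while in-sync and extreme deviants earn
    nothing.
``asymmetric_policing``
    the same expression restricted to ``0 < dtheta < pi/2``: only
    leading the group pays; laggards are policed to zero benefit.
``strong_policing``
    ``amplitude * exp(concentration * (cos(dtheta) - 1))``, a von
    Mises-shaped tolerance with its unique maximum at ``dtheta = 0``:
    policing is severe enough that even slight deviation forfeits most
    of the benefit, so there is no net gain from being out of sync and
    honesty is the best policy.  ``concentration`` sets how slight a
    deviation is punished (tolerance width ~ 1/sqrt(concentration)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable

import numpy as np

from .phase_dynamics import SyncState, wrap_phase

__all__ = [
    "StrategyKind",
    "StrategyFunction",
    "PayoffParams",
    "strategy_value",
    "group_benefit",
    "individual_payoff",
]


class StrategyKind(str, Enum):
    BINARY_BASELINE = "binary_baseline"
    SYMMETRIC_POLICING = "symmetric_policing"
    ASYMMETRIC_POLICING = "asymmetric_policing"
    STRONG_POLICING = "strong_policing"
    NO_POLICING = "no_policing"


@dataclass
class StrategyFunction:
    """A named strategy shape ``f(dtheta)``.

    ``support_halfwidth`` is the policing support half-width (pi/2 for the
    canonical policing forms; the twin peaks sit at half that).
    ``parameters`` holds named scalars for custom shapes -- currently
    ``amplitude`` (default 2.0) and ``concentration`` (default 25.0) for
    ``strong_policing``.
    """

    kind: StrategyKind
    support_halfwidth: float = np.pi / 2
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kind = StrategyKind(self.kind)
        if self.support_halfwidth <= 0 or self.support_halfwidth > np.pi:
            raise ValueError("support_halfwidth must lie in (0, pi]")

    def __call__(self, delta_theta):
        return strategy_value(delta_theta, self)


def strategy_value(delta_theta, spec: StrategyFunction):
    """Evaluate ``f(dtheta)``; input is wrapped to (-pi, pi] first."""
    scalar = np.ndim(delta_theta) == 0
    d = np.atleast_1d(wrap_phase(np.asarray(delta_theta, dtype=float)))
    hw = spec.support_halfwidth
    kind = StrategyKind(spec.kind)
    if kind in (StrategyKind.BINARY_BASELINE, StrategyKind.NO_POLICING):
        out = 1.0 - np.cos(d)
    elif kind is StrategyKind.SYMMETRIC_POLICING:
        # 1 - cos(2 pi d / (2 hw)) rescaled so that the support is (-hw, hw);
        # for hw = pi/2 this is cos(4(d - pi/4)) + 1 = 1 - cos(4 d).
        out = np.where(np.abs(d) < hw, 1.0 - np.cos(2.0 * np.pi * d / hw), 0.0)
    elif kind is StrategyKind.ASYMMETRIC_POLICING:
        out = np.where((d > 0) & (d < hw), 1.0 - np.cos(2.0 * np.pi * d / hw), 0.0)
    elif kind is StrategyKind.STRONG_POLICING:
        amplitude = float(spec.parameters.get("amplitude", 2.0))
        concentration = float(spec.parameters.get("concentration", 25.0))
        if amplitude < 0 or concentration <= 0:
            raise ValueError(
                "strong_policing needs amplitude >= 0 and concentration > 0"
            )
        out = amplitude * np.exp(concentration * (np.cos(d) - 1.0))
    else:  # pragma: no cover - StrategyKind() already rejects unknown kinds
        raise ValueError(f"unknown strategy kind: {spec.kind!r}")
    return float(out[0]) if scalar else out


def _identity(r: float) -> float:
    return r


@dataclass
class PayoffParams:
    """Payoff weighting: cost weight ``beta`` and group-benefit map ``g``.

    ``benefit`` defaults to the identity ``g(R) = R``.  A custom ``g`` is
    checked numerically to be positive and nondecreasing on (0, 1].
    """

    cost_weight: float = 1.0
    benefit: Callable[[float], float] = _identity

    def __post_init__(self) -> None:
        if self.cost_weight < 0:
            raise ValueError("cost_weight (beta) must be >= 0")
        if self.benefit is not _identity:
            grid = np.linspace(1e-6, 1.0, 64)
            vals = np.array([float(self.benefit(r)) for r in grid])
            if np.any(vals <= 0) or np.any(np.diff(vals) < -1e-12):
                raise ValueError(
                    "benefit g(R) must be positive and nondecreasing on (0, 1]"
                )


def group_benefit(sync: SyncState, params: PayoffParams) -> float:
    """Group-level benefit ``g(R)``."""
    return float(params.benefit(sync.order_parameter))


def individual_payoff(
    delta_theta,
    sync: SyncState,
    cost,
    spec: StrategyFunction,
    params: PayoffParams,
):
    """Net payoff ``p = g(R) f(dtheta) - beta * cost`` (vectorized)."""
    cost = np.asarray(cost, dtype=float)
    if np.any(cost < 0):
        raise ValueError("cost must be >= 0")
    p = group_benefit(sync, params) * strategy_value(delta_theta, spec) - (
        params.cost_weight * cost
    )
    return float(p) if np.ndim(p) == 0 else p
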