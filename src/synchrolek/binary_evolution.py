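"""Two-type (cooperator/cheater) evolutionary dynamics.

The simplest evolutionary scenario restricts phase lags to two values:
cooperators with ``alpha_co = 0`` and cheaters with a common
``alpha_ch != 0``.  At a frequency-locked equilibrium each type forms an
internally synchronized cluster and the whole fast layer collapses onto
a single gap variable ``dgap = theta_ch - theta_co`` obeying

    K^-1 d(dgap)/dt = n_co sin(-dgap + a_ch) + n_ch sin(a_ch) - n_ch sin(dgap),

with equilibrium ``dgap* = alpha_ch``.  Linear stability of that
equilibrium requires

    n_ch < 1 / (1 - cos(alpha_ch)),

the model's central result: a population can tolerate cheaters, but only
up to that fraction.  For ``alpha_ch < pi/2`` the bound exceeds 1, so no
admissible cheater fraction destabilizes synchrony.

With ``g(R) = R`` and ``f(dtheta) = 1 - cos(dtheta)`` the equilibrium
payoffs are closed-form (the effort cost is identical across types and
drops out of payoff differences):

    p_co = R (1 - cos(phi)),   p_ch = R (1 - cos(alpha_ch - phi)),

where ``R e^{i phi} = n_co + n_ch e^{i alpha_ch}``.  Feeding these into
replicator dynamics (discrete map or its continuous-time limit) gives
the slow membership dynamics; any persistent mixed population relaxes to
a 50-50 split, because the minority type always earns the higher payoff.

``critical_fraction_sweep`` provides the independent numerical check on
the analytic bound: it runs the full N-oscillator model over a grid of
``(alpha_ch, n_ch)`` and locates the smallest cheater fraction whose
equilibrium order parameter falls below an incoherence threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from .phase_dynamics import (
    IntegrationError,
    OscillatorEnsemble,
    SyncState,
    integrate_fast,
    wrap_phase,
)

__all__ = [
    "BinaryPopulation",
    "TwoClusterState",
    "SelectionParams",
    "SweepConfig",
    "StabilityResult",
    "PayoffTriple",
    "ReplicatorTrajectory",
    "StabilityWarning",
    "mean_field_sync",
    "closed_form_payoffs",
    "replicator_step",
    "replicator_flow",
    "reduced_gap_rhs",
    "integrate_reduced_gap",
    "stability_bound",
    "is_synchrony_stable",
    "numeric_stability_threshold",
    "critical_fraction_sweep",
]


class StabilityWarning(UserWarning):
    """Closed-form payoffs requested outside the synchronized regime."""


@dataclass
class BinaryPopulation:
    """Cooperator/cheater composition and their phase-lag strategies."""

    frac_cooperators: float
    frac_cheaters: float
    lag_cooperators: float = 0.0
    lag_cheaters: float = np.pi / 2

    def __post_init__(self) -> None:
        if self.frac_cooperators < 0 or self.frac_cheaters < 0:
            raise ValueError("fractions must be >= 0")
        if abs(self.frac_cooperators + self.frac_cheaters - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1 (within 1e-12)")

    @property
    def lag_gap(self) -> float:
        """Strategy offset ``alpha_ch - alpha_co`` (the effective cheater lag)."""
        return self.lag_cheaters - self.lag_cooperators


@dataclass
class TwoClusterState:
    """Gap variable ``theta_ch - theta_co`` of the two-cluster reduction."""

    gap: float

    def __post_init__(self) -> None:
        self.gap = wrap_phase(self.gap)


@dataclass
class SelectionParams:
    """Selection strength: ``k1`` for the discrete map, ``k`` for the flow.

    ``selection_strength`` must be weak enough that the discrete-map
    growth factors ``1 + k1 (p - pbar)`` stay positive; that is validated
    at each step rather than up front.
    """

    selection_strength: float = 0.1
    time_step: float = 1.0

    def __post_init__(self) -> None:
        if self.selection_strength <= 0:
            raise ValueError("selection_strength must be positive")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")


class PayoffTriple(NamedTuple):
    cooperator: float
    cheater: float
    mean: float


class StabilityResult(NamedTuple):
    stable: bool
    margin: float
    slope: float


def mean_field_sync(pop: BinaryPopulation) -> SyncState:
    """Order parameter of the two-cluster configuration.

    Cooperators sit at phase 0 and cheaters at the equilibrium gap
    ``alpha_ch - alpha_co``, so ``R e^{i phi} = n_co + n_ch e^{i gap}``.
    """
    z = pop.frac_cooperators + pop.frac_cheaters * np.exp(1j * pop.lag_gap)
    r = min(float(np.abs(z)), 1.0)
    defined = r > 1e-12
    phi = wrap_phase(float(np.angle(z))) if defined else 0.0
    return SyncState(order_parameter=r, mean_phase=phi, mean_phase_defined=defined)


def closed_form_payoffs(pop: BinaryPopulation, *, warn: bool = True) -> PayoffTriple:
    """Equilibrium payoffs ``(p_co, p_ch, pbar)`` in the clustered regime.

    Uses ``g(R) = R`` and ``f = 1 - cos``; the effort cost is uniform
    across types here and therefore omitted (it cancels from every payoff
    difference the replicator dynamics consume).  Outside the stable
    regime a :class:`StabilityWarning` is issued: the closed form presumes
    two frequency-locked clusters.
    """
    if warn and not is_synchrony_stable(pop).stable:
        warnings.warn(
            "closed-form payoffs evaluated beyond the synchrony-stability bound; "
            "the clustered equilibrium they presume does not exist there",
            StabilityWarning,
            stacklevel=2,
        )
    sync = mean_field_sync(pop)
    r, phi = sync.order_parameter, sync.mean_phase
    p_co = r * (1.0 - np.cos(phi))
    p_ch = r * (1.0 - np.cos(pop.lag_gap - phi))
    p_bar = pop.frac_cooperators * p_co + pop.frac_cheaters * p_ch
    return PayoffTriple(float(p_co), float(p_ch), float(p_bar))


def replicator_step(
    pop: BinaryPopulation, payoffs: PayoffTriple, sel: SelectionParams
) -> BinaryPopulation:
    """One generation of the discrete replicator map.

    ``n_x' = n_x (1 + k1 (p_x - pbar))``; the total fraction is conserved
    identically.  Raises if selection is strong enough to drive a growth
    factor non-positive.
    """
    k1 = sel.selection_strength
    factor_co = 1.0 + k1 * (payoffs.cooperator - payoffs.mean)
    factor_ch = 1.0 + k1 * (payoffs.cheater - payoffs.mean)
    if factor_co <= 0 or factor_ch <= 0:
        raise ValueError(
            "selection too strong: growth factor 1 + k1 (p - pbar) is non-positive"
        )
    return BinaryPopulation(
        pop.frac_cooperators * factor_co,
        pop.frac_cheaters * factor_ch,
        pop.lag_cooperators,
        pop.lag_cheaters,
    )


@dataclass
class ReplicatorTrajectory:
    """Sampled solution of the continuous replicator flow."""

    times: np.ndarray
    frac_cheaters: np.ndarray
    lag_cooperators: float
    lag_cheaters: float

    @property
    def frac_cooperators(self) -> np.ndarray:
        return 1.0 - self.frac_cheaters

    def population(self, index: int) -> BinaryPopulation:
        n_ch = float(self.frac_cheaters[index])
        return BinaryPopulation(1.0 - n_ch, n_ch, self.lag_cooperators, self.lag_cheaters)

    @property
    def final(self) -> BinaryPopulation:
        return self.population(-1)

    def sync_history(self) -> np.ndarray:
        """Two-cluster order parameter ``R`` along the trajectory."""
        return np.array(
            [mean_field_sync(self.population(i)).order_parameter
             for i in range(self.times.size)]
        )


def replicator_flow(
    pop: BinaryPopulation,
    sel: SelectionParams,
    horizon: float,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    num_samples: int = 501,
) -> ReplicatorTrajectory:
    """Continuous-time replicator dynamics with closed-form payoffs.

    Integrates ``dn_ch/dt = k n_ch (p_ch - pbar)`` (and ``n_co = 1 - n_ch``),
    recomputing the payoffs from the two-cluster mean field at every
    evaluation.  Boundary states ``n_ch in {0, 1}`` are fixed points.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    k = sel.selection_strength
    a_co, a_ch = pop.lag_cooperators, pop.lag_cheaters

    def rhs(_t, y):
        n_ch = float(np.clip(y[0], 0.0, 1.0))
        p = closed_form_payoffs(
            BinaryPopulation(1.0 - n_ch, n_ch, a_co, a_ch), warn=False
        )
        return [k * n_ch * (p.cheater - p.mean)]

    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        [pop.frac_cheaters],
        t_eval=np.linspace(0.0, horizon, num_samples),
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not sol.success:
        raise IntegrationError(f"replicator flow failed: {sol.message}")
    return ReplicatorTrajectory(
        sol.t.copy(), np.clip(sol.y[0], 0.0, 1.0), a_co, a_ch
    )


def reduced_gap_rhs(state: TwoClusterState, pop: BinaryPopulation) -> float:
    """Right-hand side of the gap equation, per unit coupling ``K``.

    ``n_co sin(-gap + a) + n_ch sin(a) - n_ch sin(gap)`` with
    ``a = alpha_ch - alpha_co`` the effective cheater lag.
    """
    a = pop.lag_gap
    return float(
        pop.frac_cooperators * np.sin(-state.gap + a)
        + pop.frac_cheaters * np.sin(a)
        - pop.frac_cheaters * np.sin(state.gap)
    )


def integrate_reduced_gap(
    gap0: float,
    pop: BinaryPopulation,
    horizon: float,
    *,
    coupling: float = 1.0,
    sample_dt: float = 0.1,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the two-cluster gap ODE; returns ``(times, gap(t))``.

    The gap is integrated unwrapped and wrapped to (-pi, pi] on output.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")

    def rhs(_t, y):
        return [coupling * reduced_gap_rhs(TwoClusterState(y[0]), pop)]

    n = max(int(round(horizon / sample_dt)), 1)
    t_eval = np.linspace(0.0, horizon, n + 1)
    sol = solve_ivp(rhs, (0.0, horizon), [gap0], t_eval=t_eval,
                    rtol=rtol, atol=atol, method="RK45")
    if not sol.success:
        raise IntegrationError(f"reduced gap integration failed: {sol.message}")
    return sol.t.copy(), wrap_phase(sol.y[0])


def stability_bound(lag_cheaters: float) -> float:
    """Critical cheater fraction ``1 / (1 - cos(alpha_ch))``.

    Values above 1 mean no admissible fraction destabilizes synchrony;
    at ``alpha_ch = 0`` (mod 2*pi) the bound is infinite and reported as
    ``inf``.
    """
    denom = 1.0 - np.cos(lag_cheaters)
    if denom < 1e-12:
        return float("inf")
    return float(1.0 / denom)


def is_synchrony_stable(pop: BinaryPopulation, *, deriv_step: float = 1e-6) -> StabilityResult:
    """Stability of the clustered equilibrium ``gap* = alpha_ch``.

    Returns ``(stable, margin, slope)`` where ``margin = bound - n_ch``
    and ``slope`` is the numerically differentiated gap RHS at the
    equilibrium (analytically ``-(n_co + n_ch cos alpha_ch)``); the sign
    of the slope cross-validates the closed-form criterion.
    """
    a = pop.lag_gap
    bound = stability_bound(a)
    margin = bound - pop.frac_cheaters
    stable = pop.frac_cheaters < bound
    up = reduced_gap_rhs(TwoClusterState(a + deriv_step), pop)
    dn = reduced_gap_rhs(TwoClusterState(a - deriv_step), pop)
    slope = (up - dn) / (2.0 * deriv_step)
    if abs(slope) > 1e-8 and (slope < 0) != stable:
        raise RuntimeError(
            "stability criterion and numeric eigenvalue sign disagree "
            f"(n_ch={pop.frac_cheaters}, alpha={a}, slope={slope})"
        )
    return StabilityResult(stable=stable, margin=float(margin), slope=float(slope))


def numeric_stability_threshold(
    lag_cheaters: float, *, xtol: float = 1e-9, deriv_step: float = 1e-6
) -> float:
    """Locate the stability loss by bisection on the numeric eigenvalue.

    Independent of :func:`stability_bound`: differentiates
    :func:`reduced_gap_rhs` at the equilibrium gap numerically and
    bisects the cheater fraction at which the slope changes sign.  Only
    meaningful when the analytic bound lies in (0, 1], i.e. for
    ``alpha_ch`` with ``cos(alpha_ch) <= 0``.
    """

    def slope(n_ch: float) -> float:
        pop = BinaryPopulation(1.0 - n_ch, n_ch, 0.0, lag_cheaters)
        up = reduced_gap_rhs(TwoClusterState(lag_cheaters + deriv_step), pop)
        dn = reduced_gap_rhs(TwoClusterState(lag_cheaters - deriv_step), pop)
        return (up - dn) / (2.0 * deriv_step)

    lo, hi = 1e-9, 1.0
    if slope(lo) * slope(hi) > 0:
        raise ValueError(
            "no stability change for cheater fractions in (0, 1]; "
            "alpha_ch is below the pi/2 threshold"
        )
    return float(bisect(slope, lo, hi, xtol=xtol))


@dataclass
class SweepConfig:
    """Full-model settings for the critical-fraction sweep.

    The fast layer is initialized cluster-exactly (cooperators at 0,
    cheaters at ``alpha_ch``) plus wrapped-normal noise of s.d.
    ``noise_sd``, so the sweep probes stability of the synchronized
    solution the analytic bound describes.  ``horizon`` is longer than a
    single display lifetime because the sweep is an asymptotic
    (equilibrium) statement: marginally unstable compositions need time
    for the instability to grow out of the seed noise.  Incoherence is
    declared when the order parameter, time-averaged over the trailing
    ``window_fraction`` of the horizon, falls below
    ``incoherence_threshold``.
    """

    population_size: int = 200
    horizon: float = 400.0
    coupling: float = 1.0
    natural_frequency: float = 0.0
    incoherence_threshold: float = 0.1
    noise_sd: float = 0.05
    window_fraction: float = 0.1
    sample_dt: float = 0.5
    rtol: float = 1e-6
    atol: float = 1e-9
    seed: int = 0


def _equilibrium_order_parameter(
    alpha_ch: float, num_cheaters: int, cfg: SweepConfig, rng: np.random.Generator
) -> float:
    n = cfg.population_size
    lags = np.zeros(n)
    lags[n - num_cheaters:] = alpha_ch
    base = np.zeros(n)
    base[n - num_cheaters:] = alpha_ch
    phases0 = wrap_phase(base + rng.normal(0.0, cfg.noise_sd, n))
    ensemble = OscillatorEnsemble(phases0, lags, cfg.natural_frequency, cfg.coupling)
    t0 = cfg.horizon * (1.0 - cfg.window_fraction)
    m = max(int(round((cfg.horizon - t0) / cfg.sample_dt)), 2)
    sample_times = np.concatenate(([0.0], np.linspace(t0, cfg.horizon, m + 1)))
    traj = integrate_fast(
        ensemble, cfg.horizon, rtol=cfg.rtol, atol=cfg.atol, sample_times=sample_times
    )
    r, _ = traj.sync_history()
    return float(r[1:].mean())  # drop the t=0 sample; window samples are uniform


def critical_fraction_sweep(
    lag_grid, fraction_grid, sim_config: SweepConfig | None = None
) -> pd.DataFrame:
    """Smallest incoherence-producing cheater fraction per phase lag.

    For each ``alpha_ch`` in ``lag_grid``, runs full fast-layer
    simulations over ``fraction_grid`` in increasing order and records
    the first fraction whose equilibrium (time-averaged) order parameter
    drops below the incoherence threshold.  Returns a DataFrame with
    columns ``alpha_ch``, ``critical_fraction`` (NaN when no fraction
    <= 1 produces incoherence) and ``order_parameter_at_critical``.
    """
    cfg = sim_config or SweepConfig()
    lag_grid = np.asarray(lag_grid, dtype=float)
    fraction_grid = np.asarray(fraction_grid, dtype=float)
    if lag_grid.size == 0 or fraction_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(np.diff(lag_grid) <= 0) or np.any(np.diff(fraction_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    if fraction_grid[0] <= 0 or fraction_grid[-1] > 1:
        raise ValueError("fractions must lie in (0, 1]")

    children = np.random.SeedSequence(cfg.seed).spawn(lag_grid.size)
    records = []
    for alpha, child in zip(lag_grid, children):
        rng = np.random.default_rng(child)
        critical, r_at = float("nan"), float("nan")
        for frac in fraction_grid:
            num_cheaters = int(round(frac * cfg.population_size))
            if num_cheaters == 0 or num_cheaters == cfg.population_size:
                continue
            try:
                r_eq = _equilibrium_order_parameter(alpha, num_cheaters, cfg, rng)
            except IntegrationError as exc:
                raise IntegrationError(
                    f"sweep failed at alpha_ch={alpha:.6g}, fraction={frac:.6g}: {exc}"
                ) from exc
            if r_eq < cfg.incoherence_threshold:
                critical, r_at = float(frac), r_eq
                break
        records.append(
            {
                "alpha_ch": float(alpha),
                "critical_fraction": critical,
                "order_parameter_at_critical": r_at,
            }
        )
    return pd.DataFrame.from_records(records)
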