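"""Fast-timescale phase dynamics of a synchronizing display group.

Each of the ``N`` displaying individuals (flashing fireflies, waving
fiddler crabs, calling frogs, ...) is a phase oscillator whose phase
``theta_i`` follows a Sakaguchi--Kuramoto equation

    dtheta_i/dt = omega + (K/N) * sum_j sin(theta_j - theta_i + alpha_i),

where ``omega`` is the (universal) intrinsic display frequency, ``K >= 0``
the coupling strength, and ``alpha_i`` the individual's *phase-lag
strategy*: ``alpha_i = 0`` seeks in-phase alignment with the group, while
``alpha_i != 0`` seeks a consistent offset from it -- signalling slightly
ahead of or behind the pack.  The coupling sum deliberately includes the
self term ``j = i`` (contributing ``sin(alpha_i)``), which is what makes
the exact two-cluster reduction in :mod:`synchrolek.binary_evolution`
consistent with the full model.  Via the mean-field identity the drive on
individual ``i`` is exactly ``K * R * sin(phi - theta_i + alpha_i)`` with
``R`` and ``phi`` the modulus and argument of the population's mean
phasor, so every right-hand-side evaluation is O(N).

The coupling drive ``u_i`` is also the *control effort* an individual
spends adjusting to its neighbours; its time-averaged square is the cost
term of the evolutionary payoff.  Intrinsic oscillation (``omega``) is
not counted as effort since all individuals oscillate equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "IntegrationError",
    "OscillatorEnsemble",
    "SyncState",
    "FastTrajectory",
    "wrap_phase",
    "order_parameter",
    "coupling_drive",
    "phase_derivatives",
    "integrate_fast",
    "time_averaged_cost",
    "cluster_gap",
]

_TWO_PI = 2.0 * np.pi


class IntegrationError(RuntimeError):
    """The ODE solver failed to meet its error tolerances."""


def wrap_phase(angle):
    """Wrap angles (radians) to the interval (-pi, pi].

    Accepts scalars or arrays; scalars come back as Python floats.
    """
    wrapped = np.pi - (np.pi - np.asarray(angle, dtype=float)) % _TWO_PI
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass
class OscillatorEnsemble:
    """State and parameters of the fast oscillator layer.

    Parameters
    ----------
    phases
        Current phases ``theta_i`` (radians); stored wrapped to (-pi, pi].
    phase_lags
        Per-individual strategies ``alpha_i`` (radians).
    natural_frequency
        Universal intrinsic frequency ``omega`` (radians / time).
    coupling
        Coupling strength ``K >= 0`` (dimensionless).
    """

    phases: np.ndarray
    phase_lags: np.ndarray
    natural_frequency: float = 0.0
    coupling: float = 1.0

    def __post_init__(self) -> None:
        self.phases = wrap_phase(np.atleast_1d(np.asarray(self.phases, dtype=float)))
        self.phase_lags = np.atleast_1d(np.asarray(self.phase_lags, dtype=float))
        if self.phases.size < 1:
            raise ValueError("ensemble needs at least one oscillator")
        if self.phases.shape != self.phase_lags.shape:
            raise ValueError(
                f"phases ({self.phases.shape}) and phase_lags "
                f"({self.phase_lags.shape}) must have the same length"
            )
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")

    @property
    def size(self) -> int:
        return self.phases.size


@dataclass
class SyncState:
    """Kuramoto order parameter ``R`` and mean phase ``phi``.

    ``R = 1`` is perfect phase synchrony, ``R = 0`` incoherence; when
    ``R = 0`` the mean phase is geometrically undefined and
    ``mean_phase_defined`` is False (``mean_phase`` is then reported as 0).
    """

    order_parameter: float
    mean_phase: float
    mean_phase_defined: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.order_parameter <= 1.0:
            raise ValueError("order parameter must lie in [0, 1]")


@dataclass
class FastTrajectory:
    """Sampled solution of the fast layer over one lifetime [0, T].

    ``phase_history`` and ``effort_history`` have shape
    ``(num_times, N)``; phases are stored wrapped to (-pi, pi].
    """

    times: np.ndarray
    phase_history: np.ndarray
    effort_history: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.phase_history = np.asarray(self.phase_history, dtype=float)
        self.effort_history = np.asarray(self.effort_history, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need at least two sample times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if abs(self.times[0]) > 1e-12:
            raise ValueError("times must start at 0")
        shape = (self.times.size, self.phase_history.shape[-1])
        if self.phase_history.shape != shape or self.effort_history.shape != shape:
            raise ValueError("history arrays must have shape (num_times, N)")

    @property
    def horizon(self) -> float:
        return float(self.times[-1])

    @property
    def size(self) -> int:
        return self.phase_history.shape[1]

    @property
    def final_phases(self) -> np.ndarray:
        return self.phase_history[-1]

    def sync_history(self) -> tuple[np.ndarray, np.ndarray]:
        """Order parameter ``R(t)`` and mean phase ``phi(t)`` at sample times."""
        z = np.exp(1j * self.phase_history).mean(axis=1)
        return np.abs(z), np.angle(z)


def order_parameter(phases) -> SyncState:
    """Order parameter of a phase set via the complex mean of unit phasors."""
    phases = np.atleast_1d(np.asarray(phases, dtype=float))
    if phases.size == 0:
        raise ValueError("order parameter requires at least one phase")
    z = np.exp(1j * phases).mean()
    r = float(np.abs(z))
    r = min(r, 1.0)  # guard rounding above 1 for identical phases
    defined = r > 1e-12
    phi = wrap_phase(float(np.angle(z))) if defined else 0.0
    return SyncState(order_parameter=r, mean_phase=phi, mean_phase_defined=defined)


def _drive(phases: np.ndarray, lags: np.ndarray, coupling: float) -> np.ndarray:
    # (K/N) sum_j sin(theta_j - theta_i + alpha_i), self term included,
    # evaluated through the mean phasor: K R sin(phi - theta_i + alpha_i).
    z = np.exp(1j * phases).mean()
    return coupling * np.abs(z) * np.sin(np.angle(z) - phases + lags)


def coupling_drive(ensemble: OscillatorEnsemble) -> np.ndarray:
    """Per-individual control effort ``u_i`` (radians / time)."""
    return _drive(ensemble.phases, ensemble.phase_lags, ensemble.coupling)


def phase_derivatives(ensemble: OscillatorEnsemble) -> np.ndarray:
    """Instantaneous ``dtheta_i/dt = omega + u_i``."""
    return ensemble.natural_frequency + coupling_drive(ensemble)


def integrate_fast(
    ensemble: OscillatorEnsemble,
    horizon: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    sample_dt: float = 0.1,
    sample_times: np.ndarray | None = None,
    method: str = "RK45",
) -> FastTrajectory:
    """Integrate the fast layer over ``[0, horizon]``.

    Uses an adaptive explicit Runge-Kutta scheme; the solution is sampled
    either on a uniform grid of spacing ``sample_dt`` or at the caller's
    ``sample_times`` (which must start at 0 and end at ``horizon``).
    Raises :class:`IntegrationError` if the solver reports failure.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if sample_times is None:
        n = max(int(round(horizon / sample_dt)), 1)
        t_eval = np.linspace(0.0, horizon, n + 1)
    else:
        t_eval = np.asarray(sample_times, dtype=float)
        if abs(t_eval[0]) > 1e-12 or abs(t_eval[-1] - horizon) > 1e-9:
            raise ValueError("sample_times must span [0, horizon]")

    lags = ensemble.phase_lags
    omega = ensemble.natural_frequency
    coupling = ensemble.coupling

    def rhs(_t, theta):
        return omega + _drive(theta, lags, coupling)

    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        ensemble.phases,
        t_eval=t_eval,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"fast-layer integration failed: {sol.message}")

    theta = sol.y.T  # (num_times, N)
    z = np.exp(1j * theta).mean(axis=1)
    effort = coupling * np.abs(z)[:, None] * np.sin(
        np.angle(z)[:, None] - theta + lags[None, :]
    )
    return FastTrajectory(sol.t.copy(), wrap_phase(theta), effort)


def time_averaged_cost(
    trajectory: FastTrajectory, window_fraction: float = 1.0
) -> np.ndarray:
    """Per-individual cost ``c_i = <|u_i|^2>`` over a trailing window.

    ``window_fraction`` selects the trailing fraction of the horizon; 1
    averages over the whole trajectory, 0.1 gives the final-10% window
    conventionally used for payoff evaluation once transients have
    decayed.  Trapezoidal quadrature over the stored effort samples.
    """
    if not 0.0 < window_fraction <= 1.0:
        raise ValueError("window_fraction must lie in (0, 1]")
    t_start = trajectory.horizon * (1.0 - window_fraction) - 1e-9
    mask = trajectory.times >= t_start
    if mask.sum() < 2:
        raise ValueError("cost window must contain at least two samples")
    t = trajectory.times[mask]
    u2 = trajectory.effort_history[mask] ** 2
    return np.trapezoid(u2, t, axis=0) / (t[-1] - t[0])


def cluster_gap(phases, cheater_mask) -> float:
    """Wrapped gap between cheater- and cooperator-cluster mean phases.

    The gap is ``circmean(theta[cheaters]) - circmean(theta[cooperators])``
    wrapped to (-pi, pi]; both groups must be non-empty.
    """
    phases = np.asarray(phases, dtype=float)
    mask = np.asarray(cheater_mask, dtype=bool)
    if not mask.any() or mask.all():
        raise ValueError("both clusters must be non-empty")
    mean_ch = np.angle(np.exp(1j * phases[mask]).mean())
    mean_co = np.angle(np.exp(1j * phases[~mask]).mean())
    return wrap_phase(mean_ch - mean_co)
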