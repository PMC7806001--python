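"""Characteristic scales, steady-state analysis, and independent 2D oracles.

The planar restriction of the 3D model is the ACE tropism model

    D kappa / Dt = (Edot / R) (lambda sin(theta) - gamma kappa),

with ``theta(s, t)`` the local angle between the tangent and the stimulus
and ``d theta / d s = -kappa`` (orientation chosen so that ``theta``
decreases as the organ bends toward the stimulus and ``kappa`` matches the
3D run's positive ``kappa1``).  :func:`ace_oracle_2d` integrates it on the
same grid and stepping as the 3D scheme, sharing nothing with the 3D code
beyond scalar arithmetic, and serves as the validation oracle for planar
scenarios.

:func:`bressan_oracle_2d` integrates the accretive-growth comparison model

    d kappa / d t = lambda exp(-eta (t - s)) sin(theta(s, t)),

in which elongation is implicit: the exponential "stiffness factor" plays
the role of a smooth growth zone of size ``1/eta`` and no material
derivative (and no proprioception) appears.

Dimensional analysis of the ACE limit yields the characteristic scales
bundled in :class:`CharacteristicScales`, chief among them the balance
number ``B = lambda Lgz / gamma`` comparing tropic drive to proprioceptive
damping.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .simulate import SimulationConfig, TrajectoryRecord

__all__ = [
    "CharacteristicScales",
    "NotConvergedError",
    "characteristic_scales",
    "ace_oracle_2d",
    "bressan_oracle_2d",
    "steady_state_kappa_max",
    "arrival_time",
    "tip_angle_series",
]


class NotConvergedError(RuntimeError):
    """The steady-state criterion never held over the recorded run."""


@dataclasses.dataclass(frozen=True)
class CharacteristicScales:
    """Characteristic length/time scales of a tropic response.

    Lc = gamma / lambda        convergence length (steady radius of curvature)
    Tc = R / (Edot gamma)      convergence time (shape relaxation)
    Tv = R / (Edot Lgz lambda) arrival time (first alignment with the stimulus)
    B  = lambda Lgz / gamma    balance number = Lgz/Lc = Tc/Tv = kappa_max Lgz
    kappa_max_pred = lambda / gamma   predicted steady maximal curvature
    """

    Lc: float
    Tc: float
    Tv: float
    B: float
    kappa_max_pred: float


def characteristic_scales(
    lambda_: float, gamma: float, Lgz: float, R: float, growth_rate: float
) -> CharacteristicScales:
    """Evaluate the characteristic scales; all inputs must be positive."""
    for name, val in (
        ("lambda_", lambda_),
        ("gamma", gamma),
        ("Lgz", Lgz),
        ("R", R),
        ("growth_rate", growth_rate),
    ):
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    scales = CharacteristicScales(
        Lc=gamma / lambda_,
        Tc=R / (growth_rate * gamma),
        Tv=R / (growth_rate * Lgz * lambda_),
        B=lambda_ * Lgz / gamma,
        kappa_max_pred=lambda_ / gamma,
    )
    # internal identities: B = Lgz/Lc = Tc/Tv = kappa_max * Lgz
    for other in (Lgz / scales.Lc, scales.Tc / scales.Tv, scales.kappa_max_pred * Lgz):
        assert abs(other - scales.B) <= 1e-12 * abs(scales.B)
    return scales


def ace_oracle_2d(
    lambda_: float,
    gamma: float,
    config: SimulationConfig,
    n_steps: int,
    theta_base: float = np.pi / 2,
    include_convection: bool = True,
    kappa0: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Independent planar integration of the ACE curvature transport law.

    Explicit Euler on the same grid and stepping as the 3D scheme: upwind
    convection confined to the apical growth zone, constant source
    prefactor ``Edot/R``, clamped base, one segment appended per step
    inheriting its predecessor's curvature.
    ``theta_base`` is the fixed angle at the clamped base between tangent
    and stimulus (pi/2 for a vertical organ under a horizontal stimulus).

    ``include_convection=False`` drops the material-transport term (and tip
    growth), leaving the pure local law ``d kappa/dt = (Edot/R)(lambda
    sin(theta) - gamma kappa)`` on a static grid -- the closed-form check
    ``kappa ~ exp(-Edot gamma t / R)`` for ``lambda = 0``.

    ``kappa0`` optionally seeds a curved initial profile (default straight).
    Returns the list of per-step curvature arrays (index 0 = initial).
    """
    ds, dt = config.ds, config.dt
    edot_rate, R, Lgz = config.growth_rate, config.R, config.Lgz
    n = config.n_segments0
    kappa = np.zeros(n) if kappa0 is None else np.asarray(kappa0, dtype=float).copy()
    history = [kappa.copy()]
    for _ in range(n_steps):
        n = kappa.shape[0]
        # frame angle alpha(n) = sum_{k<n} kappa(k) ds; theta = theta_base - alpha
        alpha = np.concatenate(([0.0], np.cumsum(kappa[:-1]))) * ds
        sin_theta = np.sin(theta_base - alpha)
        if include_convection:
            depth = (n - 1 - np.arange(n)) * ds
            v = np.maximum(Lgz - depth, 0.0) * edot_rate
        else:
            v = np.zeros(n)
        upwind = np.empty(n)
        upwind[0] = 0.0
        upwind[1:] = (kappa[1:] - kappa[:-1]) / ds
        kappa = kappa + dt * (
            (edot_rate / R) * (lambda_ * sin_theta - gamma * kappa) - v * upwind
        )
        kappa[0] = 0.0
        if include_convection:
            kappa = np.append(kappa, kappa[-1])
        history.append(kappa.copy())
    return history


def bressan_oracle_2d(
    lambda_: float,
    eta: float,
    s_grid: np.ndarray,
    n_steps: int,
    dt: float,
    theta_base: float = np.pi / 2,
) -> list[np.ndarray]:
    """Integrate the accretive-growth comparison model on a fixed grid.

    ``d kappa(s, t)/dt = lambda exp(-eta (t - s)) sin(theta(s, t))`` with
    ``theta = theta_base - integral of kappa``; the organ neither elongates
    nor convects material (accretion at the tip is implicit in the
    stiffness factor).  Provided for qualitative comparison with the AC
    model (the no-elongation ACE limit): at ``t = s`` the stiffness factor
    is 1 and both right-hand sides coincide for ``gamma = 0``.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    ds = float(s_grid[1] - s_grid[0]) if s_grid.size > 1 else 1.0
    kappa = np.zeros_like(s_grid)
    history = [kappa.copy()]
    for m in range(n_steps):
        t = m * dt
        alpha = np.concatenate(([0.0], np.cumsum(kappa[:-1]))) * ds
        sin_theta = np.sin(theta_base - alpha)
        stiffness = np.exp(-eta * np.maximum(t - s_grid, 0.0))
        kappa = kappa + dt * lambda_ * stiffness * sin_theta
        history.append(kappa.copy())
    return history


def steady_state_kappa_max(
    record: TrajectoryRecord,
    tol: float | None = None,
    window: int | None = None,
) -> float:
    """Maximal ``|kappa|`` along the organ at the end of a converged run.

    Convergence requires the per-step change rate ``max_n |kappa(m) -
    kappa(m-1)| / dt`` to stay below ``tol`` for ``window`` consecutive
    steps somewhere in the run (defaults taken from the run's
    configuration).  Raises :class:`NotConvergedError` otherwise.
    """
    tol = record.config.steady_tol if tol is None else tol
    window = record.config.steady_window if window is None else window
    rates = record.rate_series
    below = rates < tol
    run_len = 0
    ok = window == 0
    for flag in below:
        run_len = run_len + 1 if flag else 0
        if run_len >= window:
            ok = True
            break
    if not ok:
        raise NotConvergedError(
            f"change rate never stayed below {tol:g} for {window} consecutive "
            f"steps (final rate {rates[-1]:g})" if rates.size else "empty run"
        )
    return record.final.kappa_max


def tip_angle_series(record: TrajectoryRecord, direction: np.ndarray) -> np.ndarray:
    """Signed angle between the tip tangent and a stimulus direction, per step.

    The sign is taken in the plane spanned by the initial tip tangent and
    the stimulus direction, so zero crossings mark overshoot past alignment
    (the damped oscillations of high balance numbers).
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    tangents = record.tip_frames[:, 2]
    t0 = tangents[0]
    normal = np.cross(t0, direction)
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise ValueError("stimulus direction parallel to the initial tangent")
    normal = normal / norm
    cosang = np.clip(tangents @ direction, -1.0, 1.0)
    sinang = np.cross(tangents, direction) @ normal
    return np.arctan2(sinang, cosang)


def arrival_time(record: TrajectoryRecord, direction: np.ndarray) -> float:
    """First time the tip aligns with the stimulus (first zero crossing).

    Linear interpolation between the bracketing steps; raises
    :class:`NotConvergedError` if the tip never crosses alignment.
    """
    angles = tip_angle_series(record, direction)
    sign_change = np.flatnonzero(np.diff(np.sign(angles)) != 0)
    if sign_change.size == 0:
        raise NotConvergedError("tip never aligned with the stimulus direction")
    i = int(sign_change[0])
    t0, t1 = record.times[i], record.times[i + 1]
    a0, a1 = angles[i], angles[i + 1]
    if a1 == a0:
        return float(t0)
    return float(t0 + (t1 - t0) * (-a0) / (a1 - a0))
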