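"""Full simulation runs: configuration, scenarios, the step loop, recording.

The per-step loop is: evaluate the differential growth vector on the
current geometry -> advance the curvature components -> append the new tip
segment -> rebuild frames and positions -> record.  Runs are fully
deterministic given a configuration.

Scenarios
---------
``distant``          constant stimulus from infinity:  Delta = lambda0 n - gamma kappa N
``point``            point source at r_p:              Delta = lambda0 (r_p - r)/|r_p - r| - gamma kappa N
``line_twine``       attracting line + axial stimulus: Delta = lambda0 z - lambda1 rho_hat - gamma kappa N
``circumnutation``   internal oscillator:              Delta = lambda0 (cos wt m1 + sin wt m2) - gamma kappa N
``superposition``    distant + oscillator:             Delta = lambda0 n + lambda1 (...) - gamma kappa N
``custom``           whatever ``DifferentialGrowthSpec`` the caller supplies
                     (default: no terms -> pure elongation)
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .dynamics import (
    Circumnutation,
    DifferentialGrowthSpec,
    TropicTerm,
    add_tip_segment,
    differential_growth_vector,
    growth_velocity,
    step_curvature,
)
from .geometry import OrganState, frenet_from_natural, propagate_frames, straight_organ
from .stimuli import SensitivityFunction, StimulusField

__all__ = [
    "SimulationConfig",
    "Snapshot",
    "TrajectoryRecord",
    "SimulationBlowUpError",
    "build_scenario",
    "run",
]

SCENARIOS = (
    "distant",
    "point",
    "line_twine",
    "circumnutation",
    "superposition",
    "custom",
)


class SimulationBlowUpError(RuntimeError):
    """Curvature became non-finite during a run."""


@dataclasses.dataclass
class SimulationConfig:
    """Physical and numerical parameters of a run; single source of truth.

    The defaults are the standard operating point of the model: radius
    ``R = 0.1``, proprioceptive gain ``gamma = 0.01``, tropic sensitivities
    ``lambda0 = 0.1`` and ``lambda1 = 0.05`` (balance numbers
    ``B = lambda Lgz / gamma`` of 10 and 5), growth zone ``Lgz = 1``,
    initial length ``L0 = 1``, uniform elongation rate ``Edot = 0.1``,
    time step ``dt = 0.1`` and segment length ``ds = 0.01``.  All
    quantities are in dimensionless model units.

    ``ds`` must equal ``Lgz * growth_rate * dt`` (one segment appended per
    step); violating configurations are rejected, never resampled.
    ``random_seed`` is reserved: every scenario here is deterministic.
    """

    scenario: str = "distant"
    R: float = 0.1
    gamma: float = 0.01
    lambda0: float = 0.1
    lambda1: float = 0.05
    Lgz: float = 1.0
    L0: float = 1.0
    dt: float = 0.1
    ds: float = 0.01
    growth_rate: float = 0.1
    n_steps: int = 1000
    omega: float | None = None  # circumnutation rate; default 0.2 / dt
    stimulus_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    source_point: tuple[float, float, float] = (2.0, 0.0, 2.0)
    line_base: tuple[float, float, float] = (0.5, 0.0, 0.0)
    line_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    sensing_mode: str = "local"
    record_every: int = 1
    stop_on_steady: bool = False
    steady_tol: float = 1e-6
    steady_window: int = 50
    random_seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        for name in ("R", "gamma", "Lgz", "L0", "dt", "ds", "growth_rate"):
            if getattr(self, name) <= 0 and not (name == "gamma" and self.gamma == 0):
                raise ValueError(f"{name} must be positive")
        if self.omega is None:
            self.omega = 0.2 / self.dt
        expected = self.Lgz * self.growth_rate * self.dt
        if abs(self.ds - expected) > 1e-9 * max(abs(expected), abs(self.ds)):
            raise ValueError(
                "step-size relation violated: ds must equal Lgz * Edot * dt "
                f"(got ds={self.ds}, Lgz*Edot*dt={expected} from Lgz={self.Lgz}, "
                f"Edot={self.growth_rate}, dt={self.dt})"
            )
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.sensing_mode not in ("local", "apical"):
            raise ValueError("sensing_mode must be 'local' or 'apical'")

    @property
    def n_segments0(self) -> int:
        n0 = round(self.L0 / self.ds)
        if abs(n0 * self.ds - self.L0) > 1e-9:
            raise ValueError("L0 must be an integer multiple of ds")
        return n0

    def initial_state(self) -> OrganState:
        return straight_organ(self.n_segments0, self.ds, self.Lgz, self.R)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class Snapshot:
    """Full organ state plus derived fields at one recorded step."""

    step: int
    time: float
    state: OrganState
    positions: np.ndarray  # (N + 1, 3) segment endpoints
    frames: np.ndarray  # (N, 3, 3)
    kappa: np.ndarray
    phi: np.ndarray
    tau: np.ndarray

    @property
    def tip_position(self) -> np.ndarray:
        return self.positions[-1]

    @property
    def tip_frame(self) -> np.ndarray:
        return self.frames[-1]

    @property
    def kappa_max(self) -> float:
        return float(self.kappa.max())


@dataclasses.dataclass
class TrajectoryRecord:
    """Recorded output of a run.

    ``snapshots`` holds deep state copies every ``record_every`` steps (the
    final step is always included).  The per-step series (every step, not
    just recorded ones) carry the scalar diagnostics needed for convergence
    analysis: ``kappa_max_series``, the steady-state rate
    ``max_n |kappa(m) - kappa(m-1)| / dt``, and the tip kinematics.
    """

    config: SimulationConfig
    snapshots: list[Snapshot]
    times: np.ndarray  # (n_steps + 1,)
    kappa_max_series: np.ndarray  # (n_steps + 1,)
    rate_series: np.ndarray  # (n_steps,) change rate between consecutive steps
    tip_positions: np.ndarray  # (n_steps + 1, 3)
    tip_frames: np.ndarray  # (n_steps + 1, 3, 3)
    tip_kappa: np.ndarray  # (n_steps + 1, 2) natural curvature components at the tip
    steady_converged: bool
    n_steps_run: int

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]


def _make_snapshot(
    step: int, time: float, state: OrganState, frames: np.ndarray, positions: np.ndarray
) -> Snapshot:
    kappa, phi, tau = frenet_from_natural(state.kappa1, state.kappa2, state.ds)
    n = state.n_segments
    return Snapshot(
        step=step,
        time=time,
        state=state.copy(),
        positions=positions[: n + 1].copy(),
        frames=frames[:n].copy(),
        kappa=kappa,
        phi=phi,
        tau=tau,
    )


def build_scenario(
    config: SimulationConfig, extra_terms: Sequence[TropicTerm] = ()
) -> DifferentialGrowthSpec:
    """Differential-growth recipe for the configured scenario.

    Attractive tropic terms are built as a unit-magnitude field with a
    linear (Stevens exponent 1) sensitivity and sign -1, which reproduces
    the published composition formulas term for term: e.g. the distant
    scenario evaluates to ``lambda0 n - gamma kappa N`` on the cross
    section.
    """
    mode = config.sensing_mode
    terms: list[TropicTerm] = []
    if config.scenario == "distant":
        field = StimulusField("constant", direction=_unit(config.stimulus_direction))
        terms.append(
            TropicTerm(field, SensitivityFunction.linear(config.lambda0), -1.0, mode)
        )
    elif config.scenario == "point":
        field = StimulusField("point", source_point=np.asarray(config.source_point))
        terms.append(
            TropicTerm(field, SensitivityFunction.linear(config.lambda0), -1.0, mode)
        )
    elif config.scenario == "line_twine":
        axial = StimulusField("constant", direction=np.array([0.0, 0.0, 1.0]))
        radial = StimulusField(
            "line",
            direction=_unit(config.line_direction),
            line_base=np.asarray(config.line_base),
        )
        terms.append(
            TropicTerm(axial, SensitivityFunction.linear(config.lambda0), -1.0, mode)
        )
        # sign +1: the line field points away from the line, the response
        # -lambda1 rho_hat attracts the organ toward it (twining).
        terms.append(
            TropicTerm(radial, SensitivityFunction.linear(config.lambda1), +1.0, mode)
        )
    elif config.scenario == "superposition":
        field = StimulusField("constant", direction=_unit(config.stimulus_direction))
        terms.append(
            TropicTerm(field, SensitivityFunction.linear(config.lambda0), -1.0, mode)
        )
    terms.extend(extra_terms)

    circ = None
    if config.scenario == "circumnutation":
        circ = Circumnutation.circular(config.lambda0, config.omega)
    elif config.scenario == "superposition":
        circ = Circumnutation.circular(config.lambda1, config.omega)

    return DifferentialGrowthSpec(
        tropic_terms=terms,
        circumnutation=circ,
        proprioception_gamma=config.gamma,
        growth_rate=config.growth_rate,
    )


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("direction vector must be nonzero")
    return v / norm


def run(
    config: SimulationConfig,
    spec: DifferentialGrowthSpec | None = None,
    progress_every: int | None = None,
) -> TrajectoryRecord:
    """Execute a full simulation and record the trajectory.

    Raises :class:`SimulationBlowUpError` with a diagnostic if any
    curvature component becomes non-finite.
    """
    if spec is None:
        spec = build_scenario(config)
    state = config.initial_state()
    n0 = state.n_segments
    frames, positions = propagate_frames(state)

    times = [0.0]
    kmax_series = [float(np.hypot(state.kappa1, state.kappa2).max())]
    rate_series: list[float] = []
    tip_positions = [positions[n0].copy()]
    tip_frames = [frames[n0 - 1].copy()]
    tip_kappa = [(state.kappa1[-1], state.kappa2[-1])]
    snapshots = [_make_snapshot(0, 0.0, state, frames, positions)]

    steady_run = 0
    converged = False
    m_done = 0
    for m in range(config.n_steps):
        t = m * config.dt
        delta = differential_growth_vector(state, frames, positions, spec, t)
        v = growth_velocity(state, config.growth_rate)
        new_state = step_curvature(state, delta, v, config.dt, config.growth_rate)
        rate = float(
            max(
                np.abs(new_state.kappa1 - state.kappa1).max(),
                np.abs(new_state.kappa2 - state.kappa2).max(),
            )
            / config.dt
        )
        state = add_tip_segment(new_state)
        n_new = state.n_segments
        if not (
            np.isfinite(state.kappa1).all() and np.isfinite(state.kappa2).all()
        ):
            raise SimulationBlowUpError(
                f"non-finite curvature at step {m + 1} (t={t + config.dt:.6g}); "
                "check parameters against the step-size relation"
            )
        frames, positions = propagate_frames(state)
        m_done = m + 1
        t_new = m_done * config.dt
        times.append(t_new)
        kmax_series.append(float(np.hypot(state.kappa1, state.kappa2).max()))
        rate_series.append(rate)
        tip_positions.append(positions[n_new].copy())
        tip_frames.append(frames[n_new - 1].copy())
        tip_kappa.append((state.kappa1[-1], state.kappa2[-1]))
        if m_done % config.record_every == 0:
            snapshots.append(_make_snapshot(m_done, t_new, state, frames, positions))
        if progress_every and m_done % progress_every == 0:
            print(
                f"step {m_done}/{config.n_steps}  t={t_new:.3g}  "
                f"kappa_max={kmax_series[-1]:.6g}  rate={rate:.3g}"
            )
        if config.stop_on_steady:
            steady_run = steady_run + 1 if rate < config.steady_tol else 0
            if steady_run >= config.steady_window:
                converged = True
                break

    if snapshots[-1].step != m_done:
        snapshots.append(_make_snapshot(m_done, m_done * config.dt, state, frames, positions))

    return TrajectoryRecord(
        config=config,
        snapshots=snapshots,
        times=np.asarray(times),
        kappa_max_series=np.asarray(kmax_series),
        rate_series=np.asarray(rate_series),
        tip_positions=np.asarray(tip_positions),
        tip_frames=np.asarray(tip_frames),
        tip_kappa=np.asarray(tip_kappa),
        steady_converged=converged,
        n_steps_run=m_done,
    )
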