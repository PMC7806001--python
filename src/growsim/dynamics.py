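"""Differential growth composition and the curvature time-stepper.

The organ bends because one flank of the cylinder elongates faster than the
other.  That asymmetry is summarized per cross-section by the differential
growth vector ``Delta``, assembled additively from

* tropic terms -- responses to external stimulus fields (local or apical
  sensing, attracting or repelling),
* a circumnutation term -- an internal oscillator rotating ``Delta`` in the
  cross-section plane, ``lambda_c (cos psi(t) m1 + sin psi(t) m2)``,
* proprioception -- the active straightening tendency ``-gamma kappa N``,
  implemented directly on natural components as ``-gamma (kappa1, kappa2)``
  so nothing ever needs the (possibly undefined) Frenet normal.

Only the cross-sectional components ``(Delta . m1, Delta . m2)`` drive the
dynamics.  The curvature components obey a material-derivative law

    D kappa_i / Dt = (Edot / R) Delta . m_i,

discretized explicitly in time with a backward (upwind -- the growth flow
always runs base-to-tip) arc-length difference for the convection term.
The convective velocity is confined to the apical growth zone (elongation
happens only there), while the differential-growth source acts along the
whole organ with the constant rate prefactor ``Edot / R`` -- which is what
lets the near-base region, held at right angles by the clamp, converge to
the steady maximal curvature ``lambda / gamma``.  One segment of length
``ds = Lgz * Edot * dt`` is appended at the tip each step, inheriting the
curvature of its predecessor.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np

from .geometry import OrganState
from .stimuli import SensitivityFunction, StimulusField, response_vector

__all__ = [
    "TropicTerm",
    "Circumnutation",
    "DifferentialGrowthSpec",
    "differential_growth_vector",
    "growth_velocity",
    "step_curvature",
    "add_tip_segment",
    "step_size_relation",
]


@dataclasses.dataclass
class TropicTerm:
    """One stimulus-response channel of the differential growth vector.

    ``sign`` multiplies the raw response vector ``-lambda(I_perp) n_perp``:
    with ``sign=-1`` the term becomes ``+lambda n_perp`` (growth *toward*
    the field direction, the usual attractive tropism written as
    ``+lambda0 n`` in the scenario formulas); ``sign=+1`` keeps the
    repelling orientation.  ``sensing_mode`` is "local" (distributed
    sensors) or "apical" (tip senses, whole growth zone responds).
    """

    field: StimulusField
    sensitivity: SensitivityFunction
    sign: float = -1.0
    sensing_mode: str = "local"

    def __post_init__(self) -> None:
        if self.sensing_mode not in ("local", "apical"):
            raise ValueError(f"unknown sensing mode: {self.sensing_mode!r}")


@dataclasses.dataclass
class Circumnutation:
    """Internal oscillator term ``intensity (cos psi(t) m1 + sin psi(t) m2)``."""

    intensity: float
    psi: Callable[[float], float]

    @classmethod
    def circular(cls, intensity: float, omega: float) -> "Circumnutation":
        return cls(intensity, lambda t: omega * t)


@dataclasses.dataclass
class DifferentialGrowthSpec:
    """Recipe assembling the differential growth vector each step."""

    tropic_terms: Sequence[TropicTerm] = ()
    circumnutation: Circumnutation | None = None
    proprioception_gamma: float = 0.0
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.proprioception_gamma < 0:
            raise ValueError("proprioception_gamma must be >= 0")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")


def differential_growth_vector(
    state: OrganState,
    frames: np.ndarray,
    positions: np.ndarray,
    spec: DifferentialGrowthSpec,
    t: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-sectional components ``(Delta . m1, Delta . m2)`` per segment.

    Tropic responses are evaluated at each segment's base node with that
    segment's frame (or once at the tip and broadcast, for apical sensing),
    the circumnutation term adds ``(cos psi, sin psi)`` times its intensity,
    and proprioception subtracts ``gamma * (kappa1, kappa2)``.

    Returns two ``(N,)`` arrays.
    """
    n = state.n_segments
    delta1 = np.zeros(n)
    delta2 = np.zeros(n)
    m1 = frames[:, 0]
    m2 = frames[:, 1]
    tangents = frames[:, 2]
    nodes = positions[:n]

    for term in spec.tropic_terms:
        if term.sensing_mode == "apical":
            tip_resp = response_vector(
                term.field, term.sensitivity, positions[n], frames[n - 1, 2]
            )
            delta1 += term.sign * float(tip_resp @ frames[n - 1, 0])
            delta2 += term.sign * float(tip_resp @ frames[n - 1, 1])
        else:
            resp = response_vector(term.field, term.sensitivity, nodes, tangents)
            delta1 += term.sign * np.sum(resp * m1, axis=-1)
            delta2 += term.sign * np.sum(resp * m2, axis=-1)

    if spec.circumnutation is not None:
        psi = spec.circumnutation.psi(t)
        delta1 += spec.circumnutation.intensity * math.cos(psi)
        delta2 += spec.circumnutation.intensity * math.sin(psi)

    gamma = spec.proprioception_gamma
    if gamma != 0.0:
        delta1 -= gamma * state.kappa1
        delta2 -= gamma * state.kappa2
    return delta1, delta2


def growth_velocity(state: OrganState, growth_rate: float) -> np.ndarray:
    """Growth-induced material velocity at each segment's apical node.

    With a uniform elongation rate ``Edot`` confined to the apical growth
    zone of length ``Lgz``, the velocity accumulated from the base is
    ``v(n) = (Lgz - (N - 1 - n) ds) Edot`` where positive and zero below
    the growth zone.  The tip segment moves at ``Lgz * Edot``, which is
    what adds exactly one segment of length ``ds = Lgz Edot dt`` per step.
    """
    n = state.n_segments
    depth = (n - 1 - np.arange(n)) * state.ds  # distance from segment end to tip
    return np.maximum(state.growth_zone_length - depth, 0.0) * growth_rate


def step_curvature(
    state: OrganState,
    delta: tuple[np.ndarray, np.ndarray],
    v: np.ndarray,
    dt: float,
    growth_rate: float,
) -> OrganState:
    """One explicit Euler step of the curvature transport equations.

    ``kappa_i(n, m+1) = kappa_i(n, m) + dt [ (Edot/R) Delta_i(n)
    - v(n) (kappa_i(n) - kappa_i(n-1)) / ds ]`` with a backward (upwind)
    spatial difference and the clamped-base row held at zero.  The source
    prefactor ``Edot/R`` is constant along the organ; convection ``v``
    vanishes below the growth zone.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    delta1, delta2 = delta
    coeff = growth_rate / state.radius
    new = []
    for kappa, dlt in ((state.kappa1, delta1), (state.kappa2, delta2)):
        upwind = np.empty_like(kappa)
        upwind[0] = 0.0
        upwind[1:] = (kappa[1:] - kappa[:-1]) / state.ds
        knew = kappa + dt * (coeff * dlt - v * upwind)
        knew[0] = 0.0  # clamped base
        new.append(knew)
    return dataclasses.replace(state, kappa1=new[0], kappa2=new[1])


def add_tip_segment(state: OrganState) -> OrganState:
    """Append one segment at the tip, inheriting the predecessor's curvature.

    Equivalent to initializing the incoming segment one step early with
    zero curvature, zero ``Delta`` and tip velocity ``Lgz * Edot``: the
    upwind update then copies the predecessor's curvature exactly.
    """
    return dataclasses.replace(
        state,
        kappa1=np.append(state.kappa1, state.kappa1[-1]),
        kappa2=np.append(state.kappa2, state.kappa2[-1]),
    )


def step_size_relation(Lgz: float, growth_rate: float, dt: float) -> float:
    """Segment length implied by one-segment-per-step growth: ``ds = Lgz Edot dt``."""
    if Lgz <= 0 or growth_rate <= 0 or dt <= 0:
        raise ValueError("Lgz, growth_rate and dt must all be positive")
    return Lgz * growth_rate * dt
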