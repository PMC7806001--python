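"""Stimulus vector fields, cross-section projection, and sensitivity laws.

An environmental signal is a vector field ``I(r) n(r)`` (light, gravity, a
nutrient gradient direction...).  A cylindrical organ element only senses
the component of the signal perpendicular to its surface, obtained by
projecting out the tangent.  A sensitivity (gain) function maps the sensed
magnitude to a growth response; the two classical biophysical choices are
the Weber-Fechner logarithmic law and Stevens' power law, with a constant
gain as the degenerate case (e.g. gravitropism, where only inclination is
sensed).

The local response vector returned here is ``-lambda(I_perp) * n_perp``:
the *scenario* builders own the attract/repel sign, so each published
composition formula is implemented exactly once (in
:mod:`growsim.dynamics`).
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

__all__ = [
    "StimulusField",
    "SensitivityFunction",
    "DegenerateSourceError",
    "perpendicular_component",
    "response_vector",
    "line_displacement",
    "apical_broadcast",
]


class DegenerateSourceError(ValueError):
    """Query point coincides with a point source; direction undefined."""


@dataclasses.dataclass
class SensitivityFunction:
    """Maps sensed stimulus magnitude to response gain ``lambda(I)``.

    law = "constant":       lambda(I) = lambda0
    law = "weber_fechner":  lambda(I) = a + b * log(I / I0)
    law = "stevens":        lambda(I) = a * I**b
    """

    law: str
    lambda0: float = 0.0
    a: float = 0.0
    b: float = 0.0
    I0: float = 1.0

    def __call__(self, intensity: np.ndarray | float) -> np.ndarray | float:
        intensity = np.asarray(intensity, dtype=float)
        if self.law == "constant":
            return np.broadcast_to(float(self.lambda0), intensity.shape).copy()
        if self.law == "weber_fechner":
            with np.errstate(divide="ignore"):
                return self.a + self.b * np.log(intensity / self.I0)
        if self.law == "stevens":
            return self.a * intensity**self.b

        raise ValueError(f"unknown sensitivity law: {self.law!r}")

    @classmethod
    def constant(cls, lambda0: float) -> "SensitivityFunction":
        return cls("constant", lambda0=lambda0)

    @classmethod
    def linear(cls, gain: float) -> "SensitivityFunction":
        """Stevens law with exponent 1: ``lambda(I) = gain * I``."""
        return cls("stevens", a=gain, b=1.0)


@dataclasses.dataclass
class StimulusField:
    """Spatial stimulus field ``I(r) n(r)``.

    kind = "constant": parallel field from an infinitely distant source,
        direction ``direction``, magnitude ``magnitude0`` everywhere.
    kind = "point": radial field of a source at ``source_point``;
        ``direction`` at a query point aims *toward* the source (an
        attracting source under the standard scenario sign).
    kind = "line": radial field of a straight line through ``line_base``
        along ``direction``; the field at a query point aims *away* from
        the line, along the shortest displacement ``rho``.

    ``magnitude_profile`` optionally modulates the magnitude with distance
    from the source/line (e.g. a diffusive concentration profile); by
    default the magnitude is constant in space.
    """

    kind: str
    direction: np.ndarray | None = None
    source_point: np.ndarray | None = None
    line_base: np.ndarray | None = None
    magnitude0: float = 1.0
    magnitude_profile: Callable[[np.ndarray], np.ndarray] | None = None
    degenerate_tol: float = 1e-11

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "point", "line"):
            raise ValueError(f"unknown stimulus kind: {self.kind!r}")
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=float)
            norm = np.linalg.norm(self.direction)
            if abs(norm - 1.0) > 1e-12:
                raise ValueError("stimulus direction must be a unit vector")
        if self.kind in ("constant", "line") and self.direction is None:
            raise ValueError(f"{self.kind} stimulus requires a direction")
        if self.kind == "point":
            if self.source_point is None:
                raise ValueError("point stimulus requires source_point")
            self.source_point = np.asarray(self.source_point, dtype=float)
        if self.kind == "line":
            if self.line_base is None:
                raise ValueError("line stimulus requires line_base")
            self.line_base = np.asarray(self.line_base, dtype=float)

    def evaluate(self, positions: np.ndarray) -> np.ndarray:
        """Signal vectors ``I(r) n(r)`` at ``positions`` (..., 3) -> (..., 3)."""
        positions = np.asarray(positions, dtype=float)
        if self.kind == "constant":
            return self.magnitude0 * np.broadcast_to(
                self.direction, positions.shape
            ).copy()
        if self.kind == "point":
            disp = self.source_point - positions
            dist = np.linalg.norm(disp, axis=-1)
            if np.any(dist < self.degenerate_tol):
                raise DegenerateSourceError(
                    "query position coincides with the point source"
                )
            unit = disp / dist[..., None]
            mag = self.magnitude0 * np.ones_like(dist)
            if self.magnitude_profile is not None:
                mag = mag * self.magnitude_profile(dist)
            return mag[..., None] * unit
        # line: radial displacement away from the line
        rho = line_displacement(positions, self.line_base, self.direction)
        dist = np.linalg.norm(rho, axis=-1)
        mag = self.magnitude0 * np.ones_like(dist)
        if self.magnitude_profile is not None:
            mag = mag * self.magnitude_profile(dist)
        on_line = dist < self.degenerate_tol
        safe = np.where(on_line, 1.0, dist)
        # no directional information for points on the line itself
        return np.where(on_line[..., None], 0.0, mag[..., None] * rho / safe[..., None])


def perpendicular_component(signal: np.ndarray, tangent: np.ndarray) -> np.ndarray:
    """Component of the signal perpendicular to the organ surface.

    ``I_perp = T x (I x T) = I - (I . T) T`` for unit tangent ``T``; its
    magnitude is ``|I| sin(theta)`` with ``theta`` the angle between the
    tangent and the signal.  Broadcasts over leading axes.
    """
    signal = np.asarray(signal, dtype=float)
    tangent = np.asarray(tangent, dtype=float)
    return signal - np.sum(signal * tangent, axis=-1, keepdims=True) * tangent


def response_vector(
    field: StimulusField,
    sens: SensitivityFunction,
    position: np.ndarray,
    tangent: np.ndarray,
) -> np.ndarray:
    """Local response vector ``-lambda(I_perp) * n_perp``.

    The sensed magnitude is ``I_perp = |I| sin(theta)`` and ``n_perp`` its
    unit direction; when the signal is tangential (``I_perp = 0``) there is
    no directional information and the zero vector is returned.  Broadcasts
    over leading axes of ``position``/``tangent``.
    """
    signal = field.evaluate(position)
    perp = perpendicular_component(signal, tangent)
    intensity = np.linalg.norm(perp, axis=-1)
    zero = intensity == 0.0
    safe = np.where(zero, 1.0, intensity)
    gain = np.asarray(sens(np.where(zero, 1.0, intensity)), dtype=float)
    return np.where(zero[..., None], 0.0, -(gain / safe)[..., None] * perp)


def line_displacement(
    position: np.ndarray, line_base: np.ndarray, direction: np.ndarray
) -> np.ndarray:
    """Shortest displacement ``rho`` from a straight line to a point.

    ``rho = (r - r_line) - n ((r - r_line) . n)`` for the line through
    ``line_base`` with unit direction ``n``; the result is orthogonal to
    the line and zero for points on it.
    """
    rel = np.asarray(position, dtype=float) - np.asarray(line_base, dtype=float)
    direction = np.asarray(direction, dtype=float)
    return rel - np.sum(rel * direction, axis=-1, keepdims=True) * direction


def apical_broadcast(
    apex_response: np.ndarray, apex_frame: np.ndarray, local_frame: np.ndarray
) -> np.ndarray:
    """Transport the apex response to a local cross-section.

    Apical sensing means the whole organ responds to what is sensed at the
    tip alone: the response's cross-sectional components in the apex frame
    ``(r . m1(L), r . m2(L))`` are re-expressed on the local frame's
    ``(m1(s), m2(s))``.  Tangential components do not drive bending and are
    dropped.  On a straight organ (all frames equal) this is the identity
    on the cross-sectional part.
    """
    c1 = float(apex_response @ apex_frame[0])
    c2 = float(apex_response @ apex_frame[1])
    return c1 * local_frame[0] + c2 * local_frame[1]
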