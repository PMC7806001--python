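"""Discretized centerline geometry in the natural (Bishop) frame.

A rod-like organ is represented by the two curvature components
``(kappa1, kappa2)`` of its cross-section, one pair per segment of
arc-length ``ds``.  The local frame ``D(n) = (m1, m2, T)`` (rows) evolves
along the organ through rotations built from the skew-symmetric Darboux
matrix, so frames stay orthonormal by construction and everything remains
well-defined on a perfectly straight organ -- the reason this frame is
preferred over the Frenet-Serret frame, whose normal is undefined at
``kappa = 0``.

Conventions
-----------
* The base is clamped: ``kappa1[0] = kappa2[0] = 0``.
* The initial organ is vertical with ``T = z``, ``m1 = x``, ``m2 = y``,
  i.e. ``base_frame`` defaults to the identity.
* Frames are attached per segment (piecewise constant over
  ``[n*ds, (n+1)*ds)``); positions are the ``N + 1`` segment endpoints.
* The Frenet quantities are derived: ``kappa = hypot(kappa1, kappa2)``,
  ``phi = atan2(kappa2, kappa1)`` (NaN where ``kappa = 0``, where the
  normal direction carries no information), and the torsion ``tau`` is the
  backward difference of the unwrapped ``phi`` over ``ds``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "OrganState",
    "darboux_matrix",
    "segment_rotation",
    "segment_rotations",
    "propagate_frames",
    "frenet_from_natural",
    "straight_organ",
]

#: curvatures below this (in units of 1/length) are treated as exactly zero
#: when deciding whether the Frenet normal direction is defined.
KAPPA_ZERO_TOL = 1e-12


@dataclasses.dataclass
class OrganState:
    """Discretized organ centerline in natural-frame curvature components.

    Parameters
    ----------
    kappa1, kappa2 : ndarray, shape (N,)
        Curvature components along ``m1`` and ``m2`` (units 1/length), one
        per segment.  The base segment is clamped to zero curvature.
    ds : float
        Segment arc-length.
    base_frame : ndarray, shape (3, 3)
        Orthonormal frame at the clamped base, rows ``(m1, m2, T)``.
    base_position : ndarray, shape (3,)
        Cartesian origin of the centerline.
    growth_zone_length : float
        Length ``Lgz`` of the apical region where elongation occurs.
    radius : float
        Organ radius ``R``.
    """

    kappa1: np.ndarray
    kappa2: np.ndarray
    ds: float
    base_frame: np.ndarray
    base_position: np.ndarray
    growth_zone_length: float
    radius: float

    def __post_init__(self) -> None:
        self.kappa1 = np.asarray(self.kappa1, dtype=float)
        self.kappa2 = np.asarray(self.kappa2, dtype=float)
        self.base_frame = np.asarray(self.base_frame, dtype=float)
        self.base_position = np.asarray(self.base_position, dtype=float)
        if self.kappa1.shape != self.kappa2.shape or self.kappa1.ndim != 1:
            raise ValueError("kappa1 and kappa2 must be 1-D arrays of equal length")
        if self.n_segments == 0:
            raise ValueError("organ must have at least one segment")
        if self.ds <= 0:
            raise ValueError("ds must be positive")
        if self.growth_zone_length > self.length + 1e-12:
            raise ValueError(
                f"growth zone ({self.growth_zone_length}) longer than organ "
                f"({self.length})"
            )
        err = np.abs(self.base_frame @ self.base_frame.T - np.eye(3)).max()
        if err > 1e-10 or np.linalg.det(self.base_frame) < 0:
            raise ValueError("base_frame must be orthonormal with determinant +1")

    @property
    def n_segments(self) -> int:
        return self.kappa1.shape[0]

    @property
    def length(self) -> float:
        return self.n_segments * self.ds

    def copy(self) -> "OrganState":
        return OrganState(
            self.kappa1.copy(),
            self.kappa2.copy(),
            self.ds,
            self.base_frame.copy(),
            self.base_position.copy(),
            self.growth_zone_length,
            self.radius,
        )


def straight_organ(
    n_segments: int,
    ds: float,
    growth_zone_length: float,
    radius: float,
    base_frame: np.ndarray | None = None,
    base_position: np.ndarray | None = None,
) -> OrganState:
    """Straight vertical organ: ``T = z``, ``m1 = x``, ``m2 = y``, zero curvature."""
    if base_frame is None:
        base_frame = np.eye(3)
    if base_position is None:
        base_position = np.zeros(3)
    return OrganState(
        np.zeros(n_segments),
        np.zeros(n_segments),
        ds,
        np.asarray(base_frame, dtype=float),
        np.asarray(base_position, dtype=float),
        growth_zone_length,
        radius,
    )


def darboux_matrix(kappa1: float, kappa2: float) -> np.ndarray:
    """Skew-symmetric Darboux matrix generating the frame rotation.

    ``dD/ds = U D`` with rows of ``D`` being ``(m1, m2, T)``, so that
    ``dm1/ds = -kappa1 T``, ``dm2/ds = -kappa2 T`` and
    ``dT/ds = kappa1 m1 + kappa2 m2``.
    """
    return np.array(
        [
            [0.0, 0.0, -kappa1],
            [0.0, 0.0, -kappa2],
            [kappa1, kappa2, 0.0],
        ]
    )


def segment_rotation(kappa1: float, kappa2: float, ds: float) -> np.ndarray:
    """Rotation ``R = exp(U ds)`` linking consecutive frames.

    Closed Rodrigues form of the matrix exponential of the Darboux matrix:
    a rotation by angle ``kappa * ds`` about the cross-section axis
    ``(kappa2/kappa) m1 - (kappa1/kappa) m2``, or the identity when
    ``kappa = 0``.
    """
    return segment_rotations(np.array([kappa1]), np.array([kappa2]), ds)[0]


def segment_rotations(kappa1: np.ndarray, kappa2: np.ndarray, ds: float) -> np.ndarray:
    """Vectorized ``exp(U ds)`` for per-segment curvature arrays -> (N, 3, 3)."""
    kappa1 = np.asarray(kappa1, dtype=float)
    kappa2 = np.asarray(kappa2, dtype=float)
    kappa = np.hypot(kappa1, kappa2)
    angle = kappa * ds
    # Stable coefficients of the Rodrigues series:
    #   R = I + sin(k ds)/k * U + (1 - cos(k ds))/k^2 * U^2
    small = angle < 1e-8
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        c1 = np.where(small, ds, np.sin(angle) / np.where(kappa == 0, 1.0, kappa))
        c2 = np.where(
            small,
            0.5 * ds * ds,
            (1.0 - np.cos(angle)) / np.where(kappa == 0, 1.0, kappa) ** 2,
        )
    n = kappa1.shape[0]
    u = np.zeros((n, 3, 3))
    u[:, 0, 2] = -kappa1
    u[:, 2, 0] = kappa1
    u[:, 1, 2] = -kappa2
    u[:, 2, 1] = kappa2
    # overflow here only happens en route to a blow-up diagnostic downstream
    with np.errstate(invalid="ignore", over="ignore"):
        u2 = u @ u
        return np.eye(3)[None] + c1[:, None, None] * u + c2[:, None, None] * u2


def _prefix_rotations(rots: np.ndarray) -> np.ndarray:
    """Inclusive prefix products ``p[i] = R(i) @ R(i-1) @ ... @ R(0)``.

    Hillis-Steele doubling scan: O(N log N) batched 3x3 products, identical
    to the sequential left-multiplication up to round-off.
    """
    p = rots.copy()
    n = p.shape[0]
    shift = 1
    while shift < n:
        q = p.copy()
        q[shift:] = p[shift:] @ p[:-shift]
        p = q
        shift *= 2
    return p


def propagate_frames(state: OrganState) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct per-segment frames and endpoint positions from curvatures.

    ``D(n+1) = R(n) D(n)`` starting from the base frame, and
    ``r(n) = base_position + sum_{k<n} T(k) ds`` so that the returned
    ``positions`` array holds the ``N + 1`` segment endpoints (``positions[0]``
    is the base, ``positions[N]`` the apical tip).

    Returns
    -------
    frames : ndarray, shape (N, 3, 3)
    positions : ndarray, shape (N + 1, 3)
    """
    n = state.n_segments
    ds = state.ds
    frames = np.empty((n, 3, 3))
    frames[0] = state.base_frame
    if n > 1:
        rots = segment_rotations(state.kappa1[:-1], state.kappa2[:-1], ds)
        frames[1:] = _prefix_rotations(rots) @ state.base_frame
    positions = np.empty((n + 1, 3))
    positions[0] = state.base_position
    positions[1:] = state.base_position + np.cumsum(frames[:, 2] * ds, axis=0)
    return frames, positions


def frenet_from_natural(
    kappa1: np.ndarray, kappa2: np.ndarray, ds: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frenet curvature, normal angle, and torsion from natural components.

    ``kappa = sqrt(kappa1^2 + kappa2^2)``; ``phi = atan2(kappa2, kappa1)``
    unwrapped along arc-length; ``tau`` is the backward difference of
    ``phi`` over ``ds``.  Where ``kappa`` vanishes the normal direction is
    undefined and ``phi``/``tau`` are reported as NaN; ``tau`` of the first
    defined segment in a run (which has no defined predecessor) is 0.
    """
    kappa1 = np.asarray(kappa1, dtype=float)
    kappa2 = np.asarray(kappa2, dtype=float)
    kappa = np.hypot(kappa1, kappa2)
    defined = kappa > KAPPA_ZERO_TOL
    phi = np.full_like(kappa, np.nan)
    phi[defined] = np.arctan2(kappa2[defined], kappa1[defined])
    tau = np.full_like(kappa, np.nan)
    # unwrap and difference within each contiguous run of defined phi
    idx = np.flatnonzero(defined)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, breaks + 1):
            phi[run] = np.unwrap(phi[run])
            tau[run[0]] = 0.0
            if run.size > 1:
                tau[run[1:]] = np.diff(phi[run]) / ds
    return kappa, phi, tau


def max_orthonormality_error(frames: np.ndarray) -> float:
    """Max over frames of ``||D D^T - I||_inf`` (frame-integrity diagnostic)."""
    eye = np.eye(3)
    return float(np.abs(frames @ np.swapaxes(frames, -1, -2) - eye).max())
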