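"""Implant geometry of the two devices and an idealized volume-conductor field model.

The leadless pacemaker (PPG) is a rigid capsule with tip and ring electrodes;
the extravascular ICD contributes two lead ring electrodes (Ring1, Ring2) and
optionally the device can.  Two scalar distances summarize a concomitant
implant: D1 (ICD Ring2 to PPG tip) and D2 (ICD Ring1 to PPG ring), both in mm.

The pacing field is modelled as a current dipole (source/sink at the PPG tip
and ring) in an infinite homogeneous medium of the stated resistivity — the
same idealization a saline tank embodies.  Only ordering and monotonicity
properties of sensed amplitudes are meaningful in this model, never absolute
agreement with bench measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .errors import ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .synth import PacingProgram

__all__ = [
    "DistancePair",
    "DeviceGeometry",
    "electrode_distances",
    "rotation_distance_sum",
    "collinear_tradeoff",
    "sensed_amplitude",
    "pose_from_distances",
]


@dataclass(frozen=True)
class DistancePair:
    """The (D1, D2) inter-electrode distances in mm.

    Physical distances are non-negative; Monte Carlo draws from an unbounded
    normal model may carry negative coordinates and must be constructed with
    ``allow_negative=True``.
    """

    d1_mm: float
    d2_mm: float
    allow_negative: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d1_mm) and math.isfinite(self.d2_mm)):
            raise ParameterError("distances must be finite")
        if not self.allow_negative and (self.d1_mm < 0 or self.d2_mm < 0):
            raise ParameterError("distances must be >= 0")


def _vec(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,) or not np.all(np.isfinite(arr)):
        raise ParameterError("positions must be finite 3-vectors")
    return arr


@dataclass(frozen=True)
class DeviceGeometry:
    """3-D electrode positions (mm) of the PPG capsule and the ICD."""

    ppg_tip: np.ndarray
    ppg_ring: np.ndarray
    icd_ring1: np.ndarray
    icd_ring2: np.ndarray
    icd_can: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ppg_tip", _vec(self.ppg_tip))
        object.__setattr__(self, "ppg_ring", _vec(self.ppg_ring))
        object.__setattr__(self, "icd_ring1", _vec(self.icd_ring1))
        object.__setattr__(self, "icd_ring2", _vec(self.icd_ring2))
        if self.icd_can is not None:
            object.__setattr__(self, "icd_can", _vec(self.icd_can))

    @property
    def ppg_length_mm(self) -> float:
        return float(np.linalg.norm(self.ppg_tip - self.ppg_ring))

    def with_ppg_pose(self, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "DeviceGeometry":
        """Rigidly re-pose the PPG capsule: ``p -> R @ p + t``.

        ``rotation`` must be a proper 3x3 rotation matrix; the tip–ring
        separation is preserved by construction.
        """
        r = np.asarray(rotation, dtype=float)
        t = _vec(translation)
        if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ParameterError("rotation must be a 3x3 orthogonal matrix")
        return DeviceGeometry(
            ppg_tip=r @ self.ppg_tip + t,
            ppg_ring=r @ self.ppg_ring + t,
            icd_ring1=self.icd_ring1,
            icd_ring2=self.icd_ring2,
            icd_can=self.icd_can,
        )


def electrode_distances(g: DeviceGeometry) -> DistancePair:
    """Euclidean D1 (Ring2 to PPG tip) and D2 (Ring1 to PPG ring) in mm."""
    d1 = float(np.linalg.norm(g.icd_ring2 - g.ppg_tip))
    d2 = float(np.linalg.norm(g.icd_ring1 - g.ppg_ring))
    return DistancePair(d1, d2)


def rotation_distance_sum(g: DeviceGeometry) -> float:
    """D1 + D2 in mm — the scalar that orders sensed pacing-spike amplitudes
    across rigid rotations of the PPG capsule."""
    pair = electrode_distances(g)
    return pair.d1_mm + pair.d2_mm


def collinear_tradeoff(
    tip_dist_mm: float, ring_dist_mm: float, new_tip_dist_mm: float
) -> float:
    """Ring distance after moving the tip in the antiparallel collinear arrangement.

    With the capsule collinear with (and antiparallel to) the ICD electrode
    axis, bringing the tip ``delta`` mm closer pushes the ring ``delta`` mm
    further away: the new ring distance is
    ``ring_dist_mm + (tip_dist_mm - new_tip_dist_mm)``.  This is the geometric
    trade-off that makes simultaneous proximity of both electrode pairs
    infeasible.
    """
    if tip_dist_mm < 0 or ring_dist_mm < 0 or new_tip_dist_mm < 0:
        raise ParameterError("distances must be >= 0")
    return ring_dist_mm + (tip_dist_mm - new_tip_dist_mm)


def pose_from_distances(
    d1_mm: float,
    d2_mm: float,
    icd_separation_mm: float = 40.0,
    ppg_length_mm: float = 25.0,
    icd_can: np.ndarray | None = None,
) -> DeviceGeometry:
    """Construct a coplanar implant pose realizing given (D1, D2) distances.

    The ICD electrodes sit on the x-axis (Ring2 at the origin, Ring1 at
    ``icd_separation_mm``); the rigid PPG capsule of length ``ppg_length_mm``
    is placed in the z = 0 plane so that the tip lies exactly ``d1_mm`` from
    Ring2 and the ring exactly ``d2_mm`` from Ring1.  Among the feasible
    placements, the one that best realizes the bridging arrangement the D1/D2
    definitions describe (tip nearest Ring2, ring nearest Ring1) is chosen,
    making the construction deterministic.
    """
    if d1_mm <= 0 or d2_mm <= 0:
        raise ParameterError("distances must be > 0")
    r2 = np.zeros(3)
    r1 = np.array([icd_separation_mm, 0.0, 0.0])
    length = ppg_length_mm
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for alpha in np.linspace(0.0, math.pi, 1441):
        tip = d1_mm * np.array([math.cos(alpha), math.sin(alpha), 0.0])
        q = float(np.linalg.norm(tip - r1))
        if q < 1e-9 or not (abs(q - length) <= d2_mm <= q + length):
            continue
        # ring: intersection of the circle of radius d2 about Ring1 with the
        # circle of radius `length` about the tip (coplanar two-circle solve)
        a = (d2_mm**2 - length**2 + q**2) / (2.0 * q)
        h_sq = d2_mm**2 - a**2
        if h_sq < 0:
            continue
        axis = (tip - r1) / q
        base = r1 + a * axis
        perp = np.array([-axis[1], axis[0], 0.0])
        for sign in (1.0, -1.0):
            ring = base + sign * math.sqrt(h_sq) * perp
            margin = min(
                float(np.linalg.norm(ring - r2)) - d1_mm,
                float(np.linalg.norm(tip - r1)) - d2_mm,
            )
            if best is None or margin > best[0]:
                best = (margin, tip, ring)
    if best is None:
        raise ParameterError(
            f"no coplanar pose realizes D1={d1_mm}, D2={d2_mm} with this lead "
            "separation and capsule length"
        )
    return DeviceGeometry(
        ppg_tip=best[1], ppg_ring=best[2], icd_ring1=r1, icd_ring2=r2, icd_can=icd_can
    )


_VECTOR_PAIRS = {
    "ring1-ring2": ("icd_ring1", "icd_ring2"),
    "ring1-can": ("icd_ring1", "icd_can"),
    "ring2-can": ("icd_ring2", "icd_can"),
}


def sensed_amplitude(
    g: DeviceGeometry,
    program: "PacingProgram",
    resistivity_ohm_cm: float = 375.0,
    vector: str = "ring1-ring2",
    interface_ohm: float = 500.0,
) -> float:
    """Pacing-spike amplitude (mV) sensed across an ICD electrode pair.

    The pacing dipole is a point current source/sink at the PPG tip/ring in an
    infinite homogeneous medium: the potential at position ``p`` is
    ``(rho * I / 4 pi) * (1/|p - tip| - 1/|p - ring|)`` with the injected
    current ``I`` derived from the programmed amplitude through a fixed
    electrode-interface impedance.  Only relative amplitudes are meaningful.
    """
    if not (resistivity_ohm_cm > 0 and interface_ohm > 0):
        raise ParameterError("resistivity and interface impedance must be > 0")
    if vector not in _VECTOR_PAIRS:
        raise ParameterError(f"unknown sensing vector {vector!r}")
    name_a, name_b = _VECTOR_PAIRS[vector]
    e_a = getattr(g, name_a)
    e_b = getattr(g, name_b)
    if e_a is None or e_b is None:
        raise ParameterError(f"sensing vector {vector!r} requires a can electrode position")

    rho_ohm_mm = resistivity_ohm_cm * 10.0
    current_a = program.amplitude_v / interface_ohm
    k = rho_ohm_mm * current_a / (4.0 * math.pi)

    def potential_v(p: np.ndarray) -> float:
        r_tip = float(np.linalg.norm(p - g.ppg_tip))
        r_ring = float(np.linalg.norm(p - g.ppg_ring))
        if r_tip < 1e-9 or r_ring < 1e-9:
            raise ParameterError("electrode coincides with a source point (singularity)")
        return k * (1.0 / r_tip - 1.0 / r_ring)

    return abs(potential_v(e_a) - potential_v(e_b)) * 1000.0
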