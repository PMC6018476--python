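"""TCD beam triangulation and insonation-angle correction.

A hand-held Doppler probe measures the projection of the blood velocity
onto the ultrasound beam axis.  Given calibration points — (depth,
3-D location) pairs identified in the simulation/imaging frame — a beam
line is fitted by total least squares; measurement depths then map to 3-D
locations along the beam, and measured velocities are corrected for the
angle between the beam and the local flow (plane-normal) direction by
dividing by |cos theta|.  A beam nearly perpendicular to the flow
(|cos theta| <= 0.1) cannot be corrected reliably and is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BeamModel",
    "fit_beam",
    "depth_to_location",
    "angle_correct_velocity",
    "read_calibration_table",
    "UnreliableMeasurementError",
]


class UnreliableMeasurementError(ValueError):
    pass


@dataclass(frozen=True)
class BeamModel:
    """Fitted beam line: location(depth) = origin + depth * direction."""

    origin: np.ndarray
    direction: np.ndarray  # unit vector
    residual: float  # RMS distance of calibration points to the fit [m]
    calibration_points: tuple  # ((depth, location), ...)

    def __post_init__(self):
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("beam direction must be unit length")


def fit_beam(calibration_points) -> BeamModel:
    """Total-least-squares line through depth-tagged calibration points.

    ``calibration_points`` is a sequence of (depth [m], location (3,) [m]).
    The direction is the principal axis of the centered locations (sign
    chosen to follow increasing depth), and the origin is placed so that
    the mean calibration point sits at the mean calibration depth.  The
    RMS perpendicular residual is reported rather than hidden, so
    implausible calibration data surfaces in the fit quality.
    """
    pts = [(float(d), np.asarray(x, dtype=np.float64)) for d, x in calibration_points]
    depths = np.array([d for d, _ in pts])
    if len(np.unique(depths)) < 2:
        raise ValueError("need calibration points at >= 2 distinct depths")
    locs = np.stack([x for _, x in pts])
    centroid = locs.mean(axis=0)
    centered = locs - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    # orient along increasing depth
    if np.polyfit(depths, centered @ direction, 1)[0] < 0:
        direction = -direction
    origin = centroid - depths.mean() * direction
    perp = centered - np.outer(centered @ direction, direction)
    residual = float(np.sqrt((perp**2).sum(axis=1).mean()))
    return BeamModel(
        origin=origin,
        direction=direction,
        residual=residual,
        calibration_points=tuple((d, tuple(x)) for d, x in pts),
    )


def depth_to_location(beam: BeamModel, depth: float) -> np.ndarray:
    """3-D location at a given insonation depth along the fitted beam."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    return beam.origin + depth * beam.direction


def angle_correct_velocity(
    v_measured: float, beam_direction, plane_normal, toward_probe: bool = True
) -> float:
    """Correct a Doppler velocity for the beam/flow angle.

    The instrument reports v_measured = v_true * |cos theta| where theta is
    the angle between the beam axis and the flow direction (the measurement
    plane normal); the correction divides by |cos theta|.  ``toward_probe``
    carries the instrument's flow-direction indication and fixes the sign
    of the returned velocity.
    """
    b = np.asarray(beam_direction, dtype=np.float64)
    n = np.asarray(plane_normal, dtype=np.float64)
    b = b / np.linalg.norm(b)
    n = n / np.linalg.norm(n)
    cos_theta = abs(float(b @ n))
    if cos_theta <= 0.1:
        raise UnreliableMeasurementError(
            f"beam nearly perpendicular to flow (|cos theta| = {cos_theta:.3f})"
        )
    sign = 1.0 if toward_probe else -1.0
    return sign * v_measured / cos_theta


def read_calibration_table(path) -> list:
    """Read (depth, location) rows from a delimited table.

    Expected columns: ``label``, ``depth_mm``, ``x``, ``y``, ``z``
    (locations in meters, depths in millimeters, matching the plane-table
    layout used elsewhere in the package).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"depth_mm", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"calibration table must contain columns {sorted(required)}")
    return [
        (row.depth_mm * 1e-3, np.array([row.x, row.y, row.z]))
        for row in df.itertuples()
    ]
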