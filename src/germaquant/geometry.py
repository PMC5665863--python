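"""Canonical sample rotation and anterior-posterior (AP) coordinates.

Germaria are mounted at arbitrary orientations; before expression can be
read along the AP axis the sample is rotated into a canonical frame in two
steps that mirror manual 3D alignment: (1) the mid-sagittal plane of the
nucleus cloud is fit and rotated to face the stack Z axis, (2) the sample
is spun in that plane so the anterior points left (-x).  The AP coordinate
of a cell is then simply its x position with the anterior-most cell at 0,
adequate for the near-straight germarium.

All vectors are (z, y, x) um; rotations are proper orthonormal matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    """Degenerate point clouds or direction hints."""


REGION_ORDER = ["R1", "R2a", "R2b_A", "R2b_P", "R3_S1", "S2plus"]


@dataclass
class RigidFrame:
    """A rigid transform: ``x_canonical = rotation @ x + translation``."""

    rotation: np.ndarray  # 3x3 proper orthonormal
    translation: np.ndarray  # (z, y, x) um
    anterior_direction: np.ndarray  # unit vector, pre-rotation

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if abs(np.linalg.det(R) - 1) > 1e-8 or np.abs(R @ R.T - np.eye(3)).max() > 1e-8:
            raise GeometryError("rotation must be proper orthonormal")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)
        self.anterior_direction = np.asarray(self.anterior_direction, dtype=float)

    def apply(self, points_um: np.ndarray) -> np.ndarray:
        return np.asarray(points_um) @ self.rotation.T + self.translation


def fit_sagittal_plane(centers_um: np.ndarray):
    """Least-squares symmetry plane of the nucleus cloud.

    Returns ``(point_on_plane, unit_normal)``; the normal is the smallest
    principal component of the centred covariance, with its sign chosen
    toward +z.  Collinear (rank-deficient) clouds raise GeometryError.
    """
    pts = np.asarray(centers_um, dtype=float)
    if len(pts) < 4:
        raise GeometryError("need at least 4 points to fit the sagittal plane")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # SVD of the centred cloud: singular vectors = principal axes
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise GeometryError("points are collinear; no unique plane")
    normal = vt[2]
    if normal[0] < 0:  # orient toward +z
        normal = -normal
    return centroid, normal


def rotate_to_canonical(centers_um: np.ndarray, plane, anterior_hint: np.ndarray):
    """Build the canonical frame and apply it to the centres.

    After the transform, the plane normal lies along +z and the in-plane
    component of ``anterior_hint`` along -x ("anterior to the left");
    centres are translated so the minimum x is 0.  Returns
    ``(RigidFrame, transformed centres)``.
    """
    point, normal = plane
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    hint = np.asarray(anterior_hint, dtype=float)
    hint_in_plane = hint - np.dot(hint, normal) * normal
    norm_hip = np.linalg.norm(hint_in_plane)
    if norm_hip < 1e-9:
        raise GeometryError("anterior hint is parallel to the plane normal")
    a = hint_in_plane / norm_hip

    # rows of R are the source-frame directions of the target axes:
    # normal -> +z, -a -> +x (so a -> -x), y completes the right-handed set
    u_z = normal
    u_x = -a
    u_y = np.cross(u_x, u_z)  # (z,y,x)-component algebra keeps det = +1
    R = np.vstack([u_z, u_y, u_x])
    if np.linalg.det(R) < 0:  # guard: flip y to keep a proper rotation
        R[1] = -R[1]

    rotated = np.asarray(centers_um) @ R.T
    translation = np.array([0.0, 0.0, -rotated[:, 2].min()])
    frame = RigidFrame(rotation=R, translation=translation, anterior_direction=a)
    return frame, rotated + translation


def assign_ap_coordinate(transformed_centers_um: np.ndarray) -> np.ndarray:
    """AP position (um) of each cell: x coordinate, anterior-most cell at 0."""
    x = np.asarray(transformed_centers_um)[:, 2]
    return x - x.min()


def label_regions(ap_um: np.ndarray, boundaries) -> list[str]:
    """Map AP positions to germarium regions via half-open intervals.

    ``boundaries`` are strictly increasing AP positions (um); interval
    ``[b_i, b_{i+1})`` takes the next label of the fixed order
    R1, R2a, R2b_A, R2b_P, R3_S1, S2plus, and the interval beyond the last
    boundary takes the following label (S2plus when all five boundaries are
    given).  An empty boundary list labels every cell "unassigned".
    """
    bounds = list(boundaries)
    if not bounds:
        return ["unassigned"] * len(np.asarray(ap_um))
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError(f"boundaries must be strictly increasing, got {bounds}")
    if len(bounds) >= len(REGION_ORDER):
        raise ValueError(f"at most {len(REGION_ORDER) - 1} boundaries supported")
    labels = REGION_ORDER[: len(bounds) + 1]
    idx = np.searchsorted(bounds, np.asarray(ap_um, dtype=float), side="right")
    return [labels[i] for i in idx]


def angular_error_deg(recovered_axis: np.ndarray, true_axis: np.ndarray) -> float:
    """Unsigned angle (deg) between two axes (sign-insensitive)."""
    a = np.asarray(recovered_axis, float)
    b = np.asarray(true_axis, float)
    c = abs(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
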