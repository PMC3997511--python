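"""Geometry primitives used by every analysis stage.

Conventions:

* all coordinates in nm, times in us, angles in degrees;
* RMSD/RMSF are mass-unweighted;
* "backbone" means atoms N, CA, C, O;
* rotations are proper (determinant +1); reflections are never returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    CardinalityError,
    DegenerateGeometryError,
    InsufficientDataError,
    SelectionError,
)
from .structio import Frame, Trajectory, select_atoms


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise DegenerateGeometryError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise DegenerateGeometryError("rotation matrix determinant is not +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class DistanceSeries:
    label: str
    times: np.ndarray
    values: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        self.mean = float(np.mean(self.values))
        self.sd = float(np.std(self.values))

    def write_csv(self, path) -> None:
        _write_series_csv(path, self.times, self.values,
                          meta={"label": self.label, "mean_nm": self.mean,
                                "sd_nm": self.sd, "kind": "distance"})


@dataclass
class RmsdSeries:
    domain: str
    mode: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    def write_csv(self, path) -> None:
        _write_series_csv(path, self.times, self.values,
                          meta={"domain": self.domain, "mode": self.mode,
                                "kind": "rmsd"})


def _write_series_csv(path, times, values, meta: dict) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_us,value_nm\n")
        for t, v in zip(times, values):
            fh.write(f"{t:.6f},{v:.6f}\n")
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares optimal proper superposition of `mobile` onto `reference`.

    Returns the transform and the post-fit RMSD (nm). Reflections are
    excluded; degenerate inputs (fewer than 3 points, or collinear points)
    raise :class:`DegenerateGeometryError`.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise DegenerateGeometryError("point sets differ in shape")
    if mobile.ndim != 2 or mobile.shape[0] < 3:
        raise DegenerateGeometryError("superposition requires >= 3 points")

    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    x = mobile - cm
    y = reference - cr

    # collinearity check: rank of the centred mobile cloud
    if np.linalg.matrix_rank(x, tol=1e-10) < 2:
        raise DegenerateGeometryError("points are collinear or coincident")

    H = x.T @ y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    transform = RigidTransform(rotation=R, translation=t)
    fitted = transform.apply(mobile)
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return transform, rmsd


def _resolve(traj_or_top, sel):
    """Accept either a selection expression or an explicit index list."""
    top = traj_or_top.topology if isinstance(traj_or_top, Trajectory) else traj_or_top
    if isinstance(sel, str):
        return select_atoms(top, sel)
    return [int(i) for i in sel]


def rmsd_series(traj: Trajectory, analyze_sel, align_sel, reference: Frame,
                domain: str = "", mode: str = "align-then-measure") -> RmsdSeries:
    """Per-frame RMSD of `analyze_sel` after superposing each frame onto
    `reference` using `align_sel` atoms only (no re-fit on the analyzed set),
    so rigid-body displacement of the analyzed set relative to the alignment
    set is captured.
    """
    ai = _resolve(traj, analyze_sel)
    fi = _resolve(traj, align_sel)
    if not ai or not fi:
        raise SelectionError("empty selection for rmsd_series")
    ref_align = reference.coords[fi]
    ref_analyze = reference.coords[ai]
    values = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        transform, _ = kabsch_superpose(traj.coords[k][fi], ref_align)
        fitted = transform.apply(traj.coords[k][ai])
        values[k] = np.sqrt(np.mean(np.sum((fitted - ref_analyze) ** 2, axis=1)))
    return RmsdSeries(domain=domain, mode=mode, times=traj.times.copy(), values=values)


def rmsf(traj: Trajectory, atom_sel, align_sel, n_passes: int = 2) -> np.ndarray:
    """Root-mean-square fluctuation per selected atom (nm).

    Frames are aligned to an iteratively re-estimated mean structure on
    `align_sel` (`n_passes` alignment-to-mean passes), then RMSF is the root
    of the time-averaged squared deviation from the mean position.
    """
    if traj.n_frames < 2:
        raise InsufficientDataError("RMSF requires at least 2 frames")
    ai = _resolve(traj, atom_sel)
    fi = _resolve(traj, align_sel)
    if not ai or not fi:
        raise SelectionError("empty selection for rmsf")

    aligned = traj.coords.copy()
    mean = aligned.mean(axis=0)
    for _ in range(n_passes):
        for k in range(aligned.shape[0]):
            transform, _ = kabsch_superpose(aligned[k][fi], mean[fi])
            aligned[k] = transform.apply(aligned[k])
        mean = aligned.mean(axis=0)
    dev2 = np.sum((aligned[:, ai, :] - mean[ai]) ** 2, axis=2)
    return np.sqrt(dev2.mean(axis=0))


# ---------------------------------------------------------------------------
# Angles and distances
# ---------------------------------------------------------------------------

def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle in degrees, in (-180, +180].

    Sign convention: rotating p4 about the p2->p3 axis by +x degrees
    (right-hand rule) from the cis (eclipsed) arrangement yields +x.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.allclose(a, b):
            raise DegenerateGeometryError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("collinear points leave the torsion undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    angle = np.degrees(np.arctan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def pair_distance_series(traj: Trajectory, selA, selB, label: str = "") -> DistanceSeries:
    """Per-frame Euclidean distance between two single-atom selections."""
    ia = _resolve(traj, selA)
    ib = _resolve(traj, selB)
    if len(ia) != 1 or len(ib) != 1:
        raise CardinalityError(
            f"pair selections must each resolve to exactly 1 atom "
            f"(got {len(ia)} and {len(ib)})"
        )
    values = np.linalg.norm(traj.coords[:, ia[0], :] - traj.coords[:, ib[0], :], axis=1)
    return DistanceSeries(label=label or f"{selA}|{selB}",
                          times=traj.times.copy(), values=values)


def axial_rotation_angle(reference: np.ndarray, frame: np.ndarray,
                         axis=(0.0, 0.0, 1.0)) -> float:
    """Best-fit rotation angle (degrees) of `frame` relative to `reference`
    about a fixed axis, after removing centroid translation.

    Positive = counter-clockwise when viewed from the +axis direction.
    Closed form: theta = atan2(sum cross_z, sum dot) over in-plane components.
    """
    reference = np.asarray(reference, dtype=float)
    frame = np.asarray(frame, dtype=float)
    if reference.shape != frame.shape or reference.ndim != 2 or reference.shape[0] < 3:
        raise DegenerateGeometryError("need matching point sets with >= 3 points")
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)

    r = reference - reference.mean(axis=0)
    f = frame - frame.mean(axis=0)
    # in-plane components (perpendicular to the axis)
    r_p = r - np.outer(r @ a, a)
    f_p = f - np.outer(f @ a, a)
    if np.max(np.linalg.norm(r_p, axis=1)) < 1e-12:
        raise DegenerateGeometryError("all points lie on the rotation axis")
    dot = float(np.sum(np.einsum("ij,ij->i", r_p, f_p)))
    cross = float(np.sum(np.cross(r_p, f_p) @ a))
    return float(np.degrees(np.arctan2(cross, dot)))
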