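"""Flow-rate, peak-systole and wall-shear-stress quantification.

Flow rate through an ROI plane integrates the through-plane velocity
component over the lumen pixels.  Wall shear stress is the tangential
viscous traction tau = 2 * eta * edot . n (edot the rate-of-deformation
tensor, n the inward wall normal); under the no-slip/no-through
assumption this reduces, in a local frame whose z' axis is the inward
normal, to

    tau = eta * (dv_x'/dz',  dv_y'/dz',  0),

so only the wall-normal derivatives of the two tangential velocity
components are needed.  These are obtained by sampling the velocity at a
few points along the inward normal, with the wall value clamped to zero,
and differentiating a least-squares quadratic fit (a spline with no
interior knots) at the wall.  The returned shear vectors are rotated
back to the global frame and are exactly tangential by construction.

Units: velocities enter in cm/s and geometry in mm (clinical I/O
convention); derivatives are formed in SI so shear comes out in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .recon import VelocitySeries

__all__ = [
    "ROIPlane",
    "FlowCurve",
    "WallMesh",
    "WSSField",
    "BLOOD_VISCOSITY_PA_S",
    "flow_rate",
    "peak_systole_frame",
    "wall_mesh",
    "wss",
    "resample_wss_to_reference",
    "resample_velocity_to_reference",
    "stroke_volume",
]

#: dynamic viscosity of blood used throughout (Pa s)
BLOOD_VISCOSITY_PA_S = 3.2e-3


@dataclass(frozen=True)
class ROIPlane:
    """A lumen cross-section: slice ``index`` along ``axis`` plus a 2D mask."""

    axis: int
    index: int
    mask: np.ndarray  # 2D boolean over the two remaining axes, in order
    pixel_area_mm2: float

    def __post_init__(self) -> None:
        if not np.any(self.mask):
            raise ValueError("ROI mask is empty")


@dataclass
class FlowCurve:
    """Q(t) in ml/s per cardiac frame, with end-diastolic discard flags."""

    q: np.ndarray
    frame_duration_ms: float
    discard_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def kept(self) -> np.ndarray:
        if self.discard_flags.size != len(self.q):
            return np.arange(len(self.q))
        return np.flatnonzero(~self.discard_flags)


def flow_rate(vel: VelocitySeries, roi: ROIPlane) -> FlowCurve:
    """Integrate the through-plane velocity over the ROI per frame.

    Q(t) = sum_pixels v_through * pixel_area; cm/s times cm^2 is ml/s.
    """
    v_axis = vel.data[roi.axis]  # (T, nx, ny, nz)
    plane = np.take(v_axis, roi.index, axis=1 + roi.axis)  # (T, n1, n2)
    if plane.shape[1:] != roi.mask.shape:
        raise ValueError("ROI mask shape does not match the plane")
    area_cm2 = roi.pixel_area_mm2 / 100.0
    q = plane[:, roi.mask].sum(axis=1) * area_cm2
    return FlowCurve(
        q=q,
        frame_duration_ms=vel.frame_duration_ms,
        discard_flags=vel.discard_flags,
    )


def peak_systole_frame(vel: VelocitySeries, lumen_mask: np.ndarray) -> int:
    """Frame with the highest mean speed inside the lumen.

    Discard-flagged frames are excluded; ties resolve to the earliest
    frame (np.argmax convention).
    """
    if not np.any(lumen_mask):
        raise ValueError("lumen mask is empty")
    speed = np.linalg.norm(vel.data, axis=0)  # (T, ...)
    mean_speed = speed[:, lumen_mask].mean(axis=1)
    kept = vel.kept_frames()
    return int(kept[np.argmax(mean_speed[kept])])


# ---------------------------------------------------------------------------
# wall mesh
# ---------------------------------------------------------------------------

@dataclass
class WallMesh:
    """Wall points (mm) with inward unit normals."""

    points: np.ndarray   # (n, 3) mm
    normals: np.ndarray  # (n, 3), unit, pointing into the lumen
    voxel_size: float

    @property
    def n_points(self) -> int:
        return len(self.points)


def wall_mesh(lumen_mask: np.ndarray, voxel_size: float,
              smoothing_sigma: float = 1.0) -> WallMesh:
    """Marching-cubes isosurface of the lumen with inward normals.

    Normals follow the gradient of the Gaussian-smoothed mask (which
    increases toward the lumen interior) interpolated at the vertices,
    normalised, and orientation-checked against the direction to the
    lumen centroid.
    """
    if not np.any(lumen_mask) or np.all(lumen_mask):
        raise ValueError("lumen mask must have both interior and exterior")
    volume = lumen_mask.astype(float)
    verts, _faces, _n, _v = measure.marching_cubes(
        volume, level=0.5, spacing=(voxel_size,) * 3
    )
    smooth = ndimage.gaussian_filter(volume, smoothing_sigma)
    grads = np.gradient(smooth, voxel_size)
    idx_coords = (verts / voxel_size).T
    normal = np.stack(
        [ndimage.map_coordinates(g, idx_coords, order=1) for g in grads], axis=1
    )
    norm = np.linalg.norm(normal, axis=1)
    ok = norm > 1e-12
    normal[ok] /= norm[ok, None]
    centroid = np.argwhere(lumen_mask).mean(axis=0) * voxel_size
    flip = np.einsum("ij,ij->i", normal, centroid[None] - verts) < 0
    normal[flip] *= -1.0
    return WallMesh(points=verts[ok], normals=normal[ok], voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# wall shear stress
# ---------------------------------------------------------------------------

@dataclass
class WSSField:
    """Shear vectors (Pa) at wall points; invalid points carry NaN."""

    points: np.ndarray
    normals: np.ndarray
    tau: np.ndarray        # (n, 3) Pa
    eta: float
    valid: np.ndarray      # (n,) bool; False where the normal ray left the grid
    voxel_size: float = 1.0

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.tau, axis=1)

    def table(self) -> np.ndarray:
        """Columns x, y, z, nx, ny, nz, taux, tauy, tauz, |tau| (valid points)."""
        v = self.valid
        return np.column_stack(
            [self.points[v], self.normals[v], self.tau[v], self.magnitude[v]]
        )


def _local_tangent_frame(normals: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal tangents (x', y') for each inward normal z'.

    x' is built from the coordinate axis with the smallest |normal|
    component (Gram-Schmidt); y' = z' x x' completes a right-handed frame.
    """
    n = normals
    smallest = np.argmin(np.abs(n), axis=1)
    e = np.zeros_like(n)
    e[np.arange(len(n)), smallest] = 1.0
    xp = e - np.einsum("ij,ij->i", e, n)[:, None] * n
    xp /= np.linalg.norm(xp, axis=1)[:, None]
    yp = np.cross(n, xp)
    return xp, yp


def wss(
    velocity: np.ndarray,
    mesh: WallMesh,
    eta: float = BLOOD_VISCOSITY_PA_S,
    n_samples: int = 4,
    sample_spacing: Optional[float] = None,
) -> WSSField:
    """Wall shear stress at every mesh point for one velocity frame.

    ``velocity`` is the (3, nx, ny, nz) field in cm/s on the mesh's
    voxel grid.  Per wall point the two tangential velocity components
    are sampled tri-linearly at ``n_samples`` points spaced
    ``sample_spacing`` (default: one voxel) along the inward normal; the
    wall sample is clamped to zero (no-slip) and a quadratic
    least-squares fit supplies the wall-normal derivative at z' = 0.
    Points whose sampling ray leaves the grid are flagged invalid.
    """
    if velocity.ndim != 4 or velocity.shape[0] != 3:
        raise ValueError("velocity must have shape (3, nx, ny, nz)")
    h = mesh.voxel_size if sample_spacing is None else sample_spacing
    pts, nrm = mesh.points, mesh.normals
    n_pts = len(pts)
    offsets = np.arange(n_samples) * h  # mm
    # (k, n_pts, 3) sample positions in index units
    samples = (pts[None] + offsets[:, None, None] * nrm[None]) / mesh.voxel_size
    shape = np.array(velocity.shape[1:], dtype=float)
    valid = np.all((samples >= 0) & (samples <= shape - 1), axis=(0, 2))

    flat = samples.reshape(-1, 3).T
    v_samp = np.stack(
        [ndimage.map_coordinates(velocity[d], flat, order=1, mode="nearest")
         for d in range(3)]
    ).reshape(3, n_samples, n_pts)

    xp, yp = _local_tangent_frame(nrm)
    vx = np.einsum("dkn,nd->kn", v_samp, xp) * 0.01  # cm/s -> m/s
    vy = np.einsum("dkn,nd->kn", v_samp, yp) * 0.01
    vx[0] = 0.0  # no-slip at the wall
    vy[0] = 0.0
    z = offsets * 1e-3  # mm -> m
    cx = np.polyfit(z, vx, 2)
    cy = np.polyfit(z, vy, 2)
    dvx = cx[1]  # derivative of the quadratic at z'=0
    dvy = cy[1]
    tau = eta * (dvx[:, None] * xp + dvy[:, None] * yp)
    tau[~valid] = np.nan
    return WSSField(points=pts, normals=nrm, tau=tau, eta=eta, valid=valid,
                    voxel_size=mesh.voxel_size)


# ---------------------------------------------------------------------------
# resampling for voxel-wise comparison
# ---------------------------------------------------------------------------

def resample_wss_to_reference(
    reference: WSSField, test: WSSField, max_distance_voxels: float = 2.0
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Pair |tau| values by nearest test point per reference wall point.

    Pairs farther apart than ``max_distance_voxels`` reference voxels are
    dropped; the drop count is returned alongside the aligned
    (reference, test) value arrays.
    """
    ref_ok = reference.valid
    test_ok = test.valid
    if not np.any(ref_ok) or not np.any(test_ok):
        raise ValueError("no valid wall points to pair")
    tree = cKDTree(test.points[test_ok])
    dist, idx = tree.query(reference.points[ref_ok])
    keep = dist <= max_distance_voxels * reference.voxel_size
    ref_vals = reference.magnitude[ref_ok][keep]
    test_vals = test.magnitude[test_ok][idx[keep]]
    n_dropped = int((~keep).sum())
    if len(ref_vals) == 0:
        raise ValueError(f"all {n_dropped} wall-point pairs exceeded the "
                         "pairing distance; geometries do not overlap")
    return ref_vals, test_vals, n_dropped


def resample_velocity_to_reference(
    reference: VelocitySeries,
    test: VelocitySeries,
    lumen_mask: np.ndarray,
    frame_ref: int,
    frame_test: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Voxel-wise paired speeds inside the reference lumen at peak systole.

    Synthetic runs share geometry, so the mapping is the identity and
    test values are read at the reference lumen voxels (tri-linear
    interpolation degenerates to direct sampling).
    """
    ref_speed = np.linalg.norm(reference.data[:, frame_ref], axis=0)
    test_speed = np.linalg.norm(test.data[:, frame_test], axis=0)
    if ref_speed.shape != test_speed.shape or ref_speed.shape != lumen_mask.shape:
        raise ValueError("velocity grids do not match")
    return ref_speed[lumen_mask], test_speed[lumen_mask]


def save_wss_table(field: WSSField, path: str) -> None:
    """Write valid wall points as a delimited table:
    x, y, z (mm), nx, ny, nz, taux, tauy, tauz, |tau| (Pa)."""
    np.savetxt(
        path, field.table(), fmt="%.6g", delimiter="\t",
        header="x\ty\tz\tnx\tny\tnz\ttaux\ttauy\ttauz\ttau_mag",
    )


def stroke_volume(curve: FlowCurve) -> float:
    """Stroke volume (ml): rectangle-rule integral over non-discarded frames."""
    kept = curve.kept()
    if len(kept) < 2:
        raise ValueError("need at least 2 non-discarded frames")
    return float(curve.q[kept].sum() * curve.frame_duration_ms / 1000.0)
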