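"""Domain types and geometry conventions shared by the whole pipeline.

Conventions
-----------
* Voxel indices are 0-based; world coordinates are in mm following the
  NIfTI affine convention.  The affine is axis-aligned here:
  ``world = origin + spacing * index``.
* Velocities are stored in cm/s, flow in mL/s, volumes in mL, kinetic
  energy in mJ — the units in which cardiovascular flow results are
  conventionally reported.
* The cardiac time axis is cyclic: retrospectively gated reconstructions
  cover exactly one RR interval, so phase ``t`` and ``t + n_phases``
  refer to the same cardiac time.  Phase ``k`` is centred at
  ``k * rr_interval / n_phases`` ms.
* Velocity components are indexed ``(component, x, y, z, t)`` with the
  component axis ordered (x, y, z) in world axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import shapely

__all__ = [
    "VelocityField4D",
    "PhaseField",
    "BackgroundModel",
    "Mask",
    "AnalysisPlane",
    "RoiContour",
    "FlowCurve",
    "KECurve",
    "AgreementResult",
    "DatasetFormatError",
    "MetadataError",
    "GeometryError",
    "DegenerateMaskError",
]


class DatasetFormatError(ValueError):
    """Component volumes disagree in shape, affine, or layout."""


class MetadataError(ValueError):
    """A required sidecar entry (VENC, RR interval, ...) is missing or invalid."""


class GeometryError(ValueError):
    """A plane, contour, or phantom geometry does not intersect the volume."""


class DegenerateMaskError(ValueError):
    """Stationary mask does not constrain the affine background fit.

    Carries ``direction``, the world axis (or 'all') along which the mask
    voxel coordinates show no spread.
    """

    def __init__(self, message: str, direction: str):
        super().__init__(message)
        self.direction = direction


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise ValueError(f"{name} must have 3 elements, got {v.size}")
    return v


class _GridMixin:
    """Coordinate maps shared by gridded types (expects ``voxel_spacing``
    in mm, ``origin`` in world mm of voxel (0, 0, 0))."""

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel→world affine (axis-aligned)."""
        A = np.eye(4)
        A[:3, :3] = np.diag(self.voxel_spacing)
        A[:3, 3] = self.origin
        return A

    def voxel_to_world(self, ijk) -> np.ndarray:
        """Map (possibly fractional) voxel indices (..., 3) to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return self.origin + ijk * self.voxel_spacing

    def world_to_voxel(self, xyz) -> np.ndarray:
        """Map world mm (..., 3) to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - self.origin) / self.voxel_spacing


@dataclass
class VelocityField4D(_GridMixin):
    """Three-directional velocity field over a cardiac cycle.

    ``velocities`` has shape ``(3, nx, ny, nz, nt)`` in cm/s; ``venc`` is
    the per-axis velocity-encoding limit in cm/s: decoded (pre-unwrap)
    velocities lie in ``[-venc, venc)`` on each axis.
    """

    velocities: np.ndarray
    voxel_spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) world mm
    rr_interval: float  # ms
    venc: np.ndarray  # (3,) cm/s

    def __post_init__(self):
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.velocities.ndim != 5 or self.velocities.shape[0] != 3:
            raise DatasetFormatError(
                f"velocities must have shape (3, nx, ny, nz, nt); got {self.velocities.shape}"
            )
        self.voxel_spacing = _as_vec3(self.voxel_spacing, "voxel_spacing")
        self.origin = _as_vec3(self.origin, "origin")
        self.venc = _as_vec3(self.venc, "venc")
        if np.any(self.voxel_spacing <= 0):
            raise ValueError("voxel_spacing must be positive on all axes")
        if np.any(self.venc <= 0):
            raise MetadataError("venc must be positive on all axes")
        if not self.rr_interval > 0:
            raise MetadataError("rr_interval must be positive")
        if self.n_phases < 1:
            raise DatasetFormatError("need at least one cardiac phase")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.velocities.shape[1:4]

    @property
    def n_phases(self) -> int:
        return self.velocities.shape[4]

    @property
    def phase_times(self) -> np.ndarray:
        """Time of each reconstructed phase, ms from the R wave."""
        return np.arange(self.n_phases) * self.rr_interval / self.n_phases

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_spacing)) / 1000.0

    def voxel_center_grid(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (nx, ny, nz, 3)."""
        nx, ny, nz = self.grid_shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        ijk = np.stack([ii, jj, kk], axis=-1).astype(float)
        return self.voxel_to_world(ijk)

    def copy_with(self, **kw) -> "VelocityField4D":
        return replace(self, **kw)


@dataclass
class PhaseField(_GridMixin):
    """Raw velocity-encoded phase images, radians per encoding axis.

    Same grid layout as :class:`VelocityField4D`; all values in [-π, π).
    """

    phases: np.ndarray
    voxel_spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) world mm
    rr_interval: float  # ms

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 5 or self.phases.shape[0] != 3:
            raise DatasetFormatError(
                f"phases must have shape (3, nx, ny, nz, nt); got {self.phases.shape}"
            )
        self.voxel_spacing = _as_vec3(self.voxel_spacing, "voxel_spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.phases < -np.pi) or np.any(self.phases >= np.pi):
            raise ValueError("phase values must lie in [-pi, pi)")

    @property
    def n_phases(self) -> int:
        return self.phases.shape[4]


@dataclass
class BackgroundModel:
    """First-order (affine-in-space) background velocity offset.

    ``coefficients`` has shape (3, 4): per velocity component the offset
    ``a0`` (cm/s) and world-coordinate gradients ``(ax, ay, az)``
    (cm/s per mm).  The model is static in time — eddy-current offsets do
    not vary over the cardiac cycle.
    """

    coefficients: np.ndarray

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (3, 4):
            raise ValueError(
                f"coefficients must have shape (3, 4); got {self.coefficients.shape}"
            )

    @classmethod
    def zero(cls) -> "BackgroundModel":
        return cls(np.zeros((3, 4)))

    def __call__(self, points_world) -> np.ndarray:
        """Evaluate at world points (..., 3) → offsets (..., 3) cm/s."""
        pts = np.asarray(points_world, dtype=float)
        design = np.concatenate([np.ones(pts.shape[:-1] + (1,)), pts], axis=-1)
        return design @ self.coefficients.T

    def evaluate_on_grid(self, grid: _GridMixin, shape: Sequence[int]) -> np.ndarray:
        """Offsets on a voxel grid, shape (3, nx, ny, nz)."""
        nx, ny, nz = shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        pts = grid.voxel_to_world(np.stack([ii, jj, kk], axis=-1).astype(float))
        return np.moveaxis(self(pts), -1, 0)


@dataclass
class Mask:
    """Boolean voxel mask on a velocity-field grid.

    ``data`` is (nx, ny, nz) for time-invariant masks (stationary tissue)
    or (nx, ny, nz, nt) for per-phase masks (ventricular segmentations).
    """

    data: np.ndarray
    label: str = "other"  # {stationary, LV, RV, other}

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim not in (3, 4):
            raise ValueError("mask must be 3D (static) or 4D (per phase)")
        if self.label == "stationary" and self.data.ndim != 3:
            raise ValueError("a stationary mask must be time-invariant (3D)")

    @property
    def per_phase(self) -> bool:
        return self.data.ndim == 4

    def check_grid(self, fld: VelocityField4D):
        if tuple(self.data.shape[:3]) != tuple(fld.grid_shape):
            raise DatasetFormatError(
                f"mask grid {self.data.shape[:3]} does not match field {fld.grid_shape}"
            )
        if self.per_phase and self.data.shape[3] != fld.n_phases:
            raise DatasetFormatError(
                f"mask has {self.data.shape[3]} phases, field has {fld.n_phases}"
            )


@dataclass
class AnalysisPlane:
    """Oblique sampling plane in world coordinates.

    The plane is spanned by the orthonormal in-plane basis ``(u, v)``
    with through-plane direction ``normal``; pixel (i, j) sits at
    ``origin + (i - (nu-1)/2) * pixel_spacing * u + (j - (nv-1)/2) * pixel_spacing * v``
    so the plane origin is the centre of the pixel raster.
    """

    origin: np.ndarray  # world mm
    normal: np.ndarray  # unit
    in_plane_u: np.ndarray  # unit
    in_plane_v: np.ndarray  # unit
    pixel_spacing: float  # mm
    extent: tuple[int, int]  # pixel counts (nu, nv)

    _ORTHO_TOL = 1e-9

    def __post_init__(self):
        self.origin = _as_vec3(self.origin, "origin")
        self.normal = _as_vec3(self.normal, "normal")
        self.in_plane_u = _as_vec3(self.in_plane_u, "in_plane_u")
        self.in_plane_v = _as_vec3(self.in_plane_v, "in_plane_v")
        self.extent = (int(self.extent[0]), int(self.extent[1]))
        B = np.stack([self.in_plane_u, self.in_plane_v, self.normal])
        if not np.allclose(B @ B.T, np.eye(3), atol=self._ORTHO_TOL):
            raise GeometryError("{u, v, normal} must be orthonormal to 1e-9")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be positive")

    @classmethod
    def axial(
        cls,
        z_mm: float,
        center_xy: Sequence[float] = (0.0, 0.0),
        pixel_spacing: float = 1.5,
        extent: tuple[int, int] = (48, 48),
    ) -> "AnalysisPlane":
        """Convenience: plane perpendicular to the world z axis."""
        return cls(
            origin=np.array([center_xy[0], center_xy[1], z_mm]),
            normal=np.array([0.0, 0.0, 1.0]),
            in_plane_u=np.array([1.0, 0.0, 0.0]),
            in_plane_v=np.array([0.0, 1.0, 0.0]),
            pixel_spacing=pixel_spacing,
            extent=extent,
        )

    def pixel_centers_plane(self) -> np.ndarray:
        """Pixel-centre coordinates in plane mm, shape (nu, nv, 2)."""
        nu, nv = self.extent
        us = (np.arange(nu) - (nu - 1) / 2.0) * self.pixel_spacing
        vs = (np.arange(nv) - (nv - 1) / 2.0) * self.pixel_spacing
        uu, vv = np.meshgrid(us, vs, indexing="ij")
        return np.stack([uu, vv], axis=-1)

    def plane_to_world(self, uv) -> np.ndarray:
        uv = np.asarray(uv, dtype=float)
        return (
            self.origin
            + uv[..., :1] * self.in_plane_u
            + uv[..., 1:2] * self.in_plane_v
        )

    def world_to_plane(self, xyz) -> np.ndarray:
        d = np.asarray(xyz, dtype=float) - self.origin
        return np.stack([d @ self.in_plane_u, d @ self.in_plane_v], axis=-1)

    def pixel_centers_world(self) -> np.ndarray:
        return self.plane_to_world(self.pixel_centers_plane())


@dataclass
class RoiContour:
    """Closed polygonal region of interest in plane coordinates (mm).

    Vertices are ordered; closure is implicit (first != last).  A
    per-phase contour is a list of vertex arrays, one per cardiac phase.
    """

    vertices: np.ndarray  # (n, 2) mm
    phase_vertices: list[np.ndarray] | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must have shape (n, 2)")
        if self.vertices.shape[0] < 3:
            raise ValueError("a contour needs at least 3 vertices")
        if np.allclose(self.vertices[0], self.vertices[-1]):
            raise ValueError("contour closure is implicit; first vertex must differ from last")
        if not shapely.Polygon(self.vertices).is_simple:
            raise ValueError("contour must not self-intersect")
        if self.phase_vertices is not None:
            self.phase_vertices = [np.asarray(v, dtype=float) for v in self.phase_vertices]

    @classmethod
    def circle(cls, center=(0.0, 0.0), radius: float = 10.0, n: int = 96) -> "RoiContour":
        ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        pts = np.stack(
            [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)], axis=-1
        )
        return cls(pts)

    def polygon_for_phase(self, t: int) -> np.ndarray:
        if self.phase_vertices is not None:
            return self.phase_vertices[t % len(self.phase_vertices)]
        return self.vertices

    def area_mm2(self) -> float:
        return float(shapely.Polygon(self.vertices).area)


@dataclass
class FlowCurve:
    """Per-cardiac-phase volumetric flow rate through one cross-section."""

    values: np.ndarray  # mL/s, length n_phases
    rr_interval: float  # ms
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if not self.rr_interval > 0:
            raise ValueError("rr_interval must be positive")

    @property
    def n_phases(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.rr_interval / self.n_phases

    @property
    def flow_volume(self) -> float:
        """Integrated flow per heartbeat (mL); cyclic trapezoid over the RR.

        With uniformly spaced phases on a closed cycle the trapezoid rule
        reduces to mean rate × period.
        """
        return float(np.mean(self.values)) * self.rr_interval / 1000.0


@dataclass
class KECurve:
    """Total kinetic energy over a segmentation per cardiac phase (mJ)."""

    values: np.ndarray  # mJ
    rr_interval: float  # ms
    density: float = 1.06  # g/mL, recorded for provenance
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if np.any(self.values < -1e-12):
            raise ValueError("kinetic energy cannot be negative")

    @property
    def n_phases(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.rr_interval / self.n_phases


@dataclass
class AgreementResult:
    """Paired method-comparison summary: Bland–Altman bias ± SD with
    limits of agreement, least-squares regression, Pearson r and the
    exact paired Wilcoxon p value.

    Differences are oriented test − reference throughout.
    """

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    r: float = np.nan
    slope: float = np.nan
    intercept: float = np.nan
    p_wilcoxon: float = np.nan
    n: int = 0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must not exceed 1")
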