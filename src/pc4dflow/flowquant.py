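"""Through-plane flow quantification: plane resampling, ROI
integration, contour transfer and the QP/QS ratio.

Flow through a vessel cross-section is measured by resampling the
velocity field onto an oblique analysis plane (trilinear interpolation),
projecting onto the plane normal, and summing velocity × pixel area over
the pixels whose centres fall inside the ROI contour.  The integrated
flow per heartbeat (flow volume) is the cyclic trapezoidal time integral
of the per-phase flow rate — for uniformly spaced phases, mean rate ×
RR interval.  Both 2D-flow and 4D-flow acquisitions are represented in
this same data model, so a 2D-vs-4D comparison is two pipeline runs on
different inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.ndimage import map_coordinates

from .core import (
    AnalysisPlane,
    FlowCurve,
    GeometryError,
    RoiContour,
    VelocityField4D,
)

__all__ = [
    "PlanarVelocityMap",
    "extract_plane",
    "integrate_flow",
    "transfer_contour",
    "qp_qs",
    "flow_volume_for_contour",
]


@dataclass
class PlanarVelocityMap:
    """Through-plane velocity resampled on an analysis plane.

    ``through_plane`` has shape (nu, nv, nt) in cm/s, positive along the
    plane normal; ``valid`` marks pixels whose interpolation stencil lies
    inside the volume.
    """

    through_plane: np.ndarray
    valid: np.ndarray
    plane: AnalysisPlane
    rr_interval: float

    @property
    def n_phases(self) -> int:
        return self.through_plane.shape[2]


def extract_plane(field: VelocityField4D, plane: AnalysisPlane) -> PlanarVelocityMap:
    """Sample the three velocity components at plane pixel centres by
    trilinear interpolation and project onto the plane normal."""
    centers = plane.pixel_centers_world()  # (nu, nv, 3)
    vox = field.world_to_voxel(centers)  # fractional indices
    nu, nv = plane.extent
    shape = np.asarray(field.grid_shape, dtype=float)
    valid = np.all((vox >= 0.0) & (vox <= shape - 1.0), axis=-1)
    if not np.any(valid):
        raise GeometryError("analysis plane lies fully outside the volume")

    coords = vox.reshape(-1, 3).T  # (3, nu*nv)
    nt = field.n_phases
    vmap = np.zeros((nu, nv, nt))
    for t in range(nt):
        comp = np.empty((3, nu * nv))
        for c in range(3):
            comp[c] = map_coordinates(
                field.velocities[c, ..., t], coords, order=1, mode="nearest"
            )
        vmap[..., t] = (plane.normal @ comp).reshape(nu, nv)
    vmap[~valid] = np.nan
    return PlanarVelocityMap(
        through_plane=vmap, valid=valid, plane=plane, rr_interval=field.rr_interval
    )


def _pixels_inside(pmap: PlanarVelocityMap, polygon: np.ndarray) -> np.ndarray:
    """Boolean (nu, nv): pixel centres strictly inside (or on) the polygon.

    Point-in-polygon by the even–odd rule on pixel centres; pixels whose
    centre falls exactly on an edge are included on the left/bottom
    boundary only (half-open convention) via a tiny negative-x bias.
    """
    centers = pmap.plane.pixel_centers_plane()
    poly = shapely.Polygon(polygon)
    eps = 1e-9 * max(pmap.plane.pixel_spacing, 1.0)
    inside = shapely.contains_xy(
        poly, centers[..., 0].ravel() + eps, centers[..., 1].ravel() + eps
    )
    return inside.reshape(centers.shape[:2])


def integrate_flow(pmap: PlanarVelocityMap, contour: RoiContour) -> FlowCurve:
    """Per-phase flow rate (mL/s) over the ROI and its beat volume.

    flow(t) = Σ v_through(t) · pixel_area over pixels inside the contour;
    cm/s × mm² → mL/s via the factor 0.01.
    """
    area_mm2 = pmap.plane.pixel_spacing**2
    nt = pmap.n_phases
    values = np.zeros(nt)
    static = contour.phase_vertices is None
    inside = _pixels_inside(pmap, contour.vertices) if static else None
    for t in range(nt):
        sel = inside if static else _pixels_inside(pmap, contour.polygon_for_phase(t))
        sel = sel & pmap.valid
        if not np.any(sel):
            raise GeometryError("contour encloses no valid pixel centres")
        values[t] = np.nansum(pmap.through_plane[..., t][sel]) * area_mm2 * 0.01
    return FlowCurve(values=values, rr_interval=pmap.rr_interval)


def transfer_contour(contour: RoiContour, source_plane: AnalysisPlane,
                     target_plane: AnalysisPlane) -> RoiContour:
    """Re-express a contour drawn on one plane in the coordinates of
    another plane sharing the same world frame.

    The world-space polygon is unchanged; for planes describing the same
    imaging plane (equal normals, origins separated only in-plane) the
    round-trip transfer is the identity to 1e-9 mm.  Transferring
    2D-flow contours onto the matching 4D-flow plane is this operation
    with the two acquisitions' plane definitions.  If the target plane
    is not coplanar with the source, the out-of-plane component is
    projected away with a warning.
    """
    def _map(verts):
        world = source_plane.plane_to_world(verts)
        off = (world - target_plane.origin) @ target_plane.normal
        if np.max(np.abs(off)) > 1e-6:
            import warnings

            warnings.warn(
                "contour is not coplanar with the target plane "
                f"(max offset {np.max(np.abs(off)):.3g} mm); projecting",
                stacklevel=3,
            )
        return target_plane.world_to_plane(world)

    return RoiContour(
        _map(contour.vertices),
        phase_vertices=None
        if contour.phase_vertices is None
        else [_map(v) for v in contour.phase_vertices],
    )


def qp_qs(pulmonary_volume: float, systemic_volume: float) -> float:
    """Ratio of pulmonary to systemic (aortic) beat volume; ≈1 without
    shunts."""
    if not systemic_volume > 0:
        raise ValueError("systemic volume must be positive")
    return float(pulmonary_volume) / float(systemic_volume)


def flow_volume_for_contour(field: VelocityField4D, plane: AnalysisPlane,
                            contour: RoiContour, flip: bool = False) -> FlowCurve:
    """Convenience: extract the plane and integrate over the contour.

    ``flip`` negates the sign convention (flow positive along the plane
    normal) when the vessel runs against the normal.
    """
    curve = integrate_flow(extract_plane(field, plane), contour)
    if flip:
        curve = FlowCurve(values=-curve.values, rr_interval=curve.rr_interval,
                          label=curve.label)
    return curve
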