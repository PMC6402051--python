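"""Velocity decoding, first-order background phase correction, and
temporal velocity unwrapping.

The correction chain for an acquired dataset is::

    decode -> fit_background / subtract_background -> unwrap_velocity

Background offsets (eddy currents, concomitant gradients) appear as a
spatially smooth additive velocity; a first-order model — affine in the
world coordinates, static in time — is fitted over stationary voxels by
ordinary least squares and subtracted everywhere.  Velocities beyond the
VENC alias by multiples of 2·VENC; they are recovered by temporal
unwrapping of each voxel's time series.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .core import (
    BackgroundModel,
    DegenerateMaskError,
    Mask,
    PhaseField,
    VelocityField4D,
)

__all__ = [
    "decode_velocity",
    "fit_background",
    "subtract_background",
    "unwrap_velocity",
    "auto_stationary_mask",
    "UnwrapResult",
    "correct_dataset",
]


def decode_velocity(phase: PhaseField, venc) -> VelocityField4D:
    """Map encoded phase to velocity: v = venc · φ / π per axis (cm/s).

    Output values lie in [-venc, venc) on each axis.
    """
    venc = np.asarray(venc, dtype=float).reshape(3)
    if np.any(venc <= 0):
        raise ValueError("venc must be positive")
    vel = venc[:, None, None, None, None] * phase.phases / np.pi
    return VelocityField4D(
        velocities=vel,
        voxel_spacing=phase.voxel_spacing.copy(),
        origin=phase.origin.copy(),
        rr_interval=phase.rr_interval,
        venc=venc,
    )


def fit_background(field: VelocityField4D, stationary: Mask) -> BackgroundModel:
    """Ordinary-least-squares affine fit of the time-averaged velocity
    over stationary voxels against world coordinates, per component.

    The background is assumed static over the cardiac cycle, so the fit
    uses the temporal mean.  Raises :class:`DegenerateMaskError` naming
    the deficient world direction when the stationary voxels are
    coplanar (or fewer than 4).
    """
    stationary.check_grid(field)
    if stationary.per_phase:
        raise ValueError("the stationary mask must be time-invariant")
    idx = np.argwhere(stationary.data)
    if idx.shape[0] < 4:
        raise DegenerateMaskError(
            f"need at least 4 stationary voxels, got {idx.shape[0]}", direction="all"
        )
    pts = field.voxel_to_world(idx.astype(float))  # (n, 3) mm
    centered = pts - pts.mean(axis=0)
    # coplanarity check: smallest singular direction of the point cloud
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(svals[0], 1.0)
    if svals[-1] < 1e-9 * scale:
        axis = "xyz"[int(np.argmax(np.abs(vt[-1])))]
        raise DegenerateMaskError(
            f"stationary voxels are coplanar: no spread along the {axis} axis",
            direction=axis,
        )
    design = np.column_stack([np.ones(pts.shape[0]), pts])
    vbar = field.velocities[..., :].mean(axis=4)  # (3, nx, ny, nz)
    rhs = vbar[:, stationary.data].T  # (n, 3)
    coeff, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    return BackgroundModel(coeff.T)


def subtract_background(field: VelocityField4D, model: BackgroundModel) -> VelocityField4D:
    """Subtract the static background model from every cardiac phase:
    v'(x, t) = v(x, t) − model(x) per component."""
    bg = model.evaluate_on_grid(field, field.grid_shape)
    return field.copy_with(velocities=field.velocities - bg[..., np.newaxis])


class UnwrapResult(NamedTuple):
    field: VelocityField4D
    n_flagged: int  # inter-phase steps that would need more than one wrap


def unwrap_velocity(field: VelocityField4D, venc=None) -> UnwrapResult:
    """Temporal unwrapping of aliased velocities, per voxel and axis.

    Starting from the cardiac phase of minimum global mean speed (where
    true velocities are assumed within the VENC), each voxel's cyclic
    time series is corrected by ±2·VENC whenever the inter-phase jump
    exceeds the VENC — the minimal-temporal-variation correction among
    single-wrap (±1) choices.  Steps whose apparent jump would require
    more than one wrap are corrected by a single wrap and counted in
    ``n_flagged``.
    """
    venc = np.asarray(venc if venc is not None else field.venc, dtype=float).reshape(3)
    if np.any(venc <= 0):
        raise ValueError("venc must be positive")
    v = field.velocities
    speed = np.sqrt(np.sum(v**2, axis=0))  # (nx, ny, nz, nt)
    start = int(np.argmin(speed.mean(axis=(0, 1, 2))))
    rolled = np.roll(v, -start, axis=4)

    out = rolled.copy()
    n_flagged = 0
    for c in range(3):
        period = 2.0 * venc[c]
        d = np.diff(rolled[c], axis=3)
        k = np.round(d / period)
        n_flagged += int(np.count_nonzero(np.abs(k) > 1))
        k = np.clip(k, -1, 1)
        correction = -period * np.cumsum(k, axis=3)
        out[c, ..., 1:] += correction
    unwrapped = np.roll(out, start, axis=4)
    return UnwrapResult(field.copy_with(velocities=unwrapped), n_flagged)


def auto_stationary_mask(field: VelocityField4D, sd_threshold: float = 2.0) -> Mask:
    """Fallback stationary-tissue mask: voxels whose per-component
    temporal velocity SD stays below ``sd_threshold`` cm/s.

    Intended for in-vivo data where no explicit stationary mask exists;
    phantom datasets carry an exact mask in their truth instead.
    """
    sd = field.velocities.std(axis=4)  # (3, nx, ny, nz)
    return Mask(np.all(sd < sd_threshold, axis=0), label="stationary")


def correct_dataset(phase: PhaseField, venc, stationary: Mask | None = None,
                    sd_threshold: float = 2.0) -> tuple[VelocityField4D, BackgroundModel, int]:
    """Convenience pipeline: decode → fit/subtract background → unwrap.

    Returns the corrected field, the fitted background model, and the
    count of steps flagged by the unwrapper.
    """
    field = decode_velocity(phase, venc)
    if stationary is None:
        stationary = auto_stationary_mask(field, sd_threshold)
    model = fit_background(field, stationary)
    field = subtract_background(field, model)
    field, n_flagged = unwrap_velocity(field)
    return field, model, n_flagged
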