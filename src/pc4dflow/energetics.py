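"""Ventricular kinetic energy: per-voxel ½·m·v² summed over a
segmentation per cardiac phase, with peak/mean summary metrics.

The mass of a voxel is its volume times the fluid density (blood
defaults to 1.06 g/mL; phantom runs pass the phantom fluid density).
With the voxel volume in mL, density in g/mL and speed in cm/s the
per-voxel energy ½·ρ·V·|v|² carries a factor 1e-4 to land in mJ.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import KECurve, Mask, VelocityField4D

__all__ = ["compute_ke", "ke_summary", "BLOOD_DENSITY"]

BLOOD_DENSITY = 1.06  # g/mL

_KE_UNIT_FACTOR = 1e-4  # g·(cm/s)^2 -> mJ


def compute_ke(field: VelocityField4D, segmentation: Mask,
               density: float = BLOOD_DENSITY) -> KECurve:
    """Total kinetic energy inside the segmentation, per cardiac phase.

    KE(t) = Σ_{voxels in seg(t)} ½ · (density · voxel_volume) · |v(x, t)|²
    in mJ, with |v| the three-component speed.  A static segmentation is
    broadcast over all phases (with a warning); an empty segmentation at
    a phase contributes zero KE (with a warning).
    """
    if not density > 0:
        raise ValueError("density must be positive")
    segmentation.check_grid(field)
    if not segmentation.per_phase:
        warnings.warn(
            "static segmentation broadcast over all cardiac phases", stacklevel=2
        )
    speed2 = np.sum(field.velocities**2, axis=0)  # (nx, ny, nz, nt), (cm/s)^2
    voxel_mass_g = density * field.voxel_volume_ml
    nt = field.n_phases
    values = np.empty(nt)
    for t in range(nt):
        seg = segmentation.data[..., t] if segmentation.per_phase else segmentation.data
        if not np.any(seg):
            warnings.warn(f"empty segmentation at phase {t}; KE set to 0", stacklevel=2)
            values[t] = 0.0
            continue
        values[t] = 0.5 * voxel_mass_g * float(np.sum(speed2[..., t][seg])) * _KE_UNIT_FACTOR
    return KECurve(values=values, rr_interval=field.rr_interval, density=density)


def ke_summary(curve: KECurve, systole_end: float = 0.35,
               early_diastole_end: float = 0.70) -> dict[str, float]:
    """Peak and mean KE metrics over the cardiac cycle.

    The cycle is partitioned by the two boundaries, given as fractions
    of the RR interval: systole [0, systole_end), early diastole
    [systole_end, early_diastole_end), late diastole
    [early_diastole_end, 1).  The boundaries come from cine-derived
    timing and are therefore explicit inputs, not fixed constants.
    Mean KE is the time average over the full cycle.
    """
    if not 0.0 < systole_end < early_diastole_end < 1.0:
        raise ValueError(
            "require 0 < systole_end < early_diastole_end < 1 (fractions of RR)"
        )
    frac = curve.times / curve.rr_interval
    sys_w = frac < systole_end
    early_w = (frac >= systole_end) & (frac < early_diastole_end)
    late_w = frac >= early_diastole_end
    for name, w in (("systole", sys_w), ("early diastole", early_w),
                    ("late diastole", late_w)):
        if not np.any(w):
            raise ValueError(f"no cardiac phase falls in {name}; "
                             "boundaries incompatible with the phase count")
    return {
        "peak_systolic": float(curve.values[sys_w].max()),
        "peak_early_diastolic": float(curve.values[early_w].max()),
        "peak_late_diastolic": float(curve.values[late_w].max()),
        "mean": float(curve.values.mean()),
    }
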