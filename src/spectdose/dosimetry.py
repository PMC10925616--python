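"""Single-time-point cumulated activity and local-deposition dose maps.

The minimal dose-conversion step for a quantified activity image.  With a
single image and no biological clearance (the phantom setting), the
time-integrated (cumulated) activity per voxel is A / lambda — each voxel's
activity integrated over all time under pure physical decay.  The local
deposition method (LDM) then assumes every decay deposits its electron
energy in its own voxel:

    D [Gy] = A_cum [MBq s] * 1e6 [decays/(MBq s)] * E_decay [J] / m_voxel [kg]

Voxel-S-value kernel convolution is a plug-in alternative
(:data:`DOSE_KERNELS`); no kernel is bundled — LDM is the supported method.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .units import RadionuclideSpec, LU177, decay_constant_per_s
from .volume import VolumeImage

__all__ = [
    "WATER_DENSITY_KG_PER_MM3",
    "DOSE_KERNELS",
    "cumulate_stp",
    "ldm_dose",
    "voi_dose_stats",
]

#: Density of water in kg per mm^3 (1000 kg/m^3).
WATER_DENSITY_KG_PER_MM3 = 1e-6

#: Registry for voxel-S-value dose kernels, keyed by nuclide name.  Empty by
#: default; register a callable (cumulated map -> dose map) to use VSV
#: dosimetry in place of local deposition.
DOSE_KERNELS: dict[str, Callable[[VolumeImage, RadionuclideSpec], VolumeImage]] = {}


def cumulate_stp(
    activity_map: VolumeImage,
    spec: RadionuclideSpec = LU177,
) -> VolumeImage:
    """Cumulated activity per voxel (MBq s) under physical decay only.

    Per voxel, A_cum = A / lambda with lambda = ln2 / T1/2 in 1/s.  The
    single-time-point assumption: the image is the activity at time zero and
    decays physically thereafter (no biological clearance — appropriate for
    sealed phantoms; effective half-lives can be modelled by passing a spec
    with the effective T1/2).
    """
    data = np.asarray(activity_map.data, dtype=float)
    if np.any(data < 0):
        raise ValueError("activity map contains negative values")
    lam = decay_constant_per_s(spec)
    return activity_map.like(data / lam, "cumulated_MBq_s")


def ldm_dose(
    cumulated: VolumeImage,
    spec: RadionuclideSpec = LU177,
    voxel_mass_kg: Optional[float] = None,
) -> VolumeImage:
    """Local-deposition dose map (Gy) from a cumulated-activity map.

    All decay energy is absorbed in the emitting voxel.  ``voxel_mass_kg``
    defaults to water density times the voxel volume.
    """
    if cumulated.quantity != "cumulated_MBq_s":
        raise ValueError(f"expected a cumulated-activity map, got {cumulated.quantity!r}")
    if voxel_mass_kg is None:
        voxel_mass_kg = WATER_DENSITY_KG_PER_MM3 * cumulated.voxel_volume_mm3
    if not voxel_mass_kg > 0:
        raise ValueError(f"voxel mass must be positive, got {voxel_mass_kg}")
    decays = np.asarray(cumulated.data, dtype=float) * 1e6
    dose = decays * spec.energy_per_decay_J / voxel_mass_kg
    return cumulated.like(dose, "dose_Gy")


def voi_dose_stats(
    dose: VolumeImage,
    vois: Sequence[tuple[str, VolumeImage]],
) -> pd.DataFrame:
    """Mean / max / total dose statistics per named VOI."""
    records = []
    data = np.asarray(dose.data, dtype=float)
    for name, mask in vois:
        m = np.asarray(mask.data, dtype=bool)
        if m.shape != data.shape:
            raise ValueError(f"VOI {name!r} not on the dose grid")
        vals = data[m]
        records.append(
            {
                "voi": name,
                "n_voxels": int(m.sum()),
                "mean_Gy": float(vals.mean()) if vals.size else float("nan"),
                "max_Gy": float(vals.max()) if vals.size else float("nan"),
            }
        )
    return pd.DataFrame(records)
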