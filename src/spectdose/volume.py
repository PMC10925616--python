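"""3-D scalar volumes on axis-aligned grids, and resampling between grids.

A :class:`VolumeImage` is the one in-memory container every stage exchanges:
activity maps, attenuation maps, reconstructed count-rate images, masks, and
dose maps.  Axes are (x, y, z) with x = left-right, y = anterior-posterior and
z = table travel (axial); world coordinates are millimetres, and
``origin`` is the world position of the centre of voxel (0, 0, 0).

Quantities are either *extensive* (a per-voxel amount: activity in MBq,
counts, cps) or *intensive* (a field sampled at the voxel: attenuation in
1/mm, dose in Gy).  Resampling converts extensive quantities through their
density so that totals are preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

__all__ = ["VolumeImage", "resample", "EXTENSIVE_QUANTITIES"]

#: Quantities that represent a per-voxel amount rather than a point-sampled field.
EXTENSIVE_QUANTITIES = frozenset({"activity_MBq_per_voxel", "counts", "cps", "cumulated_MBq_s"})


@dataclass
class VolumeImage:
    """A 3-D scalar grid with spacing, origin, frame label and quantity label.

    Parameters
    ----------
    data
        3-D array indexed ``[ix, iy, iz]``.
    spacing
        Voxel size per axis in mm, all positive.
    origin
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    frame
        ``"NM"`` or ``"CT"`` — which half of the hybrid system the grid
        belongs to.
    quantity
        Label such as ``"activity_MBq_per_voxel"``, ``"mu_per_mm"``,
        ``"counts"``, ``"cps"``, ``"dose_Gy"`` or ``"mask"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame: str = "CT"
    quantity: str = "activity_MBq_per_voxel"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if self.frame not in ("NM", "CT"):
            raise ValueError(f"frame must be 'NM' or 'CT', got {self.frame!r}")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def is_extensive(self) -> bool:
        return self.quantity in EXTENSIVE_QUANTITIES

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def extent(self) -> list[tuple[float, float]]:
        """Per-axis world bounds [first centre - h/2, last centre + h/2]."""
        return [
            (
                self.origin[a] - 0.5 * self.spacing[a],
                self.origin[a] + self.spacing[a] * (self.shape[a] - 0.5),
            )
            for a in range(3)
        ]

    def centroid(self) -> np.ndarray:
        """Intensity-weighted centroid in world coordinates (mm)."""
        total = float(self.data.sum())
        if total <= 0:
            raise ValueError("centroid undefined for a volume with non-positive total")
        idx = np.asarray(ndimage.center_of_mass(np.asarray(self.data, dtype=float)))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def total(self) -> float:
        return float(self.data.sum())

    def copy(self, **overrides) -> "VolumeImage":
        out = replace(self, data=self.data.copy())
        for k, v in overrides.items():
            setattr(out, k, v)
        return out

    def like(self, data: np.ndarray, quantity: Optional[str] = None) -> "VolumeImage":
        """A new volume on this grid holding ``data``."""
        return VolumeImage(
            data=data,
            spacing=self.spacing,
            origin=self.origin,
            frame=self.frame,
            quantity=quantity or self.quantity,
        )

    # -- I/O --------------------------------------------------------------

    def to_nifti(self, path: Union[str, Path]) -> None:
        """Write as NIfTI-1 with a JSON sidecar for frame/quantity metadata."""
        import nibabel as nib

        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine)
        nib.save(img, str(path))
        sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii(.gz)
        Path(f"{sidecar}.json").write_text(
            json.dumps({"frame": self.frame, "quantity": self.quantity})
        )

    @classmethod
    def from_nifti(cls, path: Union[str, Path]) -> "VolumeImage":
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(abs(affine[i, i])) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        meta_path = Path(str(Path(str(path)).with_suffix("").with_suffix("")) + ".json")
        frame, quantity = "CT", "activity_MBq_per_voxel"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            frame = meta.get("frame", frame)
            quantity = meta.get("quantity", quantity)
        return cls(np.asarray(img.dataobj, dtype=float), spacing, origin, frame, quantity)


def _overlap_fraction(a: VolumeImage, b: VolumeImage) -> float:
    """Fractional overlap of the two fields of view (of the smaller one)."""
    vol = 1.0
    for (alo, ahi), (blo, bhi) in zip(a.extent(), b.extent()):
        lo, hi = max(alo, blo), min(ahi, bhi)
        if hi <= lo:
            return 0.0
        vol *= (hi - lo) / min(ahi - alo, bhi - blo)
    return vol


def resample(
    volume: VolumeImage,
    target: VolumeImage,
    method: Optional[str] = None,
) -> VolumeImage:
    """Resample ``volume`` onto the grid of ``target``.

    ``method`` is ``"linear"`` (default) or ``"nearest"``.  Continuous
    extensive quantities are interpolated as densities and rescaled by the
    target voxel volume so that totals are approximately preserved; when
    downsampling, a Gaussian anti-alias prefilter matched to the spacing
    ratio performs the volume-weighted averaging.  Boolean masks resampled
    with the default method go through their fractional indicator and are
    re-thresholded at 0.5, which preserves enclosed volume far better on a
    coarse grid than voxel-centre (nearest) sampling; pass
    ``method="nearest"`` for label-style lookup.

    Raises ``ValueError`` if the fields of view are disjoint.
    """
    if _overlap_fraction(volume, target) == 0.0:
        raise ValueError("source and target fields of view are disjoint")

    is_mask = volume.quantity == "mask" or volume.data.dtype == bool
    if method is None:
        method = "linear"
    order = 0 if method == "nearest" else 1

    src = np.asarray(volume.data, dtype=float)
    if volume.is_extensive and not is_mask:
        src = src / volume.voxel_volume_mm3  # to density

    if order == 1 and not is_mask:
        # anti-alias when the target grid is coarser than the source grid
        # (skipped for masks: smoothing + thresholding erodes convex shapes)
        sigmas = []
        for a in range(3):
            ratio = target.spacing[a] / volume.spacing[a]
            sigmas.append(0.5 * np.sqrt(max(ratio**2 - 1.0, 0.0)))
        if any(s > 0 for s in sigmas):
            src = ndimage.gaussian_filter(src, sigmas, mode="nearest")

    # target voxel centres in source index coordinates
    coords = np.meshgrid(
        *[
            (target.axis_coords(a) - volume.origin[a]) / volume.spacing[a]
            for a in range(3)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(src, coords, order=order, mode="constant", cval=0.0)

    quantity = volume.quantity
    if is_mask:
        out = out >= 0.5 if order == 1 else out.astype(bool)
    elif volume.is_extensive:
        out = out * target.voxel_volume_mm3
    return VolumeImage(out, target.spacing, target.origin, target.frame, quantity)
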