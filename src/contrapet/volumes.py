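"""Volume containers, VOI geometry, and intensity normalization.

The pipeline operates in a fixed symmetric atlas grid (RAS, mm world
coordinates): every volume is assumed pre-registered to that grid, so
left--right flipping is an exact index reversal and never a resampling
step. Three normalizations live here:

* SUV — tissue concentration (kBq/mL) divided by injected dose per body
  weight, dimensionless under the 1 g/mL tissue-density convention.
* SUVr — SUV divided by the mean SUV of a spherical reference VOI placed
  in the pons, the study's reference region.
* lateral flip — mirroring of right-lesion subjects so the lesion always
  sits on the canonical (left) side before atlas parcellation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "DynamicPETVolume",
    "SphericalVOI",
    "Dosimetry",
    "InvalidDosimetryError",
    "DegenerateReferenceError",
    "compute_suv",
    "normalize_suvr",
    "flip_lateral",
    "voi_stats",
]


class InvalidDosimetryError(ValueError):
    """Raised when injected dose or body weight is non-positive."""


class DegenerateReferenceError(ValueError):
    """Raised when a reference VOI has non-positive mean or is empty."""


@dataclass(frozen=True)
class Dosimetry:
    """Injected dose (Bq, decay-corrected to injection) and body weight (g)."""

    injected_dose_Bq: float
    body_weight_g: float
    injection_time_min: float = 0.0

    def __post_init__(self) -> None:
        if not (self.injected_dose_Bq > 0):
            raise InvalidDosimetryError(
                f"injected dose must be > 0 Bq, got {self.injected_dose_Bq}"
            )
        if not (self.body_weight_g > 0):
            raise InvalidDosimetryError(
                f"body weight must be > 0 g, got {self.body_weight_g}"
            )

    @property
    def dose_per_weight_kBq_g(self) -> float:
        """ID/BW in kBq per gram — the SUV denominator."""
        return (self.injected_dose_Bq / 1000.0) / self.body_weight_g


@dataclass
class DynamicPETVolume:
    """A 3D (static) or 4D (dynamic) voxel grid with affine and frame timing.

    Parameters
    ----------
    data : ndarray, shape (x, y, z) or (x, y, z, t)
        Voxel values: kBq/mL for raw PET, dimensionless for SUV/SUVr/TBR,
        arbitrary intensity for MRI-derived maps.
    affine : (4, 4) ndarray
        Voxel-index to world-mm map (RAS).
    frame_starts, frame_ends : sequence of float, optional
        Frame timing in minutes post injection; present iff ``data`` is 4D.
    units : str
        Free-text units tag propagated through operations.
    symmetric_x : bool
        Whether the grid is declared mirror-symmetric about the mid-sagittal
        plane so that flipping is an exact reversal of the first axis.
    provenance : dict
        Normalization history, written as a JSON sidecar on save.
    """

    data: np.ndarray
    affine: np.ndarray
    frame_starts: np.ndarray | None = None
    frame_ends: np.ndarray | None = None
    units: str = "kBq/mL"
    symmetric_x: bool = True
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be 3D or 4D")
        if self.is_dynamic:
            if self.frame_starts is None or self.frame_ends is None:
                raise ValueError("4D volume requires frame_starts and frame_ends")
            self.frame_starts = np.asarray(self.frame_starts, dtype=float)
            self.frame_ends = np.asarray(self.frame_ends, dtype=float)
            n = self.data.shape[3]
            if len(self.frame_starts) != n or len(self.frame_ends) != n:
                raise ValueError("frame timing length mismatch with data")
            if np.any(np.diff(self.frame_starts) <= 0):
                raise ValueError("frame_starts must be strictly increasing")
            if np.any(self.frame_ends <= self.frame_starts):
                raise ValueError("frame_ends must exceed frame_starts")

    @property
    def is_dynamic(self) -> bool:
        return self.data.ndim == 4

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def voxel_volume_mL(self) -> float:
        # voxel volume in mm^3 == 1e-3 mL
        return float(abs(np.linalg.det(self.affine[:3, :3]))) / 1000.0

    @property
    def frame_midpoints_min(self) -> np.ndarray:
        if not self.is_dynamic:
            raise ValueError("static volume has no frames")
        return (self.frame_starts + self.frame_ends) / 2.0

    def voxel_centers_mm(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (*shape3d, 3)."""
        nx, ny, nz = self.shape3d
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
        return np.einsum("ab,...b->...a", self.affine, idx)[..., :3]

    def frame_window_mean(self, start_min: float, end_min: float) -> "DynamicPETVolume":
        """Duration-weighted mean of frames overlapping [start, end] minutes."""
        if not self.is_dynamic:
            raise ValueError("frame_window_mean requires a dynamic volume")
        overlap = np.minimum(self.frame_ends, end_min) - np.maximum(
            self.frame_starts, start_min
        )
        w = np.clip(overlap, 0.0, None)
        if w.sum() <= 0:
            raise ValueError(f"no frames overlap window [{start_min}, {end_min}] min")
        avg = np.tensordot(self.data, w / w.sum(), axes=([3], [0]))
        prov = dict(self.provenance)
        prov["frame_window_min"] = [float(start_min), float(end_min)]
        return DynamicPETVolume(
            avg, self.affine, units=self.units, symmetric_x=self.symmetric_x,
            provenance=prov,
        )

    # ---- I/O -------------------------------------------------------------

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        nib.save(img, str(path))
        sidecar = {
            "units": self.units,
            "symmetric_x": self.symmetric_x,
            "provenance": self.provenance,
        }
        if self.is_dynamic:
            sidecar["frame_starts_min"] = self.frame_starts.tolist()
            sidecar["frame_ends_min"] = self.frame_ends.tolist()
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "DynamicPETVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        kw: dict = {}
        sc = Path(str(path) + ".json")
        if sc.exists():
            meta = json.loads(sc.read_text())
            kw["units"] = meta.get("units", "kBq/mL")
            kw["symmetric_x"] = meta.get("symmetric_x", True)
            kw["provenance"] = meta.get("provenance", {})
            if "frame_starts_min" in meta:
                kw["frame_starts"] = meta["frame_starts_min"]
                kw["frame_ends"] = meta["frame_ends_min"]
        return cls(data, img.affine, **kw)


@dataclass(frozen=True)
class SphericalVOI:
    """Sphere in world coordinates; a voxel belongs iff its center is within
    ``diameter_mm / 2`` of the center."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.diameter_mm > 0):
            raise ValueError("diameter must be positive")

    def rasterize(self, volume: DynamicPETVolume) -> np.ndarray:
        """Boolean mask on the volume's 3D grid. Errors if empty."""
        centers = volume.voxel_centers_mm()
        d2 = np.sum((centers - np.asarray(self.center_mm)) ** 2, axis=-1)
        mask = d2 <= (self.diameter_mm / 2.0) ** 2
        if not mask.any():
            raise DegenerateReferenceError(
                f"sphere VOI '{self.label}' rasterizes to an empty mask"
            )
        return mask

    def to_json(self) -> dict:
        return {
            "center_mm": list(self.center_mm),
            "diameter_mm": self.diameter_mm,
            "label": self.label,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "SphericalVOI":
        return cls(tuple(obj["center_mm"]), obj["diameter_mm"], obj.get("label", ""))


def _as_mask(volume: DynamicPETVolume, voi) -> np.ndarray:
    if isinstance(voi, SphericalVOI):
        return voi.rasterize(volume)
    mask = np.asarray(voi, dtype=bool)
    if mask.shape != volume.shape3d:
        raise ValueError("mask shape does not match volume grid")
    return mask


def compute_suv(volume: DynamicPETVolume, dose: Dosimetry) -> DynamicPETVolume:
    """Standardized uptake value: concentration / (ID/BW).

    With concentration in kBq/mL, ID in kBq and BW in g, SUV is dimensionless
    under the 1 g/mL tissue-density convention.
    """
    suv = volume.data / dose.dose_per_weight_kBq_g
    prov = dict(volume.provenance)
    prov["suv"] = {
        "injected_dose_Bq": dose.injected_dose_Bq,
        "body_weight_g": dose.body_weight_g,
    }
    return replace(volume, data=suv, units="SUV", provenance=prov)


def normalize_suvr(volume: DynamicPETVolume, reference) -> DynamicPETVolume:
    """Intensity-normalize a static volume to the mean of a reference VOI.

    The reference is the pons sphere in the human pipeline. The output mean
    over the reference mask is exactly 1 (to floating tolerance).
    """
    if volume.is_dynamic:
        raise ValueError(
            "normalize_suvr operates on static volumes; average frames first"
        )
    mask = _as_mask(volume, reference)
    ref_mean = float(volume.data[mask].mean())
    if ref_mean <= 0:
        raise DegenerateReferenceError(
            f"reference mean must be positive, got {ref_mean}"
        )
    prov = dict(volume.provenance)
    prov["suvr_reference"] = {
        "mean": ref_mean,
        "n_voxels": int(mask.sum()),
        "voi": reference.to_json() if isinstance(reference, SphericalVOI) else "mask",
    }
    return replace(volume, data=volume.data / ref_mean, units="SUVr", provenance=prov)


def flip_lateral(volume: DynamicPETVolume) -> DynamicPETVolume:
    """Mirror the volume across the mid-sagittal plane (first-axis reversal).

    Bit-exact, no resampling; an involution. Refuses grids not declared
    symmetric, because flipping such a grid would require resampling.
    """
    if not volume.symmetric_x:
        raise ValueError(
            "grid not declared mirror-symmetric; flipping would need resampling"
        )
    prov = dict(volume.provenance)
    prov["flipped_lr"] = not prov.get("flipped_lr", False)
    return replace(volume, data=volume.data[::-1].copy(), provenance=prov)


def voi_stats(volume: DynamicPETVolume, voi) -> dict:
    """Mean, maximum and volume (mL) over a VOI mask on a static volume."""
    mask = _as_mask(volume, voi)
    if not mask.any():
        raise ValueError("empty VOI mask")
    vals = volume.data[mask] if not volume.is_dynamic else volume.data[mask, :]
    return {
        "mean": float(vals.mean()),
        "max": float(vals.max()),
        "volume_mL": float(mask.sum()) * volume.voxel_volume_mL,
        "n_voxels": int(mask.sum()),
    }
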