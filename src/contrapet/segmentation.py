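"""Tumor segmentation: background-normalized ratio maps and iso-contour
region growing.

Tumor extent per modality is defined by thresholding a background-normalized
map and growing connected super-threshold regions from user seeds:

* TBR — image divided by the mean of a contralateral white-matter background
  VOI (tumor-to-background ratio).
* rCE — background-normalized contrast-enhanced T1 divided voxel-wise by the
  background-normalized native T1 (relative contrast enhancement, a surrogate
  for blood-brain-barrier leakage).
* thresholds — 1.6 for amino-acid PET (biopsy-validated) and rCE, 1.3 for T2
  hyperintensity; the TSPO-PET tumor threshold is a per-subject input because
  it is defined visually (line-profile assisted) by an expert reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import DynamicPETVolume, _as_mask

__all__ = [
    "TBRMap",
    "SegmentationResult",
    "SeedRejectedError",
    "tbr_map",
    "rce_map",
    "region_grow",
    "tumor_volumes",
]

NATIVE_EPS_FRACTION = 1e-6  # zero-guard for the rCE denominator


class SeedRejectedError(ValueError):
    """A seed voxel is below threshold or outside the confining mask."""


@dataclass
class TBRMap:
    """Background-normalized (dimensionless) map; mean over background = 1."""

    volume: DynamicPETVolume
    background: str
    modality: str  # one of CE-T1, native-T1, T2, FET, TSPO


@dataclass
class SegmentationResult:
    mask: np.ndarray
    threshold: float
    seeds: list
    connectivity: int
    confining_mask_id: str
    volume_mL: float
    n_voxels: int
    empty: bool = False
    notes: list = field(default_factory=list)


def tbr_map(volume: DynamicPETVolume, background_voi, modality: str = "") -> TBRMap:
    """Divide a static volume by the mean over a background VOI."""
    if volume.is_dynamic:
        raise ValueError("TBR maps are computed on static volumes")
    mask = _as_mask(volume, background_voi)
    bg = float(volume.data[mask].mean())
    if bg <= 0:
        raise ValueError(f"background mean must be positive, got {bg}")
    prov = dict(volume.provenance)
    prov["tbr_background_mean"] = bg
    out = DynamicPETVolume(
        volume.data / bg, volume.affine, units="TBR",
        symmetric_x=volume.symmetric_x, provenance=prov,
    )
    return TBRMap(out, background=f"mean={bg:.6g}, n={int(mask.sum())}", modality=modality)


def rce_map(tbr_ce: TBRMap, tbr_native: TBRMap) -> DynamicPETVolume:
    """Relative contrast enhancement: TBR_CE / TBR_native voxel-wise.

    Voxels whose native denominator is below a small fraction of the
    background mean are flagged missing (NaN), never infinite.
    """
    ce, nat = tbr_ce.volume, tbr_native.volume
    if ce.shape3d != nat.shape3d:
        raise ValueError("CE and native grids do not match")
    eps = NATIVE_EPS_FRACTION  # background mean is 1 after TBR normalization
    denom_ok = nat.data > eps
    out = np.where(denom_ok, ce.data / np.where(denom_ok, nat.data, 1.0), np.nan)
    prov = dict(ce.provenance)
    prov["rce"] = {"native_eps": eps, "n_missing": int((~denom_ok).sum())}
    return DynamicPETVolume(
        out, ce.affine, units="rCE", symmetric_x=ce.symmetric_x, provenance=prov
    )


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def region_grow(
    data,
    seeds,
    threshold: float,
    confining_mask: np.ndarray | None = None,
    connectivity: int = 6,
    confining_mask_id: str = "none",
) -> SegmentationResult:
    """Iso-contour region growing.

    The segmented mask is the set of voxels with value >= threshold reachable
    from any seed through face-adjacent (or 26-adjacent) super-threshold
    voxels, intersected with the confining mask. Deterministic regardless of
    traversal order (implemented via connected-component labeling). Seeds
    below threshold or outside the confinement are rejected by name.
    """
    if isinstance(data, DynamicPETVolume):
        arr = data.data
        voxvol = data.voxel_volume_mL
    else:
        arr = np.asarray(data, dtype=float)
        voxvol = 1e-3  # 1 mm^3 voxels by convention for bare arrays
    if arr.ndim != 3:
        raise ValueError("region growing operates on 3D maps")
    confine = (
        np.ones(arr.shape, dtype=bool)
        if confining_mask is None
        else np.asarray(confining_mask, dtype=bool)
    )
    above = (arr >= threshold) & confine & np.isfinite(arr)
    for s in seeds:
        s = tuple(int(v) for v in s)
        if not confine[s]:
            raise SeedRejectedError(f"seed {s} outside confining mask")
        if not (arr[s] >= threshold):
            raise SeedRejectedError(
                f"seed {s} below threshold ({arr[s]!r} < {threshold})"
            )
    labels, _ = ndimage.label(above, structure=_structure(connectivity))
    seed_labels = {labels[tuple(int(v) for v in s)] for s in seeds}
    seed_labels.discard(0)
    mask = np.isin(labels, sorted(seed_labels)) if seed_labels else np.zeros_like(above)
    return SegmentationResult(
        mask=mask,
        threshold=float(threshold),
        seeds=[tuple(int(v) for v in s) for s in seeds],
        connectivity=connectivity,
        confining_mask_id=confining_mask_id,
        volume_mL=float(mask.sum()) * voxvol,
        n_voxels=int(mask.sum()),
        empty=not mask.any(),
    )


# modality -> default iso-contour threshold; TSPO is subject-specific (visual)
DEFAULT_THRESHOLDS = {"FET": 1.6, "rCE": 1.6, "T2": 1.3}


def tumor_volumes(
    maps: dict,
    seeds: dict,
    thresholds: dict | None = None,
    confining_masks: dict | None = None,
    connectivity: int = 6,
    subject: str = "",
) -> tuple[pd.DataFrame, dict]:
    """Threshold-based tumor volumes per modality.

    Parameters
    ----------
    maps : dict modality -> DynamicPETVolume or ndarray
        Background-normalized maps (TBR/rCE) or the TSPO SUVr image. Absent
        modalities are simply omitted and reported as null volumes.
    seeds : dict modality -> list of voxel index triples
    thresholds : dict modality -> float
        Required for TSPO (per-subject, visually defined); other modalities
        fall back to the established defaults (FET/rCE 1.6, T2 1.3).
    confining_masks : dict modality -> bool ndarray, optional
        Pre-cut masks excluding adjacent structures (sinus, calvaria).

    Returns a (table, results) pair: a tidy volumes table and the per-modality
    SegmentationResult objects.
    """
    thresholds = dict(thresholds or {})
    confining_masks = confining_masks or {}
    rows = []
    results: dict[str, SegmentationResult] = {}
    for modality, vol in maps.items():
        if modality in thresholds:
            thr = thresholds[modality]
        elif modality in DEFAULT_THRESHOLDS:
            thr = DEFAULT_THRESHOLDS[modality]
        else:
            raise ValueError(f"no threshold configured for modality '{modality}'")
        mod_seeds = seeds.get(modality, [])
        if not mod_seeds:
            rows.append(
                dict(subject=subject, modality=modality, threshold=thr,
                     volume_mL=0.0, n_voxels=0, note="no lesion (no valid seed)")
            )
            continue
        res = region_grow(
            vol, mod_seeds, thr,
            confining_mask=confining_masks.get(modality),
            connectivity=connectivity,
            confining_mask_id=modality if modality in confining_masks else "none",
        )
        results[modality] = res
        rows.append(
            dict(subject=subject, modality=modality, threshold=thr,
                 volume_mL=res.volume_mL, n_voxels=res.n_voxels,
                 note="no lesion" if res.empty else "")
        )
    return pd.DataFrame(rows), results
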