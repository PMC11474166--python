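"""Interhemispheric association analyses.

Four views of the coupling between tumor and contralateral signal:

* tumor-seed correlation — across subjects, Pearson R between a tumor seed
  value and each contralateral region (optionally partialed on covariates);
* matched-region correlation — one pooled R over all (subject, region)
  pairs of ipsilateral value vs mirrored contralateral value;
* synchronicity matrix — the k x k matrix of interregional Pearson R across
  subjects, summarized by its mean off-diagonal entry;
* voxel-wise seed regression — per-voxel OLS of image value on the seed
  across subjects, yielding slope and t maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regional import AtlasParcellation, CONTRA, IPSI
from .volumes import DynamicPETVolume

__all__ = [
    "SynchronicityMatrix",
    "tumor_seed_correlation",
    "matched_region_correlation",
    "synchronicity_matrix",
    "voxelwise_seed_regression",
]


@dataclass
class SynchronicityMatrix:
    region_ids: list
    R: np.ndarray
    cohort: str
    n_subjects: int

    def __post_init__(self) -> None:
        k = len(self.region_ids)
        if self.R.shape != (k, k):
            raise ValueError("matrix shape mismatch")

    @property
    def mean_offdiagonal(self) -> float:
        """The synchronicity scalar: mean off-diagonal R (NaN-aware)."""
        off = ~np.eye(len(self.region_ids), dtype=bool)
        return float(np.nanmean(self.R[off]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.R, index=self.region_ids, columns=self.region_ids)


def tumor_seed_correlation(
    cohort_table: pd.DataFrame,
    tumor_seed_values: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pearson R (and p) between a per-subject tumor seed value and each
    contralateral region across subjects; optional covariate partialing."""
    from .outcome import partial_correlation

    contra = cohort_table[cohort_table["side"] == CONTRA]
    rows = []
    for rid, sub in contra.groupby("region_id"):
        merged = sub.set_index("subject")["value"].to_frame("region")
        merged["seed"] = tumor_seed_values
        merged = merged.dropna()
        if len(merged) < 4:
            raise ValueError(f"need >= 4 subjects with seed and region {rid}")
        if merged["seed"].std(ddof=1) == 0:
            rows.append(dict(region_id=rid, R=np.nan, p=np.nan,
                             n=len(merged), undefined=True))
            continue
        if covariates is not None:
            cov = covariates.loc[merged.index]
            res = partial_correlation(
                merged["seed"].to_numpy(), merged["region"].to_numpy(),
                cov.to_numpy(),
            )
            r, p, n = res["r"], res["p"], res["n"]
        else:
            r, p = stats.pearsonr(merged["seed"], merged["region"])
            n = len(merged)
        rows.append(dict(region_id=rid, R=float(r), p=float(p), n=int(n),
                         undefined=False))
    return pd.DataFrame(rows)


def matched_region_correlation(
    cohort_table: pd.DataFrame, atlas: AtlasParcellation
) -> dict:
    """Pooled Pearson R over all (subject, region) pairs of ipsilateral vs
    mirrored contralateral values."""
    mirror = atlas.mirror_map()
    ipsi = cohort_table[cohort_table["side"] == IPSI].copy()
    contra = cohort_table[cohort_table["side"] == CONTRA].copy()
    ipsi["mirror_id"] = ipsi["region_id"].map(mirror)
    merged = ipsi.merge(
        contra,
        left_on=["subject", "mirror_id"],
        right_on=["subject", "region_id"],
        suffixes=("_ipsi", "_contra"),
    ).dropna(subset=["value_ipsi", "value_contra"])
    if len(merged) < 10:
        raise ValueError(f"need >= 10 pooled pairs, got {len(merged)}")
    r, p = stats.pearsonr(merged["value_ipsi"], merged["value_contra"])
    return {"R": float(r), "p": float(p), "n_pairs": int(len(merged))}


def synchronicity_matrix(
    cohort_table: pd.DataFrame,
    region_ids: list | None = None,
    key: str = "region_id",
    cohort: str = "",
) -> SynchronicityMatrix:
    """Interregional Pearson-R matrix across subjects.

    Zero-variance regions get NaN rows/columns; the diagonal is exactly 1.
    """
    wide = cohort_table.pivot_table(index="subject", columns=key, values="value")
    if region_ids is not None:
        wide = wide[region_ids]
    if len(wide) < 4:
        raise ValueError("need >= 4 subjects")
    X = wide.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R[sd == 0, :] = np.nan
    R[:, sd == 0] = np.nan
    np.fill_diagonal(R, 1.0)
    return SynchronicityMatrix(
        region_ids=list(wide.columns), R=R, cohort=cohort, n_subjects=len(wide)
    )


def voxelwise_seed_regression(
    volumes: list[DynamicPETVolume] | np.ndarray,
    seed_values,
    smooth_sigma_mm: float = 0.0,
    affine: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel OLS of image value on a subject-level seed (with intercept).

    Returns (beta map, t map). beta = cov(seed, voxel)/var(seed); voxels
    with zero residual variance get the maximum representable t (flagged by
    +/- inf). Optional isotropic Gaussian pre-smoothing (off by default).
    """
    seed = np.asarray(seed_values, dtype=float)
    n = len(seed)
    if n < 4:
        raise ValueError("need >= 4 subjects")
    if isinstance(volumes, np.ndarray):
        stack = volumes.astype(float)
    else:
        if len(volumes) != n:
            raise ValueError("one volume per seed value required")
        stack = np.stack([v.data for v in volumes], axis=0)
    if smooth_sigma_mm > 0:
        from scipy.ndimage import gaussian_filter

        vox = 1.0
        if affine is not None:
            vox = float(np.abs(np.linalg.det(affine[:3, :3])) ** (1.0 / 3.0))
        stack = np.stack(
            [gaussian_filter(s, smooth_sigma_mm / vox) for s in stack], axis=0
        )
    s_c = seed - seed.mean()
    var_s = float((s_c**2).sum())
    if var_s == 0:
        raise ValueError("seed has zero variance")
    y = stack.reshape(n, -1)
    y_c = y - y.mean(axis=0)
    beta = (s_c @ y_c) / var_s
    resid = y_c - np.outer(s_c, beta)
    dof = n - 2
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 / var_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    shape = stack.shape[1:]
    return beta.reshape(shape), t.reshape(shape)
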