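"""Tracer kinetics: plasma input models, one-tissue-compartment simulation,
image-derived input extraction, and Logan graphical analysis.

The one-tissue compartment (1TC) model describes the tissue concentration as

    dC_T/dt = K1 * C_p(t) - k2 * C_T(t)
    C_T(t)  = K1 * int_0^t C_p(s) * exp(-k2 (t - s)) ds

with uptake rate K1 (mL/cm^3/min), clearance rate k2 (1/min) and total
distribution volume VT = K1/k2. Logan graphical analysis transforms the
measured time-activity curve into coordinates

    X(t) = int_0^t C_p / C_T(t),   Y(t) = int_0^t C_T / C_T(t)

whose late-time relation is linear with slope VT. The start of the linear
segment (t*) is chosen flexibly: the earliest frame such that all later
points deviate from the fitted line by at most a configured relative error
(default 10%), mirroring the standard graphical-analysis convention. VT
estimates below a threshold (default 0) are reported censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .volumes import DynamicPETVolume

__all__ = [
    "PlasmaInput",
    "TimeActivityCurve",
    "KineticParams",
    "LoganFit",
    "feng_input",
    "simulate_1tc",
    "image_derived_input",
    "logan_vt",
    "vt_map",
    "vtr_map",
]


@dataclass
class PlasmaInput:
    """Plasma (or image-derived blood) concentration sampled on a time grid
    starting at t=0 with C_p(0)=0."""

    times_min: np.ndarray
    concentration: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.times_min.ndim != 1 or self.times_min.shape != self.concentration.shape:
            raise ValueError("times and concentration must be matching 1D arrays")
        if self.times_min[0] != 0.0:
            raise ValueError("input grid must start at t=0")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if abs(self.concentration[0]) > 1e-9 * max(1.0, self.concentration.max()):
            raise ValueError("concentration must vanish at t=0")
        if np.any(self.concentration < 0):
            raise ValueError("concentration must be non-negative")

    def cumulative_integral(self, t: np.ndarray) -> np.ndarray:
        """int_0^t C_p ds at arbitrary times, by trapezoid on the sample grid."""
        cum = cumulative_trapezoid(self.concentration, self.times_min, initial=0.0)
        return np.interp(t, self.times_min, cum)

    def at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times_min, self.concentration)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"time_min": self.times_min, "value": self.concentration}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PlasmaInput":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(df["time_min"].to_numpy(), df["value"].to_numpy())


@dataclass
class TimeActivityCurve:
    """Frame-mean tissue concentrations at frame midpoints."""

    times_min: np.ndarray
    values: np.ndarray
    frame_starts: np.ndarray | None = None
    frame_ends: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_min.shape != self.values.shape:
            raise ValueError("times and values must match")

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"time_min": self.times_min, "value": self.values}
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class KineticParams:
    """1TC parameters; VT = K1/k2."""

    K1: float  # mL/cm^3/min
    k2: float  # 1/min

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 < 0:
            raise ValueError("rate constants must be non-negative")

    @property
    def VT(self) -> float:
        if self.k2 == 0:
            raise ValueError("VT undefined for k2 = 0")
        return self.K1 / self.k2


@dataclass
class LoganFit:
    """Result of a Logan graphical fit."""

    VT: float
    intercept: float
    t_star_min: float
    max_rel_error_achieved: float
    n_points_used: int
    converged: bool = True
    censored: bool = False
    warnings: list = field(default_factory=list)


def feng_input(
    A1: float = 851.1,
    A2: float = 21.9,
    A3: float = 20.8,
    l1: float = 4.134,
    l2: float = 0.1191,
    l3: float = 0.0104,
    times: np.ndarray | None = None,
    t_end_min: float = 60.0,
    dt_min: float = 0.01,
) -> PlasmaInput:
    """Tri-exponential bolus input, C_p(0) = 0 by construction:

        C_p(t) = (A1 t - A2 - A3) e^{-l1 t} + A2 e^{-l2 t} + A3 e^{-l3 t}

    clipped at zero. Defaults give a sharp bolus peaking near one minute
    followed by a slow washout, the shape of a measured arterial curve.
    """
    if min(l1, l2, l3) <= 0:
        raise ValueError("rate constants must be positive")
    if times is None:
        times = np.arange(0.0, t_end_min + dt_min / 2, dt_min)
    times = np.asarray(times, dtype=float)
    c = (
        (A1 * times - A2 - A3) * np.exp(-l1 * times)
        + A2 * np.exp(-l2 * times)
        + A3 * np.exp(-l3 * times)
    )
    c = np.clip(c, 0.0, None)
    if np.trapezoid(c, times) < 0:
        raise ValueError("input has negative area")
    return PlasmaInput(times, c)


def _1tc_fine(params: KineticParams, input: PlasmaInput, t_grid: np.ndarray) -> np.ndarray:
    """Exact 1TC solution on a grid assuming C_p piecewise linear between
    grid points (closed-form convolution per interval)."""
    cp = input.at(t_grid)
    k = params.k2
    ct = np.zeros_like(t_grid)
    h = np.diff(t_grid)
    a = cp[:-1]
    b = cp[1:]
    if k > 0:
        E = np.exp(-k * h)
        c_slope = (b - a) / h
        I = a * (1.0 - E) / k + c_slope * (h / k - (1.0 - E) / k**2)
    else:
        E = np.ones_like(h)
        I = (a + b) / 2.0 * h
    for i in range(len(h)):
        ct[i + 1] = ct[i] * E[i] + params.K1 * I[i]
    return ct


def simulate_1tc(
    params: KineticParams,
    input: PlasmaInput,
    frame_starts: np.ndarray,
    frame_ends: np.ndarray,
    dt_min: float = 0.005,
) -> TimeActivityCurve:
    """Simulate a frame-averaged 1TC tissue curve.

    The ODE is integrated on a fine grid (exact for piecewise-linear input),
    then averaged over each frame interval.
    """
    frame_starts = np.asarray(frame_starts, dtype=float)
    frame_ends = np.asarray(frame_ends, dtype=float)
    if frame_ends.max() > input.times_min.max() + 1e-9:
        raise ValueError("frames extend beyond input support")
    t_grid = np.union1d(
        np.arange(0.0, frame_ends.max() + dt_min / 2, dt_min),
        np.union1d(frame_starts, frame_ends),
    )
    ct = _1tc_fine(params, input, t_grid)
    cum = cumulative_trapezoid(ct, t_grid, initial=0.0)
    cum_at = lambda t: np.interp(t, t_grid, cum)
    means = (cum_at(frame_ends) - cum_at(frame_starts)) / (frame_ends - frame_starts)
    return TimeActivityCurve(
        (frame_starts + frame_ends) / 2.0,
        means,
        frame_starts,
        frame_ends,
        source=f"1TC K1={params.K1} k2={params.k2}",
    )


def image_derived_input(
    volume4d: DynamicPETVolume, carotid_voi
) -> PlasmaInput:
    """Per-frame mean over a blood-pool VOI (e.g. both carotid arteries),
    returned as a plasma input at frame midpoints.

    No partial-volume or metabolite correction is applied. A (0, 0) anchor is
    prepended when the first midpoint is after injection.
    """
    from .volumes import _as_mask

    if not volume4d.is_dynamic:
        raise ValueError("image-derived input requires a dynamic volume")
    mask = _as_mask(volume4d, carotid_voi)
    if not mask.any():
        raise ValueError("empty carotid VOI")
    curve = volume4d.data[mask, :].mean(axis=0)
    t = volume4d.frame_midpoints_min
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        curve = np.concatenate([[0.0], curve])
    return PlasmaInput(t, np.clip(curve, 0.0, None))


def logan_vt(
    tac: TimeActivityCurve,
    input: PlasmaInput,
    max_rel_error: float = 0.10,
    vt_threshold: float = 0.0,
) -> LoganFit:
    """Logan graphical analysis with flexible t*.

    Integrals use the trapezoid rule: the plasma integral on the input's own
    sample grid evaluated at frame midpoints, the tissue integral on frame
    midpoints with a zero anchor at t=0. t* is the earliest frame midpoint
    such that the line fitted to all later points keeps every included
    point's relative deviation within ``max_rel_error`` (relative residual
    around the fitted ordinate). Requires at least 3 points after t*.
    """
    t = tac.times_min
    ct = tac.values
    warns: list[str] = []
    valid = ct > 0
    if not valid.all():
        warns.append(f"excluded {int((~valid).sum())} frames with C_T <= 0")
    t_anchor = np.concatenate([[0.0], t])
    ct_anchor = np.concatenate([[0.0], ct])
    int_ct = cumulative_trapezoid(ct_anchor, t_anchor, initial=0.0)[1:]
    int_cp = input.cumulative_integral(t)
    x = np.where(valid, int_cp / np.where(valid, ct, 1.0), np.nan)
    y = np.where(valid, int_ct / np.where(valid, ct, 1.0), np.nan)
    ok = np.isfinite(x) & np.isfinite(y)

    idx = np.nonzero(ok)[0]
    for start in idx:
        sel = idx[idx >= start]
        if len(sel) < 3:
            break
        xs, ys = x[sel], y[sel]
        xc = xs - xs.mean()
        sxx = float((xc**2).sum())
        if sxx == 0:
            continue
        slope = float((xc * (ys - ys.mean())).sum() / sxx)
        intercept = float(ys.mean() - slope * xs.mean())
        fit = slope * xs + intercept
        denom = np.maximum(np.abs(fit), 1e-12)
        rel = float(np.max(np.abs(ys - fit) / denom))
        if rel <= max_rel_error:
            censored = slope < vt_threshold
            return LoganFit(
                VT=float(vt_threshold if censored else slope),
                intercept=float(intercept),
                t_star_min=float(t[start]),
                max_rel_error_achieved=rel,
                n_points_used=int(len(sel)),
                censored=bool(censored),
                warnings=warns,
            )
    return LoganFit(
        VT=float("nan"),
        intercept=float("nan"),
        t_star_min=float("nan"),
        max_rel_error_achieved=float("inf"),
        n_points_used=0,
        converged=False,
        warnings=warns + ["no t* satisfied the linearity criterion"],
    )


def vt_map(
    volume4d: DynamicPETVolume,
    input: PlasmaInput,
    voxel_mask: np.ndarray,
    max_rel_error: float = 0.10,
    vt_threshold: float = 0.0,
) -> DynamicPETVolume:
    """Voxel-wise Logan VT image. Voxels outside the mask carry NaN (never 0);
    the same flexible-t* policy is applied independently per voxel."""
    if not volume4d.is_dynamic:
        raise ValueError("vt_map requires a dynamic volume")
    mask = np.asarray(voxel_mask, dtype=bool)
    if mask.shape != volume4d.shape3d:
        raise ValueError("mask shape mismatch")
    out = np.full(volume4d.shape3d, np.nan)
    mids = volume4d.frame_midpoints_min
    fs, fe = volume4d.frame_starts, volume4d.frame_ends
    for ijk in zip(*np.nonzero(mask)):
        tac = TimeActivityCurve(mids, volume4d.data[ijk], fs, fe)
        fit = logan_vt(tac, input, max_rel_error, vt_threshold)
        out[ijk] = fit.VT
    prov = dict(volume4d.provenance)
    prov["logan"] = {
        "max_rel_error": max_rel_error,
        "vt_threshold": vt_threshold,
        "t_star_policy": "per-voxel flexible t*",
    }
    return DynamicPETVolume(
        out, volume4d.affine, units="VT", symmetric_x=volume4d.symmetric_x,
        provenance=prov,
    )


def vtr_map(vt_image: DynamicPETVolume, pons_voi) -> DynamicPETVolume:
    """Scale a VT image by its mean over the reference (pons) VOI so the
    reference mean of the output is 1."""
    from .volumes import DegenerateReferenceError, _as_mask

    mask = _as_mask(vt_image, pons_voi)
    ref = float(np.nanmean(vt_image.data[mask]))
    if not np.isfinite(ref) or ref <= 0:
        raise DegenerateReferenceError(f"pons VT mean must be positive, got {ref}")
    prov = dict(vt_image.provenance)
    prov["vtr_reference_mean"] = ref
    out = vt_image.data / ref
    return DynamicPETVolume(
        out, vt_image.affine, units="VTr", symmetric_x=vt_image.symmetric_x,
        provenance=prov,
    )
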