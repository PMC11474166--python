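"""Per-cell radiotracer uptake from sorted cell fractions (scRadiotracing).

After in-vivo tracer injection, hemispheres are dissociated and sorted into
myeloid-enriched (CD11b+) and myeloid-depleted fractions; each pellet's
activity is gamma-counted. The per-cell signal is

    Bq/cell      = A0 / N_cells         (A0 decay-corrected to injection)
    %ID x BW     = (Bq/cell / ID_Bq) * 100 * BW_g

i.e. the injected-dose- and body-weight-normalized activity per cell. The
F-18 half-life (109.77 min) is a configurable physical constant. Optional
purity correction (dividing the enriched-cell count by the sorted-fraction
purity) is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .volumes import Dosimetry

__all__ = [
    "F18_HALF_LIFE_MIN",
    "CellPellet",
    "decay_correct",
    "per_cell_uptake",
    "fraction_fold_change",
]

F18_HALF_LIFE_MIN = 109.77


@dataclass
class CellPellet:
    """One sorted-cell fraction from one animal."""

    subject: str
    fraction: str  # myeloid_enriched / myeloid_depleted / total
    measured_activity_Bq: float
    measurement_time_min: float  # post injection
    cell_count: int | None = None
    purity_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.measured_activity_Bq < 0:
            raise ValueError("activity must be non-negative")
        if self.fraction not in ("myeloid_enriched", "myeloid_depleted", "total"):
            raise ValueError(f"unknown fraction {self.fraction!r}")
        if self.purity_fraction is not None and not (0 <= self.purity_fraction <= 1):
            raise ValueError("purity must lie in [0, 1]")
        if self.fraction == "total" and self.purity_fraction is not None:
            raise ValueError("purity is defined only for sorted fractions")


def decay_correct(
    activity_Bq: float, elapsed_min: float, half_life_min: float = F18_HALF_LIFE_MIN
) -> float:
    """Back-correct a measured activity to injection time: A0 = A * 2^(t/T1/2)."""
    if elapsed_min < 0:
        raise ValueError("elapsed time must be non-negative")
    return float(activity_Bq * 2.0 ** (elapsed_min / half_life_min))


def per_cell_uptake(
    pellet: CellPellet,
    dose: Dosimetry,
    half_life_min: float = F18_HALF_LIFE_MIN,
    purity_correct: bool = False,
) -> dict:
    """Per-cell activity and its %ID x BW normalization.

    The pellet activity is decay-corrected to injection, divided by the cell
    count, then normalized by injected dose and scaled by body weight
    (unit: percent x gram per cell).
    """
    if not pellet.cell_count or pellet.cell_count <= 0:
        raise ValueError("cell count must be positive")
    a0 = decay_correct(
        pellet.measured_activity_Bq,
        pellet.measurement_time_min - dose.injection_time_min,
        half_life_min,
    )
    n = pellet.cell_count
    if purity_correct:
        if pellet.purity_fraction is None or pellet.purity_fraction <= 0:
            raise ValueError("purity correction requires a positive purity")
        n = pellet.cell_count * pellet.purity_fraction
    bq_per_cell = a0 / n
    pct = (bq_per_cell / dose.injected_dose_Bq) * 100.0 * dose.body_weight_g
    return {
        "Bq_per_cell": float(bq_per_cell),
        "pct_ID_x_BW_per_cell": float(pct),
        "activity_at_injection_Bq": float(a0),
        "purity_corrected": purity_correct,
    }


def fraction_fold_change(group_uptakes: dict[str, np.ndarray]) -> dict:
    """Fold change of mean per-cell uptake between groups, with one-way
    ANOVA p (pairwise Welch-free t with BH-FDR post hoc when > 2 groups).

    The fold change reported for a pair (A, B) is mean(A)/mean(B); all
    ordered pairs (in listing order) are returned alongside the omnibus
    ANOVA.
    """
    names = list(group_uptakes)
    arrays = {k: np.asarray(v, dtype=float) for k, v in group_uptakes.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs >= 2 pellets")
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate(list(arrays.values()))
    if np.allclose(pooled, pooled[0]):
        anova_p = 1.0
        anova_F = 0.0
    else:
        anova_F, anova_p = stats.f_oneway(*arrays.values())
    folds = {}
    pair_p = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            denom = arrays[b].mean()
            folds[f"{a}_vs_{b}"] = float(arrays[a].mean() / denom) if denom else np.nan
            pair_p[f"{a}_vs_{b}"] = float(
                stats.ttest_ind(arrays[a], arrays[b], equal_var=True).pvalue
            )
    out = {
        "fold_changes": folds,
        "anova_F": float(anova_F),
        "anova_p": float(anova_p),
        "n": {k: int(len(v)) for k, v in arrays.items()},
    }
    if len(names) > 2:
        keys = list(pair_p)
        _, q, _, _ = multipletests([pair_p[k] for k in keys], method="fdr_bh")
        out["pairwise_q"] = dict(zip(keys, map(float, q)))
    out["pairwise_p"] = pair_p
    return out


def pellet_table(pellets: list[CellPellet]) -> pd.DataFrame:
    """Tidy TSV-ready table of pellets."""
    return pd.DataFrame(
        [
            dict(
                subject=p.subject,
                fraction=p.fraction,
                activity_Bq=p.measured_activity_Bq,
                time_min=p.measurement_time_min,
                cells=p.cell_count,
                purity=p.purity_fraction,
            )
            for p in pellets
        ]
    )
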