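"""Second-order polynomial developmental trajectories per group.

Each metric's evolution with age is summarized, separately for control and
IUGR subjects, by a least-squares quadratic value = b0 + b1*age + b2*age^2.
Fits default to individual subject points; fitting to per-age group means is
available (``on_means=True``).  With exactly 3 distinct ages and each age
cell replaced by its mean the quadratic interpolates the means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as P

__all__ = ["TrajectoryFit", "fit_quadratic_per_group", "evaluate_trajectory"]


@dataclass
class TrajectoryFit:
    metric: str
    group: str
    coefficients: tuple  # (b0, b1, b2)
    resid_sd: float
    n: int

    def __post_init__(self):
        c = tuple(float(v) for v in self.coefficients)
        if len(c) != 3 or not np.isfinite(c).all():
            raise ValueError(f"need 3 finite coefficients, got {self.coefficients}")
        if self.n < 3:
            raise ValueError("a quadratic fit needs n >= 3")
        self.coefficients = c


def _fit_one(ages, values, metric, group, on_means):
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if on_means:
        uniq = np.unique(ages)
        values = np.array([values[ages == a].mean() for a in uniq])
        ages = uniq
    if np.unique(ages).size < 3:
        raise ValueError(
            f"group {group!r} has {np.unique(ages).size} distinct ages; "
            "a quadratic fit needs at least 3"
        )
    coef = P.polyfit(ages, values, 2)
    resid = values - P.polyval(ages, coef)
    dof = max(len(values) - 3, 1)
    return TrajectoryFit(metric=metric, group=group,
                         coefficients=tuple(coef),
                         resid_sd=float(np.sqrt((resid**2).sum() / dof)),
                         n=len(values))


def fit_quadratic_per_group(ages, values, groups, metric: str = "",
                            on_means: bool = False) -> dict:
    """Per-group least-squares quadratic fits.

    Returns {group: TrajectoryFit}.  Groups are fit independently, so
    permuting subjects within a group leaves the fits unchanged.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if not (len(ages) == len(values) == len(groups)):
        raise ValueError("ages, values and groups must have equal length")
    out = {}
    for g in dict.fromkeys(groups.tolist()):  # preserve first-seen order
        sel = groups == g
        out[g] = _fit_one(ages[sel], values[sel], metric, str(g), on_means)
    return out


def evaluate_trajectory(fit: TrajectoryFit, age_grid) -> np.ndarray:
    """Pointwise evaluation of the fitted quadratic on an age grid."""
    grid = np.asarray(age_grid, dtype=float)
    return P.polyval(grid, np.asarray(fit.coefficients))
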