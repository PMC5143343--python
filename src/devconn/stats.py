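"""Covariate-adjusted case-control comparison and partial correlation.

Group comparisons use an ordinary-least-squares general linear model with
gender and maternal education as cofactors and gestational age at birth as a
covariate; network metrics additionally adjust for age at scan, scores for
age at test.  The reported effect is the group-indicator coefficient with its
two-sided t-test p-value; no multiple-comparison correction is applied (raw
p-values are always retained so users can apply their own).

Metric-score association is assessed as an age-residualized partial
correlation: scores are first corrected for age at test and metrics for age
at scan, then the Pearson correlation of the two sets of residuals is
computed after removing gender, GA, maternal education and group.  The
p-value uses t = rho * sqrt(df / (1 - rho^2)) with df = n - 2 - #confounders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA = 0.05
TREND = 0.1

#: Metadata columns required by the design-matrix builder.
COVARIATE_COLUMNS = ["group", "gender", "maternal_education", "ga_weeks",
                     "age_at_scan", "age_at_test"]

__all__ = [
    "GroupComparison",
    "PartialCorrelation",
    "build_design_matrix",
    "glm_group_compare",
    "residualize_by_age",
    "partial_correlation",
    "run_case_control_battery",
]


@dataclass
class GroupComparison:
    name: str
    estimate: float
    se: float
    p_value: float
    covariates: list
    n_control: int
    n_iugr: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    @property
    def trend(self) -> bool:
        return self.p_value < TREND


@dataclass
class PartialCorrelation:
    metric: str
    score: str
    rho: float
    p_value: float
    confounders: list = field(default_factory=list)
    df: int = 0

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([
        dict(subject_id=r.id, group=r.group, gender=r.gender,
             maternal_education=r.maternal_education, ga_weeks=r.ga_weeks,
             age_at_scan=r.age_at_scan, age_at_test=r.age_at_test)
        for r in records
    ]).set_index("subject_id")


def build_design_matrix(records, response_kind: str) -> pd.DataFrame:
    """GLM design: intercept, group, gender, education, GA, and age.

    ``response_kind`` selects the age covariate: ``"metric"`` uses age at
    scan, ``"score"`` uses age at test.  Rows with missing covariates are
    dropped (listwise deletion, logged).  Raises if the design is rank
    deficient, naming the offending columns.
    """
    if response_kind not in ("metric", "score"):
        raise ValueError("response_kind must be 'metric' or 'score'")
    df = _records_frame(records)
    age_col = "age_at_scan" if response_kind == "metric" else "age_at_test"
    cols = ["group", "gender", "maternal_education", "ga_weeks", age_col]
    missing = df[cols].isna().any(axis=1)
    if missing.any():
        logger.warning("listwise deletion of %d subjects with missing covariates: %s",
                       int(missing.sum()), list(df.index[missing]))
        df = df[~missing]
    design = pd.DataFrame({
        "intercept": 1.0,
        "group": (df["group"] == "IUGR").astype(float),
        "gender": df["gender"].astype(float),
        "maternal_education": df["maternal_education"].astype(float),
        "ga_weeks": df["ga_weeks"].astype(float),
        "age": df[age_col].astype(float),
    }, index=df.index)
    x = design.to_numpy()
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = [c for c in design.columns[1:] if design[c].nunique() <= 1]
        raise ValueError(
            f"rank-deficient design (rank {rank} < {x.shape[1]}); "
            f"constant/collinear columns: {bad or 'unidentified'}"
        )
    return design


def glm_group_compare(values, design: pd.DataFrame, name: str = "") -> GroupComparison:
    """OLS fit of values on the design; reports the group coefficient.

    With an intercept-and-group-only design this reproduces the classical
    pooled-variance two-sample t-test exactly.
    """
    y = np.asarray(values, dtype=float)
    x = design.to_numpy() if isinstance(design, pd.DataFrame) else np.asarray(design)
    if y.shape[0] != x.shape[0]:
        raise ValueError("values and design have different lengths")
    if y.shape[0] <= x.shape[1]:
        raise ValueError("need more subjects than design columns")
    try:
        fit = sm.OLS(y, x).fit()
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise ValueError(f"singular normal equations: {err}") from err
    cols = list(design.columns) if isinstance(design, pd.DataFrame) else [
        f"x{i}" for i in range(x.shape[1])
    ]
    gi = cols.index("group") if "group" in cols else 1
    group_col = x[:, gi]
    return GroupComparison(
        name=name,
        estimate=float(fit.params[gi]),
        se=float(fit.bse[gi]),
        p_value=float(fit.pvalues[gi]),
        covariates=[c for i, c in enumerate(cols) if i not in (0, gi)],
        n_control=int((group_col == 0).sum()),
        n_iugr=int((group_col == 1).sum()),
    )


def residualize_by_age(values, ages) -> np.ndarray:
    """Residuals of an OLS regression of values on (intercept, age)."""
    y = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if y.shape[0] < 3:
        raise ValueError("need at least 3 subjects to residualize")
    if np.ptp(a) == 0:
        raise ValueError("constant ages: age effect inestimable")
    x = np.column_stack([np.ones_like(a), a])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def partial_correlation(x, y, confounders=None, confounder_names=None) -> PartialCorrelation:
    """Partial Pearson correlation of x and y given confounders.

    Both variables are residualized on (intercept + confounders); the
    correlation of the residuals is returned with a two-sided p-value on
    df = n - 2 - #confounders.  With no confounders this is the plain
    Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if confounders is None or (hasattr(confounders, "size") and confounders.size == 0):
        z = np.empty((x.shape[0], 0))
    else:
        z = np.asarray(confounders, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
    n, k = x.shape[0], z.shape[1]
    if n <= k + 2:
        raise ValueError("need n > #confounders + 2")
    d = np.column_stack([np.ones(n), z])
    bx, *_ = np.linalg.lstsq(d, x, rcond=None)
    by, *_ = np.linalg.lstsq(d, y, rcond=None)
    rx, ry = x - d @ bx, y - d @ by
    sx, sy = rx.std(), ry.std()
    # residuals that are numerically zero relative to the inputs mean the
    # variable is (near-)collinear with the confounders
    if sx <= 1e-10 * max(x.std(), 1e-300) or sy <= 1e-10 * max(y.std(), 1e-300):
        raise ValueError("zero-variance residuals: correlation undefined")
    rho = float(np.dot(rx - rx.mean(), ry - ry.mean()) / (n * sx * sy))
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df))
    names = (list(confounder_names) if confounder_names is not None
             else [f"c{i}" for i in range(k)])
    return PartialCorrelation(metric="x", score="y", rho=rho, p_value=p,
                              confounders=names, df=df)


CONFOUNDERS = ["gender", "ga_weeks", "maternal_education", "group"]


def run_case_control_battery(records, metric_table: pd.DataFrame,
                             score_table: pd.DataFrame | None = None,
                             pairs=None):
    """Full comparison + correlation battery over a cohort.

    One covariate-adjusted :class:`GroupComparison` per metric column (age
    at scan as covariate) and per score column (age at test); one
    age-residualized :class:`PartialCorrelation` per requested
    (metric, score) pair (all pairs by default), with gender, GA, maternal
    education and group as confounders.  Tables are joined on subject id;
    join failures are logged and dropped.

    Returns
    -------
    (comparisons, correlations) : list of GroupComparison, list of PartialCorrelation
    """
    meta = _records_frame(records)
    metric_table = metric_table.copy()
    comparisons = []

    def _aligned(table, kind):
        common = meta.index.intersection(table.index)
        lost = table.index.difference(meta.index)
        if len(lost):
            logger.warning("%d %s rows with no metadata: %s", len(lost), kind,
                           list(lost)[:5])
        return table.loc[common], meta.loc[common]

    mtab, mmeta = _aligned(metric_table, "metric")
    design_m = build_design_matrix(mmeta, "metric")
    mtab = mtab.loc[design_m.index]
    for col in mtab.columns:
        comparisons.append(glm_group_compare(mtab[col], design_m, name=col))

    correlations = []
    if score_table is not None and len(score_table):
        stab, smeta = _aligned(score_table, "score")
        design_s = build_design_matrix(smeta, "score")
        stab = stab.loc[design_s.index]
        for col in stab.columns:
            comparisons.append(glm_group_compare(stab[col], design_s, name=col))

        both = design_m.index.intersection(design_s.index)
        meta_b = meta.loc[both]
        conf = np.column_stack([
            meta_b["gender"].astype(float),
            meta_b["ga_weeks"].astype(float),
            meta_b["maternal_education"].astype(float),
            (meta_b["group"] == "IUGR").astype(float),
        ])
        if pairs is None:
            pairs = [(m, s) for m in mtab.columns for s in stab.columns]
        for m, s in pairs:
            xm = residualize_by_age(mtab.loc[both, m],
                                    meta_b["age_at_scan"])
            ys = residualize_by_age(stab.loc[both, s],
                                    meta_b["age_at_test"])
            pc = partial_correlation(xm, ys, conf, confounder_names=CONFOUNDERS)
            pc.metric, pc.score = m, s
            correlations.append(pc)
    return comparisons, correlations


def comparisons_frame(comparisons) -> pd.DataFrame:
    return pd.DataFrame([
        dict(name=c.name, estimate=c.estimate, se=c.se, p=c.p_value,
             n_control=c.n_control, n_iugr=c.n_iugr,
             significant=c.significant, trend=c.trend)
        for c in comparisons
    ])


def correlations_frame(correlations) -> pd.DataFrame:
    return pd.DataFrame([
        dict(metric=c.metric, score=c.score, rho=c.rho, p=c.p_value,
             df=c.df, significant=c.significant)
        for c in correlations
    ])
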