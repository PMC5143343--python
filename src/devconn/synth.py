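"""Synthetic data: toy parcellations, streamlines, and calibrated cohorts.

The cohort generator emulates the statistical structure the downstream
analysis assumes: two groups (control / IUGR) observed cross-sectionally at
1, 6 and 10 years, 93-node connectomes whose binary degree, efficiency and
clustering distributions match published group means/SDs, FA edge weights
whose level separates the groups, and neurobehavioral scores with injected
age-residualized partial correlations to named network metrics.

Generative model for one subject's connectome
---------------------------------------------
Nodes carry latent positions on a ring, drawn either uniformly or in tight
clumps; a pair's propensity to connect is a mixture of ring proximity and
pure noise, and exactly E edges (set by the subject's degree target) with the
highest propensity are realized.  A single "structure" parameter in [0, 2]
moves the expected clustering continuously from the Erdos-Renyi level
(structure 0) through a windowed ring graph (structure 1, clustering ~ 0.75)
to a clumped ring (structure 2, clustering ~ 0.88); it is calibrated once per
design cell by bisection against the cell's clustering target.  Edge FA
values are Gaussian around a per-subject mean (clipped to [fa_floor, 1]); the
tractography FA stop threshold (0.1) enters only as that floor.

Because dense graphs of this kind have diameter 2, the binary global
efficiency is pinned by density and the local efficiency by clustering, so
matching degree and clustering reproduces the published efficiency levels
without further tuning.  Normalizing each FA-weighted network to unit total
strength makes the normalized efficiencies *increase* when degree and FA
decrease, reproducing the direction of the reported group differences in the
normalized connectome without any injected effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .core import Connectome, ParcelMap, Streamline, StreamlineSet, SubjectRecord
from .construct import MERGED_CEREBELLAR_NAMES, AAL_CORTICAL_NAMES, normalize_total_strength
from . import metrics as _metrics

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorParams",
    "CellDesign",
    "ScoreModel",
    "CohortDesign",
    "default_design",
    "make_toy_parcellation",
    "make_toy_streamlines",
    "simulate_connectome",
    "simulate_cohort",
    "simulate_scores",
]


def merged_aal_node_names() -> list:
    """93 node names: 90 AAL cortical + 3 merged cerebellar super-regions."""
    return AAL_CORTICAL_NAMES + list(MERGED_CEREBELLAR_NAMES)


def _node_names(n: int) -> list:
    if n == 93:
        return merged_aal_node_names()
    return [f"Region_{i + 1}" for i in range(n)]


# ---------------------------------------------------------------------------
# toy spatial objects


@dataclass
class GeneratorParams:
    """Knobs of the toy spatial generators.

    fa_range bounds per-streamline mean FA; fa_stop is the tractography FA
    stop threshold, used only as a floor on generated FA values; density is
    the target edge density of simulated connectomes.
    """

    grid_dims: tuple = (16, 16, 8)
    n_regions: int = 8
    n_streamlines: int = 500
    fa_range: tuple = (0.1, 0.9)
    fa_stop: float = 0.1
    density: float = 0.65

    def __post_init__(self):
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        lo, hi = self.fa_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("fa_range must satisfy 0 <= lo <= hi <= 1")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must be in (0, 1]")


def make_toy_parcellation(grid_dims, n_regions: int, seed: int) -> ParcelMap:
    """Random nearest-seed parcellation of a voxel grid.

    ``n_regions`` seed voxels are placed in the grid interior and every
    interior voxel takes the label of its nearest seed (lowest label on
    ties); the outer shell (along dimensions of size > 2) stays background 0.
    Every label 1..n_regions occurs at least once (each seed keeps its own
    voxel).  Deterministic given the seed.
    """
    dims = tuple(int(d) for d in grid_dims)
    if len(dims) != 3 or any(d < 1 for d in dims):
        raise ValueError(f"grid_dims must be 3 positive integers, got {grid_dims}")
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    lo = [1 if d > 2 else 0 for d in dims]
    hi = [d - 1 if d > 2 else d for d in dims]
    interior = [
        (x, y, z)
        for x in range(lo[0], hi[0])
        for y in range(lo[1], hi[1])
        for z in range(lo[2], hi[2])
    ]
    if len(interior) < n_regions:
        raise ValueError(
            f"grid {dims} has only {len(interior)} interior voxels for "
            f"{n_regions} regions"
        )
    rng = np.random.default_rng(seed)
    seeds = np.array(interior)[rng.choice(len(interior), n_regions, replace=False)]
    volume = np.zeros(dims, dtype=np.int64)
    pts = np.array(interior)
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)  # argmin ties -> lowest seed index
    volume[pts[:, 0], pts[:, 1], pts[:, 2]] = nearest + 1
    names = {i + 1: f"Region_{i + 1}" for i in range(n_regions)}
    return ParcelMap(volume=volume, label_names=names)


def make_toy_streamlines(
    parcel_map: ParcelMap,
    n_streamlines: int,
    fa_range=(0.1, 0.9),
    seed: int = 0,
) -> StreamlineSet:
    """Random streamlines between labeled voxels of a toy parcellation.

    Endpoints sit at centers of labeled voxels; interior points interpolate
    the endpoints with small jitter, clipped to the grid.  Per-streamline
    mean FA is uniform in ``fa_range``.
    """
    lo, hi = float(fa_range[0]), float(fa_range[1])
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("fa_range must be within [0, 1]")
    labeled = np.argwhere(parcel_map.volume > 0)
    if labeled.shape[0] == 0:
        raise ValueError("parcel map has no labeled voxels")
    dims = np.array(parcel_map.volume.shape, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(int(n_streamlines)):
        a, b = labeled[rng.choice(labeled.shape[0], 2, replace=True)]
        start = a + 0.5
        end = b + 0.5
        k = int(rng.integers(2, 9))
        t = np.linspace(0.0, 1.0, k)[:, None]
        pts = start[None, :] * (1 - t) + end[None, :] * t
        if k > 2:
            pts[1:-1] += rng.normal(0.0, 0.25, size=(k - 2, 3))
            pts[1:-1] = np.clip(pts[1:-1], 0.0, dims - 1e-6)
        fa = float(rng.uniform(lo, hi)) if hi > lo else lo
        out.append(Streamline(points=pts, mean_fa=fa))
    return StreamlineSet(out)


# ---------------------------------------------------------------------------
# single-connectome simulation


def simulate_connectome(
    n_nodes: int,
    density: float,
    weight_mean: float,
    weight_sd: float,
    seed: int,
    variant: str = "fa_weighted",
) -> Connectome:
    """Erdos-Renyi connectome with truncated-normal FA-like weights.

    Edges are independent Bernoulli(density); weights are drawn from a normal
    (weight_mean, weight_sd) truncated to [0, 1].  ``variant="binary"`` sets
    all edge weights to 1.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not (0.0 < density <= 1.0):
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = int(n_nodes)
    iu, ju = np.triu_indices(n, 1)
    present = rng.random(iu.size) < density
    m = np.zeros((n, n))
    if variant == "binary":
        w = np.ones(int(present.sum()))
    elif weight_sd == 0:
        w = np.full(int(present.sum()), float(weight_mean))
    else:
        a = (0.0 - weight_mean) / weight_sd
        b = (1.0 - weight_mean) / weight_sd
        w = truncnorm.rvs(a, b, loc=weight_mean, scale=weight_sd,
                          size=int(present.sum()), random_state=rng)
    m[iu[present], ju[present]] = w
    m = m + m.T
    return Connectome(_node_names(n), m, variant)


def _structured_adjacency(n, n_edges, structure, rng, n_clumps=5, clump_sigma=0.01):
    """Exactly-n_edges adjacency from the latent ring model (see module doc).

    structure in [0, 1] mixes pure noise into ring proximity (0 = ER,
    1 = windowed ring graph); structure in (1, 2] additionally relocates each
    node, with probability structure - 1, into one of ``n_clumps`` tight
    random clumps, pushing clustering above the windowed-ring level.
    """
    s = min(float(structure), 1.0)
    pos = rng.random(n)
    if structure > 1.0:
        q = float(structure) - 1.0
        centers = rng.random(n_clumps)
        clump = rng.integers(0, n_clumps, size=n)
        clumped = rng.random(n) < q
        cpos = (centers[clump] + rng.normal(0.0, clump_sigma, size=n)) % 1.0
        pos = np.where(clumped, cpos, pos)
    iu, ju = np.triu_indices(n, 1)
    delta = np.abs(pos[iu] - pos[ju])
    d = 2.0 * np.minimum(delta, 1.0 - delta)  # circular distance scaled to [0,1]
    score = s * d + (1.0 - s) * rng.random(iu.size) + 1e-9 * rng.random(iu.size)
    order = np.argsort(score)[: int(n_edges)]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[order], ju[order]] = True
    return adj | adj.T


_STRUCTURE_CACHE: dict = {}


def _calibrate_structure(n, n_edges, clustering_target, n_clumps=5, n_reps=32):
    """Bisect the structure parameter to hit a binary clustering target.

    Deterministic (internal fixed seeds), cached per (n, n_edges, target,
    n_clumps).  Saturates at the ends of the reachable range.
    """
    key = (int(n), int(n_edges), round(float(clustering_target), 6), int(n_clumps))
    if key in _STRUCTURE_CACHE:
        return _STRUCTURE_CACHE[key]

    def mean_c(structure):
        vals = []
        for rep in range(n_reps):
            rng = np.random.default_rng(
                np.random.SeedSequence((9721, key[0], key[1], rep))
            )
            adj = _structured_adjacency(n, n_edges, structure, rng, n_clumps)
            vals.append(_metrics.average_clustering(adj.astype(float), weighted=False))
        return float(np.mean(vals))

    lo, hi = 0.0, 2.0
    if clustering_target <= mean_c(lo):
        _STRUCTURE_CACHE[key] = lo
        return lo
    if clustering_target >= mean_c(hi):
        _STRUCTURE_CACHE[key] = hi
        return hi
    for _ in range(14):
        mid = 0.5 * (lo + hi)
        if mean_c(mid) < clustering_target:
            lo = mid
        else:
            hi = mid
    out = 0.5 * (lo + hi)
    _STRUCTURE_CACHE[key] = out
    return out


# ---------------------------------------------------------------------------
# cohort design


@dataclass
class CellDesign:
    """Targets for one (age, group) cohort cell.

    degree/clustering/edge_fa targets are the means the generated subjects'
    computed metrics should reproduce; *_sd are between-subject SDs.
    ``fa_sigma`` is the within-subject SD of edge FA around the subject mean;
    it controls how much weighted shortest paths exploit strong edges and is
    calibrated so the weighted efficiency levels match the published ones.
    """

    age_years: float
    group: str
    n: int
    ga_mean: float
    ga_sd: float
    age_scan_mean: float
    age_scan_sd: float
    age_test_mean: float
    age_test_sd: float
    degree_mean: float
    degree_sd: float
    clustering: float
    edge_fa_mean: float
    edge_fa_sd: float
    fa_sigma: float = 0.045

    def validate(self, n_nodes: int):
        if self.group not in ("control", "IUGR"):
            raise ValueError(f"bad group {self.group!r}")
        if self.n < 1:
            raise ValueError("cell size must be >= 1")
        for name in ("ga_sd", "age_scan_sd", "age_test_sd", "degree_sd",
                     "edge_fa_sd", "fa_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.degree_mean <= n_nodes - 1):
            raise ValueError(
                f"degree target {self.degree_mean} unreachable with "
                f"{n_nodes} nodes"
            )
        if not (0.0 <= self.clustering < 1.0):
            raise ValueError("clustering target must be in [0, 1)")
        if not (0.0 < self.edge_fa_mean < 1.0):
            raise ValueError("edge FA mean must be in (0, 1)")


@dataclass
class ScoreModel:
    """Generative model of one neurobehavioral score.

    The score is linear in one named network metric plus confounder
    contributions plus Gaussian noise, with the noise variance solved so the
    age-residualized partial correlation between score and metric equals
    ``rho`` in expectation.  Standardized-scale defaults (mean 100, SD 15).
    """

    name: str
    mean: float = 100.0
    sd: float = 15.0
    metric: str | None = None
    rho: float = 0.0

    def __post_init__(self):
        if abs(self.rho) > 1.0:
            raise ValueError(f"target partial correlation {self.rho} outside [-1, 1]")
        if self.sd < 0:
            raise ValueError("score SD must be >= 0")
        if self.metric is not None and self.metric not in _metrics.METRIC_COLUMNS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.rho != 0.0 and self.metric is None:
            raise ValueError("a non-zero rho needs a linked metric")


@dataclass
class CohortDesign:
    """Full two-group multi-age cohort design.

    The seed fully determines the generated cohort.  Defaults (see
    :func:`default_design`) encode the published cohort: per-cell sample
    sizes, GA and age distributions, and per-cell metric targets.
    """

    cells: list
    n_nodes: int = 93
    gender_p: float = 0.5
    edu_probs: tuple = (0.3, 0.4, 0.3)
    score_models: list = field(default_factory=list)
    n_clumps: int = 5
    fa_floor: float = 0.1
    seed: int = 0

    def validate(self):
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        if not self.cells:
            raise ValueError("design has no cells")
        if not (0.0 <= self.gender_p <= 1.0):
            raise ValueError("gender proportion must be in [0, 1]")
        if abs(sum(self.edu_probs) - 1.0) > 1e-9:
            raise ValueError("education proportions must sum to 1")
        for c in self.cells:
            c.validate(self.n_nodes)
        for m in self.score_models:
            if m.metric is not None and m.metric not in _metrics.METRIC_COLUMNS:
                raise ValueError(f"unknown metric {m.metric!r}")


# Published-cohort defaults: per (age, group) sample size, GA (weeks),
# ages (years), binary degree mean/SD, binary clustering, and the implied
# mean edge FA with its between-subject SD.
_CELL_DEFAULTS = {
    (1, "control"): dict(n=7, ga=(32.2, 1.7), age_scan=(1.1, 0.2),
                         age_test=(1.7, 0.3), degree=(60.24, 1.26),
                         clustering=0.762, edge_fa=(0.3162, 0.0139)),
    (1, "IUGR"): dict(n=8, ga=(30.9, 1.7), age_scan=(1.0, 0.1),
                      age_test=(1.7, 0.4), degree=(56.87, 2.57),
                      clustering=0.743, edge_fa=(0.3097, 0.0260)),
    (6, "control"): dict(n=8, ga=(32.4, 2.3), age_scan=(6.8, 0.6),
                         age_test=(6.3, 0.7), degree=(55.13, 3.72),
                         clustering=0.763, edge_fa=(0.3504, 0.0050)),
    (6, "IUGR"): dict(n=10, ga=(32.6, 1.5), age_scan=(6.9, 0.7),
                      age_test=(6.2, 0.5), degree=(53.65, 2.96),
                      clustering=0.760, edge_fa=(0.3395, 0.0050)),
    (10, "control"): dict(n=8, ga=(32.5, 1.8), age_scan=(10.0, 1.0),
                          age_test=(9.8, 1.0), degree=(53.14, 1.735),
                          clustering=0.743, edge_fa=(0.3532, 0.0151)),
    (10, "IUGR"): dict(n=8, ga=(32.7, 1.5), age_scan=(10.2, 1.0),
                       age_test=(10.0, 0.9), degree=(48.88, 6.522),
                       clustering=0.728, edge_fa=(0.3519, 0.0050)),
}

#: Default score models: infant-scale scores (mean 100, SD 15) whose
#: age-residualized partial correlations with named metrics follow the
#: reported significant associations at 1 year.
_DEFAULT_SCORE_MODELS = (
    ("cognitive", "faw_global_efficiency", 0.6922),
    ("language", None, 0.0),
    ("motor", "faw_global_efficiency", 0.6842),
    ("socio_emotional", "faw_strength", 0.9001),
    ("adaptive", None, 0.0),
)


def default_design(
    ages=(1, 6, 10),
    n_control: int | None = None,
    n_iugr: int | None = None,
    n_nodes: int = 93,
    with_scores: bool = True,
    seed: int = 0,
) -> CohortDesign:
    """The published-cohort design, optionally resized.

    ``n_control`` / ``n_iugr`` override the per-cell sample sizes (the
    defaults are the published ones: 7/8, 8/10, 8/8).
    """
    cells = []
    for age in ages:
        for group in ("control", "IUGR"):
            if (age, group) not in _CELL_DEFAULTS:
                raise ValueError(f"no default cell for age {age}")
            d = _CELL_DEFAULTS[(age, group)]
            n = d["n"]
            if group == "control" and n_control is not None:
                n = n_control
            if group == "IUGR" and n_iugr is not None:
                n = n_iugr
            cells.append(CellDesign(
                age_years=age, group=group, n=n,
                ga_mean=d["ga"][0], ga_sd=d["ga"][1],
                age_scan_mean=d["age_scan"][0], age_scan_sd=d["age_scan"][1],
                age_test_mean=d["age_test"][0], age_test_sd=d["age_test"][1],
                degree_mean=d["degree"][0], degree_sd=d["degree"][1],
                clustering=d["clustering"],
                edge_fa_mean=d["edge_fa"][0], edge_fa_sd=d["edge_fa"][1],
            ))
    models = [
        ScoreModel(name=n, metric=m, rho=r) for n, m, r in _DEFAULT_SCORE_MODELS
    ] if with_scores else []
    return CohortDesign(cells=cells, n_nodes=n_nodes, score_models=models, seed=seed)


def null_design(base: CohortDesign | None = None) -> CohortDesign:
    """Copy of a design with the IUGR cells given the control targets.

    Covariate distributions are also equalized so the only group difference
    is the label; used for type-I-error checks of the downstream tests.
    """
    base = base or default_design(ages=(1,), with_scores=False)
    by_cell = {(c.age_years, c.group): c for c in base.cells}
    cells = []
    for c in base.cells:
        if c.group == "IUGR":
            ctrl = by_cell.get((c.age_years, "control"), c)
            cells.append(replace(
                ctrl, group="IUGR", n=c.n,
            ))
        else:
            cells.append(replace(c))
    return replace(base, cells=cells)


# ---------------------------------------------------------------------------
# cohort simulation


def _subject_connectomes(cell: CellDesign, design: CohortDesign, structure, rng):
    n = design.n_nodes
    degree_t = float(np.clip(rng.normal(cell.degree_mean, cell.degree_sd), 2, n - 1))
    n_edges = max(1, int(round(degree_t * n / 2.0)))
    adj = _structured_adjacency(n, n_edges, structure, rng, design.n_clumps)
    mu = float(np.clip(rng.normal(cell.edge_fa_mean, cell.edge_fa_sd),
                       design.fa_floor + 0.02, 0.95))
    iu, ju = np.triu_indices(n, 1)
    mask = adj[iu, ju]
    w = np.clip(rng.normal(mu, cell.fa_sigma, size=int(mask.sum())),
                design.fa_floor, 1.0)
    m = np.zeros((n, n))
    m[iu[mask], ju[mask]] = w
    m = m + m.T
    names = _node_names(n)
    binary = Connectome(names, adj.astype(float), "binary")
    fa_w = Connectome(names, m, "fa_weighted")
    fa_n = normalize_total_strength(fa_w)
    return {"binary": binary, "fa_weighted": fa_w, "fa_normalized": fa_n}


def simulate_cohort(design: CohortDesign) -> list:
    """Generate the full cohort: covariates, connectomes, and scores.

    Fully deterministic given ``design.seed``.  Returns a list of
    :class:`~devconn.core.SubjectRecord` with all three connectome variants
    attached and, when the design has score models, the scores filled in.
    """
    design.validate()
    root = np.random.SeedSequence(design.seed)
    cell_seeds = root.spawn(len(design.cells) + 1)
    subjects = []
    for ci, cell in enumerate(design.cells):
        structure = _calibrate_structure(
            design.n_nodes, int(round(cell.degree_mean * design.n_nodes / 2.0)),
            cell.clustering, design.n_clumps,
        )
        subj_seeds = cell_seeds[ci].spawn(cell.n)
        for k in range(cell.n):
            rng = np.random.default_rng(subj_seeds[k])
            ga = max(float(rng.normal(cell.ga_mean, cell.ga_sd)), 24.0)
            gender = int(rng.random() < design.gender_p)
            edu = int(rng.choice(len(design.edu_probs), p=design.edu_probs))
            age_scan = max(float(rng.normal(cell.age_scan_mean, cell.age_scan_sd)), 0.1)
            age_test = max(float(rng.normal(cell.age_test_mean, cell.age_test_sd)), 0.1)
            conns = _subject_connectomes(cell, design, structure, rng)
            subjects.append(SubjectRecord(
                id=f"{cell.group}_{cell.age_years:g}y_{k + 1:03d}",
                group=cell.group, ga_weeks=ga, gender=gender,
                maternal_education=edu, age_at_scan=age_scan,
                age_at_test=age_test, connectomes=conns,
            ))
    if design.score_models:
        score_rng_seed = cell_seeds[-1]
        simulate_scores(subjects, design.score_models, seed=score_rng_seed)
    return subjects


# Fixed confounder effect sizes of the score model (score-scale units):
# per year of age at test, per week of GA, male vs female, per education
# level, IUGR vs control.
_SCORE_EFFECTS = dict(age=0.5, ga=0.5, gender=-1.0, edu=2.0, group=-3.0)


def simulate_scores(subjects, score_models, seed=0) -> pd.DataFrame:
    """Attach scores with injected metric partial correlations.

    For each score model the score is built as mean + confounder
    contributions + lambda * (metric residual) + noise, where the metric
    residual removes age-at-test and confounder projections and lambda and
    the noise SD are solved from the target partial correlation.  For large
    cohorts the empirical age-residualized partial correlation (confounders:
    gender, GA, maternal education, group) approaches the target.

    Returns the score table (one row per subject) and also fills each
    record's ``scores`` dict.
    """
    if not subjects:
        return pd.DataFrame()
    rng = np.random.default_rng(seed)
    X = np.column_stack([
        np.ones(len(subjects)),
        [s.age_at_test for s in subjects],
        [s.gender for s in subjects],
        [s.ga_weeks for s in subjects],
        [s.maternal_education for s in subjects],
        [1.0 if s.group == "IUGR" else 0.0 for s in subjects],
    ])
    conf = (
        _SCORE_EFFECTS["age"] * X[:, 1]
        + _SCORE_EFFECTS["gender"] * X[:, 2]
        + _SCORE_EFFECTS["ga"] * X[:, 3]
        + _SCORE_EFFECTS["edu"] * X[:, 4]
        + _SCORE_EFFECTS["group"] * X[:, 5]
    )
    conf = conf - conf.mean()
    metric_cache: dict = {}
    table = {}
    for model in score_models:
        if model.metric is not None and model.rho != 0.0:
            if model.metric not in metric_cache:
                for s in subjects:
                    if not s.connectomes:
                        raise ValueError(
                            f"subject {s.id} lacks connectomes for metric "
                            f"{model.metric!r}"
                        )
                metric_cache[model.metric] = np.array([
                    _single_metric(s.connectomes, model.metric) for s in subjects
                ])
            m = metric_cache[model.metric]
            beta, *_ = np.linalg.lstsq(X, m, rcond=None)
            r_m = m - X @ beta
            sd_r = r_m.std()
        else:
            r_m, sd_r = None, 0.0
        var_conf = conf.var()
        s_r = np.sqrt(max(model.sd**2 - var_conf, 0.25 * model.sd**2))
        if r_m is not None and sd_r > 0:
            link = model.rho * s_r * r_m / sd_r
            noise_sd = s_r * np.sqrt(max(1.0 - model.rho**2, 0.0))
        else:
            link = 0.0
            noise_sd = s_r
        vals = model.mean + conf + link + rng.normal(0.0, noise_sd, len(subjects))
        table[model.name] = vals
    df = pd.DataFrame(table, index=[s.id for s in subjects])
    df.index.name = "subject_id"
    for i, s in enumerate(subjects):
        s.scores.update({k: float(v[i]) for k, v in table.items()})
    return df


def _single_metric(connectomes: dict, name: str) -> float:
    variant = {"binary": "binary", "faw": "fa_weighted", "fan": "fa_normalized"}[
        name.split("_")[0]
    ]
    conn = connectomes[variant]
    op = name.split("_", 1)[1]
    if op == "degree":
        return _metrics.average_degree(conn)
    if op == "strength":
        return _metrics.average_strength(conn)
    if op == "global_efficiency":
        return _metrics.global_efficiency(conn)
    if op == "local_efficiency":
        return _metrics.local_efficiency(conn)
    if op == "clustering":
        return _metrics.average_clustering(conn)
    raise ValueError(f"unknown metric {name!r}")
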