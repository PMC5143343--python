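"""Synthetic generators: determinism, distributional targets, calibration."""

import numpy as np
import pandas as pd
import pytest

from devconn import metrics as M
from devconn import stats as S
from devconn import synth


# ---------------------------------------------------------------------------
# toy parcellation


def test_parcellation_contains_every_region_once_at_least():
    pmap = synth.make_toy_parcellation((4, 4, 1), 4, seed=1)
    present = set(pmap.present_labels())
    assert present == {1, 2, 3, 4}
    assert set(np.unique(pmap.volume)) <= {0, 1, 2, 3, 4}


def test_parcellation_is_deterministic():
    a = synth.make_toy_parcellation((4, 4, 1), 4, seed=1)
    b = synth.make_toy_parcellation((4, 4, 1), 4, seed=1)
    assert np.array_equal(a.volume, b.volume)
    c = synth.make_toy_parcellation((4, 4, 1), 4, seed=2)
    assert not np.array_equal(a.volume, c.volume)


def test_parcellation_voxel_counts_match_recount():
    pmap = synth.make_toy_parcellation((8, 8, 2), 6, seed=7)
    counts = pmap.voxel_counts()
    for lab in range(1, 7):
        assert counts[lab] == int((pmap.volume == lab).sum())
        assert counts[lab] >= 1
    assert sum(counts.values()) + int((pmap.volume == 0).sum()) == pmap.volume.size


def test_parcellation_too_small_grid_errors():
    with pytest.raises(ValueError, match="interior voxels"):
        synth.make_toy_parcellation((3, 3, 1), 5, seed=0)


# ---------------------------------------------------------------------------
# toy streamlines


def test_zero_streamlines_gives_empty_set():
    pmap = synth.make_toy_parcellation((6, 6, 2), 4, seed=0)
    assert len(synth.make_toy_streamlines(pmap, 0, seed=1)) == 0


def test_degenerate_fa_range_pins_fa():
    pmap = synth.make_toy_parcellation((6, 6, 2), 4, seed=0)
    sls = synth.make_toy_streamlines(pmap, 10, (0.5, 0.5), seed=1)
    assert np.all(sls.fa_values() == 0.5)


def test_streamline_fa_and_count_and_bounds():
    pmap = synth.make_toy_parcellation((8, 8, 4), 5, seed=2)
    sls = synth.make_toy_streamlines(pmap, 100, (0.1, 0.9), seed=3)
    assert len(sls) == 100
    fa = sls.fa_values()
    assert np.all((fa >= 0.1) & (fa <= 0.9))
    dims = np.array(pmap.volume.shape)
    for s in sls:
        assert s.points.shape[0] >= 2
        assert np.all(s.points >= 0) and np.all(s.points < dims)


def test_streamlines_require_labeled_map():
    from devconn.core import ParcelMap

    empty = ParcelMap(volume=np.zeros((4, 4, 1), dtype=np.int64), label_names={})
    with pytest.raises(ValueError, match="no labeled voxels"):
        synth.make_toy_streamlines(empty, 5, seed=0)


# ---------------------------------------------------------------------------
# simulate_connectome


def test_full_density_gives_complete_graph():
    c = synth.simulate_connectome(5, 1.0, 0.3, 0.05, seed=1)
    assert c.edge_count() == 10


def test_connectome_seed_repeat_is_identical():
    a = synth.simulate_connectome(30, 0.5, 0.3, 0.05, seed=9)
    b = synth.simulate_connectome(30, 0.5, 0.3, 0.05, seed=9)
    assert np.array_equal(a.matrix, b.matrix)


def test_connectome_mean_weight_within_sampling_error():
    c = synth.simulate_connectome(93, 0.65, 0.21, 0.01, seed=11)
    iu, ju = np.triu_indices(93, 1)
    w = c.matrix[iu, ju]
    w = w[w > 0]
    se = 0.01 / np.sqrt(w.size)
    assert abs(w.mean() - 0.21) < 3 * se
    # realized density within binomial sampling error of the target
    p_hat = w.size / iu.size
    assert abs(p_hat - 0.65) < 4 * np.sqrt(0.65 * 0.35 / iu.size)


def test_connectome_rejects_bad_inputs():
    with pytest.raises(ValueError, match="at least 2 nodes"):
        synth.simulate_connectome(1, 0.5, 0.3, 0.05, seed=0)
    with pytest.raises(ValueError, match="density"):
        synth.simulate_connectome(5, 0.0, 0.3, 0.05, seed=0)


# ---------------------------------------------------------------------------
# cohort generation


def test_cohort_seed_repeat_is_bit_identical(small_cohort):
    from devconn.synth import default_design, simulate_cohort

    design = default_design(ages=(1,), n_control=3, n_iugr=3, n_nodes=30, seed=5)
    for cell in design.cells:
        cell.degree_mean *= 30 / 93
        cell.degree_sd *= 30 / 93
    a = simulate_cohort(design)
    b = simulate_cohort(design)
    for sa, sb in zip(a, b):
        assert sa.id == sb.id and sa.ga_weeks == sb.ga_weeks
        assert sa.scores == sb.scores
        for v in sa.connectomes:
            assert np.array_equal(sa.connectomes[v].matrix,
                                  sb.connectomes[v].matrix)


def test_cohort_covariates_follow_design(small_cohort):
    ga = np.array([s.ga_weeks for s in small_cohort])
    assert 28 < ga.mean() < 35
    assert all(s.gender in (0, 1) for s in small_cohort)
    assert all(s.maternal_education in (0, 1, 2) for s in small_cohort)
    assert all(s.age_at_scan > 0 for s in small_cohort)


def test_unreachable_degree_target_is_a_design_error():
    design = synth.default_design(ages=(1,), n_nodes=30, with_scores=False)
    with pytest.raises(ValueError, match="unreachable"):
        synth.simulate_cohort(design)  # degree 60 on 30 nodes


def test_bad_score_rho_is_a_design_error():
    with pytest.raises(ValueError, match="outside"):
        synth.ScoreModel(name="s", metric="faw_strength", rho=1.5)


def test_table_calibrated_generation_hits_one_year_targets():
    """Generated group means reproduce the 1-year calibration targets.

    Directly calibrated metrics must land within 0.5 generated SD of the
    target; emergent weighted segregation metrics (induced, not targeted)
    within 3 generated SDs.
    """
    design = synth.default_design(ages=(1,), n_control=50, n_iugr=50,
                                  with_scores=False, seed=2024)
    subjects = synth.simulate_cohort(design)
    rows = {"control": [], "IUGR": []}
    for s in subjects:
        rows[s.group].append(M.compute_metric_table(
            s.connectomes["binary"], s.connectomes["fa_weighted"],
            s.connectomes["fa_normalized"]))
    targets = {
        "control": dict(binary_degree=60.24, binary_global_efficiency=0.827,
                        binary_local_efficiency=0.881, binary_clustering=0.762,
                        faw_strength=19.05, faw_global_efficiency=0.274),
        "IUGR": dict(binary_degree=56.87, binary_global_efficiency=0.809,
                     binary_local_efficiency=0.871, binary_clustering=0.743,
                     faw_strength=17.61, faw_global_efficiency=0.263),
    }
    emergent = {
        "control": dict(faw_local_efficiency=0.301, faw_clustering=0.241),
        "IUGR": dict(faw_local_efficiency=0.293, faw_clustering=0.230),
    }
    for group, tgts in targets.items():
        df = pd.DataFrame(rows[group])
        for name, target in tgts.items():
            dev = abs(df[name].mean() - target)
            assert dev < 0.5 * df[name].std(), (group, name, dev)
        for name, target in emergent[group].items():
            dev = abs(df[name].mean() - target)
            assert dev < 3.0 * df[name].std(), (group, name, dev)


def test_default_degree_target_recovered_within_one(rng):
    # generation + recompute: group mean degrees near 60.24 / 56.87
    design = synth.default_design(ages=(1,), n_control=50, n_iugr=50,
                                  with_scores=False, seed=31)
    subjects = synth.simulate_cohort(design)
    by_group = {"control": [], "IUGR": []}
    for s in subjects:
        by_group[s.group].append(M.average_degree(s.connectomes["binary"]))
    assert abs(np.mean(by_group["control"]) - 60.24) < 1.0
    assert abs(np.mean(by_group["IUGR"]) - 56.87) < 1.0


def test_null_design_gives_small_group_difference_over_seeds():
    """Identical targets for both groups -> |t| small on average."""
    from scipy import stats as sps

    tvals = []
    for seed in range(20):
        design = synth.null_design(synth.default_design(
            ages=(1,), n_control=8, n_iugr=8, n_nodes=30, with_scores=False,
            seed=seed))
        for cell in design.cells:
            cell.degree_mean *= 30 / 93
            cell.degree_sd *= 30 / 93
        subjects = synth.simulate_cohort(design)
        deg = {"control": [], "IUGR": []}
        for s in subjects:
            deg[s.group].append(M.average_degree(s.connectomes["binary"]))
        tvals.append(sps.ttest_ind(deg["control"], deg["IUGR"]).statistic)
    assert abs(np.mean(tvals)) < 0.5
    assert np.mean(np.abs(tvals)) < 2.0


def test_null_safety_type_one_error_of_downstream_test():
    """Equal-target designs: downstream group test rejects at ~nominal rate.

    500 replicates of a small null cohort; per-metric rejection of the
    covariate-adjusted group comparison at alpha = 0.05 must land in the
    [0.02, 0.08] band.
    """
    rejections = 0
    n_reps = 500
    base = synth.null_design(synth.default_design(
        ages=(1,), n_control=10, n_iugr=10, n_nodes=24, with_scores=False))
    for cell in base.cells:
        cell.degree_mean *= 24 / 93
        cell.degree_sd *= 24 / 93
    for seed in range(n_reps):
        base.seed = 10_000 + seed
        subjects = synth.simulate_cohort(base)
        vals = [M.average_degree(s.connectomes["binary"]) for s in subjects]
        design_m = S.build_design_matrix(subjects, "metric")
        cmp_ = S.glm_group_compare(np.asarray(vals), design_m, name="degree")
        rejections += cmp_.p_value < 0.05
    rate = rejections / n_reps
    assert 0.02 <= rate <= 0.08, rate


# ---------------------------------------------------------------------------
# score simulation


def _flat_cohort(n, seed, rho_models, n_nodes=30):
    design = synth.default_design(ages=(1,), n_control=n // 2, n_iugr=n // 2,
                                  n_nodes=n_nodes, with_scores=False, seed=seed)
    for cell in design.cells:
        cell.degree_mean *= n_nodes / 93
        cell.degree_sd *= n_nodes / 93
    design.score_models = rho_models
    return synth.simulate_cohort(design)


def _empirical_partial_rho(subjects, score, metric):
    meta = pd.DataFrame({
        "age_scan": [s.age_at_scan for s in subjects],
        "age_test": [s.age_at_test for s in subjects],
        "gender": [s.gender for s in subjects],
        "ga": [s.ga_weeks for s in subjects],
        "edu": [s.maternal_education for s in subjects],
        "grp": [1.0 if s.group == "IUGR" else 0.0 for s in subjects],
    })
    from devconn.synth import _single_metric

    m = np.array([_single_metric(s.connectomes, metric) for s in subjects])
    y = np.array([s.scores[score] for s in subjects])
    xm = S.residualize_by_age(m, meta["age_scan"])
    ys = S.residualize_by_age(y, meta["age_test"])
    conf = meta[["gender", "ga", "edu", "grp"]].to_numpy()
    return S.partial_correlation(xm, ys, conf).rho


def test_null_score_has_near_zero_partial_correlation():
    models = [synth.ScoreModel(name="s0", metric="faw_strength", rho=0.0)]
    subjects = _flat_cohort(500, 61, models)
    rho = _empirical_partial_rho(subjects, "s0", "faw_strength")
    assert abs(rho) < 0.1


def test_strong_strength_linked_score_is_recovered():
    # injected partial rho 0.9001 for a strength-linked score
    models = [synth.ScoreModel(name="se", metric="faw_strength", rho=0.9001)]
    subjects = _flat_cohort(500, 62, models)
    rho = _empirical_partial_rho(subjects, "se", "faw_strength")
    assert 0.85 <= rho <= 0.95


def test_score_scale_mean_and_sd():
    models = [synth.ScoreModel(name="cog", metric="faw_strength", rho=0.5,
                               mean=100.0, sd=15.0)]
    subjects = _flat_cohort(400, 63, models)
    vals = np.array([s.scores["cog"] for s in subjects])
    se = 15.0 / np.sqrt(len(vals))
    assert abs(vals.mean() - 100.0) < 3 * se
    assert 10.0 < vals.std() < 20.0
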