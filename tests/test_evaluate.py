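import collections

import numpy as np
import pytest

from dynacase import (
    ConfusionWithIndeterminate,
    GeneratorConfig,
    JA_UTILIZATION_MODEL,
    McmcConfig,
    accuracy_measures,
    auc,
    generate_cohort,
    kfold_split,
    mean_classification_time,
    run_cross_validation,
)
from dynacase.dynclass import ClassificationOutcome


# ---------------------------------------------------------------------------
# folds


def test_balanced_folds_small():
    fold = kfold_split(10, k=5, seed=0)
    assert sorted(collections.Counter(fold).values()) == [2, 2, 2, 2, 2]


def test_fold_sizes_for_cohort_of_797():
    fold = kfold_split(797, k=5, seed=1)
    assert sorted(collections.Counter(fold).values()) == [159, 159, 159, 160, 160]


def test_fold_assignment_reproducible():
    np.testing.assert_array_equal(kfold_split(50, 5, 7), kfold_split(50, 5, 7))
    assert not np.array_equal(kfold_split(50, 5, 7), kfold_split(50, 5, 8))


def test_fold_contracts():
    with pytest.raises(ValueError):
        kfold_split(3, k=5)
    with pytest.raises(ValueError):
        kfold_split(10, k=1)


# ---------------------------------------------------------------------------
# accuracy measures


def wilson_reference(k, n, z=1.959963984540054):
    """Textbook Wilson score interval."""
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


def test_sensitivity_with_indeterminates():
    conf = ConfusionWithIndeterminate(tp=70, fn=20, ind_case=10, tn=50, fp=5,
                                      ind_control=5)
    all_data = accuracy_measures(conf, "all_data")
    classified = accuracy_measures(conf, "classified_only")
    assert all_data.sensitivity == pytest.approx(0.70)
    assert classified.sensitivity == pytest.approx(70 / 90)
    assert classified.sensitivity >= all_data.sensitivity
    # PPV/NPV identical in the two variants
    assert all_data.ppv == classified.ppv == pytest.approx(70 / 75)
    assert all_data.npv == classified.npv == pytest.approx(50 / 70)
    assert all_data.prop_indeterminate == pytest.approx(15 / 160)


def test_perfect_classifier_all_rates_one():
    conf = ConfusionWithIndeterminate(tp=40, tn=60)
    rep = accuracy_measures(conf, "all_data")
    assert (rep.sensitivity, rep.specificity, rep.ppv, rep.npv, rep.pcc) == (
        1.0, 1.0, 1.0, 1.0, 1.0,
    )


def test_wilson_intervals_match_closed_form():
    rng = np.random.default_rng(2)
    for _ in range(50):
        tp, fn, fp, tn = rng.integers(1, 200, 4)
        conf = ConfusionWithIndeterminate(tp=tp, fn=fn, fp=fp, tn=tn)
        rep = accuracy_measures(conf, "all_data")
        np.testing.assert_allclose(
            rep.sensitivity_ci, wilson_reference(tp, tp + fn), atol=1e-12
        )
        np.testing.assert_allclose(
            rep.ppv_ci, wilson_reference(tp, tp + fp), atol=1e-12
        )


def test_zero_denominators_reported_as_nan():
    conf = ConfusionWithIndeterminate(tp=0, fn=0, ind_case=10, tn=5, fp=0,
                                      ind_control=0)
    rep = accuracy_measures(conf, "classified_only")
    assert np.isnan(rep.sensitivity) and np.isnan(rep.ppv)
    assert not np.isnan(rep.specificity)


def test_confusion_addition_and_conservation():
    a = ConfusionWithIndeterminate(1, 2, 3, 4, 5, 6)
    b = ConfusionWithIndeterminate(6, 5, 4, 3, 2, 1)
    c = a + b
    assert (c.tp, c.fn, c.ind_case) == (7, 7, 7)
    assert c.n_cases == a.n_cases + b.n_cases
    conf = ConfusionWithIndeterminate.from_labels(
        ["case", "case", "control", "control", "case"],
        ["case", "indeterminate", "control", "case", "control"],
    )
    assert (conf.tp, conf.ind_case, conf.fn) == (1, 1, 1)
    assert (conf.tn, conf.fp, conf.ind_control) == (1, 1, 0)
    assert conf.n_cases == 3 and conf.n_controls == 2


def test_single_group_confusion_rejected():
    conf = ConfusionWithIndeterminate(tp=5, fn=1)
    with pytest.raises(ValueError):
        accuracy_measures(conf)


# ---------------------------------------------------------------------------
# AUC


def test_auc_separable_is_one():
    assert auc([0.1, 0.2, 0.8, 0.9], ["control", "control", "case", "case"]) == 1.0


def test_auc_all_tied_is_half():
    assert auc([0.4] * 10, ["case"] * 5 + ["control"] * 5) == 0.5


def test_auc_random_scores_near_half():
    rng = np.random.default_rng(0)
    p = rng.random(2000)
    y = rng.random(2000) < 0.5
    assert auc(p, y) == pytest.approx(0.5, abs=0.03)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        auc([0.1, 0.9], ["case", "case"])


# ---------------------------------------------------------------------------
# classification time


def _outcome(label, age):
    occ = None if age is None else int(age - 1)
    return ClassificationOutcome(0, label, occ, age)


def test_mean_classification_time():
    outs = [_outcome("case", 2.0), _outcome("control", 16.0)]
    assert mean_classification_time(outs) == pytest.approx(9.0)
    outs += [_outcome("indeterminate", None)]
    assert mean_classification_time(outs) == pytest.approx(9.0)
    assert np.isnan(mean_classification_time([_outcome("indeterminate", None)]))


def test_mean_time_over_mixed_set_matches_bruteforce():
    rng = np.random.default_rng(9)
    outs = []
    for _ in range(100):
        if rng.random() < 0.3:
            outs.append(_outcome("indeterminate", None))
        else:
            outs.append(_outcome("case", float(rng.integers(2, 17))))
    expected = np.mean([o.decision_age for o in outs if o.decision_age is not None])
    assert mean_classification_time(outs) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# cross-validation pipeline


@pytest.fixture(scope="module")
def cv_result():
    cohort = generate_cohort(GeneratorConfig(n_individuals=150, seed=42))
    mcmc = McmcConfig(n_iterations=900, burn_in=300, thinning=10, n_chains=2, seed=4)
    return (
        cohort,
        run_cross_validation(
            cohort, JA_UTILIZATION_MODEL, mcmc,
            approach="random_effects", scheme="cri", k=5, seed=11,
        ),
    )


def test_cv_confusion_conservation(cv_result):
    cohort, cv = cv_result
    n_cases = sum(ind.group == "case" for ind in cohort)
    pooled = cv.pooled_confusion
    assert pooled.n_total == len(cohort)
    assert pooled.n_cases == n_cases
    fold_sum = ConfusionWithIndeterminate()
    for fr in cv.folds:
        fold_sum = fold_sum + fr.confusion
    assert fold_sum == pooled


def test_cv_metric_identities(cv_result):
    cohort, cv = cv_result
    truth = {ind.person_id: ind.group for ind in cohort}
    # PPV recomputed from the raw outcome stream equals the reported PPV
    tp = sum(
        o.final_label == "case" and truth[o.person_id] == "case" for o in cv.outcomes
    )
    fp = sum(
        o.final_label == "case" and truth[o.person_id] == "control"
        for o in cv.outcomes
    )
    assert (tp, fp) == (cv.pooled_confusion.tp, cv.pooled_confusion.fp)
    if tp + fp:
        assert cv.pooled_all_data.ppv == pytest.approx(tp / (tp + fp))
    assert 0 <= cv.pooled_all_data.prop_indeterminate <= 1


def test_cv_evolution_unclassified_never_increases(cv_result):
    _, cv = cv_result
    prop = cv.evolution["prop_unclassified"].to_numpy()
    assert np.all(np.diff(prop) <= 1e-12)
    assert cv.evolution.shape[0] == 15


def test_cv_separated_groups_classify_well(cv_result):
    """Generator defaults separate the groups strongly, so even a reduced
    sampler should reach a high cross-validated AUC."""
    _, cv = cv_result
    assert cv.auc > 0.85
    assert cv.averaged["prop_indeterminate"] < 0.35


def test_cv_training_fold_must_contain_both_groups():
    cohort = generate_cohort(
        GeneratorConfig(n_individuals=30, case_fraction=1.0, seed=3)
    )
    mcmc = McmcConfig(n_iterations=400, burn_in=100, thinning=5, n_chains=2, seed=1)
    with pytest.raises(ValueError, match="fold"):
        run_cross_validation(cohort, JA_UTILIZATION_MODEL, mcmc, k=5, seed=0)
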