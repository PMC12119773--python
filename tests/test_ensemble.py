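"""Probability averaging, two-stage ensembling, and the metric suite."""

import numpy as np
import pytest

from attrscint.datatypes import ClassProbabilities
from attrscint.ensemble import (
    average_probabilities,
    balanced_accuracy,
    compute_metrics,
    confusion_matrix_normalized,
    decide,
    f1_from,
    two_stage_ensemble,
)


def P(*vals):
    return ClassProbabilities(np.array(vals))


WORKED_EXAMPLE = [P(0.45, 0.55), P(0.95, 0.05), P(0.48, 0.52)]


def test_worked_example_average_and_decision():
    """Three members voting 2-1 for class 1 still average to class 0 when the
    dissenter is confident: mean = (0.627, 0.373)."""
    avg = average_probabilities(WORKED_EXAMPLE)
    assert round(avg.p[0], 3) == 0.627
    assert round(avg.p[1], 3) == 0.373
    assert decide(avg) == 0


def test_average_single_member_is_identity_and_permutation_invariant():
    single = average_probabilities([P(0.3, 0.7)])
    np.testing.assert_allclose(single.p, [0.3, 0.7])
    fwd = average_probabilities(WORKED_EXAMPLE).p
    rev = average_probabilities(WORKED_EXAMPLE[::-1]).p
    np.testing.assert_allclose(fwd, rev)


def test_average_stays_on_simplex():
    rng = np.random.default_rng(0)
    members = []
    for _ in range(10):
        p1 = rng.uniform()
        members.append(P(p1, 1 - p1))
    avg = average_probabilities(members)
    assert avg.p.sum() == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        average_probabilities([])


def test_decide_argmax_and_tie_rule(caplog):
    assert decide(P(0.627, 0.373)) == 0
    assert decide(P(0.2, 0.8)) == 1
    assert decide(P(0.5, 0.5)) == 0  # tie -> negative class


def _grid(vec_fn):
    grid = {}
    for fold in range(3):
        for crop in ("lv", "whole_heart", "ribcage"):
            for view in ("anterior", "posterior", "summation"):
                grid[(fold, crop, view)] = vec_fn(fold, crop, view)
    return grid


def test_two_stage_identical_members_idempotent():
    grid = _grid(lambda f, c, v: P(0.7, 0.3))
    res = two_stage_ensemble(grid)
    np.testing.assert_allclose(res.averaged_p.p, [0.7, 0.3])
    assert len(res.members) == 27
    assert len(res.group_means) == 9


def test_two_stage_equals_flat_mean_for_balanced_grid():
    rng = np.random.default_rng(1)

    def rand(*_):
        p1 = rng.uniform()
        return P(p1, 1 - p1)

    grid = _grid(rand)
    res = two_stage_ensemble(grid)
    flat = np.mean([m.p for m in grid.values()], axis=0)
    np.testing.assert_allclose(res.averaged_p.p, flat, atol=1e-12)


def test_two_stage_single_group_worked_example():
    grid = {
        (fold, "whole_heart", "anterior"): m
        for fold, m in enumerate(WORKED_EXAMPLE)
    }
    res = two_stage_ensemble(grid)
    assert res.decision == 0
    assert len(res.group_means) == 1


def test_two_stage_rejects_empty_grid():
    with pytest.raises(ValueError):
        two_stage_ensemble({})


def test_metric_identities_on_reported_operating_points():
    assert balanced_accuracy(0.969, 0.981) == pytest.approx(0.975)
    assert balanced_accuracy(0.960, 0.952) == pytest.approx(0.956)
    assert round(f1_from(0.984, 0.969), 3) == 0.976


def test_perfectly_separated_scores_auc_one():
    labels = [0, 0, 0, 1, 1]
    probs = [P(1 - s, s) for s in (0.1, 0.2, 0.3, 0.8, 0.9)]
    report = compute_metrics(labels, probs)
    assert report.auc == 1.0
    assert report.accuracy == 1.0


def test_auc_matches_all_pairs_oracle():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = 20
        labels = rng.integers(0, 2, size=n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        scores = np.round(rng.uniform(size=n), 1)  # ties likely
        probs = [P(1 - s, s) for s in scores]
        report = compute_metrics(labels.tolist(), probs)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        pairs = sum(
            1.0 if sp > sn else 0.5 if sp == sn else 0.0
            for sp in pos for sn in neg
        )
        assert report.auc == pytest.approx(pairs / (len(pos) * len(neg)), abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    labels = rng.integers(0, 2, size=30)
    labels[:2] = [0, 1]
    scores = rng.uniform(size=30)
    a1 = compute_metrics(labels.tolist(), [P(1 - s, s) for s in scores]).auc
    warped = 1.0 / (1.0 + np.exp(-5 * (scores - 0.5)))  # strictly monotone
    a2 = compute_metrics(labels.tolist(), [P(1 - w, w) for w in warped]).auc
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_f1_consistent_with_reported_precision_and_sensitivity():
    rng = np.random.default_rng(4)
    labels = rng.integers(0, 2, size=40)
    labels[:2] = [0, 1]
    probs = [P(1 - s, s) for s in rng.uniform(size=40)]
    report = compute_metrics(labels.tolist(), probs)
    assert round(report.f1, 3) == round(
        f1_from(report.precision, report.sensitivity), 3
    )
    assert report.bac == (report.sensitivity + report.specificity) / 2


def test_single_class_labels_auc_missing(caplog):
    probs = [P(0.4, 0.6), P(0.7, 0.3)]
    with caplog.at_level("WARNING"):
        report = compute_metrics([1, 1], probs)
    assert report.auc is None
    assert report.roc == []


def test_confusion_matrix_normalized_rows():
    from attrscint.ensemble import MetricsReport

    r = MetricsReport(
        f1=0, sensitivity=0, specificity=0, precision=0, accuracy=0, bac=0,
        auc=None, tp=9, fn=1, tn=8, fp=2,
    )
    m = confusion_matrix_normalized(r)
    np.testing.assert_allclose(m, [[0.8, 0.2], [0.1, 0.9]])


def test_confusion_matrix_perfect_and_degenerate():
    from attrscint.ensemble import MetricsReport

    perfect = MetricsReport(1, 1, 1, 1, 1, 1, 1.0, tp=5, fp=0, tn=5, fn=0)
    np.testing.assert_allclose(confusion_matrix_normalized(perfect), np.eye(2))
    all_pos = MetricsReport(0, 1, 0, 0.5, 0.5, 0.5, None, tp=5, fp=5, tn=0, fn=0)
    np.testing.assert_allclose(
        confusion_matrix_normalized(all_pos), [[0, 1], [0, 1]]
    )
    empty_row = MetricsReport(0, 0, 0, 0, 0, 0, None, tp=0, fp=2, tn=3, fn=0)
    m = confusion_matrix_normalized(empty_row)
    assert np.isnan(m[1]).all()
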