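import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from serumscreen import (
    detection_rate_at_fpr,
    logistic_fit,
    metrics_from_rates,
    roc_curve,
    threshold_for_fpr,
    youden_cutoff,
)


def _auc_brute(scores, labels):
    cases = scores[labels == 1]
    ctrls = scores[labels == 0]
    wins = sum(
        1.0 if x > y else 0.5 if x == y else 0.0
        for x, y in itertools.product(cases, ctrls)
    )
    return wins / (len(cases) * len(ctrls))


def test_roc_simple_brute_force_example():
    roc = roc_curve([1, 2, 3, 4], [0, 1, 0, 1], direction="higher_is_positive")
    assert roc.auc == pytest.approx(0.75)
    assert roc.auc == _auc_brute(np.array([1, 2, 3, 4.0]), np.array([0, 1, 0, 1]))


def test_roc_perfect_separation_and_null(rng):
    roc = roc_curve([10, 11, 12, 1, 2, 3], [1, 1, 1, 0, 0, 0])
    assert roc.auc == 1.0
    n = 10_000
    scores = rng.normal(0, 1, n)
    labels = rng.integers(0, 2, n)
    while len(np.unique(labels)) < 2:
        labels = rng.integers(0, 2, n)
    roc = roc_curve(scores, labels, direction="higher_is_positive")
    assert abs(roc.auc - 0.5) < 0.02
    assert roc.ci_low < 0.5 < roc.ci_high


def test_roc_rejects_single_class():
    with pytest.raises(ValueError, match="both classes"):
        roc_curve([1, 2, 3], [1, 1, 1])


def test_roc_direction_symmetry(rng):
    scores = rng.normal(0, 1, 200)
    labels = rng.integers(0, 2, 200)
    hi = roc_curve(scores, labels, direction="higher_is_positive")
    lo = roc_curve(scores, labels, direction="lower_is_positive")
    assert hi.auc + lo.auc == pytest.approx(1.0, abs=1e-12)


def test_roc_points_monotone_and_match_sklearn(rng):
    scores = rng.normal(0, 1, 300).round(1)
    labels = rng.integers(0, 2, 300)
    roc = roc_curve(scores, labels, direction="higher_is_positive")
    assert (np.diff(roc.points["fpr"]) >= 0).all()
    assert (np.diff(roc.points["tpr"]) >= 0).all()
    # independent cross-check of the point estimate
    assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_delong_variance_against_placement_oracle(rng):
    cases = rng.normal(0.8, 1, 25).round(1)
    ctrls = rng.normal(0, 1, 40).round(1)
    scores = np.concatenate([cases, ctrls])
    labels = np.concatenate([np.ones(25), np.zeros(40)])
    roc = roc_curve(scores, labels, direction="higher_is_positive")
    # brute-force structural components
    v10 = np.array(
        [np.mean([1.0 if x > y else 0.5 if x == y else 0.0 for y in ctrls])
         for x in cases]
    )
    v01 = np.array(
        [np.mean([1.0 if x > y else 0.5 if x == y else 0.0 for x in cases])
         for y in ctrls]
    )
    var = v10.var(ddof=1) / 25 + v01.var(ddof=1) / 40
    assert roc.auc == pytest.approx(v10.mean(), abs=1e-12)
    assert roc.se == pytest.approx(np.sqrt(var), abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.data())
def test_auc_equals_u_statistic_property(data):
    n1 = data.draw(st.integers(2, 12))
    n0 = data.draw(st.integers(2, 12))
    scores = np.array(
        data.draw(
            st.lists(st.integers(0, 8), min_size=n1 + n0, max_size=n1 + n0)
        ),
        dtype=float,
    )
    labels = np.concatenate([np.ones(n1), np.zeros(n0)])
    roc = roc_curve(scores, labels, direction="higher_is_positive")
    wins = _auc_brute(scores, labels) * n1 * n0
    assert roc.auc * n1 * n0 == pytest.approx(wins, abs=1e-9)


def _youden_brute(scores, labels, direction="higher_is_positive"):
    s = scores if direction == "higher_is_positive" else -scores
    best = (-1.0, -1.0)
    for t in np.concatenate([np.unique(s), [s.max() + 1]]):
        sens = np.mean(s[labels == 1] >= t)
        spec = np.mean(s[labels == 0] < t)
        key = (sens + spec - 1, sens)
        if key > best:
            best = key
    return best


def test_youden_cutoff_matches_exhaustive_search(rng):
    for _ in range(25):
        n = int(rng.integers(10, 200))
        scores = rng.normal(0, 1, n).round(1)
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            continue
        roc = roc_curve(scores, labels, direction="higher_is_positive")
        best = youden_cutoff(roc)
        j_brute, sens_brute = _youden_brute(scores, labels)
        assert best.youden == pytest.approx(j_brute, abs=1e-12)
        assert best.sensitivity == pytest.approx(sens_brute, abs=1e-12)
        # the reported cutoff reproduces the reported confusion counts
        pos = scores > best.cutoff
        assert (pos & (labels == 1)).sum() == best.counts["tp"]
        assert (pos & (labels == 0)).sum() == best.counts["fp"]


def test_youden_perfect_separation_midpoint_cutoff():
    roc = roc_curve([5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0])
    best = youden_cutoff(roc)
    assert best.youden == pytest.approx(1.0)
    assert best.cutoff == pytest.approx(4.0)  # midpoint of 3 and 5


def test_youden_two_gaussian_analytic_crossing(table_params, rng):
    # T18 vs control sHLA-G log10 MoM: with equal weighting of the two
    # classes the optimal cutoff is where the two densities cross
    from scipy.optimize import brentq
    from scipy.stats import norm

    m1, s1 = -0.3269, 0.21661
    m0, s0 = 0.0455, 0.22564
    crossing = brentq(
        lambda x: norm.pdf(x, m1, s1) - norm.pdf(x, m0, s0), m1, m0
    )
    n = 100_000
    scores = np.concatenate(
        [rng.normal(m0, s0, n), rng.normal(m1, s1, n)]
    )
    labels = np.concatenate([np.zeros(n), np.ones(n)])
    roc = roc_curve(scores, labels, direction="lower_is_positive")
    best = youden_cutoff(roc)
    assert best.cutoff == pytest.approx(crossing, abs=0.02)


def test_metrics_from_rates_published_screening_column():
    m = metrics_from_rates(0.855, 0.887, 83, 797)
    assert m.ppv == pytest.approx(0.441, abs=5e-4)
    assert m.npv == pytest.approx(0.983, abs=5e-4)
    assert m.plr == pytest.approx(7.58, abs=5e-3)
    assert m.nlr == pytest.approx(0.16, abs=5e-3)
    assert m.counts == {"tp": 71, "fn": 12, "tn": 707, "fp": 90}


@pytest.mark.parametrize(
    "sens, spec, n_case, n_ctrl, ppv, npv, plr, nlr",
    [
        (1.0, 1.0, 50, 50, 1.0, 1.0, np.inf, 0.0),
        (0.5, 0.5, 100, 100, 0.5, 0.5, 1.0, 1.0),
    ],
)
def test_metrics_from_rates_edge_cases(sens, spec, n_case, n_ctrl, ppv, npv, plr, nlr):
    m = metrics_from_rates(sens, spec, n_case, n_ctrl)
    assert (m.ppv, m.npv) == (ppv, npv)
    assert m.plr == plr and m.nlr == nlr


def test_metrics_from_rates_round_trip(rng):
    for _ in range(20):
        sens, spec = rng.uniform(0.1, 0.99, 2)
        n_case, n_ctrl = int(rng.integers(20, 300)), int(rng.integers(20, 900))
        m = metrics_from_rates(sens, spec, n_case, n_ctrl)
        assert abs(m.sensitivity - sens) <= 1 / (2 * min(n_case, n_ctrl)) + 1e-12
        assert abs(m.specificity - spec) <= 1 / (2 * min(n_case, n_ctrl)) + 1e-12
    with pytest.raises(ValueError):
        metrics_from_rates(1.2, 0.5, 10, 10)


def test_detection_rate_reported_study_arithmetic():
    # flagged/total fractions printed as detection rates
    assert 66 / 83 == pytest.approx(0.795, abs=5e-4)
    assert 105 / 139 == pytest.approx(0.755, abs=5e-4)


def test_detection_rate_at_fpr_null_case(rng):
    n = 50_000
    scores = rng.normal(0, 1, 2 * n)
    labels = np.concatenate([np.zeros(n), np.ones(n)])
    rate, cutoff = detection_rate_at_fpr(scores, labels, 0.05,
                                         direction="higher_is_positive")
    assert rate == pytest.approx(0.05, abs=0.01)
    achieved = np.mean(scores[labels == 0] > cutoff)
    assert achieved <= 0.05


def test_detection_rate_respects_direction(table_params, rng):
    # low sHLA-G flags T18: lower_is_positive must beat the wrong polarity
    m1, s1 = -0.3269, 0.21661
    m0, s0 = 0.0455, 0.22564
    scores = np.concatenate([rng.normal(m0, s0, 2000), rng.normal(m1, s1, 500)])
    labels = np.concatenate([np.zeros(2000), np.ones(500)])
    rate_auto, _ = detection_rate_at_fpr(scores, labels, 0.05)
    rate_wrong, _ = detection_rate_at_fpr(scores, labels, 0.05,
                                          direction="higher_is_positive")
    assert rate_auto > 0.5 > rate_wrong


def test_threshold_for_fpr_unreachable():
    with pytest.raises(ValueError, match="unreachable|controls"):
        threshold_for_fpr([1.0], 0.9999)
    with pytest.raises(ValueError):
        threshold_for_fpr([1.0, 2.0], 1.5)


def test_logistic_fit_recovers_known_coefficient(rng):
    n = 50_000
    x = rng.normal(0, 1, n)
    p = 1 / (1 + np.exp(-(-1.0 + 1.5 * x)))
    y = rng.uniform(size=n) < p
    fit = logistic_fit(pd.DataFrame({"x": x}), y.astype(int))
    assert fit.converged
    assert fit.table.loc["x", "coef"] == pytest.approx(1.5, abs=0.05)
    assert fit.table.loc["x", "exp_b"] == pytest.approx(np.exp(fit.table.loc["x", "coef"]))
    lo, hi = fit.table.loc["x", ["ci_low", "ci_high"]]
    assert lo < fit.table.loc["x", "exp_b"] < hi


def test_logistic_fit_flags_perfect_separation():
    x = pd.DataFrame({"x": [-3.0, -2.0, -1.0, 1.0, 2.0, 3.0]})
    y = np.array([0, 0, 0, 1, 1, 1])
    fit = logistic_fit(x, y)
    assert fit.separation
    assert not fit.converged


def test_logistic_fit_needs_enough_rows():
    with pytest.raises(ValueError, match="observations"):
        logistic_fit(pd.DataFrame({"a": [1.0, 2.0]}), np.array([0, 1]))
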