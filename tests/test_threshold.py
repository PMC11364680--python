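import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from screentriage.errors import ConfigurationError, DegenerateInputError
from screentriage.synthetic import (
    CANCER_CATEGORY_PROBS,
    NONCANCER_CATEGORY_PROBS,
    calibrate_score_model,
)
from screentriage.threshold import (
    YoudenThresholdClassifier,
    auc,
    auc_bootstrap_ci,
    build_roc,
    youden_threshold,
)


def pairwise_auc(scores, labels):
    """All-pairs concordance oracle: P(pos > neg) + 0.5 P(pos == neg)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def brute_force_youden(scores, labels):
    """Exhaustive max of sens + spec - 1 over every observed threshold."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    best = -np.inf
    for t in np.append(np.unique(s), s.max() + 1):
        sens = (s[y] >= t).mean()
        spec = (s[~y] < t).mean()
        best = max(best, sens + spec - 1)
    return best


class TestBuildRoc:
    def test_perfect_separation_reaches_the_corner(self):
        curve = build_roc([10.0, 90.0], [False, True])
        j = curve.sensitivity + curve.specificity - 1
        assert j.max() == pytest.approx(1.0)
        assert auc(curve) == pytest.approx(1.0)

    def test_anti_concordant_pair_has_zero_best_j(self):
        curve = build_roc([90.0, 10.0], [False, True])
        assert (curve.sensitivity + curve.specificity - 1).max() == pytest.approx(0.0)
        assert auc(curve) == pytest.approx(0.0)

    def test_monotonicity_and_endpoints(self, rng):
        s = rng.integers(0, 50, 200).astype(float)  # many ties
        y = rng.random(200) < 0.3
        curve = build_roc(s, y)
        assert (np.diff(curve.sensitivity) <= 0).all()
        assert (np.diff(curve.specificity) >= 0).all()
        assert curve.sensitivity[0] == 1.0  # lowest observed score
        assert curve.sensitivity[-1] == 0.0 and curve.specificity[-1] == 1.0

    def test_operating_points_equal_exhaustive_recount(self, rng):
        s = rng.random(20) * 100
        y = np.array([True] * 8 + [False] * 12)
        curve = build_roc(s, y)
        for i, t in enumerate(curve.thresholds):
            assert curve.tp[i] == (s[y] >= t).sum()
            assert curve.tn[i] == (s[~y] < t).sum()

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            build_roc([1.0, 2.0], [True, True])


class TestAuc:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        data=hst.lists(
            hst.tuples(hst.integers(0, 40), hst.booleans()),
            min_size=2, max_size=200,
        ).filter(lambda d: 0 < sum(lab for _, lab in d) < len(d))
    )
    def test_trapezoid_equals_all_pairs_concordance(self, data):
        s = np.array([v for v, _ in data], float)  # integer grid forces ties
        y = np.array([lab for _, lab in data])
        assert auc(build_roc(s, y)) == pytest.approx(pairwise_auc(s, y), abs=1e-12)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import roc_auc_score

        s = rng.random(300) * 100
        y = rng.random(300) < 0.4
        assert auc(build_roc(s, y)) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestYouden:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        data=hst.lists(
            hst.tuples(hst.integers(0, 30), hst.booleans()),
            min_size=2, max_size=50,
        ).filter(lambda d: 0 < sum(lab for _, lab in d) < len(d))
    )
    def test_equals_brute_force_grid_maximum(self, data):
        s = np.array([v for v, _ in data], float)
        y = np.array([lab for _, lab in data])
        result = youden_threshold(build_roc(s, y))
        assert result.youden_j == pytest.approx(brute_force_youden(s, y), abs=1e-12)

    def test_ties_break_toward_the_lowest_threshold(self):
        # J = 0.5 at both observed thresholds 20 and 40 -> take 20
        s = np.array([10.0, 20.0, 30.0, 40.0])
        y = np.array([False, True, False, True])
        result = youden_threshold(build_roc(s, y))
        assert result.threshold == 20.0
        assert result.tie_break == "lowest"
        high = youden_threshold(build_roc(s, y), tie_break="highest")
        assert high.threshold == 40.0

    def test_j_is_consistent_with_sens_and_spec(self, rng):
        s = rng.random(100) * 100
        y = rng.random(100) < 0.3
        res = youden_threshold(build_roc(s, y))
        assert res.youden_j == pytest.approx(res.sensitivity + res.specificity - 1)

    def test_recovers_the_density_crossing_at_scale(self):
        # two piecewise-uniform classes whose J is maximized exactly at the
        # high cut; the empirical optimum must converge there
        rng = np.random.default_rng(7)
        nc = calibrate_score_model(NONCANCER_CATEGORY_PROBS)
        ca = calibrate_score_model(CANCER_CATEGORY_PROBS)
        s = np.concatenate([nc.sample(100_000, rng), ca.sample(5_000, rng)])
        y = np.repeat([False, True], [100_000, 5_000])
        res = youden_threshold(build_roc(s, y))
        assert res.threshold == pytest.approx(30.44, abs=3.0)


class TestBootstrapCi:
    def test_perfect_separation_gives_a_point_interval(self):
        s = np.array([1.0] * 20 + [90.0] * 20)
        y = np.array([False] * 20 + [True] * 20)
        assert auc_bootstrap_ci(s, y, n_boot=200, seed=0) == (1.0, 1.0)

    def test_interval_brackets_the_point_estimate(self, rng):
        s = rng.random(150) * 100
        y = s + rng.normal(0, 30, 150) > 60
        if y.all() or not y.any():
            pytest.skip("degenerate draw")
        point = auc(build_roc(s, y))
        lo, hi = auc_bootstrap_ci(s, y, n_boot=500, seed=3)
        assert lo <= point <= hi

    def test_reproducible_given_seed(self, rng):
        s = rng.random(80) * 100
        y = rng.random(80) < 0.4
        assert auc_bootstrap_ci(s, y, n_boot=200, seed=5) == \
            auc_bootstrap_ci(s, y, n_boot=200, seed=5)

    def test_covers_a_designed_auc(self):
        # classes built so the true concordance is ~0.9; the 95% interval
        # should cover it in nearly all repetitions
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            neg = rng.normal(0, 1, 150)
            pos = rng.normal(1.812, 1, 50)  # Phi(1.812/sqrt(2)) ~ 0.90
            s = np.concatenate([neg, pos])
            s = (s - s.min()) / (s.max() - s.min()) * 100
            y = np.repeat([False, True], [150, 50])
            lo, hi = auc_bootstrap_ci(s, y, n_boot=400, seed=rep)
            hits += lo <= 0.90 <= hi
        assert hits >= 15

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ConfigurationError):
            auc_bootstrap_ci([1, 2], [False, True], n_boot=10)


class TestEstimator:
    def test_fit_exposes_the_operating_point(self, rng):
        s = rng.random(200) * 100
        y = s + rng.normal(0, 25, 200) > 55
        est = YoudenThresholdClassifier().fit(s, y)
        ref = youden_threshold(build_roc(s, y))
        assert est.threshold_ == ref.threshold
        assert est.youden_j_ == ref.youden_j
        preds = est.predict(s)
        assert preds.dtype == bool
        assert (preds == (s >= est.threshold_)).all()

    def test_accepts_a_single_column(self, rng):
        s = rng.random(50) * 100
        y = rng.random(50) < 0.5
        if y.all() or not y.any():
            pytest.skip("degenerate draw")
        a = YoudenThresholdClassifier().fit(s.reshape(-1, 1), y)
        b = YoudenThresholdClassifier().fit(s, y)
        assert a.threshold_ == b.threshold_

    def test_sklearn_params_roundtrip(self):
        est = YoudenThresholdClassifier(tie_break="highest")
        assert est.get_params() == {"tie_break": "highest"}
        est.set_params(tie_break="lowest")
        assert est.tie_break == "lowest"
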