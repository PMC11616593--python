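"""ROC curves, Mann-Whitney AUC, Hanley-McNeil CIs, closest-to-ideal cut-offs."""

import numpy as np
import pytest

from ohlra.index import DEFAULT_COEFFICIENTS
from ohlra.roc import (
    auc,
    auc_ci,
    derive_risk_cutoffs,
    empirical_roc,
    optimal_cutoff,
)


def brute_force_auc(scores, labels):
    """Pairwise Mann-Whitney oracle: P(pos > neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def exhaustive_best_point(scores, labels):
    """Distance-to-(0,1) search over every 'predict positive if score >= c'."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    candidates = np.concatenate([np.unique(scores), [np.inf]])
    best = None
    for c in candidates:
        pred = scores >= c
        tpr = (pred & (labels == 1)).sum() / (labels == 1).sum()
        fpr = (pred & (labels == 0)).sum() / (labels == 0).sum()
        d = np.hypot(1 - tpr, fpr)
        if best is None or d < best[0] - 1e-12 or (abs(d - best[0]) <= 1e-12 and c < best[1]):
            best = (d, c, tpr, 1 - fpr)
    return best


class TestEmpiricalRoc:
    def test_perfect_separation(self):
        curve = empirical_roc([1, 2, 3, 4], [0, 0, 1, 1])
        pts = set(zip(curve.fpr, curve.tpr))
        assert {(0.0, 0.0), (0.0, 1.0), (1.0, 1.0)} <= pts

    def test_all_ties_degenerate(self):
        curve = empirical_roc([2, 2, 2, 2], [0, 1, 0, 1])
        assert np.allclose(curve.fpr, curve.tpr)

    def test_sign_reversal_mirrors_curve(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert auc(-s, y) == pytest.approx(1 - auc(s, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_roc([1, 2, 3], [1, 1, 1])


class TestAuc:
    def test_hand_example(self):
        assert auc([1, 2, 3, 4, 5], [0, 1, 0, 1, 1]) == pytest.approx(5 / 6)

    def test_perfect_and_useless(self):
        assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert auc([2, 2, 2, 2], [0, 1, 0, 1]) == 0.5

    def test_matches_brute_force_on_200_random_instances(self):
        """Exact agreement with the pairwise oracle, ties included."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            scores = rng.integers(0, 8, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )


class TestAucCi:
    def test_perfect_auc_degenerate_ci(self):
        assert auc_ci(1.0, 10, 10) == (1.0, 1.0)

    def test_formula_evaluation(self):
        lo, hi = auc_ci(0.9, 50, 50)
        assert lo == pytest.approx(0.837, abs=0.001)
        assert hi == pytest.approx(0.963, abs=0.001)

    def test_se_shrinks_with_n(self):
        widths = [np.diff(auc_ci(0.85, n, n))[0] for n in (10, 50, 200, 1000)]
        assert all(a > b for a, b in zip(widths, widths[1:]))


class TestOptimalCutoff:
    def test_perfect_separation_midpoint(self):
        curve = empirical_roc([1, 2, 3, 4], [0, 0, 1, 1])
        op = optimal_cutoff(curve)
        assert op.threshold == pytest.approx(2.5)
        assert op.sensitivity == 1.0 and op.specificity == 1.0

    def test_degenerate_curve_warns(self):
        curve = empirical_roc([2, 2, 2, 2], [0, 1, 0, 1])
        with pytest.warns(UserWarning, match="degenerate"):
            optimal_cutoff(curve)

    def test_matches_exhaustive_search(self):
        """Sens/spec at the chosen point equal the brute-force optimum, and the
        midpoint threshold reproduces that operating point."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(6, 60))
            scores = np.round(rng.normal(size=n), 1)
            labels = (scores + rng.normal(scale=1.0, size=n) > 0).astype(int)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            op = optimal_cutoff(empirical_roc(scores, labels))
            d_best, c_best, tpr_best, spec_best = exhaustive_best_point(scores, labels)
            assert np.hypot(1 - op.sensitivity, 1 - op.specificity) == pytest.approx(
                d_best, abs=1e-12
            )
            pred = scores > op.threshold
            tpr = (pred & (labels == 1)).sum() / (labels == 1).sum()
            fpr = (pred & (labels == 0)).sum() / (labels == 0).sum()
            assert tpr == pytest.approx(op.sensitivity)
            assert 1 - fpr == pytest.approx(op.specificity)


class TestDeriveRiskCutoffs:
    def test_identity_score_recovers_thresholds(self):
        """If the score IS hearing loss, cut-offs equal the dB thresholds and AUC=1."""
        import pandas as pd

        rng = np.random.default_rng(5)
        hl = rng.uniform(0, 80, 2000)
        df = pd.DataFrame({"ohlra_score": hl, "hearing_loss_dB": hl})
        cuts = derive_risk_cutoffs(df)
        assert cuts.auc == (1.0, 1.0, 1.0)
        for got, want in zip((cuts.t_low_mod, cuts.t_mod_high, cuts.t_high_vhigh), (25, 40, 60)):
            assert got == pytest.approx(want, abs=0.5)

    def test_permutation_invariance(self, continuous_cohort):
        import pandas as pd

        w = DEFAULT_COEFFICIENTS.as_array()
        score = continuous_cohort.iloc[:, :9].to_numpy() @ w
        df = pd.DataFrame({"ohlra_score": score, "hearing_loss_dB": continuous_cohort["hearing_loss"]})
        shuffled = df.sample(frac=1.0, random_state=0)
        a = derive_risk_cutoffs(df)
        b = derive_risk_cutoffs(shuffled)
        assert (a.t_low_mod, a.t_mod_high, a.t_high_vhigh) == (
            b.t_low_mod, b.t_mod_high, b.t_high_vhigh)
        assert a.auc == b.auc

    def test_single_class_dichotomization_rejected(self):
        import pandas as pd

        df = pd.DataFrame({"ohlra_score": [1.0, 2.0, 3.0], "hearing_loss_dB": [5.0, 6.0, 7.0]})
        with pytest.raises(ValueError, match="single class"):
            derive_risk_cutoffs(df)

    def test_auc_ordering_on_synthetic_cohorts(self, continuous_cohort):
        """Discriminability grows with the hearing-loss threshold (25 < 40 < 60 dB)."""
        import pandas as pd

        w = DEFAULT_COEFFICIENTS.as_array()
        score = continuous_cohort.iloc[:, :9].to_numpy() @ w
        df = pd.DataFrame({"ohlra_score": score, "hearing_loss_dB": continuous_cohort["hearing_loss"]})
        cuts = derive_risk_cutoffs(df)
        assert cuts.auc[0] < cuts.auc[1] < cuts.auc[2]
        assert cuts.t_low_mod < cuts.t_mod_high < cuts.t_high_vhigh
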