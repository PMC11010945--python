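"""ROC/AUC machinery against brute-force oracles, predictive-value algebra,
paired AUC comparison and contingency summaries."""

import numpy as np
import pandas as pd
import pytest

from fetquant.diagnostics import (
    compare_roc_paired,
    confusion_metrics,
    contingency_summary,
    metrics_from_rates,
    roc_analysis,
    youden_optimal_cutoff,
)


def auc_pair_count(scores, y):
    """Brute-force AUC: fraction of positive-negative pairs correctly ordered,
    half credit for ties."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def youden_exhaustive(scores, y):
    u = np.unique(scores)
    cands = (u[:-1] + u[1:]) / 2.0
    best_j, best = -np.inf, None
    for c in cands:
        sens = np.mean(scores[y == 1] > c)
        spec = np.mean(scores[y == 0] <= c)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best = j, (c, sens)
        elif abs(j - best_j) <= 1e-12:
            # higher sensitivity wins, then lower cutoff
            if sens > best[1] + 1e-12:
                best = (c, sens)
    return best[0], best_j


class TestROC:
    def test_perfect_separation(self):
        roc = roc_analysis([0.1, 0.2, 0.9, 1.0], [0, 0, 1, 1])
        assert roc.auc == 1.0
        assert 0.2 < roc.youden_cutoff < 0.9

    def test_small_example_pair_count(self):
        # pos = {2, 4}, neg = {1, 3}: 3 of 4 pairs correctly ordered
        scores, y = [1, 3, 2, 4], [0, 0, 1, 1]
        assert auc_pair_count(np.asarray(scores, float), np.asarray(y)) == 0.75
        roc = roc_analysis(scores, y)
        assert roc.auc == 0.75

    def test_all_ties_give_half(self):
        roc = roc_analysis([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])
        assert roc.auc == 0.5

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            roc_analysis([1, 2, 3], [1, 1, 1])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            scores = rng.integers(0, 10, n).astype(float)  # heavy ties
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            roc = roc_analysis(scores, y)
            assert roc.auc == pytest.approx(auc_pair_count(scores, y), abs=1e-12)
            if np.unique(scores).size >= 2:
                cut, j = youden_exhaustive(scores, y)
                assert roc.youden_cutoff == pytest.approx(cut)
                got_j = (
                    np.mean(scores[y == 1] > roc.youden_cutoff)
                    + np.mean(scores[y == 0] <= roc.youden_cutoff)
                    - 1.0
                )
                assert got_j == pytest.approx(j, abs=1e-12)

    def test_invariant_under_increasing_transform(self, rng):
        scores = rng.normal(size=60)
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 0, 1
        a = roc_analysis(scores, y)
        b = roc_analysis(np.exp(scores), y)
        assert a.auc == pytest.approx(b.auc)

    def test_trapezoid_equals_mann_whitney(self, rng):
        """AUC from the trapezoid rule over (1-spec, sens) equals the pair
        statistic."""
        for _ in range(50):
            n = int(rng.integers(6, 50))
            scores = rng.integers(0, 8, n).astype(float)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            roc = roc_analysis(scores, y)
            fpr = np.concatenate([[1.0], 1.0 - roc.specificity, [0.0]])
            tpr = np.concatenate([[1.0], roc.sensitivity, [0.0]])
            trap = -np.trapezoid(tpr, fpr)
            assert trap == pytest.approx(roc.auc, abs=1e-10)

    def test_ci_contains_auc_and_is_ordered(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(1, 1, 40)])
        y = np.array([0] * 40 + [1] * 40)
        roc = roc_analysis(scores, y)
        assert roc.ci[0] <= roc.auc <= roc.ci[1]

    def test_bootstrap_ci_close_to_delong(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 60), rng.normal(1.2, 1, 60)])
        y = np.array([0] * 60 + [1] * 60)
        d = roc_analysis(scores, y, ci_method="delong")
        b = roc_analysis(scores, y, ci_method="bootstrap", n_boot=1000, seed=0)
        assert d.ci[0] == pytest.approx(b.ci[0], abs=0.05)
        assert d.ci[1] == pytest.approx(b.ci[1], abs=0.05)

    def test_bootstrap_ci_coverage(self):
        """Percentile-bootstrap CI covers the generating AUC in roughly 95%
        of replicates (binormal model with known AUC)."""
        rng = np.random.default_rng(7)
        mu = 1.0
        true_auc = float(
            1.0 - __import__("scipy").stats.norm.cdf(0, loc=mu, scale=np.sqrt(2))
        )
        cover = 0
        n_rep = 100
        for _ in range(n_rep):
            scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(mu, 1, 50)])
            y = np.array([0] * 50 + [1] * 50)
            roc = roc_analysis(scores, y, ci_method="bootstrap", n_boot=400, seed=int(rng.integers(1 << 30)))
            if roc.ci[0] <= true_auc <= roc.ci[1]:
                cover += 1
        assert 85 <= cover <= 100

    def test_youden_helper_matches_stored(self, rng):
        scores = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        roc = roc_analysis(scores, y)
        assert youden_optimal_cutoff(roc) == roc.youden_cutoff


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        m = confusion_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_inverted_predictions(self):
        m = confusion_metrics([0, 1, 0, 1], [1, 0, 1, 0])
        assert m.sensitivity == 0.0 and m.specificity == 0.0

    def test_count_arithmetic(self):
        y = [1] * 230 + [0] * 54
        pred = [1] * 213 + [0] * 17 + [1] * 34 + [0] * 20
        m = confusion_metrics(y, pred)
        assert (m.tp, m.fn, m.fp, m.tn) == (213, 17, 34, 20)
        assert m.sensitivity == pytest.approx(213 / 230)
        assert m.specificity == pytest.approx(20 / 54)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion_metrics([0, 1], [0, 1, 1])

    def test_string_labels_with_positive_label(self):
        m = confusion_metrics(["t", "a", "t"], ["t", "t", "a"], positive_label="t")
        assert m.tp == 1 and m.fp == 1 and m.fn == 1


class TestMetricsFromRates:
    def test_perfect_rates(self):
        m = metrics_from_rates(1.0, 1.0, 10, 10)
        assert m.ppv == 1.0 and m.npv == 1.0

    def test_symmetric_prevalence(self):
        m = metrics_from_rates(0.8, 0.8, 100, 100)
        assert m.ppv == pytest.approx(0.8)
        assert m.npv == pytest.approx(0.8)

    def test_published_row_reproduced(self):
        # early plexus ROI-mean operating point with the cohort class sizes
        m = metrics_from_rates(0.95, 0.58, 230, 54)
        assert m.ppv == pytest.approx(0.90, abs=0.02)

    def test_roundtrip_with_confusion_metrics(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        pred = rng.integers(0, 2, 200)
        m1 = confusion_metrics(y, pred)
        if np.isnan(m1.ppv) or np.isnan(m1.npv):
            return
        m2 = metrics_from_rates(m1.sensitivity, m1.specificity, int(y.sum()), int((1 - y).sum()))
        assert m2.ppv == pytest.approx(m1.ppv)
        assert m2.npv == pytest.approx(m1.npv)

    def test_undefined_predictive_value(self):
        with pytest.raises(ValueError, match="undefined"):
            metrics_from_rates(0.0, 1.0, 10, 10)


class TestComparePairedROC:
    def test_identical_scores_give_p_one(self, rng):
        scores = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        auc_a, auc_b, p = compare_roc_paired(scores, scores, y)
        assert auc_a == auc_b
        assert p == 1.0

    def test_symmetric_in_arguments(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(size=60)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        _, _, p_ab = compare_roc_paired(a, b, y)
        _, _, p_ba = compare_roc_paired(b, a, y)
        assert p_ab == pytest.approx(p_ba)

    def test_power_against_informative_scores(self):
        """A separating score beats a random one (p < 0.01) in at least 95%
        of seeded replicates at n = 200."""
        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            y = rng.integers(0, 2, 200)
            y[:2] = [0, 1]
            informative = y + rng.normal(0, 0.3, 200)
            noise = rng.normal(size=200)
            _, _, p = compare_roc_paired(informative, noise, y)
            if p < 0.01:
                hits += 1
        assert hits >= 95


class TestContingencySummary:
    def test_packaged_composition_totals(self):
        from fetquant.fixtures import load_contingency_table

        t2 = load_contingency_table().reset_index()
        long = t2.melt(id_vars="histology", var_name="trajectory", value_name="n")
        long = long[long.trajectory != "overall"]
        samples = long.loc[long.index.repeat(long.n)][["histology", "trajectory"]]
        out = contingency_summary(samples)
        counts = out["counts"]
        assert counts.loc["total", "overall"] == 284
        assert counts.loc[["G2", "G3", "G4"], "overall"].sum() == 230
        assert out["percent"].loc["astrogliosis", "FLAIR"] == 53
        assert out["percent"].loc["astrogliosis", "overall"] == 19
        assert out["percent"].loc["G3", "overall"] == 44

    def test_single_sample_is_its_own_cell(self):
        df = pd.DataFrame({"histology": ["G3"], "trajectory": ["PET"]})
        out = contingency_summary(df)
        assert out["counts"].loc["G3", "PET"] == 1
        assert out["percent"].loc["G3", "PET"] == 100

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            contingency_summary(pd.DataFrame({"histology": [], "trajectory": []}))
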