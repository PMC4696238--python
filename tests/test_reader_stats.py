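import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import flgrade as fg
from flgrade.reader_stats import HIGH, LOW


def _labels(n_pos, n_neg):
    return np.array([HIGH] * n_pos + [LOW] * n_neg)


class TestDichotomize:
    @pytest.mark.parametrize("score,expected", [
        (50.0, HIGH),   # the threshold itself counts as high
        (49.99, LOW),
        (0.0, LOW),
        (100.0, HIGH),
    ])
    def test_threshold_rule(self, score, expected):
        assert fg.dichotomize(score) == expected


class TestPercentAgreement:
    def test_printed_overall_rate(self):
        # 220 readings with 125 correct dichotomized calls
        truth = {f"c{i}": HIGH if i < 10 else LOW for i in range(20)}
        rows = []
        n = 0
        for r in range(11):
            for i in range(20):
                correct = n < 125
                truth_high = i < 10
                score = (80 if truth_high else 20) if correct else \
                        (20 if truth_high else 80)
                rows.append({"reader_id": f"r{r}", "case_id": f"c{i}",
                             "modality": "UNAIDED", "score": score})
                n += 1
        agree, total, pct = fg.percent_agreement(pd.DataFrame(rows), truth)
        assert (agree, total) == (125, 220)
        assert round(pct, 1) == 56.8

    def test_all_correct(self):
        truth = {"a": HIGH, "b": LOW}
        df = pd.DataFrame([
            {"reader_id": "r", "case_id": "a", "modality": "U", "score": 90},
            {"reader_id": "r", "case_id": "b", "modality": "U", "score": 10}])
        assert fg.percent_agreement(df, truth)[2] == 100.0

    def test_hand_tallied_fixture(self):
        truth = {"a": HIGH, "b": LOW, "c": HIGH}
        recs = [("a", 50, True), ("a", 49, False), ("b", 50, False),
                ("b", 0, True), ("c", 99, True), ("c", 1, False)]
        df = pd.DataFrame([{"reader_id": "r", "case_id": c, "modality": "U",
                            "score": s} for c, s, _ in recs])
        expected = sum(ok for _, _, ok in recs)
        agree, total, pct = fg.percent_agreement(df, truth)
        assert agree == expected and total == 6
        assert pct == pytest.approx(100 * expected / 6)

    def test_missing_truth_rejected(self):
        df = pd.DataFrame([{"reader_id": "r", "case_id": "zz", "modality": "U",
                            "score": 50}])
        with pytest.raises(fg.StatsError) as exc:
            fg.percent_agreement(df, {"a": HIGH})
        assert exc.value.code == "unmatched_case"


class TestTrapezoidalAuc:
    def test_perfect_separation(self):
        assert fg.trapezoidal_auc([3, 4, 1, 2], _labels(2, 2)) == 1.0

    def test_all_ties(self):
        assert fg.trapezoidal_auc([5, 5, 5, 5], _labels(2, 2)) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        scores = rng.integers(0, 20, 30).astype(float)  # force some ties
        truth = _labels(14, 16)
        pos, neg = scores[:14], scores[14:]
        expected = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
        assert fg.trapezoidal_auc(scores, truth) == pytest.approx(expected)

    def test_complement_symmetry(self, rng):
        scores = rng.random(25)
        truth = _labels(10, 15)
        assert fg.trapezoidal_auc(scores, truth) + \
            fg.trapezoidal_auc(-scores, truth) == pytest.approx(1.0)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        scores = r.random(20)
        truth = _labels(8, 12)
        transformed = np.exp(3 * scores) + 1
        assert fg.trapezoidal_auc(scores, truth) == pytest.approx(
            fg.trapezoidal_auc(transformed, truth))

    def test_single_class_rejected(self):
        with pytest.raises(fg.StatsError) as exc:
            fg.trapezoidal_auc([1, 2], np.array([HIGH, HIGH]))
        assert exc.value.code == "degenerate_truth"


class TestExactBinomialCi:
    def test_perfect_auc_boundary(self):
        est = fg.auc_ci_exact_binomial(1.0, 10, 10)
        assert est.ci_high == 1.0
        assert est.ci_low == pytest.approx(0.025 ** (1 / 100))  # (alpha/2)^(1/N)

    def test_matches_tail_inversion_oracle(self):
        est = fg.auc_ci_exact_binomial(0.5, 2, 2)  # N = 4, s = 2
        # exhaustive Clopper-Pearson inversion by bisecting the tail equations
        from scipy.optimize import brentq
        lo = brentq(lambda p: stats.binom.sf(1, 4, p) - 0.025, 1e-9, 1 - 1e-9)
        hi = brentq(lambda p: stats.binom.cdf(2, 4, p) - 0.025, 1e-9, 1 - 1e-9)
        assert est.ci_low == pytest.approx(lo, abs=1e-6)
        assert est.ci_high == pytest.approx(hi, abs=1e-6)

    def test_interval_widens_as_pairs_decrease(self):
        wide = fg.auc_ci_exact_binomial(0.8, 5, 5)
        narrow = fg.auc_ci_exact_binomial(0.8, 10, 10)
        assert (wide.ci_high - wide.ci_low) > (narrow.ci_high - narrow.ci_low)


class TestLogitUstatCi:
    def test_variance_close_to_jackknife(self, rng):
        scores = np.concatenate([rng.standard_normal(10) + 1.2,
                                 rng.standard_normal(10)])
        truth = _labels(10, 10)
        var = fg.auc_ustat_variance(scores, truth)
        n = 20
        jk = np.array([fg.trapezoidal_auc(np.delete(scores, i),
                                          np.delete(truth, i)) for i in range(n)])
        var_jk = (n - 1) / n * np.sum((jk - jk.mean()) ** 2)
        assert var == pytest.approx(var_jk, rel=0.10)

    def test_interval_contains_estimate_inside_unit_interval(self, rng):
        scores = np.concatenate([rng.standard_normal(12) + 1,
                                 rng.standard_normal(12)])
        est = fg.auc_ci_logit_ustat(scores, _labels(12, 12))
        assert 0.0 < est.ci_low <= est.auc <= est.ci_high < 1.0

    def test_degenerate_auc_rejected(self):
        with pytest.raises(fg.StatsError) as exc:
            fg.auc_ci_logit_ustat([10, 9, 1, 2], _labels(2, 2))
        assert exc.value.code == "logit_undefined"


class TestEmpiricalRoc:
    def test_perfect_curve_passes_through_corner(self):
        curve = fg.empirical_roc([9, 8, 1, 2], _labels(2, 2))
        assert any(np.allclose(p, [0, 1]) for p in curve.points)

    def test_all_ties_give_diagonal(self):
        curve = fg.empirical_roc([5, 5, 5, 5], _labels(2, 2))
        assert curve.auc() == pytest.approx(0.5)
        np.testing.assert_allclose(curve.points[:, 0], curve.points[:, 1])

    def test_area_equals_mann_whitney_on_random_scores(self, rng):
        scores = rng.integers(0, 15, 50).astype(float)
        truth = _labels(20, 30)
        curve = fg.empirical_roc(scores, truth)
        assert curve.auc() == pytest.approx(fg.trapezoidal_auc(scores, truth))


class TestAverageRocDiagonal:
    def _curve(self, rng, n=12):
        scores = rng.random(2 * n)
        return fg.empirical_roc(scores + np.r_[np.full(n, 0.3), np.zeros(n)],
                                _labels(n, n))

    def test_self_average_is_identity(self, rng):
        c = self._curve(rng)
        avg = fg.average_roc_diagonal([c, c], grid_points=401)
        # compare areas and interpolated offsets rather than vertex lists
        assert avg.auc() == pytest.approx(c.auc(), abs=2e-3)

    def test_reflection_pair_averages_to_midpoint(self, rng):
        # reflecting about the (0,1)-(1,0) diagonal maps (x, y) -> (1-y, 1-x);
        # in rotated coordinates the reflected offset is v(sqrt(2) - u), so
        # the average has the closed form (v(u) + v(sqrt(2) - u)) / 2
        c = self._curve(rng)
        x, y = c.points[:, 0], c.points[:, 1]
        reflected = fg.RocCurve(np.column_stack([1 - y[::-1], 1 - x[::-1]]))
        avg = fg.average_roc_diagonal([c, reflected], grid_points=201)
        s2 = np.sqrt(2)
        grid = np.linspace(0, s2, 201)
        v = np.interp(grid, (x + y) / s2, (y - x) / s2)
        expected_v = (v + v[::-1]) / 2
        u_avg = (avg.points[:, 0] + avg.points[:, 1]) / s2
        v_avg = (avg.points[:, 1] - avg.points[:, 0]) / s2
        np.testing.assert_allclose(np.interp(grid, u_avg, v_avg), expected_v,
                                   atol=1e-9)

    def test_output_is_valid_roc(self, rng):
        curves = [self._curve(rng) for _ in range(5)]
        avg = fg.average_roc_diagonal(curves)
        assert np.allclose(avg.points[0], [0, 0])
        assert np.allclose(avg.points[-1], [1, 1])
        assert (np.diff(avg.points, axis=0) >= -1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(fg.StatsError) as exc:
            fg.average_roc_diagonal([])
        assert exc.value.code == "no_curves"


def _toy_scores(n_readers=2, n_cases=4, delta=0.0, seed=0):
    rng = np.random.default_rng(seed)
    truth = pd.DataFrame({"case_id": [f"c{k}" for k in range(n_cases)],
                          "grade": _labels(n_cases // 2, n_cases - n_cases // 2)})
    rows = []
    for i in range(n_readers):
        for k in range(n_cases):
            is_high = k < n_cases // 2
            s = np.clip(50 + (5 if is_high else -5) + 10 * rng.standard_normal(),
                        0, 100)
            rows.append({"reader_id": f"r{i}", "case_id": f"c{k}",
                         "modality": "UNAIDED", "score": float(s)})
            if delta == 0.0:
                s2 = s  # identical readings in both modalities
            else:
                s2 = np.clip(50 + (delta if is_high else -delta)
                             + 10 * rng.standard_normal(), 0, 100)
            rows.append({"reader_id": f"r{i}", "case_id": f"c{k}",
                         "modality": "AIDED", "score": float(s2)})
    return pd.DataFrame(rows), truth


class TestOrHillis:
    def test_identical_modalities_are_null(self):
        scores, truth = _toy_scores(n_readers=3, n_cases=8)
        res = fg.or_hillis_compare(scores, truth, index="AUC")
        assert res.difference == 0.0
        assert res.f_stat == 0.0
        assert res.p_value == 1.0

    def test_toy_design_matches_hand_computed_or_formulas(self):
        scores, truth = _toy_scores(n_readers=2, n_cases=6, delta=7.0, seed=3)
        res = fg.or_hillis_compare(scores, truth, index="AUC")

        # independent spreadsheet-style evaluation
        ts = truth.set_index("case_id")["grade"]
        readers = sorted(scores.reader_id.unique())
        mods = ["UNAIDED", "AIDED"]
        cases = sorted(ts.index)
        theta = np.zeros((2, 2))
        jk = np.zeros((2, 2, len(cases)))
        for i, r in enumerate(readers):
            for j, m in enumerate(mods):
                sub = scores[(scores.reader_id == r) & (scores.modality == m)]
                sub = sub.set_index("case_id").reindex(cases)
                s = sub.score.to_numpy()
                theta[i, j] = fg.trapezoidal_auc(s, ts.reindex(cases).to_numpy())
                for k in range(len(cases)):
                    jk[i, j, k] = fg.trapezoidal_auc(
                        np.delete(s, k), np.delete(ts.reindex(cases).to_numpy(), k))
        n = len(cases)
        flat = jk.reshape(4, n)
        cov = np.zeros((4, 4))
        for a in range(4):
            for b in range(4):
                cov[a, b] = (n - 1) / n * np.sum(
                    (flat[a] - flat[a].mean()) * (flat[b] - flat[b].mean()))
        cov1 = (cov[0, 1] + cov[2, 3]) / 2
        cov2 = (cov[0, 2] + cov[1, 3]) / 2
        cov3 = (cov[0, 3] + cov[1, 2]) / 2
        grand = theta.mean()
        ms_t = 2 * ((theta.mean(axis=0) - grand) ** 2).sum()
        ms_tr = ((theta - theta.mean(axis=0) - theta.mean(axis=1)[:, None]
                  + grand) ** 2).sum()
        denom = ms_tr + 2 * max(cov2 - cov3, 0)
        f = ms_t / denom
        ddf = denom ** 2 / ms_tr ** 2  # (t-1)(r-1) = 1
        assert res.f_stat == pytest.approx(f)
        assert res.ddf == pytest.approx(ddf)
        assert res.p_value == pytest.approx(float(stats.f.sf(f, 1, ddf)))
        assert res.difference == pytest.approx(theta[:, 1].mean() - theta[:, 0].mean())

    def test_all_correct_agreement_means_100(self):
        truth = pd.DataFrame({"case_id": ["a", "b"], "grade": [HIGH, LOW]})
        rows = []
        for r in ("r0", "r1"):
            for m in ("UNAIDED", "AIDED"):
                rows.append({"reader_id": r, "case_id": "a", "modality": m, "score": 90})
                rows.append({"reader_id": r, "case_id": "b", "modality": m, "score": 10})
        res = fg.or_hillis_compare(pd.DataFrame(rows), truth, index="AGREEMENT")
        assert res.mean_unaided == res.mean_aided == 100.0
        assert res.difference == 0.0

    def test_non_crossed_design_rejected(self):
        scores, truth = _toy_scores()
        scores = scores.iloc[:-1]
        with pytest.raises(fg.StatsError) as exc:
            fg.or_hillis_compare(scores, truth)
        assert exc.value.code == "design_not_crossed"

    def test_single_reader_rejected(self):
        scores, truth = _toy_scores(n_readers=1)
        with pytest.raises(fg.StatsError) as exc:
            fg.or_hillis_compare(scores, truth)
        assert exc.value.code == "insufficient_readers"
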