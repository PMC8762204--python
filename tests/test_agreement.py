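"""ICC, Bland-Altman, detection counts, and Pearson correlation."""

import numpy as np
import pandas as pd
import pytest

from respitiming import (bland_altman, classify_icc, compare_detection_counts,
                         correlation_strength, icc_two_way_mixed, pearson_r)
from respitiming.agreement import agreement_by_muscle


def brute_force_icc3(x, y):
    """Independent oracle: two-way ANOVA mean squares spelled out from raw
    sums of squares, then ICC(3,1) = (MSR - MSE) / (MSR + MSE) for k=2."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.sum() / (n * k)
    ss_rows = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((v - grand) ** 2 for v in data.ravel())
    msr = ss_rows / (n - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


HAND_TABLE = (np.array([10.0, 12.5, 9.0, 15.0, 11.0, 13.5]),
              np.array([11.0, 12.0, 10.5, 14.0, 10.0, 14.5]))


class TestIcc:
    def test_identity_is_one(self):
        x = np.random.default_rng(0).normal(size=50)
        icc, p = icc_two_way_mixed(x, x)
        assert icc == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-10

    def test_constant_offset_consistency_is_one(self):
        x = np.random.default_rng(1).normal(size=50)
        icc, _ = icc_two_way_mixed(x, x + 7.0)
        assert icc == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_lowers_absolute_agreement(self):
        x = np.random.default_rng(1).normal(size=50)
        icc_abs, _ = icc_two_way_mixed(x, x + 7.0, form="agreement")
        assert icc_abs < 0.999

    def test_hand_table_matches_brute_force(self):
        x, y = HAND_TABLE
        icc, _ = icc_two_way_mixed(x, y)
        assert icc == pytest.approx(brute_force_icc3(x, y), abs=1e-9)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        x, y = HAND_TABLE
        long = pd.DataFrame({
            "targets": np.r_[np.arange(6), np.arange(6)],
            "raters": ["a"] * 6 + ["b"] * 6,
            "scores": np.r_[x, y]})
        ref = pingouin.intraclass_corr(long, targets="targets", raters="raters",
                                       ratings="scores")
        icc3 = float(ref.loc[ref["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        icc, _ = icc_two_way_mixed(x, y)
        assert icc == pytest.approx(icc3, abs=1e-9)

    def test_affine_invariance(self):
        x, y = HAND_TABLE
        base, _ = icc_two_way_mixed(x, y)
        scaled, _ = icc_two_way_mixed(3.0 * x - 11.0, 3.0 * y - 11.0)
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([1.1, 2.1, 3.0, np.nan, 5.2])
        icc, _ = icc_two_way_mixed(x, y)
        ref, _ = icc_two_way_mixed(x[[0, 1, 4]], y[[0, 1, 4]])
        assert icc == pytest.approx(ref)

    def test_zero_variance_undefined(self):
        icc, p = icc_two_way_mixed(np.full(5, 2.0), np.full(5, 2.0))
        assert np.isnan(icc) and np.isnan(p)
        assert classify_icc(icc) == "undefined"


class TestClassifyIcc:
    @pytest.mark.parametrize("icc,label", [
        (0.3, "poor"), (0.49999, "poor"),
        (0.5, "moderate"), (0.6, "moderate"), (0.74999, "moderate"),
        (0.75, "good"), (0.8, "good"), (0.89999, "good"),
        (0.9, "excellent"), (0.95, "excellent"), (1.0, "excellent"),
    ])
    def test_bands(self, icc, label):
        assert classify_icc(icc) == label


class TestBlandAltman:
    def test_identical_series(self):
        x = np.random.default_rng(2).normal(size=30)
        ba = bland_altman(x, x)
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_constant_offset(self):
        x = np.random.default_rng(2).normal(size=30)
        ba = bland_altman(x, x + 5.0)
        assert ba.bias == pytest.approx(-5.0)
        assert ba.loa_low == pytest.approx(-5.0)
        assert ba.loa_high == pytest.approx(-5.0)

    def test_hand_arithmetic(self):
        # pairs (0,1),(2,1),(4,5): differences {-1, +1, -1}
        ba = bland_altman([0.0, 2.0, 4.0], [1.0, 1.0, 5.0])
        diffs = np.array([-1.0, 1.0, -1.0])
        assert ba.bias == pytest.approx(diffs.mean(), abs=1e-12)
        sd = diffs.std(ddof=1)
        assert ba.loa_low == pytest.approx(diffs.mean() - 1.96 * sd, abs=1e-12)
        assert ba.loa_high == pytest.approx(diffs.mean() + 1.96 * sd, abs=1e-12)

    def test_limits_cover_95_percent_gaussian(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=5000)
        y = x + rng.normal(scale=10.0, size=5000)
        ba = bland_altman(x, y)
        inside = np.mean((ba.diffs >= ba.loa_low) & (ba.diffs <= ba.loa_high))
        assert 0.93 <= inside <= 0.97

    def test_ordering_invariant(self):
        rng = np.random.default_rng(6)
        ba = bland_altman(rng.normal(size=20), rng.normal(size=20))
        assert ba.loa_low <= ba.bias <= ba.loa_high


class TestPearson:
    def test_perfect_positive(self):
        a = np.arange(10.0)
        r, p = pearson_r(a, 2.0 * a)
        assert r == pytest.approx(1.0)
        assert p < 1e-9

    def test_perfect_negative(self):
        a = np.arange(10.0)
        r, _ = pearson_r(a, -a + 3.0)
        assert r == pytest.approx(-1.0)

    def test_hand_table(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        expected = cov / (a.std() * b.std())
        r, _ = pearson_r(a, b)
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged(self):
        r, p = pearson_r(np.full(5, 1.0), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)

    @pytest.mark.parametrize("r,label", [
        (0.05, "negligible"), (0.2, "small"), (-0.2, "small"),
        (0.4, "medium"), (-0.45, "medium"), (0.5, "large"), (0.99, "large")])
    def test_strength_labels(self, r, label):
        assert correlation_strength(r) == label


def event_table(participant, source, times, muscle="scalene", kind="onset"):
    rows = []
    for i, t in enumerate(times):
        rows.append({"participant": participant, "muscle": muscle,
                     "breath_index": i, "event_kind": kind,
                     "time_ms": t, "source": source,
                     "missing": t is None or (isinstance(t, float) and np.isnan(t))})
    df = pd.DataFrame(rows, columns=["participant", "muscle", "breath_index",
                                     "event_kind", "time_ms", "source", "missing"])
    df["time_ms"] = pd.to_numeric(df["time_ms"], errors="coerce")
    df["missing"] = df["missing"].astype(bool)
    return df


class TestDetectionCounts:
    def test_counts_per_source(self):
        algo = event_table("p1", "algorithm", list(np.linspace(1000, 55000, 10)))
        times = list(np.linspace(1000, 55000, 10))
        times[3] = np.nan
        times[7] = np.nan
        rater = event_table("p1", "assessor1", times)
        counts = compare_detection_counts({"algorithm": algo, "assessor1": rater})
        assert counts.loc["scalene", "algorithm"] == 10
        assert counts.loc["scalene", "assessor1"] == 8

    def test_empty_table_zero_counts(self):
        empty = event_table("p1", "algorithm", [])
        counts = compare_detection_counts({"algorithm": empty})
        assert counts.empty or counts.sum().sum() == 0


class TestAgreementByMuscle:
    def test_noisy_rater_good_icc(self):
        rng = np.random.default_rng(9)
        truth = rng.uniform(0, 60000, 80)
        a = event_table("p1", "a1", truth)
        b = event_table("p1", "a2", truth + rng.normal(0, 30.0, 80))
        out = agreement_by_muscle(a, b)
        row = out.iloc[0]
        assert row["n_pairs"] == 80
        assert row["icc"] > 0.99  # 30 ms error SD vs minutes-wide spread
        assert row["icc_class"] == "excellent"
        assert abs(row["bias"]) < 15.0

    def test_missing_members_excluded_and_counted(self):
        truth = np.linspace(1000, 50000, 20)
        times = truth.copy().astype(object)
        times[4] = np.nan
        a = event_table("p1", "a1", list(times))
        b = event_table("p1", "a2", list(truth))
        out = agreement_by_muscle(a, b)
        assert out.iloc[0]["n_pairs"] == 19
        assert out.iloc[0]["n_dropped"] == 1
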