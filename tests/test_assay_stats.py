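import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from repairkinetics import (
    CometCellRecord,
    FociCellRecord,
    ObservationSeries,
    apply_foci_cap,
    differences_from_baseline,
    pool_timecourses,
    summarize_comet,
    summarize_h2ax,
)
from repairkinetics.assay_stats import (
    permutation_test_median_diff,
    read_comet_csv,
    read_foci_csv,
)


def comet_frame(values_by_tp, patient="P1", fraction=1):
    rows = []
    from repairkinetics.assay_stats import TIMEPOINT_MINUTES
    for tp, values in values_by_tp.items():
        for i, v in enumerate(values):
            rows.append({"patient": patient, "fraction": fraction,
                         "timepoint": tp, "minutes": TIMEPOINT_MINUTES[tp],
                         "cell": i + 1, "tail_intensity": float(v)})
    return pd.DataFrame(rows)


class TestSummarizeComet:
    def test_median_and_iqr_small_sample(self):
        df = comet_frame({"T15": [2.0, 4.0, 6.0]})
        out = summarize_comet(df).data
        assert out.loc[0, "median"] == 4.0
        assert out.loc[0, "q1"] == 3.0 and out.loc[0, "q3"] == 5.0

    def test_identical_values_zero_width_interval(self):
        df = comet_frame({"T15": [7.0] * 20})
        row = summarize_comet(df).data.iloc[0]
        assert row["median"] == 7.0
        assert row["q1"] == row["q3"] == 7.0
        assert row["ci_low"] == row["ci_high"] == 7.0

    def test_agrees_with_sort_based_oracle(self, rng):
        for _ in range(100):
            x = rng.uniform(0, 100, size=rng.integers(2, 30))
            df = comet_frame({"T15": x})
            row = summarize_comet(df, n_boot=10).data.iloc[0]
            s = np.sort(x)
            assert row["median"] == np.median(s)
            assert row["q1"] == np.percentile(s, 25)
            assert row["q3"] == np.percentile(s, 75)

    def test_invariant_to_record_order(self, rng):
        df = comet_frame({"T0": rng.uniform(0, 30, 50),
                          "T15": rng.uniform(0, 60, 50)})
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = summarize_comet(df, seed=9).data
        b = summarize_comet(shuffled, seed=9).data
        pd.testing.assert_frame_equal(a, b)

    def test_bootstrap_ci_covers_true_median(self, rng):
        # per-timepoint Gamma draws with a known median
        from scipy import stats
        shape, scale = 2.78, 3.0
        true_med = stats.gamma.ppf(0.5, shape, scale=scale)
        covered = 0
        for i in range(100):
            x = np.clip(rng.gamma(shape, scale, 500), 0, 100)
            df = comet_frame({"T15": x})
            row = summarize_comet(df, seed=i).data.iloc[0]
            covered += row["ci_low"] <= true_med <= row["ci_high"]
        assert covered >= 90

    def test_out_of_range_intensity_rejected(self):
        df = comet_frame({"T15": [5.0]})
        df.loc[0, "tail_intensity"] = 150.0
        with pytest.raises(ValueError, match="\\[0, 100\\]"):
            summarize_comet(df)

    def test_groupings(self, rng):
        frames = [comet_frame({"T15": rng.uniform(0, 50, 20)}, patient=p,
                              fraction=f)
                  for p in ("P1", "P2") for f in (1, 2)]
        df = pd.concat(frames, ignore_index=True)
        assert len(summarize_comet(df, "per-sample").data) == 4
        assert len(summarize_comet(df, "per-patient").data) == 2
        assert len(summarize_comet(df, "per-fraction").data) == 2
        with pytest.raises(ValueError, match="grouping"):
            summarize_comet(df, "per-slide")


class TestDifferencesFromBaseline:
    def test_identical_distributions_null(self, rng):
        x = rng.uniform(0, 30, 200)
        df = comet_frame({"T0": x, "T15": x})
        out = differences_from_baseline(df, n_perm=500, seed=1)
        assert out.loc[0, "difference"] == 0.0
        assert out.loc[0, "p_value"] > 0.5

    def test_known_shift_detected(self, rng):
        base = rng.gamma(2.78, 1.5, 300)
        df = comet_frame({"T0": np.clip(base, 0, 100),
                          "T15": np.clip(base + 10.0, 0, 100)})
        out = differences_from_baseline(df, n_perm=2000, seed=1)
        assert out.loc[0, "difference"] == pytest.approx(10.0, abs=1.5)
        assert out.loc[0, "p_value"] < 0.001
        assert out.loc[0, "ci_low"] <= out.loc[0, "difference"] <= \
            out.loc[0, "ci_high"]

    def test_degenerate_single_cell_groups(self):
        df = comet_frame({"T0": [5.0], "T15": [9.0]})
        out = differences_from_baseline(df)
        assert out.loc[0, "difference"] == pytest.approx(4.0)
        assert np.isnan(out.loc[0, "p_value"])
        assert np.isnan(out.loc[0, "ci_low"])

    def test_missing_baseline_rejected(self):
        df = comet_frame({"T15": [1.0, 2.0]})
        with pytest.raises(ValueError, match="baseline"):
            differences_from_baseline(df)

    def test_type_one_error_within_nominal_band(self, rng):
        # 500 null simulations at nominal 5%
        rejections = 0
        for i in range(500):
            x = rng.gamma(2.78, 3.0, 50)
            y = rng.gamma(2.78, 3.0, 50)
            _, p = permutation_test_median_diff(x, y, n_perm=500, seed=i)
            rejections += p < 0.05
        assert 0.02 <= rejections / 500 <= 0.08


class TestPoolTimecourses:
    def series(self, medians):
        return ObservationSeries(times=np.array([-15.0, 15.0, 30.0]),
                                 medians=np.asarray(medians, dtype=float))

    def test_single_series_is_identity(self):
        s = self.series([1.0, 4.0, 3.0])
        pooled = pool_timecourses([s])
        assert np.array_equal(pooled.medians, s.medians)

    def test_mean_of_medians(self):
        pooled = pool_timecourses([self.series([0, 4, 2]),
                                   self.series([2, 6, 4])])
        assert np.array_equal(pooled.medians, [1.0, 5.0, 3.0])

    def test_order_invariance(self):
        a, b, c = (self.series([0, 4, 2]), self.series([2, 6, 4]),
                   self.series([1, 1, 1]))
        p1 = pool_timecourses([a, b, c])
        p2 = pool_timecourses([c, a, b])
        assert np.array_equal(p1.medians, p2.medians)

    def test_label_mismatch_rejected(self):
        other = ObservationSeries(times=np.array([-15.0, 20.0, 30.0]),
                                  medians=np.zeros(3))
        with pytest.raises(ValueError, match="match"):
            pool_timecourses([self.series([0, 0, 0]), other])


class TestFociCap:
    @pytest.mark.parametrize("raw,expected", [
        (0, 0), (7, 7), (10, 10),  # boundary: "higher than 10" only
        (11, 25), (25, 25), (100, 25),
    ])
    def test_capping_rule(self, raw, expected):
        assert apply_foci_cap(raw) == expected

    @given(st.lists(st.integers(0, 60), min_size=1, max_size=50))
    def test_idempotent_and_elementwise(self, counts):
        arr = np.asarray(counts)
        once = apply_foci_cap(arr)
        assert np.array_equal(apply_foci_cap(once), once)
        assert np.array_equal(once, [apply_foci_cap(int(c)) for c in counts])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            apply_foci_cap(-1)


class TestSummarizeH2ax:
    def foci_frame(self, counts_by_group, group_col="timepoint"):
        rows = []
        for g, counts in counts_by_group.items():
            for i, c in enumerate(counts):
                rows.append({"patient": "P1", group_col: g, "cell": i + 1,
                             "foci_raw": int(c)})
        return pd.DataFrame(rows)

    def test_all_zero_counts(self):
        out = summarize_h2ax(self.foci_frame({"T0": [0] * 10}))
        assert out.loc[0, "pct_positive"] == 0.0
        assert out.loc[0, "median_foci"] == 0.0

    def test_capped_median_and_positivity(self):
        out = summarize_h2ax(self.foci_frame({"T30": [0, 2, 3, 12]}))
        assert out.loc[0, "pct_positive"] == pytest.approx(75.0)
        # capped counts {0, 2, 3, 25} -> median 2.5
        assert out.loc[0, "median_foci"] == pytest.approx(2.5)

    def test_threshold_configurable(self):
        df = self.foci_frame({"T30": [0, 2, 3, 12]})
        out = summarize_h2ax(df, threshold=3)
        assert out.loc[0, "pct_positive"] == pytest.approx(50.0)

    def test_baseline_mode_by_tumor_type(self, rng):
        groups = {t: rng.poisson(m, 60) for t, m in
                  [("carcinoma", 2.0), ("lymphoma", 3.5),
                   ("melanoma", 2.5), ("sarcoma", 2.0)]}
        out = summarize_h2ax(self.foci_frame(groups, group_col="tumor_type"),
                             group_col="tumor_type")
        assert len(out) == 4
        assert set(out["tumor_type"]) == set(groups)
        assert (out["median_foci_ci_low"] <= out["median_foci"]).all()
        assert (out["median_foci"] <= out["median_foci_ci_high"]).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_h2ax(pd.DataFrame(columns=["timepoint", "foci_raw"]))


class TestRecords:
    def test_comet_record_validation(self):
        CometCellRecord("P1", 1, "T15", 15.0, 1, 12.5)
        with pytest.raises(ValueError, match="inconsistent"):
            CometCellRecord("P1", 1, "T15", 30.0, 1, 12.5)
        with pytest.raises(ValueError, match="\\[0, 100\\]"):
            CometCellRecord("P1", 1, "T15", 15.0, 1, 101.0)

    def test_foci_record_capping_property(self):
        assert FociCellRecord("P1", "T30", 1, 12).foci_capped == 25
        with pytest.raises(ValueError):
            FociCellRecord("P1", "T30", 1, -2)


class TestCsvReaders:
    def test_comet_reader_tolerant_mode_skips_bad_rows(self, tmp_path):
        path = tmp_path / "comet.csv"
        path.write_text(
            "patient,fraction,timepoint,minutes,cell,tail_intensity\n"
            "P1,1,T15,15,1,12.5\n"
            "P1,1,T15,15,2,oops\n"
            "P1,1,T15,15,3,20.0\n")
        with pytest.raises(ValueError, match="line"):
            read_comet_csv(path, strict=True)
        with pytest.warns(UserWarning, match="line"):
            df = read_comet_csv(path, strict=False)
        assert len(df) == 2

    def test_foci_reader(self, tmp_path):
        path = tmp_path / "foci.csv"
        path.write_text("patient,timepoint,cell,foci_raw\n"
                        "P1,T30,1,4\nP1,T30,2,-3\n")
        with pytest.raises(ValueError):
            read_foci_csv(path, strict=True)
        with pytest.warns(UserWarning):
            df = read_foci_csv(path, strict=False)
        assert df["foci_raw"].tolist() == [4]

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="tail_intensity"):
            read_comet_csv(path)
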