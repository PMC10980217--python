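"""Agreement battery: ICC(2,1), Pearson, Lin's CCC, error and bias metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from shakerval import (
    bland_altman_points,
    icc_2way_random_absolute,
    interpret_ccc,
    interpret_icc,
    lins_ccc,
    mean_absolute_error,
    mean_bias_loa,
    pearson_r,
    per_speed_error_summary,
    reliability_matrix,
    summarize_reliability,
    summarize_validity,
)


def brute_force_icc21(m):
    """Independent oracle: two-way ANOVA mean squares from raw sums of
    squares computed with explicit loops, then the ICC(2,1) formula."""
    n, k = m.shape
    grand = sum(m[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(m[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(m[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sse = sum(
        (m[i][j] - row[i] - col[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_perfect_agreement(self):
        m = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        res = icc_2way_random_absolute(m)
        assert res.icc == pytest.approx(1.0)
        assert res.interpretation == "excellent"

    def test_hand_worked_offset_matrix(self):
        # MSR=2, MSC=1.5, MSE=0, k=2, n=3 -> ICC = 2/3
        m = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        res = icc_2way_random_absolute(m)
        assert res.icc == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_white_noise_near_zero(self, rng):
        m = rng.normal(size=(10_000, 4))
        res = icc_2way_random_absolute(m)
        assert abs(res.icc) < 0.05

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            m = rng.normal(size=(5, 10)) + rng.normal(size=(5, 1))
            res = icc_2way_random_absolute(m)
            assert res.icc == pytest.approx(brute_force_icc21(m), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        m = rng.normal(size=(30, 4)) + 2 * rng.normal(size=(30, 1))
        res = icc_2way_random_absolute(m)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(30), 4),
                "rater": np.tile(np.arange(4), 30),
                "score": m.ravel(),
            }
        )
        ref = (
            pingouin.intraclass_corr(
                long, targets="subject", raters="rater", ratings="score"
            )
            .set_index("Type")
            .loc["ICC(A,1)"]
        )
        ci_col = "CI95" if "CI95" in ref.index else "CI95%"
        assert res.icc == pytest.approx(ref["ICC"], abs=1e-6)
        assert res.ci_low == pytest.approx(ref[ci_col][0], abs=6e-3)  # rounded
        assert res.ci_high == pytest.approx(ref[ci_col][1], abs=6e-3)

    def test_listwise_deletion(self, rng):
        m = rng.normal(size=(50, 3))
        m_missing = m.copy()
        m_missing[5, 1] = np.nan
        res = icc_2way_random_absolute(m_missing)
        expected = icc_2way_random_absolute(np.delete(m, 5, axis=0))
        assert res.icc == pytest.approx(expected.icc)
        assert res.n_subjects == 49

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc_2way_random_absolute(np.array([[1.0], [2.0]]))  # one column
        with pytest.raises(ValueError):
            icc_2way_random_absolute(np.array([[1.0, 2.0]]))  # one row
        with pytest.raises(ValueError, match="zero total variance"):
            icc_2way_random_absolute(np.full((5, 3), 2.0))


class TestInterpretationBins:
    @pytest.mark.parametrize(
        "icc,category",
        [(0.97, "excellent"), (0.90, "excellent"), (0.75, "good"),
         (0.749, "moderate"), (0.50, "moderate"), (0.49, "poor"), (-0.2, "poor")],
    )
    def test_icc_bins(self, icc, category):
        assert interpret_icc(icc) == category

    @pytest.mark.parametrize(
        "ccc,category",
        [(0.88, "excellent"), (0.80, "excellent"), (0.59, "moderate"),
         (0.70, "good"), (0.30, "fair"), (0.10, "poor")],
    )
    def test_ccc_bins(self, ccc, category):
        assert interpret_ccc(ccc) == category


class TestPearson:
    def test_hand_example(self):
        assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(0.982, abs=5e-4)

    def test_perfect_and_inverse(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLinsCCC:
    def test_perfect_concordance(self):
        x = np.arange(10.0)
        ccc, lo, hi = lins_ccc(x, x)
        assert ccc == pytest.approx(1.0)

    def test_hand_example_location_shift(self):
        ccc, _, _ = lins_ccc([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert ccc == pytest.approx(4.0 / 7.0, abs=1e-12)

    def test_shifted_scaled_below_pearson(self, rng):
        x = rng.normal(size=200)
        y = 2.0 * x + 1.0  # r = 1 but biased
        ccc, lo, hi = lins_ccc(x, y)
        assert ccc < 1.0
        assert lo <= ccc <= hi

    def test_equals_pearson_when_moments_match(self, rng):
        x = rng.normal(size=500)
        y = 0.5 * x + rng.normal(size=500) * np.sqrt(1 - 0.25)
        y = (y - y.mean()) / y.std() * x.std() + x.mean()
        ccc, _, _ = lins_ccc(x, y)
        assert ccc == pytest.approx(pearson_r(x, y), abs=1e-10)

    def test_matches_direct_moment_computation(self, rng):
        x, y = rng.normal(size=100), rng.normal(size=100)
        ccc, _, _ = lins_ccc(x, y)
        direct = 2 * np.cov(x, y, bias=True)[0, 1] / (
            x.var() + y.var() + (x.mean() - y.mean()) ** 2
        )
        assert ccc == pytest.approx(direct, abs=1e-12)

    def test_both_constant_rejected(self):
        with pytest.raises(ValueError):
            lins_ccc([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_ccc_never_exceeds_pearson(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30) * rng.uniform(0.5, 3.0)
        y = rng.normal(size=30) + rng.uniform(-2, 2)
        ccc, _, _ = lins_ccc(x, y)
        assert abs(ccc) <= abs(pearson_r(x, y)) + 1e-12


class TestErrorMetrics:
    def test_mae_hand_example(self):
        assert mean_absolute_error([1.0, 3.0], [2.0, 2.0]) == pytest.approx(1.0)
        assert mean_absolute_error([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_bias_and_loa_hand_example(self):
        res = mean_bias_loa([-1.0, 1.0], [0.0, 0.0])
        assert res.bias_mg == pytest.approx(0.0)
        assert res.loa_high_mg == pytest.approx(1.96 * np.sqrt(2), abs=5e-3)
        assert res.loa_low_mg == pytest.approx(-1.96 * np.sqrt(2), abs=5e-3)

    def test_degenerate_spreads(self):
        exact = mean_bias_loa([1.0, 2.0], [1.0, 2.0])
        assert (exact.bias_mg, exact.loa_low_mg, exact.loa_high_mg) == (0, 0, 0)
        offset = mean_bias_loa([6.0, 7.0], [1.0, 2.0])
        assert offset.bias_mg == pytest.approx(5.0)
        assert offset.loa_low_mg == pytest.approx(5.0)
        assert offset.ci_high_mg == pytest.approx(5.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_mae_at_least_abs_bias(self, seed):
        rng = np.random.default_rng(seed)
        x, ref = rng.normal(size=20), rng.normal(size=20)
        assert mean_absolute_error(x, ref) >= abs(mean_bias_loa(x, ref).bias_mg) - 1e-12

    def test_bland_altman_points(self):
        pts = bland_altman_points([4.0, 2.0], [2.0, 2.0])
        assert pts["mean_of_pair_mg"].tolist() == [3.0, 2.0]
        assert pts["difference_mg"].tolist() == [2.0, 0.0]


@pytest.fixture(scope="module")
def synthetic_table():
    """Small two-brand epoch table built through the real pipeline."""
    from shakerval import ShakerConfig, build_epoch_table, build_validity_protocol, simulate_device_stream
    from conftest import noiseless_spec

    cfg = ShakerConfig()
    protocol = build_validity_protocol(cfg)
    streams, brands = [], {}
    for b, (brand, n) in enumerate([("garmin", 3), ("fitbit", 2)]):
        for i in range(n):
            spec = noiseless_spec(f"{brand}_{i}", 25.0, noise_sd_g=0.01)
            streams.append(simulate_device_stream(protocol, spec, cfg, seed=100 * b + i))
            brands[spec.device_id] = brand
    return build_epoch_table(streams, protocol, cfg, brands=brands)


class TestTableSummaries:
    def test_validity_summary_counts_and_columns(self, synthetic_table):
        out = summarize_validity(synthetic_table, "mean")
        assert set(out["brand"]) == {"garmin", "fitbit"}
        assert out.set_index("brand").loc["garmin", "n_obs"] == 3 * 420
        assert out.set_index("brand").loc["fitbit", "n_obs"] == 2 * 420

    def test_two_aggregations_share_n(self, synthetic_table):
        a = summarize_validity(synthetic_table, "mean")["n_obs"]
        b = summarize_validity(synthetic_table, "rms")["n_obs"]
        assert a.tolist() == b.tolist()

    def test_perfect_device_scores_perfectly(self):
        from shakerval import EpochTable

        ref = np.tile(np.array([10.0, 20.0, 30.0]), 20)
        df = pd.DataFrame(
            dict(
                device_id="p", brand="perfect", trial_id=0,
                frequency_hz=np.tile([1.0, 2.0, 3.0], 20),
                second_index=np.arange(60), enmo_mean_mg=ref,
                enmo_rms_mg=ref, reference_mg=ref,
            )
        )
        out = summarize_validity(EpochTable(df=df), "mean").iloc[0]
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["ccc"] == pytest.approx(1.0)
        assert out["mae_mg"] == 0.0 and out["bias_mg"] == 0.0

    def test_unknown_aggregation_rejected(self, synthetic_table):
        with pytest.raises(ValueError, match="aggregation"):
            summarize_validity(synthetic_table, "median")

    def test_per_speed_rows_and_pooling_identity(self, synthetic_table):
        per = per_speed_error_summary(synthetic_table, "rms")
        assert (per.groupby("brand").size() == 7).all()
        # pooled MAE equals the observation-weighted mean of per-speed MAEs
        pooled = summarize_validity(synthetic_table, "rms").set_index("brand")
        for brand, grp in per.groupby("brand"):
            weighted = np.average(grp["mae_mg"], weights=grp["n_obs"])
            assert weighted == pytest.approx(pooled.loc[brand, "mae_mg"])


class TestReliabilitySummary:
    def test_identical_batches_of_perfect_devices(self):
        base = np.tile(np.arange(10.0)[:, None], (1, 5))
        res = summarize_reliability([base, base.copy()])
        assert res.icc == pytest.approx(1.0)

    def test_single_batch_equals_plain_icc(self, rng):
        m = rng.normal(size=(40, 5)) + rng.normal(size=(40, 1))
        assert summarize_reliability([m]).icc == pytest.approx(
            icc_2way_random_absolute(m).icc
        )

    def test_stacking_adds_subjects(self, rng):
        m1 = rng.normal(size=(30, 5)) + rng.normal(size=(30, 1))
        m2 = rng.normal(size=(25, 5)) + rng.normal(size=(25, 1))
        res = summarize_reliability([m1, m2])
        assert res.n_subjects == 55
        assert res.icc == pytest.approx(
            icc_2way_random_absolute(np.vstack([m1, m2])).icc
        )

    def test_inconsistent_columns_rejected(self, rng):
        with pytest.raises(ValueError, match="same number"):
            summarize_reliability([rng.normal(size=(10, 5)), rng.normal(size=(10, 4))])

    def test_reliability_matrix_pivot(self, synthetic_table):
        sub = synthetic_table.df[synthetic_table.df["brand"] == "garmin"]
        from shakerval import EpochTable

        m = reliability_matrix(EpochTable(df=sub), "mean")
        assert m.shape == (420, 3)  # 7 freq x 60 s epochs, 3 devices
        assert not np.isnan(m).any()
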