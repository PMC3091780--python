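"""Array-side QC metrics: normalisation, LOD, detection, linearity, precision."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spikeqc import (
    ArraySimParams,
    MicroarrayQC,
    auto_linear_range,
    correlate_arrays,
    detection_fraction,
    estimate_lod,
    fit_linear_range,
    normalize_75th,
    precision_metrics,
    simulate_microarray,
    summarize_probes,
)
from spikeqc.microarray import QCError
from conftest import noise_free_array_params


def intensity_frame(values_by_array: dict, features=None) -> pd.DataFrame:
    rows = []
    for aid, vals in values_by_array.items():
        for i, v in enumerate(vals):
            fid = features[i] if features else f"f{i}"
            rows.append(
                dict(feature_id=fid, standard_id="s1", replicate_probe_index=i + 1,
                     blank=False, array_id=aid, sample="a", run=1,
                     labelling_id=aid, raw_intensity=float(v))
            )
    return pd.DataFrame(rows)


class TestNormalize:
    def test_percentile_zero_after_scaling(self):
        table = intensity_frame({"A": [2.0**k for k in range(1, 9)]})
        out = normalize_75th(table, pseudocount=0.0)
        # single array: baselining zeroes everything; check the scaling step alone
        v = np.log2(table["raw_intensity"])
        scaled = v - np.percentile(v, 75)
        assert np.percentile(scaled, 75) == pytest.approx(0.0, abs=1e-12)
        assert (out["log2_norm"] == 0).all()  # per-feature median of one array

    def test_identical_arrays_zero_after_baseline(self):
        vals = [5.0, 9.0, 17.0, 33.0, 65.0]
        table = intensity_frame({"A": vals, "B": vals})
        out = normalize_75th(table, pseudocount=1.0)
        assert np.allclose(out["log2_norm"], 0.0)

    def test_three_array_baseline_hand_computed(self):
        """Per-feature values {a,b,c} baselined to {a-b, 0, c-b} (b median)."""
        table = intensity_frame({"A": [3.0] * 4, "B": [7.0] * 4, "C": [15.0] * 4})
        out = normalize_75th(table, pseudocount=1.0)
        # identical values within each array, so scaling subtracts the value itself;
        # all scaled arrays are 0, baselining leaves 0
        assert np.allclose(out["log2_norm"], 0.0)
        # non-constant arrays: scale cancels between arrays with equal spread
        table2 = intensity_frame(
            {"A": [1.0, 3.0, 7.0, 15.0], "B": [3.0, 7.0, 15.0, 31.0],
             "C": [7.0, 15.0, 31.0, 63.0]}
        )
        out2 = normalize_75th(table2, pseudocount=1.0)
        wide = out2.pivot(index="feature_id", columns="array_id", values="log2_norm")
        # arrays are shifted copies (x2 in intensity); scaling aligns them exactly
        assert np.allclose(wide["A"], wide["B"]) and np.allclose(wide["B"], wide["C"])

    def test_all_zero_array_rejected(self):
        table = intensity_frame({"A": [0.0, 0.0, 0.0, 0.0]})
        with pytest.raises(QCError, match="A"):
            normalize_75th(table)

    def test_definition_invariants(self):
        """After scaling, each array's 75th pct is 0; after baselining, each
        feature's cross-array median is 0."""
        rng = np.random.default_rng(0)
        table = intensity_frame(
            {a: rng.uniform(1, 100, 20) for a in ("A", "B", "C")}
        )
        out = normalize_75th(table, pseudocount=1.0)
        med = out.groupby("feature_id")["log2_norm"].median()
        assert np.allclose(med, 0.0, atol=1e-12)
        # reconstruct the pre-baseline values: add the feature medians back
        v = np.log2(table["raw_intensity"] + 1.0)
        scaled = v - table.groupby("array_id")["raw_intensity"].transform(
            lambda x: np.percentile(np.log2(x + 1.0), 75)
        )
        for _, grp in pd.DataFrame({"a": table["array_id"], "s": scaled}).groupby("a"):
            assert np.percentile(grp["s"], 75) == pytest.approx(0.0, abs=1e-12)


class TestSummaries:
    def test_median_and_outlier_robustness(self):
        table = intensity_frame({"A": [1.0, 2.0, 100.0]})
        out = summarize_probes(table)
        assert out["raw_intensity"].iloc[0] == 2.0
        const = intensity_frame({"A": [7.0] * 100})
        assert summarize_probes(const)["raw_intensity"].iloc[0] == 7.0

    def test_noise_free_summary_is_gain_times_c(self, pools):
        ds = simulate_microarray(pools, noise_free_array_params(), n_runs=1)
        summ = summarize_probes(ds.intensities)
        for _, row in summ.iterrows():
            c = pools.level_of(row["standard_id"], row["sample"])
            if c > 0:
                assert row["raw_intensity"] == pytest.approx(
                    ds.gains[row["standard_id"]] * c, rel=1e-12
                )

    def test_unknown_statistic(self):
        with pytest.raises(QCError):
            summarize_probes(intensity_frame({"A": [1.0]}), statistic="mode")


class TestLod:
    def test_constant_blanks(self):
        assert estimate_lod([5.0, 5.0, 5.0]) == 5.0

    def test_hand_computed_three_blanks(self):
        lod = estimate_lod([90.0, 100.0, 110.0])
        t = stats.t.ppf(0.975, 2)
        assert t == pytest.approx(4.3027, abs=1e-4)
        assert lod == pytest.approx(100 + t * 10 / math.sqrt(3), abs=1e-9)
        assert lod == pytest.approx(124.84, abs=0.01)

    def test_scales_linearly(self):
        b = np.array([80.0, 95.0, 130.0, 101.0])
        assert estimate_lod(3.5 * b) == pytest.approx(3.5 * estimate_lod(b))

    def test_needs_two_blanks(self):
        with pytest.raises(QCError):
            estimate_lod([100.0])

    def test_coverage_two_and_half_percent(self):
        """The true blank mean exceeds the estimated LOD ~2.5% of the time."""
        rng = np.random.default_rng(42)
        mu, sigma, n, reps = 100.0, 20.0, 5, 10_000
        draws = rng.normal(mu, sigma, size=(reps, n))
        t = stats.t.ppf(0.975, n - 1)
        lods = draws.mean(axis=1) + t * draws.std(axis=1, ddof=1) / math.sqrt(n)
        assert (mu > lods).mean() == pytest.approx(0.025, abs=0.01)


class TestDetection:
    @pytest.mark.parametrize(
        "values,lod,expected",
        [([5, 6, 7], 1.0, 1.0), ([5, 6, 7], 10.0, 0.0), ([1, 2, 3, 9], 2.5, 0.5),
         ([1, 3, 4, 5], 2.0, 0.75), ([2.0, 3.0], 2.0, 0.5)],  # boundary tie -> absent
    )
    def test_counting(self, values, lod, expected):
        assert detection_fraction(values, lod) == expected

    def test_monotone_in_lod(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 100, 50)
        fracs = [detection_fraction(vals, lod) for lod in np.linspace(0, 120, 40)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestLinearFits:
    def test_identity_and_affine(self):
        levels = [10.0, 100.0, 1e3, 1e4, 1e5]
        values = np.log2(levels)
        fit = fit_linear_range(levels, values, (10, 1e5))
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        fit2 = fit_linear_range(levels, 2 * values + 5, (10, 1e5))
        assert fit2.slope == pytest.approx(2.0, abs=1e-12)

    def test_noise_free_simulation_slope_one(self):
        ds = simulate_microarray(
            __import__("spikeqc").make_dilution_pools(
                [__import__("spikeqc").RNAStandard(f"s{i}", 600) for i in range(5)],
                [10.0, 100.0, 1e3, 1e4, 1e5],
            ),
            noise_free_array_params(),
            n_runs=1,
        )
        summ = summarize_probes(ds.intensities)
        grp = summ[summ["standard_id"] == "s0"]
        levels = [ds.design.level_of("s0", s) for s in grp["sample"]]
        fit = fit_linear_range(levels, np.log2(grp["raw_intensity"]), (10, 1e5))
        assert fit.slope == pytest.approx(1.0, abs=1e-9)

    def test_too_few_levels(self):
        with pytest.raises(QCError):
            fit_linear_range([10.0, 100.0], [1.0, 2.0], (10, 100))

    def test_auto_range_detects_saturation(self):
        levels = np.array([10.0, 100.0, 1e3, 1e4, 1e5, 1e6])
        values = np.log2(levels)
        values[-1] = values[-2]  # flat (saturated) top level
        assert auto_linear_range(levels, values) == (10.0, 1e5)
        # enumeration oracle: the chosen window's R^2 beats every other window
        chosen = fit_linear_range(levels, values, (10.0, 1e5)).r_squared
        for lo_i in range(3):
            for hi_i in range(lo_i + 3, 6):
                r2 = fit_linear_range(levels, values, (levels[lo_i], levels[hi_i])).r_squared
                assert chosen >= r2 - 1e-9

    def test_auto_range_full_when_linear(self):
        levels = [10.0, 100.0, 1e3, 1e4, 1e5]
        assert auto_linear_range(levels, np.log2(levels)) == (10.0, 1e5)

    def test_auto_range_degenerate(self):
        with pytest.raises(QCError):
            auto_linear_range([10.0, 100.0, 1e3, 1e4], [1.0, 1.0, 1.0, 1.0])


class TestPrecision:
    def test_hand_computed_cv_and_norm_var(self, pools):
        design = pools
        raw = pd.DataFrame(
            dict(standard_id="ERCC-13", array_id=[f"a{i}" for i in range(3)],
                 sample="pool5", run=[1, 2, 3], labelling_id="l",
                 raw_intensity=[90.0, 100.0, 110.0])
        )
        norm = raw.copy()
        norm["log2_norm"] = [0.0, 0.07, 0.14]
        rep = precision_metrics(raw, norm, design)
        row = rep.iloc[0]
        assert row["cv_raw_pct"] == pytest.approx(10.0)
        assert row["var_norm_pct"] == pytest.approx(100 * (2**0.07 - 1), rel=1e-9)
        assert row["var_norm_pct"] == pytest.approx(4.97, abs=0.01)

    def test_identical_replicates_zero(self, pools):
        raw = pd.DataFrame(
            dict(standard_id="ERCC-13", array_id=[f"a{i}" for i in range(4)],
                 sample="pool5", run=[1, 1, 2, 2], labelling_id="l",
                 raw_intensity=[50.0] * 4)
        )
        norm = raw.copy()
        norm["log2_norm"] = 0.0
        rep = precision_metrics(raw, norm, pools)
        row = rep.iloc[0]
        for col in ("cv_raw_pct", "var_norm_pct", "between_run_pct", "within_run_pct"):
            assert row[col] == 0.0

    def test_low_abundance_noisier_than_high(self, default_array_dataset, pools):
        """Raw CV ordering across abundance: 1-10 copies/ng noisier than >=1e3."""
        table = default_array_dataset.intensities
        raw = summarize_probes(table)
        norm = raw.copy()
        norm["log2_norm"] = np.log2(norm["raw_intensity"])
        rep = precision_metrics(raw, norm, pools)
        low = rep[rep["level"].isin([1.0, 10.0])]["cv_raw_pct"].mean()
        high = rep[rep["level"] >= 1e3]["cv_raw_pct"].mean()
        assert low > high


class TestArrayCorrelation:
    def test_self_and_negation(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=50)
        table = intensity_frame({"A": 100 + 10 * v, "B": 100 + 10 * v})
        norm = table.copy()
        norm["log2_norm"] = np.tile(v, 2)
        norm.loc[norm["array_id"] == "B", "log2_norm"] = -v
        r_self = correlate_arrays(norm, pairs=[("A", "A")])
        assert r_self["r_squared"].iloc[0] == pytest.approx(1.0)
        r_neg = correlate_arrays(norm, pairs=[("A", "B")])
        assert r_neg["r_squared"].iloc[0] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(3)
        table = intensity_frame({"A": np.ones(10_000), "B": np.ones(10_000)})
        norm = table.copy()
        norm["log2_norm"] = rng.normal(size=20_000)
        r = correlate_arrays(norm, pairs=[("A", "B")])
        assert r["r_squared"].iloc[0] < 0.01

    def test_replicate_arrays_highly_correlated(self, default_array_dataset, pools):
        """Whole-array replicate correlation is high on default simulations."""
        from spikeqc import normalize_75th

        table = default_array_dataset.intensities
        sub = table[table["sample"].isin(["pool1", "pool5"])]
        norm = normalize_75th(sub)
        r = correlate_arrays(norm)
        assert (r["r_squared"] > 0.95).all()


class TestModelEndToEnd:
    def test_fit_produces_consistent_results(self, default_array_dataset, pools):
        res = MicroarrayQC(default_array_dataset.intensities, pools).fit()
        assert res.lod > 0
        assert res.lod_level() == 10.0
        assert set(res.linear_fits) == set(pools.standard_ids)
        for fit in res.linear_fits.values():
            assert 0.8 < fit.slope < 1.2
        text = res.summary()
        assert "LOD" in text and "slope" in text
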