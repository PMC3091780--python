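"""Fold-change estimation, volcano classification and confusion scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spikeqc import (
    confusion_vs_truth,
    fc_accuracy,
    pairwise_fold_changes,
    platform_concordance,
    simulate_panel_pair_microarray,
    volcano_classify,
)
from spikeqc.diffexp import PanelComparison, welch_pvalues
from spikeqc.microarray import QCError
from conftest import noise_free_array_params


def norm_frame(arrays: dict, run_of=None, standard="s1") -> pd.DataFrame:
    rows = []
    for aid, vals in arrays.items():
        for i, v in enumerate(vals):
            rows.append(
                dict(feature_id=f"f{i}", standard_id=standard, array_id=aid,
                     run=(run_of or {}).get(aid, 1), log2_norm=float(v))
            )
    return pd.DataFrame(rows)


def noise_free_panels(panel_pair, n_runs=3):
    """Noise-free panel simulation with exact per-feature log2 values."""
    ds = simulate_panel_pair_microarray(
        panel_pair, noise_free_array_params(), n_runs=n_runs, arrays_per_panel_per_run=2
    )
    probes = ds.intensities[
        ds.intensities["standard_id"].isin(panel_pair.expected_fc)
    ].copy()
    probes["log2_norm"] = np.log2(probes["raw_intensity"])
    return (
        probes[probes["sample"] == "A"],
        probes[probes["sample"] == "B"],
        ds,
    )


class TestPairwiseFoldChanges:
    def test_identical_and_shifted(self):
        a = norm_frame({"a1": [1.0, 2.0, 3.0]})
        b_same = norm_frame({"b1": [1.0, 2.0, 3.0]})
        fc = pairwise_fold_changes(a, b_same, pairing=[("a1", "b1")])
        assert (fc["observed_fc"] == 1.0).all()
        b_up = norm_frame({"b1": [2.0, 3.0, 4.0]})
        fc2 = pairwise_fold_changes(a, b_up, pairing=[("a1", "b1")])
        assert (fc2["observed_fc"] == 2.0).all()

    def test_anticommutes(self):
        rng = np.random.default_rng(0)
        a = norm_frame({"a1": rng.normal(size=20), "a2": rng.normal(size=20)})
        b = norm_frame({"b1": rng.normal(size=20), "b2": rng.normal(size=20)})
        pairing = [("a1", "b1"), ("a2", "b2")]
        fwd = pairwise_fold_changes(a, b, pairing=pairing)
        rev = pairwise_fold_changes(b, a, pairing=[(y, x) for x, y in pairing])
        assert np.allclose(fwd["log2_fc"].to_numpy(), -rev["log2_fc"].to_numpy())

    def test_cross_run_pair_rejected(self):
        a = norm_frame({"a1": [1.0, 2.0]}, run_of={"a1": 1})
        b = norm_frame({"b1": [1.0, 2.0]}, run_of={"b1": 2})
        with pytest.raises(QCError, match="crosses runs"):
            pairwise_fold_changes(a, b, pairing=[("a1", "b1")])

    def test_default_pairing_gives_six_comparisons(self, panel_pair):
        norm_A, norm_B, _ = noise_free_panels(panel_pair)
        fc = pairwise_fold_changes(norm_A, norm_B)
        assert fc["pair"].nunique() == 6

    def test_noise_free_recovers_truth_exactly(self, panel_pair):
        norm_A, norm_B, _ = noise_free_panels(panel_pair)
        fc = pairwise_fold_changes(norm_A, norm_B)
        obs = 2.0 ** fc.groupby("standard_id")["log2_fc"].mean()
        for sid, expected in panel_pair.expected_fc.items():
            assert obs[sid] == pytest.approx(expected, rel=1e-12)


class TestAccuracy:
    def test_exact_and_boundary(self):
        fc = pd.DataFrame(
            dict(feature_id=["f1", "f2"], standard_id="s1", pair="pair1",
                 log2_fc=[0.0, math.log2(1.1)], observed_fc=[1.0, 1.1])
        )
        res = fc_accuracy(fc, {"s1": 1.0}, tolerance=0.10)
        assert res["fraction_within"].iloc[0] == 1.0  # 1.1 vs 1.0 inclusive

    def test_monte_carlo_matches_normal_cdf(self):
        """Lognormal FC errors: the within-10% rate follows the Normal CDF."""
        rng = np.random.default_rng(7)
        n = 20_000
        sd = 0.05
        z = rng.normal(0, sd, n)
        fc = pd.DataFrame(
            dict(feature_id=[f"f{i}" for i in range(n)], standard_id="s1",
                 pair="pair1", log2_fc=z, observed_fc=2.0**z)
        )
        res = fc_accuracy(fc, {"s1": 1.0}, tolerance=0.10)
        expected = stats.norm.cdf(math.log2(1.1) / sd) - stats.norm.cdf(
            math.log2(0.9) / sd
        )
        assert res["fraction_within"].iloc[0] == pytest.approx(expected, abs=0.01)

    def test_missing_truth_rejected(self):
        fc = pd.DataFrame(
            dict(feature_id=["f1"], standard_id="s9", pair="p", log2_fc=[0.0],
                 observed_fc=[1.0])
        )
        with pytest.raises(QCError):
            fc_accuracy(fc, {"s1": 1.0})


class TestWelch:
    def test_conventions(self):
        a = np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0]])
        b = np.array([[1.0, 1.0, 1.0], [5.0, 5.0, 5.0]])
        p = welch_pvalues(a, b)
        assert p[0] == 1.0  # identical, zero variance
        assert p[1] == 0.0  # separated, zero variance

    def test_separated_with_jitter(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1e-3, size=(1, 6))
        b = 5.0 + rng.normal(0.0, 1e-3, size=(1, 6))
        assert welch_pvalues(a, b)[0] < 1e-6

    def test_matches_scipy_on_regular_data(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(50, 6))
        b = rng.normal(0.3, 1.2, size=(50, 6))
        mine = welch_pvalues(a, b)
        ref = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        assert np.allclose(mine, ref, atol=1e-12)

    def test_type_one_error_near_nominal(self):
        """Null simulation: rejection rate at alpha = 0.05 is ~5%."""
        rng = np.random.default_rng(3)
        a = rng.normal(size=(10_000, 6))
        b = rng.normal(size=(10_000, 6))
        rate = (welch_pvalues(a, b) < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.01)


class TestVolcano:
    @pytest.mark.parametrize(
        "lfc,p,cutoff,expected",
        [
            (math.log2(2.0), 0.01, 2.0, True),  # fc boundary inclusive
            (math.log2(4.0), 0.05, 2.0, False),  # p boundary exclusive
            (math.log2(1.4), 0.001, 1.5, False),
            (-math.log2(3.0), 0.01, 2.0, True),  # down-regulation counts
        ],
    )
    def test_boundaries(self, lfc, p, cutoff, expected):
        call = volcano_classify(np.array([lfc]), np.array([p]), cutoff)
        assert bool(call[0]) is expected

    def test_cutoff_monotone(self):
        rng = np.random.default_rng(4)
        lfc = rng.normal(0, 1.5, 500)
        p = rng.uniform(0, 1, 500)
        prev = None
        for cutoff in (1.1, 1.5, 2.0, 3.0):
            calls = volcano_classify(lfc, p, cutoff)
            if prev is not None:
                assert not np.any(calls & ~prev)  # raising cutoff never adds DEGs
            prev = calls

    def test_bad_cutoff(self):
        with pytest.raises(QCError):
            volcano_classify(np.array([0.0]), np.array([0.5]), 0.9)


class TestConfusion:
    def test_perfect_and_all_deg(self, panel_pair):
        standards = pd.Series(
            np.repeat(list(panel_pair.expected_fc), 100),
            index=[f"f{i}" for i in range(800)],
        )
        truth_deg = standards.map(lambda s: panel_pair.expected_fc[s] != 1.0)
        perfect = confusion_vs_truth(truth_deg, standards, panel_pair.expected_fc)
        assert (perfect.tp, perfect.tn, perfect.fp, perfect.fn) == (400, 400, 0, 0)
        all_deg = confusion_vs_truth(
            pd.Series(True, index=standards.index), standards, panel_pair.expected_fc
        )
        assert all_deg.fp == 400 and all_deg.fn == 0

    def test_noise_free_cutoff_two_loses_only_the_1p5_standard(self, panel_pair):
        norm_A, norm_B, _ = noise_free_panels(panel_pair)
        comp = PanelComparison(norm_A, norm_B, panel_pair.expected_fc).fit()
        m = comp.confusions[2.0]
        assert m.fn == 100 and m.fn_by_standard == {"ERCC-99": 100}
        assert m.fp == 0
        assert m.tp == 300 and m.tn == 400

    def test_noise_free_any_cutoff_matches_rule(self, panel_pair):
        norm_A, norm_B, _ = noise_free_panels(panel_pair)
        for cutoff in (1.2, 1.4, 1.6, 2.5, 4.9, 5.0):
            comp = PanelComparison(
                norm_A, norm_B, panel_pair.expected_fc, fc_cutoffs=(cutoff,)
            ).fit()
            m = comp.confusions[cutoff]
            lc = math.log2(cutoff)
            exp_tp = sum(
                100
                for fc in panel_pair.expected_fc.values()
                if fc != 1.0 and abs(math.log2(fc)) >= lc - 1e-12
            )
            exp_fn = 400 - exp_tp
            assert (m.tp, m.fn, m.fp, m.tn) == (exp_tp, exp_fn, 0, 400)


class TestConcordance:
    def test_identity_and_affine(self):
        fc = {"a": 2.0, "b": 0.5, "c": 1.0, "d": 4.0}
        slope, r = platform_concordance(fc, fc)
        assert slope == pytest.approx(1.0) and r == pytest.approx(1.0)
        squared = {k: v**2 for k, v in fc.items()}
        slope2, r2 = platform_concordance(fc, squared)
        assert slope2 == pytest.approx(2.0) and r2 == pytest.approx(1.0)

    def test_joint_simulation_concordant(self, panel_pair):
        """Default-noise array and qPCR simulations agree on fold changes."""
        from spikeqc import (
            ArraySimParams,
            QpcrSimParams,
            normalize_75th,
            simulate_panel_pair_qpcr,
        )
        from spikeqc.qpcr import panel_fold_changes

        arr = simulate_panel_pair_microarray(panel_pair, ArraySimParams(seed=21), n_runs=3)
        normalized = normalize_75th(arr.intensities)
        probes = normalized[normalized["standard_id"].isin(panel_pair.expected_fc)]
        comp = PanelComparison(
            probes[probes["sample"] == "A"],
            probes[probes["sample"] == "B"],
            panel_pair.expected_fc,
        ).fit()
        qds = simulate_panel_pair_qpcr(panel_pair, QpcrSimParams(seed=21), n_runs=3)
        qfc = panel_fold_changes(qds.cts, 0.9)
        qmean = (2.0 ** qfc.groupby("assay_id")["log2_fc"].mean()).to_dict()
        slope, r = platform_concordance(comp.per_standard_fc(), qmean)
        assert r >= 0.9

    def test_zero_variance_undefined(self):
        with pytest.raises(QCError):
            platform_concordance({"a": 1.0, "b": 1.0, "c": 1.0}, {"a": 1.0, "b": 1.0, "c": 1.0})
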