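"""RNA calibration chain: RPK, correction factors, spike and anchor fits."""

import numpy as np
import pandas as pd
import pytest

from absquant import rna
from absquant.core import bootstrap_fold_error, predict_copies
from absquant.simulate import (
    SimulationConfig,
    generate_catalog,
    generate_ncounter,
    generate_readcounts,
    generate_simulated_reads,
    generate_truth,
)


def table(reads, lengths, sample="s"):
    ids = [f"f{i}" for i in range(len(reads))]
    return rna.ReadCountTable(sample, pd.DataFrame({"reads": reads, "length_nt": lengths}, index=ids))


class TestRpk:
    @pytest.mark.parametrize(
        "reads,length,expected",
        [(1000, 2000, 500.0), (0, 750, 0.0), (100, 500, 200.0)],
    )
    def test_examples(self, reads, length, expected):
        assert rna.compute_rpk(reads, length) == pytest.approx(expected)

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            rna.compute_rpk(10, 0)


class TestMappabilityFactors:
    def test_uniform_coverage_all_ones(self):
        sim = table([100, 200, 300], [1000, 2000, 3000])
        f = rna.mappability_factors(sim)
        np.testing.assert_allclose(f.factors, 1.0)

    def test_half_coverage_factor_half(self):
        # 5 features, one with half the RPK of the others
        sim = table([100, 100, 100, 100, 50], [1000] * 5)
        f = rna.mappability_factors(sim)
        assert f.factors["f4"] == pytest.approx(0.5)
        assert f.factors["f0"] == pytest.approx(1.0)

    def test_absent_feature_unquantifiable(self):
        sim = table([100, 0, 100], [1000] * 3)
        f = rna.mappability_factors(sim)
        assert "f1" in f.unquantifiable
        assert "f1" not in f.factors.index

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rna.mappability_factors(table([], []))

    def test_median_centering_invariant(self):
        sim = table([10, 40, 90, 160, 250], [1000] * 5)
        f = rna.mappability_factors(sim)
        assert np.median(f.factors) == pytest.approx(1.0)

    def test_correction_idempotent(self):
        """Factors computed from already-corrected data are all 1."""
        sim = table([10, 40, 90, 160, 250], [1000] * 5)
        f = rna.mappability_factors(sim)
        corrected = rna.apply_correction(sim.rpk(), f)
        sim2 = rna.ReadCountTable(
            "c", pd.DataFrame({"reads": corrected, "length_nt": 1000}, index=corrected.index)
        )
        f2 = rna.mappability_factors(sim2)
        np.testing.assert_allclose(f2.factors, 1.0)


class TestApplyCorrection:
    def test_identity_and_scaling(self):
        factors = rna.CorrectionFactors(
            factors=pd.Series({"a": 1.0, "b": 0.5}), unquantifiable=pd.Index([])
        )
        raw = pd.Series({"a": 100.0, "b": 100.0})
        out = rna.apply_correction(raw, factors)
        assert out["a"] == 100.0
        assert out["b"] == 200.0

    def test_missing_factor_dropped_with_warning(self):
        factors = rna.CorrectionFactors(factors=pd.Series({"a": 1.0}), unquantifiable=pd.Index(["b"]))
        with pytest.warns(UserWarning, match="without a correction factor"):
            out = rna.apply_correction(pd.Series({"a": 1.0, "b": 2.0}), factors)
        assert list(out.index) == ["a"]


class TestSequencibility:
    def test_identical_tables_unit_ratio(self):
        t = table([10, 20, 30], [1000] * 3)
        out = rna.sequencibility(t, t)
        np.testing.assert_allclose(out["ratio"], 1.0)

    def test_duplicated_feature_ratio_two(self):
        sim = table([10, 10, 10, 10, 10], [1000] * 5)
        dna = table([10, 10, 20, 10, 10], [1000] * 5)
        out = rna.sequencibility(dna, sim)
        assert out.loc["f2", "ratio"] == pytest.approx(2.0)
        assert out.loc["f2", "flag"] == "ok"  # 2.0 is not > 2

    def test_flags(self):
        sim = table([10, 10, 10, 10], [1000] * 4)
        dna = table([10, 2, 50, 0], [1000] * 4)
        out = rna.sequencibility(dna, sim)
        assert out.loc["f1", "flag"] == "low"
        assert out.loc["f2", "flag"] == "high"

    def test_zero_simulated_undefined(self):
        sim = table([10, 0], [1000, 1000])
        dna = table([10, 10], [1000, 1000])
        out = rna.sequencibility(dna, sim)
        assert out.loc["f1", "flag"] == "undefined"
        assert np.isnan(out.loc["f1", "ratio"])


class TestCalibrateSpikes:
    @staticmethod
    def _run(counts, spikes, anchors, reps=("rep1",)):
        df = pd.DataFrame({r: counts for r in reps})
        return rna.NCounterRun(
            counts=df,
            spike_copies=spikes,
            anchor_ids=anchors,
            run_of_replicate={r: "run1" for r in reps},
        )

    def test_noiseless_linear(self):
        spikes = pd.Series({"s1": 1.0, "s2": 10.0, "s3": 100.0})
        counts = pd.Series({"s1": 10.0, "s2": 100.0, "s3": 1000.0, "a1": 50.0})
        run = self._run(counts, spikes, ["a1"])
        est, _ = rna.calibrate_spikes(run)
        assert est["a1"] == pytest.approx(5.0, rel=1e-12)

    def test_power_law_recovered(self):
        g, b = 7.0, 1.3
        copies = np.array([1.0, 5.0, 25.0, 125.0])
        spikes = pd.Series(copies, index=[f"s{i}" for i in range(4)])
        counts = pd.concat([pd.Series(g * copies**b, index=spikes.index), pd.Series({"a1": g * 50.0**b})])
        run = self._run(counts, spikes, ["a1"])
        est, _ = rna.calibrate_spikes(run)
        assert est["a1"] == pytest.approx(50.0, rel=1e-10)

    def test_zero_count_spike_excluded(self):
        spikes = pd.Series({"s1": 1.0, "s2": 10.0, "s3": 100.0, "s4": 1000.0})
        counts = pd.Series({"s1": 0.0, "s2": 100.0, "s3": 1000.0, "s4": 10000.0, "a1": 500.0})
        run = self._run(counts, spikes, ["a1"])
        with pytest.warns(UserWarning, match="zero counts"):
            est, _ = rna.calibrate_spikes(run)
        assert est["a1"] == pytest.approx(50.0, rel=1e-10)

    def test_too_few_spikes_fails(self):
        spikes = pd.Series({"s1": 1.0, "s2": 10.0, "s3": 100.0})
        counts = pd.Series({"s1": 0.0, "s2": 100.0, "s3": 1000.0, "a1": 500.0})
        run = self._run(counts, spikes, ["a1"])
        with pytest.raises(ValueError, match="fewer than 3"), pytest.warns(UserWarning):
            rna.calibrate_spikes(run)

    def test_monte_carlo_anchor_recovery(self, default_truth):
        """13 noisy spikes (CV 0.2) recover anchors well under 1.5-fold error."""
        fold = []
        for seed in range(50):
            run = generate_ncounter(default_truth, SimulationConfig(seed=seed, ncounter_cv=0.2))
            est, _ = rna.calibrate_spikes(run)
            true = default_truth.rna.loc[est.index, "proliferating"]
            fold.append(np.exp(np.abs(np.log(est / true))).mean())
        assert np.mean(fold) < 1.5


class TestAnchorModel:
    def test_exact_line(self):
        scores = pd.Series(np.geomspace(1, 1e4, 10), index=[f"a{i}" for i in range(10)])
        model = rna.fit_anchor_model(scores, scores)  # slope 1, intercept 0
        assert model.slope == pytest.approx(1.0, abs=1e-12)
        assert model.intercept == pytest.approx(0.0, abs=1e-10)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("base", [2.0, np.e])
    def test_distortion_recovered_exactly(self, base):
        rng = np.random.default_rng(0)
        copies = pd.Series(rng.lognormal(1, 2, 49), index=[f"a{i}" for i in range(49)])
        # scores generated from copies by inverting a slope-0.9/intercept-2 law
        slope, intercept = 0.9, 2.0
        scores = np.exp((np.log(copies) - intercept) / slope)
        model = rna.fit_anchor_model(scores, copies, log_base=base)
        # slope is base-invariant; intercept scales with the base change
        assert model.slope == pytest.approx(slope, abs=1e-9)
        assert model.intercept * np.log(base) == pytest.approx(intercept, abs=1e-9)

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(1)
        errs = []
        for _ in range(100):
            copies = pd.Series(rng.lognormal(1, 2, 49), index=[f"a{i}" for i in range(49)])
            scores = copies * np.exp(rng.normal(0, 0.3, 49))
            model = rna.fit_anchor_model(scores, copies)
            errs.append(model.slope)
        assert np.mean(errs) == pytest.approx(1.0, rel=0.05)

    def test_zero_score_anchor_excluded(self):
        scores = pd.Series({"a": 0.0, "b": 1.0, "c": 10.0, "d": 100.0})
        copies = pd.Series({"a": 1.0, "b": 1.0, "c": 10.0, "d": 100.0})
        with pytest.warns(UserWarning, match="excluding"):
            model = rna.fit_anchor_model(scores, copies)
        assert model.n_anchors == 3


class TestPredict:
    def test_anchor_score_roundtrip(self):
        scores = pd.Series(np.geomspace(1, 1e3, 5), index=list("abcde"))
        copies = 3.0 * scores**1.1
        model = rna.fit_anchor_model(scores, copies)
        out = predict_copies(model, scores)
        np.testing.assert_allclose(out.copies, copies, rtol=1e-10)

    def test_zero_score_not_detected(self):
        scores = pd.Series(np.geomspace(1, 1e3, 5), index=list("abcde"))
        model = rna.fit_anchor_model(scores, scores)
        out = predict_copies(model, pd.Series({"x": 0.0, "y": 10.0}))
        assert not out.detected["x"]
        assert np.isnan(out.copies["x"])
        assert out.detected["y"]

    def test_log_base_invariance(self):
        rng = np.random.default_rng(2)
        copies = pd.Series(rng.lognormal(1, 1.5, 20), index=[f"a{i}" for i in range(20)])
        scores = copies * np.exp(rng.normal(0, 0.2, 20))
        m_e = rna.fit_anchor_model(scores, copies, log_base=np.e)
        m_2 = rna.fit_anchor_model(scores, copies, log_base=2.0)
        query = pd.Series(np.geomspace(0.01, 1e4, 50))
        np.testing.assert_allclose(m_e.predict(query), m_2.predict(query), rtol=1e-12)

    def test_negative_scores_rejected(self):
        scores = pd.Series(np.geomspace(1, 1e3, 5))
        model = rna.fit_anchor_model(
            pd.Series([1.0, 10, 100], index=list("abc")), pd.Series([1.0, 10, 100], index=list("abc"))
        )
        with pytest.raises(ValueError):
            model.predict(pd.Series([-1.0]))


class TestBootstrap:
    def test_perfect_fit_fold_error_one(self):
        scores = pd.Series(np.geomspace(1, 1e3, 10), index=[f"a{i}" for i in range(10)])
        est = bootstrap_fold_error(scores, 2.0 * scores, n_resamples=200, rng=np.random.default_rng(0))
        assert est.mean_fold_error == pytest.approx(1.0, abs=1e-9)

    def test_fold_errors_at_least_one(self, rng):
        scores = pd.Series(rng.lognormal(0, 2, 30), index=[f"a{i}" for i in range(30)])
        copies = scores * np.exp(rng.normal(0, 0.5, 30))
        est = bootstrap_fold_error(scores, copies, n_resamples=200, rng=rng)
        assert (est.fold_errors >= 1.0 - 1e-12).all()
        assert est.mean_fold_error >= 1.0

    def test_resample_minimum(self):
        scores = pd.Series([1.0, 10, 100], index=list("abc"))
        with pytest.raises(ValueError, match="at least 100"):
            bootstrap_fold_error(scores, scores, n_resamples=10)


class TestDetectionStability:
    def test_positive_reads_always_detected(self, small_config):
        cat = generate_catalog(small_config)
        truth = generate_truth(cat, small_config)
        rc = generate_readcounts(truth, cat, small_config)
        sim = generate_simulated_reads(cat, small_config)
        factors = rna.mappability_factors(sim)
        corrected = rna.apply_correction(rc.rpk(), factors)
        model = rna.fit_anchor_model(
            corrected.iloc[:30], truth.rna.loc[corrected.index[:30], "proliferating"]
        )
        out = predict_copies(model, corrected)
        positive = rc.data.loc[corrected.index, "reads"] > 0
        assert out.detected[positive].all()
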