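import numpy as np
import pytest

from screensift import (
    CascadeConfig,
    Classification,
    SimConfig,
    classify_fold_table,
    evaluate_recovery,
    run_screen_pipeline,
    score_bundle,
    simulate_deconvolution,
    simulate_screen,
    simulate_timecourse,
)
from screensift.errors import ConfigError, CrossReferenceError
from screensift.io import write_bundle
from screensift.pipeline import mean_control_ratio
from screensift.scoring import normalize_plate
from screensift.simulate import SimTruth, RecoveryStats


class TestSimConfig:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ConfigError, match="sum"):
            SimConfig(seed=1, proportions={
                "true_rescuer": 0.5, "offtarget_single": 0.2,
                "dox_inhibitor": 0.2, "null": 0.2,
            })

    def test_missing_class_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=1, proportions={"true_rescuer": 1.0})

    def test_kill_fraction_range(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=1, kill_fraction=1.5)


class TestSimulateScreen:
    def test_noiseless_ratio_arithmetic(self):
        # One rescuer at survival 0.60, kill 0.05, no noise: on a
        # majority-null plate the plate median is the kill signal, so the
        # rescuer's normalized ratio is 0.60 / 0.05 = 12 exactly.
        cfg = SimConfig(
            seed=5,
            n_genes=100,
            n_replicates=1,
            kill_fraction=0.05,
            rescue_range=(0.60, 0.60),
            proportions={
                "true_rescuer": 0.01, "offtarget_single": 0.0,
                "dox_inhibitor": 0.0, "null": 0.99,
            },
            well_cv=0.0,
            plate_scale_sd=0.0,
        )
        sim = simulate_screen(cfg)
        (plate_id, rep), layout = next(iter(sim.dux4.layouts.items()))
        plate = normalize_plate(sim.dux4.measurements.for_plate(plate_id, rep), layout)
        rescuer_gene = sim.truth.genes_with_label("true_rescuer").pop()
        pool = sim.truth.records[rescuer_gene].pool_id
        well = next(w for w, wl in layout.wells.items() if wl.content_id == pool)
        assert plate.ratios[well] == pytest.approx(12.0)

    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=99, n_genes=50)
        a, b = simulate_screen(cfg), simulate_screen(cfg)
        write_bundle(a.dux4, tmp_path / "a")
        write_bundle(b.dux4, tmp_path / "b")
        for name in ("layout.tsv", "measurements.tsv", "library.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        assert a.truth.to_frame().equals(b.truth.to_frame())

    def test_different_seeds_differ(self):
        a = simulate_screen(SimConfig(seed=1, n_genes=50))
        b = simulate_screen(SimConfig(seed=2, n_genes=50))
        assert not a.dux4.measurements.table["signal"].equals(
            b.dux4.measurements.table["signal"]
        )

    def test_class_counts_exact(self, default_sim):
        truth = default_sim.truth
        assert len(truth.genes_with_label("true_rescuer")) == 20
        assert len(truth.genes_with_label("offtarget_single")) == 10
        assert len(truth.genes_with_label("dox_inhibitor")) == 10
        assert len(truth.genes_with_label("null")) == 960

    def test_scrambled_controls_track_kill_fraction(self, default_sim):
        # Induced channel: scrambled wells sit at the kill fraction, and the
        # plate median is null-dominated, so their mean ratio is ~1.
        ratio = mean_control_ratio(default_sim.dux4)
        assert ratio == pytest.approx(1.0, rel=0.05)
        counter_ratio = mean_control_ratio(default_sim.counter)
        assert counter_ratio == pytest.approx(1.0, rel=0.05)

    def test_rescuers_are_expressed(self, default_sim):
        for gene in default_sim.truth.genes_with_label("true_rescuer"):
            rec = default_sim.truth.records[gene]
            assert not rec.low_expression
            assert max(rec.fpkm) > 0.5


class TestPipelineRecovery:
    def test_default_recovery(self, default_sim):
        sim = default_sim
        folds = simulate_deconvolution(sim.truth, cv=0.10, seed=18)
        report = run_screen_pipeline(
            sim.dux4, sim.counter, sim.expression, CascadeConfig(), folds
        )
        stats = evaluate_recovery(report, sim.truth)
        assert stats.sensitivity >= 0.9
        assert stats.fdr <= 0.1
        assert stats.total == sim.config.n_genes

    def test_dox_inhibitors_eliminated_by_counterscreen(self, default_sim):
        sim = default_sim
        report = run_screen_pipeline(sim.dux4, sim.counter, sim.expression)
        failed_counter = {
            v.gene for v in report.verdicts if not v.counter_pass
        }
        dox = sim.truth.genes_with_label("dox_inhibitor")
        scored_dox = {v.gene for v in report.verdicts} & dox
        assert scored_dox  # inhibitors score as primary hits
        assert len(failed_counter & scored_dox) / len(scored_dox) >= 0.9

    def test_low_expression_eliminated_at_rate_one(self, default_sim):
        # Expression is noiseless: every planted low-expression gene fails
        # the expression filter whenever it reaches that stage.
        from screensift.filtering import apply_expression_filter

        low = {
            g for g, r in default_sim.truth.records.items() if r.low_expression
        }
        result = apply_expression_filter(low, default_sim.expression, 0.5)
        assert result.eliminated == low

    def test_noise_sweep_keeps_recovery(self):
        # Simulator property: recovery holds across the plausible noise range.
        for cv in (0.05, 0.20):
            sim = simulate_screen(SimConfig(seed=17, n_genes=300, well_cv=cv))
            report = run_screen_pipeline(sim.dux4, sim.counter, sim.expression)
            stats = evaluate_recovery(report, sim.truth)
            assert stats.sensitivity >= 0.9, cv


class TestSimulateDeconvolution:
    def test_noiseless_offtarget(self):
        sim = simulate_screen(SimConfig(seed=11, n_genes=100))
        folds = simulate_deconvolution(sim.truth, cv=0.0, seed=0)
        results = classify_fold_table(folds)
        for gene in sim.truth.genes_with_label("offtarget_single"):
            rec = sim.truth.records[gene]
            assert results[rec.pool_id].classification is Classification.SINGLE_DOMINANT

    def test_noiseless_rescuers_multi_or_synergy(self):
        sim = simulate_screen(SimConfig(seed=11, n_genes=100))
        folds = simulate_deconvolution(sim.truth, cv=0.0, seed=0)
        results = classify_fold_table(folds)
        for gene in sim.truth.genes_with_label("true_rescuer"):
            rec = sim.truth.records[gene]
            assert results[rec.pool_id].classification in (
                Classification.ON_TARGET_MULTI,
                Classification.ON_TARGET_SYNERGY,
            )

    def test_accuracy_against_truth(self):
        sim = simulate_screen(SimConfig(seed=7, n_genes=100))
        folds = simulate_deconvolution(sim.truth, cv=0.15, seed=7)
        results = classify_fold_table(folds)
        correct = sum(
            results[r.pool_id].classification is r.expected_deconv
            for r in sim.truth.records.values()
        )
        assert correct / len(sim.truth.records) >= 0.95


class TestSimulateTimecourse:
    def test_noiseless_values(self):
        tc = simulate_timecourse(60.0, [0, 60, 120], cv=0.0, seed=0)
        np.testing.assert_allclose(tc.abundances, [1.0, 0.5, 0.25])

    def test_non_decaying(self):
        tc = simulate_timecourse(None, [0, 60, 120], cv=0.0, seed=0)
        np.testing.assert_allclose(tc.abundances, 1.0)

    def test_first_point_normalized(self):
        tc = simulate_timecourse(44.0, [0, 30, 60], cv=0.2, seed=4)
        assert tc.abundances[0] == 1.0

    def test_bad_half_life(self):
        with pytest.raises(ConfigError):
            simulate_timecourse(-5.0, [0, 30, 60])


def brute_force_confusion(positives, truth):
    counts = {}
    for gene, rec in truth.records.items():
        counts.setdefault(rec.label, {"positive": 0, "negative": 0})
        counts[rec.label]["positive" if gene in positives else "negative"] += 1
    return counts


class TestEvaluateRecovery:
    def make_truth(self, labels):
        from screensift.simulate import TruthRecord

        return SimTruth(
            {
                f"G{i}": TruthRecord(
                    gene=f"G{i}", pool_id=f"P{i}", label=label, survival=0.5,
                    sirna_folds=(1.0, 1.0), triple_fold=1.0,
                    expected_deconv=Classification.NO_RESCUE,
                    fpkm=(1.0, 1.0), low_expression=False,
                )
                for i, label in enumerate(labels)
            }
        )

    def test_perfect_verdicts(self):
        truth = self.make_truth(["true_rescuer", "true_rescuer", "null"])
        stats = evaluate_recovery({"G0": True, "G1": True, "G2": False}, truth)
        assert stats.sensitivity == 1.0 and stats.fdr == 0.0

    def test_zero_positives_convention(self):
        truth = self.make_truth(["true_rescuer", "null"])
        stats = evaluate_recovery(set(), truth)
        assert stats.sensitivity == 0.0 and stats.fdr == 0.0

    def test_identifier_mismatch(self):
        truth = self.make_truth(["null"])
        with pytest.raises(CrossReferenceError):
            evaluate_recovery({"GHOST"}, truth)

    def test_confusion_matches_brute_force(self):
        rng = np.random.default_rng(123)
        labels = rng.choice(
            ["true_rescuer", "offtarget_single", "dox_inhibitor", "null"], size=50
        )
        truth = self.make_truth(list(labels))
        positives = {f"G{i}" for i in rng.choice(50, size=17, replace=False)}
        stats = evaluate_recovery(positives, truth)
        expected = brute_force_confusion(positives, truth)
        for label, counts in expected.items():
            assert stats.confusion[label] == counts
        assert stats.total == 50
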