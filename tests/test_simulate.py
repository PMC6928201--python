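"""The synthetic-data generator: schedules, trajectories, noise structure."""

import numpy as np
import pandas as pd
import pytest

from maternome.exceptions import ConfigError
from maternome.simulate import (
    GA_WINDOWS,
    SimulationConfig,
    simulate_detection,
    simulate_expression,
    simulate_ga_schedule,
    simulate_proteins,
    trajectory_mean,
    true_fold_change,
)


class TestSchedule:
    def test_study_design_invariants(self):
        config = SimulationConfig(n_subjects=49, seed=1)
        schedule = simulate_ga_schedule(config)
        for _subj, grp in schedule.data.groupby("subject_id"):
            assert 4 <= len(grp) <= 6
            ga = grp["ga_weeks"].to_numpy()
            assert (np.diff(ga) > 0).all()
            # each draw falls inside one of the six windows
            for t in ga:
                assert any(lo <= t < hi or (hi == 41.0 and t <= 41.0)
                           for lo, hi in GA_WINDOWS)
        assert schedule.data["labor_at_draw"].sum() == 21

    def test_six_samples_covers_every_window(self):
        config = SimulationConfig(n_subjects=5, samples_per_subject=(6, 6),
                                  n_labor_subjects=0, seed=2)
        schedule = simulate_ga_schedule(config)
        for _subj, grp in schedule.data.groupby("subject_id"):
            assert len(grp) == 6

    def test_deterministic_given_seed(self):
        a = simulate_ga_schedule(SimulationConfig(seed=9)).data
        b = simulate_ga_schedule(SimulationConfig(seed=9)).data
        pd.testing.assert_frame_equal(a, b)


class TestTrajectory:
    def test_closed_forms(self):
        assert trajectory_mean("increasing", 1.0, 40.0) == 1.0
        assert trajectory_mean("u_shape", 1.0, 25.0) == 0.0
        assert trajectory_mean("null", 1.0, 33.0) == 0.0
        assert trajectory_mean("decreasing", 2.0, 40.0) == -2.0

    def test_unknown_class_rejected(self):
        with pytest.raises(ConfigError):
            trajectory_mean("sigmoid", 1.0, 20.0)

    @pytest.mark.parametrize("cls", ["null", "increasing", "decreasing", "u_shape"])
    @pytest.mark.parametrize("amplitude", [0.5, 0.585, 1.0])
    def test_true_fc_matches_grid_evaluation(self, cls, amplitude):
        grid = np.linspace(10, 40, 301)
        values = trajectory_mean(cls, amplitude, grid)
        expected = 2.0 ** (values.max() - values.min())
        assert abs(true_fold_change(cls, amplitude) - expected) < 1e-9

    def test_amplitude_0585_gives_fc_15(self):
        assert abs(true_fold_change("increasing", 0.585) - 1.5) < 1e-3


class TestExpression:
    def test_noiseless_null_gene_is_constant_baseline(self):
        config = SimulationConfig(n_subjects=5, n_genes=2,
                                  class_assignment=("null", "null"),
                                  sd_subject=0.0, sd_resid=0.0, n_batches=1,
                                  batch_effect_sd=0.0, n_labor_subjects=0, seed=3)
        schedule = simulate_ga_schedule(config)
        expr, truth = simulate_expression(config, schedule)
        for g, baseline in zip(expr.gene_ids, truth.genes["baseline"]):
            np.testing.assert_allclose(expr.data.loc[g], baseline, atol=1e-12)

    def test_null_gene_total_variance(self):
        """Row variance of a null gene ~ sd_subject^2 + sd_resid^2 (law of total variance)."""
        config = SimulationConfig(n_subjects=300, n_genes=1,
                                  class_assignment=("null",), sd_subject=0.5,
                                  sd_resid=0.5, n_batches=1, batch_effect_sd=0.0,
                                  n_labor_subjects=0, seed=4)
        schedule = simulate_ga_schedule(config)
        expr, _ = simulate_expression(config, schedule)
        var = expr.values[0].var()
        assert abs(var - 0.5) < 0.1

    def test_subject_intercept_variance_recovered(self):
        """Per-subject mean deviations have variance -> sd_subject^2 at 500 subjects."""
        config = SimulationConfig(n_subjects=500, n_genes=1,
                                  class_assignment=("null",), sd_subject=0.5,
                                  sd_resid=0.0, n_batches=1, batch_effect_sd=0.0,
                                  n_labor_subjects=0, seed=5)
        schedule = simulate_ga_schedule(config)
        expr, truth = simulate_expression(config, schedule)
        row = pd.Series(expr.values[0], index=expr.sample_ids)
        subj = schedule.data.set_index("sample_id")["subject_id"]
        deviations = row.groupby(subj).mean() - truth.genes["baseline"].iloc[0]
        assert abs(deviations.var() - 0.25) < 0.15 * 0.25


class TestDetection:
    def test_absent_and_expressed_calling(self):
        config = SimulationConfig(n_subjects=10, n_genes=20, absent_fraction=0.25,
                                  n_labor_subjects=0, seed=6)
        schedule = simulate_ga_schedule(config)
        expr, truth = simulate_expression(config, schedule)
        det = simulate_detection(config, expr, truth)
        present = (det.data.to_numpy() < 0.05)
        expressed = truth.genes["expressed"].to_numpy()
        assert (present[expressed].mean(axis=1) == 1.0).all()
        assert (present[~expressed].mean(axis=1) == 0.0).all()

    def test_absent_fraction_removed_by_filter(self):
        from maternome.preprocess import call_present
        config = SimulationConfig(n_subjects=20, n_genes=1000, absent_fraction=0.1,
                                  n_labor_subjects=0, seed=7)
        schedule = simulate_ga_schedule(config)
        expr, truth = simulate_expression(config, schedule)
        det = simulate_detection(config, expr, truth)
        retained = call_present(expr, det)
        assert len(retained) == 900


class TestProteins:
    def test_exact_linear_coupling_without_noise(self):
        config = SimulationConfig(n_subjects=20, n_genes=10, n_pairs=2,
                                  slope_true=1.0, sd_protein=0.0,
                                  sd_protein_subject=0.0, n_protein_subjects=4,
                                  n_protein_samples=1000, n_labor_subjects=0, seed=8)
        schedule = simulate_ga_schedule(config)
        expr, _ = simulate_expression(config, schedule)
        table, pair_truth = simulate_proteins(config, expr, schedule)
        coupled = pair_truth[pair_truth["true_slope"] == 1.0].iloc[0]
        rows = table.data[table.data["protein_id"] == coupled["protein_id"]]
        mrna = expr.data.loc[coupled["gene_id"], rows["sample_id"]].to_numpy()
        np.testing.assert_allclose(rows["abundance"].to_numpy(), mrna, atol=1e-12)

    def test_default_protein_layer_spans_16_subjects_71_samples(self):
        config = SimulationConfig(seed=9, n_genes=200)
        schedule = simulate_ga_schedule(config)
        expr, _ = simulate_expression(config, schedule)
        table, _ = simulate_proteins(config, expr, schedule)
        assert len(table.subject_ids) == 16
        assert table.data["sample_id"].nunique() == 71


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(n_subjects=1)
    with pytest.raises(ConfigError):
        SimulationConfig(class_proportions={"null": 0.5})
    with pytest.raises(ConfigError):
        SimulationConfig(sd_resid=-1.0)
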