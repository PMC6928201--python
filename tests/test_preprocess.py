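"""Detection filtering, labor-sample removal, batch correction, outlier rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maternome.datatypes import DetectionMatrix, ExpressionMatrix, SampleTable
from maternome.exceptions import AnalysisError
from maternome.preprocess import (
    call_present,
    correct_batch,
    detect_outlier_samples,
    preprocess,
    remove_labor_samples,
)
from maternome.simulate import SimulationConfig, simulate_expression, simulate_ga_schedule


def _pair(n_present_per_gene, n_samples=100):
    genes = [f"G{i}" for i in range(len(n_present_per_gene))]
    samples = [f"S{j}" for j in range(n_samples)]
    expr = ExpressionMatrix(pd.DataFrame(
        np.zeros((len(genes), n_samples)), index=genes, columns=samples))
    p = np.ones((len(genes), n_samples))
    for i, k in enumerate(n_present_per_gene):
        p[i, :k] = 0.01
    det = DetectionMatrix(pd.DataFrame(p, index=genes, columns=samples))
    return expr, det


class TestCallPresent:
    def test_strictly_more_than_quarter(self):
        expr, det = _pair([26, 25, 0])
        assert call_present(expr, det) == ["G0"]

    def test_all_absent_matrix(self):
        expr, det = _pair([0, 0])
        assert call_present(expr, det) == []

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 100), st.floats(0.0, 0.9), st.floats(0.0, 0.9))
    def test_monotone_in_fraction(self, k, f1, f2):
        """Raising the presence fraction never adds genes."""
        lo, hi = sorted([f1, f2])
        expr, det = _pair([k])
        assert set(call_present(expr, det, frac=hi)) <= set(call_present(expr, det, frac=lo))

    def test_axis_mismatch_rejected(self):
        expr, det = _pair([5])
        expr2 = ExpressionMatrix(expr.data.rename(index={"G0": "H0"}))
        with pytest.raises(Exception):
            call_present(expr2, det)


class TestRemoveLabor:
    def test_flagged_samples_dropped(self, tiny_expr, tiny_meta):
        expr2, meta2, removed = remove_labor_samples(tiny_expr, tiny_meta)
        assert removed == ["S4"]
        assert expr2.sample_ids == ["S1", "S2", "S3"]
        assert set(meta2.data["subject_id"]) == {"A", "B"}

    def test_no_flags_is_identity(self, tiny_expr, tiny_meta):
        meta = SampleTable(tiny_meta.data.assign(labor_at_draw=False))
        expr2, meta2, removed = remove_labor_samples(tiny_expr, meta)
        assert removed == [] and expr2.sample_ids == tiny_expr.sample_ids

    def test_emulated_cohort_count(self):
        """282-style design: the 21 labor draws leave 261 analysis samples."""
        config = SimulationConfig(seed=12, n_genes=5)
        schedule = simulate_ga_schedule(config)
        expr, _ = simulate_expression(config, schedule)
        n_total = expr.n_samples
        expr2, _, removed = remove_labor_samples(expr, schedule)
        assert len(removed) == 21
        assert expr2.n_samples == n_total - 21


def _batch_sim(sd_resid, seed=21, n_batches=3, batch_sd=1.0):
    config = SimulationConfig(n_subjects=30, n_genes=50, sd_resid=sd_resid,
                              sd_subject=0.0, n_batches=n_batches,
                              batch_effect_sd=batch_sd, absent_fraction=0.0,
                              n_labor_subjects=0, seed=seed)
    schedule = simulate_ga_schedule(config)
    expr, truth = simulate_expression(config, schedule)
    return config, schedule, expr, truth


class TestCorrectBatch:
    def test_single_batch_identity(self, tiny_expr, tiny_meta):
        corrected, offsets = correct_batch(tiny_expr, tiny_meta)
        np.testing.assert_allclose(corrected.values, tiny_expr.values)
        assert offsets == {"B1": 0.0}

    def test_pure_offsets_recovered_exactly(self):
        """No-noise additive batch effects are removed to numerical precision."""
        _, schedule, expr, truth = _batch_sim(sd_resid=0.0)
        corrected, offsets = correct_batch(expr, schedule)
        effect = dict(zip(truth.batches["batch"], truth.batches["effect"]))
        grand = np.mean(list(effect.values()))
        batch_of = schedule.data.set_index("sample_id")["batch"]
        clean = expr.values - np.array([effect[batch_of[s]] for s in expr.sample_ids])
        # the removable component is the centered batch effect; the grand mean
        # is unidentifiable and stays in the intercept
        np.testing.assert_allclose(corrected.values, clean + grand, atol=1e-8)
        for b in offsets:
            assert abs(offsets[b] - (effect[b] - grand)) < 1e-8

    def test_idempotent(self):
        _, schedule, expr, _ = _batch_sim(sd_resid=0.3)
        once, _ = correct_batch(expr, schedule)
        twice, _ = correct_batch(once, schedule)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)

    def test_batch_means_equalized_for_null_genes(self):
        _, schedule, expr, _ = _batch_sim(sd_resid=0.5, seed=22)
        corrected, _ = correct_batch(expr, schedule)
        batch_of = schedule.data.set_index("sample_id")["batch"]
        frame = pd.DataFrame(corrected.values.T, index=corrected.sample_ids)
        means = frame.groupby(batch_of).mean()
        n_min = schedule.data["batch"].value_counts().min()
        se = 0.5 / np.sqrt(n_min)
        spread = means.max(axis=0) - means.min(axis=0)
        assert (spread < 2 * 3 * se).mean() > 0.95


class TestOutliers:
    def test_iid_noise_produces_no_flags(self):
        rng = np.random.default_rng(30)
        expr = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(400, 40)),
            index=[f"G{i}" for i in range(400)],
            columns=[f"S{j}" for j in range(40)]))
        assert detect_outlier_samples(expr) == []

    def test_shifted_sample_flagged(self):
        rng = np.random.default_rng(31)
        values = rng.normal(size=(200, 40))
        values[:120, 0] -= 5.0  # one sample grossly low on 60% of genes
        expr = ExpressionMatrix(pd.DataFrame(
            values, index=[f"G{i}" for i in range(200)],
            columns=[f"S{j}" for j in range(40)]))
        assert detect_outlier_samples(expr) == ["S0"]

    def test_ties_split_equally(self):
        expr = ExpressionMatrix(pd.DataFrame(
            np.ones((5, 3)), index=[f"G{i}" for i in range(5)],
            columns=["S1", "S2", "S3"]))
        assert detect_outlier_samples(expr) == []


def test_full_chain_order_and_report():
    config = SimulationConfig(n_subjects=20, n_genes=200, absent_fraction=0.1,
                              n_labor_subjects=5, seed=33)
    schedule = simulate_ga_schedule(config)
    expr, truth = simulate_expression(config, schedule)
    from maternome.simulate import simulate_detection
    det = simulate_detection(config, expr, truth)
    expr2, meta2, report = preprocess(expr, det, schedule)
    assert report.genes_in == 200
    assert report.genes_retained == expr2.n_genes == 180
    assert len(report.samples_removed_labor) == 5
    assert set(expr2.sample_ids) == set(meta2.sample_ids)
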