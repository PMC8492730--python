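"""Exclusion rule, elementary statistics, pipeline contract, report tables."""

import dataclasses

import numpy as np
import pytest

import octa3d as o
from octa3d.stats import CohortTable, build_table1, build_table2

from conftest import small_geometry


def _record(i, group="diabetic", ssi=9.0, metrics=None, **kw):
    return o.EyeRecord(subject_id=f"s{i:03d}", group=group, age=30.0,
                       ssi=ssi, metrics=metrics, **kw)


def _metrics(vv=0.27, d3=9.3, scp=34.4, dvc=38.9, th=321.5, mv=2.89):
    return o.EyeMetrics(vv, d3, scp, dvc, th, mv)


class TestFilterBySSI:
    def test_boundary_at_seven(self):
        records = [_record(0, ssi=6.0), _record(1, ssi=6.99),
                   _record(2, ssi=7.0), _record(3, ssi=9.5)]
        kept = o.filter_by_ssi(records)
        assert [r.subject_id for r in kept] == ["s002", "s003"]

    def test_empty_and_identity(self):
        assert o.filter_by_ssi([]) == []
        recs = [_record(i, ssi=8.0) for i in range(3)]
        assert o.filter_by_ssi(recs) == recs


class TestShapiroWilk:
    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            o.shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            o.shapiro_wilk([3.0, 3.0, 3.0])

    def test_calibration_on_normal_samples(self):
        keep = sum(
            o.shapiro_wilk(np.random.default_rng(s).normal(size=500))[1] > 0.05
            for s in range(50)
        )
        assert keep >= 45  # >= 90% of draws look normal

    def test_power_against_uniform_samples(self):
        reject = sum(
            o.shapiro_wilk(np.random.default_rng(s).uniform(size=500))[1] < 0.05
            for s in range(50)
        )
        assert reject >= 45


class TestTTest:
    def test_pooled_variance_hand_computation(self):
        t, df, p = o.two_sample_ttest([1, 2, 3, 4], [3, 4, 5, 6])
        assert t == pytest.approx(-2.1909, abs=1e-4)
        assert df == 6

    def test_swapping_groups_flips_sign(self):
        t1, _, p1 = o.two_sample_ttest([1, 2, 3, 4], [3, 4, 5, 6])
        t2, _, p2 = o.two_sample_ttest([3, 4, 5, 6], [1, 2, 3, 4])
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_identical_groups_give_p_one(self):
        t, _, p = o.two_sample_ttest([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            o.two_sample_ttest([2, 2, 2], [2, 2, 2])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert o.pearson_corr(x, 2 * x)[0] == pytest.approx(1.0)
        assert o.pearson_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_five_point_definition_oracle(self):
        x = np.array([2.0, 4.0, 5.0, 7.0, 9.0])
        y = np.array([1.0, 3.0, 2.0, 6.0, 8.0])
        r, _ = o.pearson_corr(x, y)
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        oracle = cov / (x.std() * y.std())
        assert r == pytest.approx(oracle, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            o.pearson_corr([1, 1, 1], [1, 2, 3])


class TestRunPipeline:
    def test_deterministic(self, reduced_eye):
        _, structural, octa, _ = reduced_eye
        m1 = o.run_pipeline(structural, octa)
        m2 = o.run_pipeline(structural, octa)
        assert m1 == m2

    def test_missing_input_stage_tagged(self, reduced_eye):
        _, structural, octa, _ = reduced_eye
        with pytest.raises(o.PipelineStageError, match=r"\[inputs\]"):
            o.run_pipeline(None, octa)

    def test_mismatched_geometry_stage_tagged(self, reduced_eye):
        _, structural, _, _ = reduced_eye
        g = small_geometry(nx=10, ny=10, nz=30)
        other = o.OCTAVolume(np.zeros((30, 10, 10), np.uint8), g)
        with pytest.raises(o.PipelineStageError, match=r"\[inputs\]"):
            o.run_pipeline(structural, other)

    def test_density_recovers_combined_truth(self):
        cfg = o.SimEyeConfig(
            geometry=o.reduced_geometry(), target_fraction_scp=0.08,
            target_fraction_dvc=0.10, tail_strength=0.0, ssi=10.0, seed=17,
        )
        structural, octa, truth = o.simulate_eye(cfg)
        m = o.run_pipeline(structural, octa)
        # vessels live in 170 um of retina; compare against the realized
        # whole-retina fraction
        surf = truth.surfaces
        retina_vox = (surf.outer_depth - surf.ilm_depth).sum()
        true_pct = 100 * truth.vessel_mask.n_true / retina_vox
        assert m.perfusion_density_3d_pct == pytest.approx(true_pct, abs=1.5)


class TestCohortTable:
    def _table(self, n=4, offset=0.0):
        recs = []
        rng = np.random.default_rng(0)
        for i in range(n):
            jit = rng.normal(0, 0.2, 6)
            recs.append(_record(i, "diabetic", metrics=_metrics(
                0.27 + 0.01 * jit[0], 9.3 + jit[1] - offset, 34.4 + jit[2],
                38.9 + jit[3] - offset, 321 + jit[4], 2.89 + 0.01 * jit[5])))
        for i in range(n):
            jit = rng.normal(0, 0.2, 6)
            recs.append(_record(100 + i, "control", metrics=_metrics(
                0.29 + 0.01 * jit[0], 10.3 + jit[1], 34.3 + jit[2],
                41.0 + jit[3], 319 + jit[4], 2.87 + 0.01 * jit[5])))
        return CohortTable(recs)

    def test_low_ssi_record_rejected(self):
        with pytest.raises(o.ReportError):
            CohortTable([_record(0, ssi=6.5, metrics=_metrics())])

    def test_duplicate_subjects_rejected(self):
        with pytest.raises(o.ReportError):
            CohortTable([_record(0, metrics=_metrics()),
                         _record(0, metrics=_metrics())])

    def test_table1_structure_and_oracle(self):
        table = self._table()
        t1 = build_table1(table)
        assert len(t1) == 6
        vals = table.metric_values("dvc_density_2d_pct", "diabetic")
        row = t1.loc["DVC perfusion density (%)"]
        assert row.diabetic_mean == pytest.approx(vals.mean())
        assert row.diabetic_sd == pytest.approx(vals.std(ddof=1))
        fmt = build_table1(table, formatted=True)
        assert list(fmt.columns) == ["diabetic", "control", "p"]
        assert "±" in fmt.iloc[0, 0]

    def test_identical_groups_p_is_one(self):
        # groups identical to each other but with within-group spread
        recs = []
        for i, v in enumerate([-0.5, 0.0, 0.5]):
            m = _metrics(0.27 + 0.01 * v, 9.3 + v, 34.4 + v, 38.9 + v,
                         321.5 + v, 2.89 + 0.01 * v)
            recs.append(_record(i, "diabetic", metrics=m))
            recs.append(_record(100 + i, "control", metrics=m))
        t1 = build_table1(CohortTable(recs), formatted=True)
        assert (t1["p"] == "1.000").all()

    def test_row_order_invariance(self):
        table = self._table()
        rev = CohortTable(list(reversed(table.records)))
        a = build_table1(table)
        b = build_table1(rev)
        assert np.allclose(a[["diabetic_mean", "p"]], b[["diabetic_mean", "p"]])

    def test_missing_group_rejected(self):
        recs = [_record(i, "diabetic", metrics=_metrics()) for i in range(3)]
        with pytest.raises(o.ReportError):
            build_table1(CohortTable(recs))

    def test_table2_grid_and_missing_covariate(self):
        rng = np.random.default_rng(2)
        recs = [
            _record(i, "diabetic",
                    metrics=_metrics(vv=0.27 + 0.01 * rng.normal(),
                                     d3=9 + rng.normal(),
                                     scp=34 + rng.normal(),
                                     dvc=38 + rng.normal()),
                    hba1c=float(7 + rng.normal()), diabetes_duration=float(10 + i))
            for i in range(6)
        ]
        t2 = build_table2(CohortTable(recs))
        assert len(t2) == 8  # 4 metrics x 2 covariates
        assert set(t2.columns) == {"r", "p"}
        recs_nocov = [_record(i, "diabetic", metrics=_metrics()) for i in range(3)]
        with pytest.raises(o.ReportError):
            build_table2(CohortTable(recs_nocov))

    def test_metric_self_correlation_is_one(self):
        rng = np.random.default_rng(3)
        vals = 38 + rng.normal(size=6)
        r, _ = o.pearson_corr(vals, vals)
        assert r == pytest.approx(1.0)

    def test_independent_covariate_yields_null_correlations(self):
        # permuted covariate labels: |r| stays small, rejections near alpha
        rng = np.random.default_rng(4)
        rs, ps = [], []
        for _ in range(20):
            recs = [
                _record(i, "diabetic",
                        metrics=_metrics(dvc=38 + rng.normal(),
                                         d3=9 + rng.normal(),
                                         vv=0.27 + 0.01 * rng.normal(),
                                         scp=34 + rng.normal()),
                        hba1c=float(7 + rng.normal()),
                        diabetes_duration=float(rng.uniform(5, 30)))
                for i in range(35)
            ]
            t2 = build_table2(CohortTable(recs))
            rs.extend(np.abs(t2["r"]))
            ps.extend(t2["p"])
        assert np.median(rs) < 0.2
        assert np.mean(np.array(ps) < 0.05) < 0.15
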