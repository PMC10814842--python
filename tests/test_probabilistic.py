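"""Lognormal fitting, Monte-Carlo exposure sampling and percentile reports."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resrisk.deterministic import PopulationSubgroup, ToxicologyReference, edi, risk_quotient
from resrisk.probabilistic import (
    ExposureModel,
    ExposureSimulation,
    LognormalParams,
    expected_tail_count,
    fit_lognormal,
    parse_percentile_label,
    percentile_report,
    simulate_exposure,
    stratified_run,
)

GENERAL = PopulationSubgroup(name="general", bw=53.23, lp=0.570, fi=0.048)
CHILDREN = PopulationSubgroup(name="children", bw=16.14, lp=0.366, fi=0.030)


class TestFitLognormal:
    def test_constant_observations(self):
        params = fit_lognormal([0.2, 0.2, 0.2])
        assert params.mu == pytest.approx(math.log(0.2))
        assert params.sigma == 0.0
        assert params.n_fit == 3

    def test_recovers_mu_within_three_standard_errors(self):
        rng = np.random.default_rng(21)
        x = rng.lognormal(0.0, 0.5, size=2000)
        params = fit_lognormal(x)
        assert abs(params.mu) < 3 * 0.5 / math.sqrt(2000)
        assert params.sigma == pytest.approx(0.5, rel=0.1)

    def test_drop_policy_removes_censored(self):
        params = fit_lognormal([0.1, 0.2, 0.05, 0.05], censored=[False, False, True, True],
                               censor_policy="drop")
        assert params.n_fit == 2

    def test_half_loq_substitution_uses_stored_limit(self):
        # censored rows record the LOQ as value; half_loq halves it pre-transform
        params = fit_lognormal([0.05, 0.05], censored=[True, True], censor_policy="half_loq")
        assert params.mu == pytest.approx(math.log(0.025))

    def test_explicit_loq_overrides_stored_value(self):
        params = fit_lognormal([0.9, 0.9], censored=[True, True],
                               censor_policy="loq", loq=0.05)
        assert params.mu == pytest.approx(math.log(0.05))

    def test_nonpositive_after_substitution_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            fit_lognormal([0.0, 0.1, 0.2])

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_lognormal([0.1, 0.2, 0.3], censored=[False, True, True], censor_policy="drop")


class TestSimulateExposure:
    def _sim(self, n_iter=1000, seed=0, sx=0.0, sc=0.0, subgroup=GENERAL):
        return ExposureSimulation(
            subgroup=subgroup,
            consumption_dists=[LognormalParams(math.log(0.048), sx)],
            residue_dists=[LognormalParams(math.log(0.13), sc)],
            n_iter=n_iter,
            seed=seed,
        )

    def test_degenerate_distributions_are_deterministic(self):
        sim = simulate_exposure(self._sim())
        expected = 0.048 * 0.13 / GENERAL.bw
        np.testing.assert_allclose(sim.samples, expected)
        report = percentile_report(sim.samples, 0.03)
        assert len(set(report.values)) == 1  # flat report

    def test_seed_reproducibility(self):
        a = simulate_exposure(self._sim(sx=0.5, sc=0.3, seed=9))
        b = simulate_exposure(self._sim(sx=0.5, sc=0.3, seed=9))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_samples_positive_and_sized(self):
        sim = simulate_exposure(self._sim(n_iter=257, sx=0.4, sc=0.8, seed=1))
        assert sim.samples.shape == (257,)
        assert (sim.samples > 0).all()

    def test_closed_form_lognormal_product_quantile(self):
        sx, sc = 0.5, 0.3
        sim = simulate_exposure(self._sim(n_iter=100_000, sx=sx, sc=sc, seed=4))
        combined = LognormalParams(
            mu=math.log(0.048) + math.log(0.13) - math.log(GENERAL.bw),
            sigma=math.hypot(sx, sc),
        )
        p95 = np.quantile(sim.samples, 0.95)
        assert p95 == pytest.approx(combined.quantile(0.95), rel=0.02)

    def test_multi_food_exposure_sums(self):
        sim = ExposureSimulation(
            subgroup=GENERAL,
            consumption_dists=[LognormalParams(math.log(0.048), 0.0)] * 2,
            residue_dists=[LognormalParams(math.log(0.13), 0.0)] * 2,
            n_iter=10,
        )
        np.testing.assert_allclose(
            simulate_exposure(sim).samples, 2 * 0.048 * 0.13 / GENERAL.bw
        )

    def test_mismatched_food_lists_rejected(self):
        with pytest.raises(ValueError, match="pair per food"):
            ExposureSimulation(
                subgroup=GENERAL,
                consumption_dists=[LognormalParams(0.0, 0.1)],
                residue_dists=[],
            )


class TestExposureModel:
    def test_fit_then_sample_matches_closed_form(self):
        rng = np.random.default_rng(3)
        model = ExposureModel(n_iter=50_000, seed=5).fit(
            rng.lognormal(-3.0, 0.5, 800), rng.lognormal(-2.0, 0.4, 800)
        )
        samples = model.sample(GENERAL)
        assert np.quantile(samples, 0.95) == pytest.approx(
            model.exposure_quantile(GENERAL, 0.95), rel=0.05
        )

    def test_unfitted_model_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            ExposureModel().sample(GENERAL)

    def test_sklearn_param_interface(self):
        model = ExposureModel(n_iter=123)
        assert model.get_params()["n_iter"] == 123
        model.set_params(seed=7)
        assert model.seed == 7


class TestPercentileReport:
    def test_constant_samples_flat_at_100(self):
        report = percentile_report(np.full(100, 0.03), 0.03)
        assert all(v == pytest.approx(100.0) for v in report.values)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            percentile_report([], 0.03)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            percentile_report([0.1], 0.0)

    def test_label_parsing(self):
        assert parse_percentile_label("P97.5") == pytest.approx(0.975)
        assert parse_percentile_label("P99.9") == pytest.approx(0.999)
        with pytest.raises(ValueError):
            parse_percentile_label("P150")

    def test_tail_count_warning_threshold(self):
        assert expected_tail_count("P99.9", 1000) == pytest.approx(1.0)
        assert expected_tail_count("P95", 1000) == pytest.approx(50.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), sigma=st.floats(0.0, 1.5))
    def test_monotone_in_percentile_level(self, seed, sigma):
        rng = np.random.default_rng(seed)
        samples = rng.lognormal(-5.0, sigma, size=500)
        report = percentile_report(samples, 0.03)
        assert all(a <= b + 1e-15 for a, b in zip(report.values, report.values[1:]))

    def test_convergence_of_p95_when_doubling_iterations(self):
        def p95(n_iter, seed):
            sim = ExposureSimulation(
                subgroup=GENERAL,
                consumption_dists=[LognormalParams(math.log(0.048), 0.5)],
                residue_dists=[LognormalParams(math.log(0.13), 0.4)],
                n_iter=n_iter,
                seed=seed,
            )
            return np.quantile(simulate_exposure(sim).samples, 0.95)

        base = p95(1000, seed=2)
        doubled = p95(2000, seed=3)
        # bootstrap SE of the P95 estimator at n=1000
        rng = np.random.default_rng(6)
        sim = ExposureSimulation(
            subgroup=GENERAL,
            consumption_dists=[LognormalParams(math.log(0.048), 0.5)],
            residue_dists=[LognormalParams(math.log(0.13), 0.4)],
            n_iter=1000,
            seed=2,
        )
        samples = simulate_exposure(sim).samples
        boot = [np.quantile(rng.choice(samples, samples.size, replace=True), 0.95)
                for _ in range(200)]
        assert abs(doubled - base) < 3 * np.std(boot)


def _study_frames():
    rng = np.random.default_rng(17)
    residue = pd.DataFrame(
        {
            "compound": ["pyraclostrobin"] * 30 + ["cyazofamid"] * 30,
            "residue_mg_per_kg": np.concatenate(
                [rng.lognormal(math.log(0.13), 0.8, 30), rng.lognormal(math.log(0.11), 0.8, 30)]
            ),
            "censored": 0,
        }
    )
    frames = []
    for sg, sigma in ((GENERAL, 0.5), (CHILDREN, 0.5)):
        frames.append(
            pd.DataFrame(
                {
                    "subgroup": sg.name,
                    "intake_kg_per_day": rng.lognormal(math.log(sg.fi), sigma, 200),
                    "bw_kg": sg.bw,
                }
            )
        )
    return residue, pd.concat(frames, ignore_index=True)


TOX = [ToxicologyReference("pyraclostrobin", adi=0.03, arfd=0.05),
       ToxicologyReference("cyazofamid", adi=0.2, arfd=0.2)]


class TestStratifiedRun:
    def test_one_report_per_subgroup_and_compound(self):
        residue, consumption = _study_frames()
        reports, errors = stratified_run([GENERAL, CHILDREN], residue, consumption, TOX,
                                         mode="chronic", n_iter=500, seed=1)
        assert not errors
        assert len(reports) == 4
        assert {(r.subgroup, r.compound) for r in reports} == {
            ("general", "pyraclostrobin"), ("general", "cyazofamid"),
            ("children", "pyraclostrobin"), ("children", "cyazofamid"),
        }

    def test_identical_subgroups_give_identical_reports(self):
        residue, consumption = _study_frames()
        twin = PopulationSubgroup(name="general", bw=GENERAL.bw, lp=GENERAL.lp, fi=GENERAL.fi)
        reports, _ = stratified_run([GENERAL, twin], residue, consumption, TOX,
                                    mode="acute", n_iter=300, seed=5)
        by_subgroup = {}
        for r in reports:
            by_subgroup.setdefault(r.compound, []).append(r.values)
        for values in by_subgroup.values():
            assert values[0] == values[1]

    def test_missing_subgroup_recorded_and_run_continues(self):
        residue, consumption = _study_frames()
        ghost = PopulationSubgroup(name="ghost", bw=60, lp=0.3, fi=0.05)
        reports, errors = stratified_run([GENERAL, ghost], residue, consumption, TOX,
                                         mode="chronic", n_iter=200, seed=2)
        assert "ghost" in errors
        assert {r.subgroup for r in reports} == {"general"}

    def test_children_dominate_general_at_every_level(self):
        # children's intake per kg bodyweight is higher at equal log-scale spread,
        # so their exposure distribution stochastically dominates
        residue, consumption = _study_frames()
        reports, _ = stratified_run([GENERAL, CHILDREN], residue, consumption, TOX,
                                    mode="chronic", n_iter=2000, seed=3)
        by_key = {(r.subgroup, r.compound): np.asarray(r.values) for r in reports}
        for compound in ("pyraclostrobin", "cyazofamid"):
            assert (by_key[("children", compound)] > by_key[("general", compound)]).all()

    def test_degenerate_chronic_p50_equals_deterministic_risk_quotient(self):
        stmr, adi = 0.13, 0.03
        residue = pd.DataFrame(
            {"compound": ["pyraclostrobin"] * 5, "residue_mg_per_kg": stmr, "censored": 0}
        )
        consumption = pd.DataFrame(
            {"subgroup": "general", "intake_kg_per_day": [GENERAL.fi] * 5, "bw_kg": GENERAL.bw}
        )
        reports, _ = stratified_run([GENERAL], residue, consumption, TOX[:1],
                                    mode="chronic", n_iter=500, seed=0)
        p50 = dict(zip(reports[0].levels, reports[0].values))["P50"]
        assert p50 == pytest.approx(risk_quotient(edi([(stmr, GENERAL.fi)], GENERAL.bw), adi),
                                    rel=1e-12)
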