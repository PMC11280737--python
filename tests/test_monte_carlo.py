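"""Monte Carlo layer: input sampling, distribution fitting, run semantics."""

import numpy as np
import pandas as pd
import pytest

import ptewater as pw
from ptewater.monte_carlo import MCConfig, sample_inputs


def point_config(contents, n_iter=500, seed=0, **kw):
    return MCConfig(
        conc_specs={el: pw.DistributionSpec("point", (v,)) for el, v in contents.items()},
        ef_spec=pw.DistributionSpec("point", (350.0,)),
        et_spec=pw.DistributionSpec("point", (0.20,)),
        n_iter=n_iter,
        seed=seed,
        **kw,
    )


class TestSampleInputs:
    def test_triangular_ef_support_and_mean(self):
        config = MCConfig(
            conc_specs={"As": pw.DistributionSpec("point", (21.0,))},
            ef_spec=pw.DistributionSpec("triangular", (180.0, 350.0, 365.0)),
            et_spec=pw.DistributionSpec("triangular", (0.13, 0.20, 0.33)),
            n_iter=100_000,
            seed=1,
        )
        draws = sample_inputs(config)
        ef = draws["EF"]
        assert ef.min() >= 180 and ef.max() <= 365
        mean = (180 + 350 + 365) / 3  # closed-form triangular mean
        var = (180**2 + 350**2 + 365**2 - 180 * 350 - 180 * 365 - 350 * 365) / 18
        assert abs(ef.mean() - mean) < 3 * np.sqrt(var / len(ef))
        et = draws["ET"]
        assert et.min() >= 0.13 and et.max() <= 0.33

    def test_point_masses_are_constant(self):
        draws = sample_inputs(point_config({"As": 21.0}))
        assert (draws["C_As"] == 21.0).all()
        assert (draws["EF"] == 350.0).all()

    def test_seed_determinism(self):
        cfg = pw.MCConfig(
            conc_specs={"As": pw.DistributionSpec("lognormal", (3.0, 1.2))},
            ef_spec=pw.DistributionSpec("triangular", (180.0, 350.0, 365.0)),
            et_spec=pw.DistributionSpec("triangular", (0.13, 0.20, 0.33)),
            n_iter=1000,
            seed=99,
        )
        pd.testing.assert_frame_equal(sample_inputs(cfg), sample_inputs(cfg))


class TestFitContentDistribution:
    def test_closed_form_log_moments(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(2.0, 1.0, 400)
        spec = pw.fit_content_distribution(values)
        mean, sd = values.mean(), values.std(ddof=1)
        cv = sd / mean
        assert spec.family == "lognormal"
        assert spec.params[1] == pytest.approx(np.sqrt(np.log(1 + cv**2)), rel=1e-12)
        assert spec.truncation == (values.min(), values.max())
        # for CV = 1.84 the closed form gives sd_log = 1.21587
        assert np.sqrt(np.log(1 + 1.84**2)) == pytest.approx(1.21587, abs=1e-5)

    def test_constant_vector_becomes_point_mass(self):
        spec = pw.fit_content_distribution([4.0, 4.0, 4.0])
        assert spec.family == "point" and spec.params == (4.0,)

    def test_nondetect_substitution_half_detection_limit(self):
        # Se zeros replaced by 0.41/2 = 0.205 before fitting
        values = np.array([0.0, 0.0, 1.0, 5.0, 20.0])
        spec = pw.fit_content_distribution(values, detection_limit=0.41)
        substituted = np.array([0.205, 0.205, 1.0, 5.0, 20.0])
        mean, sd = substituted.mean(), substituted.std(ddof=1)
        cv = sd / mean
        assert spec.params[1] == pytest.approx(np.sqrt(np.log(1 + cv**2)))
        assert spec.truncation[0] == pytest.approx(0.205)

    def test_all_zero_rejected(self):
        with pytest.raises(pw.InputError):
            pw.fit_content_distribution([0.0, 0.0], detection_limit=0.41)


class TestRunMonteCarlo:
    def test_degenerate_specs_reproduce_deterministic_engine(self, cohorts, defaults):
        """With every stochastic input a point mass, the MC pipeline equals the
        deterministic engine to full floating precision."""
        contents = {"As": 21.0, "Cd": 0.35, "Pb": 6.0}
        mc = pw.run_monte_carlo(point_config(contents, n_iter=50), cohorts, defaults.toxicity)
        det = pw.assess_risk(contents, cohorts, defaults.toxicity)
        for cohort in cohorts:
            draws = mc.outputs[cohort]
            assert draws["HI"].nunique() == 1
            assert draws["HI"].iloc[0] == pytest.approx(det.hi[cohort], rel=1e-14)
            assert draws["TCR"].iloc[0] == pytest.approx(det.tcr[cohort], rel=1e-14)
            sub = det.per_element[det.per_element["cohort"] == cohort].set_index("element")
            for el in contents:
                assert draws[f"HQ_{el}"].iloc[0] == pytest.approx(
                    sub.loc[el, "hq_total"], rel=1e-14
                )

    def test_hi_draw_is_exact_sum_of_hq_draws(self, samples53, cohorts, defaults):
        mc = pw.run_monte_carlo(samples53, cohorts, defaults.toxicity, n_iter=2000, seed=4)
        for cohort in cohorts:
            frame = mc.outputs[cohort]
            hq_cols = [c for c in frame.columns if c.startswith("HQ_")]
            np.testing.assert_allclose(frame[hq_cols].sum(axis=1), frame["HI"], rtol=1e-12)
            cr_cols = [c for c in frame.columns if c.startswith("CR_")]
            np.testing.assert_allclose(frame[cr_cols].sum(axis=1), frame["TCR"], rtol=1e-12)

    def test_paired_child_hq_always_exceeds_adult(self, samples53, cohorts, defaults):
        """Cohorts share draws within an iteration and the child/adult ratio
        exceeds 1 for both routes, so P(HQ_child > HQ_adult) = 1 paired."""
        mc = pw.run_monte_carlo(samples53, cohorts, defaults.toxicity, n_iter=2000, seed=8)
        assert (mc.outputs["child"]["HQ_As"] > mc.outputs["adult"]["HQ_As"]).all()
        assert (mc.outputs["child"]["HI"] > mc.outputs["adult"]["HI"]).all()

    def test_exceedance_monotone_in_threshold(self, samples53, cohorts, defaults):
        mc = pw.run_monte_carlo(samples53, cohorts, defaults.toxicity, n_iter=2000, seed=2)
        probs = [
            mc.exceedance("child", "CR_As", t) for t in (1e-7, 1e-6, 1e-5, 1e-4, 1e-3)
        ]
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_two_seeds_agree_within_monte_carlo_error(self, samples53, cohorts, defaults):
        a = pw.run_monte_carlo(samples53, cohorts, defaults.toxicity, n_iter=10_000, seed=101)
        b = pw.run_monte_carlo(samples53, cohorts, defaults.toxicity, n_iter=10_000, seed=202)
        xa = a.outputs["adult"]["HQ_As"]
        xb = b.outputs["adult"]["HQ_As"]
        se = np.sqrt(xa.var(ddof=1) / len(xa) + xb.var(ddof=1) / len(xb))
        assert abs(xa.mean() - xb.mean()) < 3 * se

    def test_percentile_consistency(self, cohorts, defaults):
        cfg = MCConfig(
            conc_specs={"As": pw.DistributionSpec("lognormal", (2.3, 1.2))},
            ef_spec=pw.DistributionSpec("triangular", (180.0, 350.0, 365.0)),
            et_spec=pw.DistributionSpec("triangular", (0.13, 0.20, 0.33)),
            n_iter=100_000,
            seed=6,
        )
        mc = pw.run_monte_carlo(cfg, cohorts, defaults.toxicity)
        draws = mc.outputs["adult"]["HQ_As"].to_numpy()
        q95 = mc.table.loc[("adult", "HQ_As"), "p95"]
        assert 0.949 <= np.mean(draws <= q95) <= 0.951

    def test_empirical_mode_resamples_observations(self, samples53, cohorts, defaults):
        cfg = MCConfig.from_samples(samples53, n_iter=3000, seed=5, conc_mode="empirical")
        draws = sample_inputs(cfg)
        observed = set(np.round(samples53.concentrations["As"], 9))
        assert set(np.round(draws["C_As"], 9)) <= observed

    def test_summary_table_mean_matches_draws(self, samples53, cohorts, defaults):
        mc = pw.run_monte_carlo(samples53, cohorts, defaults.toxicity, n_iter=2000, seed=7)
        assert mc.table.loc[("adult", "HI"), "mean"] == pytest.approx(
            mc.outputs["adult"]["HI"].mean(), rel=1e-12
        )
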