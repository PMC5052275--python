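"""Hierarchical Bayesian inference: validation, summaries, contrasts,
posterior prediction, shrinkage, and likelihood consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from cuedtoj.data import TOJDataset, generate_dataset
from cuedtoj.inference import HierarchicalTOJModel, contrast, posterior_predict
from cuedtoj.model import probe_first_probability_arrays
from cuedtoj.population import ConditionRates, PopulationSpec, RateDistribution
from conftest import subdesign


class TestValidation:
    def test_unknown_variant_rejected(self, coa80_dataset):
        with pytest.raises(ValueError):
            HierarchicalTOJModel(variant="extra_special").fit(coa80_dataset)

    def test_invalid_counts_rejected_at_dataset_construction(self):
        df = pd.DataFrame(
            {
                "subject_id": [0, 0], "condition_label": ["c", "c"],
                "soa_ms": [0.0, 30.0], "coa_ms": [80.0, 80.0],
                "cld_px": [np.nan] * 2, "n_trials": [10, 10],
                "n_probe_first": [12, 5],
            }
        )
        with pytest.raises(ValueError):
            TOJDataset(df)

    def test_too_few_chains_rejected(self, coa80_dataset):
        with pytest.raises(ValueError):
            HierarchicalTOJModel(chains=1).fit(coa80_dataset)


class TestFittedResult:
    def test_summary_orders_hdi_around_mean(self, coa80_fit):
        s = coa80_fit.summary_
        assert (s["hdi_2.5%"] <= s["mean"]).all()
        assert (s["mean"] <= s["hdi_97.5%"]).all()
        assert (s["mean"] > 0).all()

    def test_group_estimates_near_generating_values(self, coa80_fit):
        s = coa80_fit.summary_
        # Loose sanity band: posterior means within a factor ~2 of the
        # generating group medians (29, 69, 22 Hz).
        assert 20 < s.loc["v_neutral_mu", "mean"] < 40
        assert 45 < s.loc["v_p_mu[COA=80]", "mean"] < 100
        assert 10 < s.loc["v_r_mu[COA=80]", "mean"] < 45

    def test_diagnostics_reported_and_flagged(self, coa80_fit):
        d = coa80_fit.diagnostics_
        assert set(d) >= {"max_rhat", "min_ess_bulk", "rhat_threshold"}
        assert isinstance(coa80_fit.converged_, bool)

    def test_rate_draws_positive(self, coa80_fit):
        draws = coa80_fit.posterior_.subject_rate_draws("COA=80")
        for arr in draws.values():
            assert np.all(arr > 0)

    def test_sklearn_param_round_trip(self):
        est = HierarchicalTOJModel(variant="rates_only", draws=123)
        clone_params = est.get_params()
        assert clone_params["variant"] == "rates_only"
        est.set_params(draws=77)
        assert est.draws == 77


class TestContrast:
    def test_self_contrast_is_degenerate_zero(self, coa80_fit):
        c = coa80_fit.contrast("v_p_mu[COA=80]", "v_p_mu[COA=80]")
        assert c.mean == 0.0
        assert c.hdi_low == c.hdi_high == 0.0

    def test_antisymmetric_in_arguments(self, coa80_fit):
        ab = coa80_fit.contrast("v_p_mu[COA=80]", "v_r_mu[COA=80]")
        ba = contrast(coa80_fit.posterior_, "v_r_mu[COA=80]", "v_p_mu[COA=80]")
        assert np.allclose(ab.draws, -ba.draws)
        assert ab.mean == pytest.approx(-ba.mean)

    def test_detects_generating_rate_difference(self, coa80_fit):
        # Generated with v_p = 69 vs v_r = 22: difference must exclude zero.
        c = coa80_fit.contrast("v_p_mu[COA=80]", "v_r_mu[COA=80]")
        assert c.hdi_low > 0
        assert c.excludes_zero

    def test_unknown_parameter_raises(self, coa80_fit):
        with pytest.raises(KeyError):
            coa80_fit.contrast("v_p_mu[COA=80]", "v_ghost_mu")

    def test_correlation_between_rate_advantage_and_confusion_rate(self, coa80_fit):
        """(v_p - v_r) and v_cp trade off: their posterior correlation is
        negative in a cued condition with a short cue-target interval."""
        post = coa80_fit.posterior_
        diff = post.parameter_draws("v_p_mu[COA=80]") - post.parameter_draws(
            "v_r_mu[COA=80]"
        )
        vcp = post.parameter_draws("v_cp_mu[COA=80]")
        assert np.corrcoef(diff, vcp)[0, 1] < 0


class TestNullRecovery:
    def test_symmetric_generating_rates_keep_zero_in_hdi(self):
        spec = PopulationSpec(
            v_neutral=RateDistribution(30.0),
            beneficial={
                "COA=80": ConditionRates(
                    RateDistribution(35.0), RateDistribution(35.0),
                    RateDistribution(3.0, 0.5),
                )
            },
            weight_disadvantageous=0.0,
        )
        design = subdesign("exp1", ("no-cue", "COA=80"), 8)
        ds = generate_dataset(design, spec, seed=31)
        est = HierarchicalTOJModel(chains=4, warmup=400, draws=400, seed=6).fit(ds)
        c = est.contrast("v_p_mu[COA=80]", "v_r_mu[COA=80]")
        assert c.hdi_low <= 0.0 <= c.hdi_high


class TestPosteriorPredict:
    def test_bands_bounded_by_trial_counts(self, coa80_fit, coa80_dataset):
        pred = coa80_fit.posterior_predict()
        assert (pred.k_lo >= 0).all()
        assert (pred.k_hi <= pred.n_trials).all()
        assert (pred.k_lo <= pred.k_median).all()
        assert (pred.k_median <= pred.k_hi).all()
        assert len(pred) == len(coa80_dataset.table)

    def test_bands_cover_expected_counts(self, coa80_fit, coa80_subjects):
        """On recovery data the 95% predictive bands should contain each
        subject's own generating expected counts at almost every SOA cell."""
        pred = coa80_fit.posterior_predict()
        cued = pred[pred.condition_label == "COA=80"]
        by_subject = {s.subject: s for s in coa80_subjects}
        inside = []
        for _, row in cued.iterrows():
            rs = by_subject[row.subject_id].conditions["COA=80"]
            p_gen = float(
                probe_first_probability_arrays(
                    rs.v_p, rs.v_r, rs.v_cp, rs.v_neutral, row.soa_ms, 80.0
                )
            )
            expected = p_gen * row.n_trials
            inside.append(row.k_lo <= expected <= row.k_hi)
        assert np.mean(inside) >= 0.8

    def test_condition_mismatch_raises(self, coa80_fit):
        other = subdesign("exp1", ("no-cue", "COA=140"), 8)
        with pytest.raises(ValueError):
            coa80_fit.posterior_predict(other)

    def test_functional_wrapper_matches_method(self, coa80_fit):
        a = coa80_fit.posterior_predict(seed=3)
        b = posterior_predict(coa80_fit.posterior_, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestShrinkage:
    def test_subject_estimates_pulled_toward_group_mean(self, coa80_fit, coa80_dataset):
        """Partial pooling: subject-level posterior means sit between the
        no-pooling (per-subject ML) estimate and the group mean."""
        post = coa80_fit.posterior_.idata.posterior
        vp_subj = post["v_p[COA=80]"].mean(("chain", "draw")).to_numpy()
        vn_subj = post["v_neutral"].mean(("chain", "draw")).to_numpy()
        group = float(post["v_p_mu[COA=80]"].mean())
        df = coa80_dataset.table
        pulled, total = 0, 0
        for i, subject in enumerate(coa80_fit.posterior_.subjects):
            sub = df[(df.subject_id == subject) & (df.condition_label == "COA=80")]
            soa, n, k = (
                sub.soa_ms.to_numpy(), sub.n_trials.to_numpy(),
                sub.n_probe_first.to_numpy(),
            )

            def nll(params):
                vp, vr, vcp = np.exp(params)
                p = probe_first_probability_arrays(vp, vr, vcp, vn_subj[i], soa, 80.0)
                p = np.clip(p, 1e-10, 1 - 1e-10)
                return -float(np.sum(k * np.log(p) + (n - k) * np.log(1 - p)))

            res = minimize(nll, x0=np.log([50.0, 30.0, 5.0]), method="Nelder-Mead")
            ml_vp = float(np.exp(res.x[0]))
            lo, hi = sorted([ml_vp, group])
            total += 1
            pulled += (lo - 3.0) <= vp_subj[i] <= (hi + 3.0)
        assert pulled / total >= 0.7


class TestLikelihoodConsistency:
    def test_single_subject_posterior_tracks_maximum_likelihood(self):
        """With one subject, many trials, and a flat hierarchy, the posterior
        concentrates near the generating rates (which the ML fit recovers)."""
        reps = {s: 40 * r for s, r in
                zip([-120, -90, -60, -30, 0, 30, 60, 90, 120],
                    [4, 12, 20, 28, 32, 28, 20, 12, 4])}
        from cuedtoj.design import ConditionDesign, ExperimentDesign

        design = ExperimentDesign(
            "one",
            [
                ConditionDesign("no-cue", None, None, {float(s): n for s, n in reps.items()}),
                ConditionDesign("COA=80", 80.0, None, {float(s): n for s, n in reps.items()}),
            ],
            n_subjects=1,
        )
        spec = PopulationSpec(
            v_neutral=RateDistribution(30.0, 0.0),
            beneficial={
                "COA=80": ConditionRates(
                    RateDistribution(60.0, 0.0), RateDistribution(25.0, 0.0),
                    RateDistribution(8.0, 0.0),
                )
            },
            weight_disadvantageous=0.0,
        )
        ds = generate_dataset(design, spec, seed=41)
        est = HierarchicalTOJModel(chains=4, warmup=500, draws=500, seed=7).fit(ds)
        # With one subject the group hyper-mean is prior-broadened; the
        # subject-level rates are what the data pin down.
        post = est.posterior_.idata.posterior
        assert float(post["v_neutral"].mean()) == pytest.approx(30.0, rel=0.15)
        assert float(post["v_p[COA=80]"].mean()) == pytest.approx(60.0, rel=0.25)
        assert float(post["v_r[COA=80]"].mean()) == pytest.approx(25.0, rel=0.3)


class TestDisadvantageousFilter:
    def test_filter_reports_boolean_per_subject(self, coa80_fit):
        table = coa80_fit.classify_disadvantageous()
        assert set(table.columns) == {"subject_id", "disadvantageous"}
        assert len(table) == len(coa80_fit.posterior_.subjects)
        # This population was generated all-beneficial with a clear probe
        # advantage; the filter should flag (almost) nobody.
        assert table.disadvantageous.mean() <= 0.25
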