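"""Censored (M3) likelihood, empirical-Bayes estimates, SAEM estimation, VPC."""

import math

import numpy as np
import pandas as pd
import pytest

from c2pkpd import (
    DEFAULT_PARAMS,
    EventDataset,
    PKStudyDesign,
    PopulationModel,
    SAEMOptions,
    default_generator_config,
    empirical_bayes,
    generate_pkpd_study,
    individual_loglik_m3,
    saem_fit,
    simulate_individual,
    expand_regimen,
    visual_predictive_check,
)
from c2pkpd.population import EstimationError, _IndividualWork

R0_UGML = DEFAULT_PARAMS.r0 * DEFAULT_PARAMS.mw_target * 1e-6


def placebo_rows(dv_blq_lloq, observable="c2_free"):
    """One placebo individual whose free-C2 prediction is the baseline."""
    rows = [dict(id="r1", time=0.0, evid=1, amt=0.0, dv=np.nan, mdv=1, blq=0,
                 observable=".", lloq=np.nan)]
    for t, dv, blq, lloq in dv_blq_lloq:
        rows.append(dict(id="r1", time=t, evid=0, amt=0.0, dv=dv, mdv=0, blq=blq,
                         observable=observable, lloq=lloq))
    return pd.DataFrame(rows)


def model_with(sigma, lloq):
    return PopulationModel(
        theta=DEFAULT_PARAMS,
        omega={"CL": 0.05},
        sigma_prop={"c2_free": sigma, "mab_total": sigma},
        lloq={"c2_free": lloq},
    )


class TestM3Likelihood:
    def test_reduces_to_gaussian_without_censoring(self):
        data = placebo_rows([(1.0, 18.0, 0, 0.9375), (2.0, 19.5, 0, 0.9375)])
        model = model_with(sigma=0.15, lloq=0.9375)
        ll = individual_loglik_m3(model, {}, data)
        from scipy.stats import norm

        f = R0_UGML
        s = max(0.15 * f, 0.15 * 0.9375 / 2)
        expected = norm.logpdf(18.0, f, s) + norm.logpdf(19.5, f, s)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_blq_at_prediction_equals_log_half(self):
        # LLOQ set exactly at the baseline prediction: Phi(0) = 1/2
        data = placebo_rows([(1.0, R0_UGML, 1, R0_UGML)])
        model = model_with(sigma=0.15, lloq=R0_UGML)
        assert individual_loglik_m3(model, {}, data) == pytest.approx(math.log(0.5), rel=1e-12)

    def test_deep_censoring_matches_high_accuracy_normal_cdf(self):
        # f = 10·LLOQ with s = LLOQ: contribution log Phi(-9)
        lloq = R0_UGML / 10
        data = placebo_rows([(1.0, lloq, 1, lloq)])
        model = model_with(sigma=0.1, lloq=lloq)  # s = 0.1·f = lloq
        ll = individual_loglik_m3(model, {}, data)
        oracle = math.log(0.5 * math.erfc(9.0 / math.sqrt(2.0)))
        assert ll == pytest.approx(oracle, rel=1e-10)

    def test_censor_flag_not_value_drives_the_branch(self):
        """The likelihood is continuous in the prediction at the LLOQ."""
        lloq = 0.9375
        model = model_with(sigma=0.15, lloq=lloq)
        lls = []
        for scale in (0.999999, 1.000001):
            m = PopulationModel(
                theta=DEFAULT_PARAMS.with_updates(kin=DEFAULT_PARAMS.kin * scale),
                omega={"CL": 0.05},
                sigma_prop=dict(model.sigma_prop),
                lloq=dict(model.lloq),
            )
            data = placebo_rows([(1.0, lloq, 1, lloq)])
            lls.append(individual_loglik_m3(m, {}, data))
        assert lls[0] == pytest.approx(lls[1], abs=1e-4)


class TestEmpiricalBayes:
    def _dataset_at_eta(self, eta_star):
        model = PopulationModel(
            theta=DEFAULT_PARAMS.with_updates(kon=0.0),
            omega={"CL": 0.05, "Vc": 0.05},
            sigma_prop={"mab_total": 1e-4},
            estimate_flags={"CL": True, "Vc": True},
            lloq={"mab_total": 0.0},
        )
        params = model.individual_params(eta_star)
        times = np.array([0.25, 1.0, 3.0, 7.0, 14.0])
        prof = simulate_individual(params, expand_regimen([(0, 50)]), times)
        rows = [dict(id="r1", time=0.0, evid=1, amt=50.0, dv=np.nan, mdv=1, blq=0,
                     observable=".", lloq=np.nan)]
        for t, v in zip(times, prof.mab_total):
            rows.append(dict(id="r1", time=t, evid=0, amt=0.0, dv=v, mdv=0, blq=0,
                             observable="mab_total", lloq=0.0))
        return model, pd.DataFrame(rows)

    def test_likelihood_dominates_prior_as_sigma_vanishes(self):
        eta_star = {"CL": 0.15, "Vc": -0.10}
        model, data = self._dataset_at_eta(eta_star)
        res = empirical_bayes(model, data, seed=0)
        assert res.eta["CL"] == pytest.approx(eta_star["CL"], abs=1e-3)
        assert res.eta["Vc"] == pytest.approx(eta_star["Vc"], abs=1e-3)

    def test_empty_observations_return_prior_mode(self):
        model, data = self._dataset_at_eta({"CL": 0.0, "Vc": 0.0})
        doses_only = data[data["evid"] == 1]
        res = empirical_bayes(model, doses_only, seed=0)
        assert all(v == 0.0 for v in res.eta.values())

    def test_zero_omega_component_pinned_at_zero(self):
        model, data = self._dataset_at_eta({"CL": 0.15, "Vc": 0.0})
        model.omega["Vc"] = 0.0
        res = empirical_bayes(model, data, seed=0)
        assert "Vc" not in res.eta  # degenerate prior: no random effect


def rich_linear_dataset(seed=42):
    """30 rats, 50 mg/kg each, binding disabled, antibody observable only."""
    theta = DEFAULT_PARAMS.with_updates(kon=0.0)
    truth = PopulationModel(
        theta=theta,
        omega={"CL": 0.05, "Vc": 0.05},
        sigma_prop={"mab_total": 0.10},
        estimate_flags={"CL": True, "Vc": True},
        lloq={"mab_total": 0.0},
    )
    design = PKStudyDesign(
        dose_groups=(50.0,) * 10,
        n_per_group=3,
        observables=("mab_total",),
        lloq={"mab_total": 0.0},
    )
    ds, truth_df = generate_pkpd_study(truth, design, seed=seed, return_truth=True)
    return theta, truth, ds, truth_df


class TestSAEM:
    def test_rich_data_recovery_and_stabilisation(self):
        """SAEM recovers CL and Vc within 10% on a rich 30-animal design,
        omega within 50% of the realised random-effect variance, and the
        typical-value trajectory stabilises over the final iterations."""
        theta, truth, ds, truth_df = rich_linear_dataset(seed=42)
        init = PopulationModel(
            theta=theta.with_updates(CL=theta.CL * 1.5, Vc=theta.Vc * 0.7),
            omega={"CL": 0.1, "Vc": 0.1},
            sigma_prop={"mab_total": 0.2},
            estimate_flags={"CL": True, "Vc": True},
            lloq={"mab_total": 0.0},
        )
        opts = SAEMOptions(K1=100, K2=60, seed=7)
        est = saem_fit(ds, init, opts)
        assert est.theta_hat.CL == pytest.approx(theta.CL, rel=0.10)
        assert est.theta_hat.Vc == pytest.approx(theta.Vc, rel=0.10)
        # realised variance of the generating random effects is the truth
        # for this one dataset
        eta_rows = truth_df[truth_df["observable"] == "eta"]
        for p in ("CL", "Vc"):
            realised = float(np.var(eta_rows[f"eta_{p}"].to_numpy(float)))
            assert est.omega_hat[p] == pytest.approx(realised, rel=0.5)
        assert est.sigma_hat["mab_total"] == pytest.approx(0.10, rel=0.3)
        # trajectory length and late-phase stability
        assert len(est.trajectory) == opts.K1 + opts.K2
        tail = est.trajectory.iloc[-max(1, opts.K2 // 5) :]
        for p in ("CL", "Vc"):
            vals = tail[p].to_numpy()
            assert np.ptp(vals) / vals.mean() < 0.05

    def test_bit_identical_given_seed(self):
        theta, truth, ds, _ = rich_linear_dataset(seed=5)
        small = EventDataset(ds.df[ds.df["id"].isin(ds.ids()[:6])].reset_index(drop=True))
        init = PopulationModel(
            theta=theta,
            omega={"CL": 0.05, "Vc": 0.05},
            sigma_prop={"mab_total": 0.15},
            estimate_flags={"CL": True, "Vc": True},
            lloq={"mab_total": 0.0},
        )
        a = saem_fit(small, init, SAEMOptions(K1=8, K2=5, seed=3))
        b = saem_fit(small, init, SAEMOptions(K1=8, K2=5, seed=3))
        assert a.theta_hat == b.theta_hat
        assert a.omega_hat == b.omega_hat
        assert a.trajectory.equals(b.trajectory)

    def test_no_iiv_falls_back_to_direct_ml(self):
        """With omega fixed at 0 and one individual, SAEM degenerates to the
        individual maximum-likelihood fit found by direct optimisation."""
        theta, truth, ds, _ = rich_linear_dataset(seed=11)
        one = EventDataset(ds.df[ds.df["id"] == ds.ids()[0]].reset_index(drop=True))
        init = PopulationModel(
            theta=theta.with_updates(CL=theta.CL * 1.3, Vc=theta.Vc * 0.8),
            omega={"CL": 0.0, "Vc": 0.0},
            sigma_prop={"mab_total": 0.10},
            estimate_flags={"CL": True, "Vc": True},
            lloq={"mab_total": 0.0},
        )
        est = saem_fit(one, init, SAEMOptions(K1=10, K2=10, seed=1))

        # independent direct optimisation of the same individual likelihood
        from scipy.optimize import minimize

        data_i = one.df

        def neg(x):
            m = PopulationModel(
                theta=theta.with_updates(CL=math.exp(x[0]), Vc=math.exp(x[1])),
                omega={"CL": 0.0, "Vc": 0.0},
                sigma_prop={"mab_total": 0.10},
                estimate_flags={"CL": True, "Vc": True},
                lloq={"mab_total": 0.0},
            )
            return -individual_loglik_m3(m, {}, data_i)

        ref = minimize(neg, [math.log(theta.CL * 0.9), math.log(theta.Vc * 1.2)], method="Powell")
        assert est.theta_hat.CL == pytest.approx(math.exp(ref.x[0]), rel=0.05)
        assert est.theta_hat.Vc == pytest.approx(math.exp(ref.x[1]), rel=0.05)

    def test_censored_pd_study_keeps_high_dose_suppressed(self):
        """Fitting the BLQ-censored free-C2 study leaves a model whose 50
        mg/kg simulation stays below 5% of baseline through day 21."""
        model, design, _ = default_generator_config()
        ds = generate_pkpd_study(model, design, seed=100)
        init = PopulationModel(
            theta=DEFAULT_PARAMS.with_updates(CL=DEFAULT_PARAMS.CL * 1.2,
                                              kin=DEFAULT_PARAMS.kin * 0.9),
            omega={"CL": 0.05, "kin": 0.05},
            sigma_prop={"mab_total": 0.15, "c2_free": 0.2},
            estimate_flags={"CL": True, "kin": True},
            lloq=dict(model.lloq),
        )
        est = saem_fit(ds, init, SAEMOptions(K1=30, K2=20, seed=2))
        assert np.isfinite(est.trajectory["mean_loglik"]).all()
        grid = np.linspace(0, 21, 211)
        prof = simulate_individual(est.theta_hat, expand_regimen([(0, 50)]), grid)
        below = prof.c2_free_pct_baseline[grid >= 0.01]
        assert below.max() <= 5.0

    def test_zero_sigma_rejected_for_estimation(self):
        theta, truth, ds, _ = rich_linear_dataset(seed=5)
        bad = PopulationModel(
            theta=theta,
            omega={"CL": 0.05},
            sigma_prop={"mab_total": 0.0},
            estimate_flags={"CL": True},
            lloq={"mab_total": 0.0},
        )
        with pytest.raises(EstimationError):
            saem_fit(ds, bad, SAEMOptions(K1=2, K2=2, seed=0))


class TestDatasetRoundTrip:
    def test_csv_round_trip_is_lossless(self, tmp_path, defaults):
        model, design, _ = defaults
        ds = generate_pkpd_study(model, design, seed=9)
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        back = EventDataset.from_csv(path)
        pd.testing.assert_frame_equal(
            back.df.reset_index(drop=True), ds.df.reset_index(drop=True),
            check_dtype=False, atol=0, rtol=1e-9,
        )


class TestVPC:
    def test_calibrated_against_self_simulated_data(self, defaults):
        """A model simulated from itself has its observed medians inside the
        90% band at most nominal times."""
        model, _, _ = defaults
        design = PKStudyDesign(dose_groups=(50.0,), n_per_group=3)
        counts = []
        for seed in range(20):
            obs = generate_pkpd_study(model, design, seed=1000 + seed)
            v = visual_predictive_check(model, design, n_sim=100, seed=seed, observed=obs)
            b = v.bands
            b = b[(b["observable"] == "mab_total") & (b["time"] >= 0)]
            counts.append(int(((b["observed_median"] >= b["lo"]) & (b["observed_median"] <= b["hi"])).sum()))
        assert np.median(counts) >= 8  # of 9 nominal times
        assert sum(counts) >= 150  # aggregate coverage over 20 studies

    def test_single_replicate_bands_collapse(self, defaults):
        model, _, _ = defaults
        design = PKStudyDesign(dose_groups=(50.0,), n_per_group=2)
        v = visual_predictive_check(model, design, n_sim=1, seed=4)
        assert np.allclose(v.bands["lo"], v.bands["hi"])

    def test_zero_dose_design_is_flat_at_baseline(self, defaults):
        model, _, _ = defaults
        design = PKStudyDesign(dose_groups=(0.0,), n_per_group=3, observables=("c2_free",))
        v = visual_predictive_check(model, design, n_sim=5, seed=4)
        med = v.bands["med"]
        # proportional noise around a flat baseline: medians all near R0
        assert np.allclose(med, R0_UGML, rtol=0.35)
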