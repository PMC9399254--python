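"""Count and hazard models: oracle identities, robustness, recovery."""

import numpy as np
import pandas as pd
import pytest

from oatrisk.models import (
    crude_rate_ratio,
    fit_cox_first_event,
    fit_negbin,
    fit_poisson,
    overdispersion_test,
    robust_variance,
)


def _poisson_records(n=2000, log_rr=0.5, base=0.3, seed=0, alpha=None):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    py = rng.uniform(0.2, 3.0, n)
    mu = base * py * np.exp(log_rr * x)
    if alpha is None:
        y = rng.poisson(mu)
    else:
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
    return pd.DataFrame(
        {"patient_id": np.arange(n), "events": y, "person_years": py,
         "exposure": np.where(x == 1, "b", "a")}
    )


class TestCrudeRateRatio:
    def test_identical_rates_give_unity(self):
        est = crude_rate_ratio(50, 100.0, 25, 50.0)
        assert est.rr == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high

    def test_zero_events_flagged_degenerate(self):
        est = crude_rate_ratio(0, 10.0, 5, 10.0)
        assert est.degenerate and est.rr == 0.0 and np.isnan(est.ci_low)

    def test_invalid_person_time_rejected(self):
        with pytest.raises(ValueError):
            crude_rate_ratio(1, 0.0, 1, 1.0)


class TestPoisson:
    def test_saturated_exposure_reproduces_crude_ratio(self):
        rec = _poisson_records(500)
        fit = fit_poisson(rec, {"exposure": "a"})
        g = rec.groupby("exposure")[["events", "person_years"]].sum()
        crude = crude_rate_ratio(
            g.loc["b", "events"], g.loc["b", "person_years"],
            g.loc["a", "events"], g.loc["a", "person_years"],
        )
        assert fit.rate_ratio("exposure[b]").rr == pytest.approx(crude.rr, rel=1e-6)

    def test_known_log_rate_ratio_recovered(self):
        rec = _poisson_records(5000, log_rr=0.5, seed=3)
        fit = fit_poisson(rec, {"exposure": "a"})
        est = fit.rate_ratio("exposure[b]")
        assert est.ci_low < np.exp(0.5) < est.ci_high

    def test_constant_column_rejected(self):
        rec = _poisson_records(100).assign(flat=1.0)
        with pytest.raises(ValueError, match="constant|rank"):
            fit_poisson(rec, {"exposure": "a", "flat": None})

    def test_estimates_invariant_to_time_unit(self):
        rec = _poisson_records(400)
        days = rec.assign(person_years=rec["person_years"] * 365.25)
        a = fit_poisson(rec, {"exposure": "a"}).params["exposure[b]"]
        b = fit_poisson(days, {"exposure": "a"}).params["exposure[b]"]
        assert a == pytest.approx(b, abs=1e-10)

    def test_unit_weights_match_unweighted_exactly(self):
        rec = _poisson_records(400).assign(w=1.0)
        unw = fit_poisson(rec, {"exposure": "a"})
        wt = fit_poisson(rec, {"exposure": "a"}, weights="w")
        assert np.allclose(unw.params, wt.params, atol=1e-12)

    def test_half_weight_duplicates_leave_estimates_unchanged(self):
        rec = _poisson_records(300).assign(w=1.0)
        doubled = pd.concat([rec.assign(w=0.5)] * 2, ignore_index=True)
        a = fit_poisson(rec, {"exposure": "a"}, weights="w").params
        b = fit_poisson(doubled, {"exposure": "a"}, weights="w").params
        assert np.allclose(a, b, atol=1e-10)


class TestRobustVariance:
    def test_matches_model_based_for_well_specified_poisson(self):
        rec = _poisson_records(4000, seed=5)
        fit = fit_poisson(rec, {"exposure": "a"})
        robust = robust_variance(fit, rec["patient_id"])
        model_se = np.sqrt(np.diag(fit.cov))
        robust_se = np.sqrt(np.diag(robust))
        assert np.allclose(robust_se, model_se, rtol=0.10)

    def test_single_cluster_rejected(self):
        rec = _poisson_records(50)
        fit = fit_poisson(rec, {"exposure": "a"})
        with pytest.raises(ValueError):
            robust_variance(fit, np.zeros(len(rec)))


class TestNegBin:
    def test_alpha_near_zero_on_poisson_data(self):
        rec = _poisson_records(2000, seed=11)
        fit = fit_negbin(rec, {"exposure": "a"})
        assert fit.alpha < 0.05

    def test_reduces_to_poisson_as_alpha_vanishes(self):
        rec = _poisson_records(1000, seed=13)
        po = fit_poisson(rec, {"exposure": "a"})
        nb = fit_negbin(rec, {"exposure": "a"}, alpha=1e-8)
        assert np.allclose(nb.params, po.params, atol=1e-4)
        # freely estimated dispersion on Poisson data stays near zero
        free = fit_negbin(rec, {"exposure": "a"})
        assert free.alpha < 0.05
        assert np.allclose(free.params, po.params, atol=5e-3)

    def test_recovers_rate_ratio_under_overdispersion(self):
        rec = _poisson_records(4000, log_rr=0.5, seed=17, alpha=1.0)
        fit = fit_negbin(rec, {"exposure": "a"})
        est = fit.rate_ratio("exposure[b]")
        assert est.ci_low < np.exp(0.5) < est.ci_high
        assert 0.5 < fit.alpha < 1.8

    def test_weighted_profile_agrees_with_full_ml(self):
        rec = _poisson_records(1500, seed=19, alpha=0.8).assign(w=1.0)
        full = fit_negbin(rec, {"exposure": "a"})
        prof = fit_negbin(rec, {"exposure": "a"}, weights="w")
        assert prof.alpha == pytest.approx(full.alpha, rel=0.05)
        assert np.allclose(prof.params, full.params, atol=1e-3)


class TestOverdispersionTest:
    def test_detects_negative_binomial_data(self):
        hits = 0
        for seed in range(30):
            rec = _poisson_records(2000, seed=100 + seed, alpha=1.0)
            hits += overdispersion_test(rec, {"exposure": "a"})["overdispersed"]
        assert hits >= 28  # power > 90%

    def test_zero_events_defaults_to_poisson(self):
        rec = _poisson_records(50).assign(events=0)
        out = overdispersion_test(rec, {"exposure": "a"})
        assert out["family"] == "poisson" and np.isnan(out["statistic"])


def _survival_records(n=3000, log_hr=np.log(0.5), base=0.15, seed=23, cens=8.0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    t = rng.exponential(1 / (base * np.exp(log_hr * x)))
    c = rng.uniform(0, cens, n)
    return pd.DataFrame(
        {"patient_id": np.arange(n), "start": 0.0, "end": np.minimum(t, c),
         "event": (t <= c).astype(int), "grp": np.where(x == 1, "b", "a")}
    )


class TestCox:
    def test_recovers_true_hazard_ratio(self):
        rec = _survival_records()
        fit = fit_cox_first_event(rec, {"grp": "a"})
        est = fit.hazard_ratio("grp[b]")
        assert est.ci_low < 0.5 < est.ci_high

    def test_null_covariate_coverage(self):
        covered = 0
        n_rep = 40
        for seed in range(n_rep):
            rec = _survival_records(n=300, log_hr=0.0, seed=500 + seed)
            est = fit_cox_first_event(rec, {"grp": "a"}).hazard_ratio("grp[b]")
            covered += est.ci_low < 1.0 < est.ci_high
        assert covered >= int(0.85 * n_rep)

    def test_rare_events_approximate_crude_rate_ratio(self):
        rec = _survival_records(n=20000, base=0.01, cens=3.0, seed=29)
        fit = fit_cox_first_event(rec, {"grp": "a"})
        g = rec.groupby("grp").apply(
            lambda d: d["event"].sum() / d["end"].sum(), include_groups=False
        )
        crude = g["b"] / g["a"]
        assert fit.hazard_ratio("grp[b]").rr == pytest.approx(crude, rel=0.05)

    def test_no_events_rejected(self):
        rec = _survival_records(n=50).assign(event=0)
        with pytest.raises(ValueError):
            fit_cox_first_event(rec, {"grp": "a"})
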