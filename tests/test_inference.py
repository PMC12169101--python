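import numpy as np
import pandas as pd
import pytest

from forestdiv.beta_mixed import FitOptions
from forestdiv.design import RankDeficientError, build_design
from forestdiv.inference import (
    ModelSpec,
    back_transform,
    fit_model,
    omnibus_test,
    pairwise_contrasts,
    run_model_battery,
    select_time_form,
    subset_metric_table,
)
from forestdiv.results import FitResult

OPTS = FitOptions(n_starts=1)


def metric_table(seed=0, n=80, systems=("AG", "PC", "SC"), sd_u=0.4,
                 means=None, with_time=False):
    """Synthetic metric table at the MetricRecord level (bypasses communities)."""
    rng = np.random.default_rng(seed)
    means = means or {"AG": 0.55, "PC": 0.25, "SC": 0.65}
    rows = []
    for i in range(n):
        src = f"src{rng.integers(0, 25):03d}"
        system = str(rng.choice(systems))
        u = rng.normal(0, sd_u)
        base = means[system]
        t = float(rng.uniform(0, 60)) if with_time else np.nan
        inval = float(np.clip(base + 0.15 * u + rng.normal(0, 0.08), 0.01, 0.99))
        rows.append(
            {
                "study_id": f"{src}_s{i}", "source_id": src, "system": system,
                "IN": inval, "SI": inval,
                "SR": np.log(base / 0.5) + u * 0.2 + rng.normal(0, 0.2),
                "TA": np.log(base / 0.5) + u * 0.2 + rng.normal(0, 0.25),
                "n_ref": int(rng.integers(5, 40)),
                "weight": 1.0,
                "taxon_group": str(rng.choice(["insects", "birds", "mammals"])),
                "continent": str(rng.choice(["Asia", "Africa"])),
                "time_since_years": t,
            }
        )
    return pd.DataFrame(rows)


class TestModelSpecAndDesign:
    def test_family_follows_metric(self):
        assert ModelSpec(metric="IN").family == "beta_logit"
        assert ModelSpec(metric="SR").family == "gaussian"

    def test_threatened_intactness_rejected(self):
        with pytest.raises(ValueError, match="threatened"):
            ModelSpec(metric="IN", subset="threatened_animals")

    def test_cell_means_coding_without_intercept(self):
        df = metric_table(n=30)
        X, names = build_design(df, ("management",))
        assert names == ["system:AG", "system:PC", "system:SC"]
        assert np.allclose(X.sum(axis=1), 1.0)

    def test_treatment_coding_with_covariate(self):
        df = metric_table(n=30)
        X, names = build_design(df, ("management", "taxon_class"))
        assert names[0] == "intercept"
        assert "system:AG" not in names  # first level is the baseline

    def test_collinear_term_named(self):
        df = metric_table(n=30)
        df["continent"] = "Asia"  # single level -> no columns, fine
        df2 = df.copy()
        df2["time_since_years"] = 1.0  # constant column collinear w/ intercept
        with pytest.raises(RankDeficientError):
            build_design(df2, ("time", "log_time"))


class TestOmnibus:
    def test_identical_fits_give_zero_statistic(self):
        df = metric_table(n=60)
        spec = ModelSpec(metric="SR", random_structure="source_only")
        fit = fit_model(df, spec, OPTS)
        stat, dfree, p = omnibus_test(
            FitResult(**{**fit.__dict__, "n_params": fit.n_params + 1}), fit
        )
        assert stat == 0.0 and p == 1.0

    def test_df_counts_added_columns(self):
        df = metric_table(n=80)
        spec = ModelSpec(metric="SR", random_structure="source_only")
        full = fit_model(df, spec, OPTS)
        null = fit_model(
            df, ModelSpec(metric="SR", random_structure="source_only",
                          fixed_effects=("intercept_only",)), OPTS,
        )
        stat, dfree, p = omnibus_test(full, null)
        assert dfree == 2  # 3 system cells vs 1 intercept
        assert 0 <= p <= 1

    def test_mismatched_rows_rejected(self):
        df = metric_table(n=60)
        spec = ModelSpec(metric="SR", random_structure="source_only")
        f1 = fit_model(df, spec, OPTS)
        f2 = fit_model(df.iloc[:50], spec, OPTS)
        with pytest.raises(ValueError, match="different numbers of rows"):
            omnibus_test(f1, f2)


class TestTimeForm:
    def test_fewer_than_five_points_skipped(self):
        df = metric_table(n=4, systems=("PC",), with_time=True)
        spec = ModelSpec(metric="SR", random_structure="source_only")
        assert select_time_form(df, spec, OPTS) is None

    def test_strong_log_trend_selects_log_form(self):
        rng = np.random.default_rng(1)
        n = 80
        t = rng.uniform(0, 80, n)
        df = metric_table(seed=1, n=n, systems=("PL",), means={"PL": 0.4})
        df["time_since_years"] = t
        df["SR"] = -1.0 + 0.5 * np.log1p(t) + rng.normal(0, 0.25, n)
        spec = ModelSpec(metric="SR", random_structure="source_only")
        choice = select_time_form(df, spec, OPTS)
        assert choice.chosen_form == "log"
        assert choice.time_beats_intercept

    def test_pure_noise_keeps_intercept(self):
        rng = np.random.default_rng(2)
        n = 80
        df = metric_table(seed=2, n=n, systems=("PL",), means={"PL": 0.4})
        df["time_since_years"] = rng.uniform(0, 80, n)
        df["SR"] = rng.normal(0, 0.3, n)
        spec = ModelSpec(metric="SR", random_structure="source_only")
        choice = select_time_form(df, spec, OPTS)
        assert not choice.time_beats_intercept


class TestContrasts:
    def _fake_fit(self, means, ses=None):
        names = [f"system:{s}" for s in means]
        ses = ses or {s: 0.1 for s in means}
        cov = np.diag([ses[s] ** 2 for s in means])
        return FitResult(
            family="beta_logit",
            coefficients={f"system:{s}": m for s, m in means.items()},
            standard_errors={f"system:{s}": ses[s] for s in means},
            cov_fixed=cov, random_variances={"source": 0.1}, precision=10.0,
            loglik=0.0, n_obs=100, n_params=len(means) + 2, converged=True,
            term_names=names,
        )

    def test_wood_set_has_six_contrasts(self):
        fit = self._fake_fit({s: -0.5 for s in ("RI", "SC", "CC", "PL")})
        out = pairwise_contrasts(fit, "wood")
        assert len(out) == 6
        assert all(c.family_size == 6 for c in out)

    def test_equal_means_not_significant(self):
        fit = self._fake_fit({"AG": -0.4, "SP": -0.4, "PC": -0.4})
        out = pairwise_contrasts(fit, "food")
        assert all(c.p_adj == 1.0 for c in out)

    def test_absent_level_skipped(self):
        fit = self._fake_fit({"AG": -0.2, "PC": -1.2})
        out = pairwise_contrasts(fit, "food")
        assert len(out) == 1 and out[0].pair == ("AG", "PC")

    def test_bonferroni_multiplies_raw_p(self):
        fit = self._fake_fit({"AG": -0.2, "SP": -0.3, "PC": -1.2})
        out = pairwise_contrasts(fit, "food")
        for c in out:
            assert c.p_adj == pytest.approx(min(1.0, c.p_raw * 3))


class TestBackTransform:
    def test_logit_zero_maps_to_half(self):
        fit = FitResult(
            family="beta_logit", coefficients={"system:AG": 0.0},
            standard_errors={"system:AG": 0.2}, cov_fixed=np.array([[0.04]]),
            random_variances={}, precision=10.0, loglik=0.0, n_obs=50,
            n_params=3, converged=True, term_names=["system:AG"],
        )
        bt = back_transform(fit)
        assert bt["response_estimate"].iloc[0] == pytest.approx(0.5)
        assert bt["percent_change"].iloc[0] == pytest.approx(50.0)

    def test_log_ratio_maps_to_percent_reduction(self):
        fit = FitResult(
            family="gaussian", coefficients={"system:PC": np.log(0.54)},
            standard_errors={"system:PC": 0.1}, cov_fixed=np.array([[0.01]]),
            random_variances={}, precision=0.2, loglik=0.0, n_obs=50,
            n_params=3, converged=True, term_names=["system:PC"],
        )
        bt = back_transform(fit)
        assert bt["response_estimate"].iloc[0] == pytest.approx(0.54, abs=1e-9)
        assert bt["percent_change"].iloc[0] == pytest.approx(46.0)

    def test_interval_endpoints_stay_ordered(self):
        for fam, est in (("beta_logit", -0.7), ("gaussian", -0.3)):
            fit = FitResult(
                family=fam, coefficients={"a": est},
                standard_errors={"a": 0.25}, cov_fixed=np.array([[0.0625]]),
                random_variances={}, precision=1.0, loglik=0.0, n_obs=30,
                n_params=2, converged=True, term_names=["a"],
            )
            bt = back_transform(fit)
            assert bt["response_lo"].iloc[0] < bt["response_estimate"].iloc[0]
            assert bt["response_estimate"].iloc[0] < bt["response_hi"].iloc[0]


class TestBattery:
    def test_grid_cardinality_and_contrasts(self):
        table = metric_table(n=90, systems=("AG", "PC", "SC"))
        out = run_model_battery(
            {"main": table}, subsets=("animals",), metrics=("SR", "TA"),
            with_covariate_models=False, with_time_models=False, options=OPTS,
        )
        assert ("SR", "animals", "management") in out.fits
        assert ("TA", "animals", "management") in out.fits
        # food set has AG and PC present -> one contrast each metric
        assert len(out.contrasts[("SR", "animals", "food")]) == 1

    def test_subsetting_herpetofauna_pools_groups(self):
        df = metric_table(n=40)
        df.loc[:10, "taxon_group"] = "amphibians"
        df.loc[11:20, "taxon_group"] = "reptiles"
        sub = subset_metric_table(df, "herpetofauna")
        assert set(sub["taxon_group"]) <= {"amphibians", "reptiles"}
        assert len(sub) == 21

    def test_failed_fit_recorded_not_raised(self):
        table = metric_table(n=10, systems=("AG",))
        table["SR"] = np.nan  # SR model has nothing to fit
        out = run_model_battery(
            {"main": table}, subsets=("animals",), metrics=("SR",),
            with_covariate_models=False, with_time_models=False, options=OPTS,
        )
        assert ("SR", "animals", "management") in out.failures
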