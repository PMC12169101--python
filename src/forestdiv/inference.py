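"""Model specification, fitting, selection, contrasts and back-transformation.

This layer turns a tidy metric table (one row per study x system) into the
analysis outputs: per-system effect estimates with confidence intervals on
the response scale, likelihood-ratio omnibus tests, BIC-based choice of the
time-since-harvest functional form, and Bonferroni-adjusted pairwise
contrasts within the wood- and food-production system sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .beta_mixed import FitOptions, fit_beta_mixed
from .design import build_design
from .lmm import fit_gaussian_lmm
from .results import FitResult
from .systems import ANIMAL_GROUPS, HERPETOFAUNA, systems_in_set
from .transforms import inv_logit, smithson_verkuilen

logger = logging.getLogger(__name__)

#: Metric -> model family. Proportion-valued metrics get the beta family.
METRIC_FAMILY = {"IN": "beta_logit", "SI": "beta_logit", "SR": "gaussian", "TA": "gaussian"}

SUBSETS = (
    "animals", "plants", "insects", "birds", "herpetofauna", "mammals",
    "threatened_animals",
)

MIN_TIME_POINTS = 5  # time-trend models need at least this many dated records


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: metric, subset, fixed effects and random structure."""

    metric: str
    fixed_effects: tuple[str, ...] = ("management",)
    random_structure: str = "source_study_nested"
    weighted: bool = True
    subset: str = "animals"

    @property
    def family(self) -> str:
        return METRIC_FAMILY[self.metric]

    def __post_init__(self):
        if self.metric not in METRIC_FAMILY:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.subset == "threatened_animals" and self.metric == "IN":
            raise ValueError("threatened-animal models are fit for SI/SR/TA only")


def subset_metric_table(df: pd.DataFrame, subset: str) -> pd.DataFrame:
    """Select metric rows for a taxonomic subset (herpetofauna pools
    amphibians and reptiles)."""
    if subset in ("animals", "threatened_animals"):
        keep = df["taxon_group"].isin(ANIMAL_GROUPS)
    elif subset == "plants":
        keep = df["taxon_group"] == "plants"
    elif subset == "herpetofauna":
        keep = df["taxon_group"].isin(HERPETOFAUNA)
    elif subset in ("insects", "birds", "mammals"):
        keep = df["taxon_group"] == subset
    else:
        raise ValueError(f"unknown subset {subset!r}")
    return df.loc[keep]


def _prepare(df: pd.DataFrame, spec: ModelSpec):
    """Subset rows, drop incomplete covariates, build design and groups."""
    data = df.copy()
    data = data.dropna(subset=[spec.metric])
    needs_time = any(e in ("time", "log_time") for e in spec.fixed_effects)
    if needs_time:
        n0 = len(data)
        data = data.dropna(subset=["time_since_years"])
        if len(data) < n0:
            logger.info("dropped %d rows with missing time", n0 - len(data))
    if "continent" in spec.fixed_effects:
        n0 = len(data)
        data = data.dropna(subset=["continent"])
        if len(data) < n0:
            logger.info("dropped %d rows with missing continent", n0 - len(data))
    if data.empty:
        raise ValueError(f"no usable rows for {spec}")
    data = data.reset_index(drop=True)

    X, names = build_design(data, spec.fixed_effects)
    y = data[spec.metric].to_numpy(float)
    w = data["weight"].to_numpy(float) if spec.weighted else np.ones(len(data))

    source_codes, source_idx = np.unique(data["source_id"], return_inverse=True)
    if spec.random_structure == "source_study_nested":
        study_idx = data.groupby(["source_id", "study_id"], sort=True).ngroup().to_numpy()
        pairs = (
            data[["source_id", "study_id"]]
            .drop_duplicates()
            .sort_values(["source_id", "study_id"])
        )
        study_source = np.searchsorted(source_codes, pairs["source_id"].to_numpy())
    else:
        study_idx = study_source = None
    return data, y, X, names, w, source_idx, study_idx, study_source


def fit_model(
    df: pd.DataFrame, spec: ModelSpec, options: FitOptions | None = None
) -> FitResult:
    """Fit one mixed model per the spec on a (pre-subset) metric table.

    For the beta family the response is compressed with the
    Smithson–Verkuilen transform, with n = the number of rows entering this
    particular fit.
    """
    data, y, X, names, w, src, stu, stu_src = _prepare(df, spec)
    if spec.family == "beta_logit":
        y = smithson_verkuilen(y, len(y))
        fit = fit_beta_mixed(
            y, X, w, src, study_idx=stu, study_source=stu_src,
            term_names=names, options=options,
        )
    else:
        fit = fit_gaussian_lmm(
            y, X, w, src, study_idx=stu, term_names=names, options=options
        )
    fit.metric = spec.metric
    fit.subset = spec.subset
    fit.fixed_effects = spec.fixed_effects
    return fit


def omnibus_test(fit_full: FitResult, fit_null: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square test of the added fixed effect(s).

    The null model must be nested in the full model and fit on the same rows
    with the same random structure.
    """
    if fit_full.n_obs != fit_null.n_obs:
        raise ValueError("models fit on different numbers of rows; not comparable")
    if fit_full.random_structure != fit_null.random_structure:
        raise ValueError("models differ in random structure; not a fixed-effect LRT")
    df = fit_full.n_params - fit_null.n_params
    if df <= 0:
        raise ValueError("full model has no more parameters than the null")
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_null.loglik))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p


@dataclass
class TimeFormChoice:
    """Outcome of the time-functional-form comparison for one system."""

    system: str
    chosen_form: str  # "linear" | "log"
    fit_time: FitResult
    fit_intercept: FitResult
    bic_linear: float
    bic_log: float
    time_beats_intercept: bool


def select_time_form(
    df: pd.DataFrame,
    spec: ModelSpec,
    options: FitOptions | None = None,
) -> TimeFormChoice | None:
    """Choose between linear and ln(t+1) time for one system's records.

    ``df`` holds a single system's metric rows.  Fits intercept-only,
    linear-time and log-time models; the time form with the lower BIC wins
    (ties break toward linear, the fewer-transformation model).  Systems
    with fewer than five dated records are skipped (returns None).
    """
    dated = df.dropna(subset=["time_since_years", spec.metric])
    if len(dated) < MIN_TIME_POINTS:
        logger.warning(
            "system %s: only %d dated records (<%d); time model skipped",
            df["system"].iloc[0] if len(df) else "?", len(dated), MIN_TIME_POINTS,
        )
        return None
    base = replace(spec, fixed_effects=("intercept_only",))
    fit0 = fit_model(dated, base, options)
    fit_lin = fit_model(dated, replace(spec, fixed_effects=("time",)), options)
    fit_log = fit_model(dated, replace(spec, fixed_effects=("log_time",)), options)
    if fit_log.bic < fit_lin.bic:
        chosen, fit_t = "log", fit_log
    else:
        chosen, fit_t = "linear", fit_lin
    return TimeFormChoice(
        system=str(dated["system"].iloc[0]),
        chosen_form=chosen,
        fit_time=fit_t,
        fit_intercept=fit0,
        bic_linear=fit_lin.bic,
        bic_log=fit_log.bic,
        time_beats_intercept=bool(fit_t.bic < fit0.bic),
    )


@dataclass
class ContrastResult:
    """One within-set pairwise system contrast (link scale)."""

    pair: tuple[str, str]
    estimate: float
    se: float
    z: float
    p_raw: float
    p_adj: float
    family_size: int


def pairwise_contrasts(fit: FitResult, system_set: str) -> list[ContrastResult]:
    """All pairwise contrasts within the wood or food production set.

    Uses the cell-means management coefficients and their covariance;
    p-values are two-sided normal-approximation tests with a Bonferroni
    multiplier equal to the number of within-set pairs actually formed.
    Systems absent from the fit are skipped with a log note.
    """
    wanted = systems_in_set(system_set)
    terms = {t: i for i, t in enumerate(fit.term_names)}
    present = [s for s in wanted if f"system:{s}" in terms]
    for s in wanted:
        if s not in present:
            logger.info("system %s absent from fit; contrasts skipped", s)
    pairs = list(itertools.combinations(present, 2))
    m = len(pairs)
    out = []
    beta = fit.coef_array()
    for a, b in pairs:
        ia, ib = terms[f"system:{a}"], terms[f"system:{b}"]
        est = beta[ia] - beta[ib]
        var = fit.cov_fixed[ia, ia] + fit.cov_fixed[ib, ib] - 2 * fit.cov_fixed[ia, ib]
        se = float(np.sqrt(max(var, 0.0)))
        z = est / se if se > 0 else np.inf
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
        out.append(
            ContrastResult(
                pair=(a, b), estimate=float(est), se=se, z=float(z),
                p_raw=p_raw, p_adj=min(1.0, p_raw * m), family_size=m,
            )
        )
    return out


def back_transform(fit: FitResult, conf_level: float = 0.95) -> pd.DataFrame:
    """Map link-scale estimates to the response scale with Wald intervals.

    Beta-family fits are inverse-logit mapped to a proportion of the
    reference level; Gaussian fits (log-response ratios) are exponentiated
    to a managed/reference ratio.  ``percent_change`` is
    (1 - response-scale value) x 100 — the percent reduction relative to the
    undisturbed reference.
    """
    zq = stats.norm.ppf(0.5 + conf_level / 2.0)
    rows = []
    trans = inv_logit if fit.family == "beta_logit" else np.exp
    for t in fit.term_names:
        est = fit.coefficients[t]
        se = fit.standard_errors[t]
        lo, hi = est - zq * se, est + zq * se
        v, vlo, vhi = trans(est), trans(lo), trans(hi)
        rows.append(
            {
                "term": t,
                "link_estimate": est,
                "link_se": se,
                "response_estimate": float(v),
                "response_lo": float(vlo),
                "response_hi": float(vhi),
                "percent_change": (1.0 - float(v)) * 100.0,
                "percent_change_lo": (1.0 - float(vhi)) * 100.0,
                "percent_change_hi": (1.0 - float(vlo)) * 100.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BatteryResult:
    """Everything the model battery produced."""

    fits: dict[tuple, FitResult] = field(default_factory=dict)
    failures: dict[tuple, str] = field(default_factory=dict)
    comparisons: list[dict] = field(default_factory=list)
    contrasts: dict[tuple, list[ContrastResult]] = field(default_factory=dict)
    time_choices: dict[tuple, TimeFormChoice] = field(default_factory=dict)

    def comparison_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.comparisons)


def _random_structure_for(subset: str) -> str:
    # overall animal models use nested source/study intercepts; subsets with
    # mostly one study per source use a source-only intercept
    return "source_study_nested" if subset == "animals" else "source_only"


def run_model_battery(
    metric_tables: dict[str, pd.DataFrame],
    *,
    subsets: tuple[str, ...] = ("animals", "plants"),
    metrics: tuple[str, ...] = ("IN", "SI", "SR", "TA"),
    with_covariate_models: bool = True,
    with_time_models: bool = True,
    options: FitOptions | None = None,
) -> BatteryResult:
    """Run the full model grid over metrics and subsets.

    ``metric_tables`` maps table keys to metric tables: ``"main"`` for the
    full data and optionally ``"threatened"`` for the threatened-animal
    subset (which is fit for SI/SR/TA only, with a source-only intercept).
    Per metric x subset the battery fits the management-only model, the
    omnibus LRT against an intercept-only null, optional additive
    taxon-class and continent models with BIC comparisons, wood/food
    pairwise contrasts, and per-system time-form selection (animals only).
    Failed fits are recorded and the battery continues.
    """
    out = BatteryResult()
    main = metric_tables["main"]

    jobs: list[tuple[str, str, pd.DataFrame]] = []
    for subset in subsets:
        for metric in metrics:
            if subset == "threatened_animals":
                if metric == "IN":
                    continue
                table = metric_tables.get("threatened")
                if table is None:
                    continue
                jobs.append((metric, subset, subset_metric_table(table, subset)))
            else:
                jobs.append((metric, subset, subset_metric_table(main, subset)))

    for metric, subset, table in jobs:
        rs = _random_structure_for(subset)
        spec = ModelSpec(metric=metric, subset=subset, random_structure=rs)
        key = (metric, subset, "management")
        try:
            fit = fit_model(table, spec, options)
            out.fits[key] = fit
        except Exception as exc:  # battery must continue past failed fits
            logger.warning("fit failed for %s: %s", key, exc)
            out.failures[key] = str(exc)
            continue

        try:
            null = fit_model(
                table, replace(spec, fixed_effects=("intercept_only",)), options
            )
            out.fits[(metric, subset, "intercept_only")] = null
            stat, dfree, p = omnibus_test(fit, null)
            out.comparisons.append(
                {
                    "metric": metric, "subset": subset, "model": "management",
                    "bic": fit.bic, "null_bic": null.bic,
                    "lrt_stat": stat, "lrt_df": dfree, "lrt_p": p,
                }
            )
        except Exception as exc:
            out.failures[(metric, subset, "omnibus")] = str(exc)

        if with_covariate_models and subset in ("animals", "plants"):
            for extra in ("taxon_class", "continent"):
                if extra == "taxon_class" and subset != "animals":
                    continue
                ckey = (metric, subset, f"management+{extra}")
                try:
                    cfit = fit_model(
                        table,
                        replace(spec, fixed_effects=("management", extra)),
                        options,
                    )
                    out.fits[ckey] = cfit
                    out.comparisons.append(
                        {
                            "metric": metric, "subset": subset,
                            "model": f"management+{extra}",
                            "bic": cfit.bic, "null_bic": out.fits[key].bic,
                            "lrt_stat": np.nan, "lrt_df": np.nan, "lrt_p": np.nan,
                        }
                    )
                except Exception as exc:
                    out.failures[ckey] = str(exc)

        if subset in ("animals", "plants"):
            for sset in ("wood", "food"):
                try:
                    out.contrasts[(metric, subset, sset)] = pairwise_contrasts(
                        out.fits[key], sset
                    )
                except Exception as exc:
                    out.failures[(metric, subset, f"contrast_{sset}")] = str(exc)

        if with_time_models and subset == "animals":
            for system, sys_table in table.groupby("system"):
                # perennial-crop (and other per-system) time models use a
                # source-only intercept: few studies per source remain
                tspec = ModelSpec(
                    metric=metric, subset=subset, random_structure="source_only"
                )
                try:
                    choice = select_time_form(sys_table, tspec, options)
                except Exception as exc:
                    out.failures[(metric, subset, f"time_{system}")] = str(exc)
                    continue
                if choice is not None:
                    out.time_choices[(metric, subset, system)] = choice
    return out
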