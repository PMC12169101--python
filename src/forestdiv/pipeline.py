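"""End-to-end orchestration: simulate -> metrics -> fit -> report.

Each stage reads and writes delimited-text artifacts in a run directory so
stages are independently testable and a full run is reproducible from the
top-level seed alone.  The CLI in :mod:`forestdiv.cli` is a thin wrapper
around these functions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import data_model, metrics as metrics_mod, synthetic
from .beta_mixed import FitOptions
from .inference import run_model_battery, subset_metric_table
from .systems import SYSTEMS

logger = logging.getLogger(__name__)


def _setup_logging(out_dir: Path, verbose: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    handlers = [logging.StreamHandler(), logging.FileHandler(out_dir / "run.log")]
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def make_synthetic_config(cfg: dict, seed: int) -> synthetic.SyntheticConfig:
    """Build a SyntheticConfig from the `simulate:` section of a run config."""
    sim = dict(cfg.get("simulate", {}))
    effects = sim.pop("system_effects", None)
    trend = sim.pop("time_trend", None)
    kwargs = {}
    for f in dataclasses.fields(synthetic.SyntheticConfig):
        if f.name in sim:
            v = sim[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    kwargs["seed"] = seed
    config = synthetic.SyntheticConfig(**kwargs)
    if effects:
        merged = dict(config.system_effects)
        for code, e in effects.items():
            if code not in SYSTEMS:
                raise KeyError(f"simulate.system_effects: unknown system {code!r}")
            merged[code] = synthetic.SystemEffect(**e)
        config.system_effects = merged
    if trend:
        config.time_trend = synthetic.TimeTrend(
            form=trend.get("form", "none"),
            slope=trend.get("slope", 0.0),
            t_range=tuple(trend.get("t_range", (0.0, 50.0))),
        )
    return config


def cmd_simulate(cfg: dict, out_dir: str | Path, seed: int, verbose: bool = False) -> Path:
    """Generate a synthetic database; write abundance, red-list and truth tables."""
    out = Path(out_dir)
    _setup_logging(out, verbose)
    config = make_synthetic_config(cfg, seed)
    logger.info("simulate: seed=%d sources=%d", seed, config.n_sources)
    df, truth = synthetic.generate_database(config)
    data_model.write_abundance_table(df, out / "abundance.csv")
    synthetic.redlist_from_truth(truth).to_csv(out / "redlist.csv", index=False)
    truth.study_effects.to_csv(out / "ground_truth_effects.csv", index=False)
    with open(out / "ground_truth_expected.json", "w") as fh:
        json.dump({"expected_intactness": truth.expected_in}, fh, indent=2, sort_keys=True)
    logger.info("simulate: wrote %d abundance rows", len(df))
    return out / "abundance.csv"


def cmd_metrics(cfg: dict, out_dir: str | Path, seed: int = 0, verbose: bool = False) -> Path:
    """Validate input, merge threat status, average sites, compute metrics."""
    out = Path(out_dir)
    _setup_logging(out, verbose)
    abundance_path = cfg.get("abundance_table", out / "abundance.csv")
    redlist_path = cfg.get("redlist_table", out / "redlist.csv")
    df = data_model.load_abundance_table(abundance_path)
    if Path(redlist_path).exists():
        df = data_model.merge_threat_status(df, pd.read_csv(redlist_path))

    exclusions: list[dict] = []
    communities = data_model.average_site_abundances(df, exclusion_log=exclusions)
    records = metrics_mod.compute_all_metrics(communities, exclusion_log=exclusions)
    if not records:
        raise SystemExit("no metric records computable after exclusions")
    table = metrics_mod.metrics_to_frame(records)
    table.to_csv(out / "metrics.csv", index=False)

    threatened = data_model.subset_threatened(df)
    if len(threatened):
        tcomm = data_model.average_site_abundances(threatened, exclusion_log=[])
        trecs = metrics_mod.compute_all_metrics(tcomm, exclusion_log=[])
        if trecs:
            metrics_mod.metrics_to_frame(trecs).to_csv(
                out / "metrics_threatened.csv", index=False
            )

    with open(out / "exclusions.csv", "w") as fh:
        fh.write("source_id,study_id,reason\n")
        for e in exclusions:
            fh.write(f"{e['source_id']},{e['study_id']},{e['reason']}\n")

    if len(table.dropna(subset=["SR", "TA"])) >= 3:
        rho, pca = metrics_mod.metric_correlations(table)
        rho.to_csv(out / "metric_spearman.csv")
        pca["loadings"].assign(
            explained_variance=pd.Series(
                pca["explained_variance"], index=pca["loadings"].columns
            ).reindex(pca["loadings"].index)
        )
        pca["loadings"].to_csv(out / "metric_pca_loadings.csv")
        pd.DataFrame(
            {"component": pca["loadings"].columns,
             "explained_variance": pca["explained_variance"]}
        ).to_csv(out / "metric_pca_variance.csv", index=False)
    logger.info("metrics: %d study x system records", len(table))
    return out / "metrics.csv"


def cmd_fit(cfg: dict, out_dir: str | Path, seed: int = 0, verbose: bool = False) -> Path:
    """Run the model battery on the metric tables and write all outputs."""
    out = Path(out_dir)
    _setup_logging(out, verbose)
    fit_cfg = dict(cfg.get("fit", {}))
    metrics_path = cfg.get("metrics_table", out / "metrics.csv")
    tables = {"main": pd.read_csv(metrics_path, dtype={"source_id": str, "study_id": str})}
    tpath = Path(cfg.get("metrics_threatened_table", out / "metrics_threatened.csv"))
    if tpath.exists():
        tables["threatened"] = pd.read_csv(tpath, dtype={"source_id": str, "study_id": str})

    known = {"subsets", "metrics", "with_covariate_models", "with_time_models",
             "n_quad", "n_starts"}
    unknown = set(fit_cfg) - known
    if unknown:
        raise KeyError(f"fit config: unknown key(s) {sorted(unknown)}")
    options = FitOptions(
        seed=seed,
        n_quad=int(fit_cfg.get("n_quad", 15)),
        n_starts=int(fit_cfg.get("n_starts", 3)),
    )
    battery = run_model_battery(
        tables,
        subsets=tuple(fit_cfg.get("subsets", ("animals", "plants"))),
        metrics=tuple(fit_cfg.get("metrics", ("IN", "SI", "SR", "TA"))),
        with_covariate_models=bool(fit_cfg.get("with_covariate_models", True)),
        with_time_models=bool(fit_cfg.get("with_time_models", True)),
        options=options,
    )

    from .inference import back_transform

    coef_rows, bt_rows, contrast_rows, time_rows = [], [], [], []
    for key, fit in battery.fits.items():
        metric, subset, model = key
        for row in fit.summary_rows():
            coef_rows.append(
                {"metric": metric, "subset": subset, "model": model, **row,
                 "converged": fit.converged, "bic": fit.bic, "loglik": fit.loglik,
                 "n_obs": fit.n_obs}
            )
        if model == "management":
            bt = back_transform(fit)
            bt.insert(0, "metric", metric)
            bt.insert(1, "subset", subset)
            bt_rows.append(bt)
    for (metric, subset, sset), contrasts in battery.contrasts.items():
        for c in contrasts:
            contrast_rows.append(
                {"metric": metric, "subset": subset, "set": sset,
                 "system_a": c.pair[0], "system_b": c.pair[1],
                 "estimate": c.estimate, "se": c.se, "z": c.z,
                 "p_raw": c.p_raw, "p_adj": c.p_adj, "family_size": c.family_size}
            )
    for (metric, subset, system), choice in battery.time_choices.items():
        time_rows.append(
            {"metric": metric, "subset": subset, "system": system,
             "chosen_form": choice.chosen_form,
             "bic_intercept": choice.fit_intercept.bic,
             "bic_linear": choice.bic_linear, "bic_log": choice.bic_log,
             "time_beats_intercept": choice.time_beats_intercept}
        )

    pd.DataFrame(coef_rows).to_csv(out / "coefficients.csv", index=False)
    if bt_rows:
        pd.concat(bt_rows).to_csv(out / "back_transformed.csv", index=False)
    contrast_cols = ["metric", "subset", "set", "system_a", "system_b",
                     "estimate", "se", "z", "p_raw", "p_adj", "family_size"]
    time_cols = ["metric", "subset", "system", "chosen_form", "bic_intercept",
                 "bic_linear", "bic_log", "time_beats_intercept"]
    pd.DataFrame(contrast_rows, columns=contrast_cols).to_csv(
        out / "contrasts.csv", index=False)
    pd.DataFrame(time_rows, columns=time_cols).to_csv(
        out / "time_models.csv", index=False)
    battery.comparison_table().to_csv(out / "model_comparison.csv", index=False)
    if battery.failures:
        with open(out / "fit_failures.txt", "w") as fh:
            for key, msg in battery.failures.items():
                fh.write(f"{key}: {msg}\n")
        logger.warning("fit: %d model(s) failed; see fit_failures.txt", len(battery.failures))
    logger.info("fit: %d models fitted", len(battery.fits))
    return out / "back_transformed.csv"


def cmd_report(cfg: dict, out_dir: str | Path, seed: int = 0, verbose: bool = False) -> Path:
    """Assemble a human-readable markdown summary of the fit outputs."""
    out = Path(out_dir)
    _setup_logging(out, verbose)
    needed = ["back_transformed.csv", "contrasts.csv", "model_comparison.csv"]
    missing = [f for f in needed if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing fit outputs: {', '.join(missing)}")
    bt = pd.read_csv(out / "back_transformed.csv")
    contrasts = pd.read_csv(out / "contrasts.csv")
    comparison = pd.read_csv(out / "model_comparison.csv")
    time_tbl_path = out / "time_models.csv"
    time_tbl = pd.read_csv(time_tbl_path) if time_tbl_path.exists() else pd.DataFrame()

    lines = ["# Forest-management biodiversity effects", ""]
    for (metric, subset), grp in bt.groupby(["metric", "subset"], sort=True):
        lines.append(f"## {metric} — {subset}")
        lines.append("")
        lines.append("| system | estimate | 95% CI | % reduction vs reference |")
        lines.append("|---|---|---|---|")
        for _, r in grp.iterrows():
            term = str(r["term"])
            if not term.startswith("system:"):
                continue
            lines.append(
                f"| {term.removeprefix('system:')} | {r['response_estimate']:.3f} "
                f"| [{r['response_lo']:.3f}, {r['response_hi']:.3f}] "
                f"| {r['percent_change']:+.1f}% |"
            )
        lines.append("")
    lines.append("## Pairwise system contrasts (Bonferroni within wood / food sets)")
    lines.append("")
    if contrasts.empty:
        lines.append("no contrasts")
    else:
        lines.append("| metric | subset | set | pair | estimate | p (adj) |")
        lines.append("|---|---|---|---|---|---|")
        for _, r in contrasts.iterrows():
            lines.append(
                f"| {r['metric']} | {r['subset']} | {r['set']} "
                f"| {r['system_a']}–{r['system_b']} | {r['estimate']:+.3f} "
                f"| {r['p_adj']:.4f} |"
            )
    lines.append("")
    if not time_tbl.empty:
        lines.append("## Time-since-harvest/establishment models")
        lines.append("")
        lines.append("| metric | system | chosen form | beats intercept (BIC) |")
        lines.append("|---|---|---|---|")
        for _, r in time_tbl.iterrows():
            lines.append(
                f"| {r['metric']} | {r['system']} | {r['chosen_form']} "
                f"| {bool(r['time_beats_intercept'])} |"
            )
        lines.append("")
    lines.append("## Model comparison (BIC, omnibus LRT)")
    lines.append("")
    lines.append(comparison.to_csv(index=False, sep="|").strip())
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    logger.info("report: wrote %s", report)
    return report


def run_all(cfg: dict, out_dir: str | Path, seed: int, verbose: bool = False) -> Path:
    """simulate -> metrics -> fit -> report in one call (used by tests/scripts)."""
    cmd_simulate(cfg, out_dir, seed, verbose)
    cmd_metrics(cfg, out_dir, seed, verbose)
    cmd_fit(cfg, out_dir, seed, verbose)
    return cmd_report(cfg, out_dir, seed, verbose)
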