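"""End-to-end orchestration: cohorts -> lines -> metrics -> statistics.

``run_pipeline`` reads (or simulates) a bundle, runs every stage, and
writes one CSV per output plus a JSON manifest with the seed, a config
hash and per-stage row counts; ``render_tables`` turns the CSV outputs
into text tables shaped like the study's reporting tables.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .cohorts import AnalysisConfig, build_cohorts
from .io import read_bundle, write_bundle
from .lines import lines_to_frame
from .metrics import (
    group_flows,
    second_line_aa_report,
    sequence_table,
    transition_rates,
)
from .simulate import SimulationConfig, analysis_config_for_simulation, simulate_bundle
from .stats import (
    ModelError,
    build_covariates_bulk,
    build_overall_duration_records,
    covariates_to_frame,
    fit_overall_duration_cox,
    fit_single_dose_logistic,
    km_duration,
)
from .vocab import DrugVocabulary


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, date_format="%Y-%m-%d")
    return len(df)


def run_pipeline(
    out_dir: str | Path,
    bundle_dir: str | Path | None = None,
    sim_config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
    analysis_config: Optional[AnalysisConfig] = None,
    vocab: Optional[DrugVocabulary] = None,
) -> dict:
    """Run every stage and write the output directory; returns the manifest.

    Exactly one of ``bundle_dir`` (pre-existing bundle) or ``sim_config``
    (simulate first; the bundle is written under ``out/bundle``) must be
    given.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vocab = vocab or DrugVocabulary.default()

    if (bundle_dir is None) == (sim_config is None):
        raise ValueError("give exactly one of bundle_dir or sim_config")
    if bundle_dir is not None:
        bundle = read_bundle(bundle_dir, vocab=vocab)
        acfg = analysis_config or AnalysisConfig()
        seed_used = seed
        config_blob = {"bundle_dir": str(bundle_dir)}
    else:
        bundle, _truth = simulate_bundle(sim_config, seed)
        write_bundle(bundle, out / "bundle")
        acfg = analysis_config or analysis_config_for_simulation(sim_config)
        seed_used = sim_config.seed if seed is None else seed
        config_blob = json.loads(sim_config.model_dump_json())

    manifest: dict = {
        "package_version": __version__,
        "seed": seed_used,
        "config_sha256": hashlib.sha256(
            json.dumps(config_blob, sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
        "outputs": {},
        "notes": [],
    }

    def record(stage: str, filename: str, n_rows: int) -> None:
        manifest["stages"][stage] = n_rows
        manifest["outputs"][filename] = stage

    res = build_cohorts(bundle, vocab, acfg)
    record("cohorts", "cohorts.csv", _write(res.to_frame(), out / "cohorts.csv"))
    log_frames = []
    for pop, log in res.logs.items():
        df = log.to_frame()
        df.insert(0, "population", pop)
        log_frames.append(df)
    record("selection_log", "selection_log.csv",
           _write(pd.concat(log_frames, ignore_index=True), out / "selection_log.csv"))

    lines_df = lines_to_frame(res.lines, vocab)
    record("lines", "lines.csv", _write(lines_df, out / "lines.csv"))

    record("transition_rates", "transition_rates.csv",
           _write(transition_rates(res.lines, res.members), out / "transition_rates.csv"))
    record("sequence_table", "sequence_table.csv",
           _write(sequence_table(res.lines, res.members, vocab), out / "sequence_table.csv"))
    record("sequence_flows", "sequence_flows.csv",
           _write(group_flows(res.lines, res.members, vocab), out / "sequence_flows.csv"))

    report = second_line_aa_report(bundle, res.members, res.lines, vocab, acfg)
    record("second_line_report", "second_line_report.csv",
           _write(report.table, out / "second_line_report.csv"))

    if len(report.km_records):
        km = km_duration(report.km_records)
        km_summary = pd.DataFrame(
            [{
                "n": km.n, "n_events": km.n_events,
                "median_days": km.median,
                "median_ci_low_days": km.median_ci[0],
                "median_ci_high_days": km.median_ci[1],
                "mean_days": km.mean, "mean_se_days": km.mean_se,
                "mean_underestimated": km.mean_underestimated,
            }]
        )
        record("km_summary", "km_summary.csv", _write(km_summary, out / "km_summary.csv"))
        record("km_curve", "km_curve.csv", _write(km.curve, out / "km_curve.csv"))
    else:
        manifest["notes"].append("km: empty subpopulation, no duration records")

    subpop = [m for m in res.members if m.in_folfiri_aa_subpop]
    if subpop:
        covs = build_covariates_bulk(bundle, subpop, res.lines, vocab, acfg)
        X = covariates_to_frame(covs)
        y = report.single_use
        try:
            logit = fit_single_dose_logistic(X.loc[X.index.intersection(y.index)],
                                             y.astype(bool))
            df = logit.table.copy()
            df["n_used"] = logit.n_used
            record("logistic_fit", "logistic_fit.csv", _write(df, out / "logistic_fit.csv"))
        except ModelError as exc:
            manifest["notes"].append(f"logistic: {exc}")
        records = build_overall_duration_records(bundle, subpop, res.lines, acfg)
        try:
            cox = fit_overall_duration_cox(X, records)
            df = cox.table.copy()
            df["n_used"] = cox.n_used
            record("cox_fit", "cox_fit.csv", _write(df, out / "cox_fit.csv"))
        except ModelError as exc:
            manifest["notes"].append(f"cox: {exc}")
    else:
        manifest["notes"].append("models: empty subpopulation, nothing to fit")

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _fmt_pct(n: int, d: int) -> str:
    from .metrics import rate_percent

    r = rate_percent(n, d)
    return "-" if r is None else f"{n} ({r})"


def render_tables(out_dir: str | Path) -> dict[str, str]:
    """Render text tables from a pipeline output directory.

    Produces a transition-rate table (strata as columns), the second-line
    prescription-characteristics table, and the model tables when present.
    Returns {filename: text} and writes each file.
    """
    out = Path(out_dir)
    rendered: dict[str, str] = {}

    path = out / "transition_rates.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing input table {path}")
    tr = pd.read_csv(path)
    lines = ["Transition rates between lines of therapy",
             f"{'population':<18}{'transition':<12}{'RAS-mutant':>24}{'RAS-wild':>24}"]
    for pop in tr["population"].unique():
        sub = tr[tr["population"] == pop]
        for fl in sorted(sub["from_line"].unique()):
            row = {}
            for ras in ("mutant", "wild_type"):
                r = sub[(sub["from_line"] == fl) & (sub["presumed_ras"] == ras)]
                if len(r):
                    r = r.iloc[0]
                    rate = "-" if pd.isna(r["rate_percent"]) else f"{r['rate_percent']}"
                    row[ras] = f"{int(r['n_transitioned'])}/{int(r['n_evaluable'])} ({rate})"
                else:
                    row[ras] = "-"
            lines.append(f"{pop:<18}{f'{fl}->{fl+1}':<12}"
                         f"{row['mutant']:>24}{row['wild_type']:>24}")
    rendered["table_transitions.txt"] = "\n".join(lines) + "\n"

    path = out / "second_line_report.csv"
    if path.exists():
        rep = pd.read_csv(path)
        lines = ["Second-line antiangiogenic prescription characteristics", ""]
        for _, r in rep.iterrows():
            n_eval = int(r["n_evaluable"])
            lines += [
                f"stratum: {r['stratum']}   n={int(r['n_subpop'])}  evaluable n={n_eval}",
                f"  transitioned to 3rd line, n (%):  "
                f"{_fmt_pct(int(r['n_transitioned_3rd']), n_eval)}",
                "  antiangiogenic prescriptions, median (IQR): "
                + ("-" if n_eval == 0 else
                   f"{r['aa_rx_median']:g} ({r['aa_rx_q1']:g}-{r['aa_rx_q3']:g})"),
                f"  dose reduction, n (%):            "
                f"{_fmt_pct(int(r['n_dose_reduced']), n_eval)}",
                f"  prescription gap >=21d, n (%):    "
                f"{_fmt_pct(int(r['n_gap_ge21']), n_eval)}",
                f"  single prescription, n (%):       "
                f"{_fmt_pct(int(r['n_single_use']), n_eval)}",
                "",
            ]
        rendered["table_second_line.txt"] = "\n".join(lines)

    for stem, title in (("cox_fit", "Cox model: overall treatment duration "
                                    "from second-line start (hazard ratios)"),
                        ("logistic_fit", "Logistic model: single antiangiogenic "
                                         "prescription vs >=2 (odds ratios)")):
        path = out / f"{stem}.csv"
        if not path.exists():
            continue
        fit = pd.read_csv(path)
        lines = [title, f"{'covariate':<28}{'estimate':>9}{'95% CI':>17}{'p':>9}"]
        for _, r in fit.iterrows():
            lines.append(
                f"{r['term']:<28}{r['estimate']:>9.2f}"
                f"{f'{r.ci_low:.2f}-{r.ci_high:.2f}':>17}{r['p']:>9.4f}"
            )
        lines.append(f"n used: {int(fit['n_used'].iloc[0])}")
        rendered[f"table_{stem}.txt"] = "\n".join(lines) + "\n"

    for name, text in rendered.items():
        (out / name).write_text(text, encoding="utf-8")
    return rendered
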