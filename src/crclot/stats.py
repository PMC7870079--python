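"""Covariate construction and the statistical stages.

Three stages mirror the study's analysis plan for the FOLFIRI plus
antiangiogenic subpopulation:

* Kaplan-Meier estimation of second-line antiangiogenic treatment
  duration (median with log-log 95% CI; restricted mean with an
  underestimation flag when the largest observation is censored);
* a multivariate logistic model for receiving a single antiangiogenic
  prescription versus two or more (odds ratios with Wald 95% CIs);
* a multivariate Cox proportional-hazards model (Efron ties) for overall
  treatment duration from second-line start to the end of all antitumor
  therapy, with completion under the 60-day rule as the event.

Baseline covariates derive only from events in the year up to and
including the index date; concomitant covariates only from events within
the second line's half-open interval.  Rows with missing BMI or ADL are
excluded complete-case and the exclusion is reported, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields
from datetime import timedelta
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats as sps

from .cohorts import AnalysisConfig, CohortMember, age_on, second_line
from .events import collect_events
from .io import ClaimsBundle, barthel_total
from .lines import TherapyLine
from .vocab import DrugVocabulary

RIGHT_SIDED_CODES = tuple(f"C18.{i}" for i in range(5))  # C18.0-C18.4
LEFT_SIDED_PREFIXES = ("C18.5", "C18.6", "C18.7", "C19", "C20")

#: covariates of the single-dose logistic model, in reporting order
LOGISTIC_COVARIATES = [
    "designated_cancer_hospital", "age_ge70_at_2l", "male", "left_sided",
    "presumed_ras_wild", "bmi_le_18_5", "adl_not_independent",
    "oral_fp_prev_line", "irinotecan_prev_line", "prev_line_ge180d",
    "early_recurrence",
]
#: the Cox model adds the concomitant second-line covariates
COX_COVARIATES = LOGISTIC_COVARIATES + [
    "qual_proteinuria_2l", "quant_proteinuria_2l", "antihypertensive_2l",
    "anticholinergic_2l", "anticoagulant_2l",
]


class ModelError(RuntimeError):
    """Raised when a model cannot produce a trustworthy fit (separation,
    no events, non-convergence)."""


@dataclass
class CovariateVector:
    patient_id: str
    designated_cancer_hospital: bool
    age_ge70_at_2l: bool
    male: bool
    left_sided: bool
    right_sided: bool
    presumed_ras_wild: bool
    bmi_le_18_5: Optional[bool]  # None when BMI missing at baseline
    adl_not_independent: Optional[bool]  # None when no Barthel at baseline
    oral_fp_prev_line: bool
    irinotecan_prev_line: bool
    prev_line_ge180d: bool
    early_recurrence: bool
    qual_proteinuria_2l: bool
    quant_proteinuria_2l: bool
    antihypertensive_2l: bool
    anticholinergic_2l: bool
    anticoagulant_2l: bool

    @property
    def bmi_missing(self) -> bool:
        return self.bmi_le_18_5 is None

    @property
    def adl_missing(self) -> bool:
        return self.adl_not_independent is None


@dataclass
class SurvivalRecord:
    duration_days: int
    event: bool


@dataclass
class ModelFit:
    kind: str  # 'logistic' | 'cox'
    table: pd.DataFrame  # term, estimate, ci_low, ci_high, p
    n_used: int
    n_excluded_missing: int
    converged: bool


def _in_line_window(dates: pd.Series, line: TherapyLine) -> pd.Series:
    return (dates >= line.start_date) & (dates < line.end_date)


def build_covariates_bulk(
    bundle: ClaimsBundle,
    members: list[CohortMember],
    lines_by_pid: dict[str, list[TherapyLine]],
    vocab: DrugVocabulary,
    config: AnalysisConfig | None = None,
) -> list[CovariateVector]:
    """Assemble covariate vectors at second-line start for many members.

    Every member must have an index date (a derived second line).
    """
    config = config or AnalysisConfig()
    events = collect_events(bundle)
    birth_year = dict(zip(bundle.patients["patient_id"], bundle.patients["birth_year"]))
    sex = dict(zip(bundle.patients["patient_id"], bundle.patients["sex"]))
    hospital = dict(zip(bundle.patients["patient_id"], bundle.patients["hospital_id"]))
    designated = dict(zip(bundle.hospitals["hospital_id"],
                          bundle.hospitals["designated_cancer"]))

    out: list[CovariateVector] = []
    for member in members:
        pid = member.patient_id
        if member.index_date is None:
            raise ValueError(f"{pid}: no index date (no second line)")
        index = member.index_date
        lines = lines_by_pid[pid]
        line2 = second_line(lines)
        prev = lines[lines.index(line2) - 1]
        ev = events[pid]

        codes = [code for _, code, conf in ev.dx if conf]
        right = any(c in RIGHT_SIDED_CODES for c in codes)
        left = any(c.startswith(LEFT_SIDED_PREFIXES) for c in codes)

        base_start = index - timedelta(days=config.baseline_window_days)
        bmi_flag = adl_flag = None
        latest_bmi = latest_adl = None
        for d, kind, value in ev.ass:
            if not (base_start <= d <= index):
                continue
            if kind == "bmi" and (latest_bmi is None or d >= latest_bmi[0]):
                latest_bmi = (d, value)
            elif kind == "barthel" and (latest_adl is None or d >= latest_adl[0]):
                latest_adl = (d, value)
        if latest_bmi is not None:
            bmi_flag = float(latest_bmi[1]) <= 18.5
        if latest_adl is not None:
            adl_flag = barthel_total(latest_adl[1]) < 100

        prev_classes = {vocab.drug_class(d) for d in prev.regimen.all_drugs}
        rx2_classes = {
            vocab.drug_class(drug) for d, drug, _, _ in ev.rx
            if line2.start_date <= d < line2.end_date
        }
        proc2_kinds = {
            kind for d, kind in ev.proc
            if line2.start_date <= d < line2.end_date
        }

        out.append(CovariateVector(
            patient_id=pid,
            designated_cancer_hospital=bool(designated[hospital[pid]]),
            age_ge70_at_2l=age_on(int(birth_year[pid]), index) >= 70,
            male=sex[pid] == "male",
            left_sided=left,
            right_sided=right,
            presumed_ras_wild=member.presumed_ras == "wild_type",
            bmi_le_18_5=bmi_flag,
            adl_not_independent=adl_flag,
            oral_fp_prev_line="fluoropyrimidine_oral" in prev_classes,
            irinotecan_prev_line="irinotecan" in prev_classes,
            prev_line_ge180d=prev.duration_days >= 180,
            early_recurrence=member.population == "early_recurrence",
            qual_proteinuria_2l="proteinuria_qualitative" in proc2_kinds,
            quant_proteinuria_2l="proteinuria_quantitative" in proc2_kinds,
            antihypertensive_2l="antihypertensive" in rx2_classes,
            anticholinergic_2l="anticholinergic" in rx2_classes,
            anticoagulant_2l="anticoagulant" in rx2_classes,
        ))
    return out


def build_covariates(
    bundle: ClaimsBundle,
    member: CohortMember,
    lines: list[TherapyLine],
    vocab: DrugVocabulary,
    config: AnalysisConfig | None = None,
) -> CovariateVector:
    """Assemble the covariate vector for one member at second-line start."""
    return build_covariates_bulk(
        bundle, [member], {member.patient_id: lines}, vocab, config
    )[0]


def covariates_to_frame(covariates: list[CovariateVector]) -> pd.DataFrame:
    rows = []
    for cv in covariates:
        row = {f.name: getattr(cv, f.name) for f in dataclass_fields(CovariateVector)}
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("patient_id")
    return df


@dataclass
class KMResult:
    median: float
    median_ci: tuple[float, float]
    mean: float
    mean_se: float
    curve: pd.DataFrame  # time, survival
    mean_underestimated: bool  # largest observation censored
    n: int
    n_events: int


def km_duration(records: pd.DataFrame | list[SurvivalRecord]) -> KMResult:
    """Product-limit estimate of a duration distribution.

    ``records`` holds ``duration_days`` and ``event`` (True = completed).
    The restricted mean is computed up to the largest observed time and is
    flagged as underestimated when the largest observation is censored.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            [{"duration_days": r.duration_days, "event": r.event} for r in records]
        )
    if records.empty:
        raise ValueError("km_duration needs at least one record")
    durations = records["duration_days"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    ci_low, ci_high = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    t_max = float(durations.max())
    largest_censored = not events[durations == durations.max()].any()
    rmst, var = _restricted_mean(kmf, t_max)
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    return KMResult(
        median=median,
        median_ci=(ci_low, ci_high),
        mean=float(rmst),
        mean_se=float(np.sqrt(var)),
        curve=curve,
        mean_underestimated=largest_censored,
        n=len(records),
        n_events=int(events.sum()),
    )


def _restricted_mean(kmf: KaplanMeierFitter, t_max: float) -> tuple[float, float]:
    """Restricted mean survival time up to ``t_max`` and its variance.

    Area under the product-limit step function, with the standard
    risk-set variance (sum over event times of d_i/(n_i(n_i-d_i)) times
    the squared remaining area).
    """
    sf = kmf.survival_function_.iloc[:, 0]
    times = np.asarray(sf.index, dtype=float)
    surv = sf.to_numpy(dtype=float)
    grid = np.concatenate([times[times <= t_max], [t_max]])
    # survival just before each grid step
    steps = np.diff(grid)
    s_left = surv[: len(grid) - 1]
    rmst = float(np.sum(s_left * steps))

    ev = kmf.event_table
    var = 0.0
    for t, row in ev.iterrows():
        d, n = float(row["observed"]), float(row["at_risk"])
        if d == 0 or t > t_max or n - d <= 0:
            continue
        mask = grid[:-1] >= t
        area_after = float(np.sum(s_left[mask] * steps[mask]))
        var += area_after**2 * d / (n * (n - d))
    return rmst, var


def _complete_case(X: pd.DataFrame, covariates: list[str]) -> tuple[pd.DataFrame, int]:
    sub = X[covariates].copy()
    mask = sub.notna().all(axis=1)
    return sub.loc[mask].astype(float), int((~mask).sum())


def fit_single_dose_logistic(
    X: pd.DataFrame, y: pd.Series, covariates: list[str] | None = None
) -> ModelFit:
    """Logistic model for one antiangiogenic prescription vs two or more.

    ``y`` is True for single use, so odds ratios > 1 mean higher odds of
    stopping after one prescription.  Complete-case on missing covariates.
    """
    import statsmodels.api as sm

    covariates = covariates or LOGISTIC_COVARIATES
    Xc, n_excluded = _complete_case(X, covariates)
    yc = y.reindex(Xc.index).astype(float)
    if yc.nunique() < 2:
        raise ModelError("logistic outcome is constant; no finite fit exists")
    design = sm.add_constant(Xc, has_constant="add")
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-convergence is raised below
            fit = sm.Logit(yc, design).fit(disp=0, maxiter=200)
    except Exception as exc:  # includes PerfectSeparationError
        raise ModelError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False) or not np.isfinite(fit.bse).all():
        raise ModelError("logistic fit did not converge (possible separation)")
    params = fit.params.drop("const")
    se = fit.bse.drop("const")
    p = fit.pvalues.drop("const")
    z = sps.norm.ppf(0.975)
    table = pd.DataFrame(
        {
            "term": params.index,
            "estimate": np.exp(params.values),
            "ci_low": np.exp(params.values - z * se.values),
            "ci_high": np.exp(params.values + z * se.values),
            "p": p.values,
        }
    )
    return ModelFit(kind="logistic", table=table, n_used=len(Xc),
                    n_excluded_missing=n_excluded, converged=True)


def build_overall_duration_records(
    bundle: ClaimsBundle,
    members: list[CohortMember],
    lines_by_pid: dict[str, list[TherapyLine]],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Overall treatment duration from second-line start to the end of all
    antitumor therapy (last line's expected final dose date), with the
    60-day completion rule deciding event vs censoring."""
    config = config or AnalysisConfig()
    margin = config.line.completion_margin_days
    data_end = dict(zip(bundle.patients["patient_id"], bundle.patients["data_end"]))
    rows = []
    for m in members:
        lines = lines_by_pid.get(m.patient_id, [])
        line2 = second_line(lines)
        if line2 is None:
            continue
        last = lines[-1]
        final_efd = last.expected_final_dose_date
        event = (data_end[m.patient_id] - final_efd).days >= margin
        end = final_efd if event else min(final_efd, data_end[m.patient_id])
        rows.append(
            {
                "patient_id": m.patient_id,
                "duration_days": (end - line2.start_date).days,
                "event": event,
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "duration_days", "event"])


def fit_overall_duration_cox(
    X: pd.DataFrame, records: pd.DataFrame, covariates: list[str] | None = None
) -> ModelFit:
    """Cox proportional-hazards fit (Efron ties) of overall treatment
    duration on the covariate set; complete-case on missing covariates."""
    covariates = covariates or COX_COVARIATES
    Xc, n_excluded = _complete_case(X, covariates)
    rec = records.set_index("patient_id").reindex(Xc.index)
    df = Xc.copy()
    df["duration_days"] = rec["duration_days"].astype(float)
    df["event"] = rec["event"].astype(bool)
    if not df["event"].any():
        raise ModelError("no events; Cox model cannot be fit")
    import warnings

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # fit failures are raised as ModelError
            cph.fit(df, duration_col="duration_days", event_col="event")
    except Exception as exc:
        raise ModelError(f"Cox fit failed: {exc}") from exc
    summ = cph.summary
    table = pd.DataFrame(
        {
            "term": summ.index,
            "estimate": summ["exp(coef)"].values,
            "ci_low": summ["exp(coef) lower 95%"].values,
            "ci_high": summ["exp(coef) upper 95%"].values,
            "p": summ["p"].values,
        }
    )
    return ModelFit(kind="cox", table=table, n_used=len(df),
                    n_excluded_missing=n_excluded, converged=True)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, 1 df."""
    cells = np.array([[a, b], [c, d]], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be nonnegative")
    if (cells.sum(axis=0) == 0).any() or (cells.sum(axis=1) == 0).any():
        raise ValueError("all margins of the 2x2 table must be positive")
    stat, p, _, _ = sps.chi2_contingency(cells, correction=False)
    return float(stat), float(p)
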