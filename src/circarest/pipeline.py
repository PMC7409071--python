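"""Per-subject orchestration and cohort-level reporting.

``run_subject`` executes ingest -> dichotomy (72-h triage, then the full
window) -> rest-activity HMM -> spectral rhythm/r24 -> cosinor -> DLMO for
one subject directory. Stages the protocol tolerates missing (saliva
panels, temperature) downgrade to warnings; only unusable activity aborts.

``run_cohort`` aggregates the per-subject reports into a covariate table,
group contrasts (Welch / Fisher), the correlation matrix of the four RACR
parameters (I<O, P1-1, RI, r24), the low/high classification counts, and
the AICc determinant analysis of I<O.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cosinor, determinants, dichotomy, dlmo, ingest, resthmm, \
    rhythmspec
from .config import AnalysisConfig
from .series import BedSpans


def _config_hash(config: AnalysisConfig) -> str:
    return hashlib.sha1(
        yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.Timestamp):
        return obj.isoformat()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


@dataclass
class SubjectReport:
    subject_id: str
    config_hash: str
    seed: int
    io_72h: dichotomy.IOResult | None = None
    io_full: dichotomy.IOResult | None = None
    hmm_derived: resthmm.HmmDerived | None = None
    activity_rhythm: rhythmspec.RhythmEstimate | None = None
    activity_r24: rhythmspec.AutocorrResult | None = None
    temperature_rhythm: rhythmspec.RhythmEstimate | None = None
    temperature_cosinor: cosinor.CosinorFit | None = None
    temperature_class: cosinor.TempRhythmClass | None = None
    cortisol_cosinor: cosinor.CosinorFit | None = None
    dlmo_result: dlmo.DLMOResult | None = None
    completeness: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {f.name: _jsonable(getattr(self, f.name))
             for f in dataclasses.fields(self)}
        # drop the bulky ranked tables / raw arrays that are not per-subject
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=str)


def run_subject(subject_dir, config: AnalysisConfig | None = None) -> SubjectReport:
    cfg = config or AnalysisConfig()
    data = ingest.read_subject_dir(subject_dir, cfg.ingest)
    report = SubjectReport(subject_id=data.subject_id,
                           config_hash=_config_hash(cfg), seed=cfg.seed,
                           completeness=data.completeness or {},
                           covariates=data.covariates or {})
    if data.activity is None or data.activity.present().sum() == 0:
        raise ingest.IngestError(
            f"{data.subject_id}: no usable activity data; aborting")

    act5 = ingest.aggregate(data.activity, cfg.hmm.bin_min, "mean")

    # rest-activity HMM first: it provides the bed-span fallback
    hmm_path = None
    try:
        model = resthmm.fit_hmm(act5, harmonic=False, seed=cfg.seed,
                                config=cfg.hmm)
        hmm_path = resthmm.decode_states(model, act5)
        report.hmm_derived = resthmm.derive_metrics(model, hmm_path)
    except resthmm.HmmError as exc:
        report.warnings.append(f"hmm: {exc}")

    beds = None
    if data.diary is not None and len(data.diary) > 0:
        beds = data.diary.bed_spans()
    elif report.hmm_derived is not None and report.hmm_derived.sleep:
        sw = report.hmm_derived.sleep
        beds = BedSpans(spans=list(zip(sw.onsets, sw.wakes)),
                        provenance="hmm")
    if beds is None:
        report.warnings.append("dichotomy: no diary and no HMM rest windows")
    else:
        try:
            report.io_72h = dichotomy.compute_io_72h(data.activity, beds,
                                                     cfg.dichotomy)
        except dichotomy.DichotomyError as exc:
            report.warnings.append(f"io_72h: {exc}")
        try:
            report.io_full = dichotomy.compute_io(data.activity, beds,
                                                  config=cfg.dichotomy)
        except dichotomy.DichotomyError as exc:
            report.warnings.append(f"io_full: {exc}")

    # spectral rhythm + r24 on hourly aggregates
    for name, series in (("activity", data.activity),
                         ("temperature", data.temperature)):
        if series is None:
            report.warnings.append(f"{name}: absent")
            continue
        try:
            hourly = ingest.aggregate(series, 60, "mean")
            interp = ingest.interpolate_missing(hourly, cfg.ingest)
            spec = rhythmspec.periodogram(interp.series, cfg.rhythm)
            est = rhythmspec.dominant_rhythm(
                spec, seed=cfg.seed, config=cfg.rhythm,
                fraction_interpolated=interp.fraction_interpolated)
            setattr(report, f"{name}_rhythm", est)
            if name == "activity":
                report.activity_r24 = rhythmspec.autocorr24(hourly)
        except (rhythmspec.RhythmError, ingest.IngestError) as exc:
            report.warnings.append(f"{name} rhythm: {exc}")

    if data.temperature is not None:
        try:
            report.temperature_cosinor = cosinor.fit_temperature_cosinor(
                data.temperature, seed=cfg.seed, config=cfg.cosinor)
            if report.temperature_rhythm is not None:
                report.temperature_class = cosinor.classify_temperature_rhythm(
                    report.temperature_rhythm, report.temperature_cosinor)
        except cosinor.CosinorError as exc:
            report.warnings.append(f"temperature cosinor: {exc}")

    if data.cortisol is not None:
        try:
            report.cortisol_cosinor = cosinor.fit_cortisol_cosinor(
                data.cortisol, seed=cfg.seed, config=cfg.cosinor)
        except cosinor.CosinorError as exc:
            report.warnings.append(f"cortisol: {exc}")
    else:
        report.warnings.append("cortisol: panel absent")

    if data.melatonin is not None:
        try:
            report.dlmo_result = dlmo.dlmo_for_subject(
                data.melatonin, data.light,
                group=(data.covariates or {}).get("group"),
                config=cfg.dlmo)
        except dlmo.DlmoError as exc:
            report.warnings.append(f"dlmo: {exc}")
    else:
        report.warnings.append("melatonin: panel absent")
    return report


# ---------------------------------------------------------------------------
# Cohort level
# ---------------------------------------------------------------------------

RACR_PARAMS = ("io_percent", "p11", "ri", "r24")

DEFAULT_CANDIDATES = ("activity_amplitude", "sleep_duration_sd",
                      "out_median_activity", "mid_HA", "exercise_days",
                      "age", "meq_score", "psqi_global")


@dataclass
class CohortReport:
    config_hash: str
    seed: int
    table: pd.DataFrame
    group_medians: dict
    contrasts: dict
    racr_correlations: pd.DataFrame | None
    classification_counts: dict
    determinant_result: determinants.ModelSelectionResult | None
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        det = None
        if self.determinant_result is not None:
            det = _jsonable(dataclasses.asdict(self.determinant_result))
            det["ranked"] = self.determinant_result.ranked.head(10) \
                .assign(predictors=lambda d: d["predictors"].map(list)) \
                .to_dict("records")
        return {
            "config_hash": self.config_hash, "seed": self.seed,
            "table": self.table.to_dict("records"),
            "group_medians": _jsonable(self.group_medians),
            "contrasts": _jsonable(self.contrasts),
            "racr_correlations": (self.racr_correlations.to_dict()
                                  if self.racr_correlations is not None
                                  else None),
            "classification_counts": self.classification_counts,
            "determinants": det,
            "warnings": self.warnings,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(_jsonable(self.to_dict()), fh, indent=1, default=str)


def subject_row(report: SubjectReport) -> dict:
    """Flatten a SubjectReport into one covariate-table row."""
    row = {"subject_id": report.subject_id}
    cov = report.covariates or {}
    for key in ("group", "age", "sex", "exercise_days", "meq_score",
                "psqi_global", "hads_total", "mdasi_sleep"):
        if key in cov:
            row[key] = cov[key]
    if report.io_full is not None:
        row["io_percent"] = report.io_full.io_percent
        row["out_median_activity"] = report.io_full.out_median
    if report.io_72h is not None:
        row["io_72h"] = report.io_72h.io_percent
        row["io_category"] = report.io_72h.category
    if report.hmm_derived is not None:
        h = report.hmm_derived
        row.update(p11=h.p11, ri=h.ri, mid_MA=h.mid_MA, mid_HA=h.mid_HA,
                   center_of_rest=h.center_of_rest_h)
        if h.sleep is not None:
            row["sleep_duration_sd"] = h.sleep.sleep_duration_sd_h
    if report.activity_rhythm is not None:
        row["activity_amplitude"] = report.activity_rhythm.amplitude
        row["activity_acrophase"] = report.activity_rhythm.acrophase_h
    if report.activity_r24 is not None:
        row["r24"] = report.activity_r24.r24
    if report.temperature_class is not None:
        row["temp_class"] = report.temperature_class.label
        row["temp_physiologic"] = int(
            report.temperature_class.label == "physiologic")
    if report.temperature_cosinor is not None:
        row["temp_amplitude"] = report.temperature_cosinor.amplitude
        row["temp_acrophase"] = report.temperature_cosinor.acrophase_h
    if report.cortisol_cosinor is not None:
        c = report.cortisol_cosinor
        row.update(cortisol_mesor=c.mesor, cortisol_amplitude=c.amplitude,
                   cortisol_acrophase=c.acrophase_h,
                   cortisol_significant=(int(c.significant)
                                         if c.significant is not None
                                         else None))
    if report.dlmo_result is not None and report.dlmo_result.dlmo_time:
        row["dlmo_h"] = report.dlmo_result.dlmo_clock_h
    return row


def cohort_report_from_rows(rows: list, config: AnalysisConfig | None = None,
                            candidates=None) -> CohortReport:
    """Cohort-level statistics from flattened subject rows (deterministic:
    re-running on stored rows reproduces the report)."""
    cfg = config or AnalysisConfig()
    table = pd.DataFrame(rows)
    warnings_ = []
    numeric = [c for c in table.columns
               if pd.api.types.is_numeric_dtype(table[c])
               and c not in ("seed",)]
    group_medians = {}
    for g, sub in table.groupby("group"):
        group_medians[g] = {
            c: {"median": float(sub[c].median()),
                "min": float(sub[c].min()), "max": float(sub[c].max()),
                "n": int(sub[c].notna().sum())}
            for c in numeric if sub[c].notna().any()}

    contrasts = {}
    groups = sorted(table["group"].dropna().unique()) \
        if "group" in table else []
    if len(groups) == 2:
        ga = table[table["group"] == groups[0]]
        gb = table[table["group"] == groups[1]]
        if len(ga) < 2 or len(gb) < 2:
            warnings_.append("a group has < 2 subjects; contrasts skipped")
        else:
            for c in numeric:
                a = ga[c].dropna()
                b = gb[c].dropna()
                if len(a) >= 2 and len(b) >= 2 and (a.var() + b.var()) > 0:
                    contrasts[c] = determinants.group_compare(a, b, "welch")
            if "io_category" in table.columns:
                tab = pd.crosstab(table["group"], table["io_category"])
                if tab.shape == (2, 2):
                    contrasts["io_category"] = determinants.group_compare(
                        tab.to_numpy(), kind="fisher")
    else:
        warnings_.append("need exactly 2 groups for contrasts")

    racr = None
    racr_cols = [c for c in RACR_PARAMS if c in table.columns]
    if len(racr_cols) >= 2:
        racr = table[racr_cols].corr(method="spearman")

    counts = {}
    if "io_category" in table.columns:
        for g, sub in table.groupby("group"):
            counts[g] = {"low": int((sub["io_category"] == "low").sum()),
                         "high": int((sub["io_category"] == "high").sum())}

    det = None
    cand = [c for c in (candidates or DEFAULT_CANDIDATES)
            if c in table.columns]
    if "io_percent" in table.columns and cand:
        try:
            det = determinants.select_model(
                table, "io_percent", cand,
                include_intercept=cfg.determinants.include_intercept,
                config=cfg.determinants)
        except determinants.DeterminantsError as exc:
            warnings_.append(f"determinants: {exc}")

    return CohortReport(config_hash=_config_hash(cfg), seed=cfg.seed,
                        table=table, group_medians=group_medians,
                        contrasts=contrasts, racr_correlations=racr,
                        classification_counts=counts,
                        determinant_result=det, warnings=warnings_)


def run_cohort(cohort_dir, config: AnalysisConfig | None = None,
               candidates=None) -> CohortReport:
    cfg = config or AnalysisConfig()
    cohort_dir = Path(cohort_dir)
    subject_dirs = sorted(d for d in cohort_dir.iterdir()
                          if d.is_dir() and (d / "activity.csv").exists())
    rows = []
    warnings_ = []
    for d in subject_dirs:
        try:
            rows.append(subject_row(run_subject(d, cfg)))
        except ingest.IngestError as exc:
            warnings_.append(str(exc))
    report = cohort_report_from_rows(rows, cfg, candidates)
    report.warnings = warnings_ + report.warnings
    return report
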