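"""End-to-end orchestration: markers (or simulation) → features → reports.

The pipeline runs the stages in order — zero-phase filtering, gait event
detection, step segmentation, parameter extraction, per-subject
summaries, SI features, GHQ-12 scoring, and the cohort correlation /
regression analysis — and writes a report bundle (features CSV,
correlation CSV/text, regression JSON/text, manifest).  Subjects that
fail a stage (too few events, a missing side, below the minimum step
count) are excluded listwise with the reason recorded in the manifest.
Given the same configuration and seed the bundle is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import (GaitsymError, PipelineConfigError, SideMissingError)
from .events import EventConfig, detect_events, segment_steps
from .io import (MARKERS, GHQResponse, TrialTrajectories, read_ghq_csv,
                 read_marker_table, write_ghq_csv, write_marker_table)
from .parameters import (DEFAULT_MIN_STEPS, MFC_WINDOW, SubjectGaitSummary,
                         compute_mfc, compute_step_metrics, summarize_subject)
from .preprocess import FilterSpec, lowpass_filter
from .stats import (DEFAULT_PREDICTORS, FEATURE_COLUMNS, CorrelationReport,
                    RegressionReport, correlation_table, fit_ols)
from .symmetry import SIFeatures, score_ghq12, si_features
from .synthetic import CohortSpec, SyntheticCohort, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "preprocess_trial",
           "extract_subject", "build_cohort_table", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Serializable configuration for one pipeline run.

    Either ``marker_files``/``ghq_csv`` (analysis of recorded data) or
    ``simulate=True`` (synthetic cohort) must be set.
    """

    out_dir: str = "gaitsym_out"
    seed: int = 0
    # input mode
    marker_files: list[str] = field(default_factory=list)
    marker_format: str | None = None
    ghq_csv: str | None = None
    # simulation mode
    simulate: bool = False
    n_subjects: int = 126
    coupling: str = "default"          # "default" | "null"
    marker_noise_rms: float = 0.0
    n_steps: int = 36
    # preprocessing
    cutoff_hz: float = 6.0
    filter_order: int = 4
    # event detection
    refractory_s: float = 0.4
    heel_band_m: float = 0.015
    toe_rise_m: float = 0.005
    # parameters
    mfc_window: tuple[float, float] = MFC_WINDOW
    ground_ref: str = "midstance_median"
    min_steps: int = DEFAULT_MIN_STEPS
    # statistics
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    alpha: float = 0.05
    fdr: bool = False

    def validate(self) -> None:
        if not self.simulate and not self.marker_files:
            raise PipelineConfigError(
                "config must set simulate=true or list marker_files"
            )
        if not 0 < self.cutoff_hz:
            raise PipelineConfigError("cutoff_hz must be positive")
        if self.ground_ref not in ("midstance_median", "absolute"):
            raise PipelineConfigError(f"unknown ground_ref {self.ground_ref!r}")
        if not 0 <= self.mfc_window[0] < self.mfc_window[1] <= 1:
            raise PipelineConfigError(f"invalid mfc_window {self.mfc_window}")
        if self.min_steps < 1:
            raise PipelineConfigError("min_steps must be >= 1")
        if self.coupling not in ("default", "null"):
            raise PipelineConfigError(f"unknown coupling {self.coupling!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.mfc_window, list):
            cfg.mfc_window = tuple(cfg.mfc_window)
        if isinstance(cfg.predictors, list):
            cfg.predictors = tuple(cfg.predictors)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mfc_window"] = list(self.mfc_window)
        d["predictors"] = list(self.predictors)
        return d

    def filter_spec(self, fs: float) -> FilterSpec:
        return FilterSpec(cutoff_hz=self.cutoff_hz, order=self.filter_order, fs=fs)

    def event_config(self) -> EventConfig:
        # trials are filtered once up front, not inside the detector
        return EventConfig(refractory_s=self.refractory_s,
                           heel_band_m=self.heel_band_m,
                           toe_rise_m=self.toe_rise_m,
                           apply_filter=False)


@dataclass
class PipelineResult:
    features: pd.DataFrame
    correlation: CorrelationReport | None
    regression: RegressionReport | None
    manifest: dict


def preprocess_trial(trial: TrialTrajectories, spec: FilterSpec) -> TrialTrajectories:
    """Return a copy of the trial with every coordinate low-pass filtered."""
    out = trial.copy()
    for m in MARKERS:
        for axis in range(3):
            out.positions[m][:, axis] = lowpass_filter(
                trial.positions[m][:, axis], spec
            )
    return out


def extract_subject(trials: TrialTrajectories | list[TrialTrajectories],
                    config: PipelineConfig | None = None
                    ) -> tuple[SubjectGaitSummary, SIFeatures]:
    """Run filtering → events → parameters → summary → SI for one subject.

    Accepts one trial or a list of passes; records are pooled across
    passes before summarizing.
    """
    config = config or PipelineConfig(simulate=True)
    if isinstance(trials, TrialTrajectories):
        trials = [trials]
    step_records, swing_records = [], []
    for trial in trials:
        filtered = preprocess_trial(trial, config.filter_spec(trial.fs))
        events = detect_events(filtered, config=config.event_config())
        steps = segment_steps(events, trial.fs)
        step_records.extend(compute_step_metrics(filtered, steps))
        swing_records.extend(compute_mfc(filtered, events,
                                         ground_ref=config.ground_ref,
                                         window=config.mfc_window))
    summary = summarize_subject(trials[0].subject_id, step_records,
                                swing_records, min_steps=config.min_steps)
    return summary, si_features(summary)


def _feature_row(summary: SubjectGaitSummary, si: SIFeatures) -> dict:
    row: dict = {"subject_id": summary.subject_id}
    for p in ("step_length", "step_width", "double_support", "mfc"):
        row[f"{p}_mean"] = summary.pooled_mean[p]
        row[f"{p}_sd"] = summary.pooled_sd[p]
    row.update(si.as_dict())
    row["n_steps"] = summary.total_steps
    row["included"] = summary.included
    return row


def build_cohort_table(subject_rows: list[dict],
                       ghq: dict[str, GHQResponse],
                       covariates: dict[str, dict] | None = None
                       ) -> tuple[pd.DataFrame, list[dict]]:
    """Join feature rows with scored GHQ responses; report exclusions.

    Returns the table of included subjects and a list of exclusion
    records ``{"subject_id", "reason"}``.
    """
    covariates = covariates or {}
    rows, excluded = [], []
    for row in subject_rows:
        sid = row["subject_id"]
        if not row.get("included", True):
            excluded.append({"subject_id": sid,
                             "reason": f"below min steps ({row['n_steps']})"})
            continue
        if sid not in ghq:
            excluded.append({"subject_id": sid, "reason": "no GHQ response"})
            continue
        full = dict(row)
        full["ghq_total"] = score_ghq12(ghq[sid]).total
        full.update(covariates.get(sid, {}))
        rows.append(full)
    return pd.DataFrame(rows), excluded


def _simulate_inputs(config: PipelineConfig) -> tuple[SyntheticCohort, dict]:
    spec_kwargs = dict(n_subjects=config.n_subjects)
    base = CohortSpec().base
    base = dataclasses.replace(base, marker_noise_rms=config.marker_noise_rms,
                               n_steps=config.n_steps)
    if config.coupling == "null":
        cohort_spec = CohortSpec.null(base=base, **spec_kwargs)
    else:
        cohort_spec = CohortSpec(base=base, **spec_kwargs)
    cohort = simulate_cohort(cohort_spec, config.seed)
    return cohort, {"mode": "simulate", "n_subjects": config.n_subjects}


def run_pipeline(config: PipelineConfig,
                 write_outputs: bool = True) -> PipelineResult:
    """Execute all stages and (optionally) write the report bundle.

    Raises
    ------
    PipelineConfigError
        On an invalid configuration.
    GaitsymError subclasses
        Propagated from a failed stage (inputs unreadable, no subject
        surviving inclusion, degenerate statistics).
    """
    config.validate()
    warnings_count = 0
    subject_rows: list[dict] = []
    exclusions: list[dict] = []
    ghq: dict[str, GHQResponse] = {}
    covariates: dict[str, dict] = {}

    if config.simulate:
        cohort, source = _simulate_inputs(config)
        trials_by_subject = {s.subject_id: [s.trial] for s in cohort.subjects}
        ghq = {s.subject_id: s.ghq for s in cohort.subjects}
        covariates = {s.subject_id: {"age": s.age, "sex": s.sex}
                      for s in cohort.subjects}
    else:
        source = {"mode": "extract", "marker_files": list(config.marker_files)}
        trials_by_subject = {}
        for fname in config.marker_files:
            trial = read_marker_table(fname, config.marker_format)
            trials_by_subject.setdefault(trial.subject_id, []).append(trial)
        if config.ghq_csv:
            ghq = {r.subject_id: r for r in read_ghq_csv(config.ghq_csv)}

    for sid, trials in trials_by_subject.items():
        try:
            summary, si = extract_subject(trials, config)
        except GaitsymError as exc:
            exclusions.append({"subject_id": sid, "reason": str(exc)})
            warnings_count += 1
            continue
        subject_rows.append(_feature_row(summary, si))

    table, more_excluded = build_cohort_table(subject_rows, ghq, covariates)
    exclusions.extend(more_excluded)

    correlation = regression = None
    if not table.empty and "ghq_total" in table.columns and len(table) >= 3:
        correlation = correlation_table(table, alpha=config.alpha, fdr=config.fdr)
        predictors = tuple(c for c in config.predictors if c in table.columns)
        if len(table) > len(predictors) + 1:
            regression = fit_ols(table, predictors=predictors)

    cfg_dict = config.to_dict()
    manifest = {
        "gaitsym_version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "source": source,
        "n_subjects_in": len(trials_by_subject) if config.simulate or
        config.marker_files else 0,
        "n_subjects_included": int(len(table)),
        "exclusions": exclusions,
        "warnings": warnings_count,
    }
    result = PipelineResult(features=table, correlation=correlation,
                            regression=regression, manifest=manifest)
    if write_outputs:
        _write_bundle(result, Path(config.out_dir))
    return result


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out_dir / "features.csv", index=False,
                           float_format="%.9g")
    if result.correlation is not None:
        result.correlation.table.to_csv(out_dir / "correlations.csv",
                                        index=False, float_format="%.9g")
        (out_dir / "correlations.txt").write_text(str(result.correlation) + "\n")
    if result.regression is not None:
        reg = result.regression
        payload = {
            "r": reg.r, "r2": reg.r2, "F": reg.f_stat,
            "df1": reg.df1, "df2": reg.df2, "p": reg.f_pvalue, "n": reg.n,
            "coefficients": reg.coefficients.to_dict(orient="records"),
        }
        (out_dir / "regression.json").write_text(json.dumps(payload, indent=2))
        (out_dir / "regression.txt").write_text(str(reg) + "\n")
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


def export_cohort(cohort: SyntheticCohort, out_dir: str | Path,
                  format: str = "csv_wide") -> None:
    """Write a simulated cohort's marker files, GHQ CSV and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "trc" if format == "trc" else "csv"
    gt: dict[str, dict] = {}
    for s in cohort.subjects:
        if s.trial is not None:
            write_marker_table(s.trial, out / f"{s.subject_id}.{ext}", format)
        gt[s.subject_id] = {
            "latent": s.latent, "age": s.age, "sex": s.sex,
            "heel_contacts": {f: s.truth.heel_contacts[f].tolist() for f in "LR"},
            "toe_offs": {f: s.truth.toe_offs[f].tolist() for f in "LR"},
            "steps": [dataclasses.asdict(st) for st in s.truth.steps],
            "swings": [dataclasses.asdict(sw) for sw in s.truth.swings],
        }
    write_ghq_csv(cohort.ghq_responses, out / "ghq.csv")
    (out / "ground_truth.json").write_text(json.dumps(
        {"seed": cohort.seed, "subjects": gt}, indent=1))
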