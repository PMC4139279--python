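"""End-to-end study orchestration.

Runs the whole analysis on a cohort (synthetic or loaded from CSVs):
subject-level quality control (beat coverage > 90 % in MODERATE and
SEVERE), artifact reconstruction and anchor-exclusion marking, last-30-min
phase windows, AC/DC spectra over ``T = 1..t_max`` on entire and stable
series, occlusion/recovery time-constant fits, SDNN, and the cohort
statistics: per-phase medians with interquartile ranges, paired Wilcoxon
comparisons between consecutive phases (Bonferroni x3) reported as
significant-T ranges, entire-vs-stable comparisons, the post-SEVERE
5-minute window vs BASELINE, and Spearman correlations between AC/DC and
the time-matched acid-base biomarkers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import DegenerateInputError, FetalPRSAError, UCO_PHASES
from .preprocessing import (
    QUALITY_MIN,
    beat_quality_fraction,
    mark_anchor_exclusions,
    reconstruct_artifacts,
)
from .prsa import CapacityResult, capacity_spectrum
from .stats import (
    ALPHA,
    BONFERRONI_FACTOR,
    CorrelationResult,
    quartile_summary,
    sdnn,
    significant_T_ranges,
    spearman,
    wilcoxon_signed_rank_paired,
)
from .synthetic_data import SubjectRecord, SyntheticConfig, generate_cohort
from .uco_response import (
    concatenate_stable_segments,
    extract_aligned_responses,
    fit_time_constants,
    phase_analysis_window,
    stable_intervals,
)

__all__ = ["AnalysisOptions", "ReportBundle", "run_full_analysis", "write_report_bundle"]

logger = logging.getLogger(__name__)

ANALYSIS_PHASES = ("BASELINE", "MILD", "MODERATE", "SEVERE")
PHASE_PAIRS = (("BASELINE", "MILD"), ("MILD", "MODERATE"), ("MODERATE", "SEVERE"))
POST_SEVERE_WINDOW_S = 300.0


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunables of the full analysis (spectra, windows, statistics)."""

    t_max: int = 50
    L: int = 50
    min_anchors: int = 150
    variants: tuple[str, ...] = ("entire", "stable")
    allow_cross_boundary: bool = False
    include_baseline_in_correlations: bool = True
    post_severe_window: bool = True
    tau_fit_phase: str = "SEVERE"
    alpha: float = ALPHA
    bonferroni_factor: int = BONFERRONI_FACTOR


@dataclass
class ReportBundle:
    """All tables produced by one run, plus the run manifest."""

    capacity: pd.DataFrame
    cohort_medians: pd.DataFrame
    phase_comparisons: pd.DataFrame
    entire_vs_stable: pd.DataFrame
    post_severe: pd.DataFrame
    correlations: pd.DataFrame
    tau: pd.DataFrame
    sdnn: pd.DataFrame
    qc: pd.DataFrame
    manifest: dict


@dataclass
class _SubjectAnalysis:
    record: SubjectRecord
    included: bool
    quality: dict
    capacities: list = field(default_factory=list)
    sdnn_ms: dict = field(default_factory=dict)
    tau_stim: float = float("nan")
    tau_rec: float = float("nan")
    tau_rms: float = float("nan")
    biomarker_by_phase: dict = field(default_factory=dict)


def _analyze_subject(record: SubjectRecord, opts: AnalysisOptions) -> _SubjectAnalysis:
    series = reconstruct_artifacts(record.series)
    series = mark_anchor_exclusions(series)
    schedule = record.schedule

    quality = {}
    for phase in ("MODERATE", "SEVERE"):
        if schedule.has_phase(phase):
            p = schedule.phase(phase)
            quality[phase] = beat_quality_fraction(series, (p.start, p.end))
    included = all(f > QUALITY_MIN for f in quality.values())
    out = _SubjectAnalysis(record, included, quality)
    logger.info(
        "subject %s: %d beats, quality %s, %s",
        record.subject_id, series.n_beats,
        {k: round(v, 4) for k, v in quality.items()},
        "included" if included else "EXCLUDED",
    )
    if not included:
        return out

    t_range = range(1, opts.t_max + 1)
    for phase in ANALYSIS_PHASES:
        if not schedule.has_phase(phase):
            continue
        pw = phase_analysis_window(schedule, record.biomarkers, phase)
        out.biomarker_by_phase[phase] = pw.biomarker
        if "entire" in opts.variants:
            entire = series.slice_time_window(pw.start, pw.end)
            out.capacities += capacity_spectrum(
                entire, t_range, opts.L, opts.min_anchors,
                subject=record.subject_id, phase=phase, variant="entire",
            )
        if "stable" in opts.variants:
            ivs = [
                (max(lo, pw.start), min(hi, pw.end))
                for lo, hi in stable_intervals(schedule, phase)
            ]
            ivs = [(lo, hi) for lo, hi in ivs if hi > lo]
            stable = concatenate_stable_segments(series, ivs)
            out.capacities += capacity_spectrum(
                stable, t_range, opts.L, opts.min_anchors,
                subject=record.subject_id, phase=phase, variant="stable",
                allow_cross_boundary=opts.allow_cross_boundary,
            )
            out.sdnn_ms[phase] = sdnn(stable)

    if opts.post_severe_window and schedule.has_phase("SEVERE"):
        end = schedule.phase("SEVERE").end
        post = series.slice_time_window(end, end + POST_SEVERE_WINDOW_S)
        out.capacities += capacity_spectrum(
            post, t_range, opts.L, opts.min_anchors,
            subject=record.subject_id, phase="POST_SEVERE", variant="entire",
        )

    if schedule.has_phase(opts.tau_fit_phase) and schedule.events_in_phase(opts.tau_fit_phase):
        onset = extract_aligned_responses(series, schedule, opts.tau_fit_phase, "onset")
        release = extract_aligned_responses(series, schedule, opts.tau_fit_phase, "release")
        model = fit_time_constants(onset, release)
        out.tau_stim, out.tau_rec, out.tau_rms = (
            model.tau_stim, model.tau_rec, model.residual_rms,
        )
    return out


def _capacity_frame(caps: list[CapacityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.subject, c.phase, c.variant, c.T, c.s, c.ac_abs, c.dc_abs,
                c.n_anchors_dec, c.n_anchors_acc, c.reliable_dec, c.reliable_acc,
            )
            for c in caps
        ],
        columns=[
            "subject", "phase", "variant", "T", "s", "AC_abs_ms", "DC_abs_ms",
            "n_anchors_dec", "n_anchors_acc", "reliable_dec", "reliable_acc",
        ],
    )


def _paired_ranges(
    cap_df: pd.DataFrame,
    subjects: list[str],
    opts: AnalysisOptions,
    group_a: dict,
    group_b: dict,
    label: str,
) -> list[dict]:
    """Per-T paired Wilcoxon between two (phase, variant) groups -> ranges."""
    rows = []
    for capacity, col in (("AC", "AC_abs_ms"), ("DC", "DC_abs_ms")):
        pvals: dict[int, float] = {}
        for T in sorted(cap_df["T"].unique()):
            try:
                a = _values_by_subject(cap_df, subjects, T, col, **group_a)
                b = _values_by_subject(cap_df, subjects, T, col, **group_b)
                pvals[int(T)] = wilcoxon_signed_rank_paired(a, b)
            except DegenerateInputError:
                pvals[int(T)] = float("nan")
        ranges = significant_T_ranges(pvals, opts.alpha, opts.bonferroni_factor)
        finite = [v for v in pvals.values() if not np.isnan(v)]
        rows.append(
            {
                "comparison": label,
                "capacity": capacity,
                "variant": group_a.get("variant", "entire"),
                "significant_T_ranges": ";".join(f"{a}-{b}" for a, b in ranges),
                "n_significant_T": sum(b - a + 1 for a, b in ranges),
                "min_p_raw": float(min(finite)) if finite else float("nan"),
            }
        )
    return rows


def _values_by_subject(cap_df, subjects, T, col, phase, variant) -> np.ndarray:
    sel = cap_df[
        (cap_df["phase"] == phase) & (cap_df["variant"] == variant) & (cap_df["T"] == T)
    ].set_index("subject")[col]
    vals = sel.reindex(subjects).to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise DegenerateInputError(f"missing capacity for some subject at T={T}")
    return vals


def run_full_analysis(
    cohort: list[SubjectRecord] | None = None,
    config: SyntheticConfig | None = None,
    options: AnalysisOptions = AnalysisOptions(),
) -> ReportBundle:
    """Run the whole study and return the report bundle.

    Provide either a ``cohort`` (simulated or loaded from files) or a
    :class:`SyntheticConfig` from which one is generated.  Deterministic
    given the configuration seed.
    """
    if cohort is None:
        if config is None:
            raise ValueError("need a cohort or a SyntheticConfig")
        cohort = generate_cohort(config)
    analyses = []
    failures = []
    for record in cohort:
        try:
            analyses.append(_analyze_subject(record, options))
        except FetalPRSAError as exc:
            logger.error("subject %s failed: %s", record.subject_id, exc)
            failures.append({"subject": record.subject_id, "error": str(exc)})
    qc = pd.DataFrame(
        [
            {
                "subject": a.record.subject_id,
                "quality_moderate": a.quality.get("MODERATE", float("nan")),
                "quality_severe": a.quality.get("SEVERE", float("nan")),
                "included": a.included,
            }
            for a in analyses
        ]
    )
    kept = [a for a in analyses if a.included]
    if not kept:
        raise DegenerateInputError("all subjects excluded by quality control")
    subjects = [a.record.subject_id for a in kept]

    cap_df = _capacity_frame([c for a in kept for c in a.capacities])

    med_rows = []
    for (phase, variant, T), grp in cap_df.groupby(["phase", "variant", "T"]):
        for capacity, col in (("AC", "AC_abs_ms"), ("DC", "DC_abs_ms")):
            vals = grp[col].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            q = quartile_summary(vals)
            med_rows.append(
                {
                    "phase": phase, "variant": variant, "capacity": capacity,
                    "T": int(T), "median_ms": q.median, "q1_ms": q.q1,
                    "q3_ms": q.q3, "n": int(vals.size),
                    "all_reliable": bool(
                        grp["reliable_dec" if capacity == "DC" else "reliable_acc"].all()
                    ),
                }
            )
    cohort_medians = pd.DataFrame(med_rows).sort_values(
        ["variant", "capacity", "phase", "T"], ignore_index=True
    )

    comp_rows = []
    for pa, pb in PHASE_PAIRS:
        for variant in options.variants:
            comp_rows += _paired_ranges(
                cap_df, subjects, options,
                {"phase": pb, "variant": variant},
                {"phase": pa, "variant": variant},
                f"{pa}-{pb}",
            )
    phase_comparisons = pd.DataFrame(comp_rows)

    evs_rows = []
    if {"entire", "stable"} <= set(options.variants):
        for phase in UCO_PHASES:
            if (cap_df["phase"] == phase).any():
                evs_rows += _paired_ranges(
                    cap_df, subjects, options,
                    {"phase": phase, "variant": "entire"},
                    {"phase": phase, "variant": "stable"},
                    f"{phase}:entire-vs-stable",
                )
    entire_vs_stable = pd.DataFrame(evs_rows)

    post_rows = []
    if options.post_severe_window and (cap_df["phase"] == "POST_SEVERE").any():
        post_rows = _paired_ranges(
            cap_df, subjects, options,
            {"phase": "POST_SEVERE", "variant": "entire"},
            {"phase": "BASELINE", "variant": "entire"},
            "BASELINE-POST_SEVERE",
        )
    post_severe = pd.DataFrame(post_rows)

    corr_phases = [
        p for p in ANALYSIS_PHASES
        if options.include_baseline_in_correlations or p != "BASELINE"
    ]
    cap_lookup = {
        (r.subject, r.phase, r.variant, r.T): (r.AC_abs_ms, r.DC_abs_ms)
        for r in cap_df.itertuples()
    }
    corr_rows = []
    for variant in options.variants:
        for ci, capacity in enumerate(("AC", "DC")):
            for T in sorted(cap_df["T"].unique()):
                vals: list[float] = []
                bio: dict[str, list[float]] = {
                    "pH": [], "lactate": [], "base_deficit": []
                }
                ok = True
                for a in kept:
                    for phase in corr_phases:
                        key = (a.record.subject_id, phase, variant, T)
                        pair = cap_lookup.get(key)
                        if pair is None or np.isnan(pair[ci]):
                            ok = False
                            break
                        vals.append(float(pair[ci]))
                        s = a.biomarker_by_phase[phase]
                        bio["pH"].append(s.ph)
                        bio["lactate"].append(s.lactate)
                        bio["base_deficit"].append(s.base_deficit)
                    if not ok:
                        break
                if not ok:
                    continue
                for biomarker in ("pH", "lactate", "base_deficit"):
                    try:
                        rho, p = spearman(vals, bio[biomarker])
                    except DegenerateInputError:
                        continue
                    corr_rows.append(
                        CorrelationResult(
                            capacity, int(T), variant, biomarker, rho, p, len(vals)
                        )
                    )
    correlations = pd.DataFrame(
        [
            (c.capacity, c.T, c.variant, c.biomarker, c.rho, c.p, c.n)
            for c in corr_rows
        ],
        columns=["capacity", "T", "variant", "biomarker", "rho", "p", "n"],
    )

    tau = pd.DataFrame(
        [
            {
                "subject": a.record.subject_id,
                "tau_stim_s": a.tau_stim,
                "tau_rec_s": a.tau_rec,
                "residual_rms_ms": a.tau_rms,
            }
            for a in kept
        ]
    )
    sdnn_df = pd.DataFrame(
        [
            {"subject": a.record.subject_id, "phase": ph, "sdnn_ms": v}
            for a in kept
            for ph, v in sorted(a.sdnn_ms.items())
        ]
    )

    manifest = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "n_subjects": len(cohort),
        "n_included": len(kept),
        "failures": failures,
        "options": {
            "t_max": options.t_max, "L": options.L,
            "min_anchors": options.min_anchors,
            "variants": list(options.variants),
            "allow_cross_boundary": options.allow_cross_boundary,
        },
    }
    if config is not None:
        blob = json.dumps(config.model_dump(), sort_keys=True, default=str)
        manifest["seed"] = config.seed
        manifest["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()

    return ReportBundle(
        capacity=cap_df,
        cohort_medians=cohort_medians,
        phase_comparisons=phase_comparisons,
        entire_vs_stable=entire_vs_stable,
        post_severe=post_severe,
        correlations=correlations,
        tau=tau,
        sdnn=sdnn_df,
        qc=qc,
        manifest=manifest,
    )


def write_report_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write every report table as CSV plus ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "capacity.csv": bundle.capacity,
        "cohort_medians.csv": bundle.cohort_medians,
        "phase_comparisons.csv": bundle.phase_comparisons,
        "entire_vs_stable.csv": bundle.entire_vs_stable,
        "post_severe.csv": bundle.post_severe,
        "correlations.csv": bundle.correlations,
        "tau.csv": bundle.tau,
        "sdnn.csv": bundle.sdnn,
        "qc.csv": bundle.qc,
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False)
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n"
    )
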