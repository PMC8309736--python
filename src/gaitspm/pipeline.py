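"""End-to-end study pipeline: load -> events -> window -> normalize ->
ensemble -> normality screen -> 1D paired mapping + scalar tests.

The paired unit defaults to one median curve per subject and condition
(n = subjects); an alternative per-step pairing (step i of TR against step
i of WR, stacked across subjects) is available but non-default.  Every
analyzed channel/phase field appears in the report exactly once, or in the
skipped list with a reason.  All 30 fields are tested without
cross-channel multiplicity correction by default, mirroring the practice
of reporting each joint/DOF separately; a Bonferroni-across-fields option
exists.  Given a fixed configuration (including the seed) the report is
reproducible bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import io as gio
from .events import (
    SpatiotemporalSummary,
    detect_events,
    segment_steps,
    select_analysis_window,
    spatiotemporal,
)
from .normalize import FIELD_KEYS, NormalizedEnsemble, build_ensemble, field_label, step_curves
from .recording import Recording
from .stats import (
    NormalityReport,
    SPMResult,
    choose_test,
    ks_normality,
    scalar_paired_test,
    snpm_paired,
    spm_paired_rft,
)
from .synth import Cohort

logger = logging.getLogger(__name__)

CONDITIONS = ("WR", "TR")
SCALAR_METRICS = ("mean_velocity_kmh", "mean_stride_length_m", "mean_frequency_per_min", "analyzed_distance_m")


@dataclass
class PipelineConfig:
    """All knobs of the study pipeline; every stochastic step is seeded."""

    seed: int
    inputs: dict[str, dict[str, str]] | None = None  # subject -> condition -> path
    target_speed_kmh: float | dict[str, float] | None = None
    k_sd: float = 2.0
    speed_band_kmh: float | None = None
    n_steps: int = 20
    v_contact_ms: float = 1.5
    v_toeoff_ms: float = 2.0
    n_nodes: int = 100
    alpha: float = 0.05
    alpha_normality: float = 0.05
    n_permutations: int = 10000
    test_method: str = "nonparametric"  # "nonparametric" | "parametric" | "auto"
    lilliefors: bool = False
    pairing: str = "subject_median"  # or "step"
    bonferroni_channels: bool = False
    fields: list[str] | None = None  # labels; None = all 30
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.test_method not in ("nonparametric", "parametric", "auto"):
            raise ValueError(f"unknown test_method {self.test_method!r}")
        if self.pairing not in ("subject_median", "step"):
            raise ValueError(f"unknown pairing {self.pairing!r}")
        if self.seed is None:
            raise ValueError("a seed is required")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    def target_for(self, subject: str) -> float:
        if isinstance(self.target_speed_kmh, dict):
            return self.target_speed_kmh[subject]
        if self.target_speed_kmh is None:
            raise ValueError("target_speed_kmh is not configured")
        return float(self.target_speed_kmh)


@dataclass
class FieldResult:
    label: str
    spm: SPMResult
    normality_fraction_non_normal: float
    method: str

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "method": self.method,
            "normality_fraction_non_normal": self.normality_fraction_non_normal,
            "spm": self.spm.to_dict(),
        }


@dataclass
class StudyReport:
    """Per-field SPM results plus the spatiotemporal table and logs."""

    fields: dict[str, FieldResult]
    skipped_fields: dict[str, str]
    spatiotemporal_by_subject: dict[str, dict[str, SpatiotemporalSummary]]
    scalar_tests: dict[str, tuple[float, float, str]]
    exclusions: list[str]
    config: dict
    ensemble: NormalizedEnsemble | None = None

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "fields": {k: v.to_dict() for k, v in sorted(self.fields.items())},
            "skipped_fields": dict(sorted(self.skipped_fields.items())),
            "spatiotemporal": {
                s: {c: dataclasses.asdict(st) for c, st in conds.items()}
                for s, conds in sorted(self.spatiotemporal_by_subject.items())
            },
            "scalar_tests": {k: {"statistic": v[0], "p": v[1], "test": v[2]} for k, v in self.scalar_tests.items()},
            "exclusions": self.exclusions,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self._write_plot_data(out / "plot_data.csv")
        self._write_clusters(out / "clusters.csv")
        table = report_table1(self)
        (out / "table1.csv").write_text(table["csv"])
        (out / "table1.md").write_text(table["markdown"])
        if self.ensemble is not None:
            gio.write_ensemble(self.ensemble, out / "ensemble.npz")
        return out

    def _write_clusters(self, path: Path) -> None:
        lines = ["field,start_node,end_node,extent,sign,p_value"]
        for label, fr in sorted(self.fields.items()):
            for c in fr.spm.clusters:
                lines.append(f"{label},{c.start_node},{c.end_node},{c.extent},{c.sign},{c.p_value:.6g}")
        path.write_text("\n".join(lines) + "\n")

    def _write_plot_data(self, path: Path) -> None:
        """Figure-parity tidy CSV: condition medians/IQR, difference, t."""
        ens = self.ensemble
        lines = ["field,node,wr_median,wr_iqr,tr_median,tr_iqr,diff_median,diff_iqr,t,t_critical"]
        if ens is None:
            path.write_text(lines[0] + "\n")
            return
        i_wr, i_tr = ens.conditions.index("WR"), ens.conditions.index("TR")
        for key in ens.fields:
            label = field_label(key)
            if label not in self.fields:
                continue
            k = ens.field_index(key)
            wr = ens.median[:, i_wr, k]
            tr = ens.median[:, i_tr, k]
            diff = tr - wr
            wr_med, tr_med, d_med = np.median(wr, 0), np.median(tr, 0), np.median(diff, 0)
            q = lambda a: np.subtract(*np.percentile(a, [75, 25], axis=0))
            wr_iqr, tr_iqr, d_iqr = q(wr), q(tr), q(diff)
            spm = self.fields[label].spm
            for node in range(ens.n_nodes):
                lines.append(
                    f"{label},{node},{wr_med[node]:.6g},{wr_iqr[node]:.6g},{tr_med[node]:.6g},"
                    f"{tr_iqr[node]:.6g},{d_med[node]:.6g},{d_iqr[node]:.6g},"
                    f"{spm.t_curve[node]:.6g},{spm.critical_threshold:.6g}"
                )
        path.write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Per-trial processing
# --------------------------------------------------------------------------


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    if path.suffix.lower() == ".mvnx":
        return gio.read_mvnx(path)
    return gio.read_angles_csv(path)


def process_trial(
    rec: Recording, target_speed_kmh: float, config: PipelineConfig
) -> tuple[dict, SpatiotemporalSummary]:
    """Events -> window -> per-step normalized curves + spatiotemporal summary."""
    events = detect_events(rec, v_contact_ms=config.v_contact_ms, v_toeoff_ms=config.v_toeoff_ms)
    steps = segment_steps(events, rec.sample_rate, rec.trial_id)
    window = select_analysis_window(
        steps, rec, target_speed_kmh,
        k_sd=config.k_sd, n_steps=config.n_steps, speed_band_kmh=config.speed_band_kmh,
    )
    start = next(i for i, s in enumerate(steps) if s.start == window[0].start)
    curves: dict[tuple, list[np.ndarray]] = {key: [] for key in FIELD_KEYS}
    for offset, step in enumerate(window):
        idx = start + offset
        nxt = steps[idx + 1] if idx + 1 < len(steps) else None
        if nxt is None or nxt.start != step.end or nxt.lead_side is step.lead_side:
            logger.warning("%s: step at sample %d lacks a consecutive successor; dropped from curves",
                           rec.trial_id, step.start)
            continue
        for key, curve in step_curves(rec.angles, step, nxt, config.n_nodes).items():
            curves[key].append(curve)
    summary = spatiotemporal(window, rec)
    return curves, summary


# --------------------------------------------------------------------------
# Study driver
# --------------------------------------------------------------------------


def _recordings_iter(config: PipelineConfig, cohort: Cohort | None):
    if cohort is not None:
        for subj in cohort.subjects:
            target = (
                config.target_for(subj.subject_id)
                if config.target_speed_kmh is not None
                else subj.truths["WR"].velocity_kmh
            )
            yield subj.subject_id, target, subj.recordings
    else:
        if not config.inputs:
            raise ValueError("no inputs configured and no cohort given")
        for subject, paths in config.inputs.items():
            recs = {cond: load_recording(p) for cond, p in paths.items()}
            yield subject, config.target_for(subject), recs


def run_study(config: PipelineConfig, cohort: Cohort | None = None) -> StudyReport:
    """Execute the full analysis and assemble a study report.

    Subjects failing any stage in one condition (no gait, speed criterion
    never met, too few steps) are excluded with a logged reason, mirroring
    manual quality screening; at least 2 subjects must survive.
    """
    exclusions: list[str] = []
    curves_all: dict[str, dict[str, dict[tuple, list[np.ndarray]]]] = {}
    spatio: dict[str, dict[str, SpatiotemporalSummary]] = {}

    for subject, target, recs in _recordings_iter(config, cohort):
        if not all(c in recs for c in CONDITIONS):
            exclusions.append(f"{subject}: missing a condition")
            continue
        try:
            per_cond_curves, per_cond_spatio = {}, {}
            for cond in CONDITIONS:
                per_cond_curves[cond], per_cond_spatio[cond] = process_trial(recs[cond], target, config)
            curves_all[subject] = per_cond_curves
            spatio[subject] = per_cond_spatio
        except Exception as exc:  # noqa: BLE001 - stage errors exclude the subject
            exclusions.append(f"{subject}: {exc}")
            logger.warning("subject %s excluded: %s", subject, exc)

    if len(curves_all) < 2:
        raise RuntimeError(f"fewer than 2 subjects survived processing; exclusions: {exclusions}")

    ens = build_ensemble(curves_all, n_nodes=config.n_nodes)

    requested = config.fields
    fields: dict[str, FieldResult] = {}
    skipped: dict[str, str] = {}
    n_tested = sum(
        1 for key in FIELD_KEYS if requested is None or field_label(key) in requested
    )
    alpha_eff = config.alpha / n_tested if config.bonferroni_channels else config.alpha
    seed_seq = np.random.SeedSequence(config.seed)
    field_seeds = seed_seq.generate_state(len(FIELD_KEYS)) % (2**31 - 1)

    for fi, key in enumerate(FIELD_KEYS):
        label = field_label(key)
        if requested is not None and label not in requested:
            skipped[label] = "not in configured field subset"
            continue
        diffs = _paired_diffs(ens, key, config.pairing)
        method = config.test_method
        frac_non_normal = float("nan")
        if diffs.shape[0] >= 4:
            report = ks_normality(diffs, alpha=config.alpha_normality, lilliefors=config.lilliefors)
            frac_non_normal = report.fraction_non_normal
            if method == "auto":
                method = choose_test(report)
        elif method == "auto":
            logger.warning("%s: too few observations for a normality screen; using nonparametric test", label)
            method = "nonparametric"
        if method == "nonparametric":
            spm = snpm_paired(diffs, alpha=alpha_eff, n_permutations=config.n_permutations,
                              seed=int(field_seeds[fi]))
        else:
            spm = spm_paired_rft(diffs, alpha=alpha_eff)
        fields[label] = FieldResult(
            label=label, spm=spm, normality_fraction_non_normal=frac_non_normal, method=method,
        )

    scalar_tests = {}
    subjects = sorted(spatio)
    for metric in SCALAR_METRICS:
        wr = np.array([getattr(spatio[s]["WR"], metric) for s in subjects])
        tr = np.array([getattr(spatio[s]["TR"], metric) for s in subjects])
        try:
            scalar_tests[metric] = scalar_paired_test(wr, tr, alpha_normality=config.alpha_normality,
                                                      lilliefors=config.lilliefors)
        except ValueError as exc:
            logger.warning("scalar test for %s not computed: %s", metric, exc)
            scalar_tests[metric] = (float("nan"), float("nan"), "not_computed")

    report = StudyReport(
        fields=fields,
        skipped_fields=skipped,
        spatiotemporal_by_subject=spatio,
        scalar_tests=scalar_tests,
        exclusions=exclusions,
        config=config.to_dict(),
        ensemble=ens,
    )
    if config.output_dir:
        report.save(config.output_dir)
    return report


def _paired_diffs(ens: NormalizedEnsemble, key, pairing: str) -> np.ndarray:
    if pairing == "subject_median":
        return ens.paired_differences(key)
    k = ens.field_index(key)
    i_wr, i_tr = ens.conditions.index("WR"), ens.conditions.index("TR")
    d = ens.steps[:, i_tr, k] - ens.steps[:, i_wr, k]  # (S, M, N), step-index matched
    return d.reshape(-1, ens.n_nodes)


# --------------------------------------------------------------------------
# Table-1-style summary
# --------------------------------------------------------------------------

_METRIC_TITLES = {
    "mean_velocity_kmh": "Mean Velocity (km/h)",
    "mean_stride_length_m": "Mean Stride Length (m)",
    "mean_frequency_per_min": "Mean Frequency (Strides Per Minute)",
    "analyzed_distance_m": "Analyzed Running Distance (m)",
}


def report_table1(report: StudyReport) -> dict:
    """Two-condition spatiotemporal table (mean +/- SD and paired p)."""
    subjects = sorted(report.spatiotemporal_by_subject)
    values = {
        cond: {
            m: np.array([getattr(report.spatiotemporal_by_subject[s][cond], m) for s in subjects])
            for m in SCALAR_METRICS
        }
        for cond in CONDITIONS
    }
    rows = {}
    for cond in CONDITIONS:
        rows[cond] = {m: (float(values[cond][m].mean()), float(values[cond][m].std(ddof=1))) for m in SCALAR_METRICS}
    p_row = {m: report.scalar_tests[m][1] for m in SCALAR_METRICS}

    header = [""] + [_METRIC_TITLES[m] for m in SCALAR_METRICS]
    cond_names = {"WR": "Warm-Up Run", "TR": "Transition Run"}
    csv_lines = [",".join(header)]
    md_lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
    for cond in CONDITIONS:
        cells = [f"{rows[cond][m][0]:.2f} +/- {rows[cond][m][1]:.2f}" for m in SCALAR_METRICS]
        csv_lines.append(",".join([cond_names[cond]] + cells))
        md_lines.append("| " + " | ".join([cond_names[cond]] + cells) + " |")
    p_cells = [f"{p_row[m]:.2g}" for m in SCALAR_METRICS]
    csv_lines.append(",".join(["p-value"] + p_cells))
    md_lines.append("| " + " | ".join(["p-value"] + p_cells) + " |")

    return {
        "rows": rows,
        "p_values": p_row,
        "csv": "\n".join(csv_lines) + "\n",
        "markdown": "\n".join(md_lines) + "\n",
    }
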