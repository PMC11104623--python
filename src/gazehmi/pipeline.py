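"""Reproducible simulate -> detect -> filter -> metrics -> stats pipeline.

A single master seed fans out to named sub-seeds (participants, statistics)
through :class:`numpy.random.SeedSequence`, so each stage can be re-run
independently and the whole pipeline is byte-deterministic for a given
configuration.  Datasets are written as plain CSV plus a YAML configuration
snapshot; the analysis report is JSON plus CSV tables, and every number in
it is recomputable from the stored inputs and the snapshot.
"""
from __future__ import annotations

import dataclasses
import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dip import dip_null, dip_test
from .events import (DetectionSettings, GazeStream, filter_primary,
                     filter_secondary, parse_trial)
from .exceptions import ConfigurationError, SchemaError
from .geometry import SceneGeometry, wrap_angle
from .metrics import (SessionLayout, curvature_index, decoding_outcome_table,
                      signed_angle)
from .simulate import KinematicParams, LearnerState, simulate_experiment
from .stats import (holm_correct, learning_trend_test, perm_mixed_anova,
                    perm_ttest)

__all__ = ["PipelineConfig", "AnalysisReport", "run_simulate",
           "load_dataset", "run_analyze", "run_report"]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; round-trips unchanged through YAML."""

    seed: int = 0
    n_participants: int = 22
    savings: float = 0.9
    stream_mode: str = "none"
    order_policy: str = "counterbalanced"
    single_condition: Optional[str] = None
    scene: dict = field(default_factory=dict)
    kinematics: dict = field(default_factory=dict)
    learner: dict = field(default_factory=dict)
    layout: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    stats: dict = field(default_factory=lambda: {
        "n_perm": 10000, "alpha": 0.05, "dip_n_mc": 999})

    # -- construction helpers ------------------------------------------------
    def build_scene(self) -> SceneGeometry:
        return SceneGeometry(**self.scene)

    def build_kinematics(self) -> KinematicParams:
        return KinematicParams(**self.kinematics)

    def build_learner(self) -> LearnerState:
        return LearnerState(**self.learner)

    def build_layout(self) -> SessionLayout:
        return SessionLayout(**self.layout)

    def build_detection(self) -> DetectionSettings:
        return DetectionSettings(**self.detection)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


TRIALS_FILE = "trials.csv"
SAMPLES_FILE = "samples.csv"
CONFIG_FILE = "config_snapshot.yaml"


def run_simulate(config: PipelineConfig, outdir) -> Path:
    """Simulate a cohort and write the dataset + provenance to ``outdir``.

    Writes the trial table (one row per trial with kinematic ground truth,
    decoding outcome and feedback specification), optionally the long-format
    1 kHz gaze samples, and the configuration snapshot.  Idempotent for a
    fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials, streams = simulate_experiment(
        n_participants=config.n_participants, savings=config.savings,
        layout=config.build_layout(), kinematics=config.build_kinematics(),
        scene=config.build_scene(), learner=config.build_learner(),
        seed=config.seed, stream_mode=config.stream_mode,
        order_policy=config.order_policy,
        single_condition=config.single_condition)
    trials.to_csv(outdir / TRIALS_FILE, index=False)
    if streams:
        rows = []
        for (pid, sess), lst in streams.items():
            for st in lst:
                rows.append(pd.DataFrame({
                    "participant": pid, "session": sess,
                    "trial": st.trial_id, "t_ms": st.t,
                    "x_deg": st.x, "y_deg": st.y,
                    "fixation_off_ms": st.fixation_off_t}))
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / SAMPLES_FILE, index=False)
    config.to_yaml(outdir / CONFIG_FILE)
    return outdir


_TRIAL_REQUIRED = {"participant", "session", "condition", "order", "trial",
                   "phase", "intended_object", "intended_clock",
                   "endpoint_x", "endpoint_y", "amplitude", "duration_ms",
                   "latency_ms", "too_far", "decoding_error"}


def load_dataset(outdir):
    """Load a simulated (or user-supplied) dataset from disk."""
    outdir = Path(outdir)
    trials = pd.read_csv(outdir / TRIALS_FILE)
    missing = _TRIAL_REQUIRED - set(trials.columns)
    if missing:
        raise SchemaError(f"trial table lacks columns {sorted(missing)}")
    streams = None
    sample_path = outdir / SAMPLES_FILE
    if sample_path.exists():
        samples = pd.read_csv(sample_path)
        streams = {}
        for (pid, sess, trial), grp in samples.groupby(
                ["participant", "session", "trial"]):
            streams.setdefault((pid, sess), {})[trial] = GazeStream(
                t=grp["t_ms"].to_numpy(), x=grp["x_deg"].to_numpy(),
                y=grp["y_deg"].to_numpy(),
                fixation_off_t=float(grp["fixation_off_ms"].iloc[0]),
                trial_id=int(trial))
    return trials, streams


@dataclass
class AnalysisReport:
    """Phase summaries, per-trial outcome table, statistics, provenance."""

    summaries: pd.DataFrame
    outcome_table: pd.DataFrame
    stats: dict
    exclusions: dict
    provenance: dict
    metrics: pd.DataFrame

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "exclusions": self.exclusions,
            "stats": self.stats,
            "summaries": self.summaries.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, default=float)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json())
        self.metrics.to_csv(outdir / "metrics.csv", index=False)
        self.outcome_table.to_csv(outdir / "outcomes.csv", index=False)
        self.summaries.to_csv(outdir / "summaries.csv", index=False)


def _detect_and_merge(trials: pd.DataFrame, streams, layout: SessionLayout,
                      detection: DetectionSettings, scene: SceneGeometry):
    """Re-derive endpoint/latency/curvature columns from raw gaze streams
    via the offline detector; returns (trials', exclusion counts)."""
    trials = trials.copy()
    counts = {"no_primary": 0, "detected": 0}
    for col in ("det_valid", "det_curvature"):
        trials[col] = np.nan
    idx = trials.set_index(["participant", "session", "trial"]).index
    trials["det_valid"] = False
    for (pid, sess), per_trial in streams.items():
        for trial_id, stream in per_trial.items():
            events = parse_trial(stream, settings=detection)
            key = (pid, sess, trial_id)
            try:
                row = np.flatnonzero(idx == key)[0]
            except IndexError:
                continue
            if not events or events[0].order != "primary":
                counts["no_primary"] += 1
                continue
            prim = events[0]
            counts["detected"] += 1
            trials.iloc[row, trials.columns.get_loc("endpoint_x")] = prim.endpoint.x
            trials.iloc[row, trials.columns.get_loc("endpoint_y")] = prim.endpoint.y
            trials.iloc[row, trials.columns.get_loc("amplitude")] = prim.amplitude
            trials.iloc[row, trials.columns.get_loc("duration_ms")] = prim.duration
            trials.iloc[row, trials.columns.get_loc("latency_ms")] = prim.latency
            trials.iloc[row, trials.columns.get_loc("det_valid")] = prim.valid
            try:
                trials.iloc[row, trials.columns.get_loc("det_curvature")] = \
                    curvature_index(prim.trajectory).value
            except Exception:
                pass
            # refresh endpoint angles from the detected end point
            a_int = signed_angle(prim.endpoint,
                                 trials.iloc[row]["intended_clock"])
            trials.iloc[row, trials.columns.get_loc("angle_to_intended")] = a_int
            trials.iloc[row, trials.columns.get_loc("angle_to_optimal")] = \
                float(wrap_angle(a_int + scene.distortion))
    return trials, counts


def run_analyze(trials: pd.DataFrame, config: PipelineConfig,
                streams=None) -> AnalysisReport:
    """Run filters, metrics, summaries and statistics over a dataset.

    When raw gaze streams are present the endpoint metrics are re-derived
    through the offline saccade detector; otherwise the generator's exact
    kinematic ground truth serves as the detected values.  Validity filters
    are applied either way, and every exclusion is counted by reason.
    """
    layout = config.build_layout()
    scene = config.build_scene()
    detection = config.build_detection()
    exclusions: Dict[str, int] = {}
    if streams:
        trials, det_counts = _detect_and_merge(trials, streams, layout,
                                               detection, scene)
        exclusions.update(det_counts)
        valid = trials["det_valid"].astype(bool)
    else:
        amp = trials["amplitude"]
        dur = trials["duration_ms"]
        lat = trials["latency_ms"]
        ok_amp = (amp >= 3.5) & (amp <= 10.5)
        ok_dur = dur < 100.0
        ok_lat = lat > 100.0
        exclusions["amplitude"] = int((~ok_amp).sum())
        exclusions["duration"] = int((ok_amp & ~ok_dur).sum())
        exclusions["latency"] = int((ok_amp & ok_dur & ~ok_lat).sum())
        valid = ok_amp & ok_dur & ok_lat
    exclusions["total"] = int(len(trials))
    exclusions["retained"] = int(valid.sum())
    exclusions["excluded"] = exclusions["total"] - exclusions["retained"]

    vt = trials[valid].copy()
    metric_cols = ["participant", "session", "condition", "order", "trial",
                   "phase", "intended_object", "angle_to_intended",
                   "angle_to_optimal", "latency_ms", "amplitude",
                   "duration_ms"]
    if "det_curvature" in vt.columns:
        metric_cols.append("det_curvature")
    metrics = vt[metric_cols].copy()

    summaries = (vt.groupby(["order", "condition", "phase"], observed=True)
                 .agg(angle_to_optimal_mean=("angle_to_optimal", "mean"),
                      angle_to_optimal_sd=("angle_to_optimal", "std"),
                      angle_to_intended_mean=("angle_to_intended", "mean"),
                      angle_to_intended_sd=("angle_to_intended", "std"),
                      latency_mean=("latency_ms", "mean"),
                      latency_sd=("latency_ms", "std"),
                      n=("trial", "count"))
                 .reset_index())

    outcome_table = decoding_outcome_table(trials, layout)

    stats_cfg = config.stats
    n_perm = int(stats_cfg.get("n_perm", 10000))
    alpha = float(stats_cfg.get("alpha", 0.05))
    dip_n_mc = int(stats_cfg.get("dip_n_mc", 999))
    ss = np.random.SeedSequence(config.seed).spawn(4)
    seed_ttest, seed_anova, seed_dip, seed_trend = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]

    stats_out: Dict[str, dict] = {}

    # learning trend on per-trial decoding outcomes
    if len(outcome_table) and outcome_table["participant"].nunique() >= 2:
        trend = learning_trend_test(outcome_table, n_perm=n_perm,
                                    seed=seed_trend)
        stats_out["learning_trend"] = trend.test.to_dict()
        stats_out["learning_trend"]["mean_slope"] = \
            float(trend.slopes["slope"].mean())
    else:
        stats_out["learning_trend"] = {"note": "not computed (needs >= 2 "
                                               "participants with outcomes)"}

    # phase effects on the angle to the optimal point
    cells = (vt[vt["phase"].isin(["early", "late"])]
             .groupby(["participant", "order", "condition", "phase"],
                      observed=True)["angle_to_optimal"].mean()
             .reset_index().rename(columns={"angle_to_optimal": "value"}))
    anova_done = False
    if cells["participant"].nunique() >= 4:
        try:
            anova = perm_mixed_anova(
                cells, dv="value", subject="participant", between="order",
                within=("condition", "phase"), n_perm=n_perm,
                seed=seed_anova)
            stats_out["anova_angle_to_optimal"] = {
                k: v for k, v in anova.effects.items()}
            stats_out["anova_angle_to_optimal"]["scheme"] = anova.scheme
            anova_done = True
        except Exception as exc:  # unbalanced single-condition cohorts etc.
            stats_out["anova_angle_to_optimal"] = {"note": str(exc)}
    else:
        stats_out["anova_angle_to_optimal"] = {
            "note": "not computed (needs >= 4 participants)"}

    # post-hoc family: early vs late, late vs zero, baseline vs zero
    post_hoc = {}
    per_participant = cells.pivot_table(index="participant", columns="phase",
                                        values="value", observed=True)
    if {"early", "late"}.issubset(per_participant.columns) \
            and per_participant.notna().all(axis=None) \
            and len(per_participant) >= 2:
        res = perm_ttest(per_participant["early"].abs().to_numpy(),
                         per_participant["late"].abs().to_numpy(),
                         paired=True, alternative="greater",
                         n_perm=n_perm, seed=seed_ttest)
        post_hoc["early_vs_late_abs_angle"] = res.to_dict()
        res2 = perm_ttest(per_participant["late"].to_numpy(), 0.0,
                          alternative="two-sided", n_perm=n_perm,
                          seed=seed_ttest + 1)
        post_hoc["late_vs_zero"] = res2.to_dict()
    pre = (vt[vt["phase"] == "pre"]
           .groupby("participant")["angle_to_intended"].mean())
    if len(pre) >= 2:
        res3 = perm_ttest(pre.to_numpy(), 0.0, alternative="two-sided",
                          n_perm=n_perm, seed=seed_ttest + 2)
        post_hoc["pre_angle_to_intended_vs_zero"] = res3.to_dict()
    if post_hoc:
        raw = [v["p"] for v in post_hoc.values()]
        adj, reject = holm_correct(raw, alpha=alpha)
        for (k, v), pa, rj in zip(post_hoc.items(), adj, reject):
            v["p_holm"] = float(pa)
            v["reject"] = bool(rj)
    stats_out["post_hoc"] = post_hoc

    # unimodality of the pooled first-session learning-phase angles
    dip_out = {}
    s1 = vt[(vt["session"] == 1)
            & vt["phase"].isin(["early", "mid", "late"])]
    for cond, grp in s1.groupby("condition", observed=True):
        angles = grp["angle_to_optimal"].to_numpy()
        if angles.size >= 10:
            sub = angles
            if sub.size > 2000:   # cap the dip cost; power is unaffected
                pick = np.random.default_rng(seed_dip).choice(
                    sub.size, 2000, replace=False)
                sub = sub[pick]
            r = dip_test(sub, n_mc=dip_n_mc, seed=seed_dip)
            dip_out[cond] = {"D": r.D, "p": r.p_value, "n": r.n,
                             "n_mc": r.n_mc}
    stats_out["dip_session1"] = dip_out

    provenance = {
        "package_version": __version__,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "alpha": alpha,
        "n_perm": n_perm,
        "detection_source": "streams" if streams else "ground_truth",
    }
    return AnalysisReport(summaries=summaries, outcome_table=outcome_table,
                          stats=stats_out, exclusions=exclusions,
                          provenance=provenance, metrics=metrics)


def run_report(report: AnalysisReport, outdir) -> Path:
    """Render a human-readable markdown summary and diagnostic figures."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.save(outdir)

    lines = ["# Simulated gaze-interface analysis report", ""]
    lines.append(f"Package version {report.provenance['package_version']}, "
                 f"config {report.provenance['config_hash']}, "
                 f"seed {report.provenance['seed']}.")
    lines.append("")
    lines.append("## Exclusions")
    for k, v in report.exclusions.items():
        lines.append(f"- {k}: {v}")
    lines.append("")
    lines.append("## Phase summaries (mean +- SD)")
    lines.append("")
    lines.append(report.summaries.to_string(index=False))
    lines.append("")
    lines.append("## Statistics")
    for name, block in report.stats.items():
        lines.append(f"### {name}")
        if not block:
            lines.append("not computed")
        else:
            lines.append("```json")
            lines.append(json.dumps(block, indent=2, default=float))
            lines.append("```")
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))

    # learning curve
    ot = report.outcome_table
    if len(ot):
        fig, ax = plt.subplots(figsize=(7, 4))
        for cond, grp in ot.groupby("condition", observed=True):
            curve = (grp.groupby("learning_trial")["outcome"].mean()
                     .rolling(10, min_periods=1).mean())
            ax.plot(curve.index, curve.values, label=cond)
        ax.set_xlabel("learning trial")
        ax.set_ylabel("P(valid decoding)")
        ax.set_ylim(0, 1)
        ax.legend()
        fig.savefig(outdir / "learning_curve.png", dpi=120,
                    bbox_inches="tight")
        plt.close(fig)

    # angle by phase
    s = report.summaries
    if len(s):
        order_levels = list(s["order"].unique())
        fig, axes = plt.subplots(1, max(len(order_levels), 1),
                                 figsize=(5 * max(len(order_levels), 1), 4),
                                 squeeze=False)
        phase_order = ["pre", "early", "mid", "late", "post"]
        for ax, order in zip(axes[0], order_levels):
            sub = s[s["order"] == order]
            for cond, grp in sub.groupby("condition", observed=True):
                grp = grp.set_index("phase").reindex(phase_order).dropna(
                    subset=["angle_to_optimal_mean"])
                ax.errorbar(grp.index, grp["angle_to_optimal_mean"],
                            yerr=grp["angle_to_optimal_sd"], marker="o",
                            label=cond)
            ax.set_title(order)
            ax.set_ylabel("angle to optimal point (arc deg)")
            ax.axhline(0, color="grey", lw=0.5)
            ax.legend()
        fig.savefig(outdir / "angle_by_phase.png", dpi=120,
                    bbox_inches="tight")
        plt.close(fig)

    # latency by phase
    if len(s):
        fig, ax = plt.subplots(figsize=(7, 4))
        phase_order = ["pre", "early", "mid", "late", "post"]
        for (order, cond), grp in s.groupby(["order", "condition"],
                                            observed=True):
            grp = grp.set_index("phase").reindex(phase_order).dropna(
                subset=["latency_mean"])
            ax.plot(grp.index, grp["latency_mean"], marker="o",
                    label=f"{order}/{cond}")
        ax.set_ylabel("primary saccade latency (ms)")
        ax.legend(fontsize=8)
        fig.savefig(outdir / "latency_by_phase.png", dpi=120,
                    bbox_inches="tight")
        plt.close(fig)

    return outdir
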