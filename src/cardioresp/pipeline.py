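"""End-to-end orchestration: simulate -> detect -> classify -> stats -> models.

A :class:`RunConfig` fully determines a run; the config echo plus the seed
reproduce deterministic stages bit for bit.  Each stage is an importable
function so the analysis drivers, the test suite and the CLI all share one
code path.
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

from . import classify as cls
from . import mlm, stats, synthetic
from .signals import (
    PhaseSeries,
    RRISeries,
    SignalTrace,
    bandpass_ecg,
    build_rri_series,
    detect_r_waves,
    detect_respiratory_transitions,
    estimate_noise_sd,
    subtract_baseline,
)

log = logging.getLogger("cardioresp")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serialisable to YAML."""

    generator: synthetic.GeneratorConfig = field(default_factory=synthetic.GeneratorConfig)
    simulate: bool = True
    input_dir: str | None = None
    out_dir: str = "run"
    use_detection: bool = True      # False: classify on ground-truth event series
    write_signals: bool = False

    min_phase_s: float = 0.5
    quiet_window_s: float = 10.0    # length of the task-free window used for noise SD
    refractory_s: float = 0.2
    boundary_fraction: float = 0.5
    alpha: float = 0.05
    center_rt: bool = False
    correct_only_rt: bool = True
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["delay_range_s"] = list(d["generator"]["delay_range_s"])
        return d

    @classmethod
    def from_dict(cls_, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        if "flow_sign_convention" in gen:
            gen.pop("flow_sign_convention")
        if "delay_range_s" in gen:
            gen["delay_range_s"] = tuple(gen["delay_range_s"])
        return cls_(generator=synthetic.GeneratorConfig(**gen), **d)

    @classmethod
    def from_yaml(cls_, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls_.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# detection stage


def detect_subject(
    flow: SignalTrace,
    ecg: SignalTrace,
    min_phase_s: float = 0.5,
    quiet_window_s: float = 10.0,
    refractory_s: float = 0.2,
) -> tuple[PhaseSeries, RRISeries]:
    """Raw traces -> detected phase series and RRI series.

    The flow noise SD is estimated over the task-free lead-in window
    (``[1 s, 1 s + quiet_window_s]``), matching the rule that transition
    onsets must clear the baseline noise band by 2 SD.
    """
    flow0 = subtract_baseline(flow)
    noise_sd = estimate_noise_sd(flow0, (1.0, 1.0 + quiet_window_s))
    phases = detect_respiratory_transitions(flow0, noise_sd, min_phase_s=min_phase_s)
    ecg_f = bandpass_ecg(ecg)
    r_times = detect_r_waves(ecg_f, refractory_s=refractory_s)
    return phases, build_rri_series(r_times)


# ---------------------------------------------------------------------------
# group statistics stage


def group_stats_report(trials: pd.DataFrame, alpha: float = 0.05) -> dict:
    """The full group-level battery on a classified trial table.

    Keys mirror the analysis sequence: phase conditions (NOt/IEt/EIt),
    half conditions, first-test-trial restriction, the 2x2 design inside
    double-transition trials, velocity bins, and the two frequency
    analyses.
    """
    report: dict = {}

    def omnibus(wide):
        # repeated-measures machinery needs a handful of complete subjects
        if len(wide) < 3 or len(wide) < wide.shape[1] or wide.shape[1] < 2:
            log.warning("too few complete subjects (%d) for a %d-condition omnibus",
                        len(wide), wide.shape[1])
            return None
        return stats.choose_omnibus(wide, alpha)

    means_phase = cls.condition_means(trials, "phase")
    wide_rt = stats._complete_wide(means_phase, "mean_z")
    wide_acc = stats._complete_wide(means_phase, "accuracy")
    report["phase"] = {
        "means": means_phase,
        "normality": stats.normality_and_sphericity(wide_rt) if len(wide_rt) >= 3 else [],
        "rt": omnibus(wide_rt),
        "accuracy": omnibus(wide_acc),
        "n_subjects": int(len(wide_rt)),
    }

    means_half = cls.condition_means(trials, "half")
    wide_half = stats._complete_wide(means_half, "mean_z")
    report["half"] = {
        "means": means_half,
        "rt": omnibus(wide_half),
        "n_subjects": int(len(wide_half)),
    }

    first = trials[(trials["trial"] == 1) & trials["correct"]].copy()
    first["cell"] = cls.half_condition(first)
    first = first[first["cell"].notna() & first["rt_robust_z"].notna()]
    try:
        report["first_test"] = (
            stats.kruskal_with_ranksum_posthoc(first["rt_robust_z"], first["cell"], alpha)
            if first["cell"].nunique() >= 2
            else None
        )
    except ValueError as err:  # e.g. all values identical at tiny scale
        log.warning("first-test analysis skipped: %s", err)
        report["first_test"] = None

    dbl = trials[(trials["condition"] == "DOUBLE") & trials["correct"]]
    try:
        a, b = stats.two_way_anova_trials(
            dbl["rt_robust_z"], dbl["iet_half"], dbl["eit_half"], alpha
        )
        report["double"] = {"iet": a, "eit": b, "n_trials": int(len(dbl))}
    except ValueError as err:
        report["double"] = {"error": str(err), "n_trials": int(len(dbl))}

    means_bin = cls.condition_means(trials, "bin")
    wide_bin = stats._complete_wide(means_bin, "mean_z")
    report["bin"] = {
        "means": means_bin,
        "rt": omnibus(wide_bin),
        "n_subjects": int(len(wide_bin)),
    }

    report["frequency"] = stats.frequency_analysis(trials, alpha)
    return report


def _jsonable(obj):
    if isinstance(obj, stats.TestResult):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def stats_report_markdown(report: dict) -> str:
    """Render the group-stats report as a readable summary."""

    def fmt(res: stats.TestResult | None) -> str:
        if res is None:
            return "not computed"
        dfs = ", ".join(f"{d:g}" for d in res.df)
        s = f"{res.name}: statistic = {res.statistic:.4g} (df {dfs}), p = {res.p_value:.3g}"
        if res.correction:
            s += f" [{res.correction}]"
        for ph in res.posthoc:
            s += f"\n  - {ph['pair'][0]} vs {ph['pair'][1]}: p_bonf = {ph['p_bonf']:.3g}"
        return s

    lines = ["# Group statistics report", ""]
    lines += ["## Phase conditions (NOt / IEt / EIt)",
              f"- RT: {fmt(report['phase']['rt'])}",
              f"- accuracy: {fmt(report['phase']['accuracy'])}", ""]
    lines += ["## Half conditions (IEt-1st ... EIt-2nd)",
              f"- correct-trial robust-z RT: {fmt(report['half']['rt'])}", ""]
    lines += ["## First test trial only (trial-level)", f"- {fmt(report['first_test'])}", ""]
    if "error" in report["double"]:
        lines += ["## Double-transition trials", f"- skipped: {report['double']['error']}", ""]
    else:
        lines += ["## Double-transition trials (2x2 half design)",
                  f"- IEt main effect: {fmt(report['double']['iet'])}",
                  f"- EIt main effect: {fmt(report['double']['eit'])}", ""]
    lines += ["## RRI-velocity bins", f"- correct-trial robust-z RT: {fmt(report['bin']['rt'])}", ""]
    lines += ["## Frequency analyses",
              f"- high-positive velocity rate by half condition: {fmt(report['frequency']['test_by_half'])}",
              f"- late-EI rate by velocity bin: {fmt(report['frequency']['test_by_bin'])}", ""]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# input loading / validation


def load_subject_dir(d: Path) -> dict:
    """Load one subject directory of the on-disk layout (TSV + JSON)."""
    out: dict = {"subject_dir": d}
    for name in ("flow", "ecg"):
        p = d / f"{name}.tsv"
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            fs = 1.0 / np.median(np.diff(df["time_s"].to_numpy()[:1000]))
            out[name] = SignalTrace(
                df["value"].to_numpy(), fs_hz=float(round(fs)), channel=name,
                t0=float(df["time_s"].iloc[0]),
            )
    ev = d / "events.tsv"
    if ev.exists():
        out["events"] = pd.read_csv(ev, sep="\t")
    tr = d / "truth.json"
    if tr.exists():
        with open(tr) as fh:
            out["truth"] = json.load(fh)
    return out


def validate_inputs(input_dir: str | Path) -> list[dict]:
    """QC sweep over an input directory; returns a list of violations."""
    root = Path(input_dir)
    violations: list[dict] = []
    subdirs = sorted(p for p in root.glob("sub-*") if p.is_dir())
    if not subdirs:
        violations.append({"file": str(root), "problem": "no subject directories (sub-*)"})
    for d in subdirs:
        data = load_subject_dir(d)
        span_end = None
        for name in ("flow", "ecg"):
            p = d / f"{name}.tsv"
            if name not in data:
                violations.append({"file": str(p), "problem": "missing trace"})
                continue
            df = pd.read_csv(p, sep="\t")
            t = df["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                violations.append({"file": str(p), "problem": "non-monotone time column"})
            dt = np.diff(t[: min(len(t), 10_000)])
            if dt.size and (np.max(dt) - np.min(dt)) > 1e-6:
                violations.append({"file": str(p), "problem": "non-uniform sampling"})
            elif dt.size and abs(1.0 / np.median(dt) - 1000.0) > 1.0:
                violations.append({"file": str(p), "problem": "sampling rate not 1 kHz"})
            span_end = t[-1] if span_end is None else min(span_end, t[-1])
        if "events" not in data:
            violations.append({"file": str(d / "events.tsv"), "problem": "missing events"})
            continue
        ev = data["events"]
        bad_rt = ev["press_time_s"] <= ev["cue_time_s"]
        if bad_rt.any():
            violations.append(
                {"file": str(d / "events.tsv"),
                 "problem": f"non-positive RT in {int(bad_rt.sum())} trials"}
            )
        if span_end is not None and (ev["press_time_s"] > span_end).any():
            violations.append(
                {"file": str(d / "events.tsv"), "problem": "events outside signal span"}
            )
        counts = ev.groupby("block").size()
        if counts.nunique() > 1:
            violations.append(
                {"file": str(d / "events.tsv"), "problem": "unequal test count across blocks"}
            )
    return violations


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full analysis and write all artefacts under ``cfg.out_dir``.

    Stages: simulate (or load) -> detect (or take ground-truth event series)
    -> classify trials -> group statistics -> windowed multilevel models.
    Returns the output directory.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    trials_parts: list[pd.DataFrame] = []
    qc_parts: list[dict] = []
    n_subjects = 0

    if cfg.simulate:
        gen = cfg.generator
        render = cfg.use_detection or cfg.write_signals
        for data in synthetic.simulate_cohort(gen, render_signals=render):
            n_subjects += 1
            if cfg.write_signals:
                synthetic.write_subject(out / "data", data)
            if cfg.use_detection:
                phases, rri = detect_subject(
                    data.flow, data.ecg,
                    min_phase_s=cfg.min_phase_s,
                    quiet_window_s=min(cfg.quiet_window_s, gen.lead_in_s - 2.0),
                    refractory_s=cfg.refractory_s,
                )
            else:
                phases, rri = data.phases, RRISeries(data.r_times)
            tdf, qc = cls.build_trial_table(
                data.subject, data.events, phases, rri, cfg.boundary_fraction
            )
            trials_parts.append(tdf)
            qc_parts.append(qc)
            log.info("subject %d: %d trials classified", data.subject, len(tdf))
    else:
        if cfg.input_dir is None:
            raise ValueError("input_dir required when simulate is disabled")
        problems = validate_inputs(cfg.input_dir)
        if problems:
            raise ValueError(f"input validation failed: {problems}")
        for d in sorted(Path(cfg.input_dir).glob("sub-*")):
            n_subjects += 1
            data = load_subject_dir(d)
            phases, rri = detect_subject(
                data["flow"], data["ecg"],
                min_phase_s=cfg.min_phase_s,
                quiet_window_s=cfg.quiet_window_s,
                refractory_s=cfg.refractory_s,
            )
            tdf, qc = cls.build_trial_table(
                n_subjects, data["events"], phases, rri, cfg.boundary_fraction
            )
            trials_parts.append(tdf)
            qc_parts.append(qc)

    trials = pd.concat(trials_parts, ignore_index=True)
    trials.to_csv(out / "trials.tsv", sep="\t", index=False, float_format="%.6f")
    with open(out / "qc.json", "w") as fh:
        json.dump({"subjects": qc_parts}, fh, indent=1)

    report = group_stats_report(trials, cfg.alpha)
    with open(out / "stats_report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1)
    (out / "stats_report.md").write_text(stats_report_markdown(report))

    agg = mlm.aggregate_windows(trials, correct_only_rt=cfg.correct_only_rt)
    prepared = mlm.normalize_and_center(agg, center_rt=cfg.center_rt)
    fits = mlm.fit_models(prepared)
    for mid, f in fits.items():
        with open(out / f"model{mid}.json", "w") as fh:
            json.dump(f.to_dict(), fh, indent=1)
    (out / "tables.md").write_text(mlm.tables_markdown(fits))

    provenance = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.generator.seed,
        "n_subjects": n_subjects,
        "n_trials": int(len(trials)),
        "n_windows": int(len(agg)),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1)
    return out
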