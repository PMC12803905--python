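"""Synthetic cohort generator for the cardiorespiratory DMTS experiment.

Emulates, with known ground truth, the recordings of a delayed
matching-to-sample (DMTS) study: per subject a continuous nasal-flow trace, an
ECG-equivalent R-wave train (optionally rendered as a full ECG waveform), and
a task-event stream of 30 blocks x (4 sample cues, a 10-13 s delay, 3 test
cues) = 90 test trials, 45 match / 45 nonmatch.

Physiology
----------
* Respiratory cycle periods are i.i.d. gamma with mean ``1/resp_rate_hz``
  (default 0.278 Hz) and coefficient of variation ``resp_cv`` (default 0.268).
  Each cycle starts at an exhalation-to-inhalation (EI) transition; flow is a
  positive half-sine during inhalation and a negative half-sine during
  exhalation (inhalation-positive sign convention, recorded in metadata).
* Heartbeats follow integral-pulse-frequency modulation (IPFM) of an
  instantaneous RR-interval target that is ``rri_base_s - rsa_amp_s`` during
  inhalation and ``rri_base_s + rsa_amp_s`` during exhalation, ramped over
  ``rsa_ramp_s`` — respiratory sinus arrhythmia with RRIs shortening during
  inhalation and lengthening during exhalation.

Behaviour
---------
Reaction times are lognormal around a subject-specific baseline, with two
injectable effects: a fixed prolongation ``beta_eit2nd_s`` when an EI
transition falls in the second half of the trial, and a linear dependence
``beta_drri`` on the realized RRI velocity (RRI at press minus RRI at cue).
The EI-in-2nd-half label depends on the final RT, so the injection uses a
single adjustment pass and the ground-truth labels are recomputed from the
final RT.  Accuracy is Bernoulli with a decrement on trials containing an EI
transition.

Everything is driven by a single :class:`GeneratorConfig` and a seed; holding
both fixed, output is bit-reproducible.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import PhaseSeries, RRISeries, SignalTrace

FLOW_SIGN_CONVENTION = "inhalation-positive"

STIMULUS_LEVELS = 6  # symbol, colour, count, position: 6 levels each


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the experiment's structure: 36 subjects, 30 blocks of
    4 sample cues + 3 test cues (90 test trials, 45 match), mean respiratory
    rate 0.278 Hz with cycle-period CV 26.8 %, mean RRI 0.85 s with RSA
    half-amplitude 0.05 s, ~90 % accuracy with a decrement on EI-transition
    trials.
    """

    n_subjects: int = 36
    n_blocks: int = 30
    tests_per_block: int = 3
    samples_per_block: int = 4
    delay_range_s: tuple[float, float] = (10.0, 13.0)

    resp_rate_hz: float = 0.278
    resp_cv: float = 0.268
    insp_fraction: float = 0.4
    flow_amp: float = 1.0

    rri_base_s: float = 0.85
    rsa_amp_s: float = 0.05
    rsa_ramp_s: float = 0.4

    rt_base_s: float = 1.0
    rt_base_sd_s: float = 0.15   # SD of subject-specific baseline RTs
    rt_sigma_lognorm: float = 0.25
    rt_min_s: float = 0.2
    rt_max_s: float = 4.0
    beta_eit2nd_s: float = 0.25
    beta_drri: float = 1.0
    acc_base: float = 0.92
    acc_eit_drop: float = 0.05
    # slow attentional-state fluctuation (one latent state per block):
    # low attention lengthens RTs and lowers accuracy, giving the
    # within-subject RT/accuracy covariation the window-level models target
    attn_rt_s: float = 0.1
    attn_acc: float = 0.05

    # defaults put flow at ~20 dB and ECG at ~10 dB SNR (rms signal / noise SD)
    noise_sd_flow: float = 0.07
    noise_sd_ecg: float = 0.049
    fs_hz: float = 1000.0
    seed: int = 0

    # schedule constants the protocol leaves open
    lead_in_s: float = 12.0       # task-free baseline segment before breathing/task
    sample_cue_s: float = 1.0
    sample_gap_s: float = 0.5
    inter_trial_gap_s: float = 2.0
    inter_block_s: float = 2.0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_blocks, self.tests_per_block, self.samples_per_block) <= 0:
            raise ValueError("counts must be positive")
        if not (0 < self.insp_fraction < 1):
            raise ValueError("insp_fraction must lie in (0, 1)")
        if self.resp_rate_hz <= 0 or self.resp_cv < 0:
            raise ValueError("respiratory rate must be positive, CV non-negative")
        if self.rsa_amp_s >= self.rri_base_s:
            raise ValueError("rsa_amp_s must be smaller than rri_base_s")
        if self.rri_base_s <= 0:
            raise ValueError("rri_base_s must be positive")
        if not (0 < self.acc_base - self.acc_eit_drop < 1):
            raise ValueError("acc_base - acc_eit_drop must lie in (0, 1)")
        lo, hi = self.delay_range_s
        if not (0 < lo <= hi):
            raise ValueError("delay range must be positive and ordered")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    def block_duration_max_s(self) -> float:
        per_sample = self.sample_cue_s + self.sample_gap_s
        per_test = self.rt_max_s + self.inter_trial_gap_s
        return (
            self.samples_per_block * per_sample
            + self.delay_range_s[1]
            + self.tests_per_block * per_test
            + self.inter_block_s
        )

    def duration_s(self) -> float:
        """Upper bound on the recording length needed for the full schedule."""
        return self.lead_in_s + self.n_blocks * self.block_duration_max_s() + 10.0

    def subject_seeds(self) -> list[int]:
        """Independent, reproducible per-subject seeds derived from ``seed``."""
        ss = np.random.SeedSequence(self.seed)
        return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(self.n_subjects)]


def stimulus_space() -> list[tuple[int, int, int, int]]:
    """All distinct stimulus identities (symbol, colour, count, position)."""
    return list(itertools.product(range(STIMULUS_LEVELS), repeat=4))


# ---------------------------------------------------------------------------
# respiration


def _draw_cycle_periods(config: GeneratorConfig, rng: np.random.Generator, duration: float) -> np.ndarray:
    mean = 1.0 / config.resp_rate_hz
    n_max = int(np.ceil(duration / mean * 2.5)) + 10
    if config.resp_cv == 0:
        periods = np.full(n_max, mean)
    else:
        shape = 1.0 / config.resp_cv**2
        periods = rng.gamma(shape, mean / shape, size=n_max)
    # keep enough cycles to cover the duration past the breathing onset
    cum = np.cumsum(periods)
    n = int(np.searchsorted(cum, duration)) + 2
    return periods[:n]


def generate_respiration(
    config: GeneratorConfig,
    subject_seed: int,
    duration_s: float | None = None,
    render: bool = True,
) -> tuple[SignalTrace | None, PhaseSeries]:
    """Simulate one subject's breathing.

    Cycles start at EI transitions; inhalation occupies ``insp_fraction`` of
    each cycle.  With ``render=False`` only the ground-truth
    :class:`PhaseSeries` is produced (no waveform), for fast label-level
    simulation.

    Returns the flow trace (or ``None``) and the exact ground-truth phases.
    Noise-free flow crosses zero exactly at every transition time.
    """
    duration = config.duration_s() if duration_s is None else float(duration_s)
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(subject_seed)
    periods = _draw_cycle_periods(config, rng, duration - config.lead_in_s)
    ei = config.lead_in_s + np.concatenate([[0.0], np.cumsum(periods)])
    ie = ei[:-1] + config.insp_fraction * periods
    # ground truth only covers the rendered trace; rendering itself uses the
    # full cycle list so the final partial phase is still drawn
    phases = PhaseSeries(ei[ei < duration], ie[ie < duration])
    if not render:
        return None, phases

    n = int(round(duration * config.fs_hz))
    t = np.arange(n) / config.fs_hz
    # piecewise half-sines between consecutive transitions
    bounds, kinds = PhaseSeries(ei, ie).merged()
    seg = np.searchsorted(bounds, t, side="right") - 1
    flow = np.zeros(n)
    inside = (seg >= 0) & (seg < len(bounds) - 1)
    s = seg[inside]
    start = bounds[s]
    length = bounds[s + 1] - start
    sign = kinds[s].astype(float)  # +1 inhalation, -1 exhalation
    flow[inside] = config.flow_amp * sign * np.sin(np.pi * (t[inside] - start) / length)
    if config.noise_sd_flow > 0:
        flow = flow + rng.normal(0.0, config.noise_sd_flow, size=n)
    trace = SignalTrace(
        flow,
        fs_hz=config.fs_hz,
        channel="flow",
        baseline_level=0.0,
        noise_sd=config.noise_sd_flow,
        meta={"sign_convention": FLOW_SIGN_CONVENTION, "lead_in_s": config.lead_in_s},
    )
    return trace, phases


# ---------------------------------------------------------------------------
# heartbeats

# QRS-complex template: (amplitude mV, offset s, width s) Gaussian components
_ECG_TEMPLATE = (
    (0.10, -0.200, 0.040),   # P
    (-0.15, -0.030, 0.010),  # Q
    (1.00, 0.000, 0.008),    # R
    (-0.20, 0.030, 0.010),   # S
    (0.25, 0.180, 0.050),    # T
)


def _instantaneous_rri(config: GeneratorConfig, phases: PhaseSeries, t: np.ndarray) -> np.ndarray:
    """RSA-modulated RR-interval target on a time grid, ramped at transitions."""
    s = -phases.phase_at(t).astype(float)  # +1 exhalation (long RRI), -1 inhalation
    if config.rsa_ramp_s > 0 and t.size > 1:
        dt = t[1] - t[0]
        w = max(int(round(config.rsa_ramp_s / dt)), 1)
        kernel = np.ones(w) / w
        pad = np.concatenate([np.repeat(s[0], w), s, np.repeat(s[-1], w)])
        s = np.convolve(pad, kernel, mode="same")[w:-w]
    return config.rri_base_s + config.rsa_amp_s * s


def generate_heartbeats(
    config: GeneratorConfig,
    phases: PhaseSeries,
    subject_seed: int,
    duration_s: float | None = None,
    render_ecg: bool = True,
    grid_dt_s: float | None = None,
) -> tuple[np.ndarray, SignalTrace | None]:
    """Simulate one subject's heartbeat train by IPFM.

    Beat times satisfy ``integral of 1/rri_target from 0 to R_k = k + phi``
    for a random initial phase ``phi``; the target RRI is
    ``rri_base_s -/+ rsa_amp_s`` during inhalation/exhalation with a linear
    ramp of ``rsa_ramp_s`` at each transition, producing respiratory sinus
    arrhythmia.  Optionally renders an ECG waveform as a sum of QRS-complex
    templates centred at the beat times plus Gaussian noise.
    """
    if config.rsa_amp_s >= config.rri_base_s:
        raise ValueError("rsa_amp_s must be smaller than rri_base_s")
    duration = config.duration_s() if duration_s is None else float(duration_s)
    rng = np.random.default_rng(np.random.SeedSequence((subject_seed, 1)))
    dt = (1.0 / config.fs_hz if render_ecg else 0.01) if grid_dt_s is None else grid_dt_s
    t = np.arange(0.0, duration, dt)
    rri_t = _instantaneous_rri(config, phases, t)
    # IPFM: beats at integer crossings of the integrated instantaneous rate
    integral = np.concatenate([[0.0], np.cumsum(dt / rri_t)])
    t_edges = np.concatenate([t, [t[-1] + dt]])
    phi = rng.uniform(0.0, 1.0)
    targets = np.arange(phi, integral[-1], 1.0)
    r_times = np.interp(targets, integral, t_edges)

    ecg = None
    if render_ecg:
        n = int(round(duration * config.fs_hz))
        x = np.zeros(n)
        fs = config.fs_hz
        half = int(round(0.35 * fs))
        tt = np.arange(-half, half + 1) / fs
        template = np.zeros_like(tt)
        for amp, off, width in _ECG_TEMPLATE:
            template += amp * np.exp(-0.5 * ((tt - off) / width) ** 2)
        for r in r_times:
            c = int(round(r * fs))
            a, b = c - half, c + half + 1
            ta, tb = max(a, 0), min(b, n)
            if ta >= tb:
                continue
            x[ta:tb] += template[ta - a : tb - a]
        if config.noise_sd_ecg > 0:
            x = x + rng.normal(0.0, config.noise_sd_ecg, size=n)
        ecg = SignalTrace(
            x,
            fs_hz=fs,
            channel="ecg",
            noise_sd=config.noise_sd_ecg,
            meta={"r_amp_mv": 1.0},
        )
    return r_times, ecg


def rsa_contrast(rri_series: RRISeries, phases: PhaseSeries) -> float:
    """Mean RRI over exhalation-contained intervals minus inhalation-contained ones.

    An interval counts as phase-contained when both of its R waves fall in
    the same phase.  Positive under normal RSA.
    """
    r = rri_series.r_times
    ph = phases.phase_at(r)
    same = ph[:-1] == ph[1:]
    rri = rri_series.rri
    inh = rri[same & (ph[:-1] == 1)]
    exh = rri[same & (ph[:-1] == -1)]
    if inh.size == 0 or exh.size == 0:
        return float("nan")
    return float(exh.mean() - inh.mean())


# ---------------------------------------------------------------------------
# task events


def _classify_interval(phases: PhaseSeries, cue: float, press: float) -> tuple[str, str, str]:
    """Ground-truth condition and half labels for one trial (open interval)."""
    ei = phases.transitions_in(cue, press, "ei")
    ie = phases.transitions_in(cue, press, "ie")
    if ei.size and ie.size:
        cond = "DOUBLE"
    elif ei.size:
        cond = "EIt"
    elif ie.size:
        cond = "IEt"
    else:
        cond = "INH" if phases.phase_at(cue)[0] == 1 else "EXH"
    mid = cue + (press - cue) / 2.0
    eit_half = ("1st" if ei[0] < mid else "2nd") if ei.size else "none"
    iet_half = ("1st" if ie[0] < mid else "2nd") if ie.size else "none"
    return cond, eit_half, iet_half


def generate_task_events(
    config: GeneratorConfig,
    phases: PhaseSeries,
    rri_series: RRISeries,
    subject_seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one subject's DMTS event stream on top of their physiology.

    Emits per-block sample-cue times, the 10-13 s delay, and per test trial a
    cue time, press time, reaction time, response and correctness, with
    match/nonmatch balanced across the subject's trials and stimulus
    identities drawn from the 6x6x6x6 space.

    RT construction (single adjustment pass): a lognormal base RT; plus
    ``beta_eit2nd_s`` when an EI transition falls in the second half of the
    base-RT window; plus ``beta_drri`` times the realized RRI velocity at the
    adjusted press time; the final ground-truth labels are recomputed from
    the final RT.

    Returns the event table and a ground-truth dict holding the true trial
    labels, RRI velocities, and the injected effect sizes.
    """
    rng = np.random.default_rng(np.random.SeedSequence((subject_seed, 2)))
    n_tests = config.n_blocks * config.tests_per_block
    span = phases.span()
    last_r = rri_series.r_times[-1] if len(rri_series.r_times) else 0.0

    n_match = n_tests // 2
    is_match = np.zeros(n_tests, dtype=bool)
    is_match[:n_match] = True
    rng.shuffle(is_match)

    space = stimulus_space()
    # subject-specific RT baseline (different intercepts between subjects)
    base = max(config.rt_base_s + rng.normal(0.0, config.rt_base_sd_s), 2 * config.rt_min_s)
    mu = np.log(base) - config.rt_sigma_lognorm**2 / 2.0

    rows = []
    truth_rows = []
    t = config.lead_in_s + config.inter_block_s
    k = 0
    for block in range(1, config.n_blocks + 1):
        attn = float(rng.normal())  # slow attentional state, one draw per block
        sample_ids = rng.choice(len(space), size=config.samples_per_block, replace=False)
        sample_times = []
        for _ in range(config.samples_per_block):
            sample_times.append(t)
            t += config.sample_cue_s + config.sample_gap_s
        delay = rng.uniform(*config.delay_range_s)
        t += delay
        for trial in range(1, config.tests_per_block + 1):
            cue = t
            rt0 = float(rng.lognormal(mu, config.rt_sigma_lognorm)) + config.attn_rt_s * attn
            rt0 = float(np.clip(rt0, config.rt_min_s, config.rt_max_s))
            # pass 1: EI-in-2nd-half prolongation under the base RT
            ei0 = phases.transitions_in(cue, cue + rt0, "ei")
            hit_2nd = bool(ei0.size > 0 and ei0[0] >= cue + rt0 / 2.0)
            rt1 = rt0 + (config.beta_eit2nd_s if hit_2nd else 0.0)
            # pass 2: RRI-velocity dependence at the adjusted press time
            d1 = float(rri_series.rri_at(cue + rt1)[0] - rri_series.rri_at(cue)[0])
            if np.isnan(d1):
                d1 = 0.0
            rt = float(np.clip(rt1 + config.beta_drri * d1, config.rt_min_s, config.rt_max_s))
            press = cue + rt
            if press > span[1] or press > last_r:
                raise RuntimeError("task schedule exceeds physiological signal duration")

            cond, eit_half, iet_half = _classify_interval(phases, cue, press)
            d_final = float(rri_series.rri_at(press)[0] - rri_series.rri_at(cue)[0])
            p_correct = (
                config.acc_base
                - (config.acc_eit_drop if cond in ("EIt", "DOUBLE") else 0.0)
                - config.attn_acc * attn  # attn raises RT, so it must lower accuracy
            )
            p_correct = float(np.clip(p_correct, 0.05, 0.99))
            correct = bool(rng.random() < p_correct)
            match = bool(is_match[k])
            if match:
                stim = int(rng.choice(sample_ids))
            else:
                stim = int(rng.integers(len(space)))
                while stim in sample_ids:
                    stim = int(rng.integers(len(space)))
            response = "old" if (match == correct) else ("new" if match else "old")
            rows.append(
                dict(
                    block=block,
                    trial=trial,
                    cue_time_s=cue,
                    press_time_s=press,
                    rt_s=rt,
                    response=response,
                    correct=correct,
                    is_match=match,
                    stimulus_id=stim,
                )
            )
            truth_rows.append(
                dict(
                    block=block,
                    trial=trial,
                    condition=cond,
                    eit_half=eit_half,
                    iet_half=iet_half,
                    delta_rri=d_final,
                    injected_eit2nd=hit_2nd,
                    injected_drri=d1,
                )
            )
            t = press + config.inter_trial_gap_s
            k += 1
        t += config.inter_block_s

    events = pd.DataFrame(rows)
    truth = {
        "ei_times": phases.ei_times.tolist(),
        "ie_times": phases.ie_times.tolist(),
        "r_times": rri_series.r_times.tolist(),
        "trials": truth_rows,
        "effects": {
            "beta_eit2nd_s": config.beta_eit2nd_s,
            "beta_drri": config.beta_drri,
            "acc_base": config.acc_base,
            "acc_eit_drop": config.acc_eit_drop,
        },
    }
    return events, truth


# ---------------------------------------------------------------------------
# subject / cohort orchestration


@dataclass
class SubjectData:
    """Everything simulated for one subject."""

    subject: int
    flow: SignalTrace | None
    ecg: SignalTrace | None
    phases: PhaseSeries
    r_times: np.ndarray
    events: pd.DataFrame
    truth: dict = field(repr=False, default_factory=dict)


def simulate_subject(
    config: GeneratorConfig,
    subject: int,
    subject_seed: int,
    render_signals: bool = True,
) -> SubjectData:
    """Simulate one subject end to end.

    ``render_signals=False`` skips waveform rendering (flow/ECG are ``None``)
    and runs the heartbeat integrator on a coarse grid — the fast path for
    label-level simulation studies.
    """
    flow, phases = generate_respiration(config, subject_seed, render=render_signals)
    r_times, ecg = generate_heartbeats(
        config, phases, subject_seed, render_ecg=render_signals
    )
    rri = RRISeries(r_times)
    events, truth = generate_task_events(config, phases, rri, subject_seed)
    return SubjectData(subject, flow, ecg, phases, r_times, events, truth)


def simulate_cohort(config: GeneratorConfig, render_signals: bool = False):
    """Yield :class:`SubjectData` for every subject in the cohort."""
    for subject, seed in enumerate(config.subject_seeds(), start=1):
        yield simulate_subject(config, subject, seed, render_signals=render_signals)


# ---------------------------------------------------------------------------
# on-disk layout


def write_subject(out_dir: str | Path, data: SubjectData) -> Path:
    """Write one subject's traces and events as TSV/JSON under ``out_dir``."""
    d = Path(out_dir) / f"sub-{data.subject:02d}"
    d.mkdir(parents=True, exist_ok=True)
    for trace, name in ((data.flow, "flow"), (data.ecg, "ecg")):
        if trace is None:
            continue
        df = pd.DataFrame({"time_s": trace.times, "value": trace.values})
        df.to_csv(d / f"{name}.tsv", sep="\t", index=False, float_format="%.6f")
    data.events.to_csv(d / "events.tsv", sep="\t", index=False, float_format="%.6f")
    def _default(o):
        if isinstance(o, (np.floating, np.integer, np.bool_)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(d / "truth.json", "w") as fh:
        json.dump(data.truth, fh, default=_default)
    return d


def write_config(out_dir: str | Path, config: GeneratorConfig) -> Path:
    import yaml

    p = Path(out_dir) / "config.yaml"
    p.parent.mkdir(parents=True, exist_ok=True)
    cfg = asdict(config)
    cfg["delay_range_s"] = list(cfg["delay_range_s"])
    cfg["flow_sign_convention"] = FLOW_SIGN_CONVENTION
    with open(p, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return p
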