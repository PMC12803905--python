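"""Trial-level cardiorespiratory classification.

Each test trial — the open interval from test-cue onset to button press — is
assigned:

* a respiratory-phase **condition**: ``INH`` / ``EXH`` when no transition
  falls inside the interval (wholly within one inhalation or exhalation),
  ``EIt`` / ``IEt`` when exactly one transition type occurs, ``DOUBLE`` when
  both do; ``INH`` and ``EXH`` pool into the transition-free ``NOt`` class;
* **half labels**: whether the first EI (and/or IE) transition inside the
  trial falls before or after the RT midpoint (``1st`` / ``2nd``; a
  transition exactly at the midpoint counts as ``2nd``);
* the **RRI velocity** ``delta_rri`` = RRI overlapping the press minus RRI
  overlapping the cue (and the variant ``delta_rri_b`` using the last RRI
  ending at or before the cue);
* a per-subject **velocity bin** (``high_neg``/``low_neg``/``low_pos``/
  ``high_pos``): within each sign, the trial's |delta_rri| relative to the
  subject's maximum of that sign, split at a configurable fraction
  (default 0.5, i.e. 10**log10(0.5));
* a **robust z score** of RT, (RT - median) / IQR over the subject's
  correct trials.

Conventions the classification fixes (transitions exactly at cue or press are
outside the open interval; delta_rri = 0 falls in ``low_pos``; a boundary
ratio goes to the high bin) are documented in ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import PhaseSeries, RRISeries

CONDITIONS = ("INH", "IEt", "EXH", "EIt", "DOUBLE")
HALF_CONDITIONS = ("IEt-1st", "IEt-2nd", "EIt-1st", "EIt-2nd")
DRRI_BINS = ("high_neg", "low_neg", "low_pos", "high_pos")


@dataclass(frozen=True)
class SubjectRtScale:
    """Robust location/scale of one subject's correct-trial RTs."""

    subject: int
    median_s: float
    iqr_s: float


def classify_trial(cue_time: float, press_time: float, phases: PhaseSeries) -> tuple[str, str, str]:
    """Condition and half labels for one trial.

    Only transitions strictly inside ``(cue_time, press_time)`` count.  The
    half label of each transition type comes from the first transition of
    that type: ``1st`` if it precedes ``cue + RT/2``, else ``2nd``.

    Raises ``ValueError`` when the phase series does not cover the trial.
    """
    if press_time <= cue_time:
        raise ValueError("press must follow cue")
    lo, _ = phases.span()
    # the phase is undefined before the first transition; after the last one
    # the trailing phase simply continues, so only the cue side is checked
    if not (lo <= cue_time):
        raise ValueError("trial outside phase-series coverage")
    ei = phases.transitions_in(cue_time, press_time, "ei")
    ie = phases.transitions_in(cue_time, press_time, "ie")
    if ei.size and ie.size:
        cond = "DOUBLE"
    elif ei.size:
        cond = "EIt"
    elif ie.size:
        cond = "IEt"
    else:
        cond = "INH" if phases.phase_at(cue_time)[0] == 1 else "EXH"
    mid = cue_time + (press_time - cue_time) / 2.0
    eit_half = ("1st" if ei[0] < mid else "2nd") if ei.size else "none"
    iet_half = ("1st" if ie[0] < mid else "2nd") if ie.size else "none"
    return cond, eit_half, iet_half


def compute_delta_rri(cue_time: float, press_time: float, rri: RRISeries) -> float:
    """RRI velocity: RRI containing the press minus RRI containing the cue.

    Each event belongs to the interval ``(R_{n-1}, R_n]`` that covers it;
    NaN when either event falls outside R-wave coverage; exactly zero when
    both fall in the same interval.
    """
    vals = rri.rri_at([cue_time, press_time])
    return float(vals[1] - vals[0])


def compute_delta_rri_b(cue_time: float, press_time: float, rri: RRISeries) -> float:
    """Variant velocity: press RRI minus the last RRI ending at or before the cue.

    NaN when no complete interval ends at or before the cue or the press is
    uncovered.
    """
    idx = int(np.searchsorted(rri.r_times, cue_time, side="right")) - 1
    # interval idx (1-based) ends at r_times[idx]; needs idx >= 1
    if idx < 1:
        return float("nan")
    prior = rri.rri[idx - 1]
    press_rri = rri.rri_at([press_time])[0]
    return float(press_rri - prior)


def bin_delta_rri(delta: pd.Series, boundary_fraction: float = 0.5) -> pd.Series:
    """Velocity bins for one subject's trials.

    Within each sign, a trial's magnitude is referred to the subject's
    maximum |delta_rri| of that sign; ratios at or above
    ``boundary_fraction`` (default 0.5 = 10**log10(0.5)) fall in the high
    bin, below it in the low bin.  Zero velocities go to ``low_pos``; NaNs
    stay missing.
    """
    if not (0 < boundary_fraction < 1):
        raise ValueError("boundary_fraction must lie in (0, 1)")
    d = pd.Series(delta, dtype=float)
    out = pd.Series(pd.NA, index=d.index, dtype="object")
    valid = d.notna()
    pos = valid & (d > 0)
    neg = valid & (d < 0)
    zero = valid & (d == 0)
    if pos.any():
        m = d[pos].abs().max()
        r = d[pos].abs() / m
        out[pos] = np.where(r >= boundary_fraction, "high_pos", "low_pos")
    if neg.any():
        m = d[neg].abs().max()
        r = d[neg].abs() / m
        out[neg] = np.where(r >= boundary_fraction, "high_neg", "low_neg")
    out[zero] = "low_pos"
    return out


def robust_z_rt(rt_s: pd.Series, correct: pd.Series) -> tuple[pd.Series, SubjectRtScale | None]:
    """Robust z of RT for one subject: (RT - median) / IQR over correct trials.

    z is assigned to correct trials only (incorrect trials get NaN, matching
    the correct-trial analyses).  Returns ``(z, scale)``; with fewer than 4
    correct trials or zero IQR the subject is unusable and z is all-NaN with
    ``scale=None``.
    """
    rt = pd.Series(rt_s, dtype=float)
    ok = pd.Series(correct, dtype=bool)
    z = pd.Series(np.nan, index=rt.index, dtype=float)
    vals = rt[ok].to_numpy()
    if vals.size < 4:
        return z, None
    med = float(np.median(vals))
    iqr = float(np.percentile(vals, 75) - np.percentile(vals, 25))
    if iqr <= 0:
        return z, None
    z[ok] = (rt[ok] - med) / iqr
    return z, SubjectRtScale(-1, med, iqr)


# ---------------------------------------------------------------------------
# full trial table


def build_trial_table(
    subject: int,
    events: pd.DataFrame,
    phases: PhaseSeries,
    rri: RRISeries,
    boundary_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the full per-trial record table for one subject.

    Adds condition/half labels, NOt flag, delta_rri (+ the before-cue
    variant), velocity bins and robust-z RT to the event table.  Trials the
    phase series cannot cover are excluded and reported in the QC dict.
    """
    df = events.copy()
    df.insert(0, "subject", subject)
    conds, eih, ieh = [], [], []
    excluded = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            c, e, ie_ = classify_trial(row.cue_time_s, row.press_time_s, phases)
        except ValueError as err:
            keep[i] = False
            excluded.append({"block": int(row.block), "trial": int(row.trial), "reason": str(err)})
            continue
        conds.append(c)
        eih.append(e)
        ieh.append(ie_)
    df = df[keep].reset_index(drop=True)
    df["condition"] = conds
    df["not_flag"] = df["condition"].isin(["INH", "EXH"])
    df["eit_half"] = eih
    df["iet_half"] = ieh
    df["delta_rri"] = [
        compute_delta_rri(c, p, rri) for c, p in zip(df["cue_time_s"], df["press_time_s"])
    ]
    df["delta_rri_b"] = [
        compute_delta_rri_b(c, p, rri) for c, p in zip(df["cue_time_s"], df["press_time_s"])
    ]
    df["delta_rri_bin"] = bin_delta_rri(df["delta_rri"], boundary_fraction)
    z, scale = robust_z_rt(df["rt_s"], df["correct"])
    df["rt_robust_z"] = z
    qc = {
        "subject": subject,
        "n_trials": int(len(df)),
        "excluded_trials": excluded,
        "iqr_zero_or_insufficient": scale is None,
        "rt_median_s": None if scale is None else scale.median_s,
        "rt_iqr_s": None if scale is None else scale.iqr_s,
        "n_missing_delta_rri": int(df["delta_rri"].isna().sum()),
    }
    return df, qc


def half_condition(trials: pd.DataFrame) -> pd.Series:
    """Half-condition label for single-transition trials (IEt-1st ... EIt-2nd).

    NaN for transition-free and DOUBLE trials (DOUBLE contributes to both
    types and is analysed separately).
    """
    lab = pd.Series(pd.NA, index=trials.index, dtype="object")
    iet = trials["condition"] == "IEt"
    eit = trials["condition"] == "EIt"
    lab[iet] = "IEt-" + trials.loc[iet, "iet_half"].astype(str)
    lab[eit] = "EIt-" + trials.loc[eit, "eit_half"].astype(str)
    return lab


def condition_means(trials: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Per-subject per-condition mean robust-z RT (correct trials) and accuracy.

    Groupings
    ---------
    ``phase``  : NOt / IEt / EIt (INH+EXH pooled; DOUBLE dropped)
    ``half``   : IEt-1st / IEt-2nd / EIt-1st / EIt-2nd
    ``bin``    : the four delta_rri velocity bins
    ``double`` : DOUBLE trials, iet_half x eit_half cross (trial-level z kept)
    ``first_test`` : like ``half`` restricted to each block's first test trial

    Returns a tidy frame ``subject, condition, mean_z, n_correct, accuracy,
    n_trials``; subject x condition cells with no trials are absent.
    """
    df = trials.copy()
    if grouping == "phase":
        df = df[df["condition"] != "DOUBLE"].copy()
        df["cell"] = np.where(df["not_flag"], "NOt", df["condition"])
    elif grouping == "half":
        df["cell"] = half_condition(df)
        df = df[df["cell"].notna()]
    elif grouping == "first_test":
        df = df[df["trial"] == 1].copy()
        df["cell"] = half_condition(df)
        df = df[df["cell"].notna()]
    elif grouping == "bin":
        df = df[df["delta_rri_bin"].notna()].copy()
        df["cell"] = df["delta_rri_bin"]
    elif grouping == "double":
        df = df[df["condition"] == "DOUBLE"].copy()
        df["cell"] = (
            "IEt-" + df["iet_half"].astype(str) + "+EIt-" + df["eit_half"].astype(str)
        )
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = []
    for (subject, cell), g in df.groupby(["subject", "cell"], sort=True):
        zc = g.loc[g["correct"], "rt_robust_z"]
        rows.append(
            dict(
                subject=subject,
                condition=cell,
                mean_z=float(zc.mean()) if len(zc) else np.nan,
                n_correct=int(g["correct"].sum()),
                accuracy=float(g["correct"].mean()),
                n_trials=int(len(g)),
            )
        )
    return pd.DataFrame(rows)
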