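"""Independent brute-force oracles used to validate the fast implementations.

Deliberately naive: plain Python loops over raw event lists, no shared code
with the package's vectorised paths.
"""

from __future__ import annotations

import numpy as np


def classify_bruteforce(cue: float, press: float, ei_times, ie_times):
    """Trial condition and half labels by scanning every transition."""
    ei_in = [float(t) for t in ei_times if cue < t < press]
    ie_in = [float(t) for t in ie_times if cue < t < press]
    if ei_in and ie_in:
        cond = "DOUBLE"
    elif ei_in:
        cond = "EIt"
    elif ie_in:
        cond = "IEt"
    else:
        # phase at cue: most recent transition at or before cue
        last_kind = None
        last_t = -np.inf
        for t in ei_times:
            if t <= cue and t > last_t:
                last_t, last_kind = t, "ei"
        for t in ie_times:
            if t <= cue and t > last_t:
                last_t, last_kind = t, "ie"
        cond = "INH" if last_kind == "ei" else "EXH"
    mid = cue + (press - cue) / 2.0
    eit_half = ("1st" if min(ei_in) < mid else "2nd") if ei_in else "none"
    iet_half = ("1st" if min(ie_in) < mid else "2nd") if ie_in else "none"
    return cond, eit_half, iet_half


def rri_at_bruteforce(t: float, r_times) -> float:
    """RRI owning time t under the (R_{n-1}, R_n] convention, by linear scan."""
    for i in range(1, len(r_times)):
        if r_times[i - 1] < t <= r_times[i]:
            return float(r_times[i] - r_times[i - 1])
    return float("nan")


def delta_rri_bruteforce(cue: float, press: float, r_times) -> float:
    return rri_at_bruteforce(press, r_times) - rri_at_bruteforce(cue, r_times)


def delta_rri_b_bruteforce(cue: float, press: float, r_times) -> float:
    """Press RRI minus the last complete RRI ending at or before the cue."""
    prior = float("nan")
    for i in range(1, len(r_times)):
        if r_times[i] <= cue:
            prior = float(r_times[i] - r_times[i - 1])
    return rri_at_bruteforce(press, r_times) - prior


def bin_bruteforce(deltas, c: float = 0.5) -> list:
    """Per-subject velocity binning by explicit loops."""
    pos = [abs(d) for d in deltas if d == d and d > 0]
    neg = [abs(d) for d in deltas if d == d and d < 0]
    mpos = max(pos) if pos else None
    mneg = max(neg) if neg else None
    out = []
    for d in deltas:
        if d != d:
            out.append(None)
        elif d == 0:
            out.append("low_pos")
        elif d > 0:
            out.append("high_pos" if abs(d) / mpos >= c else "low_pos")
        else:
            out.append("high_neg" if abs(d) / mneg >= c else "low_neg")
    return out


def robust_z_bruteforce(rts) -> list:
    """Sort-based median/IQR standardisation."""
    x = sorted(float(v) for v in rts)
    n = len(x)

    def quantile(q):  # linear interpolation, matching the conventional definition
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    med = quantile(0.5)
    iqr = quantile(0.75) - quantile(0.25)
    return [(float(v) - med) / iqr for v in rts]


def aggregate_bruteforce(trials) -> dict:
    """Window aggregation by explicit accumulation; keys (subject, window)."""
    acc: dict = {}
    for row in trials.itertuples(index=False):
        w = (int(row.block) - 1) // 2 + 1
        key = (row.subject, w)
        slot = acc.setdefault(
            key, {"rt": [], "eit2": 0, "iet2": 0, "ok": 0, "n": 0, "drri": []}
        )
        slot["n"] += 1
        if row.correct:
            slot["ok"] += 1
            slot["rt"].append(row.rt_s)
        if row.eit_half == "2nd":
            slot["eit2"] += 1
        if row.iet_half == "2nd":
            slot["iet2"] += 1
        if row.delta_rri == row.delta_rri:
            slot["drri"].append(row.delta_rri)
    out = {}
    for key, s in acc.items():
        out[key] = {
            "mean_rt": sum(s["rt"]) / len(s["rt"]) if s["rt"] else float("nan"),
            "eit2nd_rate": s["eit2"] / s["n"],
            "iet2nd_rate": s["iet2"] / s["n"],
            "accuracy": s["ok"] / s["n"],
            "delta_rri": sum(s["drri"]) / len(s["drri"]) if s["drri"] else float("nan"),
        }
    return out


def friedman_bruteforce(matrix: np.ndarray) -> float:
    """Friedman chi-square by explicit within-row ranking (mean ranks for ties)."""
    n, k = matrix.shape
    ranks = np.zeros_like(matrix, dtype=float)
    for i in range(n):
        row = matrix[i]
        order = sorted(range(k), key=lambda j: row[j])
        j = 0
        while j < k:
            j2 = j
            while j2 + 1 < k and row[order[j2 + 1]] == row[order[j]]:
                j2 += 1
            mean_rank = (j + j2) / 2.0 + 1.0
            for jj in range(j, j2 + 1):
                ranks[i][order[jj]] = mean_rank
            j = j2 + 1
    rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3.0 * n * (k + 1)
    # tie correction as in the standard definition
    ties = 0.0
    for i in range(n):
        _, counts = np.unique(matrix[i], return_counts=True)
        ties += float((counts**3 - counts).sum())
    corr = 1.0 - ties / (n * k * (k**2 - 1))
    return chi2 / corr if corr > 0 else 0.0
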