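"""Signal containers and detectors for respiratory flow and ECG traces.

The raw inputs of the pipeline are two continuous channels sampled at 1 kHz:
nasal airflow (differential pressure, arbitrary units; inhalation positive by
the declared sign convention) and a lead-II ECG (mV).  This module turns them
into the two event series everything downstream consumes:

* a :class:`PhaseSeries` — the alternating exhalation-to-inhalation (EI) and
  inhalation-to-exhalation (IE) transition times that partition time into
  inhalation and exhalation intervals, detected as threshold-validated zero
  crossings of the baseline-subtracted flow;
* an :class:`RRISeries` — R-wave times and the derived RR intervals
  (RRI_n = R_n - R_{n-1}), detected with a derivative-energy (Pan-Tompkins
  style) QRS detector on the band-passed ECG.

All functions are pure: the same input always yields the same output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled single-channel physiological trace.

    Parameters
    ----------
    values : ndarray
        Sample values (flow: pressure units, inhalation-positive;
        ECG: mV).
    fs_hz : float
        Sampling rate; the acquisition standard here is 1000 Hz.
    channel : str
        Free-form channel label, e.g. ``"flow"`` or ``"ecg"``.
    baseline_level : float
        Known or estimated DC baseline in the units of ``values``.
    noise_sd : float or None
        Baseline noise SD if known (generators record the injected value).
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    fs_hz: float = 1000.0
    channel: str = ""
    baseline_level: float = 0.0
    noise_sd: float | None = None
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.values.ndim != 1:
            raise ValueError("SignalTrace values must be one-dimensional")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("SignalTrace values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) / self.fs_hz


@dataclass(frozen=True)
class PhaseSeries:
    """Alternating EI (inhalation-onset) and IE (exhalation-onset) times.

    The merged sequence of transitions strictly alternates; inhalation
    occupies ``[EI_k, IE_k)`` and exhalation ``[IE_k, EI_{k+1})``.
    """

    ei_times: np.ndarray
    ie_times: np.ndarray

    def __post_init__(self) -> None:
        ei = np.asarray(self.ei_times, dtype=float)
        ie = np.asarray(self.ie_times, dtype=float)
        object.__setattr__(self, "ei_times", ei)
        object.__setattr__(self, "ie_times", ie)
        for arr, name in ((ei, "ei_times"), (ie, "ie_times")):
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        t, k = self.merged()
        if t.size > 1 and np.any(k[1:] == k[:-1]):
            raise ValueError("EI and IE transitions must strictly alternate")

    def merged(self) -> tuple[np.ndarray, np.ndarray]:
        """All transition times with type codes (+1 for EI, -1 for IE)."""
        t = np.concatenate([self.ei_times, self.ie_times])
        k = np.concatenate(
            [np.ones(len(self.ei_times), dtype=int), -np.ones(len(self.ie_times), dtype=int)]
        )
        order = np.argsort(t, kind="stable")
        return t[order], k[order]

    @property
    def n_cycles(self) -> int:
        return max(len(self.ei_times) - 1, 0)

    def phase_at(self, t) -> np.ndarray:
        """+1 where ``t`` falls in inhalation, -1 in exhalation, 0 outside coverage."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        times, kinds = self.merged()
        out = np.zeros(t.shape, dtype=int)
        if times.size == 0:
            return out
        idx = np.searchsorted(times, t, side="right") - 1
        inside = idx >= 0
        out[inside] = kinds[idx[inside]]
        return out

    def transitions_in(self, a: float, b: float, kind: str) -> np.ndarray:
        """Transition times of ``kind`` ('ei' or 'ie') strictly inside (a, b)."""
        arr = self.ei_times if kind == "ei" else self.ie_times
        return arr[(arr > a) & (arr < b)]

    def span(self) -> tuple[float, float]:
        t, _ = self.merged()
        if t.size == 0:
            return (np.nan, np.nan)
        return float(t[0]), float(t[-1])


@dataclass(frozen=True)
class RRISeries:
    """R-wave times and RR intervals, addressable by any covered time point.

    ``RRI_n = R_n - R_{n-1}`` owns the half-open interval ``(R_{n-1}, R_n]``,
    so an event coincident with an R wave belongs to the interval that R wave
    terminates.
    """

    r_times: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r_times, dtype=float)
        object.__setattr__(self, "r_times", r)
        if r.size >= 2 and not np.all(np.diff(r) > 0):
            raise ValueError("R-wave times must be strictly increasing")

    @property
    def rri(self) -> np.ndarray:
        """RR intervals in seconds; length = number of R waves - 1."""
        return np.diff(self.r_times)

    def interval_index(self, t) -> np.ndarray:
        """1-based interval index n with ``R_{n-1} < t <= R_n``; -1 outside coverage."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.r_times, t, side="left")
        out = idx.astype(int)
        bad = (idx == 0) | (idx >= len(self.r_times))
        out[bad] = -1
        return out

    def rri_at(self, t) -> np.ndarray:
        """RRI of the interval covering each time; NaN outside coverage."""
        idx = self.interval_index(t)
        out = np.full(idx.shape, np.nan)
        ok = idx > 0
        if np.any(ok):
            out[ok] = self.rri[idx[ok] - 1]
        return out


# ---------------------------------------------------------------------------
# flow processing


def subtract_baseline(trace: SignalTrace, baseline_level: float | None = None) -> SignalTrace:
    """Subtract the ambient-pressure baseline from a flow trace.

    Uses ``trace.baseline_level`` when no explicit level is given.  The
    returned trace has ``baseline_level = 0``.
    """
    level = trace.baseline_level if baseline_level is None else float(baseline_level)
    if not np.isfinite(level):
        raise ValueError("baseline level must be finite")
    return replace(trace, values=trace.values - level, baseline_level=0.0)


def estimate_noise_sd(trace: SignalTrace, quiet_window: tuple[float, float]) -> float:
    """SD of the baseline-subtracted signal over a quiet (task-free) window.

    The window is given in seconds; it must span at least one second so the
    estimate is stable at 1 kHz.
    """
    a, b = quiet_window
    if b - a < 1.0:
        raise ValueError("quiet window must span at least 1 s")
    t = trace.times
    mask = (t >= a) & (t < b)
    if not np.any(mask):
        raise ValueError("quiet window contains no samples")
    seg = trace.values[mask] - trace.baseline_level
    return float(np.std(seg))


def detect_respiratory_transitions(
    trace: SignalTrace,
    noise_sd: float,
    min_phase_s: float = 0.5,
    smooth_hz: float | None = 5.0,
) -> PhaseSeries:
    """Detect EI/IE transitions as threshold-validated zero crossings.

    A candidate onset is a zero crossing after which the flow deviates from
    baseline by more than ``2 * noise_sd`` before re-crossing zero
    (hysteresis); sub-threshold excursions are discarded as chatter.  Upward
    crossings mark inhalation onsets (EI) and downward crossings exhalation
    onsets (IE) under the inhalation-positive sign convention.  Strict
    alternation is enforced by dropping any onset repeating the previous
    type, and onsets closer than ``min_phase_s`` to the previous kept onset
    are debounced.

    On noisy traces the crossing structure is read from a zero-phase
    low-pass (``smooth_hz``, well above the respiratory band) so that
    sample-level noise chatter does not fragment the crossings; the 2 SD
    validation threshold still refers to the raw baseline noise.  Noise-free
    traces are used as-is.  Crossing times are refined by linear
    interpolation between the samples bracketing the sign change.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if min_phase_s <= 0:
        raise ValueError("min_phase_s must be positive")
    x = trace.values - trace.baseline_level
    if noise_sd > 0 and smooth_hz is not None and x.size > 30:
        sos = sps.butter(4, smooth_hz, btype="lowpass", fs=trace.fs_hz, output="sos")
        x = sps.sosfiltfilt(sos, x)
    n = x.size
    if n < 2:
        return PhaseSeries(np.array([]), np.array([]))
    thr = 2.0 * noise_sd

    sign = np.sign(x)
    # a leading zero-run is a resting baseline: let its end register as a crossing
    nz = np.nonzero(sign)[0]
    if nz.size == 0:
        return PhaseSeries(np.array([]), np.array([]))
    if nz[0] > 0:
        sign[: nz[0]] = -sign[nz[0]]
    # interior exact zeros belong to the preceding excursion (forward fill)
    if np.any(sign == 0):
        idx = np.where(sign != 0, np.arange(n), 0)
        np.maximum.accumulate(idx, out=idx)
        sign = sign[idx]
    cross = np.nonzero(sign[1:] * sign[:-1] < 0)[0] + 1  # index of first sample after crossing
    if cross.size == 0:
        return PhaseSeries(np.array([]), np.array([]))

    # max |x| in each segment between consecutive crossings (and after the last)
    bounds = np.concatenate([cross, [n]])
    absx = np.abs(x)
    seg_max = np.maximum.reduceat(absx, bounds[:-1])

    keep: list[tuple[float, int]] = []
    t = trace.times
    fs = trace.fs_hz
    for j, c in enumerate(cross):
        if seg_max[j] <= thr:
            continue  # excursion never clears the noise band
        kind = 1 if x[c] > 0 else -1
        if keep and kind == keep[-1][1]:
            continue  # alternation: drop the later same-type onset
        # linear interpolation of the zero crossing between samples c-1 and c
        x0, x1 = x[c - 1], x[c]
        frac = x0 / (x0 - x1) if x0 != x1 else 0.0
        tc = t[c - 1] + frac / fs
        # debounce: a same-type onset within min_phase_s marks a spurious
        # micro-cycle — drop it together with the intervening opposite onset
        if len(keep) >= 2 and tc - keep[-2][0] < min_phase_s:
            keep.pop()
            continue
        keep.append((tc, kind))
    ei = np.array([tt for tt, k in keep if k == 1])
    ie = np.array([tt for tt, k in keep if k == -1])
    return PhaseSeries(ei, ie)


# ---------------------------------------------------------------------------
# ECG processing


def bandpass_ecg(trace: SignalTrace, low_hz: float = 0.5, high_hz: float = 40.0) -> SignalTrace:
    """Zero-phase Butterworth band-pass (default 0.5-40 Hz) of an ECG trace.

    Removes baseline drift and high-frequency noise without shifting R-wave
    times (forward-backward filtering).
    """
    nyq = trace.fs_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError("require 0 < low_hz < high_hz < fs/2")
    sos = sps.butter(2, [low_hz, high_hz], btype="bandpass", fs=trace.fs_hz, output="sos")
    y = sps.sosfiltfilt(sos, trace.values)
    return replace(trace, values=y, baseline_level=0.0)


def detect_r_waves(
    trace: SignalTrace,
    refractory_s: float = 0.2,
    integration_window_s: float = 0.15,
    threshold_fraction: float = 0.4,
) -> np.ndarray:
    """Derivative-energy QRS detection on a band-passed ECG.

    Pan-Tompkins style: differentiate, square, moving-window integrate, then
    pick peaks of the integrated energy separated by at least the refractory
    period and exceeding ``threshold_fraction`` times the median peak height
    (adaptive threshold).  Each detection is refined to the local maximum of
    the band-passed ECG within the integration window.

    Returns strictly increasing R-wave times in seconds; empty for flat
    input.
    """
    x = trace.values
    if x.size < 3 or np.ptp(x) == 0:
        return np.array([])
    fs = trace.fs_hz
    # narrow QRS-band filter for the energy stage only; peak refinement
    # happens on the input trace
    if x.size > 50:
        sos = sps.butter(2, [5.0, min(25.0, fs / 2 * 0.9)], btype="bandpass", fs=fs, output="sos")
        xe = sps.sosfiltfilt(sos, x)
    else:
        xe = x
    deriv = np.gradient(xe) * fs
    energy = deriv**2
    win = max(int(round(integration_window_s * fs)), 1)
    integ = sps.convolve(energy, np.ones(win) / win, mode="same")

    dist = max(int(round(refractory_s * fs)), 1)
    peaks, props = sps.find_peaks(integ, distance=dist, height=0.0)
    if peaks.size == 0:
        return np.array([])
    heights = props["peak_heights"]
    # QRS peaks sit orders of magnitude above inter-beat energy; anchor the
    # adaptive threshold on the upper tail so noise peaks cannot drag it down
    thr = threshold_fraction * float(np.quantile(heights, 0.90))
    peaks = peaks[heights > thr]
    if peaks.size == 0:
        return np.array([])

    # refine to the local ECG maximum around each energy peak
    half = win // 2
    r_idx = np.empty(peaks.size, dtype=int)
    for i, p in enumerate(peaks):
        a = max(p - half, 0)
        b = min(p + half + 1, x.size)
        r_idx[i] = a + int(np.argmax(x[a:b]))
    r_idx = np.unique(r_idx)
    # re-apply the refractory period after refinement
    kept = [int(r_idx[0])]
    for idx in r_idx[1:]:
        if idx - kept[-1] >= dist:
            kept.append(int(idx))
        elif x[idx] > x[kept[-1]]:
            kept[-1] = int(idx)
    return trace.t0 + np.asarray(kept, dtype=float) / fs


def build_rri_series(r_times) -> RRISeries:
    """Build an :class:`RRISeries` from >= 2 strictly increasing R-wave times."""
    r = np.asarray(r_times, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two R-wave times")
    if not np.all(np.diff(r) > 0):
        raise ValueError("R-wave times must be strictly increasing")
    return RRISeries(r)


def qc_rri_outliers(series: RRISeries, n_sd: float = 3.0) -> np.ndarray:
    """Indices (1-based interval index) of RRIs more than ``n_sd`` subject-SDs
    from the subject mean — the automatic stand-in for manual beat review."""
    rri = series.rri
    if rri.size < 2:
        return np.array([], dtype=int)
    sd = rri.std()
    if sd == 0:
        return np.array([], dtype=int)
    z = np.abs(rri - rri.mean()) / sd
    return np.nonzero(z > n_sd)[0] + 1
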