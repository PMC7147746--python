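"""Quantification of simulated seizure dynamics.

Detection of ictal discharges from probe potassium traces, wavefront
arrival times and speeds from radial profiles, space-time burst diagrams,
burst/discharge synchrony across probes, and two closed-form magnitude
estimates (Nernst sensitivity, electrodiffusion drift speed) used to judge
which transport mechanisms matter.

Conventions: an ictal discharge (ID) is detected as an excursion of [K]_o
above an onset threshold (default 4 mM, the level at which discharges
initiate) with a hysteresis band to ignore burst-scale chatter; a wavefront
arrival at a radial position is the onset of that position's own k-th
discharge, so successive waves remain separable even when a slow wave is
still travelling while the next one starts at the centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .params import NERNST_MV

__all__ = [
    "summarize_record",
    "DischargeEvent",
    "WaveFront",
    "WaveSpeedFit",
    "detect_discharges",
    "discharge_intervals",
    "front_arrival_times",
    "wavefront_speed",
    "envelope_front",
    "rate_discharges",
    "rate_onsets",
    "space_time_pattern",
    "burst_synchrony",
    "electrodiffusion_speed",
    "nernst_sensitivity",
]


# ----------------------------------------------------------------------
# Discharge detection
# ----------------------------------------------------------------------
@dataclass
class DischargeEvent:
    """One detected ictal discharge on a single trace."""

    onset_t: float
    offset_t: float
    peak_K_o: float
    onset_K_o: float

    @property
    def duration(self) -> float:
        return self.offset_t - self.onset_t


def detect_discharges(t: np.ndarray, K_o: np.ndarray,
                      on_threshold: float = 4.0,
                      off_hysteresis: float = 0.5,
                      min_gap: float = 5.0) -> List[DischargeEvent]:
    """Hysteresis detector for ictal discharges on a potassium trace.

    An event opens at an upward crossing of ``on_threshold`` and closes when
    the trace falls below ``on_threshold - off_hysteresis``; events whose
    gap is shorter than ``min_gap`` seconds are merged.  Crossing times are
    linearly interpolated between samples.  An event still open at the end
    of the trace is closed at the final sample.
    """
    t = np.asarray(t, dtype=float)
    K = np.asarray(K_o, dtype=float)
    if t.size == 0 or K.size == 0:
        raise ValueError("empty trace")
    if t.size != K.size:
        raise ValueError("t and K_o must have equal length")
    off_threshold = on_threshold - off_hysteresis

    events: List[DischargeEvent] = []
    above = K >= on_threshold
    below = K < off_threshold
    i = 0
    n = t.size
    while i < n:
        ups = np.flatnonzero(above[i:])
        if ups.size == 0:
            break
        j = i + int(ups[0])
        onset = _cross_time(t, K, j, on_threshold, upward=True)
        downs = np.flatnonzero(below[j:])
        if downs.size == 0:
            k = n - 1
            offset = t[-1]
        else:
            k = j + int(downs[0])
            offset = _cross_time(t, K, k, off_threshold, upward=False)
        peak = float(K[j:k + 1].max())
        events.append(DischargeEvent(onset, offset, peak, float(K[j])))
        i = k + 1

    merged: List[DischargeEvent] = []
    for ev in events:
        if merged and ev.onset_t - merged[-1].offset_t < min_gap:
            prev = merged[-1]
            merged[-1] = DischargeEvent(prev.onset_t, ev.offset_t,
                                        max(prev.peak_K_o, ev.peak_K_o),
                                        prev.onset_K_o)
        else:
            merged.append(ev)
    return merged


def _cross_time(t, K, idx, level, upward):
    """Linear interpolation of the crossing time at sample ``idx``."""
    if idx == 0:
        return float(t[0])
    k0, k1 = K[idx - 1], K[idx]
    if k1 == k0:
        return float(t[idx])
    frac = (level - k0) / (k1 - k0)
    frac = min(max(frac, 0.0), 1.0)
    return float(t[idx - 1] + frac * (t[idx] - t[idx - 1]))


def discharge_intervals(events: Sequence[DischargeEvent]) -> np.ndarray:
    """Onset-to-onset intervals between successive discharges (s)."""
    onsets = np.array([ev.onset_t for ev in events])
    return np.diff(onsets)


# ----------------------------------------------------------------------
# Wavefront speed
# ----------------------------------------------------------------------
@dataclass
class WaveFront:
    """Threshold arrival times of one outward wave along a radial ray."""

    arrivals: List[Tuple[float, float]]   # (position mm, time s)
    threshold: float
    wave_index: int
    missing: List[float] = field(default_factory=list)


@dataclass
class WaveSpeedFit:
    speed: float          # mm/s
    n_points: int
    residual: float       # rms of the position fit, mm
    intercept: float


def front_arrival_times(ray_t: np.ndarray, ray_r: np.ndarray,
                        ray_K: np.ndarray,
                        threshold: float = 5.0,
                        off_hysteresis: float = 1.0,
                        wave_index: int = 0,
                        r_min: float = 0.5, r_max: float = 2.5) -> WaveFront:
    """Arrival time of the ``wave_index``-th potassium wave per position.

    For each radial position in ``[r_min, r_max]`` the local trace is
    segmented into discharges with the hysteresis detector and the onset of
    its ``wave_index``-th event is the arrival.  Positions whose trace never
    produces that event are recorded as missing, not errors.

    The default arrival threshold sits midway between the quiescent stall
    level (just under 4 mM, which ambient fluctuations occasionally graze)
    and the wave peak (8 mM and above): the front is steep, so the fitted
    speed is insensitive to the exact level, but a threshold at the
    ignition level itself would register spurious simultaneous "arrivals"
    wherever the slowly charging background touches it.
    """
    ray_t = np.asarray(ray_t, dtype=float)
    ray_K = np.asarray(ray_K, dtype=float)
    arrivals: List[Tuple[float, float]] = []
    missing: List[float] = []
    for col, r in enumerate(np.asarray(ray_r, dtype=float)):
        if not (r_min <= r <= r_max):
            continue
        events = detect_discharges(ray_t, ray_K[:, col],
                                   on_threshold=threshold,
                                   off_hysteresis=off_hysteresis)
        if len(events) > wave_index:
            arrivals.append((float(r), events[wave_index].onset_t))
        else:
            missing.append(float(r))
    return WaveFront(arrivals=arrivals, threshold=threshold,
                     wave_index=wave_index, missing=missing)


def wavefront_speed(front: WaveFront) -> WaveSpeedFit:
    """Robust front speed from position-versus-arrival-time.

    Fits position as a linear function of arrival time with the Theil-Sen
    estimator (median of pairwise slopes): a minority of corrupted
    arrivals — a position triggered early by a stray excursion — does not
    drag the slope, while on clean fronts the estimate coincides with
    least squares.  The slope is the outward speed in mm/s; the residual
    is the rms scatter of positions about the fitted line.
    """
    if len(front.arrivals) < 2:
        raise ValueError(f"need at least 2 arrivals to fit a speed, "
                         f"got {len(front.arrivals)}")
    pos = np.array([a[0] for a in front.arrivals])
    times = np.array([a[1] for a in front.arrivals])
    if np.ptp(times) == 0.0:
        raise ValueError("all arrivals simultaneous; speed undefined")
    slope, intercept, _, _ = stats.theilslopes(pos, times)
    resid = float(np.sqrt(np.mean((pos - (slope * times + intercept)) ** 2)))
    return WaveSpeedFit(speed=float(slope), n_points=len(front.arrivals),
                        residual=resid, intercept=float(intercept))


def envelope_front(ray_t: np.ndarray, ray_r: np.ndarray,
                   ray_activity: np.ndarray,
                   smooth_window: float = 2.0,
                   threshold: float = 10.0,
                   wave_index: int = 0,
                   min_duration: float = 5.0,
                   r_min: float = 0.5, r_max: float = 2.9) -> WaveFront:
    """Front of the time-averaged outer envelope of burst activity.

    The firing-rate profile at each position is averaged over a sliding
    window (default 2 s, long against single bursts, short against the
    slow potassium wave); the envelope arrival at a position is the onset
    of the ``wave_index``-th excursion of the averaged activity above
    ``threshold`` (Hz) lasting at least ``min_duration`` seconds.  The
    duration requirement is the same sustained-activity criterion that
    defines a discharge: spatially synchronized preictal bursts cross the
    threshold everywhere at once for a second or two and would otherwise
    register as a near-infinite-speed "front".  Fit with
    :func:`wavefront_speed` to obtain the slow envelope-wave speed.
    """
    ray_t = np.asarray(ray_t, dtype=float)
    act = np.asarray(ray_activity, dtype=float)
    if ray_t.size < 2:
        raise ValueError("need at least two time samples")
    cadence = float(np.median(np.diff(ray_t)))
    w = max(1, int(round(smooth_window / cadence)))
    kernel = np.ones(w) / w
    smoothed = np.apply_along_axis(
        lambda c: np.convolve(c, kernel, mode="same"), 0, act)
    arrivals: List[Tuple[float, float]] = []
    missing: List[float] = []
    for col, r in enumerate(np.asarray(ray_r, dtype=float)):
        if not (r_min <= r <= r_max):
            continue
        events = detect_discharges(ray_t, smoothed[:, col],
                                   on_threshold=threshold,
                                   off_hysteresis=threshold / 2.0,
                                   min_gap=smooth_window)
        events = [ev for ev in events if ev.duration >= min_duration]
        if len(events) > wave_index:
            arrivals.append((float(r), events[wave_index].onset_t))
        else:
            missing.append(float(r))
    return WaveFront(arrivals=arrivals, threshold=threshold,
                     wave_index=wave_index, missing=missing)


def rate_discharges(t: np.ndarray, nu: np.ndarray,
                    rate_threshold: float = 10.0,
                    smooth_window: float = 2.0,
                    min_gap: float = 20.0,
                    min_duration: float = 5.0) -> List[DischargeEvent]:
    """Discharges delimited by the firing-rate burst envelope.

    The somatic rate is averaged over ``smooth_window`` seconds (long
    against single bursts, short against a discharge, matching the
    envelope-front smoothing); a discharge opens at an upward crossing of
    ``rate_threshold`` and closes when the averaged rate drops to a fifth
    of it, with ``min_gap`` merging.  Events shorter than ``min_duration``
    are isolated interictal bursts, not ictal discharges, and are dropped.
    This delimits the *high-rate phase* of an ictal discharge — the
    quantity a duration refers to — independently of how long the
    potassium excursion takes to clear afterwards (without diffusion the
    potassium tail outlasts the activity considerably).
    """
    t = np.asarray(t, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if t.size == 0:
        raise ValueError("empty trace")
    cadence = float(np.median(np.diff(t)))
    w = max(1, int(round(smooth_window / cadence)))
    smoothed = np.convolve(nu, np.ones(w) / w, mode="same")
    events = detect_discharges(t, smoothed, on_threshold=rate_threshold,
                               off_hysteresis=rate_threshold * 0.8,
                               min_gap=min_gap)
    return [ev for ev in events if ev.duration >= min_duration]


def rate_onsets(t: np.ndarray, nu: np.ndarray, K_o: np.ndarray,
                rate_threshold: float = 10.0,
                smooth_window: float = 1.0,
                min_gap: float = 20.0) -> List[Tuple[float, float]]:
    """Discharge onsets from the firing-rate envelope, with [K]_o there.

    Independent of the potassium detector (no circularity): returns
    ``(onset_time, K_o_at_onset)`` pairs, giving the potassium level at
    which discharges initiate.
    """
    K = np.asarray(K_o, dtype=float)
    events = rate_discharges(t, nu, rate_threshold=rate_threshold,
                             smooth_window=smooth_window, min_gap=min_gap)
    t = np.asarray(t, dtype=float)
    return [(ev.onset_t, float(np.interp(ev.onset_t, t, K)))
            for ev in events]


# ----------------------------------------------------------------------
# Space-time structure and synchrony
# ----------------------------------------------------------------------
@dataclass
class SpaceTimePattern:
    """Voltage over (position, time) for a strip, with burst timing."""

    t: np.ndarray         # (m,)
    y: np.ndarray         # (k,) positions along the strip, mm
    V: np.ndarray         # (m, k)

    def burst_onset_inclinations(self, threshold: float = 25.0
                                 ) -> List[float]:
        """Per-burst front inclination across the strip, s/mm.

        A burst is a contiguous interval in which the strip-maximum voltage
        exceeds ``threshold``; within each burst the per-position onset
        times are fitted linearly against position.  Synchronous bursts give
        inclinations near zero (vertical stripes in the y-t diagram); a
        front travelling at speed c gives 1/c.
        """
        strip_max = self.V.max(axis=1)
        above = strip_max >= threshold
        edges = np.diff(above.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        stops = list(np.flatnonzero(edges == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            stops.append(len(above))
        inclinations = []
        for a, b in zip(starts, stops):
            onsets, pos = [], []
            for col in range(self.V.shape[1]):
                idx = np.flatnonzero(self.V[a:b, col] >= threshold)
                if idx.size:
                    onsets.append(self.t[a + idx[0]])
                    pos.append(self.y[col])
            if len(onsets) >= 3 and np.ptp(pos) > 0:
                slope = np.polyfit(pos, onsets, 1)[0]
                inclinations.append(float(slope))
        return inclinations


def space_time_pattern(times: np.ndarray, positions: np.ndarray,
                       V: np.ndarray,
                       window: Optional[Tuple[float, float]] = None,
                       pos_range: Optional[Tuple[float, float]] = None
                       ) -> SpaceTimePattern:
    """Crop a voltage strip capture to a window and position range.

    ``V`` has shape (time, position).  Raises when the requested window or
    range does not intersect the data.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    V = np.asarray(V, dtype=float)
    tmask = np.ones_like(times, dtype=bool)
    if window is not None:
        tmask = (times >= window[0]) & (times <= window[1])
    pmask = np.ones_like(positions, dtype=bool)
    if pos_range is not None:
        pmask = (positions >= pos_range[0]) & (positions <= pos_range[1])
    if not tmask.any():
        raise ValueError("window outside the recorded time range")
    if not pmask.any():
        raise ValueError("position range outside the recorded strip")
    return SpaceTimePattern(t=times[tmask], y=positions[pmask],
                            V=V[np.ix_(tmask, pmask)])


def burst_synchrony(t: np.ndarray, traces: Dict[str, np.ndarray],
                    burst_threshold: float = 25.0,
                    id_threshold: float = 10.0,
                    id_smooth_window: float = 1.0,
                    match_window: float = 0.5,
                    min_gap: float = 20.0) -> pd.DataFrame:
    """Pairwise onset delays of fast bursts and of slow discharge onsets.

    For every probe pair, fast-burst onsets (upward crossings of
    ``burst_threshold`` on the raw trace, 100 ms refractory) are matched to
    the nearest onset at the other probe within ``match_window`` seconds,
    and discharge onsets are detected on the 1-s-averaged trace with
    ``min_gap`` merging.  The returned frame has one row per matched pair of
    onsets, with ``kind`` either ``"burst"`` or ``"discharge"`` — on a
    propagating seizure the discharge delays are seconds per millimetre
    while burst delays stay at the sampling scale.
    """
    t = np.asarray(t, dtype=float)
    if len(traces) < 2:
        raise ValueError("need at least two probe traces")
    cadence = float(np.median(np.diff(t)))

    def crossings(sig, level, refractory):
        sig = np.asarray(sig, dtype=float)
        up = np.flatnonzero((sig[1:] >= level) & (sig[:-1] < level)) + 1
        kept, last = [], -np.inf
        for i in up:
            if t[i] - last >= refractory:
                kept.append(t[i])
                last = t[i]
        return np.array(kept)

    w = max(1, int(round(id_smooth_window / cadence)))
    kernel = np.ones(w) / w
    rows = []
    labels = list(traces)
    for a_i in range(len(labels)):
        for b_i in range(a_i + 1, len(labels)):
            la, lb = labels[a_i], labels[b_i]
            for kind, level, refractory, sig_a, sig_b in (
                ("burst", burst_threshold, 0.1, traces[la], traces[lb]),
                ("discharge", id_threshold, min_gap,
                 np.convolve(traces[la], kernel, "same"),
                 np.convolve(traces[lb], kernel, "same")),
            ):
                window = match_window if kind == "burst" else min_gap
                on_a = crossings(sig_a, level, refractory)
                on_b = crossings(sig_b, level, refractory)
                if on_a.size == 0 or on_b.size == 0:
                    continue
                for ta in on_a:
                    k = int(np.argmin(np.abs(on_b - ta)))
                    delay = on_b[k] - ta
                    if abs(delay) <= window:
                        rows.append({"pair": f"{la}-{lb}", "kind": kind,
                                     "onset_t": ta, "delay": delay})
    return pd.DataFrame(rows, columns=["pair", "kind", "onset_t", "delay"])


# ----------------------------------------------------------------------
# Whole-record summary
# ----------------------------------------------------------------------
def summarize_record(record, n_waves: int = 2, probe: str = "S1",
                     skip_initial: int = 1) -> dict:
    """Standard measurements on one simulation record.

    Returns a dict with the detected discharges at the centre probe (their
    durations and onset-to-onset intervals), the fitted speeds of the first
    ``n_waves`` outward potassium waves, the potassium level at
    rate-envelope discharge onsets, and the slow envelope-front speed.
    Measurements that cannot be made on the record (no second wave, say)
    are reported as None rather than raised.

    The timing statistics describe the recurrent quasi-periodic regime, so
    the first ``skip_initial`` discharges — which grow out of the
    artificial uniform initial state and are systematically shorter and
    earlier — are excluded from durations, intervals and onset levels.
    Wave speeds are indexed from the very first wave, which is itself a
    quantity of interest.
    """
    t = record.t_probe
    K = record.probes[probe][:, 0]
    nu = record.probes[probe][:, 5]
    events = detect_discharges(t, K)
    activity = rate_discharges(t, nu)
    recurrent = activity[skip_initial:]
    # an event still open when the run ends has no measurable duration
    closed = [ev for ev in recurrent if ev.offset_t < t[-1]]
    out = {
        "events": events,
        # discharge timing statistics come from the activity envelope;
        # durations are of the high-rate phase, which the potassium
        # excursion can outlast when clearance is slow
        "durations": [ev.duration for ev in closed],
        "intervals": discharge_intervals(recurrent).tolist(),
        "wave_speeds": [],
        "onset_K": [float(np.interp(ev.onset_t, t, K)) for ev in recurrent],
        "envelope_speed": None,
    }
    for k in range(n_waves):
        try:
            front = front_arrival_times(record.ray_t, record.ray_r,
                                        record.ray_K, wave_index=k)
            out["wave_speeds"].append(wavefront_speed(front).speed)
        except ValueError:
            out["wave_speeds"].append(None)
    try:
        env = envelope_front(record.ray_t, record.ray_r, record.ray_nu)
        out["envelope_speed"] = wavefront_speed(env).speed
    except ValueError:
        pass
    return out


# ----------------------------------------------------------------------
# Closed-form magnitude estimates
# ----------------------------------------------------------------------
def electrodiffusion_speed(u_K: float, voltage_gradient: float) -> float:
    """Drift speed of potassium in an extracellular field, mm/s.

    ``u_K`` is the ionic mobility in cm^2/(s V) and ``voltage_gradient`` the
    field in mV/mm.  The product u_K * V' is the transport speed of
    concentration perturbations; at physiological field strengths it comes
    out at micrometres per second, which is why the electric-drift term is
    dropped from the potassium balance.
    """
    if u_K <= 0:
        raise ValueError("ion mobility must be positive")
    # cm^2 -> mm^2 (x100); mV/mm -> V/mm (x1e-3)
    return u_K * 100.0 * voltage_gradient * 1e-3


def nernst_sensitivity(concentration: float) -> float:
    """Sensitivity |dV_ion/d[ion]| = 26.6 mV / [ion], in mV/mM.

    Evaluated at 7 mM extracellular potassium this gives 3.8 mV/mM, an
    order of magnitude above the ~0.2 mV/mM sensitivity to the 130 mM
    intracellular pool — the basis for holding the large pools constant.
    """
    if np.any(np.asarray(concentration) <= 0):
        raise ValueError("concentration must be positive")
    return NERNST_MV / concentration
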