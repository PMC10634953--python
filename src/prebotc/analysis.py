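"""Metrics on simulated activity: spikes, activity modes, population rhythm.

Definitions used throughout the package:

* a spike is an upward crossing of -35 mV (1 ms lockout);
* population firing rate is the number of spikes per 20 ms bin per neuron,
  in Hz;
* rhythm frequency is the inverse of the interval between successive peaks
  of the population rate;
* an uncoupled neuron is *silent*, *bursting* (recurrent clusters of spikes
  separated by quiescent gaps), or *tonic* (continuous spiking);
* pre-inspiratory participation counts neurons that spike between 500 ms
  after one burst peak and 500 ms after the next.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import signal

from .biophysics import SPIKE_THRESHOLD

__all__ = [
    "ActivityLabel",
    "RhythmMetrics",
    "detect_spikes",
    "spike_shape_metrics",
    "classify_activity",
    "population_rate",
    "rhythm_metrics",
    "cycle_triggered_average",
    "preinspiratory_fraction",
]


class ActivityLabel(str, Enum):
    SILENT = "silent"
    BURSTING = "bursting"
    TONIC = "tonic"


def detect_spikes(v: np.ndarray, dt: float, threshold: float = SPIKE_THRESHOLD,
                  refractory: float = 1.0) -> np.ndarray:
    """Spike times (ms) from a uniformly sampled voltage trace."""
    v = np.asarray(v, float)
    crossings = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold)) + 1
    if crossings.size == 0:
        return np.zeros(0)
    times = crossings * dt
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


class NoSpikesError(RuntimeError):
    """Raised when spike-shape quantification finds no steady spiking."""


def spike_shape_metrics(p, env, drive: float, duration: float = 20_000.0,
                        dt: float = 0.025, n_spikes: int = 40,
                        sample_ms: float = 0.5,
                        q10: float = 1.5) -> tuple[float, float]:
    """Spike height and AHP trough of a neuron in steady repetitive spiking.

    Simulates a single uncoupled neuron under tonic drive ``drive`` (nS) and
    returns ``(height, ahp)``: the mean peak membrane potential and the mean
    inter-spike minimum over the last ``n_spikes`` inter-spike intervals of a
    ``duration``-ms run.  The voltage trace is analysed at ``sample_ms``
    resolution (the recording decimation used for trace storage); the broad
    AHP trough is insensitive to this, the sharp peak mildly so.  Intended
    for use with ``g_NaP = 0`` so bursting cannot corrupt the AHP
    measurement.  Raises :class:`NoSpikesError` if the neuron does not spike
    repetitively at this drive.
    """
    from .engine import SimulationConfig, simulate_neurons

    stride = max(1, int(round(sample_ms / dt)))
    cfg = SimulationConfig(duration=duration, transient=0.0, dt=dt,
                           record_stride=stride, q10=q10)
    rec = simulate_neurons(p, env, cfg, g_tonic=float(drive), record_v=True)
    v = rec.traces["V"][:, 0]
    sdt = stride * dt
    spikes = rec.spikes_of(0)
    if spikes.size < n_spikes + 1:
        raise NoSpikesError(
            f"only {spikes.size} spikes at drive {drive} nS; "
            f"need {n_spikes + 1} for shape quantification")
    idx = np.floor(spikes / sdt).astype(int)
    peaks, troughs = [], []
    for a, b in zip(idx[-(n_spikes + 1):-1], idx[-n_spikes:]):
        seg = v[a:b]
        peaks.append(seg.max())
        troughs.append(seg.min())
    return float(np.mean(peaks)), float(np.mean(troughs))


def classify_activity(spike_times: np.ndarray, window: tuple[float, float],
                      min_spikes: int = 3, gap_floor: float = 300.0,
                      gap_isi_factor: float = 5.0,
                      min_cluster_spikes: int = 3) -> ActivityLabel:
    """Label an uncoupled neuron's steady-state activity mode.

    Spikes inside ``window`` are clustered by inter-spike gaps exceeding
    ``max(gap_floor, gap_isi_factor * median ISI)``; the neuron is *bursting*
    when at least three clusters emerge, each containing at least
    ``min_cluster_spikes`` spikes, *tonic* when it spikes without that gap
    structure, *silent* below ``min_spikes``.  Requiring three spikes per
    cluster keeps the sparse doublet firing that appears just above the
    spiking threshold from masquerading as bursting: a burst has internal
    structure (a fast intra-burst spike rate), a doublet does not.
    """
    t0, t1 = window
    ts = np.asarray(spike_times, float)
    ts = ts[(ts >= t0) & (ts <= t1)]
    if ts.size < min_spikes:
        return ActivityLabel.SILENT
    isi = np.diff(ts)
    gap = max(gap_floor, gap_isi_factor * float(np.median(isi)))
    breaks = np.flatnonzero(isi > gap)
    clusters = np.split(ts, breaks + 1)
    if len(clusters) >= 3 and all(len(c) >= min_cluster_spikes for c in clusters):
        return ActivityLabel.BURSTING
    return ActivityLabel.TONIC


def population_rate(spike_times: np.ndarray, n_neurons: int,
                    t_range: tuple[float, float], bin_ms: float = 20.0):
    """Population firing-rate histogram.

    Returns ``(bin_centers_ms, rate_hz)`` with
    ``rate = count / (N * bin)`` in Hz, so summing ``rate * bin * N`` over
    bins recovers the total spike count.
    """
    t0, t1 = t_range
    edges = np.arange(t0, t1 + bin_ms / 2, bin_ms)
    counts, _ = np.histogram(np.asarray(spike_times, float), bins=edges)
    rate = counts / (n_neurons * bin_ms / 1000.0)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, rate


@dataclass
class RhythmMetrics:
    """Summary of a population-rate rhythm."""

    peak_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    frequency: float = 0.0      # Hz, mean inverse interpeak interval
    amplitude: float = 0.0      # Hz, mean peak rate
    burst_duration: float = 0.0  # ms, full width at half maximum
    rise_time: float = 0.0      # ms
    decay_time: float = 0.0     # ms
    is_rhythmic: bool = False


def rhythm_metrics(t_ms: np.ndarray, rate_hz: np.ndarray,
                   min_peaks: int = 5, cv_max: float = 0.5,
                   peak_frac: float = 0.2, min_separation: float = 200.0,
                   quiescence_frac: float = 0.5, min_amplitude: float = 5.0,
                   ) -> RhythmMetrics:
    """Detect population bursts in a rate trace and summarize the rhythm.

    Peaks must exceed ``peak_frac`` of the trace's 95th percentile and be
    separated by at least ``min_separation`` ms; the rhythm is accepted when
    ``min_peaks`` peaks occur with interpeak coefficient of variation below
    ``cv_max`` *and* the trace is quiescent between bursts (median rate below
    ``quiescence_frac`` of the mean peak height).  The quiescence condition
    separates genuine population bursts from the fast low-amplitude ripples
    of partially synchronized tonic firing, which ride on a high baseline.
    Burst duration/rise/decay are measured at half maximum of the
    cycle-triggered average above its inter-burst baseline; frequency is the
    median per-cycle inverse interpeak interval.
    """
    t_ms = np.asarray(t_ms, float)
    rate = np.asarray(rate_hz, float)
    out = RhythmMetrics()
    if rate.size < 3 or not np.any(rate > 0):
        return out
    bin_ms = t_ms[1] - t_ms[0]
    height = peak_frac * np.percentile(rate, 95)
    if height <= 0:
        return out
    distance = max(1, int(round(min_separation / bin_ms)))
    peaks, props = signal.find_peaks(rate, height=height, distance=distance)
    out.peak_times = t_ms[peaks]
    if peaks.size >= 2:
        ipi = np.diff(out.peak_times)
        out.frequency = float(np.median(1000.0 / ipi))
        out.amplitude = float(np.mean(rate[peaks]))
        quiescent = float(np.median(rate)) < quiescence_frac * out.amplitude
        out.is_rhythmic = bool(
            peaks.size >= min_peaks
            and np.std(ipi) / np.mean(ipi) < cv_max
            and quiescent
            and out.amplitude >= min_amplitude
        )
        cta_t, cta = cycle_triggered_average(t_ms, rate, out.peak_times)
        if cta.size:
            base = np.percentile(cta, 10)
            half = base + (cta.max() - base) / 2.0
            above = cta >= half
            ipk = int(np.argmax(cta))
            lo = ipk
            while lo > 0 and above[lo - 1]:
                lo -= 1
            hi = ipk
            while hi < cta.size - 1 and above[hi + 1]:
                hi += 1
            out.burst_duration = float((hi - lo + 1) * bin_ms)
            out.rise_time = float((ipk - lo) * bin_ms)
            out.decay_time = float((hi - ipk) * bin_ms)
    return out


def cycle_triggered_average(t_ms: np.ndarray, rate_hz: np.ndarray,
                            peak_times: np.ndarray,
                            pre_ms: float | None = None,
                            post_ms: float | None = None):
    """Average rate waveform across cycles aligned at burst peaks.

    Window defaults to half the median interpeak interval on each side.
    Returns ``(lag_ms, waveform)``; empty arrays when < 2 peaks.
    """
    t_ms = np.asarray(t_ms, float)
    rate = np.asarray(rate_hz, float)
    peak_times = np.asarray(peak_times, float)
    if peak_times.size < 2:
        return np.zeros(0), np.zeros(0)
    bin_ms = t_ms[1] - t_ms[0]
    half = float(np.median(np.diff(peak_times))) / 2.0
    pre = pre_ms if pre_ms is not None else half
    post = post_ms if post_ms is not None else half
    wpre = int(round(pre / bin_ms))
    wpost = int(round(post / bin_ms))
    segs = []
    for pt in peak_times:
        k = int(round((pt - t_ms[0]) / bin_ms))
        if k - wpre >= 0 and k + wpost < rate.size:
            segs.append(rate[k - wpre:k + wpost + 1])
    if not segs:
        return np.zeros(0), np.zeros(0)
    lag = (np.arange(-wpre, wpost + 1)) * bin_ms
    return lag, np.mean(segs, axis=0)


def preinspiratory_fraction(spike_trains: list[np.ndarray],
                            burst_peaks: np.ndarray,
                            burst_duration: float = 0.0,
                            lead: float = 500.0) -> np.ndarray:
    """Fraction of neurons spiking between consecutive population bursts.

    For each cycle the window runs from ``lead`` ms after one burst peak to
    ``lead`` ms after the next; when the burst outlasts ``lead`` the window
    start is pushed to the burst's end (the stated manual extension).
    Returns one fraction per cycle; raises ValueError with < 2 bursts.
    """
    burst_peaks = np.asarray(burst_peaks, float)
    if burst_peaks.size < 2:
        raise ValueError("need at least two detected bursts")
    start_off = max(lead, burst_duration)
    n = len(spike_trains)
    fracs = []
    for p0, p1 in zip(burst_peaks[:-1], burst_peaks[1:]):
        w0, w1 = p0 + start_off, p1 + lead
        active = sum(
            1 for ts in spike_trains if np.any((ts >= w0) & (ts <= w1))
        )
        fracs.append(active / n)
    return np.asarray(fracs)
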