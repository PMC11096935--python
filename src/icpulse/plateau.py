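"""ICP plateau-wave detection and baseline / plateau period selection.

A plateau wave is a sustained elevation of mean ICP driven by a vasodilatory
cascade.  Operationally (on slow trend means): mean ICP rises above 40 mmHg,
by at least 15 mmHg over its pre-wave reference, with a cerebral perfusion
pressure (CPP = mean ABP - mean ICP) drop of at least 10 mmHg, sustained for
at least 3 minutes.  The pre-wave reference is the median trend ICP over the
baseline-length window before the rise onset; the rise onset is found as the
last upward crossing of reference + 5 mmHg before the peak (a two-pass fixed
point, since reference and rise onset define each other).

The analysis periods are the ~4 min immediately preceding the rise onset
(baseline) and the part of the wave where mean ICP stays at or above 90% of
the wave's maximum (plateau phase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .io import Recording, TimeSeries
from .preprocess import moving_mean
from .pulses import PulsePair

__all__ = [
    "TrendSeries",
    "PlateauWave",
    "PlateauCriteria",
    "compute_trends",
    "detect_plateau_waves",
    "select_periods",
    "label_pulses",
]

logger = logging.getLogger(__name__)


@dataclass
class TrendSeries:
    """Slow trend means of the three channels plus derived CPP."""

    mean_icp: TimeSeries
    mean_abp: TimeSeries
    mean_cbfv: TimeSeries
    cpp: TimeSeries  # recomputed as mean_abp - mean_icp, never read from file

    @property
    def fs(self) -> float:
        return self.mean_icp.fs


@dataclass(frozen=True)
class PlateauCriteria:
    """Thresholds of the operational plateau-wave definition."""

    icp_absolute: float = 40.0  # mmHg, peak mean ICP must exceed this
    icp_rise: float = 15.0  # mmHg, rise over the pre-wave reference
    cpp_drop: float = 10.0  # mmHg, CPP fall below its pre-wave reference
    min_duration: float = 180.0  # s, persistence of the rise condition
    rise_margin: float = 5.0  # mmHg above reference defining the wave boundary
    baseline_length: float = 240.0  # s, pre-wave reference / baseline window


@dataclass
class PlateauWave:
    """A detected wave with its analysis intervals (seconds)."""

    wave_interval: tuple[float, float]
    peak_icp: float
    baseline_icp: float
    baseline_interval: tuple[float, float] | None = None
    plateau_interval: tuple[float, float] | None = None


def compute_trends(recording: Recording, trend_window: float = 10.0) -> TrendSeries:
    """Windowed trend means per channel; CPP derived as ABP minus ICP."""
    if recording.duration < trend_window:
        raise ValueError("recording shorter than the trend window")
    mi = moving_mean(recording.icp, trend_window)
    ma = moving_mean(recording.abp, trend_window)
    mc = moving_mean(recording.cbfv, trend_window)
    cpp = replace(mi, samples=ma.samples - mi.samples, unit="mmHg", label="cpp")
    return TrendSeries(mean_icp=mi, mean_abp=ma, mean_cbfv=mc, cpp=cpp)


def _longest_true_run(mask: np.ndarray) -> int:
    """Length of the longest contiguous run of True."""
    if not mask.any():
        return 0
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return int(np.max(edges[1::2] - edges[::2]))


def detect_plateau_waves(
    trends: TrendSeries, criteria: PlateauCriteria | None = None
) -> list[PlateauWave]:
    """Find plateau waves on the trend series.

    Candidate seeds are the maximal intervals where trend ICP exceeds the
    absolute threshold; each candidate's boundaries are extended outward to
    the crossings of reference + rise_margin, and the candidate is accepted
    when the peak, relative-rise, CPP-drop and persistence criteria all hold.
    Returns accepted waves in time order, non-overlapping; empty list when
    nothing qualifies.
    """
    c = criteria or PlateauCriteria()
    x = trends.mean_icp.samples
    cpp = trends.cpp.samples
    fs = trends.fs
    n = x.size
    base_w = int(round(c.baseline_length * fs))

    above = x > c.icp_absolute
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    seeds = list(zip(edges[::2], edges[1::2]))  # [start, end) index pairs

    waves: list[PlateauWave] = []
    last_end = 0
    for s0, s1 in seeds:
        if s0 < last_end:
            continue  # inside a previously accepted wave
        peak = s0 + int(np.argmax(x[s0:s1]))
        peak_val = float(x[peak])

        # fixed point: reference window <-> rise onset
        rise_onset = s0
        ref = float(np.median(x[max(0, s0 - base_w) : max(s0, 1)]))
        for _ in range(2):
            below = np.flatnonzero(x[:peak] <= ref + c.rise_margin)
            rise_onset = int(below[-1] + 1) if below.size else 0
            lo = max(0, rise_onset - base_w)
            if rise_onset > lo:
                ref = float(np.median(x[lo:rise_onset]))

        after = np.flatnonzero(x[peak:] <= ref + c.rise_margin)
        wave_end = int(peak + after[0]) if after.size else n

        # criteria re-check on the extracted candidate
        if peak_val <= c.icp_absolute:
            continue
        if peak_val - ref < c.icp_rise:
            continue
        lo = max(0, rise_onset - base_w)
        cpp_ref = float(np.median(cpp[lo:rise_onset])) if rise_onset > lo else float(cpp[0])
        if cpp_ref - float(cpp[rise_onset:wave_end].min()) < c.cpp_drop:
            continue
        sustained = _longest_true_run(x[rise_onset:wave_end] >= ref + c.icp_rise)
        if sustained / fs < c.min_duration:
            continue

        waves.append(
            PlateauWave(
                wave_interval=(rise_onset / fs, wave_end / fs),
                peak_icp=peak_val,
                baseline_icp=ref,
            )
        )
        last_end = wave_end
    return waves


def select_periods(
    wave: PlateauWave,
    trends: TrendSeries,
    baseline_length: float = 240.0,
    plateau_fraction: float = 0.9,
    min_baseline: float = 60.0,
) -> PlateauWave | None:
    """Fill in the baseline and plateau analysis intervals of a wave.

    Baseline: the ``baseline_length`` seconds immediately preceding the rise
    onset (shortened with a warning when the recording starts later; the wave
    is excluded -- ``None`` -- below a 60 s floor).  Plateau: the maximal
    contiguous interval inside the wave where trend ICP is at or above
    ``plateau_fraction`` times the wave's maximum.
    """
    fs = trends.fs
    x = trends.mean_icp.samples
    w0, w1 = wave.wave_interval
    b0 = w0 - baseline_length
    if b0 < 0:
        if w0 < min_baseline:
            logger.warning(
                "wave at %.0f s: only %.0f s of pre-wave signal (< %.0f s floor); excluded",
                w0, w0, min_baseline,
            )
            return None
        logger.warning(
            "wave at %.0f s: baseline shortened to %.0f s of available signal", w0, w0
        )
        b0 = 0.0
    i0, i1 = int(round(w0 * fs)), int(round(w1 * fs))
    seg = x[i0:i1]
    thr = plateau_fraction * float(seg.max())
    mask = seg >= thr
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    runs = list(zip(edges[::2], edges[1::2]))
    a, b = max(runs, key=lambda r: r[1] - r[0])
    plateau = ((i0 + a) / fs, (i0 + b) / fs)
    return replace(
        wave,
        baseline_interval=(b0, w0),
        plateau_interval=plateau,
    )


def label_pulses(pairs: list[PulsePair], wave: PlateauWave) -> list[str | None]:
    """Period label per pair: "baseline", "plateau", or None (outside both).

    A pair belongs to a period when its ICP pulse onset time falls inside the
    corresponding interval.
    """
    if wave.baseline_interval is None or wave.plateau_interval is None:
        raise ValueError("wave periods not selected; call select_periods first")
    b0, b1 = wave.baseline_interval
    p0, p1 = wave.plateau_interval
    labels: list[str | None] = []
    for pair in pairs:
        t = pair.icp_pulse.onset_time
        if b0 <= t < b1:
            labels.append("baseline")
        elif p0 <= t < p1:
            labels.append("plateau")
        else:
            labels.append(None)
    return labels
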