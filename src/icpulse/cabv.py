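"""Cerebral arterial blood volume change from CBFV: constant-flow-forward model.

Over one cardiac cycle the change in cerebral arterial blood volume is the
integral of arterial inflow minus venous outflow.  Venous outflow has low
pulsatility, so it is approximated by the arterial inflow averaged in a long
(6 s) window; replacing flow by TCD velocity (constant insonated cross-
section) gives, per sample n of a cycle,

    dCaBV(n) = sum_{i=1..n} [CBFV(i) - meanCBFV(i)] * dt    [cm]

The units are cm (flow normalised by the vessel cross-section), so absolute
values are comparable only within one recording.  Both model assumptions are
contracts rather than checks; a heuristic monitor logs a warning when the
slow mean varies by more than 5% within a single pulse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import TimeSeries
from .pulses import Pulse, PulsePair

__all__ = ["CaBVPulse", "compute_cabv", "cabv_for_pairs"]

logger = logging.getLogger(__name__)

#: relative within-pulse variation of the slow mean above which the
#: low-venous-pulsatility assumption is flagged
MEAN_VARIATION_WARN = 0.05


@dataclass
class CaBVPulse:
    """Cumulative arterial volume change over one cycle, in cm."""

    values: np.ndarray
    fs: float
    onset_index: int  # of the source CBFV pulse

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def onset_time(self) -> float:
        return self.onset_index / self.fs

    def __len__(self) -> int:
        return self.values.size


def compute_cabv(
    cbfv_pulse: Pulse,
    mean_series: TimeSeries,
    frozen_mean: bool = False,
) -> CaBVPulse:
    """Cumulative sum of CBFV deviation from its slow mean over one cycle.

    ``mean_series`` is the 6-s moving mean of the same preprocessed CBFV
    channel, sampled at the pulse's rate and covering its index span.  With
    ``frozen_mean`` the slow mean is held at its onset value across the pulse
    (sensitivity-analysis variant); by default it is evaluated per sample.
    """
    if mean_series.fs != cbfv_pulse.fs:
        raise ValueError(
            f"fs mismatch: pulse {cbfv_pulse.fs} Hz vs mean series {mean_series.fs} Hz"
        )
    a = cbfv_pulse.onset_index
    b = a + len(cbfv_pulse)
    if a < 0 or b > len(mean_series):
        raise ValueError("mean series does not cover the pulse's index span")
    mean = mean_series.samples[a:b]
    m_lo, m_hi = float(mean.min()), float(mean.max())
    if m_lo > 0 and (m_hi - m_lo) / m_lo > MEAN_VARIATION_WARN:
        logger.warning(
            "slow CBFV mean varies %.1f%% within pulse at %.2f s; "
            "low-venous-pulsatility assumption strained",
            100 * (m_hi - m_lo) / m_lo,
            cbfv_pulse.onset_time,
        )
    if frozen_mean:
        mean = np.full_like(mean, mean[0])
    dev = cbfv_pulse.samples - mean
    values = np.cumsum(dev) / cbfv_pulse.fs
    return CaBVPulse(values, cbfv_pulse.fs, cbfv_pulse.onset_index)


def cabv_for_pairs(
    pairs: list[PulsePair],
    mean_series: TimeSeries,
    frozen_mean: bool = False,
) -> list[tuple[PulsePair, CaBVPulse]]:
    """Volume pulse for every (QC-filtered) pair; failures are logged, not fatal.

    Output order follows the input; pairs whose CBFV pulse cannot be evaluated
    (e.g. the mean series does not cover its span) are skipped with a log line.
    """
    out = []
    for pair in pairs:
        try:
            out.append((pair, compute_cabv(pair.cbfv_pulse, mean_series, frozen_mean)))
        except ValueError as exc:
            logger.info(
                "skipping pair at %.2f s: %s", pair.cbfv_pulse.onset_time, exc
            )
    return out
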