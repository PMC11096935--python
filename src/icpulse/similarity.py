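"""Pulse normalization, synchronization and the difference index (DI).

Each reliable ICP / CaBV pulse pair is min-max normalized to [0, 1] and
synchronized at the start of the ascending slope (the onset minimum, which is
sample 0 of every onset-anchored pulse).  The difference index is the sum of
absolute sample-wise differences from the onset to the end of the CaBV pulse
-- the area between the two normalized contours.  Lower DI means more similar
shapes.  DI is reported as the raw sum (not divided by the sample count), so
it scales with beat length; ``n_compared`` is stored so users can derive a
length-normalized variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cabv import CaBVPulse
from .pulses import Pulse

__all__ = [
    "NormalizedPulse",
    "DIRecord",
    "DegeneratePulseError",
    "normalize_pulse",
    "synchronize",
    "difference_index",
    "score_pairs",
]

logger = logging.getLogger(__name__)


class DegeneratePulseError(ValueError):
    """Raised when a pulse has zero peak-to-trough amplitude."""


@dataclass
class NormalizedPulse:
    """Amplitude-normalized pulse: min 0, max 1, onset at index 0."""

    values: np.ndarray
    fs: float
    channel: str = ""
    onset_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def onset_time(self) -> float:
        return self.onset_index / self.fs

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class DIRecord:
    """Per-pulse-pair difference index with provenance."""

    di: float
    n_compared: int
    wave_id: str = ""
    period_label: str | None = None  # "baseline" | "plateau" | None
    onset_time: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.di <= self.n_compared:
            raise ValueError("DI must lie in [0, n_compared]")


def normalize_pulse(pulse: Pulse | CaBVPulse) -> NormalizedPulse:
    """Min-max rescale a pulse to the range [0, 1]."""
    x = pulse.samples if isinstance(pulse, Pulse) else pulse.values
    if x.size == 0:
        raise DegeneratePulseError("empty pulse")
    lo, hi = float(x.min()), float(x.max())
    if hi - lo == 0:
        raise DegeneratePulseError("flat pulse: zero peak-to-trough amplitude")
    return NormalizedPulse(
        (x - lo) / (hi - lo),
        pulse.fs,
        getattr(pulse, "channel", "cabv"),
        pulse.onset_index,
    )


def synchronize(
    icp_norm: NormalizedPulse, cabv_norm: NormalizedPulse
) -> tuple[NormalizedPulse, NormalizedPulse]:
    """Align both pulses at the start of their ascending slopes.

    Onset-anchored pulses already start at their onset minimum at index 0, so
    no resampling or shifting is performed and lengths may differ.  A pulse
    whose global minimum is not at index 0 is passed through with a warning
    (it is not rotated), since that usually indicates an upstream detection
    or QC problem worth auditing.
    """
    for p, name in ((icp_norm, "icp"), (cabv_norm, "cabv")):
        if len(p) == 0:
            raise ValueError(f"empty {name} pulse")
        if int(np.argmin(p.values)) != 0:
            logger.warning(
                "%s pulse at %.2f s: global minimum not at the onset sample",
                name,
                p.onset_time,
            )
    return icp_norm, cabv_norm


def difference_index(
    icp_norm: NormalizedPulse,
    cabv_norm: NormalizedPulse,
    wave_id: str = "",
    period_label: str | None = None,
    length_mismatch: str = "hold_last",
) -> DIRecord:
    """Sum of absolute differences from the onset to the end of the CaBV pulse.

    The comparison window is the CaBV pulse length ``M``.  When the ICP pulse
    is shorter, its final sample is held to the end of the window (default);
    with ``length_mismatch="truncate"`` the window shrinks to the shorter
    pulse instead.
    """
    if len(icp_norm) == 0 or len(cabv_norm) == 0:
        raise ValueError("cannot score an empty pulse")
    icp = icp_norm.values
    cabv = cabv_norm.values
    if length_mismatch == "hold_last":
        m = len(cabv)
        if icp.size < m:
            icp = np.concatenate([icp, np.full(m - icp.size, icp[-1])])
    elif length_mismatch == "truncate":
        m = min(len(cabv), len(icp))
    else:
        raise ValueError(f"unknown length_mismatch policy: {length_mismatch!r}")
    di = float(np.abs(icp[:m] - cabv[:m]).sum())
    return DIRecord(
        di=di,
        n_compared=m,
        wave_id=wave_id,
        period_label=period_label,
        onset_time=icp_norm.onset_time,
    )


def score_pairs(
    cabv_pairs: list,
    labels: list[str | None],
    wave_id: str = "",
    length_mismatch: str = "hold_last",
) -> list[DIRecord]:
    """One DI record per labeled pair.

    ``cabv_pairs`` is the output of :func:`icpulse.cabv.cabv_for_pairs`
    (``(PulsePair, CaBVPulse)`` tuples) and ``labels`` the per-pair period
    labels from plateau-period selection.  Pairs outside the labeled periods
    are excluded (logged at debug level); degenerate pulses are skipped with
    a log line.
    """
    if len(cabv_pairs) != len(labels):
        raise ValueError("labels must match cabv_pairs one-to-one")
    records = []
    for (pair, cabv_pulse), label in zip(cabv_pairs, labels):
        if label is None:
            logger.debug(
                "pair at %.2f s outside labeled periods; excluded",
                pair.icp_pulse.onset_time,
            )
            continue
        try:
            icp_n = normalize_pulse(pair.icp_pulse)
            cabv_n = normalize_pulse(cabv_pulse)
        except DegeneratePulseError as exc:
            logger.info("skipping degenerate pair at %.2f s: %s", pair.icp_pulse.onset_time, exc)
            continue
        icp_n, cabv_n = synchronize(icp_n, cabv_n)
        records.append(
            difference_index(icp_n, cabv_n, wave_id, label, length_mismatch)
        )
    return records
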