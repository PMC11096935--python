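"""Synthetic neuromonitoring recordings with ground-truth annotations.

Generates concurrent ICP / ABP / CBFV channels at 50 Hz that emulate the
statistical structure the plateau-wave similarity analysis assumes:

* cardiac-cycle pulses at a configurable heart rate with beat-to-beat
  variability;
* triphasic ICP pulses (percussion / tidal / dicrotic peaks, P1-P3) whose
  shape morphs toward a pathologically rounded single hump as mean ICP rises;
* a TCD-like CBFV pulse with a sharp systolic upstroke and dicrotic decay,
  whose shape stays fixed while its mean and pulsatility are modulated;
* one ICP plateau-wave episode per recording (baseline -> ramp -> sustained
  plateau -> ramp down) with an unchanged ABP mean, so cerebral perfusion
  pressure falls during the wave by construction;
* additive Gaussian noise and injectable artifacts (spikes, flatlines,
  dropout-to-zero) with their intervals recorded in the ground truth.

The generator is phenomenological: it reproduces waveform geometry and level
statistics, not vasodilatory-cascade dynamics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .io import Recording, TimeSeries

__all__ = [
    "PulseMorphology",
    "EpisodePlan",
    "GroundTruth",
    "render_pulse",
    "cbfv_pulse_shape",
    "abp_pulse_shape",
    "generate_recording",
    "generate_cohort",
    "write_ground_truth",
    "read_ground_truth",
]

#: reference conditions under which the morphology invariants (3 maxima at
#: roundness 0, 1 maximum at roundness 1) are asserted
REFERENCE_CYCLE_S = 0.86
REFERENCE_FS = 200.0

#: exponent (< 1) of the half-sine diastolic mound; the sub-unit power gives
#: every cycle a sharp, deep diastolic trough so that onset minima resist
#: trend slopes, filtering and band-limited noise
MOUND_POWER = 0.15


@dataclass(frozen=True)
class PulseMorphology:
    """Parametric triphasic ICP pulse shape.

    Amplitudes are relative (dimensionless, >= 0); latencies are fractions of
    the cycle length and must be strictly increasing.  ``roundness`` in [0, 1]
    blends the rendered pulse from a saw-tooth triphasic shape (0: three
    distinct maxima, P1 dominant) to a rounded single hump (1: one maximum),
    mimicking the documented evolution of the ICP pulse as mean pressure rises
    and cerebrospinal compliance falls.
    """

    p1_amp: float = 1.0
    p2_amp: float = 0.8
    p3_amp: float = 0.6
    p1_time: float = 0.16
    p2_time: float = 0.45
    p3_time: float = 0.70
    peak_width: float = 0.30
    roundness: float = 0.0
    #: amplitude of the diastolic mound (pedestal) underlying the three peaks,
    #: relative to the largest peak amplitude; at MOUND_POWER the pedestal is
    #: nearly flat mid-cycle, so it lifts all three peaks almost equally and
    #: P1 remains the global maximum of the saw-tooth shape
    base_amp: float = 0.45

    def __post_init__(self) -> None:
        amps = (self.p1_amp, self.p2_amp, self.p3_amp)
        if any(a < 0 for a in amps):
            raise ValueError("peak amplitudes must be non-negative")
        lats = (self.p1_time, self.p2_time, self.p3_time)
        if not all(0 < t < 1 for t in lats):
            raise ValueError("peak latencies must lie in (0, 1)")
        if not (lats[0] < lats[1] < lats[2]):
            raise ValueError("peak latencies must be strictly increasing")
        if not 0 < self.peak_width < 1:
            raise ValueError("peak_width must lie in (0, 1)")
        if not 0 <= self.roundness <= 1:
            raise ValueError("roundness must lie in [0, 1]")


def _raised_cosine(u: np.ndarray, center: float, width: float) -> np.ndarray:
    """cos^2 bump of unit height on |u - center| < width/2, zero elsewhere."""
    out = np.zeros_like(u)
    m = np.abs(u - center) < width / 2
    out[m] = np.cos(np.pi * (u[m] - center) / width) ** 2
    return out


def render_pulse(
    morphology: PulseMorphology, cycle_length: float, fs: float
) -> np.ndarray:
    """Render one cardiac cycle of the parametric ICP pulse.

    Returns ``round(cycle_length * fs)`` samples covering [0, cycle_length);
    the cycle starts and ends at its minimum (value 0), so the onset sits at
    index 0.  The waveform is a sum of raised-cosine components at the three
    peak latencies over a broad diastolic mound; ``roundness`` linearly blends
    it toward a single widened P2-dominant hump.  Deterministic.
    """
    if not 0.3 <= cycle_length <= 2.0:
        raise ValueError(f"cycle_length {cycle_length} s outside [0.3, 2.0] s")
    if not fs > 24.0:
        raise ValueError(f"fs {fs} Hz too low (must exceed 24 Hz)")
    m = morphology
    n = int(round(cycle_length * fs))
    u = np.arange(n) / n  # fraction of cycle

    amax = max(m.p1_amp, m.p2_amp, m.p3_amp)
    # sub-unit-power half-sine diastolic mound: steep, equal-magnitude slopes
    # at both cycle edges make the beat-to-beat junction a sharp symmetric V,
    # so the onset minimum survives slow-trend slopes, zero-phase filtering
    # and band-limited noise without shifting
    mound = m.base_amp * amax * np.sin(np.pi * u) ** MOUND_POWER
    tri = (
        m.p1_amp * _raised_cosine(u, m.p1_time, m.peak_width)
        + m.p2_amp * _raised_cosine(u, m.p2_time, m.peak_width)
        + m.p3_amp * _raised_cosine(u, m.p3_time, m.peak_width)
        + mound
    )
    # rounded target: single broad mid-cycle hump (the shape the volume pulse
    # itself takes under the constant-flow-forward model)
    hump_center = 0.5
    hump_width = 0.95
    rounded = amax * _raised_cosine(u, hump_center, hump_width) + mound

    r = m.roundness
    return (1 - r) * tri + r * rounded


def cbfv_pulse_shape(cycle_length: float, fs: float) -> np.ndarray:
    """Fixed TCD-like CBFV cycle: sharp systolic upstroke, dicrotic decay.

    Unit peak height, onset minimum (0) at index 0.  The shape is a modeling
    choice: no consensus waveform parameters exist for the CBFV pulse, and the
    analysis only modulates its mean and pulsatility.
    """
    if not 0.3 <= cycle_length <= 2.0:
        raise ValueError(f"cycle_length {cycle_length} s outside [0.3, 2.0] s")
    n = int(round(cycle_length * fs))
    u = np.arange(n) / n
    shape = (
        1.0 * _raised_cosine(u, 0.15, 0.30)
        + 0.35 * _raised_cosine(u, 0.45, 0.34)
        + 0.30 * np.sin(np.pi * u) ** MOUND_POWER
    )
    return shape / shape.max()


def abp_pulse_shape(cycle_length: float, fs: float) -> np.ndarray:
    """Arterial pressure cycle: systolic peak with a dicrotic notch."""
    n = int(round(cycle_length * fs))
    u = np.arange(n) / n
    shape = (
        1.0 * _raised_cosine(u, 0.20, 0.36)
        + 0.45 * _raised_cosine(u, 0.50, 0.36)
        + 0.30 * np.sin(np.pi * u) ** MOUND_POWER
    )
    return shape / shape.max()


@dataclass(frozen=True)
class EpisodePlan:
    """Parameters of one synthetic recording containing one plateau wave.

    Level set-points default to the reported cohort medians (baseline ICP
    19.4 mmHg rising to 42.7 mmHg; CBFV 44.2 falling to 32.9 cm/s; ABP held
    at 93.9 mmHg), so cerebral perfusion pressure falls by ~23 mmHg during
    the wave.  Durations are seconds, heart rate beats/min.
    """

    total_duration: float = 780.0
    baseline_icp_mean: float = 19.4
    plateau_icp_mean: float = 42.7
    baseline_cbfv_mean: float = 44.2
    plateau_cbfv_mean: float = 32.9
    abp_mean: float = 93.9
    wave_start: float = 270.0
    wave_rise_duration: float = 45.0
    wave_plateau_duration: float = 300.0
    wave_fall_duration: float = 45.0
    heart_rate_mean: float = 70.0
    heart_rate_cv: float = 0.04
    noise_sd_icp: float = 0.15
    noise_sd_abp: float = 0.6
    noise_sd_cbfv: float = 0.8
    artifact_rate: float = 0.2  # events / min
    seed: int = 0
    fs: float = 50.0
    # morphology programme
    baseline_roundness: float = 0.15
    plateau_roundness: float = 0.85
    icp_pulse_amp: float = 4.0  # mmHg peak-to-trough at baseline
    icp_amp_coupling: float = 0.08  # fractional amplitude gain per mmHg of mean ICP rise
    cbfv_pulse_amp: float = 28.0  # cm/s
    cbfv_pulsatility_gain: float = 0.25  # fractional amplitude gain at plateau
    abp_pulse_amp: float = 40.0  # mmHg
    #: optional extra linear lift of the late-diastolic tail (fraction of
    #: pulse height); the half-sine mound already anchors each beat's minimum
    #: at its onset, so the default adds none
    diastolic_tilt: float = 0.0

    def __post_init__(self) -> None:
        if not self.total_duration > 0:
            raise ValueError("total_duration must be positive")
        for name in ("wave_rise_duration", "wave_plateau_duration", "wave_fall_duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.plateau_icp_mean > self.baseline_icp_mean:
            raise ValueError("plateau_icp_mean must exceed baseline_icp_mean")
        if self.wave_start < 0 or self.wave_end > self.total_duration:
            raise ValueError("wave interval must be contained in the recording")
        if not 30 <= self.heart_rate_mean <= 200:
            raise ValueError("heart_rate_mean outside plausible range")
        if self.heart_rate_cv < 0 or self.artifact_rate < 0:
            raise ValueError("heart_rate_cv and artifact_rate must be non-negative")

    @property
    def wave_end(self) -> float:
        return (
            self.wave_start
            + self.wave_rise_duration
            + self.wave_plateau_duration
            + self.wave_fall_duration
        )

    @property
    def wave_interval(self) -> tuple[float, float]:
        return (self.wave_start, self.wave_end)

    @classmethod
    def no_wave(cls, seed: int = 0, total_duration: float = 600.0, **kwargs) -> "EpisodePlan":
        """A recording with essentially flat ICP (a 2-mmHg bump that satisfies
        no plateau-wave criterion), for detector-specificity checks."""
        base_icp = kwargs.pop("baseline_icp_mean", 19.4)
        base_cbfv = kwargs.pop("baseline_cbfv_mean", 44.2)
        base_round = kwargs.pop("baseline_roundness", 0.15)
        return cls(
            total_duration=total_duration,
            baseline_icp_mean=base_icp,
            plateau_icp_mean=base_icp + 2.0,
            baseline_cbfv_mean=base_cbfv,
            plateau_cbfv_mean=base_cbfv - 1.0,
            wave_start=total_duration * 0.4,
            wave_rise_duration=30.0,
            wave_plateau_duration=60.0,
            wave_fall_duration=30.0,
            baseline_roundness=base_round,
            plateau_roundness=base_round,
            seed=seed,
            **kwargs,
        )


@dataclass
class GroundTruth:
    """Construction-time annotations of one synthetic recording."""

    true_onsets: dict[str, np.ndarray]  # channel -> sample indices (source fs)
    wave_interval: tuple[float, float]  # programmed wave [start, end] in s
    pulse_roundness: np.ndarray  # per-beat roundness actually rendered
    artifact_intervals: list[tuple[str, str, float, float]]  # (channel, kind, start, end) s
    fs: float = 50.0

    def __post_init__(self) -> None:
        for ch, on in self.true_onsets.items():
            on = np.asarray(on)
            if np.any(np.diff(on) <= 0):
                raise ValueError(f"onsets for {ch} not strictly increasing")


def _ramp_profile(t: np.ndarray, plan: EpisodePlan) -> np.ndarray:
    """0 at baseline, 1 on the plateau, linear over rise and fall."""
    r0 = plan.wave_start
    r1 = r0 + plan.wave_rise_duration
    f0 = r1 + plan.wave_plateau_duration
    f1 = f0 + plan.wave_fall_duration
    out = np.zeros_like(t)
    rising = (t >= r0) & (t < r1)
    out[rising] = (t[rising] - r0) / (r1 - r0)
    out[(t >= r1) & (t < f0)] = 1.0
    falling = (t >= f0) & (t < f1)
    out[falling] = 1.0 - (t[falling] - f0) / (f1 - f0)
    return out


def generate_recording(plan: EpisodePlan) -> tuple[Recording, GroundTruth]:
    """Synthesize one three-channel 50 Hz recording and its ground truth.

    Beat lengths are drawn around 60/heart_rate_mean with the configured
    coefficient of variation and rounded to whole samples so every onset falls
    exactly on the sampling grid.  Each channel is assembled beat by beat: the
    rendered cycle (unit height, onset at 0) gets a small diastolic tilt, is
    mean-centred, scaled to the instantaneous pulse amplitude and added to the
    channel's slow trend, so the windowed mean of the channel tracks the
    programmed trend and every beat's minimum sits on its onset sample.
    Gaussian noise is added per channel and artifacts injected afterwards.
    Fully reproducible from ``plan.seed``.
    """
    rng = np.random.default_rng(plan.seed)
    fs = plan.fs
    n_total = int(round(plan.total_duration * fs))

    # --- beat grid (integer-sample beat lengths) ---
    onsets = [0]
    beat_samples: list[int] = []
    mean_period = 60.0 / plan.heart_rate_mean
    while True:
        period = mean_period * (1.0 + plan.heart_rate_cv * rng.standard_normal())
        period = float(np.clip(period, 0.35, 1.9))
        nb = max(int(round(period * fs)), int(round(0.35 * fs)))
        if onsets[-1] + nb >= n_total:
            break
        beat_samples.append(nb)
        onsets.append(onsets[-1] + nb)
    onset_arr = np.asarray(onsets, dtype=int)
    n_beats = len(beat_samples)  # complete beats; the last onset starts a partial beat

    t_axis = np.arange(n_total) / fs
    rho = _ramp_profile(t_axis, plan)
    m_icp = plan.baseline_icp_mean + (plan.plateau_icp_mean - plan.baseline_icp_mean) * rho
    m_cbfv = plan.baseline_cbfv_mean + (plan.plateau_cbfv_mean - plan.baseline_cbfv_mean) * rho
    m_abp = np.full(n_total, plan.abp_mean)

    icp = m_icp.copy()
    cbfv = m_cbfv.copy()
    abp = m_abp.copy()
    roundness_per_beat = np.empty(n_beats)

    tilt = plan.diastolic_tilt

    def _beat_wave(shape_unit: np.ndarray, amp: float) -> np.ndarray:
        """Tilt, centre and scale one rendered cycle (unit peak height)."""
        nb = shape_unit.size
        shv = shape_unit + tilt * np.arange(nb) / nb
        return amp * (shv - shv.mean())

    for k in range(n_beats):
        s, nb = onsets[k], beat_samples[k]
        cyc = nb / fs
        mid = (s + nb / 2) / fs
        rho_k = float(_ramp_profile(np.array([mid]), plan)[0])
        r_k = plan.baseline_roundness + (plan.plateau_roundness - plan.baseline_roundness) * rho_k
        roundness_per_beat[k] = r_k

        icp_shape = render_pulse(replace(PulseMorphology(), roundness=r_k), cyc, fs)
        icp_shape = icp_shape / icp_shape.max()
        d_icp = (plan.plateau_icp_mean - plan.baseline_icp_mean) * rho_k
        amp_icp = plan.icp_pulse_amp * (1.0 + plan.icp_amp_coupling * d_icp)
        icp[s : s + nb] += _beat_wave(icp_shape, amp_icp)

        amp_cbfv = plan.cbfv_pulse_amp * (1.0 + plan.cbfv_pulsatility_gain * rho_k)
        cbfv[s : s + nb] += _beat_wave(cbfv_pulse_shape(cyc, fs), amp_cbfv)
        abp[s : s + nb] += _beat_wave(abp_pulse_shape(cyc, fs), plan.abp_pulse_amp)

    # partial final beat: first samples of one more rendered cycle
    s = onsets[-1]
    ln = n_total - s
    if ln > 0:
        cyc = float(np.clip(max(mean_period, (ln + 1) / fs), 0.3, 2.0))
        tail = slice(s, n_total)
        rho_k = float(_ramp_profile(np.array([s / fs]), plan)[0])
        r_k = plan.baseline_roundness + (plan.plateau_roundness - plan.baseline_roundness) * rho_k
        icp_shape = render_pulse(replace(PulseMorphology(), roundness=r_k), cyc, fs)
        icp_shape = icp_shape / icp_shape.max()
        icp[tail] += _beat_wave(icp_shape, plan.icp_pulse_amp)[:ln]
        cbfv[tail] += _beat_wave(cbfv_pulse_shape(cyc, fs), plan.cbfv_pulse_amp)[:ln]
        abp[tail] += _beat_wave(abp_pulse_shape(cyc, fs), plan.abp_pulse_amp)[:ln]

    # --- noise ---
    if plan.noise_sd_icp > 0:
        icp += rng.normal(0.0, plan.noise_sd_icp, n_total)
    if plan.noise_sd_abp > 0:
        abp += rng.normal(0.0, plan.noise_sd_abp, n_total)
    if plan.noise_sd_cbfv > 0:
        cbfv += rng.normal(0.0, plan.noise_sd_cbfv, n_total)

    # --- artifacts: spike, flatline, dropout-to-zero ---
    channels = {"icp": icp, "abp": abp, "cbfv": cbfv}
    artifacts: list[tuple[str, str, float, float]] = []
    n_events = rng.poisson(plan.artifact_rate * plan.total_duration / 60.0)
    for _ in range(n_events):
        kind = rng.choice(["spike", "flatline", "dropout"])
        if kind == "dropout":
            ch = "cbfv"
            dur = float(rng.uniform(0.5, 2.0))
        elif kind == "spike":
            ch = str(rng.choice(["icp", "abp", "cbfv"]))
            dur = float(rng.uniform(0.1, 0.3))
        else:
            ch = str(rng.choice(["icp", "abp", "cbfv"]))
            dur = float(rng.uniform(1.0, 3.0))
        start = float(rng.uniform(0.0, plan.total_duration - dur))
        i0, i1 = int(round(start * fs)), int(round((start + dur) * fs))
        i1 = min(i1, n_total)
        x = channels[ch]
        if kind == "spike":
            bump = {"icp": 110.0, "abp": 150.0, "cbfv": 260.0}[ch]
            x[i0:i1] += bump * np.sin(np.pi * np.arange(i1 - i0) / max(i1 - i0, 1)) ** 2
        elif kind == "flatline":
            x[i0:i1] = x[i0]
        else:
            x[i0:i1] = 0.0
        artifacts.append((ch, kind, i0 / fs, i1 / fs))

    recording = Recording(
        icp=TimeSeries(icp, fs, "mmHg", "icp"),
        abp=TimeSeries(abp, fs, "mmHg", "abp"),
        cbfv=TimeSeries(cbfv, fs, "cm/s", "cbfv"),
    )
    gt = GroundTruth(
        true_onsets={ch: onset_arr.copy() for ch in ("icp", "abp", "cbfv")},
        wave_interval=plan.wave_interval,
        pulse_roundness=roundness_per_beat,
        artifact_intervals=artifacts,
        fs=fs,
    )
    return recording, gt


# jitter applied to cohort-level plan parameters (multiplicative log-normal,
# sigma 0.05 ~ +/-10% at 2 sigma); draws that would break the plateau-wave
# criteria (plateau ICP >= 41 mmHg, rise >= 16 mmHg) are redrawn so every
# simulated wave remains detectable in principle
_JITTER_SIGMA = 0.05
_MIN_PLATEAU_ICP = 41.0
_MIN_RISE_ICP = 16.0


def generate_cohort(
    n_waves: int, plan_template: EpisodePlan | None = None, seed: int = 0
) -> list[tuple[Recording, GroundTruth]]:
    """Generate ``n_waves`` independent recordings with jittered plans.

    Level parameters (ICP baseline and rise, CBFV levels, ABP, heart rate)
    receive independent log-normal jitter around the template; each recording
    gets a child seed derived from ``seed``.  Deterministic.
    """
    if n_waves < 1:
        raise ValueError("n_waves must be >= 1")
    template = plan_template or EpisodePlan()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_waves)]
    rng = np.random.default_rng(ss.spawn(1)[0])

    out = []
    for w in range(n_waves):
        for _ in range(100):
            f = np.exp(_JITTER_SIGMA * rng.standard_normal(6))
            base_icp = template.baseline_icp_mean * f[0]
            rise_icp = (template.plateau_icp_mean - template.baseline_icp_mean) * f[1]
            if base_icp + rise_icp >= _MIN_PLATEAU_ICP and rise_icp >= _MIN_RISE_ICP:
                break
        plan = replace(
            template,
            baseline_icp_mean=base_icp,
            plateau_icp_mean=base_icp + rise_icp,
            baseline_cbfv_mean=template.baseline_cbfv_mean * f[2],
            plateau_cbfv_mean=template.plateau_cbfv_mean * f[2],
            abp_mean=template.abp_mean * f[3],
            heart_rate_mean=float(np.clip(template.heart_rate_mean * f[4], 50, 110)),
            icp_pulse_amp=template.icp_pulse_amp * f[5],
            seed=child_seeds[w],
        )
        out.append(generate_recording(plan))
    return out


def write_ground_truth(gt: GroundTruth, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write ground truth as sidecar CSV tables.

    ``<prefix>_onsets.csv``: channel, sample_index, roundness (ICP beats).
    ``<prefix>_intervals.csv``: kind, channel, start_s, end_s (wave + artifacts).
    """
    prefix = Path(path_prefix)
    onsets_path = prefix.parent / (prefix.name + "_onsets.csv")
    intervals_path = prefix.parent / (prefix.name + "_intervals.csv")
    with open(onsets_path, "w", newline="", encoding="utf-8") as fh:
        wr = csv.writer(fh)
        wr.writerow(["channel", "sample_index", "roundness"])
        for ch, on in gt.true_onsets.items():
            for i, idx in enumerate(on):
                r = gt.pulse_roundness[i] if ch == "icp" and i < len(gt.pulse_roundness) else ""
                wr.writerow([ch, int(idx), f"{r:.6f}" if r != "" else ""])
    with open(intervals_path, "w", newline="", encoding="utf-8") as fh:
        wr = csv.writer(fh)
        wr.writerow(["kind", "channel", "start_s", "end_s"])
        wr.writerow(["wave", "", f"{gt.wave_interval[0]:.3f}", f"{gt.wave_interval[1]:.3f}"])
        for ch, kind, a, b in gt.artifact_intervals:
            wr.writerow([f"artifact:{kind}", ch, f"{a:.3f}", f"{b:.3f}"])
    return onsets_path, intervals_path


def read_ground_truth(path_prefix: str | Path, fs: float = 50.0) -> GroundTruth:
    """Inverse of :func:`write_ground_truth`."""
    prefix = Path(path_prefix)
    onsets: dict[str, list[int]] = {}
    roundness: list[float] = []
    with open(prefix.parent / (prefix.name + "_onsets.csv"), encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            onsets.setdefault(row["channel"], []).append(int(row["sample_index"]))
            if row["channel"] == "icp" and row["roundness"]:
                roundness.append(float(row["roundness"]))
    wave = (0.0, 0.0)
    artifacts: list[tuple[str, str, float, float]] = []
    with open(prefix.parent / (prefix.name + "_intervals.csv"), encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            if row["kind"] == "wave":
                wave = (float(row["start_s"]), float(row["end_s"]))
            else:
                artifacts.append(
                    (row["channel"], row["kind"].split(":", 1)[1], float(row["start_s"]), float(row["end_s"]))
                )
    return GroundTruth(
        true_onsets={ch: np.asarray(v, dtype=int) for ch, v in onsets.items()},
        wave_interval=wave,
        pulse_roundness=np.asarray(roundness),
        artifact_intervals=artifacts,
        fs=fs,
    )
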