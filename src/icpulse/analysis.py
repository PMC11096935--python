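"""End-to-end orchestration: recordings -> per-pulse DI -> cohort comparison.

The user-facing API follows the model / results idiom: build a
:class:`PlateauSimilarityModel` from recordings (or a synthetic cohort),
call :meth:`~PlateauSimilarityModel.fit`, and read estimates, per-wave
tables and the paired test off the returned
:class:`PlateauSimilarityResults`, whose :meth:`summary` prints a compact
report.  Underneath, each recording runs the fixed stage order: trend
computation -> plateau-wave detection and period selection -> channel
preprocessing -> onset detection -> beat segmentation -> QC -> pairing ->
volume-pulse computation -> labeling -> DI scoring; the cohort comparison
then pairs per-wave DI aggregates.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .cabv import cabv_for_pairs
from .plateau import (
    PlateauCriteria,
    PlateauWave,
    compute_trends,
    detect_plateau_waves,
    label_pulses,
    select_periods,
)
from .preprocess import PreprocessConfig, moving_mean, preprocess_series
from .pulses import QCConfig, detect_onsets, pair_pulses, qc_pulse, segment_pulses
from .similarity import DIRecord, score_pairs
from .stats import ComparisonResult, PeriodSummary, build_report, compare_periods, summarize
from .synth import EpisodePlan, generate_cohort, generate_recording

__all__ = [
    "PipelineConfig",
    "PlateauSimilarityModel",
    "PlateauSimilarityResults",
    "RecordingOutcome",
]

logger = logging.getLogger(__name__)


def _from_mapping(cls, data: dict):
    """Build a (frozen) dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the analysis, nested per stage."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    plateau: PlateauCriteria = field(default_factory=PlateauCriteria)
    pairing_tolerance_s: float = 0.25
    onset_window_s: float = 6.0
    onset_max_scale_s: float = 1.2
    di_length_mismatch: str = "hold_last"  # or "truncate"
    cabv_frozen_mean: bool = False
    statistics_pairing: str = "per_wave"  # or "pooled"
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sub = {
            "preprocess": PreprocessConfig,
            "qc": QCConfig,
            "plateau": PlateauCriteria,
        }
        kwargs = {}
        for key, sub_cls in sub.items():
            if key in data:
                block = data.pop(key)
                kwargs[key] = _from_mapping(sub_cls, block) if isinstance(block, dict) else block
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: v for k, v in out.items()}


@dataclass
class RecordingOutcome:
    """Per-recording artifacts of one pipeline run."""

    recording_id: str
    waves: list[PlateauWave]
    di_records: list[DIRecord]
    n_pulses_detected: int
    n_pulses_accepted: int
    qc_reasons: dict[str, int]
    period_means: dict[str, dict[str, float]]  # variable -> period -> mean level
    error: str | None = None


def run_recording(
    recording: sio.Recording,
    config: PipelineConfig | None = None,
    recording_id: str = "rec",
) -> RecordingOutcome:
    """Run the full single-recording pipeline.

    Returns an outcome object even when no wave is found (empty DI list);
    stage failures are captured in ``outcome.error`` rather than raised, so a
    cohort run degrades only the affected recording.
    """
    cfg = config or PipelineConfig()
    trends = compute_trends(recording, cfg.preprocess.trend_window)
    waves = detect_plateau_waves(trends, cfg.plateau)
    waves = [
        w
        for w in (
            select_periods(w, trends, cfg.plateau.baseline_length) for w in waves
        )
        if w is not None
    ]
    if not waves:
        return RecordingOutcome(recording_id, [], [], 0, 0, {}, {})

    icp200 = preprocess_series(recording.icp, cfg.preprocess)
    cbfv200 = preprocess_series(recording.cbfv, cfg.preprocess)
    cbfv_mean = moving_mean(cbfv200, cfg.preprocess.mean_window)

    icp_onsets = detect_onsets(icp200, cfg.onset_window_s, cfg.onset_max_scale_s)
    cbfv_onsets = detect_onsets(cbfv200, cfg.onset_window_s, cfg.onset_max_scale_s)
    icp_pulses = segment_pulses(icp200, icp_onsets, "icp")
    cbfv_pulses = segment_pulses(cbfv200, cbfv_onsets, "cbfv")
    n_detected = len(icp_pulses) + len(cbfv_pulses)

    qc_reasons: dict[str, int] = {}
    accepted = {}
    for name, pulses in (("icp", icp_pulses), ("cbfv", cbfv_pulses)):
        kept = []
        for p in pulses:
            res = qc_pulse(p, cfg.qc)
            if res:
                kept.append(p)
            else:
                qc_reasons[res.reason] = qc_reasons.get(res.reason, 0) + 1
        accepted[name] = kept
    n_accepted = len(accepted["icp"]) + len(accepted["cbfv"])

    pairs = pair_pulses(accepted["icp"], accepted["cbfv"], cfg.pairing_tolerance_s)
    cabv_pairs = cabv_for_pairs(pairs, cbfv_mean, cfg.cabv_frozen_mean)

    di_records: list[DIRecord] = []
    period_means: dict[str, dict[str, float]] = {}
    for w_idx, wave in enumerate(waves):
        wave_id = recording_id if len(waves) == 1 else f"{recording_id}.w{w_idx}"
        labels = label_pulses([p for p, _ in cabv_pairs], wave)
        di_records.extend(
            score_pairs(cabv_pairs, labels, wave_id, cfg.di_length_mismatch)
        )
        period_means[wave_id] = _period_levels(recording, wave)

    return RecordingOutcome(
        recording_id=recording_id,
        waves=waves,
        di_records=di_records,
        n_pulses_detected=n_detected,
        n_pulses_accepted=n_accepted,
        qc_reasons=qc_reasons,
        period_means=period_means,
    )


def _period_levels(recording: sio.Recording, wave: PlateauWave) -> dict[str, float]:
    """Mean channel levels over the selected baseline and plateau intervals."""
    fs = recording.fs
    out = {}
    for label, interval in (
        ("baseline", wave.baseline_interval),
        ("plateau", wave.plateau_interval),
    ):
        a, b = int(round(interval[0] * fs)), int(round(interval[1] * fs))
        for ch, series in recording.channels().items():
            out[f"{ch}_{label}"] = float(np.mean(series.samples[a:b]))
    return out


class PlateauSimilarityModel:
    """ICP vs cerebral-arterial-volume pulse-shape similarity across waves.

    Parameters
    ----------
    recordings : list of Recording
        Concurrent ICP/ABP/CBFV recordings, one (or more) plateau wave each.
    recording_ids : list of str, optional
        Stable identifiers; defaults to ``rec00``, ``rec01``, ...
    config : PipelineConfig, optional
        Stage tunables; defaults reproduce the standard chain (200 Hz, 12 Hz
        low-pass, 6 s slow mean, 10 s trends, 0.25 s pairing tolerance).
    """

    def __init__(
        self,
        recordings: list[sio.Recording],
        recording_ids: list[str] | None = None,
        config: PipelineConfig | None = None,
    ) -> None:
        if not recordings:
            raise ValueError("at least one recording is required")
        self.recordings = list(recordings)
        self.recording_ids = list(recording_ids) if recording_ids else [
            f"rec{i:02d}" for i in range(len(recordings))
        ]
        if len(self.recording_ids) != len(self.recordings):
            raise ValueError("recording_ids must match recordings one-to-one")
        self.config = config or PipelineConfig()

    @classmethod
    def from_paths(
        cls, paths: list[str | Path], config: PipelineConfig | None = None
    ) -> "PlateauSimilarityModel":
        recs = [sio.read_recording(p) for p in paths]
        ids = [Path(p).stem for p in paths]
        return cls(recs, ids, config)

    @classmethod
    def from_synthetic_cohort(
        cls,
        n_waves: int = 15,
        seed: int = 0,
        plan_template: EpisodePlan | None = None,
        config: PipelineConfig | None = None,
    ) -> "PlateauSimilarityModel":
        cohort = generate_cohort(n_waves, plan_template, seed)
        recs = [r for r, _ in cohort]
        model = cls(recs, config=config)
        model.ground_truths = [g for _, g in cohort]
        return model

    def fit(self) -> "PlateauSimilarityResults":
        """Run the pipeline on every recording and the cohort comparison."""
        outcomes = []
        for rec, rid in zip(self.recordings, self.recording_ids):
            try:
                outcomes.append(run_recording(rec, self.config, rid))
            except Exception as exc:  # stage isolation: degrade one recording only
                logger.error("recording %s failed: %s", rid, exc)
                outcomes.append(RecordingOutcome(rid, [], [], 0, 0, {}, {}, error=str(exc)))
        return PlateauSimilarityResults(self, outcomes)


class PlateauSimilarityResults:
    """Fitted results: per-pulse DI table, per-wave aggregates, paired test."""

    def __init__(self, model: PlateauSimilarityModel, outcomes: list[RecordingOutcome]):
        self.model = model
        self.outcomes = outcomes
        self.di_records: list[DIRecord] = [r for o in outcomes for r in o.di_records]
        self.comparison: ComparisonResult | None = None
        if any(r.period_label in ("baseline", "plateau") for r in self.di_records):
            try:
                self.comparison = compare_periods(
                    self.di_records,
                    model.config.statistics_pairing,
                    model.config.alpha,
                )
            except ValueError as exc:
                logger.warning("cohort comparison unavailable: %s", exc)

    # -- tabular views ---------------------------------------------------

    @property
    def di_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wave_id": [r.wave_id for r in self.di_records],
                "period_label": [r.period_label for r in self.di_records],
                "onset_time": [r.onset_time for r in self.di_records],
                "di": [r.di for r in self.di_records],
                "n_compared": [r.n_compared for r in self.di_records],
            }
        )

    @property
    def n_waves(self) -> int:
        return sum(len(o.waves) for o in self.outcomes)

    def signal_summaries(self) -> dict[str, dict[str, PeriodSummary]]:
        """Median [Q1-Q3] of the channel levels across waves, per period."""
        frames: dict[str, dict[str, list[float]]] = {}
        for o in self.outcomes:
            for levels in o.period_means.values():
                for key, val in levels.items():
                    ch, label = key.rsplit("_", 1)
                    frames.setdefault(ch.upper(), {}).setdefault(label, []).append(val)
        return {
            var: {
                label: summarize(vals, var, label) for label, vals in periods.items()
            }
            for var, periods in frames.items()
        }

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        """Plain-text report: per-wave DI, period summaries, test outcome."""
        if self.comparison is None:
            counts = {o.recording_id: len(o.waves) for o in self.outcomes}
            return (
                "Pulse-similarity analysis: no cohort comparison available\n"
                f"waves per recording: {counts}\n"
            )
        return build_report(
            self.comparison,
            signal_summaries=self.signal_summaries(),
            config_echo=self.model.config.echo(),
        )

    def save(self, out_dir: str | Path) -> None:
        """Write DI table, JSON summary and the text report into ``out_dir``."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary: dict = {
            "n_waves": self.n_waves,
            "n_di_records": len(self.di_records),
        }
        if self.comparison is not None:
            t = self.comparison.test
            summary.update(
                {
                    "wilcoxon": {
                        "statistic": t.statistic,
                        "p_value": t.p_value,
                        "n_pairs": t.n_pairs,
                        "method": t.method,
                    },
                    "di_summaries": self.comparison.summaries,
                }
            )
        if self.di_records:
            sio.write_results(self.di_records, summary, out_dir)
        with open(out_dir / "report.txt", "w", encoding="utf-8") as fh:
            fh.write(self.summary())

    def plot_di(self, ax=None):
        """Box plot of per-wave median DI, baseline vs plateau phase."""
        import matplotlib.pyplot as plt

        if self.comparison is None:
            raise ValueError("no comparison to plot")
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        pw = self.comparison.per_wave
        ax.boxplot(
            [pw["baseline"], pw["plateau"]], tick_labels=["baseline", "plateau phase"]
        )
        ax.set_ylabel("difference index (a.u.)")
        ax.set_title(
            f"DI per wave (n={len(pw)}), Wilcoxon p={self.comparison.test.p_value:.2g}"
        )
        return ax
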