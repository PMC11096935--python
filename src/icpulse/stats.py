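"""Per-period summaries and the paired Wilcoxon signed-rank comparison.

The pipeline is unconditionally nonparametric: values are summarized as
median with first and third quartiles, and baseline-vs-plateau differences
are tested with the Wilcoxon signed-rank test.  Zero differences are dropped
(Wilcoxon's original rule, the common default in clinical statistics
software), ties in |d| receive average ranks, and the reported statistic is
W = min(sum of positive ranks, sum of negative ranks).  Two-sided p-values
are exact -- by shift convolution of the signed-rank distribution -- up to
n = 25, and use a tie- and continuity-corrected normal approximation beyond.

The primary inference unit is the wave: each wave contributes one baseline
and one plateau aggregate (median DI), matching a design where per-period
values are reported across waves.  A pooled per-pulse mode exists for
exploration but is pseudo-replicated and flagged as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .similarity import DIRecord

__all__ = [
    "PeriodSummary",
    "PairedTestResult",
    "ComparisonResult",
    "summarize",
    "wilcoxon_signed_rank",
    "compare_periods",
    "build_report",
]

logger = logging.getLogger(__name__)

EXACT_N_MAX = 25  # exact signed-rank distribution up to this n


@dataclass(frozen=True)
class PeriodSummary:
    """Median and quartiles of one variable in one period."""

    variable: str
    period_label: str
    median: float
    q1: float
    q3: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("summary requires n >= 1")
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles must bracket the median")


@dataclass(frozen=True)
class PairedTestResult:
    """Wilcoxon signed-rank outcome."""

    statistic: float  # W = min(W+, W-) after zero removal
    p_value: float
    n_pairs: int  # pairs contributing after zero removal
    method: str  # "exact" | "normal-approximation"


@dataclass
class ComparisonResult:
    """Paired baseline-vs-plateau comparison plus per-period summaries."""

    test: PairedTestResult
    summaries: dict[str, PeriodSummary]
    per_wave: pd.DataFrame  # wave_id, baseline, plateau aggregates
    pairing: str
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.test.p_value < self.alpha


def summarize(values, variable: str = "", period_label: str = "") -> PeriodSummary:
    """Median / Q1 / Q3 by linear interpolation between order statistics."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("summaries require finite values")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method="linear")
    return PeriodSummary(variable, period_label, float(med), float(q1), float(q3), x.size)


def _exact_two_sided_p(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided tail probability of the signed-rank sum.

    ``ranks2`` are the (doubled, hence integer) ranks of |d| and ``w2`` the
    observed min(W+, W-) on the doubled scale.  Builds the null distribution
    of the positive-rank sum by shift convolution over all 2^n equiprobable
    sign assignments and sums both tails.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        counts[r:] = counts[r:] + counts[:-r] if r > 0 else 2 * counts[r:]
    counts /= counts.sum()
    w2i = int(np.floor(w2 + 1e-9))
    p = counts[: w2i + 1].sum() + counts[total - w2i :].sum()
    return float(min(p, 1.0))


def wilcoxon_signed_rank(x, y) -> PairedTestResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Differences ``d = x - y``; zeros dropped; |d| ranked with average ranks on
    ties; W = min(positive-rank sum, negative-rank sum).  Exact p up to
    n = 25 (ties handled exactly on the doubled-rank lattice), otherwise a
    normal approximation with tie variance correction and a 0.5 continuity
    correction.  Requires at least 5 nonzero differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equally long")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise ValueError(
            f"only {n} nonzero differences; the signed-rank test needs >= 5 "
            "(an exact-binomial sign-test fallback is out of scope)"
        )
    r = rankdata(np.abs(d))  # average ranks on ties
    w_plus = float(r[d > 0].sum())
    w_minus = float(r[d < 0].sum())
    w = min(w_plus, w_minus)

    if n <= EXACT_N_MAX:
        ranks2 = np.round(2 * r).astype(int)
        p = _exact_two_sided_p(ranks2, 2 * w)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(r, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w - mu + 0.5) / sigma  # w <= mu, continuity correction toward center
        p = float(min(2 * norm.cdf(z), 1.0))
        method = "normal-approximation"
    return PairedTestResult(statistic=w, p_value=p, n_pairs=n, method=method)


def compare_periods(
    di_records: list[DIRecord],
    pairing: str = "per_wave",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Baseline-vs-plateau DI comparison.

    ``per_wave`` (default): each wave contributes its median DI per period,
    and the signed-rank test pairs the two medians across waves.  Waves
    missing either period are excluded with a warning.  ``pooled`` pairs the
    i-th baseline pulse with the i-th plateau pulse within each wave
    (truncated to the shorter period) -- exploratory only, as pulses within a
    wave are not independent (pseudo-replication).
    """
    df = pd.DataFrame(
        {
            "wave_id": [r.wave_id for r in di_records],
            "period": [r.period_label for r in di_records],
            "di": [r.di for r in di_records],
        }
    )
    df = df[df["period"].isin(["baseline", "plateau"])]
    if df.empty:
        raise ValueError("no labeled DI records to compare")

    rows = []
    x_parts, y_parts = [], []
    for wave_id, g in df.groupby("wave_id", sort=True):
        base = g.loc[g["period"] == "baseline", "di"].to_numpy()
        plat = g.loc[g["period"] == "plateau", "di"].to_numpy()
        if base.size == 0 or plat.size == 0:
            logger.warning("wave %s missing a period; excluded from the comparison", wave_id)
            continue
        rows.append(
            {
                "wave_id": wave_id,
                "baseline": float(np.median(base)),
                "plateau": float(np.median(plat)),
                "n_baseline": base.size,
                "n_plateau": plat.size,
            }
        )
        if pairing == "pooled":
            m = min(base.size, plat.size)
            x_parts.append(base[:m])
            y_parts.append(plat[:m])
    per_wave = pd.DataFrame(rows)
    if per_wave.empty:
        raise ValueError("no wave contributed both periods")

    if pairing == "per_wave":
        x = per_wave["baseline"].to_numpy()
        y = per_wave["plateau"].to_numpy()
    elif pairing == "pooled":
        logger.warning("pooled pairing pseudo-replicates pulses within waves")
        x = np.concatenate(x_parts)
        y = np.concatenate(y_parts)
    else:
        raise ValueError(f"unknown pairing mode: {pairing!r}")

    test = wilcoxon_signed_rank(x, y)
    summaries = {
        "baseline": summarize(x, "DI", "baseline"),
        "plateau": summarize(y, "DI", "plateau"),
    }
    return ComparisonResult(
        test=test, summaries=summaries, per_wave=per_wave, pairing=pairing, alpha=alpha
    )


def build_report(
    comparison: ComparisonResult,
    signal_summaries: dict[str, dict[str, PeriodSummary]] | None = None,
    config_echo: dict | None = None,
    path=None,
) -> str:
    """Render a deterministic plain-text run report; optionally write it.

    ``signal_summaries`` maps variable name (ICP, CBFV, ABP) to its per-period
    summaries.  The report mirrors the per-wave layout of a cohort table:
    one row per wave, then per-period medians and the test outcome.
    """
    lines = ["# Pulse-similarity analysis report", ""]
    if config_echo:
        lines.append("## Configuration")
        for k in sorted(config_echo):
            lines.append(f"  {k}: {config_echo[k]}")
        lines.append("")
    lines.append("## Per-wave median DI")
    lines.append("  wave_id          baseline    plateau   n_base  n_plat")
    for _, row in comparison.per_wave.iterrows():
        lines.append(
            f"  {str(row['wave_id']):<15} {row['baseline']:>9.3f}  {row['plateau']:>9.3f}"
            f"  {int(row['n_baseline']):>6d}  {int(row['n_plateau']):>6d}"
        )
    lines.append("")
    lines.append("## Period summaries (median [Q1-Q3])")
    blocks = {"DI": comparison.summaries}
    if signal_summaries:
        blocks.update(signal_summaries)
    for var, periods in blocks.items():
        for label in ("baseline", "plateau"):
            if label in periods:
                s = periods[label]
                lines.append(
                    f"  {var:<6} {label:<9} {s.median:8.3f} [{s.q1:.3f}-{s.q3:.3f}]  n={s.n}"
                )
    lines.append("")
    t = comparison.test
    lines.append("## Wilcoxon signed-rank (baseline vs plateau)")
    lines.append(
        f"  W = {t.statistic:g}, p = {t.p_value:.6g}, n = {t.n_pairs}, method = {t.method}"
    )
    lines.append(f"  significant at alpha = {comparison.alpha:g}: {comparison.significant}")
    lines.append("")
    text = "\n".join(lines)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
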