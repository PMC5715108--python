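"""Functional-stability statistics for longitudinal designs.

Within each subject, per-taxon abundance changes (in percentage points
of total bacteria) are computed between the initial time point and every
later time point.  Three statistics summarise how concordantly the
functionally redundant taxa respond:

* the fraction of taxa that decreased (50% = highest discordance, 0 or
  100% = fully concordant change),
* the "absolute change" |sum of signed changes| — the net shift of the
  whole pathway — versus the "total change" (sum of unsigned changes),
  equal only when all taxa move in the same direction; their ratio
  measures response concordance,
* a random baseline of uniform integer draws on [-100, 100] against
  which the squared deviation of observed fractions from 50% is tested.

Taxa absent at both time points (tied zeros) are excluded, mirroring
the paired-test convention.  A zero change counts as a non-decrease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class StabilityError(Exception):
    pass


@dataclass
class ChangeRecord:
    """Per-taxon signed abundance changes for one (baseline, later)
    time-point pair of one subject."""

    subject_id: str
    baseline_timepoint: int
    later_timepoint: int
    changes: dict[str, float]  # taxon -> change in percentage points


@dataclass
class StabilitySummary:
    """Direction statistics of one change record."""

    subject_id: str
    comparison: tuple[int, int]
    fraction_decreasing: float  # % of taxa with negative change
    absolute_change: float  # |sum of signed changes|
    total_change: float  # sum of |changes|

    @property
    def ratio(self) -> float:
        """100 x absolute/total; undefined (NaN) when total is 0."""
        if self.total_change == 0:
            return float("nan")
        return 100.0 * self.absolute_change / self.total_change


def taxon_changes(
    series: Mapping[int, Mapping[str, float]], subject_id: str = "s0"
) -> list[ChangeRecord]:
    """Change records between the initial time point and all later ones.

    ``series`` maps timepoint -> {taxon: abundance in % of total
    bacteria}.  Taxa at zero abundance in both time points of a pair
    (tied zeros) are excluded from that record.
    """
    tps = sorted(series)
    if len(tps) < 2:
        warnings.warn("single time point: no change records", stacklevel=2)
        return []
    base_tp = tps[0]
    base = series[base_tp]
    records = []
    for tp in tps[1:]:
        later = series[tp]
        taxa = set(base) | set(later)
        changes = {}
        for t in sorted(taxa):
            b, l = float(base.get(t, 0.0)), float(later.get(t, 0.0))
            if b == 0 and l == 0:
                continue
            changes[t] = l - b
        records.append(ChangeRecord(subject_id, base_tp, tp, changes))
    return records


def fraction_decreasing(record: ChangeRecord) -> float:
    """% of retained taxa with a strictly negative change (zero counts
    as non-decrease)."""
    if not record.changes:
        return float("nan")
    vals = np.array(list(record.changes.values()))
    return 100.0 * float((vals < 0).mean())


def absolute_vs_total(record: ChangeRecord) -> StabilitySummary:
    """Absolute (net, unsigned) vs total (sum of unsigned) change."""
    if not record.changes:
        raise StabilityError("record has no retained taxa")
    vals = np.array(list(record.changes.values()))
    return StabilitySummary(
        subject_id=record.subject_id,
        comparison=(record.baseline_timepoint, record.later_timepoint),
        fraction_decreasing=fraction_decreasing(record),
        absolute_change=float(abs(vals.sum())),
        total_change=float(np.abs(vals).sum()),
    )


def summarize_subjects(
    per_subject_series: Mapping[str, Mapping[int, Mapping[str, float]]]
) -> pd.DataFrame:
    """Stability summary table over subjects (one row per record)."""
    rows = []
    for subject, series in per_subject_series.items():
        for rec in taxon_changes(series, subject):
            if not rec.changes:
                continue
            s = absolute_vs_total(rec)
            rows.append(
                {"subject_id": subject, "baseline": s.comparison[0],
                 "later": s.comparison[1],
                 "fraction_decreasing": s.fraction_decreasing,
                 "absolute_change": s.absolute_change,
                 "total_change": s.total_change, "ratio": s.ratio}
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "baseline", "later", "fraction_decreasing",
                       "absolute_change", "total_change", "ratio"],
    )


def random_baseline(
    n_draws: int = 1000, n_repeats: int = 20, seed: int = 0
) -> np.ndarray:
    """Random-community baseline: per repeat, ``n_draws`` uniform
    integers on [-100, 100] inclusive; returns the % negative of each
    repeat (zero counts as non-decrease; expectation 100/201)."""
    rng = np.random.default_rng(seed)
    draws = rng.integers(-100, 101, size=(n_repeats, n_draws))
    return 100.0 * (draws < 0).mean(axis=1)


def variance_test(
    observed_fractions: Sequence[float],
    baseline_fractions: Sequence[float],
    *,
    deviation: str = "sq",
) -> tuple[float, float, float]:
    """Test whether observed fractions deviate from 50% more than the
    random baseline.

    Per record the deviation from 50 is squared (default) or absolute;
    a two-sample t test compares observed vs baseline deviations.
    Returns (mean observed deviation, mean baseline deviation, P).
    """
    obs = np.asarray(observed_fractions, dtype=float)
    base = np.asarray(baseline_fractions, dtype=float)
    if len(obs) < 2 or len(base) < 2:
        raise StabilityError("both groups need n >= 2")
    if deviation == "sq":
        dev_o, dev_b = (obs - 50.0) ** 2, (base - 50.0) ** 2
    elif deviation == "abs":
        dev_o, dev_b = np.abs(obs - 50.0), np.abs(base - 50.0)
    else:
        raise StabilityError("deviation must be 'sq' or 'abs'")
    if dev_o.var(ddof=1) == 0 and dev_b.var(ddof=1) == 0:
        warnings.warn("degenerate variances: P undefined", stacklevel=2)
        return float(dev_o.mean()), float(dev_b.mean()), float("nan")
    t = stats.ttest_ind(dev_o, dev_b, equal_var=False)
    return float(dev_o.mean()), float(dev_b.mean()), float(t.pvalue)
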