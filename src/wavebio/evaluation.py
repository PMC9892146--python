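"""Metric evaluation: threshold sweeps, impairment ranking, trend summaries.

A sweep reports, for each threshold of one metric in one direction, the
matching-assessment percentage (share of samples of the target truth class
that the metric calls correctly) and the type-1-error percentage
(confidently wrong calls as a share of ALL test samples).  The asymmetric
denominators are deliberate: efficiency is judged against the opportunity
(the target class), while the error rate is judged against the whole
monitoring effort.  Both percentages are non-increasing in the threshold
because the trigger sets are nested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .assessment import AssessmentResult, assess_samples, count_indicators
from .taxonomy import IndicatorRegistry
from .training import CategoryPriors, FrequencyTable, SampleRecord, round_half_up

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class EvaluationConfig:
    """Threshold grids and the impaired/unimpaired BAP cut."""

    ptit_thresholds: tuple[int, ...] = (3, 4, 5, 6, 7)
    tpi_thresholds: tuple[float, ...] = (0.50, 0.70, 0.90, 0.95, 0.98)
    impaired_cut: float = 5.0  # BAP <= cut counts as truly impaired
    smoothing: float = 0.0

    def __post_init__(self) -> None:
        if list(self.ptit_thresholds) != sorted(set(self.ptit_thresholds)):
            raise ValueError("ptit_thresholds must be strictly increasing")
        if list(self.tpi_thresholds) != sorted(set(self.tpi_thresholds)):
            raise ValueError("tpi_thresholds must be strictly increasing")
        if any(k < 1 for k in self.ptit_thresholds):
            raise ValueError("ptit thresholds must be >= 1")
        if any(not 0.5 <= t <= 1.0 for t in self.tpi_thresholds):
            raise ValueError("tpi thresholds must lie in [0.5, 1]")


@dataclass(frozen=True)
class SweepRow:
    threshold: float
    matching_percent: float
    type1_percent: float


@dataclass
class SweepTable:
    """Sweep results for one metric in one target direction."""

    metric: str  # "ptit" | "tpi"
    direction: str  # "unimpaired" | "impaired"
    rows: list[SweepRow] = field(default_factory=list)
    n_target: int = 0
    n_total: int = 0

    def __post_init__(self) -> None:
        thresholds = [r.threshold for r in self.rows]
        if thresholds != sorted(set(thresholds)):
            raise ValueError("sweep thresholds must be strictly increasing")
        for r in self.rows:
            if not (0.0 <= r.matching_percent <= 100.0
                    and 0.0 <= r.type1_percent <= 100.0):
                raise ValueError(f"percentage out of [0, 100] in row {r}")

    @classmethod
    def from_columns(cls, metric: str, direction: str,
                     thresholds: Sequence[float], matching: Sequence[float],
                     type1: Sequence[float], n_target: int = 0,
                     n_total: int = 0) -> "SweepTable":
        rows = [SweepRow(t, m, e) for t, m, e in zip(thresholds, matching, type1,
                                                     strict=True)]
        return cls(metric, direction, rows, n_target, n_total)

    def matching(self) -> list[float]:
        return [r.matching_percent for r in self.rows]

    def type1(self) -> list[float]:
        return [r.type1_percent for r in self.rows]

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        frame = pd.DataFrame({
            "metric": self.metric, "direction": self.direction,
            "threshold": [r.threshold for r in self.rows],
            "matching_percent": self.matching(),
            "type1_percent": self.type1(),
            "n_target": self.n_target, "n_total": self.n_total,
        })
        if rounded:
            frame["matching_percent"] = [round_half_up(v, 0) for v in
                                         frame["matching_percent"]]
            frame["type1_percent"] = [round_half_up(v, 1) for v in
                                      frame["type1_percent"]]
        return frame


def _truth_classes(test: Sequence[SampleRecord], impaired_cut: float,
                   ) -> tuple[list[int], list[int], int]:
    """Indices of truly-unimpaired and truly-impaired samples.

    Truth uses BAP <= cut when a score is present, else the four-tier
    category grouping; samples with neither are excluded with a logged
    count.
    """
    unimp, imp = [], []
    n_excluded = 0
    for i, s in enumerate(test):
        if s.bap is not None:
            impaired = s.bap <= impaired_cut
        else:
            cat = s.resolved_category()
            if cat is None:
                n_excluded += 1
                continue
            impaired = cat.impaired
        (imp if impaired else unimp).append(i)
    if n_excluded:
        logger.warning("excluded %d samples lacking BAP and category", n_excluded)
    return unimp, imp


def _sweep(scores: Sequence[float], thresholds: Sequence[float],
           target_idx: list[int], opposing_idx: list[int], n_total: int,
           metric: str, direction: str) -> SweepTable:
    if not target_idx:
        raise ValueError(f"no truly-{direction} samples in the test set")
    if not opposing_idx:
        raise ValueError(f"no opposing-truth samples for the {direction} sweep")
    rows = []
    for thr in thresholds:
        n_match = sum(1 for i in target_idx if scores[i] >= thr)
        n_err = sum(1 for i in opposing_idx if scores[i] >= thr)
        rows.append(SweepRow(thr, 100.0 * n_match / len(target_idx),
                             100.0 * n_err / n_total))
    table = SweepTable(metric, direction, rows, len(target_idx), n_total)
    # nested trigger sets make both columns non-increasing; guard anyway
    assert all(a.matching_percent >= b.matching_percent
               and a.type1_percent >= b.type1_percent
               for a, b in zip(rows, rows[1:]))
    logger.info("%s/%s sweep: n_target=%d n_total=%d", metric, direction,
                len(target_idx), n_total)
    return table


def sweep_ptit(test: Sequence[SampleRecord], registry: IndicatorRegistry,
               config: EvaluationConfig | None = None,
               ) -> dict[str, SweepTable]:
    """PTIT threshold sweep; returns one table per target direction."""
    config = config or EvaluationConfig()
    unimp_idx, imp_idx = _truth_classes(test, config.impaired_cut)
    n_total = len(unimp_idx) + len(imp_idx)
    counts = [count_indicators(s.taxa, registry) for s in test]
    n_unimp_ind = [c[0] for c in counts]
    n_imp_ind = [c[1] for c in counts]
    return {
        "unimpaired": _sweep(n_unimp_ind, config.ptit_thresholds, unimp_idx,
                             imp_idx, n_total, "ptit", "unimpaired"),
        "impaired": _sweep(n_imp_ind, config.ptit_thresholds, imp_idx,
                           unimp_idx, n_total, "ptit", "impaired"),
    }


def sweep_tpi(test: Sequence[SampleRecord], freq: FrequencyTable,
              priors: CategoryPriors, registry: IndicatorRegistry,
              config: EvaluationConfig | None = None,
              ) -> dict[str, SweepTable]:
    """TPI threshold sweep on the posterior components; undefined
    posteriors never trigger a call."""
    config = config or EvaluationConfig()
    unimp_idx, imp_idx = _truth_classes(test, config.impaired_cut)
    n_total = len(unimp_idx) + len(imp_idx)
    results = assess_samples(test, registry, freq, priors,
                             smoothing=config.smoothing)
    p_ni = [r.posterior.p_nonimpacted if r.posterior.defined else -1.0
            for r in results]
    p_im = [r.posterior.p_impaired if r.posterior.defined else -1.0
            for r in results]
    return {
        "unimpaired": _sweep(p_ni, config.tpi_thresholds, unimp_idx, imp_idx,
                             n_total, "tpi", "unimpaired"),
        "impaired": _sweep(p_im, config.tpi_thresholds, imp_idx, unimp_idx,
                           n_total, "tpi", "impaired"),
    }


def rank_by_impairment(results: Sequence[AssessmentResult],
                       ) -> list[AssessmentResult]:
    """Order samples for follow-up investigation.

    Descending probability of impairment; ties broken by the impaired
    indicator count (descending) then sample id (ascending).  Undefined
    posteriors sort last.
    """
    def key(r: AssessmentResult):
        undefined = not r.posterior.defined
        p = r.posterior.p_impaired if r.posterior.defined else 0.0
        return (undefined, -p, -r.n_impaired_indicators, r.sample_id)

    return sorted(results, key=key)


@dataclass(frozen=True)
class TrendSummary:
    mean_matching_decrease: float
    max_type1_ratio: float | None  # None when no successive ratio is defined


def trend_summary(table: SweepTable) -> TrendSummary:
    """Per-step trend of a sweep: the mean decrease in matching percentage
    between successive thresholds, and the largest ratio by which the
    type-1 percentage fails to shrink (successive value over previous;
    steps with a zero previous value are excluded)."""
    if len(table.rows) < 2:
        raise ValueError("trend summary requires at least 2 sweep rows")
    matching = table.matching()
    type1 = table.type1()
    decreases = [a - b for a, b in zip(matching, matching[1:])]
    ratios = [b / a for a, b in zip(type1, type1[1:]) if a > 0]
    return TrendSummary(sum(decreases) / len(decreases),
                        max(ratios) if ratios else None)
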