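"""Indicator selection and class-conditional frequency estimation.

Training samples are 100-organism kick-sample subsamples labelled with a
Biological Assessment Profile (BAP) score on a 0-10 scale, banded into four
impact categories.  Indicator taxa are chosen by contrasting occurrence
frequencies between the non-impacted and impaired pools, with a
Sørensen-contribution screen that rejects taxa contributing materially to
within-category community similarity of the *opposing* condition.  The
selected indicators and their per-category occurrence frequencies are the
parameters of the presence-only assessment metrics.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .taxonomy import (IndicatorRegistry, WaveTaxon, _norm,
                       _packaged_dictionary)

logger = logging.getLogger(__name__)

#: Pooled classes used for frequencies and priors; moderate and severe
#: impacts are combined because severely impacted samples are scarce.
FREQ_CLASSES = ("non", "slight", "impaired")


class ConditionCategory(str, Enum):
    """Four-tier impact category from the BAP score."""

    NON = "non"
    SLIGHT = "slight"
    MODERATE = "moderate"
    SEVERE = "severe"

    @property
    def impaired(self) -> bool:
        return self in (ConditionCategory.MODERATE, ConditionCategory.SEVERE)

    @property
    def pooled(self) -> str:
        """The pooled frequency class (moderate + severe -> impaired)."""
        return "impaired" if self.impaired else self.value


def assign_category(bap: float) -> ConditionCategory:
    """Band a BAP score into the four-tier impact category.

    non: 7.5-10, slight: 5.0-7.5, moderate: 2.5-5.0, severe: 0-2.5.
    Boundary scores resolve upward (7.5 -> non, 5.0 -> slight, 2.5 ->
    severe); note that the two-way impaired/unimpaired grouping cuts at
    BAP <= 5, so a score of exactly 5.0 is "slight" in the four-tier
    banding yet grouped as impaired.
    """
    if not 0.0 <= bap <= 10.0:
        raise ValueError(f"BAP score {bap} outside [0, 10]")
    if bap >= 7.5:
        return ConditionCategory.NON
    if bap >= 5.0:
        return ConditionCategory.SLIGHT
    if bap > 2.5:
        return ConditionCategory.MODERATE
    return ConditionCategory.SEVERE


@dataclass(frozen=True)
class SampleRecord:
    """One field sample: its taxa at WAVE resolution plus truth labels."""

    sample_id: str
    taxa: frozenset[str]
    bap: float | None = None
    category: ConditionCategory | None = None

    def __post_init__(self) -> None:
        if self.bap is not None and not 0.0 <= self.bap <= 10.0:
            raise ValueError(f"sample {self.sample_id}: BAP {self.bap} outside [0, 10]")
        object.__setattr__(self, "taxa", frozenset(self.taxa))

    def resolved_category(self) -> ConditionCategory | None:
        if self.category is not None:
            return self.category
        if self.bap is not None:
            return assign_category(self.bap)
        return None

    def is_impaired(self) -> bool | None:
        """Two-way truth grouping: BAP <= 5 is impaired when a score is
        available, otherwise moderate/severe categories count as impaired."""
        if self.bap is not None:
            return self.bap <= 5.0
        if self.category is not None:
            return self.category.impaired
        return None


@dataclass
class CategoryPriors:
    """Overall proportions of the three pooled condition classes."""

    p_non: float
    p_slight: float
    p_impaired: float

    def __post_init__(self) -> None:
        vals = (self.p_non, self.p_slight, self.p_impaired)
        if any(v < 0 for v in vals):
            raise ValueError("priors must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"priors sum to {sum(vals)}, expected 1")

    @classmethod
    def from_counts(cls, n_non: int, n_slight: int, n_impaired: int) -> "CategoryPriors":
        total = n_non + n_slight + n_impaired
        if total == 0:
            raise ValueError("no samples to derive priors from")
        return cls(n_non / total, n_slight / total, n_impaired / total)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_non, self.p_slight, self.p_impaired)


@dataclass
class FrequencyTable:
    """Per-taxon occurrence frequencies in each pooled condition class.

    Keys are WAVE taxon labels; values are (f_non, f_slight, f_impaired),
    each the proportion of samples of that class containing the taxon.
    """

    _data: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    _labels: dict[str, str] = field(default_factory=dict)

    def set(self, label: str, freqs: tuple[float, float, float]) -> None:
        if not all(0.0 <= f <= 1.0 for f in freqs):
            raise ValueError(f"frequencies for {label!r} outside [0, 1]: {freqs}")
        key = _norm(label)
        self._data[key] = tuple(float(f) for f in freqs)
        self._labels[key] = label

    def freq(self, label: str) -> tuple[float, float, float]:
        return self._data[_norm(label)]

    def __contains__(self, label: str) -> bool:
        return _norm(label) in self._data

    def __len__(self) -> int:
        return len(self._data)

    def labels(self) -> list[str]:
        return list(self._labels.values())

    @classmethod
    def from_registry(cls, registry: IndicatorRegistry) -> "FrequencyTable":
        """Build from a registry whose entries carry frequencies."""
        table = cls()
        for entry in registry.entries.values():
            if entry.frequencies is None:
                raise ValueError(f"registry entry {entry.taxon.label!r} has no frequencies")
            table.set(entry.taxon.label, entry.frequencies)
        return table

    def to_frame(self, registry: IndicatorRegistry | None = None) -> pd.DataFrame:
        rows = []
        for key, label in self._labels.items():
            f = self._data[key]
            row = {"taxon": label, "freq_non": f[0], "freq_slight": f[1],
                   "freq_impaired": f[2]}
            if registry is not None:
                row["direction"] = registry.direction(label)
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path: str | Path, registry: IndicatorRegistry | None = None) -> None:
        path = Path(path)
        frame = self.to_frame(registry)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(frame.to_dict(orient="records"),
                                       indent=2, default=float),
                            encoding="utf-8")
        else:
            frame.to_csv(path, index=False)


def sorensen_index(a: Iterable[str], b: Iterable[str]) -> float:
    """Sørensen presence/absence similarity 2C/(A+B).

    C is the number of shared taxa, A and B the per-sample taxa counts.
    Defined as 0 when both sets are empty.
    """
    a, b = set(a), set(b)
    denom = len(a) + len(b)
    if denom == 0:
        return 0.0
    return 2.0 * len(a & b) / denom


def _presence_matrix(samples: Sequence[SampleRecord]) -> tuple[np.ndarray, list[str]]:
    labels = sorted({t for s in samples for t in s.taxa})
    index = {t: j for j, t in enumerate(labels)}
    mat = np.zeros((len(samples), len(labels)), dtype=float)
    for i, s in enumerate(samples):
        for t in s.taxa:
            mat[i, index[t]] = 1.0
    return mat, labels


def taxon_contributions(samples: Sequence[SampleRecord]) -> dict[str, float]:
    """Per-taxon share of the within-category Sørensen similarity.

    Over all sample pairs (i, j) the summed Sørensen numerator is
    sum_pairs 2|a∩b|/(|a|+|b|); taxon t's contribution is the part of that
    sum due to pairs in which t occurs in both samples,

        c_t = [sum over pairs with t in both of 2/(|a|+|b|)] / total,

    so contributions sum to 1 whenever any pair shares a taxon.  When no
    pair shares any taxon all contributions are reported as 0 with a
    warning.  Quadratic in the number of samples, computed as dense matrix
    products.
    """
    if len(samples) < 2:
        raise ValueError("taxon_contributions requires at least 2 samples")
    mat, labels = _presence_matrix(samples)
    if not labels:
        warnings.warn("no taxa present in any sample; contributions are all 0",
                      stacklevel=2)
        return {}
    sizes = mat.sum(axis=1)
    pair_sizes = sizes[:, None] + sizes[None, :]
    with np.errstate(divide="ignore"):
        weights = np.where(pair_sizes > 0, 2.0 / np.where(pair_sizes > 0, pair_sizes, 1.0), 0.0)
    np.fill_diagonal(weights, 0.0)
    # sum over unordered pairs with t in both = 0.5 * m_t' W m_t
    per_taxon = 0.5 * np.einsum("it,ij,jt->t", mat, weights, mat, optimize=True)
    total = per_taxon.sum()
    if total <= 0.0:
        warnings.warn("no sample pair shares a taxon; contributions are all 0",
                      stacklevel=2)
        return {t: 0.0 for t in labels}
    return {t: float(c / total) for t, c in zip(labels, per_taxon)}


def occurrence_frequency(samples: Sequence[SampleRecord]) -> dict[str, float]:
    """Proportion of samples containing each taxon."""
    n = len(samples)
    counts: dict[str, int] = {}
    for s in samples:
        for t in s.taxa:
            counts[t] = counts.get(t, 0) + 1
    return {t: c / n for t, c in counts.items()}


def _taxon_rank(label: str) -> str:
    hit = _packaged_dictionary().lookup(label)
    return hit.rank if hit is not None else "family"


def select_indicators(training: Sequence[SampleRecord],
                      contribution_cutoff: float = 0.02) -> IndicatorRegistry:
    """Select indicator taxa from a categorized training set.

    The unimpaired reference pool is the non-impacted samples only (sharper
    contrast than pooling with slightly-impacted); the impaired pool is the
    moderately plus severely impacted samples.  A taxon indicates
    unimpaired condition when its occurrence frequency in the non-impacted
    pool exceeds its frequency in the impaired pool AND it contributes less
    than ``contribution_cutoff`` (default 2%) to the Sørensen similarity of
    the impaired pool; impaired indicators are the mirror image.  The two
    frequency conditions are strict inequalities in opposite directions, so
    no taxon can qualify for both directions.
    """
    pools: dict[str, list[SampleRecord]] = {"non": [], "impaired": []}
    for s in training:
        cat = s.resolved_category()
        if cat is None:
            continue
        if cat is ConditionCategory.NON:
            pools["non"].append(s)
        elif cat.impaired:
            pools["impaired"].append(s)
    for name, pool in pools.items():
        if len(pool) < 2:
            raise ValueError(f"{name} pool has {len(pool)} samples; need at least 2")

    freq_non = occurrence_frequency(pools["non"])
    freq_imp = occurrence_frequency(pools["impaired"])
    contrib_non = taxon_contributions(pools["non"])
    contrib_imp = taxon_contributions(pools["impaired"])

    registry = IndicatorRegistry()
    for label in sorted(set(freq_non) | set(freq_imp)):
        f_n = freq_non.get(label, 0.0)
        f_i = freq_imp.get(label, 0.0)
        if f_n > f_i and contrib_imp.get(label, 0.0) < contribution_cutoff:
            registry.add(WaveTaxon(label, _taxon_rank(label)), "unimpaired")
        elif f_i > f_n and contrib_non.get(label, 0.0) < contribution_cutoff:
            registry.add(WaveTaxon(label, _taxon_rank(label)), "impaired")
    logger.info("selected %d unimpaired and %d impaired indicators",
                registry.n_unimpaired, registry.n_impaired)
    return registry


def estimate_frequencies(training: Sequence[SampleRecord],
                         registry: IndicatorRegistry,
                         ) -> tuple[FrequencyTable, CategoryPriors]:
    """Class-conditional occurrence frequencies and category priors.

    Frequency of a taxon in a class is the number of samples of that class
    containing it divided by the class size; moderate and severe samples
    are pooled as "impaired".  Frequencies are kept exact, including zeros
    (smoothing, if wanted, is applied at assessment time).  Priors are the
    class proportions of the training set.
    """
    by_class: dict[str, list[SampleRecord]] = {c: [] for c in FREQ_CLASSES}
    n_unlabelled = 0
    for s in training:
        cat = s.resolved_category()
        if cat is None:
            n_unlabelled += 1
            continue
        by_class[cat.pooled].append(s)
    if n_unlabelled:
        raise ValueError(f"{n_unlabelled} training samples lack a category or BAP score")
    for name, pool in by_class.items():
        if not pool:
            raise ValueError(f"no training samples in category {name!r}")

    class_freqs = {c: occurrence_frequency(by_class[c]) for c in FREQ_CLASSES}
    table = FrequencyTable()
    for label in registry.labels():
        table.set(label, tuple(class_freqs[c].get(label, 0.0) for c in FREQ_CLASSES))
    priors = CategoryPriors.from_counts(*(len(by_class[c]) for c in FREQ_CLASSES))
    return table, priors


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.175 -> 0.18 at 2 decimals)."""
    q = Decimal(1).scaleb(-decimals)
    # damp float representation noise (0.085 stored as 0.08499999...)
    return float(Decimal(repr(round(x, decimals + 8))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_frequencies(table: FrequencyTable, registry: IndicatorRegistry,
                          decimals: int | None = 2,
                          ) -> dict[str, dict[str, dict[str, float]]]:
    """Median and quartiles of each direction's frequencies per class.

    Quantiles use linear interpolation of the order statistics at position
    h = (n-1)p + 1; results are rounded half-up to ``decimals`` (None keeps
    raw floats).  Returns {direction: {class: {median, q25, q75, n}}};
    directions with no registry taxa are omitted with a warning.
    """
    out: dict[str, dict[str, dict[str, float]]] = {}
    for direction in ("unimpaired", "impaired"):
        labels = [l for l in registry.labels(direction) if l in table]
        if not labels:
            warnings.warn(f"no frequencies for direction {direction!r}; omitted",
                          stacklevel=2)
            continue
        cols = np.array([table.freq(l) for l in labels], dtype=float)
        out[direction] = {}
        for j, cls in enumerate(FREQ_CLASSES):
            med, q25, q75 = (float(np.percentile(cols[:, j], p, method="linear"))
                             for p in (50, 25, 75))
            if decimals is not None:
                med, q25, q75 = (round_half_up(v, decimals) for v in (med, q25, q75))
            out[direction][cls] = {"median": med, "q25": q25, "q75": q75,
                                   "n": len(labels)}
    return out
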