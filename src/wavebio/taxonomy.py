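"""Taxonomic normalization to WAVE field resolution and the indicator registry.

The WAVE citizen-science protocol identifies benthic macroinvertebrates at
the coarsest resolution a trained volunteer can manage in the field: family
level, with five exceptions that are hard to tell apart without a
microscope.  Pelecypoda (clams/mussels), Hirudinea (leeches) and Turbellaria
(flatworms) aggregate at class, Amphipoda (scuds) at order, and the
red-colored midge genus *Chironomus* is kept at genus while the rest of
Chironomidae stays at family.

The indicator registry holds the taxa used by the presence-only metrics,
each tagged with the biological condition it indicates (unimpaired or
impaired) and optionally its class-conditional occurrence frequencies.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("class", "subclass", "order", "family", "genus", "species")

#: Clades aggregated above family rank, and the one genus kept below it.
CLASS_EXCEPTIONS = {"pelecypoda": "Pelecypoda",
                    "hirudinea": "Hirudinea",
                    "hirudinae": "Hirudinea",  # variant spelling
                    "turbellaria": "Turbellaria"}
ORDER_EXCEPTIONS = {"amphipoda": "Amphipoda"}
GENUS_EXCEPTIONS = {"chironomus": "Chironomus"}

DIRECTIONS = ("unimpaired", "impaired")


def _norm(name: str) -> str:
    return " ".join(name.split()).casefold()


@dataclass(frozen=True)
class TaxonIdentity:
    """A taxonomic identification as recorded in a sample table.

    Parameters
    ----------
    rank : str
        One of class/subclass/order/family/genus/species.
    name : str
        Taxon name at that rank.
    lineage : mapping, optional
        Names of ancestor ranks, e.g. ``{"family": "Chironomidae",
        "order": "Diptera"}``.
    """

    rank: str
    name: str
    lineage: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unrecognized rank {self.rank!r}; expected one of {RANKS}")
        if not self.name or not self.name.strip():
            raise ValueError("taxon name must be non-empty")

    def name_at(self, rank: str) -> str | None:
        if self.rank == rank:
            return self.name
        if self.lineage:
            for key, value in self.lineage.items():
                if key == rank:
                    return value
        return None


@dataclass(frozen=True)
class WaveTaxon:
    """A taxon label at WAVE field resolution.

    ``recognized`` is False when the input identity could not be resolved to
    a family or exception clade; such taxa are reported, never silently
    dropped.
    """

    label: str
    rank: str = "family"
    recognized: bool = True

    def __str__(self) -> str:
        return self.label


class TaxonDictionary:
    """Maps taxon names (any rank) to their WAVE aggregation label.

    Covers the indicator taxa plus common member families/genera of the five
    exception clades; anything else passes through at family rank when a
    family name is available.
    """

    def __init__(self, rows: Iterable[tuple[str, str, str, str]]):
        self._map: dict[str, WaveTaxon] = {}
        for name, rank, wave_label, wave_rank in rows:
            self._map[_norm(name)] = WaveTaxon(wave_label, wave_rank)

    def lookup(self, name: str) -> WaveTaxon | None:
        return self._map.get(_norm(name))

    @classmethod
    def packaged(cls) -> "TaxonDictionary":
        path = resources.files("wavebio.data").joinpath("taxon_dictionary.csv")
        with path.open("r", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            return cls((r["name"], r["rank"], r["wave_label"], r["wave_rank"])
                       for r in reader)

    def n_aggregation_exceptions(self) -> int:
        """Number of distinct WAVE labels aggregated at non-family rank."""
        return len({t.label for t in self._map.values() if t.rank != "family"})


_PACKAGED_DICT: TaxonDictionary | None = None


def _packaged_dictionary() -> TaxonDictionary:
    global _PACKAGED_DICT
    if _PACKAGED_DICT is None:
        _PACKAGED_DICT = TaxonDictionary.packaged()
    return _PACKAGED_DICT


def reduce_to_wave_resolution(identity: TaxonIdentity,
                              dictionary: TaxonDictionary | None = None) -> WaveTaxon:
    """Collapse a taxonomic identification to the WAVE field resolution.

    Family level, except members of Pelecypoda, Hirudinea and Turbellaria
    (class), Amphipoda (order) and the genus *Chironomus* (genus).  Matching
    is case-insensitive and whitespace-trimmed; no fuzzy matching.  An
    identity with no resolvable family and no dictionary match returns an
    unrecognized-flagged taxon rather than raising.
    """
    if dictionary is None:
        dictionary = _packaged_dictionary()

    genus = identity.name_at("genus")
    if genus is not None and _norm(genus) in GENUS_EXCEPTIONS:
        return WaveTaxon(GENUS_EXCEPTIONS[_norm(genus)], "genus")

    for rank in ("class", "subclass"):
        name = identity.name_at(rank)
        if name is not None and _norm(name) in CLASS_EXCEPTIONS:
            return WaveTaxon(CLASS_EXCEPTIONS[_norm(name)], "class")

    order = identity.name_at("order")
    if order is not None and _norm(order) in ORDER_EXCEPTIONS:
        return WaveTaxon(ORDER_EXCEPTIONS[_norm(order)], "order")

    # Dictionary lookup resolves exception-clade members given without
    # lineage (e.g. "Gammaridae" alone -> Amphipoda).
    hit = dictionary.lookup(identity.name)
    if hit is not None:
        return hit

    family = identity.name_at("family")
    if family is not None:
        return WaveTaxon(family.strip(), "family")

    return WaveTaxon(identity.name.strip(), identity.rank, recognized=False)


@dataclass
class IndicatorEntry:
    taxon: WaveTaxon
    direction: str  # "unimpaired" | "impaired"
    frequencies: tuple[float, float, float] | None = None  # (non, slight, impaired)


@dataclass
class IndicatorRegistry:
    """The selected indicator taxa keyed by WAVE label.

    Each taxon carries exactly one direction: the biological condition whose
    presence it indicates.
    """

    entries: dict[str, IndicatorEntry] = field(default_factory=dict)

    def add(self, taxon: WaveTaxon, direction: str,
            frequencies: tuple[float, float, float] | None = None) -> None:
        if direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
        key = _norm(taxon.label)
        if key in self.entries and self.entries[key].direction != direction:
            raise ValueError(
                f"taxon {taxon.label!r} already registered with direction "
                f"{self.entries[key].direction!r}; refusing conflicting {direction!r}")
        self.entries[key] = IndicatorEntry(taxon, direction, frequencies)

    def direction(self, label: str) -> str | None:
        entry = self.entries.get(_norm(label))
        return entry.direction if entry else None

    def __contains__(self, label: str) -> bool:
        return _norm(label) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self, direction: str | None = None) -> list[str]:
        return [e.taxon.label for e in self.entries.values()
                if direction is None or e.direction == direction]

    @property
    def n_unimpaired(self) -> int:
        return len(self.labels("unimpaired"))

    @property
    def n_impaired(self) -> int:
        return len(self.labels("impaired"))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries.values():
            f = e.frequencies or (None, None, None)
            rows.append({"taxon": e.taxon.label, "rank": e.taxon.rank,
                         "direction": e.direction, "freq_non": f[0],
                         "freq_slight": f[1], "freq_impaired": f[2]})
        return pd.DataFrame(rows, columns=["taxon", "rank", "direction",
                                           "freq_non", "freq_slight", "freq_impaired"])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        frame = self.to_frame()
        if path.suffix.lower() == ".json":
            # stdlib json keeps shortest-repr floats, so values round-trip
            path.write_text(json.dumps(frame.to_dict(orient="records"),
                                       indent=2, default=float),
                            encoding="utf-8")
        else:
            frame.to_csv(path, index=False)


def load_indicator_registry(source: str | Path | pd.DataFrame) -> IndicatorRegistry:
    """Load an indicator registry from CSV/JSON (or a pre-read DataFrame).

    Expected columns: taxon, rank, direction, and optionally freq_non,
    freq_slight, freq_impaired.  Duplicate taxa with conflicting directions
    and malformed rows raise with the offending row named.
    """
    if isinstance(source, pd.DataFrame):
        frame = source
    else:
        path = Path(source)
        if path.suffix.lower() == ".json":
            # stdlib json parses floats exactly (read_json's parser is lossy)
            frame = pd.DataFrame(json.loads(path.read_text(encoding="utf-8")))
        else:
            frame = pd.read_csv(path)
    if frame.empty:
        warnings.warn("indicator registry source is empty", stacklevel=2)
        return IndicatorRegistry()

    required = {"taxon", "rank", "direction"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"registry source missing columns: {sorted(missing)}")

    registry = IndicatorRegistry()
    has_freq = {"freq_non", "freq_slight", "freq_impaired"} <= set(frame.columns)
    for i, row in frame.iterrows():
        taxon, rank, direction = row["taxon"], row["rank"], row["direction"]
        if pd.isna(taxon) or pd.isna(direction) or direction not in DIRECTIONS:
            raise ValueError(f"malformed registry row {i}: {row.to_dict()}")
        freqs = None
        if has_freq:
            freqs = (float(row["freq_non"]), float(row["freq_slight"]),
                     float(row["freq_impaired"]))
            if not all(0.0 <= f <= 1.0 for f in freqs):
                raise ValueError(f"registry row {i} has frequency outside [0, 1]")
        registry.add(WaveTaxon(str(taxon).strip(), str(rank)), str(direction), freqs)
    logger.info("loaded indicator registry: %d unimpaired, %d impaired",
                registry.n_unimpaired, registry.n_impaired)
    return registry


def load_packaged_registry() -> IndicatorRegistry:
    """The indicator registry shipped with the package (32 unimpaired-
    and 16 impaired-condition indicators with their New York frequencies)."""
    path = resources.files("wavebio.data").joinpath("indicator_table.csv")
    with resources.as_file(path) as p:
        return load_indicator_registry(p)
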