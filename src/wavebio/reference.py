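"""Packaged New York reference parameters.

The indicator table ships the 48 indicator taxa (32 unimpaired, 16
impaired) with their occurrence frequencies in non-impacted, slightly
impacted and impaired training samples; the priors file records the
training-set composition (406 non-impacted, 728 slightly impacted, 287
impaired samples).  The method is regional by construction — users in
other regions substitute their own table through the same loaders.
"""

from __future__ import annotations

import json
from importlib import resources

from .taxonomy import IndicatorRegistry, load_packaged_registry
from .training import CategoryPriors, FrequencyTable

__all__ = ["load_packaged_registry", "load_packaged_frequencies",
           "load_packaged_priors", "packaged_training_counts"]


def packaged_training_counts() -> tuple[int, int, int]:
    """(n_non, n_slight, n_impaired) of the reference training set."""
    path = resources.files("wavebio.data").joinpath("training_priors.json")
    counts = json.loads(path.read_text(encoding="utf-8"))
    return counts["n_non"], counts["n_slight"], counts["n_impaired"]


def load_packaged_priors() -> CategoryPriors:
    return CategoryPriors.from_counts(*packaged_training_counts())


def load_packaged_frequencies() -> FrequencyTable:
    return FrequencyTable.from_registry(load_packaged_registry())
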