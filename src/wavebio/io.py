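"""Reading sample tables and writing reports.

Sample input is long-format delimited text, one row per (sample, taxon)
observation with columns ``sample_id, taxon, rank[, count]`` (counts are
accepted and ignored — the metrics are presence-only), plus an optional
per-sample metadata table ``sample_id, bap[, category]``.  Taxa are
normalized to WAVE resolution on read and deduplicated to sets;
unrecognized identifications are kept, flagged and counted, never silently
dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .assessment import AssessmentResult
from .evaluation import SweepTable
from .taxonomy import TaxonDictionary, TaxonIdentity, reduce_to_wave_resolution
from .training import (CategoryPriors, ConditionCategory, FrequencyTable,
                       SampleRecord)

logger = logging.getLogger(__name__)


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", encoding="utf-8")


def read_samples(path: str | Path, metadata_path: str | Path | None = None,
                 dictionary: TaxonDictionary | None = None,
                 ) -> list[SampleRecord]:
    """Read a long-format sample table (and optional metadata) into records."""
    frame = _read_table(path)
    required = {"sample_id", "taxon", "rank"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"sample table missing required columns: {sorted(missing)}")

    meta: dict[str, tuple[float | None, ConditionCategory | None]] = {}
    if metadata_path is not None:
        mframe = _read_table(metadata_path)
        if "sample_id" not in mframe.columns:
            raise ValueError("metadata table missing required column: ['sample_id']")
        for _, row in mframe.iterrows():
            bap = float(row["bap"]) if "bap" in mframe.columns and pd.notna(row.get("bap")) else None
            cat = None
            if "category" in mframe.columns and pd.notna(row.get("category")):
                cat = ConditionCategory(str(row["category"]).strip().lower())
            meta[str(row["sample_id"])] = (bap, cat)

    taxa_by_sample: dict[str, set[str]] = {}
    n_unrecognized: dict[str, int] = {}
    for i, row in frame.iterrows():
        if pd.isna(row["sample_id"]) or pd.isna(row["taxon"]) or pd.isna(row["rank"]):
            raise ValueError(f"sample table row {i} has missing values: {row.to_dict()}")
        identity = TaxonIdentity(str(row["rank"]).strip().lower(),
                                 str(row["taxon"]).strip())
        taxon = reduce_to_wave_resolution(identity, dictionary)
        if not taxon.recognized:
            n_unrecognized[taxon.label] = n_unrecognized.get(taxon.label, 0) + 1
        taxa_by_sample.setdefault(str(row["sample_id"]), set()).add(taxon.label)
    if n_unrecognized:
        logger.warning("unrecognized taxa kept and flagged: %s", n_unrecognized)

    if metadata_path is not None:
        orphans = sorted(set(meta) - set(taxa_by_sample))
        if orphans:
            raise ValueError(f"metadata references unknown sample ids: {orphans}")

    if frame.empty:
        logger.warning("sample table %s has a header but no rows", path)
    samples = []
    for sid, taxa in taxa_by_sample.items():
        bap, cat = meta.get(sid, (None, None))
        samples.append(SampleRecord(sid, frozenset(taxa), bap=bap, category=cat))
    return samples


def write_samples(samples: Sequence[SampleRecord], out_dir: str | Path,
                  ) -> tuple[Path, Path]:
    """Write records back to the long-format schema (samples + metadata)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [{"sample_id": s.sample_id, "taxon": t, "rank": "family"}
            for s in samples for t in sorted(s.taxa)]
    samples_path = out_dir / "samples.csv"
    pd.DataFrame(rows, columns=["sample_id", "taxon", "rank"]).to_csv(
        samples_path, index=False)
    meta_rows = [{"sample_id": s.sample_id, "bap": s.bap,
                  "category": s.resolved_category().value
                  if s.resolved_category() else None}
                 for s in samples]
    meta_path = out_dir / "sample_metadata.csv"
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)
    return samples_path, meta_path


def load_frequency_table(path: str | Path) -> FrequencyTable:
    """Read a frequency table CSV/JSON (taxon, freq_non, freq_slight,
    freq_impaired; extra columns ignored)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        frame = pd.DataFrame(json.loads(path.read_text(encoding="utf-8")))
    else:
        frame = pd.read_csv(path)
    required = {"taxon", "freq_non", "freq_slight", "freq_impaired"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"frequency table missing columns: {sorted(missing)}")
    table = FrequencyTable()
    for _, row in frame.iterrows():
        table.set(str(row["taxon"]), (float(row["freq_non"]),
                                      float(row["freq_slight"]),
                                      float(row["freq_impaired"])))
    return table


def load_priors(path: str | Path) -> CategoryPriors:
    """Read priors from JSON, either counts (n_non, n_slight, n_impaired)
    or proportions (p_non, p_slight, p_impaired)."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if {"n_non", "n_slight", "n_impaired"} <= set(data):
        return CategoryPriors.from_counts(data["n_non"], data["n_slight"],
                                          data["n_impaired"])
    if {"p_non", "p_slight", "p_impaired"} <= set(data):
        return CategoryPriors(data["p_non"], data["p_slight"], data["p_impaired"])
    raise ValueError("priors JSON must give n_* counts or p_* proportions")


def results_frame(results: Sequence[AssessmentResult]) -> pd.DataFrame:
    cols = ["sample_id", "n_unimpaired_indicators", "n_impaired_indicators",
            "ptit_call", "p_nonimpacted", "p_slight", "p_impaired",
            "tpi_call", "flags"]
    rows = [{"sample_id": r.sample_id,
             "n_unimpaired_indicators": r.n_unimpaired_indicators,
             "n_impaired_indicators": r.n_impaired_indicators,
             "ptit_call": r.ptit_call,
             "p_nonimpacted": r.posterior.p_nonimpacted,
             "p_slight": r.posterior.p_slight,
             "p_impaired": r.posterior.p_impaired,
             "tpi_call": r.tpi_call,
             "flags": ";".join(r.flags)} for r in results]
    return pd.DataFrame(rows, columns=cols)


def _run_metadata(config: dict | None, seed: int | None) -> dict:
    cfg = config or {}
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]
    return {"version": __version__, "seed": seed, "config_hash": digest,
            "config": cfg}


def write_report(results: Sequence[AssessmentResult], path: str | Path,
                 fmt: str = "csv", config: dict | None = None,
                 seed: int | None = None) -> None:
    """Write assessment results as CSV, or JSON with run metadata."""
    path = Path(path)
    frame = results_frame(results)
    if fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "json":
        payload = {"metadata": _run_metadata(config, seed),
                   "results": frame.to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def write_sweeps(tables: Sequence[SweepTable], path: str | Path,
                 rounded: bool = True) -> None:
    """Concatenate sweep tables to one CSV (matching to whole percent,
    type-1 to one decimal, mirroring the report convention)."""
    frame = pd.concat([t.to_frame(rounded=rounded) for t in tables],
                      ignore_index=True)
    frame.to_csv(Path(path), index=False)
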