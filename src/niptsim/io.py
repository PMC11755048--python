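"""Tab-separated I/O with schema validation, gestational-age parsing, the
packaged T21 clinical-case table, and YAML configuration loading.

All tables are plain TSV so every artifact in the pipeline (count matrices,
sample metadata, reference panels, call tables, LoD tables, fragment-length
lists) is diffable and round-trips exactly on values.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .caller import CallResult, ReadCountProfile, ReferencePanel
from .errors import ConfigurationError, SchemaError
from .genome import CHROMOSOMES
from .mixture import LoDBinResult, LoDTable
from .synthetic import (
    CohortParams,
    FFLaw,
    FFLawStratum,
    SampleRecord,
    SequencingParams,
    TruncNormal,
)

__all__ = [
    "parse_gestational_age",
    "Table2Case",
    "load_table2",
    "read_count_matrix",
    "write_count_matrix",
    "read_metadata",
    "write_metadata",
    "read_panel",
    "write_panel",
    "write_calls",
    "read_lengths",
    "write_lengths",
    "write_lod_table",
    "read_lod_table",
    "load_config",
]

METADATA_COLUMNS = (
    "sample_id",
    "ff",
    "gestational_age_weeks",
    "maternal_age_years",
    "maternal_weight_kg",
    "fetal_sex",
    "karyotype",
    "twin",
)


def parse_gestational_age(text: str | float) -> float:
    """Parse gestational age to decimal weeks.

    Accepts clinical "weeks+days" notation ("17+3" -> 17 + 3/7), plain
    integers, or decimal weeks.
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = text.strip()
    if "+" in s:
        weeks_s, days_s = s.split("+", 1)
        weeks, days = int(weeks_s), int(days_s)
        if not 0 <= days <= 6:
            raise SchemaError(f"gestational-age days must be 0-6, got {days} in {text!r}")
        return weeks + days / 7.0
    return float(s)


@dataclass(frozen=True)
class Table2Case:
    """One clinically confirmed T21 screening case (z and FF as reported)."""

    status: str  # true_positive / false_positive / false_negative
    case_index: int
    age_years: float
    ga_label: str
    ga_weeks: float
    z_chr21: float
    ff_pct: float


def load_table2() -> list[Table2Case]:
    """The packaged table of 17 T21 screening cases: 14 true positives, 2
    false positives, and 1 false negative, each with chr21 z and FF."""
    with importlib.resources.files("niptsim.data").joinpath("table2_t21.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t", dtype=str)
    cases = [
        Table2Case(
            status=row.status,
            case_index=int(row.case_index),
            age_years=float(row.age_years),
            ga_label=row.gestational_age,
            ga_weeks=parse_gestational_age(row.gestational_age),
            z_chr21=float(row.z_chr21),
            ff_pct=float(row.ff_pct),
        )
        for row in frame.itertuples()
    ]
    counts = pd.Series([c.status for c in cases]).value_counts()
    assert counts["true_positive"] == 14 and counts["false_positive"] == 2
    return cases


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


# --- count matrices ---------------------------------------------------------


def write_count_matrix(profiles: Sequence[ReadCountProfile], path: str | Path) -> None:
    chroms = profiles[0].chromosomes if profiles else CHROMOSOMES
    frame = pd.DataFrame(
        [{"sample_id": p.sample_id, **{c: p.counts[c] for c in chroms}} for p in profiles]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_count_matrix(
    path: str | Path, chromosomes: Sequence[str] = CHROMOSOMES
) -> list[ReadCountProfile]:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, ("sample_id", *chromosomes), "count matrix")
    return [
        ReadCountProfile(
            sample_id=str(row["sample_id"]),
            counts={c: int(row[c]) for c in chromosomes},
        )
        for _, row in frame.iterrows()
    ]


# --- sample metadata --------------------------------------------------------


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    frame = pd.DataFrame([{c: getattr(r, c) for c in METADATA_COLUMNS} for r in records])
    frame.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[SampleRecord]:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, METADATA_COLUMNS, "metadata table")
    return [
        SampleRecord(
            sample_id=str(row.sample_id),
            ff=float(row.ff),
            gestational_age_weeks=float(row.gestational_age_weeks),
            maternal_age_years=float(row.maternal_age_years),
            maternal_weight_kg=float(row.maternal_weight_kg),
            fetal_sex=str(row.fetal_sex),
            karyotype=str(row.karyotype),
            twin=bool(row.twin),
        )
        for row in frame.itertuples()
    ]


# --- reference panels -------------------------------------------------------


def write_panel(panel: ReferencePanel, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "chrom": list(panel.mu),
            "mu": [panel.mu[c] for c in panel.mu],
            "sigma": [panel.sigma[c] for c in panel.mu],
            "n": panel.n_reference,
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> ReferencePanel:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, ("chrom", "mu", "sigma", "n"), "panel table")
    return ReferencePanel(
        mu=dict(zip(frame["chrom"], frame["mu"].astype(float))),
        sigma=dict(zip(frame["chrom"], frame["sigma"].astype(float))),
        n_reference=int(frame["n"].iloc[0]),
    )


# --- calls ------------------------------------------------------------------


def write_calls(results: Sequence[CallResult], path: str | Path) -> None:
    rows = []
    for res in results:
        for chrom, z in res.z_values.items():
            rows.append(
                {
                    "sample_id": res.sample_id,
                    "chrom": chrom,
                    "z": z,
                    "call": res.calls.get(chrom, "no_call"),
                    "qc_status": res.qc_status,
                    "ff": res.ff if res.ff is not None else np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- fragment lengths -------------------------------------------------------


def write_lengths(lengths: Sequence[int] | np.ndarray, path: str | Path) -> None:
    Path(path).write_text("\n".join(str(int(v)) for v in lengths) + "\n")


def read_lengths(path: str | Path) -> np.ndarray:
    values = [int(line) for line in Path(path).read_text().split()]
    if not values:
        raise SchemaError(f"no fragment lengths found in {path}")
    return np.array(values, dtype=int)


# --- LoD tables -------------------------------------------------------------


def write_lod_table(table: LoDTable, path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "bin_lo": b.ff_lo,
                "bin_hi": b.ff_hi,
                "n": b.n_replicates,
                "detected": b.n_detected,
                "rate_pct": b.detection_rate_pct,
            }
            for b in table.bins
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_lod_table(path: str | Path) -> LoDTable:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, ("bin_lo", "bin_hi", "n", "detected"), "LoD table")
    return LoDTable(
        bins=tuple(
            LoDBinResult(
                ff_lo=float(r.bin_lo),
                ff_hi=float(r.bin_hi),
                n_replicates=int(r.n),
                n_detected=int(r.detected),
            )
            for r in frame.itertuples()
        )
    )


# --- configuration ----------------------------------------------------------


def load_config(path: str | Path) -> tuple[CohortParams, SequencingParams]:
    """Load simulation configuration from a YAML file.

    Top-level keys: ``cohort`` (n_samples, seed required; optional ff_law,
    weight_law, ga_law, age_law, male_fraction, twin_rate) and optional
    ``sequencing`` (any SequencingParams field). Laws are given as mappings,
    e.g. ``weight_law: {mean: 56.43, sd: 8, lo: 40, hi: 110}``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "cohort" not in raw:
        raise ConfigurationError("config must contain a 'cohort' section")
    cohort_raw = dict(raw["cohort"])
    if "seed" not in cohort_raw:
        raise ConfigurationError("config cohort section must set an explicit seed")

    for law_key in ("weight_law", "ga_law", "age_law"):
        if law_key in cohort_raw:
            cohort_raw[law_key] = TruncNormal(**cohort_raw[law_key])
    if "ff_law" in cohort_raw:
        ff_raw = dict(cohort_raw["ff_law"])
        if "strata" in ff_raw:
            ff_raw["strata"] = tuple(
                FFLawStratum(**stratum) for stratum in ff_raw["strata"]
            )
        cohort_raw["ff_law"] = FFLaw(**ff_raw)
    try:
        cohort = CohortParams(**cohort_raw)
    except TypeError as exc:
        raise ConfigurationError(f"bad cohort config: {exc}") from exc

    seq_raw = raw.get("sequencing", {})
    try:
        seq = SequencingParams(**seq_raw)
    except TypeError as exc:
        raise ConfigurationError(f"bad sequencing config: {exc}") from exc
    return cohort, seq
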