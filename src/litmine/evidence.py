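"""Summaries of curated antibacterial evidence tables.

An evidence table collects microdilution results from the literature: one
row per reported measurement of a plant extract against a bacterium, with
the plant species, plant part, extraction solvent, the bacterium as printed
(possibly strain-qualified, e.g. "S. aureus ATCC 25923"), the measured value
and a citation key.  Values are minimum inhibitory concentrations (MIC) in
mg/mL; a trailing ``#`` marks a MIC50 (concentration inhibiting 50% of
growth) and percent or percent-range entries (e.g. "0.25-0.5%") are carried
with ``unit="percent"`` and excluded from mg/mL means.

Two families of statistics are produced:

* **category shares** — the percentage of table rows per species, plant
  part, solvent or bacterium ("reports", i.e. row-weighted);
* **per-bacterium mean activity** — the arithmetic mean MIC in mg/mL over
  rows matching a normalized bacterial species.

Bacterium names are normalized by stripping strain designators (ATCC/DSM/
MSP/W numbers) and expanding genus abbreviations through a packaged
epithet-to-genus mapping ("S. aureus" -> "Staphylococcus aureus").
Resistance qualifiers ("Methicillin-resistant ...") are stripped for value
pooling but kept as distinct categories in the share tables, where they
denote clinically distinct report types.

A transcription of a published microdilution evidence table for Cistus
extracts ships with the package as ``data/cistus_mic_table.csv`` and is the
default input of the evidence pipeline.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from statistics import fmean
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityRecord",
    "EvidenceSummary",
    "load_activity_table",
    "write_activity_table",
    "packaged_table_path",
    "normalize_bacterium",
    "category_share",
    "mean_activity",
    "summarize",
]

_STRAIN_RE = re.compile(r"\b(?:ATCC|DSM|MSP)\s*\d+|\bW\d+\b")
_QUALIFIER_RE = re.compile(r"^(Methicillin-(?:resistant|sensitive))\s+", re.IGNORECASE)
_RANGE_RE = re.compile(r"^(\d+(?:\.\d+)?)\s*[-–]\s*(\d+(?:\.\d+)?)\s*%?$")
_PERCENT_RE = re.compile(r"^(\d+(?:\.\d+)?)\s*%$")

SHARE_FIELDS = ("species", "part", "solvent", "bacterium")


def _load_genus_map() -> dict[str, str]:
    text = resources.files("litmine.data").joinpath("genus_abbreviations.tsv").read_text()
    out = {}
    for line in text.splitlines():
        if line.strip():
            epithet, genus = line.split("\t")
            out[epithet.strip().lower()] = genus.strip()
    return out


_GENUS_MAP = _load_genus_map()


@dataclass(frozen=True)
class ActivityRecord:
    """One row of an antibacterial evidence table."""

    species: str
    part: str
    solvent: str
    bacterium_raw: str
    bacterium: str          # normalized "Genus species"
    value: float
    value_raw: str          # as printed, e.g. "0.0512 #" or "0.25-0.5%"
    unit: str               # "mg_per_mL" | "percent"
    measure: str            # "MIC" | "MIC50"
    reference: str

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("activity value must be positive")
        if self.unit not in ("mg_per_mL", "percent"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.measure not in ("MIC", "MIC50"):
            raise ValueError(f"unknown measure {self.measure!r}")


def normalize_bacterium(raw: str, keep_qualifiers: bool = False) -> str:
    """Canonical "Genus species" for a printed bacterium name.

    Strips strain designators (ATCC/DSM/MSP/W + digits) and, unless
    ``keep_qualifiers``, resistance qualifiers; expands a leading genus
    abbreviation via the packaged epithet-to-genus mapping.  Unmappable
    abbreviations are kept as printed with a warning.
    """
    if not raw or not raw.strip():
        raise ValueError("empty bacterium name")
    s = _STRAIN_RE.sub("", raw).strip()
    qualifier = ""
    m = _QUALIFIER_RE.match(s)
    if m:
        qualifier = m.group(1)
        s = s[m.end():]
    s = " ".join(s.split())
    parts = s.split()
    if len(parts) >= 2 and parts[0].endswith("."):
        genus = _GENUS_MAP.get(parts[1].lower())
        if genus is None:
            logger.warning("cannot expand genus abbreviation in %r; kept as printed", raw)
        else:
            s = " ".join([genus] + parts[1:])
    if keep_qualifiers and qualifier:
        s = f"{qualifier} {s}"
    return s


def _parse_value(text: str, row_number: int) -> tuple[float, str, str]:
    """(value, unit, measure) from a printed value cell."""
    v = text.strip()
    measure = "MIC"
    if v.endswith("#"):
        measure = "MIC50"
        v = v[:-1].strip()
    m = _RANGE_RE.match(v)
    if m and ("%" in v or "–" in v or "-" in v):
        lo, hi = float(m.group(1)), float(m.group(2))
        return (lo + hi) / 2.0, "percent", measure
    m = _PERCENT_RE.match(v)
    if m:
        return float(m.group(1)), "percent", measure
    try:
        return float(v), "mg_per_mL", measure
    except ValueError:
        raise ValueError(f"row {row_number}: cannot parse activity value {text!r}") from None


def packaged_table_path() -> Path:
    """Path of the packaged Cistus microdilution evidence table."""
    return Path(str(resources.files("litmine.data").joinpath("cistus_mic_table.csv")))


def load_activity_table(path: str | Path | None = None) -> list[ActivityRecord]:
    """Read an evidence CSV (columns species,part,solvent,bacterium,value,
    reference) into validated records; ``None`` loads the packaged table."""
    if path is None:
        path = packaged_table_path()
    records: list[ActivityRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"species", "part", "solvent", "bacterium", "value", "reference"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise KeyError(f"evidence table {path} missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            value, unit, measure = _parse_value(row["value"], i)
            if unit == "percent":
                logger.warning(
                    "row %d: percent-unit entry %r excluded from mg/mL means",
                    i, row["value"],
                )
            records.append(
                ActivityRecord(
                    species=row["species"].strip(),
                    part=row["part"].strip(),
                    solvent=row["solvent"].strip(),
                    bacterium_raw=row["bacterium"].strip(),
                    bacterium=normalize_bacterium(row["bacterium"]),
                    value=value,
                    value_raw=row["value"].strip(),
                    unit=unit,
                    measure=measure,
                    reference=row["reference"].strip(),
                )
            )
    return records


def write_activity_table(records: Sequence[ActivityRecord], path: str | Path) -> None:
    """Write records back to the canonical CSV; loading a table and writing
    it again reproduces the file byte-identically."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["species", "part", "solvent", "bacterium", "value", "reference"])
        for r in records:
            writer.writerow(
                [r.species, r.part, r.solvent, r.bacterium_raw, r.value_raw, r.reference]
            )


def _solvent_category(solvent: str) -> str:
    """Compound hydroalcoholic labels collapse to their leading word."""
    return solvent.split("(")[0].strip()


def _share_key(record: ActivityRecord, field: str) -> str:
    if field == "species":
        return record.species
    if field == "part":
        return record.part
    if field == "solvent":
        return _solvent_category(record.solvent)
    if field == "bacterium":
        return normalize_bacterium(record.bacterium_raw, keep_qualifiers=True)
    raise ValueError(f"unknown share field {field!r}")


def category_share(
    records: Sequence[ActivityRecord], field: str, collapse_strains: bool = False
) -> pd.DataFrame:
    """Percent of reports per category of ``field``.

    With ``collapse_strains`` the unit of counting is the distinct
    (species, part, solvent, normalized bacterium) combination rather than
    the raw table row; by default every row counts as one report.  Returns
    a DataFrame with exact and display-rounded shares, sorted by share
    descending then category.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    if collapse_strains:
        units: Iterable = {
            (r.species, r.part, _solvent_category(r.solvent), r.bacterium)
            for r in records
        }
        keyed = [
            {"species": u[0], "part": u[1], "solvent": u[2], "bacterium": u[3]}[field]
            for u in units
        ]
    else:
        keyed = [_share_key(r, field) for r in records]
    counts = pd.Series(keyed).value_counts()
    total = int(counts.sum())
    out = pd.DataFrame(
        {
            "category": counts.index,
            "count": counts.to_numpy(),
            "share_exact": 100.0 * counts.to_numpy() / total,
        }
    )
    out["share_pct"] = out["share_exact"].round().astype(int)
    return out.sort_values(
        ["share_exact", "category"], ascending=[False, True], ignore_index=True
    )


def mean_activity(
    records: Sequence[ActivityRecord],
    bacterium: str,
    measure_scope: str = "MIC_only",
) -> tuple[float | None, int]:
    """Arithmetic mean mg/mL value over rows whose normalized bacterium
    matches, and the number of values pooled.

    ``measure_scope`` is ``"MIC_only"`` (MIC50-flagged rows excluded — the
    scope under which published headline means are reproduced) or
    ``"MIC_and_MIC50"``.  Percent-unit rows never enter the mean.  Returns
    ``(None, 0)`` when nothing matches.
    """
    if measure_scope not in ("MIC_only", "MIC_and_MIC50"):
        raise ValueError(f"unknown measure_scope {measure_scope!r}")
    target = normalize_bacterium(bacterium)
    vals = [
        r.value
        for r in records
        if r.bacterium == target
        and r.unit == "mg_per_mL"
        and (measure_scope == "MIC_and_MIC50" or r.measure == "MIC")
    ]
    if not vals:
        return None, 0
    return fmean(vals), len(vals)


@dataclass(frozen=True)
class EvidenceSummary:
    """Category shares per field and per-bacterium mean activities."""

    shares: dict[str, pd.DataFrame]
    means: pd.DataFrame  # columns: bacterium, mean_mic, n
    n_records: int
    measure_scope: str

    def to_json_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "measure_scope": self.measure_scope,
            "shares": {
                f: df[["category", "count", "share_exact", "share_pct"]].to_dict("records")
                for f, df in self.shares.items()
            },
            "means": self.means.to_dict("records"),
        }


def summarize(
    records: Sequence[ActivityRecord],
    measure_scope: str = "MIC_only",
    collapse_strains: bool = False,
) -> EvidenceSummary:
    """Full evidence summary: shares for every field plus a per-bacterium
    mean-MIC table (means reported to 3 decimals, exact values retained)."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    shares = {
        f: category_share(records, f, collapse_strains=collapse_strains)
        for f in SHARE_FIELDS
    }
    rows = []
    for bact in sorted({r.bacterium for r in records}):
        mean, n = mean_activity(records, bact, measure_scope=measure_scope)
        if n:
            rows.append({"bacterium": bact, "mean_mic": mean, "n": n})
    means = pd.DataFrame(rows, columns=["bacterium", "mean_mic", "n"]).sort_values(
        ["n", "bacterium"], ascending=[False, True], ignore_index=True
    )
    return EvidenceSummary(
        shares=shares, means=means, n_records=len(records), measure_scope=measure_scope
    )
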