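"""Reading article and patent metadata exports into a uniform corpus.

A :class:`Corpus` is an ordered collection of :class:`Document` records —
one per article or patent — carrying the metadata the downstream analyses
need: publication year, citation count and Open Access flag.  The text used
for clustering is always the concatenation of title and abstract.

Readers accept bibliographic-database CSV exports (comma-separated, quoted,
header row).  A ``column_map`` adapts dialects whose column names differ
from the defaults (``Title``/``Year``/``Abstract``/``Cited by``/``Open
Access``).  The canonical on-disk corpus format is a CSV with columns
``id,title,abstract,year,citations,open_access,source`` that round-trips
losslessly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "Corpus",
    "read_scopus_csv",
    "read_espacenet_export",
    "read_corpus_csv",
    "write_corpus_csv",
    "write_manifest",
    "split_by_open_access",
    "split_top_cited",
]

#: Open Access column values treated as "not open access".  Any other
#: non-empty value counts as open access (databases encode OA as text labels).
CLOSED_TOKENS = frozenset({"", "no", "false", "0", "closed", "closed access", "none"})

CANONICAL_COLUMNS = ("id", "title", "abstract", "year", "citations", "open_access", "source")


@dataclass(frozen=True)
class Document:
    """One article or patent record."""

    id: str
    title: str = ""
    abstract: str = ""
    year: int | None = None
    citations: int | None = None
    open_access: bool | None = None
    source: str = "article"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("Document id must be non-empty")
        if self.source not in ("article", "patent"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.year is not None and not 1800 <= self.year <= 2100:
            raise ValueError(f"year {self.year} outside [1800, 2100]")
        if self.citations is not None and self.citations < 0:
            raise ValueError("citations must be non-negative")

    @property
    def text(self) -> str:
        """Title and abstract concatenated — the input to all text analyses."""
        return f"{self.title} {self.abstract}".strip()


class Corpus:
    """Ordered, id-unique collection of documents."""

    def __init__(self, documents: Iterable[Document], provenance: str = ""):
        self.documents: list[Document] = list(documents)
        self.provenance = provenance
        ids = [d.id for d in self.documents]
        if len(set(ids)) != len(ids):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise ValueError(f"duplicate document ids: {sorted(dups)[:5]}")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, i):
        return self.documents[i]

    def __repr__(self) -> str:
        return f"Corpus(n={len(self)}, provenance={self.provenance!r})"

    def subset(self, ids: Iterable[str], provenance: str | None = None) -> "Corpus":
        wanted = set(ids)
        return Corpus(
            (d for d in self.documents if d.id in wanted),
            provenance=provenance if provenance is not None else self.provenance,
        )


def _cell(row: Mapping, key: str) -> str:
    val = row.get(key, "")
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return ""
    return str(val).strip()


def _parse_int(text: str) -> int | None:
    if text == "":
        return None
    return int(float(text))


def _parse_open_access(text: str, closed_tokens: frozenset[str]) -> bool | None:
    return text.strip().lower() not in closed_tokens


def _read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, dtype=str, keep_default_na=False, encoding="utf-8",
            encoding_errors="replace",
        )
    except FileNotFoundError:
        raise
    except (OSError, pd.errors.ParserError) as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc


def read_scopus_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    closed_tokens: frozenset[str] = CLOSED_TOKENS,
) -> Corpus:
    """Read a bibliographic CSV export into a Corpus of articles.

    ``column_map`` maps required/optional logical names (``Title``, ``Year``,
    ``Abstract``, ``Cited by``, ``Open Access``, ``EID``) to the actual column
    names of the export.  ``Title``/``Year``/``Abstract`` must be present
    after mapping; the others enrich the documents when available.
    """
    frame = _read_table(path)
    colmap = {k: k for k in ("Title", "Year", "Abstract", "Cited by", "Open Access", "EID")}
    if column_map:
        colmap.update(column_map)
    for logical in ("Title", "Year", "Abstract"):
        if colmap[logical] not in frame.columns:
            raise KeyError(
                f"required column {colmap[logical]!r} (for {logical}) "
                f"missing from {path}"
            )
    docs = []
    n_missing_abstract = 0
    for i, row in enumerate(frame.to_dict("records")):
        abstract = _cell(row, colmap["Abstract"])
        if not abstract:
            n_missing_abstract += 1
        doc_id = _cell(row, colmap["EID"]) or f"doc{i + 1:05d}"
        year_text = _cell(row, colmap["Year"])
        cited = _cell(row, colmap["Cited by"]) if colmap["Cited by"] in frame.columns else ""
        oa_col = colmap["Open Access"]
        oa = (
            _parse_open_access(_cell(row, oa_col), closed_tokens)
            if oa_col in frame.columns
            else None
        )
        docs.append(
            Document(
                id=doc_id,
                title=_cell(row, colmap["Title"]),
                abstract=abstract,
                year=_parse_int(year_text),
                citations=_parse_int(cited),
                open_access=oa,
                source="article",
            )
        )
    if n_missing_abstract:
        logger.warning("%d row(s) in %s have empty abstracts", n_missing_abstract, path)
    return Corpus(docs, provenance=str(path))


def read_espacenet_export(path: str | Path) -> Corpus:
    """Read a patent metadata export (title/abstract fields) as patents."""
    frame = _read_table(path)
    lower = {c.lower().strip(): c for c in frame.columns}
    title_col = lower.get("title")
    abstract_col = lower.get("abstract")
    if title_col is None:
        raise KeyError(f"patent export {path} lacks a title column")
    id_col = next(
        (lower[k] for k in ("publication number", "id", "no") if k in lower), None
    )
    docs = []
    for i, row in enumerate(frame.to_dict("records")):
        doc_id = (_cell(row, id_col) if id_col else "") or f"pat{i + 1:05d}"
        year_col = lower.get("year")
        docs.append(
            Document(
                id=doc_id,
                title=_cell(row, title_col),
                abstract=_cell(row, abstract_col) if abstract_col else "",
                year=_parse_int(_cell(row, year_col)) if year_col else None,
                source="patent",
            )
        )
    return Corpus(docs, provenance=str(path))


def read_corpus_csv(path: str | Path) -> Corpus:
    """Read the canonical corpus CSV written by :func:`write_corpus_csv`."""
    frame = _read_table(path)
    missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise KeyError(f"canonical corpus {path} missing columns {missing}")
    docs = []
    for row in frame.to_dict("records"):
        oa_text = _cell(row, "open_access")
        docs.append(
            Document(
                id=_cell(row, "id"),
                title=_cell(row, "title"),
                abstract=_cell(row, "abstract"),
                year=_parse_int(_cell(row, "year")),
                citations=_parse_int(_cell(row, "citations")),
                open_access=None if oa_text == "" else oa_text == "true",
                source=_cell(row, "source") or "article",
            )
        )
    return Corpus(docs, provenance=str(path))


def write_corpus_csv(corpus: Corpus, path: str | Path) -> None:
    """Write the canonical corpus CSV (lossless round-trip)."""
    rows = []
    for d in corpus:
        rows.append(
            {
                "id": d.id,
                "title": d.title,
                "abstract": d.abstract,
                "year": "" if d.year is None else str(d.year),
                "citations": "" if d.citations is None else str(d.citations),
                "open_access": "" if d.open_access is None else str(d.open_access).lower(),
                "source": d.source,
            }
        )
    pd.DataFrame(rows, columns=CANONICAL_COLUMNS).to_csv(path, index=False)


def write_manifest(corpus: Corpus, path: str | Path) -> None:
    """JSON manifest with provenance and simple counts."""
    payload = {
        "provenance": corpus.provenance,
        "n_documents": len(corpus),
        "n_articles": sum(d.source == "article" for d in corpus),
        "n_patents": sum(d.source == "patent" for d in corpus),
        "n_open_access": sum(bool(d.open_access) for d in corpus),
        "n_with_year": sum(d.year is not None for d in corpus),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def split_by_open_access(corpus: Corpus) -> tuple[Corpus, Corpus]:
    """Partition into (open-access, non-open-access) corpora.

    Documents with an unknown flag are excluded from both groups and counted
    in a log message.  Document order is preserved within each group.
    """
    unknown = sum(d.open_access is None for d in corpus)
    if unknown:
        logger.warning("%d document(s) with unknown open-access flag excluded", unknown)
    open_docs = [d for d in corpus if d.open_access is True]
    closed_docs = [d for d in corpus if d.open_access is False]
    return (
        Corpus(open_docs, provenance=f"{corpus.provenance} [open access]"),
        Corpus(closed_docs, provenance=f"{corpus.provenance} [closed access]"),
    )


def split_top_cited(corpus: Corpus, fraction: float) -> tuple[Corpus, Corpus]:
    """Partition into (most-cited ceil(fraction*n), remainder).

    Documents are ranked by citation count descending with ties broken by id
    ascending, so the cut is deterministic even inside a tie band.  Order
    within each returned corpus follows that ranking.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    missing = [d.id for d in corpus if d.citations is None]
    if missing:
        raise ValueError(f"citations unknown for {len(missing)} document(s)")
    ranked = sorted(corpus, key=lambda d: (-d.citations, d.id))
    n_top = math.ceil(fraction * len(ranked))
    return (
        Corpus(ranked[:n_top], provenance=f"{corpus.provenance} [top cited]"),
        Corpus(ranked[n_top:], provenance=f"{corpus.provenance} [rest]"),
    )
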