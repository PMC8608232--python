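"""Bibliographic record I/O.

Records enter the pipeline as MEDLINE flat files, CSV, or JSON-lines and are
validated into a :class:`Corpus` of :class:`PaperRecord` objects.  MEDLINE
exports carry no reference lists, so citation links for MEDLINE input are
supplied through a sidecar two-column TSV edge file (citing_id, cited_id).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

_FORMATS_READ = ("medline", "csv", "jsonl")
_FORMATS_WRITE = ("csv", "jsonl")

CSV_COLUMNS = ["id", "title", "abstract", "year", "cited_ids", "keywords"]


@dataclass
class PaperRecord:
    """One bibliographic item.

    ``cited_ids`` lists the identifiers this paper cites; they may point at
    records absent from the corpus (dangling references are legal and simply
    ignored when the citation graph is built).
    """

    id: str
    title: str = ""
    abstract: str = ""
    year: int = 0
    cited_ids: list[str] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)

    def validate(self) -> "PaperRecord":
        """Enforce record invariants in place; raise ``ValueError`` if unfixable.

        Self-citations and duplicate cited ids are repaired silently (the
        record is kept); a missing id or non-positive year is fatal for the
        record.
        """
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not isinstance(self.year, int) or self.year <= 0:
            raise ValueError(f"record {self.id!r}: year must be a positive integer")
        seen: set[str] = set()
        cleaned = []
        for cid in self.cited_ids:
            if cid == self.id or cid in seen or not cid:
                continue
            seen.add(cid)
            cleaned.append(cid)
        self.cited_ids = cleaned
        return self


@dataclass
class Corpus:
    """An ordered collection of unique-id records plus free-text provenance.

    ``meta`` is an open dictionary used by the synthetic generator to carry
    its configuration and ground-truth community map alongside the records;
    file readers leave it empty.
    """

    records: list[PaperRecord] = field(default_factory=list)
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PaperRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def by_id(self) -> dict[str, PaperRecord]:
        return {r.id: r for r in self.records}


def _dedupe(records: Iterable[PaperRecord], provenance: str) -> Corpus:
    """Keep the first occurrence of each id; warn about the rest."""
    seen: set[str] = set()
    kept: list[PaperRecord] = []
    for rec in records:
        if rec.id in seen:
            logger.warning("duplicate id %r: keeping first occurrence", rec.id)
            continue
        seen.add(rec.id)
        kept.append(rec)
    return Corpus(records=kept, provenance=provenance)


def _validated(raw: Iterable[tuple[int, PaperRecord]]) -> Iterator[PaperRecord]:
    n_dropped = 0
    for lineno, rec in raw:
        try:
            yield rec.validate()
        except (ValueError, TypeError) as exc:
            n_dropped += 1
            logger.warning("dropping invalid record near line %d: %s", lineno, exc)
    if n_dropped:
        logger.warning("dropped %d invalid record(s)", n_dropped)


def _split_list(cell: str) -> list[str]:
    return [tok.strip() for tok in cell.split(";") if tok.strip()] if cell else []


def _iter_jsonl(path: Path) -> Iterator[tuple[int, PaperRecord]]:
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                yield lineno, PaperRecord(
                    id=str(obj["id"]),
                    title=obj.get("title", "") or "",
                    abstract=obj.get("abstract", "") or "",
                    year=int(obj["year"]),
                    cited_ids=[str(c) for c in obj.get("cited_ids", [])],
                    keywords=[str(k) for k in obj.get("keywords", [])],
                )
            except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
                logger.warning("dropping invalid record near line %d: %s", lineno, exc)


def _iter_csv(path: Path) -> Iterator[tuple[int, PaperRecord]]:
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, 2):
            try:
                yield lineno, PaperRecord(
                    id=row["id"],
                    title=row.get("title", "") or "",
                    abstract=row.get("abstract", "") or "",
                    year=int(row["year"]),
                    cited_ids=_split_list(row.get("cited_ids", "")),
                    keywords=_split_list(row.get("keywords", "")),
                )
            except (KeyError, ValueError, TypeError) as exc:
                logger.warning("dropping invalid record near line %d: %s", lineno, exc)


def _iter_medline(path: Path) -> Iterator[tuple[int, PaperRecord]]:
    """Parse a tag-based MEDLINE flat file.

    Mapping: PMID->id, TI->title, AB->abstract, DP->year (first 4-digit
    token), MH and OT->keywords.  Continuation lines (leading spaces) extend
    the previous tag.  Reference lists are not part of the format; see the
    sidecar edge file.
    """
    fields: dict[str, list[str]] = {}
    tag = None
    start = 1

    def flush(lineno: int) -> Iterator[tuple[int, PaperRecord]]:
        if not fields:
            return
        pmid = (fields.get("PMID") or [""])[0].strip()
        year = 0
        for token in " ".join(fields.get("DP", [])).replace("-", " ").split():
            if len(token) == 4 and token.isdigit():
                year = int(token)
                break
        yield lineno, PaperRecord(
            id=pmid,
            title=" ".join(fields.get("TI", [])),
            abstract=" ".join(fields.get("AB", [])),
            year=year,
            keywords=[kw.strip(" *") for kw in fields.get("MH", []) + fields.get("OT", [])],
        )

    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                yield from flush(start)
                fields, tag, start = {}, None, lineno + 1
            elif line.startswith("      ") and tag:
                fields[tag][-1] += " " + line.strip()
            elif len(line) > 4 and line[4] == "-":
                tag = line[:4].strip()
                fields.setdefault(tag, []).append(line[5:].strip())
        yield from flush(start)


def read_citation_edges(path: str | Path) -> dict[str, list[str]]:
    """Read a sidecar TSV of (citing_id, cited_id) pairs, no header."""
    edges: dict[str, list[str]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0] and parts[1]:
                edges.setdefault(parts[0], []).append(parts[1])
    return edges


def read_records(
    path: str | Path,
    format: str,
    citation_edges: str | Path | None = None,
) -> Corpus:
    """Read and validate bibliographic records.

    Parameters
    ----------
    path:
        Input file.
    format:
        One of ``medline``, ``csv``, ``jsonl``.
    citation_edges:
        Optional sidecar TSV (citing_id, cited_id) attaching reference lists;
        required in practice for MEDLINE input, which has none of its own.

    Records failing validation are dropped with a logged warning; duplicate
    ids keep the first occurrence.
    """
    path = Path(path)
    if format not in _FORMATS_READ:
        raise ValueError(f"unknown input format {format!r}; expected one of {_FORMATS_READ}")
    if not path.exists():
        raise FileNotFoundError(path)
    iterators = {"jsonl": _iter_jsonl, "csv": _iter_csv, "medline": _iter_medline}
    corpus = _dedupe(_validated(iterators[format](path)), provenance=f"{format}:{path}")
    if citation_edges is not None:
        edge_map = read_citation_edges(citation_edges)
        for rec in corpus.records:
            if rec.id in edge_map:
                rec.cited_ids = list(dict.fromkeys(rec.cited_ids + edge_map[rec.id]))
                rec.validate()
    return corpus


def write_records(corpus: Corpus, path: str | Path, format: str) -> None:
    """Write a corpus as CSV or JSON-lines; round-trips through read_records."""
    path = Path(path)
    if format not in _FORMATS_WRITE:
        raise ValueError(f"unknown output format {format!r}; expected one of {_FORMATS_WRITE}")
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in corpus:
                fh.write(
                    json.dumps(
                        {
                            "id": rec.id,
                            "title": rec.title,
                            "abstract": rec.abstract,
                            "year": rec.year,
                            "cited_ids": rec.cited_ids,
                            "keywords": rec.keywords,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            for rec in corpus:
                writer.writerow(
                    [
                        rec.id,
                        rec.title,
                        rec.abstract,
                        rec.year,
                        ";".join(rec.cited_ids),
                        ";".join(rec.keywords),
                    ]
                )


def filter_by_year(corpus: Corpus, max_year: int) -> Corpus:
    """Return a new corpus with exactly the records published up to max_year."""
    if max_year <= 0:
        raise ValueError("max_year must be positive")
    return Corpus(
        records=[r for r in corpus if r.year <= max_year],
        provenance=f"{corpus.provenance} | year<={max_year}",
        meta=dict(corpus.meta),
    )
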