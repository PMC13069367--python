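"""Data model and file I/O for summary corpora and Likert ratings tables.

A *corpus* is a collection of summaries keyed by ``(timeline_id, system_id)``:
one summary of one user timeline produced by one summarization system (a human
expert or a model pipeline). Each summary may optionally be split into the
three mandated clinical aspects: overall mental-state assessment,
inter/intrapersonal patterns, and changes over time.

JSONL is the canonical on-disk format (one UTF-8 JSON object per line); CSV is
a convenience dialect with a fixed header in which embedded newlines are
RFC-4180 quoted and the aspect list is serialized as a JSON array in a single
column. Identifiers are case-sensitive opaque strings and are never
normalized, so distinct spellings are never silently merged.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import CorpusParseError, PairingError, ValidationError

__all__ = [
    "SummaryDocument",
    "SummaryCorpus",
    "RatingRow",
    "RatingsTable",
    "CRITERIA",
    "read_corpus",
    "write_corpus",
    "read_ratings",
    "write_ratings",
]

#: The five human-evaluation criteria: overall factual consistency, overall
#: usefulness, and aspect-specific usefulness for the three clinical aspects.
CRITERIA = (
    "factual_consistency",
    "general_usefulness",
    "mental_state",
    "patterns",
    "changes_over_time",
)

N_ASPECTS = 3


@dataclass(frozen=True)
class SummaryDocument:
    """One summary of one timeline by one system.

    Parameters
    ----------
    timeline_id, system_id
        Opaque, case-sensitive identifiers.
    text
        The full summary text; must be non-blank.
    aspects
        Optional tuple of exactly three paragraphs (mental-state assessment,
        inter/intrapersonal patterns, changes over time). When present their
        newline-join must equal ``text``.
    """

    timeline_id: str
    system_id: str
    text: str
    aspects: tuple[str, str, str] | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.text, str) or not self.text.strip():
            raise ValidationError(
                f"summary ({self.timeline_id!r}, {self.system_id!r}): "
                "text must be a non-blank string"
            )
        if self.aspects is not None:
            aspects = tuple(self.aspects)
            object.__setattr__(self, "aspects", aspects)
            if len(aspects) != N_ASPECTS:
                raise ValidationError(
                    f"summary ({self.timeline_id!r}, {self.system_id!r}): "
                    f"expected {N_ASPECTS} aspect paragraphs, got {len(aspects)}"
                )
            if "\n".join(aspects) != self.text:
                raise ValidationError(
                    f"summary ({self.timeline_id!r}, {self.system_id!r}): "
                    "newline-joined aspects do not reproduce text"
                )

    @property
    def key(self) -> tuple[str, str]:
        return (self.timeline_id, self.system_id)


class SummaryCorpus:
    """An immutable (timeline x system) collection of summaries.

    Documents are stored sorted by ``(timeline_id, system_id)`` so that every
    downstream statistic is invariant to the record order of the input file.
    """

    def __init__(self, documents: Iterable[SummaryDocument]):
        docs = sorted(documents, key=lambda d: d.key)
        index: dict[tuple[str, str], SummaryDocument] = {}
        for doc in docs:
            if doc.key in index:
                raise ValidationError(
                    f"duplicate (timeline, system) pair {doc.key!r}"
                )
            index[doc.key] = doc
        self._documents: tuple[SummaryDocument, ...] = tuple(docs)
        self._index = index

    @property
    def documents(self) -> tuple[SummaryDocument, ...]:
        return self._documents

    @property
    def systems(self) -> tuple[str, ...]:
        return tuple(sorted({d.system_id for d in self._documents}))

    @property
    def timelines(self) -> tuple[str, ...]:
        return tuple(sorted({d.timeline_id for d in self._documents}))

    def __len__(self) -> int:
        return len(self._documents)

    def __iter__(self) -> Iterator[SummaryDocument]:
        return iter(self._documents)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SummaryCorpus):
            return NotImplemented
        return self._documents == other._documents

    def __repr__(self) -> str:
        return (
            f"SummaryCorpus({len(self)} documents, "
            f"{len(self.timelines)} timelines, {len(self.systems)} systems)"
        )

    def document(self, timeline_id: str, system_id: str) -> SummaryDocument:
        try:
            return self._index[(timeline_id, system_id)]
        except KeyError:
            raise KeyError(
                f"no summary for timeline {timeline_id!r}, system {system_id!r}"
            ) from None

    def documents_for_system(self, system_id: str) -> tuple[SummaryDocument, ...]:
        """All summaries of one system, ordered by timeline_id."""
        docs = tuple(d for d in self._documents if d.system_id == system_id)
        if not docs:
            raise KeyError(f"no summaries for system {system_id!r}")
        return docs

    def paired_timelines(self, system_a: str, system_b: str) -> tuple[str, ...]:
        """Timelines for which the corpus is paired-complete on (a, b).

        Raises
        ------
        PairingError
            If any timeline has a summary for one system but not the other;
            paired permutation tests require exactly one summary per
            (timeline, system).
        """
        t_a = {d.timeline_id for d in self._documents if d.system_id == system_a}
        t_b = {d.timeline_id for d in self._documents if d.system_id == system_b}
        unpaired = sorted(t_a ^ t_b)
        if unpaired:
            raise PairingError(
                f"corpus is not paired-complete for ({system_a!r}, {system_b!r}); "
                f"unpaired timelines: {', '.join(unpaired)}"
            )
        if not t_a:
            raise PairingError(
                f"no timelines shared by systems {system_a!r} and {system_b!r}"
            )
        return tuple(sorted(t_a))


# ---------------------------------------------------------------------------
# corpus I/O

_CSV_HEADER = ["timeline_id", "system_id", "text", "aspects"]


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("jsonl", "csv"):
            raise ValueError(f"unknown format {format!r}; expected 'jsonl' or 'csv'")
        return format
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".json"):
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")


def _document_from_record(
    record: dict, where: str
) -> SummaryDocument:
    for key in ("timeline_id", "system_id", "text"):
        if key not in record or record[key] is None:
            raise CorpusParseError(f"{where}: missing field {key!r}")
    aspects = record.get("aspects")
    if aspects is not None:
        if not isinstance(aspects, (list, tuple)):
            raise CorpusParseError(f"{where}: 'aspects' must be a JSON array")
        aspects = tuple(str(a) for a in aspects)
    return SummaryDocument(
        timeline_id=str(record["timeline_id"]),
        system_id=str(record["system_id"]),
        text=str(record["text"]),
        aspects=aspects,  # type: ignore[arg-type]
    )


def read_corpus(path: str | Path, format: str | None = None) -> SummaryCorpus:
    """Read a summary corpus from JSONL or CSV.

    The format is inferred from the suffix when not given. Malformed records
    raise :class:`CorpusParseError` naming the offending line (JSONL) or
    record (CSV, where quoted fields may span physical lines).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    documents: list[SummaryDocument] = []
    if fmt == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusParseError(
                        f"{path}, line {lineno}: invalid JSON ({exc.msg})"
                    ) from exc
                if not isinstance(record, dict):
                    raise CorpusParseError(
                        f"{path}, line {lineno}: expected a JSON object"
                    )
                documents.append(
                    _document_from_record(record, f"{path}, line {lineno}")
                )
    else:
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or set(reader.fieldnames) < {
                "timeline_id",
                "system_id",
                "text",
            }:
                raise CorpusParseError(
                    f"{path}: CSV header must contain "
                    "timeline_id, system_id, text"
                )
            for recno, row in enumerate(reader, start=1):
                where = f"{path}, record {recno}"
                aspects_raw = (row.get("aspects") or "").strip()
                record: dict = {
                    "timeline_id": row.get("timeline_id"),
                    "system_id": row.get("system_id"),
                    "text": row.get("text"),
                }
                if aspects_raw:
                    try:
                        record["aspects"] = json.loads(aspects_raw)
                    except json.JSONDecodeError as exc:
                        raise CorpusParseError(
                            f"{where}: 'aspects' is not a JSON array ({exc.msg})"
                        ) from exc
                documents.append(_document_from_record(record, where))
    return SummaryCorpus(documents)


def write_corpus(
    corpus: SummaryCorpus, path: str | Path, format: str | None = None
) -> None:
    """Write a corpus to JSONL or CSV; round-trips exactly via read_corpus."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for doc in corpus:
                record: dict = {
                    "timeline_id": doc.timeline_id,
                    "system_id": doc.system_id,
                    "text": doc.text,
                }
                if doc.aspects is not None:
                    record["aspects"] = list(doc.aspects)
                fh.write(json.dumps(record, ensure_ascii=False) + "\n")
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_HEADER)
            for doc in corpus:
                aspects = (
                    json.dumps(list(doc.aspects), ensure_ascii=False)
                    if doc.aspects is not None
                    else ""
                )
                writer.writerow(
                    [doc.timeline_id, doc.system_id, doc.text, aspects]
                )


# ---------------------------------------------------------------------------
# ratings


@dataclass(frozen=True)
class RatingRow:
    """One rater's 1-5 Likert score for one (timeline, system, criterion)."""

    timeline_id: str
    system_id: str
    criterion: str
    rater_id: str
    score: int

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValidationError(
                f"unknown criterion {self.criterion!r}; "
                f"allowed: {', '.join(CRITERIA)}"
            )
        if not isinstance(self.score, int) or isinstance(self.score, bool):
            raise ValidationError(
                f"score must be an integer, got {self.score!r}"
            )
        if not 1 <= self.score <= 5:
            raise ValidationError(
                f"score must be in 1..5, got {self.score} "
                f"({self.timeline_id!r}, {self.system_id!r}, {self.criterion})"
            )

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.timeline_id, self.system_id, self.criterion, self.rater_id)


@dataclass(frozen=True)
class RatingsTable:
    """A validated collection of Likert rating rows.

    At most one row per (timeline, system, criterion, rater).
    """

    rows: tuple[RatingRow, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        rows = tuple(sorted(self.rows, key=lambda r: r.key))
        object.__setattr__(self, "rows", rows)
        seen: set[tuple[str, str, str, str]] = set()
        for row in rows:
            if row.key in seen:
                raise ValidationError(f"duplicate rating row for {row.key!r}")
            seen.add(row.key)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self):
        """The rows as a pandas DataFrame (one column per field)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "timeline_id": r.timeline_id,
                    "system_id": r.system_id,
                    "criterion": r.criterion,
                    "rater_id": r.rater_id,
                    "score": r.score,
                }
                for r in self.rows
            ],
            columns=["timeline_id", "system_id", "criterion", "rater_id", "score"],
        )


_RATINGS_HEADER = ["timeline_id", "system_id", "criterion", "rater_id", "score"]


def read_ratings(path: str | Path) -> RatingsTable:
    """Read a ratings CSV with header timeline_id,system_id,criterion,rater_id,score."""
    path = Path(path)
    rows: list[RatingRow] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) != set(
            _RATINGS_HEADER
        ):
            raise CorpusParseError(
                f"{path}: ratings CSV header must be "
                + ",".join(_RATINGS_HEADER)
            )
        for recno, row in enumerate(reader, start=1):
            try:
                score = int(row["score"])
            except (TypeError, ValueError):
                raise CorpusParseError(
                    f"{path}, record {recno}: score {row.get('score')!r} "
                    "is not an integer"
                ) from None
            rows.append(
                RatingRow(
                    timeline_id=row["timeline_id"],
                    system_id=row["system_id"],
                    criterion=row["criterion"],
                    rater_id=row["rater_id"],
                    score=score,
                )
            )
    return RatingsTable(tuple(rows))


def write_ratings(table: RatingsTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_RATINGS_HEADER)
        for r in table.rows:
            writer.writerow(
                [r.timeline_id, r.system_id, r.criterion, r.rater_id, r.score]
            )
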