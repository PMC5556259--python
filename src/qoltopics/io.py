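"""Readers and writers for corpora, questionnaires, lexicons, annotations and models.

All artifacts are plain text: JSONL for corpora (CSV accepted), JSON for
questionnaires and model metadata, TSV for numeric tables and two-column
lexicons, one-term-per-line files for term sets, CSV for annotations.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A file violated the expected schema (missing field, duplicate key...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawMessage:
    """One social-media message; a message is one document for topic modeling."""

    message_id: str
    thread_id: str
    user_id: str
    date: str  # ISO-8601 when parseable; kept verbatim otherwise (unused downstream)
    text: str


@dataclass(frozen=True)
class QuestionnaireItem:
    item_number: int  # combined numbering: QLQ-C30 1-30, QLQ-BR23 31-53
    scale: str
    text: str

    def __post_init__(self) -> None:
        if self.item_number < 1:
            raise SchemaError(f"item_number must be >= 1, got {self.item_number}")
        if not self.text:
            raise SchemaError(f"item {self.item_number}: empty text")


@dataclass(frozen=True)
class Questionnaire:
    instrument_name: str
    items: tuple[QuestionnaireItem, ...]

    def __post_init__(self) -> None:
        numbers = [it.item_number for it in self.items]
        if len(set(numbers)) != len(numbers):
            dupes = sorted({n for n in numbers if numbers.count(n) > 1})
            raise SchemaError(f"duplicate item numbers: {dupes}")

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class LexiconSet:
    """Term resources driving normalization and vocabulary construction.

    ``medical_terms`` is the MED seed set (MeSH-style terms plus drug and
    alternative-treatment lists); entries may be multi-word. ``lay_to_medical``
    maps patient vocabulary to the professional term (e.g. "crabe" -> "cancer").
    """

    medical_terms: set[str] = field(default_factory=set)
    lay_to_medical: dict[str, str] = field(default_factory=dict)
    stopwords: set[str] = field(default_factory=set)
    slang: set[str] = field(default_factory=set)
    pseudonyms: set[str] = field(default_factory=set)
    noise_terms: set[str] = field(default_factory=set)
    spelling_dictionary: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mapping, name in ((self.lay_to_medical, "lay_to_medical"),
                              (self.spelling_dictionary, "spelling_dictionary")):
            selfmaps = [k for k, v in mapping.items() if k == v]
            if selfmaps:
                raise SchemaError(f"{name}: keys mapping to themselves: {selfmaps}")


@dataclass(frozen=True)
class AnnotationRow:
    item_number: int
    topic_id: int
    validated: bool


@dataclass
class AnnotationTable:
    """Expert judgments: is item->topic a valid relationship?"""

    rows: list[AnnotationRow]

    def __post_init__(self) -> None:
        pairs = [(r.item_number, r.topic_id) for r in self.rows]
        if len(set(pairs)) != len(pairs):
            raise SchemaError("duplicate (item_number, topic_id) pairs in annotations")
        self._index = {(r.item_number, r.topic_id): r.validated for r in self.rows}

    def lookup(self, item_number: int, topic_id: int) -> bool | None:
        return self._index.get((item_number, topic_id))

    def validated_topics(self) -> set[int]:
        return {r.topic_id for r in self.rows if r.validated}


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

_CORPUS_FIELDS = ("message_id", "thread_id", "user_id", "date", "text")


def read_corpus(path: str | Path, format: str | None = None) -> list[RawMessage]:
    """Read a corpus of messages from JSONL (canonical) or CSV.

    One record per message; input order is preserved. Raises
    :class:`SchemaError` naming the offending record on a missing text field
    or a duplicated ``message_id``.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format: {format!r}")

    records: list[dict] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
                records.append(obj)
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            records = list(csv.DictReader(fh))

    messages: list[RawMessage] = []
    seen: set[str] = set()
    for i, rec in enumerate(records, 1):
        if rec.get("text") is None:
            mid = rec.get("message_id", f"record #{i}")
            raise SchemaError(f"{path}: record {mid}: missing text field")
        if rec.get("message_id") is None:
            raise SchemaError(f"{path}: record #{i}: missing message_id")
        mid = str(rec["message_id"])
        if mid in seen:
            raise SchemaError(f"{path}: duplicate message_id {mid!r}")
        seen.add(mid)
        messages.append(RawMessage(
            message_id=mid,
            thread_id=str(rec.get("thread_id", "")),
            user_id=str(rec.get("user_id", "")),
            date=str(rec.get("date", "") or ""),
            text=str(rec["text"]),
        ))
    return messages


def write_corpus(messages: list[RawMessage], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in messages:
            fh.write(json.dumps({f: getattr(m, f) for f in _CORPUS_FIELDS},
                                ensure_ascii=False) + "\n")


def corpus_summary(corpus: list[RawMessage]) -> tuple[int, int, int]:
    """(n_users, n_threads, n_messages) — distinct users, distinct threads, messages."""
    return (len({m.user_id for m in corpus}),
            len({m.thread_id for m in corpus}),
            len(corpus))


# ---------------------------------------------------------------------------
# questionnaire
# ---------------------------------------------------------------------------

def read_questionnaire(path: str | Path) -> Questionnaire:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    try:
        items = tuple(QuestionnaireItem(int(it["item_number"]), str(it["scale"]),
                                        str(it["text"]))
                      for it in obj["items"])
        return Questionnaire(str(obj["instrument_name"]), items)
    except KeyError as exc:
        raise SchemaError(f"{path}: missing key {exc}") from exc


def write_questionnaire(q: Questionnaire, path: str | Path) -> None:
    obj = {"instrument_name": q.instrument_name,
           "items": [{"item_number": it.item_number, "scale": it.scale,
                      "text": it.text} for it in q.items]}
    Path(path).write_text(json.dumps(obj, ensure_ascii=False, indent=1),
                          encoding="utf-8")


# ---------------------------------------------------------------------------
# lexicons
# ---------------------------------------------------------------------------

_SET_FILES = {"medical_terms": "medical_terms.txt", "stopwords": "stopwords.txt",
              "slang": "slang.txt", "pseudonyms": "pseudonyms.txt",
              "noise_terms": "noise_terms.txt"}
_MAP_FILES = {"lay_to_medical": "lay_to_medical.tsv",
              "spelling_dictionary": "spelling_dictionary.tsv"}


def _read_term_file(path: Path) -> set[str]:
    if not path.exists():
        return set()
    terms = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.add(line)
    return terms


def _read_map_file(path: Path) -> dict[str, str]:
    if not path.exists():
        return {}
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SchemaError(f"{path}:{lineno}: expected 2 tab-separated columns")
        mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def read_lexicons(directory: str | Path) -> LexiconSet:
    """Read a lexicon directory; absent files yield empty resources."""
    d = Path(directory)
    kwargs: dict = {k: _read_term_file(d / fn) for k, fn in _SET_FILES.items()}
    kwargs.update({k: _read_map_file(d / fn) for k, fn in _MAP_FILES.items()})
    return LexiconSet(**kwargs)


def write_lexicons(lex: LexiconSet, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for attr, fn in _SET_FILES.items():
        (d / fn).write_text("\n".join(sorted(getattr(lex, attr))) + "\n",
                            encoding="utf-8")
    for attr, fn in _MAP_FILES.items():
        lines = [f"{k}\t{v}" for k, v in sorted(getattr(lex, attr).items())]
        (d / fn).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(path)
    required = {"item_number", "topic_id", "validated"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: annotations need columns {sorted(required)}")
    rows = [AnnotationRow(int(r.item_number), int(r.topic_id), bool(int(r.validated)))
            for r in df.itertuples()]
    return AnnotationTable(rows)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["item_number", "topic_id", "validated"])
        for r in table.rows:
            w.writerow([r.item_number, r.topic_id, int(r.validated)])


# ---------------------------------------------------------------------------
# model artifacts
# ---------------------------------------------------------------------------

def save_model(model, directory: str | Path) -> None:
    """Persist a fitted topic model as JSON metadata + TSV numeric tables.

    Human-inspectable and language-neutral; floats carry full double precision
    (repr round-trip), so ``load_model(save_model(m))`` is bit-identical.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "K": int(model.n_topics),
        "alpha0": float(model.alpha0),
        "alpha": float(model.alpha0) / int(model.n_topics),
        "beta": float(model.beta),
        "seed": model.random_state,
        "iterations": int(model.n_iter),
        "burn_in": int(model.burn_in),
        "vocabulary": list(model.vocabulary_) if model.vocabulary_ is not None else None,
    }
    (d / "model.json").write_text(json.dumps(meta, ensure_ascii=False, indent=1),
                                  encoding="utf-8")
    np.savetxt(d / "phi.tsv", model.components_, delimiter="\t", fmt="%.17g")
    np.savetxt(d / "theta.tsv", model.theta_, delimiter="\t", fmt="%.17g")


def load_model(directory: str | Path):
    from .lda import GibbsLDA  # local import: avoid circularity

    d = Path(directory)
    meta = json.loads((d / "model.json").read_text(encoding="utf-8"))
    model = GibbsLDA(n_topics=meta["K"], alpha0=meta["alpha0"], beta=meta["beta"],
                     n_iter=meta["iterations"], burn_in=meta["burn_in"],
                     random_state=meta["seed"])
    model.components_ = np.loadtxt(d / "phi.tsv", delimiter="\t", ndmin=2)
    model.theta_ = np.loadtxt(d / "theta.tsv", delimiter="\t", ndmin=2)
    model.vocabulary_ = meta["vocabulary"]
    model.n_features_in_ = model.components_.shape[1]
    return model
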