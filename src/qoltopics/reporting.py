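"""Table renderers and derived-number computations over published tables.

Every renderer is a pure function of its inputs and byte-stable: rendering
the same objects twice yields identical strings. Formats are TSV (tab
columns, one header line) and GitHub-style Markdown.

The module also loads a machine-readable copy of the published study tables
(two French breast-cancer corpora scored against the EORTC QLQ-C30/BR23
instruments) and recomputes the derived figures — precision, matched-
dimension rates, corpus shares — from those printed inputs.
"""

from __future__ import annotations

import json
import math
from importlib import resources

from .alignment import AlignmentResult, EmergingTopicReport
from .io import AnnotationTable, Questionnaire
from .lda import GibbsLDA, top_words


def format_count_percent(count: int, total: int) -> str:
    """Render "n (p)" with the percent to 2 decimals, e.g. "523 (3.10)"."""
    pct = 100.0 * count / total if total else 0.0
    return f"{count} ({pct:.2f})"


def load_published_results() -> dict:
    """The published study tables (corpus sizes, counts, dimension map)."""
    with resources.files("qoltopics.data").joinpath(
            "published_results.json").open(encoding="utf-8") as fh:
        return json.load(fh)


def matched_dimension_rate(dimension_map: list[dict], corpus_key: str
                           ) -> tuple[int, int, int]:
    """(matched, total, percent) questionnaire dimensions with >= 1 topic.

    ``corpus_key`` selects the ``<key>_topics`` column. The percent is the
    floor of 100*matched/total, matching the convention of the published
    figures (22/23 -> 95, 20/23 -> 86).
    """
    col = f"{corpus_key}_topics"
    total = len(dimension_map)
    matched = sum(1 for row in dimension_map if row[col])
    pct = math.floor(100.0 * matched / total) if total else 0
    return matched, total, pct


def unrelated_topic_labels(published: dict) -> set[str]:
    """Distinct topic labels matched to no questionnaire dimension."""
    out: set[str] = set()
    for labels in published["unrelated_topics"].values():
        out.update(labels)
    return out


# ---------------------------------------------------------------------------
# renderers
# ---------------------------------------------------------------------------

def topic_table(model: GibbsLDA, labels: dict[int, str] | None = None,
                n_words: int = 10, translations: dict[str, str] | None = None,
                fmt: str = "tsv") -> str:
    """One row per topic: topic no., top words, optional translations, label.

    The label column stays empty when no labels are given — it is the column
    the expert fills in.
    """
    V = model.components_.shape[1]
    n = min(n_words, V)
    header = ["topic", "top_words"]
    if translations is not None:
        header.append("translations")
    header.append("label")

    rows: list[list[str]] = []
    for t in range(model.n_topics):
        words = [str(w) for w, _ in top_words(model, t, n=n)]
        row = [str(t + 1), ", ".join(words)]
        if translations is not None:
            row.append(", ".join(translations.get(w, "") for w in words))
        row.append((labels or {}).get(t, ""))
        rows.append(row)
    return _render(header, rows, fmt)


def distribution_table(counts: list[tuple[int, float]] | list[int],
                       total: int | None = None, fmt: str = "tsv") -> str:
    """Per-topic document distribution: "topic\tn (percent)" plus a sum row."""
    if counts and isinstance(counts[0], tuple):
        ns = [int(c) for c, _ in counts]
    else:
        ns = [int(c) for c in counts]
    total = total if total is not None else sum(ns)
    rows = [[str(t + 1), format_count_percent(n, total)]
            for t, n in enumerate(ns)]
    rows.append(["sum", format_count_percent(sum(ns), total)])
    return _render(["topic", "n (percent)"], rows, fmt)


def alignment_map_table(alignment: AlignmentResult,
                        annotations: AnnotationTable,
                        questionnaire: Questionnaire,
                        n_topics: int,
                        fmt: str = "tsv") -> str:
    """Instrument-scale view of the alignment plus unrelated topics.

    Groups items by their scale (in first-appearance order), lists each
    scale's validated best topics, and closes with a "topics without a
    relationship" section: topics that are the validated topic of no item.
    """
    scale_items: dict[str, list[int]] = {}
    for item in questionnaire.items:
        scale_items.setdefault(item.scale, []).append(item.item_number)
    best = {r.item_number: r.best_topic_id for r in alignment.rows}

    validated_topics: set[int] = set()
    rows: list[list[str]] = []
    for scale, numbers in scale_items.items():
        topics: list[int] = []
        for num in numbers:
            if num not in best:
                continue
            t = best[num]
            if annotations.lookup(num, t):
                if t not in topics:
                    topics.append(t)
                validated_topics.add(t)
        rows.append([scale,
                     ", ".join(str(n) for n in numbers),
                     ", ".join(str(t + 1) for t in topics) or "N/A"])
    unrelated = [t for t in range(n_topics) if t not in validated_topics]
    rows.append(["Topics without a relationship", "N/A",
                 ", ".join(str(t + 1) for t in unrelated) or "N/A"])
    return _render(["scale", "items", "topics"], rows, fmt)


def cross_corpus_table(pairing: list[tuple[int, int, float]],
                       counts_a: list[tuple[int, float]],
                       counts_b: list[tuple[int, float]],
                       matched_a: set[int] | None = None,
                       matched_b: set[int] | None = None,
                       fmt: str = "tsv") -> str:
    """Topics found on both corpora vs only one; partitions both topic sets.

    ``matched_a``/``matched_b`` optionally mark topics matched to a
    questionnaire item. Unpaired cells render "N/A"; every topic of either
    model appears exactly once.
    """
    paired_a = {a for a, _, _ in pairing}
    paired_b = {b for _, b, _ in pairing}

    def flag(t: int, matched: set[int] | None) -> str:
        if matched is None:
            return ""
        return "Yes" if t in matched else "No"

    def cp(entry) -> str:
        count, pct = entry
        return f"{int(count)} ({pct:.2f})"

    rows: list[list[str]] = []
    rows.append(["[topics on both]", "", "", "", "", ""])
    for a, b, s in sorted(pairing, key=lambda p: p[0]):
        rows.append([str(a + 1), cp(counts_a[a]),
                     str(b + 1), cp(counts_b[b]),
                     f"{s:.4f}", flag(a, matched_a) or flag(b, matched_b)])
    rows.append(["[topics on only one]", "", "", "", "", ""])
    for a in range(len(counts_a)):
        if a not in paired_a:
            rows.append([str(a + 1), cp(counts_a[a]),
                         "N/A", "N/A", "N/A", flag(a, matched_a)])
    for b in range(len(counts_b)):
        if b not in paired_b:
            rows.append(["N/A", "N/A", str(b + 1), cp(counts_b[b]),
                         "N/A", flag(b, matched_b)])
    return _render(
        ["topic_a", "n_a (percent)", "topic_b", "n_b (percent)",
         "similarity", "matched_to_questionnaire"], rows, fmt)


def emerging_table(report: EmergingTopicReport, total_docs: int,
                   fmt: str = "tsv") -> str:
    rows = [[str(t + 1), format_count_percent(c, total_docs)]
            for t, c, _ in report.topics]
    return _render(["topic", "n (percent)"], rows, fmt)


def _render(header: list[str], rows: list[list[str]], fmt: str) -> str:
    if fmt == "tsv":
        lines = ["\t".join(header)]
        lines += ["\t".join(r) for r in rows]
        return "\n".join(lines) + "\n"
    if fmt == "markdown":
        lines = ["| " + " | ".join(header) + " |",
                 "| " + " | ".join("---" for _ in header) + " |"]
        lines += ["| " + " | ".join(r) + " |" for r in rows]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}; use 'tsv' or 'markdown'")
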