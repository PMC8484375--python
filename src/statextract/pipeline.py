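"""End-to-end extraction pipeline.

``get_stats`` mirrors the two-step extraction on a piece of text: character
normalization and operator repair, sentence selection, sticked-result
decomposition, structured parsing, p recomputation, classification, and —
opt-in — consistency checking and significance filtering.
``process_article`` runs the same pipeline over a section-structured
article within a chosen text scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import pvalue, statparser, sticker, textnorm
from .article_io import Article, select_scope
from .checker import DocumentReport, check_consistency, is_significant
from .records import Recomputation, StatRecord
from .render import render_record, render_records


@dataclass
class ExtractionOptions:
    T2t: bool = False
    R2r: bool = False
    estimateZ: bool = False
    one_sided: bool = False
    alpha: float = 0.05
    check: bool = False


@dataclass
class Extraction:
    """All per-result artifacts for one block of text, aligned by index."""

    sticked: list[sticker.StickedResult] = field(default_factory=list)
    records: list[StatRecord] = field(default_factory=list)
    recomputations: list[Recomputation] = field(default_factory=list)
    categories: list[str] = field(default_factory=list)
    #: canonical unified string per sticked result (label-stripped,
    #: numbers compiled); empty strings are dropped
    stats: list[str] = field(default_factory=list)


def extract_text(text: str, opts: ExtractionOptions | None = None,
                 section: str = "") -> Extraction:
    """Run the full pipeline on one normalized-or-raw text block."""
    opts = opts or ExtractionOptions()
    norm = textnorm.normalize(text)
    ext = Extraction()
    for pos, sent in enumerate(sticker.to_sentences(norm.text)):
        if not sticker.is_candidate(sent):
            continue
        cand = sticker.SentenceCandidate(sent, section, pos)
        for sr in sticker.extract_sticked(cand):
            records = statparser.parse(sr, T2t=opts.T2t, R2r=opts.R2r)
            if not records:
                continue
            ext.sticked.append(sr)
            canonical = render_records(records)
            if canonical:
                ext.stats.append(canonical)
            for rec in records:
                pvalue.validate_ranges(rec)
                recomp = pvalue.recompute(
                    rec, one_sided=opts.one_sided, estimateZ=opts.estimateZ
                )
                ext.records.append(rec)
                ext.recomputations.append(recomp)
                ext.categories.append(pvalue.classify(rec, recomp))
    return ext


def get_stats(text: str, output: str = "stats",
              opts: ExtractionOptions | None = None):
    """Extract statistics from raw text.

    ``output='stats'`` returns the canonical sticked-result strings;
    ``'standardStats'`` the structured records; ``'computable'`` /
    ``'checkable'`` the records filtered by category.
    """
    opts = opts or ExtractionOptions()
    ext = extract_text(text, opts)
    if output == "stats":
        return ext.stats
    pairs = list(zip(ext.records, ext.categories))
    if output == "standardStats":
        return [r for r, _ in pairs if r.is_standard]
    if output == "computable":
        return [r for r, c in pairs if c in ("computable", "checkable")]
    if output == "checkable":
        return [r for r, c in pairs if c == "checkable"]
    raise ValueError(f"unknown output level: {output!r}")


def process_article(article: Article, text_mode: int = 1,
                    opts: ExtractionOptions | None = None) -> DocumentReport:
    """Run the pipeline over the selected text scope of one article."""
    opts = opts or ExtractionOptions()
    scope = select_scope(article, text_mode)
    report = DocumentReport(article_id=article.id)
    for block in scope.blocks:
        ext = extract_text(block, opts)
        report.records.extend(ext.records)
        report.categories.extend(ext.categories)
        report.sticked.extend(sr.text for sr in ext.sticked)
        for rec, recomp in zip(ext.records, ext.recomputations):
            report.significant.append(is_significant(rec, recomp, opts.alpha))
            if opts.check:
                report.consistency.append(
                    check_consistency(rec, recomp, opts.alpha, opts.one_sided)
                )
    report.counts = report.recount()
    return report


def unify(snippet: str, T2t: bool = False, R2r: bool = False) -> str:
    """Canonical unified representation of one reported result string.

    Convenience wrapper used for single-result round trips: normalization,
    sticking, parsing and canonical rendering in one call.
    """
    opts = ExtractionOptions(T2t=T2t, R2r=R2r)
    stats = get_stats(snippet, output="stats", opts=opts)
    return ", ".join(stats)


def parse_one(snippet: str, T2t: bool = False, R2r: bool = False) -> list[StatRecord]:
    """Structured records for one reported result string."""
    opts = ExtractionOptions(T2t=T2t, R2r=R2r)
    ext = extract_text(snippet, opts)
    return ext.records
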