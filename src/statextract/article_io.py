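"""Read NISO-JATS XML or plain text into a section-structured article.

NISO-JATS (the Journal Article Tag Suite) stores scientific articles as
layout-free XML.  Only paragraph text is kept: tables, figures and graphics
are dropped by design, because tabulated results cannot be compiled
reliably.  Text scope selection mirrors the three ``text.mode`` levels:
1 = full text and abstract, 2 = method and result sections, 3 = result
sections only.
"""

from __future__ import annotations

import json
import re
import warnings as _warnings
from dataclasses import dataclass, field
from importlib import resources

from lxml import etree

#: Elements whose textual content never enters a section body.
_DROP_TAGS = ("table-wrap", "table", "fig", "graphic", "disp-formula-group",
              "supplementary-material", "media")


class JATSParseError(ValueError):
    """Raised for malformed XML; carries the byte offset of the failure."""

    def __init__(self, message: str, byte_offset: int | None = None):
        super().__init__(message)
        self.byte_offset = byte_offset


@dataclass
class Section:
    title: str
    body: str
    level: int = 0
    parent: int | None = None  # index of the enclosing section, if any


@dataclass
class Article:
    id: str = ""
    abstract: str = ""
    sections: list[Section] = field(default_factory=list)
    source_format: str = "jats"


@dataclass
class TextScope:
    mode: int
    blocks: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _patterns() -> dict:
    with resources.files("statextract.data").joinpath("section_patterns.json").open(
        encoding="utf-8"
    ) as fh:
        return json.load(fh)


_PATTERNS = _patterns()


def _own_text(sec: etree._Element) -> str:
    """Paragraph text belonging to *sec* itself, excluding nested <sec>."""
    parts: list[str] = []
    for child in sec:
        tag = etree.QName(child).localname if isinstance(child.tag, str) else ""
        if tag in ("sec", "title") or tag in _DROP_TAGS:
            continue
        parts.append(" ".join(child.itertext()))
    text = " ".join(p.strip() for p in parts if p.strip())
    return re.sub(r"\s+", " ", text).strip()


def parse_jats(xml: bytes | str) -> Article:
    """Parse a JATS-style document into an :class:`Article`.

    Tolerant of dialect variation (CERMINE output is valid input).  A
    missing ``<body>`` yields an article with no sections; malformed XML
    raises :class:`JATSParseError` naming the byte offset.
    """
    data = xml.encode("utf-8") if isinstance(xml, str) else xml
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        offset = None
        if exc.lineno and exc.lineno > 0:
            lines = data.split(b"\n")
            offset = sum(len(l) + 1 for l in lines[: exc.lineno - 1])
            offset += max((exc.position[1] if exc.position else 1) - 1, 0)
        raise JATSParseError(
            f"malformed XML at byte offset {offset}: {exc}", byte_offset=offset
        ) from exc

    # Drop non-prose content everywhere before extracting text.
    etree.strip_elements(root, *_DROP_TAGS, with_tail=False)

    art = Article(source_format="jats")

    aid = root.find(".//front//article-id")
    if aid is None:
        aid = root.find(".//article-id")
    if aid is not None and aid.text:
        art.id = aid.text.strip()

    abstract = root.find(".//front//abstract")
    if abstract is None:
        abstract = root.find(".//abstract")
    if abstract is not None:
        art.abstract = re.sub(r"\s+", " ", " ".join(abstract.itertext())).strip()

    body = root.find(".//body")
    if body is None:
        return art

    def _walk(el: etree._Element, level: int, parent: int | None) -> None:
        for child in el:
            tag = etree.QName(child).localname if isinstance(child.tag, str) else ""
            if tag != "sec":
                continue
            title_el = child.find("title")
            title = ""
            if title_el is not None:
                title = re.sub(r"\s+", " ", " ".join(title_el.itertext())).strip()
            idx = len(art.sections)
            art.sections.append(Section(title, _own_text(child), level, parent))
            _walk(child, level + 1, idx)

    # Paragraphs directly under <body> (no <sec>) form an untitled section.
    loose = _own_text(body)
    if loose:
        art.sections.append(Section("", loose, 0, None))
    _walk(body, 0, None)
    return art


def parse_plaintext(text: str, article_id: str = "") -> Article:
    """Wrap plain text as a single-section article."""
    return Article(
        id=article_id,
        sections=[Section("", text.strip(), 0, None)],
        source_format="plaintext",
    )


def _classify_title(title: str) -> str:
    low = title.lower()
    if any(pat in low for pat in _PATTERNS["result_like"]):
        return "result"
    if any(pat in low for pat in _PATTERNS["method_like"]):
        return "method"
    return "other"


def classify_sections(article: Article) -> list[str]:
    """Per-section class; a subsection inherits its ancestor's class unless
    its own title matches a pattern."""
    classes: list[str] = []
    for i, sec in enumerate(article.sections):
        cls = _classify_title(sec.title)
        if cls == "other" and sec.parent is not None:
            cls = classes[sec.parent]
        classes.append(cls)
    return classes


def select_scope(article: Article, mode: int) -> TextScope:
    """Select the text blocks to be searched for statistical results."""
    if mode not in (1, 2, 3):
        raise ValueError(f"text mode must be 1, 2 or 3, got {mode!r}")
    scope = TextScope(mode=mode)
    if mode == 1:
        if article.abstract:
            scope.blocks.append(article.abstract)
        scope.blocks.extend(s.body for s in article.sections if s.body)
        return scope

    wanted = {"result"} if mode == 3 else {"result", "method"}
    classes = classify_sections(article)
    for sec, cls in zip(article.sections, classes):
        if cls in wanted and sec.body:
            scope.blocks.append(sec.body)
    if not scope.blocks:
        msg = (
            f"no section titles matched the mode-{mode} patterns; "
            "results in this article will be missed"
        )
        scope.warnings.append(msg)
        _warnings.warn(msg, stacklevel=2)
    return scope
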