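"""Character normalization and operator repair.

Scientific full text mixes character codecs (UTF-8, HTML entities, numeric
character references) and synonym glyphs for one and the same symbol (Greek
small beta, German sharp s, ``&beta;``).  PDF-to-XML converters additionally
garble or drop comparison operators.  This module maps everything onto one
canonical ASCII dialect so the downstream pattern matching only ever sees
``beta``, ``chi2``, ``<``, ``>``, ``=``, ``<=``, ``>=`` and the sentinel
``<=>`` ("operator unknown").
"""

from __future__ import annotations

import html
import json
import re
from dataclasses import dataclass, field
from importlib import resources


@dataclass
class Substitution:
    """One logged replacement: where, what, with what, and under which rule."""

    position: int
    original: str
    replacement: str
    rule: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "position": self.position,
                "original": self.original,
                "replacement": self.replacement,
                "rule": self.rule,
            },
            ensure_ascii=False,
        )


@dataclass
class NormalizedText:
    text: str
    substitutions: list[Substitution] = field(default_factory=list)

    def log_jsonl(self) -> str:
        return "\n".join(s.to_json() for s in self.substitutions)


def _load_json(name: str) -> dict:
    with resources.files("statextract.data").joinpath(name).open(encoding="utf-8") as fh:
        return json.load(fh)


_CHAR_MAP: dict[str, str] = _load_json("entities.json")["map"]
_CORRUPTION_MAP: dict[str, str] = _load_json("operator_corruptions.json")["map"]

_ENTITY_RE = re.compile(r"&(#x?[0-9a-fA-F]+|[A-Za-z][A-Za-z0-9]*);")

# Tokens next to which a lost or garbled operator is repaired.  Bounded on
# purpose: repairs happen only in statistical context, never in prose.
_STAT_TOKEN = (
    r"(?:ps?|Z|t|T|F|rs?|R|chi2|Q|H|G2|U|BF|beta|d|eta2|R2|OR|RR|SE|df[12]?|M|SD|ts|Fs|Zs)"
    r"(?:\([^()]*\))?"
)
_NUMBER = r"[-+]?(?:\.\d|\d)"

_MISSING_OP_RE = re.compile(
    rf"\b({_STAT_TOKEN})([ \t]+)(?=({_NUMBER}))"
)
_CORRUPT_CHARS = "".join(re.escape(c) for c in _CORRUPTION_MAP)
_GARBLED_OP_RE = re.compile(
    rf"\b({_STAT_TOKEN})[ \t]*([{_CORRUPT_CHARS}])[ \t]*(?=({_NUMBER}))"
)

_DELTA_R2_RE = re.compile(r"Delta\s*R2")


def normalize_characters(raw: str | bytes) -> NormalizedText:
    """Map all synonym spellings of a character onto one canonical token.

    Handles HTML named entities and numeric character references (decimal
    and hex), Greek letters, the German sharp s, superscript digits and
    relational-operator glyphs.  Undecodable bytes are replaced with a
    neutral placeholder and logged, never raised.  The operation is
    idempotent.
    """
    subs: list[Substitution] = []

    if isinstance(raw, bytes):
        decoded = raw.decode("utf-8", errors="replace")
        if "�" in decoded:
            subs.append(
                Substitution(decoded.index("�"), "<undecodable>", " ", "undecodable-byte")
            )
        raw = decoded

    # 1. HTML entities and numeric character references.
    out: list[str] = []
    pos = 0
    for m in _ENTITY_RE.finditer(raw):
        out.append(raw[pos : m.start()])
        unescaped = html.unescape(m.group(0))
        if unescaped != m.group(0):
            subs.append(Substitution(m.start(), m.group(0), unescaped, "html-entity"))
            out.append(unescaped)
        else:
            out.append(m.group(0))
        pos = m.end()
    out.append(raw[pos:])
    text = "".join(out)

    # 2. Character-level canonicalization from the shipped table.
    chars: list[str] = []
    for i, ch in enumerate(text):
        repl = _CHAR_MAP.get(ch)
        if repl is not None and repl != ch:
            subs.append(Substitution(i, ch, repl, "char-map"))
            chars.append(repl)
        else:
            chars.append(ch)
    text = "".join(chars)

    # 3. 'Delta' directly in front of R2 is dropped (Delta-R2 reports keep
    #    only the R2 share; the drop is logged so nothing vanishes silently).
    def _drop_delta(m: re.Match) -> str:
        subs.append(Substitution(m.start(), m.group(0), "R2", "delta-r2-drop"))
        return "R2"

    text = _DELTA_R2_RE.sub(_drop_delta, text)

    return NormalizedText(text=text, substitutions=subs)


def repair_operators(text: str) -> NormalizedText:
    """Repair garbled comparison operators and mark missing ones.

    Between a recognized statistic/p token and an adjacent number, a known
    corruption glyph (e.g. the Times-encoding ``¼`` standing for ``=``) is
    replaced by the operator it stands for; a completely absent operator is
    replaced by the sentinel ``<=>``.  Clean text is a no-op.
    """
    subs: list[Substitution] = []

    def _fix_garbled(m: re.Match) -> str:
        op = _CORRUPTION_MAP[m.group(2)]
        subs.append(Substitution(m.start(2), m.group(2), op, "garbled-operator"))
        return f"{m.group(1)} {op} "

    text = _GARBLED_OP_RE.sub(_fix_garbled, text)

    def _fix_missing(m: re.Match) -> str:
        subs.append(Substitution(m.end(1), "", "<=>", "missing-operator"))
        return f"{m.group(1)} <=> "

    text = _MISSING_OP_RE.sub(_fix_missing, text)

    return NormalizedText(text=text, substitutions=subs)


def normalize(raw: str | bytes) -> NormalizedText:
    """Full normalization: character canonicalization, then operator repair."""
    first = normalize_characters(raw)
    second = repair_operators(first.text)
    return NormalizedText(second.text, first.substitutions + second.substitutions)
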