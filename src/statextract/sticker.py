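"""Select result-bearing sentences and decompose them into sticked results.

Step 1 of the two-step extraction.  A candidate sentence contains at least
one letter and an operator followed by a number.  Candidates are split at a
configurable set of words and at prose words immediately followed by a
comma; each fragment is trimmed of leading and trailing prose (everything
behind the last operator pointing to a number is removed), numbers are
unified (fractions, percents, e-notation, thousands commas), and fragments
holding more than one test-result are split again under the assumption
that a test statistic is reported in front of its p value.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources

from .records import INTERVAL_ARTIFACT
from .render import format_float, format_float_nozero

_CFG = json.loads(
    resources.files("statextract.data").joinpath("stopwords.json").read_text("utf-8")
)
SPLIT_WORDS: list[str] = _CFG["split_words"]
KEEP_WORDS: set[str] = {w.lower() for w in _CFG["keep_words"]}

_OP = r"(?:<=>|<=|>=|[<>=])"
_OP_NUM = rf"{_OP}\s*[-+]?[\d.]"

_ABBREV = {
    "fig", "figs", "eq", "eqs", "al", "cf", "vs", "etc", "ca", "approx",
    "resp", "ref", "refs", "no", "nos", "dr", "prof", "st", "e", "i", "g",
}


@dataclass
class SentenceCandidate:
    text: str
    source_section: str = ""
    position: int = 0


@dataclass
class StickedResult:
    text: str
    source: SentenceCandidate | None = None
    flags: set[str] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)


def to_sentences(block: str) -> list[str]:
    """Split a text block into sentences.

    Square brackets are converted to round brackets first; boundaries are
    never placed inside round brackets, after common abbreviations, or
    inside decimal numbers.
    """
    text = block.replace("[", "(").replace("]", ")")
    sentences: list[str] = []
    depth = 0
    start = 0
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(depth - 1, 0)
        elif ch in ".!?" and depth == 0:
            j = i + 1
            while j < n and text[j] in ".!?":
                j += 1
            if j < n and text[j].isspace():
                k = j
                while k < n and text[k].isspace():
                    k += 1
                nxt = text[k] if k < n else ""
                m = re.search(r"([A-Za-z]+)$", text[start:i])
                word = m.group(1) if m else ""
                is_abbrev = word.lower() in _ABBREV or (
                    len(word) == 1 and word.islower()
                )
                if not is_abbrev and (nxt.isupper() or nxt.isdigit() or nxt == "("):
                    sentences.append(text[start:j].strip())
                    start = k
                    i = k
                    continue
            i = j
            continue
        i += 1
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return [s for s in sentences if s]


def is_candidate(sentence: str) -> bool:
    """True iff the sentence has at least one letter and an operator
    followed by a number."""
    return bool(re.search(r"[A-Za-z]", sentence)) and bool(
        re.search(_OP_NUM, sentence)
    )


# ---------------------------------------------------------------- intervals

_INTERVAL_RE = re.compile(
    r"[-+]?[\d.]+\s*(<|>)\s*([A-Za-z][A-Za-z0-9]*)\s*\1\s*([-+]?[\d.]+)"
)


def _resolve_intervals(text: str, flags: set[str], warnings: list[str]) -> str:
    """Interval reports ('.12<r<.22') collapse to the upper bound with '=';
    p-value intervals are dropped.  Both are acknowledged artifacts and are
    flagged for downstream scrutiny."""

    def _sub(m: re.Match) -> str:
        flags.add(INTERVAL_ARTIFACT)
        letter = m.group(2)
        if letter in ("p", "ps"):
            warnings.append(f"dropped p-value interval report: {m.group(0)!r}")
            return ""
        warnings.append(f"interval report collapsed to upper bound: {m.group(0)!r}")
        return f"{letter} = {m.group(3)}"

    return _INTERVAL_RE.sub(_sub, text)


# ------------------------------------------------------------ paren unwrap

def _unwrap_result_parens(s: str) -> str:
    """Drop parentheses whose content itself reports a comparison (e.g.
    '(SD = 1.4)'), so the content joins the item stream; df brackets like
    't(12)' contain no operator and are preserved."""
    out: list[str] = []
    i = 0
    n = len(s)
    while i < n:
        ch = s[i]
        if ch == "(":
            depth = 1
            j = i + 1
            while j < n and depth:
                if s[j] == "(":
                    depth += 1
                elif s[j] == ")":
                    depth -= 1
                j += 1
            if depth == 0:
                content = s[i + 1 : j - 1]
                if re.search(_OP_NUM, content):
                    out.append(", " + _unwrap_result_parens(content) + ", ")
                else:
                    out.append(s[i:j])
                i = j
                continue
        out.append(ch)
        i += 1
    return "".join(out)


# -------------------------------------------------------- number unification

_THOUSANDS_RE = re.compile(r"(\d),(\d{3})\b")
_ENOT_RE = re.compile(r"\b(\d+(?:\.\d+)?)[eE]([-+]?\d+)\b")
_PERCENT_RE = re.compile(r"([\d.]+)\s*%")
_ARITH_RE = re.compile(rf"({_OP}\s*)([-+]?\d*\.?\d+)\s*([*/])\s*(\d*\.?\d+)")


def unify_numbers(text: str) -> str:
    """Unify number representations in a snippet.

    Thousands commas in numbers >= 1000 are removed, e-notation and
    percents are compiled to decimals, and value-level arithmetic (a/b
    fractions, p-value corrections like '.05/2') is evaluated.
    """
    while _THOUSANDS_RE.search(text):
        text = _THOUSANDS_RE.sub(r"\1\2", text)
    text = text.replace(";", ",")
    text = _ENOT_RE.sub(lambda m: format_float(float(m.group(0))), text)
    text = _PERCENT_RE.sub(
        lambda m: format_float_nozero(float(m.group(1)) / 100.0), text
    )

    def _arith(m: re.Match) -> str:
        a, op, b = float(m.group(2)), m.group(3), float(m.group(4))
        if op == "/" and b == 0:
            return m.group(0)
        v = a / b if op == "/" else a * b
        return m.group(1) + format_float_nozero(v)

    text = _ARITH_RE.sub(_arith, text)
    return re.sub(r"\s+", " ", text).strip(" ,")


# ------------------------------------------------------------------ trimming

_LEAD_RE = re.compile(rf"\b[A-Za-z][A-Za-z0-9]*\s*(?:\([^()]*\))?\s*{_OP_NUM}")
# number tokens end on a digit (or exponent/percent) so a sentence-final
# period is never swallowed into the value
_NUM_TOKEN = (
    r"[-+]?[\d.,]*\d(?:[eE][-+]?\d+)?"
    r"(?:\s*[*/]\s*[\d.]*\d)?\s*%?"
)
_TRAIL_RE = re.compile(rf"{_OP}\s*{_NUM_TOKEN}")

_STAT_TOKEN_RE = re.compile(
    r"(?:Z|t|T|F|r|R|chi2|Q|H|G2|U|BF)(?:[0-9]+|[a-z]{3,})?s?"
    r"\s*(?:\([^()]*\))?\s*(?:<=>|<=|>=|[<>=])"
)
_P_CMP_RE = re.compile(rf"\bps?\s*{_OP_NUM}")
_P_START_RE = re.compile(rf"^\(?\s*(?:ps?\s*{_OP}|ns\b)")


def _trim(snippet: str) -> str | None:
    m = _LEAD_RE.search(snippet)
    if m is None:
        return None
    s = snippet[m.start() :]
    has_ns = bool(re.search(r"\bns\b", s))
    last = None
    for last in _TRAIL_RE.finditer(s):
        pass
    if last is None:
        return None
    s = s[: last.end()].rstrip(" ,;")
    if has_ns and not re.search(r"\bns\b", s):
        s += ", ns"
    return s


def _split_multiresult(snippet: str) -> list[str]:
    """Split a snippet holding several complete results, assuming a test
    statistic is reported in front of its p value: a new result begins at a
    statistic token that follows a p comparison."""
    pieces: list[str] = []
    depth = 0
    cur_start = 0
    seen_p = False
    i = 0
    n = len(snippet)
    while i < n:
        ch = snippet[i]
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(depth - 1, 0)
        elif ch == "," and depth == 0:
            rest = snippet[i + 1 :].lstrip()
            if seen_p and _STAT_TOKEN_RE.match(rest):
                pieces.append(snippet[cur_start:i].strip(" ,"))
                cur_start = i + 1
                seen_p = False
            elif _P_CMP_RE.match(rest):
                seen_p = True
        i += 1
    pieces.append(snippet[cur_start:].strip(" ,"))
    return [p for p in pieces if p]


# ---------------------------------------------------------------- main entry

_SPLIT_WORD_RE = re.compile(
    r"\b(?:" + "|".join(w + "|" + w.capitalize() for w in SPLIT_WORDS) + r")\b"
)
_WORD_COMMA_RE = re.compile(r"\b([A-Za-z]{2,})\s*,")


def extract_sticked(
    sentence: SentenceCandidate | str,
) -> list[StickedResult]:
    """Decompose one candidate sentence into unified sticked results."""
    source = sentence if isinstance(sentence, SentenceCandidate) else None
    text = sentence.text if isinstance(sentence, SentenceCandidate) else sentence

    flags: set[str] = set()
    warnings: list[str] = []
    text = _resolve_intervals(text, flags, warnings)
    text = _unwrap_result_parens(text)
    text = _SPLIT_WORD_RE.sub("\x00", text)

    def _word_comma(m: re.Match) -> str:
        return m.group(0) if m.group(1).lower() in KEEP_WORDS else "\x00"

    text = _WORD_COMMA_RE.sub(_word_comma, text)

    snippets = [t.strip(" ,;") for t in text.split("\x00")]
    snippets = [t for t in snippets if t]

    # A fragment that starts with a bare p value or 'ns' belongs to the
    # statistic reported in front of it.
    merged: list[str] = []
    for snip in snippets:
        if merged and _P_START_RE.match(snip) and not _P_CMP_RE.search(merged[-1]):
            merged[-1] = merged[-1] + ", " + snip
        else:
            merged.append(snip)

    results: list[StickedResult] = []
    for snip in merged:
        trimmed = _trim(snip)
        if trimmed is None:
            continue
        unified = unify_numbers(trimmed)
        for piece in _split_multiresult(unified):
            if not is_candidate(piece):
                continue
            results.append(
                StickedResult(
                    text=piece,
                    source=source,
                    flags=set(flags),
                    warnings=list(warnings),
                )
            )
    return results
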