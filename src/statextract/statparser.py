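"""Parse sticked results into structured records of standard statistics.

Step 2 of the extraction.  Each sticked result is split into comma-separated
items (``F(1, 46) = 21``, ``p<.05``, ``df = 12``, ``SE = .77``, ``ns`` ...),
statistic labels and indices are stripped, numbers are compiled, and the
items are assembled into :class:`~statextract.records.StatRecord` objects.
Statistics outside the standard whitelist survive only through an attached
p value.
"""

from __future__ import annotations

import re
from fractions import Fraction

from .records import (
    AMBIGUOUS_OPERATOR,
    EFFECT_MEASURES,
    NS_REPORTED,
    R_PROMOTED,
    T_PROMOTED,
    TEST_STATISTICS,
    Effect,
    StatRecord,
)
from .render import format_float, format_float_nozero
from .sticker import StickedResult

_OP = r"(?:<=>|<=|>=|[<>=])"

#: letter combinations that must never be promoted to a standard statistic
_EXCLUDED_TOKENS = {"rp", "sr", "pr", "LR", "I2"}
#: single letters that are standard only *without* bracketed dfs
_EXCLUDED_WITH_DF = {"A", "B", "c", "d"}

_NUMBER_RE = re.compile(
    r"^\s*([-+]?)\s*(?:"
    r"(\d+(?:,\d{3})+(?:\.\d+)?)"  # comma-grouped
    r"|(\d*\.?\d+)[eE]([-+]?\d+)"  # scientific
    r"|(\d*\.?\d+)\s*/\s*(\d*\.?\d+)"  # fraction
    r"|(\d*\.?\d+)\s*%"  # percent
    r"|(\d*\.?\d+)"  # plain decimal
    r")\s*$"
)


def compile_number(token: str) -> float:
    """Compile one numeric token to its decimal value.

    Handles plain decimals, ``a/b`` fractions, ``xe±k`` scientific
    notation, ``x%`` percents (returned as proportions) and comma-grouped
    integers.  Fractions are evaluated with exact rational arithmetic
    before conversion to float.
    """
    m = _NUMBER_RE.match(token)
    if m is None:
        raise ValueError(f"not a numeric token: {token!r}")
    sign = -1.0 if m.group(1) == "-" else 1.0
    if m.group(2) is not None:
        return sign * float(m.group(2).replace(",", ""))
    if m.group(3) is not None:
        return sign * float(f"{m.group(3)}e{m.group(4)}")
    if m.group(5) is not None:
        return sign * float(Fraction(m.group(5)) / Fraction(m.group(6)))
    if m.group(7) is not None:
        return sign * float(m.group(7)) / 100.0
    return sign * float(m.group(8))


def strip_label(
    token: str, T2t: bool = False, R2r: bool = False, has_df: bool = False
) -> tuple[str, str, set[str]]:
    """Strip the label/index from a statistic token.

    Returns ``(symbol, index_label, flags)``; unknown or excluded tokens
    map to ``('nonstandard', '', set())``.  Capital ``T``/``R`` promote to
    ``t``/``r`` only under the respective option, with a flag recording the
    promotion.
    """
    nonstd = ("nonstandard", "", set())
    if not token or not token[0].isalpha():
        return nonstd
    if token in ("p", "ps"):
        return ("p", "", set())
    if token in _EXCLUDED_TOKENS:
        return nonstd
    if token in _EXCLUDED_WITH_DF and has_df:
        return nonstd

    def _exact(tok: str) -> str | None:
        if tok in TEST_STATISTICS or tok in EFFECT_MEASURES:
            return tok
        return None

    # plural: 'ts(27)', 'rs', 'Fs' — trailing s is not an index
    base = token[:-1] if len(token) > 1 and token.endswith("s") else None
    for cand in (token, base):
        if cand is None:
            continue
        sym = _exact(cand)
        if sym is not None:
            if cand in _EXCLUDED_WITH_DF and has_df:
                return nonstd
            return (sym, "", set())
        if cand == "T" and T2t:
            return ("t", "", {T_PROMOTED})
        if cand == "R" and R2r:
            return ("r", "", {R_PROMOTED})

    # label/index suffix: digits ('t2') or a lowercase word ('Finteraction')
    for stem_len in range(len(token) - 1, 0, -1):
        stem, suffix = token[:stem_len], token[stem_len:]
        sym = _exact(stem)
        promoted: set[str] = set()
        if sym is None:
            if stem == "T" and T2t:
                sym, promoted = "t", {T_PROMOTED}
            elif stem == "R" and R2r:
                sym, promoted = "r", {R_PROMOTED}
            else:
                continue
        if suffix.isdigit() or (suffix.islower() and suffix.isalpha() and len(suffix) >= 3):
            return (sym, suffix, promoted)
        return nonstd
    return nonstd


_ITEM_RE = re.compile(
    rf"^([A-Za-z][A-Za-z0-9]*)\s*(?:\(([^()]*)\))?\s*({_OP})\s*([-+]?[\d.]*\d\s*%?)$"
)


def _split_items(text: str) -> list[str]:
    items: list[str] = []
    depth = 0
    start = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(depth - 1, 0)
        elif ch == "," and depth == 0:
            items.append(text[start:i].strip())
            start = i + 1
    items.append(text[start:].strip())
    return [it for it in items if it]


def _parse_df_args(args: str, record: StatRecord) -> None:
    nums: list[float] = []
    for part in args.split(","):
        part = part.strip()
        if not part:
            continue
        try:
            nums.append(compile_number(part))
        except ValueError:
            record.warnings.append(f"unparsed df argument: {part!r}")
    if not nums:
        return
    record.df1 = nums[0]
    if len(nums) > 1:
        if record.symbol == "F":
            record.df2 = nums[1]
        else:
            record.warnings.append("second df argument ignored for non-F statistic")
    _check_degenerate_df(record)


def _check_degenerate_df(record: StatRecord) -> None:
    for attr in ("df1", "df2"):
        v = getattr(record, attr)
        if v is not None and v <= 0:
            setattr(record, attr, None)
            record.warnings.append(f"degenerate {attr} dropped")


def parse(
    sticked: StickedResult | str,
    T2t: bool = False,
    R2r: bool = False,
) -> list[StatRecord]:
    """Parse one sticked result into structured records.

    Most sticked results yield a single record; a snippet reporting two
    statistics in a row ('r(12) = .22, Z = .75, p = .45') yields one record
    per statistic, with the single p value attached to the nearest
    preceding statistic.
    """
    if isinstance(sticked, str):
        sticked = StickedResult(text=sticked)
    text = sticked.text

    records: list[StatRecord] = []
    current: StatRecord | None = None

    def _new_record() -> StatRecord:
        rec = StatRecord(raw=text)
        rec.flags |= sticked.flags
        rec.warnings.extend(sticked.warnings)
        records.append(rec)
        return rec

    for item in _split_items(text):
        if re.fullmatch(r"ns\.?", item):
            if current is None:
                current = _new_record()
                current.symbol = "p_only"
            current.flags.add(NS_REPORTED)
            continue

        m = _ITEM_RE.match(item)
        if m is None:
            # not an operator item; ignore (prose remnant)
            continue
        token, args, op, valstr = m.groups()

        if token in ("df", "df1", "df2"):
            if current is None:
                continue
            try:
                v = compile_number(valstr)
            except ValueError:
                continue
            if token == "df2":
                if current.symbol == "F":
                    current.df2 = v
                else:
                    current.warnings.append("df2 ignored for non-F statistic")
            elif token == "df1" or current.df1 is None:
                current.df1 = v
            else:
                current.df2 = v if current.symbol == "F" else current.df2
            _check_degenerate_df(current)
            continue

        if token == "SE":
            if current is not None and current.se is None:
                try:
                    current.se = compile_number(valstr)
                    current.se_str = valstr
                except ValueError:
                    current.warnings.append(f"unparsed SE value: {valstr!r}")
            continue

        try:
            value = compile_number(valstr)
        except ValueError:
            continue

        symbol, index, flags = strip_label(
            token, T2t=T2t, R2r=R2r, has_df=args is not None
        )

        if symbol == "p":
            if op == "<=>":
                pass  # sentinel stays; consistency checking treats it as unknown
            if current is None or current.p_op is not None:
                current = _new_record()
                current.symbol = "p_only"
            current.p_op = op
            current.p_reported = value
            current.p_str = valstr
            if op == "<=>":
                current.flags.add(AMBIGUOUS_OPERATOR)
            continue

        if symbol in EFFECT_MEASURES:
            attach = (
                current is not None
                and current.symbol in TEST_STATISTICS
                and current.p_op is None
            )
            if attach:
                current.effects.append(Effect(symbol, op, value, valstr))
            else:
                current = _new_record()
                current.symbol = symbol
                current.stat_op = op
                current.stat_value = value
                current.value_str = valstr
                current.flags |= flags
            continue

        # test statistic (whitelisted) or nonstandard
        rec = _new_record()
        rec.symbol = symbol
        rec.index_label = index
        rec.flags |= flags
        rec.stat_op = op
        rec.stat_value = value
        rec.value_str = valstr
        if symbol == "BF" and args is not None and args.strip() in ("01", "10"):
            direction = args.strip()
            if direction == "01":
                if value == 0:
                    rec.warnings.append("BF(01) = 0 cannot be inverted; record rejected")
                    records.pop()
                    current = None
                    continue
                rec.stat_value = 1.0 / value
                rec.value_str = format_float(rec.stat_value)
                if op == "<":
                    rec.stat_op = ">"
                elif op == ">":
                    rec.stat_op = "<"
            rec.bf_direction = "H1_over_H0"
        elif args is not None:
            _parse_df_args(args, rec)
        current = rec

    # records that carry nothing at all are noise
    kept = [
        r
        for r in records
        if r.stat_value is not None or r.p_reported is not None or r.effects
        or NS_REPORTED in r.flags
    ]
    return kept


__all__ = ["compile_number", "strip_label", "parse"]
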