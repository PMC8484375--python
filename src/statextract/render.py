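"""Canonical rendering of parsed records back to unified result strings.

The canonical dialect spaces ``=`` and the sentinel ``<=>`` but writes
``<``, ``>``, ``<=``, ``>=`` tight against the number, matching the way
unified sticked results are conventionally printed.  Values produced by
arithmetic compilation (fractions, percents, corrected p values) drop the
leading zero; values produced by e-notation compilation or Bayes-factor
inversion keep it; untouched tokens keep their reported spelling.
"""

from __future__ import annotations

from .records import StatRecord


def format_op(op: str) -> str:
    if op == "=":
        return " = "
    if op == "<=>":
        return " <=> "
    return op


def format_float(v: float) -> str:
    """Plain decimal string, no exponent, no trailing zeros."""
    s = f"{v:.10g}"
    if "e" in s or "E" in s:
        s = f"{v:.12f}".rstrip("0").rstrip(".")
    return s


def format_float_nozero(v: float) -> str:
    """Like :func:`format_float` but without the leading zero ('.5')."""
    s = format_float(v)
    if s.startswith("0."):
        s = s[1:]
    elif s.startswith("-0."):
        s = "-" + s[2:]
    return s


def _df_str(v: float) -> str:
    return format_float(v)


def render_record(rec: StatRecord) -> str:
    """One record -> its canonical unified string; '' if nothing survives.

    Nonstandard statistics are dropped (only an attached p value survives);
    'ns' markers are not rendered; index labels are removed.
    """
    parts: list[str] = []
    if rec.symbol == "p_only":
        pass
    elif rec.symbol == "nonstandard":
        pass
    else:
        sym = "BF(10)" if rec.symbol == "BF" else rec.symbol
        stat = sym
        if rec.df1 is not None:
            dfs = _df_str(rec.df1)
            if rec.df2 is not None:
                dfs += f", {_df_str(rec.df2)}"
            stat += f"({dfs})"
        if rec.stat_op is not None and rec.value_str:
            stat += f"{format_op(rec.stat_op)}{rec.value_str}"
        parts.append(stat)
        if rec.se is not None:
            parts.append(f"SE = {rec.se_str}")
    for eff in rec.effects:
        parts.append(eff.render())
    if rec.p_op is not None and rec.p_str:
        parts.append(f"p{format_op(rec.p_op)}{rec.p_str}")
    return ", ".join(parts)


def render_records(records: list[StatRecord]) -> str:
    """All records of one sticked result, joined in reading order."""
    return ", ".join(s for s in (render_record(r) for r in records) if s)
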