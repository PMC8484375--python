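"""Core record types shared across the extraction pipeline.

A *sticked result* is one unified string holding a single reported result
(statistic token, optional degrees of freedom, an operator pointing to a
number, plus any attached p value and effect measures).  Parsing a sticked
result yields one or more :class:`StatRecord` objects; recomputing its p
value yields a :class:`Recomputation`; comparing reported with recomputed
p values yields a :class:`ConsistencyFlag`.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# Test statistics for which a p value can (in principle) be recomputed from
# the reported value and degrees of freedom.
TEST_STATISTICS = frozenset({"Z", "t", "F", "chi2", "r", "Q", "H", "G2", "U", "BF"})

# Effect measures that travel alongside (or instead of) a test statistic.
EFFECT_MEASURES = frozenset({"beta", "d", "eta2", "R2", "OR", "RR"})

STANDARD_SYMBOLS = TEST_STATISTICS | EFFECT_MEASURES

#: Comparison operators in canonical form.  ``<=>`` is the sentinel meaning
#: "operator unknown" (destroyed during PDF conversion).
OPERATORS = ("<=>", "<=", ">=", "<", ">", "=")

SENTINEL = "<=>"

#: Record-level flags.
T_PROMOTED = "T_promoted"
R_PROMOTED = "R_promoted"
Z_ESTIMATED = "z_estimated"
NS_REPORTED = "ns_reported"
INTERVAL_ARTIFACT = "interval_artifact"
AMBIGUOUS_OPERATOR = "ambiguous_operator"


@dataclass
class Effect:
    """One effect measure attached to a test result, e.g. ``d = .2``."""

    measure: str
    op: str
    value: float
    value_str: str

    def render(self) -> str:
        from .render import format_op  # local import avoids a cycle

        return f"{self.measure}{format_op(self.op)}{self.value_str}"


@dataclass
class StatRecord:
    """Structured parse of one reported statistical result."""

    raw: str = ""
    symbol: str = "nonstandard"
    index_label: str = ""
    df1: float | None = None
    df2: float | None = None
    stat_op: str | None = None
    stat_value: float | None = None
    value_str: str = ""
    se: float | None = None
    se_str: str = ""
    effects: list[Effect] = field(default_factory=list)
    p_op: str | None = None
    p_reported: float | None = None
    p_str: str = ""
    bf_direction: str | None = None  # "H1_over_H0" | "H0_over_H1"
    flags: set[str] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    @property
    def is_standard(self) -> bool:
        return self.symbol in STANDARD_SYMBOLS or self.symbol == "p_only"

    def to_dict(self) -> dict:
        return {
            "raw": self.raw,
            "symbol": self.symbol,
            "index_label": self.index_label,
            "df1": self.df1,
            "df2": self.df2,
            "stat_op": self.stat_op,
            "stat_value": self.stat_value,
            "se": self.se,
            "effects": [(e.measure, e.op, e.value) for e in self.effects],
            "p_op": self.p_op,
            "p_reported": self.p_reported,
            "bf_direction": self.bf_direction,
            "flags": sorted(self.flags),
            "warnings": list(self.warnings),
        }


@dataclass
class Recomputation:
    """Recomputed p values for one record.

    ``method`` names the distribution route taken; ``none`` means no
    recomputation was possible (missing dfs, out-of-range statistic, or a
    statistic such as U or BF for which no route is defined).
    """

    p_two_sided: float | None = None
    p_one_sided: float | None = None
    method: str = "none"

    @property
    def possible(self) -> bool:
        return self.p_two_sided is not None


#: Checkability taxonomy: a result whose recomputed p can be compared with a
#: reported one is *checkable*; one that merely allows recomputation is
#: *computable*; anything else is *uncomputable*.
CHECKABLE = "checkable"
COMPUTABLE = "computable"
UNCOMPUTABLE = "uncomputable"


@dataclass
class ConsistencyFlag:
    """Verdict from comparing a reported p value against its recomputation."""

    verdict: str  # consistent | inconsistent | decision_error | indeterminate | not_checkable
    reported_interval: tuple[float, float] | None = None
    recomputed: float | None = None
    note: str = ""
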