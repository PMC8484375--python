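"""Recompute p values from parsed records and classify checkability.

Two-sided recomputation routes: Z via the standard normal, t via Student's
t, F via the F distribution, chi-square-family statistics (chi2, Q, H, G2)
via the chi-square distribution with the reported df, and r via the exact
transform t = r * sqrt(df / (1 - r^2)).  One-sided p values (upper tail of
the signed statistic) exist for t, Z and r only.  U statistics and Bayes
factors carry no recomputation.  A Z statistic can be estimated as
coefficient/SE for beta and d values reported with a standard error but no
test statistic.
"""

from __future__ import annotations

import math

from scipy import stats

from .records import (
    CHECKABLE,
    COMPUTABLE,
    UNCOMPUTABLE,
    Z_ESTIMATED,
    Recomputation,
    StatRecord,
)

_CHISQ_FAMILY = {"chi2", "Q", "H", "G2"}


def p_from_stat(
    symbol: str,
    stat_value: float,
    df1: float | None = None,
    df2: float | None = None,
    tails: str = "two",
) -> float | None:
    """p value for one statistic, or None when no route exists.

    Two-sided: Z: 2*(1-Phi(|z|)); t: 2*(1-T_df(|t|)); F: 1-F_{df1,df2}(f);
    chi-square family: 1-ChiSq_df(x); r: via the t transform.  One-sided
    (t, Z, r only): the upper tail of the signed statistic.
    """
    if stat_value is None:
        return None
    if symbol == "Z":
        if tails == "one":
            return float(stats.norm.sf(stat_value))
        return float(2.0 * stats.norm.sf(abs(stat_value)))
    if symbol == "t":
        if df1 is None:
            return None
        if tails == "one":
            return float(stats.t.sf(stat_value, df1))
        return float(2.0 * stats.t.sf(abs(stat_value), df1))
    if symbol == "F":
        if df1 is None or df2 is None or tails == "one":
            return None
        if stat_value < 0:
            return None
        return float(stats.f.sf(stat_value, df1, df2))
    if symbol in _CHISQ_FAMILY:
        if df1 is None or tails == "one":
            return None
        if stat_value < 0:
            return None
        return float(stats.chi2.sf(stat_value, df1))
    if symbol == "r":
        if df1 is None:
            return None
        if abs(stat_value) >= 1.0:
            return None
        t_val = stat_value * math.sqrt(df1 / (1.0 - stat_value**2))
        return p_from_stat("t", t_val, df1, tails=tails)
    return None


def estimate_z(coefficient: float, se: float) -> float | None:
    """Estimated Z statistic for a coefficient reported with its SE."""
    if se is None or se <= 0:
        return None
    return coefficient / se


def recompute(
    record: StatRecord, one_sided: bool = False, estimateZ: bool = False
) -> Recomputation:
    """Recompute p values for one record, choosing the distribution route
    from its symbol; optionally estimate Z for beta/d-with-SE records."""
    sym = record.symbol
    v = record.stat_value

    if sym in ("beta", "d") and estimateZ and record.se is not None and v is not None:
        z = estimate_z(v, record.se)
        if z is None:
            record.warnings.append("non-positive SE; Z not estimated")
            return Recomputation(method="none")
        record.flags.add(Z_ESTIMATED)
        return Recomputation(
            p_two_sided=p_from_stat("Z", z),
            p_one_sided=None,
            method="estimated_Z",
        )

    if v is None:
        return Recomputation(method="none")

    if sym == "r" and record.df1 is not None and abs(v) >= 1.0:
        record.warnings.append("|r| >= 1: outside valid range, p not recomputed")
        return Recomputation(method="none")
    if sym in _CHISQ_FAMILY | {"F"} and v < 0:
        record.warnings.append(f"negative {sym} value, p not recomputed")
        return Recomputation(method="none")

    p2 = p_from_stat(sym, v, record.df1, record.df2, tails="two")
    if p2 is None:
        return Recomputation(method="none")
    method = {
        "Z": "normal",
        "t": "student_t",
        "F": "fisher_F",
        "r": "r_via_t",
    }.get(sym, "chi_square")
    p1 = None
    if one_sided and sym in ("t", "Z", "r"):
        p1 = p_from_stat(sym, v, record.df1, tails="one")
    return Recomputation(p_two_sided=p2, p_one_sided=p1, method=method)


def classify(record: StatRecord, recomp: Recomputation) -> str:
    """checkable (recomputable p AND reported p), computable (recomputable
    p), or uncomputable.  'ns' reports with a recomputable statistic are
    computable, not checkable."""
    if recomp.possible and record.p_reported is not None:
        return CHECKABLE
    if recomp.possible:
        return COMPUTABLE
    return UNCOMPUTABLE


def validate_ranges(record: StatRecord) -> list[str]:
    """Range warnings for reported p, r and R2 values; the record is kept."""
    warnings: list[str] = []
    if record.p_reported is not None and not 0.0 <= record.p_reported <= 1.0:
        warnings.append(f"reported p value {record.p_reported} outside [0, 1]")
    if record.symbol == "r" and record.stat_value is not None and abs(record.stat_value) > 1:
        warnings.append(f"reported r value {record.stat_value} outside [-1, 1]")
    if record.symbol == "R2" and record.stat_value is not None and not 0.0 <= record.stat_value <= 1.0:
        warnings.append(f"reported R2 value {record.stat_value} outside [0, 1]")
    for eff in record.effects:
        if eff.measure == "R2" and not 0.0 <= eff.value <= 1.0:
            warnings.append(f"reported R2 value {eff.value} outside [0, 1]")
    record.warnings.extend(warnings)
    return warnings
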