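"""p-value recomputation against independent density-integration oracles.

The oracles integrate hand-written density formulas numerically
(scipy.integrate.quad over the textbook pdf expressions) and are entirely
independent of the closed-form survival functions used by the
implementation.
"""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from statextract import (
    classify,
    estimate_z,
    p_from_stat,
    parse_one,
    recompute,
    validate_ranges,
)

# ------------------------------------------------- hand-written densities


def norm_pdf(x):
    return math.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)


def t_pdf(x, df):
    c = math.gamma((df + 1) / 2.0) / (math.sqrt(df * math.pi) * math.gamma(df / 2.0))
    return c * (1.0 + x * x / df) ** (-(df + 1) / 2.0)


def chi2_pdf(x, df):
    if x <= 0:
        return 0.0
    return x ** (df / 2.0 - 1.0) * math.exp(-x / 2.0) / (
        2.0 ** (df / 2.0) * math.gamma(df / 2.0)
    )


def f_pdf(x, d1, d2):
    if x <= 0:
        return 0.0
    logc = (
        0.5 * d1 * math.log(d1 / d2)
        + math.lgamma((d1 + d2) / 2.0)
        - math.lgamma(d1 / 2.0)
        - math.lgamma(d2 / 2.0)
    )
    logf = (d1 / 2.0 - 1.0) * math.log(x) - ((d1 + d2) / 2.0) * math.log(
        1.0 + d1 * x / d2
    )
    return math.exp(logc + logf)


def upper_tail(pdf, x, *args):
    val, _ = quad(pdf, x, np.inf, args=args, limit=200)
    return val


# --------------------------------------------------------------- oracles


def test_z_two_sided_matches_normal_integration():
    for z in (0.5, 1.0, 1.96, 2.58, 3.5):
        assert p_from_stat("Z", z) == pytest.approx(
            2.0 * upper_tail(norm_pdf, z), abs=1e-8
        )


def test_t_two_sided_matches_density_integration():
    for v, df in [(1.0, 5), (1.96, 89), (2.5, 12), (3.2, 40), (0.3, 2)]:
        assert p_from_stat("t", v, df) == pytest.approx(
            2.0 * upper_tail(t_pdf, v, df), abs=1e-8
        )


def test_chi2_family_matches_density_integration():
    for v, df in [(3.841, 1), (7.81, 3), (12.3, 12), (30.1, 20)]:
        expected = upper_tail(chi2_pdf, v, df)
        for sym in ("chi2", "Q", "H", "G2"):
            assert p_from_stat(sym, v, df) == pytest.approx(expected, abs=1e-8)


def test_f_matches_density_integration():
    for v, d1, d2 in [(3.12, 2, 12), (21.0, 1, 46), (0.12, 12, 1222), (5.0, 5, 60)]:
        assert p_from_stat("F", v, d1, d2) == pytest.approx(
            upper_tail(f_pdf, v, d1, d2), abs=1e-8
        )


def test_r_equals_t_transform():
    for r, df in [(0.52, 13), (0.12, 18), (-0.4, 30)]:
        t_val = r * math.sqrt(df / (1 - r * r))
        assert p_from_stat("r", r, df) == pytest.approx(
            2.0 * upper_tail(t_pdf, abs(t_val), df), abs=1e-8
        )


def test_r_null_distribution_monte_carlo():
    """The r route agrees with the simulated null of the sample correlation
    at n = 15 (df = 13)."""
    rng = np.random.default_rng(42)
    n, reps = 15, 40000
    x = rng.standard_normal((reps, n))
    y = rng.standard_normal((reps, n))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r_null = (xc * yc).sum(axis=1) / np.sqrt(
        (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
    )
    observed = 0.52
    mc_p = float(np.mean(np.abs(r_null) >= observed))
    assert p_from_stat("r", observed, 13) == pytest.approx(mc_p, abs=0.01)


# ----------------------------------------------------------- invariants


def test_one_sided_is_half_of_two_sided_for_positive_stats():
    for v in (0.1, 0.5, 1.0, 2.0, 3.3):
        assert p_from_stat("Z", v, tails="one") == pytest.approx(
            p_from_stat("Z", v) / 2.0, abs=1e-12
        )
        for df in (3, 30, 300):
            assert p_from_stat("t", v, df, tails="one") == pytest.approx(
                p_from_stat("t", v, df) / 2.0, abs=1e-12
            )


def test_monotone_decreasing_in_statistic_magnitude():
    grids = {
        "Z": [(v, None, None) for v in np.linspace(0.1, 4, 10)],
        "t": [(v, 15, None) for v in np.linspace(0.1, 4, 10)],
        "F": [(v, 3, 40) for v in np.linspace(0.1, 10, 10)],
        "chi2": [(v, 5, None) for v in np.linspace(0.1, 30, 10)],
        "r": [(v, 20, None) for v in np.linspace(0.05, 0.95, 10)],
    }
    for sym, grid in grids.items():
        ps = [p_from_stat(sym, v, d1, d2) for v, d1, d2 in grid]
        assert all(a > b for a, b in zip(ps, ps[1:])), sym


def test_t_converges_to_z_at_huge_df():
    for v in (0.5, 1.96, 3.0):
        assert p_from_stat("t", v, 1e6) == pytest.approx(
            p_from_stat("Z", v), abs=1e-4
        )


def test_f_with_one_numerator_df_equals_squared_t():
    for t_val, df in [(1.5, 10), (2.2, 28), (3.0, 100)]:
        assert p_from_stat("F", t_val**2, 1, df) == pytest.approx(
            p_from_stat("t", t_val, df), abs=1e-10
        )


def test_no_recomputation_routes():
    assert p_from_stat("U", 55.0, 10) is None
    assert p_from_stat("BF", 2.0) is None
    assert p_from_stat("t", 2.0, None) is None
    assert p_from_stat("F", 2.0, 3, None) is None


def test_out_of_range_statistics_yield_no_p():
    assert p_from_stat("r", 1.2, 13) is None
    assert p_from_stat("F", -1.0, 2, 10) is None
    assert p_from_stat("chi2", -0.5, 3) is None


# ------------------------------------------------------- Z estimation


@pytest.mark.parametrize(
    "coef, se, expected",
    [(22.0, 0.77, 28.571428), (0.0, 1.0, 0.0), (1.1, 0.71, 1.549296)],
)
def test_estimate_z(coef, se, expected):
    assert estimate_z(coef, se) == pytest.approx(expected, rel=1e-6)


def test_estimate_z_rejects_nonpositive_se():
    assert estimate_z(1.0, 0.0) is None
    assert estimate_z(1.0, -2.0) is None


def test_estimated_z_feeds_normal_recomputation():
    (rec,) = parse_one("beta = 1.1, SE = .71")
    recomp = recompute(rec, estimateZ=True)
    assert recomp.method == "estimated_Z"
    z = 1.1 / 0.71
    assert recomp.p_two_sided == pytest.approx(2.0 * upper_tail(norm_pdf, z), abs=1e-8)
    assert classify(rec, recomp) == "computable"


# ------------------------------------------------------ classification


@pytest.mark.parametrize(
    "text, expected",
    [
        ("t(89) = 1.96, p = .05", "checkable"),
        ("t(89) = 1.96", "computable"),
        ("r = .12, p < .05", "uncomputable"),
        ("t(18) = 1.1, ns", "computable"),
        ("t>2", "uncomputable"),
        ("p<0.05", "uncomputable"),
        ("chi2(12) = 12.3", "computable"),
    ],
)
def test_checkability_taxonomy(text, expected):
    (rec,) = parse_one(text)
    assert classify(rec, recompute(rec)) == expected


def test_every_record_gets_exactly_one_category(small_corpus, default_opts):
    from statextract import parse_jats, process_article

    for art in small_corpus[:6]:
        rep = process_article(parse_jats(art.xml), 1, default_opts)
        assert len(rep.categories) == len(rep.records)
        assert set(rep.categories) <= {"checkable", "computable", "uncomputable"}


# ------------------------------------------------------- range warnings


@pytest.mark.parametrize(
    "text, n_warnings",
    [
        ("t(12) = 2.0, p = 1.2", 1),
        ("r(13) = -.3, p = .3", 0),
        ("R2 = 1.4, p = .01", 1),
        ("r = 1.3, p = .01", 1),
    ],
)
def test_reported_value_range_warnings(text, n_warnings):
    (rec,) = parse_one(text)
    rec.warnings.clear()
    assert len(validate_ranges(rec)) == n_warnings
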