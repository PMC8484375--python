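"""Synthetic JATS articles with planted, ground-truthed statistical results.

The generator emulates the reporting dialects found in real psychology
articles (APA style, labeled degrees of freedom, semicolon separators,
indexed statistics, fractions, percent R2, e-notation Bayes factors, 'ns'
reports, corrected p values, multi-result shorthand, coefficients with
standard errors, and interval reports) and embeds them in grammatical
carrier sentences inside a four-section JATS document.  Every plant is
recorded with the canonical string and category the pipeline is expected
to recover, so extraction recall and precision are measurable without any
downloaded corpus.  ``corrupt_for_pdf`` additionally emulates the operator
destruction typical of PDF-to-XML conversion.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict

import numpy as np
from lxml import etree
from scipy import stats

from .render import format_float, format_float_nozero
from .textnorm import _STAT_TOKEN  # context pattern shared with the repairer

DIALECTS = (
    "apa_t", "apa_F", "apa_r", "apa_Z", "apa_chi2",
    "labeled_df", "semicolon", "indexed", "fraction", "percent_R2",
    "enotation_BF", "ns", "corrected_p", "multi_result", "beta_SE",
    "interval",
)

#: dialects excluded from exact-recall scoring (acknowledged artifacts)
ARTIFACT_DIALECTS = frozenset({"interval"})

SECTION_TARGETS = ("abstract", "method", "results", "discussion", "footnote")


@dataclass
class PlantedResult:
    dialect: str
    section_target: str
    input_text: str
    expected_canonical: str
    expected_category: str  # checkable | computable | uncomputable
    expected_significant: bool
    article_id: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), ensure_ascii=False)


@dataclass
class FixtureSpec:
    n_articles: int = 10
    results_low: int = 2
    results_high: int = 6
    dialect_weights: dict | None = None
    seed: int = 0


@dataclass
class FixtureArticle:
    article_id: str
    xml: str
    plants: list[PlantedResult] = field(default_factory=list)


# --------------------------------------------------------------- dialects

def _pstr(p: float, k: int = 3) -> str:
    s = f"{p:.{k}f}"
    return s[1:] if s.startswith("0.") else s


def _two_sided_t(v: float, df: int) -> float:
    return float(2.0 * stats.t.sf(abs(v), df))


def _plant_apa_t(rng) -> PlantedResult:
    df = int(rng.integers(5, 120))
    v = round(float(rng.uniform(0.3, 5.0)), 2)
    p = _two_sided_t(v, df)
    pv = round(p, 3)
    frag = f"t({df}) = {v:.2f}, p = {_pstr(pv)}"
    return PlantedResult(
        "apa_t", "", frag, f"t({df}) = {v:.2f}, p = {_pstr(pv)}",
        "checkable", p <= 0.05 or pv <= 0.05,
    )


def _plant_apa_F(rng) -> PlantedResult:
    df1 = int(rng.integers(1, 10))
    df2 = int(rng.integers(10, 200))
    v = round(float(rng.uniform(0.1, 15.0)), 2)
    p = float(stats.f.sf(v, df1, df2))
    thr = float(rng.choice([0.05, 0.01]))
    if p < thr:
        frag = f"F({df1}, {df2}) = {v:.2f}, p < {_pstr(thr, 2)}"
        canon = f"F({df1}, {df2}) = {v:.2f}, p<{_pstr(thr, 2)}"
        sig = True
    else:
        frag = f"F({df1}, {df2}) = {v:.2f}, p > {_pstr(thr, 2)}"
        canon = f"F({df1}, {df2}) = {v:.2f}, p>{_pstr(thr, 2)}"
        sig = p <= 0.05
    return PlantedResult("apa_F", "", frag, canon, "checkable", sig)


def _plant_apa_r(rng) -> PlantedResult:
    df = int(rng.integers(10, 100))
    r = round(float(rng.uniform(0.1, 0.8)), 2)
    t_val = r * np.sqrt(df / (1.0 - r**2))
    p = _two_sided_t(float(t_val), df)
    pv = round(p, 3)
    rstr = f"{r:.2f}"[1:]
    frag = f"r({df}) = {rstr}, p = {_pstr(pv)}"
    return PlantedResult(
        "apa_r", "", frag, frag, "checkable", p <= 0.05 or pv <= 0.05
    )


def _plant_apa_Z(rng) -> PlantedResult:
    v = round(float(rng.uniform(0.3, 4.0)), 2)
    p = float(2.0 * stats.norm.sf(v))
    pv = round(p, 3)
    frag = f"Z = {v:.2f}, p = {_pstr(pv)}"
    return PlantedResult(
        "apa_Z", "", frag, frag, "checkable", p <= 0.05 or pv <= 0.05
    )


def _plant_apa_chi2(rng) -> PlantedResult:
    df = int(rng.integers(1, 20))
    v = round(float(rng.uniform(0.5, 40.0)), 2)
    p = float(stats.chi2.sf(v, df))
    thr = 0.05
    op = "<" if p < thr else ">"
    frag = f"chi2({df}) = {v:.2f}, p {op} .05"
    canon = f"chi2({df}) = {v:.2f}, p{op}.05"
    return PlantedResult("apa_chi2", "", frag, canon, "checkable", p <= 0.05)


def _plant_labeled_df(rng) -> PlantedResult:
    df = int(rng.integers(5, 120))
    v = round(float(rng.uniform(2.0, 5.0)), 2)
    p = _two_sided_t(v, df)
    frag = f"t = {v:.2f}, df = {df}, p < .05" if p < 0.05 else \
        f"t = {v:.2f}, df = {df}, p > .05"
    op = "<" if p < 0.05 else ">"
    canon = f"t({df}) = {v:.2f}, p{op}.05"
    return PlantedResult("labeled_df", "", frag, canon, "checkable", p <= 0.05)


def _plant_semicolon(rng) -> PlantedResult:
    df1 = int(rng.integers(1, 6))
    df2 = int(rng.integers(1000, 3000))
    v = round(float(rng.uniform(4.0, 30.0)), 2)
    p = float(stats.f.sf(v, df1, df2))
    df2_str = f"{df2:,}"
    frag = f"F({df1}; {df2_str}) = {v:.2f}; p < .05"
    canon = f"F({df1}, {df2}) = {v:.2f}, p<.05"
    return PlantedResult("semicolon", "", frag, canon, "checkable", True)


def _plant_indexed(rng) -> PlantedResult:
    df1 = int(rng.integers(1, 6))
    df2 = int(rng.integers(10, 120))
    v = round(float(rng.uniform(8.0, 20.0)), 2)
    p = float(stats.f.sf(v, df1, df2))
    label = str(rng.choice(["interaction", "model", "contrast", "2"]))
    frag = f"F{label}({df1}, {df2}) = {v:.2f}, p < .05"
    canon = f"F({df1}, {df2}) = {v:.2f}, p<.05"
    return PlantedResult("indexed", "", frag, canon, "checkable", True)


def _plant_fraction(rng) -> PlantedResult:
    df = int(rng.integers(5, 60))
    b = int(rng.choice([2, 4, 5, 8]))
    a = int(rng.integers(1, 2 * b))
    v = a / b
    p = _two_sided_t(v, df)
    op = "<" if p < 0.05 else ">"
    frag = f"t({df}) = {a}/{b}, p {op} .05"
    canon = f"t({df}) = {format_float_nozero(v)}, p{op}.05"
    return PlantedResult("fraction", "", frag, canon, "checkable", p <= 0.05)


def _plant_percent_R2(rng) -> PlantedResult:
    x = int(rng.integers(1, 80))
    delta = bool(rng.random() < 0.5)
    prefix = "ΔR2" if delta else "R2"
    frag = f"{prefix} = {x}%, p < .05"
    canon = f"R2 = {format_float_nozero(x / 100.0)}, p<.05"
    return PlantedResult("percent_R2", "", frag, canon, "uncomputable", True)


def _plant_enotation_BF(rng) -> PlantedResult:
    m = int(rng.choice([1, 2, 4, 5, 8]))
    k = int(rng.integers(1, 4))
    inv = 1.0 / (m * 10**k)
    frag = f"BF(01) = {m}e{k}"
    canon = f"BF(10) = {format_float(inv)}"
    return PlantedResult("enotation_BF", "", frag, canon, "uncomputable", False)


def _plant_ns(rng) -> PlantedResult:
    df = int(rng.integers(10, 60))
    v = round(float(rng.uniform(0.2, 1.2)), 2)
    p = _two_sided_t(v, df)
    frag = f"t({df}) = {v:.2f}, ns"
    canon = f"t({df}) = {v:.2f}"
    return PlantedResult("ns", "", frag, canon, "computable", p <= 0.05)


def _plant_corrected_p(rng) -> PlantedResult:
    df = int(rng.integers(30, 200))
    v = round(float(rng.uniform(3.0, 6.0)), 2)
    frag = f"t({df}) = {v:.2f}, p < .05/2"
    canon = f"t({df}) = {v:.2f}, p<.025"
    return PlantedResult("corrected_p", "", frag, canon, "checkable", True)


def _plant_multi_result(rng) -> PlantedResult:
    df = int(rng.integers(10, 60))
    v = round(float(rng.uniform(3.5, 8.0)), 1)
    frag = f"all ts({df}) > {v}, ps < .01"
    canon = f"t({df})>{v}, p<.01"
    return PlantedResult("multi_result", "", frag, canon, "checkable", True)


def _plant_beta_SE(rng) -> PlantedResult:
    b = round(float(rng.uniform(0.5, 25.0)), 2)
    se = round(float(rng.uniform(0.1, 2.0)), 2)
    with_p = bool(rng.random() < 0.5)
    sestr = f"{se:.2f}"
    if with_p:
        frag = f"beta = {b:.2f}, SE = {sestr}, p < .01"
        canon = f"beta = {b:.2f}, SE = {sestr}, p<.01"
        return PlantedResult("beta_SE", "", frag, canon, "uncomputable", True)
    frag = f"beta = {b:.2f}, SE = {sestr}"
    return PlantedResult("beta_SE", "", frag, frag, "uncomputable", False)


def _plant_interval(rng) -> PlantedResult:
    lo = round(float(rng.uniform(0.05, 0.3)), 2)
    hi = round(lo + float(rng.uniform(0.05, 0.3)), 2)
    lostr, histr = f"{lo:.2f}"[1:], f"{hi:.2f}"[1:]
    frag = f"{lostr}<r<{histr}, .87<p<.65"
    canon = f"r = {histr}"
    return PlantedResult("interval", "", frag, canon, "uncomputable", False)


_PLANTERS = {
    "apa_t": _plant_apa_t,
    "apa_F": _plant_apa_F,
    "apa_r": _plant_apa_r,
    "apa_Z": _plant_apa_Z,
    "apa_chi2": _plant_apa_chi2,
    "labeled_df": _plant_labeled_df,
    "semicolon": _plant_semicolon,
    "indexed": _plant_indexed,
    "fraction": _plant_fraction,
    "percent_R2": _plant_percent_R2,
    "enotation_BF": _plant_enotation_BF,
    "ns": _plant_ns,
    "corrected_p": _plant_corrected_p,
    "multi_result": _plant_multi_result,
    "beta_SE": _plant_beta_SE,
    "interval": _plant_interval,
}


# ------------------------------------------------------ carriers/distractors

_CARRIERS = (
    "The main effect was significant, {res}.",
    "As predicted, the difference was reliable, {res}, supporting our hypothesis.",
    "The analysis revealed a clear effect ({res}).",
    "Group comparisons showed the expected pattern, {res}.",
    "This contrast reached the criterion, {res}, in the full sample.",
)

_CARRIER_FOOTNOTE = "In a footnote we note that the control contrast gave {res}."

_DISTRACTORS = (
    "The sample comprised 48 students from 6 classes.",
    "Participants completed the task twice during 2019.",
    "Stimuli appeared on screen for 500 ms each.",
    "We measured performance across all sessions without incident.",
    "Three raters coded the responses independently.",
)

_ABSTRACT_LEAD = "We report a preregistered study on attentional control. "
_INTRO = (
    "Prior work suggests that attentional control varies across contexts. "
    "We designed two experiments to examine this question."
)
_METHOD_LEAD = "Participants performed a cued detection task. "
_DISCUSSION_LEAD = "The findings replicate earlier reports. "

#: a tabulated result that must NOT be extracted (tables are out of scope)
_TABLE_RESULT = "F(1, 10) = 9.10, p < .01"


# ------------------------------------------------------------ article build

def _section_for(rng) -> str:
    return str(
        rng.choice(
            np.array(SECTION_TARGETS),
            p=[0.1, 0.15, 0.55, 0.1, 0.1],
        )
    )


def render_article(spec: FixtureSpec, seed: int | None = None,
                   article_id: str = "art-0") -> FixtureArticle:
    """One synthetic JATS article with planted results and ground truth."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_results = int(rng.integers(spec.results_low, spec.results_high + 1))

    dialects = list(_PLANTERS)
    if spec.dialect_weights:
        weights = np.array([spec.dialect_weights.get(d, 0.0) for d in dialects])
    else:
        weights = np.ones(len(dialects))
    weights = weights / weights.sum()

    plants: list[PlantedResult] = []
    for _ in range(n_results):
        dialect = str(rng.choice(np.array(dialects), p=weights))
        plant = _PLANTERS[dialect](rng)
        plant.section_target = _section_for(rng)
        plant.article_id = article_id
        plants.append(plant)

    def _carrier(plant: PlantedResult) -> str:
        if plant.section_target == "footnote":
            return _CARRIER_FOOTNOTE.format(res=plant.input_text)
        tpl = _CARRIERS[int(rng.integers(0, len(_CARRIERS)))]
        return tpl.format(res=plant.input_text)

    by_section: dict[str, list[str]] = {k: [] for k in SECTION_TARGETS}
    for plant in plants:
        by_section[plant.section_target].append(_carrier(plant))

    def _distract() -> str:
        return _DISTRACTORS[int(rng.integers(0, len(_DISTRACTORS)))]

    abstract = _ABSTRACT_LEAD + " ".join(by_section["abstract"]) + " " + _distract()
    method = _METHOD_LEAD + _distract() + " " + " ".join(by_section["method"])
    results = (
        " ".join(by_section["results"] + by_section["footnote"]) + " " + _distract()
    )
    discussion = _DISCUSSION_LEAD + " ".join(by_section["discussion"]) + " " + _distract()

    article = etree.Element("article")
    front = etree.SubElement(article, "front")
    meta = etree.SubElement(front, "article-meta")
    etree.SubElement(meta, "article-id").text = article_id
    abs_el = etree.SubElement(meta, "abstract")
    etree.SubElement(abs_el, "p").text = abstract.strip()
    body = etree.SubElement(article, "body")
    for title, text in (
        ("Introduction", _INTRO),
        ("Method", method),
        ("Results", results),
        ("Discussion", discussion),
    ):
        sec = etree.SubElement(body, "sec")
        etree.SubElement(sec, "title").text = title
        etree.SubElement(sec, "p").text = text.strip()
        if title == "Results":
            tw = etree.SubElement(sec, "table-wrap")
            etree.SubElement(tw, "table").text = _TABLE_RESULT

    xml = etree.tostring(article, pretty_print=True, encoding="unicode")
    return FixtureArticle(article_id=article_id, xml=xml, plants=plants)


def generate_corpus(spec: FixtureSpec) -> list[FixtureArticle]:
    """Deterministic corpus: same spec (incl. seed) -> byte-identical XML."""
    if spec.n_articles < 1:
        raise ValueError("corpus needs at least one article")
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=spec.n_articles)
    return [
        render_article(spec, seed=int(s), article_id=f"art-{i}")
        for i, s in enumerate(seeds)
    ]


# ------------------------------------------------------------- corruption

_CORRUPT_RE = re.compile(rf"\b({_STAT_TOKEN})\s*(<=|>=|[<>=])\s*(?=[-+]?[.\d])")

_GARBLE = {"=": "¼", "<": "˂", ">": "˃"}


@dataclass
class CorruptionInfo:
    n_destroyed: int = 0
    n_garbled: int = 0


def corrupt_for_pdf(
    xml: str, seed: int, rate: float = 1.0, garble_frac: float = 0.0
) -> tuple[str, CorruptionInfo]:
    """Emulate PDF-conversion operator loss on a clean fixture document.

    Each comparison operator standing between a statistic/p token and a
    number is, with probability ``rate``, destroyed (replaced by white
    space; repairable only as the sentinel ``<=>``) or — with probability
    ``garble_frac`` among corrupted ones — garbled into a known ligature
    artifact that the repairer can restore exactly.
    """
    rng = np.random.default_rng(seed)
    info = CorruptionInfo()
    root = etree.fromstring(xml.encode("utf-8"))

    def _corrupt_text(text: str) -> str:
        def _sub(m: re.Match) -> str:
            if rng.random() >= rate:
                return m.group(0)
            op = m.group(2)
            if rng.random() < garble_frac and op in _GARBLE:
                info.n_garbled += 1
                return f"{m.group(1)} {_GARBLE[op]} "
            info.n_destroyed += 1
            return f"{m.group(1)} "

        return _CORRUPT_RE.sub(_sub, text)

    for el in root.iter():
        if el.text:
            el.text = _corrupt_text(el.text)
        if el.tail:
            el.tail = _corrupt_text(el.tail)
    return etree.tostring(root, pretty_print=True, encoding="unicode"), info


def write_corpus(spec: FixtureSpec, outdir, corrupt_rate: float = 0.0,
                 garble_frac: float = 0.0) -> list[FixtureArticle]:
    """Write XML files plus a ground-truth JSON-lines file to *outdir*."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    articles = generate_corpus(spec)
    with (outdir / "ground_truth.jsonl").open("w", encoding="utf-8") as gt:
        for art in articles:
            xml = art.xml
            if corrupt_rate > 0:
                xml, _ = corrupt_for_pdf(
                    xml, seed=spec.seed + 1, rate=corrupt_rate,
                    garble_frac=garble_frac,
                )
            (outdir / f"{art.article_id}.xml").write_text(xml, encoding="utf-8")
            for plant in art.plants:
                gt.write(plant.to_json() + "\n")
    return articles
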