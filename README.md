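# statextract

Extract, recompute and check statistical results reported in the running
text of scientific articles.

## The problem

Empirical reports — above all in psychology and the medical sciences —
state their evidence as in-text test results: `t(89) = 1.96, p = .05`,
`F(2, 12) = 3.12, p < .05`, `χ²(3) = 7.81, p < .05`. Meta-research on
reporting quality needs these results in structured form: to recount
significant findings, to recompute p values from test statistics and
degrees of freedom, and to flag reports whose stated p value disagrees
with the one their own numbers imply. In practice the results are buried
in prose, written in dozens of dialects (semicolons for commas, labeled
degrees of freedom, indexed statistics, fractions, percents, `ns`,
Bayes-factor subscripts), encoded in mixed character codecs, and — for
PDF-converted input — stripped of their comparison operators entirely.

`statextract` is a library, CLI and batch auditor for this task. It reads
NISO-JATS XML (the layout-free archiving standard for scientific
articles, including the output of PDF converters such as CERMINE) or
plain text, and runs a two-step extraction:

1. **Sticking.** Text is normalized to one canonical dialect (HTML
   entities and Greek letters resolved, garbled operators repaired,
   destroyed operators replaced by the sentinel `<=>`), split into
   sentences, and every sentence containing a letter and an operator
   pointing to a number is decomposed into unified *sticked results* —
   one string per reported result, numbers compiled to decimals.
2. **Parsing.** Each sticked result is parsed into a structured record:
   statistic symbol (`Z, t, F, χ², r, Q, H, G², U, BF` and the effect
   measures `β, d, η², OR, RR, R²`), degrees of freedom, operator, value,
   standard error, attached p value.

Where the record permits, the two-sided p value is recomputed from the
standard distribution laws —

- `Z`: p = 2·(1 − Φ(|z|))
- `t`: p = 2·(1 − T_ν(|t|))
- `F`: p = 1 − F_{ν₁,ν₂}(f)
- `χ², Q, H, G²`: p = 1 − χ²_ν(x)
- `r`: via t = r·√(ν/(1 − r²))

— with optional one-sided p values for `t`, `Z`, `r` and an optional
Z ≈ β/SE estimate for coefficients reported with a standard error. Every
result is classified as **checkable** (recomputable p that is also
reported), **computable** (recomputable p, none reported), or
**uncomputable**, and an opt-in consistency check compares reported
against recomputed p values, flagging *decision errors* where the two
fall on opposite sides of the significance threshold.

## Worked example

```python
from statextract import get_stats, parse_one, recompute, classify, check_consistency

get_stats("The interaction was significant, Finteraction(1, 46) = 21; p<.05, as expected.")
# ['F(1, 46) = 21, p<.05']

rec, = parse_one("t(28) = 2.2, p = .036")
recomp = recompute(rec)
print(round(recomp.p_two_sided, 6))        # 0.036225
print(classify(rec, recomp))               # checkable
print(check_consistency(rec, recomp).verdict)  # consistent
```

The recomputed two-sided p value 0.036225 lies inside the rounding
interval [.0355, .0365) of the reported `.036`, so the report is
consistent. The same record reported as `p > .05` would be a decision
error: its recomputed p is significant at α = .05 while the report
claims otherwise.

From the shell:

```sh
statextract fixtures --n 10 --seed 1 --out corpus/   # synthetic ground-truthed corpus
statextract extract corpus/art-0.xml --text-mode 2 --output checkable --check
statextract audit corpus/*.xml --check               # per-article counts + corpus summary
```

`--text-mode` restricts the search scope: 1 = full text and abstract,
2 = method and result sections, 3 = result sections only.

## Scope

Results printed in tables are excluded by design (table layouts cannot
be compiled reliably); PDF-to-XML conversion itself, and heuristics for
study methods, software or sample counts, are out of scope.
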