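# Methods

## Extraction model

A *potential statistical result* is any letter or letter–number
combination pointing to a number through a comparison operator
(`<, >, =, <=, >=`). Extraction is a two-step procedure.

**Step 1 — sticking.** Input text is normalized (below), split into
sentences (square brackets are first converted to round brackets, and
boundaries are never placed inside brackets, after common abbreviations,
or inside numbers), and sentences with at least one letter and an
operator followed by a number are selected. Candidates are split into
fragments at a configurable word list (`and`, `or`, `were`, `of`, … —
shipped as data in `data/stopwords.json`, since no canonical list
exists) and at any prose word immediately followed by a comma. Each
fragment is trimmed: leading text before the first letter-anchored
token-with-operator is removed, as is everything behind the last
operator pointing to a number (an `ns` marker is retained as a flag).
Number representations are unified: thousands commas in values ≥ 1000
removed, `e`-notation and percents compiled to decimals, and
value-level arithmetic (`1/2`, `.05/2`, `.05*3`) evaluated — one rule
covers both fraction values and corrected p values. A fragment holding
several complete results is split again under the assumption that a
test statistic is reported in front of its p value: a new result starts
at a statistic token that follows a p comparison. By the same
assumption, a single trailing p value in a two-statistic fragment
(`r(12) = .22, Z = .75, p = .45`) attaches to the nearest preceding
statistic, and such fragments are *not* split.

**Step 2 — parsing.** Each sticked result is split at top-level commas
into items. Statistic labels and indices are stripped (digit suffixes,
lowercase word suffixes of length ≥ 3, plural `s`); capital `T`/`R`
promote to `t`/`r` only under the opt-in `T2t`/`R2r` options, flagged.
The letter combinations `rp, sr, pr, LR, I2`, bare squared tokens, and
the single letters `A, B, c, d` with bracketed degrees of freedom are
never standard statistics — their p value alone survives. Degrees of
freedom are read from round brackets or from labeled items
(`df = 12`, `df1/df2`); non-positive dfs are dropped with a warning.
`BF(01) = x` is inverted to the H1-over-H0 scale as `BF(10) = 1/x`
(x = 0 rejects the record). Effect measures attach to an open test
statistic record when one exists and otherwise open their own record.

## Checkability and consistency

A record is **checkable** when its p value can be recomputed *and* a
p value is reported, **computable** when recomputation alone is
possible (`ns` reports with a recomputable statistic are computable,
not checkable), and **uncomputable** otherwise. `U` statistics and
Bayes factors carry no recomputation route (group sizes and priors are
not recoverable from the statistic); `Q`, `H` and `G²` are evaluated on
the chi-square distribution with the reported df, the standard
asymptotic reference.

Consistency checking is opt-in, because deviations are multicausal
(directed tests, rounding, typos, conversion errors). `p = v` reported
with k decimals is consistent iff the recomputed p lies in the
half-open rounding interval `[v − 0.5·10⁻ᵏ, v + 0.5·10⁻ᵏ)`; trailing
zeros count as claimed precision. Bounds (`<, <=, >, >=`) are taken
literally. An inconsistency whose reported and recomputed p fall on
opposite sides of α (default 0.05) is a *decision error*. The sentinel
operator `<=>` ("operator unknown") is always *indeterminate*, and for
significance filtering a sentinel report at a value ≤ α is counted as
potentially significant and flagged — the conservative reading, since
it is indistinguishable from a significant report.

One-sided p values (upper tail of the signed statistic; available for
`t`, `Z`, `r`) are computed only on request; a record inconsistent
two-sided but consistent one-sided is rescued as consistent with a
note, again only under the one-sided option.

## Character normalization and operator repair

The canonical dialect is plain ASCII: Greek letters become their
spelled-out names (`β → beta`, `χ² → chi2`, `η² → eta2`), HTML named
entities and numeric character references (decimal and hex) are
decoded, relational glyphs collapse to `<=`, `>=`, `-`; the table lives
in `data/entities.json`. `Delta` directly before `R2` is dropped (the
incremental-variance share keeps only its R² reading) and logged.
Undecodable bytes become a neutral placeholder, logged, never raised.
Every replacement is recorded as (position, original, replacement,
rule), serializable as JSON lines; 1:1-length rules are invertible.

Operator repair is deliberately narrow: only between a recognized
statistic/p token and an adjacent number is a known corruption glyph
(e.g. `¼`, the Times-encoding artifact for `=`) restored, or a missing
operator replaced by `<=>`. Prose is never touched. The corruption map
is curated data (`data/operator_corruptions.json`), not code, because
converter artifacts vary by toolchain and era.

## Text scope

JATS parsing keeps paragraph text per section and drops tables,
figures and graphics outright — tabulated results cannot be compiled
reliably and are out of scope. Scope modes: 1 = abstract + full body,
2 = method- and result-like sections, 3 = result-like only. Title
classification uses case-insensitive substring sets (method-like:
`method, material, procedure, analys, statistic`; result-like:
`result, finding`), shipped as data so they are tunable; a subsection
inherits its ancestor's class unless its own title matches. Everything
in the body (acknowledgments, appendices) counts toward mode 1.
Footnote text stays with its owning section.

## Synthetic corpus

The fixture generator emulates the reporting dialects the extractor
must survive, not the science around them: each planted result is drawn
with realistic ranges (t/F/χ²/r values and dfs typical of behavioral
research; reported `p = v` strings are the correctly rounded recomputed
values, so clean plants are internally consistent), embedded in a
grammatical carrier sentence, and recorded with the exact canonical
string and category the pipeline should recover. Articles have the
conventional four sections plus abstract, distractor sentences with
numbers but no operators, and one tabulated result that must *not* be
extracted. `corrupt_for_pdf` destroys (or, optionally, garbles into
known ligature artifacts) the operators standing between a statistic
token and a number, with per-operator bookkeeping, so repair can be
scored exactly. What the generator does **not** emulate: genuinely
malformed sentence structure, OCR noise, statistics split across line
breaks, tables rendered as running text, and non-English prose —
perfect recall on fixtures therefore bounds, but does not guarantee,
performance on real articles. Interval reports (`.12<r<.22`) are
planted but excluded from recall scoring: they collapse to the upper
bound with `=`, an acknowledged artifact that is flagged
(`interval_artifact`) rather than silently accepted.

Test and acceptance runs use 25- and 200-article corpora with fixed
seeds — large enough that every dialect appears many times in every
section role, small enough to keep the whole suite in seconds.

## Numerical choices

- p values from `scipy.stats` survival functions; full precision
  internally, 6 significant digits in serialized output.
- Fractions are evaluated in exact rational arithmetic before float
  conversion.
- Canonical number formatting: values produced by arithmetic
  compilation (fractions, percents, corrected p) print without a
  leading zero (`.5`, `.34`, `.025`); e-notation compilation and BF
  inversion print plain decimals (`200`, `0.005`); untouched tokens
  keep their reported spelling.
- Division by zero in value arithmetic leaves the token untouched;
  `BF(01) = 0` rejects the record with a log entry.
- `|r| ≥ 1` with df, negative F or χ²: no recomputation, range
  warning, record kept.

## Known limitations

- The stop-word split list and section-title patterns are seeds, not
  exhaustive; both are data files meant to be extended per corpus.
- A second p value following a statistic that already has one opens a
  p-only record rather than rejecting the parse; genuinely
  contradictory duplicate reports are thus preserved, not flagged.
- Coordinates and other letter-number prose (`z = 3` in a coordinate
  triple) are indistinguishable from Z statistics and will be treated
  as computable results.
- An `r` reported without df is uncomputable even if the sample size
  appears elsewhere in the article; cross-sentence inference is not
  attempted.
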