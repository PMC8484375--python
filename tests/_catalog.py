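"""Catalogue of reporting dialects and their canonical unified forms.

Each pair maps one reported-result string, in a dialect observed in real
psychology articles, to the canonical sticked-result string the pipeline
is expected to produce (labels stripped, numbers compiled, separators
unified).  Empty-statistic dialects (nonstandard letters) survive only
through their p value.  The capital-T promotion option is assumed on.
"""

REPORTED_TO_CANONICAL = [
    # APA style
    ("t(12) = 1.9, p>.05", "t(12) = 1.9, p>.05"),
    ("F(2, 12) = 3.12, p<.05", "F(2, 12) = 3.12, p<.05"),
    ("r(13) = .52, p<.05", "r(13) = .52, p<.05"),
    ("Z = 1.9, p>.05", "Z = 1.9, p>.05"),
    ("Q(13) = .52, p>.05", "Q(13) = .52, p>.05"),
    # labeled degrees of freedom
    ("t = 1.9, df = 12, p>.05", "t(12) = 1.9, p>.05"),
    ("F = 3.12, df1 = 3, df2 = 14, p<.05", "F(3, 14) = 3.12, p<.05"),
    # separators and thousands commas
    ("F(1, 46) = 21; p<.05", "F(1, 46) = 21, p<.05"),
    ("F(12; 1,222) = .12, p<.05", "F(12, 1222) = .12, p<.05"),
    ("F(12; 122) = 2,123; p<.05", "F(12, 122) = 2123, p<.05"),
    # 'ns' instead of a p value
    ("t(12) = 1.9, ns", "t(12) = 1.9"),
    # effect size in between
    ("t(12) = 1.9, d = .2, p>.05", "t(12) = 1.9, d = .2, p>.05"),
    # multi-result shorthand
    ("all ts(27)>4.2, p<0.01", "t(27)>4.2, p<0.01"),
    ("all rs<0.2, all ps>.01", "r<0.2, p>.01"),
    # p value only
    ("p<0.05", "p<0.05"),
    # indexed/labeled statistics
    ("t2(122) = 1, p>.05", "t(122) = 1, p>.05"),
    ("Finteraction(1, 46) = 2.8, p<.05", "F(1, 46) = 2.8, p<.05"),
    ("G2(41) = 2.3, p<.05", "G2(41) = 2.3, p<.05"),
    # capital T promotion
    ("T(12) = 2.33, p<.05", "t(12) = 2.33, p<.05"),
    # number compilation
    ("t(12) = 1/2, p>.05", "t(12) = .5, p>.05"),
    ("t(122) = 3, p<.05/2", "t(122) = 3, p<.025"),
    # two statistics in a row share the trailing p
    ("r(12) = .22, Z = .75, p = .45", "r(12) = .22, Z = .75, p = .45"),
    # computable without p
    ("chi2(12) = 12.3", "chi2(12) = 12.3"),
    # coefficients with standard errors
    ("beta = 22, SE = .77, p<0.01", "beta = 22, SE = .77, p<0.01"),
    ("beta = 1.1, SE = .71", "beta = 1.1, SE = .71"),
    # percent R2 (incremental-variance reports drop the Delta)
    ("ΔR2 = 34%, p<.05", "R2 = .34, p<.05"),
    # Bayes factors
    ("beta = 1.2, BF(10)<1, p = .72", "beta = 1.2, BF(10)<1, p = .72"),
    ("BF(01) = 2e2", "BF(10) = 0.005"),
    # nonstandard statistics: only the p value survives
    ("rp(12) = .22, p = .45", "p = .45"),
    ("sr(12) = .22, p = .45", "p = .45"),
    ("pr(12) = .22, p = .45", "p = .45"),
    ("LR(12) = .1, p>.05", "p>.05"),
    ("I2(22) = 1, p>.05", "p>.05"),
    ("²(22) = 1, p>.05", "p>.05"),
    ("A(12) = 2.3, p<.05", "p<.05"),
    ("B(12) = 2.3, p<.05", "p<.05"),
    ("c(12) = 2.3, p<.05", "p<.05"),
    ("d(12) = 2.3, p<.05", "p<.05"),
    # interval reports collapse to the upper bound (acknowledged artifact)
    (".12<r<.22, .87<p<.65", "r = .22"),
]
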