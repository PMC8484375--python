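import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from statextract import ExtractionOptions, FixtureSpec, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """Deterministic 25-article synthetic corpus with ground truth."""
    return generate_corpus(FixtureSpec(n_articles=25, seed=11))


@pytest.fixture(scope="session")
def default_opts():
    return ExtractionOptions(T2t=True, R2r=True, check=True)


MINIMAL_JATS = b"""<article>
  <front><article-meta>
    <article-id>demo-1</article-id>
    <abstract><p>We tested attention, t(30) = 2.75, p = .010.</p></abstract>
  </article-meta></front>
  <body>
    <sec><title>Introduction</title><p>Prior work is mixed.</p></sec>
    <sec>
      <title>Method</title><p>We recruited 31 adults.</p>
      <sec><title>Statistical analyses</title><p>Alpha was set a priori.</p></sec>
    </sec>
    <sec><title>Results</title>
      <p>The effect was reliable, t(12) = 2.3, p = .04.</p>
      <table-wrap><table><tr><td>F(1, 10) = 9.1, p = .011</td></tr></table></table-wrap>
    </sec>
    <sec><title>Discussion</title><p>We replicate earlier findings, r(40) = .35, p = .02.</p></sec>
  </body>
</article>"""


@pytest.fixture()
def minimal_jats():
    return MINIMAL_JATS
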