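import pytest

from crispr_outcomes.hdr import build_template_set
from crispr_outcomes.simulate import make_toy_locus


@pytest.fixture(scope="session")
def locus():
    return make_toy_locus()


@pytest.fixture(scope="session")
def template_set(locus):
    return build_template_set(locus.amplicon, locus.homolog, locus.odn)


@pytest.fixture(scope="session")
def overhang(locus):
    return locus.overhang()
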