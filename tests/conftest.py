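"""Shared fixtures: deterministic marker loci, designed amplicons, tags."""

import numpy as np
import pytest

from liqbio import MarkerVariant, TagSet, design_amplicon


def random_context(seed: int, length: int = 300) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), length))


@pytest.fixture(scope="session")
def snv_context():
    return random_context(11)


@pytest.fixture(scope="session")
def snv_marker(snv_context):
    ref = snv_context[150]
    alt = next(b for b in "ACGT" if b != ref)
    return MarkerVariant("P1", "TP53", "p.C275Y", "chr17", 151, ref, alt,
                         variant_class="missense")


@pytest.fixture(scope="session")
def snv_amplicon(snv_context, snv_marker):
    return design_amplicon(snv_context, 1, snv_marker)


@pytest.fixture(scope="session")
def ins_amplicon():
    ctx = random_context(12)
    marker = MarkerVariant("P2", "NPM1", "p.W288fs", "chr5", 151,
                           ctx[150], ctx[150] + "TCTG",
                           variant_class="frameshift")
    return design_amplicon(ctx, 1, marker)


@pytest.fixture(scope="session")
def del_amplicon():
    ctx = random_context(13)
    marker = MarkerVariant("P3", "WT1", "p.K459fs", "chr11", 151,
                           ctx[150:153], "", variant_class="frameshift")
    return design_amplicon(ctx, 1, marker)


@pytest.fixture(scope="session")
def tagset():
    return TagSet.default()
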