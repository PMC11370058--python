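import numpy as np
import pytest

from umispike import fixtures, spike


@pytest.fixture(scope="session")
def ref_small():
    """1-contig reference with two 700 bp targets."""
    return fixtures.make_reference(1, 2, 700, seed=1)


@pytest.fixture(scope="session")
def panel_small(ref_small):
    return fixtures.make_variant_panel(ref_small, 25, seed=3)


@pytest.fixture(scope="session")
def template_small(ref_small):
    return fixtures.make_template(ref_small, 80.0, 3.0, seed=7)


@pytest.fixture(scope="session")
def painted(template_small, panel_small):
    """(ref_lib, alt_lib) copies of the small template."""
    ref_lib, _ = spike.paint_alleles(template_small, panel_small, "ref")
    alt_lib, _ = spike.paint_alleles(template_small, panel_small, "alt")
    return ref_lib, alt_lib


@pytest.fixture(scope="session")
def annotation_dbs(ref_small, panel_small):
    return fixtures.make_annotation_dbs(panel_small, ref_small, seed=9)


def brute_alt_fraction(fragments, variant):
    """Independent per-locus pileup: plain loop over reads, no shared code."""
    pos0 = variant.pos - 1
    alt = depth = 0
    for frag in fragments:
        if frag.contig != variant.contig:
            continue
        for start, seq in ((frag.frag_start, frag.r1_seq),
                           (frag.r2_start, frag.r2_seq)):
            if start <= pos0 < start + len(seq):
                depth += 1
                alt += seq[pos0 - start] == variant.alt
    return (alt / depth if depth else None), depth
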