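import pytest

from mitorho.haplogroups import packaged_tree
from mitorho.haplotypes import FULL_RANGE, Haplotype, SeqRange
from mitorho.variants import parse_motif, parse_variant


def var(token: str):
    """Parse a token without reference-base validation (test shorthand)."""
    return parse_variant(token, ref_check="off")


def motif(text: str):
    return parse_motif(text, ref_check="off")


def hap(hid, variants=(), ranges=(FULL_RANGE,), **kwargs):
    if isinstance(variants, str):
        variants = motif(variants)
    return Haplotype(id=hid, ranges=tuple(SeqRange(*r) for r in ranges),
                     variants=frozenset(variants), **kwargs)


@pytest.fixture(scope="session")
def tree():
    return packaged_tree()
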