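import random

import pytest

from crispritools.genome_io import Feature, GenomeRecord
from crispritools.fixtures import (
    FixtureSpec,
    GeneSpec,
    OfftargetSpec,
    SrnaSpec,
    generate_fixture,
)


def make_genome(seq: str, rec_id: str = "chr", circular: bool = False):
    return [GenomeRecord(id=rec_id, seq=seq, circular=circular)]


def make_feature(start, end, strand="+", ftype="CDS", fid="g1", rec_id="chr", **kw):
    return Feature(
        id=fid, record_id=rec_id, start=start, end=end, strand=strand,
        ftype=ftype, **kw,
    )


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def standard_fixture():
    """A planted fixture exercising genes, sRNAs and off-target decoys."""
    spec = FixtureSpec(
        seed=11,
        record_length=3200,
        genes=(
            GeneSpec(length=300, planted_pams=(9, 60)),
            GeneSpec(length=150, strand="-", planted_pams=(12,)),
        ),
        srnas=(
            SrnaSpec(length=80),
            SrnaSpec(length=66, strand="-"),
            SrnaSpec(length=80, targetable=False),
            SrnaSpec(length=20, targetable=False),
        ),
        planted_offtargets=(OfftargetSpec(gene_index=0, pam_slot=0, copies=2),),
    )
    return generate_fixture(spec)
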