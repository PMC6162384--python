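import numpy as np
import pytest

from diplomethyl import (
    PhasedVariant,
    ReadObservation,
    VariantIndex,
    regression_fixture,
)


@pytest.fixture(scope="session")
def mini_dataset():
    """Small frozen diploid dataset shared across integration tests."""
    return regression_fixture("mini-diploid")


@pytest.fixture
def three_phv_index():
    variants = [
        PhasedVariant("chr1", 100, "A", "C"),
        PhasedVariant("chr1", 200, "G", "T"),
        PhasedVariant("chr1", 300, "T", "A"),
    ]
    return variants, VariantIndex(variants)


def make_read(read_id="r1", chrom="chr1", start=0, end=1000, phv_bases=None,
              cpg_ipd=None):
    return ReadObservation(
        read_id=read_id,
        chrom=chrom,
        start=start,
        end=end,
        phv_bases=phv_bases or {},
        cpg_ipd=cpg_ipd or {},
    )
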