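import numpy as np
import pytest

from mpralleles.oligo import VariantRecord


def make_genome(seed: int = 0, length: int = 600, chrom: str = "chr1") -> dict:
    rng = np.random.default_rng(seed)
    return {chrom: "".join(rng.choice(list("ACGT"), size=length))}


@pytest.fixture
def toy_genome() -> dict:
    return make_genome()


@pytest.fixture
def snp_variant(toy_genome) -> VariantRecord:
    chrom, seq = next(iter(toy_genome.items()))
    pos = 300  # 1-based; far from both ends
    ref = seq[pos - 1]
    alt = next(b for b in "ACGT" if b != ref)
    return VariantRecord(
        id="rs1", chrom=chrom, pos=pos, ref=ref, alts=(alt,), locus_id="L1"
    )
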