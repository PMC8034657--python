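import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from retentio.annotation_io import (
    GeneModel,
    GenomicInterval,
    Intron,
    JunctionCounts,
    Transcript,
    derive_introns,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def two_exon_gene() -> dict[str, GeneModel]:
    """One gene, one transcript, exons [0,100) and [200,300) on +."""
    tx = Transcript(
        "T1",
        [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)],
        biotype="protein_coding",
    )
    return {"GENE1": GeneModel("GENE1", "chr1", "+", [tx])}


@pytest.fixture
def simple_intron(two_exon_gene) -> Intron:
    return next(iter(derive_introns(two_exon_gene).values()))


def make_junctions(
    intron_id: str, spliced: int, five: int = 10, three: int = 10,
    sample_id: str = "s1",
) -> JunctionCounts:
    return JunctionCounts(
        pd.DataFrame(
            [
                {
                    "intron_id": intron_id,
                    "spliced": spliced,
                    "five_prime": five,
                    "three_prime": three,
                }
            ]
        ),
        sample_id,
    )


# ---------------------------------------------------------------------------
# NMD fixtures: a 3-exon gene on an all-alanine (stop-free) backbone
# ---------------------------------------------------------------------------


def make_nmd_gene(stop_at: int | None, retained: str):
    """Build a 3-exon plus-strand gene over a GCT-repeat chromosome.

    Exons at [0,90), [189,288), [387,486); introns i1=[90,189),
    i2=[288,387) — every feature length is a multiple of 3, so reading
    frame 0 is preserved whichever intron is retained.  ``stop_at`` places
    a TAA at that chromosome offset (must be a multiple of 3 to stay in
    frame from the ATG at 0); ``retained`` selects which intron ("i1" or
    "i2") is retained.  The genuine stop codon ends exon 3.
    """
    seq = list("GCT" * 162)  # 486 nt, no stop codon in frame 0
    seq[0:3] = "ATG"
    seq[483:486] = "TAA"
    if stop_at is not None:
        assert stop_at % 3 == 0
        seq[stop_at : stop_at + 3] = "TAA"
    chrom_seq = "".join(seq)
    exons = [
        GenomicInterval("chrN", 0, 90),
        GenomicInterval("chrN", 189, 288),
        GenomicInterval("chrN", 387, 486),
    ]
    tx = Transcript("TN", exons, biotype="protein_coding")
    gene = {"GN": GeneModel("GN", "chrN", "+", [tx])}
    introns = derive_introns(gene)
    key = "GN:chrN:90-189:+" if retained == "i1" else "GN:chrN:288-387:+"
    return tx, introns[key], {"chrN": chrom_seq}
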