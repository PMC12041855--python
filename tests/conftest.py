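import io

import pytest

from rg4dyn.annotation import (ReadEnd, ReadEndSet, TranscriptCatalog,
                               TranscriptModel, load_transcripts)
from rg4dyn.simulate import SimulationConfig


@pytest.fixture
def two_exon_plus() -> TranscriptModel:
    """Exons [0,50)+[100,150), CDS [120,140), + strand: 70/20/10 nt regions."""
    return TranscriptModel("txA", "geneA", "chr1", "+",
                           ((0, 50), (100, 150)), 120, 140)


@pytest.fixture
def single_exon_pair() -> TranscriptCatalog:
    """One coding transcript per strand, same intervals, on a 10 kb chrom."""
    bed = "\n".join([
        "\t".join(["chr1", "100", "1100", "txP", "0", "+", "300", "900",
                   "0", "1", "1000,", "0,"]),
        "\t".join(["chr1", "2100", "3100", "txM", "0", "-", "2300", "2900",
                   "0", "1", "1000,", "0,"]),
    ]) + "\n"
    return load_transcripts(io.StringIO(bed), "BED12",
                            chrom_sizes={"chr1": 10000})


@pytest.fixture
def small_cfg() -> SimulationConfig:
    """Scaled-down generator: fast enough for unit tests, same structure."""
    return SimulationConfig(seed=11, n_transcripts=40, read_depth=50_000,
                            expression_depth=200_000, rpf_depth=200_000)


def make_reads(records, library="BG4", condition="GV") -> ReadEndSet:
    reads = [ReadEnd(*r) for r in records]
    return ReadEndSet(reads, total=len(reads), library=library,
                      condition=condition)
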