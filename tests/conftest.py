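import numpy as np
import pytest

from lrqc.io_formats import AlignmentRecord, GenomeLayout, PairRecord


@pytest.fixture
def layout():
    """Two-chromosome toy genome, long enough for default fit ranges."""
    return GenomeLayout.from_dict({"chr1": 30_000_000, "chr2": 30_000_000})


@pytest.fixture
def small_layout():
    return GenomeLayout.from_dict({"chr1": 1_000, "chr2": 500})


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_pair(chrom1="chr1", pos1=0, chrom2="chr1", pos2=0, strand1="+",
              strand2="+", duplicate=False, unmapped=False, mapq=60):
    return PairRecord(chrom1, pos1, strand1, chrom2, pos2, strand2,
                      duplicate=duplicate, unmapped=unmapped, mapq_min=mapq)


def make_read(read_id, chrom, start, end, barcode=None, strand="+",
              duplicate=False, mapq=60):
    if chrom is None:
        return AlignmentRecord(read_id, None, 0, 0, strand, 0, barcode=barcode)
    return AlignmentRecord(read_id, chrom, start, end, strand, mapq,
                           duplicate=duplicate, barcode=barcode)


def write_pairs_text(path, lines, header=True):
    with open(path, "w") as fh:
        if header:
            fh.write("## pairs format v1.0\n#columns: readID chr1 pos1 chr2 pos2 strand1 strand2\n")
        for line in lines:
            fh.write(line + "\n")
    return path
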