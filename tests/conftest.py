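import numpy as np
import pytest

from ejcnmd.annotation3ui import GenomicInterval, TranscriptModel


def make_transcript(
    exons,
    stop_end=None,
    strand="+",
    chrom="chr1",
    tid="T1",
    gid="G1",
    appris="principal1",
    biotype="protein_coding",
):
    ivals = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    ivals.sort(key=lambda e: e.start, reverse=(strand == "-"))
    t = TranscriptModel(tid, gid, ivals, stop_end, appris, biotype)
    t.validate()
    return t


def random_transcript(rng, tid="T", gid="G", chrom="chr1"):
    """Random multi-exon transcript with a stop at a random exonic boundary."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 7))
    pos = int(rng.integers(100, 1000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(20, 300))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(30, 400))
    if strand == "-":
        exons = exons[::-1]
    # stop boundary at a random spliced offset (0..spliced_length)
    total = sum(e - s for s, e in exons)
    offset = int(rng.integers(0, total + 1))
    t = make_transcript(exons, None, strand, chrom, tid, gid)
    t.stop_end = t.spliced_to_genomic(offset)
    return t


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
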