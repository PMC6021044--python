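import numpy as np
import pytest

from atollpop import GenotypeMatrix, LocusMeta, MISSING


def make_matrix(calls, individuals=None, locus_length_bp=80):
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    individuals = individuals or [f"ind{i}" for i in range(n)]
    loci = [LocusMeta(id=f"loc{j}", chrom="c1", pos=j + 1, ref="A", alt="C")
            for j in range(L)]
    return GenotypeMatrix(individuals=individuals, loci=loci, calls=calls,
                          locus_length_bp=locus_length_bp)


@pytest.fixture
def tiny_matrix():
    """3 individuals x 4 loci with one missing call and one monomorphic locus."""
    return make_matrix(
        [
            [0, 2, 0, 1],
            [1, 2, 0, MISSING],
            [2, 1, 0, 0],
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_matrix(rng, n=6, L=12, missing_rate=0.1):
    calls = rng.integers(0, 3, size=(n, L)).astype(np.int8)
    calls[rng.random((n, L)) < missing_rate] = MISSING
    return make_matrix(calls)


def fastq_record(seq, quals, read_id="r1"):
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(seq), id=read_id, description="")
    rec.letter_annotations["phred_quality"] = list(quals)
    return rec
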