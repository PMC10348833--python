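import random

import pytest

from splicefrag.gene_model import GeneModel, GenomicInterval, Transcript
from splicefrag.simulate import fig3_model, fixg1_model


def iv(a, b, chrom="chrT", strand="+"):
    return GenomicInterval(chrom, a, b, strand)


def random_genome(seed, lengths):
    rng = random.Random(seed)
    return {c: "".join(rng.choices("ACGT", k=n)) for c, n in lengths.items()}


@pytest.fixture(scope="session")
def fixg1():
    return fixg1_model()


@pytest.fixture(scope="session")
def fixg1_genome():
    return random_genome(101, {"chrFIXG1": 1000})


@pytest.fixture(scope="session")
def fig3():
    return fig3_model()


@pytest.fixture(scope="session")
def fig3_genome():
    return random_genome(103, {"chrFIG3": 1000})


def partition_oracle(transcripts):
    """Per-base brute-force subexon partition: label every genomic base with
    its covering-exon set and the nearest boundary class, then merge runs."""
    exons = [e for t in transcripts for e in t.exons]
    cuts = {e.start for e in exons} | {e.end for e in exons}
    covered = sorted({p for e in exons for p in range(e.start, e.end)})
    runs = []
    for p in covered:
        if runs and p == runs[-1][1] and p not in cuts:
            runs[-1] = (runs[-1][0], p + 1)
        else:
            runs.append((p, p + 1))
    return runs


def make_gtf(path, transcripts, genome=None, fasta_path=None):
    from splicefrag.simulate import write_fasta, write_gtf

    write_gtf(transcripts, path)
    if genome is not None and fasta_path is not None:
        write_fasta(genome, fasta_path)
    return path
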