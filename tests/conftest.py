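import numpy as np
import pytest

from sigassign import (
    ChannelAlphabet,
    SignatureSet,
    sbs96_alphabet,
    synthetic_signatures,
)


@pytest.fixture(scope="session")
def sbs96():
    return sbs96_alphabet()


@pytest.fixture(scope="session")
def sigs6(sbs96) -> SignatureSet:
    """Six sparse synthetic signatures over SBS-96."""
    return synthetic_signatures(6, sbs96, seed=101)


@pytest.fixture(scope="session")
def sigs20_separated(sbs96) -> SignatureSet:
    """Twenty well-separated synthetic signatures (pairwise cosine < 0.3)."""
    return synthetic_signatures(20, sbs96, seed=11, max_pairwise_cosine=0.3)


@pytest.fixture
def toy_alphabet():
    return ChannelAlphabet(("A[C>A]A", "A[C>G]A", "A[C>T]A", "A[T>A]A"), "toy")


@pytest.fixture(scope="session")
def synthetic_fasta(tmp_path_factory):
    """A small synthetic contig covering every trinucleotide context.

    The sequence enumerates all 64 trinucleotides back to back plus an
    N-containing stretch for the skip paths. Plain-text FASTA written at
    test time.
    """
    bases = "ACGT"
    tris = [a + b + c for a in bases for b in bases for c in bases]
    seq = "".join(tris)
    path = tmp_path_factory.mktemp("ref") / "ref.fa"
    with open(path, "w") as fh:
        fh.write(">chrT\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
        fh.write(">chrN\nACGTNNNACGT\n")
    return path


def write_vcf(path, rows, sample="S1"):
    """Minimal VCF 4.2 writer for fixtures; rows = (chrom, pos, ref, alt)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chrT,length=192>\n")
        fh.write("##contig=<ID=chrN,length=11>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for chrom, pos, ref, alt in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t0/1\n")
    return path


@pytest.fixture
def vcf_writer():
    return write_vcf


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
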