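"""Probabilistically assign signatures to individual somatic mutations.

Writes a tiny synthetic reference genome and a VCF of SNVs sampled from a
known two-signature mixture, builds the SBS-96 catalog with trinucleotide
contexts from the FASTA, fits signatures, and annotates every mutation with
the posterior probability that each active signature caused it.
"""

import tempfile
from pathlib import Path

import numpy as np

from sigassign import (
    annotate_mutations,
    assign_sample,
    build_catalog_from_vcf,
    sbs96_alphabet,
    synthetic_signatures,
)

workdir = Path(tempfile.mkdtemp())
alphabet = sbs96_alphabet()
reference = synthetic_signatures(6, alphabet, seed=101)

# synthetic contig covering every trinucleotide once
bases = "ACGT"
seq = "".join(a + b + c for a in bases for b in bases for c in bases)
fasta = workdir / "ref.fa"
fasta.write_text(">chr1\n" + seq + "\n")

# draw 400 mutation channels from a 70:30 mixture of SYN1 and SYN5, then
# synthesize a VCF record for each channel at a matching contig position
rng = np.random.default_rng(1)
mix = rng.multinomial(280, reference.column("SYN1")) + rng.multinomial(
    120, reference.column("SYN5")
)
comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
rows = []
for k, count in enumerate(mix):
    if count == 0:
        continue
    chan = alphabet.labels[k]  # e.g. "A[C>T]G"
    tri, alt = chan[0] + chan[2] + chan[6], chan[4]
    pos0 = seq.find(tri)
    if pos0 < 1:  # use the reverse-complement orientation instead
        tri = "".join(comp[b] for b in reversed(tri))
        alt = comp[alt]
        pos0 = seq.find(tri)
    rows.extend([(pos0 + 2, tri[1], alt)] * count)

vcf = workdir / "tumor.vcf"
with open(vcf, "w") as fh:
    fh.write("##fileformat=VCFv4.2\n##contig=<ID=chr1>\n")
    fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n")
    for pos, ref, alt in sorted(rows):
        fh.write(f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t0/1\n")

catalog, records = build_catalog_from_vcf(vcf, fasta, alphabet)
print(f"catalog: {int(catalog.totals()[0])} SNVs classified into 96 channels")

result = assign_sample(catalog.counts[:, 0], reference, sample_id="TUMOR")
annotate_mutations(records, result, reference)

print("active signatures:", result.activities.as_dict())
for rec in records[:5]:
    probs = {s: round(p, 3) for s, p in rec.probabilities.items()}
    print(f"  chr1:{rec.pos} {rec.ref}>{rec.alt}  {rec.channel}  {probs}")

# The fit recovers the 280/120 split, and each mutation's probabilities sum
# to 1 over the active signatures: they are the shares of that channel's
# reconstructed count contributed by each signature, so mutations in a
# channel dominated by one signature get a near-certain attribution.
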