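"""Reading and writing mutational matrices, signature files, and building
SBS-96 catalogs from somatic variant calls.

Matrix files are tab-delimited: first column holds channel labels (header
cell conventionally "MutationType"), remaining columns one sample each.
Signature files use the same layout with one column per signature (the
COSMIC text format). VCF and minimal MAF input is classified against a
user-supplied reference FASTA into the 96 pyrimidine-strand trinucleotide
channels.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .types import Catalog, ChannelAlphabet, MutationRecord, SignatureSet

__all__ = [
    "sbs96_alphabet",
    "read_matrix",
    "write_matrix",
    "read_signatures",
    "write_signatures",
    "align_catalog",
    "Sbs96Classifier",
    "classify_sbs",
    "build_catalog_from_vcf",
    "build_catalog_from_maf",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"


def sbs96_alphabet() -> ChannelAlphabet:
    """The canonical SBS-96 alphabet: 6 pyrimidine-referenced substitutions
    x 16 flanking contexts, substitution-major, flanks in A<C<G<T order
    (the conventional plotting order, e.g. A[C>A]A ... T[T>G]T)."""
    labels = [
        f"{five}[{sub}]{three}"
        for sub in _SUBSTITUTIONS
        for five in _BASES
        for three in _BASES
    ]
    return ChannelAlphabet(tuple(labels), schema_name="SBS96")


def _guess_schema(labels: tuple[str, ...]) -> str:
    if labels == sbs96_alphabet().labels:
        return "SBS96"
    if len(labels) == 96 and set(labels) == set(sbs96_alphabet().labels):
        return "SBS96"
    return "custom"


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected channel column plus >= 1 data column")
    df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate channel labels {dupes}")
    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise ValueError(f"{path}: non-numeric or missing cells in columns {bad}")
    return values


def read_matrix(path) -> Catalog:
    """Read a tab-delimited channels-x-samples mutation matrix."""
    values = _read_table(path)
    if (values.values < 0).any():
        raise ValueError(f"{path}: negative counts")
    labels = tuple(values.index)
    alphabet = ChannelAlphabet(labels, schema_name=_guess_schema(labels))
    return Catalog(alphabet, tuple(values.columns), values.to_numpy(dtype=float))


def write_matrix(catalog: Catalog, path, header_comment: str | None = None) -> None:
    """Write a catalog in the tab-delimited matrix format (round-trips with
    ``read_matrix``). Integer-valued counts are written as integers."""
    arr = catalog.counts
    as_int = np.allclose(arr, np.round(arr))
    df = pd.DataFrame(
        arr.astype(np.int64) if as_int else arr,
        index=list(catalog.alphabet.labels),
        columns=list(catalog.sample_ids),
    )
    df.index.name = "MutationType"
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")


def read_signatures(path) -> SignatureSet:
    """Read a COSMIC-style tab-delimited signature file; columns are
    renormalized to sum exactly 1 (warning if off by more than 1e-6)."""
    values = _read_table(path)
    labels = tuple(values.index)
    alphabet = ChannelAlphabet(labels, schema_name=_guess_schema(labels))
    return SignatureSet.from_raw(
        alphabet, tuple(values.columns), values.to_numpy(dtype=float)
    )


def write_signatures(sigs: SignatureSet, path) -> None:
    df = pd.DataFrame(
        sigs.probs,
        index=list(sigs.alphabet.labels),
        columns=list(sigs.signature_ids),
    )
    df.index.name = "MutationType"
    df.to_csv(path, sep="\t", float_format="%.18g")


def align_catalog(catalog: Catalog, alphabet: ChannelAlphabet) -> Catalog:
    """Reorder a catalog's channels to match a reference alphabet (the
    signature file's order is authoritative). An unmatched label on either
    side is an error — silent misalignment is worse than failure."""
    if catalog.alphabet.labels == alphabet.labels:
        return catalog
    have = {lab: k for k, lab in enumerate(catalog.alphabet.labels)}
    missing = [lab for lab in alphabet.labels if lab not in have]
    if missing:
        raise ValueError(f"catalog lacks channel(s) {missing[:5]} required by signatures")
    extra = [lab for lab in catalog.alphabet.labels if lab not in set(alphabet.labels)]
    if extra:
        raise ValueError(f"catalog has channel(s) {extra[:5]} absent from signatures")
    order = [have[lab] for lab in alphabet.labels]
    return Catalog(alphabet, catalog.sample_ids, catalog.counts[order, :])


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def classify_sbs(chrom: str, pos: int, ref: str, alt: str, reference: Fasta) -> str:
    """Map a single-base substitution to its pyrimidine-strand SBS-96
    channel "X[R>A]Y".

    ``pos`` is 1-based. When the reference base is a purine the substitution
    and its flanks are reverse-complemented, so a substitution and its
    reverse complement land on the same channel.
    """
    ref = ref.upper()
    alt = alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"non-ACGT allele: {ref}>{alt}")
    if chrom not in reference:
        raise ValueError(f"contig {chrom!r} not in reference")
    contig = reference[chrom]
    if pos < 2 or pos + 1 > len(contig):
        raise ValueError(f"{chrom}:{pos}: flank outside contig")
    tri = str(contig[pos - 2 : pos + 1]).upper()
    if any(b not in _BASES for b in tri):
        raise ValueError(f"{chrom}:{pos}: non-ACGT context {tri!r}")
    if tri[1] != ref:
        raise ValueError(
            f"{chrom}:{pos}: ref allele {ref!r} does not match reference base {tri[1]!r}"
        )
    if ref in "AG":
        tri = _revcomp(tri)
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


class Sbs96Classifier:
    """FASTA-backed trinucleotide-context classifier for SNVs.

    Tracks how many candidate variants were skipped (non-SNV, reference
    mismatch, N context, missing contig...) and why.
    """

    def __init__(self, reference_fasta, alphabet: ChannelAlphabet | None = None):
        self.reference = (
            reference_fasta
            if isinstance(reference_fasta, Fasta)
            else Fasta(str(reference_fasta))
        )
        self.alphabet = alphabet or sbs96_alphabet()
        self.skipped: dict[str, int] = {}

    def classify(self, chrom: str, pos: int, ref: str, alt: str) -> str | None:
        """Channel label, or None (with the reason tallied) if the variant
        cannot be classified."""
        if len(ref) != 1 or len(alt) != 1:
            self._skip("not_snv")
            return None
        try:
            return classify_sbs(chrom, pos, ref, alt, self.reference)
        except ValueError as exc:
            self._skip(_skip_reason(str(exc)))
            return None

    def _skip(self, reason: str) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + 1

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())


def _skip_reason(msg: str) -> str:
    for key, reason in (
        ("not a single-base", "not_snv"),
        ("non-ACGT allele", "non_acgt_allele"),
        ("not in reference", "missing_contig"),
        ("flank outside", "edge_of_contig"),
        ("non-ACGT context", "n_context"),
        ("does not match reference", "reference_mismatch"),
    ):
        if key in msg:
            return reason
    return "other"


def _records_to_catalog(
    records: list[MutationRecord], alphabet: ChannelAlphabet
) -> Catalog:
    sample_ids = tuple(dict.fromkeys(r.sample_id for r in records))
    if not sample_ids:
        sample_ids = ("sample",)
    counts = np.zeros((len(alphabet), len(sample_ids)), dtype=float)
    chan_idx = {lab: k for k, lab in enumerate(alphabet.labels)}
    samp_idx = {s: j for j, s in enumerate(sample_ids)}
    for r in records:
        counts[chan_idx[r.channel], samp_idx[r.sample_id]] += 1
    return Catalog(alphabet, sample_ids, counts)


def build_catalog_from_vcf(
    paths,
    reference_fasta,
    alphabet: ChannelAlphabet | None = None,
) -> tuple[Catalog, list[MutationRecord]]:
    """Build an SBS-96 catalog from one or more VCF files.

    Sample naming: the VCF's single sample name when the file carries
    exactly one sample, otherwise the file stem. Multi-allelic records are
    split per alt allele; only single-base substitutions are classified,
    everything else is skipped and tallied.

    Returns the catalog plus the retained mutation records (for later
    per-mutation probability annotation). The per-sample column totals equal
    the number of accepted SNVs (conservation).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    clf = Sbs96Classifier(reference_fasta, alphabet)
    records: list[MutationRecord] = []
    for path in paths:
        with pysam.VariantFile(str(path)) as vcf:
            samples = list(vcf.header.samples)
            sample_id = samples[0] if len(samples) == 1 else Path(path).stem
            for rec in vcf:
                for alt in rec.alts or ():
                    channel = clf.classify(rec.chrom, rec.pos, rec.ref, alt)
                    if channel is None:
                        continue
                    records.append(
                        MutationRecord(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref.upper(),
                            alt=alt.upper(),
                            sample_id=sample_id,
                            channel=channel,
                        )
                    )
    if clf.n_skipped:
        warnings.warn(
            f"skipped {clf.n_skipped} unclassifiable variant(s): {clf.skipped}",
            stacklevel=2,
        )
    catalog = _records_to_catalog(records, clf.alphabet)
    return catalog, records


_MAF_COLUMNS = {
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "sample": "Tumor_Sample_Barcode",
}


def build_catalog_from_maf(
    path,
    reference_fasta,
    alphabet: ChannelAlphabet | None = None,
) -> tuple[Catalog, list[MutationRecord]]:
    """Build an SBS-96 catalog from a MAF file (minimal dialect: only the
    Chromosome / Start_Position / Reference_Allele / Tumor_Seq_Allele2 /
    Tumor_Sample_Barcode columns are used)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    missing = [c for c in _MAF_COLUMNS.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: MAF lacks required column(s) {missing}")
    clf = Sbs96Classifier(reference_fasta, alphabet)
    records: list[MutationRecord] = []
    for row in df.itertuples(index=False):
        chrom = getattr(row, _MAF_COLUMNS["chrom"])
        pos = int(getattr(row, _MAF_COLUMNS["pos"]))
        ref = getattr(row, _MAF_COLUMNS["ref"])
        alt = getattr(row, _MAF_COLUMNS["alt"])
        sample = getattr(row, _MAF_COLUMNS["sample"])
        channel = clf.classify(chrom, pos, ref, alt)
        if channel is None:
            continue
        records.append(
            MutationRecord(
                chrom=chrom, pos=pos, ref=ref.upper(), alt=alt.upper(),
                sample_id=sample, channel=channel,
            )
        )
    if clf.n_skipped:
        warnings.warn(
            f"skipped {clf.n_skipped} unclassifiable variant(s): {clf.skipped}",
            stacklevel=2,
        )
    return _records_to_catalog(records, clf.alphabet), records
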