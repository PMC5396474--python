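"""Input readers and per-allele window construction.

Reads the reference sequence (FASTA), 3' UTR intervals (BED6, name column =
gene id), SNPs (VCF) and mature miRNA sequences (FASTA), resolves strand and
coordinates, and cuts the +/- 30 nt window around each UTR SNP for both
alleles on the transcript sense strand.

Coordinate conventions are centralized here: BED is 0-based half-open, VCF
positions are 1-based. ``vcf_pos_to_zero_based`` is the only place the VCF
offset is converted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pysam
from Bio import SeqIO
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 30

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA_ALPHABET = frozenset("ACGTN")
_RNA_ALPHABET = frozenset("ACGU")

WILD = "wild"
VARIANT = "variant"


@dataclass(frozen=True)
class UtrRecord:
    """A 3' UTR interval with its transcript-sense sequence.

    ``start``/``end`` are 0-based half-open genomic coordinates;
    ``sequence`` is the sense strand of the transcript, 5'->3' (i.e. the
    reverse complement of the plus-strand slice for minus-strand genes).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"UTR {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"UTR {self.gene_id}: bad strand {self.strand!r}")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"UTR {self.gene_id}: sequence length {len(self.sequence)} != "
                f"interval span {self.end - self.start}"
            )
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"UTR {self.gene_id}: non-DNA characters {sorted(bad)}")

    def contains(self, pos0: int) -> bool:
        """True if the 0-based genomic position falls inside the interval."""
        return self.start <= pos0 < self.end


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNV assigned to one UTR gene (plus-strand alleles)."""

    snp_id: str
    chrom: str
    pos: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str
    gene_id: str

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"SNP {self.snp_id}: alleles must be single bases")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.snp_id}: ref == alt ({self.ref_allele})")


@dataclass(frozen=True)
class AlleleWindow:
    """The <=61 nt transcript-sense window around one SNP for one allele."""

    snp_id: str
    gene_id: str
    allele: str  # "wild" or "variant"
    sequence: str
    snp_offset: int

    def __post_init__(self) -> None:
        if self.allele not in (WILD, VARIANT):
            raise ValueError(f"allele must be 'wild' or 'variant', got {self.allele!r}")
        if not 0 <= self.snp_offset < len(self.sequence):
            raise ValueError(
                f"{self.snp_id}: snp_offset {self.snp_offset} outside window "
                f"of length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class MiRnaRecord:
    """A mature miRNA: identifier plus 5'->3' RNA sequence."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise ValueError(f"miRNA {self.mirna_id}: non-RNA characters {sorted(bad)}")
        n = len(self.sequence)
        if not 15 <= n <= 30:
            raise ValueError(f"miRNA {self.mirna_id}: length {n} outside [15, 30]")
        if not 19 <= n <= 25:
            logger.warning(
                "miRNA %s has unusual length %d (mature miRNAs are 19-25 nt)",
                self.mirna_id,
                n,
            )


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    if base not in _DNA_ALPHABET:
        raise ValueError(f"non-DNA base {base!r}")
    return base.translate(_DNA_COMPLEMENT)


def vcf_pos_to_zero_based(pos: int) -> int:
    """Convert a 1-based VCF position to a 0-based genomic coordinate."""
    return pos - 1


def load_utrs(bed_path: str, fasta_path: str) -> list[UtrRecord]:
    """Read BED6 UTR intervals and attach their sense-strand sequences.

    Minus-strand records carry the reverse-complemented (sense) sequence.
    An interval on an unknown contig or extending past its end is a hard
    error naming the record.
    """
    fasta = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
    records: list[UtrRecord] = []
    with open(bed_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{bed_path}:{lineno}: expected BED6 (6 columns), got {len(fields)}"
                )
            chrom, start, end, gene_id, _score, strand = fields[:6]
            start, end = int(start), int(end)
            if chrom not in fasta:
                raise ValueError(f"UTR {gene_id}: unknown contig {chrom!r}")
            contig_len = len(fasta[chrom])
            if start < 0 or end > contig_len:
                raise ValueError(
                    f"UTR {gene_id}: interval [{start}, {end}) outside contig "
                    f"{chrom} of length {contig_len}"
                )
            plus = str(fasta[chrom][start:end])
            sequence = reverse_complement(plus) if strand == "-" else plus
            records.append(
                UtrRecord(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    sequence=sequence,
                )
            )
    return records


def load_mirnas(fasta_path: str) -> list[MiRnaRecord]:
    """Read mature miRNA sequences (U or T accepted; stored as RNA)."""
    records = []
    for rec in SeqIO.parse(fasta_path, "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        records.append(MiRnaRecord(mirna_id=rec.id, sequence=seq))
    return records


def load_snps(vcf_path: str, utrs: Iterable[UtrRecord]) -> list[SnpRecord]:
    """Read SNVs from a VCF and keep those falling inside an annotated UTR.

    Multi-allelic records are split into one candidate per ALT; indels and
    multi-base alleles are dropped. A SNP covered by two overlapping UTRs
    yields one record per gene. Unparsable records are skipped with a
    logged warning.
    """
    by_chrom: dict[str, list[UtrRecord]] = {}
    for utr in utrs:
        by_chrom.setdefault(utr.chrom, []).append(utr)

    records: list[SnpRecord] = []
    n_skipped = 0
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            try:
                chrom = rec.chrom
                pos = rec.pos  # 1-based
                ref = rec.ref
                alts = rec.alts or ()
                snp_id = rec.id or f"{chrom}:{pos}"
            except Exception as exc:  # malformed record
                n_skipped += 1
                logger.warning("skipping malformed VCF record: %s", exc)
                continue
            pos0 = vcf_pos_to_zero_based(pos)
            for alt in alts:
                if ref is None or len(ref) != 1 or alt is None or len(alt) != 1:
                    continue  # indel / multi-base allele
                if ref == alt or alt not in "ACGT" or ref not in "ACGT":
                    continue
                for utr in by_chrom.get(chrom, ()):
                    if utr.contains(pos0):
                        records.append(
                            SnpRecord(
                                snp_id=snp_id,
                                chrom=chrom,
                                pos=pos,
                                ref_allele=ref,
                                alt_allele=alt,
                                gene_id=utr.gene_id,
                            )
                        )
    if n_skipped:
        logger.warning("skipped %d malformed VCF records", n_skipped)
    return records


def make_allele_windows(
    snp: SnpRecord, utr: UtrRecord, flank: int = DEFAULT_FLANK
) -> tuple[AlleleWindow, AlleleWindow]:
    """Cut the wild and variant windows around one SNP.

    The window is the intersection of [snp - flank, snp + flank] with the
    UTR, expressed on the transcript sense strand (so for minus-strand
    genes the alleles are complemented and the window runs 3'->5' in
    genomic space). Both windows are identical except at ``snp_offset``.
    """
    pos0 = vcf_pos_to_zero_based(snp.pos)
    if not utr.contains(pos0):
        raise ValueError(
            f"SNP {snp.snp_id} at {snp.chrom}:{snp.pos} lies outside UTR "
            f"{utr.gene_id} [{utr.start}, {utr.end})"
        )
    gstart = max(utr.start, pos0 - flank)
    gend = min(utr.end, pos0 + flank + 1)

    if utr.strand == "+":
        base_seq = utr.sequence[gstart - utr.start : gend - utr.start]
        offset = pos0 - gstart
        ref_base, alt_base = snp.ref_allele, snp.alt_allele
    else:
        # utr.sequence is already sense (reverse complement of plus strand):
        # sense index of plus-strand position p is (utr.end - 1 - p).
        base_seq = utr.sequence[utr.end - gend : utr.end - gstart]
        offset = gend - 1 - pos0
        ref_base = complement_base(snp.ref_allele)
        alt_base = complement_base(snp.alt_allele)

    if base_seq[offset] != ref_base:
        logger.warning(
            "SNP %s: reference base in %s UTR is %s, VCF REF implies %s",
            snp.snp_id,
            utr.gene_id,
            base_seq[offset],
            ref_base,
        )

    def substitute(base: str) -> str:
        return base_seq[:offset] + base + base_seq[offset + 1 :]

    wild = AlleleWindow(
        snp_id=snp.snp_id,
        gene_id=utr.gene_id,
        allele=WILD,
        sequence=substitute(ref_base),
        snp_offset=offset,
    )
    variant = AlleleWindow(
        snp_id=snp.snp_id,
        gene_id=utr.gene_id,
        allele=VARIANT,
        sequence=substitute(alt_base),
        snp_offset=offset,
    )
    return wild, variant
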