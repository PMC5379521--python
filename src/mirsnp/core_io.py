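"""Readers/writers for the external formats and the shared coordinate conventions.

Conventions used throughout the package:

* sequences are DNA internally: uppercase, ``U`` normalized to ``T`` on input;
* intervals are 0-based half-open internally (:class:`GenomicInterval`);
* positions in files and in reported tables follow each format's native
  convention (VCF is 1-based; all human-facing output positions are 1-based).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "CollapsedRead",
    "GenomicInterval",
    "VariantRecord",
    "VariantSet",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_collapsed_reads",
    "write_collapsed_reads",
    "read_group_map",
    "read_variants",
    "write_vcf",
    "extract_interval",
]

_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVN", "TGCAYRMKSWVHDBN")

#: IUPAC degenerate base -> set of concrete bases (DNA alphabet).
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "K": "GT", "M": "AC", "S": "CG", "W": "AT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_LETTERS = frozenset(IUPAC_SETS)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC letters supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_seq(raw: str, context: str = "") -> tuple[str, str]:
    """Uppercase, U->T; returns (normalized, alphabet_note)."""
    up = raw.upper()
    alphabet = "RNA" if "U" in up else "DNA"
    norm = up.replace("U", "T")
    bad = set(norm) - _IUPAC_LETTERS
    if bad:
        raise ValueError(
            f"non-IUPAC characters {sorted(bad)} in sequence {context!r}"
        )
    if not norm:
        raise ValueError(f"empty sequence {context!r}")
    return norm, alphabet


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, normalized to uppercase DNA."""

    id: str
    seq: str
    alphabet_note: str = "DNA"

    def __post_init__(self) -> None:
        norm, _ = _normalize_seq(self.seq, self.id)
        object.__setattr__(self, "seq", norm)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CollapsedRead:
    """One unique small-RNA sequence with its read count in one library."""

    seq: str
    count: int
    library_id: str = "lib1"

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"collapsed read count must be >= 1, got {self.count}")
        norm, _ = _normalize_seq(self.seq, "collapsed read")
        object.__setattr__(self, "seq", norm)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class VariantRecord:
    """A single-nucleotide variant with per-group allele counts/frequencies.

    ``pos`` is 1-based (VCF convention). ``group_counts`` maps
    group -> allele -> number of non-missing haplotypes carrying it;
    ``group_freqs`` are the corresponding within-group frequencies.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: list[str]
    group_freqs: dict[str, dict[str, float]] = field(default_factory=dict)
    group_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    id: str = "."

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1:
            raise ValueError("ref allele must be a single base")
        for a in self.alt_alleles:
            if len(a) != 1:
                raise ValueError("alt alleles must be single bases")
        for group, freqs in self.group_freqs.items():
            total = sum(freqs.values())
            if total > 1.0 + 1e-9:
                raise ValueError(
                    f"allele frequencies for group {group!r} sum to {total} > 1"
                )

    @property
    def zero_based(self) -> int:
        return self.pos - 1

    def major_allele(self, group: str) -> str | None:
        """Allele with frequency > 0.5 within ``group`` (None if no majority)."""
        freqs = self.group_freqs.get(group, {})
        for allele, f in freqs.items():
            if f > 0.5:
                return allele
        return None


@dataclass
class VariantSet:
    """Parsed SNPs plus bookkeeping about skipped records."""

    records: list[VariantRecord]
    n_indels_skipped: int = 0
    samples: dict[str, str] = field(default_factory=dict)  # sample -> group

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def in_interval(self, interval: GenomicInterval) -> list[VariantRecord]:
        return [
            v
            for v in self.records
            if v.chrom == interval.chrom
            and interval.start <= v.zero_based < interval.end
        ]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Raises on an empty file and on duplicate record ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        norm, alpha = _normalize_seq(str(rec.seq), rec.id)
        records.append(SequenceRecord(rec.id, norm, alpha))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[SequenceRecord], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Collapsed small-RNA reads

def read_collapsed_reads(
    path: str | Path, dialect: str = "header_xN", library_id: str | None = None
) -> list[CollapsedRead]:
    """Read collapsed (unique-sequence) reads with abundance annotation.

    Dialects: ``header_xN`` (``>id_x123``), ``header_count`` (``>id count=123``)
    and ``tsv`` (``sequence<TAB>count``).
    """
    path = Path(path)
    lib = library_id if library_id is not None else path.stem
    reads: list[CollapsedRead] = []
    if dialect == "tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected seq<TAB>count")
                try:
                    count = int(parts[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad count {parts[1]!r}") from exc
                reads.append(CollapsedRead(parts[0], count, lib))
    elif dialect in ("header_xN", "header_count"):
        with open(path) as fh:
            header = None
            header_line = 0
            chunks: list[str] = []
            def flush() -> None:
                if header is None:
                    return
                seq = "".join(chunks)
                count = _parse_count(header, dialect, path, header_line)
                reads.append(CollapsedRead(seq, count, lib))
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    flush()
                    header, header_line, chunks = line[1:], lineno, []
                else:
                    chunks.append(line)
            flush()
    else:
        raise ValueError(f"unknown collapsed-read dialect {dialect!r}")
    if not reads:
        raise ValueError(f"no reads parsed from {path}")
    return reads


def _parse_count(header: str, dialect: str, path, lineno: int) -> int:
    if dialect == "header_xN":
        if "_x" not in header:
            raise ValueError(f"{path}:{lineno}: header {header!r} lacks _xN count")
        token = header.rsplit("_x", 1)[1].split()[0]
    else:
        token = None
        for word in header.split():
            if word.startswith("count="):
                token = word[len("count=") :]
        if token is None:
            raise ValueError(f"{path}:{lineno}: header {header!r} lacks count=N")
    try:
        count = int(token)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: bad count {token!r}") from exc
    if count < 1:
        raise ValueError(f"{path}:{lineno}: non-positive count {count}")
    return count


def write_collapsed_reads(path: str | Path, reads: Iterable[CollapsedRead]) -> None:
    """Write reads in the ``header_xN`` dialect (``>r<i>_x<count>``)."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads, 1):
            fh.write(f">r{i}_x{read.count}\n{read.seq}\n")


# ---------------------------------------------------------------------------
# Variants

def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``sample_id<TAB>group`` -> mapping."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, group = line.split("\t")[:2]
            mapping[sample] = group
    if not mapping:
        raise ValueError(f"empty group map {path}")
    return mapping


def read_variants(path: str | Path, group_map: Mapping[str, str]) -> VariantSet:
    """Read SNPs from a VCF, computing per-group allele counts/frequencies.

    Indel records are skipped (and counted); degenerate bases in alleles are
    expanded to their IUPAC sets. Missing genotypes are excluded from the
    frequency denominators, not imputed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    missing = sorted(set(group_map) - set(vcf_samples))
    if missing:
        raise ValueError(f"samples in group map absent from VCF: {missing}")
    sample_idx = {s: i for i, s in enumerate(vcf_samples)}
    groups: dict[str, list[int]] = {}
    for sample, group in group_map.items():
        groups.setdefault(group, []).append(sample_idx[sample])

    records: list[VariantRecord] = []
    n_indels = 0
    for var in vcf:
        alleles = [var.REF] + list(var.ALT)
        expanded: list[list[str]] = []
        is_indel = False
        for a in alleles:
            if a in ("-", "*") or len(a) != 1:
                is_indel = True
                break
            expanded.append(list(IUPAC_SETS[a.upper()]))
        if is_indel:
            n_indels += 1
            continue
        gts = var.genotype.array()  # (n_samples, ploidy+1); -1 = missing
        ploidy = gts.shape[1] - 1
        group_counts: dict[str, dict[str, int]] = {}
        group_freqs: dict[str, dict[str, float]] = {}
        for group, idxs in groups.items():
            counts: dict[str, int] = {}
            n_called = 0
            for i in idxs:
                for j in range(ploidy):
                    ai = int(gts[i, j])
                    if ai < 0:
                        continue
                    bases = expanded[ai]
                    # degenerate allele: split the call across its base set
                    for b in bases:
                        counts[b] = counts.get(b, 0) + 1
                    n_called += len(bases)
            if n_called:
                group_counts[group] = counts
                group_freqs[group] = {b: c / n_called for b, c in counts.items()}
            else:
                group_counts[group] = {}
                group_freqs[group] = {}
        alt_bases = sorted({b for a in expanded[1:] for b in a} - {var.REF.upper()})
        records.append(
            VariantRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref_allele=var.REF.upper(),
                alt_alleles=alt_bases,
                group_freqs=group_freqs,
                group_counts=group_counts,
                id=var.ID or ".",
            )
        )
    return VariantSet(records, n_indels, dict(group_map))


def write_vcf(
    path: str | Path,
    variants: Sequence[tuple[str, int, str, list[str], list[tuple[int, int]]]],
    samples: Sequence[str],
    contigs: Mapping[str, int],
) -> None:
    """Write a minimal VCF 4.2 with GT fields.

    ``variants`` rows are ``(chrom, pos1, ref, alts, genotypes)`` where
    ``genotypes`` holds one ``(a1, a2)`` allele-index pair per sample
    (-1 = missing). Intended for the synthetic-data generator; reading back
    goes through cyvcf2.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, pos, ref, alts, gts in variants:
            alt_field = ",".join(alts) if alts else "."
            gt_strs = [
                "./."
                if a1 < 0 or a2 < 0
                else f"{a1}/{a2}"
                for a1, a2 in gts
            ]
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt_field}\t.\tPASS\t.\tGT\t"
                + "\t".join(gt_strs)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Interval extraction

def extract_interval(
    genome: Mapping[str, str] | Sequence[SequenceRecord], interval: GenomicInterval
) -> SequenceRecord:
    """Extract the sequence of an interval; minus strand is reverse-complemented."""
    if not isinstance(genome, Mapping):
        genome = {rec.id: rec.seq for rec in genome}
    try:
        chrom_seq = genome[interval.chrom]
    except KeyError as exc:
        raise ValueError(f"unknown chromosome {interval.chrom!r}") from exc
    if interval.end > len(chrom_seq):
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
            f"chromosome length {len(chrom_seq)}"
        )
    seq = chrom_seq[interval.start : interval.end]
    if interval.strand == "-":
        seq = reverse_complement(seq)
    name = f"{interval.chrom}:{interval.start}-{interval.end}({interval.strand})"
    return SequenceRecord(name, seq)
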