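"""Annotation of miRNA loci from collapsed small-RNA reads.

The chain follows standard plant small-RNA practice: length filter (16-30 nt)
and contaminant exclusion; homology assignment to a reference mature-miRNA set
(Hamming distance <= 2, no indels); a cap on exact genomic matches (default
15) for the remaining reads; secondary-structure analysis of candidate
precursors (maximum-pairing Nussinov fold, community hairpin criteria); and
miRNA* detection with the canonical 2-nt 3' overhang duplex geometry.

Folding is maximum-cardinality nested pairing rather than an energy model:
it is deterministic and exactly checkable against exhaustive enumeration.
A dot-bracket import hook (:func:`structure_from_dotbracket`) lets callers
substitute structures computed by an external thermodynamic folder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import (
    CollapsedRead,
    GenomicInterval,
    SequenceRecord,
    extract_interval,
    reverse_complement,
)

__all__ = [
    "HairpinStructure",
    "HairpinCriteria",
    "HairpinEvaluation",
    "MiRNALocus",
    "ExpressionRecord",
    "DiscoveryConfig",
    "filter_reads",
    "match_conserved",
    "count_genome_matches",
    "find_occurrences",
    "fold_nussinov",
    "structure_from_dotbracket",
    "evaluate_hairpin",
    "find_star",
    "compute_rpm",
    "discover_mirnas",
    "expression_table",
]

#: base pairs allowed in hairpin stems (DNA letters; G:T is the G:U wobble)
ALLOWED_PAIRS = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
)


@dataclass(frozen=True)
class HairpinStructure:
    """A nested (pseudoknot-free) pairing of a sequence."""

    seq: str
    pairs: tuple[tuple[int, int], ...]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner_array(self) -> np.ndarray:
        """partner[i] = index paired with i, or -1."""
        partner = np.full(len(self.seq), -1, dtype=np.int64)
        for i, j in self.pairs:
            partner[i] = j
            partner[j] = i
        return partner

    def dotbracket(self) -> str:
        chars = ["."] * len(self.seq)
        for i, j in self.pairs:
            chars[i], chars[j] = "(", ")"
        return "".join(chars)


def structure_from_dotbracket(seq: str, dotbracket: str) -> HairpinStructure:
    """Import hook: build a structure from an external folder's dot-bracket."""
    if len(seq) != len(dotbracket):
        raise ValueError("sequence and dot-bracket lengths differ")
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket at column {i}")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"unexpected dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket: unclosed '('")
    return HairpinStructure(seq, tuple(sorted(pairs)))


def fold_nussinov(seq: str, min_loop: int = 3) -> HairpinStructure:
    """Maximum-cardinality nested pairing (Nussinov) with deterministic traceback.

    Allowed pairs are A:T, G:C and the G:T wobble; hairpin loops must span at
    least ``min_loop`` unpaired bases. On ties the traceback prefers pairing
    the left end to the smallest admissible partner.
    """
    seq = seq.upper().replace("U", "T")
    if set(seq) - set("ACGT"):
        raise ValueError("fold_nussinov requires a plain ACGT sequence")
    n = len(seq)
    if n < min_loop + 2:
        return HairpinStructure(seq, ())

    can_pair = np.zeros((n, n), dtype=bool)
    enc = np.frombuffer(seq.encode(), dtype=np.uint8)
    for a, b in ALLOWED_PAIRS:
        ia = enc == ord(a)
        ib = enc == ord(b)
        can_pair |= np.outer(ia, ib)

    N = np.zeros((n + 1, n + 1), dtype=np.int64)  # N[i, j] over seq[i..j]
    for d in range(min_loop + 1, n):
        for i in range(0, n - d):
            j = i + d
            best = N[i + 1, j]
            ks = np.nonzero(can_pair[i, i + min_loop + 1 : j + 1])[0]
            if ks.size:
                ks = ks + i + min_loop + 1
                vals = 1 + N[i + 1, ks - 1] + N[ks + 1, j]
                vmax = int(vals.max())
                if vmax > best:
                    best = vmax
            N[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        target = N[i, j]
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if can_pair[i, k] and 1 + N[i + 1, k - 1] + N[k + 1, j] == target:
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return HairpinStructure(seq, tuple(sorted(pairs)))


@dataclass(frozen=True)
class HairpinCriteria:
    """Community precursor criteria (config-exposed thresholds)."""

    max_unpaired_mature: int = 4
    min_paired_fraction: float = 0.5
    max_partner_spread: int | None = 6  # extra span allowed for partners
    mature_must_not_span_loop: bool = True


@dataclass
class HairpinEvaluation:
    passed: bool
    arm: str  # "5p" | "3p" | "?"
    mature_start: int  # 0-based within precursor
    unpaired_mature: int
    paired_fraction: float
    reasons: list[str] = field(default_factory=list)

    @property
    def diagnostics(self) -> dict[str, object]:
        return {
            "arm": self.arm,
            "unpaired_mature": self.unpaired_mature,
            "paired_fraction": round(self.paired_fraction, 4),
            "reasons": ";".join(self.reasons) or "ok",
        }


def evaluate_hairpin(
    precursor_seq: str,
    mature_seq: str,
    structure: HairpinStructure,
    criteria: HairpinCriteria | None = None,
) -> HairpinEvaluation:
    """Check the Meyers-style precursor criteria for one mature placement.

    Pass requires: the mature lies on a single arm (no self-pairing within the
    mature, all pairing partners on one side), at most ``max_unpaired_mature``
    mature bases unpaired, and a precursor paired fraction at or above the
    threshold.
    """
    criteria = criteria or HairpinCriteria()
    ms = precursor_seq.find(mature_seq)
    if ms < 0:
        raise ValueError("mature sequence not found in precursor")
    me = ms + len(mature_seq) - 1
    partner = structure.partner_array()
    reasons: list[str] = []

    internal = [
        i for i in range(ms, me + 1) if ms <= partner[i] <= me and partner[i] >= 0
    ]
    partners = [int(partner[i]) for i in range(ms, me + 1) if partner[i] >= 0]
    left = [p for p in partners if p < ms]
    right = [p for p in partners if p > me]
    if criteria.mature_must_not_span_loop and (internal or (left and right)):
        reasons.append("spans-loop")
    if not partners:
        reasons.append("mature-unpaired")

    unpaired = sum(1 for i in range(ms, me + 1) if partner[i] < 0)
    if unpaired > criteria.max_unpaired_mature:
        reasons.append(f"unpaired-mature {unpaired} > {criteria.max_unpaired_mature}")

    paired_fraction = 2 * structure.n_pairs / len(precursor_seq)
    if paired_fraction < criteria.min_paired_fraction:
        reasons.append(
            f"paired-fraction {paired_fraction:.3f} < {criteria.min_paired_fraction}"
        )

    if criteria.max_partner_spread is not None and partners:
        spread = (max(partners) - min(partners) + 1) - len(mature_seq)
        if spread > criteria.max_partner_spread:
            reasons.append(f"partner-spread {spread} > {criteria.max_partner_spread}")

    arm = "5p" if (right and not left) else ("3p" if (left and not right) else "?")
    return HairpinEvaluation(
        passed=not reasons,
        arm=arm,
        mature_start=ms,
        unpaired_mature=unpaired,
        paired_fraction=paired_fraction,
        reasons=reasons,
    )


def find_star(
    precursor_seq: str,
    mature_seq: str,
    structure: HairpinStructure,
    observed_reads: Iterable[str],
    end_shift: int = 0,
) -> str | None:
    """Predicted miRNA* confirmed by an observed read, or None.

    The star is the duplex partner of the mature with 2-nt 3' overhangs on
    both ends: in precursor coordinates it spans
    ``[partner(mature_end) + 2, partner(mature_start) + 2]``. With
    ``end_shift`` = 1, reads whose ends deviate by one base are accepted.
    """
    ms = precursor_seq.find(mature_seq)
    if ms < 0:
        raise ValueError("mature sequence not found in precursor")
    me = ms + len(mature_seq) - 1
    partner = structure.partner_array()

    def projected_partner(idx: int, step: int) -> int | None:
        # walk inward from an unpaired mature end to the nearest paired base
        for i in range(idx, ms - 1 if step < 0 else me + 1, step):
            if partner[i] >= 0:
                return int(partner[i]) - (idx - i)
        return None

    p_me = projected_partner(me, -1)
    p_ms = projected_partner(ms, 1)
    if p_me is None or p_ms is None:
        return None
    lo, hi = p_me + 2, p_ms + 2
    if lo > hi:
        lo, hi = hi, lo  # mature on the 3' arm: partner order reverses
    lo = max(lo, 0)
    hi = min(hi, len(precursor_seq) - 1)
    if hi - lo + 1 < len(mature_seq) - 4 or _span_overlap(lo, hi, ms, me):
        return None
    observed = set(observed_reads)
    for da in range(-end_shift, end_shift + 1):
        for db in range(-end_shift, end_shift + 1):
            a, b = lo + da, hi + db
            if a < 0 or b >= len(precursor_seq) or a >= b:
                continue
            cand = precursor_seq[a : b + 1]
            if cand in observed:
                return cand
    return None


def _span_overlap(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 <= b1 and b0 <= a1


# ---------------------------------------------------------------------------
# Read-level filters and matching

def filter_reads(
    reads: Sequence[CollapsedRead],
    min_len: int = 16,
    max_len: int = 30,
    exclusion_sets: Mapping[str, Sequence[SequenceRecord]] | None = None,
) -> tuple[list[CollapsedRead], dict[str, int]]:
    """Length filter plus exact-substring contaminant exclusion.

    A read is rejected if its length is outside ``[min_len, max_len]`` or if
    it occurs verbatim as a substring of any sequence in an exclusion set
    (mRNA / rRNA / repeat proxies). Returns kept reads and a rejection report.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    exclusion_sets = exclusion_sets or {}
    report = {"length": 0}
    for name in exclusion_sets:
        report[f"contaminant:{name}"] = 0
    kept: list[CollapsedRead] = []
    for read in reads:
        if not (min_len <= len(read.seq) <= max_len):
            report["length"] += 1
            continue
        hit = None
        for name, records in exclusion_sets.items():
            if any(read.seq in rec.seq for rec in records):
                hit = name
                break
        if hit is not None:
            report[f"contaminant:{hit}"] += 1
            continue
        kept.append(read)
    report["kept"] = len(kept)
    return kept, report


def match_conserved(
    read_seq: str,
    reference_mirnas: Sequence[SequenceRecord],
    max_mismatch: int = 2,
) -> tuple[str, int] | None:
    """Best reference assignment by Hamming distance (<= ``max_mismatch``).

    Comparison is length-matched only (no indels). Ties break to the first
    reference in file order. Returns ``(reference_id, mismatches)`` or None.
    """
    if not reference_mirnas:
        raise ValueError("empty reference miRNA set")
    read_seq = read_seq.upper().replace("U", "T")
    best: tuple[str, int] | None = None
    for ref in reference_mirnas:
        if len(ref.seq) != len(read_seq):
            continue
        mm = sum(1 for a, b in zip(read_seq, ref.seq) if a != b)
        if mm <= max_mismatch and (best is None or mm < best[1]):
            best = (ref.id, mm)
    return best


def find_occurrences(
    read_seq: str, genome: Mapping[str, str]
) -> list[tuple[str, int, str]]:
    """Exact occurrences of a read on both genome strands.

    Returns ``(chrom, start, strand)`` with ``start`` the 0-based position of
    the match on the forward strand (for '-', the reverse complement of the
    read matches there). Overlapping occurrences are all counted.
    """
    hits: list[tuple[str, int, str]] = []
    rc = reverse_complement(read_seq)
    for chrom in sorted(genome):
        seq = genome[chrom]
        for probe, strand in ((read_seq, "+"), (rc, "-")):
            if probe == rc and read_seq == rc and strand == "-":
                continue  # palindromic read: one occurrence per location
            start = seq.find(probe)
            while start >= 0:
                hits.append((chrom, start, strand))
                start = seq.find(probe, start + 1)
    return hits


def count_genome_matches(read_seq: str, genome: Mapping[str, str]) -> int:
    """Number of exact genomic occurrences of a read (both strands)."""
    if len(read_seq) < 10:
        raise ValueError("reads shorter than 10 nt match too ambiguously")
    return len(find_occurrences(read_seq, genome))


def compute_rpm(raw_count: int, library_total: int) -> float:
    """Reads per million: ``raw_count * 1e6 / library_total``."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return raw_count * 1_000_000 / library_total


# ---------------------------------------------------------------------------
# Locus-level discovery

@dataclass(frozen=True)
class MiRNALocus:
    """An annotated hairpin locus."""

    id: str
    precursor_interval: GenomicInterval
    mature_interval: GenomicInterval
    precursor_seq: str
    mature_seq: str
    star_seq: str | None
    arm: str
    class_label: str  # conserved | known | specific_with_star | specific_candidate
    reference_id: str | None = None
    structure: HairpinStructure | None = None

    def __post_init__(self) -> None:
        if self.mature_seq not in self.precursor_seq:
            raise ValueError("mature sequence must be a substring of the precursor")
        if self.star_seq is not None and self.star_seq not in self.precursor_seq:
            raise ValueError("star sequence must be a substring of the precursor")


@dataclass(frozen=True)
class ExpressionRecord:
    mirna_id: str
    library_id: str
    raw_count: int
    rpm: float


@dataclass(frozen=True)
class DiscoveryConfig:
    min_len: int = 16
    max_len: int = 30
    max_mismatch: int = 2
    genome_match_cap: int = 15
    flank_sizes: tuple[int, ...] = (25, 40, 60, 90, 130, 200)
    min_loop: int = 3
    criteria: HairpinCriteria = HairpinCriteria()
    known_families: frozenset[str] = frozenset()
    star_end_shift: int = 0
    max_occurrences_folded: int = 4  # loci examined per read


def _candidate_windows(
    chrom_len: int, start: int, end: int, strand: str, flank_sizes: Sequence[int]
) -> list[tuple[int, int]]:
    """Anchored candidate precursor windows (genome coords) for one occurrence.

    For each flank size, one window extends the read downstream and one
    upstream *in read orientation*; on the minus strand the genomic direction
    flips accordingly.
    """
    windows: list[tuple[int, int]] = []
    for f in flank_sizes:
        if strand == "+":
            cands = [(start, min(end + f, chrom_len)), (max(start - f, 0), end)]
        else:
            cands = [(max(start - f, 0), end), (start, min(end + f, chrom_len))]
        for a, b in cands:
            if (a, b) not in windows and b - a > end - start:
                windows.append((a, b))
    return windows


def discover_mirnas(
    reads_by_library: Mapping[str, Sequence[CollapsedRead]],
    genome: Mapping[str, str] | Sequence[SequenceRecord],
    reference_mirnas: Sequence[SequenceRecord],
    exclusion_sets: Mapping[str, Sequence[SequenceRecord]] | None = None,
    config: DiscoveryConfig | None = None,
) -> tuple[list[MiRNALocus], dict[str, int]]:
    """Full annotation chain from collapsed reads to hairpin loci.

    Reads are pooled across libraries, filtered, homology-assigned, capped on
    genomic copy number, and their candidate precursors folded and evaluated.
    Returns the loci plus a per-stage accounting report.
    """
    config = config or DiscoveryConfig()
    if not isinstance(genome, Mapping):
        genome = {rec.id: rec.seq for rec in genome}

    # pool identical sequences across libraries
    totals: dict[str, int] = {}
    libs_of: dict[str, set[str]] = {}
    all_reads: list[CollapsedRead] = []
    for lib, reads in reads_by_library.items():
        for r in reads:
            all_reads.append(CollapsedRead(r.seq, r.count, lib))
            totals[r.seq] = totals.get(r.seq, 0) + r.count
            libs_of.setdefault(r.seq, set()).add(lib)

    kept, report = filter_reads(all_reads, config.min_len, config.max_len, exclusion_sets)
    kept_seqs = sorted({r.seq for r in kept}, key=lambda s: (-totals[s], s))
    report["unique_kept"] = len(kept_seqs)
    report["over_match_cap"] = 0
    report["unmapped"] = 0
    report["no_hairpin"] = 0

    reads_per_lib: dict[str, set[str]] = {}
    for r in kept:
        reads_per_lib.setdefault(r.library_id, set()).add(r.seq)

    loci: list[MiRNALocus] = []
    claimed: list[GenomicInterval] = []
    used_ids: set[str] = set()
    n_specific = 0
    for seq in kept_seqs:
        assigned = match_conserved(seq, reference_mirnas, config.max_mismatch)
        occurrences = find_occurrences(seq, genome)
        if not occurrences:
            report["unmapped"] += 1
            continue
        if assigned is None and len(occurrences) > config.genome_match_cap:
            report["over_match_cap"] += 1
            continue

        best: tuple[tuple[int, int, int], MiRNALocus] | None = None
        for chrom, start, strand in occurrences[: config.max_occurrences_folded]:
            chrom_len = len(genome[chrom])
            seen_windows: set[tuple[int, int]] = set()
            for f in sorted(config.flank_sizes):
                if best is not None and best[0][0] == 0:
                    # a fully paired mature cannot be beaten on the
                    # (unpaired, window length) key by any larger window
                    break
                for a, b in _candidate_windows(
                    chrom_len, start, start + len(seq), strand, (f,)
                ):
                    if (a, b) in seen_windows:
                        continue
                    seen_windows.add((a, b))
                    interval = GenomicInterval(chrom, a, b, strand)
                    prec = extract_interval(genome, interval).seq
                    if seq not in prec:
                        continue
                    structure = fold_nussinov(prec, config.min_loop)
                    ev = evaluate_hairpin(prec, seq, structure, config.criteria)
                    if not ev.passed:
                        continue
                    key = (ev.unpaired_mature, b - a, a)
                    if best is not None and key >= best[0]:
                        continue
                    # star must come from a library that also holds the mature
                    obs: set[str] = set()
                    for lib in libs_of.get(seq, ()):
                        obs |= reads_per_lib.get(lib, set())
                    star = find_star(prec, seq, structure, obs, config.star_end_shift)
                    mat0 = prec.find(seq)
                    if strand == "+":
                        m_iv = GenomicInterval(chrom, a + mat0, a + mat0 + len(seq), "+")
                    else:
                        m_iv = GenomicInterval(chrom, b - mat0 - len(seq), b - mat0, "-")
                    if assigned is not None:
                        label = (
                            "known"
                            if assigned[0] in config.known_families
                            else "conserved"
                        )
                        locus_id = f"{assigned[0]}"
                    elif star is not None:
                        label = "specific_with_star"
                        locus_id = ""
                    else:
                        label = "specific_candidate"
                        locus_id = ""
                    locus = MiRNALocus(
                        id=locus_id,
                        precursor_interval=interval,
                        mature_interval=m_iv,
                        precursor_seq=prec,
                        mature_seq=seq,
                        star_seq=star,
                        arm=ev.arm,
                        class_label=label,
                        reference_id=assigned[0] if assigned else None,
                        structure=structure,
                    )
                    best = (key, locus)
        if best is None:
            report["no_hairpin"] += 1
            continue
        locus = best[1]
        if any(locus.mature_interval.overlaps(c) for c in claimed):
            # lower-abundance read from an already-annotated hairpin
            # (isoform or the star arm); the first, more abundant read wins
            continue
        claimed.append(locus.precursor_interval)
        if not locus.id:
            n_specific += 1
            locus = dataclass_replace_id(locus, f"csa-mir{n_specific}")
        if locus.id in used_ids:  # second locus of the same family
            suffix = 2
            while f"{locus.id}-{suffix}" in used_ids:
                suffix += 1
            locus = dataclass_replace_id(locus, f"{locus.id}-{suffix}")
        used_ids.add(locus.id)
        loci.append(locus)
    report["loci"] = len(loci)
    return loci, report


def dataclass_replace_id(locus: MiRNALocus, new_id: str) -> MiRNALocus:
    from dataclasses import replace

    return replace(locus, id=new_id)


def expression_table(
    loci: Sequence[MiRNALocus],
    reads_by_library: Mapping[str, Sequence[CollapsedRead]],
) -> list[ExpressionRecord]:
    """Per-library RPM expression for each annotated mature sequence."""
    records: list[ExpressionRecord] = []
    for lib, reads in reads_by_library.items():
        total = sum(r.count for r in reads)
        counts: dict[str, int] = {}
        for r in reads:
            counts[r.seq] = counts.get(r.seq, 0) + r.count
        for locus in loci:
            raw = counts.get(locus.mature_seq, 0)
            rpm = compute_rpm(raw, total) if total > 0 else 0.0
            records.append(ExpressionRecord(locus.id, lib, raw, rpm))
    return records
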