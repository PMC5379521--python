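"""Gain and loss of miRNA-target interactions between two genotype groups.

The comparison applies one group's SNP alleles to mature miRNAs ("snp-miRNA")
and to target mRNAs ("snp-mRNA"), re-runs the target search under each allele
configuration, and classifies every interaction as conserved, disrupted
(present only under the reference group's alleles) or created (present only
under the alternative group's alleles). Created sites are cross-checked
against the second group's annotated transcripts: the best global-alignment
ortholog must exceed 90% identity (strictly) and must itself carry the
predicted binding site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align

from .core_io import GenomicInterval, SequenceRecord, VariantRecord, reverse_complement
from .mirna_discovery import MiRNALocus
from .target_engine import ScoreParams, TargetInteraction, find_sites

__all__ = [
    "SnpSequence",
    "InteractionDelta",
    "OrthologMatch",
    "GroupComparison",
    "apply_variants",
    "build_snp_mirna",
    "build_snp_transcript",
    "diff_targets",
    "align_global",
    "ortholog_validate",
    "compare_groups",
    "call_group_unique_targets",
]


@dataclass(frozen=True)
class SnpSequence:
    """A sequence with group alleles applied (substitutions only)."""

    base_id: str
    variant_seq: str
    applied_variants: tuple[tuple[int, str, str], ...]  # (1-based local pos, ref, alt)
    group: str = ""

    @property
    def is_reference(self) -> bool:
        return not self.applied_variants


def apply_variants(
    seq: str, local_variants: Sequence[tuple[int, str, str]], base_id: str = "", group: str = ""
) -> SnpSequence:
    """Apply local substitutions ``(pos1, ref, alt)`` to a sequence.

    Each stated ref allele must match the base sequence at its 1-based
    position; mismatches raise, naming the position.
    """
    chars = list(seq)
    for pos, ref, alt in local_variants:
        if not (1 <= pos <= len(seq)):
            raise ValueError(f"variant position {pos} outside sequence of length {len(seq)}")
        if chars[pos - 1] != ref:
            raise ValueError(
                f"ref allele mismatch at position {pos}: expected {ref}, "
                f"sequence has {chars[pos - 1]}"
            )
        if len(alt) != 1:
            raise ValueError("only single-base substitutions are supported")
        chars[pos - 1] = alt
    return SnpSequence(base_id, "".join(chars), tuple(local_variants), group)


def _group_alt_alleles(variant: VariantRecord, group: str) -> list[str]:
    """Allele(s) defining a group's sequence at one site.

    The group-major allele (frequency > 0.5) defines the sequence; exact ties
    (e.g. from degenerate-base expansion) yield every tied top allele.
    """
    freqs = variant.group_freqs.get(group, {})
    if not freqs:
        return [variant.ref_allele]
    top = max(freqs.values())
    majors = sorted(a for a, f in freqs.items() if abs(f - top) < 1e-9)
    if top > 0.5:
        return majors[:1] if len(majors) == 1 else majors
    return majors  # no majority: report each tied/leading allele haplotype


def _lift_to_local(
    variant: VariantRecord, interval: GenomicInterval
) -> tuple[int, str, str] | None:
    """Genomic SNP -> (local 1-based pos, ref, alt) within a strand-aware interval."""
    pos0 = variant.zero_based
    if variant.chrom != interval.chrom or not (interval.start <= pos0 < interval.end):
        return None
    if interval.strand == "+":
        local = pos0 - interval.start + 1
        return local, variant.ref_allele, ""
    local = interval.end - pos0
    return local, reverse_complement(variant.ref_allele), ""


def _expand_haplotypes(
    base_seq: str,
    base_id: str,
    group: str,
    site_changes: list[list[tuple[int, str, str]]],
    cap: int,
) -> list[SnpSequence]:
    """Joint enumeration of per-site allele choices, capped.

    ``site_changes[k]`` lists the alternative substitutions at site k (may be
    empty if the group carries the reference). Beyond ``cap`` sequences, the
    enumeration falls back to per-SNP marginals.
    """
    import itertools

    options = [changes if changes else [None] for changes in site_changes]
    n_joint = 1
    for opt in options:
        n_joint *= len(opt)
    combos: list[tuple] = []
    if n_joint <= cap:
        combos = list(itertools.product(*options))
    else:  # marginal fallback: one substitution at a time
        for k, changes in enumerate(site_changes):
            for ch in changes:
                combo = [None] * len(site_changes)
                combo[k] = ch
                combos.append(tuple(combo))
        combos = combos[:cap]
    out: list[SnpSequence] = []
    seen: set[str] = set()
    for combo in combos:
        subs = sorted(ch for ch in combo if ch is not None)
        snp_seq = apply_variants(base_seq, subs, base_id, group)
        if snp_seq.variant_seq not in seen:
            seen.add(snp_seq.variant_seq)
            out.append(snp_seq)
    return out


def build_snp_mirna(
    locus: MiRNALocus,
    variants: Sequence[VariantRecord],
    group: str,
    max_haplotypes: int = 8,
) -> list[SnpSequence]:
    """Mature-miRNA sequence(s) carrying a group's alleles.

    Genomic SNPs are lifted to mature-local coordinates (strand-aware, alleles
    complemented on the minus strand); the group-major allele defines the
    sequence, with ties enumerated jointly up to ``max_haplotypes``.
    Variants outside the mature interval are ignored.
    """
    site_changes: list[list[tuple[int, str, str]]] = []
    for v in variants:
        lifted = _lift_to_local(v, locus.mature_interval)
        if lifted is None:
            continue
        local, local_ref, _ = lifted
        if locus.mature_seq[local - 1] != local_ref:
            continue  # annotation/VCF disagree on the reference base; skip
        changes = []
        for allele in _group_alt_alleles(v, group):
            local_alt = (
                allele if locus.mature_interval.strand == "+" else reverse_complement(allele)
            )
            if local_alt != local_ref:
                changes.append((local, local_ref, local_alt))
        site_changes.append(changes)
    if not site_changes:
        return [SnpSequence(locus.id, locus.mature_seq, (), group)]
    return _expand_haplotypes(
        locus.mature_seq, locus.id, group, site_changes, max_haplotypes
    )


def build_snp_transcript(
    transcript: SequenceRecord,
    gene_model: GenomicInterval,
    variants: Sequence[VariantRecord],
    group: str,
    max_haplotypes: int = 8,
) -> list[SnpSequence]:
    """Transcript sequence(s) carrying a group's alleles (snp-mRNA)."""
    site_changes: list[list[tuple[int, str, str]]] = []
    for v in variants:
        lifted = _lift_to_local(v, gene_model)
        if lifted is None:
            continue
        local, local_ref, _ = lifted
        if transcript.seq[local - 1] != local_ref:
            continue
        changes = []
        for allele in _group_alt_alleles(v, group):
            local_alt = allele if gene_model.strand == "+" else reverse_complement(allele)
            if local_alt != local_ref:
                changes.append((local, local_ref, local_alt))
        site_changes.append(changes)
    if not site_changes:
        return [SnpSequence(transcript.id, transcript.seq, (), group)]
    return _expand_haplotypes(
        transcript.seq, transcript.id, group, site_changes, max_haplotypes
    )


@dataclass
class InteractionDelta:
    """Fate of one miRNA-transcript interaction across the two groups."""

    mirna_id: str
    transcript_id: str
    status: str  # conserved | disrupted | created
    cause: str  # mirna_snp | target_snp | none
    ref_score: float | None
    alt_score: float | None
    ref_site: tuple[int, int] | None
    alt_site: tuple[int, int] | None
    ortholog: "OrthologMatch | None" = None


def diff_targets(
    interactions_ref: Sequence[TargetInteraction],
    interactions_alt: Sequence[TargetInteraction],
    cause: str = "none",
) -> list[InteractionDelta]:
    """Match the two interaction sets and classify each site's fate.

    Sites pair up when their transcript ids are equal and their intervals
    overlap (SNPs may shift the optimal window by a base). Matched pairs are
    conserved; ref-only sites are disrupted; alt-only sites are created.
    """
    deltas: list[InteractionDelta] = []
    used_alt: set[int] = set()
    for r in interactions_ref:
        match_idx = None
        for k, a in enumerate(interactions_alt):
            if k in used_alt or a.transcript_id != r.transcript_id:
                continue
            if a.site_start <= r.site_end and r.site_start <= a.site_end:
                match_idx = k
                break
        if match_idx is None:
            deltas.append(
                InteractionDelta(
                    r.mirna_id, r.transcript_id, "disrupted", cause,
                    r.score, None, (r.site_start, r.site_end), None,
                )
            )
        else:
            used_alt.add(match_idx)
            a = interactions_alt[match_idx]
            deltas.append(
                InteractionDelta(
                    r.mirna_id, r.transcript_id, "conserved", cause,
                    r.score, a.score,
                    (r.site_start, r.site_end), (a.site_start, a.site_end),
                )
            )
    for k, a in enumerate(interactions_alt):
        if k not in used_alt:
            deltas.append(
                InteractionDelta(
                    a.mirna_id, a.transcript_id, "created", cause,
                    None, a.score, None, (a.site_start, a.site_end),
                )
            )
    return deltas


# ---------------------------------------------------------------------------
# Orthologue validation

def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def align_global(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> tuple[Align.Alignment, float]:
    """Optimal global alignment and its identity (matches / alignment columns)."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(match, mismatch, gap)
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    return alignment, identity


@dataclass
class OrthologMatch:
    snp_mrna_id: str
    ortholog_id: str
    identity: float
    site_contained: bool
    accepted: bool


def _shared_kmers(a: str, b_index: set[str], k: int) -> bool:
    return any(a[i : i + k] in b_index for i in range(0, len(a) - k + 1, k))


def ortholog_validate(
    snp_mrna: SequenceRecord | SnpSequence,
    ortholog_transcripts: Sequence[SequenceRecord],
    interaction: TargetInteraction,
    min_identity: float = 0.90,
    params: ScoreParams | None = None,
    prescreen_k: int = 12,
) -> OrthologMatch:
    """Check that a created site is genuinely present in the second group.

    The best ortholog by global-alignment identity must exceed
    ``min_identity`` (strictly) and must carry a site for the same miRNA,
    at or below the score cutoff, overlapping the lifted site region.
    """
    if not ortholog_transcripts:
        raise ValueError("empty ortholog transcript set")
    params = params or ScoreParams()
    if isinstance(snp_mrna, SnpSequence):
        query_id, query_seq = snp_mrna.base_id, snp_mrna.variant_seq
    else:
        query_id, query_seq = snp_mrna.id, snp_mrna.seq

    # shared-k-mer prescreen, falling back to all orthologs if nothing shares
    kmers = {
        query_seq[i : i + prescreen_k]
        for i in range(len(query_seq) - prescreen_k + 1)
    }
    shortlist = [
        t for t in ortholog_transcripts if _shared_kmers(t.seq, kmers, prescreen_k)
    ] or list(ortholog_transcripts)

    best_id, best_identity, best_alignment = "", -1.0, None
    for t in shortlist:
        alignment, identity = align_global(query_seq, t.seq)
        if identity > best_identity:
            best_id, best_identity, best_alignment = t.id, identity, alignment
    ortho_seq = next(t for t in ortholog_transcripts if t.id == best_id)

    site_contained = False
    if best_alignment is not None and interaction.mirna_seq:
        # lift the site interval through the alignment coordinate map
        lo0, hi0 = interaction.site_start - 1, interaction.site_end  # half-open
        lifted = _lift_span(best_alignment, lo0, hi0)
        if lifted is not None:
            l_lo, l_hi = lifted
            mirna_rec = SequenceRecord(interaction.mirna_id, interaction.mirna_seq)
            for site in find_sites(mirna_rec, ortho_seq, params):
                if site.site_start - 1 < l_hi and l_lo < site.site_end:
                    site_contained = True
                    break
    accepted = best_identity > min_identity and site_contained
    return OrthologMatch(query_id, best_id, best_identity, site_contained, accepted)


def _lift_span(alignment: Align.Alignment, lo: int, hi: int) -> tuple[int, int] | None:
    """Map a [lo, hi) span on the query through a pairwise alignment."""
    try:
        aligned_q, aligned_t = alignment.aligned
    except Exception:  # pragma: no cover
        return None
    t_lo = t_hi = None
    for (qs, qe), (ts, te) in zip(aligned_q, aligned_t):
        if qe <= lo or qs >= hi:
            continue
        off_lo = max(lo, qs) - qs
        off_hi = min(hi, qe) - qs
        seg_lo, seg_hi = ts + off_lo, ts + off_hi
        t_lo = seg_lo if t_lo is None else min(t_lo, seg_lo)
        t_hi = seg_hi if t_hi is None else max(t_hi, seg_hi)
    if t_lo is None:
        return None
    return t_lo, t_hi


# ---------------------------------------------------------------------------
# Group comparison driver

@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    deltas: list[InteractionDelta]
    a_unique: list[InteractionDelta] = field(default_factory=list)
    b_unique: list[InteractionDelta] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            f"{self.group_a}_unique": len(self.a_unique),
            f"{self.group_b}_unique": len(self.b_unique),
            "conserved": sum(1 for d in self.deltas if d.status == "conserved"),
        }


def compare_groups(
    loci: Sequence[MiRNALocus],
    transcripts: Sequence[SequenceRecord],
    gene_models: Mapping[str, GenomicInterval],
    variants: Sequence[VariantRecord],
    group_a: str,
    group_b: str,
    params: ScoreParams | None = None,
    ortholog_transcripts: Sequence[SequenceRecord] | None = None,
    min_identity: float = 0.90,
    max_haplotypes: int = 8,
) -> GroupComparison:
    """Full two-group interaction comparison.

    Group A supplies the reference sequences (its alleles are applied to the
    annotated mature/transcript sequences where they differ); group B's
    alleles define the alternative snp-miRNAs and snp-mRNAs. Created sites
    are ortholog-validated when ``ortholog_transcripts`` is given.
    """
    params = params or ScoreParams()
    deltas: list[InteractionDelta] = []
    tx_by_id = {t.id: t for t in transcripts}

    # group sequences per transcript
    tx_variants: dict[str, list[SnpSequence]] = {}
    tx_ref: dict[str, SnpSequence] = {}
    for t in transcripts:
        model = gene_models.get(t.id)
        if model is None:
            tx_ref[t.id] = SnpSequence(t.id, t.seq, (), group_a)
            tx_variants[t.id] = [SnpSequence(t.id, t.seq, (), group_b)]
            continue
        a_haps = build_snp_transcript(t, model, variants, group_a, max_haplotypes)
        tx_ref[t.id] = a_haps[0]
        tx_variants[t.id] = build_snp_transcript(
            t, model, variants, group_b, max_haplotypes
        )

    for locus in loci:
        a_mirnas = build_snp_mirna(locus, variants, group_a, max_haplotypes)
        b_mirnas = build_snp_mirna(locus, variants, group_b, max_haplotypes)
        mirna_changed = {m.variant_seq for m in a_mirnas} != {
            m.variant_seq for m in b_mirnas
        }
        for t in transcripts:
            ref_seq = tx_ref[t.id]
            ref_tx = SequenceRecord(t.id, ref_seq.variant_seq)
            ref_sites = _best_sites(a_mirnas, locus.id, ref_tx, params)
            alt_sites: list[TargetInteraction] = []
            for b_hap in tx_variants[t.id]:
                alt_tx = SequenceRecord(t.id, b_hap.variant_seq)
                alt_sites = _merge_sites(
                    alt_sites, _best_sites(b_mirnas, locus.id, alt_tx, params)
                )
            if not ref_sites and not alt_sites:
                continue
            target_changed = (
                tx_ref[t.id].variant_seq
                != tx_variants[t.id][0].variant_seq
            )
            if mirna_changed and not target_changed:
                cause = "mirna_snp"
            elif target_changed and not mirna_changed:
                cause = "target_snp"
            elif mirna_changed and target_changed:
                cause = "mirna_snp+target_snp"
            else:
                cause = "none"
            deltas.extend(diff_targets(ref_sites, alt_sites, cause))

    # ortholog validation of created sites
    if ortholog_transcripts:
        for d in deltas:
            if d.status != "created":
                continue
            b_seq = tx_variants[d.transcript_id][0]
            site = TargetInteraction(
                mirna_id=d.mirna_id,
                transcript_id=d.transcript_id,
                site_start=d.alt_site[0],
                site_end=d.alt_site[1],
                alignment=(),
                score=d.alt_score or 0.0,
                mirna_seq=_mirna_seq_for(loci, d.mirna_id, variants, group_b, max_haplotypes),
            )
            d.ortholog = ortholog_validate(
                b_seq, ortholog_transcripts, site, min_identity, params
            )

    comparison = GroupComparison(group_a, group_b, deltas)
    comparison.a_unique = [d for d in deltas if d.status == "disrupted"]
    comparison.b_unique = [d for d in deltas if d.status == "created"]
    return comparison


def _mirna_seq_for(loci, mirna_id, variants, group, max_haplotypes) -> str:
    for locus in loci:
        if locus.id == mirna_id:
            return build_snp_mirna(locus, variants, group, max_haplotypes)[0].variant_seq
    return ""


def _best_sites(
    mirna_haps: Sequence[SnpSequence],
    mirna_id: str,
    transcript: SequenceRecord,
    params: ScoreParams,
) -> list[TargetInteraction]:
    sites: list[TargetInteraction] = []
    for hap in mirna_haps:
        hits = find_sites(
            SequenceRecord(mirna_id, hap.variant_seq), transcript, params
        )
        sites = _merge_sites(sites, hits)
    return sites


def _merge_sites(
    current: list[TargetInteraction], new: list[TargetInteraction]
) -> list[TargetInteraction]:
    """Union of site lists, overlapping sites collapsed to the best score."""
    merged = list(current)
    for site in new:
        overlap = [
            k
            for k, s in enumerate(merged)
            if s.transcript_id == site.transcript_id
            and s.site_start <= site.site_end
            and site.site_start <= s.site_end
        ]
        if not overlap:
            merged.append(site)
        else:
            k = overlap[0]
            if site.score < merged[k].score:
                merged[k] = site
    merged.sort(key=lambda s: (s.transcript_id, s.site_start))
    return merged


def call_group_unique_targets(
    comparison: GroupComparison, require_ortholog: bool = False
) -> dict[str, object]:
    """Tabulate group-unique targets from a comparison.

    A-unique targets are interactions present under group A's alleles and
    absent under B's (disrupted-by-B); B-unique are created-under-B. With
    ``require_ortholog``, created calls additionally need an accepted
    ortholog match.
    """
    a_rows = [
        {
            "mirna_id": d.mirna_id,
            "transcript_id": d.transcript_id,
            "unique_to": comparison.group_a,
            "score": d.ref_score,
            "site": d.ref_site,
            "cause": d.cause,
            "ortholog_accepted": None,
        }
        for d in comparison.a_unique
    ]
    b_rows = []
    for d in comparison.b_unique:
        if require_ortholog and not (d.ortholog and d.ortholog.accepted):
            continue
        b_rows.append(
            {
                "mirna_id": d.mirna_id,
                "transcript_id": d.transcript_id,
                "unique_to": comparison.group_b,
                "score": d.alt_score,
                "site": d.alt_site,
                "cause": d.cause,
                "ortholog_accepted": bool(d.ortholog and d.ortholog.accepted)
                if d.ortholog
                else None,
            }
        )
    return {
        f"{comparison.group_a}_unique": len(a_rows),
        f"{comparison.group_b}_unique": len(b_rows),
        "rows": a_rows + b_rows,
    }
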