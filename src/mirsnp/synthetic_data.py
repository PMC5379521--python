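"""Seeded two-group scenario generator with planted ground truth.

The generator emulates the study design the pipeline targets: two cucumber
genotype groups sharing one reference genome, small-RNA libraries whose reads
derive from planted hairpin loci, miRNA binding sites written into
transcripts at exact penalty scores, group-differentiated SNPs planted inside
mature miRNAs and binding sites (fixed ref in group A, fixed alt in group B),
and degradome tags concentrated at the base opposite miRNA position 10.

Every planted artifact is verified against the analysis modules at build
time (hairpins re-folded and re-evaluated, sites re-scored, impact events
re-searched), so generator bugs surface as generation errors rather than as
silent test failures. All randomness flows from a single root seed through
fixed per-component child streams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    CollapsedRead,
    GenomicInterval,
    SequenceRecord,
    VariantRecord,
    reverse_complement,
    write_collapsed_reads,
    write_fasta,
    write_vcf,
)
from .mirna_discovery import (
    HairpinCriteria,
    MiRNALocus,
    evaluate_hairpin,
    find_star,
    fold_nussinov,
)
from .target_engine import ScoreParams, find_sites, score_duplex

__all__ = [
    "ScenarioConfig",
    "ScenarioBundle",
    "GenerationError",
    "make_hairpin",
    "plant_binding_site",
    "plant_impact_event",
    "make_degradome",
    "make_scenario",
    "write_scenario",
]

_BASES = "ACGT"
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
_WOBBLE = {"G": "T", "T": "G"}  # site base giving a G:U against this miRNA base

#: fixed child-stream labels (appending a component must not perturb others)
_STREAMS = {
    "transcripts": 1,
    "hairpins": 2,
    "sites": 3,
    "events": 4,
    "genome": 5,
    "reads": 6,
    "degradome": 7,
    "background": 8,
    "mature_snps": 9,
}


class GenerationError(RuntimeError):
    """A planted artifact failed its build-time verification."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-design parameters of a synthetic two-group scenario."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 30_000
    n_mirnas: int = 8
    n_conserved: int = 4
    n_with_star: int = 2
    mature_len: int = 21
    loop_len: int = 12
    star_mismatches: int = 1
    n_transcripts: int = 12
    transcript_len: int = 600
    n_planted_sites: int = 10
    n_a_unique: int = 3
    n_b_unique: int = 2
    n_neutral: int = 2
    n_mature_snp_mirnas: int = 2
    cutoff_margin: float = 1.0
    n_samples_per_group: int = 5
    group_a: str = "china"
    group_b: str = "india"
    libraries: tuple[str, ...] = ("leaf", "root")
    peak_fraction: float = 0.5
    total_tags: int = 40
    tag_len: int = 20
    background_snp_rate: float = 0.001
    params: ScoreParams = ScoreParams()

    def __post_init__(self) -> None:
        if self.cutoff_margin <= 0:
            raise ValueError("cutoff_margin must be > 0")
        if not (0 < self.peak_fraction <= 1):
            raise ValueError("peak_fraction must be in (0, 1]")
        if self.n_planted_sites > self.n_transcripts:
            raise ValueError("more planted sites than transcripts to hold them")
        if self.n_a_unique + self.n_b_unique + self.n_neutral > self.n_planted_sites:
            raise ValueError("more planted events than planted sites")
        if self.n_mature_snp_mirnas + 1 > self.n_mirnas:
            raise ValueError("not enough miRNAs for the requested mature SNPs")
        if self.n_conserved + self.n_with_star > self.n_mirnas:
            raise ValueError("n_conserved + n_with_star exceeds n_mirnas")


def _rng(config_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([config_seed % (2**31), _STREAMS[label]])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# Hairpins

def make_hairpin(
    rng: np.random.Generator,
    mature_len: int = 21,
    loop_len: int = 12,
    star_mismatches: int = 0,
    criteria: HairpinCriteria | None = None,
    min_loop: int = 3,
    max_attempts: int = 200,
) -> tuple[str, str, str]:
    """A precursor with planted duplex geometry: ``(precursor, mature, star)``.

    The precursor is mature + loop + reverse-complement(mature) + 2-nt tail,
    giving the canonical 2-nt 3' overhang star. ``star_mismatches``
    substitutions are written on the star arm; the result is verified by
    folding: it must pass the hairpin criteria exactly when
    ``star_mismatches`` does not exceed ``max_unpaired_mature``.
    """
    if star_mismatches > mature_len:
        raise ValueError("star_mismatches cannot exceed mature length")
    criteria = criteria or HairpinCriteria()
    expected_pass = star_mismatches <= criteria.max_unpaired_mature
    for _ in range(max_attempts):
        mature = _random_seq(rng, mature_len)
        loop = "A" * loop_len
        # tail bases must pair with nothing relevant (not mature[0:2], not loop A)
        tail_opts = [
            c
            for c in "AC"
            if all(
                (mb, c) not in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
                                ("G", "T"), ("T", "G"))
                for mb in mature[:2]
            )
        ]
        if not tail_opts:
            continue
        tail = tail_opts[0] * 2
        arm = list(reverse_complement(mature))
        # mismatch positions away from the duplex ends keep the geometry stable
        inner = list(range(3, mature_len - 3))
        if star_mismatches > len(inner):
            continue
        picks = sorted(rng.choice(inner, size=star_mismatches, replace=False)) if star_mismatches else []
        ok = True
        for mi in picks:
            arm_idx = mature_len - 1 - mi  # arm base pairing mature[mi]
            partner = mature[mi]
            sub = "A" if partner != "T" else "C"
            if arm[arm_idx] == sub:
                ok = False
                break
            arm[arm_idx] = sub
        if not ok:
            continue
        precursor = mature + loop + "".join(arm) + tail
        structure = fold_nussinov(precursor, min_loop)
        ev = evaluate_hairpin(precursor, mature, structure, criteria)
        if ev.unpaired_mature != star_mismatches or ev.passed != expected_pass:
            continue
        star_lo = mature_len + loop_len + 2
        star = precursor[star_lo : star_lo + mature_len]
        if expected_pass:
            found = find_star(precursor, mature, structure, {star})
            if found != star:
                continue
        return precursor, mature, star
    raise GenerationError(
        f"could not build a verified hairpin with {star_mismatches} star mismatches"
    )


# ---------------------------------------------------------------------------
# Binding sites

def _edit_site(
    rng: np.random.Generator,
    mirna: str,
    target_score: float,
    params: ScoreParams,
) -> str:
    """A site sequence whose duplex penalty equals ``target_score`` exactly."""
    m = len(mirna)
    core = set(range(params.core_start, params.core_end + 1))
    outside = [p for p in range(1, m + 1) if p not in core]
    inside = sorted(core & set(range(1, m + 1)))
    out_gu = [p for p in outside if mirna[p - 1] in _WOBBLE]
    in_gu = [p for p in inside if mirna[p - 1] in _WOBBLE]

    t2 = round(target_score * 2)
    if abs(target_score * 2 - t2) > 1e-9:
        raise ValueError(
            f"target score {target_score} not reachable: penalties step in 0.5"
        )
    # units (half-points): outside mismatch 2, outside gu 1, core mismatch 4, core gu 2
    solution = None
    for c_mm in range(len(inside) + 1):  # core usage last (outside-then-inside)
        for c_gu in range(len(in_gu) + 1):
            rem = t2 - 4 * c_mm - 2 * c_gu
            if rem < 0:
                continue
            for a_mm in range(min(len(outside), rem // 2) + 1):
                b_gu = rem - 2 * a_mm
                if b_gu <= len(out_gu) and a_mm + b_gu <= len(outside):
                    solution = (a_mm, b_gu, c_mm, c_gu)
                    break
            if solution:
                break
        if solution:
            break
    if solution is None:
        near = []
        for delta in (1, -1, 2, -2, 3, -3):
            if t2 + delta >= 0:
                near.append((t2 + delta) / 2)
        raise ValueError(
            f"target score {target_score} unreachable for this miRNA; "
            f"nearest candidates: {sorted(set(near))}"
        )
    a_mm, b_gu, c_mm, c_gu = solution

    site = list(reverse_complement(mirna))  # perfect site, score 0

    def site_index(pos: int) -> int:
        return len(site) - pos  # base opposite miRNA position ``pos``

    gu_pos = list(rng.permutation(out_gu)[:b_gu]) + list(rng.permutation(in_gu)[:c_gu])
    mm_pool_out = [p for p in outside if p not in gu_pos]
    mm_pool_in = [p for p in inside if p not in gu_pos]
    mm_pos = list(rng.permutation(mm_pool_out)[:a_mm]) + list(
        rng.permutation(mm_pool_in)[:c_mm]
    )
    for p in gu_pos:
        site[site_index(p)] = _WOBBLE[mirna[p - 1]]
    for p in mm_pos:
        mb = mirna[p - 1]
        banned = {_COMP[mb], _WOBBLE.get(mb, "")}
        choices = [b for b in _BASES if b not in banned]
        site[site_index(p)] = choices[int(rng.integers(0, len(choices)))]
    return "".join(site)


def plant_binding_site(
    rng: np.random.Generator,
    transcript_seq: str,
    mirna_seq: str,
    target_score: float,
    position: int,
    params: ScoreParams | None = None,
    max_attempts: int = 50,
    require_reported: bool = True,
) -> str:
    """Write a binding site of exact penalty ``target_score`` at ``position``.

    ``position`` is the 0-based site start on the transcript. The planted
    window is re-scored before returning; when the score is at or below the
    cutoff the site must also be reported by :func:`find_sites` at exactly
    the planted coordinates and score (surrounding sequence can otherwise
    offer a better overlapping alignment).
    """
    params = params or ScoreParams()
    m = len(mirna_seq)
    if position < 0 or position + m > len(transcript_seq):
        raise ValueError("site does not fit at the requested position")
    for _ in range(max_attempts):
        site = _edit_site(rng, mirna_seq, target_score, params)
        new_tx = transcript_seq[:position] + site + transcript_seq[position + m :]
        score, _cols = score_duplex(mirna_seq, site, params)
        if abs(score - target_score) > 1e-9:
            continue
        if target_score <= params.cutoff + 1e-9 and require_reported:
            hits = [
                h
                for h in find_sites(
                    SequenceRecord("q", mirna_seq), SequenceRecord("t", new_tx), params
                )
                if h.site_start - 1 < position + m and position < h.site_end
            ]
            if (
                len(hits) != 1
                or hits[0].site_start != position + 1
                or hits[0].site_end != position + m
                or abs(hits[0].score - target_score) > 1e-9
            ):
                continue
        return new_tx
    raise GenerationError(
        f"failed to plant a verifiable site of score {target_score}"
    )


# ---------------------------------------------------------------------------
# Impact events

@dataclass(frozen=True)
class PlantedEvent:
    kind: str  # a_unique | b_unique | neutral
    mirna_id: str
    transcript_id: str
    transcript_pos: int  # 1-based position of the SNP on the transcript
    ref_base: str  # base in group A / reference transcript
    alt_base: str  # base fixed in group B
    site_start: int  # 1-based planted site coords
    site_end: int


def _overlapping_best(mirna: str, tx: str, lo0: int, hi0: int, params) -> float | None:
    """Best reported score overlapping [lo0, hi0) on the transcript, or None."""
    hits = [
        h
        for h in find_sites(SequenceRecord("q", mirna), SequenceRecord("t", tx), params)
        if h.site_start - 1 < hi0 and lo0 < h.site_end
    ]
    return min((h.score for h in hits), default=None)


def plant_impact_event(
    rng: np.random.Generator,
    kind: str,
    mirna_seq: str,
    transcript_seq: str,
    site_start0: int,
    params: ScoreParams | None = None,
    margin: float = 1.0,
) -> tuple[str, int, str, str]:
    """A single-base SNP inside a planted site that crosses (or not) the cutoff.

    Returns ``(ref_transcript_seq, pos0, ref_base, alt_base)`` where the
    reference transcript may differ from the input for ``b_unique`` (the
    working site is the *alternative* state, so the broken base is written
    into the reference). Verified by re-running the site search under both
    alleles:

    * ``a_unique`` — ref site reported at <= cutoff - margin; under the alt
      base no site at all survives at the cutoff;
    * ``b_unique`` — mirror image (ref broken, alt working);
    * ``neutral`` — both alleles keep a reported site at <= cutoff.
    """
    params = params or ScoreParams()
    m = len(mirna_seq)
    lo0, hi0 = site_start0, site_start0 + m
    cutoff = params.cutoff
    base_score = _overlapping_best(mirna_seq, transcript_seq, lo0, hi0, params)
    if base_score is None or base_score > cutoff - margin + 1e-9:
        raise GenerationError(
            f"planted site must score <= cutoff - margin before an event "
            f"(found {base_score})"
        )
    positions = list(rng.permutation(np.arange(lo0, hi0)))
    for pos0 in positions:
        cur = transcript_seq[pos0]
        for new in rng.permutation([b for b in _BASES if b != cur]):
            edited = transcript_seq[:pos0] + new + transcript_seq[pos0 + 1 :]
            broken = _overlapping_best(mirna_seq, edited, lo0, hi0, params)
            if kind in ("a_unique", "b_unique"):
                # need: edited allele kills the site with margin to spare
                win_scores = [
                    score_duplex(mirna_seq, edited[lo0:hi0], params)[0]
                ]
                if broken is not None or min(win_scores) < cutoff + margin - 1e-9:
                    continue
                if kind == "a_unique":
                    return transcript_seq, int(pos0), cur, new
                return edited, int(pos0), new, cur
            if kind == "neutral":
                if broken is None or broken > cutoff + 1e-9:
                    continue
                if abs(broken - base_score) < 1e-9:
                    continue  # a do-nothing substitution is not an event
                return transcript_seq, int(pos0), cur, new
    raise GenerationError(
        f"no single-base edit achieves a {kind} event with margin {margin}"
    )


# ---------------------------------------------------------------------------
# Degradome

def make_degradome(
    rng: np.random.Generator,
    cleavage_pos: int,
    transcript_seq: str,
    total_tags: int = 40,
    peak_fraction: float = 0.5,
    tag_len: int = 20,
) -> list[tuple[str, int]]:
    """Degradome tags for one transcript: a peak plus uniform noise.

    ``round(peak_fraction * total_tags)`` tags start exactly at the 1-based
    ``cleavage_pos``; the remainder start uniformly at other valid positions.
    All tags are verbatim transcript substrings of length ``tag_len``.
    """
    if not (0 < peak_fraction <= 1):
        raise ValueError("peak_fraction must be in (0, 1]")
    if total_tags < 1:
        raise ValueError("total_tags must be >= 1")
    L = len(transcript_seq)
    if L < tag_len:
        raise ValueError("transcript shorter than tag length")
    eff = L - tag_len + 1
    if not (1 <= cleavage_pos <= eff):
        raise ValueError("cleavage position leaves no room for a full tag")
    n_peak = round(peak_fraction * total_tags)
    n_noise = total_tags - n_peak
    counts: dict[int, int] = {}
    if n_peak:
        counts[cleavage_pos] = n_peak
    others = [p for p in range(1, eff + 1) if p != cleavage_pos]
    for p in rng.choice(len(others), size=n_noise, replace=True) if n_noise else []:
        pos = others[int(p)]
        counts[pos] = counts.get(pos, 0) + 1
    return [
        (transcript_seq[pos - 1 : pos - 1 + tag_len], c)
        for pos, c in sorted(counts.items())
    ]


# ---------------------------------------------------------------------------
# Whole scenario

_CONSERVED_FAMILIES = ("miR156", "miR159", "miR164", "miR166", "miR396", "miR399",
                       "miR171", "miR398")


@dataclass
class ScenarioBundle:
    config: ScenarioConfig
    genome: dict[str, str]
    transcripts_a: list[SequenceRecord]
    transcripts_b: list[SequenceRecord]
    gene_models: dict[str, GenomicInterval]
    loci: list[MiRNALocus]
    reference_mirnas: list[SequenceRecord]
    reads_by_library: dict[str, list[CollapsedRead]]
    vcf_rows: list[tuple[str, int, str, list[str], list[tuple[int, int]]]]
    variant_records: list[VariantRecord]
    samples: list[str]
    group_map: dict[str, str]
    degradome_tags: list[tuple[str, int]]
    truth_sites: list[dict]
    truth_events: list[PlantedEvent]
    truth_mature_snps: list[dict]
    truth_degradome: list[dict]

    @property
    def genome_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _fixed_difference_freqs(
    config: ScenarioConfig, ref: str, alt: str
) -> tuple[dict, dict]:
    n = 2 * config.n_samples_per_group
    counts = {
        config.group_a: {ref: n},
        config.group_b: {alt: n},
    }
    freqs = {config.group_a: {ref: 1.0}, config.group_b: {alt: 1.0}}
    return freqs, counts


def make_scenario(config: ScenarioConfig | None = None) -> ScenarioBundle:
    """Generate a complete, self-verified two-group dataset."""
    config = config or ScenarioConfig()
    p = config.params
    m = config.mature_len

    # --- hairpins -----------------------------------------------------------
    rng_h = _rng(config.seed, "hairpins")
    hairpins: list[tuple[str, str, str]] = []
    matures_seen: set[str] = set()
    while len(hairpins) < config.n_mirnas:
        prec, mat, star = make_hairpin(
            rng_h, m, config.loop_len, config.star_mismatches
        )
        if mat in matures_seen:
            continue
        matures_seen.add(mat)
        hairpins.append((prec, mat, star))

    # roles: conserved first, then with-star specific, then candidates;
    # the last n_mature_snp_mirnas miRNAs carry mature SNPs and get no sites
    mirna_ids: list[str] = []
    classes: list[str] = []
    for k in range(config.n_mirnas):
        if k < config.n_conserved:
            mirna_ids.append(_CONSERVED_FAMILIES[k % len(_CONSERVED_FAMILIES)])
            classes.append("conserved")
        elif k < config.n_conserved + config.n_with_star:
            mirna_ids.append(f"csa-mir{k - config.n_conserved + 1}")
            classes.append("specific_with_star")
        else:
            mirna_ids.append(f"csa-mir{k - config.n_conserved + 1}")
            classes.append("specific_candidate")

    reference_mirnas = [
        SequenceRecord(mirna_ids[k], hairpins[k][1])
        for k in range(config.n_conserved)
    ]
    rng_t = _rng(config.seed, "transcripts")
    # decoy reference entries exercise the mismatch matcher without assignments
    reference_mirnas.append(SequenceRecord("miR-decoy1", _random_seq(rng_t, m)))
    reference_mirnas.append(SequenceRecord("miR-decoy2", _random_seq(rng_t, m)))

    # --- transcripts and planted sites -------------------------------------
    tx_ids = [f"tx{i + 1:02d}" for i in range(config.n_transcripts)]
    tx_seqs = {tid: _random_seq(rng_t, config.transcript_len) for tid in tx_ids}

    site_mirnas = [
        k for k in range(config.n_mirnas - config.n_mature_snp_mirnas)
    ]
    rng_s = _rng(config.seed, "sites")
    cutoff = p.cutoff
    margin = config.cutoff_margin
    n_events = config.n_a_unique + config.n_b_unique + config.n_neutral
    site_plan: list[tuple[str, float]] = []  # (kind, planted ref-working score)
    for _ in range(config.n_a_unique):
        site_plan.append(("a_unique", cutoff - margin))
    for _ in range(config.n_b_unique):
        site_plan.append(("b_unique", cutoff - margin))
    for _ in range(config.n_neutral):
        site_plan.append(("neutral", 1.0))
    passive_scores = [0.0, 0.5, 1.5, 2.0, 2.5, 3.0]
    for j in range(config.n_planted_sites - n_events):
        site_plan.append(("passive", passive_scores[j % len(passive_scores)]))

    truth_sites: list[dict] = []
    site_assignments: list[tuple[str, int, str, int, float]] = []
    for j, (kind, score) in enumerate(site_plan):
        tid = tx_ids[j]  # one planted site per transcript
        mk = site_mirnas[j % len(site_mirnas)]
        pos0 = int(rng_s.integers(60, config.transcript_len - 60 - m))
        tx_seqs[tid] = plant_binding_site(
            rng_s, tx_seqs[tid], hairpins[mk][1], score, pos0, p
        )
        site_assignments.append((kind, mk, tid, pos0, score))
        truth_sites.append(
            {
                "mirna_id": mirna_ids[mk],
                "transcript_id": tid,
                "site_start": pos0 + 1,
                "site_end": pos0 + m,
                "score": score,
                "kind": kind,
            }
        )

    # --- impact events ------------------------------------------------------
    rng_e = _rng(config.seed, "events")
    events: list[PlantedEvent] = []
    for kind, mk, tid, pos0, score in site_assignments:
        if kind == "passive":
            continue
        new_ref, snp0, ref_b, alt_b = plant_impact_event(
            rng_e, kind, hairpins[mk][1], tx_seqs[tid], pos0, p, margin
        )
        tx_seqs[tid] = new_ref
        events.append(
            PlantedEvent(
                kind, mirna_ids[mk], tid, snp0 + 1, ref_b, alt_b,
                pos0 + 1, pos0 + m,
            )
        )

    # --- genome layout ------------------------------------------------------
    rng_g = _rng(config.seed, "genome")
    chrom_ids = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_arrays = {c: list(_random_seq(rng_g, config.chrom_length)) for c in chrom_ids}
    gene_models: dict[str, GenomicInterval] = {}
    loci: list[MiRNALocus] = []

    cursors = {c: 400 for c in chrom_ids}
    placements: list[tuple[str, str]] = [("tx", tid) for tid in tx_ids] + [
        ("mir", str(k)) for k in range(config.n_mirnas)
    ]
    for idx, (ptype, key) in enumerate(placements):
        chrom = chrom_ids[idx % len(chrom_ids)]
        gap = int(rng_g.integers(200, 600))
        start = cursors[chrom] + gap
        if ptype == "tx":
            seq = tx_seqs[key]
        else:
            seq = hairpins[int(key)][0]
        end = start + len(seq)
        if end > config.chrom_length - 400:
            raise GenerationError(
                "chromosomes too short for the configured layout; "
                "increase chrom_length"
            )
        chrom_arrays[chrom][start:end] = list(seq)
        cursors[chrom] = end
        if ptype == "tx":
            gene_models[key] = GenomicInterval(chrom, start, end, "+")
        else:
            k = int(key)
            prec, mat, star = hairpins[k]
            structure = fold_nussinov(prec)
            ev = evaluate_hairpin(prec, mat, structure)
            loci.append(
                MiRNALocus(
                    id=mirna_ids[k],
                    precursor_interval=GenomicInterval(chrom, start, end, "+"),
                    mature_interval=GenomicInterval(chrom, start, start + m, "+"),
                    precursor_seq=prec,
                    mature_seq=mat,
                    star_seq=star if classes[k] == "specific_with_star" else None,
                    arm=ev.arm,
                    class_label=classes[k],
                    reference_id=mirna_ids[k] if classes[k] == "conserved" else None,
                    structure=structure,
                )
            )
    genome = {c: "".join(arr) for c, arr in chrom_arrays.items()}

    # transcripts must be verbatim genome substrings (ungapped gene models)
    transcripts_a = [SequenceRecord(tid, tx_seqs[tid]) for tid in tx_ids]
    for t in transcripts_a:
        gmod = gene_models[t.id]
        if genome[gmod.chrom][gmod.start : gmod.end] != t.seq:
            raise GenerationError("gene model does not match the genome")

    # --- variants -----------------------------------------------------------
    samples = [f"{config.group_a}_{i + 1}" for i in range(config.n_samples_per_group)]
    samples += [f"{config.group_b}_{i + 1}" for i in range(config.n_samples_per_group)]
    group_map = {
        s: (config.group_a if s.startswith(config.group_a) else config.group_b)
        for s in samples
    }
    na = config.n_samples_per_group

    vcf_rows = []
    variant_records: list[VariantRecord] = []
    blocked: list[tuple[str, int, int]] = []  # spans where background SNPs may not fall

    def add_fixed_diff(chrom: str, pos1: int, ref: str, alt: str) -> None:
        gts = [(0, 0)] * na + [(1, 1)] * na
        vcf_rows.append((chrom, pos1, ref, [alt], gts))
        freqs, counts = _fixed_difference_freqs(config, ref, alt)
        variant_records.append(
            VariantRecord(chrom, pos1, ref, [alt], freqs, counts)
        )
        blocked.append((chrom, pos1 - 1, pos1))

    for ev_ in events:
        gmod = gene_models[ev_.transcript_id]
        gpos1 = gmod.start + ev_.transcript_pos  # + strand: local pos -> genomic 1-based
        assert genome[gmod.chrom][gpos1 - 1] == ev_.ref_base
        add_fixed_diff(gmod.chrom, gpos1, ev_.ref_base, ev_.alt_base)

    # mature-sequence SNPs (on the dedicated, site-free miRNAs)
    rng_m = _rng(config.seed, "mature_snps")
    truth_mature_snps: list[dict] = []
    mature_snp_ks = list(
        range(config.n_mirnas - config.n_mature_snp_mirnas, config.n_mirnas)
    )
    for k in mature_snp_ks:
        locus = next(l for l in loci if l.id == mirna_ids[k])
        local = int(rng_m.integers(4, m - 3))  # 1-based position within the mature
        ref_b = locus.mature_seq[local - 1]
        alt_b = str(rng_m.choice([b for b in _BASES if b != ref_b]))
        gpos1 = locus.mature_interval.start + local
        add_fixed_diff(locus.mature_interval.chrom, gpos1, ref_b, alt_b)
        truth_mature_snps.append(
            {
                "mirna_id": mirna_ids[k],
                "mature_pos": local,
                "ref": ref_b,
                "alt": alt_b,
            }
        )

    # the planted-site spans and every mature interval stay background-free
    for s in truth_sites:
        gmod = gene_models[s["transcript_id"]]
        blocked.append(
            (gmod.chrom, gmod.start + s["site_start"] - 3, gmod.start + s["site_end"] + 2)
        )
    for l in loci:
        iv = l.mature_interval
        blocked.append((iv.chrom, iv.start - 2, iv.end + 2))

    rng_b = _rng(config.seed, "background")
    n_hap = 2 * na
    k_choices = [k for k in range(1, n_hap) if k != n_hap // 2]
    for chrom in chrom_ids:
        L = len(genome[chrom])
        n_bg = rng_b.poisson(config.background_snp_rate * L)
        positions = sorted(int(x) for x in rng_b.integers(0, L, size=n_bg))
        for pos0 in positions:
            if any(c == chrom and s <= pos0 < e for c, s, e in blocked):
                continue
            if any(r[0] == chrom and r[1] == pos0 + 1 for r in vcf_rows):
                continue
            ref_b = genome[chrom][pos0]
            if ref_b not in _BASES:
                continue
            alt_b = str(rng_b.choice([b for b in _BASES if b != ref_b]))
            gts = []
            counts = {config.group_a: {}, config.group_b: {}}
            for grp in (config.group_a, config.group_b):
                k_alt = int(rng_b.choice(k_choices))
                alleles = [1] * k_alt + [0] * (n_hap - k_alt)
                perm = rng_b.permutation(alleles)
                for i in range(na):
                    gts.append((int(perm[2 * i]), int(perm[2 * i + 1])))
                counts[grp] = {ref_b: n_hap - k_alt, alt_b: k_alt}
            freqs = {
                g: {b: c / n_hap for b, c in cs.items()} for g, cs in counts.items()
            }
            vcf_rows.append((chrom, pos0 + 1, ref_b, [alt_b], gts))
            variant_records.append(
                VariantRecord(chrom, pos0 + 1, ref_b, [alt_b], freqs, counts)
            )
    order = {c: i for i, c in enumerate(chrom_ids)}
    vcf_rows.sort(key=lambda r: (order[r[0]], r[1]))
    variant_records.sort(key=lambda v: (order[v.chrom], v.pos))

    # --- group-B transcripts (orthologs) ------------------------------------
    transcripts_b: list[SequenceRecord] = []
    for t in transcripts_a:
        gmod = gene_models[t.id]
        chars = list(t.seq)
        for v in variant_records:
            if v.chrom != gmod.chrom or not (gmod.start <= v.zero_based < gmod.end):
                continue
            major = v.major_allele(config.group_b)
            if major is not None and major != chars[v.zero_based - gmod.start]:
                chars[v.zero_based - gmod.start] = major
        transcripts_b.append(SequenceRecord(f"hwk_{t.id}", "".join(chars)))

    # --- reads --------------------------------------------------------------
    rng_r = _rng(config.seed, "reads")
    reads_by_library: dict[str, list[CollapsedRead]] = {}
    for lib in config.libraries:
        reads: list[CollapsedRead] = []
        for k, (prec, mat, star) in enumerate(hairpins):
            reads.append(CollapsedRead(mat, int(rng_r.integers(30, 80)), lib))
            if classes[k] == "specific_with_star":
                reads.append(CollapsedRead(star, int(rng_r.integers(3, 9)), lib))
        # genome-derived noise (no hairpin), plus length-filter fodder
        for _ in range(3):
            chrom = chrom_ids[int(rng_r.integers(0, len(chrom_ids)))]
            pos = int(rng_r.integers(0, len(genome[chrom]) - 24))
            reads.append(CollapsedRead(genome[chrom][pos : pos + 24], int(rng_r.integers(2, 10)), lib))
        reads.append(CollapsedRead(_random_seq(rng_r, 15), 4, lib))  # too short
        reads.append(CollapsedRead(_random_seq(rng_r, 31), 4, lib))  # too long
        reads_by_library[lib] = reads

    # --- degradome ----------------------------------------------------------
    rng_d = _rng(config.seed, "degradome")
    degradome_tags: list[tuple[str, int]] = []
    truth_degradome: list[dict] = []
    for kind, mk, tid, pos0, score in site_assignments:
        if kind == "b_unique":
            continue  # no working site in group A, hence no cleavage signal
        tx = tx_seqs[tid]
        hits = [
            h
            for h in find_sites(
                SequenceRecord(mirna_ids[mk], hairpins[mk][1]),
                SequenceRecord(tid, tx),
                p,
            )
            if h.site_start == pos0 + 1
        ]
        if not hits:
            raise GenerationError("planted site lost before degradome generation")
        cpos = hits[0].cleavage_pos
        tags = make_degradome(
            rng_d, cpos, tx, config.total_tags, config.peak_fraction, config.tag_len
        )
        degradome_tags.extend(tags)
        truth_degradome.append(
            {"transcript_id": tid, "cleavage_pos": cpos, "mirna_id": mirna_ids[mk]}
        )

    bundle = ScenarioBundle(
        config=config,
        genome=genome,
        transcripts_a=transcripts_a,
        transcripts_b=transcripts_b,
        gene_models=gene_models,
        loci=loci,
        reference_mirnas=reference_mirnas,
        reads_by_library=reads_by_library,
        vcf_rows=vcf_rows,
        variant_records=variant_records,
        samples=samples,
        group_map=group_map,
        degradome_tags=degradome_tags,
        truth_sites=truth_sites,
        truth_events=events,
        truth_mature_snps=truth_mature_snps,
        truth_degradome=truth_degradome,
    )
    _verify_bundle(bundle)
    return bundle


def _verify_bundle(bundle: ScenarioBundle) -> None:
    """Re-check planted truths against the analysis modules."""
    config = bundle.config
    p = config.params
    tx_a = {t.id: t for t in bundle.transcripts_a}
    mat_of = {l.id: l.mature_seq for l in bundle.loci}
    for s in bundle.truth_sites:
        if s["kind"] == "b_unique":
            continue
        hits = [
            h
            for h in find_sites(
                SequenceRecord(s["mirna_id"], mat_of[s["mirna_id"]]),
                tx_a[s["transcript_id"]],
                p,
            )
            if h.site_start == s["site_start"]
        ]
        if s["score"] <= p.cutoff:
            if not hits or abs(hits[0].score - s["score"]) > 1e-9:
                raise GenerationError(
                    f"planted site verification failed for {s['transcript_id']}"
                )
    for l in bundle.loci:
        ev = evaluate_hairpin(l.precursor_seq, l.mature_seq, l.structure)
        if not ev.passed:
            raise GenerationError(f"planted hairpin {l.id} fails its own criteria")


# ---------------------------------------------------------------------------
# Serialization

def write_scenario(bundle: ScenarioBundle, outdir: str | Path) -> Path:
    """Write the bundle as a text-only dataset directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = bundle.config

    write_fasta(
        outdir / "genome.fa",
        [SequenceRecord(c, s) for c, s in bundle.genome.items()],
    )
    write_fasta(outdir / "transcripts_A.fa", bundle.transcripts_a)
    write_fasta(outdir / "transcripts_B.fa", bundle.transcripts_b)
    write_fasta(outdir / "ref_mirnas.fa", bundle.reference_mirnas)
    for lib, reads in bundle.reads_by_library.items():
        write_collapsed_reads(outdir / f"reads_{lib}.fa", reads)
    write_vcf(
        outdir / "variants.vcf",
        bundle.vcf_rows,
        bundle.samples,
        bundle.genome_lengths,
    )
    with open(outdir / "groups.tsv", "w") as fh:
        for s in bundle.samples:
            fh.write(f"{s}\t{bundle.group_map[s]}\n")
    with open(outdir / "gene_models.tsv", "w") as fh:
        fh.write("transcript_id\tchrom\tstart\tend\tstrand\n")
        for tid, iv in bundle.gene_models.items():
            fh.write(f"{tid}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n")
    with open(outdir / "degradome.tsv", "w") as fh:
        for seq, count in bundle.degradome_tags:
            fh.write(f"{seq}\t{count}\n")
    with open(outdir / "mirnas.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for l in bundle.loci:
            piv, miv = l.precursor_interval, l.mature_interval
            fh.write(
                f"{piv.chrom}\tmirsnp\tmiRNA_primary_transcript\t{piv.start + 1}\t"
                f"{piv.end}\t.\t{piv.strand}\t.\tID={l.id};class={l.class_label}\n"
            )
            fh.write(
                f"{miv.chrom}\tmirsnp\tmiRNA\t{miv.start + 1}\t{miv.end}\t.\t"
                f"{miv.strand}\t.\tID={l.id}.mature;Parent={l.id}\n"
            )

    truth = outdir / "truth"
    truth.mkdir(exist_ok=True)
    with open(truth / "hairpins.tsv", "w") as fh:
        fh.write("mirna_id\tclass\tchrom\tstart\tend\tmature_seq\tstar_seq\n")
        for l in bundle.loci:
            iv = l.precursor_interval
            fh.write(
                f"{l.id}\t{l.class_label}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{l.mature_seq}\t{l.star_seq or ''}\n"
            )
    with open(truth / "sites.tsv", "w") as fh:
        fh.write("mirna_id\ttranscript_id\tsite_start\tsite_end\tscore\tkind\n")
        for s in bundle.truth_sites:
            fh.write(
                f"{s['mirna_id']}\t{s['transcript_id']}\t{s['site_start']}\t"
                f"{s['site_end']}\t{s['score']}\t{s['kind']}\n"
            )
    with open(truth / "events.tsv", "w") as fh:
        fh.write(
            "kind\tmirna_id\ttranscript_id\ttranscript_pos\tref\talt\t"
            "site_start\tsite_end\n"
        )
        for e in bundle.truth_events:
            fh.write(
                f"{e.kind}\t{e.mirna_id}\t{e.transcript_id}\t{e.transcript_pos}\t"
                f"{e.ref_base}\t{e.alt_base}\t{e.site_start}\t{e.site_end}\n"
            )
    with open(truth / "mature_snps.tsv", "w") as fh:
        fh.write("mirna_id\tmature_pos\tref\talt\n")
        for row in bundle.truth_mature_snps:
            fh.write(
                f"{row['mirna_id']}\t{row['mature_pos']}\t{row['ref']}\t{row['alt']}\n"
            )
    with open(truth / "degradome.tsv", "w") as fh:
        fh.write("transcript_id\tcleavage_pos\tmirna_id\n")
        for row in bundle.truth_degradome:
            fh.write(
                f"{row['transcript_id']}\t{row['cleavage_pos']}\t{row['mirna_id']}\n"
            )

    cfg = dataclasses.asdict(config)
    cfg["params"] = dataclasses.asdict(config.params)
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
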