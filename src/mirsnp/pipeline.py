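"""End-to-end orchestration of the analysis stages with provenance capture.

Stage order: discover -> targets -> diversity -> impact -> degradome-confirm
-> report. A failure in one stage halts the run naming the stage; every
output directory carries exactly one ``manifest.json`` with the tool version,
the configuration snapshot, input digests, the seed, and per-stage row
counts, so a rerun from the same inputs and manifest seed reproduces every
table byte for byte. The per-stage helpers (``stage_*``) are shared with the
CLI subcommands, so running stages individually on each other's outputs
reproduces ``run_full``'s tables exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .core_io import (
    GenomicInterval,
    SequenceRecord,
    read_collapsed_reads,
    read_fasta,
    read_group_map,
    read_variants,
)
from .degradome import confirm_interaction, map_tags
from .diversity import classify_loci, diversity_table
from .mirna_discovery import (
    DiscoveryConfig,
    MiRNALocus,
    discover_mirnas,
    expression_table,
)
from .snp_impact import call_group_unique_targets, compare_groups
from .target_engine import ScoreParams, TargetInteraction, find_sites

__all__ = [
    "PipelineConfig",
    "StageError",
    "run_full",
    "read_gene_models",
    "read_loci_tsv",
    "read_interactions_tsv",
    "stage_targets",
    "stage_diversity",
    "stage_impact",
    "stage_degradome",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int = 0
    group_a: str | None = None  # defaults to first group in file order
    group_b: str | None = None
    n_perm: int = 199
    min_identity: float = 0.90
    alpha: float = 0.05
    tag_len: int = 20
    flank: int = 2000
    params: ScoreParams = field(default_factory=ScoreParams)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)


_INPUT_FILES = (
    "genome.fa",
    "transcripts_A.fa",
    "transcripts_B.fa",
    "ref_mirnas.fa",
    "variants.vcf",
    "groups.tsv",
    "gene_models.tsv",
    "degradome.tsv",
)


# ---------------------------------------------------------------------------
# Table readers/writers shared by run_full and the CLI stages

def read_gene_models(path: str | Path) -> dict[str, GenomicInterval]:
    df = pd.read_csv(path, sep="\t")
    return {
        row.transcript_id: GenomicInterval(
            row.chrom, int(row.start), int(row.end), row.strand
        )
        for row in df.itertuples()
    }


def loci_frame(loci: Sequence[MiRNALocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": l.id,
                "class": l.class_label,
                "chrom": l.precursor_interval.chrom,
                "precursor_start": l.precursor_interval.start + 1,
                "precursor_end": l.precursor_interval.end,
                "strand": l.precursor_interval.strand,
                "mature_start": l.mature_interval.start + 1,
                "mature_end": l.mature_interval.end,
                "arm": l.arm,
                "mature_seq": l.mature_seq,
                "star_seq": l.star_seq or "",
            }
            for l in loci
        ]
    )


def read_loci_tsv(path: str | Path, genome: Mapping[str, str]) -> list[MiRNALocus]:
    """Reconstruct annotated loci from a ``mirna_loci.tsv`` (structures omitted)."""
    from .core_io import extract_interval

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    loci = []
    for row in df.to_dict("records"):
        piv = GenomicInterval(
            row["chrom"],
            int(row["precursor_start"]) - 1,
            int(row["precursor_end"]),
            row["strand"],
        )
        miv = GenomicInterval(
            row["chrom"],
            int(row["mature_start"]) - 1,
            int(row["mature_end"]),
            row["strand"],
        )
        loci.append(
            MiRNALocus(
                id=row["mirna_id"],
                precursor_interval=piv,
                mature_interval=miv,
                precursor_seq=extract_interval(genome, piv).seq,
                mature_seq=row["mature_seq"],
                star_seq=row["star_seq"] or None,
                arm=row["arm"],
                class_label=row["class"],
            )
        )
    return loci


def interactions_frame(interactions: Sequence[TargetInteraction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": i.mirna_id,
                "transcript_id": i.transcript_id,
                "site_start": i.site_start,
                "site_end": i.site_end,
                "score": i.score,
                "alignment": i.alignment_string(),
                "cleavage_pos": i.cleavage_pos,
                "cleavage_approximate": i.cleavage_approximate,
            }
            for i in interactions
        ]
    )


def read_interactions_tsv(path: str | Path) -> list[TargetInteraction]:
    df = pd.read_csv(path, sep="\t")
    return [
        TargetInteraction(
            mirna_id=row.mirna_id,
            transcript_id=row.transcript_id,
            site_start=int(row.site_start),
            site_end=int(row.site_end),
            alignment=(),
            score=float(row.score),
            cleavage_pos=int(row.cleavage_pos),
            cleavage_approximate=bool(row.cleavage_approximate),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Stage helpers

def stage_targets(
    loci: Sequence[MiRNALocus],
    transcripts: Sequence[SequenceRecord],
    params: ScoreParams,
) -> list[TargetInteraction]:
    interactions: list[TargetInteraction] = []
    for locus in loci:
        for t in transcripts:
            interactions.extend(
                find_sites(SequenceRecord(locus.id, locus.mature_seq), t, params)
            )
    return interactions


def stage_diversity(
    loci,
    interactions,
    variants,
    genome_lengths,
    gene_models,
    config: PipelineConfig,
) -> pd.DataFrame:
    classes = classify_loci(
        loci, interactions, genome_lengths, gene_models, config.flank
    )
    results = diversity_table(
        classes, variants, genome_lengths, n_perm=config.n_perm, seed=config.seed
    )
    return pd.DataFrame(
        [
            {
                "class": r.class_name,
                "n_sites": r.n_sites,
                "n_variant_sites": r.n_variant_sites,
                "pi": r.pi,
                "perm_p": "" if r.perm_p is None else r.perm_p,
                "n_perm": r.n_perm,
                "seed": r.seed,
            }
            for r in results
        ]
    )


def stage_impact(
    loci,
    transcripts_a,
    transcripts_b,
    gene_models,
    variants,
    group_a: str,
    group_b: str,
    config: PipelineConfig,
):
    comparison = compare_groups(
        loci,
        transcripts_a,
        gene_models,
        variants,
        group_a,
        group_b,
        config.params,
        ortholog_transcripts=transcripts_b,
        min_identity=config.min_identity,
    )
    table = call_group_unique_targets(comparison)
    deltas_df = pd.DataFrame(
        [
            {
                "mirna_id": d.mirna_id,
                "transcript_id": d.transcript_id,
                "status": d.status,
                "cause": d.cause,
                "ref_score": "" if d.ref_score is None else d.ref_score,
                "alt_score": "" if d.alt_score is None else d.alt_score,
                "ref_site": _span(d.ref_site),
                "alt_site": _span(d.alt_site),
                "ortholog_id": d.ortholog.ortholog_id if d.ortholog else "",
                "ortholog_identity": round(d.ortholog.identity, 4)
                if d.ortholog
                else "",
                "ortholog_accepted": d.ortholog.accepted if d.ortholog else "",
            }
            for d in comparison.deltas
        ]
    )
    return comparison, table, deltas_df


def stage_degradome(
    interactions: Sequence[TargetInteraction],
    tags: Sequence[tuple[str, int]],
    transcripts: Sequence[SequenceRecord],
    config: PipelineConfig,
):
    profiles, tag_report = map_tags(tags, transcripts, config.tag_len)
    by_tx = {p.transcript_id: p for p in profiles}
    calls = []
    for inter in interactions:
        prof = by_tx.get(inter.transcript_id)
        if prof is None:
            continue
        call = confirm_interaction(
            inter, prof, alpha=config.alpha, tag_len=config.tag_len
        )
        if call is not None:
            calls.append((inter, call))
    calls_df = pd.DataFrame(
        [
            {
                "mirna_id": i.mirna_id,
                "transcript_id": c.transcript_id,
                "predicted_cleavage": i.cleavage_pos,
                "called_position": c.position,
                "category": c.category,
                "count": c.count_at_position,
                "p_value": c.p_value,
                "significant": c.significant,
            }
            for i, c in calls
        ]
    )
    return calls_df, tag_report


def read_degradome_tags(path: str | Path) -> list[tuple[str, int]]:
    return [
        (row[0], int(row[1]))
        for row in pd.read_csv(path, sep="\t", header=None).itertuples(index=False)
    ]


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _span(site: tuple[int, int] | None) -> str:
    return "" if site is None else f"{site[0]}-{site[1]}"


def _config_dict(config: PipelineConfig) -> dict:
    out = dataclasses.asdict(config)
    out["params"] = dataclasses.asdict(config.params)
    disc = dataclasses.asdict(config.discovery)
    disc["known_families"] = sorted(config.discovery.known_families)
    disc["criteria"] = dataclasses.asdict(config.discovery.criteria)
    out["discovery"] = disc
    return out


# ---------------------------------------------------------------------------
# Full run

def run_full(
    indir: str | Path, outdir: str | Path, config: PipelineConfig | None = None
) -> Path:
    """Run every stage on a dataset directory; returns the output directory."""
    config = config or PipelineConfig()
    indir, outdir = Path(indir), Path(outdir)

    # pre-flight: every input must exist before any stage runs
    read_files = sorted(indir.glob("reads_*.fa"))
    missing = [f for f in _INPUT_FILES if not (indir / f).exists()]
    if not read_files:
        missing.append("reads_<library>.fa")
    if missing:
        raise FileNotFoundError(f"missing inputs in {indir}: {', '.join(missing)}")
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool_version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "inputs": {
            f.name: _digest(f)
            for f in [indir / name for name in _INPUT_FILES] + read_files
        },
        "stages": {},
    }

    genome = {r.id: r.seq for r in read_fasta(indir / "genome.fa")}
    transcripts_a = read_fasta(indir / "transcripts_A.fa")
    transcripts_b = read_fasta(indir / "transcripts_B.fa")
    ref_mirnas = read_fasta(indir / "ref_mirnas.fa")
    gene_models = read_gene_models(indir / "gene_models.tsv")
    group_map = read_group_map(indir / "groups.tsv")
    reads_by_library = {
        f.stem.replace("reads_", ""): read_collapsed_reads(f, "header_xN")
        for f in read_files
    }

    groups = sorted(set(group_map.values()))
    group_a = config.group_a or groups[0]
    group_b = config.group_b or next(g for g in groups if g != group_a)

    try:
        loci, report = discover_mirnas(
            reads_by_library, genome, ref_mirnas, None, config.discovery
        )
        expr = expression_table(loci, reads_by_library)
        loci_frame(loci).to_csv(outdir / "mirna_loci.tsv", sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(e) for e in expr]).to_csv(
            outdir / "expression.tsv", sep="\t", index=False, float_format="%.4f"
        )
        manifest["stages"]["discover"] = {"loci": len(loci), **report}
    except Exception as exc:
        raise StageError("discover", str(exc)) from exc

    try:
        interactions = stage_targets(loci, transcripts_a, config.params)
        interactions_frame(interactions).to_csv(
            outdir / "interactions.tsv", sep="\t", index=False
        )
        manifest["stages"]["targets"] = {"interactions": len(interactions)}
    except Exception as exc:
        raise StageError("targets", str(exc)) from exc

    try:
        variants = read_variants(indir / "variants.vcf", group_map)
        genome_lengths = {c: len(s) for c, s in genome.items()}
        stage_diversity(
            loci, interactions, variants.records, genome_lengths, gene_models, config
        ).to_csv(outdir / "diversity.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["stages"]["diversity"] = {
            "snps": len(variants.records),
            "indels_skipped": variants.n_indels_skipped,
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("diversity", str(exc)) from exc

    try:
        comparison, table, deltas_df = stage_impact(
            loci, transcripts_a, transcripts_b, gene_models, variants.records,
            group_a, group_b, config,
        )
        deltas_df.to_csv(outdir / "deltas.tsv", sep="\t", index=False)
        pd.DataFrame(table["rows"]).to_csv(
            outdir / "unique_targets.tsv", sep="\t", index=False
        )
        manifest["stages"]["impact"] = {
            "deltas": len(comparison.deltas),
            f"{group_a}_unique": table[f"{group_a}_unique"],
            f"{group_b}_unique": table[f"{group_b}_unique"],
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("impact", str(exc)) from exc

    try:
        tags = read_degradome_tags(indir / "degradome.tsv")
        calls_df, tag_report = stage_degradome(
            interactions, tags, transcripts_a, config
        )
        calls_df.to_csv(
            outdir / "degradome_calls.tsv", sep="\t", index=False, float_format="%.6g"
        )
        manifest["stages"]["degradome"] = {"calls": len(calls_df), **tag_report}
    except StageError:
        raise
    except Exception as exc:
        raise StageError("degradome", str(exc)) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
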