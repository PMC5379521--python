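"""Degradome (PARE) tag mapping, t-plots, and cleavage-category classification.

Degradome tags are 5' sequence prefixes of uncapped mRNA fragments; a pile-up
at the transcript position opposite miRNA position 10 evidences miRNA-guided
cleavage. Positions are ranked CleaveLand-style relative to the transcript's
tag-count distribution:

* category 0 — count > 1, equal to the transcript maximum, maximum unique;
* category 1 — count > 1, equal to a shared maximum;
* category 2 — count > 1, above the median of stored counts but below max;
* category 3 — count > 1, at or below the median;
* category 4 — count of exactly 1.

The per-site p-value uses a uniform-null binomial model over effective
transcript positions (a count-shuffling resampling variant is provided as a
cross-check); both are reconstructions of "statistically significant
cleavage", which the pipeline exposes rather than hard-codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import SequenceRecord
from .target_engine import TargetInteraction

__all__ = [
    "TagProfile",
    "CleavageCall",
    "map_tags",
    "classify_site",
    "site_pvalue",
    "site_pvalue_resampled",
    "confirm_interaction",
    "tplot_data",
]


@dataclass
class TagProfile:
    """5'-end tag counts along one transcript (1-based positions)."""

    transcript_id: str
    counts: dict[int, int]
    transcript_length: int
    multi_mapped: set[int] | None = None

    @property
    def total_tags(self) -> int:
        return sum(self.counts.values())

    def count_at(self, position: int) -> int:
        return self.counts.get(position, 0)


@dataclass
class CleavageCall:
    transcript_id: str
    position: int
    category: int
    count_at_position: int
    p_value: float
    significant: bool


def map_tags(
    tags: Sequence[tuple[str, int]],
    transcripts: Sequence[SequenceRecord],
    tag_len: int = 20,
    min_tag_len: int = 15,
) -> tuple[list[TagProfile], dict[str, int]]:
    """Map tag 5' ends onto transcripts by exact prefix matching.

    ``tags`` are ``(sequence, count)`` pairs; each tag is truncated to
    ``tag_len`` and every exact occurrence records the tag's count at the
    match's 1-based start position. Tags matching several transcripts are
    counted on each (position flagged multi-mapped). Tags shorter than
    ``min_tag_len`` are skipped and counted in the report.
    """
    report = {"tags": len(tags), "too_short": 0, "unmatched": 0, "multi": 0}
    profiles: dict[str, TagProfile] = {
        t.id: TagProfile(t.id, {}, len(t.seq), set()) for t in transcripts
    }
    for seq, count in tags:
        seq = seq.upper().replace("U", "T")[:tag_len]
        if len(seq) < min_tag_len:
            report["too_short"] += 1
            continue
        hits: list[tuple[str, int]] = []
        for t in transcripts:
            start = t.seq.find(seq)
            while start >= 0:
                hits.append((t.id, start + 1))
                start = t.seq.find(seq, start + 1)
        if not hits:
            report["unmatched"] += 1
            continue
        multi = len({tid for tid, _ in hits}) > 1
        if multi:
            report["multi"] += 1
        for tid, pos in hits:
            prof = profiles[tid]
            prof.counts[pos] = prof.counts.get(pos, 0) + count
            if multi:
                prof.multi_mapped.add(pos)
    return [p for p in profiles.values() if p.counts], report


def classify_site(
    profile: TagProfile, position: int, include_zeros_in_median: bool = False
) -> int | None:
    """CleaveLand-style category of the tag count at one position.

    Returns None when no tag starts at the position. The median is computed
    over stored (nonzero) positions by default; ``include_zeros_in_median``
    switches to the full transcript-length distribution.
    """
    if not (1 <= position <= profile.transcript_length):
        raise ValueError(
            f"position {position} outside transcript of length "
            f"{profile.transcript_length}"
        )
    c = profile.count_at(position)
    if c == 0:
        return None
    if c == 1:
        return 4
    values = list(profile.counts.values())
    if include_zeros_in_median:
        values = values + [0] * (profile.transcript_length - len(values))
    m = max(values)
    med = median(values)
    if c == m:
        n_at_max = sum(1 for v in profile.counts.values() if v == m)
        return 0 if n_at_max == 1 else 1
    if c > med:
        return 2
    return 3


def site_pvalue(profile: TagProfile, position: int, tag_len: int = 20) -> float:
    """Binomial tail probability of the observed count under a uniform null.

    ``p = P(X >= c)`` for ``X ~ Binomial(total_tags, 1/effective_positions)``
    with ``effective_positions = transcript_length - tag_len + 1``.
    """
    if profile.total_tags < 1:
        raise ValueError("profile has no tags")
    eff = profile.transcript_length - tag_len + 1
    if eff <= 0:
        raise ValueError("effective positions <= 0 (transcript shorter than tag)")
    c = profile.count_at(position)
    if c == 0:
        return 1.0
    return float(stats.binom.sf(c - 1, profile.total_tags, 1.0 / eff))


def site_pvalue_resampled(
    profile: TagProfile,
    position: int,
    tag_len: int = 20,
    n_shuffles: int = 999,
    seed: int = 0,
) -> float:
    """Resampling cross-check: shuffle counts across positions.

    Each shuffle reassigns the observed count multiset to uniformly drawn
    positions; p is the fraction of shuffles in which the maximum count at
    the target position's rank reaches the observed count.
    """
    eff = profile.transcript_length - tag_len + 1
    if eff <= 0:
        raise ValueError("effective positions <= 0")
    rng = np.random.default_rng(seed)
    c = profile.count_at(position)
    if c == 0:
        return 1.0
    total = profile.total_tags
    hits = 0
    for _ in range(n_shuffles):
        placed = rng.integers(0, eff, size=total)
        top = np.bincount(placed).max()
        if top >= c:
            hits += 1
    return (1 + hits) / (n_shuffles + 1)


def confirm_interaction(
    interaction: TargetInteraction,
    profile: TagProfile,
    window: int = 1,
    alpha: float = 0.05,
    tag_len: int = 20,
    include_zeros_in_median: bool = False,
) -> CleavageCall | None:
    """Degradome support for a predicted interaction, or None.

    Looks within ``window`` of the predicted cleavage position and returns
    the best call (lowest category, then highest count). ``significant`` is
    the binomial test at level ``alpha``.
    """
    center = interaction.cleavage_pos
    best: CleavageCall | None = None
    for pos in range(center - window, center + window + 1):
        if not (1 <= pos <= profile.transcript_length):
            continue
        cat = classify_site(profile, pos, include_zeros_in_median)
        if cat is None:
            continue
        p = site_pvalue(profile, pos, tag_len)
        call = CleavageCall(
            profile.transcript_id,
            pos,
            cat,
            profile.count_at(pos),
            p,
            p < alpha,
        )
        if (
            best is None
            or call.category < best.category
            or (call.category == best.category and call.count_at_position > best.count_at_position)
        ):
            best = call
    return best


def tplot_data(profile: TagProfile) -> tuple[np.ndarray, np.ndarray]:
    """Positions and counts for a t-plot (all stored positions, sorted)."""
    pos = np.array(sorted(profile.counts), dtype=np.int64)
    counts = np.array([profile.counts[p] for p in pos], dtype=np.int64)
    return pos, counts
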