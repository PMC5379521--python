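"""Plant miRNA-target site search with position-weighted penalty scoring.

The scheme is the classical plant complementarity score: the miRNA is read
5'->3' against the site read 3'->5'; each miRNA position contributes

* 0 for a Watson-Crick pair,
* ``gu_penalty`` (default 0.5) for a G:U wobble,
* ``mismatch_penalty`` (default 1.0) for any other opposition,
* ``bulge_penalty`` (default 1.0) for a bulged base, at most one bulge,

with every penalty doubled when the miRNA position falls in the core region
(positions ``core_start``..``core_end``, default 2..13). Sites scoring at or
below ``cutoff`` (default 4.0) are reported. Cleavage is inferred opposite
miRNA position 10, the canonical slicing register of plant AGO1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core_io import SequenceRecord

__all__ = [
    "ScoreParams",
    "AlignmentColumn",
    "TargetInteraction",
    "score_duplex",
    "score_from_alignment",
    "find_sites",
    "cleavage_position",
]

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}  # G:U wobble in DNA letters

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class ScoreParams:
    """Penalty parameters for duplex scoring."""

    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    bulge_penalty: float = 1.0
    core_start: int = 2
    core_end: int = 13
    cutoff: float = 4.0

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.gu_penalty, self.bulge_penalty) < 0:
            raise ValueError("penalties must be >= 0")
        if not (1 <= self.core_start <= self.core_end):
            raise ValueError("require 1 <= core_start <= core_end")

    def multiplier(self, mirna_pos: int) -> float:
        """Penalty multiplier at a 1-based miRNA position (2x in the core)."""
        return 2.0 if self.core_start <= mirna_pos <= self.core_end else 1.0


@dataclass(frozen=True)
class AlignmentColumn:
    """One column of a duplex alignment.

    ``mirna_pos`` is 1-based from the miRNA 5' end (None for a site bulge's
    extra base, which is charged to ``charged_pos``); ``site_pos`` is the
    1-based position within the site sequence (None for a miRNA bulge).
    ``state`` is one of ``match | gu | mismatch | bulge``.
    """

    mirna_pos: int | None
    site_pos: int | None
    state: str
    charged_pos: int = 0  # miRNA position whose core status prices this column


def pair_state(mirna_base: str, site_base: str) -> str:
    pair = (mirna_base, site_base)
    if pair in _WC:
        return "match"
    if pair in _GU:
        return "gu"
    return "mismatch"


def score_from_alignment(
    alignment: Sequence[AlignmentColumn], params: ScoreParams
) -> float:
    """Recompute the penalty score of an alignment from its column states."""
    total = 0.0
    for col in alignment:
        mult = params.multiplier(col.charged_pos)
        if col.state == "match":
            continue
        if col.state == "gu":
            total += params.gu_penalty * mult
        elif col.state == "mismatch":
            total += params.mismatch_penalty * mult
        elif col.state == "bulge":
            total += params.bulge_penalty * mult
        else:  # pragma: no cover
            raise ValueError(f"unknown state {col.state!r}")
    return total


def _columns_no_bulge(mirna: str, site: str) -> list[AlignmentColumn]:
    m = len(mirna)
    cols = []
    for k in range(m):
        site_pos = m - k  # 1-based: miRNA pos 1 faces the site 3' end
        state = pair_state(mirna[k], site[site_pos - 1])
        cols.append(AlignmentColumn(k + 1, site_pos, state, charged_pos=k + 1))
    return cols


def _columns_mirna_bulge(mirna: str, site: str, b: int) -> list[AlignmentColumn]:
    """miRNA position ``b`` (1-based) is bulged; site has length m-1."""
    m, s = len(mirna), len(site)
    cols = []
    for k in range(m):
        pos = k + 1
        if pos == b:
            cols.append(AlignmentColumn(pos, None, "bulge", charged_pos=pos))
            continue
        # reversed-site index of the base facing this miRNA position
        r = k if pos < b else k - 1
        site_pos = s - r
        state = pair_state(mirna[k], site[site_pos - 1])
        cols.append(AlignmentColumn(pos, site_pos, state, charged_pos=pos))
    return cols


def _columns_site_bulge(mirna: str, site: str, b: int) -> list[AlignmentColumn]:
    """Reversed-site index ``b-1`` is bulged (b in 1..m+1); site length m+1.

    The bulged site base sits between miRNA positions b-1 and b and is
    charged to miRNA position min(b, m).
    """
    m, s = len(mirna), len(site)
    cols = []
    for k in range(m):
        pos = k + 1
        r = k if pos < b else k + 1
        site_pos = s - r
        state = pair_state(mirna[k], site[site_pos - 1])
        cols.append(AlignmentColumn(pos, site_pos, state, charged_pos=pos))
        if pos == b - 1:
            cols.append(
                AlignmentColumn(None, s - (b - 1), "bulge", charged_pos=min(b, m))
            )
    if b == 1:
        cols.insert(0, AlignmentColumn(None, s, "bulge", charged_pos=1))
    return cols


def score_duplex(
    mirna_seq: str, site_seq: str, params: ScoreParams | None = None
) -> tuple[float, tuple[AlignmentColumn, ...]]:
    """Minimal-penalty alignment of a miRNA against a candidate site.

    ``site_seq`` is given 5'->3' as it appears on the transcript. The site may
    be one base shorter (one miRNA base bulged) or one base longer (one site
    base bulged) than the miRNA. Returns ``(score, alignment)``; ties are
    broken toward the smallest bulge position.
    """
    params = params or ScoreParams()
    mirna_seq = mirna_seq.upper().replace("U", "T")
    site_seq = site_seq.upper().replace("U", "T")
    m, s = len(mirna_seq), len(site_seq)
    if abs(s - m) > 1:
        raise ValueError(f"site length {s} differs from miRNA length {m} by > 1")
    candidates: list[list[AlignmentColumn]] = []
    if s == m:
        candidates.append(_columns_no_bulge(mirna_seq, site_seq))
    elif s == m - 1:
        candidates = [
            _columns_mirna_bulge(mirna_seq, site_seq, b) for b in range(1, m + 1)
        ]
    else:
        candidates = [
            _columns_site_bulge(mirna_seq, site_seq, b) for b in range(1, m + 2)
        ]
    best_cols: list[AlignmentColumn] | None = None
    best = float("inf")
    for cols in candidates:
        sc = score_from_alignment(cols, params)
        if sc < best - 1e-12:
            best, best_cols = sc, cols
    assert best_cols is not None
    return best, tuple(best_cols)


@dataclass(frozen=True)
class TargetInteraction:
    """One miRNA-site pairing on a transcript (1-based inclusive coords)."""

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    alignment: tuple[AlignmentColumn, ...]
    score: float
    cleavage_pos: int = 0
    cleavage_approximate: bool = False
    mirna_seq: str = ""
    site_seq: str = ""

    def alignment_string(self) -> str:
        """Display string over columns: ``|`` match, ``:`` G:U, ``.`` mismatch, ``-`` bulge."""
        glyphs = {"match": "|", "gu": ":", "mismatch": ".", "bulge": "-"}
        return "".join(glyphs[c.state] for c in self.alignment)


def cleavage_position(interaction: TargetInteraction) -> tuple[int, bool]:
    """Transcript coordinate opposite miRNA position 10.

    Returns ``(position, approximate)``; ``approximate`` is True when a bulge
    falls within miRNA positions 9-11, in which case the bulge-free convention
    ``site_end - 9`` is used.
    """
    bulge_near_core = any(
        c.state == "bulge" and 9 <= c.charged_pos <= 11 for c in interaction.alignment
    )
    if bulge_near_core:
        return interaction.site_end - 9, True
    for col in interaction.alignment:
        if col.mirna_pos == 10 and col.site_pos is not None:
            return interaction.site_start + col.site_pos - 1, False
    return interaction.site_end - 9, True  # pragma: no cover


def _penalty_table(mirna: str, params: ScoreParams) -> np.ndarray:
    """(m, 4) penalty of miRNA position k+1 facing site base A/C/G/T."""
    m = len(mirna)
    table = np.zeros((m, 4))
    for k, mb in enumerate(mirna):
        mult = params.multiplier(k + 1)
        for sb, j in _BASE_IDX.items():
            st = pair_state(mb, sb)
            if st == "gu":
                table[k, j] = params.gu_penalty * mult
            elif st == "mismatch":
                table[k, j] = params.mismatch_penalty * mult
    return table


def _window_scores(mirna: str, tx: np.ndarray, params: ScoreParams) -> dict[int, np.ndarray]:
    """Best alignment score for every window, vectorized over window starts.

    Returns ``{window_length: scores}`` where ``scores[w]`` is the minimal
    penalty of the window starting at 0-based ``w`` (lengths m-1, m, m+1).
    """
    m = len(mirna)
    L = len(tx)
    A = _penalty_table(mirna, params)
    out: dict[int, np.ndarray] = {}
    core = np.array([params.multiplier(p) for p in range(1, m + 2)])

    # no bulge: P0(w) = sum_k A[k, tx[w+m-1-k]]
    if L >= m:
        n = L - m + 1
        p0 = np.zeros(n)
        for k in range(m):
            p0 += A[k, tx[m - 1 - k : m - 1 - k + n]]
        out[m] = p0

    # miRNA bulge, site length m-1: for bulge position b (1..m):
    # pre[b] = sum_{k<=b-2} A[k, tx[w+m-2-k]], suf[b] = sum_{k>=b} A[k, tx[w+m-1-k]]
    if m >= 2 and L >= m - 1:
        n = L - (m - 1) + 1
        U = np.zeros((m, n))
        V = np.zeros((m, n))
        for k in range(m):
            lo = m - 2 - k
            if 0 <= lo and lo + n <= L:
                U[k] = A[k, tx[lo : lo + n]]
            hi = m - 1 - k
            if 0 <= hi and hi + n <= L:
                V[k] = A[k, tx[hi : hi + n]]
        preU = np.vstack([np.zeros(n), np.cumsum(U, axis=0)])  # preU[j] = sum_{k<j}
        sufV = np.vstack([np.cumsum(V[::-1], axis=0)[::-1], np.zeros(n)])
        scores = np.full(n, np.inf)
        for b in range(1, m + 1):
            bp = params.bulge_penalty * core[b - 1]
            scores = np.minimum(scores, bp + preU[b - 1] + sufV[b])
        out[m - 1] = scores

    # site bulge, site length m+1: bulge at reversed index b-1 (b in 1..m+1)
    if L >= m + 1:
        s = m + 1
        n = L - s + 1
        U = np.zeros((m, n))  # k aligned before the bulge: faces tx[w+m-k]
        V = np.zeros((m, n))  # k aligned after the bulge: faces tx[w+m-1-k]
        for k in range(m):
            lo = m - k
            U[k] = A[k, tx[lo : lo + n]]
            hi = m - 1 - k
            V[k] = A[k, tx[hi : hi + n]]
        preU = np.vstack([np.zeros(n), np.cumsum(U, axis=0)])
        sufV = np.vstack([np.cumsum(V[::-1], axis=0)[::-1], np.zeros(n)])
        scores = np.full(n, np.inf)
        for b in range(1, m + 2):
            bp = params.bulge_penalty * core[min(b, m) - 1]
            scores = np.minimum(scores, bp + preU[b - 1] + sufV[b - 1])
        out[m + 1] = scores

    return out


def find_sites(
    mirna: SequenceRecord | str,
    transcript: SequenceRecord,
    params: ScoreParams | None = None,
    mirna_id: str | None = None,
) -> list[TargetInteraction]:
    """All non-overlapping candidate sites for a miRNA on a transcript.

    Every window of length m-1, m and m+1 is scored; windows at or below the
    cutoff are kept, overlapping windows collapsed to the lowest-scoring one
    (ties to the leftmost), and the result sorted by site start.
    """
    params = params or ScoreParams()
    if isinstance(mirna, SequenceRecord):
        mirna_seq, mid = mirna.seq, mirna.id
    else:
        mirna_seq, mid = mirna.upper().replace("U", "T"), mirna_id or "mirna"
    m = len(mirna_seq)
    tx_seq = transcript.seq
    if len(tx_seq) < m - 1:
        return []
    tx = np.array([_BASE_IDX.get(b, 0) for b in tx_seq], dtype=np.int64)
    window_scores = _window_scores(mirna_seq, tx, params)

    hits: list[TargetInteraction] = []
    for length, scores in window_scores.items():
        idx = np.nonzero(scores <= params.cutoff + 1e-9)[0]
        for w in idx:
            site_seq = tx_seq[w : w + length]
            score, cols = score_duplex(mirna_seq, site_seq, params)
            if score > params.cutoff + 1e-9:
                continue
            inter = TargetInteraction(
                mirna_id=mid,
                transcript_id=transcript.id,
                site_start=int(w) + 1,
                site_end=int(w) + length,
                alignment=cols,
                score=score,
                mirna_seq=mirna_seq,
                site_seq=site_seq,
            )
            pos, approx = cleavage_position(inter)
            hits.append(replace(inter, cleavage_pos=pos, cleavage_approximate=approx))

    # collapse overlapping windows: keep the lowest score; ties prefer the
    # bulge-free (length-m) window, then the leftmost
    hits.sort(
        key=lambda h: (
            h.score,
            abs(h.site_end - h.site_start + 1 - m),
            h.site_start,
            h.site_end,
        )
    )
    kept: list[TargetInteraction] = []
    for h in hits:
        if all(
            h.site_end < k.site_start or k.site_end < h.site_start for k in kept
        ):
            kept.append(h)
    kept.sort(key=lambda h: h.site_start)
    return kept
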