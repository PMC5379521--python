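"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mirsnp.synthetic_data import ScenarioConfig, make_scenario
from mirsnp.target_engine import ScoreParams

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic scenario shared by read-only tests."""
    return make_scenario(ScenarioConfig(seed=7))


@pytest.fixture(scope="session")
def scenario_dir(bundle, tmp_path_factory):
    from mirsnp.synthetic_data import write_scenario

    d = tmp_path_factory.mktemp("scenario")
    write_scenario(bundle, d)
    return d


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive, separate code paths)

def oracle_duplex_score(mirna: str, site: str, params: ScoreParams) -> float:
    """Recursive enumeration of every <=1-bulge alignment; minimal penalty."""
    m, s = len(mirna), len(site)
    r = site[::-1]

    def mult(pos: int) -> float:
        return 2.0 if params.core_start <= pos <= params.core_end else 1.0

    def pair_pen(i: int, j: int) -> float:
        pair = (mirna[i], r[j])
        if pair in _WC:
            return 0.0
        if pair in _GU:
            return params.gu_penalty * mult(i + 1)
        return params.mismatch_penalty * mult(i + 1)

    def go(i: int, j: int, bulges: int) -> float:
        if i == m and j == s:
            return 0.0
        best = math.inf
        if i < m and j < s:
            best = min(best, pair_pen(i, j) + go(i + 1, j + 1, bulges))
        if bulges < 1 and i < m:
            best = min(best, params.bulge_penalty * mult(i + 1) + go(i + 1, j, 1))
        if bulges < 1 and j < s:
            best = min(
                best, params.bulge_penalty * mult(min(i + 1, m)) + go(i, j + 1, 1)
            )
        return best

    return go(0, 0, 0)


def oracle_find_sites(mirna: str, transcript: str, params: ScoreParams):
    """Brute-force window scan + the stated collapse rule; (start1, end1, score)."""
    m = len(mirna)
    hits = []
    for length in (m - 1, m, m + 1):
        for w in range(0, len(transcript) - length + 1):
            sc = oracle_duplex_score(mirna, transcript[w : w + length], params)
            if sc <= params.cutoff + 1e-9:
                hits.append((w + 1, w + length, sc))
    # ties prefer the bulge-free window (length m), then the leftmost
    hits.sort(key=lambda h: (h[2], abs(h[1] - h[0] + 1 - m), h[0], h[1]))
    kept = []
    for h in hits:
        if all(h[1] < k[0] or k[1] < h[0] for k in kept):
            kept.append(h)
    return sorted(kept)


def oracle_max_nested_pairs(seq: str, min_loop: int = 3) -> int:
    """Exhaustive recursion over nested pairings (no memoisation)."""
    allowed = _WC | _GU

    def rec(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in allowed:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1)


def oracle_pi_pairwise(seqs) -> float:
    """Direct double loop over haplotype pairs."""
    n = len(seqs)
    L = len(seqs[0])
    good = [c for c in range(L) if all(s[c] in "ACGT" for s in seqs)]
    if not good:
        return 0.0
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            diffs = sum(1 for c in good if seqs[i][c] != seqs[j][c])
            total += diffs / len(good)
            pairs += 1
    return total / pairs


def oracle_cleavage_category(counts: dict[int, int], position: int):
    """Direct restatement of the category definitions."""
    c = counts.get(position, 0)
    if c == 0:
        return None
    if c == 1:
        return 4
    values = sorted(counts.values())
    mx = values[-1]
    mid = len(values) // 2
    med = (
        values[mid]
        if len(values) % 2
        else (values[mid - 1] + values[mid]) / 2
    )
    if c == mx:
        return 0 if values.count(mx) == 1 else 1
    return 2 if c > med else 3


def oracle_nw_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Textbook Needleman-Wunsch score matrix."""
    n, m = len(a), len(b)
    D = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        D[i][0] = i * gap
    for j in range(1, m + 1):
        D[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            D[i][j] = max(D[i - 1][j - 1] + sub, D[i - 1][j] + gap, D[i][j - 1] + gap)
    return D[n][m]
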