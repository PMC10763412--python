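"""Independent brute-force oracles used only by the tests.

Each oracle re-derives a quantity by direct enumeration, deliberately
avoiding the implementation path it checks.
"""

from __future__ import annotations

from math import comb

PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -1.0, ("T", "A"): -1.0,
    ("G", "T"): -0.5, ("T", "G"): -0.5,
}
MIN_HAIRPIN = 3


def brute_a_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    """All maximal A-runs of length >= min_len by position-wise scanning."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "A":
            j = i
            while j < n and seq[j] == "A":
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def brute_oof_uaug(seq: str) -> int:
    """Classify every ATG occurrence directly from the definition."""
    n = len(seq)
    total = 0
    for p in range(n):
        if seq[p : p + 3] != "ATG":
            continue
        oof = (n - p) % 3 != 0
        uorf = False
        q = p + 3
        while q + 3 <= n:
            if seq[q : q + 3] in ("TAA", "TAG", "TGA"):
                uorf = True
                break
            q += 3
        if oof or uorf:
            total += 1
    return total


def enumerate_structures(seq: str) -> list[frozenset[tuple[int, int]]]:
    """Every pseudoknot-free structure with hairpin loops >= 3 nt."""

    def rec(i: int, j: int) -> list[frozenset]:
        if j - i + 1 <= 0:
            return [frozenset()]
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if (seq[i], seq[k]) in PAIR_ENERGY:
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        out.append(inner | outer | {(i, k)})
        return out

    return rec(0, len(seq) - 1)


def structure_energy(seq: str, pairs: frozenset[tuple[int, int]]) -> float:
    """Stacking-only scoring: each helix step gets the mean pair strength."""
    return sum(
        0.5 * (PAIR_ENERGY[(seq[i], seq[j])] + PAIR_ENERGY[(seq[i + 1], seq[j - 1])])
        for i, j in pairs
        if (i + 1, j - 1) in pairs
    )


def exhaustive_mfe(seq: str) -> float:
    """Minimum energy over every enumerated structure (feasible to ~12 nt)."""
    return min(structure_energy(seq, s) for s in enumerate_structures(seq))


def fisher_two_tailed(table) -> float:
    """Two-tailed Fisher exact p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0

    def prob(k: int) -> float:
        return comb(col1, k) * comb(n - col1, row1 - k) / comb(n, row1)

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))
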