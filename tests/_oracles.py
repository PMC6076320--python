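"""Independent brute-force oracles used to validate the implementation.

These deliberately re-implement the documented conventions with plain
Python (lists, explicit candidate enumeration) so they share no code with
the package's vectorised/numba paths.
"""
from __future__ import annotations

from itertools import combinations

ACGT = "ACGT"
AMBIG = set("RYSWKMBDHVN")


def dp_identity(a: str, b: str) -> tuple[float, int, int]:
    """(identity, aligned_length, matches) via a quadratic tuple DP.

    Convention: free-end-gap global alignment, match +1 / mismatch 0 /
    internal gap -1; among score-optimal alignments the one with the most
    matches and then the fewest aligned columns; terminal overhangs
    excluded from the aligned length; ambiguity codes never match. Python's
    native tuple ordering does the lexicographic maximisation.
    """
    la, lb = len(a), len(b)

    def is_match(x: str, y: str) -> bool:
        return x == y and x in ACGT

    # cell value: (score, matches, -columns), boundary cells are free sources
    h = [[(0, 0, 0)] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        row, above = h[i], h[i - 1]
        for j in range(1, lb + 1):
            m = 1 if is_match(a[i - 1], b[j - 1]) else 0
            ds, dm, dc = above[j - 1]
            us, um, uc = above[j]
            ls, lm, lc = row[j - 1]
            row[j] = max((ds + m, dm + m, dc - 1),
                         (us - 1, um, uc - 1),
                         (ls - 1, lm, lc - 1))
    candidates = [h[i][lb] for i in range(1, la + 1)] + [h[la][j] for j in range(1, lb + 1)]
    _, matches, negcols = max(candidates)
    cols = -negcols
    identity = matches / cols if cols else 0.0
    return identity, cols, matches


def enumerate_rarefaction(counts: list[int], m: int) -> float:
    """Mean richness over all size-m subsamples of the individual multiset."""
    individuals = []
    for taxon, c in enumerate(counts):
        individuals.extend([taxon] * c)
    total = 0
    n_comb = 0
    for combo in combinations(range(len(individuals)), m):
        total += len({individuals[k] for k in combo})
        n_comb += 1
    return total / n_comb


def classify_day_rule(temps: list[float], min_readings: int = 24) -> str:
    """Re-statement of the suitability rule, written independently."""
    if len(temps) < min_readings:
        return "insufficient_data"
    tmax, tmin = max(temps), min(temps)
    if tmax < -0.5:
        return "unsuitable"
    mean = sum(temps) / len(temps)
    if -0.5 <= mean <= 2.0 and (tmax - tmin) < 3.0:
        return "suitable"
    return "neither"
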