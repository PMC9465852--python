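"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumerate every case, O(n^3)
clustering, literal step-up/step-down definitions) and shares no code with
the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

NONCANONICAL_PAS = [
    "UAUAAA",
    "AGUAAA",
    "AAGAAA",
    "AAUAUA",
    "AAUACA",
    "CAUAAA",
    "GAUAAA",
    "AAUGAA",
    "UUUAAA",
    "ACUAAA",
]


def brute_force_scan(seq: str) -> set[tuple]:
    """Enumerate every motif pattern at every start position.

    Returns {(class, start_1based, end_1based, matched)} with the same
    collapse semantics the scanner promises: longest canonical CPE at each
    start, G-variant extended to UUUUGUA when followed by A.
    """
    hits = set()
    n = len(seq)
    for i in range(n):
        for pat in ("UUUUAAU", "UUUUAU"):  # longest first
            if seq[i : i + len(pat)] == pat:
                hits.add(("CPE_CANONICAL", i + 1, i + len(pat), pat))
                break
        if seq[i : i + 7] == "UUUUGUA":
            hits.add(("CPE_G", i + 1, i + 7, "UUUUGUA"))
        elif seq[i : i + 6] == "UUUUGU":
            hits.add(("CPE_G", i + 1, i + 6, "UUUUGU"))
        for pat in ("AAUAAA", "AUUAAA"):
            if seq[i : i + 6] == pat:
                hits.add(("PAS_CANONICAL", i + 1, i + 6, pat))
        for pat in NONCANONICAL_PAS:
            if seq[i : i + 6] == pat:
                hits.add(("PAS_NONCANONICAL", i + 1, i + 6, pat))
    return hits


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def holm_stepdown(p: np.ndarray) -> np.ndarray:
    """Literal Holm step-down definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_max = 0.0
    for rank, i in enumerate(order):
        running_max = max(running_max, min((m - rank) * p[i], 1.0))
        adj[i] = running_max
    return adj


def complete_linkage_heights(points: np.ndarray) -> list[float]:
    """O(n^3) agglomerative complete-linkage merge heights (Euclidean)."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    while len(clusters) > 1:
        best = (np.inf, None)
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dist = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if dist < best[0]:
                best = (dist, (a, b))
        dist, (a, b) = best
        heights.append(dist)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return heights


def venn_counts(sets: dict[str, set]) -> dict[frozenset, int]:
    """Inclusion-exclusion-free direct enumeration of Venn cells."""
    names = list(sets)
    out: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo), set())
            exactly = inside - outside
            if exactly:
                out[frozenset(combo)] = len(exactly)
    return out
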