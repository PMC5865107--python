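"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive - exhaustive enumeration and direct
formula transcription - and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def compositions(total: int, parts: int):
    """All compositions of ``total`` into exactly ``parts`` positive parts."""
    if parts == 1:
        yield (total,)
        return
    for first in range(1, total - parts + 2):
        for rest in compositions(total - first, parts - 1):
            yield (first,) + rest


def weak_compositions(total: int, parts: int):
    """All compositions of ``total`` into ``parts`` non-negative parts."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in weak_compositions(total - first, parts - 1):
            yield (first,) + rest


def enumerate_tables(rows, cols):
    """Every non-negative integer matrix with the given marginals."""
    rows, cols = tuple(rows), tuple(cols)

    def rec(r, colrem):
        if r == len(rows) - 1:
            yield (tuple(colrem),)
            return

        def comp(i, rem, cur):
            if i == len(cols) - 1:
                if rem <= colrem[-1]:
                    yield cur + (rem,)
                return
            for v in range(min(rem, colrem[i]) + 1):
                yield from comp(i + 1, rem - v, cur + (v,))

        for row in comp(0, rows[r], ()):
            newrem = tuple(c - v for c, v in zip(colrem, row))
            yield from ((row,) + rest for rest in rec(r + 1, newrem))

    yield from rec(0, cols)


def shannon_entropy(flat, m):
    return -sum((v / m) * math.log(v / m) for v in flat if v > 0)


def exact_min_entropy(rows, cols) -> float:
    """Exhaustive minimum table entropy under fixed marginals."""
    m = sum(rows)
    return min(
        shannon_entropy([v for row in tab for v in row], m)
        for tab in enumerate_tables(rows, cols)
    )


def divergence(alloc, total, availability) -> float:
    return sum(
        (a / total) * math.log((a / total) / q)
        for a, q in zip(alloc, availability) if a > 0
    )


def exact_min_divergence(total: int, availability) -> float:
    """Exhaustive minimum KL divergence over integer allocations."""
    best = math.inf
    usable = [q > 0 for q in availability]
    k = len(availability)
    for alloc in weak_compositions(total, k):
        if any(a > 0 and not u for a, u in zip(alloc, usable)):
            continue
        best = min(best, divergence(alloc, total, availability))
    return best


def kruskal_wallis_formula(groups) -> tuple[float, int]:
    """Direct transcription of the tie-corrected Kruskal-Wallis statistic."""
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = flat.size
    order = np.argsort(flat, kind="mergesort")
    ranks = np.empty(n_total)
    i = 0
    while i < n_total:
        j = i
        while j + 1 < n_total and flat[order[j + 1]] == flat[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0  # mid-rank
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        size = len(g)
        h += ranks[start:start + size].sum() ** 2 / size
        start += size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    _, counts = np.unique(flat, return_counts=True)
    ties = sum(t**3 - t for t in counts)
    correction = 1.0 - ties / (n_total**3 - n_total)
    return h / correction, len(groups) - 1


def permanova_f_direct(d2: np.ndarray, labels) -> float:
    """Pseudo-F from squared distances, transcribed from the definition."""
    labels = np.asarray(labels)
    n = d2.shape[0]
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for value in set(labels.tolist()):
        idx = [i for i in range(n) if labels[i] == value]
        ss_within += sum(
            d2[i, j] for a, i in enumerate(idx) for j in idx[a + 1:]
        ) / len(idx)
    k = len(set(labels.tolist()))
    ss_between = ss_total - ss_within
    if ss_within == 0:
        return math.inf
    return (ss_between / (k - 1)) / (ss_within / (n - k))
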