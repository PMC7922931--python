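"""Independent brute-force oracles used to cross-check the implementation.

Kept deliberately naive: full sliding-window Hamming scans and power-set
enumeration, with no shared code paths with the package internals.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _codes(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        table[b] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def accepts(matches: int, n: int, threshold: float) -> bool:
    """Strict '>threshold' identity rule with decimal-boundary snapping."""
    v = threshold * n
    iv = round(v)
    bound = iv if abs(v - iv) < 1e-9 else v
    return matches > bound


def brute_force_hits(read_seq: str, genome_seq: str, threshold: float,
                     strands: str = "both") -> set[tuple[int, str, int]]:
    """Every (start, strand, matches) placement above threshold, by full scan.

    Ungapped, full read length; N on either side is a mismatch.
    """
    n = len(read_seq)
    g = _codes(genome_seq)
    if len(g) < n:
        return set()
    windows = np.lib.stride_tricks.sliding_window_view(g, n)
    out = set()
    variants = [("+", read_seq)]
    if strands == "both":
        variants.append(("-", revcomp(read_seq)))
    v = threshold * n
    iv = round(v)
    bound = iv if abs(v - iv) < 1e-9 else v
    for strand, seq in variants:
        r = _codes(seq)
        ok = r != 4
        matches = ((windows == r) & ok & (windows != 4)).sum(axis=1)
        for start in np.nonzero(matches > bound)[0]:
            out.add((int(start), strand, int(matches[start])))
    return out


def brute_force_qgram_positions(genome_seq: str, q: int) -> int:
    """Count of N-free length-q windows by direct scanning."""
    return sum(
        "N" not in genome_seq[i : i + q] for i in range(len(genome_seq) - q + 1)
    )


def power_set_maximal_cliques(nodes, edge) -> list[tuple]:
    """All inclusion-maximal cliques by exhaustive subset enumeration.

    ``edge(a, b)`` is the adjacency predicate.  Exponential; keep |nodes| <= 15.
    """
    nodes = sorted(nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(edge(a, b) for a, b in itertools.combinations(subset, 2)):
                cliques.append(set(subset))
    maximal = [
        c for c in cliques if not any(c < other for other in cliques)
    ]
    return sorted(tuple(sorted(c)) for c in maximal)


def naive_upgma_cophenetic(values: np.ndarray) -> np.ndarray:
    """Condensed cophenetic distances from a from-scratch UPGMA agglomeration."""
    n = len(values)
    clusters = {i: [i] for i in range(n)}
    dist = {
        (i, j): float(np.linalg.norm(values[i] - values[j]))
        for i in range(n)
        for j in range(i + 1, n)
    }
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        for x in clusters[a]:
            for y in clusters[b]:
                coph[x, y] = coph[y, x] = h
        merged = clusters[a] + clusters[b]
        for c in list(clusters):
            if c in (a, b):
                continue
            ka = (min(a, c), max(a, c))
            kb = (min(b, c), max(b, c))
            d = (len(clusters[a]) * dist.pop(ka) + len(clusters[b]) * dist.pop(kb)) / len(merged)
            dist[(min(c, next_id), max(c, next_id))] = d
        dist.pop((a, b))
        del clusters[a], clusters[b]
        clusters[next_id] = merged
        next_id += 1
    return coph[np.triu_indices(n, k=1)]
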