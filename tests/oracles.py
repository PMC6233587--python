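"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the operation definitions alone, with naive
character loops and stock library calls, deliberately sharing no code with
the package.
"""

from __future__ import annotations

import networkx as nx


def primitive(motif: str) -> bool:
    return all(
        motif != motif[:d] * (len(motif) // d)
        for d in range(1, len(motif))
        if len(motif) % d == 0
    )


def brute_force_ssrs(seq: str, min_repeats: dict[int, int]) -> set[tuple]:
    """Every maximal perfect tract (leftmost phase, whole repeats) as
    (start, end, motif, n_repeats), by testing every (offset, motif-length)."""
    seq = seq.upper()
    n = len(seq)
    found = set()
    for length in range(1, 7):
        for s in range(n - length + 1):
            motif = seq[s : s + length]
            if any(c not in "ACGT" for c in motif) or not primitive(motif):
                continue
            # s must start a maximal period-`length` run
            if s >= 1 and s - 1 + length < n:
                left, right = seq[s - 1], seq[s - 1 + length]
                if left == right and left in "ACGT":
                    continue
            # extend the periodic region base by base
            e = s + length
            while e < n and seq[e] == seq[e - length] and seq[e] in "ACGT":
                e += 1
            k = (e - s) // length
            if k >= min_repeats[length]:
                found.add((s, s + k * length, motif, k))
    return found


def components_merge(intervals: list[tuple[int, int]], max_gap: int) -> list[set[int]]:
    """Connected components of the 'gap <= max_gap' graph over intervals."""
    graph = nx.Graph()
    graph.add_nodes_from(range(len(intervals)))
    for i, (s1, e1) in enumerate(intervals):
        for j, (s2, e2) in enumerate(intervals):
            if i < j:
                gap = max(s1, s2) - min(e1, e2)
                if gap <= max_gap:
                    graph.add_edge(i, j)
    return [set(c) for c in nx.connected_components(graph)]


def overlap_components(intervals: list[tuple[str, int, int]]) -> list[set[int]]:
    """Connected components of the interval-overlap graph (shared base,
    same chromosome)."""
    graph = nx.Graph()
    graph.add_nodes_from(range(len(intervals)))
    for i, (c1, s1, e1) in enumerate(intervals):
        for j, (c2, s2, e2) in enumerate(intervals):
            if i < j and c1 == c2 and s1 < e2 and s2 < e1:
                graph.add_edge(i, j)
    return [set(c) for c in nx.connected_components(graph)]


def enumerate_primer_pairs(
    template: str,
    tract: tuple[int, int],
    min_len=16,
    max_len=22,
    min_gc=40.0,
    max_gc=60.0,
    min_tm=50.0,
    max_tm=60.0,
    min_product=100,
    max_product=500,
) -> set[tuple[int, int, int, int]]:
    """All qualifying (fwd_start, fwd_len, rev_start, rev_len) windows."""

    def gc(s: str) -> float:
        return 100.0 * sum(c in "GC" for c in s) / len(s)

    def tm(s: str) -> float:
        return 64.9 + 41.0 * (sum(c in "GC" for c in s) - 16.4) / len(s)

    def ok(s: str) -> bool:
        return "N" not in s and min_gc <= gc(s) <= max_gc and min_tm <= tm(s) <= max_tm

    template = template.upper()
    ts, te = tract
    n = len(template)
    out = set()
    for flen in range(min_len, max_len + 1):
        for fs in range(0, ts - flen + 1):
            if not ok(template[fs : fs + flen]):
                continue
            for rlen in range(min_len, max_len + 1):
                for rs in range(te, n - rlen + 1):
                    product = rs + rlen - fs
                    if not (min_product <= product <= max_product):
                        continue
                    if ok(template[rs : rs + rlen]):
                        out.add((fs, flen, rs, rlen))
    return out


def greedy_spacing(positions: list[tuple[str, int]], min_distance: int) -> set[int]:
    """Indices retained by per-chromosome greedy left-to-right spacing."""
    order = sorted(range(len(positions)), key=lambda i: positions[i])
    kept: set[int] = set()
    last: dict[str, int] = {}
    for i in order:
        chrom, start = positions[i]
        if chrom not in last or start - last[chrom] >= min_distance:
            kept.add(i)
            last[chrom] = start
    return kept
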