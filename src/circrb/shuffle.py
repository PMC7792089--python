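"""Dinucleotide-preserving sequence shuffling.

Negative training instances are generated by shuffling each binding site so
that all 16 dinucleotide counts (AA, AC, ..., TT) are *exactly* preserved.
This blocks a classifier from separating foreground and background on
low-level composition (e.g. CpG content) alone, which a plain mononucleotide
shuffle would leak.

The construction is the Euler-path scheme of Altschul & Erikson: view the
sequence as a walk on the multigraph whose vertices are the bases and whose
edges are the observed adjacent pairs; any Eulerian walk from the original
first base to the original last base spells a sequence with identical
dinucleotide counts.  A walk is sampled by choosing a random "last exit"
edge per vertex that forms an arborescence towards the end vertex, then
randomising the order of the remaining exits.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dinucleotide_shuffle", "dinucleotide_counts"]


def dinucleotide_counts(s: str) -> dict[str, int]:
    """Counts of all 16 dinucleotides appearing in ``s`` (absent pairs -> 0)."""
    counts = {a + b: 0 for a in "ACGT" for b in "ACGT"}
    for i in range(len(s) - 1):
        pair = s[i : i + 2]
        if pair in counts:
            counts[pair] += 1
    return counts


def _sample_euler_walk(s: str, rng: np.random.Generator) -> str:
    vertices = sorted(set(s))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for i in range(len(s) - 1):
        edges[s[i]].append(s[i + 1])
    last = s[-1]

    if len(vertices) == 1:  # homopolymer: single vertex, walk is forced
        return s

    # Pick a random last-exit edge for every vertex except the final one and
    # accept when following those exits from each vertex reaches the final
    # vertex (i.e. the chosen exits form an arborescence towards it).
    others = [v for v in vertices if v != last]
    while True:
        last_exit = {v: edges[v][rng.integers(len(edges[v]))] for v in others}
        ok = True
        for v in others:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_exit.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    shuffled_exits: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_exit:
            pool.remove(last_exit[v])
        rng.shuffle(pool)
        if v in last_exit:
            pool.append(last_exit[v])
        shuffled_exits[v] = pool

    walk = [s[0]]
    ptr = {v: 0 for v in vertices}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = shuffled_exits[cur][ptr[cur]]
        ptr[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


def dinucleotide_shuffle(s: str, seed: int | np.random.Generator, max_retries: int = 10) -> str:
    """Return a shuffle of ``s`` with identical dinucleotide counts and termini.

    ``seed`` may be an integer or a Generator (so callers shuffling many
    sequences can stream one RNG through).  If the walk reproduces the input
    on a sequence that admits other walks, up to ``max_retries`` re-draws are
    made before accepting the input itself (low-complexity sequences can have
    a unique Eulerian walk).
    """
    s = s.upper().replace("U", "T")
    if len(s) < 2:
        raise ValueError("sequence must have length >= 2 to dinucleotide-shuffle")
    if any(ch not in "ACGT" for ch in s):
        raise ValueError("sequence must contain only A/C/G/T (shuffle raw sites before padding)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = _sample_euler_walk(s, rng)
    tries = 0
    while out == s and tries < max_retries:
        out = _sample_euler_walk(s, rng)
        tries += 1
    return out
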