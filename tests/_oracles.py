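"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives the expected result from the operation's
definition by exhaustive scanning or textbook dynamic programming,
sharing no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np


def primitive(unit: str) -> bool:
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


def brute_ssr_hits(seq: str, thresholds: dict[int, int]) -> list[tuple]:
    """Every maximal primitive repeat run, found candidate-by-candidate.

    For each start position and unit length: count full repeats forward
    base by base, demand base-level left-maximality, primitivity and the
    repeat threshold.  Returns (unit, unit_len, repeats, start, end)
    tuples sorted like the miner's output.
    """
    seq = seq.upper()
    n = len(seq)
    found = []
    for i in range(n):
        for u in range(1, 7):
            if u not in thresholds or i + 2 * u > n:
                continue
            unit = seq[i : i + u]
            if "N" in unit or not primitive(unit):
                continue
            t = u
            while i + t < n and seq[i + t] == seq[i + t - u] and seq[i + t] != "N":
                t += 1
            k = t // u
            if k < thresholds[u]:
                continue
            # left-maximal at base resolution: the periodic run must not
            # extend one base to the left
            if i > 0 and seq[i - 1] == seq[i - 1 + u] and seq[i - 1] != "N":
                continue
            found.append((unit, u, k, i, i + u * k))
    found.sort(key=lambda h: (h[3], h[1]))
    return found


def brute_join(hits: list[tuple], max_gap: int) -> list[tuple]:
    """Definition-based compound joining on (unit, u, k, start, end)
    tuples: chains of hits whose successive gaps are <= max_gap merge;
    type is 'c' when every gap <= 0, 'c*' when any gap is in [1, max_gap].
    Returns (units_joined, type, start, end) tuples."""
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: (h[3], h[4]))
    out = []
    chain = [hits[0]]
    for h in hits[1:]:
        if h[3] - chain[-1][4] <= max_gap:
            chain.append(h)
        else:
            out.append(_emit_chain(chain))
            chain = [h]
    out.append(_emit_chain(chain))
    return out


def _emit_chain(chain: list[tuple]) -> tuple:
    if len(chain) == 1:
        unit, u, k, s, e = chain[0]
        return (unit, f"p{u}", s, e)
    gaps = [b[3] - a[4] for a, b in zip(chain, chain[1:])]
    typ = "c*" if any(g >= 1 for g in gaps) else "c"
    return ("-".join(h[0] for h in chain), typ, chain[0][3], chain[-1][4])


def levenshtein(a: str, b: str) -> int:
    """Unit-cost global edit distance, row-vectorised DP."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a.encode(), start=1):
        sub = prev[:-1] + (bb != ca)
        up = prev[1:] + 1
        tmp = np.minimum(sub, up)
        # resolve the left (insertion) dependency with a prefix-min:
        # cur[j] = min(i + j, min_{k<=j} tmp[k] + (j - k))
        idx = np.arange(1, len(b) + 1)
        cur = np.empty(len(b) + 1, dtype=prev.dtype)
        cur[0] = i
        cur[1:] = idx + np.minimum(np.minimum.accumulate(tmp - idx), i)
        prev = cur
    return int(prev[-1])


def identity_oracle(a: str, b: str) -> float:
    return max(0.0, 1.0 - levenshtein(a, b) / min(len(a), len(b)))


def greedy_reference(signatures, threshold: float):
    """The same greedy loop as the clusterer but with the DP identity and
    no prefilter; returns a partition as a list of member-index lists."""
    order = sorted(range(len(signatures)), key=lambda i: -len(signatures[i].signature))
    seeds: list[int] = []
    clusters: list[list[int]] = []
    for i in order:
        placed = False
        for ci, si in enumerate(seeds):
            if (
                identity_oracle(signatures[i].signature, signatures[si].signature)
                >= threshold - 1e-12
            ):
                clusters[ci].append(i)
                placed = True
                break
        if not placed:
            seeds.append(i)
            clusters.append([i])
    return clusters


def brute_adapter_offset(bases: str, adapter: str, max_error_rate: float,
                         min_overlap: int = 1):
    """Exhaustive semi-global adapter scan mirroring the stated rule."""
    best = None
    best_score = -1
    for i in range(0, len(bases) - min_overlap + 1):
        compared = min(len(adapter), len(bases) - i)
        errors = sum(x != y for x, y in zip(bases[i:], adapter[:compared]))
        if errors > max_error_rate * compared:
            continue
        if compared - errors > best_score:
            best_score = compared - errors
            best = i
    return best


def brute_merge(r1_bases: str, r2rc_bases: str, min_overlap: int,
                max_density: float):
    """Overlap choice by exhaustive scan: returns (L, density) of the
    density-minimising overlap (ties to larger L) or None if rejected."""
    best = None
    for L in range(min_overlap, min(len(r1_bases), len(r2rc_bases)) + 1):
        m = sum(
            x != y for x, y in zip(r1_bases[len(r1_bases) - L :], r2rc_bases[:L])
        )
        d = m / L
        if best is None or d < best[1] or (d == best[1] and L > best[0]):
            best = (L, d)
    if best is None or best[1] > max_density:
        return None
    return best


def exhaustive_pair_ranking(fwd, rev, ssr_span, params, product_range, max_diff_tm):
    """Re-derive the feasible pair list and its ordering from the stated
    constraints and penalty, independent of the implementation."""
    feasible = []
    for f in fwd:
        for r in rev:
            r_end = r.start + r.length
            if f.start > ssr_span[0] or r_end < ssr_span[1]:
                continue
            if r.start < f.start + f.length:
                continue
            size = r_end - f.start
            if not product_range[0] <= size <= product_range[1]:
                continue
            if abs(f.tm - r.tm) > max_diff_tm + 1e-9:
                continue
            pen = (
                abs(f.tm - params.tm_opt)
                + 0.25 * abs(f.length - params.size_opt)
                + abs(r.tm - params.tm_opt)
                + 0.25 * abs(r.length - params.size_opt)
                + 2.0 * abs(f.tm - r.tm)
            )
            feasible.append((pen, size, f.start, f.seq, r.seq))
    feasible.sort()
    return feasible
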