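"""Flank-signature clustering: excise the repeat, group reads that share
flanking sequence at >= 90% identity, and keep informative clusters.

The clustering is the greedy incremental scheme used by redundancy
removers: candidates are taken longest first, compared against existing
cluster seeds in seed-creation order, and join the first seed reaching
the identity threshold, otherwise found a new cluster.  Which reads end
up together therefore depends on seed choice — an arbitrariness inherent
to the scheme — but is fully deterministic here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib

from .mining import SSRHit
from .seqio import Read


@dataclass
class FlankSignature:
    """Concatenated flanks of one merged read, repeat excised."""

    source_id: str
    signature: str
    ssr: SSRHit
    full_length: int
    source_seq: str = ""


@dataclass
class FlankCluster:
    """A group of flank signatures presumed to come from one locus."""

    cluster_id: int
    seed: FlankSignature
    members: list[FlankSignature]


def excise_ssr(seq: Read, hit: SSRHit) -> FlankSignature:
    """Remove the repeat span; signature = left flank ++ right flank."""
    n = len(seq.bases)
    if not (0 <= hit.start <= hit.end <= n):
        raise ValueError(
            f"hit span [{hit.start},{hit.end}) out of bounds for "
            f"{seq.id!r} (length {n})"
        )
    return FlankSignature(
        source_id=seq.id,
        signature=seq.bases[: hit.start] + seq.bases[hit.end :],
        ssr=hit,
        full_length=n,
        source_seq=seq.bases,
    )


def identity(a: str, b: str) -> float:
    """Global-alignment identity: 1 - edit distance / shorter length.

    Matches the spirit of "identical bases over the shorter sequence":
    for substitution-only divergence this equals matches/shorter exactly.
    Clamped to [0, 1]; empty input is an error.
    """
    if not a or not b:
        raise ValueError("identity of empty sequence is undefined")
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return max(0.0, 1.0 - d / min(len(a), len(b)))


class _SeedIndex:
    """Per-seed screening data for the sound pair prefilters."""

    __slots__ = ("cluster", "counts", "kmers")

    def __init__(self, cluster: FlankCluster, word_size: int):
        sig = cluster.seed.signature
        self.cluster = cluster
        self.counts = Counter(sig)
        self.kmers = (
            {sig[i : i + word_size] for i in range(len(sig) - word_size + 1)}
            if len(sig) >= word_size
            else set()
        )


def _cannot_reach(
    sig: str,
    counts: Counter,
    kmers: set[str],
    seed: _SeedIndex,
    threshold: float,
    word_size: int,
) -> bool:
    """Sound screens proving identity(sig, seed) < threshold.

    Composition bound: aligned matches cannot exceed the per-base shared
    composition, so identity <= sum(min counts)/shorter.  k-word bound:
    at most k positional k-words are destroyed per edit, so two sequences
    within the threshold edit budget must still share a k-word whenever
    (shorter - k + 1) - k*budget > 0; only then can an empty k-word
    intersection rule the pair out.  Neither screen ever discards a pair
    that the full alignment would accept.
    """
    lmin = min(len(sig), sum(seed.counts.values()))
    shared = sum(min(counts[c], seed.counts[c]) for c in counts)
    if shared / lmin < threshold:
        return True
    budget = int((1.0 - threshold) * lmin)
    if (lmin - word_size + 1) - word_size * budget > 0:
        if kmers and seed.kmers and not (kmers & seed.kmers):
            return True
    return False


def greedy_cluster(
    signatures: list[FlankSignature],
    threshold: float = 0.90,
    word_size: int = 10,
    use_word_filter: bool = True,
) -> list[FlankCluster]:
    """Greedy incremental clustering of flank signatures.

    Signatures are processed longest first (ties keep input order); each
    joins the first existing seed with identity >= threshold, in seed
    creation order, else founds a new cluster.  The prefilter only skips
    pairs provably below threshold, so the partition is identical with
    the filter off.
    """
    order = sorted(range(len(signatures)), key=lambda i: -len(signatures[i].signature))
    clusters: list[FlankCluster] = []
    index: list[_SeedIndex] = []
    eps = 1e-12
    for i in order:
        sig = signatures[i]
        counts = Counter(sig.signature) if use_word_filter else None
        kmers = (
            {
                sig.signature[j : j + word_size]
                for j in range(len(sig.signature) - word_size + 1)
            }
            if use_word_filter and len(sig.signature) >= word_size
            else set()
        )
        placed = False
        for seed in index:
            if use_word_filter and _cannot_reach(
                sig.signature, counts, kmers, seed, threshold, word_size
            ):
                continue
            if identity(sig.signature, seed.cluster.seed.signature) >= threshold - eps:
                seed.cluster.members.append(sig)
                placed = True
                break
        if not placed:
            cluster = FlankCluster(cluster_id=len(clusters), seed=sig, members=[sig])
            clusters.append(cluster)
            index.append(_SeedIndex(cluster, word_size))
    return clusters


def filter_clusters(
    clusters: list[FlankCluster],
    min_members: int = 2,
    require_motif_consistency: bool = False,
) -> list[FlankCluster]:
    """Keep clusters large enough to show polymorphism (>= min_members)
    and, optionally, whose members all carry the same canonical motif."""
    kept = []
    for c in clusters:
        if len(c.members) < min_members:
            continue
        if require_motif_consistency:
            key = c.seed.ssr.motif_key
            if any(m.ssr.motif_key != key for m in c.members):
                continue
        kept.append(c)
    return kept
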