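"""Locus-level allele analysis.

A cluster of flank signatures becomes a locus: its alleles are the
distinct full-sequence lengths among members, the observed count is how
many there are, and the potential count is the number of lattice
positions of step unit_len between the shortest and longest allele
inclusive — an estimate of how many alleles the population could hold
between the extremes already seen.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .clustering import FlankCluster, FlankSignature
from .dna import canonical_rotation
from .mining import SSRHit

if TYPE_CHECKING:  # pragma: no cover
    from .config import PipelineConfig


@dataclass
class Locus:
    """Per-cluster allele table."""

    locus_number: int
    motif_unit: str
    unit_len: int
    allele_lengths: list[int]
    observed: int
    range_min: int
    range_max: int
    potential: int
    representative_seq: str = ""
    representative_hit: SSRHit | None = None
    cluster: FlankCluster | None = None


def potential_alleles(range_min: int, range_max: int, unit_len: int) -> int:
    """Lattice count: floor((max - min)/unit) + 1.

    Off-grid gaps (flank indels) are tolerated by the floor rather than
    treated as errors.
    """
    if unit_len < 1:
        raise ValueError("unit_len must be >= 1")
    return (range_max - range_min) // unit_len + 1


def tabulate_alleles(cluster: FlankCluster, locus_number: int = 0) -> Locus:
    """Turn a filtered cluster into a locus allele table."""
    lengths = sorted({m.full_length for m in cluster.members})
    seed_hit = cluster.seed.ssr
    unit_len = seed_hit.unit_len
    lo, hi = lengths[0], lengths[-1]
    return Locus(
        locus_number=locus_number,
        motif_unit="-".join(seed_hit.motif_key)
        if seed_hit.parts
        else canonical_rotation(seed_hit.unit),
        unit_len=unit_len,
        allele_lengths=lengths,
        observed=len(lengths),
        range_min=lo,
        range_max=hi,
        potential=potential_alleles(lo, hi, unit_len),
        cluster=cluster,
    )


def select_loci(loci: list[Locus], cfg: "PipelineConfig") -> list[Locus]:
    """Locus selection rule.

    Default: keep loci whose observed allele count reaches the minimum
    allele count.  With Special Search enabled, the criterion is replaced
    by the potential-allele threshold, admitting loci whose observed
    alleles are few but whose length spread implies unsampled variants.
    """
    if cfg.special_search:
        return [l for l in loci if l.potential >= cfg.special_min_potential]
    return [l for l in loci if l.observed >= cfg.min_allele_cnt]


def choose_representative(
    cluster: FlankCluster, seed: int | random.Random
) -> FlankSignature:
    """Uniform seeded draw among the cluster's distinct sequence variants.

    Variants are deduplicated by full sequence before drawing so abundant
    alleles carry no extra weight; the same seed and input always give
    the same choice.
    """
    rng = random.Random(seed) if isinstance(seed, int) else seed
    by_seq: dict[str, FlankSignature] = {}
    for m in cluster.members:
        by_seq.setdefault(m.source_seq or m.signature, m)
    variants = [by_seq[s] for s in sorted(by_seq)]
    return variants[rng.randrange(len(variants))]


def max_pool_alleles(n_individuals: int, ploidy: int = 2) -> int:
    """Upper bound on distinct alleles a pooled sample can contain:
    ploidy x individuals (72 for 36 diploids)."""
    if n_individuals < 1 or ploidy < 1:
        raise ValueError("n_individuals and ploidy must be >= 1")
    return ploidy * n_individuals
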