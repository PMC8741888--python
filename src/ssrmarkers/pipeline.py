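"""End-to-end orchestration: trim, merge, filter, mine, cluster, count
alleles, select loci, design primers; per-stage counts along the way.

Stage counts use the conventional row labels ("Original FASTQ file",
"Trimming", ..., "Primers selected") so a run log can be compared at a
glance with published stage tables.  Counts are monotone non-increasing
from the input through Filter 2, and "Primers selected" (loci for which
at least one pair was found) never exceeds "Unique loci".
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from itertools import zip_longest
from typing import Iterable

from .clustering import excise_ssr, filter_clusters, greedy_cluster
from .config import PipelineConfig
from .loci import Locus, choose_representative, select_loci, tabulate_alleles
from .mining import filter_candidates, find_perfect_ssrs, join_compound
from .preprocess import filter_restriction, merge_pair, trim_read
from .primers import design_for_locus, render_records
from .seqio import OutputRecord, Read, read_fastq

STAGE_LABELS = (
    "Original FASTQ file",
    "Trimming",
    "Pair-end merge",
    "Filter 1",
    "Filter 2",
    "Clusters",
    "Filter 3",
    "Unique loci",
    "Primers selected",
)


class PipelineError(RuntimeError):
    """Fatal error naming the stage where it happened."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    records: list[OutputRecord]
    counts: dict[str, int]
    loci: list[Locus]
    rejections: Counter = field(default_factory=Counter)


def run_pipeline_reads(
    pairs: Iterable[tuple[Read, Read]], cfg: PipelineConfig
) -> PipelineResult:
    """Run the pipeline on an in-memory stream of read pairs."""
    counts = {label: 0 for label in STAGE_LABELS}
    rejections: Counter = Counter()

    # trim + merge + restriction filter, streaming
    merged: list[Read] = []
    for r1, r2 in pairs:
        counts["Original FASTQ file"] += 1
        t1 = trim_read(r1, cfg.adapter_seqs, cfg.trim)
        t2 = trim_read(r2, cfg.adapter_seqs, cfg.trim)
        if t1 is None or t2 is None:
            rejections["trim_dropped"] += 1
            continue
        counts["Trimming"] += 1
        m = merge_pair(t1, t2, cfg.merge)
        if m is None:
            rejections["unmerged"] += 1
            continue
        counts["Pair-end merge"] += 1
        if not filter_restriction(m, cfg.restriction_pattern, cfg.restriction_anchor):
            rejections["no_restriction_site"] += 1
            continue
        counts["Filter 1"] += 1
        merged.append(m)

    # SSR mining + Filter 2
    signatures = []
    for read in merged:
        hits = join_compound(
            find_perfect_ssrs(read.bases, cfg.min_repeats), cfg.compound_max_gap
        )
        decision = filter_candidates(read, hits, cfg)
        if not decision.passed:
            rejections[decision.reason] += 1
            continue
        counts["Filter 2"] += 1
        signatures.append(excise_ssr(read, decision.hit))

    clusters = greedy_cluster(
        signatures, cfg.cluster_identity, cfg.cluster_word_size
    )
    counts["Clusters"] = len(clusters)
    kept = filter_clusters(
        clusters, cfg.min_cluster_members, cfg.require_motif_consistency
    )
    counts["Filter 3"] = len(kept)
    rejections["small_or_inconsistent_cluster"] += len(clusters) - len(kept)

    loci = [tabulate_alleles(c) for c in kept]
    selected = select_loci(loci, cfg)
    for n, locus in enumerate(selected, start=1):
        locus.locus_number = n
    counts["Unique loci"] = len(selected)

    rng = random.Random(cfg.rng_seed)
    records: list[OutputRecord] = []
    primer_loci = 0
    for locus in selected:
        rep = choose_representative(locus.cluster, rng)
        locus.representative_seq = rep.source_seq
        # recompute the repeat span on the representative rather than
        # trusting upstream coordinates (guards against misplacement)
        rep_hits = join_compound(
            find_perfect_ssrs(rep.source_seq, cfg.min_repeats), cfg.compound_max_gap
        )
        decision = filter_candidates(
            Read(id=rep.source_id, bases=rep.source_seq, quals=[40] * len(rep.source_seq)),
            rep_hits,
            cfg,
        )
        locus.representative_hit = decision.hit if decision.passed else rep.ssr
        pairs_ranked = design_for_locus(locus, cfg)
        if not pairs_ranked:
            rejections["no_primer_pair"] += 1
            continue
        primer_loci += 1
        records.extend(render_records(locus, pairs_ranked, cfg.prefix))
    counts["Primers selected"] = primer_loci

    return PipelineResult(
        records=records, counts=counts, loci=selected, rejections=rejections
    )


def run_pipeline(r1_path, r2_path, cfg: PipelineConfig) -> PipelineResult:
    """Run the pipeline from two FASTQ files (the same file twice for
    single-end data: merging reduces identical mates to the original)."""

    def paired():
        sentinel = object()
        for r1, r2 in zip_longest(
            read_fastq(r1_path), read_fastq(r2_path), fillvalue=sentinel
        ):
            if r1 is sentinel or r2 is sentinel:
                raise PipelineError(
                    "Original FASTQ file",
                    f"{r1_path} and {r2_path} have different record counts",
                )
            yield r1, r2

    return run_pipeline_reads(paired(), cfg)


def write_counts(counts: dict[str, int], path) -> None:
    """Sidecar stage-count log, one label\tcount per line."""
    with open(path, "w") as fh:
        for label in STAGE_LABELS:
            fh.write(f"{label}\t{counts.get(label, 0)}\n")
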