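"""Synthetic multi-individual enriched SSR library generator.

Emulates the library structure the pipeline assumes: each locus is one
repeat flanked by two unique regions, fragments carry the residual
restriction pattern at both ends, adapters are read through when a
fragment is shorter than the read, every diploid individual contributes
two allele draws per locus, and paired reads overlap across the repeat
because fragments are kept shorter than twice the read length.  A
ground-truth manifest sufficient to recompute every expected pipeline
output accompanies the FASTQ pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clustering import identity
from .dna import gc_fraction, revcomp
from .mining import DEFAULT_MIN_REPEATS, find_perfect_ssrs, join_compound
from .seqio import Read, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study-condition knobs for the simulated library.

    Defaults emulate the published study design: 36 diploid individuals
    (two pooled populations), 250-cycle paired-end reads, an enriched
    restriction-digest library of di- and tetranucleotide repeats, and
    fragments short enough for the mates to overlap when merged.
    """

    n_individuals: int = 36
    n_loci: int = 20
    read_len: int = 250
    flank_len: tuple[int, int] = (90, 110)
    unit_lengths: tuple[int, ...] = (2, 4)
    n_alleles: tuple[int, int] = (5, 9)
    repeat_min: int = 7
    repeat_span: int = 12
    restriction_pattern: str = "GATC"
    adapter: str = "AGATCGGAAGAGC"
    error_rate: float = 0.0
    coverage: int = 2
    seed: int = 0
    min_merge_overlap: int = 10
    max_locus_flank_identity: float = 0.80
    ploidy: int = 2

    def max_fragment_len(self) -> int:
        return (
            2 * len(self.restriction_pattern)
            + 2 * self.flank_len[1]
            + max(self.unit_lengths) * (self.repeat_min + self.repeat_span)
        )


@dataclass
class SimLocusSpec:
    """One planted locus: motif, unique flanks, allele pool, genotypes."""

    locus_id: str
    unit: str
    flank_left: str
    flank_right: str
    allele_repeat_counts: list[int]
    genotypes: list[tuple[int, int]]  # repeat counts, 2 per individual

    def fragment(self, repeats: int, restriction: str) -> str:
        return (
            restriction
            + self.flank_left
            + self.unit * repeats
            + self.flank_right
            + restriction
        )


@dataclass
class TrueLocus:
    """Manifest row for one planted locus."""

    locus_id: str
    unit: str
    flank_left: str
    flank_right: str
    planted_repeat_counts: list[int]
    realized_lengths: list[int]  # distinct fragment lengths actually drawn
    expected_observed: int
    expected_potential: int
    signature: str  # restriction + flanks with the repeat excised


@dataclass
class ReadOrigin:
    read_id: str
    locus_id: str
    repeat_count: int


@dataclass
class GroundTruth:
    loci: list[TrueLocus]
    reads: list[ReadOrigin]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def _random_primitive_unit(rng: np.random.Generator, length: int) -> str:
    from .dna import is_primitive

    while True:
        unit = _random_dna(rng, length)
        if is_primitive(unit) and len(set(unit)) > 1:
            return unit


def _sample_locus(
    rng: np.random.Generator,
    cfg: SimConfig,
    taken_signatures: list[str],
    locus_id: str,
) -> SimLocusSpec:
    """Rejection-sample a locus whose flanks mine cleanly.

    The assembled fragment must contain exactly one detectable repeat,
    exactly at the planted span, and the flank signature must stay below
    the identity ceiling against every previously accepted locus so that
    clustering correctness is not confounded by simulation artifacts.
    Flank GC is kept moderate so primer design has material to work with.
    """
    u_len = int(rng.choice(cfg.unit_lengths))
    unit = _random_primitive_unit(rng, u_len)
    n_all = int(rng.integers(cfg.n_alleles[0], cfg.n_alleles[1] + 1))
    counts = sorted(
        int(c)
        for c in rng.choice(
            np.arange(cfg.repeat_min, cfg.repeat_min + cfg.repeat_span + 1),
            size=n_all,
            replace=False,
        )
    )
    k_max = counts[-1]
    restr = cfg.restriction_pattern
    for _ in range(500):
        lf = int(rng.integers(cfg.flank_len[0], cfg.flank_len[1] + 1))
        lr = int(rng.integers(cfg.flank_len[0], cfg.flank_len[1] + 1))
        flank_l = _random_dna(rng, lf)
        flank_r = _random_dna(rng, lr)
        if not (0.30 <= gc_fraction(flank_l) <= 0.70):
            continue
        if not (0.30 <= gc_fraction(flank_r) <= 0.70):
            continue
        frag = restr + flank_l + unit * k_max + flank_r + restr
        hits = join_compound(find_perfect_ssrs(frag, DEFAULT_MIN_REPEATS))
        if len(hits) != 1:
            continue
        h = hits[0]
        want_start = len(restr) + lf
        if (
            h.type != f"p{u_len}"
            or h.start != want_start
            or h.end != want_start + u_len * k_max
        ):
            continue
        sig = restr + flank_l + flank_r + restr
        if any(
            identity(sig, other) >= cfg.max_locus_flank_identity
            for other in taken_signatures
        ):
            continue
        genotypes = [
            tuple(int(x) for x in rng.choice(counts, size=cfg.ploidy))
            for _ in range(cfg.n_individuals)
        ]
        taken_signatures.append(sig)
        return SimLocusSpec(
            locus_id=locus_id,
            unit=unit,
            flank_left=flank_l,
            flank_right=flank_r,
            allele_repeat_counts=counts,
            genotypes=genotypes,
        )
    raise RuntimeError(f"could not sample acceptable flanks for {locus_id}")


def read_pair_from_fragment(
    fragment: str, read_len: int, adapter: str = ""
) -> tuple[str, str]:
    """Sequencer view of one fragment: R1 is the first read_len bases of
    fragment+adapter, R2 the first read_len bases of its reverse
    complement plus adapter (adapter read-through happens exactly when
    the fragment is shorter than the read)."""
    r1 = (fragment + adapter)[:read_len]
    r2 = (revcomp(fragment) + adapter)[:read_len]
    return r1, r2


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return bytes(arr).decode()


def _quals(rng: np.random.Generator, length: int) -> list[int]:
    return [int(q) for q in rng.integers(35, 41, size=length)]


def build_library(cfg: SimConfig) -> tuple[list[tuple[Read, Read]], GroundTruth]:
    """Generate the library in memory; deterministic under cfg.seed."""
    if cfg.max_fragment_len() > 2 * cfg.read_len - cfg.min_merge_overlap:
        raise ValueError(
            f"fragments up to {cfg.max_fragment_len()} bp cannot overlap "
            f"at read length {cfg.read_len} (limit "
            f"{2 * cfg.read_len - cfg.min_merge_overlap})"
        )
    rng = np.random.default_rng(cfg.seed)
    signatures: list[str] = []
    specs = [
        _sample_locus(rng, cfg, signatures, f"L{i + 1:03d}")
        for i in range(cfg.n_loci)
    ]

    pairs: list[tuple[Read, Read]] = []
    origins: list[ReadOrigin] = []
    true_loci: list[TrueLocus] = []
    for spec, sig in zip(specs, signatures):
        realized = sorted({k for g in spec.genotypes for k in g})
        base_len = len(sig)
        lengths = [base_len + len(spec.unit) * k for k in realized]
        true_loci.append(
            TrueLocus(
                locus_id=spec.locus_id,
                unit=spec.unit,
                flank_left=spec.flank_left,
                flank_right=spec.flank_right,
                planted_repeat_counts=spec.allele_repeat_counts,
                realized_lengths=lengths,
                expected_observed=len(lengths),
                expected_potential=(lengths[-1] - lengths[0]) // len(spec.unit) + 1,
                signature=sig,
            )
        )
        for ind, genotype in enumerate(spec.genotypes):
            for copy, k in enumerate(genotype):
                frag = spec.fragment(k, cfg.restriction_pattern)
                for c in range(cfg.coverage):
                    r1s, r2s = read_pair_from_fragment(
                        frag, cfg.read_len, cfg.adapter
                    )
                    r1s = _apply_errors(rng, r1s, cfg.error_rate)
                    r2s = _apply_errors(rng, r2s, cfg.error_rate)
                    rid = f"sim.{spec.locus_id}.i{ind}.a{copy}.c{c}"
                    pairs.append(
                        (
                            Read(id=rid, bases=r1s, quals=_quals(rng, len(r1s))),
                            Read(id=rid, bases=r2s, quals=_quals(rng, len(r2s))),
                        )
                    )
                    origins.append(ReadOrigin(rid, spec.locus_id, k))
    return pairs, GroundTruth(loci=true_loci, reads=origins)


def simulate_library(cfg: SimConfig, out_dir) -> GroundTruth:
    """Write R1/R2 FASTQ and the two manifest TSVs; returns the truth.

    Files: reads_R1.fastq, reads_R2.fastq, truth_loci.tsv (one row per
    planted locus), truth_reads.tsv (one row per read pair).  Output is
    byte-identical for a fixed config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs, truth = build_library(cfg)
    write_fastq((p[0] for p in pairs), out / "reads_R1.fastq")
    write_fastq((p[1] for p in pairs), out / "reads_R2.fastq")
    write_truth(truth, out)
    return truth


def write_truth(truth: GroundTruth, out_dir) -> None:
    out = Path(out_dir)
    with open(out / "truth_loci.tsv", "w") as fh:
        fh.write(
            "locus_id\tunit\tflank_left\tflank_right\tplanted_repeats\t"
            "realized_lengths\texpected_observed\texpected_potential\tsignature\n"
        )
        for l in truth.loci:
            fh.write(
                "\t".join(
                    [
                        l.locus_id,
                        l.unit,
                        l.flank_left,
                        l.flank_right,
                        ",".join(map(str, l.planted_repeat_counts)),
                        ",".join(map(str, l.realized_lengths)),
                        str(l.expected_observed),
                        str(l.expected_potential),
                        l.signature,
                    ]
                )
                + "\n"
            )
    with open(out / "truth_reads.tsv", "w") as fh:
        fh.write("read_id\tlocus_id\trepeat_count\n")
        for r in truth.reads:
            fh.write(f"{r.read_id}\t{r.locus_id}\t{r.repeat_count}\n")


def read_truth(loci_path, reads_path=None) -> GroundTruth:
    loci = []
    with open(loci_path) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            loci.append(
                TrueLocus(
                    locus_id=f[0],
                    unit=f[1],
                    flank_left=f[2],
                    flank_right=f[3],
                    planted_repeat_counts=[int(x) for x in f[4].split(",")],
                    realized_lengths=[int(x) for x in f[5].split(",")],
                    expected_observed=int(f[6]),
                    expected_potential=int(f[7]),
                    signature=f[8],
                )
            )
    reads = []
    if reads_path is not None:
        with open(reads_path) as fh:
            fh.readline()
            for line in fh:
                f = line.rstrip("\n").split("\t")
                reads.append(ReadOrigin(f[0], f[1], int(f[2])))
    return GroundTruth(loci=loci, reads=reads)


@dataclass
class LocusRecovery:
    """Recovery verdict for one planted locus."""

    locus_id: str
    expected_selected: bool
    found: bool
    observed_reported: int | None = None
    observed_expected: int | None = None
    potential_reported: int | None = None
    potential_expected: int | None = None
    has_primers: bool = False

    @property
    def observed_exact(self) -> bool:
        return self.found and self.observed_reported == self.observed_expected

    @property
    def potential_exact(self) -> bool:
        return self.found and self.potential_reported == self.potential_expected


@dataclass
class RecoveryReport:
    """Aggregate recovery of planted loci by a pipeline run."""

    per_locus: list[LocusRecovery]
    n_expected: int
    n_found: int
    n_output_loci: int
    n_matched_output: int

    @property
    def recall(self) -> float:
        return self.n_found / self.n_expected if self.n_expected else 1.0

    @property
    def precision(self) -> float:
        return (
            self.n_matched_output / self.n_output_loci if self.n_output_loci else 1.0
        )

    @property
    def observed_exact_fraction(self) -> float:
        found = [l for l in self.per_locus if l.found]
        if not found:
            return 1.0
        return sum(l.observed_exact for l in found) / len(found)

    @property
    def potential_exact_fraction(self) -> float:
        found = [l for l in self.per_locus if l.found]
        if not found:
            return 1.0
        return sum(l.potential_exact for l in found) / len(found)


def _expected_selected(locus: TrueLocus, cfg) -> bool:
    """Would this planted locus pass the locus-selection rule?"""
    if cfg.special_search:
        return locus.expected_potential >= cfg.special_min_potential
    return locus.expected_observed >= cfg.min_allele_cnt


def score_recovery(result, truth: GroundTruth, cfg, match_identity: float = 0.90):
    """Compare a pipeline run against the manifest.

    `result` is the PipelineResult of the run (its loci carry the
    representative sequences used for matching) or a bare list of output
    loci.  Each reported locus is matched to the planted locus whose
    excised flank signature it aligns to at >= match_identity; per locus
    the report says whether it was found and whether the observed and
    potential allele counts are exactly right.  Recall is over planted
    loci expected to pass the selection thresholds under `cfg`.
    """
    out_loci = getattr(result, "loci", result)
    primer_loci = set()
    if hasattr(result, "records"):
        for rec in result.records:
            primer_loci.add(rec.sequence)

    out_sigs = []
    for locus in out_loci:
        hit = locus.representative_hit
        seq = locus.representative_seq
        sig = seq[: hit.start] + seq[hit.end :] if hit is not None else seq
        out_sigs.append((locus, sig))

    matched_out = set()
    per_locus: list[LocusRecovery] = []
    for tl in truth.loci:
        expected = _expected_selected(tl, cfg)
        best = None
        for idx, (locus, sig) in enumerate(out_sigs):
            if identity(sig, tl.signature) >= match_identity:
                best = idx
                break
        if best is None:
            per_locus.append(
                LocusRecovery(
                    locus_id=tl.locus_id,
                    expected_selected=expected,
                    found=False,
                    observed_expected=tl.expected_observed,
                    potential_expected=tl.expected_potential,
                )
            )
            continue
        matched_out.add(best)
        locus = out_sigs[best][0]
        per_locus.append(
            LocusRecovery(
                locus_id=tl.locus_id,
                expected_selected=expected,
                found=True,
                observed_reported=locus.observed,
                observed_expected=tl.expected_observed,
                potential_reported=locus.potential,
                potential_expected=tl.expected_potential,
                has_primers=locus.representative_seq in primer_loci,
            )
        )
    n_expected = sum(l.expected_selected for l in per_locus)
    n_found = sum(l.expected_selected and l.found for l in per_locus)
    return RecoveryReport(
        per_locus=per_locus,
        n_expected=n_expected,
        n_found=n_found,
        n_output_loci=len(out_sigs),
        n_matched_output=len(matched_out),
    )
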