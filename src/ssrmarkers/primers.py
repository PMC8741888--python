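"""PCR primer design for microsatellite loci.

Melting temperatures come from nearest-neighbor thermodynamics with the
unified parameter set (per-stack dH/dS, terminal initiation terms,
symmetry correction) and the standard monovalent-salt entropy
correction.  Candidate primers are enumerated exhaustively under length,
Tm, GC, homopolymer and self-complementarity bounds; pairs must bracket
the whole repeat, fall inside the product size window and agree in Tm
within MAX_DIFF_TM, and are ranked by a weighted penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .dna import gc_fraction, max_homopolymer, revcomp
from .loci import Locus
from .seqio import BEST_FLAG, OutputRecord

if TYPE_CHECKING:  # pragma: no cover
    from .config import PipelineConfig

R_GAS = 1.987  # cal / (mol K)

# Unified nearest-neighbor set: dH in kcal/mol, dS in cal/(mol K),
# keyed by the top-strand dinucleotide (complementary stacks share values).
_NN = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# fill in the complementary-equivalent stacks (TT = AA read on the other strand, ...)
for _k in list(_NN):
    _rc = revcomp(_k)
    if _rc not in _NN:
        _NN[_rc] = _NN[_k]

_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)
_SYM_DS = -1.4


@dataclass
class PrimerParams:
    """Primer constraint block (reference-tool conventional defaults)."""

    size_min: int = 18
    size_opt: int = 20
    size_max: int = 27
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    gc_min: float = 0.20
    gc_max: float = 0.80
    max_homopolymer: int = 4
    max_self_comp: int = 8
    num_return: int = 5
    oligo_conc: float = 50e-9  # molar
    monovalent: float = 50e-3  # molar


def melting_temperature(
    oligo: str, oligo_conc: float = 50e-9, monovalent: float = 50e-3
) -> float:
    """Nearest-neighbor Tm in degrees C.

    Tm = 1000*dH / (dS + R ln(C_T/x)) - 273.15 with x = 4 for
    non-self-complementary duplexes (x = 1 plus the symmetry entropy term
    for self-complementary ones), and the monovalent-salt correction
    dS += 0.368 (N-1) ln[mono+].  Valid for 10-36-mers over {A,C,G,T}.
    """
    oligo = oligo.upper()
    if not 10 <= len(oligo) <= 36:
        raise ValueError(f"oligo length {len(oligo)} outside 10..36")
    if set(oligo) - set("ACGT"):
        raise ValueError(f"ambiguous bases in oligo {oligo!r}")

    dh = 0.0
    ds = 0.0
    for term in (oligo[0], oligo[-1]):
        h, s = _INIT_GC if term in "GC" else _INIT_AT
        dh += h
        ds += s
    for i in range(len(oligo) - 1):
        h, s = _NN[oligo[i : i + 2]]
        dh += h
        ds += s

    symmetric = oligo == revcomp(oligo)
    if symmetric:
        ds += _SYM_DS
    ds += 0.368 * (len(oligo) - 1) * math.log(monovalent)
    x = 1.0 if symmetric else 4.0
    return 1000.0 * dh / (ds + R_GAS * math.log(oligo_conc / x)) - 273.15


def _self_complementarity(seq: str) -> int:
    """Longest contiguous complementary stretch between the oligo and its
    own reverse complement at any ungapped offset (a crude dimer screen)."""
    rc = revcomp(seq)
    n = len(seq)
    best = 0
    for off in range(-(n - 1), n):
        run = 0
        for i in range(n):
            j = i + off
            if 0 <= j < n:
                if seq[i] == rc[j]:
                    run += 1
                    best = max(best, run)
                else:
                    run = 0
        run = 0
    return best


@dataclass
class PrimerCandidate:
    """One candidate oligo on the template.

    start is the leftmost template coordinate of the primer's footprint
    (for a reverse primer this is where its 3' end anneals); the footprint
    is [start, start+length).
    """

    seq: str
    start: int
    length: int
    tm: float
    gc: float
    orientation: str  # 'forward' | 'reverse'

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.start, self.start + self.length)


@dataclass
class PrimerPair:
    fwd: PrimerCandidate
    rev: PrimerCandidate
    product_size: int
    penalty: float
    is_best: bool = False


def enumerate_candidates(
    template: str,
    region: tuple[int, int],
    orientation: str,
    params: PrimerParams,
    ssr_span: tuple[int, int] | None = None,
    avoid_primer_in_ssr: bool = False,
) -> list[PrimerCandidate]:
    """Exhaustive scan for candidate primers with footprint inside `region`.

    Every substring with admissible length is tested against the GC,
    homopolymer, self-complementarity and Tm bounds; reverse candidates
    are the reverse complements of template windows.  With the in-repeat
    post-filter on, footprints intersecting the repeat span are excluded.
    """
    lo, hi = region
    lo = max(lo, 0)
    hi = min(hi, len(template))
    out: list[PrimerCandidate] = []
    for length in range(params.size_min, params.size_max + 1):
        for s in range(lo, hi - length + 1):
            if avoid_primer_in_ssr and ssr_span is not None:
                if s < ssr_span[1] and s + length > ssr_span[0]:
                    continue
            window = template[s : s + length]
            if "N" in window:
                continue
            seq = window if orientation == "forward" else revcomp(window)
            gc = gc_fraction(seq)
            if not params.gc_min <= gc <= params.gc_max:
                continue
            if max_homopolymer(seq) > params.max_homopolymer:
                continue
            if _self_complementarity(seq) > params.max_self_comp:
                continue
            tm = melting_temperature(seq, params.oligo_conc, params.monovalent)
            if not params.tm_min <= tm <= params.tm_max:
                continue
            out.append(
                PrimerCandidate(
                    seq=seq,
                    start=s,
                    length=length,
                    tm=tm,
                    gc=gc,
                    orientation=orientation,
                )
            )
    return out


def pair_penalty(
    fwd: PrimerCandidate, rev: PrimerCandidate, params: PrimerParams
) -> float:
    """Weighted objective: per-primer Tm and length deviations from the
    optima plus a double-weighted pair Tm difference."""
    p = 0.0
    for c in (fwd, rev):
        p += abs(c.tm - params.tm_opt) + 0.25 * abs(c.length - params.size_opt)
    p += 2.0 * abs(fwd.tm - rev.tm)
    return p


def pair_and_rank(
    fwd: list[PrimerCandidate],
    rev: list[PrimerCandidate],
    ssr_span: tuple[int, int],
    params: PrimerParams,
    product_size_range: tuple[int, int],
    max_diff_tm: float,
) -> list[PrimerPair]:
    """All feasible combinations, ranked; at most num_return returned.

    Hard constraints: the product (fwd 5' end through rev 3'-most covered
    base) spans the whole repeat, its size falls inside the product
    window, the primers do not overlap each other, and the pair Tm
    difference is within MAX_DIFF_TM.  Ranking: ascending penalty, ties
    to the smaller product then the leftmost forward primer.  An empty
    result means the locus is dropped from the output (a counted
    outcome).
    """
    eps = 1e-9
    pairs: list[PrimerPair] = []
    for f in fwd:
        for r in rev:
            if f.start > ssr_span[0]:
                continue
            r_end = r.start + r.length
            if r_end < ssr_span[1]:
                continue
            if r.start < f.start + f.length:
                continue
            product = r_end - f.start
            if not product_size_range[0] <= product <= product_size_range[1]:
                continue
            if abs(f.tm - r.tm) > max_diff_tm + eps:
                continue
            pairs.append(
                PrimerPair(
                    fwd=f,
                    rev=r,
                    product_size=product,
                    penalty=pair_penalty(f, r, params),
                )
            )
    pairs.sort(key=lambda p: (p.penalty, p.product_size, p.fwd.start))
    pairs = pairs[: params.num_return]
    if pairs:
        pairs[0].is_best = True
    return pairs


def design_for_locus(locus: Locus, cfg: "PipelineConfig") -> list[PrimerPair]:
    """Enumerate and rank primer pairs on a locus representative."""
    template = locus.representative_seq
    hit = locus.representative_hit
    if hit is None:
        raise ValueError(f"locus {locus.locus_number} has no representative hit")
    span = (hit.start, hit.end)
    fwd = enumerate_candidates(
        template, (0, span[0] if cfg.avoid_primer_in_ssr else len(template)),
        "forward", cfg.primer, span, cfg.avoid_primer_in_ssr,
    )
    rev = enumerate_candidates(
        template, (span[1] if cfg.avoid_primer_in_ssr else 0, len(template)),
        "reverse", cfg.primer, span, cfg.avoid_primer_in_ssr,
    )
    return pair_and_rank(
        fwd, rev, span, cfg.primer, cfg.product_size_range, cfg.max_diff_tm
    )


def render_records(
    locus: Locus, pairs: list[PrimerPair], prefix: str
) -> list[OutputRecord]:
    """One 12-column output record per ranked pair; ids are
    <prefix><locus_number>-<pair_number> and only rank 1 carries |BEST|."""
    recs = []
    for k, pair in enumerate(pairs, start=1):
        recs.append(
            OutputRecord(
                id=f"{prefix}{locus.locus_number}-{k}",
                size=pair.product_size,
                fwd_seq=pair.fwd.seq,
                fwd_tm=round(pair.fwd.tm, 2),
                rev_seq=pair.rev.seq,
                rev_tm=round(pair.rev.tm, 2),
                motif=locus.representative_hit.label
                if locus.representative_hit
                else f"({locus.motif_unit})?",
                range=f"{locus.range_min}-{locus.range_max}",
                alleles_observed=locus.observed,
                alleles_potential=locus.potential,
                best_flag=BEST_FLAG if pair.is_best else "",
                sequence=locus.representative_seq,
            )
        )
    return recs


def validate_pairs(
    pairs: list[PrimerPair],
    ssr_span: tuple[int, int],
    product_size_range: tuple[int, int],
    max_diff_tm: float,
    avoid_primer_in_ssr: bool = False,
) -> list[str]:
    """Post-hoc constraint audit; returns human-readable violations
    (empty list = all pairs satisfy every hard constraint)."""
    eps = 1e-9
    problems = []
    for i, p in enumerate(pairs):
        if abs(p.fwd.tm - p.rev.tm) > max_diff_tm + eps:
            problems.append(f"pair {i}: dTm {abs(p.fwd.tm - p.rev.tm):.3f}")
        if not product_size_range[0] <= p.product_size <= product_size_range[1]:
            problems.append(f"pair {i}: product {p.product_size} out of range")
        if p.fwd.start > ssr_span[0] or p.rev.start + p.rev.length < ssr_span[1]:
            problems.append(f"pair {i}: product does not span the repeat")
        if avoid_primer_in_ssr:
            for c in (p.fwd, p.rev):
                a, b = c.footprint
                if a < ssr_span[1] and b > ssr_span[0]:
                    problems.append(f"pair {i}: {c.orientation} primer inside repeat")
    return problems
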