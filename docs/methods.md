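# Methods

This note records the models, algorithms and numerical choices behind
each pipeline stage, the design decisions that were genuinely open, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Data model

The input is a pooled, untagged library of N diploid individuals,
enriched for repeat-bearing fragments after restriction digestion (or
mechanically sheared, in which case the restriction filter is disabled).
Each informative fragment is assumed to be

    restriction_site ++ left flank ++ (unit × k) ++ right flank ++ restriction_site

with unique flanks identifying the locus and the repeat count k varying
among alleles. Fragments are size-selected below twice the read length
so that the two mates of a pair overlap and can be merged into the full
fragment; allele identity is then simply the merged-fragment length.
A pool of N diploids can contribute at most 2N distinct alleles per
locus — 72 under the default 36-individual design — which is a sanity
cap, not a parameter.

## Trimming and merging

Adapter removal is a semi-global Hamming scan: every 3' offset is
scored, offsets with error rate above `ADAPTER_MAX_ERROR_RATE` (0.10)
are rejected, and the qualifying offset maximising (matched − errors)
wins, ties to the leftmost. The minimum adapter overlap is 1 rather
than the more usual 3: a fragment one or two bases shorter than the read
leaves a 1–2 nt adapter stub whose survival would later block the
overlap merger; clipping on a single matching base costs at most a few
genomic 3' bases, which the mate restores during merging. Quality
trimming is the classic 5'→3' sliding window (window 4, mean Q < 15
cuts; minimum length 36 drops the read).

Merging reverse-complements R2 and evaluates every suffix/prefix
overlap length L ≥ 10, scoring each by mismatch density m/L. The
density-minimising candidate is accepted at density ≤ 0.25; ties break
toward the longer overlap. The tie-break matters inside repeats, where
several zero-mismatch overlaps can exist: preferring the longer overlap
is deterministic and biases against spurious repeat-length changes
("fake alleles") that overlap misplacement would create. Consensus
bases take the higher-quality call (quality = difference) at
disagreements and the max quality at agreements. Identical mates —
the single-end trick of passing the same file twice — merge at full
length back to the original read, unchanged.

## Repeat mining

Perfect repeats are maximal base-level runs of period u ∈ 1..6 with at
least {10, 6, 5, 5, 5, 5} repeats (the de-facto defaults of the
standard SSR search tools; configurable via `MIN_REPEATS`). A run is
reported once, phased at its leftmost start, under its shortest
(primitive) unit; by the Fine–Wilf periodicity argument a run of two or
more repeats cannot be simultaneously primitive under two different
unit lengths, so no span is double-reported. N breaks runs and never
appears inside a reported unit. Trailing partial units are not counted
(span = unit_len × repeats exactly).

Compound repeats: consecutive runs merge into type `c` when the gap is
≤ 0 (adjacent, or overlapping by phase) and `c*` when the gap is
1..`COMPOUND_MAX_GAP` (default 100). The literature names these types
without defining the gap rule; this is the simplest consistent reading
and is isolated behind one operation. For a compound hit the repeat
count is the maximum over constituents (what the minimum-repetition
filter tests) and the lattice step for potential-allele counting is the
minimum constituent unit length (the conservative choice).

Filter 2 keeps sequences with exactly one qualifying hit (type not
excluded, repeats ≥ `MIN_MOTIF_REPETITION`, both flanks ≥
`MIN_FLANK_LEN`). Multi-repeat sequences are rejected because the
downstream clustering excises exactly one repeat region per sequence.

## Flank clustering

The repeat span is excised and the concatenated flanks are clustered by
the greedy incremental scheme of the classic redundancy removers:
candidates longest-first, each compared against existing cluster seeds
in creation order, joining the first seed at identity ≥ 0.90, else
founding a new cluster. Identity is defined as
1 − (global edit distance)/(shorter length), clamped at zero — for
substitution-only divergence this equals matches/shorter exactly, and it
is unambiguous where co-optimal alignments would disagree about
"matches". Edit distances come from edlib; the test suite re-derives
them with an independent dynamic program.

Two screening bounds may skip a seed comparison, both provably sound:
a character-composition bound (aligned matches cannot exceed the shared
per-base composition) and a k-word bound (an edit destroys at most k
positional k-words, so sequences within the threshold edit budget must
share a k-word whenever the budget is small enough for that bound to
bind). At threshold 0.90 and realistic flank lengths the k-word bound
is rarely binding — a lossy k-mer screen of the kind fast clusterers use
would change partitions, which is exactly what these screens are
guaranteed never to do (and the suite verifies filter-on/off equality).

Filter 3 drops clusters with fewer than `MIN_CLUSTER_MEMBERS` (default
2) members — singleton clusters cannot demonstrate polymorphism — and
can optionally require all members to share one canonical (rotation-
independent) motif. This stage is the pipeline's most interpretive
step: nothing in the upstream literature pins down what it removes, so
both knobs are explicit configuration.

## Allele tables and locus selection

Alleles are distinct full merged-sequence lengths within a cluster
(flank-length variation inside a 90%-identity cluster is negligible, and
length is what a genotyping assay reads out). For allele lengths
spanning [min, max] with unit length u,

    observed  = number of distinct lengths
    potential = ⌊(max − min)/u⌋ + 1

i.e. the count of u-lattice positions between the extremes inclusive;
the floor tolerates off-lattice gaps from rare flank indels rather than
failing. potential ≥ observed always, with equality exactly when every
lattice length between the extremes is present.

Selection: observed ≥ `MIN_ALLEL_CNT` (default 5) normally; with
*Special Search* on, the criterion is **replaced** by
potential ≥ `SPECIAL_DIF` (default 8). Replacement, not conjunction:
enabling the option must be able to admit loci with few observed but
widely spread alleles, which a conjunction could not. The
representative sequence for primer design is drawn uniformly among the
cluster's *distinct* sequence variants (deduplication prevents abundance
bias) with a generator seeded by `RNG_SEED`, making runs reproducible.

## Primer design

Melting temperatures use unified nearest-neighbor thermodynamics:
per-stack ΔH/ΔS plus terminal initiation terms, the symmetry correction
for self-complementary oligos, the monovalent-salt entropy correction
ΔS += 0.368·(N−1)·ln[mono+], and Tm = 1000·ΔH/(ΔS + R·ln(C/x)) − 273.15
with x = 4 for non-self-complementary duplexes at total strand
concentration C (defaults 50 nM oligo, 50 mM monovalent). Valid for
10–36-mers over {A,C,G,T}; ambiguous bases are an error.

Candidates are enumerated exhaustively (every start × length) under
length 18–27 (optimum 20), Tm 57–63 (optimum 60), GC 20–80%,
homopolymer ≤ 4, and a crude ungapped self-complementarity cap of 8.
Pairs must not overlap each other, must span the entire repeat, fall in
the product window (default 100–300 bp) and agree within `MAX_DIFF_TM`.
Ranking minimises

    Σ_{p ∈ {fwd, rev}} |Tm_p − 60| + 0.25·|len_p − 20|  +  2·|Tm_fwd − Tm_rev|

(ties: smaller product, then leftmost forward primer); the weights are a
deliberate simplification of the reference designer's objective and are
configurable. Top `PRIMER_NUM_RETURN` (5) pairs are reported, rank 1
flagged `|BEST|`. A locus whose candidate sets admit no feasible pair
is dropped and counted, which is why "Primers selected" can fall below
"Unique loci". The repeat span used for design is re-mined on the
representative itself rather than trusted from upstream bookkeeping,
guarding against misplace-the-repeat coordinate bugs; the optional
`AVOID_PRIMER_IN_SSR` post-filter additionally rejects candidates whose
footprint touches the repeat. A post-hoc validator re-checks every hard
constraint on every emitted pair.

## Synthetic libraries

The simulator emulates the assumed data model directly: per locus a
primitive di- or tetranucleotide unit, two unique flanks (90–110 bp,
GC 30–70%), 5–9 distinct allele repeat counts in 7..19, genotypes drawn
uniformly (two per diploid individual), fragments wrapped with the GATC
restriction residue and read as 250-bp pairs with adapter read-through
when the fragment is shorter than the read, i.i.d. substitution errors
at a configurable rate (0 by default), and plausible Q35–40 qualities.
Flanks are rejection-sampled so that the assembled fragment mines to
exactly the planted repeat (no incidental repeats, no junction
artifacts) and so that inter-locus flank identity stays below 0.80 —
this isolates clustering correctness from simulation accidents. The
manifest records realized (post-genotype-draw) allele lengths, so
expected observed/potential counts are exact even when sampling misses
a planted allele. Output is byte-identical under a fixed seed.

What the generator does **not** emulate: PCR stutter, enrichment bias,
indel sequencing errors (available as an option only via the error
model's substitution rate — indels are off by default), coverage
heterogeneity, and quality-error coupling. Passing recovery tests
therefore demonstrates the pipeline's logic is exact on clean,
well-formed libraries; they do not quantify robustness to stutter or
chimeric reads in real data.

Recovery scoring matches each reported locus to the planted locus whose
excised signature it aligns to at ≥ 0.90 identity. Recall is measured
over planted loci expected to pass the selection thresholds, at the
locus stage of the pipeline result; primer-stage attrition is reported
separately, mirroring the distinction between "Unique loci" and
"Primers selected".

## Problem sizes used in the checks

The standard verification runs use a 20-locus × 36-individual library
at coverage 2 (2,880 read pairs) for end-to-end recovery, 10,000
fragments for merge completeness, 1,000 planted 300-mers for miner
oracle equivalence, and 200 signatures for clustering oracle
equivalence — sizes chosen so the whole suite completes in about a
minute and a half on one core while still exercising every code path at
realistic sequence lengths.

## Known limitations

- Imperfect (mismatch-tolerant) repeat detection is limited to the
  compound `c*` gap rule; a mutation inside a long run splits it.
- Identity-0.90 greedy clustering inherits the seed-dependence of all
  first-fit schemes; deterministic ordering makes it reproducible, not
  canonical.
- Thermodynamic screening covers Tm and a crude self-complementarity
  cap, not hairpin/dimer ΔG or mispriming libraries.
- Allele identity by total length cannot separate length-identical
  alleles with different internal structure.
- Stage counts from published runs of comparable pipelines depend on the
  exact external tools used there and are not reproduction targets;
  only their monotone trends are meaningful for comparison.
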