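# Methods

This note documents the models implemented in `sgarray`, the parameter
choices that matter, the numerical conventions, and what the simulators
do and do not emulate.

## Target-site design

A Cas9 target site is a 20-nt protospacer followed by an NGG PAM. The
scanner reports every `5'-N21-GG-3'` window on the given strand and
every `5'-CC-N21-3'` window as a minus-strand site (protospacer
reverse-complemented), including overlapping windows; windows containing
N are skipped rather than raising. Coordinates are 0-based half-open on
the reference strand; protospacers are always written 5'→3' on the
protospacer strand, positions 1–20 with position 21 the PAM N.

Filter conventions:

* **GC filter** — G/C count over positions 2–20 divided by 19, kept iff
  strictly greater than 0.35. Position 1 is excluded because many
  expression systems force a 5' G there regardless of the target.
* **Positional preferences** — A/T at 14, A/T at 15, C/G at 18, counted
  0–3. These three are composition features associated with higher
  editing activity; they are preferences in the selection order, not
  hard filters.
* **Cut position** — the blunt cut is modelled between protospacer
  positions 17 and 18 (3 bp 5' of the PAM). The "early ORF" rule
  measures the fraction of spliced coding bases 5' of that cut boundary
  (per transcript, in reading orientation) and requires ≤ 0.5. Using the
  cut site rather than the site start or a downstream PTC position is a
  design choice: it is the position where the lesion is introduced and
  is invariant to site strand.
* **Seed uniqueness** — the PAM-proximal 13-mer must occur exactly once
  genome-wide *followed by an NGG* (both strands). Requiring the PAM
  co-occurrence matches the functional definition of a seed-driven
  off-target; counting the bare 13-mer is available via
  `require_pam=False`.
* **TTTT exclusion** — spacers containing the Pol III terminator can be
  excluded (`exclude_TTTT`), default off: low activity of such spacers
  is an observation, not a hard rule.

Per-gene selection is a pure lexicographic minimum: seed-unique first,
then more positional preferences, then GC pass, then earliest cut
fraction; ties break on lowest genome start then + strand, making the
choice deterministic and permutation-invariant. Genes with several
transcripts use the minimum cut fraction over transcripts that contain
the site, which implicitly prefers sites present in all variants. A
gene with no qualifying candidate is reported undesignable rather than
silently dropped.

## LIC assembly model

T4 DNA polymerase's 3'→5' exonuclease resects a duplex end until the
first position where the single supplied dNTP (dTTP by default) can be
re-incorporated; the enzyme then idles, so the overhang length equals
the 0-based index of the first stop base from the 3' terminus. Chewing
both blunt ends of a linearized vector exposes two 5' single-stranded
overhangs whose lengths are fully determined by the vector sequence.

The target-specific oligo is modelled as bridging the two chewed ends:
its left arm restores the bases resected from the top strand (pairing
with the right-end overhang), its right arm is the reverse complement of
the left-end overhang, and the spacer between them remains
single-stranded after annealing — the gap repaired in the bacterial
host. Consequently arm lengths are not free parameters: a contiguous
gap over the spacer requires each arm to complement its full overhang,
and a design is feasible iff `left + right + len(spacer)` equals the
configured oligo length (71 by default). `synthetic_vector()` places the
stop bases so that the default geometry 26 + 19 + 26 = 71 holds. The
spacer/gap length defaults to 19 nt with 20 supported: vectors that
encode the invariant 5' G of the transcript shorten the variable region
by one base. The constant (universal reverse-strand) oligo is validated
separately against a designated constant region of the vector; the
assembly is circularizable iff both oligo–vector junctions (and the
constant oligo, when given) are mismatch-free.

Thermodynamics, enzyme kinetics and transformation efficiency are out of
scope; validation is purely base-pairing arithmetic.

## Orthogonal pooling and deconvolution

Geometry: 96-well plates (8 rows × 12 columns) in sets of 32. Every
clone enters exactly two pools per set — its position pool (same well
coordinate across the set's plates; 96 per set) and its group pool (the
4-column block of its plate: columns 1–4, 5–8, 9–12; 96 per set, 32
wells each, Roman-numbered plate-major). The well → (position pool,
group pool) map is injective within a set, so a clone's two pools
identify its address. The last set may be partial; its barcode structure
is unchanged and missing plates simply leave pools smaller or empty.

Barcodes: 12 first-level barcodes identify matrix plates (6 for
position matrices, 6 for group matrices, i.e. 6 sets per sequencing
run); 8 × 12 second/third-level combinations identify the matrix-plate
well, i.e. the pool. Capacity per run: 12 × 96 = 1,152 pools; at 32
clones per pool and 2 pools per clone, 18,432 clones. The default
barcode tables are generated deterministically with pairwise Hamming
distance ≥ 3; demultiplexing is exact by default (tolerance 0,
configurable to 1), and colliding tables are a configuration error.
Because barcode triples repeat across sequencing runs, deconvolution of
a multi-run scheme requires the run index.

Deconvolution considers only spacers that exactly match a designed
library member ("error-free"); all other observed spacers are tallied
separately as synthesis errors. A spacer is *present* in a pool iff it
has ≥ `min_reads` (default 5) reads and ≥ `min_fraction` (default 0.5%)
of the pool's library-matched reads — thresholds are this package's
defaults, chosen so that a true member at pool size 32 (expected share
~3%) passes comfortably while singleton error reads do not. Candidate
wells are the consistent (group plate, position well) intersections per
set, unioned across sets; exactly one candidate ⇒ `unique`, several ⇒
`ambiguous`, evidence from both pool kinds with no consistent
intersection ⇒ `inconsistent`, otherwise `absent`. The rule is
deliberately conservative: a duplicated clone always yields ≥ 2
candidates and therefore ambiguity, never a wrong unique call, and
adding read depth cannot move a unique call to a different well.

## Amplicon indel calling and genotyping

Indel calling is anchor-based: the `anchor_len` (15 nt) flanks
immediately up- and downstream of the protospacer must occur exactly
once in the read; the length difference of the intervening segment gives
the net indel, positioned by longest common prefix with the reference
target. When anchors fail (indel into a flank, sequencing errors in the
anchor), the read is globally aligned with edlib and indels are read off
the CIGAR; reads whose edit distance exceeds 25% of the reference length
are unalignable and excluded from all denominators.

A read is mutated iff an indel overlaps the protospacer extended by 1 nt
on each side (closed window — abutting indels count; insertions use
their point coordinate). Substitution-only reads are never mutated.
`mutation_frequency = mutated / aligned`; with zero aligned reads the
frequency is undefined and raised as an error. Using alignable rather
than raw reads as the denominator is a documented choice: unalignable
reads carry no evidence about the locus.

Genotyping reduces each aligned read to its on-target indel signature;
signatures at ≥ 20% of aligned reads become alleles (threshold chosen to
resolve up to ~4 alleles while absorbing PCR/sequencing noise; the
denominator is aligned reads). Classes: `not_evaluable` below 50
aligned reads; `unmodified` with no non-wild-type allele;
`all_allelic_frameshift` when every allele is out of frame (net length
mod 3 ≠ 0) and wild type stays below the allele threshold; `partial`
otherwise. Classification is stable under allele-fraction perturbations
smaller than the distance to the threshold.

## Activity statistics

Quartiles use linear interpolation (numpy default, type 7) so Tukey
fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR) are reproducible bit for bit.
Below n = 4 the filter is skipped with a warning. The positional test
splits constructs by A/T vs C/G at one protospacer position and
compares mean activities with a two-tailed unpaired t-test; a two-tailed
F test on the variances at α = 0.05 selects Welch's correction.
Per-position p-values are reported raw — the analysis is exploratory
and the positions are compared against a 0.05 reference line, not
against a family-wise threshold. Positions 1–20 are scanned by default;
the range is configurable.

## Simulators

One PRNG family (`numpy.random.default_rng`) with an explicit seed per
stochastic operation; identical seeds reproduce outputs exactly.

* **Genome** — intergenic spacers around genes whose single transcript
  is a valid ORF (ATG, no internal stop, terminal stop) split over 2–4
  exons with GT..AG introns, alternating strands. Real gene structure
  (UTRs, alternative transcripts, repeats, biased composition) is not
  emulated, so design tests exercise coordinate arithmetic and filters,
  not annotation edge cases of real genomes.
* **Oligo synthesis** — independent per-base substitution/insertion/
  deletion; with total per-base error p the correct fraction of L-mers
  is (1 − p)^L. The defaults (sub 0.007, indel 0.0015 + 0.0015 per
  base) put ~50% of 71-mers error-free, the regime of chip synthesis
  where roughly half the picked clones carry a correct insert.
* **Picking** — uniform i.i.d. draws, or a Pólya-urn scheme
  (`duplicate_bias` added to a member's weight at each pick) emulating
  clonal pre-amplification; the urn inflates duplicate runs beyond the
  Poisson expectation while leaving the marginal uniform. At unbiased
  fold f the unique fraction follows the occupancy law 1 − e^(−f),
  and exact occupancy moments back the confidence bands in tests.
* **Reads** — pooled reads are barcode1+2+3 + spacer with optional
  substitutions; amplicon reads place one indel from a configured
  signed-length spectrum at the cut site, plus optional off-window
  indels and substitutions. No quality-score model, no chimeras; read
  errors are substitutions only by default since synthesis errors
  dominate the error budget being modelled.

Passing round-trip tests on these simulators demonstrates the internal
consistency of scheme, demultiplexer and deconvolution logic — not
robustness to the full error structure of real sequencing data.

## Problem sizes in the shipped checks

The round-trip acceptance campaign uses 4 sets × 8 plates (3,072
clones) at read depth 8 — the property being checked (bijective
recovery, zero false calls) is size-independent beyond a full set, and
this size keeps the whole suite fast. Coupon-collector checks use 3,000
constructs at folds 1.24 and 3.77 with 99% bands from exact occupancy
moments; editing-frequency recovery uses depth 1,000 at a 30% on-target
rate with a binomial 99% band.
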