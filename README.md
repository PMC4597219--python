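# sgarray

Toolkit for building and validating **arrayed CRISPR sgRNA libraries** from
chip-synthesized oligo pools. It is aimed at groups who generate knockout
cell lines at scale and need, on the computational side: rule-based Cas9
target-site design, an in-silico model of ligation-independent cloning
(LIC) assembly, an orthogonal plate-pooling scheme with barcode
deconvolution to sequence-validate thousands of arrayed clones in one
run, amplicon-based indel quantification with knockout-clone genotyping,
and activity statistics. Seeded simulators for every stage make the whole
pipeline testable without wet-lab data.

## What it computes

**Target design.** Sites are 23-nt `N20-NGG` matches found on both strands
(`5'-N21-GG-3'` and `5'-CC-N21-3'`). Protospacer positions are numbered
1–20 (position 21 = the PAM N); a candidate is annotated with

* GC fraction over positions 2–20 (kept iff > 0.35, strict),
* positional preferences A/T@14, A/T@15, C/G@18,
* uniqueness of the PAM-proximal 13-mer seed (+NGG) genome-wide,
* the cut position (between positions 17/18, 3 bp 5' of the PAM) as a
  fraction of the ORF — only cuts in the first half qualify.

One site per gene is selected deterministically (seed-unique ≻ more
positional preferences ≻ GC pass ≻ earliest in ORF; ties by coordinate).

**Pooling & deconvolution.** Clones in 96-well plates, 32 plates per set.
Each clone joins exactly two pools: its *position pool* (same well across
the 32 plates) and its *group pool* (4-column block of its plate; 3 per
plate, Roman-numbered). 12 first-level barcodes × 96 second/third-level
combinations address 1,152 pools = 18,432 clones per sequencing run
(each clone sits in 2 pools). A spacer seen in one position pool and one
consistent group pool is uniquely allocated; clonal duplicates produce
ambiguity but never false calls.

**Editing quantification.** Reads are anchor-aligned to the amplicon
reference (edlib global alignment as fallback); a read is *mutated* iff
an indel spans or touches the protospacer ±1 nt. Frequency =
mutated/aligned. Monoclones with ≥ 50 alignable reads are genotyped:
indel signatures at ≥ 20% of reads become alleles; clones whose alleles
are all out of frame (length mod 3 ≠ 0) with no residual wild type are
*all-allelic frameshift* (knockout) clones.

**Statistics.** Tukey fences (type-7 quartiles) for outliers and box
plots; per-position A/T-vs-C/G activity comparison by a two-tailed
unpaired t-test, with an F test (α = 0.05) gating Welch's correction.

## Worked example

```python
from sgarray import design, pooling, simulate

genome, genes = simulate.simulate_genome(simulate.SimConfig(seed=7, n_genes=6))
sites, failed = design.design_library(genome, genes)
print(len(sites), "designed;", len(failed), "undesignable")
site = sites["gene001"]
print(site.protospacer, site.pam, f"cds_fraction={site.cds_fraction:.3f}")

print(pooling.scheme_capacity())
print(simulate.picking_coverage(14880, 12000))
```

prints

```
6 designed; 0 undesignable
CCGCAACGGTCGCATGGCTC AGG cds_fraction=0.250
(1152, 18432)
1.24
```

i.e. every synthetic gene received a 20-nt protospacer with an NGG PAM
cutting in the first quarter of its ORF; one sequencing run of the pooling
scheme resolves 1,152 pools (18,432 clones); and picking 14,880 colonies
from a 12,000-member pool is 1.24-fold coverage.

The same operations are exposed on the command line:

```
sgarray simulate genome --seed 3 --n-genes 5 --fasta-out g.fa --gff-out g.gff3
sgarray design --genome g.fa --gff g.gff3 --out sites.tsv
sgarray scheme build --n-plates 308 --out scheme.tsv
```

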