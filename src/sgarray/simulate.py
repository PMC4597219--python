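"""Synthetic-data generation for every pipeline stage.

Emulates the experimental workflow end to end so that design, cloning,
pooling deconvolution and amplicon genotyping are all testable without
external data: a small genome with annotated multi-exon genes, chip
oligo pools with per-base synthesis errors, colony picking with an
optional clonal-duplicate bias, pooled-plate reads carrying the
3-barcode addressing, and edited amplicon reads drawn from a configured
indel spectrum. All generators are deterministic under their seed.

The clonal-duplicate bias follows a Polya-urn pre-amplification: every
time a member is picked its sampling weight grows by ``duplicate_bias``,
mimicking bacterial amplification before plating, which inflates runs of
duplicates beyond the Poisson expectation of unbiased picking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .design import GeneModel, Transcript, revcomp
from .pooling import PoolingScheme, WellAddress

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class SimConfig:
    """Shared knobs for the synthetic-data generators.

    Defaults emulate the study conditions: 71-mer oligos synthesized on a
    chip at an error regime giving roughly half the clones a correct
    insert, 96-well plates in 32-plate sets, and an on-target indel rate
    of 30% for amplicon simulations.
    """

    seed: int = 0
    n_genes: int = 10
    mean_cds_codons: int = 120
    exons_per_gene: tuple[int, int] = (2, 4)
    intergenic_len: int = 300
    intron_len: int = 80
    substitution_rate: float = 0.007
    insertion_rate: float = 0.0015
    deletion_rate: float = 0.0015
    duplicate_bias: float = 0.0
    read_depth: int = 50
    indel_spectrum: dict[int, float] = field(
        default_factory=lambda: {-7: 0.1, -3: 0.15, -2: 0.2, -1: 0.3, 1: 0.15, 2: 0.1}
    )


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def simulate_genome(
    config: SimConfig | None = None, chrom: str = "chr1"
) -> tuple[dict[str, str], list[tuple[str, GeneModel]]]:
    """Generate a genome with multi-exon protein-coding genes.

    Each gene carries one transcript whose CDS is a valid ORF (ATG start,
    no internal stop, terminal stop) split across 2-4 exons separated by
    GT..AG introns; genes alternate between strands. Returns the genome
    as {chrom: sequence} and the gene models with their CDS intervals in
    genome coordinates.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    parts: list[str] = []
    genes: list[tuple[str, GeneModel]] = []
    cursor = 0
    for g in range(cfg.n_genes):
        spacer = _random_seq(rng, cfg.intergenic_len)
        parts.append(spacer)
        cursor += len(spacer)
        n_codons = max(20, int(rng.normal(cfg.mean_cds_codons, cfg.mean_cds_codons / 5)))
        orf = _random_orf(rng, n_codons)
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        cuts = sorted(rng.choice(np.arange(10, len(orf) - 10), size=n_exons - 1, replace=False))
        pieces = [orf[a:b] for a, b in zip([0] + list(cuts), list(cuts) + [len(orf)])]
        strand = "+" if g % 2 == 0 else "-"
        if strand == "-":
            pieces = [revcomp(p) for p in reversed(pieces)]
        intervals: list[tuple[int, int]] = []
        for i, piece in enumerate(pieces):
            start = cursor
            parts.append(piece)
            cursor += len(piece)
            intervals.append((start, cursor))
            if i < len(pieces) - 1:
                intron = "GT" + _random_seq(rng, cfg.intron_len - 4) + "AG"
                parts.append(intron)
                cursor += len(intron)
        gene_id = f"gene{g + 1:03d}"
        genes.append(
            (chrom, GeneModel(gene_id, (Transcript(f"{gene_id}.t1", strand, tuple(intervals)),)))
        )
    parts.append(_random_seq(rng, cfg.intergenic_len))
    return {chrom: "".join(parts)}, genes


def translate_cds(genome: Mapping[str, str], chrom: str, tr: Transcript) -> str:
    """Spliced CDS of a transcript in reading orientation (for validity checks)."""
    seq = "".join(genome[chrom][s:e] for s, e in tr.cds)
    return seq if tr.strand == "+" else revcomp(seq)


# ---------------------------------------------------------------------------
# oligo synthesis errors
# ---------------------------------------------------------------------------

def mutate_sequence(
    seq: str,
    rng: np.random.Generator,
    substitution_rate: float,
    insertion_rate: float = 0.0,
    deletion_rate: float = 0.0,
) -> str:
    """Apply an independent per-base error process to one sequence."""
    out: list[str] = []
    bases = "ACGT"
    for b in seq:
        r = rng.random()
        if r < deletion_rate:
            continue
        if r < deletion_rate + insertion_rate:
            out.append(bases[rng.integers(4)])
            out.append(b)
            continue
        if r < deletion_rate + insertion_rate + substitution_rate:
            choices = [x for x in bases if x != b]
            out.append(choices[rng.integers(3)])
        else:
            out.append(b)
    return "".join(out)


def simulate_oligo_pool(
    designs: Mapping[str, str],
    substitution_rate: float = 0.007,
    insertion_rate: float = 0.0,
    deletion_rate: float = 0.0,
    copies: int = 1,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Chip-synthesize an oligo pool: independent per-base errors per molecule.

    Returns (member_id, possibly mutated sequence) for ``copies`` molecules
    per design. With total per-base error p, the correct fraction of
    L-mers is (1 - p)^L in expectation.
    """
    rng = np.random.default_rng(seed)
    pool: list[tuple[str, str]] = []
    for member_id, seq in designs.items():
        for _ in range(copies):
            pool.append(
                (member_id,
                 mutate_sequence(seq, rng, substitution_rate, insertion_rate, deletion_rate))
            )
    return pool


# ---------------------------------------------------------------------------
# colony picking
# ---------------------------------------------------------------------------

def simulate_picking(
    pool: Sequence[tuple[str, str]],
    n_colonies: int,
    duplicate_bias: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Pick colonies from a polyclonal pool, with optional clonal bias.

    duplicate_bias = 0 draws colonies i.i.d. uniformly from the pool.
    duplicate_bias > 0 runs a Polya urn: each pick increases that member's
    weight by the bias, modelling clonal amplification before plating,
    which overrepresents duplicates relative to unbiased sampling.
    """
    if n_colonies <= 0:
        raise ValueError("n_colonies must be positive")
    if not pool:
        raise ValueError("pool is empty")
    rng = np.random.default_rng(seed)
    n = len(pool)
    if duplicate_bias == 0.0:
        idx = rng.integers(0, n, size=n_colonies)
        return [pool[i] for i in idx]
    picks: list[int] = []
    for t in range(n_colonies):
        # P(member i) = (1 + bias * c_i) / (n + bias * t): mixture of a fresh
        # uniform draw and a uniform re-draw from previous picks
        if rng.random() < n / (n + duplicate_bias * t) or not picks:
            picks.append(int(rng.integers(0, n)))
        else:
            picks.append(picks[int(rng.integers(0, len(picks)))])
    return [pool[i] for i in picks]


def arrange_in_plates(
    picked: Sequence[tuple[str, str]], scheme: PoolingScheme
) -> dict[WellAddress, tuple[str, str]]:
    """Array picked colonies into the scheme's wells, in picking order."""
    return {addr: rec for addr, rec in zip(scheme.wells(), picked)}


def picking_coverage(n_colonies: int, n_constructs: int) -> float:
    """Picking coverage fold = colonies picked / distinct constructs, 2 decimals."""
    if n_constructs <= 0:
        raise ZeroDivisionError("n_constructs must be positive")
    return round(n_colonies / n_constructs, 2)


def expected_unique_fraction(fold: float) -> float:
    """Coupon-collector expectation: fraction of constructs seen at coverage f."""
    return 1.0 - math.exp(-fold)


def unique_count_moments(n: int, m: int) -> tuple[float, float]:
    """Exact mean and variance of the number of distinct constructs seen.

    m uniform draws from n equally likely constructs: classic occupancy
    moments, used for confidence intervals around the coupon-collector
    expectation.
    """
    q1 = (1 - 1 / n) ** m
    q2 = (1 - 2 / n) ** m
    mean = n * (1 - q1)
    var = n * q1 + n * (n - 1) * q2 - n * n * q1 * q1
    return mean, max(var, 0.0)


def plan_iterations(
    library: Iterable[str], allocated: Iterable[str]
) -> list[str]:
    """Members still missing after a round: the next synthesis pool."""
    return sorted(set(library) - set(allocated))


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_pool_reads(
    assignments: Mapping[WellAddress, tuple[str, str]],
    scheme: PoolingScheme,
    depth: int = 20,
    substitution_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[str], dict[WellAddress, str]]:
    """Sequence the pooled matrix plates of an arrayed picking run.

    Every occupied clone well contributes ``depth`` reads to each of its
    two pools; a read is barcode1 + barcode2 + barcode3 + spacer, with
    optional substitution errors over the spacer. Returns the reads and
    the ground-truth well -> spacer table. depth=0 yields no reads.
    """
    rng = np.random.default_rng(seed)
    reads: list[str] = []
    truth: dict[WellAddress, str] = {}
    for addr, (_, spacer) in assignments.items():
        truth[addr] = spacer
        for pool in scheme.pools_of(addr):
            b1, b2, b3 = scheme.pool_barcode_triple(pool)
            prefix = b1 + b2 + b3
            for _ in range(depth):
                s = spacer
                if substitution_rate > 0:
                    s = mutate_sequence(s, rng, substitution_rate)
                reads.append(prefix + s)
    return reads, truth


def simulate_amplicon_reads(
    reference_seq: str,
    target_start: int,
    target_end: int,
    depth: int = 1000,
    edit_rate: float = 0.30,
    indel_spectrum: Mapping[int, float] | None = None,
    cut_offset: int = 17,
    off_window_rate: float = 0.0,
    substitution_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[str], list[int]]:
    """Simulate locus amplicon reads with a configured editing outcome.

    With probability ``edit_rate`` a read carries one indel drawn from
    ``indel_spectrum`` (signed length -> probability), placed at the cut
    site (``cut_offset`` into the target interval). ``off_window_rate``
    adds reads whose indel lies far outside the target window (they must
    not count as mutated). Returns the reads and the true signed indel
    length per read (0 = unedited, off-window indels also recorded as 0).
    """
    rng = np.random.default_rng(seed)
    spectrum = dict(indel_spectrum or {-2: 0.3, -1: 0.4, 1: 0.3})
    lengths = list(spectrum)
    probs = np.array([spectrum[l] for l in lengths], dtype=float)
    probs /= probs.sum()
    cut = target_start + cut_offset
    reads: list[str] = []
    truth: list[int] = []
    far = max(target_end + 40, len(reference_seq) - 30)
    for _ in range(depth):
        r = rng.random()
        if r < edit_rate:
            ln = int(lengths[rng.choice(len(lengths), p=probs)])
            if ln < 0:
                read = reference_seq[:cut] + reference_seq[cut - ln:]
            else:
                ins = _random_seq(rng, ln)
                read = reference_seq[:cut] + ins + reference_seq[cut:]
            truth.append(ln)
        elif r < edit_rate + off_window_rate:
            read = reference_seq[: far - 2] + reference_seq[far:]  # 2-nt deletion far away
            truth.append(0)
        else:
            read = reference_seq
            truth.append(0)
        if substitution_rate > 0:
            read = mutate_sequence(read, rng, substitution_rate)
        reads.append(read)
    return reads, truth
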