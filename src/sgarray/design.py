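"""CRISPR target-site scanning and rule-based selection for Cas9 (SpCas9, NGG).

The design engine scans an annotated genome for 23-nt Cas9 target sites
(20-nt protospacer + NGG PAM), annotates each candidate with the
composition- and position-based features that correlate with genome
editing activity, and deterministically picks one site per gene.

Coordinate conventions
----------------------
All genome coordinates are 0-based, half-open, on the reference strand.
Protospacers are always reported 5'->3' on the protospacer strand.
Protospacer positions are numbered 1..20 with position 1 the most 5'
base and position 21 the N of the PAM; the nuclease cut is modelled as
the canonical blunt cut between positions 17 and 18 (3 bp 5' of the PAM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SITE_LEN = 23  # 20-nt protospacer + 3-nt PAM


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN)."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    strand: str  # '+' or '-'
    cds: tuple[tuple[int, int], ...]  # sorted, non-overlapping genomic intervals

    def __post_init__(self):
        ivs = sorted(self.cds)
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping CDS intervals in {self.transcript_id}")
        object.__setattr__(self, "cds", tuple(ivs))

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcripts, each a list of CDS intervals.

    Total CDS length not divisible by 3 is tolerated (partial models)
    but flagged via :attr:`partial`.
    """

    gene_id: str
    transcripts: tuple[Transcript, ...]

    @property
    def partial(self) -> bool:
        return any(t.cds_length % 3 != 0 for t in self.transcripts)


@dataclass
class TargetSite:
    """A candidate protospacer+PAM with coordinates and filter annotations."""

    chrom: str
    strand: str                   # strand carrying the protospacer 5'->3'
    genome_start: int             # 0-based half-open start of the 23-nt site
    protospacer: str              # 20 nt, 5'->3' on the protospacer strand
    pam: str                      # 3 nt, must match NGG
    gene_id: str = ""
    gc_2_20: float = float("nan")
    seed_unique: bool | None = None
    positional_flags: tuple[bool, bool, bool] = (False, False, False)
    cds_fraction: float = float("nan")  # min over passing transcripts

    def __post_init__(self):
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if self.pam[1:3] != "GG":
            raise ValueError("PAM must match NGG")

    @property
    def seed13(self) -> str:
        """PAM-proximal 13-mer seed (protospacer positions 8-20)."""
        return self.protospacer[7:20]

    @property
    def genome_end(self) -> int:
        return self.genome_start + SITE_LEN

    @property
    def cut_coord(self) -> int:
        """Genome coordinate of the blunt-cut boundary (between positions 17/18)."""
        if self.strand == "+":
            return self.genome_start + 17
        return self.genome_start + 6


@dataclass
class DesignRules:
    """Tunable selection rules.

    gc_min is a strict lower bound on the G/C fraction over protospacer
    positions 2-20 (19 bases); max_cds_fraction restricts the cut site to
    the early portion of the ORF; exclude_TTTT optionally drops spacers
    containing the Pol III terminator TTTT.
    """

    gc_min: float = 0.35
    seed_len: int = 13
    max_cds_fraction: float = 0.5
    exclude_TTTT: bool = False

    def __post_init__(self):
        if not 0.0 <= self.gc_min <= 1.0:
            raise ValueError("gc_min must lie in [0, 1]")
        if self.seed_len > 20:
            raise ValueError("seed_len must be <= 20")


def scan_target_sites(sequence: str, chrom: str = "") -> list[TargetSite]:
    """Scan a sequence for Cas9 target sites on both strands, unfiltered.

    Finds every 5'-N21-GG-3' site (reported on the + strand) and every
    5'-CC-N21-3' site (reported as a - strand site with the protospacer
    reverse-complemented). Overlapping sites are all reported; windows
    containing N are skipped. Empty or short input yields an empty list.
    """
    seq = sequence.upper()
    n = len(seq)
    sites: list[TargetSite] = []
    for i in range(n - SITE_LEN + 1):
        window = seq[i : i + SITE_LEN]
        if "N" in window:
            continue
        # + strand: N20 [N]GG
        if window[21] == "G" and window[22] == "G":
            sites.append(
                TargetSite(
                    chrom=chrom, strand="+", genome_start=i,
                    protospacer=window[:20], pam=window[20:23],
                )
            )
        # - strand: CC[N] N20  (revcomp is N20 NGG)
        if window[0] == "C" and window[1] == "C":
            rc = revcomp(window)
            sites.append(
                TargetSite(
                    chrom=chrom, strand="-", genome_start=i,
                    protospacer=rc[:20], pam=rc[20:23],
                )
            )
    return sites


def gc_fraction_2_20(protospacer: str) -> float:
    """G/C fraction over protospacer positions 2-20 (19 bases)."""
    window = protospacer[1:20]
    return sum(b in "GC" for b in window) / len(window)


def gc_filter(site: TargetSite, rules: DesignRules | None = None) -> bool:
    """True iff GC fraction over positions 2-20 strictly exceeds gc_min."""
    rules = rules or DesignRules()
    return gc_fraction_2_20(site.protospacer) > rules.gc_min


# preferred base sets at 1-based protospacer positions
_PREFERENCES = ((14, "AT"), (15, "AT"), (18, "CG"))


def positional_preference(site: TargetSite) -> int:
    """Number of satisfied positional preferences: A/T at 14, A/T at 15, C/G at 18."""
    return sum(site.protospacer[pos - 1] in bases for pos, bases in _PREFERENCES)


def positional_flags(site: TargetSite) -> tuple[bool, bool, bool]:
    return tuple(site.protospacer[pos - 1] in bases for pos, bases in _PREFERENCES)


def cds_position(site: TargetSite, gene: GeneModel) -> list[tuple[str, float]]:
    """Fraction of the coding sequence 5' of the cut, per transcript.

    For each transcript whose CDS contains the cut boundary, returns
    (transcript_id, fraction) where fraction is the number of coding bases
    5' of the cut (in the transcript's reading direction) divided by the
    total CDS length. Returns an empty list when the site lies outside all
    CDS intervals.
    """
    cut = site.cut_coord
    out: list[tuple[str, float]] = []
    for tr in gene.transcripts:
        total = tr.cds_length
        if total == 0:
            continue
        if not any(s <= cut <= e for s, e in tr.cds):
            continue
        # coding bases strictly left of the cut boundary on the genome
        left = sum(min(e, cut) - s for s, e in tr.cds if s < cut)
        frac = left / total if tr.strand == "+" else (total - left) / total
        out.append((tr.transcript_id, frac))
    return out


def cds_pass(site: TargetSite, gene: GeneModel, rules: DesignRules | None = None) -> bool:
    rules = rules or DesignRules()
    fracs = cds_position(site, gene)
    return any(f <= rules.max_cds_fraction for _, f in fracs)


def seed_uniqueness(
    site: TargetSite,
    genome: Mapping[str, str],
    seed_len: int = 13,
    require_pam: bool = True,
) -> bool:
    """True iff the PAM-proximal seed occurs exactly once genome-wide.

    Counts occurrences of the seed k-mer immediately followed by an NGG PAM
    (the functional definition of an off-target seed match), on both strands
    of every sequence in ``genome``. With require_pam=False the bare k-mer
    is counted instead.
    """
    seed = site.protospacer[20 - seed_len : 20]
    hits = 0
    for seq in genome.values():
        seq = seq.upper()
        for s in (seq, revcomp(seq)):
            start = 0
            while True:
                j = s.find(seed, start)
                if j < 0:
                    break
                if not require_pam:
                    hits += 1
                else:
                    pam = s[j + seed_len : j + seed_len + 3]
                    if len(pam) == 3 and pam[1:3] == "GG":
                        hits += 1
                if hits > 1:
                    return False
                start = j + 1
    return hits == 1


def annotate_site(
    site: TargetSite,
    gene: GeneModel,
    genome: Mapping[str, str],
    rules: DesignRules | None = None,
) -> TargetSite:
    """Fill in all filter annotations for a candidate site."""
    rules = rules or DesignRules()
    fracs = [f for _, f in cds_position(site, gene)]
    passing = [f for f in fracs if f <= rules.max_cds_fraction]
    return replace(
        site,
        gene_id=gene.gene_id,
        gc_2_20=gc_fraction_2_20(site.protospacer),
        seed_unique=seed_uniqueness(site, genome, rules.seed_len),
        positional_flags=positional_flags(site),
        cds_fraction=min(passing) if passing else (min(fracs) if fracs else float("nan")),
    )


def _selection_key(site: TargetSite, rules: DesignRules):
    frac = site.cds_fraction
    return (
        0 if site.seed_unique else 1,
        -positional_preference(site),
        0 if gc_filter(site, rules) else 1,
        frac if not math.isnan(frac) else float("inf"),
        site.genome_start,
        0 if site.strand == "+" else 1,
    )


def select_one_per_gene(
    candidates: Sequence[TargetSite], rules: DesignRules | None = None
) -> TargetSite | None:
    """Deterministically choose the best candidate site for one gene.

    Lexicographic preference: unique seed, then more satisfied positional
    preferences, then passing the GC filter, then earliest cut position in
    the ORF; ties break on lowest genome_start, then + strand. Returns None
    for an empty candidate list (gene undesignable). Pure function of its
    inputs: permutation-invariant and deterministic.
    """
    rules = rules or DesignRules()
    pool = list(candidates)
    if rules.exclude_TTTT:
        pool = [c for c in pool if "TTTT" not in c.protospacer]
    if not pool:
        return None
    return min(pool, key=lambda c: _selection_key(c, rules))


def design_gene(
    gene: GeneModel,
    genome: Mapping[str, str],
    chrom: str,
    rules: DesignRules | None = None,
) -> TargetSite | None:
    """Scan, annotate and select one target site for a single gene.

    Candidates are sites whose cut falls in the first ``max_cds_fraction``
    of the ORF of at least one transcript; among those, sites present in
    all transcripts are preferred implicitly through the cds_fraction
    annotation (min over passing transcripts).
    """
    rules = rules or DesignRules()
    lo = min(s for t in gene.transcripts for s, _ in t.cds)
    hi = max(e for t in gene.transcripts for _, e in t.cds)
    lo = max(0, lo - SITE_LEN)
    region = genome[chrom][lo : hi + SITE_LEN]
    candidates = []
    for site in scan_target_sites(region, chrom):
        site.genome_start += lo
        annotated = annotate_site(site, gene, genome, rules)
        if math.isnan(annotated.cds_fraction):
            continue
        if annotated.cds_fraction > rules.max_cds_fraction:
            continue
        candidates.append(annotated)
    return select_one_per_gene(candidates, rules)


def design_library(
    genome: Mapping[str, str],
    genes: Iterable[tuple[str, GeneModel]],
    rules: DesignRules | None = None,
) -> tuple[dict[str, TargetSite], list[str]]:
    """Design one site per gene across a genome.

    Parameters
    ----------
    genome : mapping of chrom -> sequence
    genes : iterable of (chrom, GeneModel)

    Returns (designed sites by gene_id, list of undesignable gene ids).
    """
    rules = rules or DesignRules()
    designed: dict[str, TargetSite] = {}
    failed: list[str] = []
    for chrom, gene in genes:
        site = design_gene(gene, genome, chrom, rules)
        if site is None:
            failed.append(gene.gene_id)
        else:
            designed[gene.gene_id] = site
    return designed, failed
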