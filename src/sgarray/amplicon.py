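"""Amplicon indel quantification and knockout-clone genotyping.

Quantifies genome editing from locus-specific deep-sequencing reads:
each read is compared to the amplicon reference, indels are located, and
a read counts as *mutated* when an indel spans or touches the CRISPR
target site (the protospacer interval extended by 1 nt on each side, so
abutting indels count). Monoclonal cell lines are genotyped from the
same calls: distinct indels carried by at least an allele-fraction
threshold of reads become alleles, frameshift status follows from the
signed indel length mod 3, and only clones with at least 50 alignable
reads are evaluated at all.

Indel calling is anchor based: exact flanking k-mers (default 15 nt)
immediately up- and downstream of the target interval are located in the
read, and the offset difference gives the net indel; when the anchors
cannot be found exactly, a global alignment (edlib) over the whole read
is used as fallback. Substitution-only reads are never counted as
mutated. Reads that cannot be aligned are excluded from denominators.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib

MIN_EVALUABLE_READS = 50        # monoclones below this are not evaluated
DEFAULT_ANCHOR_LEN = 15
DEFAULT_ALLELE_MIN_FRACTION = 0.20


class ReferenceError_(ValueError):
    pass


@dataclass(frozen=True)
class AmpliconReference:
    """An amplicon reference sequence with the protospacer interval marked."""

    sequence: str
    target_start: int   # 0-based half-open protospacer interval
    target_end: int

    def __post_init__(self):
        if not 0 <= self.target_start < self.target_end <= len(self.sequence):
            raise ReferenceError_("target interval outside reference")

    @property
    def target(self) -> str:
        return self.sequence[self.target_start : self.target_end]


@dataclass(frozen=True)
class Indel:
    """A called indel: start in reference coordinates, signed length.

    length < 0 is a deletion occupying [start, start - length); length > 0
    an insertion at point coordinate ``start``.
    """

    start: int
    length: int

    @property
    def interval(self) -> tuple[int, int]:
        if self.length < 0:
            return self.start, self.start - self.length
        return self.start, self.start  # insertion: point coordinate


@dataclass(frozen=True)
class ReadCall:
    aligned: bool
    indels: tuple[Indel, ...] = ()


@dataclass
class AmpliconCall:
    """Per-locus editing tally."""

    total_reads: int
    aligned_reads: int
    mutated_reads: int
    indel_spectrum: Counter = field(default_factory=Counter)  # (start, signed len) -> reads

    @property
    def mutation_frequency(self) -> float:
        return self.mutated_reads / self.aligned_reads


@dataclass
class CloneGenotype:
    clone_id: str
    aligned_reads: int
    evaluable: bool
    alleles: list[tuple[int, float, str]] = field(default_factory=list)  # (len, fraction, frame)
    genotype_class: str = "not_evaluable"  # unmodified | partial | all_allelic_frameshift


def _locate_anchor(read: str, anchor: str) -> int | None:
    """Position of a unique exact anchor occurrence in the read, else None."""
    first = read.find(anchor)
    if first < 0 or read.find(anchor, first + 1) >= 0:
        return None
    return first


def call_indels(
    read: str,
    reference: AmpliconReference,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    max_edit_fraction: float = 0.25,
) -> ReadCall:
    """Align one read to the amplicon reference and call indels.

    Anchor route: the ``anchor_len``-mers flanking the target interval are
    located exactly and uniquely in the read; the distance between them,
    compared with the reference, gives the net indel inside the target
    region, positioned by the longest common prefix between the observed
    and reference target segments. Anchor failure falls back to edlib
    global alignment over the whole read; reads whose edit distance
    exceeds ``max_edit_fraction`` of the reference length are unaligned.
    """
    ref = reference.sequence.upper()
    read = read.upper()
    ts, te = reference.target_start, reference.target_end
    if ts < anchor_len or te + anchor_len > len(ref):
        raise ReferenceError_(
            "reference too short to place anchors around the target interval"
        )
    up = ref[ts - anchor_len : ts]
    down = ref[te : te + anchor_len]
    u = _locate_anchor(read, up)
    d = _locate_anchor(read, down)
    if u is not None and d is not None and d >= u + anchor_len:
        observed = read[u + anchor_len : d]
        net = len(observed) - (te - ts)
        if net == 0:
            return ReadCall(aligned=True, indels=())
        # position the indel by common prefix with the reference target
        ref_t = ref[ts:te]
        i = 0
        while i < min(len(observed), len(ref_t)) and observed[i] == ref_t[i]:
            i += 1
        return ReadCall(aligned=True, indels=(Indel(start=ts + i, length=net),))
    return _call_indels_alignment(read, reference, max_edit_fraction)


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _call_indels_alignment(
    read: str, reference: AmpliconReference, max_edit_fraction: float
) -> ReadCall:
    res = edlib.align(read, reference.sequence.upper(), mode="NW", task="path")
    if res["editDistance"] > max_edit_fraction * len(reference.sequence):
        return ReadCall(aligned=False)
    indels: list[Indel] = []
    ref_pos = 0
    for n_str, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n_str)
        if op in "=XM":
            ref_pos += n
        elif op == "D":  # in edlib's query-vs-target CIGAR, D consumes the target
            indels.append(Indel(start=ref_pos, length=-n))
            ref_pos += n
        elif op == "I":
            indels.append(Indel(start=ref_pos, length=n))
    return ReadCall(aligned=True, indels=tuple(indels))


def indel_touches_target(
    indel: Indel, reference: AmpliconReference, pad: int = 1
) -> bool:
    """Does the indel span or touch the target site?

    The protospacer interval is extended by ``pad`` nt on each side and
    treated as closed, so indels abutting the protospacer count as
    on-target.
    """
    lo, hi = reference.target_start - pad, reference.target_end + pad
    s, e = indel.interval
    if indel.length > 0:  # insertion point
        return lo <= s <= hi
    return s < hi and e > lo


def editing_frequency(
    reads: Iterable[str],
    reference: AmpliconReference,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
) -> AmpliconCall:
    """Tally mutated reads at a locus and compute the editing frequency.

    A read is mutated iff it carries at least one indel spanning or
    touching the target interval; indels entirely outside that window are
    ignored. mutation_frequency = mutated / aligned; raises when no read
    aligns (frequency undefined).
    """
    total = aligned = mutated = 0
    spectrum: Counter = Counter()
    for read in reads:
        total += 1
        call = call_indels(read, reference, anchor_len=anchor_len)
        if not call.aligned:
            continue
        aligned += 1
        on_target = [i for i in call.indels if indel_touches_target(i, reference)]
        if on_target:
            mutated += 1
            for i in on_target:
                spectrum[(i.start, i.length)] += 1
    if aligned == 0:
        raise ZeroDivisionError("no aligned reads: editing frequency undefined")
    return AmpliconCall(
        total_reads=total, aligned_reads=aligned, mutated_reads=mutated,
        indel_spectrum=spectrum,
    )


def genotype_clone(
    reads: Iterable[str],
    reference: AmpliconReference,
    clone_id: str = "",
    allele_min_fraction: float = DEFAULT_ALLELE_MIN_FRACTION,
    min_reads: int = MIN_EVALUABLE_READS,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
) -> CloneGenotype:
    """Classify a monoclone's genotype from its amplicon reads.

    Each aligned read is reduced to its on-target indel signature (or wild
    type); signatures carried by at least ``allele_min_fraction`` of
    aligned reads become alleles. Classes:

    * ``not_evaluable`` — fewer than ``min_reads`` aligned reads;
    * ``unmodified`` — no non-wild-type allele;
    * ``all_allelic_frameshift`` — every allele is out of frame and the
      wild-type fraction is below the allele threshold;
    * ``partial`` — anything else (wild-type or in-frame allele retained).
    """
    signature_counts: Counter = Counter()
    aligned = 0
    for read in reads:
        call = call_indels(read, reference, anchor_len=anchor_len)
        if not call.aligned:
            continue
        aligned += 1
        on_target = tuple(
            (i.start, i.length) for i in call.indels
            if indel_touches_target(i, reference)
        )
        signature_counts[on_target if on_target else "wt"] += 1

    if aligned < min_reads:
        return CloneGenotype(clone_id, aligned, evaluable=False)

    wt_fraction = signature_counts.get("wt", 0) / aligned
    alleles: list[tuple[int, float, str]] = []
    for sig, n in sorted(signature_counts.items(), key=lambda kv: -kv[1]):
        frac = n / aligned
        if sig == "wt" or frac < allele_min_fraction:
            continue
        net = sum(length for _, length in sig)
        frame = "out" if net % 3 != 0 else "in"
        alleles.append((net, frac, frame))
    if wt_fraction >= allele_min_fraction:
        alleles.append((0, wt_fraction, "wt"))

    non_wt = [a for a in alleles if a[2] != "wt"]
    if not non_wt:
        cls = "unmodified"
    elif all(a[2] == "out" for a in non_wt) and wt_fraction < allele_min_fraction:
        cls = "all_allelic_frameshift"
    else:
        cls = "partial"
    return CloneGenotype(clone_id, aligned, evaluable=True, alleles=alleles,
                         genotype_class=cls)


def project_report(genotypes: Iterable[CloneGenotype]) -> dict[str, int]:
    """Histogram of evaluable clones per targeting project.

    Partitions evaluable clones into unmodified / at least one mutated
    allele (but not all-allelic frameshift) / all-allelic frameshift.
    """
    counts = {"unmodified": 0, "mutated": 0, "all_allelic_frameshift": 0}
    for g in genotypes:
        if not g.evaluable:
            continue
        if g.genotype_class == "unmodified":
            counts["unmodified"] += 1
        elif g.genotype_class == "all_allelic_frameshift":
            counts["all_allelic_frameshift"] += 1
        else:
            counts["mutated"] += 1
    return counts
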