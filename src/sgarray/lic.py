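"""Ligation-independent cloning (LIC) chewback and oligo-assembly model.

T4 DNA polymerase 3'->5' exonuclease activity resects double-stranded
ends until it reaches the first position where the single dNTP supplied
in the reaction (the "stop" nucleotide, dTTP here) can be re-incorporated.
Resecting both blunt ends of a linearized vector therefore exposes two
long 5' single-stranded overhangs whose lengths are set entirely by the
vector sequence and the chosen stop base.

A target-specific ssDNA oligo whose two arms are exact reverse
complements of the two overhangs bridges the ends: annealing circularizes
the plasmid, leaving a single-stranded gap over the spacer region that
the bacterial host repairs after transformation. The model below designs
that oligo, and validates an assembly base by base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .design import revcomp


@dataclass(frozen=True)
class ChewbackResult:
    """Outcome of resecting one 3' end."""

    end: str                # 'left' or 'right'
    overhang_len: int       # bases removed from the recessed strand
    overhang_seq: str       # exposed single-stranded 5' region, 5'->3'
    remaining_strand: str   # the chewed strand after resection, 5'->3'


@dataclass(frozen=True)
class LinearVector:
    """A blunt-ended linear double-stranded vector.

    top_strand and bottom_strand are both written 5'->3' and must be exact
    reverse complements before chewback. ``constant_region`` optionally
    marks the top-strand interval covered by the constant (universal
    reverse-strand) oligo.
    """

    top_strand: str
    bottom_strand: str
    constant_region: tuple[int, int] | None = None

    def __post_init__(self):
        if self.bottom_strand != revcomp(self.top_strand):
            raise ValueError("strands are not reverse complements")

    def __len__(self) -> int:
        return len(self.top_strand)


@dataclass(frozen=True)
class OligoDesign:
    """A target-specific LIC oligo: left arm + spacer + right arm."""

    spacer: str
    left_arm: str
    right_arm: str

    @property
    def full_seq(self) -> str:
        return self.left_arm + self.spacer + self.right_arm


@dataclass(frozen=True)
class AssemblyReport:
    mismatches: int
    gap_length: int
    circularizable: bool
    constant_mismatches: int | None = None


class AssemblyInfeasibleError(ValueError):
    """Raised when an oligo cannot anneal to the chewed vector."""


def chewback(strand: str, stop_base: str) -> ChewbackResult:
    """Resect a strand from its 3' end up to the first stop base.

    The exonuclease removes 3'-terminal bases one at a time; at the first
    occurrence of ``stop_base`` the polymerase re-incorporates the supplied
    dNTP and the enzyme idles, so that base is retained. overhang_len is
    the 0-based index of the first stop base counted from the 3' terminus,
    i.e. the number of bases removed. A strand lacking the stop base is
    fully resected (degenerate design) and a warning is issued.
    """
    if not strand:
        raise ValueError("empty strand")
    stop_base = stop_base.upper()
    if stop_base not in "ACGT":
        raise ValueError("stop_base must be one of A/C/G/T")
    s = strand.upper()
    idx = None
    for offset in range(len(s)):
        if s[len(s) - 1 - offset] == stop_base:
            idx = offset
            break
    if idx is None:
        warnings.warn(
            f"stop base {stop_base} absent; strand fully resected", stacklevel=2
        )
        idx = len(s)
    removed = s[len(s) - idx :] if idx else ""
    return ChewbackResult(
        end="", overhang_len=idx, overhang_seq=removed, remaining_strand=s[: len(s) - idx]
    )


def vector_overhangs(vector: LinearVector, stop_base: str = "T") -> tuple[ChewbackResult, ChewbackResult]:
    """Chew both ends of a linear vector; return (left, right) overhangs.

    The left end exposes the top strand's 5' region (bottom strand 3' end
    resected); the right end exposes the bottom strand's 5' region (top
    strand 3' end resected). overhang_seq is the exposed single-stranded
    vector sequence, 5'->3'.
    """
    top = vector.top_strand.upper()
    bottom = vector.bottom_strand.upper()
    right = chewback(top, stop_base)
    left = chewback(bottom, stop_base)
    left_exposed = top[: left.overhang_len]
    right_exposed = bottom[: right.overhang_len]
    return (
        ChewbackResult("left", left.overhang_len, left_exposed, left.remaining_strand),
        ChewbackResult("right", right.overhang_len, right_exposed, right.remaining_strand),
    )


def make_oligo(
    spacer: str,
    vector: LinearVector,
    total_len: int = 71,
    stop_base: str = "T",
) -> OligoDesign:
    """Design the single target-specific oligo for a spacer and vector.

    The oligo bridges the two chewed vector ends: its left arm restores the
    bases resected from the top strand's 3' end (pairing with the right-end
    overhang) and its right arm is the reverse complement of the left-end
    overhang. The spacer sits between the arms and remains single-stranded
    after annealing (the gap repaired in the host). Arm lengths follow from
    the chewback, so a design is only feasible when
    ``overhang_left + overhang_right + len(spacer) == total_len``.
    """
    left_oh, right_oh = vector_overhangs(vector, stop_base)
    arm_left = revcomp(right_oh.overhang_seq)   # == resected top-strand bases
    arm_right = revcomp(left_oh.overhang_seq)
    got = len(arm_left) + len(arm_right) + len(spacer)
    if got != total_len:
        raise AssemblyInfeasibleError(
            f"arms ({len(arm_left)}+{len(arm_right)}) + spacer ({len(spacer)}) "
            f"= {got} nt, expected total_len={total_len}"
        )
    return OligoDesign(spacer=spacer.upper(), left_arm=arm_left, right_arm=arm_right)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b)) + abs(len(a) - len(b))


def validate_assembly(
    oligo: OligoDesign,
    vector: LinearVector,
    constant_oligo: str | None = None,
    stop_base: str = "T",
) -> AssemblyReport:
    """Check an oligo against the chewed vector, base by base.

    Counts mismatches in both double-stranded junctions (left arm vs the
    right-end overhang, right arm vs the left-end overhang), reports the
    single-stranded gap length (the unpaired spacer), and declares the
    assembly circularizable iff both junctions are mismatch-free. When a
    constant oligo and a vector constant_region are given, the constant
    oligo is additionally checked for exact reverse-complementarity to
    that region.
    """
    left_oh, right_oh = vector_overhangs(vector, stop_base)
    mm = _hamming(oligo.left_arm, revcomp(right_oh.overhang_seq))
    mm += _hamming(oligo.right_arm, revcomp(left_oh.overhang_seq))
    const_mm = None
    if constant_oligo is not None and vector.constant_region is not None:
        s, e = vector.constant_region
        const_mm = _hamming(constant_oligo.upper(), revcomp(vector.top_strand[s:e].upper()))
    return AssemblyReport(
        mismatches=mm,
        gap_length=len(oligo.spacer),
        circularizable=(mm == 0) and (const_mm in (None, 0)),
        constant_mismatches=const_mm,
    )


def synthetic_vector(
    arm_left_len: int = 26,
    arm_right_len: int = 26,
    duplex_len: int = 120,
    stop_base: str = "T",
    seed: int = 0,
) -> LinearVector:
    """Generate a random vector whose chewback yields prescribed overhangs.

    The top strand is built so the first occurrence of the stop base's
    complement from the 5' end is at index ``arm_right_len`` (left-end
    overhang) and the first stop base from the 3' end is at offset
    ``arm_left_len`` (right-end overhang). Default 26+26 arms pair with a
    19-nt spacer to give the standard 71-mer oligo.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    stop = stop_base.upper()
    stop_comp = revcomp(stop)
    other3 = [b for b in "ACGT" if b != stop_comp]
    other5 = [b for b in "ACGT" if b != stop]

    # 5' segment: arm_right_len bases without stop_comp, then one stop_comp
    head = "".join(rng.choice(other3, size=arm_right_len)) + stop_comp
    # 3' segment: one stop base, then arm_left_len bases without it
    tail = stop + "".join(rng.choice(other5, size=arm_left_len))
    mid = "".join(rng.choice(list("ACGT"), size=duplex_len))
    top = head + mid + tail
    return LinearVector(
        top_strand=top,
        bottom_strand=revcomp(top),
        constant_region=(len(head), len(head) + duplex_len),
    )
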