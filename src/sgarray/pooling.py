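"""Orthogonal plate pooling scheme and deconvolution of pooled sequencing.

Clones are arrayed in 96-well plates (rows A-H, columns 1-12) organized
in sets of 32 plates. Within a set every clone is mixed into exactly two
pools:

* a *position pool* — one per well coordinate (96 per set), holding the
  clones at that coordinate across all 32 plates of the set;
* a *group pool* — one per contiguous 4-column block of one plate
  (columns 1-4, 5-8, 9-12; 3 per plate, 96 per set, 32 wells each),
  numbered with Roman numerals plate-major (plate 1 -> I, II, III; ...).

The intersection of a clone's position pool (which well) and group pool
(which plate + which column block) identifies its address. Pools are
addressed for sequencing by a 3-barcode scheme: barcode 1 (12 choices)
identifies the matrix plate holding a set's position pools or group
pools, and barcodes 2 x 3 (8 x 12 = 96 combinations) identify the well
of that matrix plate, i.e. the pool. 12 x 96 = 1,152 distinguishable
pools per sequencing run; at 32 clones per pool and 2 pools per clone
that is 1,152 x 32 / 2 = 18,432 clones per run.

Deconvolution considers only reads whose spacer exactly matches a
designed library member ("error-free"); near-miss spacers are synthesis
errors and are reported separately.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

ROWS = "ABCDEFGH"


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> 'A1'..'H12'."""
    return f"{ROWS[row]}{col + 1}"


def parse_well(name: str) -> tuple[int, int]:
    return ROWS.index(name[0]), int(name[1:]) - 1


def roman(n: int) -> str:
    """Roman numeral for n >= 1 (group-pool labels I..XCVI and beyond)."""
    vals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for v, sym in vals:
        while n >= v:
            out.append(sym)
            n -= v
    return "".join(out)


@dataclass(frozen=True)
class WellAddress:
    set_index: int     # 0-based set
    plate: int         # 0-based plate within the set
    well: str          # 'A1'..'H12'


@dataclass(frozen=True)
class PoolId:
    set_index: int
    kind: str          # 'position' or 'group'
    label: str         # well name for position pools, Roman numeral for group pools


def _default_barcode_table(n: int, length: int, seed: int, min_dist: int = 3) -> list[str]:
    """Deterministic barcode set with pairwise Hamming distance >= min_dist."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out: list[str] = []
    while len(out) < n:
        cand = "".join(rng.choice(bases, size=length))
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_dist for bc in out):
            out.append(cand)
    return out


def default_barcodes() -> tuple[list[str], list[str], list[str]]:
    """The three barcode tables: 12 first-level, 8 second-level, 12 third-level."""
    return (
        _default_barcode_table(12, 6, seed=101),
        _default_barcode_table(8, 6, seed=202),
        _default_barcode_table(12, 6, seed=303),
    )


class ConfigError(ValueError):
    pass


@dataclass
class PoolingScheme:
    """Full clone-well <-> pool <-> barcode-triple mapping for a picking run."""

    n_plates: int
    plates_per_set: int = 32
    rows: int = 8
    cols: int = 12
    block_cols: int = 4
    barcodes: tuple[list[str], list[str], list[str]] = field(default_factory=default_barcodes)

    def __post_init__(self):
        if self.n_plates < 1:
            raise ConfigError("need at least one plate")
        if self.cols % self.block_cols != 0:
            raise ConfigError("column count must be divisible by the block width")
        bc1, bc2, bc3 = self.barcodes
        if len(bc2) * len(bc3) != self.rows * self.cols:
            raise ConfigError("barcode2 x barcode3 must cover the matrix-plate wells")

    # -- geometry -----------------------------------------------------------

    @property
    def wells_per_plate(self) -> int:
        return self.rows * self.cols

    @property
    def n_sets(self) -> int:
        return math.ceil(self.n_plates / self.plates_per_set)

    def plates_in_set(self, set_index: int) -> int:
        if set_index < self.n_sets - 1:
            return self.plates_per_set
        return self.n_plates - self.plates_per_set * (self.n_sets - 1)

    def wells(self) -> Iterator[WellAddress]:
        for s in range(self.n_sets):
            for p in range(self.plates_in_set(s)):
                for r in range(self.rows):
                    for c in range(self.cols):
                        yield WellAddress(s, p, well_name(r, c))

    # -- well -> pools ------------------------------------------------------

    def column_block(self, well: str) -> int:
        _, col = parse_well(well)
        return col // self.block_cols

    def group_label(self, plate: int, block: int) -> str:
        n_blocks = self.cols // self.block_cols
        return roman(plate * n_blocks + block + 1)

    def pools_of(self, addr: WellAddress) -> tuple[PoolId, PoolId]:
        """The (position pool, group pool) a clone well belongs to."""
        block = self.column_block(addr.well)
        return (
            PoolId(addr.set_index, "position", addr.well),
            PoolId(addr.set_index, "group", self.group_label(addr.plate, block)),
        )

    def group_pool_address(self, label: str) -> tuple[int, int]:
        """Roman group label -> (plate, column block), both 0-based."""
        n_blocks = self.cols // self.block_cols
        idx = _roman_to_int(label) - 1
        return idx // n_blocks, idx % n_blocks

    def position_pools(self, set_index: int) -> list[PoolId]:
        return [
            PoolId(set_index, "position", well_name(r, c))
            for r in range((self.rows)) for c in range(self.cols)
        ]

    def group_pools(self, set_index: int) -> list[PoolId]:
        n_blocks = self.cols // self.block_cols
        return [
            PoolId(set_index, "group", self.group_label(p, b))
            for p in range(self.plates_per_set) for b in range(n_blocks)
        ]

    def pool_members(self, pool: PoolId) -> list[WellAddress]:
        n = self.plates_in_set(pool.set_index)
        if pool.kind == "position":
            return [WellAddress(pool.set_index, p, pool.label) for p in range(n)]
        plate, block = self.group_pool_address(pool.label)
        if plate >= n:
            return []
        return [
            WellAddress(pool.set_index, plate, well_name(r, block * self.block_cols + c))
            for r in range(self.rows) for c in range(self.block_cols)
        ]

    # -- barcodes -----------------------------------------------------------

    def matrix_plate_barcode1(self, set_index: int, kind: str) -> int:
        """Index into the barcode-1 table for a set's position/group matrix plate.

        Half the table serves position matrix plates, half group matrix
        plates; sets beyond one sequencing run reuse barcodes run-major.
        """
        half = len(self.barcodes[0]) // 2
        offset = 0 if kind == "position" else half
        return offset + set_index % half

    def sequencing_run(self, set_index: int) -> int:
        return set_index // (len(self.barcodes[0]) // 2)

    def pool_barcode_triple(self, pool: PoolId) -> tuple[str, str, str]:
        bc1, bc2, bc3 = self.barcodes
        b1 = bc1[self.matrix_plate_barcode1(pool.set_index, pool.kind)]
        # the pool sits in a well of its matrix plate
        if pool.kind == "position":
            row, col = parse_well(pool.label)
        else:
            idx = _roman_to_int(pool.label) - 1
            row, col = idx // self.cols, idx % self.cols
        return b1, bc2[row], bc3[col]

    def triple_to_pool(self, run: int = 0) -> dict[tuple[str, str, str], PoolId]:
        """Barcode triple -> pool, for all sets of one sequencing run."""
        half = len(self.barcodes[0]) // 2
        out: dict[tuple[str, str, str], PoolId] = {}
        for s in range(run * half, min(self.n_sets, (run + 1) * half)):
            for pool in self.position_pools(s) + self.group_pools(s):
                out[self.pool_barcode_triple(pool)] = pool
        return out

    def n_runs(self) -> int:
        half = len(self.barcodes[0]) // 2
        return math.ceil(self.n_sets / half)

    # -- export -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """One row per clone well with its pools and the pools' barcodes."""
        rows = []
        for addr in self.wells():
            pos, grp = self.pools_of(addr)
            b1p, b2p, b3p = self.pool_barcode_triple(pos)
            b1g, b2g, b3g = self.pool_barcode_triple(grp)
            rows.append(
                dict(
                    set=addr.set_index + 1, plate=addr.plate + 1, well=addr.well,
                    position_pool=pos.label, group_pool=grp.label,
                    pos_bc1=b1p, pos_bc2=b2p, pos_bc3=b3p,
                    grp_bc1=b1g, grp_bc2=b2g, grp_bc3=b3g,
                )
            )
        return pd.DataFrame(rows)

    def pick_lists(self) -> pd.DataFrame:
        """Liquid-handler style transfer list: source well -> matrix-plate well."""
        rows = []
        for addr in self.wells():
            for pool in self.pools_of(addr):
                b1, b2, b3 = self.pool_barcode_triple(pool)
                bc2_table, bc3_table = self.barcodes[1], self.barcodes[2]
                dest = well_name(bc2_table.index(b2), bc3_table.index(b3))
                rows.append(
                    dict(
                        set=addr.set_index + 1, source_plate=addr.plate + 1,
                        source_well=addr.well, matrix=pool.kind, dest_well=dest,
                    )
                )
        return pd.DataFrame(rows)


_ROMAN_MAP = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100, "D": 500, "M": 1000}


def _roman_to_int(s: str) -> int:
    total = 0
    for a, b in itertools.zip_longest(s, s[1:]):
        v = _ROMAN_MAP[a]
        total += -v if b and v < _ROMAN_MAP[b] else v
    return total


def build_scheme(n_plates: int, plates_per_set: int = 32, rows: int = 8, cols: int = 12,
                 block_cols: int = 4, barcodes=None) -> PoolingScheme:
    """Construct the pooling scheme for a picking run of ``n_plates`` plates."""
    kwargs = {} if barcodes is None else {"barcodes": barcodes}
    return PoolingScheme(
        n_plates=n_plates, plates_per_set=plates_per_set, rows=rows, cols=cols,
        block_cols=block_cols, **kwargs,
    )


def scheme_capacity(
    n_barcode1: int = 12,
    n_barcode2: int = 8,
    n_barcode3: int = 12,
    pool_size: int = 32,
    pools_per_clone: int = 2,
) -> tuple[int, int]:
    """Pool and clone capacity of one sequencing run.

    n_pools = barcode1 x (barcode2 x barcode3); each pool holds pool_size
    clones but every clone occupies pools_per_clone pools, so
    n_clones = n_pools * pool_size / pools_per_clone.
    """
    n_pools = n_barcode1 * n_barcode2 * n_barcode3
    n_clones = n_pools * pool_size // pools_per_clone
    return n_pools, n_clones


# ---------------------------------------------------------------------------
# demultiplexing & deconvolution
# ---------------------------------------------------------------------------

@dataclass
class PoolObservation:
    """Per-pool read tallies: spacer sequence -> count."""

    pool: PoolId
    counts: Counter

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _check_table(table: Sequence[str], max_mismatch: int, name: str) -> None:
    for a, b in itertools.combinations(table, 2):
        if sum(x != y for x, y in zip(a, b)) <= 2 * max_mismatch:
            raise ConfigError(
                f"{name} barcodes {a!r} and {b!r} collide at mismatch radius {max_mismatch}"
            )


def _match_barcode(obs: str, table: Sequence[str], max_mismatch: int) -> str | None:
    if max_mismatch == 0:
        return obs if obs in table else None
    best, best_d = None, max_mismatch + 1
    for bc in table:
        d = sum(x != y for x, y in zip(obs, bc))
        if d < best_d:
            best, best_d = bc, d
    return best


def demultiplex(
    reads: Iterable[str],
    barcodes: tuple[Sequence[str], Sequence[str], Sequence[str]],
    max_mismatch: int = 0,
) -> tuple[dict[tuple[str, str, str], Counter], int]:
    """Assign reads to barcode triples; returns (triple -> spacer counts, n discarded).

    Read layout: barcode1 + barcode2 + barcode3 + spacer region. Each read
    is assigned to exactly one triple (all three barcodes must match within
    ``max_mismatch``) or discarded.
    """
    bc1, bc2, bc3 = barcodes
    for table, name in ((bc1, "level-1"), (bc2, "level-2"), (bc3, "level-3")):
        _check_table(table, max_mismatch, name)
    l1, l2, l3 = len(bc1[0]), len(bc2[0]), len(bc3[0])
    out: dict[tuple[str, str, str], Counter] = defaultdict(Counter)
    discarded = 0
    for read in reads:
        b1 = _match_barcode(read[:l1], bc1, max_mismatch)
        b2 = _match_barcode(read[l1 : l1 + l2], bc2, max_mismatch)
        b3 = _match_barcode(read[l1 + l2 : l1 + l2 + l3], bc3, max_mismatch)
        if b1 is None or b2 is None or b3 is None:
            discarded += 1
            continue
        out[(b1, b2, b3)][read[l1 + l2 + l3 :]] += 1
    return dict(out), discarded


@dataclass
class Allocation:
    """Deconvolution verdict for one designed spacer."""

    spacer: str
    status: str                               # unique | ambiguous | absent | inconsistent
    address: WellAddress | None = None        # set when unique
    candidates: tuple[WellAddress, ...] = ()
    position_reads: int = 0
    group_reads: int = 0


def _present_pools(
    observations: Mapping[tuple[str, str, str], Counter],
    triple_map: Mapping[tuple[str, str, str], PoolId],
    library: set[str],
    min_reads: int,
    min_fraction: float,
) -> tuple[dict[str, list[tuple[PoolId, int]]], Counter]:
    """spacer -> pools it is present in (with read support); plus error-spacer tally."""
    presence: dict[str, list[tuple[PoolId, int]]] = defaultdict(list)
    synthesis_errors: Counter = Counter()
    for triple, counts in observations.items():
        if triple not in triple_map:
            raise ConfigError(f"observed barcode triple {triple} not in scheme")
        pool = triple_map[triple]
        matched = {s: c for s, c in counts.items() if s in library}
        total = sum(matched.values())
        for s, c in counts.items():
            if s not in library:
                synthesis_errors[s] += c
                continue
            if c >= min_reads and total > 0 and c / total >= min_fraction:
                presence[s].append((pool, c))
    return presence, synthesis_errors


def deconvolve(
    observations: Mapping[tuple[str, str, str], Counter],
    scheme: PoolingScheme,
    library: Iterable[str],
    min_reads: int = 5,
    min_fraction: float = 0.005,
    run: int | None = None,
) -> tuple[list[Allocation], Counter]:
    """Deconvolve pooled observations into per-spacer well allocations.

    Only exact matches to designed library members are considered
    ("error-free" calls); everything else is tallied as synthesis errors
    and returned alongside. A spacer counts as present in a pool iff its
    read count is >= min_reads and >= min_fraction of the pool's
    library-matched reads. Per set, candidate wells are the consistent
    intersections of position-pool and group-pool evidence; a spacer is
    ``unique`` iff exactly one candidate exists across all sets,
    ``ambiguous`` for more, ``inconsistent`` when both pool kinds fired
    but no intersection is consistent, and ``absent`` otherwise.
    """
    lib = set(library)
    if run is None:
        if scheme.n_runs() > 1:
            raise ConfigError(
                "scheme spans multiple sequencing runs; barcode triples repeat "
                "across runs, so deconvolve one run at a time (run=...)"
            )
        run = 0
    triple_map = scheme.triple_to_pool(run)
    presence, synthesis_errors = _present_pools(
        observations, triple_map, lib, min_reads, min_fraction
    )

    allocations: list[Allocation] = []
    for spacer in sorted(lib):
        pools = presence.get(spacer, [])
        by_set: dict[int, dict[str, list[tuple[PoolId, int]]]] = defaultdict(
            lambda: {"position": [], "group": []}
        )
        for pool, c in pools:
            by_set[pool.set_index][pool.kind].append((pool, c))
        candidates: list[WellAddress] = []
        pos_reads = grp_reads = 0
        saw_both = False
        for s, kinds in by_set.items():
            P, G = kinds["position"], kinds["group"]
            pos_reads += sum(c for _, c in P)
            grp_reads += sum(c for _, c in G)
            if P and G:
                saw_both = True
            for (p, _), (g, _) in itertools.product(P, G):
                plate, block = scheme.group_pool_address(g.label)
                if scheme.column_block(p.label) == block:
                    candidates.append(WellAddress(s, plate, p.label))
        if len(candidates) == 1:
            status, address = "unique", candidates[0]
        elif len(candidates) > 1:
            status, address = "ambiguous", None
        elif saw_both:
            status, address = "inconsistent", None
        else:
            status, address = "absent", None
        allocations.append(
            Allocation(
                spacer=spacer, status=status, address=address,
                candidates=tuple(candidates),
                position_reads=pos_reads, group_reads=grp_reads,
            )
        )
    return allocations, synthesis_errors


def allocation_report(
    allocations: Sequence[Allocation], library: Iterable[str]
) -> dict:
    """Summary of a deconvolution round: counts, coverage, per-plate map."""
    lib = set(library)
    n_unique = sum(a.status == "unique" for a in allocations)
    per_plate: Counter = Counter()
    for a in allocations:
        if a.status == "unique":
            per_plate[(a.address.set_index + 1, a.address.plate + 1)] += 1
    return {
        "library_size": len(lib),
        "n_unique": n_unique,
        "n_ambiguous": sum(a.status == "ambiguous" for a in allocations),
        "n_inconsistent": sum(a.status == "inconsistent" for a in allocations),
        "n_absent": sum(a.status == "absent" for a in allocations),
        "coverage": n_unique / len(lib) if lib else 0.0,
        "per_plate": dict(per_plate),
    }
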