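"""Projection of regions between species and cross-species sharing calls.

The alignment map abstracts a whole-genome multiple sequence alignment as
pairwise, gap-free colinear blocks: within a block every base of species A
maps 1:1 to a base of species B, either in the same orientation (``+``) or
reflected (``-``).  A region of species A is *shared* with species B when
its projected image overlaps a single B region of the allowed kind by at
least ``min_overlap`` bases (10 bp by default); overlap is summed per
candidate partner across discontiguous projected pieces, never across
partners.

Phylogenetic categories follow the reference-centric scheme: a region
shared in at least three species total is *deeply shared*; shared with at
least one non-primate, *beyond primates*; shared only with the other
primate, *primates only*; otherwise reference-species-only (labelled
``human_only`` for the default human reference).  The exclusive label uses
the precedence deeply_shared > beyond_primates > primates_only >
human_only, while boolean flags preserve the overlapping category reading
(a deeply shared region usually also qualifies as beyond-primates).
"""

from __future__ import annotations

import bisect
import os
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .core import GenomicInterval, RegulatoryRegion, ValidationError


@dataclass(frozen=True)
class Block:
    """One gap-free colinear alignment block between two species."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    strand: str  # '+' same orientation, '-' reflected

    def __post_init__(self) -> None:
        if self.start_a < 0 or self.start_a >= self.end_a:
            raise ValidationError(f"bad block A-interval [{self.start_a}, {self.end_a})")
        if self.start_b < 0:
            raise ValidationError("negative B start")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad block strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end_a - self.start_a

    @property
    def end_b(self) -> int:
        return self.start_b + self.length

    def reverse(self) -> "Block":
        """The same block viewed from species B (reflection is involutive)."""
        return Block(self.chrom_b, self.start_b, self.end_b,
                     self.chrom_a, self.start_a, self.strand)


class AlignmentMap:
    """Pairwise colinear block map with per-chromosome binary-search indexes.

    Blocks are registered for ordered species pairs; adding a block for
    (A, B) automatically registers its reverse for (B, A).  Within a pair
    blocks must be non-overlapping on each side.
    """

    def __init__(self) -> None:
        # (species_a, species_b) -> chrom_a -> sorted list of Block
        self._blocks: dict[tuple[str, str], dict[str, list[Block]]] = {}
        self._starts: dict[tuple[str, str], dict[str, list[int]]] = {}
        self._ends: dict[tuple[str, str], dict[str, list[int]]] = {}
        self._finalized = False

    @property
    def species_pairs(self) -> set[tuple[str, str]]:
        return set(self._blocks)

    def pair_blocks(self, species_a: str, species_b: str) -> list[Block]:
        """All blocks for an ordered pair, in A-coordinate order."""
        self._finalize()
        per_chrom = self._blocks.get((species_a, species_b), {})
        return [b for chrom in sorted(per_chrom) for b in per_chrom[chrom]]

    def register_pair(self, species_a: str, species_b: str) -> None:
        """Declare a species pair with (possibly) no alignable blocks."""
        if species_a == species_b:
            raise ValidationError("a species pair must join two distinct species")
        self._finalized = False
        self._blocks.setdefault((species_a, species_b), {})
        self._blocks.setdefault((species_b, species_a), {})

    def add_block(self, species_a: str, species_b: str, block: Block) -> None:
        if species_a == species_b:
            raise ValidationError("alignment block must join two distinct species")
        self._finalized = False
        self._blocks.setdefault((species_a, species_b), {}).setdefault(
            block.chrom_a, []).append(block)
        rev = block.reverse()
        self._blocks.setdefault((species_b, species_a), {}).setdefault(
            rev.chrom_a, []).append(rev)

    def _finalize(self) -> None:
        if self._finalized:
            return
        self._starts, self._ends = {}, {}
        for pair, per_chrom in self._blocks.items():
            self._starts[pair] = {}
            self._ends[pair] = {}
            for chrom, blocks in per_chrom.items():
                blocks.sort(key=lambda b: b.start_a)
                for prev, cur in zip(blocks, blocks[1:]):
                    if cur.start_a < prev.end_a:
                        raise ValidationError(
                            f"overlapping blocks on {pair} {chrom}: "
                            f"[{prev.start_a},{prev.end_a}) and [{cur.start_a},{cur.end_a})")
                self._starts[pair][chrom] = [b.start_a for b in blocks]
                self._ends[pair][chrom] = [b.end_a for b in blocks]
        self._finalized = True

    def blocks_overlapping(self, iv: GenomicInterval, target: str) -> list[Block]:
        self._finalize()
        pair = (iv.species, target)
        if pair not in self._blocks:
            raise ValidationError(f"no alignment between {iv.species!r} and {target!r}")
        per_chrom = self._blocks[pair]
        if iv.chrom not in per_chrom:
            return []
        blocks = per_chrom[iv.chrom]
        ends = self._ends[pair][iv.chrom]
        starts = self._starts[pair][iv.chrom]
        i = bisect.bisect_right(ends, iv.start)
        out: list[Block] = []
        while i < len(blocks) and starts[i] < iv.end:
            out.append(blocks[i])
            i += 1
        return out


def project_interval(
    iv: GenomicInterval, amap: AlignmentMap, target: str
) -> list[GenomicInterval]:
    """Project an interval through the block map into ``target`` coordinates.

    Returns one target interval per overlapped block (possibly
    discontiguous), each the exact per-base image of the covered
    sub-interval; an empty list if the interval lies outside the alignment.
    """
    if iv.species == target:
        raise ValidationError("projection target equals source species")
    pieces: list[GenomicInterval] = []
    for b in amap.blocks_overlapping(iv, target):
        sub_s = max(iv.start, b.start_a)
        sub_e = min(iv.end, b.end_a)
        if b.strand == "+":
            t_s = b.start_b + (sub_s - b.start_a)
            t_e = b.start_b + (sub_e - b.start_a)
        else:
            t_s = b.start_b + (b.end_a - sub_e)
            t_e = b.start_b + (b.end_a - sub_s)
        pieces.append(GenomicInterval(target, b.chrom_b, t_s, t_e))
    return pieces


@dataclass(frozen=True)
class SharingRecord:
    region_id: str
    target_species: str
    overlap_bp: int
    shared: bool
    matched_region_id: str | None
    alignable: bool


@dataclass(frozen=True)
class PhyloAssignment:
    region_id: str
    shared_with: frozenset[str]
    n_species: int
    category: str          # exclusive label
    deeply_shared: bool    # overlapping-category flags
    beyond_primates: bool
    primates_only: bool


class _RegionIndex:
    """Sorted-interval index over regions of one species/chromosome set."""

    def __init__(self, regions: list[RegulatoryRegion]) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, list[RegulatoryRegion]]] = {}
        per_chrom: dict[str, list[RegulatoryRegion]] = defaultdict(list)
        for r in regions:
            per_chrom[r.chrom].append(r)
        for chrom, rs in per_chrom.items():
            rs.sort(key=lambda r: (r.span.start, r.id))
            starts = np.array([r.span.start for r in rs], dtype=np.int64)
            ends = np.array([r.span.end for r in rs], dtype=np.int64)
            maxend = np.maximum.accumulate(ends)
            self._by_chrom[chrom] = (starts, ends, maxend, rs)

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[RegulatoryRegion, int]]:
        """Regions overlapping [start, end) with per-region overlap in bp."""
        if chrom not in self._by_chrom:
            return []
        starts, ends, maxend, rs = self._by_chrom[chrom]
        hi = int(np.searchsorted(starts, end, side="left"))
        out: list[tuple[RegulatoryRegion, int]] = []
        i = hi - 1
        while i >= 0:
            if maxend[i] <= start:
                break
            if ends[i] > start:
                ov = int(min(ends[i], end) - max(starts[i], start))
                if ov > 0:
                    out.append((rs[i], ov))
            i -= 1
        return out


_MODES = ("crm_vs_crm", "singleton_same_tf", "crm_composition_filter")


def compute_sharing(
    regions_a: list[RegulatoryRegion],
    regions_b: list[RegulatoryRegion],
    amap: AlignmentMap,
    min_overlap: int = 10,
    mode: str = "crm_vs_crm",
    required_tfs: set[str] | frozenset[str] | None = None,
) -> list[SharingRecord]:
    """Decide, for each eligible A region, sharing with species B.

    ``crm_vs_crm`` compares CRMs to CRMs with no constraint on TF content or
    order; ``singleton_same_tf`` compares singletons to singletons bound by
    the identical TF; ``crm_composition_filter`` restricts the A side to
    CRMs containing all of ``required_tfs`` while the B side remains any
    CRM.  One record is emitted per eligible A region.
    """
    if min_overlap < 1:
        raise ValidationError("min_overlap must be >= 1")
    if mode not in _MODES:
        raise ValidationError(f"unknown sharing mode {mode!r}")
    if mode == "crm_composition_filter" and not required_tfs:
        raise ValidationError("crm_composition_filter requires required_tfs")
    if not regions_a:
        return []
    species_a = {r.species for r in regions_a}
    species_b = {r.species for r in regions_b} if regions_b else set()
    if len(species_a) != 1 or len(species_b) > 1:
        raise ValidationError("regions must each come from a single species")
    if species_b and species_a == species_b:
        raise ValidationError("sharing requires two distinct species")

    if mode == "singleton_same_tf":
        eligible_a = [r for r in regions_a if r.kind == "singleton"]
        candidates = [r for r in regions_b if r.kind == "singleton"]
        index_by_tf = {
            tf: _RegionIndex([r for r in candidates if next(iter(r.tf_set)) == tf])
            for tf in {next(iter(r.tf_set)) for r in candidates}
        }
        index = None
    else:
        if mode == "crm_vs_crm":
            eligible_a = [r for r in regions_a if r.kind == "crm"]
        else:
            req = frozenset(required_tfs)  # type: ignore[arg-type]
            eligible_a = [r for r in regions_a if r.kind == "crm" and req <= r.tf_set]
        index = _RegionIndex([r for r in regions_b if r.kind == "crm"])
        index_by_tf = {}

    target = next(iter(species_b)) if species_b else "?"
    records: list[SharingRecord] = []
    for r in eligible_a:
        if mode == "singleton_same_tf":
            tf = next(iter(r.tf_set))
            idx = index_by_tf.get(tf)
        else:
            idx = index
        pieces = project_interval(r.span, amap, target) if species_b else []
        per_partner: dict[str, int] = defaultdict(int)
        for piece in pieces:
            if idx is None:
                continue
            for partner, ov in idx.overlapping(piece.chrom, piece.start, piece.end):
                per_partner[partner.id] += ov
        if per_partner:
            best_id = max(sorted(per_partner), key=lambda k: per_partner[k])
            best_ov = per_partner[best_id]
        else:
            best_id, best_ov = None, 0
        shared = best_ov >= min_overlap
        records.append(SharingRecord(
            region_id=r.id,
            target_species=target,
            overlap_bp=best_ov,
            shared=shared,
            matched_region_id=best_id if shared else None,
            alignable=bool(pieces),
        ))
    return records


def compute_sharing_all(
    regions_a: list[RegulatoryRegion],
    regions_b: list[RegulatoryRegion],
    amap: AlignmentMap,
    min_overlap: int = 10,
) -> list[SharingRecord]:
    """Sharing records for every A region: CRM mode for CRMs, same-TF mode
    for singletons."""
    return (
        compute_sharing(regions_a, regions_b, amap, min_overlap, "crm_vs_crm")
        + compute_sharing(regions_a, regions_b, amap, min_overlap, "singleton_same_tf")
    )


@dataclass(frozen=True)
class PairwiseSharing:
    pct_a_to_b: float | None
    pct_b_to_a: float | None
    average_pct: float | None
    n_alignable_a: int
    n_alignable_b: int


def pairwise_sharing_percent(
    records_ab: list[SharingRecord], records_ba: list[SharingRecord]
) -> PairwiseSharing:
    """Directional and averaged sharing percentages, alignable denominator."""

    def _pct(records: list[SharingRecord]) -> tuple[float | None, int]:
        alignable = [r for r in records if r.alignable]
        if not alignable:
            return None, 0
        return 100.0 * sum(r.shared for r in alignable) / len(alignable), len(alignable)

    pct_ab, n_a = _pct(records_ab)
    pct_ba, n_b = _pct(records_ba)
    if pct_ab is None or pct_ba is None:
        avg = None
    else:
        avg = (pct_ab + pct_ba) / 2.0
    return PairwiseSharing(pct_ab, pct_ba, avg, n_a, n_b)


def assign_phylo_categories(
    regions: list[RegulatoryRegion],
    records_by_species: dict[str, list[SharingRecord]],
    species_roles: dict[str, str],
) -> list[PhyloAssignment]:
    """Assign the phylogenetic category to every reference region.

    ``records_by_species`` maps each non-reference species to the sharing
    records computed against it; ``species_roles`` maps those species to
    ``primate`` / ``non_primate``.  The result order follows ``regions``
    and is invariant to the order species are processed.
    """
    shared_with: dict[str, set[str]] = {r.id: set() for r in regions}
    for sp in sorted(records_by_species):
        if sp not in species_roles:
            raise ValidationError(f"species {sp!r} missing a primate/non_primate role")
        if species_roles[sp] not in ("primate", "non_primate"):
            raise ValidationError(f"bad role {species_roles[sp]!r} for species {sp!r}")
        for rec in records_by_species[sp]:
            if rec.shared and rec.region_id in shared_with:
                shared_with[rec.region_id].add(sp)
    out: list[PhyloAssignment] = []
    for r in regions:
        sw = frozenset(shared_with[r.id])
        n = 1 + len(sw)
        deeply = n >= 3
        beyond = any(species_roles[s] == "non_primate" for s in sw)
        primates_only = bool(sw) and all(species_roles[s] == "primate" for s in sw)
        if deeply:
            label = "deeply_shared"
        elif beyond:
            label = "beyond_primates"
        elif primates_only:
            label = "primates_only"
        else:
            label = "human_only"  # reference-species-only
        out.append(PhyloAssignment(
            region_id=r.id, shared_with=sw, n_species=n, category=label,
            deeply_shared=deeply, beyond_primates=beyond, primates_only=primates_only,
        ))
    return out


def alignability(
    regions: list[RegulatoryRegion], amap: AlignmentMap, target: str
) -> tuple[float, dict[str, bool]]:
    """Fraction of regions with at least one base projectable to ``target``."""
    flags = {
        r.id: bool(project_interval(r.span, amap, target)) for r in regions
    }
    frac = sum(flags.values()) / len(flags) if flags else 0.0
    return frac, flags


def overlap_threshold_sweep(
    regions_a: list[RegulatoryRegion],
    regions_b: list[RegulatoryRegion],
    amap: AlignmentMap,
    thresholds: list[int],
    mode: str = "crm_vs_crm",
    required_tfs: set[str] | None = None,
) -> dict[int, int]:
    """Shared-region counts at each minimum-overlap threshold (ascending)."""
    if thresholds != sorted(thresholds):
        raise ValidationError("thresholds must be sorted ascending")
    out: dict[int, int] = {}
    for t in thresholds:
        records = compute_sharing(regions_a, regions_b, amap, t, mode, required_tfs)
        out[t] = sum(r.shared for r in records)
    return out


# ---------------------------------------------------------------------------
# alignment map I/O: documented 7-column TSV
#   species_a  chrom_a  start_a  end_a  chrom_b  start_b  strand
# with a header line "#pair <species_a> <species_b>" before each pair's rows.


def write_alignment_map(amap: AlignmentMap, path: str | os.PathLike) -> None:
    amap._finalize()
    with open(path, "w") as fh:
        fh.write("#species_a\tchrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tstrand\tspecies_b\n")
        for (sa, sb) in sorted(amap._blocks):
            if sa > sb:
                continue  # each unordered pair stored once; reverse is derived
            for chrom in sorted(amap._blocks[(sa, sb)]):
                for b in amap._blocks[(sa, sb)][chrom]:
                    fh.write(f"{sa}\t{b.chrom_a}\t{b.start_a}\t{b.end_a}\t"
                             f"{b.chrom_b}\t{b.start_b}\t{b.strand}\t{sb}\n")


def read_alignment_map(path: str | os.PathLike) -> AlignmentMap:
    from .core import ParseError

    amap = AlignmentMap()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 8:
                raise ParseError(f"expected 8 columns, got {len(f)}", str(path), lineno)
            sa, ca, s_a, e_a, cb, s_b, strand, sb = f
            amap.add_block(sa, sb, Block(ca, int(s_a), int(e_a), cb, int(s_b), strand))
    return amap
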