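"""Shared fixtures and tiny builders for the test suite.

All fixtures are generated programmatically; nothing is read from disk
except through the package's own writers.
"""

from __future__ import annotations

import numpy as np
import pytest

from crmshare.core import CRM, GenomicInterval, Peak, RegulatoryRegion
from crmshare.cross_species import AlignmentMap, Block


def make_peak(species: str, summit: int, tf: str, pid: str,
              chrom: str = "chr1", halfwidth: int = 50,
              score: float = 1.0) -> Peak:
    return Peak(
        interval=GenomicInterval(species, chrom, max(0, summit - halfwidth),
                                 summit + halfwidth),
        tf=tf, summit=summit, score=score, id=pid)


def make_region(species: str, start: int, end: int, kind: str = "crm",
                tfs: tuple[str, ...] = ("CEBPA", "HNF4A"), rid: str = "r0",
                chrom: str = "chr1") -> RegulatoryRegion:
    span = GenomicInterval(species, chrom, start, end)
    if kind == "crm":
        crm = CRM(id=rid, species=species, members=(), span=span,
                  tf_set=frozenset(tfs), width=end - start)
        return RegulatoryRegion.from_crm(crm)
    peak = Peak(interval=span, tf=tfs[0], summit=(start + end) // 2,
                score=1.0, id=rid)
    return RegulatoryRegion.from_peak(peak)


def identity_map(species_a: str, species_b: str, length: int = 100_000,
                 offset: int = 0, chrom: str = "chr1") -> AlignmentMap:
    """One block covering [0, length) of A, shifted by ``offset`` in B."""
    amap = AlignmentMap()
    amap.add_block(species_a, species_b,
                   Block(chrom, 0, length, chrom, offset, "+"))
    return amap


def random_block_map(rng: np.random.Generator, species_a: str, species_b: str,
                     n_segments: int = 10, seg_len: int = 1000,
                     p_alignable: float = 0.7) -> AlignmentMap:
    """Segmented map: A segment i maps to a shuffled B segment, random strand."""
    amap = AlignmentMap()
    perm = rng.permutation(n_segments)
    for i in range(n_segments):
        if rng.random() < p_alignable:
            strand = "+" if rng.random() < 0.5 else "-"
            amap.add_block(species_a, species_b, Block(
                "chr1", i * seg_len, (i + 1) * seg_len,
                "chr1", int(perm[i]) * seg_len, strand))
    return amap


def perbase_image(amap: AlignmentMap, species_a: str, species_b: str,
                  length: int) -> dict[int, int]:
    """Brute-force per-base projection map A -> B over [0, length)."""
    out: dict[int, int] = {}
    for b in amap.pair_blocks(species_a, species_b):
        for x in range(b.start_a, min(b.end_a, length)):
            if b.strand == "+":
                out[x] = b.start_b + (x - b.start_a)
            else:
                out[x] = b.start_b + (b.end_a - 1 - x)
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(12345))
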