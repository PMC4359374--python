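"""Intersect curated regulatory disease mutations with categorized regions.

Identical allele changes (same ``mutation_id``) are counted once per
region even when the catalog lists them under several diseases.  Per-gene
tables mirror the shape of a "disease variants per region category"
summary: one row per (gene, phylogenetic category) with its unique
mutation count.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .core import MutationRecord, RegulatoryRegion


@dataclass
class MutationOverlap:
    per_region: pd.DataFrame   # region_id, kind, category, n_mutations, mutation_ids, genes
    per_gene: pd.DataFrame     # gene, category, kind, n_mutations
    n_mutations_in_regions: int


def overlap_mutations(
    regions: list[RegulatoryRegion],
    assignments: dict,
    mutations: list[MutationRecord],
) -> MutationOverlap:
    """Per-region and per-gene unique-mutation counts.

    ``assignments`` maps region id to its PhyloAssignment (exclusive
    category labels).  A mutation overlaps a region when its position falls
    inside the half-open region span.
    """
    tree: dict[str, IntervalTree] = {}
    for ri, r in enumerate(regions):
        tree.setdefault(r.chrom, IntervalTree())[r.span.start:r.span.end] = ri

    region_hits: dict[int, dict[str, MutationRecord]] = defaultdict(dict)
    all_hit_ids: set[str] = set()
    for m in mutations:
        t = tree.get(m.chrom)
        if t is None:
            continue
        for iv in t.overlap(m.pos, m.pos + 1):
            region_hits[iv.data][m.mutation_id] = m   # dedup per allele change
            all_hit_ids.add(m.mutation_id)

    region_rows = []
    gene_counts: dict[tuple[str, str, str], set[str]] = defaultdict(set)
    for ri, r in enumerate(regions):
        hits = region_hits.get(ri, {})
        category = assignments[r.id].category if r.id in assignments else "."
        genes = sorted({m.gene for m in hits.values()})
        region_rows.append((r.id, r.kind, category, len(hits),
                            ",".join(sorted(hits)) or ".",
                            ",".join(genes) or "."))
        for mid, m in hits.items():
            gene_counts[(m.gene, category, r.kind)].add(mid)

    per_region = pd.DataFrame(
        region_rows,
        columns=["region_id", "kind", "category", "n_mutations",
                 "mutation_ids", "genes"])
    per_gene = pd.DataFrame(
        [(g, c, k, len(ids)) for (g, c, k), ids in sorted(gene_counts.items())],
        columns=["gene", "category", "kind", "n_mutations"])
    return MutationOverlap(per_region=per_region, per_gene=per_gene,
                           n_mutations_in_regions=len(all_hit_ids))


def category_gene_sets(overlap: MutationOverlap) -> dict[str, list[str]]:
    """Deduplicated gene lists per phylogenetic category (exportable for
    external enrichment tools).  A gene hit in several categories appears
    in each corresponding list."""
    out: dict[str, set[str]] = defaultdict(set)
    for _, row in overlap.per_gene.iterrows():
        out[row["category"]].add(row["gene"])
    return {cat: sorted(genes) for cat, genes in sorted(out.items())}
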