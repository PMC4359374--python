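"""Region annotation: genomic location, nearest gene, expression association,
conservation profiles and binned ChIP signal.

Location labels follow a fixed priority when a region touches several
feature classes: TSS ±3 kb > intron > intergenic > exon.  Nearest-gene
association is measured anchor-to-TSS.  Conservation profiles are anchored
at the CRM span center or the singleton summit.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionRecord, GeneModel, RegulatoryRegion, ValidationError

LOCATION_LABELS = ("tss_3kb", "intron", "intergenic", "exon")


# ---------------------------------------------------------------------------
# conservation track


class ConservationTrack:
    """Sparse per-base conservation scores as sorted constant-value segments.

    Segments must be non-overlapping within a chromosome; positions not
    covered by any segment read back as NaN ("missing").
    """

    def __init__(self, segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._segments = segments
        for chrom, (starts, ends, _) in segments.items():
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"overlapping track segments on {chrom}")

    @classmethod
    def from_rows(cls, rows: list[tuple[str, int, int, float]]) -> "ConservationTrack":
        per_chrom: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
        for chrom, s, e, v in rows:
            per_chrom[chrom].append((s, e, v))
        segments = {}
        for chrom, items in per_chrom.items():
            items.sort()
            starts = np.array([s for s, _, _ in items], dtype=np.int64)
            ends = np.array([e for _, e, _ in items], dtype=np.int64)
            vals = np.array([v for _, _, v in items], dtype=float)
            segments[chrom] = (starts, ends, vals)
        return cls(segments)

    def to_rows(self) -> list[tuple[str, int, int, float]]:
        rows = []
        for chrom in sorted(self._segments):
            starts, ends, vals = self._segments[chrom]
            rows.extend((chrom, int(s), int(e), float(v))
                        for s, e, v in zip(starts, ends, vals))
        return rows

    def values_at(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); NaN where the track has a gap.

        ``start`` may be negative (when a window runs off the chromosome
        edge); such positions are NaN.
        """
        out = np.full(end - start, np.nan)
        if chrom not in self._segments or end <= start:
            return out
        starts, ends, vals = self._segments[chrom]
        pos = np.arange(max(start, 0), end, dtype=np.int64)
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        valid = np.zeros(len(pos), dtype=bool)
        valid[ok] = pos[ok] < ends[idx[ok]]
        out[pos[valid] - start] = vals[idx[valid]]
        return out


# ---------------------------------------------------------------------------
# gene index + location / nearest gene


class GeneIndex:
    """Interval indexes over TSS windows, introns and exons of a gene set."""

    def __init__(self, genes: list[GeneModel], tss_halfwidth: int = 3000):
        self.genes = list(genes)
        self.tss_halfwidth = tss_halfwidth
        self._tss_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._intron_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._exon_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._tss_by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
        per_chrom: dict[str, list[GeneModel]] = defaultdict(list)
        for g in genes:
            per_chrom[g.chrom].append(g)
            lo = max(0, g.tss - tss_halfwidth)
            self._tss_tree[g.chrom][lo:g.tss + tss_halfwidth + 1] = g.gene_id
            for s, e in g.introns:
                self._intron_tree[g.chrom][s:e] = g.gene_id
            for s, e in g.exons:
                self._exon_tree[g.chrom][s:e] = g.gene_id
        for chrom, gs in per_chrom.items():
            gs.sort(key=lambda g: (g.tss, g.gene_id))
            self._tss_by_chrom[chrom] = (
                np.array([g.tss for g in gs], dtype=np.int64),
                [g.gene_id for g in gs],
            )

    def chroms(self) -> set[str]:
        return set(self._tss_by_chrom)


def classify_location(
    region: RegulatoryRegion, genes: GeneIndex | list[GeneModel]
) -> str:
    """Location class of a region under the priority
    TSS±3kb > intron > intergenic > exon."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    span = region.span
    chrom, s, e = span.chrom, span.start, span.end
    if index._tss_tree[chrom].overlap(s, e):
        return "tss_3kb"
    if index._intron_tree[chrom].overlap(s, e):
        return "intron"
    if not index._exon_tree[chrom].overlap(s, e):
        return "intergenic"
    return "exon"


def nearest_gene(
    region: RegulatoryRegion, genes: GeneIndex | list[GeneModel]
) -> tuple[str, int] | None:
    """Gene whose TSS is closest to the region anchor; ties go to the
    lexicographically smaller gene id.  None when the chromosome has no
    gene (the caller is expected to report such exclusions)."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    if region.chrom not in index._tss_by_chrom:
        return None
    tss, ids = index._tss_by_chrom[region.chrom]
    i = int(np.searchsorted(tss, region.anchor))
    cands = [c for c in (i - 1, i) if 0 <= c < len(tss)]
    best = min(cands, key=lambda c: (abs(int(tss[c]) - region.anchor), ids[c]))
    return ids[best], abs(int(tss[best]) - region.anchor)


# ---------------------------------------------------------------------------
# expression association


@dataclass
class ExpressionComparison:
    """Per-(kind x shared-in-N) FPKM summaries plus rank-sum comparisons."""

    summary: pd.DataFrame   # kind, n_species, n, mean_fpkm, median_fpkm
    tests: pd.DataFrame     # comparison, n_species, n_crm, n_singleton, stat, p, p_adj
    n_excluded: int         # regions without a gene association


def expression_by_category(
    assignments: list,
    kinds: dict[str, str],
    nearest: dict[str, str | None],
    expression: list[ExpressionRecord] | pd.DataFrame,
    tissue: str = "liver",
    include_zero_fpkm: bool = True,
) -> ExpressionComparison:
    """Associate regions to nearest-gene FPKM and compare CRMs to singletons.

    ``assignments`` are PhyloAssignments (region_id, n_species); ``kinds``
    maps region id to crm/singleton; ``nearest`` maps region id to gene id
    (None = excluded).  The test is a two-sided Wilcoxon rank-sum per
    shared-in-N stratum plus a pooled deeply-shared-CRM (N>=3) vs all
    singletons comparison, Benjamini-Hochberg adjusted across the family.
    """
    if isinstance(expression, pd.DataFrame):
        expr_df = expression
    else:
        expr_df = pd.DataFrame(
            [(r.gene_id, r.tissue, r.fpkm) for r in expression],
            columns=["gene_id", "tissue", "fpkm"])
    fpkm_map = (expr_df[expr_df["tissue"] == tissue]
                .set_index("gene_id")["fpkm"].to_dict())

    rows = []
    n_excluded = 0
    for a in assignments:
        gene = nearest.get(a.region_id)
        if gene is None or gene not in fpkm_map:
            n_excluded += 1
            continue
        fpkm = fpkm_map[gene]
        if not include_zero_fpkm and fpkm == 0:
            continue
        rows.append((a.region_id, kinds[a.region_id], a.n_species, gene, fpkm))
    df = pd.DataFrame(rows, columns=["region_id", "kind", "n_species", "gene_id", "fpkm"])

    summary = (df.groupby(["kind", "n_species"])["fpkm"]
               .agg(n="size", mean_fpkm="mean", median_fpkm="median")
               .reset_index())

    tests = []
    for n in sorted(df["n_species"].unique()):
        crm = df[(df.kind == "crm") & (df.n_species == n)]["fpkm"].to_numpy()
        sing = df[(df.kind == "singleton") & (df.n_species == n)]["fpkm"].to_numpy()
        tests.append((f"crm_vs_singleton_N{n}", n, len(crm), len(sing),
                      *_ranksum(crm, sing)))
    deep_crm = df[(df.kind == "crm") & (df.n_species >= 3)]["fpkm"].to_numpy()
    all_sing = df[df.kind == "singleton"]["fpkm"].to_numpy()
    tests.append(("deep_crm_vs_singleton", -1, len(deep_crm), len(all_sing),
                  *_ranksum(deep_crm, all_sing)))
    tdf = pd.DataFrame(tests, columns=["comparison", "n_species", "n_crm",
                                       "n_singleton", "stat", "p"])
    mask = tdf["p"].notna()
    tdf["p_adj"] = np.nan
    if mask.any():
        tdf.loc[mask, "p_adj"] = multipletests(tdf.loc[mask, "p"], method="fdr_bh")[1]
    return ExpressionComparison(summary=summary, tests=tdf, n_excluded=n_excluded)


def _ranksum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if len(a) < 2 or len(b) < 2:
        return np.nan, np.nan
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# conservation profile


@dataclass
class ConservationProfile:
    offsets: np.ndarray      # -window .. +window
    mean_score: np.ndarray   # NaN where no region had data at that offset
    n_regions: int
    n_missing: np.ndarray    # per offset, how many regions lacked data


def conservation_profile(
    regions: list[RegulatoryRegion],
    track: ConservationTrack,
    window: int = 1000,
) -> ConservationProfile:
    """Mean per-offset conservation around region anchors (±window bp)."""
    if not regions:
        raise ValidationError("conservation_profile requires at least one region")
    width = 2 * window + 1
    acc = np.zeros(width)
    cnt = np.zeros(width, dtype=np.int64)
    for r in regions:
        vals = track.values_at(r.chrom, r.anchor - window, r.anchor + window + 1)
        good = ~np.isnan(vals)
        acc[good] += vals[good]
        cnt[good] += 1
    mean = np.divide(acc, cnt, out=np.full(width, np.nan), where=cnt > 0)
    return ConservationProfile(
        offsets=np.arange(-window, window + 1),
        mean_score=mean,
        n_regions=len(regions),
        n_missing=len(regions) - cnt,
    )


# ---------------------------------------------------------------------------
# binned ChIP signal


def signal_matrix(
    regions: list[RegulatoryRegion],
    chip_positions: np.ndarray,
    input_positions: np.ndarray,
    bin_size: int = 100,
    window: int = 5000,
) -> np.ndarray:
    """Input-subtracted read counts in fixed bins around region anchors.

    Row order follows the input region order; values are ChIP minus input
    counts per bin and may be negative.
    """
    if window % bin_size != 0:
        raise ValidationError("window must be divisible by bin size")
    chip = np.sort(np.asarray(chip_positions))
    inp = np.sort(np.asarray(input_positions))
    n_bins = 2 * window // bin_size
    out = np.zeros((len(regions), n_bins), dtype=np.int64)
    edges_rel = np.arange(-window, window + bin_size, bin_size)
    for i, r in enumerate(regions):
        edges = r.anchor + edges_rel
        out[i] = np.diff(np.searchsorted(chip, edges)) - \
            np.diff(np.searchsorted(inp, edges))
    return out
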