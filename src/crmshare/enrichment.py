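"""GWAS lead-SNP window construction and region-category enrichment.

Each lead SNP receives a genomic window: a fixed ±halfwidth (2.5 kb by
default), or in LD mode the span of all proxies in linkage disequilibrium
with it (r² ≥ 0.8, proxies capped at ±100 kb).  Overlapping windows are
collapsed into one interval whose trait set is deduplicated, so identical
disease traits of co-located lead SNPs count once.

Enrichment of a region category c for a trait t is an upper-tail
hypergeometric test: among the n regions overlapping any window carrying
t, x fall in category c, out of K category members in a population of N
regions (all CRMs + singletons of the reference species).  Bonferroni
correction spans every (category × trait) pair tested in a run.

Two empirical null models calibrate the hypergeometric p-values: (1)
shuffling the SNP trait annotation across lead SNPs, and (2) redrawing a
positionally random SNP set matched on minor allele frequency and distance
to the nearest TSS.  An enrichment is flagged significant by a null model
when fewer than 5 % of its null p-values are at or below the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .core import GeneModel, GenomicInterval, LeadSNP, RegulatoryRegion, ValidationError


# ---------------------------------------------------------------------------
# windows


@dataclass(frozen=True)
class SNPWindow:
    interval: GenomicInterval
    traits: frozenset[tuple[str, str]]   # (disease_trait, summary_category), deduped
    member_snps: tuple[str, ...]


def _snp_interval(snp: LeadSNP, mode: str, halfwidth: int, r2_min: float,
                  ld_fallback_fixed: bool) -> tuple[int, int]:
    if mode == "fixed":
        return max(0, snp.pos - halfwidth), snp.pos + halfwidth + 1
    positions = [snp.pos] + [p for p, r2 in snp.proxies if r2 >= r2_min]
    if len(positions) == 1 and ld_fallback_fixed:
        return max(0, snp.pos - halfwidth), snp.pos + halfwidth + 1
    return min(positions), max(positions) + 1


def build_snp_windows(
    snps: list[LeadSNP],
    mode: str = "fixed",
    halfwidth: int = 2500,
    r2_min: float = 0.8,
    ld_fallback_fixed: bool = False,
) -> list[SNPWindow]:
    """Per-SNP windows, merged where they overlap, with trait-set dedup.

    In LD mode a lead SNP without qualifying proxies degenerates to a 1 bp
    interval (``ld_fallback_fixed=True`` switches to the fixed window
    instead).  Merging is idempotent.
    """
    if halfwidth < 0:
        raise ValidationError("halfwidth must be >= 0")
    if mode not in ("fixed", "ld"):
        raise ValidationError(f"unknown window mode {mode!r}")
    raw: list[tuple[str, int, int, LeadSNP]] = []
    for s in snps:
        lo, hi = _snp_interval(s, mode, halfwidth, r2_min, ld_fallback_fixed)
        raw.append((s.chrom, lo, hi, s))
    raw.sort(key=lambda t: (t[0], t[1], t[2], t[3].rsid))
    windows: list[SNPWindow] = []
    cur: list[tuple[str, int, int, LeadSNP]] = []

    def _flush() -> None:
        if not cur:
            return
        chrom = cur[0][0]
        lo = min(t[1] for t in cur)
        hi = max(t[2] for t in cur)
        traits = frozenset((t[3].disease_trait, t[3].summary_category) for t in cur)
        members = tuple(sorted(t[3].rsid for t in cur))
        windows.append(SNPWindow(
            interval=GenomicInterval("_", chrom, lo, hi),
            traits=traits, member_snps=members))

    for item in raw:
        if cur and item[0] == cur[0][0] and item[1] < max(t[2] for t in cur):
            cur.append(item)
        else:
            _flush()
            cur = [item]
    _flush()
    return windows


# ---------------------------------------------------------------------------
# hypergeometric enrichment


def hypergeom_pvalue(x: int, K: int, n: int, N: int) -> float:
    """Upper-tail P[X >= x] for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(x - 1, N, K, n))


@dataclass
class EnrichmentResult:
    category: str            # "<phylo label>:<kind>"
    trait: str
    x: int                   # category regions overlapping trait windows
    K: int                   # category size
    n: int                   # regions overlapping trait windows
    N: int                   # all regions
    fold: float
    p: float
    p_bonferroni: float
    null_significant: dict[str, bool] = field(default_factory=dict)


def _region_categories(regions: list[RegulatoryRegion], assignments: dict) -> list[str]:
    cats = []
    for r in regions:
        a = assignments[r.id]
        cats.append(f"{a.category}:{r.kind}")
    return cats


def _grouping_index(grouping: str) -> int:
    if grouping == "disease_trait":
        return 0
    if grouping == "summary_category":
        return 1
    raise ValidationError(f"unknown trait grouping {grouping!r}")


def hypergeometric_enrichment(
    regions: list[RegulatoryRegion],
    assignments: dict,
    windows: list[SNPWindow],
    grouping: str = "summary_category",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment per (category × trait) pair.

    ``assignments`` maps region id to its PhyloAssignment.  Pairs whose
    trait windows overlap no region at all (n = 0) are omitted.
    """
    gi = _grouping_index(grouping)
    N = len(regions)
    cats = _region_categories(regions, assignments)
    cat_sizes: dict[str, int] = {}
    for c in cats:
        cat_sizes[c] = cat_sizes.get(c, 0) + 1

    tree: dict[str, IntervalTree] = {}
    for wi, w in enumerate(windows):
        tree.setdefault(w.interval.chrom, IntervalTree())[
            w.interval.start:w.interval.end] = wi

    trait_regions: dict[str, set[int]] = {}
    for ri, r in enumerate(regions):
        t = tree.get(r.chrom)
        if t is None:
            continue
        for iv in t.overlap(r.span.start, r.span.end):
            for trait_pair in windows[iv.data].traits:
                trait_regions.setdefault(trait_pair[gi], set()).add(ri)

    results: list[EnrichmentResult] = []
    for trait in sorted(trait_regions):
        rset = trait_regions[trait]
        n = len(rset)
        per_cat: dict[str, int] = {}
        for ri in rset:
            per_cat[cats[ri]] = per_cat.get(cats[ri], 0) + 1
        for cat in sorted(cat_sizes):
            K = cat_sizes[cat]
            x = per_cat.get(cat, 0)
            p = hypergeom_pvalue(x, K, n, N)
            fold = (x / n) / (K / N)
            results.append(EnrichmentResult(
                category=cat, trait=trait, x=x, K=K, n=n, N=N,
                fold=fold, p=p, p_bonferroni=p))
    n_tests = len(results)
    for r in results:
        r.p_bonferroni = min(1.0, r.p * n_tests)
    return results


# ---------------------------------------------------------------------------
# shared machinery for the null models


def _snp_region_pairs(
    regions: list[RegulatoryRegion],
    positions: np.ndarray,
    chroms: list[str],
    halfwidths_lo: np.ndarray,
    halfwidths_hi: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(snp_idx, region_idx) pairs where the SNP window overlaps the region."""
    tree: dict[str, IntervalTree] = {}
    for ri, r in enumerate(regions):
        tree.setdefault(r.chrom, IntervalTree())[r.span.start:r.span.end] = ri
    ps, pr = [], []
    for si in range(len(positions)):
        t = tree.get(chroms[si])
        if t is None:
            continue
        lo = positions[si] - halfwidths_lo[si]
        hi = positions[si] + halfwidths_hi[si]
        for iv in t.overlap(int(lo), int(hi)):
            ps.append(si)
            pr.append(iv.data)
    return np.array(ps, dtype=np.int64), np.array(pr, dtype=np.int64)


def _snp_window_extents(snps: list[LeadSNP], mode: str, halfwidth: int,
                        r2_min: float, ld_fallback_fixed: bool
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    pos = np.array([s.pos for s in snps], dtype=np.int64)
    lo = np.zeros(len(snps), dtype=np.int64)
    hi = np.zeros(len(snps), dtype=np.int64)
    for i, s in enumerate(snps):
        a, b = _snp_interval(s, mode, halfwidth, r2_min, ld_fallback_fixed)
        lo[i] = s.pos - a
        hi[i] = b - s.pos
    return pos, lo, hi, [s.chrom for s in snps]


def _counts_for_labels(
    label_codes: np.ndarray,
    pair_snp: np.ndarray,
    pair_region: np.ndarray,
    cat_codes: np.ndarray,
    n_traits: int,
    n_cats: int,
    n_regions: int,
) -> tuple[np.ndarray, np.ndarray]:
    """n (per trait) and x (per category × trait) from incidence pairs."""
    key = label_codes[pair_snp].astype(np.int64) * n_regions + pair_region
    u = np.unique(key)
    t_u = (u // n_regions).astype(np.int64)
    r_u = (u % n_regions).astype(np.int64)
    n_t = np.bincount(t_u, minlength=n_traits)
    x = np.zeros((n_cats, n_traits), dtype=np.int64)
    np.add.at(x, (cat_codes[r_u], t_u), 1)
    return n_t, x


@dataclass
class NullModelResult:
    observed_p: float
    frac_null_le: float    # add-one empirical p: (1 + #{null <= obs}) / (1 + B)
    significant: bool


def _flag_results(
    obs_p: np.ndarray,        # (C, T)
    null_p: np.ndarray,       # (iters, C, T)
    cat_names: list[str],
    trait_names: list[str],
    tested: np.ndarray,       # (C, T) bool: observed n > 0
) -> dict[tuple[str, str], NullModelResult]:
    # add-one convention: the observed sample counts as one more draw from
    # the null, which keeps the flag rate strictly below the nominal level
    # under a true null even for perfectly continuous p-values
    n_iter = null_p.shape[0]
    frac = (1.0 + np.sum(null_p <= obs_p[None, :, :] + 1e-12, axis=0)) / (1.0 + n_iter)
    out: dict[tuple[str, str], NullModelResult] = {}
    for ci, cat in enumerate(cat_names):
        for ti, trait in enumerate(trait_names):
            if not tested[ci, ti]:
                continue
            out[(cat, trait)] = NullModelResult(
                observed_p=float(obs_p[ci, ti]),
                frac_null_le=float(frac[ci, ti]),
                significant=bool(frac[ci, ti] < 0.05),
            )
    return out


def _label_codes(snps: list[LeadSNP], grouping: str) -> tuple[np.ndarray, list[str]]:
    gi = _grouping_index(grouping)
    labels = [(s.disease_trait, s.summary_category)[gi] for s in snps]
    names = sorted(set(labels))
    lookup = {t: i for i, t in enumerate(names)}
    return np.array([lookup[t] for t in labels], dtype=np.int64), names


def _vector_hypergeom_sf(x: np.ndarray, N: int, K: np.ndarray, n: np.ndarray) -> np.ndarray:
    return stats.hypergeom.sf(x - 1, N, K, n)


def null_shuffle_labels(
    snps: list[LeadSNP],
    regions: list[RegulatoryRegion],
    assignments: dict,
    n_iter: int = 1000,
    seed: int = 0,
    mode: str = "fixed",
    halfwidth: int = 2500,
    r2_min: float = 0.8,
    grouping: str = "summary_category",
) -> dict[tuple[str, str], NullModelResult]:
    """Trait-shuffle null: permute the SNP trait annotation ``n_iter`` times
    and recompute every (category × trait) hypergeometric p-value.

    A pair is flagged significant when fewer than 5 % of null p-values are
    at or below the observed one.
    """
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} gives a coarse null; >=100 recommended",
                      stacklevel=2)
    rng = np.random.Generator(np.random.PCG64(seed))
    labels, trait_names = _label_codes(snps, grouping)
    cats = _region_categories(regions, assignments)
    cat_names = sorted(set(cats))
    cat_codes = np.array([cat_names.index(c) for c in cats], dtype=np.int64)
    C, T, NR = len(cat_names), len(trait_names), len(regions)
    K = np.bincount(cat_codes, minlength=C)

    pos, lo, hi, chroms = _snp_window_extents(snps, mode, halfwidth, r2_min, False)
    ps, pr = _snp_region_pairs(regions, pos, chroms, lo, hi)

    n_obs, x_obs = _counts_for_labels(labels, ps, pr, cat_codes, T, C, NR)
    obs_p = _vector_hypergeom_sf(x_obs, NR, K[:, None], n_obs[None, :])

    n_null = np.zeros((n_iter, T), dtype=np.int64)
    x_null = np.zeros((n_iter, C, T), dtype=np.int64)
    for it in range(n_iter):
        perm = rng.permutation(labels)
        n_null[it], x_null[it] = _counts_for_labels(perm, ps, pr, cat_codes, T, C, NR)
    null_p = _vector_hypergeom_sf(
        x_null, NR, K[None, :, None], n_null[:, None, :])
    tested = np.broadcast_to(n_obs[None, :] > 0, (C, T))
    return _flag_results(obs_p, null_p, cat_names, trait_names, tested)


def _nearest_tss_distance(positions: np.ndarray, genes: list[GeneModel]) -> np.ndarray:
    tss = np.sort(np.array([g.tss for g in genes], dtype=np.int64))
    idx = np.searchsorted(tss, positions)
    left = np.abs(positions - tss[np.clip(idx - 1, 0, len(tss) - 1)])
    right = np.abs(positions - tss[np.clip(idx, 0, len(tss) - 1)])
    return np.minimum(left, right)


def _gather_rows(indptr: np.ndarray, indices: np.ndarray,
                 ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate indices[indptr[i]:indptr[i+1]] for i in ids, with owners."""
    starts = indptr[ids]
    lens = indptr[ids + 1] - starts
    total = int(lens.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lens)[:-1]])
    flat = np.arange(total, dtype=np.int64) - np.repeat(cum, lens) + np.repeat(starts, lens)
    owners = np.repeat(np.arange(len(ids), dtype=np.int64), lens)
    return indices[flat], owners


def null_matched_snps(
    snps: list[LeadSNP],
    snp_universe: list[LeadSNP],
    genes: list[GeneModel],
    regions: list[RegulatoryRegion],
    assignments: dict,
    n_iter: int = 1000,
    seed: int = 0,
    halfwidth: int = 2500,
    maf_bins: np.ndarray | None = None,
    tss_dist_bins: np.ndarray | None = None,
    grouping: str = "summary_category",
) -> dict[tuple[str, str], NullModelResult]:
    """Matched-SNP null: each iteration redraws, per lead SNP, a universe
    SNP from the same (MAF × TSS-distance) bin, without replacement within
    an iteration, and recomputes the enrichment p-values.

    Matched SNPs carry no LD proxies, so windows are fixed ±halfwidth on
    both the observed and null side of this comparison.  Empty matching
    bins fall back to the nearest non-empty bin (with a warning).
    """
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} gives a coarse null; >=100 recommended",
                      stacklevel=2)
    rng = np.random.Generator(np.random.PCG64(seed))
    maf_bins = np.asarray(maf_bins if maf_bins is not None
                          else [0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
    tss_dist_bins = np.asarray(tss_dist_bins if tss_dist_bins is not None
                               else [0, 2_000, 10_000, 50_000, 200_000, np.inf])

    labels, trait_names = _label_codes(snps, grouping)
    cats = _region_categories(regions, assignments)
    cat_names = sorted(set(cats))
    cat_codes = np.array([cat_names.index(c) for c in cats], dtype=np.int64)
    C, T, NR = len(cat_names), len(trait_names), len(regions)
    K = np.bincount(cat_codes, minlength=C)

    def _bin_ids(some: list[LeadSNP]) -> np.ndarray:
        pos = np.array([s.pos for s in some], dtype=np.int64)
        maf = np.array([s.maf for s in some])
        mb = np.clip(np.digitize(maf, maf_bins) - 1, 0, len(maf_bins) - 2)
        tb = np.clip(np.digitize(_nearest_tss_distance(pos, genes), tss_dist_bins) - 1,
                     0, len(tss_dist_bins) - 2)
        return mb * (len(tss_dist_bins) - 1) + tb

    real_bins = _bin_ids(snps)
    uni_bins = _bin_ids(snp_universe)
    n_tb = len(tss_dist_bins) - 1
    uni_by_bin: dict[int, np.ndarray] = {
        int(b): np.nonzero(uni_bins == b)[0] for b in np.unique(uni_bins)}

    def _resolve_bin(b: int) -> np.ndarray:
        if b in uni_by_bin:
            return uni_by_bin[b]
        mb, tb = divmod(b, n_tb)
        best = min(uni_by_bin, key=lambda o: abs(o // n_tb - mb) + abs(o % n_tb - tb))
        warnings.warn(f"empty matching bin {b}; falling back to bin {best}",
                      stacklevel=2)
        return uni_by_bin[best]

    # observed (fixed windows, consistent with the null side)
    pos, lo, hi, chroms = _snp_window_extents(snps, "fixed", halfwidth, 0.8, False)
    ps, pr = _snp_region_pairs(regions, pos, chroms, lo, hi)
    n_obs, x_obs = _counts_for_labels(labels, ps, pr, cat_codes, T, C, NR)
    obs_p = _vector_hypergeom_sf(x_obs, NR, K[:, None], n_obs[None, :])

    # universe incidence (CSR over universe snps)
    upos = np.array([s.pos for s in snp_universe], dtype=np.int64)
    uchroms = [s.chrom for s in snp_universe]
    uhw = np.full(len(snp_universe), halfwidth, dtype=np.int64)
    ups, upr = _snp_region_pairs(regions, upos, uchroms, uhw, uhw + 1)
    order = np.argsort(ups, kind="stable")
    ups, upr = ups[order], upr[order]
    indptr = np.searchsorted(ups, np.arange(len(snp_universe) + 1))

    n_null = np.zeros((n_iter, T), dtype=np.int64)
    x_null = np.zeros((n_iter, C, T), dtype=np.int64)
    bin_members = {int(b): np.nonzero(real_bins == b)[0] for b in np.unique(real_bins)}
    bin_pool = {b: _resolve_bin(b) for b in bin_members}
    sampled = np.zeros(len(snps), dtype=np.int64)
    for it in range(n_iter):
        for b, members in bin_members.items():
            pool = bin_pool[b]
            replace = len(pool) < len(members)
            sampled[members] = rng.choice(pool, size=len(members), replace=replace)
        regs, owners = _gather_rows(indptr, upr, sampled)
        n_null[it], x_null[it] = _counts_for_labels(
            labels, owners, regs, cat_codes, T, C, NR)
    null_p = _vector_hypergeom_sf(
        x_null, NR, K[None, :, None], n_null[:, None, :])
    tested = np.broadcast_to(n_obs[None, :] > 0, (C, T))
    return _flag_results(obs_p, null_p, cat_names, trait_names, tested)


# ---------------------------------------------------------------------------
# randomized-overlap Z-test (generic: e.g. region sets vs external peak sets)


@dataclass
class OverlapZTest:
    observed: int
    null_mean: float
    null_sd: float
    z: float | None
    p: float | None
    degenerate: bool


def randomized_overlap_ztest(
    query_regions: list[RegulatoryRegion],
    reference_intervals: list[GenomicInterval],
    universe: list[GenomicInterval],
    n_iter: int = 1000,
    seed: int = 0,
) -> OverlapZTest:
    """Observed vs randomized overlap count with a normal-approximation p.

    Each iteration re-places every query region, width-preserved, uniformly
    within the allowed universe intervals (e.g. open-chromatin regions) and
    counts how many placements overlap the reference set by >=1 bp.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    ref = sorted((iv.start, iv.end) for iv in reference_intervals)
    merged: list[list[int]] = []
    for s, e in ref:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    rs = np.array([m[0] for m in merged], dtype=np.int64)
    re_ = np.array([m[1] for m in merged], dtype=np.int64)

    def _overlaps(starts: np.ndarray, widths: np.ndarray) -> np.ndarray:
        if len(rs) == 0:
            return np.zeros(len(starts), dtype=bool)
        idx = np.searchsorted(rs, starts + widths) - 1
        ok = idx >= 0
        res = np.zeros(len(starts), dtype=bool)
        res[ok] = re_[np.clip(idx[ok], 0, len(re_) - 1)] > starts[ok]
        return res

    q_starts = np.array([r.span.start for r in query_regions], dtype=np.int64)
    widths = np.array([len(r.span) for r in query_regions], dtype=np.int64)
    observed = int(_overlaps(q_starts, widths).sum())

    u_start = np.array([u.start for u in universe], dtype=np.int64)
    u_len = np.array([len(u) for u in universe], dtype=np.int64)
    null_counts = np.zeros(n_iter, dtype=np.int64)
    for qi in range(len(query_regions)):
        w = int(widths[qi])
        slots = u_len - w + 1
        ok = slots > 0
        if not ok.any():
            raise ValidationError(
                f"no universe interval can hold a region of width {w}")
        weights = np.where(ok, slots, 0).astype(float)
        cum = np.cumsum(weights)
        draw = rng.random(n_iter) * cum[-1]
        which = np.searchsorted(cum, draw, side="right")
        offs = (rng.random(n_iter) * slots[which]).astype(np.int64)
        starts = u_start[which] + offs
        null_counts += _overlaps(starts, np.full(n_iter, w, dtype=np.int64))

    mean = float(null_counts.mean())
    sd = float(null_counts.std(ddof=1)) if n_iter > 1 else 0.0
    if sd == 0.0:
        return OverlapZTest(observed=observed, null_mean=mean, null_sd=sd,
                            z=None, p=None, degenerate=True)
    z = (observed - mean) / sd
    return OverlapZTest(observed=observed, null_mean=mean, null_sd=sd,
                        z=z, p=float(stats.norm.sf(z)), degenerate=False)
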