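"""Synthetic multi-species study generator.

Every input the pipeline consumes — peak calls in five species, a pairwise
colinear alignment map, gene models, expression tables, a GWAS lead-SNP
catalog with LD proxies, a regulatory-mutation catalog, a conservation
track, ChIP/input read positions and region sequences — is generated here
with planted statistical structure, so each downstream stage can be tested
against known ground truth without any external data.

The default configuration emulates the real study's shape at desk scale:
five species (two primates, two rodents, one carnivore outgroup), four
liver TFs, ~35 % reference–macaque sharing and ~15 % reference–non-primate
sharing (which yields a deeply-shared fraction close to the real study's
16 %), elevated liver expression near deeply shared CRMs, liver-category
GWAS SNPs placed near deeply shared CRMs at a configurable multiple of the
chance rate, mutations inside shared CRMs, and elevated conservation
scores over shared regions.

Randomness is split into one child stream per output type (all derived
from the master seed), so changing e.g. the number of genes cannot perturb
peak placement.  Same seed, same config => byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import ConservationTrack
from .core import (
    ConfigError,
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    LeadSNP,
    MutationRecord,
    Peak,
    RegulatoryRegion,
)
from .cross_species import AlignmentMap, Block, project_interval
from .motifs import PWM

_DEFAULT_SPECIES = ("human", "macaque", "dog", "mouse", "rat")
_DEFAULT_ROLES = {
    "human": "primate", "macaque": "primate",
    "dog": "non_primate", "mouse": "non_primate", "rat": "non_primate",
}
_DEFAULT_TFS = ("CEBPA", "HNF4A", "FOXA1", "ONECUT1")

_GWAS_CATEGORIES = (
    "liver", "blood lipid", "drug response", "cancer", "immune system",
    "diabetes", "cardiovascular", "blood", "bone", "brain", "kidney",
    "lung", "obesity", "blood pressure", "eye", "skin", "hair",
    "reproduction", "aging", "infection", "psychiatric", "addiction",
    "other measurement", "other disease", "other trait",
)

# consensus strings for the four bundled synthetic liver-TF motifs
_CONSENSI = {
    "CEBPA": "TTGCACAATC",
    "HNF4A": "GGGTCAAAGG",
    "FOXA1": "TGTTTACTTA",
    "ONECUT1": "AATCGATTGC",
}

# stream order for SeedSequence.spawn; fixed so outputs are independent
_STREAMS = ("alignment", "peaks", "genes_expression", "gwas", "mutations",
            "conservation", "reads", "sequences")


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study.  Defaults are the study conditions."""

    seed: int = 0
    species: tuple[str, ...] = _DEFAULT_SPECIES
    species_roles: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_ROLES))
    reference: str = "human"
    # planted P(reference site also occupied in the other species)
    species_tree: dict[tuple[str, str], float] = field(default_factory=lambda: {
        ("human", "macaque"): 0.35,
        ("human", "dog"): 0.15,
        ("human", "mouse"): 0.15,
        ("human", "rat"): 0.15,
    })
    tfs: tuple[str, ...] = _DEFAULT_TFS
    genome_length: int = 25_000_000
    n_crm_sites: int = 1600
    n_singleton_sites: int = 900
    n_background_sites: int = 150          # per non-reference species
    crm_tf_count_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.55, 3: 0.30, 4: 0.15})
    summit_jitter_sd: float = 20.0
    peak_halfwidth_range: tuple[int, int] = (100, 300)
    n_genes: int = 2000
    tissues: tuple[str, ...] = ("liver", "kidney", "brain", "heart")
    liver_fpkm_boost: float = 4.0
    n_gwas_snps: int = 3000
    liver_snp_enrichment: float = 3.0
    liver_category_weight: float = 0.2
    snp_window_halfwidth: int = 2500
    universe_factor: int = 20              # universe size = factor * n_gwas_snps
    n_mutations: int = 300
    mutation_shared_fraction: float = 0.7
    gerp_shared_mean: float = 2.0
    gerp_background_mean: float = 0.0
    gerp_sd: float = 0.5
    gerp_resolution: int = 10
    gerp_flank: int = 1200
    alignment_block_length_mean: int = 2000
    alignable_fraction: float = 0.9
    inversion_prob: float = 0.1
    reads_per_peak: int = 15

    # site-placement grid: one site per 5 kb cell keeps planted sites from
    # clustering with each other
    _CELL: int = 5000

    def validate(self) -> None:
        for (_, _), p in self.species_tree.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"sharing probability out of [0,1]: {p}")
        if not 0.0 <= self.alignable_fraction <= 1.0:
            raise ConfigError("alignable_fraction must be in [0, 1]")
        if abs(sum(self.crm_tf_count_distribution.values()) - 1.0) > 1e-9:
            raise ConfigError("crm_tf_count_distribution must sum to 1")
        if self.liver_fpkm_boost <= 0 or self.liver_snp_enrichment <= 0:
            raise ConfigError("effect sizes must be > 0")
        for n in (self.n_crm_sites, self.n_singleton_sites, self.n_genes,
                  self.n_gwas_snps, self.n_mutations, self.n_background_sites):
            if n < 0:
                raise ConfigError("counts must be >= 0")
        n_cells = self.genome_length // self._CELL - 2
        if self.n_crm_sites + self.n_singleton_sites > n_cells:
            raise ConfigError(
                f"genome of {self.genome_length} bp has room for {n_cells} sites, "
                f"{self.n_crm_sites + self.n_singleton_sites} requested")
        if self.reference not in self.species:
            raise ConfigError(f"reference {self.reference!r} not in species list")

    # species coordinate offsets make per-species coordinates differ so
    # projection arithmetic is actually exercised
    def species_offset(self, sp: str) -> int:
        return 1000 * self.species.index(sp)

    def genome_length_of(self, sp: str) -> int:
        return self.genome_length + self.species_offset(sp)

    def sharing_prob(self, other: str) -> float:
        for (a, b), p in self.species_tree.items():
            if {a, b} == {self.reference, other}:
                return p
        return 0.0

    def rng(self, stream: str) -> np.random.Generator:
        idx = _STREAMS.index(stream)
        return np.random.Generator(np.random.PCG64(
            np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[idx]))


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, seed=seed)


# ---------------------------------------------------------------------------
# alignment map


def simulate_alignment_map(cfg: SimConfig) -> AlignmentMap:
    """Colinear gap-free block map over all species pairs.

    A single ancestral coordinate system is tiled into segments; each
    segment is alignable (for every pair, consistently) with probability
    ``alignable_fraction``, and each species may carry it inverted with
    probability ``inversion_prob``.  Consistency across pairs means a site
    projected reference->A and reference->B lands where A->B projection
    expects it.
    """
    cfg.validate()
    rng = cfg.rng("alignment")
    L = cfg.genome_length
    mean = cfg.alignment_block_length_mean

    lengths: list[int] = []
    total = 0
    while total < L:
        ln = int(rng.uniform(0.5 * mean, 1.5 * mean))
        ln = min(ln, L - total)
        lengths.append(ln)
        total += ln
    starts = np.concatenate([[0], np.cumsum(lengths[:-1])]).astype(np.int64)
    ends = starts + np.array(lengths, dtype=np.int64)
    n_seg = len(lengths)

    alignable = rng.random(n_seg) < cfg.alignable_fraction
    flipped = rng.random((n_seg, len(cfg.species))) < cfg.inversion_prob

    amap = AlignmentMap()
    for i, sa in enumerate(cfg.species):
        for j in range(i + 1, len(cfg.species)):
            sb = cfg.species[j]
            amap.register_pair(sa, sb)
            da, db = cfg.species_offset(sa), cfg.species_offset(sb)
            for k in np.nonzero(alignable)[0]:
                strand = "+" if flipped[k, i] == flipped[k, j] else "-"
                amap.add_block(sa, sb, Block(
                    "chr1", int(starts[k]) + da, int(ends[k]) + da,
                    "chr1", int(starts[k]) + db, strand))
    return amap


# ---------------------------------------------------------------------------
# peaks


def simulate_peaks(
    cfg: SimConfig, amap: AlignmentMap
) -> tuple[dict[str, list[Peak]], pd.DataFrame]:
    """Plant CRM and singleton sites in the reference and their orthologs.

    Returns per-species peak lists and the ground-truth table: one row per
    planted reference site with its TF content, reference span, and
    per-species occupancy/alignability, sufficient to recompute every
    planted quantity without re-reading generated files.
    """
    cfg.validate()
    rng = cfg.rng("peaks")
    ref = cfg.reference
    others = [s for s in cfg.species if s != ref]
    L = cfg.genome_length
    cell = cfg._CELL
    n_sites = cfg.n_crm_sites + cfg.n_singleton_sites

    usable_cells = np.arange(1, L // cell - 1)
    chosen = rng.choice(usable_cells, size=n_sites, replace=False)
    anchors = chosen * cell + rng.integers(1000, 3000, size=n_sites)
    kinds = np.array(["crm"] * cfg.n_crm_sites + ["singleton"] * cfg.n_singleton_sites)

    tf_counts = rng.choice(
        sorted(cfg.crm_tf_count_distribution),
        size=n_sites,
        p=[cfg.crm_tf_count_distribution[k] for k in sorted(cfg.crm_tf_count_distribution)],
    )
    probs = {sp: cfg.sharing_prob(sp) for sp in others}
    occupied = {sp: rng.random(n_sites) < probs[sp] for sp in others}

    hw_lo, hw_hi = cfg.peak_halfwidth_range
    peaks: dict[str, list[Peak]] = {sp: [] for sp in cfg.species}
    rows: list[dict] = []

    def _place_site(sp: str, site_id: str, anchor: int, tf_list: list[str]) -> tuple[int, int]:
        """Emit one peak per TF around the anchor; returns the site span."""
        Ls = cfg.genome_length_of(sp)
        k = len(tf_list)
        offsets = (np.arange(k) - (k - 1) / 2.0) * 100.0
        span_s, span_e = None, None
        for tf, off in zip(tf_list, offsets):
            summit = int(round(anchor + off + rng.normal(0.0, cfg.summit_jitter_sd)))
            hw = int(rng.integers(hw_lo, hw_hi + 1))
            start = max(0, summit - hw)
            end = min(Ls, summit + hw)
            if not (start <= summit < end):
                continue
            peaks[sp].append(Peak(
                interval=GenomicInterval(sp, "chr1", start, end),
                tf=tf, summit=summit,
                score=float(np.exp(rng.normal(2.0, 1.0))),
                id=f"{sp}_{site_id}_{tf}",
            ))
            span_s = start if span_s is None else min(span_s, start)
            span_e = end if span_e is None else max(span_e, end)
        return span_s if span_s is not None else anchor, \
            span_e if span_e is not None else anchor + 1

    for i in range(n_sites):
        site_id = f"site_{i:05d}"
        anchor = int(anchors[i])
        if kinds[i] == "crm":
            tf_list = [cfg.tfs[t] for t in rng.permutation(len(cfg.tfs))[: tf_counts[i]]]
        else:
            tf_list = [cfg.tfs[int(rng.integers(len(cfg.tfs)))]]
        span_s, span_e = _place_site(ref, site_id, anchor, tf_list)
        row: dict = {
            "site_id": site_id, "kind": kinds[i], "anchor": anchor,
            "span_start": span_s, "span_end": span_e, "tfs": "|".join(tf_list),
        }
        n_shared = 0
        for sp in others:
            pieces = project_interval(
                GenomicInterval(ref, "chr1", anchor, anchor + 1), amap, sp)
            is_alignable = bool(pieces)
            occ = bool(occupied[sp][i])
            row[f"alignable_{sp}"] = is_alignable
            row[f"occupied_{sp}"] = occ
            if occ and is_alignable:
                n_shared += 1
                _place_site(sp, site_id, pieces[0].start, tf_list)
        row["n_species_truth"] = 1 + n_shared
        row["shared_truth"] = n_shared >= 1
        row["deep_truth"] = n_shared >= 2
        rows.append(row)

    # species-specific background sites (never recorded as shared truth)
    for sp in others:
        Ls = cfg.genome_length_of(sp)
        for j in range(cfg.n_background_sites):
            anchor = int(rng.integers(5000, Ls - 5000))
            if rng.random() < 0.6:
                k = int(rng.choice(sorted(cfg.crm_tf_count_distribution),
                                   p=[cfg.crm_tf_count_distribution[x]
                                      for x in sorted(cfg.crm_tf_count_distribution)]))
                tf_list = [cfg.tfs[t] for t in rng.permutation(len(cfg.tfs))[:k]]
            else:
                tf_list = [cfg.tfs[int(rng.integers(len(cfg.tfs)))]]
            _place_site(sp, f"bg_{sp}_{j:04d}", anchor, tf_list)

    for sp in cfg.species:
        peaks[sp].sort(key=lambda p: (p.summit, p.id))
    truth = pd.DataFrame(rows)
    return peaks, truth


# ---------------------------------------------------------------------------
# annotations


@dataclass
class AnnotationSet:
    genes: list[GeneModel]
    expression: list[ExpressionRecord]
    snps: list[LeadSNP]
    universe: list[LeadSNP]
    mutations: list[MutationRecord]
    track: ConservationTrack
    boosted_genes: set[str]          # ground truth for the expression effect


def _nearest_gene_ids(tss_sorted: np.ndarray, ids_sorted: list[str],
                      positions: np.ndarray) -> list[str]:
    idx = np.searchsorted(tss_sorted, positions)
    out = []
    for p, i in zip(positions, idx):
        cands = []
        if i > 0:
            cands.append(i - 1)
        if i < len(tss_sorted):
            cands.append(i)
        best = min(cands, key=lambda c: (abs(int(tss_sorted[c]) - int(p)), ids_sorted[c]))
        out.append(ids_sorted[best])
    return out


def simulate_annotations(cfg: SimConfig, truth: pd.DataFrame) -> AnnotationSet:
    """Gene models, expression, GWAS catalog + universe, mutations, GERP track.

    Liver-category lead SNPs are given probability
    ``(liver_snp_enrichment - 1) * beta`` of targeted placement next to a
    random deeply shared CRM (beta = the chance rate at which a uniform SNP
    window catches a deep CRM), so enrichment 1 is exactly the uniform null
    and the net liver rate is ~enrichment x background.
    """
    cfg.validate()
    ref = cfg.reference
    L = cfg.genome_length

    # -- genes + expression -------------------------------------------------
    rng = cfg.rng("genes_expression")
    gene_starts = np.sort(rng.choice(np.arange(5000, L - 10000), size=cfg.n_genes,
                                     replace=False))
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    exon_template = [(0, 200), (1000, 1200), (2000, 2200), (3000, 3200)]
    genes: list[GeneModel] = []
    for i, (g, strand) in enumerate(zip(gene_starts, strands)):
        exons = tuple((int(g) + s, int(g) + e) for s, e in exon_template)
        tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
        genes.append(GeneModel(gene_id=f"gene_{i:05d}", chrom="chr1",
                               strand=str(strand), tss=tss, exons=exons))
    tss_arr = np.array([g.tss for g in genes])
    order = np.argsort(tss_arr, kind="stable")
    tss_sorted = tss_arr[order]
    ids_sorted = [genes[int(i)].gene_id for i in order]

    deep_crm = truth[(truth["kind"] == "crm") & truth["deep_truth"]]
    deep_anchor = ((deep_crm["span_start"] + deep_crm["span_end"]) // 2).to_numpy()
    boosted = set(_nearest_gene_ids(tss_sorted, ids_sorted, deep_anchor))

    expression: list[ExpressionRecord] = []
    for g in genes:
        for tissue in cfg.tissues:
            fpkm = float(np.exp(rng.normal(1.0, 1.0)))
            if tissue == "liver" and g.gene_id in boosted:
                fpkm *= cfg.liver_fpkm_boost
            expression.append(ExpressionRecord(g.gene_id, tissue, fpkm))

    # -- GWAS catalog -------------------------------------------------------
    rng = cfg.rng("gwas")
    cats = list(_GWAS_CATEGORIES)
    w = np.full(len(cats), (1.0 - cfg.liver_category_weight) / (len(cats) - 1))
    w[cats.index("liver")] = cfg.liver_category_weight
    cat_idx = rng.choice(len(cats), size=cfg.n_gwas_snps, p=w)

    half = cfg.snp_window_halfwidth
    spans = deep_crm[["span_start", "span_end"]].to_numpy()
    if len(spans):
        beta = float(np.sum(spans[:, 1] - spans[:, 0] + 2 * half) / L)
    else:
        beta = 0.0
    p_target = min(1.0, max(0.0, (cfg.liver_snp_enrichment - 1.0) * beta))

    snps: list[LeadSNP] = []
    for i in range(cfg.n_gwas_snps):
        cat = cats[cat_idx[i]]
        if cat == "liver" and len(spans) and rng.random() < p_target:
            s, e = spans[int(rng.integers(len(spans)))]
            pos = int(rng.integers(s - half + 100, e + half - 100))
        else:
            pos = int(rng.integers(half, L - half))
        n_prox = int(rng.integers(0, 6))
        proxies = []
        for _ in range(n_prox):
            d = int(rng.integers(-100_000, 100_001))
            r2 = float(rng.uniform(0.4, 0.8)) if rng.random() < 0.5 \
                else float(rng.uniform(0.8, 1.0))
            proxies.append((max(0, pos + d), r2))
        snps.append(LeadSNP(
            rsid=f"rs{i:06d}", chrom="chr1", pos=pos,
            disease_trait=f"{cat}:t{int(rng.integers(3))}",
            summary_category=cat, maf=float(rng.uniform(0.01, 0.5)),
            proxies=tuple(proxies)))

    n_uni = cfg.universe_factor * cfg.n_gwas_snps
    uni_pos = rng.integers(half, L - half, size=n_uni)
    uni_maf = rng.uniform(0.01, 0.5, size=n_uni)
    universe = [LeadSNP(rsid=f"u{i:06d}", chrom="chr1", pos=int(p),
                        disease_trait=".", summary_category=".", maf=float(m))
                for i, (p, m) in enumerate(zip(uni_pos, uni_maf))]

    # -- regulatory mutations ----------------------------------------------
    rng = cfg.rng("mutations")
    shared_crm = truth[(truth["kind"] == "crm") & truth["shared_truth"]]
    shared_spans = shared_crm[["span_start", "span_end"]].to_numpy()
    bases = np.array(list("ACGT"))
    diseases = ["coagulation defect", "lipid disorder", "hepatic disease",
                "metabolic syndrome", "other"]
    mutations: list[MutationRecord] = []
    for i in range(cfg.n_mutations):
        if len(shared_spans) and rng.random() < cfg.mutation_shared_fraction:
            s, e = shared_spans[int(rng.integers(len(shared_spans)))]
            pos = int(rng.integers(s, e))
        else:
            pos = int(rng.integers(0, L))
        ref_b, alt_b = rng.choice(bases, size=2, replace=False)
        gene = _nearest_gene_ids(tss_sorted, ids_sorted, np.array([pos]))[0]
        mutations.append(MutationRecord(
            chrom="chr1", pos=pos, gene=gene,
            disease=diseases[int(rng.integers(len(diseases)))],
            mutation_id=f"chr1:{pos}:{ref_b}>{alt_b}"))
    # duplicate ~5% of records under a second disease name: identical allele
    # changes must be counted once downstream
    n_dup = max(1, cfg.n_mutations // 20) if cfg.n_mutations else 0
    for j in range(n_dup):
        m = mutations[int(rng.integers(len(mutations)))]
        mutations.append(MutationRecord(
            chrom=m.chrom, pos=m.pos, gene=m.gene,
            disease=m.disease + " (recurrent)", mutation_id=m.mutation_id))

    # -- conservation track -------------------------------------------------
    rng = cfg.rng("conservation")
    res, flank = cfg.gerp_resolution, cfg.gerp_flank
    t = truth.sort_values("anchor")
    seg_starts: list[int] = []
    seg_ends: list[int] = []
    seg_vals: list[float] = []
    for _, row in t.iterrows():
        center = (int(row["span_start"]) + int(row["span_end"])) // 2
        w_s = max(0, center - flank)
        w_e = min(L, center + flank + res)
        shared = bool(row["shared_truth"])
        for s in range(w_s, w_e, res):
            e = min(s + res, w_e)
            inside = shared and s < row["span_end"] and e > row["span_start"]
            mu = cfg.gerp_shared_mean if inside else cfg.gerp_background_mean
            seg_starts.append(s)
            seg_ends.append(e)
            seg_vals.append(float(rng.normal(mu, cfg.gerp_sd)))
    track = ConservationTrack.from_rows(
        [("chr1", s, e, v) for s, e, v in zip(seg_starts, seg_ends, seg_vals)])

    return AnnotationSet(genes=genes, expression=expression, snps=snps,
                         universe=universe, mutations=mutations, track=track,
                         boosted_genes=boosted)


# ---------------------------------------------------------------------------
# ChIP/input reads and region sequences


def simulate_chip_reads(
    cfg: SimConfig, ref_peaks: list[Peak]
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """5' read positions per TF around summits, plus uniform input reads."""
    rng = cfg.rng("reads")
    L = cfg.genome_length
    per_tf: dict[str, list[np.ndarray]] = {tf: [] for tf in cfg.tfs}
    total = 0
    for p in ref_peaks:
        reads = np.clip(np.round(rng.normal(p.summit, 80.0, size=cfg.reads_per_peak)),
                        0, L - 1).astype(np.int64)
        per_tf[p.tf].append(reads)
        total += len(reads)
    chip = {tf: (np.sort(np.concatenate(v)) if v else np.empty(0, dtype=np.int64))
            for tf, v in per_tf.items()}
    input_reads = np.sort(rng.integers(0, L, size=max(1, total // 4)))
    return chip, input_reads


def default_pwms(major: float = 0.79) -> dict[str, PWM]:
    """The four bundled synthetic liver-TF motifs (width 10)."""
    pwms = {}
    for tf, cons in _CONSENSI.items():
        m = np.full((len(cons), 4), (1.0 - major) / 3.0)
        for i, base in enumerate(cons):
            m[i, "ACGT".index(base)] = major
        pwms[tf] = PWM(id=tf, matrix=m, background=np.full(4, 0.25))
    return pwms


def simulate_region_sequences(
    cfg: SimConfig,
    regions: list[RegulatoryRegion],
    pwms: dict[str, PWM] | None = None,
    plant_prob_crm: float = 0.6,
    plant_prob_singleton: float = 0.8,
) -> dict[str, str]:
    """I.i.d. background sequence per region with planted motif consensi.

    For every TF bound in a region, its motif consensus is planted at a
    random offset with a kind-dependent probability (singletons higher, as
    observed for real peak sets).
    """
    rng = cfg.rng("sequences")
    pwms = pwms or default_pwms()
    alphabet = np.array(list("ACGT"))
    out: dict[str, str] = {}
    for r in regions:
        length = len(r.span)
        seq = rng.choice(alphabet, size=length)
        p_plant = plant_prob_crm if r.kind == "crm" else plant_prob_singleton
        for tf in sorted(r.tf_set):
            if tf not in pwms:
                continue
            cons = pwms[tf].consensus
            if length >= len(cons) and rng.random() < p_plant:
                off = int(rng.integers(0, length - len(cons) + 1))
                seq[off:off + len(cons)] = list(cons)
        out[r.id] = "".join(seq)
    return out


# ---------------------------------------------------------------------------
# one-call study


@dataclass
class SimulatedStudy:
    cfg: SimConfig
    amap: AlignmentMap
    peaks: dict[str, list[Peak]]
    truth: pd.DataFrame
    annotations: AnnotationSet


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Generate the full synthetic study (alignment, peaks, annotations)."""
    amap = simulate_alignment_map(cfg)
    peaks, truth = simulate_peaks(cfg, amap)
    annotations = simulate_annotations(cfg, truth)
    return SimulatedStudy(cfg=cfg, amap=amap, peaks=peaks, truth=truth,
                          annotations=annotations)
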