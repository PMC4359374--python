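"""End-to-end pipeline driver: simulate -> build -> share -> annotate ->
enrich -> report.

Every stage is also callable standalone through its module; this driver
wires them together, writes the result tables as TSV and records a
manifest with the seed and a parameter hash so that reruns with the same
configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .annotation import (
    ConservationTrack,
    GeneIndex,
    classify_location,
    conservation_profile,
    expression_by_category,
    nearest_gene,
    signal_matrix,
)
from .clustering import ClusterParams, build_crms
from .core import ConfigError, Peak, RegulatoryRegion
from .cross_species import (
    AlignmentMap,
    alignability,
    assign_phylo_categories,
    compute_sharing_all,
    overlap_threshold_sweep,
    pairwise_sharing_percent,
    read_alignment_map,
    write_alignment_map,
)
from .enrichment import (
    build_snp_windows,
    hypergeometric_enrichment,
    null_matched_snps,
    null_shuffle_labels,
)
from .motifs import THRESHOLD_TIERS, scan_regions
from .motifs import motif_fraction_test
from .mutations import category_gene_sets, overlap_mutations
from .synthetic import (
    AnnotationSet,
    SimConfig,
    SimulatedStudy,
    default_pwms,
    simulate_chip_reads,
    simulate_region_sequences,
    simulate_study,
)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    simulate: SimConfig | None = None
    input_dir: str | None = None          # alternative to in-process simulation
    cluster: ClusterParams = field(default_factory=ClusterParams)
    min_overlap: int = 10
    overlap_thresholds: tuple[int, ...] = (1, 10, 25, 50)
    window_mode: str = "fixed"
    window_halfwidth: int = 2500
    r2_min: float = 0.8
    null_iters: int = 1000
    run_null_models: bool = True
    run_motifs: bool = True
    signal_bin: int = 100
    signal_window: int = 5000

    def validate(self) -> None:
        if self.simulate is None and self.input_dir is None:
            raise ConfigError("either an inline simulation config or an input "
                              "directory is required")
        if self.input_dir is not None and not os.path.isdir(self.input_dir):
            raise ConfigError(f"input directory does not exist: {self.input_dir}")

    def param_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {"|".join(k) if isinstance(k, tuple) else str(k): _as_jsonable(v)
                for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# study I/O (the file formats the CLI `simulate` writes and `run` can read)


def write_study(study: SimulatedStudy, outdir: str | os.PathLike) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, peaks in study.peaks.items():
        for tf in study.cfg.tfs:
            cio.write_peaks([p for p in peaks if p.tf == tf],
                            out / f"peaks_{sp}_{tf}.bed")
    write_alignment_map(study.amap, out / "alignment.tsv")
    ann = study.annotations
    cio.write_gene_models(ann.genes, out / "genes.bed12")
    cio.write_expression(ann.expression, out / "expression.tsv")
    cio.write_gwas_catalog(ann.snps, out / "gwas_catalog.tsv")
    cio.write_gwas_catalog(ann.universe, out / "snp_universe.tsv")
    cio.write_mutations(ann.mutations, out / "mutations.tsv")
    cio.write_bedgraph(ann.track.to_rows(), out / "conservation.bedgraph")
    study.truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    with open(out / "sim_config.json", "w") as fh:
        json.dump(_as_jsonable(study.cfg), fh, indent=1, sort_keys=True)


def load_study_inputs(indir: str | os.PathLike, cfg: SimConfig) -> SimulatedStudy:
    """Read back a study written by :func:`write_study` (ground truth not
    required for the pipeline itself)."""
    ind = Path(indir)
    for required in ("alignment.tsv", "genes.bed12", "expression.tsv",
                     "gwas_catalog.tsv", "mutations.tsv"):
        if not (ind / required).exists():
            raise ConfigError(f"missing input file: {ind / required}")
    peaks = {
        sp: [p for tf in cfg.tfs
             for p in cio.read_peaks(ind / f"peaks_{sp}_{tf}.bed", sp, tf)]
        for sp in cfg.species
    }
    amap = read_alignment_map(ind / "alignment.tsv")
    ann = AnnotationSet(
        genes=cio.read_gene_models(ind / "genes.bed12"),
        expression=cio.read_expression(ind / "expression.tsv"),
        snps=cio.read_gwas_catalog(ind / "gwas_catalog.tsv"),
        universe=(cio.read_gwas_catalog(ind / "snp_universe.tsv")
                  if (ind / "snp_universe.tsv").exists() else []),
        mutations=cio.read_mutations(ind / "mutations.tsv"),
        track=ConservationTrack.from_rows(
            cio.read_bedgraph(ind / "conservation.bedgraph"))
        if (ind / "conservation.bedgraph").exists()
        else ConservationTrack.from_rows([]),
        boosted_genes=set(),
    )
    truth = (pd.read_csv(ind / "ground_truth.tsv", sep="\t")
             if (ind / "ground_truth.tsv").exists() else pd.DataFrame())
    return SimulatedStudy(cfg=cfg, amap=amap, peaks=peaks, truth=truth,
                          annotations=ann)


# ---------------------------------------------------------------------------
# helpers shared with tests and the acceptance script


def regions_from_peaks(
    peaks: list[Peak], params: ClusterParams
) -> list[RegulatoryRegion]:
    crms, singles = build_crms(peaks, params)
    return ([RegulatoryRegion.from_crm(c) for c in crms]
            + [RegulatoryRegion.from_peak(p) for p in singles])


def categorize_reference(
    study: SimulatedStudy,
    params: ClusterParams | None = None,
    min_overlap: int = 10,
) -> tuple[list[RegulatoryRegion], dict, dict[str, list[RegulatoryRegion]]]:
    """Build regions for all species, compute sharing vs the reference and
    assign phylogenetic categories.  Returns (reference regions,
    {region_id: PhyloAssignment}, per-species regions)."""
    params = params or ClusterParams()
    cfg = study.cfg
    regions = {sp: regions_from_peaks(study.peaks[sp], params) for sp in cfg.species}
    ref_regions = regions[cfg.reference]
    records = {
        sp: compute_sharing_all(ref_regions, regions[sp], study.amap, min_overlap)
        for sp in cfg.species if sp != cfg.reference
    }
    assignments = assign_phylo_categories(ref_regions, records, cfg.species_roles)
    return ref_regions, {a.region_id: a for a in assignments}, regions


# ---------------------------------------------------------------------------
# the driver


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, outdir: str | os.PathLike) -> Path:
    """Run every stage and write the result tables under ``outdir``.

    Reruns with an identical configuration (and therefore seed) produce
    byte-identical tables.  Any stage failure raises a RuntimeError naming
    the stage.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {}

    stage = "simulate"
    try:
        if config.simulate is not None:
            cfg = config.simulate
            study = simulate_study(cfg)
        else:
            with open(Path(config.input_dir) / "sim_config.json") as fh:  # type: ignore[arg-type]
                raw = json.load(fh)
            cfg = _sim_config_from_json(raw)
            study = load_study_inputs(config.input_dir, cfg)  # type: ignore[arg-type]
        ref = cfg.reference
        counts["n_peaks"] = {sp: len(study.peaks[sp]) for sp in cfg.species}

        stage = "build_crms"
        ref_regions, assignments, regions = categorize_reference(
            study, config.cluster, config.min_overlap)
        crm_count = sum(1 for r in ref_regions if r.kind == "crm")
        counts["n_ref_crms"] = crm_count
        counts["n_ref_singletons"] = len(ref_regions) - crm_count
        cat_counts: dict[str, int] = {}
        for a in assignments.values():
            cat_counts[a.category] = cat_counts.get(a.category, 0) + 1
        counts["category_counts"] = cat_counts
        cio.write_regions(ref_regions, out / "regions_categories.tsv", assignments)

        stage = "sharing_matrices"
        rows = []
        for sp in cfg.species:
            if sp == ref:
                continue
            ab = compute_sharing_all(ref_regions, regions[sp], study.amap,
                                     config.min_overlap)
            ba = compute_sharing_all(regions[sp], ref_regions, study.amap,
                                     config.min_overlap)
            pw = pairwise_sharing_percent(ab, ba)
            align_frac, _ = alignability(ref_regions, study.amap, sp)
            rows.append((ref, sp, pw.pct_a_to_b, pw.pct_b_to_a, pw.average_pct,
                         pw.n_alignable_a, pw.n_alignable_b, 100.0 * align_frac))
        _write(pd.DataFrame(rows, columns=[
            "species_a", "species_b", "pct_a_to_b", "pct_b_to_a", "average_pct",
            "n_alignable_a", "n_alignable_b", "pct_alignable_a"]),
            out / "sharing_matrix.tsv")

        other = next(sp for sp in cfg.species if sp != ref)
        sweep = overlap_threshold_sweep(
            ref_regions, regions[other], study.amap,
            list(config.overlap_thresholds))
        _write(pd.DataFrame(sorted(sweep.items()),
                            columns=["min_overlap_bp", "n_shared_crms"]),
               out / "threshold_sweep.tsv")

        stage = "annotation"
        ann = study.annotations
        gene_index = GeneIndex(ann.genes)
        nearest = {r.id: (lambda hit: hit[0] if hit else None)(
            nearest_gene(r, gene_index)) for r in ref_regions}
        loc_rows = []
        for r in ref_regions:
            a = assignments[r.id]
            loc_rows.append((r.id, r.kind, a.n_species,
                             classify_location(r, gene_index)))
        loc = pd.DataFrame(loc_rows, columns=["region_id", "kind", "n_species",
                                              "location"])
        _write(loc.groupby(["kind", "n_species", "location"])
               .size().rename("n").reset_index(), out / "location_classes.tsv")

        stage = "expression"
        comp = expression_by_category(
            list(assignments.values()),
            {r.id: r.kind for r in ref_regions},
            nearest, ann.expression, tissue="liver")
        _write(comp.summary, out / "expression_summary.tsv")
        _write(comp.tests, out / "expression_tests.tsv")

        stage = "conservation"
        prof_rows = []
        for n_sp in range(1, len(cfg.species) + 1):
            for kind in ("crm", "singleton"):
                sel = [r for r in ref_regions
                       if r.kind == kind and assignments[r.id].n_species == n_sp]
                if not sel:
                    continue
                prof = conservation_profile(sel, ann.track, window=1000)
                center = slice(900, 1101)  # mean over +-100 bp and the flanks
                prof_rows.append((
                    kind, n_sp, len(sel),
                    float(np.nanmean(prof.mean_score[center])),
                    float(np.nanmean(np.concatenate(
                        [prof.mean_score[:200], prof.mean_score[-200:]]))),
                ))
        _write(pd.DataFrame(prof_rows, columns=[
            "kind", "n_species", "n_regions", "mean_center", "mean_flank"]),
            out / "conservation_profile.tsv")

        stage = "signal"
        chip, input_reads = simulate_chip_reads(cfg, study.peaks[ref])
        crm_regions = [r for r in ref_regions if r.kind == "crm"][:200]
        sig_rows = []
        for tf in cfg.tfs:
            mat = signal_matrix(crm_regions, chip[tf], input_reads,
                                config.signal_bin, config.signal_window)
            mean_prof = mat.mean(axis=0)
            for b, v in enumerate(mean_prof):
                sig_rows.append((tf, -config.signal_window + b * config.signal_bin,
                                 float(v)))
        _write(pd.DataFrame(sig_rows, columns=["tf", "bin_start", "mean_signal"]),
               out / "signal_profile.tsv")

        if config.run_motifs:
            stage = "motifs"
            pwms = default_pwms()
            seqs = simulate_region_sequences(cfg, ref_regions, pwms)
            mrows = []
            for tf in cfg.tfs:
                crm_ids = [r.id for r in ref_regions
                           if r.kind == "crm" and tf in r.tf_set]
                s_ids = [r.id for r in ref_regions
                         if r.kind == "singleton" and tf in r.tf_set]
                tf_seqs = {rid: seqs[rid] for rid in crm_ids + s_ids}
                hits = scan_regions(tf_seqs, pwms[tf], pvalue_threshold=1e-2)
                for tier, thr in THRESHOLD_TIERS.items():
                    hit_ids = {h.region_id for h in hits if h.pvalue <= thr}
                    res = motif_fraction_test(crm_ids, s_ids, hit_ids, tf, thr)
                    mrows.append((tf, tier, thr, res.frac_crm, res.frac_singleton,
                                  res.statistic, res.p, res.method))
            _write(pd.DataFrame(mrows, columns=[
                "tf", "tier", "threshold", "frac_crm", "frac_singleton",
                "chi2", "p", "method"]), out / "motif_fractions.tsv")

        stage = "gwas_enrichment"
        windows = build_snp_windows(ann.snps, mode=config.window_mode,
                                    halfwidth=config.window_halfwidth,
                                    r2_min=config.r2_min)
        counts["n_snp_windows"] = len(windows)
        results = hypergeometric_enrichment(ref_regions, assignments, windows,
                                            "summary_category")
        if config.run_null_models:
            shuffle = null_shuffle_labels(
                ann.snps, ref_regions, assignments, config.null_iters,
                seed=cfg.seed + 1, mode=config.window_mode,
                halfwidth=config.window_halfwidth, r2_min=config.r2_min)
            matched = null_matched_snps(
                ann.snps, ann.universe, ann.genes, ref_regions, assignments,
                config.null_iters, seed=cfg.seed + 2,
                halfwidth=config.window_halfwidth)
            for res in results:
                key = (res.category, res.trait)
                res.null_significant = {
                    "shuffle": shuffle[key].significant if key in shuffle else False,
                    "matched": matched[key].significant if key in matched else False,
                }
        erows = [(r.category, r.trait, r.x, r.K, r.n, r.N, r.fold, r.p,
                  r.p_bonferroni,
                  r.null_significant.get("shuffle"),
                  r.null_significant.get("matched")) for r in results]
        _write(pd.DataFrame(erows, columns=[
            "category", "trait", "x", "K", "n", "N", "fold", "p",
            "p_bonferroni", "null_shuffle_significant",
            "null_matched_significant"]), out / "gwas_enrichment.tsv")
        trait_results = hypergeometric_enrichment(
            ref_regions, assignments,
            build_snp_windows(ann.snps, mode="ld", halfwidth=config.window_halfwidth,
                              r2_min=config.r2_min),
            "disease_trait")
        _write(pd.DataFrame(
            [(r.category, r.trait, r.x, r.K, r.n, r.N, r.fold, r.p, r.p_bonferroni)
             for r in trait_results],
            columns=["category", "trait", "x", "K", "n", "N", "fold", "p",
                     "p_bonferroni"]), out / "gwas_enrichment_traits.tsv")

        stage = "mutations"
        mo = overlap_mutations(ref_regions, assignments, ann.mutations)
        _write(mo.per_region[mo.per_region["n_mutations"] > 0],
               out / "mutations_per_region.tsv")
        _write(mo.per_gene, out / "mutations_per_gene.tsv")
        counts["n_mutations_in_regions"] = mo.n_mutations_in_regions
        gene_sets = category_gene_sets(mo)
        with open(out / "mutation_gene_sets.json", "w") as fh:
            json.dump(gene_sets, fh, indent=1, sort_keys=True)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "param_hash": config.param_hash(),
            "counts": counts,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(_as_jsonable(manifest), fh, indent=1, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _sim_config_from_json(raw: dict) -> SimConfig:
    kwargs = dict(raw)
    kwargs["species"] = tuple(kwargs["species"])
    kwargs["tfs"] = tuple(kwargs["tfs"])
    kwargs["tissues"] = tuple(kwargs["tissues"])
    kwargs["peak_halfwidth_range"] = tuple(kwargs["peak_halfwidth_range"])
    kwargs["species_tree"] = {
        tuple(k.split("|")): v for k, v in kwargs["species_tree"].items()}
    kwargs["crm_tf_count_distribution"] = {
        int(k): v for k, v in kwargs["crm_tf_count_distribution"].items()}
    kwargs.pop("_CELL", None)
    return SimConfig(**kwargs)
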