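# crmshare

Cross-species analysis of combinatorial transcription-factor (TF) binding:
build cis-regulatory modules (CRMs) from heterotypic ChIP-seq peaks,
classify their sharing across species through a genome-alignment map, and
relate shared CRMs to gene expression, conservation, motif quality, GWAS
variants and regulatory disease mutations.

## The problem

Individual TF binding events turn over rapidly between mammals, and the
number of bound regions in any one tissue far exceeds the number of genes —
so occupancy alone is a weak filter for function.  Two orthogonal filters
help: *combinatorial* binding (several tissue-specific TFs bound within a
few hundred bp) and *evolutionary* sharing (the same kind of bound region in
the orthologous position of other species).  `crmshare` implements both
filters and the downstream statistics that test whether the filtered
regions are biologically meaningful, for a liver-style study design: five
species (two primates, two rodents, one outgroup) × four TFs.

## The model

- **CRM construction.** Peak summits are chained by transitive
  single-linkage: consecutive sorted summits ≤ *D* apart (default 300 bp)
  join one cluster; clusters with ≥ 2 distinct TFs become CRMs, everything
  else stays a singleton.
- **Sharing.** A region is shared with species *s* if its image under the
  pairwise colinear alignment map overlaps a single region of the allowed
  kind in *s* by ≥ 10 bp (CRM↔CRM regardless of TF content; singleton ↔
  singleton of the identical TF).  Regions shared in ≥ 3 species are
  *deeply shared*; the other exclusive categories are *beyond primates*,
  *primates only* and reference-only.
- **Enrichment.** For GWAS lead SNPs with windows *w* (fixed ±2.5 kb or the
  LD span at r² ≥ 0.8), the enrichment of category *c* for trait *t* is the
  upper tail P[X ≥ x], X ~ Hypergeometric(N, K, n): N regions, K in *c*, n
  overlapping windows carrying *t*, x in both.  Bonferroni correction spans
  all (c, t) pairs; two empirical null models (trait shuffling and
  MAF/TSS-distance–matched random SNPs, 1000 iterations each) guard against
  structure the hypergeometric ignores.
- **Motif quality.** PWM log-odds scores with exact theoretical p-values by
  dynamic programming over the discretized score distribution; per-TF 2×2
  chi-square compares motif fractions between CRMs and singletons at
  stringent/moderate/lenient thresholds (10⁻⁴/10⁻³/10⁻²).

A fully parameterized synthetic-data generator plants all of this structure
(sharing rates, expression boost near deep CRMs, liver-SNP enrichment,
mutations in shared CRMs, elevated conservation), so every stage is testable
against ground truth without external data.  See `docs/methods.md` for the
full model description and default rationale.

## Worked example

```python
from crmshare import SimConfig, simulate_study, build_snp_windows, \
    hypergeometric_enrichment
from crmshare.pipeline import categorize_reference
from crmshare.cross_species import compute_sharing_all, pairwise_sharing_percent

study = simulate_study(SimConfig(seed=1))
regions, assignments, per_species = categorize_reference(study)

ab = compute_sharing_all(regions, per_species["macaque"], study.amap, 10)
ba = compute_sharing_all(per_species["macaque"], regions, study.amap, 10)
print(pairwise_sharing_percent(ab, ba).pct_a_to_b)   # 34.73774720550301

windows = build_snp_windows(study.annotations.snps)  # ±2.5 kb, merged
results = hypergeometric_enrichment(regions, assignments, windows)
liver = next(r for r in results
             if r.category == "deeply_shared:crm" and r.trait == "liver")
print(liver.x, liver.K, liver.n, liver.N)            # 84 253 434 2500
print(round(liver.fold, 2), liver.p_bonferroni)      # 1.91 1.306...e-08
```

The first number is the percentage of human CRMs/singletons (among those
alignable to macaque) shared with macaque — close to the 35% occupancy the
generator plants.  The enrichment line reads: of 2500 human regions, 253
are deeply shared CRMs; 434 regions sit within 2.5 kb of a liver-category
lead SNP, 84 of them deeply shared CRMs — 1.9-fold more than expected, with
a Bonferroni-corrected hypergeometric p ≈ 10⁻⁸ (the generator plants the
liver-SNP excess at 3× before window-merging dilution).  Both null models
confirm the call.

The same analysis runs end to end from the command line:

```bash
crmshare run --seed 1 --out results/          # simulate → ... → report
crmshare simulate --seed 1 --out study/       # write all input files
crmshare run --input-dir study/ --out results2/
```

`results/` then contains the region/category table, sharing matrices, the
threshold sweep, location/conservation/expression tables, motif-fraction
chi-squares, GWAS enrichments with null-model flags, mutation tables and a
manifest with the seed and parameter hash (reruns are byte-identical).

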