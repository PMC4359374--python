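# Methods

`crmshare` implements a multi-species analysis of combinatorial
transcription-factor (TF) binding in a single tissue: construction of
cis-regulatory modules (CRMs) from heterotypic ChIP-seq peaks, cross-species
sharing classification through a whole-genome alignment abstraction, and the
downstream statistics that relate shared CRMs to gene location, conservation,
expression, motif quality, common trait-associated variants and rare
regulatory disease mutations.  This note records the models, the defaults and
why they hold, and the choices made where the design was genuinely open.

## Coordinates and region model

All coordinates are 0-based half-open; 1-based catalog formats (GWAS lead
SNPs, mutation tables) are converted at the I/O boundary.  Peaks and CRMs are
strandless; strand is honored only to derive a transcription start site (TSS)
from a gene model.  A peak's summit is stored as an absolute position because
clustering operates on summits.

## CRM construction

Peaks of one species are sorted by summit and chained by transitive
single-linkage: consecutive summits at most `max_summit_distance` (default
300 bp, inclusive) apart join one cluster, so a cluster may span far more
than 300 bp.  Clusters with at least two distinct TFs become CRMs; clusters
failing the distinct-TF test — including homotypic runs — are decomposed back
into singletons.  Transitive chaining is the only order-independent reading
of pairwise summit merging; decomposing homotypic clusters follows from the
definition of a CRM requiring two distinct factors (no homotypic-cluster
class exists).  The CRM span runs from the minimum member start to the
maximum member end, which is why CRM widths exceed single-peak widths.

## Cross-species sharing

The alignment map is a set of pairwise, gap-free colinear blocks (an
abstraction of a multiple-genome alignment); within a block each base maps
1:1, either colinearly or reflected for inverted blocks.  A region is
projected into a partner species as one interval per overlapped block.  A
region is *shared* when its projected image overlaps a single partner region
of the allowed kind by at least `min_overlap` bases (default 10 bp; a
1/10/25/50 bp sweep is provided).  Overlap is summed per candidate partner
across discontiguous projected pieces but never across partners.  CRMs
compare against CRMs with no constraint on TF content or order; singletons
compare against singletons bound by the identical TF.  Sharing percentages
use alignable regions (≥1 projectable base) as the denominator, and the
pairwise figure is the mean of the two directional percentages.

Phylogenetic categories are reference-centric with five species, two of them
primates.  A region shared in ≥3 species total is *deeply shared*; shared
with ≥1 non-primate, *beyond primates*; shared only with the other primate,
*primates only*; otherwise reference-only (labelled `human_only` for the
default human-like reference).  The exclusive label uses the precedence
deeply_shared > beyond_primates > primates_only > human_only, and boolean
flags preserve the overlapping reading (with only two primates, deeply
shared regions usually also qualify as beyond-primates).

## Annotation

Location classes follow a fixed priority when a region touches several
feature classes: TSS ±3 kb > intron > intergenic > exon, with TSS windows of
±3 kb around each gene's 5′ end.  Nearest-gene association is measured
anchor-to-TSS (anchor = CRM span midpoint or singleton summit; span midpoint
was chosen over mean-of-summits for the CRM center — both are within a few
bases on typical CRMs and the midpoint is well defined for any member
configuration).  Conservation profiles average per-base scores over ±1 kb
around anchors, tracking missing data per offset.  ChIP signal matrices
count reads minus input reads in 100 bp bins over ±5 kb; values may be
negative.

Expression association records the nearest-gene FPKM per region, stratified
by kind × shared-in-N.  The comparison is a two-sided Wilcoxon rank-sum
(normal approximation) per stratum plus a pooled deeply-shared-CRM vs
all-singletons contrast, Benjamini–Hochberg adjusted across the family.  A
rank test was chosen because FPKM distributions are heavy-tailed; zero-FPKM
genes are retained by default (exclusion would bias category comparisons).
Degenerate strata (<2 observations, or all-tied values) report p = missing
or 1 respectively.

## Motif analysis

Scores are log₂-odds against the background composition with pseudocount
0.01 folded into the matrix probabilities.  The null score distribution of a
random background word is computed exactly by positional convolution over
weights discretized to a granularity (default 0.01 bits; each word's
discretization error is bounded by width × granularity / 2).  P-value
thresholds (stringent 10⁻⁴, moderate 10⁻³, lenient 10⁻²) convert to score
cutoffs through this distribution; scanning uses the same discretized
weights so cutoff comparisons are exact.  Both strands are scanned;
N-containing windows are skipped.  CRM-vs-singleton motif-quality
differences use a 2×2 chi-square (df = 1, no continuity correction, matching
the textbook statistic), with a Fisher-exact fallback when an expected cell
drops below 5.  Matrix–matrix comparison maximizes, over shifts and both
orientations, the Pearson correlation of overlapping columns multiplied by
overlap width / max(width) — the normalization penalizes alignments
supported by few flanking columns; the exact constant is not standardized,
and overlap/max-width is this package's choice.

## GWAS enrichment and null models

Each lead SNP receives a window: fixed ±2.5 kb, or in LD mode the span of
all proxies with r² ≥ 0.8 (proxies capped at ±100 kb; with no qualifying
proxies the window degenerates to 1 bp at the lead, with an optional flag to
fall back to the fixed window).  Overlapping windows merge with trait-set
deduplication, so identical traits of co-located leads count once.

Enrichment of category c for trait t is upper-tail hypergeometric: among
the n regions overlapping any window carrying t, x fall in c, with K
category members among N regions.  N is all CRMs + singletons of the
reference species (the natural population when categories are tested
against each other; the sampled unit is the region).  Bonferroni correction
spans every (category × trait) pair tested in the run — the most
conservative family.  Both trait granularities run: ~25 summary categories
and raw disease traits.

Two empirical null models calibrate these p-values:

1. **Trait shuffle** — permute the summary annotation across lead SNPs 1000
   times and recompute every p-value.
2. **Matched SNPs** — redraw, per lead SNP and iteration, a random universe
   SNP from the same minor-allele-frequency × TSS-distance bin (without
   replacement within an iteration; empty bins fall back to the nearest
   non-empty bin).  Matched SNPs carry no LD proxies, so this null runs on
   fixed windows on both its observed and null sides.

Inside the null machinery, regions are annotated with the traits of their
overlapping *individual* SNP windows (the merged-window dedup only affects
the reported table); observed and null statistics use the identical
computation, so the comparison is internally consistent.  A pair is flagged
significant when the add-one empirical p, (1 + #{null ≤ observed}) /
(1 + iterations), is below 0.05.  The add-one convention is the standard
finite-sample-valid estimator; it caps the null flag rate at 48/1001 ≈ 4.8%
before tie conservatism, whereas the naive #{null ≤ obs}/iterations < 0.05
rule sits at 4.9% and can drift above 5% when the null draw is
under-dispersed.  Under-dispersion is also why the default SNP universe is
20× the catalog: sampling without replacement from a small universe shrinks
the null variance by roughly a factor 1 − 1/universe_factor, which at 5×
made the matched null measurably anti-conservative in calibration runs.

A generic randomized-overlap z-test is provided for comparing region sets
against external interval collections: each query region is re-placed,
width-preserved, uniformly within an allowed universe (e.g. open-chromatin
intervals) 1000 times; the observed ≥1 bp overlap count is scored against
the resulting normal-approximated null.

## Mutation overlap

Mutations intersect regions by point position; identical allele changes
(same chrom:pos:ref>alt) count once per region regardless of how many
disease annotations the catalog lists.  Per-gene tables accumulate unique
mutation counts per (gene, category, kind); gene sets per category are
exported for external enrichment tools rather than re-implementing those
services.

## The synthetic study

The generator emulates the statistical structure the analysis assumes —
not nucleotide-level realism.  One ancestral coordinate system is tiled
into segments (mean 2 kb); each segment is alignable with probability 0.9
consistently across all pairs, and each species may carry it inverted with
probability 0.1, so projections compose consistently across species while
exercising reflection arithmetic.  Species coordinates are offset so
projection is never the identity.

Defaults, and why: genome 25 Mb per species; 1600 CRM sites (2–4 TFs with
probabilities 0.55/0.30/0.15, summits spread 100 bp apart with 20 bp
jitter) and 900 singleton sites planted on a 5 kb grid in the reference,
plus 150 species-specific background sites per other species; pairwise
occupancy of the orthologous site with probability 0.35 (reference–macaque,
matching the ~35% sharing reported for closely related primates and
rodents) and 0.15 for the three non-primates, which yields a deeply shared
fraction near 16%, the proportion seen in the real five-species study.
Occupancy is conditionally independent across species given the reference
site, so non-reference pairwise sharing is not separately calibrated — a
deliberate simplification of the species tree.

Annotations: 2000 genes placed uniformly (4 exons of 200 bp, 800 bp
introns), log-normal FPKM (log-mean 1, log-sd 1) in four tissues; genes
nearest a deeply shared CRM get their liver FPKM multiplied by 4.  A GWAS
catalog of 3000 lead SNPs over 25 summary categories (liver weighted 0.2,
~600 liver SNPs); each liver SNP is placed next to a random deeply shared
CRM with probability (enrichment − 1) × β, where β is the chance rate at
which a uniform ±2.5 kb window catches a deep CRM — so enrichment 1 is
*exactly* the uniform null and the net liver rate is ≈ enrichment ×
background.  These sizes come from a power analysis: the planted fold is
diluted by window merging and by untargeted liver SNPs, and the detection
z-score scales with √(liver SNPs × deep CRMs / genome length); at the
chosen sizes a pilot gave worst-case Bonferroni p ≈ 5 × 10⁻⁵ across seeds
for the planted 3× cell, comfortably inside the ≥90%-of-seeds detection
requirement, while enrichment 1 stays calibrated.  300 mutations (70%
inside shared-CRM spans, the rest uniform, ~5% duplicated allele changes),
a 10 bp-resolution conservation track (background mean 0, shared-region
mean 2, sd 0.5) covering ±1.2 kb around every site, ChIP reads (15 per
peak, sd 80 around summits) with uniform input at a quarter of the ChIP
depth, and region sequences of i.i.d. background with the bound TFs'
synthetic consensus motifs (width 10, major-base probability 0.79) planted
at probability 0.6 in CRMs and 0.8 in singletons — singletons higher, as
observed for real peak collections.

Randomness is split into one child stream per output type, all derived from
the master seed, so changing one output's size cannot perturb another; the
same seed reproduces every output byte-identically.  What passing tests on
this generator do **not** show: robustness to gapped alignments, paralogy,
chromatin-driven peak-width structure, LD computed from genotypes, or any
nucleotide-level signal beyond the planted consensi.

## Pipeline, formats and problem sizes

The driver runs simulate → build → share → annotate → scan → enrich →
report, writing TSV tables and a manifest with the seed and a SHA-256
parameter hash; reruns with the same configuration are byte-identical (no
timestamps are written).  Gene models travel as 12-column BED, the
alignment map as a documented 7-column TSV, catalogs as TSV, conservation
as bedGraph, matrices as JASPAR or minimal MEME.  The pipeline and CLI
accept a JSON configuration file; JSON was chosen over YAML because the
stdlib serialization is byte-stable and doubles as the hash input.

The test suite runs the oracle-equivalence checks at full size (1000 random
clusterings; 200 two-species sharing instances; all hypergeometric margins
to N = 40; 4^w motif enumerations to width 8) and the simulation-based
checks at 20 seeds of the default study; the acceptance script reruns the
default study once plus a five-seed sharing-recovery experiment.  These
sizes were chosen so the whole suite completes on a single CPU in well
under half an hour while every tolerance stated above is exercised.

## Known limitations

Blocks are gap-free and pre-split; chain/net or MAF alignment input is out
of scope.  The singleton sharing rule compares singletons to singletons of
the same TF (a singleton opposite a CRM containing that TF is not counted
as shared — the flags make the choice explicit).  The hypergeometric
treats regions as exchangeable draws; wider regions have slightly higher
window-catch probability, which is exactly what the matched-SNP and
shuffle nulls are there to absorb.  DAVID/GeneMANIA-style gene-set
enrichment of mutation gene lists is exported, not computed.
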