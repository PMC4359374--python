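"""Readers and writers for the plain-text formats the pipeline touches.

BED-like files keep their native 0-based half-open coordinates.  GWAS and
mutation catalogs are 1-based on disk and converted here, in both
directions, so analysis code only ever sees 0-based positions.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from .core import (
    CRM,
    CrmShareError,
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    LeadSNP,
    MutationRecord,
    ParseError,
    Peak,
    RegulatoryRegion,
    ValidationError,
)

# ---------------------------------------------------------------------------
# peaks


def read_peaks(path: str | os.PathLike, species: str, tf: str) -> list[Peak]:
    """Read a BED-like peak file: chrom, start, end, name, score, summit_offset.

    The summit offset is relative to ``start``; the returned Peak stores the
    absolute summit position.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"expected >=6 columns (chrom start end name score summit_offset), "
                    f"got {len(fields)}", str(path), lineno)
            chrom, start_s, end_s, name, score_s, offset_s = fields[:6]
            try:
                start, end, offset = int(start_s), int(end_s), int(offset_s)
                score = float(score_s)
            except ValueError as exc:
                raise ParseError(f"non-numeric coordinate or score: {exc}", str(path), lineno)
            try:
                interval = GenomicInterval(species, chrom, start, end)
                peaks.append(Peak(interval=interval, tf=tf, summit=start + offset,
                                  score=score, id=name))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.id}\t"
                f"{p.score:g}\t{p.summit - p.interval.start}\n"
            )


# ---------------------------------------------------------------------------
# regulatory regions (CRMs + singletons), optionally with category annotation

_REGION_COLUMNS = [
    "chrom", "start", "end", "region_id", "kind", "species", "anchor",
    "tfs", "member_peaks", "summit", "score", "category", "shared_with", "n_species",
]


def write_regions(
    regions: Sequence[RegulatoryRegion],
    path: str | os.PathLike,
    assignments: dict | None = None,
) -> None:
    """Write CRMs and singletons as a BED-compatible TSV.

    ``assignments`` maps region id to a PhyloAssignment; when given, the
    category columns are filled so the file mirrors a "regions with
    phylogenetic categories" table.  Round-trips losslessly through
    :func:`read_regions`.
    """
    seen: set[str] = set()
    for r in regions:
        if r.id in seen:
            raise ValidationError(f"duplicate region id {r.id!r}")
        seen.add(r.id)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_REGION_COLUMNS) + "\n")
        for r in regions:
            span = r.span
            if r.kind == "crm":
                crm: CRM = r.region  # type: ignore[assignment]
                tfs = ",".join(sorted(crm.tf_set))
                members = ",".join(crm.members) or "."
                summit, score = ".", "."
            else:
                peak: Peak = r.region  # type: ignore[assignment]
                tfs = peak.tf
                members = "."
                summit, score = str(peak.summit), f"{peak.score:g}"
            if assignments is not None and r.id in assignments:
                a = assignments[r.id]
                category = a.category
                shared_with = ",".join(sorted(a.shared_with)) or "."
                n_species = str(a.n_species)
            else:
                category = shared_with = n_species = "."
            fh.write("\t".join([
                span.chrom, str(span.start), str(span.end), r.id, r.kind, r.species,
                str(r.anchor), tfs, members, summit, score, category, shared_with, n_species,
            ]) + "\n")


def read_regions(path: str | os.PathLike) -> tuple[list[RegulatoryRegion], dict[str, dict]]:
    """Read a region table written by :func:`write_regions`.

    Returns the regions plus, for every region with category columns, a dict
    ``{region_id: {"category": ..., "shared_with": set, "n_species": int}}``.
    """
    regions: list[RegulatoryRegion] = []
    categories: dict[str, dict] = {}
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != len(_REGION_COLUMNS):
                raise ParseError(f"expected {len(_REGION_COLUMNS)} columns, got {len(f)}",
                                 str(path), lineno)
            (chrom, start, end, region_id, kind, species, anchor, tfs, members,
             summit, score, category, shared_with, n_species) = f
            if region_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate region id {region_id!r}")
            seen.add(region_id)
            span = GenomicInterval(species, chrom, int(start), int(end))
            if kind == "crm":
                crm = CRM(id=region_id, species=species,
                          members=tuple(members.split(",")) if members != "." else (),
                          span=span, tf_set=frozenset(tfs.split(",")),
                          width=len(span))
                regions.append(RegulatoryRegion(kind="crm", region=crm, anchor=int(anchor)))
            elif kind == "singleton":
                peak = Peak(interval=span, tf=tfs, summit=int(summit),
                            score=float(score), id=region_id)
                regions.append(RegulatoryRegion(kind="singleton", region=peak, anchor=int(anchor)))
            else:
                raise ParseError(f"unknown region kind {kind!r}", str(path), lineno)
            if category != ".":
                categories[region_id] = {
                    "category": category,
                    "shared_with": set() if shared_with == "." else set(shared_with.split(",")),
                    "n_species": int(n_species),
                }
    return regions, categories


# ---------------------------------------------------------------------------
# gene models (12-column BED: exon blocks)


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from 12-column BED (blocks = exons, name = gene id)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 12:
                raise ParseError(f"expected 12 BED columns, got {len(f)}", str(path), lineno)
            chrom, start_s, _end, name, _score, strand = f[:6]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError("block count does not match block lists", str(path), lineno)
            start = int(start_s)
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
            try:
                genes.append(GeneModel(gene_id=name, chrom=chrom, strand=strand,
                                       tss=tss, exons=exons))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.start, g.end
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - start) for s, e in g.exons)
            fh.write("\t".join([
                g.chrom, str(start), str(end), g.gene_id, "0", g.strand,
                str(start), str(end), "0", str(len(g.exons)), sizes, offsets,
            ]) + "\n")


# ---------------------------------------------------------------------------
# expression (long TSV: gene_id, tissue, fpkm)


def read_expression(path: str | os.PathLike) -> list[ExpressionRecord]:
    records: list[ExpressionRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 3:
                raise ParseError(f"expected 3 columns, got {len(f)}", str(path), lineno)
            try:
                records.append(ExpressionRecord(f[0], f[1], float(f[2])))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"bad expression record: {exc}", str(path), lineno)
    return records


def write_expression(records: Iterable[ExpressionRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\ttissue\tfpkm\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.tissue}\t{r.fpkm:.6g}\n")


# ---------------------------------------------------------------------------
# GWAS catalog (1-based on disk)

_GWAS_COLUMNS = ["rsid", "chrom", "pos", "disease_trait", "summary_category", "maf", "proxies"]


def read_gwas_catalog(path: str | os.PathLike) -> list[LeadSNP]:
    """Read a lead-SNP catalog TSV; proxy column format ``pos:r2;pos:r2`` (1-based)."""
    snps: list[LeadSNP] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 7:
                raise ParseError(f"expected 7 columns, got {len(f)}", str(path), lineno)
            rsid, chrom, pos_s, trait, summary, maf_s, proxies_s = f
            proxies: list[tuple[int, float]] = []
            if proxies_s not in (".", ""):
                for item in proxies_s.split(";"):
                    p, r2 = item.split(":")
                    proxies.append((int(p) - 1, float(r2)))
            try:
                snps.append(LeadSNP(rsid=rsid, chrom=chrom, pos=int(pos_s) - 1,
                                    disease_trait=trait, summary_category=summary,
                                    maf=float(maf_s), proxies=tuple(proxies)))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"bad lead SNP record: {exc}", str(path), lineno)
    return snps


def write_gwas_catalog(snps: Iterable[LeadSNP], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_GWAS_COLUMNS) + "\n")
        for s in snps:
            proxies = ";".join(f"{p + 1}:{r2:.4g}" for p, r2 in s.proxies) or "."
            fh.write(f"{s.rsid}\t{s.chrom}\t{s.pos + 1}\t{s.disease_trait}\t"
                     f"{s.summary_category}\t{s.maf:.4g}\t{proxies}\n")


# ---------------------------------------------------------------------------
# regulatory mutations (1-based on disk)


def read_mutations(path: str | os.PathLike) -> list[MutationRecord]:
    """Read a mutation catalog TSV: chrom, pos (1-based), ref, alt, gene, disease."""
    muts: list[MutationRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 6:
                raise ParseError(f"expected 6 columns, got {len(f)}", str(path), lineno)
            chrom, pos_s, ref, alt, gene, disease = f
            pos = int(pos_s) - 1
            muts.append(MutationRecord(chrom=chrom, pos=pos, gene=gene, disease=disease,
                                       mutation_id=f"{chrom}:{pos}:{ref}>{alt}"))
    return muts


def write_mutations(muts: Iterable[MutationRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\tgene\tdisease\n")
        for m in muts:
            _, _, change = m.mutation_id.rpartition(":")
            ref, _, alt = change.partition(">")
            fh.write(f"{m.chrom}\t{m.pos + 1}\t{ref}\t{alt}\t{m.gene}\t{m.disease}\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | os.PathLike) -> list[tuple[str, int, int, float]]:
    """Read bedGraph rows (chrom, start, end, value); 0-based half-open."""
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) != 4:
                raise ParseError(f"expected 4 bedGraph columns, got {len(f)}", str(path), lineno)
            start, end = int(f[1]), int(f[2])
            if start < 0 or start >= end:
                raise ParseError(f"bad bedGraph interval [{start}, {end})", str(path), lineno)
            rows.append((f[0], start, end, float(f[3])))
    return rows


def write_bedgraph(rows: Iterable[tuple[str, int, int, float]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.4g}\n")


# ---------------------------------------------------------------------------
# FASTA (region sequences)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
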