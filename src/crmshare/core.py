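"""Core domain types shared by every stage of the pipeline.

All genomic coordinates are 0-based and half-open (``[start, end)``), the
native BED convention.  Catalog formats that ship 1-based positions (GWAS
lead SNPs, regulatory-mutation tables) are converted at the I/O boundary,
never inside analysis code.

Peaks and CRMs are strandless: transcription-factor occupancy has no
orientation.  Strand is honored only where a transcription start site has
to be derived from a gene model.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class CrmShareError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(CrmShareError):
    """A domain object violates one of its invariants."""


class ParseError(CrmShareError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        where = f"{path}:{line}: " if path is not None and line is not None else ""
        super().__init__(where + message)


class ConfigError(CrmShareError):
    """A configuration value is out of range or inconsistent."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval on one species' assembly."""

    species: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start coordinate: {self}")
        if self.start >= self.end:
            raise ValidationError(f"empty or inverted interval: {self}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (same chrom assumed checked)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A single TF-bound region called from ChIP-seq, with its summit.

    The summit is stored as an absolute genomic position (not an offset)
    because CRM construction clusters summits directly.
    """

    interval: GenomicInterval
    tf: str
    summit: int
    score: float
    id: str

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside peak interval "
                f"[{self.interval.start}, {self.interval.end}) for peak {self.id!r}"
            )

    @property
    def species(self) -> str:
        return self.interval.species

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class CRM:
    """A cis-regulatory module: >=2 distinct TFs with proximal summits.

    ``span`` runs from the minimum member-peak start to the maximum member-peak
    end, so CRM widths exceed single-peak widths.
    """

    id: str
    species: str
    members: tuple[str, ...]          # member peak ids, ordered by summit
    span: GenomicInterval
    tf_set: frozenset[str]
    width: int

    def __post_init__(self) -> None:
        if len(self.tf_set) < 2:
            raise ValidationError(f"CRM {self.id!r} has <2 distinct TFs: {set(self.tf_set)}")
        if self.width != len(self.span):
            raise ValidationError(f"CRM {self.id!r} width {self.width} != span length {len(self.span)}")


@dataclass(frozen=True)
class RegulatoryRegion:
    """A CRM or a singleton peak, with the anchor used by profile analyses.

    The anchor is the span center for a CRM and the peak summit for a
    singleton.
    """

    kind: str                  # "crm" | "singleton"
    region: CRM | Peak
    anchor: int

    def __post_init__(self) -> None:
        if self.kind not in ("crm", "singleton"):
            raise ValidationError(f"unknown region kind {self.kind!r}")
        span = self.span
        if not (span.start <= self.anchor < span.end):
            raise ValidationError(f"anchor {self.anchor} outside span of region {self.id!r}")

    @classmethod
    def from_crm(cls, crm: CRM) -> "RegulatoryRegion":
        return cls(kind="crm", region=crm, anchor=crm.span.center)

    @classmethod
    def from_peak(cls, peak: Peak) -> "RegulatoryRegion":
        return cls(kind="singleton", region=peak, anchor=peak.summit)

    @property
    def id(self) -> str:
        return self.region.id

    @property
    def species(self) -> str:
        return self.region.species if isinstance(self.region, CRM) else self.region.interval.species

    @property
    def span(self) -> GenomicInterval:
        return self.region.span if isinstance(self.region, CRM) else self.region.interval

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def tf_set(self) -> frozenset[str]:
        if isinstance(self.region, CRM):
            return self.region.tf_set
        return frozenset([self.region.tf])


@dataclass(frozen=True)
class GeneModel:
    """Gene with TSS and exon structure; ``tss`` is the 5' end under strand."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id!r}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if s < 0 or s >= e:
                raise ValidationError(f"gene {self.gene_id!r}: bad exon ({s}, {e})")
            if s < prev_end:
                raise ValidationError(f"gene {self.gene_id!r}: exons overlap or are unsorted")
            prev_end = e
        five_prime = self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1
        if self.tss != five_prime:
            raise ValidationError(
                f"gene {self.gene_id!r}: tss {self.tss} is not the 5' end ({five_prime}) "
                f"under strand {self.strand}"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i][1] < self.exons[i + 1][0]
        )


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    tissue: str
    fpkm: float

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValidationError(f"negative FPKM for {self.gene_id!r}/{self.tissue!r}")


@dataclass(frozen=True)
class MutationRecord:
    """One curated regulatory disease mutation (point coordinate, 0-based).

    ``mutation_id`` is unique per distinct allele change at a position, so
    identical changes reported for several diseases collapse to one id.
    """

    chrom: str
    pos: int
    gene: str
    disease: str
    mutation_id: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"negative mutation position: {self}")


@dataclass(frozen=True)
class LeadSNP:
    """GWAS catalog lead SNP with optional LD proxies (positions 0-based)."""

    rsid: str
    chrom: str
    pos: int
    disease_trait: str
    summary_category: str
    maf: float
    proxies: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"negative SNP position for {self.rsid}")
        if not (0.0 < self.maf <= 0.5):
            raise ValidationError(f"MAF out of (0, 0.5] for {self.rsid}: {self.maf}")
        for p, r2 in self.proxies:
            if not (0.0 <= r2 <= 1.0):
                raise ValidationError(f"proxy r2 out of [0,1] for {self.rsid}: {r2}")
            if abs(p - self.pos) > 100_000:
                raise ValidationError(
                    f"proxy at {p} is more than 100 kb from lead SNP {self.rsid} at {self.pos}"
                )
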