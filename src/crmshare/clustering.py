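"""CRM construction: cluster per-species ChIP-seq peaks by summit proximity.

Clustering is transitive single-linkage on summit positions: after sorting
summits within a chromosome, consecutive summits no more than
``max_summit_distance`` apart (inclusive) join the same cluster, so a
cluster may span far more than that distance.  Clusters with at least
``min_distinct_tfs`` distinct TFs become CRMs; every other peak — including
members of homotypic clusters — is returned as a singleton.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .core import CRM, GenomicInterval, Peak, ValidationError


@dataclass(frozen=True)
class ClusterParams:
    max_summit_distance: int = 300
    min_distinct_tfs: int = 2

    def __post_init__(self) -> None:
        if self.max_summit_distance <= 0:
            raise ValidationError("max_summit_distance must be > 0")
        if self.min_distinct_tfs < 2:
            raise ValidationError("min_distinct_tfs must be >= 2")


def build_crms(
    peaks: list[Peak],
    params: ClusterParams = ClusterParams(),
) -> tuple[list[CRM], list[Peak]]:
    """Partition peaks into CRMs and singletons.

    Every input peak appears exactly once in the output: either as a member
    of one CRM or in the singleton list.  The partition is independent of
    input order (peaks are sorted by summit, ties broken by peak id).
    """
    if not peaks:
        return [], []
    species = {p.species for p in peaks}
    if len(species) > 1:
        raise ValidationError(f"build_crms requires a single species, got {sorted(species)}")
    ids = [p.id for p in peaks]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate peak ids in input")
    (sp,) = species

    crms: list[CRM] = []
    singletons: list[Peak] = []
    by_chrom: dict[str, list[Peak]] = defaultdict(list)
    for p in peaks:
        by_chrom[p.chrom].append(p)

    crm_index = 0
    for chrom in sorted(by_chrom):
        chrom_peaks = sorted(by_chrom[chrom], key=lambda p: (p.summit, p.id))
        cluster: list[Peak] = [chrom_peaks[0]]
        clusters: list[list[Peak]] = []
        for p in chrom_peaks[1:]:
            if p.summit - cluster[-1].summit <= params.max_summit_distance:
                cluster.append(p)
            else:
                clusters.append(cluster)
                cluster = [p]
        clusters.append(cluster)
        for cl in clusters:
            tfs = frozenset(p.tf for p in cl)
            if len(tfs) >= params.min_distinct_tfs:
                span = GenomicInterval(
                    sp, chrom,
                    min(p.interval.start for p in cl),
                    max(p.interval.end for p in cl),
                )
                crms.append(CRM(
                    id=f"{sp}_crm_{crm_index:05d}",
                    species=sp,
                    members=tuple(p.id for p in cl),
                    span=span,
                    tf_set=tfs,
                    width=len(span),
                ))
                crm_index += 1
            else:
                singletons.extend(cl)
    return crms, singletons


def summit_distance_histogram(
    peaks: list[Peak],
    max_d: int,
    bin_width: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of nearest *heterotypic* summit distances.

    For each peak, the distance to the closest summit of a different TF on
    the same chromosome is recorded if it is <= ``max_d``; the total count
    therefore equals the number of peaks with a heterotypic neighbour within
    ``max_d``.  Returns ``(bin_edges, counts)``.
    """
    if len(peaks) < 2:
        raise ValidationError("summit_distance_histogram needs >= 2 peaks")
    distances: list[int] = []
    by_chrom: dict[str, list[Peak]] = defaultdict(list)
    for p in peaks:
        by_chrom[p.chrom].append(p)
    for chrom_peaks in by_chrom.values():
        for p in chrom_peaks:
            best: int | None = None
            for q in chrom_peaks:
                if q is p or q.tf == p.tf:
                    continue
                d = abs(q.summit - p.summit)
                if best is None or d < best:
                    best = d
            if best is not None and best <= max_d:
                distances.append(best)
    edges = np.arange(0, max_d + bin_width, bin_width)
    counts, _ = np.histogram(distances, bins=edges)
    return edges, counts


def rank_crms_by_tf_score(
    crms: list[CRM],
    peak_index: dict[str, Peak],
    tf: str,
    k: int,
) -> list[CRM]:
    """Top-k CRMs containing ``tf``, ranked by their best member score for it.

    This reproduces the "top peak-intensity" CRM set used as the comparator
    to the shared-CRM set: each CRM's rank score is the maximum peak-caller
    score among its member peaks of the requested TF.  Ties are broken by
    CRM id so the ranking is deterministic.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    scored: list[tuple[float, str, CRM]] = []
    for crm in crms:
        member_scores = [
            peak_index[pid].score for pid in crm.members if peak_index[pid].tf == tf
        ]
        if member_scores:
            scored.append((max(member_scores), crm.id, crm))
    scored.sort(key=lambda t: (-t[0], t[1]))
    if k > len(scored):
        warnings.warn(
            f"requested top {k} CRMs for {tf} but only {len(scored)} contain it",
            stacklevel=2,
        )
    return [crm for _, _, crm in scored[:k]]
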