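"""PWM scanning with exact theoretical score-distribution p-values.

Scores are log-odds in bits against a background base composition.  The
null score distribution of a random background word is computed exactly by
positional convolution over scores discretized to a fixed granularity;
p-value thresholds (stringent 1e-4, moderate 1e-3, lenient 1e-2) are
converted to score cutoffs through that distribution.  Scanning and the
distribution use the same discretized weights, so cutoff comparisons are
exact rather than float-fuzzy.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ValidationError

THRESHOLD_TIERS = {"stringent": 1e-4, "moderate": 1e-3, "lenient": 1e-2}

_BASE_ORDER = "ACGT"
_WEIGHT_CLIP_BITS = -100.0  # stand-in for -inf when pseudocount is zero


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: width x 4 probabilities, column order ACGT."""

    id: str
    matrix: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValidationError("PWM matrix must be width x 4")
        if m.shape[0] < 4:
            raise ValidationError("PWM width must be >= 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("PWM columns must each sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValidationError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASE_ORDER[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """Log2-odds weights with the pseudocount folded in."""
        p = self.matrix + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            w = np.log2(p / self.background)
        if np.any(np.isneginf(w)):
            warnings.warn(f"PWM {self.id}: -inf weights clipped to "
                          f"{_WEIGHT_CLIP_BITS} bits", stacklevel=2)
            w = np.maximum(w, _WEIGHT_CLIP_BITS)
        return w

    def reverse_complement(self) -> "PWM":
        return PWM(id=self.id + "_rc", matrix=self.matrix[::-1, ::-1].copy(),
                   background=self.background[::-1].copy(),
                   pseudocount=self.pseudocount)

    @classmethod
    def from_counts(cls, id: str, counts: np.ndarray,
                    background: np.ndarray | None = None,
                    pseudocount: float = 0.01) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        probs = counts / counts.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(id=id, matrix=probs, background=bg, pseudocount=pseudocount)


def read_jaspar(path) -> list[PWM]:
    """Read JASPAR-format matrices via Biopython."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in _BASE_ORDER], dtype=float).T
            out.append(PWM.from_counts(id=m.matrix_id or m.name, counts=counts))
    return out


def read_meme(path) -> list[PWM]:
    """Read MEME minimal-format matrices via Biopython."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    for m in record:
        probs = np.array([m.pwm[b] for b in _BASE_ORDER], dtype=float).T
        probs = probs / probs.sum(axis=1, keepdims=True)
        out.append(PWM(id=m.name, matrix=probs, background=np.full(4, 0.25)))
    return out


# ---------------------------------------------------------------------------
# exact score distribution


@dataclass
class ScoreDistribution:
    """Exact null distribution of the log-odds score, discretized.

    ``scores`` ascend; ``sf[i]`` is the background probability of a score
    >= scores[i].
    """

    granularity: float
    scores: np.ndarray       # achievable discretized scores, ascending
    probs: np.ndarray        # probability mass per score
    sf: np.ndarray           # survival function: P(S >= scores[i])

    def pvalue(self, score: float) -> float:
        """P(background score >= score); robust to granularity rounding."""
        i = int(np.searchsorted(self.scores, score - self.granularity / 2.0))
        if i >= len(self.scores):
            return 0.0
        return float(self.sf[i])

    def score_cutoff(self, pvalue_threshold: float) -> float:
        """Smallest achievable score whose p-value is <= the threshold.

        Returns max score + granularity when even the maximum score is not
        rare enough (then no position can pass).
        """
        idx = np.nonzero(self.sf <= pvalue_threshold)[0]
        if len(idx) == 0:
            return float(self.scores[-1] + self.granularity)
        return float(self.scores[idx[0]])


def exact_score_distribution(pwm: PWM, granularity: float = 0.01) -> ScoreDistribution:
    """Distribution of the PWM score of a random background word.

    Positional convolution over integer-discretized weights: exact up to
    the rounding of each column's weights to multiples of ``granularity``
    (total error bounded by width x granularity / 2).
    """
    if granularity <= 0:
        raise ValidationError("granularity must be > 0")
    q = np.round(pwm.log_odds() / granularity).astype(np.int64)
    bg = pwm.background
    dist: dict[int, float] = {0: 1.0}
    for row in q:
        nxt: dict[int, float] = defaultdict(float)
        for s, p in dist.items():
            for b in range(4):
                nxt[s + int(row[b])] += p * bg[b]
        dist = dict(nxt)
    keys = np.array(sorted(dist), dtype=np.int64)
    probs = np.array([dist[k] for k in keys])
    sf = probs[::-1].cumsum()[::-1]
    return ScoreDistribution(granularity=granularity,
                             scores=keys * granularity,
                             probs=probs, sf=sf)


# ---------------------------------------------------------------------------
# scanning


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    pwm_id: str
    offset: int
    strand: str
    score: float
    pvalue: float


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASE_ORDER):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, qweights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer window scores and validity (no N) for every window start."""
    w = qweights.shape[0]
    n_win = len(codes) - w + 1
    scores = np.zeros(n_win, dtype=np.int64)
    safe = np.where(codes < 0, 0, codes)
    for i in range(w):
        scores += qweights[i][safe[i:i + n_win]]
    bad = (codes < 0).astype(np.int32)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    valid = (cbad[w:] - cbad[:-w]) == 0
    return scores, valid


def scan_regions(
    sequences: dict[str, str],
    pwm: PWM,
    pvalue_threshold: float = 1e-4,
    granularity: float = 0.01,
) -> list[MotifHit]:
    """Scan both strands of each sequence, keeping positions whose score
    reaches the cutoff implied by the p-value threshold.

    Offsets are 0-based window starts in the forward sequence for both
    strands.  Windows containing N are skipped; sequences shorter than the
    motif yield no hits.
    """
    if not (0.0 < pvalue_threshold <= 1.0):
        raise ValidationError("pvalue_threshold must be in (0, 1]")
    dist = exact_score_distribution(pwm, granularity)
    cutoff = dist.score_cutoff(pvalue_threshold)
    cutoff_q = int(round(cutoff / granularity))
    q_fwd = np.round(pwm.log_odds() / granularity).astype(np.int64)
    q_rev = np.round(pwm.reverse_complement().log_odds() / granularity).astype(np.int64)

    hits: list[MotifHit] = []
    w = pwm.width
    for region_id in sequences:
        seq = sequences[region_id]
        if len(seq) < w:
            continue
        codes = _encode(seq)
        for strand, qw in (("+", q_fwd), ("-", q_rev)):
            scores, valid = _window_scores(codes, qw)
            for pos in np.nonzero(valid & (scores >= cutoff_q))[0]:
                s = float(scores[pos] * granularity)
                hits.append(MotifHit(region_id=region_id, pwm_id=pwm.id,
                                     offset=int(pos), strand=strand,
                                     score=s, pvalue=dist.pvalue(s)))
    return hits


# ---------------------------------------------------------------------------
# CRM vs singleton motif-quality comparison


@dataclass
class MotifFractionResult:
    tf: str
    threshold: float
    n_crm: int
    n_crm_with_hit: int
    n_singleton: int
    n_singleton_with_hit: int
    frac_crm: float
    frac_singleton: float
    statistic: float | None
    p: float
    df: int
    method: str  # "chi2" or "fisher"


def motif_fraction_test(
    crm_ids: list[str],
    singleton_ids: list[str],
    hit_region_ids: set[str],
    tf: str = "",
    threshold: float = np.nan,
) -> MotifFractionResult:
    """2x2 chi-square: fraction of CRMs vs singletons with >=1 motif hit.

    Falls back to Fisher's exact test (with a warning) when an expected
    cell count is below 5.
    """
    n_c, n_s = len(crm_ids), len(singleton_ids)
    if n_c == 0 or n_s == 0:
        raise ValidationError("both region kinds must be non-empty")
    x_c = sum(1 for r in crm_ids if r in hit_region_ids)
    x_s = sum(1 for r in singleton_ids if r in hit_region_ids)
    table = np.array([[x_c, n_c - x_c], [x_s, n_s - x_s]], dtype=float)
    expected = stats.contingency.expected_freq(table)
    if np.any(expected < 5):
        warnings.warn("expected cell count < 5; using Fisher's exact test",
                      stacklevel=2)
        _, p = stats.fisher_exact(table)
        statistic, df, method = None, 1, "fisher"
    else:
        chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
        statistic, method = float(chi2), "chi2"
    return MotifFractionResult(
        tf=tf, threshold=threshold,
        n_crm=n_c, n_crm_with_hit=x_c, n_singleton=n_s, n_singleton_with_hit=x_s,
        frac_crm=x_c / n_c, frac_singleton=x_s / n_s,
        statistic=statistic, p=float(p), df=int(df), method=method)


# ---------------------------------------------------------------------------
# matrix-matrix comparison


@dataclass(frozen=True)
class MatrixComparison:
    shift: int
    strand: str
    correlation: float       # Pearson r over the overlapping columns
    ncor: float              # r * overlap_width / max(width_a, width_b)
    overlap: int


def compare_matrices(pwm_a: PWM, pwm_b: PWM, min_overlap: int = 4) -> MatrixComparison:
    """Best shifted alignment of two matrices on either orientation.

    The Pearson correlation of the overlapping columns is normalized by
    overlap width over the wider matrix, penalizing alignments supported by
    few flanking positions.  Returns the maximizing configuration.
    """
    best: MatrixComparison | None = None
    wa, wb = pwm_a.width, pwm_b.width
    for strand, mb in (("+", pwm_b.matrix), ("-", pwm_b.reverse_complement().matrix)):
        for shift in range(-(wb - min_overlap), wa - min_overlap + 1):
            a_lo, a_hi = max(0, shift), min(wa, shift + wb)
            ov = a_hi - a_lo
            if ov < min_overlap:
                continue
            sub_a = pwm_a.matrix[a_lo:a_hi].ravel()
            sub_b = mb[a_lo - shift:a_hi - shift].ravel()
            if np.std(sub_a) == 0 or np.std(sub_b) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(sub_a, sub_b)[0, 1])
            ncor = r * ov / max(wa, wb)
            cand = MatrixComparison(shift=shift, strand=strand,
                                    correlation=r, ncor=ncor, overlap=ov)
            if best is None or cand.ncor > best.ncor or (
                    cand.ncor == best.ncor and (cand.strand, cand.shift) <
                    (best.strand, best.shift)):
                best = cand
    assert best is not None
    return best
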