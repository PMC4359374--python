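"""Exact score distribution vs exhaustive enumeration, scanning behavior,
the CRM/singleton chi-square, and matrix comparison."""

import itertools

import numpy as np
import pytest

from crmshare.core import ValidationError
from crmshare.motifs import (
    PWM,
    compare_matrices,
    exact_score_distribution,
    motif_fraction_test,
    read_jaspar,
    read_meme,
    scan_regions,
)

UNIFORM_BG = np.full(4, 0.25)
SKEWED_BG = np.array([0.4, 0.1, 0.1, 0.4])


def random_pwm(rng, width, pwm_id="m", background=None):
    m = rng.dirichlet(np.full(4, 0.8), size=width)
    return PWM(id=pwm_id, matrix=m,
               background=UNIFORM_BG if background is None else background)


def consensus_pwm(consensus, major=0.85, background=None):
    m = np.full((len(consensus), 4), (1 - major) / 3)
    for i, b in enumerate(consensus):
        m[i, "ACGT".index(b)] = major
    return PWM(id=f"cons_{consensus}", matrix=m,
               background=UNIFORM_BG if background is None else background)


def enumerate_distribution(pwm, granularity):
    """Independent oracle: exhaustive 4^w enumeration over all words, using
    the same per-column weight rounding as the DP."""
    q = np.round(pwm.log_odds() / granularity).astype(np.int64)
    dist = {}
    for word in itertools.product(range(4), repeat=pwm.width):
        s = int(sum(q[i, b] for i, b in enumerate(word)))
        p = float(np.prod([pwm.background[b] for b in word]))
        dist[s] = dist.get(s, 0.0) + p
    scores = np.array(sorted(dist)) * granularity
    probs = np.array([dist[k] for k in sorted(dist)])
    return scores, probs


class TestScoreDistribution:
    @pytest.mark.parametrize("width", [4, 5, 6, 7, 8])
    @pytest.mark.parametrize("bg", [UNIFORM_BG, SKEWED_BG])
    def test_matches_exhaustive_enumeration(self, rng, width, bg):
        pwm = random_pwm(rng, width, background=bg)
        dist = exact_score_distribution(pwm, granularity=0.01)
        scores, probs = enumerate_distribution(pwm, 0.01)
        assert np.allclose(dist.scores, scores, atol=1e-12)
        assert np.allclose(dist.probs, probs, atol=1e-10)
        assert np.isclose(dist.probs.sum(), 1.0, atol=1e-9)

    def test_rounding_error_bounded_by_granularity(self, rng):
        g = 0.01
        pwm = random_pwm(rng, 6)
        w = pwm.log_odds()
        q = np.round(w / g) * g
        # per word, |exact - discretized| <= width * g / 2
        assert np.max(np.abs(w - q)) <= g / 2 + 1e-12

    def test_survival_function_non_increasing(self, rng):
        dist = exact_score_distribution(random_pwm(rng, 6))
        assert np.all(np.diff(dist.sf) <= 1e-15)

    def test_pvalue_at_minimum_score_is_one(self, rng):
        dist = exact_score_distribution(random_pwm(rng, 5))
        assert dist.pvalue(float(dist.scores[0])) == pytest.approx(1.0)
        assert dist.pvalue(-1e9) == pytest.approx(1.0)

    def test_top_score_pvalue_counts_maximizing_words(self):
        # single dominant base per column: exactly one maximizing word
        pwm = consensus_pwm("ACGT", major=0.97)
        dist = exact_score_distribution(pwm, granularity=0.001)
        assert dist.pvalue(float(dist.scores[-1])) == pytest.approx(1 / 256, rel=1e-6)

    def test_cutoff_monotone_in_threshold(self, rng):
        dist = exact_score_distribution(random_pwm(rng, 8))
        cuts = [dist.score_cutoff(p) for p in (1e-4, 1e-3, 1e-2)]
        assert cuts[0] >= cuts[1] >= cuts[2]

    def test_bad_granularity_rejected(self, rng):
        with pytest.raises(ValidationError):
            exact_score_distribution(random_pwm(rng, 5), granularity=0.0)


class TestScan:
    def test_consensus_sequence_hits_at_offset_zero(self):
        pwm = consensus_pwm("ACGTACGTAC")
        hits = scan_regions({"r": "ACGTACGTAC"}, pwm, 1e-4)
        assert any(h.offset == 0 and h.strand == "+" for h in hits)

    def test_all_n_sequence_has_no_hits(self):
        pwm = consensus_pwm("ACGTACGTAC")
        assert scan_regions({"r": "N" * 50}, pwm, 1e-2) == []

    def test_short_sequence_has_no_hits(self):
        pwm = consensus_pwm("ACGTACGTAC")
        assert scan_regions({"r": "ACGT"}, pwm, 1e-2) == []

    def test_hit_sets_nested_across_thresholds(self, rng):
        pwm = random_pwm(rng, 8)
        seq = "".join(rng.choice(list("ACGT"), size=3_000))
        keys = [
            {(h.region_id, h.offset, h.strand)
             for h in scan_regions({"r": seq}, pwm, thr)}
            for thr in (1e-4, 1e-3, 1e-2)
        ]
        assert keys[0] <= keys[1] <= keys[2]

    def test_reverse_complement_mirrors_hits(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        pwm = random_pwm(rng, 6)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        rc = seq.translate(comp)[::-1]
        fwd = scan_regions({"r": seq}, pwm, 1e-2)
        rev = scan_regions({"r": rc}, pwm, 1e-2)
        L, w = len(seq), pwm.width
        mirrored = {(L - w - h.offset, {"+": "-", "-": "+"}[h.strand],
                     round(h.score, 6)) for h in rev}
        assert {(h.offset, h.strand, round(h.score, 6)) for h in fwd} == mirrored

    def test_lenient_hit_rate_calibrated(self, rng):
        # quick version; the full 3-SD calibration is in the acceptance suite
        pwm = random_pwm(rng, 10)
        dist = exact_score_distribution(pwm, 0.001)
        cutoff = dist.score_cutoff(1e-2)
        expect = 2 * dist.pvalue(cutoff)
        n_pos = 0
        n_hits = 0
        for i in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=2_000))
            n_pos += len(seq) - pwm.width + 1
            n_hits += len(scan_regions({"r": seq}, pwm, 1e-2, granularity=0.001))
        rate = n_hits / n_pos
        sd = np.sqrt(expect * (1 - expect) / n_pos)
        assert abs(rate - expect) < 4 * sd


class TestMotifFractionTest:
    def test_matches_textbook_chi_square(self):
        # 2x2 table [[30,70],[50,50]]: chi2 = sum (o-e)^2/e, df=1
        crm_ids = [f"c{i}" for i in range(100)]
        s_ids = [f"s{i}" for i in range(100)]
        hits = set(crm_ids[:30]) | set(s_ids[:50])
        res = motif_fraction_test(crm_ids, s_ids, hits)
        table = np.array([[30, 70], [50, 50]], dtype=float)
        row, col = table.sum(1, keepdims=True), table.sum(0, keepdims=True)
        expected = row @ col / table.sum()
        chi2 = float(((table - expected) ** 2 / expected).sum())
        assert res.statistic == pytest.approx(chi2)
        assert res.method == "chi2" and res.df == 1

    def test_identical_fractions_give_zero_statistic(self):
        crm_ids = [f"c{i}" for i in range(40)]
        s_ids = [f"s{i}" for i in range(40)]
        hits = set(crm_ids[:20]) | set(s_ids[:20])
        res = motif_fraction_test(crm_ids, s_ids, hits)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_empty_category_rejected(self):
        with pytest.raises(ValidationError):
            motif_fraction_test([], ["s1"], set())

    def test_small_expected_counts_fall_back_to_fisher(self):
        crm_ids = ["c1", "c2", "c3"]
        s_ids = ["s1", "s2", "s3"]
        with pytest.warns(UserWarning, match="Fisher"):
            res = motif_fraction_test(crm_ids, s_ids, {"c1"})
        assert res.method == "fisher"


class TestCompareMatrices:
    def test_self_comparison_is_perfect(self, rng):
        pwm = random_pwm(rng, 8)
        res = compare_matrices(pwm, pwm)
        assert res.shift == 0 and res.strand == "+"
        assert res.correlation == pytest.approx(1.0)
        assert res.ncor == pytest.approx(1.0)

    def test_reverse_complement_found_on_minus(self, rng):
        pwm = random_pwm(rng, 8)
        res = compare_matrices(pwm, pwm.reverse_complement())
        assert res.strand == "-"
        assert res.correlation == pytest.approx(1.0)

    def test_matches_exhaustive_shift_oracle(self, rng):
        def oracle(a, b, min_ov=4):
            best = None
            for strand, mb in (("+", b.matrix),
                               ("-", b.reverse_complement().matrix)):
                wa, wb = len(a.matrix), len(mb)
                for shift in range(-wb + 1, wa):
                    lo, hi = max(0, shift), min(wa, shift + wb)
                    if hi - lo < min_ov:
                        continue
                    x = a.matrix[lo:hi].ravel()
                    y = mb[lo - shift:hi - shift].ravel()
                    if x.std() == 0 or y.std() == 0:
                        r = 0.0
                    else:
                        r = float(np.corrcoef(x, y)[0, 1])
                    ncor = r * (hi - lo) / max(wa, wb)
                    if best is None or ncor > best:
                        best = ncor
            return best

        for _ in range(20):
            a = random_pwm(rng, int(rng.integers(5, 12)))
            b = random_pwm(rng, int(rng.integers(5, 12)))
            res = compare_matrices(a, b)
            assert res.ncor == pytest.approx(oracle(a, b))

    def test_shifted_submotif_recovered(self):
        a = consensus_pwm("AACCGGTTAA")
        b = consensus_pwm("CCGGTT")          # = columns 2..8 of a
        res = compare_matrices(a, b)
        assert res.shift == 2 and res.strand == "+"
        assert res.correlation == pytest.approx(1.0)
        assert res.ncor == pytest.approx(6 / 10)


class TestMatrixIO:
    def test_jaspar_roundtrip(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">MA0001.1 TEST\n"
            "A [ 10  0  5  5 ]\n"
            "C [  0 10  5  0 ]\n"
            "G [  0  0  0  5 ]\n"
            "T [  0  0  0  0 ]\n")
        (pwm,) = read_jaspar(path)
        assert pwm.width == 4
        assert pwm.matrix[0, 0] == pytest.approx(1.0)
        assert pwm.matrix[2, 1] == pytest.approx(0.5)

    def test_meme_minimal(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF TEST1\nletter-probability matrix: alength= 4 w= 4 "
            "nsites= 20 E= 0\n"
            " 0.97 0.01 0.01 0.01\n 0.01 0.97 0.01 0.01\n"
            " 0.01 0.01 0.97 0.01\n 0.01 0.01 0.01 0.97\n")
        (pwm,) = read_meme(path)
        assert pwm.consensus == "ACGT"
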