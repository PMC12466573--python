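import itertools
import math

import numpy as np
import pytest

from regulonkit.core import GenomicInterval, Peak
from regulonkit.motif import (
    PWM,
    ScoreModel,
    build_pwm,
    em_discover,
    iupac_consensus,
    prep_peaks,
    pwm_pvalue_table,
    read_meme,
    revcomp,
    scan_regions,
    scan_sequences,
    shared_regions,
    write_meme,
)
from regulonkit.synth import default_planted_pwm, generate_genome


def make_peak(summit, fe, start=None, end=None, chrom="c1"):
    start = summit - 500 if start is None else start
    end = summit + 500 if end is None else end
    return Peak(
        interval=GenomicInterval(chrom, max(0, start), end, "."),
        summit=summit,
        fold_enrichment=fe,
        neg_log10_q=3.0,
        name=f"p{summit}",
    )


class TestPrepPeaks:
    LENS = {"c1": 10_000}

    def test_fragment_is_201bp(self, cfg):
        (frag,) = prep_peaks([make_peak(800, 2.0)], cfg, self.LENS)
        assert (frag.start, frag.end) == (700, 901)
        assert len(frag) == 201

    def test_fe_boundary_inclusive(self, cfg):
        assert prep_peaks([make_peak(800, 1.74)], cfg, self.LENS) == []
        assert len(prep_peaks([make_peak(800, 1.75)], cfg, self.LENS)) == 1

    def test_clip_at_chromosome_start(self, cfg):
        (frag,) = prep_peaks([make_peak(40, 2.0, start=0, end=500)], cfg, self.LENS)
        assert (frag.start, frag.end) == (0, 141)

    def test_summit_past_chromosome_end(self, cfg):
        peak = make_peak(9_999, 2.0, start=9_000, end=10_000)
        with pytest.raises(ValueError):
            prep_peaks([peak], cfg, {"c1": 9_500})


class TestSharedRegions:
    def test_overlap_boundary(self, cfg):
        a = [GenomicInterval("c1", 0, 201)]
        _, frac50 = shared_regions(a, [GenomicInterval("c1", 151, 352)], cfg)
        _, frac49 = shared_regions(a, [GenomicInterval("c1", 152, 353)], cfg)
        assert frac50 == 1.0
        assert frac49 == 0.0

    def test_identical_sets(self, cfg):
        a = [GenomicInterval("c1", 0, 201), GenomicInterval("c1", 500, 701)]
        pairs, frac = shared_regions(a, a, cfg)
        assert frac == 1.0
        assert len(pairs) == 2

    def test_empty_set_a(self, cfg):
        with pytest.raises(ValueError):
            shared_regions([], [GenomicInterval("c1", 0, 201)], cfg)


class TestBuildPwm:
    def test_one_hot(self):
        pwm = build_pwm(["ACG"] * 4, pseudocount=0.0)
        assert np.allclose(pwm.probs[:, 0], [1, 0, 0, 0])
        assert np.allclose(pwm.probs[:, 2], [0, 0, 1, 0])

    def test_counting(self):
        pwm = build_pwm(["AA", "AC"], pseudocount=0.0)
        assert np.allclose(pwm.probs[:, 1], [0.5, 0.5, 0, 0])

    def test_unequal_lengths(self):
        with pytest.raises(ValueError, match="equal length"):
            build_pwm(["AA", "ACG"])

    def test_non_acgt(self):
        with pytest.raises(ValueError):
            build_pwm(["AN", "AC"])

    def test_recovers_generator_pwm_at_200_sites(self):
        # multinomial sampling error at n=200 keeps every cell within 0.1
        truth = default_planted_pwm()
        rng = np.random.default_rng(0)
        sites = [truth.sample(rng) for _ in range(200)]
        est = build_pwm(sites, pseudocount=0.0)
        assert np.abs(est.probs - truth.probs).max() <= 0.1


class TestIupacConsensus:
    def _pwm(self, col):
        probs = np.tile(np.asarray(col, float)[:, None], (1, 1))
        return PWM(probs=probs / probs.sum(0), background=np.full(4, 0.25))

    def test_one_hot_g(self):
        assert iupac_consensus(self._pwm([0, 0, 1, 0])) == "G"

    def test_two_fold_r(self):
        assert iupac_consensus(self._pwm([0.45, 0.05, 0.45, 0.05])) == "R"

    def test_uniform_n(self):
        assert iupac_consensus(self._pwm([0.25, 0.25, 0.25, 0.25])) == "N"

    def test_planted_structure(self):
        assert default_planted_pwm().consensus() == "TGGCCGRAWHYSRHC"


class TestPvalueTable:
    def test_width1_single_base(self):
        pwm = build_pwm(["A", "A"], pseudocount=0.4)
        tbl = pwm_pvalue_table(pwm)
        assert tbl.pvalue(tbl.max_total) == pytest.approx(0.25)

    def test_survival_function_monotone(self):
        pwm = default_planted_pwm()
        tbl = pwm_pvalue_table(pwm)
        assert (np.diff(tbl.sf) <= 1e-12).all()

    def test_total_probability(self):
        tbl = pwm_pvalue_table(default_planted_pwm())
        assert tbl.pmf.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("width", [1, 2, 3, 4, 5])
    def test_matches_exhaustive_enumeration(self, width):
        # oracle: enumerate all 4^width words, score each with the same
        # discretized bins, and accumulate exact background probabilities
        rng = np.random.default_rng(width)
        raw = rng.dirichlet(np.ones(4) * 2, size=width).T
        bg = np.array([0.14, 0.36, 0.36, 0.14])
        pwm = PWM(probs=raw, background=bg)
        tbl = pwm_pvalue_table(pwm)
        word_scores = {}
        for word in itertools.product(range(4), repeat=width):
            score = sum(int(tbl.bin_scores[b, j]) for j, b in enumerate(word))
            prob = math.prod(bg[b] for b in word)
            word_scores[word] = (score, prob)
        for s in {sc for sc, _ in word_scores.values()}:
            oracle_p = sum(p for sc, p in word_scores.values() if sc >= s)
            assert tbl.pvalue(s) == pytest.approx(oracle_p, abs=1e-12)

    def test_granularity_positive(self):
        with pytest.raises(ValueError):
            pwm_pvalue_table(default_planted_pwm(), granularity=0)


class TestScan:
    def test_planted_consensus_found(self):
        consensus = "TGGCCGTACGGATCA"
        pwm = build_pwm([consensus] * 3, pseudocount=0.1)
        seq = "AT" * 40 + consensus + "GC" * 40
        hits = scan_sequences(pwm, {"c1": seq}, 1e-4)
        fwd = [h for h in hits if h.strand == "+"]
        assert any(h.interval.start == 80 for h in fwd)
        assert all(h.matched_seq == consensus for h in fwd)

    def test_reverse_complement_found_on_minus(self):
        consensus = "TGGCCGTACGGATCA"
        pwm = build_pwm([consensus] * 3, pseudocount=0.1)
        seq = "AT" * 40 + revcomp(consensus) + "GC" * 40
        hits = scan_sequences(pwm, {"c1": seq}, 1e-4)
        minus = [h for h in hits if h.strand == "-"]
        assert any(h.interval.start == 80 for h in minus)
        assert all(h.matched_seq == consensus for h in minus if h.interval.start == 80)

    def test_impossible_threshold_gives_no_hits(self):
        pwm = default_planted_pwm()
        tbl = pwm_pvalue_table(pwm)
        p_best = tbl.pvalue(tbl.max_total)
        seq = generate_genome(1, 20_000, 0.5)["synchr1"]
        assert scan_sequences(pwm, {"c1": seq}, p_best / 10) == []

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            scan_sequences(default_planted_pwm(), {"c1": "ACGT" * 10}, 0.0)

    def test_windows_with_n_skipped(self):
        consensus = "TGGCCGTACGGATCA"
        pwm = build_pwm([consensus] * 3, pseudocount=0.1)
        seq = consensus.replace("A", "N", 1) + "T" * 30 + consensus
        hits = scan_sequences(pwm, {"c1": seq}, 1e-4)
        assert {h.interval.start for h in hits if h.strand == "+"} == {45}

    def test_mirror_symmetry_on_reverse_complement(self):
        # scanning the reverse complement swaps strands and mirrors coordinates
        pwm = default_planted_pwm()
        seq = _rand_seq(np.random.default_rng(9), 5_000, gc=0.6)
        hits_f = scan_sequences(pwm, {"c1": seq}, 1e-3, both_strands=True)
        hits_r = scan_sequences(pwm, {"c1": revcomp(seq)}, 1e-3, both_strands=True)
        n = len(seq)
        mirrored = {
            (n - h.interval.end, "-" if h.strand == "+" else "+") for h in hits_r
        }
        assert {(h.interval.start, h.strand) for h in hits_f} == mirrored

    @pytest.mark.parametrize("width", [3, 4, 5])
    def test_matches_bruteforce_window_oracle(self, width):
        # oracle: score every window against the enumerated exact p-values
        rng = np.random.default_rng(width + 10)
        raw = rng.dirichlet(np.ones(4), size=width).T
        pwm = PWM(probs=raw, background=np.full(4, 0.25))
        tbl = pwm_pvalue_table(pwm)
        word_p = {}
        for word in itertools.product("ACGT", repeat=width):
            s = sum(int(tbl.bin_scores["ACGT".index(b), j]) for j, b in enumerate(word))
            word_p["".join(word)] = tbl.pvalue(s)
        seq = _rand_seq(np.random.default_rng(3), 2_000)
        for p_max, inclusive in [(1e-2, False), (1e-2, True), (0.05, False)]:
            hits = scan_sequences(
                pwm, {"c1": seq}, p_max, both_strands=True, inclusive=inclusive
            )
            got = {(h.interval.start, h.strand) for h in hits}
            expect = set()
            for i in range(len(seq) - width + 1):
                w = seq[i : i + width]
                if (word_p[w] <= p_max if inclusive else word_p[w] < p_max):
                    expect.add((i, "+"))
                wr = revcomp(w)
                if (word_p[wr] <= p_max if inclusive else word_p[wr] < p_max):
                    expect.add((i, "-"))
            assert got == expect

    def test_scan_regions_maps_to_genomic_coordinates(self):
        consensus = "TGGCCGTACGGATCA"
        pwm = build_pwm([consensus] * 3, pseudocount=0.1)
        seq = "A" * 500 + consensus + "G" * 500
        region = GenomicInterval("c1", 450, 600, ".")
        hits = scan_regions(pwm, {"c1": seq}, [region], 1e-4)
        assert any(h.interval.start == 500 and h.strand == "+" for h in hits)

    def test_scan_regions_deduplicates_overlaps(self):
        consensus = "TGGCCGTACGGATCA"
        pwm = build_pwm([consensus] * 3, pseudocount=0.1)
        seq = "A" * 500 + consensus + "G" * 500
        regions = [GenomicInterval("c1", 450, 600), GenomicInterval("c1", 480, 620)]
        hits = scan_regions(pwm, {"c1": seq}, regions, 1e-4)
        starts = [h.interval.start for h in hits if h.strand == "+"]
        assert starts.count(500) == 1


class TestEmDiscover:
    def test_recovers_planted_motif(self):
        truth = default_planted_pwm()
        rng = np.random.default_rng(11)
        bg = np.array([0.14, 0.36, 0.36, 0.14])
        seqs = []
        for _ in range(200):
            frag = list("".join(rng.choice(list("ACGT"), p=bg) for _ in range(201)))
            site = truth.sample(rng)
            pos = int(rng.integers(0, 201 - truth.width))
            frag[pos : pos + truth.width] = list(site)
            seqs.append("".join(frag))
        pwm, sites = em_discover(seqs, truth.width, restarts=8, seed=11)
        assert len(sites) > 100
        dist = _consensus_distance(pwm, truth, min_prob=0.9)
        assert dist <= 1

    def test_null_background_low_information(self):
        # frozen regression value: at seed 5 the null IC lands at ~0.43
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=201)) for _ in range(200)]
        pwm, _ = em_discover(seqs, 15, restarts=2, seed=5)
        assert pwm.information_content < 0.5

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(30)]
        a, _ = em_discover(seqs, 8, restarts=3, seed=4)
        b, _ = em_discover(seqs, 8, restarts=3, seed=4)
        assert np.array_equal(a.probs, b.probs)

    def test_all_too_short(self):
        with pytest.raises(ValueError):
            em_discover(["ACGT", "AC"], 15, restarts=1, seed=0)


class TestMemeIO:
    def test_round_trip(self, tmp_path):
        pwm = default_planted_pwm()
        p = tmp_path / "motif.meme"
        write_meme(pwm, p)
        back = read_meme(p)
        assert back.width == pwm.width
        assert np.abs(back.probs - pwm.probs).max() < 1e-5
        assert np.allclose(back.background, pwm.background, atol=1e-5)


def _rand_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _consensus_distance(found: PWM, truth: PWM, min_prob: float) -> int:
    """Hamming distance on truth columns with a base probability >= min_prob,
    minimized over strand (discovery is defined only up to orientation)."""
    best = None
    for cand in (found, found.reverse_complement()):
        d = 0
        for j in range(truth.width):
            b = int(np.argmax(truth.probs[:, j]))
            if truth.probs[b, j] < min_prob:
                continue
            if int(np.argmax(cand.probs[:, j])) != b:
                d += 1
        best = d if best is None else min(best, d)
    return best
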