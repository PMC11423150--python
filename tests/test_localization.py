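"""Chromosome scanning, top-region selection, PWM motif significance."""

import numpy as np
import pytest

from nldnn.localization import (
    PWMScanner,
    intersect_ratio,
    motif_instance_ratio,
    scan_chromosome,
    select_top_regions,
    ScanResult,
)
from nldnn.synthetic import default_motif_pwm, revcomp
from nldnn.windows import BASES, GenomeAssembly, IntervalSet


class ConstantZeroModel:
    def predict(self, x, batch_size=64):
        return np.zeros((len(x), x.shape[2]))


@pytest.fixture(scope="module")
def genome1800():
    rng = np.random.default_rng(2)
    return GenomeAssembly({"chr1": "".join(rng.choice(list("ACGT"), size=1800))})


class TestScan:
    def test_chromosome_1800_gives_three_windows(self, genome1800):
        scan = scan_chromosome(ConstantZeroModel(), genome1800, "chr1")
        assert list(scan.starts) == [0, 600, 1200]

    def test_partial_final_window_dropped(self):
        rng = np.random.default_rng(0)
        g = GenomeAssembly({"c": "".join(rng.choice(list("ACGT"), size=1999))})
        scan = scan_chromosome(ConstantZeroModel(), g, "c")
        assert len(scan.starts) == 3

    def test_constant_zero_model_leftmost_ties(self, genome1800):
        scan = scan_chromosome(ConstantZeroModel(), genome1800, "chr1")
        assert np.array_equal(scan.max_values, np.zeros(3))
        assert np.array_equal(scan.max_positions, scan.starts)

    def test_maxima_match_per_window_loop(self, genome1800, tiny_model):
        scan = scan_chromosome(tiny_model, genome1800, "chr1")
        from nldnn.windows import one_hot

        for i, s in enumerate(scan.starts):
            seq = genome1800["chr1"][s : s + 600]
            pred = np.maximum(tiny_model.predict(one_hot(seq)[None])[0], 0.0)
            assert np.isclose(scan.max_values[i], pred.max(), atol=1e-12)
            assert scan.max_positions[i] == s + pred.argmax()


class TestSelectTop:
    def _scan(self, values):
        n = len(values)
        return ScanResult("chr1", 600, np.arange(n) * 600, np.asarray(values),
                          np.arange(n) * 600)

    def test_three_hundred_windows_top_percent_is_three(self):
        scan = self._scan(np.arange(300.0))
        regions = select_top_regions(scan, 0.01)
        assert len(regions) == 3
        starts = [s for _, s, _ in ((c, s, e) for c, s, e, *_ in regions)]
        assert starts == [297 * 600, 298 * 600, 299 * 600]

    def test_fraction_one_selects_all(self):
        scan = self._scan(np.arange(10.0))
        assert len(select_top_regions(scan, 1.0)) == 10

    def test_at_least_one_region(self):
        scan = self._scan(np.array([1.0, 2.0]))
        assert len(select_top_regions(scan, 0.01)) == 1

    def test_ties_break_leftmost(self):
        scan = self._scan(np.array([5.0, 5.0, 5.0, 1.0]))
        regions = select_top_regions(scan, 0.5)
        starts = [s for _, s, *_ in regions]
        assert starts == [0, 600]

    def test_matches_full_sort_oracle(self, rng):
        values = rng.normal(size=200)
        scan = self._scan(values)
        regions = select_top_regions(scan, 0.05)
        k = 10
        oracle = sorted(np.lexsort((np.arange(200), -values))[:k] * 600)
        starts = [s for _, s, *_ in regions]
        assert starts == list(oracle)

    def test_monotone_in_fraction(self, rng):
        values = rng.normal(size=100)
        scan = self._scan(values)
        sizes = [len(select_top_regions(scan, f)) for f in (0.01, 0.1, 0.5, 1.0)]
        assert sizes == sorted(sizes)


class TestIntersectRatio:
    def test_full_cover_gives_one(self):
        regions = IntervalSet([("chr1", 0, 600), ("chr1", 600, 1200)])
        peaks = IntervalSet([("chr1", 0, 10_000)])
        assert intersect_ratio(regions, peaks) == 1.0

    def test_no_peaks_gives_zero(self):
        regions = IntervalSet([("chr1", 0, 600)])
        assert intersect_ratio(regions, IntervalSet()) == 0.0

    def test_matches_allpairs_oracle(self, rng):
        regions = IntervalSet()
        for i in range(20):
            regions.add("chr1", i * 1000, i * 1000 + 600)
        peak_list = [(int(s), int(s) + 300) for s in rng.integers(0, 20_000, 10)]
        peaks = IntervalSet([("chr1", s, e) for s, e in peak_list])
        expected = np.mean([
            any(s < pe and ps < e for ps, pe in peak_list)
            for _, s, e, *_ in regions
        ])
        assert np.isclose(intersect_ratio(regions, peaks), expected)


class TestPWMScanner:
    def test_consensus_scores_maximum(self):
        pwm = default_motif_pwm(width=8, seed=1)
        scanner = PWMScanner(pwm)
        consensus = "".join(BASES[i] for i in pwm.argmax(axis=0))
        scores = scanner.score_sequence(consensus)
        assert scores[0] == scanner.int_scores.max(axis=0).sum()

    def test_exact_null_matches_enumeration_on_tiny_pwm(self):
        """Brute-force oracle: enumerate all 4^5 windows under a non-uniform
        background and compare tail probabilities."""
        rng = np.random.default_rng(3)
        pwm = rng.dirichlet(np.ones(4), size=5).T  # (4, 5)
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        scanner = PWMScanner(pwm, background=bg)
        from itertools import product

        probs, scores = [], []
        for word in product(range(4), repeat=5):
            p = np.prod([bg[b] for b in word])
            s = sum(scanner.int_scores[b, j] for j, b in enumerate(word))
            probs.append(p)
            scores.append(s)
        probs, scores = np.array(probs), np.array(scores)
        for q in (0.5, 0.9, 0.99, 0.9999):
            thr = np.quantile(scores, q)
            exact = probs[scores >= thr].sum()
            assert np.isclose(scanner.pvalue(int(thr)), exact, atol=1e-9)

    def test_hits_match_bruteforce_on_1kb(self, rng):
        pwm = default_motif_pwm(width=9, seed=2)
        scanner = PWMScanner(pwm)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        # plant a consensus to guarantee at least one hit
        consensus = "".join(BASES[i] for i in pwm.argmax(axis=0))
        seq = seq[:500] + consensus + seq[509:]
        hits = scanner.hits(seq, 1e-4)
        thr = scanner.threshold_score(1e-4)
        expected = []
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for i in range(len(s) - 9 + 1):
                score = sum(scanner.int_scores[BASES.index(s[i + j]), j]
                            for j in range(9))
                if score >= thr:
                    pos = i if strand == "+" else len(seq) - 9 - i
                    expected.append((pos, strand))
        assert sorted(hits) == sorted(expected)
        assert (500, "+") in hits

    def test_false_hit_rate_calibrated_to_nominal_level(self):
        """Per-position hit rate on random background matches the exact
        achieved level near 1e-4 (binomial tolerance)."""
        rng = np.random.default_rng(7)
        pwm = rng.dirichlet(np.full(4, 2.0), size=12).T
        scanner = PWMScanner(pwm)
        level = scanner.achieved_level(1e-4)
        assert level < 1e-4
        n = 400_000
        seq = "".join(rng.choice(list("ACGT"), size=n + 11))
        scores = scanner.score_sequence(seq)
        thr = scanner.threshold_score(1e-4)
        hit_rate = float((scores >= thr).mean())
        # binomial 4-sigma band around the exact level
        sigma = np.sqrt(level * (1 - level) / n)
        assert abs(hit_rate - level) < 4 * sigma + 1e-7
        # and the discretized null puts the achieved level close to nominal
        assert level > 1e-5

    def test_zero_entries_get_pseudocount(self):
        pwm = np.zeros((4, 4))
        pwm[0] = 1.0
        scanner = PWMScanner(pwm)
        assert np.isfinite(scanner.int_scores).all()


class TestMotifInstanceRatio:
    def test_planted_consensus_counted(self, rng):
        pwm = default_motif_pwm(width=10, seed=5)
        consensus = "".join(BASES[i] for i in pwm.argmax(axis=0))
        bg = "".join(rng.choice(list("ACGT"), size=1200))
        seq = bg[:300] + consensus + bg[310:]
        genome = GenomeAssembly({"chr1": seq})
        with_motif = IntervalSet([("chr1", 0, 600)])
        without = IntervalSet([("chr1", 600, 1200)])
        assert motif_instance_ratio(with_motif, genome, pwm) == 1.0
        assert motif_instance_ratio(without, genome, pwm) in (0.0, 1.0)  # bg rarely hits
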