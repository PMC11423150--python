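"""Synthetic world generator: determinism, planted structure, domain gap."""

import numpy as np
import pytest
from scipy import stats

from nldnn.synthetic import (
    SyntheticSpec,
    default_motif_pwm,
    kmer_counts,
    make_genome,
    make_variant_set,
    revcomp,
)
from nldnn.windows import BASES


def small_spec(**overrides):
    kwargs = dict(genome_length_per_chrom=30_000, chrom_names=("chr1",),
                  n_peaks=4, seed=11)
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


class TestSpecValidation:
    def test_pwm_columns_must_sum_to_one(self):
        bad = np.full((4, 5), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            small_spec(motif_pwm=bad)

    def test_halfwidth_bounded_by_window(self):
        with pytest.raises(ValueError, match="halfwidth"):
            small_spec(peak_halfwidth=300)

    def test_genome_length_floor(self):
        with pytest.raises(ValueError, match="genome length"):
            SyntheticSpec(genome_length_per_chrom=1000)


class TestMakeGenome:
    def test_deterministic_given_seed_and_species(self):
        spec = small_spec()
        g1, t1 = make_genome(spec, "A")
        g2, t2 = make_genome(spec, "A")
        assert g1["chr1"] == g2["chr1"]
        assert np.array_equal(t1.coverage.tracks["chr1"], t2.coverage.tracks["chr1"])
        assert list(t1.peaks) == list(t2.peaks)

    def test_species_differ(self):
        spec = small_spec()
        ga, _ = make_genome(spec, "A")
        gb, _ = make_genome(spec, "B")
        assert ga["chr1"] != gb["chr1"]

    def test_no_peaks_gives_pure_noise(self):
        spec = small_spec(n_peaks=0, noise_sd=0.5)
        _, truth = make_genome(spec, "A")
        assert len(truth.peaks) == 0
        cov = truth.coverage.tracks["chr1"]
        assert cov.max() < 5 * 0.5  # just truncated noise

    def test_noiseless_single_peak_max_equals_amplitude(self):
        spec = small_spec(n_peaks=1, noise_sd=0.0, peak_amplitude_range=(7.5, 7.5))
        _, truth = make_genome(spec, "A")
        cov = truth.coverage.tracks["chr1"]
        (chrom, start, end, *_), = list(truth.peaks)
        center = (start + end) // 2
        assert np.isclose(cov.max(), 7.5, atol=1e-9)
        assert abs(int(np.argmax(cov)) - center) <= 1

    def test_every_motif_inside_exactly_one_peak(self):
        spec = small_spec()
        _, truth = make_genome(spec, "A")
        W = spec.motif_pwm.shape[1]
        for chrom, start, _ in truth.motif_positions:
            containing = [1 for c, s, e, *_ in truth.peaks
                          if c == chrom and s <= start and start + W <= e]
            assert sum(containing) == 1

    def test_planted_motifs_match_consensus(self):
        spec = small_spec()
        genome, truth = make_genome(spec, "A")
        consensus = "".join(BASES[i] for i in spec.motif_pwm.argmax(axis=0))
        W = len(consensus)
        agreements = []
        for chrom, start, strand in truth.motif_positions:
            seq = genome[chrom][start : start + W]
            if strand == "-":
                seq = revcomp(seq)
            agreements.append(sum(a == b for a, b in zip(seq, consensus)) / W)
        # PWM is 0.92-sharp: near-consensus on average
        assert np.mean(agreements) > 0.8

    def test_coverage_nonnegative(self):
        spec = small_spec(noise_sd=2.0)
        _, truth = make_genome(spec, "A")
        assert truth.coverage.tracks["chr1"].min() >= 0

    def test_peak_signal_clears_background(self):
        # amplitude_min > 4 * noise_sd => in-peak maxima beat the 99th
        # percentile of out-of-peak coverage
        spec = small_spec(peak_amplitude_range=(5.0, 20.0), noise_sd=0.4)
        _, truth = make_genome(spec, "A")
        cov = truth.coverage.tracks["chr1"]
        mask = np.zeros(len(cov), dtype=bool)
        for _, s, e, *_ in truth.peaks:
            mask[s:e] = True
        in_peak_max = min(cov[s:e].max() for _, s, e, *_ in truth.peaks)
        background_q99 = np.quantile(cov[~mask], 0.99)
        assert in_peak_max > background_q99

    def test_too_many_peaks_raises_placement_error(self):
        with pytest.raises(ValueError, match="genome_length_per_chrom"):
            make_genome(small_spec(n_peaks=50), "A")

    def test_accessibility_track_generated(self):
        spec = small_spec(accessibility=True)
        _, truth = make_genome(spec, "A")
        assert truth.accessibility is not None
        acc = truth.accessibility.tracks["chr1"]
        assert acc.min() >= 0 and acc.max() > 1


class TestDomainGap:
    def test_species_differ_in_kmer_profile_but_share_motif(self):
        """Chi-square on 3-mer counts: A-vs-B exceeds A-vs-A (median, 10 seeds)."""

        def chi2(c1, c2):
            tot = c1 + c2 + 1e-9
            e1 = tot * c1.sum() / tot.sum()
            e2 = tot * c2.sum() / tot.sum()
            return float((((c1 - e1) ** 2) / (e1 + 1e-9)).sum()
                         + (((c2 - e2) ** 2) / (e2 + 1e-9)).sum())

        across, within = [], []
        for seed in range(10):
            spec1 = small_spec(seed=100 + seed)
            spec2 = small_spec(seed=200 + seed)
            ga, _ = make_genome(spec1, "A")
            gb, _ = make_genome(spec1, "B")
            ga2, _ = make_genome(spec2, "A")
            ca = kmer_counts(ga["chr1"])
            cb = kmer_counts(gb["chr1"])
            ca2 = kmer_counts(ga2["chr1"])
            across.append(chi2(ca, cb))
            within.append(chi2(ca, ca2))
        assert np.median(across) > np.median(within)


@pytest.fixture(scope="module")
def world():
    spec = small_spec()
    genome, truth = make_genome(spec, "A")
    return spec, genome, truth


class TestVariantSet:

    def test_count_contract(self, world):
        spec, genome, truth = world
        table = make_variant_set(truth, genome, n_pos=1, n_neg_per_pos=3, seed=0)
        assert (table.label == "positive").sum() == 1
        assert (table.label == "negative").sum() <= 3

    def test_ref_matches_genome(self, world):
        spec, genome, truth = world
        table = make_variant_set(truth, genome, n_pos=5, seed=1)
        for rec in table.itertuples():
            assert genome[rec.chrom][rec.pos] == rec.ref
            assert rec.ref != rec.alt

    def test_negatives_within_ld_radius_outside_motifs(self, world):
        """Brute-force distance scan: every negative is LD-proximal to a
        positive and no negative falls inside a planted motif."""
        spec, genome, truth = world
        ld = 400
        W = spec.motif_pwm.shape[1]
        table = make_variant_set(truth, genome, n_pos=5, n_neg_per_pos=4,
                                 ld_radius=ld, seed=2, motif_width=W)
        pos = table[table.label == "positive"]
        motif_spans = [(c, s, s + W) for c, s, _ in truth.motif_positions]
        for rec in table[table.label == "negative"].itertuples():
            dists = [abs(rec.pos - p.pos) for p in pos.itertuples()
                     if p.chrom == rec.chrom]
            assert min(dists) <= ld
            assert not any(c == rec.chrom and s <= rec.pos < e
                           for c, s, e in motif_spans)

    def test_positives_inside_motifs(self, world):
        spec, genome, truth = world
        W = spec.motif_pwm.shape[1]
        table = make_variant_set(truth, genome, n_pos=5, seed=3, motif_width=W)
        spans = [(c, s, s + W) for c, s, _ in truth.motif_positions]
        for rec in table[table.label == "positive"].itertuples():
            assert any(c == rec.chrom and s <= rec.pos < e for c, s, e in spans)

    def test_too_many_positives_requested(self, world):
        spec, genome, truth = world
        with pytest.raises(ValueError, match="motif instances"):
            make_variant_set(truth, genome, n_pos=10_000)


class TestHelpers:
    def test_revcomp(self):
        assert revcomp("ACGTN") == "NACGT"

    def test_kmer_counts_total(self):
        counts = kmer_counts("ACGTACGT", k=3)
        assert counts.sum() == 6  # L - k + 1

    def test_kmer_counts_skip_n(self):
        assert kmer_counts("ACNGT", k=3).sum() == 0

    def test_default_pwm_columns_sum_to_one(self):
        pwm = default_motif_pwm()
        assert np.allclose(pwm.sum(axis=0), 1.0)
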