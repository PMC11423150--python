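"""Synthetic two-species genomes with planted TF binding.

Generates everything the rest of the stack consumes, with the statistical
structure the method assumes: an order-2 Markov background drawn from a
species-specific 3-mer table, a species-private repeat element, non-overlapping
binding peaks each carrying a homotypic cluster of planted motif instances, a
peak-shaped per-base coverage track with truncated Gaussian noise, an optional
accessibility track, and TF-specific variant sets with nearby (LD-proximal)
negatives.

The two species share the motif PWM exactly while differing in background
composition — the domain gap that cross-species adaptation must bridge.
Binding strength is realized through motif multiplicity (homotypic clusters):
peak amplitude grows with the number of planted copies, so the regression
target is genuinely predictable from sequence.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import BASES, CoverageTrack, GenomeAssembly, IntervalSet

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def default_motif_pwm(width: int = 12, sharpness: float = 0.92, seed: int = 7) -> np.ndarray:
    """A sharp random motif: one dominant base per column at `sharpness`."""
    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 4, size=width)
    pwm = np.full((4, width), (1.0 - sharpness) / 3.0)
    pwm[consensus, np.arange(width)] = sharpness
    return pwm


def default_kmer_tables() -> dict[str, np.ndarray]:
    """Distinct 3-mer tables: species A skews GC-rich, species B AT-rich.

    Entry [c, b] is P(base b | preceding dinucleotide c), contexts indexed as
    4*first + second.
    """
    tables = {}
    for species, gc in (("A", 0.60), ("B", 0.38)):
        at = (1.0 - gc) / 2.0
        base_p = np.array([at, gc / 2.0, gc / 2.0, at])
        rng = np.random.default_rng(zlib.crc32(species.encode()))
        table = np.empty((16, 4))
        for ctx in range(16):
            jitter = rng.dirichlet(np.full(4, 8.0))
            p = 0.7 * base_p + 0.3 * jitter
            table[ctx] = p / p.sum()
        tables[species] = table
    return tables


def default_repeats(motif_pwm: np.ndarray | None = None) -> dict[str, tuple[str, float]]:
    """Species-private repeat elements (SINE-like short interspersed runs).

    The target species' repeat embeds a one-mismatch decoy of the motif
    consensus.  A one-mismatch site lies inside the natural instance
    distribution, so any detector robust to sampling noise scores it like a
    true site; within the target species the decoy's fixed repeat flanks make
    it abundant, recognizable background, but a model trained on the other
    species has never seen it labeled negative — the species-specific context
    feature that degrades cross-species prediction.
    """
    if motif_pwm is None:
        motif_pwm = default_motif_pwm()
    consensus = [BASES[i] for i in np.asarray(motif_pwm).argmax(axis=0)]
    decoy = consensus.copy()
    pos = 5 % len(decoy)  # one fixed substitution breaks the exact site
    decoy[pos] = BASES[(BASES.index(decoy[pos]) + 1) % 4]
    decoy_seq = "".join(decoy)
    return {
        "A": ("GGCCGGGCGCGGTGGCTCACGCCTGTAATCC", 0.03),
        "B": ("TTAGAGAC" + decoy_seq + "ATCACTTTGGG", 0.08),
    }


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic world (both species)."""

    genome_length_per_chrom: int = 100_000
    chrom_names: tuple[str, ...] = ("chr1", "chr2")
    motif_pwm: np.ndarray = field(default_factory=default_motif_pwm)
    n_peaks: int = 60  # total across chromosomes, split evenly
    peak_halfwidth: int = 120
    peak_amplitude_range: tuple[float, float] = (4.0, 30.0)
    background_kmer_bias: dict[str, np.ndarray] = field(default_factory=default_kmer_tables)
    repeat_element: dict[str, tuple[str, float]] | None = None  # default derives from PWM
    noise_sd: float = 0.4
    accessibility: bool = False
    seed: int = 0

    def __post_init__(self):
        self.motif_pwm = np.asarray(self.motif_pwm, dtype=float)
        if not np.allclose(self.motif_pwm.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if self.repeat_element is None:
            self.repeat_element = default_repeats(self.motif_pwm)
        if self.peak_halfwidth * 2 >= 600:
            raise ValueError("peak_halfwidth*2 must be < window length 600")
        for species, (_, rate) in self.repeat_element.items():
            if not 0 <= rate < 1:
                raise ValueError(f"insertion_rate for {species} must be in [0,1)")
        if self.genome_length_per_chrom < 10 * 600:
            raise ValueError("genome length must be >= 6000 bases per chromosome")


@dataclass
class SyntheticTruth:
    """Ground truth for one species' genome."""

    peaks: IntervalSet
    motif_positions: list[tuple[str, int, str]]  # (chrom, start, strand)
    coverage: CoverageTrack
    accessibility: CoverageTrack | None = None


def _species_rng(spec: SyntheticSpec, species_id: str) -> np.random.Generator:
    return np.random.default_rng([spec.seed, zlib.crc32(species_id.encode())])


def _markov_sequence(rng: np.random.Generator, table: np.ndarray, length: int) -> np.ndarray:
    """Order-2 Markov chain over base indices, contexts = 4*prev2 + prev1."""
    cum = np.cumsum(table, axis=1)
    cum[:, -1] = 1.0
    out = np.empty(length, dtype=np.int8)
    out[0] = rng.integers(0, 4)
    out[1] = rng.integers(0, 4)
    u = rng.random(length)
    for i in range(2, length):
        ctx = 4 * out[i - 2] + out[i - 1]
        out[i] = np.searchsorted(cum[ctx], u[i], side="right")
    return out


def _sample_motif(rng: np.random.Generator, pwm: np.ndarray) -> np.ndarray:
    width = pwm.shape[1]
    u = rng.random(width)
    cum = np.cumsum(pwm, axis=0)
    return np.array([np.searchsorted(cum[:, j], u[j], side="right") for j in range(width)],
                    dtype=np.int8)


def make_genome(
    spec: SyntheticSpec, species_id: str
) -> tuple[GenomeAssembly, SyntheticTruth]:
    """Generate one species' genome, planted peaks, and coverage.

    Deterministic given (spec.seed, species_id).  Peaks are non-overlapping
    intervals of width 4*halfwidth; each holds a homotypic cluster of 4-12
    motif copies and a Gaussian coverage bump whose amplitude interpolates the
    amplitude range with copy number.  Coverage noise is N(0, noise_sd)
    truncated at zero.
    """
    rng = _species_rng(spec, species_id)
    table = spec.background_kmer_bias[species_id]
    repeat_seq, repeat_rate = spec.repeat_element[species_id]
    W = spec.motif_pwm.shape[1]
    hw = spec.peak_halfwidth
    peak_half_extent = 2 * hw
    a_min, a_max = spec.peak_amplitude_range
    n_chroms = len(spec.chrom_names)
    peaks_per_chrom = [
        spec.n_peaks // n_chroms + (1 if i < spec.n_peaks % n_chroms else 0)
        for i in range(n_chroms)
    ]

    chroms: dict[str, str] = {}
    peaks = IntervalSet()
    motif_positions: list[tuple[str, int, str]] = []
    cov: dict[str, np.ndarray] = {}
    acc: dict[str, np.ndarray] = {}

    for chrom, n_peaks in zip(spec.chrom_names, peaks_per_chrom):
        L = spec.genome_length_per_chrom
        seq = _markov_sequence(rng, table, L)

        # non-overlapping peak centers with clearance for negatives between
        margin = peak_half_extent + 600
        min_gap = 2 * peak_half_extent + 1200
        span = L - 2 * margin
        if n_peaks > 0 and span < (n_peaks - 1) * min_gap:
            raise ValueError(
                f"cannot place {n_peaks} non-overlapping peaks on a "
                f"{L}-base chromosome; limiting parameter: genome_length_per_chrom"
            )
        if n_peaks > 0:
            slack = span - (n_peaks - 1) * min_gap
            cuts = np.sort(rng.random(n_peaks)) * slack
            centers = (margin + cuts + np.arange(n_peaks) * min_gap).astype(int)
        else:
            centers = np.array([], dtype=int)

        # repeat insertions outside peaks
        n_repeats = int(repeat_rate * L / len(repeat_seq))
        repeat_arr = np.array([BASES.index(b) for b in repeat_seq], dtype=np.int8)
        placed = 0
        guard = 0
        while placed < n_repeats and guard < 20 * n_repeats:
            guard += 1
            pos = int(rng.integers(0, L - len(repeat_seq)))
            if centers.size and np.any(
                np.abs(centers - pos) < peak_half_extent + len(repeat_seq)
            ):
                continue
            seq[pos : pos + len(repeat_arr)] = repeat_arr
            placed += 1

        coverage = np.zeros(L)
        for center in centers:
            # homotypic motif cluster: two copies anchored in the peak-edge
            # strips (so every window overlapping the peak by >20% of 600 bp
            # contains a full motif) plus interior copies; total copy number
            # grades the binding strength (amplitude)
            n_extra = int(rng.integers(2, 11))
            n_copies = 2 + n_extra
            amplitude = a_min + (a_max - a_min) * (n_extra - 2) / 8.0
            strip = 121  # minimum qualifying overlap, bases
            left = int(rng.integers(-2 * hw, -2 * hw + strip - W + 1))
            right = int(rng.integers(2 * hw - strip, 2 * hw - W + 1))
            offsets = [left, right]
            slots = np.arange(-2 * hw + strip, 2 * hw - strip - W, W + 4)
            extra = rng.choice(slots, size=min(n_extra, len(slots)), replace=False)
            offsets.extend(int(e) for e in extra)
            for off in offsets:
                start = int(center + off)
                motif = _sample_motif(rng, spec.motif_pwm)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    motif_str = revcomp("".join(BASES[b] for b in motif))
                    motif = np.array([BASES.index(b) for b in motif_str], dtype=np.int8)
                seq[start : start + W] = motif
                motif_positions.append((chrom, start, strand))
            lo = max(0, center - 3 * hw)
            hi = min(L, center + 3 * hw + 1)
            d = np.arange(lo, hi) - center
            coverage[lo:hi] += amplitude * np.exp(-(d**2) / (2.0 * hw**2))
            peaks.add(chrom, center - peak_half_extent, center + peak_half_extent)

        if spec.noise_sd > 0:
            coverage = coverage + rng.normal(0.0, spec.noise_sd, size=L)
        coverage = np.maximum(coverage, 0.0)

        if spec.accessibility:
            access = np.zeros(L)
            for center in centers:
                lo = max(0, center - 6 * hw)
                hi = min(L, center + 6 * hw + 1)
                d = np.arange(lo, hi) - center
                access[lo:hi] += 10.0 * np.exp(-(d**2) / (2.0 * (2 * hw) ** 2))
            # accessible-but-unbound regions: open chromatin without motif
            for _ in range(max(1, n_peaks // 2)):
                center = int(rng.integers(margin, L - margin))
                if centers.size and np.min(np.abs(centers - center)) < 2 * peak_half_extent:
                    continue
                lo, hi = max(0, center - 4 * hw), min(L, center + 4 * hw + 1)
                d = np.arange(lo, hi) - center
                access[lo:hi] += 6.0 * np.exp(-(d**2) / (2.0 * (2 * hw) ** 2))
            acc[chrom] = np.maximum(access + rng.normal(0, spec.noise_sd, L), 0.0)

        chroms[chrom] = "".join(BASES[b] for b in seq)
        cov[chrom] = coverage

    genome = GenomeAssembly(chroms)
    truth = SyntheticTruth(
        peaks=peaks,
        motif_positions=motif_positions,
        coverage=CoverageTrack(cov),
        accessibility=CoverageTrack(acc) if spec.accessibility else None,
    )
    return genome, truth


def make_variant_set(
    truth: SyntheticTruth,
    genome: GenomeAssembly,
    n_pos: int,
    n_neg_per_pos: int = 3,
    ld_radius: int = 500,
    seed: int = 0,
    motif_width: int = 12,
) -> pd.DataFrame:
    """TF-specific variants: positives inside motif instances, negatives nearby.

    Positives substitute a single base inside a planted motif instance;
    negatives substitute bases within `ld_radius` of a positive but outside
    every motif instance, emulating LD-proximal non-functional SNPs.  Each
    positive defines an LD group carrying a causal flag.
    """
    if len(truth.motif_positions) < n_pos:
        raise ValueError(
            f"requested {n_pos} positives but truth has only "
            f"{len(truth.motif_positions)} motif instances"
        )
    rng = np.random.default_rng(seed)
    motif_spans: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, _ in truth.motif_positions:
        motif_spans.setdefault(chrom, []).append((start, start + motif_width))

    def in_motif(chrom: str, pos: int) -> bool:
        return any(lo <= pos < hi for lo, hi in motif_spans.get(chrom, []))

    picks = rng.choice(len(truth.motif_positions), size=n_pos, replace=False)
    records = []
    skipped = 0
    for group, idx in enumerate(picks):
        chrom, mstart, _ = truth.motif_positions[idx]
        pos = int(mstart + rng.integers(0, motif_width))
        ref = genome[chrom][pos]
        alt = rng.choice([b for b in BASES if b != ref])
        records.append((chrom, pos, ref, alt, "positive", group, True))
        clen = genome.length(chrom)
        lo, hi = max(0, pos - ld_radius), min(clen, pos + ld_radius + 1)
        candidates = [p for p in range(lo, hi) if not in_motif(chrom, p)
                      and genome[chrom][p] != "N"]
        if not candidates:
            skipped += n_neg_per_pos
            continue
        n_take = min(n_neg_per_pos, len(candidates))
        if n_take < n_neg_per_pos:
            skipped += n_neg_per_pos - n_take
        for p in rng.choice(candidates, size=n_take, replace=False):
            nref = genome[chrom][int(p)]
            nalt = rng.choice([b for b in BASES if b != nref])
            records.append((chrom, int(p), nref, nalt, "negative", group, False))
    if skipped:
        import logging

        logging.getLogger(__name__).warning(
            "skipped %d negative variants (no non-motif base in LD window)", skipped
        )
    return pd.DataFrame(
        records, columns=["chrom", "pos", "ref", "alt", "label", "group", "causal"]
    )


def kmer_counts(seq: str, k: int = 3) -> np.ndarray:
    """Count vector over all 4**k k-mers (positions with N skipped)."""
    idx = {b: i for i, b in enumerate(BASES)}
    counts = np.zeros(4**k)
    code, valid = 0, 0
    mask = 4 ** (k - 1)
    for ch in seq:
        if ch not in idx:
            code, valid = 0, 0
            continue
        code = (code % mask) * 4 + idx[ch]
        valid += 1
        if valid >= k:
            counts[code] += 1
    return counts
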