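"""Genome containers and the window-construction pipeline.

Turns a genome + peak intervals + per-base coverage into labeled, one-hot
encoded, chromosome-split training windows: fixed-length windows on a regular
offset grid, blacklist exclusion, overlap-ratio labeling, GC-matched negative
selection, and log-scaled per-base regression targets.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

WINDOW_LEN = 600
WINDOW_OFFSET = 100
BASES = "ACGT"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


# --------------------------------------------------------------------- types
class GenomeAssembly:
    """Chromosome name -> uppercase sequence over {A,C,G,T,N}."""

    def __init__(self, chroms: dict[str, str]):
        if len(set(chroms)) != len(chroms):
            raise ValueError("duplicate chromosome names")
        for name, seq in chroms.items():
            if len(seq) == 0:
                raise ValueError(f"chromosome {name} is empty")
        self.chroms = {name: seq.upper() for name, seq in chroms.items()}

    def __getitem__(self, chrom: str) -> str:
        return self.chroms[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def names(self) -> list[str]:
        return list(self.chroms)

    def length(self, chrom: str) -> int:
        return len(self.chroms[chrom])


class IntervalSet:
    """Sorted genomic intervals with overlap queries (0-based half-open)."""

    def __init__(self, records: list[tuple] | None = None):
        # record: (chrom, start, end) + optional (name, score, strand)
        self.records: list[tuple] = []
        self._trees: dict[str, IntervalTree] = {}
        for rec in records or []:
            self.add(*rec)

    def add(self, chrom: str, start: int, end: int, *extra):
        if not start < end:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        self.records.append((chrom, int(start), int(end), *extra))
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(sorted(self.records, key=lambda r: (r[0], r[1], r[2])))

    def overlap_bases(self, chrom: str, start: int, end: int) -> int:
        """Bases of [start, end) covered by the union of intervals."""
        tree = self._trees.get(chrom)
        if tree is None:
            return 0
        hits = sorted((max(iv.begin, start), min(iv.end, end))
                      for iv in tree.overlap(start, end))
        covered, cursor = 0, start
        for lo, hi in hits:
            lo = max(lo, cursor)
            if hi > lo:
                covered += hi - lo
                cursor = hi
        return covered

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))


class CoverageTrack:
    """Per-chromosome per-base float signal; missing chromosomes read as 0."""

    def __init__(self, tracks: dict[str, np.ndarray] | None = None):
        self.tracks: dict[str, np.ndarray] = {}
        for chrom, values in (tracks or {}).items():
            self.set(chrom, values)

    def set(self, chrom: str, values: np.ndarray):
        arr = np.asarray(values, dtype=np.float64)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite coverage on {chrom}")
        self.tracks[chrom] = arr

    def fetch(self, chrom: str, start: int, end: int) -> np.ndarray:
        track = self.tracks.get(chrom)
        if track is None:
            return np.zeros(end - start)
        out = np.zeros(end - start)
        lo, hi = max(start, 0), min(end, len(track))
        if hi > lo:
            out[lo - start : hi - start] = track[lo:hi]
        return out


@dataclass
class LabeledWindow:
    chrom: str
    start: int
    label: str  # "positive" | "negative"
    gc: float
    onehot: np.ndarray  # (4, L), rows A,C,G,T
    target: np.ndarray  # (L,), log-scaled coverage; zeros for negatives
    accessibility: np.ndarray | None = None

    @property
    def end(self) -> int:
        return self.start + self.onehot.shape[1]


@dataclass
class SplitSpec:
    train_chroms: list[str]
    val_chroms: list[str] = field(default_factory=list)
    test_chroms: list[str] = field(default_factory=list)

    def __post_init__(self):
        groups = [set(self.train_chroms), set(self.val_chroms), set(self.test_chroms)]
        for i in range(3):
            for j in range(i + 1, 3):
                if groups[i] & groups[j]:
                    raise ValueError(
                        f"split lists overlap: {sorted(groups[i] & groups[j])}"
                    )


# ---------------------------------------------------------------- operations
def enumerate_windows(
    genome: GenomeAssembly,
    window_len: int = WINDOW_LEN,
    offset: int = WINDOW_OFFSET,
    exclude: IntervalSet | None = None,
) -> list[tuple[str, int]]:
    """All (chrom, start) windows on the offset grid, minus excluded ones.

    Starts run 0, offset, 2*offset, ... with start + window_len <= chromosome
    length; a window overlapping `exclude` by even one base is dropped.
    """
    if window_len <= 0 or offset <= 0:
        raise ValueError("window_len and offset must be positive")
    out = []
    for chrom in genome.names():
        clen = genome.length(chrom)
        if clen < window_len:
            log.info("chromosome %s shorter than window (%d < %d); no windows",
                     chrom, clen, window_len)
            continue
        for start in range(0, clen - window_len + 1, offset):
            if exclude is not None and exclude.overlaps(chrom, start, start + window_len):
                continue
            out.append((chrom, start))
    return out


def label_windows(
    windows: list[tuple[str, int]],
    peaks: IntervalSet,
    min_overlap_ratio: float = 0.2,
    window_len: int = WINDOW_LEN,
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Partition windows into positives and the zero-overlap negative pool.

    Positive iff (bases overlapping the peak union) / window_len strictly
    exceeds `min_overlap_ratio`; negative iff the overlap is exactly zero.
    Gray-zone windows (overlap in (0, threshold]) belong to neither set.
    """
    if not 0 < min_overlap_ratio <= 1:
        raise ValueError("min_overlap_ratio must lie in (0, 1]")
    positives, negatives = [], []
    for chrom, start in windows:
        ov = peaks.overlap_bases(chrom, start, start + window_len)
        if ov / window_len > min_overlap_ratio:
            positives.append((chrom, start))
        elif ov == 0:
            negatives.append((chrom, start))
    return positives, negatives


def gc_fraction(seq: str) -> float:
    n = len(seq)
    return (seq.count("G") + seq.count("C")) / n if n else 0.0


def gc_match_negatives(
    positive_gc: np.ndarray,
    pool: list,
    pool_gc: np.ndarray,
    n_select: int,
    bins: int = 20,
    seed: int = 0,
) -> list:
    """Sample `n_select` pool entries whose GC histogram matches the positives.

    GC fractions are histogrammed into `bins` equal-width bins on [0, 1];
    per-bin quotas follow the positive bin proportions.  An underfull bin's
    deficit spills into the nearest neighbouring bins.  Deterministic for a
    given seed; sampling is without replacement.
    """
    if len(pool) == 0:
        raise ValueError("negative pool is empty")
    if n_select <= 0:
        return []
    if n_select >= len(pool):
        log.warning("requested %d negatives but pool has %d; returning all",
                    n_select, len(pool))
        return list(pool)
    rng = np.random.default_rng(seed)
    edges = np.linspace(0.0, 1.0, bins + 1)
    pos_bin = np.clip(np.digitize(positive_gc, edges) - 1, 0, bins - 1)
    pool_bin = np.clip(np.digitize(pool_gc, edges) - 1, 0, bins - 1)
    pos_counts = np.bincount(pos_bin, minlength=bins).astype(float)
    quota = pos_counts / pos_counts.sum() * n_select
    # largest-remainder rounding to integer quotas summing to n_select
    base = np.floor(quota).astype(int)
    rem = quota - base
    short = n_select - base.sum()
    for idx in np.argsort(-rem)[:short]:
        base[idx] += 1
    by_bin = {b: list(np.flatnonzero(pool_bin == b)) for b in range(bins)}
    chosen: list[int] = []
    deficit = np.zeros(bins, dtype=int)
    for b in range(bins):
        cands = by_bin[b]
        take = min(base[b], len(cands))
        if take:
            picked = rng.choice(len(cands), size=take, replace=False)
            picked_ids = [cands[i] for i in picked]
            chosen.extend(picked_ids)
            by_bin[b] = [c for c in cands if c not in set(picked_ids)]
        deficit[b] = base[b] - take
    total_deficit = int(deficit.sum())
    if total_deficit:
        log.warning("GC bins underfull by %d; drawing from adjacent bins",
                    total_deficit)
    for b in np.flatnonzero(deficit):
        need = deficit[b]
        for dist in range(1, bins):
            for nb in (b - dist, b + dist):
                if need == 0 or not 0 <= nb < bins:
                    continue
                cands = by_bin[nb]
                take = min(need, len(cands))
                if take:
                    picked = rng.choice(len(cands), size=take, replace=False)
                    picked_ids = [cands[i] for i in picked]
                    chosen.extend(picked_ids)
                    by_bin[nb] = [c for c in cands if c not in set(picked_ids)]
                    need -= take
            if need == 0:
                break
    return [pool[i] for i in chosen]


def one_hot(seq: str) -> np.ndarray:
    """(4, L) one-hot with row order A,C,G,T; N encodes as an all-zero column."""
    arr = np.zeros((4, len(seq)))
    for i, base in enumerate(seq):
        if base in _BASE_INDEX:
            arr[_BASE_INDEX[base], i] = 1.0
        elif base != "N":
            raise ValueError(f"non-ACGTN character {base!r} at position {i}")
    return arr


def decode_onehot(onehot: np.ndarray) -> str:
    cols = onehot.argmax(axis=0)
    blank = onehot.sum(axis=0) == 0
    return "".join("N" if b else BASES[c] for c, b in zip(cols, blank))


def encode_window(
    chrom: str,
    start: int,
    sequence: str,
    label: str,
    coverage: CoverageTrack,
    accessibility: CoverageTrack | None = None,
) -> LabeledWindow:
    """Build the model-ready payload for one window.

    Positive targets are log10(1 + raw coverage) per base, so zero coverage
    maps to exactly 0; negative windows carry all-zero targets.
    """
    L = len(sequence)
    onehot = one_hot(sequence)
    if label == "positive":
        raw = coverage.fetch(chrom, start, start + L)
        target = np.log10(1.0 + raw)
    else:
        target = np.zeros(L)
    acc = None
    if accessibility is not None:
        acc = np.log10(1.0 + accessibility.fetch(chrom, start, start + L))
    return LabeledWindow(chrom, start, label, gc_fraction(sequence), onehot, target, acc)


def split_by_chromosome(
    windows: list[LabeledWindow], split: SplitSpec
) -> tuple[list[LabeledWindow], list[LabeledWindow], list[LabeledWindow]]:
    """Assign each window to train/val/test by chromosome.

    Windows on chromosomes absent from every list default to train.
    """
    val, test = set(split.val_chroms), set(split.test_chroms)
    out: tuple[list, list, list] = ([], [], [])
    for w in windows:
        if w.chrom in val:
            out[1].append(w)
        elif w.chrom in test:
            out[2].append(w)
        else:
            out[0].append(w)
    return out


def build_windows(
    genome: GenomeAssembly,
    peaks: IntervalSet,
    coverage: CoverageTrack,
    accessibility: CoverageTrack | None = None,
    blacklist: IntervalSet | None = None,
    window_len: int = WINDOW_LEN,
    offset: int = WINDOW_OFFSET,
    min_overlap_ratio: float = 0.2,
    neg_ratio: int = 3,
    gc_bins: int = 20,
    seed: int = 0,
) -> tuple[list[LabeledWindow], list[LabeledWindow]]:
    """Full pipeline: enumerate, label, GC-match, encode.

    Returns (positives, matched negatives); the negative set is sized
    `neg_ratio` times the positive count (or the whole pool if smaller).
    """
    grid = enumerate_windows(genome, window_len, offset, blacklist)
    pos_coords, neg_pool = label_windows(grid, peaks, min_overlap_ratio, window_len)
    pos_gc = np.array([gc_fraction(genome[c][s : s + window_len]) for c, s in pos_coords])
    pool_gc = np.array([gc_fraction(genome[c][s : s + window_len]) for c, s in neg_pool])
    matched = gc_match_negatives(
        pos_gc, neg_pool, pool_gc, neg_ratio * len(pos_coords), gc_bins, seed
    ) if pos_coords else []
    positives = [
        encode_window(c, s, genome[c][s : s + window_len], "positive", coverage,
                      accessibility)
        for c, s in pos_coords
    ]
    negatives = [
        encode_window(c, s, genome[c][s : s + window_len], "negative", coverage,
                      accessibility)
        for c, s in matched
    ]
    return positives, negatives


def windows_to_arrays(
    windows: list[LabeledWindow], with_accessibility: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (N, C, L) inputs and (N, L) targets."""
    x = np.stack([w.onehot for w in windows])
    if with_accessibility:
        acc = np.stack([
            w.accessibility if w.accessibility is not None
            else np.zeros(w.onehot.shape[1])
            for w in windows
        ])
        x = np.concatenate([x, acc[:, None, :]], axis=1)
    y = np.stack([w.target for w in windows])
    return x, y
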