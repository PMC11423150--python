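"""Readers and writers for the plain-text genomics formats the package uses.

FASTA (via pyfaidx for indexed reads, 60-column wrapped writes), BED3/BED6,
bedGraph (0-based half-open, fixed-point, run-length merged), and variant
tables as TSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .windows import CoverageTrack, GenomeAssembly, IntervalSet


def write_fasta(genome: GenomeAssembly, path: str, width: int = 60):
    with open(path, "w") as fh:
        for chrom in genome.names():
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> GenomeAssembly:
    fa = Fasta(path, sequence_always_upper=True, rebuild=True)
    genome = GenomeAssembly({name: str(fa[name][:]) for name in fa.keys()})
    fa.close()
    for ext in (".fai",):
        try:
            os.remove(path + ext)
        except OSError:
            pass
    return genome


def write_bed(intervals: IntervalSet, path: str):
    with open(path, "w") as fh:
        for rec in intervals:
            fh.write("\t".join(str(v) for v in rec) + "\n")


def read_bed(path: str) -> IntervalSet:
    out = IntervalSet()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            out.add(chrom, start, end, *fields[3:6])
    return out


def write_bedgraph(track: CoverageTrack, path: str, decimals: int = 4):
    """Run-length merged bedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom, values in track.tracks.items():
            rounded = np.round(values, decimals)
            if len(rounded) == 0:
                continue
            change = np.flatnonzero(np.diff(rounded)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(rounded)]])
            for s, e in zip(starts, ends):
                v = rounded[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.{decimals}f}\n")


def read_bedgraph(path: str, chrom_lengths: dict[str, int]) -> CoverageTrack:
    track = CoverageTrack({c: np.zeros(n) for c, n in chrom_lengths.items()})
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")
            if chrom in track.tracks:
                track.tracks[chrom][int(start) : int(end)] = float(value)
    return track


def read_bigwig(path: str, chrom_lengths: dict[str, int]) -> CoverageTrack:
    """Per-base coverage from a bigWig file (requires pyBigWig)."""
    import pyBigWig

    bw = pyBigWig.open(path)
    try:
        track = CoverageTrack()
        for chrom, n in chrom_lengths.items():
            if chrom not in bw.chroms():
                track.set(chrom, np.zeros(n))
                continue
            values = np.nan_to_num(
                np.asarray(bw.values(chrom, 0, min(n, bw.chroms()[chrom])),
                           dtype=np.float64)
            )
            if len(values) < n:
                values = np.pad(values, (0, n - len(values)))
            track.set(chrom, values)
        return track
    finally:
        bw.close()


def write_window_set(out_dir: str, positives, negatives, window_len: int = 600):
    """Persist encoded windows: a tensor cache plus BED manifests."""
    os.makedirs(out_dir, exist_ok=True)
    from .windows import windows_to_arrays

    x_pos, y_pos = windows_to_arrays(positives) if positives else (
        np.empty((0, 4, window_len)), np.empty((0, window_len)))
    x_neg, y_neg = windows_to_arrays(negatives) if negatives else (
        np.empty((0, 4, window_len)), np.empty((0, window_len)))
    np.savez_compressed(
        os.path.join(out_dir, "windows.npz"),
        x_pos=x_pos, y_pos=y_pos, x_neg=x_neg, y_neg=y_neg,
        pos_chrom=np.array([w.chrom for w in positives]),
        pos_start=np.array([w.start for w in positives], dtype=np.int64),
        neg_chrom=np.array([w.chrom for w in negatives]),
        neg_start=np.array([w.start for w in negatives], dtype=np.int64),
    )
    for name, group in (("positives.bed", positives), ("negatives.bed", negatives)):
        with open(os.path.join(out_dir, name), "w") as fh:
            for w in group:
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.label}\n")


def read_window_set(out_dir: str) -> dict[str, np.ndarray]:
    with np.load(os.path.join(out_dir, "windows.npz"), allow_pickle=False) as z:
        return {k: z[k] for k in z.files}


def write_variants(table: pd.DataFrame, path: str):
    cols = [c for c in ("chrom", "pos", "ref", "alt", "label", "group", "causal")
            if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False)


def read_variants(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
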