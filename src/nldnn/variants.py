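"""Variant-effect scoring, SNP classification, causal prioritization, ISSM.

The effect of a single-base substitution is measured by predicting coverage
for the reference and alternative windows centered on the variant and summing
the per-base differences over a neighbourhood D around it — absolute
differences for classification-style scoring, signed for effect-size
(MPRA-style) fitting.  Scoring every possible substitution at every position
of a window yields the 4xL in-silico saturation mutagenesis (ISSM) matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import classification_metrics
from .windows import BASES, GenomeAssembly, one_hot

__all__ = [
    "EffectScore",
    "effect_score",
    "effect_scores",
    "issm",
    "snp_classification",
    "prioritize_causal",
]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class EffectScore:
    value: float
    mode: str  # "abs" | "signed"
    d_radius: int
    shifted: bool = False  # window shifted at a chromosome edge


def _variant_windows(
    genome: GenomeAssembly, chrom: str, pos: int, ref: str, alt: str,
    window_len: int,
) -> tuple[str, str, int, bool]:
    """Reference and alternative windows centered on the variant.

    Returns (ref_seq, alt_seq, variant offset within window, shifted flag);
    near a chromosome edge the window shifts to stay in bounds and the
    neighbourhood follows the variant.
    """
    clen = genome.length(chrom)
    if not 0 <= pos < clen:
        raise ValueError(f"variant position {pos} outside {chrom} (length {clen})")
    if clen < window_len:
        raise ValueError(f"{chrom} shorter than the scoring window")
    half = window_len // 2
    start = pos - half
    shifted = False
    if start < 0:
        start, shifted = 0, True
    elif start + window_len > clen:
        start, shifted = clen - window_len, True
    seq = genome[chrom][start : start + window_len]
    offset = pos - start
    if seq[offset] != ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: genome has {seq[offset]}, "
            f"variant says {ref}"
        )
    alt_seq = seq[:offset] + alt.upper() + seq[offset + 1 :]
    return seq, alt_seq, offset, shifted


def effect_score(
    model,
    genome: GenomeAssembly,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    window_len: int = 600,
    d_radius: int = 100,
    mode: str = "abs",
) -> EffectScore:
    """Score one variant: sum of per-base prediction changes near the variant."""
    ref_seq, alt_seq, offset, shifted = _variant_windows(
        genome, chrom, pos, ref, alt, window_len
    )
    x = np.stack([one_hot(ref_seq), one_hot(alt_seq)])
    pred = model.predict(x)
    lo, hi = max(0, offset - d_radius), min(window_len, offset + d_radius + 1)
    diff = pred[1, lo:hi] - pred[0, lo:hi]
    if mode == "abs":
        value = float(np.abs(diff).sum())
    elif mode == "signed":
        value = float(diff.sum())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return EffectScore(value, mode, d_radius, shifted)


def effect_scores(
    model,
    genome: GenomeAssembly,
    variants: pd.DataFrame,
    window_len: int = 600,
    d_radius: int = 100,
    mode: str = "abs",
    batch_size: int = 64,
) -> np.ndarray:
    """Vectorized effect scores for a variant table (chrom/pos/ref/alt)."""
    seqs, offsets = [], []
    for rec in variants.itertuples():
        ref_seq, alt_seq, offset, _ = _variant_windows(
            genome, rec.chrom, int(rec.pos), rec.ref, rec.alt, window_len
        )
        seqs.extend([ref_seq, alt_seq])
        offsets.append(offset)
    x = np.stack([one_hot(s) for s in seqs])
    pred = model.predict(x, batch_size=batch_size)
    out = np.empty(len(variants))
    for i, offset in enumerate(offsets):
        lo, hi = max(0, offset - d_radius), min(window_len, offset + d_radius + 1)
        diff = pred[2 * i + 1, lo:hi] - pred[2 * i, lo:hi]
        out[i] = np.abs(diff).sum() if mode == "abs" else diff.sum()
    return out


def issm(
    model,
    sequence: str,
    d_radius: int = 100,
    batch_size: int = 128,
) -> np.ndarray:
    """In-silico saturation mutagenesis matrix, shape (4, L).

    Entry (b, i) is the absolute effect of substituting base b at position i;
    entries at the reference base are 0.  All 3L substituted windows are
    scored in batches against a single reference prediction.
    """
    L = len(sequence)
    ref_onehot = one_hot(sequence)
    ref_pred = model.predict(ref_onehot[None])[0]
    muts: list[tuple[int, int]] = []  # (position, base index)
    batch: list[np.ndarray] = []
    for i, base in enumerate(sequence):
        for b, letter in enumerate(BASES):
            if letter == base:
                continue
            alt = ref_onehot.copy()
            alt[:, i] = 0.0
            alt[b, i] = 1.0
            muts.append((i, b))
            batch.append(alt)
    preds = model.predict(np.stack(batch), batch_size=batch_size)
    matrix = np.zeros((4, L))
    for (i, b), pred in zip(muts, preds):
        lo, hi = max(0, i - d_radius), min(L, i + d_radius + 1)
        matrix[b, i] = np.abs(pred[lo:hi] - ref_pred[lo:hi]).sum()
    return matrix


def snp_classification(effects: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(ROC-AUC, PR-AUC) for separating positive from negative SNPs."""
    prauc, rocauc = classification_metrics(np.asarray(effects), np.asarray(labels))
    return rocauc, prauc


def prioritize_causal(
    effects: np.ndarray, causal_index: int
) -> tuple[bool, float]:
    """Causal-SNP prioritization within one LD group.

    hit: the designated causal variant has the strictly largest effect.
    ratio: causal effect / best effect among the others (+inf if the others
    are all zero); ratio > 1 iff hit.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.size < 2:
        raise ValueError("an LD group needs at least two variants")
    others = np.delete(effects, causal_index)
    best_other = float(others.max())
    causal = float(effects[causal_index])
    if best_other == 0.0:
        return causal > 0, float("inf")
    ratio = causal / best_other
    return ratio > 1.0, ratio
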