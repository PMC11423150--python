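"""Model interpretation: kernel motifs, attribution maps, site categories.

Motif discovery reads the trained first convolutional layer directly: around
each positive test sequence's predicted coverage maximum, a 60-bp window is
extracted and every kernel picks its best-activating sub-region; aligned
sub-regions become a count matrix and hence a PWM.  Attribution is
gradient-of-the-window-maximum times input.  Predicted binding sites are
categorized TP/FP/FN from min-max + sigmoid rescaled predicted and true
tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor
from .windows import BASES, one_hot

__all__ = [
    "KernelMotif",
    "kernel_motifs",
    "attribution",
    "scale_track",
    "categorize_sites",
    "write_meme",
]


@dataclass
class KernelMotif:
    kernel: int
    support: int  # number of aligned sub-sequences
    pwm: np.ndarray  # (4, K), columns sum to 1
    information_content: np.ndarray  # bits per column

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=0))


def _information_content(pwm: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ic = 2.0 + np.nansum(pwm * np.log2(np.where(pwm > 0, pwm, 1.0)), axis=0)
    return ic


def kernel_motifs(
    model,
    x_pos: np.ndarray,
    extract_len: int = 60,
    min_support: int = 10,
    activation_fraction: float = 0.5,
    pseudocount: float = 0.25,
) -> list[KernelMotif]:
    """PWMs from first-layer kernels aligned at their best sub-regions.

    For each positive window: predict, locate the coverage maximum, extract
    the `extract_len` window centered there (clipped at edges); per kernel,
    score every sub-region at stride 1 with the first-layer convolution and
    keep the argmax sub-region if its activation exceeds
    `activation_fraction` times that kernel's global maximum over the set.
    Kept sub-regions are stacked into count matrices; kernels with fewer
    than `min_support` contributions are dropped.
    """
    if len(x_pos) == 0:
        return []
    first_conv = model.generator.block0.conv
    weight = first_conv.weight.data  # (n_kernels, C, K)
    n_kernels, _, K = weight.shape
    if K > extract_len:
        raise ValueError("first-layer kernel wider than the extraction window")
    preds = model.predict(x_pos)
    L = x_pos.shape[2]
    half = extract_len // 2
    subregions: list[np.ndarray] = []  # (4, extract_len) per sequence
    for x, pred in zip(x_pos, preds):
        center = int(pred.argmax())
        lo = min(max(0, center - half), L - extract_len)
        subregions.append(x[:4, lo : lo + extract_len])
    # score all sub-windows of each extraction with each kernel
    n_sub = extract_len - K + 1
    best_scores = np.empty((len(subregions), n_kernels))
    best_offsets = np.empty((len(subregions), n_kernels), dtype=int)
    for s, region in enumerate(subregions):
        # (n_kernels, n_sub) activation of each placement
        acts = np.stack([
            np.tensordot(weight[:, :4, :], region[:, off : off + K], axes=([1, 2], [0, 1]))
            for off in range(n_sub)
        ], axis=1)
        best_offsets[s] = acts.argmax(axis=1)
        best_scores[s] = acts.max(axis=1)
    global_max = best_scores.max(axis=0)
    motifs = []
    for k in range(n_kernels):
        keep = best_scores[:, k] > activation_fraction * global_max[k]
        if keep.sum() < min_support:
            continue
        counts = np.full((4, K), pseudocount)
        for s in np.flatnonzero(keep):
            off = best_offsets[s, k]
            counts += subregions[s][:, off : off + K]
        pwm = counts / counts.sum(axis=0, keepdims=True)
        motifs.append(KernelMotif(k, int(keep.sum()), pwm, _information_content(pwm)))
    return motifs


def attribution(model, x: np.ndarray) -> np.ndarray:
    """Gradient-times-input contribution of each base to the window maximum.

    The scalar head is the maximum over per-base outputs; its gradient with
    respect to the one-hot input, multiplied elementwise by the input and
    summed over channels, gives one contribution per position.  All-zero
    columns (N bases) contribute exactly 0.
    """
    single = x.ndim == 2
    if single:
        x = x[None]
    was = model.training
    model.eval()
    xt = Tensor(x, requires_grad=True)
    out = model(xt)
    out.max(axis=1).sum().backward()
    model.train(was)
    contrib = (xt.grad * x).sum(axis=1)
    return contrib[0] if single else contrib


def scale_track(x: np.ndarray) -> np.ndarray:
    """Min-max rescale to [-1, 1], then sigmoid to (0, 1).

    A constant vector maps to 0.5 everywhere (sigmoid of 0).
    """
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        import logging

        logging.getLogger(__name__).info("constant track; scaled value is 0.5")
        return np.full_like(x, 0.5)
    z = 2.0 * (x - lo) / (hi - lo) - 1.0
    return 1.0 / (1.0 + np.exp(-z))


def categorize_sites(
    pred: np.ndarray, true: np.ndarray, prescaled: bool = False
) -> str:
    """Categorize one window/site from scaled prediction P and truth T.

    P and T are the window maxima of the sigmoid-rescaled tracks.  Rules:
    TP iff P > 0.7 and T > 0.7; FP iff P > 0.5, T < 0.5 and |P - T| > 0.5;
    FN iff P < 0.5, T > 0.5 and |P - T| > 0.5; otherwise "other".
    """
    if np.shape(pred) != np.shape(true):
        raise ValueError("pred and true must have the same shape")
    if prescaled:
        P, T = float(np.max(pred)), float(np.max(true))
    else:
        P, T = float(np.max(scale_track(pred))), float(np.max(scale_track(true)))
    if P > 0.7 and T > 0.7:
        return "TP"
    if P > 0.5 and T < 0.5 and abs(P - T) > 0.5:
        return "FP"
    if P < 0.5 and T > 0.5 and abs(P - T) > 0.5:
        return "FN"
    return "other"


def write_meme(motifs: list[KernelMotif], path: str, alphabet: str = "ACGT"):
    """Minimal MEME motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF kernel_{m.kernel}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.pwm.shape[1]} "
                f"nsites= {m.support} E= 0\n"
            )
            for col in m.pwm.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")
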