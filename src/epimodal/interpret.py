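"""Convolutional-kernel motif extraction.

Each first-layer convolutional kernel (320 of them in the default models;
width 8 for the CNN encoder, 26 for the CNN/RNN encoder) is summarised as a
position-specific frequency matrix (PSFM): for every test window the
contiguous subsequence with the kernel's largest activation is taken, and
the qualifying subsequences (max activation > 0) are stacked into
column-wise base frequencies with a small pseudocount.  PSFMs are exported
in MEME minimal motif format so external motif-comparison tools can query
them against reference databases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import BASES, one_hot


@dataclass
class MotifPSFM:
    """A kernel's motif profile: 4 x width probabilities (rows A,C,G,T)."""

    kernel_id: int
    width: int
    probs: np.ndarray
    nsites: int

    def __post_init__(self):
        if self.probs.shape != (4, self.width):
            raise ValueError("probs must be 4 x width")
        if (self.probs < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PSFM columns must sum to 1")
        if self.nsites < 1:
            raise ValueError("a PSFM needs at least one contributing site")

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (2 + sum p log2 p)."""
        p = np.clip(self.probs, 1e-12, 1.0)
        return 2.0 + (p * np.log2(p)).sum(axis=0)


def max_activation_window(kernel: np.ndarray, window: np.ndarray) -> tuple[int, float]:
    """Offset and value of a kernel's maximal cross-correlation position.

    ``kernel`` is (4, K), ``window`` a one-hot (4, L) matrix, K <= L.
    Ties break toward the smallest offset.
    """
    K = kernel.shape[1]
    L = window.shape[1]
    if K > L:
        raise ValueError(f"kernel width {K} exceeds window length {L}")
    patches = np.lib.stride_tricks.sliding_window_view(window, K, axis=1)  # (4, L-K+1, K)
    acts = np.einsum("cok,ck->o", patches, kernel)
    offset = int(np.argmax(acts))  # argmax returns the first maximum
    return offset, float(acts[offset])


def build_psfm(kernel: np.ndarray, test_windows, kernel_id: int = 0,
               activation_threshold: float = 0.0,
               pseudocount: float = 0.001) -> MotifPSFM | None:
    """Build a kernel's PSFM from its max-activating test subsequences.

    Windows may be sequences (str) or one-hot matrices.  A window
    contributes only if its maximal activation exceeds the threshold;
    returns None (kernel inactive) when no window qualifies.
    """
    width = kernel.shape[1]
    counts = np.zeros((4, width))
    nsites = 0
    for w in test_windows:
        oh = one_hot(w) if isinstance(w, str) else np.asarray(w)
        offset, act = max_activation_window(kernel, oh)
        if act <= activation_threshold:
            continue
        counts += oh[:, offset : offset + width]
        nsites += 1
    if nsites == 0:
        return None
    counts += pseudocount
    probs = counts / counts.sum(axis=0, keepdims=True)
    return MotifPSFM(kernel_id=kernel_id, width=width, probs=probs, nsites=nsites)


def extract_motifs(first_layer_kernels: np.ndarray, test_windows,
                   activation_threshold: float = 0.0,
                   pseudocount: float = 0.001) -> list[MotifPSFM]:
    """PSFMs for every first-layer kernel; inactive kernels are dropped."""
    windows = [one_hot(w) if isinstance(w, str) else np.asarray(w) for w in test_windows]
    out = []
    for kid, kernel in enumerate(first_layer_kernels):
        psfm = build_psfm(kernel, windows, kernel_id=kid,
                          activation_threshold=activation_threshold,
                          pseudocount=pseudocount)
        if psfm is not None:
            out.append(psfm)
    return out


# --- MEME minimal motif format ----------------------------------------------

def export_meme(psfms, path, background=(0.25, 0.25, 0.25, 0.25)) -> None:
    """Write PSFMs in MEME minimal motif format (version 4)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.6f} C {:.6f} G {:.6f} T {:.6f}\n\n".format(*background))
        for p in psfms:
            fh.write(f"MOTIF kernel_{p.kernel_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= {p.nsites} E= 0\n"
            )
            for col in p.probs.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list[MotifPSFM]:
    """Re-parse a MEME minimal motif file written by :func:`export_meme`."""
    out = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("MOTIF"):
            name = line.split()[1]
            kernel_id = int(name.rsplit("_", 1)[1]) if "_" in name else 0
            i += 1
            header = lines[i].split()
            width = int(header[header.index("w=") + 1])
            nsites = int(header[header.index("nsites=") + 1])
            rows = []
            for j in range(width):
                rows.append([float(v) for v in lines[i + 1 + j].split()])
            probs = np.asarray(rows).T
            probs = probs / probs.sum(axis=0, keepdims=True)
            out.append(MotifPSFM(kernel_id=kernel_id, width=width, probs=probs, nsites=nsites))
            i += width
        i += 1
    return out
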