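"""Motif discovery from trained convolution detectors.

Each convolution filter behaves as a motif detector: on every positive test
fragment where a detector fires anywhere (some position with activation
> 0), the window under its strongest activation (leftmost argmax on ties)
is extracted.  Stacking a detector's extracted windows column-wise gives a
position frequency matrix (PFM); padding characters ``N`` are excluded from
the counts of their column.  PFMs convert to letter probabilities (with a
pseudocount) for sequence-logo rendering and MEME minimal-format export,
which downstream motif-comparison tools such as Tomtom consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .capsnet import CapsuleNetwork, conv_feature_maps
from .encoding import encode_sequence

__all__ = [
    "MotifPFM",
    "extract_subsequences",
    "build_pfm",
    "discover_motifs",
    "information_content",
    "export_meme",
    "parse_meme",
    "plot_logo",
]

#: PFM/MEME column order (standard, distinct from the encoding's A,T,C,G).
PFM_BASES = "ACGT"
_PFM_INDEX = {b: i for i, b in enumerate(PFM_BASES)}


@dataclass
class MotifPFM:
    """Position frequency matrix of one detector.

    ``counts`` is (h, 4) over A,C,G,T; ``non_n_totals[i]`` is the number of
    contributing subsequences with a real base (not N) in column ``i``;
    ``n_subsequences`` is how many windows were stacked.
    """

    detector_id: int
    counts: np.ndarray
    non_n_totals: np.ndarray
    n_subsequences: int

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def probabilities(self, pseudocount: float = 0.25) -> np.ndarray:
        """Per-column letter probabilities; all-N columns become uniform."""
        probs = np.empty_like(self.counts, dtype=np.float64)
        for i in range(self.width):
            tot = self.non_n_totals[i]
            if tot == 0:
                probs[i] = 0.25
            else:
                probs[i] = (self.counts[i] + pseudocount) / (tot + 4 * pseudocount)
        return probs

    def consensus(self) -> str:
        """Highest-count base per column (N for all-N columns)."""
        out = []
        for i in range(self.width):
            if self.non_n_totals[i] == 0:
                out.append("N")
            else:
                out.append(PFM_BASES[int(np.argmax(self.counts[i]))])
        return "".join(out)


def extract_subsequences(net: CapsuleNetwork, sequences: list[str]) -> dict[int, list[str]]:
    """Strongest-activation windows per detector over positive fragments.

    For each detector and fragment, a window is taken only if the detector's
    maximum activation on that fragment is strictly positive; the window
    starts at the leftmost argmax.  Detectors that never fire map to empty
    lists.
    """
    cfg = net.config
    h = cfg.kernel_size
    W = net.params["conv_w"].data
    b = net.params["conv_b"].data
    out: dict[int, list[str]] = {k: [] for k in range(cfg.n_filters)}
    for s in sequences:
        enc = encode_sequence(s)
        maps = conv_feature_maps(enc.matrix, W, b)  # (P, K)
        best = maps.max(axis=0)
        arg = maps.argmax(axis=0)  # leftmost tie-break
        for k in range(cfg.n_filters):
            if best[k] > 0.0:
                j = int(arg[k])
                out[k].append(enc.sequence[j : j + h])
    return out


def build_pfm(subsequences: list[str], h: int, detector_id: int = 0) -> MotifPFM:
    """Stack equal-length windows into a PFM; ``N`` counts toward no column."""
    counts = np.zeros((h, 4), dtype=np.int64)
    non_n = np.zeros(h, dtype=np.int64)
    for s in subsequences:
        if len(s) != h:
            raise ValueError(f"subsequence {s!r} does not have width {h}")
        for i, ch in enumerate(s.upper().replace("U", "T")):
            j = _PFM_INDEX.get(ch)
            if j is not None:
                counts[i, j] += 1
                non_n[i] += 1
    return MotifPFM(detector_id=detector_id, counts=counts, non_n_totals=non_n, n_subsequences=len(subsequences))


def discover_motifs(
    net: CapsuleNetwork,
    positive_sequences: list[str],
    min_subsequences: int = 10,
) -> list[MotifPFM]:
    """PFMs for every detector with at least ``min_subsequences`` windows."""
    subs = extract_subsequences(net, positive_sequences)
    return [
        build_pfm(v, net.config.kernel_size, detector_id=k)
        for k, v in subs.items()
        if len(v) >= min_subsequences
    ]


def information_content(pfm: MotifPFM, pseudocount: float = 0.25) -> np.ndarray:
    """Per-column information content in bits: ``2 + sum_b p_b log2 p_b``.

    All-N columns score 0 bits (uniform probabilities by construction).
    """
    probs = pfm.probabilities(pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    return 2.0 + plogp.sum(axis=1)


# ---------------------------------------------------------------------------
# MEME minimal format


def export_meme(
    pfms: list[MotifPFM],
    background: np.ndarray | None = None,
    pseudocount: float = 0.25,
) -> str:
    """Render PFMs as MEME minimal-format text (alphabet ACGT).

    Empty PFMs (no contributing subsequences) are skipped with a warning.
    """
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=np.float64)
    if abs(background.sum() - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.5f}" for b, f in zip(PFM_BASES, background)),
        "",
    ]
    n_written = 0
    for pfm in pfms:
        if pfm.n_subsequences == 0:
            warnings.warn(f"detector {pfm.detector_id}: empty PFM skipped")
            continue
        probs = pfm.probabilities(pseudocount)
        lines.append(f"MOTIF detector_{pfm.detector_id}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pfm.width} nsites= {pfm.n_subsequences} E= 0"
        )
        for row in probs:
            lines.append(" " + " ".join(f"{p:.6f}" for p in row))
        lines.append("")
        n_written += 1
    if n_written == 0:
        raise ValueError("no non-empty PFMs to export")
    return "\n".join(lines)


def parse_meme(text: str) -> list[tuple[str, np.ndarray]]:
    """Minimal MEME parser: (motif name, (w, 4) probability matrix) pairs."""
    motifs: list[tuple[str, np.ndarray]] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        if lines[i].startswith("MOTIF"):
            name = lines[i].split()[1]
            i += 1
            while i < len(lines) and not lines[i].startswith("letter-probability"):
                i += 1
            header = lines[i]
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(1, w + 1):
                rows.append([float(x) for x in lines[i + j].split()])
            motifs.append((name, np.array(rows)))
            i += w
        i += 1
    return motifs


# ---------------------------------------------------------------------------
# Sequence logos (matplotlib glyph rendering; RNA display uses U)


def plot_logo(pfm: MotifPFM, path: str | Path, rna: bool = True, pseudocount: float = 0.25) -> None:
    """Draw an information-content-scaled sequence logo to an image file."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728", "U": "#d62728"}
    probs = pfm.probabilities(pseudocount)
    ic = information_content(pfm, pseudocount)
    fp = FontProperties(family="DejaVu Sans", weight="bold")

    fig, ax = plt.subplots(figsize=(0.6 * pfm.width + 0.8, 2.2))
    for col in range(pfm.width):
        heights = probs[col] * ic[col]
        order = np.argsort(heights)  # small letters at the bottom
        y = 0.0
        for j in order:
            h = heights[j]
            if h <= 1e-3:
                continue
            letter = PFM_BASES[j]
            if rna and letter == "T":
                letter = "U"
            tp = TextPath((0, 0), letter, size=1.0, prop=fp)
            bb = tp.get_extents()
            tr = (
                Affine2D()
                .translate(-bb.x0, -bb.y0)
                .scale(0.9 / bb.width, h / bb.height)
                .translate(col + 0.05, y)
            )
            ax.add_patch(PathPatch(tr.transform_path(tp), facecolor=colors[letter], edgecolor="none"))
            y += h
    ax.set_xlim(0, pfm.width)
    ax.set_ylim(0, 2.0)
    ax.set_xticks(np.arange(pfm.width) + 0.5)
    ax.set_xticklabels(np.arange(1, pfm.width + 1))
    ax.set_ylabel("bits")
    ax.set_title(f"detector_{pfm.detector_id} (n={pfm.n_subsequences})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
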