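"""Sliding-window binding-site scanning on full-length circRNAs.

A circRNA is covalently closed, so a binding site may cross the back-splice
junction (the point where the sequence wraps).  The scanner slides a window
of the model's training fragment length over the sequence; in circular mode
every position is a valid window start, with junction-crossing windows read
from the virtually concatenated sequence.  Each window is scored
independently by the trained model's positive-capsule norm and hits are
ranked by score.

Coordinates are 1-based inclusive.  Wrapped hits keep their start on the
original sequence and set ``wrapped`` instead of reporting an end beyond
the sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .capsnet import CapsuleNetwork
from .encoding import encode_batch

__all__ = ["ScanHit", "scan_circrna", "report_top_hits", "hits_to_frame", "write_hits_tsv", "write_hits_bed"]


@dataclass(frozen=True)
class ScanHit:
    """One scored window: 1-based inclusive coordinates on the input."""

    start: int
    end: int
    wrapped: bool
    score: float

    def positions(self, seq_length: int) -> set[int]:
        """The 1-based positions covered (wrap-aware)."""
        if not self.wrapped:
            return set(range(self.start, self.end + 1))
        return set(range(self.start, seq_length + 1)) | set(range(1, self.end + 1))


def scan_circrna(
    sequence: str,
    model: CapsuleNetwork | None = None,
    stride: int = 1,
    circular: bool = True,
    window: int | None = None,
    scorer: Callable[[str], float] | None = None,
    batch_size: int = 512,
) -> list[ScanHit]:
    """Score every window of the fragment length along a circRNA.

    ``window`` defaults to the model's training fragment length.  In
    circular mode there is one window per start position ``1, 1+stride, ...``
    up to the sequence length, wrapping across the junction; in linear mode
    windows must fit inside the sequence.  ``scorer`` (a function of the
    window string) replaces the model for testing.  Hits are ranked by
    score descending, ties broken by start ascending.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    seq = sequence.upper().replace("U", "T")
    L = len(seq)
    W = window if window is not None else (model.config.input_length if model else None)
    if W is None:
        raise ValueError("supply a model or an explicit window length")
    if not circular and L < W:
        raise ValueError(f"sequence length {L} shorter than window {W}; use circular=True")

    if circular:
        extended = seq + seq[: W - 1]
        starts = list(range(0, L, stride))
    else:
        extended = seq
        starts = list(range(0, L - W + 1, stride))
    windows = [extended[s : s + W] for s in starts]

    if scorer is not None:
        scores = np.array([scorer(w) for w in windows], dtype=np.float64)
    else:
        scores = model.predict_scores(encode_batch(windows), batch_size=batch_size)

    hits = []
    for s0, sc in zip(starts, scores):
        start = s0 + 1
        wrapped = start + W - 1 > L
        end = ((s0 + W - 1) % L) + 1 if wrapped else start + W - 1
        hits.append(ScanHit(start=start, end=end, wrapped=wrapped, score=float(sc)))
    hits.sort(key=lambda h: (-h.score, h.start))
    return hits


def report_top_hits(hits: list[ScanHit], k: int = 1, seq_length: int | None = None) -> list[ScanHit]:
    """Greedy top-``k`` non-overlapping hits by descending score.

    Ties go to the earlier start (the input ranking guarantees this).
    ``seq_length`` is required when wrapped hits are present, to resolve
    overlap across the junction.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not hits:
        raise ValueError("empty hit list")
    if seq_length is None:
        if any(h.wrapped for h in hits):
            raise ValueError("seq_length required when wrapped hits are present")
        seq_length = max(h.end for h in hits)
    chosen: list[ScanHit] = []
    covered: set[int] = set()
    for h in hits:  # already ranked score desc, start asc
        pos = h.positions(seq_length)
        if covered & pos:
            continue
        chosen.append(h)
        covered |= pos
        if len(chosen) == k:
            break
    return chosen


def hits_to_frame(hits: list[ScanHit], circrna_id: str = "circRNA") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "circrna": [circrna_id] * len(hits),
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "wrapped": [h.wrapped for h in hits],
            "score": [h.score for h in hits],
        }
    )


def write_hits_tsv(hits_by_id: dict[str, list[ScanHit]], path: str | Path) -> None:
    frames = [hits_to_frame(h, cid) for cid, h in hits_by_id.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_hits_bed(hits_by_id: dict[str, list[ScanHit]], seq_lengths: dict[str, int], path: str | Path) -> None:
    """BED6 (0-based half-open); a wrapped hit emits two intervals."""
    rows = []
    for cid, hits in hits_by_id.items():
        L = seq_lengths[cid]
        for i, h in enumerate(hits):
            name = f"{cid}_hit{i + 1}"
            if h.wrapped:
                rows.append((cid, h.start - 1, L, name, h.score))
                rows.append((cid, 0, h.end, name, h.score))
            else:
                rows.append((cid, h.start - 1, h.end, name, h.score))
    with open(path, "w") as fh:
        for chrom, s, e, name, score in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score:.6f}\t+\n")
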