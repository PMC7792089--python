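"""Binding-site dataset construction.

Pipeline from a FASTA of observed binding-site fragments to a balanced,
fixed-length, encoded training set:

1. exact-duplicate positives are removed (observed CLIP-derived sites are
   heavily redundant);
2. a fragment-length threshold is fixed by the Tukey boxplot upper fence
   ``Q3 + 1.5 * IQR`` over the kept site lengths; longer sites are treated
   as outliers and discarded;
3. shorter sites are centred and padded with ``N`` (all-zero rows, inert
   under convolution) out to exactly the threshold length;
4. one dinucleotide-shuffled negative is generated per kept positive, so the
   classes are balanced and share their exact dinucleotide composition.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .encoding import OneHotMatrix, encode_batch, encode_sequence, normalize_sequence
from .shuffle import dinucleotide_shuffle

__all__ = [
    "BindingSiteRecord",
    "LengthPolicy",
    "BindingSiteDataset",
    "length_threshold",
    "pad_or_discard",
    "build_dataset",
    "read_fasta",
    "write_fasta",
]

DISCARD = "discard"  #: sentinel returned for over-length sites


@dataclass(frozen=True)
class BindingSiteRecord:
    """One fragment with its label and provenance.

    ``source`` is ``observed`` for real sites, ``shuffled`` for
    dinucleotide-shuffled negatives (``origin_id`` then names the positive
    they were derived from) and ``synthetic`` for simulated sites.
    """

    id: str
    raw_sequence: str
    label: str  # "positive" | "negative"
    source: str  # "observed" | "shuffled" | "synthetic"
    origin_id: str | None = None

    def __post_init__(self):
        if self.label not in ("positive", "negative"):
            raise ValueError(f"bad label {self.label!r}")
        if self.source not in ("observed", "shuffled", "synthetic"):
            raise ValueError(f"bad source {self.source!r}")
        if self.label == "negative" and self.source == "shuffled" and not self.origin_id:
            raise ValueError("shuffled negatives must carry the id of their source positive")


@dataclass(frozen=True)
class LengthPolicy:
    """Fixed-length policy: pad/centre to ``threshold_L``, discard above it."""

    threshold_L: int
    pad_char: str = "N"

    def __post_init__(self):
        if self.threshold_L < 1:
            raise ValueError("threshold_L must be >= 1")


def length_threshold(lengths: Sequence[int]) -> int:
    """Tukey boxplot upper fence of site lengths, rounded to nearest integer.

    Quartiles use linear interpolation.  Callers discard sites longer than
    the returned value.
    """
    if len(lengths) == 0:
        raise ValueError("no lengths supplied")
    arr = np.asarray(lengths, dtype=np.float64)
    q1, q3 = np.percentile(arr, [25.0, 75.0])  # linear interpolation
    fence = q3 + 1.5 * (q3 - q1)
    return int(np.rint(fence))


def pad_sequence(seq: str, policy: LengthPolicy) -> str:
    """Centre ``seq`` in a window of ``threshold_L`` N's (odd remainder 3')."""
    deficit = policy.threshold_L - len(seq)
    if deficit < 0:
        raise ValueError("sequence longer than threshold")
    left = deficit // 2
    right = deficit - left
    return policy.pad_char * left + seq + policy.pad_char * right


def pad_or_discard(record: BindingSiteRecord, policy: LengthPolicy) -> OneHotMatrix | str:
    """Encode a record at the policy length, or return the discard sentinel.

    Sites longer than ``threshold_L`` are length outliers under the boxplot
    rule and yield :data:`DISCARD`; shorter sites are centred and N-padded.
    """
    if len(record.raw_sequence) > policy.threshold_L:
        return DISCARD
    return encode_sequence(pad_sequence(record.raw_sequence, policy))


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path | io.TextIOBase) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a (wrapped or unwrapped) FASTA file."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Dataset container


@dataclass
class BindingSiteDataset:
    """Balanced positive/negative fragments under one length policy."""

    records: list[BindingSiteRecord]
    policy: LengthPolicy
    n_discarded: int = 0
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def positives(self) -> list[BindingSiteRecord]:
        return [r for r in self.records if r.label == "positive"]

    @property
    def negatives(self) -> list[BindingSiteRecord]:
        return [r for r in self.records if r.label == "negative"]

    def encoded(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, y): X is (N, L, 4) padded one-hot, y is 0/1 labels."""
        seqs = [pad_sequence(normalize_sequence(r.raw_sequence), self.policy) for r in self.records]
        X = encode_batch(seqs)
        y = np.array([1 if r.label == "positive" else 0 for r in self.records], dtype=np.int64)
        return X, y

    def manifest(self) -> pd.DataFrame:
        """Tab-friendly per-record table (id, label, length, source, origin)."""
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "label": [r.label for r in self.records],
                "length": [len(r.raw_sequence) for r in self.records],
                "source": [r.source for r in self.records],
                "origin_id": [r.origin_id or "" for r in self.records],
            }
        )

    def write_manifest(self, path: str | Path) -> None:
        self.manifest().to_csv(path, sep="\t", index=False)

    def write_negatives_fasta(self, path: str | Path) -> None:
        write_fasta([(r.id, r.raw_sequence) for r in self.negatives], path)


def build_dataset(
    positives: str | Path | Sequence[tuple[str, str]],
    policy: LengthPolicy | None = None,
    seed: int = 0,
) -> BindingSiteDataset:
    """Build a balanced dataset from positive fragments.

    ``positives`` is a FASTA path or an (id, sequence) list.  Exact duplicate
    sequences are removed (first id wins).  If ``policy`` is None the length
    threshold is fitted on the deduplicated sites by :func:`length_threshold`.
    One dinucleotide-shuffled negative is emitted per kept positive, so the
    output is balanced and the two pools share their dinucleotide counts.
    Fully deterministic under ``seed``.
    """
    if isinstance(positives, (str, Path)) or isinstance(positives, io.TextIOBase):
        pairs = read_fasta(positives)
    else:
        pairs = list(positives)
    if not pairs:
        raise ValueError("no positive sequences supplied")

    seen: set[str] = set()
    deduped: list[tuple[str, str]] = []
    for name, seq in pairs:
        norm = normalize_sequence(seq)
        if norm in seen:
            continue
        seen.add(norm)
        deduped.append((name, norm))

    if policy is None:
        policy = LengthPolicy(length_threshold([len(s) for _, s in deduped]))

    rng = np.random.default_rng(seed)
    records: list[BindingSiteRecord] = []
    n_discarded = 0
    for name, seq in deduped:
        if len(seq) > policy.threshold_L:
            n_discarded += 1
            continue
        pos = BindingSiteRecord(id=name, raw_sequence=seq, label="positive", source="observed")
        neg = BindingSiteRecord(
            id=f"{name}_shuf",
            raw_sequence=dinucleotide_shuffle(seq, rng),
            label="negative",
            source="shuffled",
            origin_id=name,
        )
        records.extend([pos, neg])
    if not records:
        raise ValueError("all positives were discarded by the length policy")
    return BindingSiteDataset(records=records, policy=policy, n_discarded=n_discarded)
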