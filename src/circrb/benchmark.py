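"""The planted-motif benchmark protocol.

Real circRNA–RBP binding-site corpora (CLIP-derived fragment sets and the
spliced circRNA sequences they come from) are external downloads; the
package's reference benchmark instead uses the synthetic generator at a
fixed, documented scale so every stage — dataset construction, training,
cross-validation, motif discovery and full-circRNA scanning — can be
exercised and scored end to end on one CPU.

Benchmark conditions (see also :mod:`circrb.synthetic`): 2000 positives of
50 nt over a uniform background, one ACTAAC occurrence planted per positive
at a uniform offset, negatives by dinucleotide shuffling.  The benchmark
network uses 64 convolution detectors of width 9 (8 primary capsules of
8 dims), two routing rounds and global max pooling; training follows the
default schedule (Adam, batch 64, up to 30 epochs, early stopping with
patience 5).
"""

from __future__ import annotations

import numpy as np

from .model import CircRBModel, CircRBResults
from .scan import report_top_hits
from .synthetic import SimConfig, simulate_dataset, simulate_full_circrna
from .training import CVResult, TrainConfig, cross_validate

__all__ = [
    "BENCHMARK_FILTERS",
    "benchmark_sim_config",
    "benchmark_train_config",
    "benchmark_model",
    "fit_benchmark",
    "planted_motif_cv",
    "label_shuffled_cv",
    "top_motif_consensus",
    "consensus_match_count",
    "scan_overlap_fraction",
    "pooling_ablation",
]

BENCHMARK_FILTERS = 64


def benchmark_sim_config(seed: int) -> SimConfig:
    return SimConfig(seed=seed)  # n_pos=2000, L=50, ACTAAC, uniform background


def benchmark_train_config(seed: int) -> TrainConfig:
    return TrainConfig(max_epochs=30, patience=5, seed=seed)


def benchmark_model(ds) -> CircRBModel:
    return CircRBModel(ds, n_filters=BENCHMARK_FILTERS)


def fit_benchmark(seed: int) -> CircRBResults:
    """One 80/20 fit of the benchmark model at the given seed."""
    ds, _ = simulate_dataset(benchmark_sim_config(seed))
    return benchmark_model(ds).fit(benchmark_train_config(seed))


def planted_motif_cv(seed: int, k: int = 5) -> CVResult:
    """Stratified k-fold CV of the benchmark classifier."""
    ds, _ = simulate_dataset(benchmark_sim_config(seed))
    return benchmark_model(ds).cross_validate(k=k, train_config=benchmark_train_config(seed))


def label_shuffled_cv(seed: int, k: int = 5) -> CVResult:
    """Null control: identical protocol with labels randomly permuted."""
    ds, _ = simulate_dataset(benchmark_sim_config(seed))
    X, y = ds.encoded()
    y_null = np.random.default_rng(seed).permutation(y)
    model = benchmark_model(ds)
    return cross_validate(X, y_null, model.config, benchmark_train_config(seed), k=k)


def top_motif_consensus(results: CircRBResults, min_subsequences: int = 10) -> str:
    """Consensus of the highest-total-information PFM of a fitted model."""
    from .motifs import information_content

    pfms = results.motifs(min_subsequences=min_subsequences)
    if not pfms:
        raise RuntimeError("no detector passed the minimum-contribution filter")
    ics = [information_content(p).sum() for p in pfms]
    return pfms[int(np.argmax(ics))].consensus()


def consensus_match_count(consensus: str, motif: str = "ACTAAC") -> int:
    """Best ungapped alignment of ``motif`` inside ``consensus``: positions matched."""
    if len(consensus) < len(motif):
        consensus, motif = motif, consensus
    return max(
        sum(a == b for a, b in zip(consensus[off : off + len(motif)], motif))
        for off in range(len(consensus) - len(motif) + 1)
    )


def scan_overlap_fraction(
    results: CircRBResults,
    seed: int,
    n_circ: int = 20,
    L_circ: int = 500,
    n_sites: int = 2,
) -> float:
    """Fraction of simulated circRNAs whose top scan hit overlaps a truth site."""
    cfg = benchmark_sim_config(seed)
    hits = 0
    for i in range(n_circ):
        seq, truth = simulate_full_circrna(cfg, L_circ, n_sites=n_sites, seed=seed * 100_003 + i)
        top = report_top_hits(results.scan(seq), k=1, seq_length=len(seq))[0]
        covered = top.positions(len(seq))
        for _, row in truth.iterrows():
            if row.wrapped:
                site = set(range(row.start, L_circ + 1)) | set(range(1, row.end + 1))
            else:
                site = set(range(row.start, row.end + 1))
            if covered & site:
                hits += 1
                break
    return hits / n_circ


def pooling_ablation(seed: int, n_pos: int = 300, epochs: int = 10) -> tuple[float, float]:
    """Small end-to-end run with and without global max pooling.

    Returns ``(auc_with_pooling, auc_without_pooling)`` on a reduced problem
    (the ablation checks the alternative wiring end to end; the full
    benchmark scale is not needed to exercise it).
    """
    ds, _ = simulate_dataset(SimConfig(n_pos=n_pos, seed=seed))
    tc = TrainConfig(max_epochs=epochs, seed=seed)
    with_pool = CircRBModel(ds, n_filters=32, maxpool=True).fit(tc).test_auc
    without_pool = CircRBModel(ds, n_filters=32, maxpool=False).fit(tc).test_auc
    return with_pool, without_pool
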