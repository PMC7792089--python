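"""User-facing modelling surface.

:class:`CircRBModel` is built from a binding-site dataset (or straight from
a FASTA of positive fragments) and owns the architecture configuration;
``fit()`` trains the capsule network and returns a :class:`CircRBResults`
carrying the trained network, the loss trajectory, diagnostics and a
``summary()`` table.  Cross-validation, motif discovery and full-circRNA
scanning hang off these two objects.

Typical use::

    ds, truth = simulate_dataset(SimConfig(n_pos=500, seed=7))
    model = CircRBModel(ds, n_filters=32)
    res = model.fit()
    print(res.summary())
    hits = res.scan("ACGT..." * 100)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .capsnet import CapsNetConfig, CapsuleNetwork, LossConfig
from .datasets import BindingSiteDataset, LengthPolicy, build_dataset, pad_sequence
from .encoding import encode_batch, normalize_sequence
from .motifs import MotifPFM, discover_motifs, export_meme
from .scan import ScanHit, report_top_hits, scan_circrna
from .training import CVResult, TrainConfig, TrainResult, cross_validate, roc_auc, train

__all__ = ["CircRBModel", "CircRBResults", "default_kernel_size"]

#: Fragment length at which the wider convolution window is preferred.
LONG_FRAGMENT_NT = 100


def default_kernel_size(fragment_length: int) -> int:
    """9 for short fragments, 11 for long ones (>= 100 nt)."""
    return 11 if fragment_length >= LONG_FRAGMENT_NT else 9


class CircRBModel:
    """Capsule-network binding-site model bound to one dataset.

    Parameters
    ----------
    dataset
        A :class:`BindingSiteDataset` (balanced positives/negatives under a
        fixed length policy).
    config
        Full :class:`CapsNetConfig`; if omitted, one is derived from the
        dataset's fragment length and ``**overrides`` (e.g. ``n_filters=32``,
        ``maxpool=False``, ``routing_iters=3``).
    """

    def __init__(self, dataset: BindingSiteDataset, config: CapsNetConfig | None = None, **overrides):
        self.dataset = dataset
        L = dataset.policy.threshold_L
        if config is None:
            overrides.setdefault("kernel_size", default_kernel_size(L))
            config = CapsNetConfig(input_length=L, **overrides)
        elif overrides:
            config = replace(config, **overrides)
        if config.input_length != L:
            raise ValueError(
                f"config input_length {config.input_length} != dataset fragment length {L}"
            )
        self.config = config
        self._X, self._y = dataset.encoded()

    @classmethod
    def from_fasta(cls, positives_fasta, policy: LengthPolicy | None = None, seed: int = 0, **overrides):
        """Build the balanced dataset from positive fragments, then the model."""
        ds = build_dataset(positives_fasta, policy=policy, seed=seed)
        return cls(ds, **overrides)

    @property
    def exog_shape(self) -> tuple[int, ...]:
        return self._X.shape

    def fit(self, train_config: TrainConfig = TrainConfig(), test_fraction: float = 0.2) -> "CircRBResults":
        """Train on a stratified (1 - test_fraction) split, score the rest.

        The held-out portion yields the reported AUC and is the pool motif
        discovery draws from.
        """
        from sklearn.model_selection import train_test_split

        idx_tr, idx_te = train_test_split(
            np.arange(len(self._y)),
            test_size=test_fraction,
            stratify=self._y,
            random_state=train_config.seed,
        )
        net = CapsuleNetwork(self.config, seed=train_config.seed)
        tr_res = train(self._X[idx_tr], self._y[idx_tr], net, train_config)
        test_scores = net.predict_scores(self._X[idx_te])
        test_auc, roc = roc_auc(test_scores, self._y[idx_te])
        return CircRBResults(
            model=self,
            network=net,
            train_result=tr_res,
            train_config=train_config,
            test_indices=idx_te,
            test_scores=test_scores,
            test_auc=test_auc,
            roc_points=roc,
        )

    def cross_validate(self, k: int = 5, train_config: TrainConfig = TrainConfig()) -> CVResult:
        """Stratified k-fold CV (each fold 1/k held out) with per-fold AUC."""
        return cross_validate(self._X, self._y, self.config, train_config, k=k)


@dataclass
class CircRBResults:
    """A fitted capsule network plus its training/evaluation record."""

    model: CircRBModel
    network: CapsuleNetwork
    train_result: TrainResult
    train_config: TrainConfig
    test_indices: np.ndarray
    test_scores: np.ndarray
    test_auc: float
    roc_points: tuple[np.ndarray, np.ndarray]
    _motifs: list[MotifPFM] | None = field(default=None, repr=False)

    # -- prediction --------------------------------------------------------

    def predict(self, sequences: list[str] | np.ndarray) -> np.ndarray:
        """Binding scores (positive-capsule norms) for fragments.

        String fragments shorter than the model length are centred and
        N-padded; encoded arrays are scored as-is.
        """
        if isinstance(sequences, np.ndarray):
            return self.network.predict_scores(sequences)
        policy = self.model.dataset.policy
        padded = [pad_sequence(normalize_sequence(s), policy) for s in sequences]
        return self.network.predict_scores(encode_batch(padded))

    # -- motifs ------------------------------------------------------------

    def motifs(self, min_subsequences: int = 10, sequences: list[str] | None = None) -> list[MotifPFM]:
        """PFMs from the detectors, fed the held-out positive fragments.

        ``sequences`` overrides the default pool (e.g. to pool CV folds).
        """
        if sequences is None:
            recs = self.model.dataset.records
            policy = self.model.dataset.policy
            sequences = [
                pad_sequence(normalize_sequence(recs[i].raw_sequence), policy)
                for i in self.test_indices
                if recs[i].label == "positive"
            ]
        pfms = discover_motifs(self.network, sequences, min_subsequences=min_subsequences)
        self._motifs = pfms
        return pfms

    def export_meme(self, path: str | Path, **kwargs) -> None:
        pfms = self._motifs if self._motifs is not None else self.motifs()
        Path(path).write_text(export_meme(pfms, **kwargs))

    # -- scanning ----------------------------------------------------------

    def scan(self, sequence: str, stride: int = 1, circular: bool = True) -> list[ScanHit]:
        """Rank all windows of a full circRNA by binding score."""
        return scan_circrna(sequence, model=self.network, stride=stride, circular=circular)

    def top_binding_sites(self, sequence: str, k: int = 1, **kwargs) -> list[ScanHit]:
        hits = self.scan(sequence, **kwargs)
        return report_top_hits(hits, k=k, seq_length=len(sequence))

    # -- reporting / persistence -------------------------------------------

    def summary(self) -> str:
        """Plain-text fit summary (architecture, training record, test AUC)."""
        cfg = self.model.config
        tr = self.train_result
        n_params = sum(p.data.size for p in self.network.params.values())
        rows = [
            ("fragment length (nt)", cfg.input_length),
            ("conv filters x window", f"{cfg.n_filters} x {cfg.kernel_size}"),
            ("primary capsules", f"{cfg.n_primary} x {cfg.caps_dim}d"),
            ("digit capsules", f"{cfg.n_classes} x {cfg.out_caps_dim}d"),
            ("routing rounds", cfg.routing_iters),
            ("global max pooling", cfg.maxpool),
            ("trainable parameters", n_params),
            ("instances (train/test)", f"{len(self.model._y) - len(self.test_indices)}/{len(self.test_indices)}"),
            ("epochs run (best)", f"{tr.n_epochs} ({tr.best_epoch})"),
            ("final train loss", f"{tr.train_loss[-1]:.4f}"),
            ("best validation loss", f"{tr.best_val_loss:.4f}"),
            ("held-out test AUC", f"{self.test_auc:.4f}"),
        ]
        width = max(len(str(k)) for k, _ in rows)
        lines = ["circRB capsule-network results", "=" * 44]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def loss_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(self.train_result.n_epochs),
                "train_loss": self.train_result.train_loss,
                "val_loss": self.train_result.val_loss,
            }
        )

    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint (weights + architecture + fit record)."""
        self.network.save(
            path,
            extra={
                "test_auc": self.test_auc,
                "train_loss": list(map(float, self.train_result.train_loss)),
                "val_loss": list(map(float, self.train_result.val_loss)),
            },
        )
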