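"""Model configuration, fold splitting with leakage isolation, training loop.

The classifier is a compact transformer encoder over tokenized peptides
(optionally concatenated with the allele's 34-residue pocket pseudo
sequence), trained with binary cross-entropy and Adam.  Eluted-ligand (EL)
records carry hard 0/1 targets and binding-affinity (BA) records carry soft
targets in [0, 1]; both mix freely in the same batches under the shared
soft-target BCE.

Data folds are produced by random splitting followed by overlap isolation:
any peptide sequence landing in more than one fold has all of its
occurrences moved to a single fold, so train/validation/test never share a
peptide.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encode import MAX_LEN_SEQ, MAX_LEN_SEQ_MHC, VOCAB_SIZE, batch_encode
from .io import Dataset
from .nn import Adam, TransformerClassifier

logger = logging.getLogger("mhc2tx")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults: the 4-layer SEQ:MHC variant)."""

    d_model: int = 128
    n_layers: int = 4
    n_heads: int = 2
    d_ff: int = 512
    head_hidden: int = 310
    dropout: float = 0.1
    max_len: int = MAX_LEN_SEQ_MHC
    vocab_size: int = VOCAB_SIZE

    def __post_init__(self) -> None:
        if self.n_layers not in (2, 4, 8):
            raise ValueError("n_layers must be one of {2, 4, 8}")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.max_len not in (MAX_LEN_SEQ, MAX_LEN_SEQ_MHC):
            raise ValueError(f"max_len must be {MAX_LEN_SEQ} or {MAX_LEN_SEQ_MHC}")

    @property
    def with_mhc(self) -> bool:
        return self.max_len == MAX_LEN_SEQ_MHC


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: BCE loss + Adam, 300 epochs by default."""

    epochs: int = 300
    learning_rate: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 256
    seeds: tuple[int, ...] = (0, 1, 2, 3)
    early_stop_patience: int | None = None  # epochs without val-AUC gain; off by default

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be ≥ 1")
        if not self.seeds:
            raise ValueError("need at least one seed")


@dataclass(frozen=True)
class SplitSpec:
    """Fractions for train/validation/test plus the shuffling seed."""

    fractions: tuple[float, float, float] = (0.9, 0.05, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be nonnegative")


def build_model(config: ModelConfig, seed: int = 0, dtype=np.float32) -> TransformerClassifier:
    """Instantiate the transformer classifier with seeded initialization."""
    return TransformerClassifier(config, seed=seed, dtype=dtype)


def bce_loss(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross-entropy, accepting soft targets in [0, 1].

    ``−mean[t·log p + (1−t)·log(1−p)]``; predictions must lie strictly inside
    (0, 1).  Soft targets let continuous BA labels share the loss with binary
    EL labels.
    """
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("predictions and targets must have equal length")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("predictions must lie strictly inside (0, 1)")
    return float(-np.mean(t * np.log(p) + (1 - t) * np.log1p(-p)))


def split_with_overlap_isolation(dataset: Dataset, spec: SplitSpec) -> Dataset:
    """Randomly assign folds, then force each peptide sequence into one fold.

    Records are first partitioned per the configured fractions (random
    permutation, contiguous blocks).  Every peptide sequence that landed in
    more than one fold then has all its occurrences reassigned to the fold of
    its first occurrence in the permutation order, so the folds' sequence
    sets are pairwise disjoint.  Deterministic given the SplitSpec seed.
    """
    if any(r.fold is not None for r in dataset.records):
        raise ValueError("folds already assigned")
    n = len(dataset.records)
    fr_train, fr_val, fr_test = spec.fractions
    if n and (fr_train == 0.0 or fr_val == 0.0 or fr_test == 0.0):
        raise ValueError("zero fraction with nonempty dataset")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_train = int(round(fr_train * n))
    n_val = int(round(fr_val * n))
    fold_of_index: dict[int, str] = {}
    for pos, idx in enumerate(order):
        if pos < n_train:
            fold_of_index[idx] = "train"
        elif pos < n_train + n_val:
            fold_of_index[idx] = "validation"
        else:
            fold_of_index[idx] = "test"
    # overlap isolation: first occurrence (in permutation order) wins
    seq_fold: dict[str, str] = {}
    for idx in order:
        seq = dataset.records[idx].sequence
        seq_fold.setdefault(seq, fold_of_index[idx])
    records = [
        rec.with_fold(seq_fold[rec.sequence]) for rec in dataset.records
    ]
    out = Dataset(records=records, alleles=dict(dataset.alleles))
    for a, b in (("train", "validation"), ("train", "test"), ("validation", "test")):
        sa = {r.sequence for r in out.records if r.fold == a}
        sb = {r.sequence for r in out.records if r.fold == b}
        assert not sa & sb, "overlap isolation failed"
    return out


def predict(
    model: TransformerClassifier,
    records,
    alleles=None,
    batch_size: int = 512,
) -> np.ndarray:
    """Presentation scores in (0, 1), order-preserving and batching-invariant."""
    ids, mask, _ = batch_encode(list(records), alleles, with_mhc=model.config.with_mhc)
    out = np.empty(len(ids), dtype=np.float64)
    for i in range(0, len(ids), batch_size):
        out[i : i + batch_size] = model.forward(
            ids[i : i + batch_size], mask[i : i + batch_size], train=False
        )
    return out


def train(
    model: TransformerClassifier,
    train_fold: Dataset,
    val_fold: Dataset,
    train_config: TrainConfig,
    seed: int = 0,
) -> tuple[TransformerClassifier, list[dict]]:
    """Train with BCE + Adam; return the best-validation-AUC checkpoint.

    History holds one entry per epoch with mean train loss, validation loss
    and validation AUC.  All stochasticity (shuffling, dropout) is keyed off
    ``seed``; with fixed seeds the run is bitwise reproducible.
    """
    from .metrics import roc_auc

    if not len(train_fold.records) or not len(val_fold.records):
        raise ValueError("train and validation folds must be nonempty")
    with_mhc = model.config.with_mhc
    alleles = {**train_fold.alleles, **val_fold.alleles}
    ids, mask, targets = batch_encode(train_fold.records, alleles, with_mhc)
    val_ids, val_mask, val_targets = batch_encode(val_fold.records, alleles, with_mhc)
    val_binary = np.isin(val_targets, (0.0, 1.0))
    if len(np.unique(val_targets[val_binary])) < 2:
        logger.warning("validation fold lacks both classes; val AUC will be nan")

    ss = np.random.SeedSequence(seed)
    shuffle_rng, dropout_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    opt = Adam(model.params(), lr=train_config.learning_rate, betas=train_config.betas)
    history: list[dict] = []
    best_auc, best_state, best_epoch = -np.inf, model.get_state(), -1
    n = len(ids)
    bs = train_config.batch_size
    for epoch in range(train_config.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for i in range(0, n, bs):
            sel = order[i : i + bs]
            p = model.forward(ids[sel], mask[sel], train=True, rng=dropout_rng)
            t = targets[sel].astype(np.float64)
            eps = 1e-12
            loss = float(
                -np.mean(t * np.log(p + eps) + (1 - t) * np.log1p(-p + eps))
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i // bs}: {loss}"
                )
            model.zero_grad()
            model.backward((p - t) / len(sel))  # d(BCE∘sigmoid)/d(logits)
            opt.step()
            losses.append(loss)
        # validation pass
        val_p = np.empty(len(val_ids))
        for i in range(0, len(val_ids), 512):
            val_p[i : i + 512] = model.forward(
                val_ids[i : i + 512], val_mask[i : i + 512], train=False
            )
        vt = val_targets.astype(np.float64)
        val_loss = float(
            -np.mean(vt * np.log(val_p + 1e-12) + (1 - vt) * np.log1p(-val_p + 1e-12))
        )
        labels = val_targets[val_binary].astype(int)
        if len(np.unique(labels)) == 2:
            val_auc = roc_auc(val_p[val_binary], labels)
        else:
            val_auc = float("nan")
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "val_auc": val_auc,
            }
        )
        logger.info(
            "epoch %d: train loss %.4f, val loss %.4f, val AUC %s",
            epoch, history[-1]["train_loss"], val_loss,
            f"{val_auc:.4f}" if np.isfinite(val_auc) else "nan",
        )
        if np.isfinite(val_auc) and val_auc > best_auc:
            best_auc, best_state, best_epoch = val_auc, model.get_state(), epoch
        if (
            train_config.early_stop_patience is not None
            and epoch - max(best_epoch, 0) >= train_config.early_stop_patience
        ):
            logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
            break
    model.set_state(best_state)
    return model, history


def _vocabulary_hash() -> str:
    import hashlib
    import json

    from .encode import TOKEN_TO_ID

    return hashlib.sha256(
        json.dumps(TOKEN_TO_ID, sort_keys=True).encode()
    ).hexdigest()[:16]


def save_checkpoint(model: TransformerClassifier, path: str | Path) -> None:
    """Persist weights, the ModelConfig and the vocabulary hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        pickle.dump(
            {
                "config": model.config,
                "state": model.get_state(),
                "vocabulary_hash": _vocabulary_hash(),
            },
            fh,
        )


def load_checkpoint(path: str | Path) -> TransformerClassifier:
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    if blob.get("vocabulary_hash", _vocabulary_hash()) != _vocabulary_hash():
        raise ValueError("checkpoint was written with a different vocabulary")
    model = TransformerClassifier(blob["config"])
    model.set_state(blob["state"])
    return model
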