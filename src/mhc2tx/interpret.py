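"""Shapley-value attribution of peptide positions.

Each attributed position is a player in a cooperative game whose value
function is the model score with "absent" positions replaced by the MASK
token (masking, rather than deletion, keeps the positional encoding of the
remaining residues intact).  Exact enumeration over all 2^k coalitions is
available for k ≤ 12 positions; longer inputs use permutation sampling with
antithetic (forward/reversed) permutation pairs.

Exact attributions satisfy the classical axioms — efficiency (values sum to
the prediction minus the all-masked baseline), symmetry, and null player —
which the test suite checks on closed-form stub games.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Callable, Sequence

import numpy as np

from .encode import MASK

EXACT_LIMIT = 12


@dataclass(frozen=True)
class AttributionVector:
    """Per-position Shapley values plus the all-masked baseline score."""

    positions: tuple[int, ...]  # indices into the token sequence
    values: np.ndarray  # one value per attributed position
    baseline: float  # model score with every attributed position masked
    prediction: float  # unmasked model score

    def __post_init__(self) -> None:
        if len(self.values) != len(self.positions):
            raise ValueError("one value per attributed position required")

    def top_positions(self, k: int) -> list[int]:
        order = np.argsort(self.values, kind="stable")[::-1]
        return [self.positions[i] for i in order[:k]]


def _coalition_scores(
    score_fn: Callable[[np.ndarray], np.ndarray],
    ids: np.ndarray,
    positions: Sequence[int],
    subsets: np.ndarray,
    batch_size: int = 4096,
) -> np.ndarray:
    """Score one masked variant per subset row (True = position present)."""
    variants = np.repeat(ids[None, :], len(subsets), axis=0)
    for j, pos in enumerate(positions):
        variants[~subsets[:, j], pos] = MASK
    out = np.empty(len(subsets), dtype=np.float64)
    for i in range(0, len(variants), batch_size):
        out[i : i + batch_size] = np.asarray(score_fn(variants[i : i + batch_size]))
    return out


def shapley_attribution(
    score_fn: Callable[[np.ndarray], np.ndarray],
    ids: np.ndarray,
    positions: Sequence[int],
    mode: str = "exact",
    n_samples: int = 200,
    seed: int = 0,
) -> AttributionVector:
    """Shapley values of the given token positions under MASK-ablation.

    Parameters
    ----------
    score_fn:
        Maps a batch of token-id matrices (n × L) to scores (n,).  For a
        trained model use :func:`model_score_fn`.
    ids:
        The full token sequence of the record being explained.
    positions:
        Token indices to attribute (typically the peptide residues).
    mode:
        ``"exact"`` enumerates all 2^k coalitions (k ≤ 12); ``"sampled"``
        uses antithetic permutation sampling and converges to the exact
        values as ``n_samples`` grows.
    """
    ids = np.asarray(ids)
    positions = tuple(int(p) for p in positions)
    k = len(positions)
    if k == 0:
        raise ValueError("no positions to attribute")
    if mode == "exact":
        if k > EXACT_LIMIT:
            raise ValueError(
                f"exact mode limited to {EXACT_LIMIT} positions, got {k}"
            )
        subsets = (
            (np.arange(2**k)[:, None] >> np.arange(k)) & 1
        ).astype(bool)
        scores = _coalition_scores(score_fn, ids, positions, subsets)
        sizes = subsets.sum(axis=1)
        # weight of v(S) − v(S\{i}) contributions: |S\{i}|!(k−|S|)!/k!
        values = np.zeros(k)
        for i in range(k):
            with_i = subsets[:, i]
            partner = np.arange(2**k) ^ (1 << i)  # same subset without i
            w = np.array(
                [1.0 / (k * comb(k - 1, s - 1)) for s in sizes[with_i]]
            )
            values[i] = np.sum(w * (scores[with_i] - scores[partner[with_i]]))
        baseline = float(scores[0])
        prediction = float(scores[-1])
        return AttributionVector(positions, values, baseline, prediction)
    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    values = np.zeros(k)
    baseline = float(
        _coalition_scores(score_fn, ids, positions, np.zeros((1, k), dtype=bool))[0]
    )
    prediction = float(
        _coalition_scores(score_fn, ids, positions, np.ones((1, k), dtype=bool))[0]
    )
    n_pairs = (n_samples + 1) // 2
    total = 0
    for _ in range(n_pairs):
        perm = rng.permutation(k)
        for order in (perm, perm[::-1]):  # antithetic pair
            # incremental coalitions along the permutation
            subsets = np.zeros((k + 1, k), dtype=bool)
            for step, pos_idx in enumerate(order):
                subsets[step + 1] = subsets[step]
                subsets[step + 1, pos_idx] = True
            scores = _coalition_scores(score_fn, ids, positions, subsets)
            values[order] += np.diff(scores)
            total += 1
    values /= total
    return AttributionVector(positions, values, baseline, prediction)


def model_score_fn(model, mask: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Adapt a trained classifier to the score-function interface.

    The attention mask is held fixed: MASK tokens stay attended (they encode
    "residue ablated", not padding).
    """

    def fn(ids_batch: np.ndarray) -> np.ndarray:
        m = np.repeat(mask[None, :], len(ids_batch), axis=0)
        return model.forward(ids_batch, m, train=False)

    return fn


def peptide_positions(peptide_length: int) -> list[int]:
    """Token indices of the peptide residues (between START and STOP)."""
    return list(range(1, 1 + peptide_length))


def attribution_frame(attr: AttributionVector, tokens: np.ndarray):
    """Tabulate attributions keyed by position and residue token id."""
    import pandas as pd

    return pd.DataFrame(
        {
            "position": list(attr.positions),
            "token_id": [int(tokens[p]) for p in attr.positions],
            "shapley_value": attr.values,
        }
    )
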