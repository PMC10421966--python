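"""Binding-affinity label transform and decoy (synthetic negative) generation.

Eluted-ligand mass spectrometry only observes presented peptides, so negative
examples must be synthesized.  Two strategies are provided:

* uniform decoys — peptides sampled randomly and uniformly from a proteome,
  a fixed number for each length between 15 and 21 residues;
* source-anchored decoys — peptides sampled only from the non-presented
  regions of proteins that contributed at least one presented peptide, so the
  negatives share the positives' source-protein context.

Binding-affinity (BA) measurements are mapped from IC50 (nM) to a [0, 1]
label via ``1 − log(IC50)/log(50000)``, clamped, so BA and EL records share
one label scale.  No BA decoys are generated: the BA assay itself observes
weak and non-binders.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io import PeptideRecord

logger = logging.getLogger("mhc2tx")

#: IC50 (nM) mapped to label 0.0; the transform's dynamic-range ceiling.
IC50_MAX_NM = 50_000.0


@dataclass(frozen=True)
class DecoyConfig:
    """Decoy sampling parameters.

    ``per_length_count`` drives the uniform strategy (that many decoys per
    length); ``per_positive_ratio`` drives the source-anchored strategy
    (decoys per positive, lengths cycled over the range).
    """

    length_min: int = 15
    length_max: int = 21
    per_length_count: int = 100
    per_positive_ratio: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.length_min <= self.length_max <= 33:
            raise ValueError("decoy lengths must satisfy 1 ≤ min ≤ max ≤ 33")


def transform_affinity(ic50_nM: float) -> float:
    """Map an IC50 (nM) to the shared [0, 1] label: ``1 − log(IC50)/log(50000)``.

    Strictly decreasing on [1, 50000]; values outside that range clamp to the
    label endpoints (the loss downstream requires labels in [0, 1]).
    """
    ic50 = float(ic50_nM)
    if not ic50 > 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    return float(min(1.0, max(0.0, 1.0 - math.log(ic50) / math.log(IC50_MAX_NM))))


def inverse_transform_affinity(label: float) -> float:
    """IC50 (nM) whose transformed label equals ``label``: ``50000^(1−label)``."""
    if not 0.0 <= label <= 1.0:
        raise ValueError("label must be in [0, 1]")
    return float(IC50_MAX_NM ** (1.0 - label))


def _decoy_record(
    sequence: str, protein_id: str, organism: str, allele: str | None = None
) -> PeptideRecord:
    return PeptideRecord(
        sequence=sequence,
        assay_type="EL",
        target=0.0,
        allele_name=allele,
        organism=organism,
        provenance="synthetic",
        source_protein_id=protein_id,
    )


def sample_uniform_decoys(
    proteome: dict[str, str],
    config: DecoyConfig,
    organism: str = "human",
) -> list[PeptideRecord]:
    """Sample ``per_length_count`` decoys uniformly for each length in range.

    Every decoy is a contiguous substring of a proteome protein, drawn
    uniformly over all (protein, start) windows of its length, without
    replacement within a (protein, start, length) key.  Deterministic given
    ``config.seed``.
    """
    if not proteome:
        raise ValueError("empty proteome")
    rng = np.random.default_rng(config.seed)
    ids = sorted(proteome)
    records: list[PeptideRecord] = []
    for length in range(config.length_min, config.length_max + 1):
        counts = np.array([max(0, len(proteome[i]) - length + 1) for i in ids])
        total = int(counts.sum())
        if total < config.per_length_count:
            raise ValueError(
                f"proteome supplies only {total} windows of length {length}, "
                f"need {config.per_length_count}"
            )
        offsets = np.concatenate([[0], np.cumsum(counts)])
        picks = rng.choice(total, size=config.per_length_count, replace=False)
        picks.sort()
        for flat in picks:
            pi = int(np.searchsorted(offsets, flat, side="right") - 1)
            start = int(flat - offsets[pi])
            pid = ids[pi]
            records.append(
                _decoy_record(proteome[pid][start : start + length], pid, organism)
            )
    return records


def presented_spans(
    positives: list[PeptideRecord], source_proteins: dict[str, str]
) -> dict[str, list[tuple[int, int]]]:
    """Half-open [start, end) spans of every positive within its source protein.

    All occurrences of each positive sequence are marked, so repeated motifs
    never leak into the decoy pool.
    """
    spans: dict[str, list[tuple[int, int]]] = {pid: [] for pid in source_proteins}
    for rec in positives:
        pid = rec.source_protein_id
        if pid is None or pid not in source_proteins:
            raise KeyError(f"positive {rec.sequence!r} has unknown source protein {pid!r}")
        protein = source_proteins[pid]
        start = protein.find(rec.sequence)
        if start < 0:
            raise ValueError(
                f"positive {rec.sequence!r} not found in source protein {pid!r}"
            )
        while start >= 0:
            spans[pid].append((start, start + len(rec.sequence)))
            start = protein.find(rec.sequence, start + 1)
    return spans


def sample_source_anchored_decoys(
    positives: list[PeptideRecord],
    source_proteins: dict[str, str],
    config: DecoyConfig,
    organism: str = "mouse",
) -> list[PeptideRecord]:
    """Sample decoys from the non-presented regions of positive-bearing proteins.

    Exactly ``per_positive_ratio × len(positives)`` decoys are drawn (lengths
    cycled uniformly over the configured range) from proteins contributing at
    least one positive; no decoy shares any residue position with a presented
    span.  Proteins too covered to yield a given length are skipped with a
    warning; only a globally exhausted pool raises.
    """
    if not positives:
        raise ValueError("no positives supplied")
    rng = np.random.default_rng(config.seed)
    spans = presented_spans(positives, source_proteins)
    contributing = sorted({r.source_protein_id for r in positives})

    # per-protein residue coverage masks of the presented spans
    covered: dict[str, np.ndarray] = {}
    for pid in contributing:
        mask = np.zeros(len(source_proteins[pid]), dtype=bool)
        for s, e in spans[pid]:
            mask[s:e] = True
        covered[pid] = mask

    def legal_starts(pid: str, length: int) -> np.ndarray:
        mask = covered[pid]
        n = len(mask) - length + 1
        if n <= 0:
            return np.empty(0, dtype=int)
        # a start is legal iff the window [s, s+length) touches no presented residue
        window_hits = np.convolve(mask.astype(int), np.ones(length, dtype=int), "valid")
        return np.flatnonzero(window_hits == 0)

    # proteins with no legal window at any requested length contribute nothing
    usable = []
    for pid in contributing:
        if any(
            legal_starts(pid, L).size
            for L in range(config.length_min, config.length_max + 1)
        ):
            usable.append(pid)
        else:
            logger.warning(
                "protein %s too covered by presented peptides for decoys", pid
            )
    if not usable:
        raise ValueError("no contributing protein can yield any legal decoy")
    contributing = usable

    n_decoys = config.per_positive_ratio * len(positives)
    lengths = [
        config.length_min + (i % (config.length_max - config.length_min + 1))
        for i in range(n_decoys)
    ]
    used: set[tuple[str, int, int]] = set()
    records: list[PeptideRecord] = []
    warned: set[str] = set()
    for length in lengths:
        placed = False
        for pid in rng.permutation(contributing):
            starts = legal_starts(pid, length)
            starts = starts[
                [(pid, int(s), length) not in used for s in starts]
            ]
            if starts.size == 0:
                if pid not in warned:
                    logger.warning(
                        "protein %s too covered by presented peptides for decoys", pid
                    )
                    warned.add(pid)
                continue
            s = int(rng.choice(starts))
            used.add((pid, s, length))
            records.append(
                _decoy_record(
                    source_proteins[pid][s : s + length], pid, organism,
                    allele=positives[0].allele_name,
                )
            )
            placed = True
            break
        if not placed:
            raise ValueError(
                f"no contributing protein can yield a further decoy of length {length}"
            )
    return records
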