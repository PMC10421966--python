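"""Planted-motif immunopeptidome simulator with ground truth.

Emulates the statistical structure of single-allele MHCII data so the whole
pipeline is testable without downloads: each simulated allele carries a
9-position position-weight matrix (PWM) whose low-entropy columns play the
role of anchor positions (the canonical P1/P4/P6/P9 pockets).  Positive
eluted-ligand records are background peptides with a PWM-sampled binding
core inserted at a random admissible offset; decoys are pure-background
peptides with lengths uniform on 15–21, at a configurable decoy:positive
ratio.  Binding-affinity records receive IC50 values linked to the latent
motif score through a logistic, constructed so the standard IC50→[0,1]
transform recovers the logistic exactly.

Every peptide is paired with a :class:`SimTruth` entry (generating allele,
core offset, binder flag, latent score), giving downstream tests an oracle
for anchor recovery and separability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoys import IC50_MAX_NM, transform_affinity
from .io import CANONICAL_AA, PSEUDO_LEN, AlleleRecord, Dataset, PeptideRecord

CORE_LEN = 9
#: canonical MHCII anchor pockets within the 9-mer core (1-based P1/P4/P6/P9)
DEFAULT_ANCHORS = (1, 4, 6, 9)

#: approximate vertebrate proteome residue frequencies (order: ACDEFGHIKLMNPQRSTVWY)
BACKGROUND_FREQS = np.array(
    [
        0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
        0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032,
    ]
)
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()


@dataclass(frozen=True)
class MotifModel:
    """One simulated allele: its PWM, anchor positions and pseudo sequence."""

    allele_name: str
    pwm: np.ndarray  # 9×20 column-stochastic over CANONICAL_AA
    anchor_positions: tuple[int, ...]  # 1-based core positions with low entropy
    pseudo_sequence: str

    def __post_init__(self) -> None:
        if self.pwm.shape != (CORE_LEN, len(CANONICAL_AA)):
            raise ValueError("PWM must be 9×20")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        for p in self.anchor_positions:
            if self.pwm[p - 1].max() < 0.7:
                raise ValueError(f"anchor position {p} is not low-entropy")
        if len(self.pseudo_sequence) != PSEUDO_LEN:
            raise ValueError("pseudo sequence must be 34 long")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated immunopeptidome.

    Defaults mirror the desk-scale corpus: 2 alleles × 1250 positives with a
    5:1 decoy ratio (2500 positives + 12 500 decoys), lengths concentrated on
    13–17, a 10% complement of BA records and 2% EL label noise.
    """

    n_alleles: int = 2
    n_positives: int = 1250  # per allele
    decoy_ratio: int = 5
    length_range: tuple[int, int] = (9, 33)
    length_concentration: tuple[int, int] = (13, 17)  # bulk of the mass
    ba_fraction: float = 0.1  # extra BA records per positive
    noise: float = 0.02  # EL label-flip probability
    anchor_sharpness: float = 0.85  # anchor-column max probability
    # (a, b) in σ(a·score + b): places consensus binders near IC50 10 nM and
    # background peptides near the 50 000 nM ceiling
    ba_link: tuple[float, float] = (1.0, -10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alleles < 1 or self.n_positives < 1:
            raise ValueError("need at least one allele and one positive")
        if self.decoy_ratio < 1:
            raise ValueError("decoy_ratio must be ≥ 1")
        if not 0 <= self.noise < 1 or not 0 <= self.ba_fraction <= 1:
            raise ValueError("probabilities must be valid")
        lo, hi = self.length_range
        if not CORE_LEN <= lo <= hi <= 33:
            raise ValueError("length range must lie within [9, 33]")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated peptide."""

    allele_name: str
    core_start: int  # offset of the planted core; −1 for background peptides
    true_binder: bool
    latent_score: float  # best sliding-window log-odds under the generating PWM


def make_motifs(config: SimConfig, seed: int | None = None) -> list[MotifModel]:
    """Deterministically build pairwise-distinct allele motifs.

    Anchor columns concentrate mass ``anchor_sharpness`` on one residue;
    distinct alleles use disjoint anchor-residue assignments, keeping the
    total-variation distance between corresponding anchor columns ≥ 0.3.
    Non-anchor columns follow the background.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_aa = len(CANONICAL_AA)
    motifs: list[MotifModel] = []
    # disjoint anchor residues across alleles → guaranteed column separation
    choices = rng.permutation(n_aa)
    needed = config.n_alleles * len(DEFAULT_ANCHORS)
    if needed > n_aa:  # recycle with offset when many alleles are requested
        choices = np.concatenate([choices, rng.permutation(n_aa)])
    pseudo_pool: set[str] = set()
    for a in range(config.n_alleles):
        pwm = np.tile(BACKGROUND_FREQS, (CORE_LEN, 1))
        anchors = DEFAULT_ANCHORS
        for j, pos in enumerate(anchors):
            aa_idx = int(choices[(a * len(anchors) + j) % len(choices)])
            col = BACKGROUND_FREQS * (1 - config.anchor_sharpness)
            col[aa_idx] += config.anchor_sharpness
            pwm[pos - 1] = col / col.sum()
        while True:
            pseudo = "".join(
                rng.choice(list(CANONICAL_AA), size=PSEUDO_LEN, p=BACKGROUND_FREQS)
            )
            if pseudo not in pseudo_pool:
                pseudo_pool.add(pseudo)
                break
        motifs.append(
            MotifModel(
                allele_name=f"SIM-{a:02d}",
                pwm=pwm,
                anchor_positions=anchors,
                pseudo_sequence=pseudo,
            )
        )
    return motifs


def score_peptide(motif: MotifModel, peptide: str) -> tuple[float, int]:
    """Best sliding 9-mer log-odds score and its (leftmost) core start.

    Score of a window = Σ_i log(PWM[i, aa] / background[aa]); unknown
    residues ('X') contribute 0.
    """
    if len(peptide) < CORE_LEN:
        raise ValueError("peptide shorter than the 9-residue core")
    aa_index = {aa: i for i, aa in enumerate(CANONICAL_AA)}
    log_odds = np.log(motif.pwm / BACKGROUND_FREQS[None, :])
    best, best_start = -np.inf, 0
    for start in range(len(peptide) - CORE_LEN + 1):
        s = 0.0
        for i, c in enumerate(peptide[start : start + CORE_LEN]):
            if c in aa_index:
                s += log_odds[i, aa_index[c]]
        if s > best + 1e-12:
            best, best_start = s, start
    return float(best), int(best_start)


def _sample_background(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(CANONICAL_AA), size=length, p=BACKGROUND_FREQS))


def _sample_core(rng: np.random.Generator, pwm: np.ndarray) -> str:
    return "".join(
        CANONICAL_AA[rng.choice(len(CANONICAL_AA), p=pwm[i])] for i in range(CORE_LEN)
    )


def _positive_length(rng: np.random.Generator, config: SimConfig) -> int:
    lo, hi = config.length_range
    clo, chi = config.length_concentration
    # 80% of mass uniform on the concentrated band, 20% on the full range
    if rng.random() < 0.8:
        return int(rng.integers(clo, chi + 1))
    return int(rng.integers(lo, hi + 1))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate(config: SimConfig) -> tuple[Dataset, list[SimTruth]]:
    """Generate a ground-truthed Dataset of EL positives, decoys and BA records.

    Per allele: ``n_positives`` EL positives (planted core, target 1, flipped
    with probability ``noise``), ``decoy_ratio × n_positives`` EL decoys
    (pure background, lengths uniform on 15–21, target 0, same flip), and
    ``round(ba_fraction × n_positives)`` BA records whose IC50 is
    ``50000^(1 − σ(a·score + b))`` so the affinity transform recovers
    ``σ(a·score + b)`` exactly.  Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    motifs = make_motifs(config)
    records: list[PeptideRecord] = []
    truths: list[SimTruth] = []
    a_lnk, b_lnk = config.ba_link

    for motif in motifs:
        # EL positives: background with a planted PWM core
        for _ in range(config.n_positives):
            length = _positive_length(rng, config)
            pep = _sample_background(rng, length)
            start = int(rng.integers(0, length - CORE_LEN + 1))
            pep = pep[:start] + _sample_core(rng, motif.pwm) + pep[start + CORE_LEN :]
            score, _ = score_peptide(motif, pep)
            flipped = rng.random() < config.noise
            records.append(
                PeptideRecord(
                    sequence=pep,
                    assay_type="EL",
                    target=0.0 if flipped else 1.0,
                    allele_name=motif.allele_name,
                    provenance="synthetic",
                )
            )
            truths.append(SimTruth(motif.allele_name, start, True, score))
        # EL decoys: pure background, decoy-length convention 15–21
        for _ in range(config.decoy_ratio * config.n_positives):
            length = int(rng.integers(15, 22))
            pep = _sample_background(rng, length)
            score, _ = score_peptide(motif, pep)
            flipped = rng.random() < config.noise
            records.append(
                PeptideRecord(
                    sequence=pep,
                    assay_type="EL",
                    target=1.0 if flipped else 0.0,
                    allele_name=motif.allele_name,
                    provenance="synthetic",
                )
            )
            truths.append(SimTruth(motif.allele_name, -1, False, score))
        # BA records: half with cores, half background, IC50 linked to score
        n_ba = round(config.ba_fraction * config.n_positives)
        for i in range(n_ba):
            length = _positive_length(rng, config)
            pep = _sample_background(rng, length)
            if i % 2 == 0:
                start = int(rng.integers(0, length - CORE_LEN + 1))
                pep = (
                    pep[:start] + _sample_core(rng, motif.pwm) + pep[start + CORE_LEN :]
                )
            else:
                start = -1
            score, _ = score_peptide(motif, pep)
            label = _sigmoid(a_lnk * score + b_lnk)
            # IC50 drawn from the logistic link; the on-disk target goes
            # through the standard transform, which inverts the link exactly
            ic50 = IC50_MAX_NM ** (1.0 - label)
            records.append(
                PeptideRecord(
                    sequence=pep,
                    assay_type="BA",
                    target=transform_affinity(ic50),
                    allele_name=motif.allele_name,
                    provenance="synthetic",
                )
            )
            truths.append(SimTruth(motif.allele_name, start, label >= 0.5, score))

    alleles = {
        m.allele_name: AlleleRecord(m.allele_name, m.pseudo_sequence) for m in motifs
    }
    return Dataset(records=records, alleles=alleles), truths


def truth_frame(truths: list[SimTruth]) -> pd.DataFrame:
    """Tabular sidecar of the ground truth, aligned row-for-row with records."""
    return pd.DataFrame(
        {
            "allele": [t.allele_name for t in truths],
            "core_start": [t.core_start for t in truths],
            "true_binder": [t.true_binder for t in truths],
            "latent_score": [t.latent_score for t in truths],
        }
    )
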