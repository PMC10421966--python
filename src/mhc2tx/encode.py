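"""Tokenization, padding/masking and sinusoidal positional encoding.

Peptides (≤33 residues) are bracketed by START/STOP tokens; in SEQ:MHC mode
the allele's 34-residue pocket pseudo sequence follows the STOP token, giving
a fixed input length of 33 + 2 + 34 = 69 (35 in peptide-only SEQ mode).
Remaining positions are PAD, excluded from attention via the boolean mask.

The vocabulary has 25 tokens: PAD, START, STOP, MASK, X, then the 20
canonical amino acids in alphabetical order.  MASK is reserved for feature
ablation (Shapley coalitions), not used in supervised training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import CANONICAL_AA, PSEUDO_LEN, AlleleRecord, PeptideRecord

#: fixed input lengths for the two feature modes
MAX_LEN_SEQ = 35  # 33 peptide + START/STOP
MAX_LEN_SEQ_MHC = 69  # + 34-residue pseudo sequence

PAD, START, STOP, MASK, UNK = 0, 1, 2, 3, 4

SPECIAL_TOKENS = {"<pad>": PAD, "<start>": START, "<stop>": STOP, "<mask>": MASK}

#: token → id; X (unknown residue) sits at 4, then A=5 … Y=24.
TOKEN_TO_ID: dict[str, int] = {
    **SPECIAL_TOKENS,
    "X": UNK,
    **{aa: 5 + i for i, aa in enumerate(CANONICAL_AA)},
}
ID_TO_TOKEN: dict[int, str] = {v: k for k, v in TOKEN_TO_ID.items()}
VOCAB_SIZE = len(TOKEN_TO_ID)  # 25


def save_vocabulary(path: str | Path) -> None:
    """Serialize the token table (for provenance records)."""
    Path(path).write_text(json.dumps(TOKEN_TO_ID, indent=1, sort_keys=True))


@dataclass(frozen=True)
class TokenSequence:
    """Fixed-length token ids plus the attention mask (True on real tokens)."""

    ids: np.ndarray
    attention_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.ids.shape != self.attention_mask.shape:
            raise ValueError("ids and mask must have equal length")
        if not np.array_equal(self.attention_mask, self.ids != PAD):
            raise ValueError("mask must be False exactly at PAD positions")


def tokenize(peptide: str, pseudo: str | None = None, L: int | None = None) -> TokenSequence:
    """Encode ``[START, peptide…, STOP, pseudo…?, PAD…]`` at fixed length L.

    L defaults to 69 when a pseudo sequence is given, 35 otherwise, and must
    be consistent with the pseudo presence if supplied explicitly.
    """
    if len(peptide) > MAX_LEN_SEQ - 2:
        raise ValueError(f"peptide longer than {MAX_LEN_SEQ - 2}: {len(peptide)}")
    if pseudo is not None and len(pseudo) != PSEUDO_LEN:
        raise ValueError(f"pseudo sequence must be {PSEUDO_LEN} long, got {len(pseudo)}")
    expected = MAX_LEN_SEQ_MHC if pseudo is not None else MAX_LEN_SEQ
    if L is None:
        L = expected
    elif L != expected:
        raise ValueError(f"L={L} inconsistent with pseudo presence (expected {expected})")
    ids = np.zeros(L, dtype=np.int64)
    body = [START, *(TOKEN_TO_ID[c] for c in peptide), STOP]
    if pseudo is not None:
        body.extend(TOKEN_TO_ID[c] for c in pseudo)
    ids[: len(body)] = body
    return TokenSequence(ids=ids, attention_mask=ids != PAD)


def detokenize(tokens: TokenSequence) -> tuple[str, str | None]:
    """Invert :func:`tokenize`, returning ``(peptide, pseudo_or_None)``."""
    ids = tokens.ids[tokens.attention_mask]
    if len(ids) < 2 or ids[0] != START:
        raise ValueError("token sequence does not start with START")
    stop = int(np.flatnonzero(ids == STOP)[0])
    peptide = "".join(ID_TO_TOKEN[int(i)] for i in ids[1:stop])
    rest = ids[stop + 1 :]
    pseudo = "".join(ID_TO_TOKEN[int(i)] for i in rest) if len(rest) else None
    return peptide, pseudo


def positional_encoding(L: int, d: int = 128) -> np.ndarray:
    """The fixed sinusoidal position matrix of the original transformer.

    ``PE[pos, 2i] = sin(pos / 10000^(2i/d))``, ``PE[pos, 2i+1] = cos(·)``;
    deterministic and non-trainable.
    """
    if d % 2:
        raise ValueError("embedding dimension must be even")
    pos = np.arange(L, dtype=np.float64)[:, None]
    i2 = np.arange(0, d, 2, dtype=np.float64)[None, :]
    angles = pos / np.power(10000.0, i2 / d)
    pe = np.empty((L, d), dtype=np.float64)
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


def batch_encode(
    records: list[PeptideRecord],
    alleles: dict[str, AlleleRecord] | None = None,
    with_mhc: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode records into ``(ids N×L, mask N×L, targets N)``, order preserved.

    SEQ:MHC mode (``with_mhc=True``) requires every record's allele to resolve
    in ``alleles``.
    """
    L = MAX_LEN_SEQ_MHC if with_mhc else MAX_LEN_SEQ
    ids = np.zeros((len(records), L), dtype=np.int64)
    targets = np.empty(len(records), dtype=np.float32)
    for i, rec in enumerate(records):
        pseudo = None
        if with_mhc:
            if rec.allele_name is None or alleles is None or rec.allele_name not in alleles:
                raise KeyError(
                    f"record {i}: allele {rec.allele_name!r} unresolved in SEQ:MHC mode"
                )
            pseudo = alleles[rec.allele_name].pseudo_sequence
        ids[i] = tokenize(rec.sequence, pseudo, L).ids
        targets[i] = rec.target
    return ids, ids != PAD, targets
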