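"""Domain types and readers/writers for peptide datasets, proteomes and allele tables.

The on-disk dataset format is a delimited text table (tab-separated by default,
comma via ``dialect="csv"``) with a mandatory header naming the columns
``sequence, assay_type, target, allele, organism, provenance, source_protein,
fold``.  Binding-affinity (BA) rows carry the already-transformed target in
[0, 1]; raw IC50 values are converted upstream by
:func:`mhc2tx.decoys.transform_affinity`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("mhc2tx")

#: 20 canonical amino acids, alphabetical.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Full residue alphabet: canonical plus 'X' for unknown/noncanonical.
ALPHABET = set(CANONICAL_AA) | {"X"}
#: Rare noncanonical letters found in MS-derived tables, rewritten to 'X'.
NONCANONICAL_REMAP = set("BZUO")

#: Longest peptide the models accept.
MAX_PEPTIDE_LEN = 33
#: Fixed length of the MHCII binding-pocket pseudo sequence.
PSEUDO_LEN = 34

ASSAY_TYPES = ("EL", "BA")
ORGANISMS = ("human", "mouse")
PROVENANCES = ("experimental", "synthetic")
FOLDS = ("train", "validation", "test")

DATASET_COLUMNS = [
    "sequence",
    "assay_type",
    "target",
    "allele",
    "organism",
    "provenance",
    "source_protein",
    "fold",
]


class DatasetError(ValueError):
    """Raised when a table row or record violates a dataset invariant."""


def sanitize_sequence(seq: str) -> str:
    """Uppercase a residue string and rewrite rare noncanonical letters to 'X'.

    B/Z/U/O (ambiguous or translational oddities occasionally present in
    MS-derived tables) are remapped with a logged warning; any other letter
    outside the 21-letter alphabet is an error.
    """
    seq = str(seq).strip().upper()
    if any(c in NONCANONICAL_REMAP for c in seq):
        logger.warning("noncanonical residue(s) in %r rewritten to 'X'", seq)
        seq = "".join("X" if c in NONCANONICAL_REMAP else c for c in seq)
    bad = sorted(set(seq) - ALPHABET)
    if bad:
        raise DatasetError(f"illegal residue characters {bad} in sequence {seq!r}")
    return seq


@dataclass(frozen=True)
class PeptideRecord:
    """One labeled peptide observation (eluted-ligand binary or binding-affinity)."""

    sequence: str
    assay_type: str  # "EL" or "BA"
    target: float  # EL: 0/1; BA: transformed affinity in [0, 1]
    allele_name: str | None = None
    organism: str = "human"
    provenance: str = "experimental"
    source_protein_id: str | None = None
    fold: str | None = None  # train / validation / test, or None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", sanitize_sequence(self.sequence))
        if not 1 <= len(self.sequence) <= MAX_PEPTIDE_LEN:
            raise DatasetError(
                f"sequence length {len(self.sequence)} outside [1, {MAX_PEPTIDE_LEN}]"
            )
        if self.assay_type not in ASSAY_TYPES:
            raise DatasetError(f"unknown assay_type {self.assay_type!r}")
        t = float(self.target)
        object.__setattr__(self, "target", t)
        if self.assay_type == "EL" and t not in (0.0, 1.0):
            raise DatasetError(f"EL target must be 0 or 1, got {t}")
        if self.assay_type == "BA" and not 0.0 <= t <= 1.0:
            raise DatasetError(f"target out of range: BA target {t} not in [0, 1]")
        if self.organism not in ORGANISMS:
            raise DatasetError(f"unknown organism {self.organism!r}")
        if self.provenance not in PROVENANCES:
            raise DatasetError(f"unknown provenance {self.provenance!r}")
        if self.fold is not None and self.fold not in FOLDS:
            raise DatasetError(f"unknown fold {self.fold!r}")

    def with_fold(self, fold: str | None) -> "PeptideRecord":
        return replace(self, fold=fold)


@dataclass(frozen=True)
class AlleleRecord:
    """MHCII allele name plus its 34-residue binding-pocket pseudo sequence."""

    name: str
    pseudo_sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pseudo_sequence", sanitize_sequence(self.pseudo_sequence)
        )
        if len(self.pseudo_sequence) != PSEUDO_LEN:
            raise DatasetError(
                f"allele {self.name!r}: pseudo sequence length "
                f"{len(self.pseudo_sequence)} != {PSEUDO_LEN}"
            )


@dataclass
class Dataset:
    """Ordered peptide records plus the allele lookup they reference."""

    records: list[PeptideRecord] = field(default_factory=list)
    alleles: dict[str, AlleleRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for rec in self.records:
            if rec.allele_name is not None and rec.allele_name not in self.alleles:
                raise DatasetError(
                    f"record allele {rec.allele_name!r} not in allele table"
                )

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, fold: str) -> "Dataset":
        """Records assigned to one fold, sharing the allele table."""
        return Dataset(
            records=[r for r in self.records if r.fold == fold], alleles=self.alleles
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sequence": r.sequence,
                "assay_type": r.assay_type,
                "target": r.target,
                "allele": r.allele_name if r.allele_name is not None else "",
                "organism": r.organism,
                "provenance": r.provenance,
                "source_protein": (
                    r.source_protein_id if r.source_protein_id is not None else ""
                ),
                "fold": r.fold if r.fold is not None else "",
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=DATASET_COLUMNS)


def _record_from_row(row: pd.Series) -> PeptideRecord:
    def _opt(key: str) -> str | None:
        v = row.get(key, "")
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return None
        v = str(v).strip()
        return v or None

    assay = str(row["assay_type"]).strip().upper()
    if assay not in ASSAY_TYPES:
        raise DatasetError(f"unknown assay_type {assay!r}")
    return PeptideRecord(
        sequence=str(row["sequence"]),
        assay_type=assay,
        target=float(row["target"]),
        allele_name=_opt("allele"),
        organism=str(row.get("organism", "human")).strip() or "human",
        provenance=str(row.get("provenance", "experimental")).strip() or "experimental",
        source_protein_id=_opt("source_protein"),
        fold=_opt("fold"),
    )


def read_dataset(
    path: str | Path,
    dialect: str = "tsv",
    alleles: dict[str, AlleleRecord] | None = None,
    permissive: bool = False,
) -> Dataset:
    """Read a peptide dataset table.

    Parameters
    ----------
    path:
        Delimited text file with a header naming at least
        ``sequence, assay_type, target``.
    dialect:
        ``"tsv"`` (default) or ``"csv"``.
    alleles:
        Optional allele lookup to attach; when omitted, alleles named by
        records are looked up nowhere and the Dataset is built without an
        allele table (callers needing pseudo sequences attach one).
    permissive:
        When true, invalid rows are counted and logged instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = {"tsv": "\t", "csv": ","}[dialect]
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = {"sequence", "assay_type", "target"} - set(frame.columns)
    if missing:
        raise DatasetError(f"dataset table missing columns {sorted(missing)}")
    records: list[PeptideRecord] = []
    n_bad = 0
    for i, row in frame.iterrows():
        try:
            records.append(_record_from_row(row))
        except (DatasetError, ValueError) as exc:
            if not permissive:
                raise DatasetError(f"row {i}: {exc}") from exc
            n_bad += 1
            logger.warning("skipping invalid row %d: %s", i, exc)
    if n_bad:
        logger.warning("skipped %d invalid rows while reading %s", n_bad, path)
    if alleles is None:
        # no lookup supplied: referenced alleles get placeholder (all-X) pseudo
        # sequences; callers needing real ones attach a table from read_pseudo_table
        alleles = {
            name: AlleleRecord(name, "X" * PSEUDO_LEN)
            for name in sorted({r.allele_name for r in records if r.allele_name})
        }
    return Dataset(records=records, alleles=dict(alleles))


def write_dataset(dataset: Dataset, path: str | Path, dialect: str = "tsv") -> None:
    """Write a Dataset so that :func:`read_dataset` restores it field-for-field."""
    sep = {"tsv": "\t", "csv": ","}[dialect]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = dataset.to_frame()
    # targets written with full precision so BA labels round-trip exactly
    frame["target"] = [repr(float(t)) for t in frame["target"]]
    frame.to_csv(path, sep=sep, index=False)


#: Published corpus statistics for the full-scale training data (IEDB-sourced
#: human+mouse records and the NOD mouse I-Ag7 eluted-ligand set).
REFERENCE_COUNTS = {
    "iedb_peptides": 447_232,
    "iedb_alleles": 85,
    "nod_el_records": 5_394,
    "nod_fold_sizes": (4_669, 467, 258),  # train / validation / test
    "max_peptide_length": 33,
}


def verify_reference_counts(iedb: Dataset, nod: Dataset) -> dict[str, bool]:
    """Compare locally loaded full-scale corpora against the published counts.

    Intended for the optional full-data check when the archived corpus has
    been downloaded; returns one boolean per statistic.
    """
    nod_folds = tuple(
        sum(r.fold == f for r in nod.records) for f in ("train", "validation", "test")
    )
    max_len = max(
        (len(r.sequence) for ds in (iedb, nod) for r in ds.records), default=0
    )
    return {
        "iedb_peptides": len(iedb.records) == REFERENCE_COUNTS["iedb_peptides"],
        "iedb_alleles": len(
            {r.allele_name for r in iedb.records if r.allele_name}
        ) == REFERENCE_COUNTS["iedb_alleles"],
        "nod_el_records": len(nod.records) == REFERENCE_COUNTS["nod_el_records"],
        "nod_fold_sizes": nod_folds == REFERENCE_COUNTS["nod_fold_sizes"],
        "max_peptide_length": max_len == REFERENCE_COUNTS["max_peptide_length"],
    }


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA proteome into ``{protein_id: sequence}``.

    Ids are truncated at the first whitespace token (Biopython's default);
    sequences are uppercased and a terminal ``*`` (stop) is stripped.
    Duplicate ids and empty files are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    proteome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in proteome:
            raise DatasetError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        proteome[rec.id] = seq
    if not proteome:
        raise DatasetError(f"no FASTA records in {path}")
    return proteome


def read_pseudo_table(path: str | Path, dialect: str = "tsv") -> dict[str, AlleleRecord]:
    """Read a two-column allele → 34-mer pseudo-sequence table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = {"tsv": "\t", "csv": ","}[dialect]
    frame = pd.read_csv(
        path, sep=sep, dtype=str, header=None, comment="#", keep_default_na=False
    )
    # accept an optional header line
    first = str(frame.iloc[0, 0]).lower() if len(frame) else ""
    if first in {"allele", "name", "allele_name"}:
        frame = frame.iloc[1:]
    table: dict[str, AlleleRecord] = {}
    for _, row in frame.iterrows():
        name = str(row.iloc[0]).strip()
        pseudo = str(row.iloc[1]).strip()
        if len(pseudo) != PSEUDO_LEN:
            raise DatasetError(
                f"allele {name!r}: pseudo sequence length {len(pseudo)} != {PSEUDO_LEN}"
            )
        table[name] = AlleleRecord(name=name, pseudo_sequence=pseudo)
    return table


def write_pseudo_table(
    alleles: Iterable[AlleleRecord] | dict[str, AlleleRecord], path: str | Path
) -> None:
    if isinstance(alleles, dict):
        alleles = alleles.values()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for a in alleles:
            fh.write(f"{a.name}\t{a.pseudo_sequence}\n")
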