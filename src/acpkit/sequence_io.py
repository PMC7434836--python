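"""Reading, validating and labelling peptide sequences.

Peptides are short sequences (anticancer peptides are typically 5-30
residues) over the 20 standard amino acids.  This module is the single
entry point for getting sequences into the toolkit: FASTA in, validated
:class:`Peptide` records out, with binary anticancer / non-anticancer
labels attached either from a positives/negatives file pair or
programmatically.

Validation is strict by default: any residue outside the 20-letter
alphabet raises, because every downstream descriptor normalises by the
full residue count and silently dropped residues would corrupt the
denominators.  Records (never single residues) can be dropped with
``drop_invalid=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, in alphabetical one-letter order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)


class AcpkitError(Exception):
    """Base class for all toolkit errors."""


class FastaParseError(AcpkitError):
    """The input could not be parsed as FASTA."""


class SequenceValidationError(AcpkitError):
    """A sequence contains residues outside the 20-letter alphabet."""


@dataclass(frozen=True)
class Peptide:
    """A validated peptide: an identifier plus an amino-acid sequence.

    Parameters
    ----------
    id : str
        Non-empty record identifier (first whitespace-delimited token of
        the FASTA header).
    sequence : str
        Uppercase residues over ``ACDEFGHIKLMNPQRSTVWY``; length >= 1.
    description : str
        Remainder of the FASTA header after the id, kept as metadata.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceValidationError("peptide id must be non-empty")
        if len(self.sequence) < 1:
            raise SequenceValidationError(
                f"peptide {self.id!r}: sequence must have length >= 1"
            )
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise SequenceValidationError(
                f"peptide {self.id!r}: residue(s) {sorted(bad)} outside the "
                f"20-letter amino-acid alphabet {ALPHABET}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Peptides plus binary labels (1 = anticancer, 0 = non-anticancer)."""

    peptides: list[Peptide]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.peptides):
            raise ValueError(
                f"{len(self.peptides)} peptides but {len(self.labels)} labels"
            )
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]


def read_fasta(
    path: str | Path,
    uppercase: bool = True,
    drop_invalid: bool = False,
) -> list[Peptide]:
    """Read and validate peptides from a FASTA file.

    Returns one :class:`Peptide` per record in file order.  Wrapped and
    unwrapped sequence lines are both accepted.  ``uppercase`` folds
    lowercase residues before validation.  With ``drop_invalid``, whole
    records failing validation are skipped with a warning instead of
    raising; residues are never dropped individually.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # reject text before the first header: Biopython silently skips it
    with open(path) as handle:
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: not FASTA — first non-blank line does not "
                        f"start with '>': {line.strip()[:40]!r}"
                    )
                break
    peptides: list[Peptide] = []
    seen: set[str] = set()
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # malformed record structure
        raise FastaParseError(f"{path}: {exc}") from exc
    for rec in records:
        seq = str(rec.seq)
        if uppercase:
            seq = seq.upper()
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        try:
            pep = Peptide(id=rec.id, sequence=seq, description=desc)
        except SequenceValidationError:
            if drop_invalid:
                warnings.warn(f"dropping invalid record {rec.id!r} in {path}")
                continue
            raise
        if pep.id in seen:
            raise SequenceValidationError(
                f"duplicate peptide id {pep.id!r} in {path}"
            )
        seen.add(pep.id)
        peptides.append(pep)
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: str | Path) -> None:
    """Write peptides to FASTA (inverse of :func:`read_fasta`)."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description=p.description)
        for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


def load_labeled(
    pos_path: str | Path,
    neg_path: str | Path,
    uppercase: bool = True,
    drop_invalid: bool = False,
) -> LabeledDataset:
    """Load a labelled dataset from a positives / negatives FASTA pair.

    Positives (anticancer peptides) get label 1, negatives label 0.
    Overlapping ids between the two files are an error; an empty class
    raises a warning but proceeds (some workflows only score one class).
    """
    pos = read_fasta(pos_path, uppercase=uppercase, drop_invalid=drop_invalid)
    neg = read_fasta(neg_path, uppercase=uppercase, drop_invalid=drop_invalid)
    overlap = {p.id for p in pos} & {p.id for p in neg}
    if overlap:
        raise SequenceValidationError(
            f"ids present in both classes: {sorted(overlap)[:5]}"
        )
    if not pos:
        warnings.warn(f"positive class is empty ({pos_path})")
    if not neg:
        warnings.warn(f"negative class is empty ({neg_path})")
    peptides = pos + neg
    labels = np.array([1] * len(pos) + [0] * len(neg), dtype=int)
    return LabeledDataset(peptides=peptides, labels=labels)


def write_labels(dataset: LabeledDataset, path: str | Path) -> None:
    """Write an id → label table (TSV, two columns)."""
    pd.DataFrame({"id": dataset.ids, "label": dataset.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path, ids: Sequence[str] | None = None) -> np.ndarray:
    """Read a label table written by :func:`write_labels`.

    If ``ids`` is given, labels are returned in that order and missing
    or extra ids are an error.
    """
    table = pd.read_csv(path, sep="\t")
    if not {"id", "label"} <= set(table.columns):
        raise FastaParseError(f"{path}: expected columns 'id' and 'label'")
    table["id"] = table["id"].astype(str)
    if ids is None:
        return table["label"].to_numpy(dtype=int)
    lookup = dict(zip(table["id"], table["label"]))
    missing = [i for i in ids if i not in lookup]
    if missing:
        raise SequenceValidationError(f"labels missing for ids {missing[:5]}")
    return np.array([lookup[i] for i in ids], dtype=int)
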