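"""Peptide sequence I/O and validation.

Peptides are short stretches of the 20 standard amino acids, optionally
carrying a binary class label: ``1`` for a linear B-cell epitope (BCE),
``0`` for an experimentally negative peptide (non-BCE).  Curated datasets
additionally restrict peptide length to 5-25 residues; shorter and longer
peptides (rare in the source immunology databases) behave as outliers
during model development and are filtered out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 standard amino acids in fixed alphabetical order."""

AA_SET = frozenset(AMINO_ACIDS)

#: Default curation length bounds (inclusive).
MIN_CURATED_LENGTH = 5
MAX_CURATED_LENGTH = 25

POSITIVE_LABEL = 1
NEGATIVE_LABEL = 0


class SequenceValidationError(ValueError):
    """A sequence contains characters outside the 20-letter alphabet."""


class FastaParseError(ValueError):
    """A file is not valid FASTA."""


@dataclass(frozen=True)
class Peptide:
    """A validated amino-acid sequence with an optional binary label.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header word).
    sequence : str
        Residues over ``ACDEFGHIKLMNPQRSTVWY``; lowercase input is
        uppercased on construction.
    label : int, optional
        ``1`` for BCE (positive), ``0`` for non-BCE (negative),
        ``None`` when unlabeled.
    """

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = sorted(set(seq) - AA_SET)
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: non-standard amino acid character(s) "
                f"{', '.join(repr(c) for c in bad)}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0, 1 or None")

    def __len__(self) -> int:
        return len(self.sequence)

    def with_label(self, label: Optional[int]) -> "Peptide":
        return Peptide(self.id, self.sequence, label)


def _dedupe_ids(peptides: list[Peptide]) -> list[Peptide]:
    """Give duplicate ids unique internal keys ``id#k`` (warning per clash)."""
    seen: dict[str, int] = {}
    out = []
    for p in peptides:
        if p.id in seen:
            seen[p.id] += 1
            new_id = f"{p.id}#{seen[p.id]}"
            warnings.warn(
                f"duplicate id {p.id!r} renamed to {new_id!r}", stacklevel=3
            )
            out.append(Peptide(new_id, p.sequence, p.label))
        else:
            seen[p.id] = 0
            out.append(p)
    return out


def read_fasta(
    path: str | Path,
    label: Optional[int] = None,
    permissive: bool = False,
) -> list[Peptide]:
    """Read peptides from a FASTA file.

    Parameters
    ----------
    path : path-like
        FASTA file; multi-line sequences are allowed.
    label : int, optional
        Label assigned to every record (for paired positive/negative files).
    permissive : bool
        When true, records with non-standard characters are dropped with a
        warning instead of raising.

    Returns
    -------
    list of Peptide, in file order.
    """
    path = Path(path)
    with open(path) as handle:
        first = ""
        for line in handle:
            if line.strip():
                first = line
                break
        if first and not first.startswith(">"):
            raise FastaParseError(
                f"{path}: not FASTA — first non-empty line does not start "
                f"with '>': {first.strip()[:40]!r}"
            )
    peptides: list[Peptide] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            peptides.append(Peptide(rec.id, str(rec.seq), label))
        except SequenceValidationError:
            if permissive:
                warnings.warn(f"dropping invalid record {rec.id!r} in {path}")
            else:
                raise
    return _dedupe_ids(peptides)


def write_fasta(peptides: Iterable[Peptide], path: str | Path) -> None:
    """Write peptides as FASTA (one record per peptide, ids as headers)."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def read_table(path: str | Path) -> list[Peptide]:
    """Read a TSV with columns ``id``, ``sequence`` and optional ``label``."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sequence": str})
    missing = {"id", "sequence"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    has_label = "label" in df.columns
    peptides = [
        Peptide(
            row.id,
            row.sequence,
            int(row.label) if has_label and pd.notna(row.label) else None,
        )
        for row in df.itertuples(index=False)
    ]
    return _dedupe_ids(peptides)


def write_table(peptides: Iterable[Peptide], path: str | Path) -> None:
    """Write peptides as a TSV with columns id, sequence, label."""
    df = pd.DataFrame(
        [(p.id, p.sequence, p.label) for p in peptides],
        columns=["id", "sequence", "label"],
    )
    df.to_csv(path, sep="\t", index=False)


def length_filter(
    peptides: Sequence[Peptide],
    min_len: int = MIN_CURATED_LENGTH,
    max_len: int = MAX_CURATED_LENGTH,
) -> tuple[list[Peptide], list[Peptide]]:
    """Partition peptides into (kept, dropped) by inclusive length bounds.

    Peptides shorter than ``min_len`` or longer than ``max_len`` residues
    are dropped; order is preserved in both outputs.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    kept = [p for p in peptides if min_len <= len(p) <= max_len]
    dropped = [p for p in peptides if not (min_len <= len(p) <= max_len)]
    return kept, dropped
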