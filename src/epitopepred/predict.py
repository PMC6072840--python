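"""Prediction modes: classify peptides, or mine candidate epitopes from
protein sequences with sliding windows.

Peptide mode scores each input peptide with a trained (ensemble)
classifier and calls it an epitope when the probability is at or above
the model's decision cutoff.  Scanning mode slides windows of the
typical epitope length range (12-25 residues by default) along a
protein, scores every window like a peptide, and reports the windows
that clear the cutoff; an optional greedy merge keeps only the
highest-probability hit among mutually overlapping windows.  All
coordinates are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import AA_SET, MAX_CURATED_LENGTH, MIN_CURATED_LENGTH, Peptide

POSITIVE_CALL = "BCE"
NEGATIVE_CALL = "non-BCE"

#: Default scan window lengths: the typical linear-epitope length range.
DEFAULT_WINDOW_LENGTHS: tuple[int, ...] = tuple(range(12, 26))


@dataclass(frozen=True)
class ScanHit:
    """One scoring window that cleared the decision cutoff."""

    protein_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    sequence: str
    probability: float
    call: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError("invalid coordinates")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinates do not match window length")


def classify_peptides(peptides: Sequence[Peptide], model) -> pd.DataFrame:
    """Score peptides and call BCE / non-BCE at the model cutoff.

    Returns a DataFrame with columns id, probability, call in input
    order.  Peptides a member encoder cannot handle (e.g. length 1 for
    dipeptide features) get ``call="error"`` with a NaN probability and
    the run continues.  Lengths outside the curated training range
    (5-25) are scored but trigger a warning.
    """
    rows = []
    outside = [
        p.id
        for p in peptides
        if not (MIN_CURATED_LENGTH <= len(p) <= MAX_CURATED_LENGTH)
    ]
    if outside:
        warnings.warn(
            f"{len(outside)} peptide(s) outside the trained length range "
            f"[{MIN_CURATED_LENGTH}, {MAX_CURATED_LENGTH}]: {outside[:5]}"
        )
    for p in peptides:
        try:
            prob = float(model.predict_probabilities([p])[0])
        except Exception as exc:  # per-record failure must not kill the run
            warnings.warn(f"could not score {p.id!r}: {exc}")
            rows.append((p.id, np.nan, "error"))
            continue
        call = POSITIVE_CALL if prob >= model.cutoff else NEGATIVE_CALL
        rows.append((p.id, prob, call))
    return pd.DataFrame(rows, columns=["id", "probability", "call"])


def _merge_overlapping(hits: list[ScanHit]) -> list[ScanHit]:
    """Greedy: walk hits in descending probability, keep a hit only if it
    overlaps no already-kept hit."""
    kept: list[ScanHit] = []
    for h in hits:
        if all(
            h.end < k.start or h.start > k.end for k in kept
        ):
            kept.append(h)
    return kept


def scan_protein(
    protein_id: str,
    sequence: str,
    model,
    window_lengths: Iterable[int] = DEFAULT_WINDOW_LENGTHS,
    stride: int = 1,
    merge_overlaps: bool = False,
) -> list[ScanHit]:
    """Score sliding windows of a protein and return above-cutoff hits.

    Every window of each requested length, advanced by ``stride``, is
    scored exactly as a peptide.  Windows containing residues outside
    the 20-letter alphabet (e.g. ``X``) are skipped and counted in a
    warning.  Hits are sorted by probability descending (then by start
    coordinate for ties); with ``merge_overlaps`` the greedy
    highest-probability representative of each overlapping cluster is
    kept.
    """
    if stride < 1:
        raise ValueError("stride must be positive")
    sequence = sequence.upper()
    lengths = sorted(set(int(w) for w in window_lengths))
    if not lengths or lengths[0] < 1:
        raise ValueError("window_lengths must be positive")
    L = len(sequence)
    if L < lengths[0]:
        warnings.warn(
            f"{protein_id!r}: protein length {L} is shorter than every "
            "requested window; no windows scored"
        )
        return []
    windows: list[tuple[int, int, str]] = []
    n_skipped = 0
    for w in lengths:
        for start0 in range(0, L - w + 1, stride):
            frag = sequence[start0 : start0 + w]
            if set(frag) - AA_SET:
                n_skipped += 1
                continue
            windows.append((start0 + 1, start0 + w, frag))
    if n_skipped:
        warnings.warn(
            f"{protein_id!r}: skipped {n_skipped} window(s) containing "
            "non-standard residues"
        )
    if not windows:
        return []
    peptides = [
        Peptide(f"{protein_id}:{s}-{e}", frag) for s, e, frag in windows
    ]
    probs = model.predict_probabilities(peptides)
    hits = [
        ScanHit(protein_id, s, e, frag, float(pr), POSITIVE_CALL)
        for (s, e, frag), pr in zip(windows, probs)
        if pr >= model.cutoff
    ]
    hits.sort(key=lambda h: (-h.probability, h.start, h.end))
    if merge_overlaps:
        hits = _merge_overlapping(hits)
    return hits


def hits_to_frame(hits: Sequence[ScanHit]) -> pd.DataFrame:
    """Tabulate scan hits (1-based inclusive coordinates)."""
    return pd.DataFrame(
        [
            (h.protein_id, h.start, h.end, h.sequence, h.probability, h.call)
            for h in hits
        ],
        columns=["protein_id", "start", "end", "sequence", "probability", "call"],
    )
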