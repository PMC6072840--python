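"""Dataset curation: redundancy reduction, benchmark/independent split,
and a synthetic peptide generator.

Redundancy reduction removes peptides whose pairwise sequence identity to
an already-retained peptide exceeds a threshold (default 70%), so that
training and evaluation sets are non-redundant.  Identity is computed by
an ungapped sliding of the shorter sequence along the longer one, taking
the best offset and dividing matches by the shorter length — a
transparent greedy surrogate for CD-HIT-style clustering that avoids any
binary dependency; it is an approximation, not a re-implementation, of
that tool.

The labeling of peptides as epitope/non-epitope (two or more concordant
B-cell assays, per the source database's assay annotations) is a
data-provenance contract of the input files, not something computable
here; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .seqio import AMINO_ACIDS, Peptide

#: Residues enriched in linear B-cell epitopes (positives).
POSITIVE_BIAS_RESIDUES = "NDPY"
#: Residues enriched in experimentally negative peptides.
NEGATIVE_BIAS_RESIDUES = "AELVM"


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped best-offset identity between two sequences.

    The shorter sequence is slid along the longer at every full-overlap
    offset; identity is the maximum number of matching positions divided
    by the shorter length.  Symmetric in its arguments.
    """
    if len(a) > len(b):
        a, b = b, a
    short = np.frombuffer(a.encode(), dtype="S1")
    long_ = np.frombuffer(b.encode(), dtype="S1")
    n = len(short)
    best = 0
    for off in range(len(long_) - n + 1):
        matches = int(np.count_nonzero(short == long_[off : off + n]))
        if matches > best:
            best = matches
            if best == n:
                break
    return best / n


def reduce_redundancy(
    peptides: list[Peptide], identity_threshold: float = 0.70
) -> list[Peptide]:
    """Greedy redundancy reduction at a pairwise identity threshold.

    Peptides are sorted by length descending (stable); each peptide is
    assigned to the first retained representative with identity strictly
    greater than ``identity_threshold``, otherwise it becomes a new
    representative.  Only representatives are returned.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}"
        )
    ordered = sorted(peptides, key=len, reverse=True)
    representatives: list[Peptide] = []
    for p in ordered:
        for rep in representatives:
            if pairwise_identity(p.sequence, rep.sequence) > identity_threshold:
                break
        else:
            representatives.append(p)
    return representatives


def stratified_split(
    peptides: list[Peptide],
    benchmark_fraction: float = 0.80,
    seed: int = 0,
) -> tuple[list[Peptide], list[Peptide]]:
    """Random per-class split into (benchmark, independent) sets.

    Within each label class, ``round(class_size * benchmark_fraction)``
    peptides are drawn (without replacement) for the benchmark set; the
    rest form the independent set.  Reproducible given ``seed``.
    """
    if not (0.0 <= benchmark_fraction <= 1.0):
        raise ValueError("benchmark_fraction must be in [0, 1]")
    unlabeled = [p.id for p in peptides if p.label is None]
    if unlabeled:
        raise ValueError(f"unlabeled peptide(s): {unlabeled[:5]}")
    rng = np.random.default_rng(seed)
    benchmark: list[Peptide] = []
    independent: list[Peptide] = []
    for label in sorted({p.label for p in peptides}):
        members = [p for p in peptides if p.label == label]
        n_bench = round(len(members) * benchmark_fraction)
        order = rng.permutation(len(members))
        chosen = set(order[:n_bench].tolist())
        benchmark.extend(p for i, p in enumerate(members) if i in chosen)
        independent.extend(p for i, p in enumerate(members) if i not in chosen)
    return benchmark, independent


def _class_distribution(bias_residues: str, bias_strength: float) -> np.ndarray:
    """Residue sampling weights: biased residues up-weighted by (1 + b)."""
    w = np.ones(len(AMINO_ACIDS))
    for r in bias_residues:
        w[AMINO_ACIDS.index(r)] *= 1.0 + bias_strength
    return w / w.sum()


def generate_synthetic_dataset(
    n_pos: int,
    n_neg: int,
    length_range: tuple[int, int] = (5, 25),
    bias_strength: float = 3.0,
    seed: int = 0,
) -> list[Peptide]:
    """Generate labeled peptides with class-biased residue composition.

    Emulates the compositional contrast seen between real linear B-cell
    epitopes and negatives: positives are enriched in N, D, P, Y and
    negatives in A, E, L, V, M, each up-weighted by ``1 + bias_strength``
    relative to a uniform background.  Lengths are uniform over
    ``length_range`` (inclusive).  ``bias_strength = 0`` gives both
    classes the same (uniform) distribution — a null dataset on which no
    classifier can beat chance in expectation.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    lo, hi = length_range
    if lo < 1 or lo > hi:
        raise ValueError(f"invalid length_range {length_range}")
    if bias_strength < 0:
        raise ValueError("bias_strength must be non-negative")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ACIDS))
    peptides: list[Peptide] = []
    for label, n, biased in (
        (1, n_pos, POSITIVE_BIAS_RESIDUES),
        (0, n_neg, NEGATIVE_BIAS_RESIDUES),
    ):
        probs = _class_distribution(biased, bias_strength)
        lengths = rng.integers(lo, hi + 1, size=n)
        prefix = "pos" if label == 1 else "neg"
        for i, length in enumerate(lengths):
            seq = "".join(rng.choice(alphabet, size=length, p=probs))
            peptides.append(Peptide(f"{prefix}{i + 1}", seq, label))
    return peptides


def generate_synthetic_protein(length: int, seed: int = 0) -> str:
    """A uniform-random protein sequence, for scanning-mode tests."""
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(np.array(list(AMINO_ACIDS)), size=length))
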