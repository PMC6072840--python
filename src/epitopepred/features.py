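"""Fixed-length descriptor encodings for variable-length peptides.

Six descriptor families turn a peptide of length N (5-25 residues in
curated data) into a fixed-width numeric vector:

========  =====  =========================================================
family    width  description
========  =====  =========================================================
AAC          20  amino-acid composition, percentages (sums to 100)
DPC         400  dipeptide composition; overlapping adjacent pairs counted
                 and divided by peptide length N, x100 (sums to 100(N-1)/N)
CTD         147  composition-transition-distribution: per physicochemical
                 property (7 of them) 3 group percentages, 3 group-pair
                 transition rates, and 15 positional-distribution values
AAI       20/160 AAindex encoding from eight cluster-central indices;
                 full mode = 8x20 composition-weighted index values,
                 averaged mode (default) = their mean over the 8 indices
PCP           9  global physicochemical summaries (class fractions,
                 turn-forming fraction, absolute charge per residue,
                 molecular weight, aliphatic index)
BPF(k)     20*k  one-hot binary profile of the first (N-terminal) or last
                 (C-terminal) k residues; short peptides zero-pad at the
                 inner end
========  =====  =========================================================

Hybrid feature sets H1-H17 concatenate families in a fixed enumerated
order (e.g. H7 = AAC + PCP, width 29; H15 = DPC + PCP, width 409), and
the six binary-profile sets are BPFN5, BPFC5, BPFN5C5, BPFN10, BPFC10
and BPFN10C10.  Every encoder is a pure per-peptide function: encoding a
list is exactly the row-stack of per-peptide encodings, with no
cross-peptide normalization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight as _bio_molecular_weight

from .seqio import AMINO_ACIDS, Peptide

# ---------------------------------------------------------------------------
# bundled configuration data

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_DIPEPTIDES = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]


def _load_data(name: str) -> dict:
    with resources.files("epitopepred.data").joinpath(name).open() as fh:
        return json.load(fh)


_aaindex_raw = _load_data("aaindex8.json")["indices"]
AAINDEX_ACCESSIONS: tuple[str, ...] = tuple(_aaindex_raw)
#: (8, 20) array of index values, rows = accessions, cols = alphabet order.
AAINDEX_TABLE = np.array(
    [[_aaindex_raw[acc][a] for a in AMINO_ACIDS] for acc in AAINDEX_ACCESSIONS]
)

_ctd_raw = _load_data("ctd_groups.json")["properties"]
#: list of (property_name, [(group_label, frozenset(residues)) x3])
CTD_PROPERTIES: list[tuple[str, list[tuple[str, frozenset]]]] = [
    (p["name"], [(label, frozenset(res)) for label, res in p["groups"]])
    for p in _ctd_raw
]
for _name, _groups in CTD_PROPERTIES:
    _all = set().union(*(g for _, g in _groups))
    assert _all == set(AMINO_ACIDS), f"CTD property {_name} does not cover alphabet"
    assert sum(len(g) for _, g in _groups) == 20, f"CTD property {_name} overlaps"

# PCP residue classes
HYDROPHOBIC = frozenset("FIWLVMYCA")
HYDROPHILIC = frozenset("SQTRKNDE")
NEUTRAL = frozenset("HGP")
POSITIVE = frozenset("KHR")
NEGATIVE = frozenset("DE")
TURN_FORMING = frozenset("NGPS")

PCP_COLUMNS = [
    "PCP_frac_hydrophobic",
    "PCP_frac_hydrophilic",
    "PCP_frac_neutral",
    "PCP_frac_positive",
    "PCP_frac_negative",
    "PCP_frac_turn",
    "PCP_abs_charge",
    "PCP_mol_weight",
    "PCP_aliphatic_index",
]

# ---------------------------------------------------------------------------
# per-family encoders


def encode_aac(p: Peptide) -> np.ndarray:
    """Amino-acid composition: 100 * count(a) / N in alphabet order."""
    n = len(p)
    if n < 1:
        raise ValueError("empty peptide")
    v = np.zeros(20)
    for ch in p.sequence:
        v[_AA_INDEX[ch]] += 1
    return 100.0 * v / n


def encode_dpc(p: Peptide, denominator: str = "N") -> np.ndarray:
    """Dipeptide composition over the 400 ordered pairs, x100.

    Overlapping adjacent pairs are counted.  The default denominator is
    the peptide length N, so vectors sum to 100(N-1)/N; pass
    ``denominator="N-1"`` for vectors that sum to exactly 100.
    """
    n = len(p)
    if n < 2:
        raise ValueError(f"peptide {p.id!r}: DPC needs length >= 2")
    if denominator not in ("N", "N-1"):
        raise ValueError("denominator must be 'N' or 'N-1'")
    v = np.zeros(400)
    s = p.sequence
    for i in range(n - 1):
        v[_AA_INDEX[s[i]] * 20 + _AA_INDEX[s[i + 1]]] += 1
    return 100.0 * v / (n if denominator == "N" else n - 1)


def _ctd_distribution(positions: list[int], n: int) -> list[float]:
    """Positions (1-based) of first / 25th / 50th / 75th percentile / last
    occurrence, as percentages of sequence length; zeros when absent."""
    c = len(positions)
    if c == 0:
        return [0.0] * 5
    picks = [1, math.ceil(0.25 * c), math.ceil(0.50 * c), math.ceil(0.75 * c), c]
    return [100.0 * positions[max(k, 1) - 1] / n for k in picks]


def encode_ctd(p: Peptide) -> np.ndarray:
    """Composition-transition-distribution descriptor (147 values)."""
    n = len(p)
    if n < 2:
        raise ValueError(f"peptide {p.id!r}: CTD transitions need length >= 2")
    s = p.sequence
    out: list[float] = []
    for _prop, groups in CTD_PROPERTIES:
        membership = [
            next(gi for gi, (_, res) in enumerate(groups) if ch in res) for ch in s
        ]
        counts = [membership.count(g) for g in range(3)]
        # C: group percentages
        out.extend(100.0 * c / n for c in counts)
        # T: unordered group-pair crossings among adjacent residues
        trans = {(0, 1): 0, (0, 2): 0, (1, 2): 0}
        for a, b in zip(membership, membership[1:]):
            if a != b:
                trans[(min(a, b), max(a, b))] += 1
        out.extend(100.0 * trans[k] / (n - 1) for k in ((0, 1), (0, 2), (1, 2)))
        # D: positional spread per group
        for g in range(3):
            positions = [i + 1 for i, m in enumerate(membership) if m == g]
            out.extend(_ctd_distribution(positions, n))
    return np.asarray(out)


def encode_aai(p: Peptide, averaged: bool = True) -> np.ndarray:
    """AAindex encoding from the eight bundled high-quality indices.

    Full mode (``averaged=False``): for each index and residue type, the
    index value weighted by that residue's composition fraction — 160
    values in index-major order.  Averaged mode (default, used in the
    models): the mean of the eight per-index blocks, a 20-vector.
    """
    frac = encode_aac(p) / 100.0
    full = AAINDEX_TABLE * frac[np.newaxis, :]
    if averaged:
        return full.mean(axis=0)
    return full.ravel()


def encode_pcp(p: Peptide) -> np.ndarray:
    """Nine global physicochemical properties (fixed order, see PCP_COLUMNS)."""
    n = len(p)
    if n < 1:
        raise ValueError("empty peptide")
    s = p.sequence
    count = {a: s.count(a) for a in AMINO_ACIDS}
    frac = lambda group: sum(count[a] for a in group) / n  # noqa: E731
    abs_charge = abs(
        (count["R"] + count["K"] - count["D"] - count["E"]) / n - 0.03
    )
    mw = _bio_molecular_weight(s, seq_type="protein")
    aliphatic = (
        count["A"] + 2.9 * count["V"] + 3.9 * count["I"] + 3.9 * count["L"]
    ) / n
    return np.array(
        [
            frac(HYDROPHOBIC),
            frac(HYDROPHILIC),
            frac(NEUTRAL),
            frac(POSITIVE),
            frac(NEGATIVE),
            frac(TURN_FORMING),
            abs_charge,
            mw,
            aliphatic,
        ]
    )


def encode_bpf(p: Peptide, terminus: str, k: int) -> np.ndarray:
    """Binary profile: one-hot blocks for the first/last k residues.

    ``terminus="N"`` takes residues 1..k; ``terminus="C"`` takes the last
    k residues in sequence order.  Peptides shorter than k leave the
    missing positions (at the inner end of the window) as all-zero
    blocks.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if terminus not in ("N", "C"):
        raise ValueError("terminus must be 'N' or 'C'")
    n = len(p)
    v = np.zeros(20 * k)
    if terminus == "N":
        for j in range(min(k, n)):
            v[20 * j + _AA_INDEX[p.sequence[j]]] = 1.0
    else:
        # last k residues occupy the rightmost blocks in sequence order
        m = min(k, n)
        tail = p.sequence[n - m :]
        for j, ch in enumerate(tail, start=k - m):
            v[20 * j + _AA_INDEX[ch]] = 1.0
    return v


# ---------------------------------------------------------------------------
# specs and registry


@dataclass(frozen=True)
class FeatureSpec:
    """A named descriptor scheme with a fixed width and column order."""

    name: str
    components: tuple[str, ...]
    width: int
    column_names: tuple[str, ...]


@dataclass(frozen=True)
class FeatureMatrix:
    """Peptide ids (rows) x descriptor columns, as a dense float matrix."""

    ids: tuple[str, ...]
    spec: FeatureSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.ids), self.spec.width):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.ids)} peptides x width {self.spec.width}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.ids), columns=list(self.spec.column_names)
        )


def _ctd_columns() -> list[str]:
    cols = []
    for prop, groups in CTD_PROPERTIES:
        labels = [label for label, _ in groups]
        cols.extend(f"CTD_{prop}_C_{g}" for g in labels)
        cols.extend(
            f"CTD_{prop}_T_{labels[i]}~{labels[j]}"
            for i, j in ((0, 1), (0, 2), (1, 2))
        )
        for g in labels:
            cols.extend(
                f"CTD_{prop}_D_{g}_{q}" for q in ("first", "p25", "p50", "p75", "last")
            )
    return cols


def _bpf_columns(terminus: str, k: int) -> list[str]:
    return [
        f"BPF{terminus}{k}_p{j + 1}_{a}" for j in range(k) for a in AMINO_ACIDS
    ]


#: component name -> (width, column names, encoder)
_COMPONENTS: dict[str, tuple[int, list[str], Callable[[Peptide], np.ndarray]]] = {
    "AAC": (20, [f"AAC_{a}" for a in AMINO_ACIDS], encode_aac),
    "DPC": (400, [f"DPC_{d}" for d in _DIPEPTIDES], encode_dpc),
    "CTD": (147, _ctd_columns(), encode_ctd),
    "AAI": (20, [f"AAI_{a}" for a in AMINO_ACIDS], encode_aai),
    "AAIFULL": (
        160,
        [f"AAI_{acc}_{a}" for acc in AAINDEX_ACCESSIONS for a in AMINO_ACIDS],
        lambda p: encode_aai(p, averaged=False),
    ),
    "PCP": (9, list(PCP_COLUMNS), encode_pcp),
    "BPFN5": (100, _bpf_columns("N", 5), lambda p: encode_bpf(p, "N", 5)),
    "BPFC5": (100, _bpf_columns("C", 5), lambda p: encode_bpf(p, "C", 5)),
    "BPFN10": (200, _bpf_columns("N", 10), lambda p: encode_bpf(p, "N", 10)),
    "BPFC10": (200, _bpf_columns("C", 10), lambda p: encode_bpf(p, "C", 10)),
}

#: named composites: hybrids H1-H17 and the paired binary profiles
_COMPOSITES: dict[str, tuple[str, ...]] = {
    "H1": ("AAC", "AAI"),
    "H2": ("AAC", "DPC", "AAI"),
    "H3": ("AAC", "DPC", "AAI", "CTD"),
    "H4": ("AAC", "DPC", "AAI", "CTD", "PCP"),
    "H5": ("AAC", "DPC"),
    "H6": ("AAC", "CTD"),
    "H7": ("AAC", "PCP"),
    "H8": ("AAI", "DPC"),
    "H9": ("AAI", "DPC", "CTD"),
    "H10": ("AAI", "DPC", "CTD", "PCP"),
    "H11": ("AAI", "CTD"),
    "H12": ("AAI", "PCP"),
    "H13": ("DPC", "CTD"),
    "H14": ("DPC", "CTD", "PCP"),
    "H15": ("DPC", "PCP"),
    "H16": ("CTD", "DPC"),
    "H17": ("AAC", "AAI", "PCP"),
    "BPFN5C5": ("BPFN5", "BPFC5"),
    "BPFN10C10": ("BPFN10", "BPFC10"),
}

#: the 28 feature sets screened in model selection
ALL_SPEC_NAMES: tuple[str, ...] = (
    "AAC",
    "AAI",
    "DPC",
    "CTD",
    "PCP",
    *(f"H{i}" for i in range(1, 18)),
    "BPFN5",
    "BPFC5",
    "BPFN5C5",
    "BPFN10",
    "BPFC10",
    "BPFN10C10",
)


def list_specs() -> list[str]:
    """Names accepted by :func:`get_spec` (custom '+'-joins also work)."""
    return list(ALL_SPEC_NAMES) + ["AAIFULL"]


def get_spec(name: str) -> FeatureSpec:
    """Resolve a registered spec name or a '+'-joined custom composite."""
    if name in _COMPOSITES:
        components = _COMPOSITES[name]
    elif name in _COMPONENTS:
        components = (name,)
    elif "+" in name:
        components = tuple(part.strip() for part in name.split("+"))
    else:
        raise KeyError(
            f"unknown feature spec {name!r}; registered: {', '.join(list_specs())}"
        )
    cols: list[str] = []
    width = 0
    for comp in components:
        if comp in _COMPOSITES:  # e.g. custom "H7+CTD"
            sub = get_spec(comp)
            cols.extend(sub.column_names)
            width += sub.width
            continue
        if comp not in _COMPONENTS:
            raise KeyError(
                f"unknown feature component {comp!r} in spec {name!r}; "
                f"registered: {', '.join(list_specs())}"
            )
        w, c, _ = _COMPONENTS[comp]
        cols.extend(c)
        width += w
    return FeatureSpec(name, components, width, tuple(cols))


def encode_peptide(p: Peptide, spec: FeatureSpec | str) -> np.ndarray:
    """Encode one peptide under a spec (concatenating components in order)."""
    if isinstance(spec, str):
        spec = get_spec(spec)
    parts = []
    for comp in spec.components:
        if comp in _COMPOSITES:
            parts.append(encode_peptide(p, get_spec(comp)))
        else:
            parts.append(_COMPONENTS[comp][2](p))
    return np.concatenate(parts)


def encode(peptides: Sequence[Peptide], spec: FeatureSpec | str) -> FeatureMatrix:
    """Encode peptides into a :class:`FeatureMatrix` (rows in input order)."""
    if isinstance(spec, str):
        spec = get_spec(spec)
    if len(peptides) == 0:
        return FeatureMatrix((), spec, np.empty((0, spec.width)))
    rows = np.vstack([encode_peptide(p, spec) for p in peptides])
    return FeatureMatrix(tuple(p.id for p in peptides), spec, rows)
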