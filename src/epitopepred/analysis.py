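"""Compositional and positional contrasts between epitope and
non-epitope peptide sets.

Two complementary views of what distinguishes linear B-cell epitopes
from experimentally negative peptides:

* **Composition**: per-peptide amino-acid (AAC) or dipeptide (DPC)
  composition vectors are compared feature-wise between the two classes
  with Welch's unequal-variance t-test.  In curated epitope data this
  shows N, D, P and Y (and proline-containing dipeptides) enriched in
  epitopes, and A, E, L, V, M enriched in negatives.
* **Position**: for each of the first (N-terminal) or last (C-terminal)
  ``window`` positions, per-residue 0/1 occurrence indicators are
  compared between classes by a two-sample t-test — the statistic behind
  two-sample sequence logos.  On 0/1 indicators this t-test is
  equivalent to a two-proportion comparison.

No multiple-testing correction is applied by default (raw p <= alpha is
reported); a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import encode
from .seqio import AMINO_ACIDS, Peptide


def composition_comparison(
    pos: Sequence[Peptide],
    neg: Sequence[Peptide],
    scheme: Literal["AAC", "DPC"] = "AAC",
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Feature-wise Welch t-test of composition between two peptide sets.

    Returns a table with one row per composition feature (20 for AAC,
    400 for DPC): class means and standard errors, the Welch t statistic
    (positive when the epitope set has the larger mean), its two-sided
    p-value, which class the feature is enriched in, and a significance
    flag at ``alpha``.  Rows are sorted by p-value; features constant in
    both sets are flagged ``constant`` and not tested.  The fraction of
    testable features significant at ``alpha`` is stored in
    ``result.attrs["fraction_significant"]``.
    """
    if scheme not in ("AAC", "DPC"):
        raise ValueError("scheme must be 'AAC' or 'DPC'")
    if not pos or not neg:
        raise ValueError("both peptide sets must be non-empty")
    Xp = encode(pos, scheme)
    Xn = encode(neg, scheme)
    names = [c.split("_", 1)[1] for c in Xp.spec.column_names]
    rows = []
    for j, name in enumerate(names):
        a, b = Xp.values[:, j], Xn.values[:, j]
        mean_p, mean_n = float(a.mean()), float(b.mean())
        se_p = float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else np.nan
        se_n = float(b.std(ddof=1) / np.sqrt(b.size)) if b.size > 1 else np.nan
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            if mean_p == mean_n:
                t, p, enriched = np.nan, np.nan, "constant"
            else:  # disjoint constants: infinitely separated
                t, p = np.inf if mean_p > mean_n else -np.inf, 0.0
                enriched = "pos" if mean_p > mean_n else "neg"
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            t, p = float(t), float(p)
            enriched = "pos" if mean_p > mean_n else ("neg" if mean_n > mean_p else "none")
        rows.append((name, mean_p, mean_n, se_p, se_n, t, p, enriched))
    df = pd.DataFrame(
        rows,
        columns=[
            "feature", "mean_pos", "mean_neg", "se_pos", "se_neg",
            "t", "p", "enriched_in",
        ],
    )
    if bh_correction:
        tested = df["p"].notna()
        adj = np.full(len(df), np.nan)
        adj[tested.to_numpy()] = stats.false_discovery_control(
            df.loc[tested, "p"].to_numpy()
        )
        df["p_adj"] = adj
        df["significant"] = df["p_adj"] <= alpha
    else:
        df["significant"] = df["p"] <= alpha
    df = df.sort_values("p", na_position="last", kind="stable").reset_index(drop=True)
    n_tested = int(df["p"].notna().sum())
    df.attrs["fraction_significant"] = (
        float(df["significant"].sum() / n_tested) if n_tested else 0.0
    )
    df.attrs["alpha"] = alpha
    return df


def positional_enrichment(
    pos: Sequence[Peptide],
    neg: Sequence[Peptide],
    terminus: Literal["N", "C"] = "N",
    window: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-position, per-residue enrichment between two peptide sets.

    Position ``j`` counts from the first residue for ``terminus="N"``
    and from the last residue for ``terminus="C"``.  Peptides shorter
    than ``j`` are skipped at that position (counts adjust accordingly).
    For each residue observed at a position, the 0/1 occurrence
    indicators of the two classes are compared by a two-sample t-test;
    residues with p < ``alpha`` are flagged overrepresented (enriched in
    the epitope set) or underrepresented by the sign of the frequency
    difference.
    """
    if terminus not in ("N", "C"):
        raise ValueError("terminus must be 'N' or 'C'")
    if window < 1:
        raise ValueError("window must be positive")
    if not pos or not neg:
        raise ValueError("both peptide sets must be non-empty")

    def residue_at(p: Peptide, j: int) -> str | None:
        if len(p) < j:
            return None
        return p.sequence[j - 1] if terminus == "N" else p.sequence[-j]

    rows = []
    for j in range(1, window + 1):
        col_pos = [r for r in (residue_at(p, j) for p in pos) if r is not None]
        col_neg = [r for r in (residue_at(p, j) for p in neg) if r is not None]
        if not col_pos or not col_neg:
            warnings.warn(f"position {j}: no peptides long enough in one set")
            continue
        present = sorted(set(col_pos) | set(col_neg))
        for residue in present:
            ind_p = np.array([1.0 if r == residue else 0.0 for r in col_pos])
            ind_n = np.array([1.0 if r == residue else 0.0 for r in col_neg])
            freq_p, freq_n = float(ind_p.mean()), float(ind_n.mean())
            if ind_p.var(ddof=1) == 0 and ind_n.var(ddof=1) == 0:
                t, p = (np.nan, np.nan) if freq_p == freq_n else (
                    np.inf if freq_p > freq_n else -np.inf, 0.0)
            else:
                t, p = stats.ttest_ind(ind_p, ind_n, equal_var=False)
                t, p = float(t), float(p)
            if not np.isnan(p) and p < alpha and freq_p != freq_n:
                direction = "overrepresented" if freq_p > freq_n else "underrepresented"
            else:
                direction = ""
            rows.append((j, residue, freq_p, freq_n, t, p, direction))
    df = pd.DataFrame(
        rows,
        columns=["position", "residue", "frequency_pos", "frequency_neg",
                 "t", "p", "direction"],
    )
    df.attrs["terminus"] = terminus
    df.attrs["alpha"] = alpha
    return df
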