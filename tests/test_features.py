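import math

import numpy as np
import pytest

from epitopepred.features import (
    AAINDEX_TABLE,
    CTD_PROPERTIES,
    encode,
    encode_aac,
    encode_aai,
    encode_bpf,
    encode_ctd,
    encode_dpc,
    encode_pcp,
    get_spec,
    list_specs,
)
from epitopepred.seqio import AMINO_ACIDS, Peptide

AA = {a: i for i, a in enumerate(AMINO_ACIDS)}

EXPECTED_WIDTHS = {
    "AAC": 20,
    "DPC": 400,
    "CTD": 147,
    "AAI": 20,
    "AAIFULL": 160,
    "PCP": 9,
    "BPFN5": 100,
    "BPFC5": 100,
    "BPFN5C5": 200,
    "BPFN10": 200,
    "BPFC10": 200,
    "BPFN10C10": 400,
    "H1": 40,
    "H2": 440,
    "H3": 587,
    "H4": 596,
    "H5": 420,
    "H6": 167,
    "H7": 29,
    "H8": 420,
    "H9": 567,
    "H10": 576,
    "H11": 167,
    "H12": 29,
    "H13": 547,
    "H14": 556,
    "H15": 409,
    "H16": 547,
    "H17": 49,
}


@pytest.mark.parametrize("name,width", sorted(EXPECTED_WIDTHS.items()))
def test_spec_widths(name, width):
    spec = get_spec(name)
    assert spec.width == width
    assert len(spec.column_names) == width
    assert len(set(spec.column_names)) == width  # unique, ordered columns


def test_every_registered_spec_encodes_to_declared_width():
    pep = Peptide("x", "NPNAYKLMWQRTSC")
    for name in list_specs():
        spec = get_spec(name)
        assert encode_aac(pep).shape == (20,)  # sanity anchor
        assert encode([pep], spec).values.shape == (1, spec.width)


# ---------------------------------------------------------------------------
# AAC


class TestAAC:
    def test_homopolymer(self):
        v = encode_aac(Peptide("x", "AAAAA"))
        assert v[AA["A"]] == 100.0 and v.sum() == 100.0

    def test_full_alphabet_uniform(self):
        v = encode_aac(Peptide("x", AMINO_ACIDS))
        assert np.allclose(v, 5.0)

    def test_npna(self):
        v = encode_aac(Peptide("x", "NPNA"))
        assert v[AA["N"]] == 50.0
        assert v[AA["P"]] == 25.0
        assert v[AA["A"]] == 25.0

    def test_sums_to_100(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(
                rng.choice(list(AMINO_ACIDS), size=rng.integers(1, 30))
            )
            assert encode_aac(Peptide("x", seq)).sum() == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# DPC


class TestDPC:
    def test_aaa(self):
        v = encode_dpc(Peptide("x", "AAA"))
        assert v[0] == pytest.approx(100 * 2 / 3)
        assert np.count_nonzero(v) == 1

    def test_acac(self):
        v = encode_dpc(Peptide("x", "ACAC"))
        assert v[AA["A"] * 20 + AA["C"]] == pytest.approx(50.0)
        assert v[AA["C"] * 20 + AA["A"]] == pytest.approx(25.0)

    def test_sum_convention_and_nonzero_bound(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(2, 26))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
            v = encode_dpc(Peptide("x", seq))
            assert v.sum() == pytest.approx(100 * (n - 1) / n)
            assert np.count_nonzero(v) <= n - 1

    def test_alternative_denominator_sums_to_100(self):
        v = encode_dpc(Peptide("x", "ACDEF"), denominator="N-1")
        assert v.sum() == pytest.approx(100.0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            encode_dpc(Peptide("x", "A"))


# ---------------------------------------------------------------------------
# CTD


def brute_force_ctd(seq: str) -> list[float]:
    """Independent re-derivation of the 147 CTD values by explicit loops."""
    n = len(seq)
    out = []
    for _prop, groups in CTD_PROPERTIES:
        which = []
        for ch in seq:
            for gi, (_, residues) in enumerate(groups):
                if ch in residues:
                    which.append(gi)
                    break
        for g in range(3):
            out.append(100.0 * which.count(g) / n)
        for pair in [(0, 1), (0, 2), (1, 2)]:
            count = 0
            for i in range(n - 1):
                if {which[i], which[i + 1]} == set(pair):
                    count += 1
            out.append(100.0 * count / (n - 1))
        for g in range(3):
            pos = [i + 1 for i, w in enumerate(which) if w == g]
            if not pos:
                out.extend([0.0] * 5)
                continue
            c = len(pos)
            for k in (1, math.ceil(0.25 * c), math.ceil(0.5 * c),
                      math.ceil(0.75 * c), c):
                out.append(100.0 * pos[max(k, 1) - 1] / n)
    return out


class TestCTD:
    def test_homopolymer_blocks(self):
        v = encode_ctd(Peptide("x", "LLLLL"))
        # hydrophobicity is the first property; L is in its 3rd group
        assert v[0] == 0.0 and v[1] == 0.0 and v[2] == 100.0
        assert np.all(v[3:6] == 0.0)  # no transitions in a homopolymer
        d_third_group = v[6 + 10 : 6 + 15]
        assert np.allclose(d_third_group, [20, 40, 60, 80, 100])

    def test_width_and_bounds(self):
        v = encode_ctd(Peptide("x", "NPNAYKLMC"))
        assert v.shape == (147,)
        assert np.all(v >= 0.0) and np.all(v <= 100.0)

    def test_composition_block_sums_to_100_per_property(self):
        v = encode_ctd(Peptide("x", "WNDPAYKLMCF"))
        for prop_idx in range(7):
            block = v[21 * prop_idx : 21 * prop_idx + 3]
            assert block.sum() == pytest.approx(100.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            seq = "".join(
                rng.choice(list(AMINO_ACIDS), size=rng.integers(2, 26))
            )
            assert np.allclose(
                encode_ctd(Peptide("x", seq)), brute_force_ctd(seq)
            )


# ---------------------------------------------------------------------------
# AAI


class TestAAI:
    def test_widths(self):
        p = Peptide("x", "NPNAY")
        assert encode_aai(p, averaged=True).shape == (20,)
        assert encode_aai(p, averaged=False).shape == (160,)

    def test_homopolymer_single_entry_is_table_mean(self):
        v = encode_aai(Peptide("x", "AAAA"))
        assert np.count_nonzero(v) == 1
        expected = AAINDEX_TABLE[:, AA["A"]].mean()
        assert v[AA["A"]] == pytest.approx(expected)

    def test_averaged_is_mean_of_full_blocks(self):
        p = Peptide("x", "NPNAYKC")
        full = encode_aai(p, averaged=False).reshape(8, 20)
        assert np.allclose(encode_aai(p, averaged=True), full.mean(axis=0))


# ---------------------------------------------------------------------------
# PCP


class TestPCP:
    def test_alanine_homopolymer(self):
        v = encode_pcp(Peptide("x", "AAAA"))
        frac_hydrophobic, _, _, _, frac_neg, frac_turn, charge, mw, ai = (
            v[0], v[1], v[2], v[3], v[4], v[5], v[6], v[7], v[8],
        )
        assert ai == pytest.approx(1.0)
        assert frac_turn == 0.0 and frac_neg == 0.0
        assert frac_hydrophobic == 1.0
        assert charge == pytest.approx(0.03)
        # 4 alanine residues + one water
        assert mw == pytest.approx(4 * 71.08 + 18.02, abs=0.1)

    def test_balanced_charge_gives_offset_constant(self):
        v = encode_pcp(Peptide("x", "KKDDGG"))
        assert v[6] == pytest.approx(0.03)

    def test_polylysine(self):
        v = encode_pcp(Peptide("x", "KKKK"))
        assert v[3] == 1.0  # positive fraction
        assert v[6] == pytest.approx(0.97)  # |1 - 0.03|


# ---------------------------------------------------------------------------
# BPF


class TestBPF:
    def test_n_terminal_one_hot(self):
        v = encode_bpf(Peptide("x", "ACDEF"), "N", 5)
        assert v.shape == (100,)
        for j, ch in enumerate("ACDEF"):
            block = v[20 * j : 20 * (j + 1)]
            assert block[AA[ch]] == 1.0 and block.sum() == 1.0

    def test_total_ones_min_k_n(self):
        for seq in ("ACD", "ACDEFGH"):
            for k in (5, 10):
                v = encode_bpf(Peptide("x", seq), "N", k)
                assert v.sum() == min(k, len(seq))

    def test_c_terminal_takes_last_k_in_order(self):
        v = encode_bpf(Peptide("x", "WWACDEF"), "C", 5)
        for j, ch in enumerate("ACDEF"):
            assert v[20 * j + AA[ch]] == 1.0

    def test_short_peptide_pads_inner_end(self):
        # N-terminal: residues fill the leading blocks, trailing blocks zero
        v = encode_bpf(Peptide("x", "ACD"), "N", 5)
        assert np.all(v[60:] == 0.0)
        # C-terminal: residues fill the trailing blocks, leading blocks zero
        v = encode_bpf(Peptide("x", "ACD"), "C", 5)
        assert np.all(v[:40] == 0.0)
        assert v[40 + AA["A"]] == 1.0 and v[80 + AA["D"]] == 1.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            encode_bpf(Peptide("x", "ACD"), "N", 0)
        with pytest.raises(ValueError):
            encode_bpf(Peptide("x", "ACD"), "Q", 5)


# ---------------------------------------------------------------------------
# composite encoding


class TestEncode:
    def test_matrix_equals_stacked_rows(self):
        peps = [Peptide("a", "NPNAY"), Peptide("b", "LLVAE"), Peptide("c", "KWCMR")]
        m = encode(peps, "H7")
        for i, p in enumerate(peps):
            row = np.concatenate([encode_aac(p), encode_pcp(p)])
            assert np.allclose(m.values[i], row)
        assert m.ids == ("a", "b", "c")

    def test_unknown_spec_lists_registered_names(self):
        with pytest.raises(KeyError, match="AAC"):
            get_spec("NOPE")

    def test_custom_plus_join(self):
        spec = get_spec("AAC+CTD")
        assert spec.width == 167

    def test_encoding_is_pure(self):
        p = Peptide("x", "NPNAYKLM")
        a = encode([p], "H4").values
        b = encode([p], "H4").values
        assert np.array_equal(a, b)

    def test_no_cross_peptide_normalization(self):
        p = Peptide("a", "NPNAY")
        alone = encode([p], "H15").values[0]
        with_others = encode(
            [p, Peptide("b", "WWWWW"), Peptide("c", "KKKKK")], "H15"
        ).values[0]
        assert np.array_equal(alone, with_others)
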