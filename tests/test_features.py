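"""Feature extractors against straight-line oracle transcriptions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbpred import (LengthError, PSSMatrix, SyntheticSpec, ValidationError,
                    encode_mcd_groups, extract_all_views, generate_dataset,
                    mcd_features, nmbac_features, property_table,
                    psepssm_features, pssm_ab_features)
from dbpred.features import MCD_REGIONS, _quarters
from dbpred.io import AA_ORDER

from conftest import random_sequence

# --- independent oracles (deliberately naive loop transcriptions) ----------

RAW_TABLE = property_table(standardized=False)


def oracle_standardized_table():
    out = np.empty_like(RAW_TABLE)
    for j in range(6):
        col = RAW_TABLE[:, j]
        mean = sum(col) / 20
        sd = math.sqrt(sum((v - mean) ** 2 for v in col) / 20)
        for i in range(20):
            out[i, j] = (col[i] - mean) / sd
    return out


def oracle_nmbac(sequence, lg):
    table = oracle_standardized_table()
    n = len(sequence)
    feats = []
    for j in range(6):
        for lag in range(1, lg + 1):
            total = 0.0
            for i in range(n - lag):
                xi = table[AA_ORDER.index(sequence[i]), j]
                xl = table[AA_ORDER.index(sequence[i + lag]), j]
                total += xi * xl
            feats.append(total / (n - lag))
    return np.array(feats)


def oracle_pssm_ab(scores):
    L = scores.shape[0]
    feats = []
    for i in range(1, 21):
        lo, hi = (i - 1) * L // 20, i * L // 20
        for j in range(20):
            feats.append(sum(scores[z, j] for z in range(lo, hi)) / (hi - lo))
    return np.array(feats)


def oracle_psepssm(scores, lag_max):
    L = scores.shape[0]
    P = np.zeros_like(scores, dtype=float)
    for i in range(L):
        row = scores[i]
        mean = sum(row) / 20
        sd = math.sqrt(sum((v - mean) ** 2 for v in row) / 20)
        if sd > 0:
            P[i] = [(v - mean) / sd for v in row]
    feats = []
    for j in range(20):
        feats.append(sum(P[i, j] for i in range(L)) / L)
    for lag in range(1, lag_max + 1):
        for j in range(20):
            total = sum((P[i, j] - P[i + lag, j]) ** 2 for i in range(L - lag))
            feats.append(total / (L - lag))
    return np.array(feats)


# --- property table ---------------------------------------------------------

def test_standardized_properties_zero_mean_unit_sd():
    std = property_table(standardized=True)
    np.testing.assert_allclose(std.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(std.std(axis=0), 1.0, atol=1e-12)


def test_property_table_spot_values():
    # two raw entries checked against the published property compilation
    i_a, i_w = AA_ORDER.index("A"), AA_ORDER.index("W")
    assert RAW_TABLE[i_a, 0] == 0.62       # hydrophobicity of A
    assert RAW_TABLE[i_w, 4] == 2.663      # SASA of W


# --- MCD ---------------------------------------------------------------------

class TestMcd:
    @pytest.mark.parametrize("sequence, expected", [
        ("AVDCALSK", "11321476"),   # the descriptor's reference encoding
        ("AAAA", "1111"),
        ("CKMW", "2675"),
    ])
    def test_group_encoding(self, sequence, expected):
        assert encode_mcd_groups(sequence) == expected

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValidationError):
            encode_mcd_groups("ACX")

    def test_dimension_is_882(self, rng):
        for length in (8, 25, 100, 341):
            assert mcd_features(random_sequence(rng, length)).shape == (882,)

    def test_too_short_sequence_raises(self):
        with pytest.raises(LengthError):
            mcd_features("AVDCALS")  # length 7 < one residue pair per quarter

    def test_homopolymer_regions(self):
        v = mcd_features("A" * 40)
        for r in range(14):
            block = v[63 * r: 63 * (r + 1)]
            comp, trans = block[:7], block[7:28]
            assert comp[0] == 1.0 and comp[1:].sum() == 0.0
            assert np.all(trans == 0.0)

    def test_composition_sums_to_one_per_region(self, rng):
        v = mcd_features(random_sequence(rng, 73))
        for r in range(14):
            assert abs(v[63 * r: 63 * r + 7].sum() - 1.0) < 1e-9

    def test_distribution_in_unit_interval(self, rng):
        for _ in range(5):
            v = mcd_features(random_sequence(rng, int(rng.integers(8, 200))))
            for r in range(14):
                dist = v[63 * r + 28: 63 * (r + 1)]
                assert np.all(dist >= 0.0) and np.all(dist <= 1.0)

    def test_against_straight_line_ctd(self):
        """Fixed 25-residue sequence vs an independent C/T/D recomputation."""
        seq = "ACDEFGHIKLMNPQRSTVWYACDEF"
        encoded = encode_mcd_groups(seq)
        quarters = _quarters(len(seq))
        expected = []
        for parts in MCD_REGIONS:
            region = "".join(encoded[i] for p in parts for i in quarters[p])
            m = len(region)
            comp = [region.count(str(g)) / m for g in range(1, 8)]
            trans = []
            for g in range(1, 8):
                for h in range(g + 1, 8):
                    cnt = 0
                    for a, b in zip(region, region[1:]):
                        if {a, b} == {str(g), str(h)}:
                            cnt += 1
                    trans.append(cnt / (m - 1))
            dist = []
            for g in range(1, 8):
                pos = [k + 1 for k, ch in enumerate(region) if ch == str(g)]
                if not pos:
                    dist.extend([0.0] * 5)
                else:
                    n_occ = len(pos)
                    for frac in (None, 0.25, 0.5, 0.75, 1.0):
                        idx = 1 if frac is None else max(1, math.ceil(frac * n_occ))
                        dist.append(pos[idx - 1] / m)
            expected.extend(comp + trans + dist)
        np.testing.assert_allclose(mcd_features(seq), expected, atol=1e-12)


# --- NMBAC -------------------------------------------------------------------

class TestNmbac:
    def test_dimension(self, rng):
        assert nmbac_features(random_sequence(rng, 50), lg=10).shape == (60,)

    def test_length_guard(self):
        with pytest.raises(LengthError):
            nmbac_features("ACDEF", lg=5)

    def test_homopolymer_gives_squared_property(self):
        std = property_table(standardized=True)
        v = nmbac_features("A" * 30, lg=4)
        a = AA_ORDER.index("A")
        expected = np.repeat(std[a] ** 2, 4)
        np.testing.assert_allclose(v, expected, atol=1e-12)

    def test_hand_rolled_short_sequence(self):
        """'ACDK' at lg=2, hydrophobicity only, against explicit sums."""
        std = property_table(standardized=True)
        h = {aa: std[AA_ORDER.index(aa), 0] for aa in "ACDK"}
        v = nmbac_features("ACDK", lg=2)
        lag1 = (h["A"] * h["C"] + h["C"] * h["D"] + h["D"] * h["K"]) / 3
        lag2 = (h["A"] * h["D"] + h["C"] * h["K"]) / 2
        np.testing.assert_allclose(v[:2], [lag1, lag2], atol=1e-12)

    def test_matches_oracle_on_random_sequences(self, rng):
        for _ in range(20):
            n = int(rng.integers(15, 120))
            seq = random_sequence(rng, n)
            got = nmbac_features(seq, lg=10)
            np.testing.assert_allclose(got, oracle_nmbac(seq, 10), atol=1e-10)


# --- PSSM-AB -----------------------------------------------------------------

class TestPssmAb:
    def test_constant_profile(self):
        pssm = PSSMatrix("x", np.full((40, 20), 3.0))
        np.testing.assert_allclose(pssm_ab_features(pssm), 3.0)

    def test_indicator_block(self):
        scores = np.zeros((40, 20))
        scores[:2] = 1.0  # block 1 rows only
        v = pssm_ab_features(PSSMatrix("x", scores))
        np.testing.assert_allclose(v[:20], 1.0)
        np.testing.assert_allclose(v[20:], 0.0)

    def test_length_guard(self):
        with pytest.raises(LengthError):
            pssm_ab_features(PSSMatrix("x", np.zeros((19, 20))))

    def test_matches_oracle_including_ragged_lengths(self, rng):
        for L in (20, 23, 40, 57, 101):
            scores = rng.integers(-10, 11, size=(L, 20)).astype(float)
            got = pssm_ab_features(PSSMatrix("x", scores))
            assert got.shape == (400,)
            np.testing.assert_allclose(got, oracle_pssm_ab(scores), atol=1e-10)


# --- PsePSSM -----------------------------------------------------------------

class TestPsePssm:
    def test_dimension_at_default_lag(self, rng):
        scores = rng.integers(-5, 6, size=(30, 20))
        assert psepssm_features(PSSMatrix("x", scores)).shape == (320,)

    def test_constant_rows_standardize_to_zero(self):
        pssm = PSSMatrix("x", np.full((25, 20), 7.0))
        np.testing.assert_array_equal(psepssm_features(pssm), 0.0)

    def test_length_guard(self):
        with pytest.raises(LengthError):
            psepssm_features(PSSMatrix("x", np.zeros((15, 20))), lag_max=15)

    def test_matches_oracle(self, rng):
        for _ in range(10):
            L = int(rng.integers(16, 80))
            scores = rng.integers(-10, 11, size=(L, 20)).astype(float)
            got = psepssm_features(PSSMatrix("x", scores))
            np.testing.assert_allclose(got, oracle_psepssm(scores, 15),
                                       atol=1e-10)


# --- batch extraction --------------------------------------------------------

class TestExtractAllViews:
    def test_shapes_across_views(self, small_dataset):
        records, pssms, _ = small_dataset
        views = extract_all_views(records[:5], pssms, lg=10)
        assert views["mcd"].values.shape == (5, 882)
        assert views["nmbac"].values.shape == (5, 60)
        assert views["pssm_ab"].values.shape == (5, 400)
        assert views["psepssm"].values.shape == (5, 320)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            extract_all_views([], {})

    def test_missing_pssm_lists_offenders(self, small_dataset):
        records, pssms, _ = small_dataset
        partial = {k: v for k, v in pssms.items() if k != records[0].id}
        with pytest.raises(ValidationError, match=records[0].id):
            extract_all_views(records, partial)

    def test_reordering_rows_reorders_all_views(self, small_dataset, rng):
        records, pssms, _ = small_dataset
        views = extract_all_views(records, pssms)
        perm = rng.permutation(len(records))
        shuffled = extract_all_views([records[i] for i in perm], pssms)
        for name in views:
            np.testing.assert_array_equal(shuffled[name].values,
                                          views[name].values[perm])
            assert shuffled[name].ids == tuple(views[name].ids[i] for i in perm)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=25, max_value=500), st.integers(0, 2**31 - 1))
def test_dimensions_invariant_over_lengths(length, seed):
    """Every view's width is independent of sequence length."""
    rng = np.random.default_rng(seed)
    seq = random_sequence(rng, length)
    scores = rng.integers(-10, 11, size=(length, 20))
    assert mcd_features(seq).shape == (882,)
    assert nmbac_features(seq, lg=10).shape == (60,)
    assert pssm_ab_features(PSSMatrix("x", scores)).shape == (400,)
    assert psepssm_features(PSSMatrix("x", scores), lag_max=15).shape == (320,)
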