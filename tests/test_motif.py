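import math
from math import comb, fsum

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cysredox.motif import (
    ALPHABET,
    FLANK_POSITIONS,
    PROPERTY_ORDER,
    background_frequencies,
    build_pwm,
    extract_window,
    pwm_heatmap_matrix,
    plogo_score,
    significance_threshold,
)


def binom_tail_oracle(k, n, p, upper):
    """Brute-force exact binomial tail by direct term summation."""
    rng = range(k, n + 1) if upper else range(0, k + 1)
    return fsum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in rng)


class TestWindows:
    def test_center_of_15mer_protein_is_the_protein(self):
        db = {"P": "AAAAAAACAAAAAAA"}
        assert extract_window(db, "P", 8) == "AAAAAAACAAAAAAA"

    def test_n_terminal_padding(self):
        db = {"P": "MACDEFKG"}
        assert extract_window(db, "P", 3) == "-----MACDEFKG--"

    def test_c_terminal_cysteine_padding(self):
        db = {"P": "AAAAAAAC"}
        assert extract_window(db, "P", 8) == "AAAAAAAC" + "-" * 7

    def test_non_cysteine_position_rejected(self):
        db = {"P": "MACDEFKG"}
        with pytest.raises(ValueError):
            extract_window(db, "P", 2)


class TestBackground:
    def test_single_window_background(self):
        p = background_frequencies(["AAAAAAACAAAAAAA"])
        assert (p.loc["A"] == 1.0).all()
        assert (p.drop(index="A") == 0.0).all().all()

    def test_two_windows_split_position(self):
        w1 = "AAAAAAACAAAAAAA"
        w2 = "AAAAAAACGAAAAAA"
        p = background_frequencies([w1, w2])
        assert p.loc["A", 1] == pytest.approx(0.5)
        assert p.loc["G", 1] == pytest.approx(0.5)
        assert p.loc["A", -1] == pytest.approx(1.0)

    def test_columns_sum_to_one_excluding_pads(self):
        windows = ["-----MACDEFKG--", "AAAAAAACAAAAAAA"]
        p = background_frequencies(windows)
        assert np.allclose(p.sum(axis=0), 1.0)

    def test_uniform_background_monte_carlo(self):
        rng = np.random.default_rng(42)
        letters = np.array(list(ALPHABET))
        windows = []
        for _ in range(10_000):
            w = rng.choice(letters, size=15)
            w[7] = "C"
            windows.append("".join(w))
        p = background_frequencies(windows)
        sd = math.sqrt(0.05 * 0.95 / 10_000)
        assert (np.abs(p.values - 0.05) < 3 * sd + 1e-12).mean() > 0.99

    def test_all_pad_position_is_error(self):
        with pytest.raises(ValueError):
            background_frequencies(["-------CAAAAAAA"])


class TestPlogoScore:
    def test_full_enrichment_closed_form(self):
        # P(X >= 5 | n=5, p=0.1) = 0.1^5
        assert plogo_score(5, 5, 0.1) == pytest.approx(5.0)

    def test_depletion_closed_form(self):
        # P(X <= 0 | n=5, p=0.1) = 0.9^5
        assert plogo_score(0, 5, 0.1) == pytest.approx(math.log10(0.9**5))

    def test_matches_brute_force_tail(self):
        expected = -math.log10(binom_tail_oracle(3, 10, 0.05, upper=True))
        assert plogo_score(3, 10, 0.05) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_background_rejected(self, p):
        with pytest.raises(ValueError):
            plogo_score(1, 5, p)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=40), st.sampled_from([0.05, 0.2, 0.5]))
    def test_monotone_in_k_on_enrichment_side(self, n, p):
        scores = [plogo_score(k, n, p) for k in range(n + 1) if k / n >= p]
        assert scores == sorted(scores)


class TestThreshold:
    def test_bonferroni_constant_rounds_to_published_cutoff(self):
        assert round(significance_threshold(0.05, 20, 14), 2) == 3.75

    def test_unit_case_is_zero(self):
        assert significance_threshold(1.0, 1, 1) == pytest.approx(0.0)

    def test_single_position_closed_form(self):
        assert significance_threshold(0.05, 20, 1) == pytest.approx(-math.log10(0.0025))


def _windows_with_plant(rng, n, plant_fraction, residue="K", offset=-1):
    letters = np.array(list(ALPHABET))
    # 5%-per-residue uniform background
    out = []
    for i in range(n):
        w = rng.choice(letters, size=15)
        w[7] = "C"
        if i < int(plant_fraction * n):
            w[7 + offset] = residue
        out.append("".join(w))
    return out


class TestPwm:
    def test_planted_lysine_at_minus1_crosses_threshold(self):
        rng = np.random.default_rng(0)
        fg = _windows_with_plant(rng, 100, 0.6, "K", -1)
        bg = background_frequencies(_windows_with_plant(rng, 4000, 0.0))
        pwm = build_pwm(fg, bg)
        assert pwm.score.loc["K", -1] > 3.75
        assert pwm.significant.loc["K", -1] == 1

    def test_planted_acidic_residue_recovered(self):
        rng = np.random.default_rng(1)
        fg = _windows_with_plant(rng, 100, 0.5, "D", 1)
        bg = background_frequencies(_windows_with_plant(rng, 4000, 0.0))
        pwm = build_pwm(fg, bg)
        assert pwm.score.loc["D", 1] > 3.75

    def test_counts_account_for_every_nonpad_residue(self):
        rng = np.random.default_rng(2)
        fg = _windows_with_plant(rng, 50, 0.0)
        pwm = build_pwm(fg, background_frequencies(fg))
        for j in FLANK_POSITIONS:
            assert pwm.k[j].sum() == pwm.n[j] == 50

    def test_heatmap_reorder_preserves_values(self):
        rng = np.random.default_rng(3)
        fg = _windows_with_plant(rng, 30, 0.0)
        pwm = build_pwm(fg, background_frequencies(fg))
        identity = pwm_heatmap_matrix(pwm, list(ALPHABET))
        assert identity.equals(pwm.score)
        rev = pwm_heatmap_matrix(pwm, list(ALPHABET)[::-1])
        assert list(rev.index) == list(ALPHABET)[::-1]
        assert rev.loc["K", -1] == pwm.score.loc["K", -1]
        charged_first = pwm_heatmap_matrix(pwm, PROPERTY_ORDER)
        assert list(charged_first.index[:5]) == ["K", "R", "H", "D", "E"]

    def test_invalid_residue_order_rejected(self):
        rng = np.random.default_rng(4)
        fg = _windows_with_plant(rng, 10, 0.0)
        pwm = build_pwm(fg, background_frequencies(fg))
        with pytest.raises(ValueError):
            pwm_heatmap_matrix(pwm, list(ALPHABET)[:-1] + ["A"])
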