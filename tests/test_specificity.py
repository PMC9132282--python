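import numpy as np
import pytest

from kinassign import specificity as spec
from kinassign import windows as win
from kinassign.errors import InputError, NormalizationError


def windows_from(strings):
    return [win.window_from_string(s) for s in strings]


def random_windows(rng, n, length=15):
    return windows_from("".join(rng.choice(list(win.AMINO_ACIDS), size=length))
                        for _ in range(n))


class TestSequenceWeights:
    def test_identical_windows_share_unit_weight(self):
        ws = windows_from(["AAAAAAASAAAAAAA"] * 5)
        assert np.allclose(spec.sequence_weights(ws), 1.0)

    def test_distinct_window_outweighs_duplicates(self):
        ws = windows_from(["AAAAAAASAAAAAAA", "AAAAAAASAAAAAAA",
                           "CCCCCCCTCCCCCCC"])
        w = spec.sequence_weights(ws)
        assert w[2] > w[0] == pytest.approx(w[1])

    def test_matches_hand_computed_henikoff_weights(self):
        strings = ["ACDAAAASAAAAAAA", "ACEAAAATAAAAAAA", "GCDAAAASAAAAAAA"]
        ws = windows_from(strings)
        # independent per-column 1/(r*s) accumulation
        raw = np.zeros(3)
        for j in range(15):
            col = [s[j] for s in strings]
            counts = {c: col.count(c) for c in set(col)}
            r = len(counts)
            for i, c in enumerate(col):
                raw[i] += 1.0 / (r * counts[c])
        expected = raw * 3 / raw.sum()
        assert np.allclose(spec.sequence_weights(ws), expected, atol=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(InputError):
            spec.sequence_weights([])


class TestRelativeEntropy:
    def test_identical_distributions_give_zero(self, rng):
        q = rng.dirichlet(np.ones(20))
        assert spec.column_relative_entropy(q, q) == pytest.approx(0.0, abs=1e-12)

    def test_indicator_vs_uniform_is_log2_20(self):
        p = np.zeros(20)
        p[3] = 1.0
        q = np.full(20, 1 / 20)
        assert spec.column_relative_entropy(p, q) == pytest.approx(
            np.log2(20), abs=1e-12)

    def test_two_point_vs_uniform_is_log2_10(self):
        p = np.zeros(20)
        p[0] = p[1] = 0.5
        q = np.full(20, 1 / 20)
        assert spec.column_relative_entropy(p, q) == pytest.approx(
            np.log2(10), abs=1e-12)

    def test_zero_background_entry_rejected(self):
        q = np.zeros(20)
        q[0] = 1.0
        with pytest.raises(InputError):
            spec.column_relative_entropy(np.full(20, 1 / 20), q)

    def test_matches_loop_oracle_on_random_pairs(self, rng):
        for _ in range(1000):
            p = rng.dirichlet(np.ones(20) * rng.uniform(0.2, 5))
            q = np.maximum(rng.dirichlet(np.ones(20)), 1e-6)
            q = q / q.sum()
            expected = sum(pi * np.log2(pi / qi)
                           for pi, qi in zip(p, q) if pi > 0)
            got = spec.column_relative_entropy(p, q)
            assert got == pytest.approx(expected, abs=1e-9)
            assert got >= -1e-12


class TestBuildPfm:
    def test_vanishing_pseudocounts_approach_indicator(self):
        ws = windows_from(["ACDEFGHSIKLMNPQ"])
        pfm = spec.build_pfm(ws, pseudocount_mass=1e-9)
        for i, ch in enumerate("ACDEFGHSIKLMNPQ"):
            assert pfm.values[i, win.AA_INDEX[ch]] == pytest.approx(1.0, abs=1e-6)

    def test_all_pad_column_falls_back_to_background(self):
        ws = windows_from(["-------SAAAAAAA", "-------TAAAAAAA"])
        bg = spec.BackgroundModel.uniform()
        pfm = spec.build_pfm(ws, background=bg, pseudocount_mass=1.0)
        assert np.allclose(pfm.values[0], 1 / 20)

    def test_matches_hand_computed_count_table(self):
        strings = ["ACDEFGHSIKLMNPQ", "ACDEFGHSIKLMNPQ", "GCDEFGHTIKLMNPQ",
                   "ACDEFGHSIKLMNPQ", "ACDEFGHYIKLMNPQ"]
        ws = windows_from(strings)
        pfm = spec.build_pfm(ws, weights=np.ones(5), pseudocount_mass=1.0,
                             background=spec.BackgroundModel.uniform())
        for j in range(15):
            for a, aa in enumerate(win.AMINO_ACIDS):
                count = sum(1 for s in strings if s[j] == aa)
                expected = (count + 1.0 / 20) / (5 + 1.0)
                assert pfm.values[j, a] == pytest.approx(expected, abs=1e-12)

    def test_pad_counts_redistribute_to_background(self):
        ws = windows_from(["--DEFGHSIKLMNPQ", "ACDEFGHSIKLMNPQ"])
        bg = spec.BackgroundModel.uniform()
        pfm = spec.build_pfm(ws, background=bg, pseudocount_mass=1.0)
        # column 0: one observed 'A', one pad -> pseudo mass (1 + 1) * 1/20
        expected_a = (1 + 2.0 / 20) / (1 + 2.0)
        assert pfm.values[0, win.AA_INDEX["A"]] == pytest.approx(expected_a)

    def test_columns_sum_to_one(self, rng):
        pfm = spec.build_pfm(random_windows(rng, 20),
                             background=spec.BackgroundModel.proteome_default())
        assert np.allclose(pfm.values.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(pfm.column_weights >= 0)
        assert pfm.theoretical_min <= pfm.theoretical_max

    def test_empty_windows_rejected(self):
        with pytest.raises(InputError):
            spec.build_pfm([])


class TestBuildPssm:
    def test_pfm_equal_to_background_gives_zero_matrix(self):
        bg = spec.BackgroundModel.proteome_default()
        pfm = spec.matrix_from_frequencies(np.tile(bg.frequencies, (15, 1)), bg)
        pssm = spec.build_pssm(pfm, bg)
        assert np.allclose(pssm.values, 0.0, atol=1e-9)
        assert pssm.theoretical_min == pytest.approx(0.0, abs=1e-9)
        assert pssm.theoretical_max == pytest.approx(0.0, abs=1e-9)

    def test_enriched_cell_is_log2_ratio(self):
        bg = spec.BackgroundModel("proteome", np.full(20, 0.05))
        freqs = np.tile(bg.frequencies, (15, 1)).copy()
        freqs[3] = 0.5 / 19
        freqs[3, 0] = 0.5
        pfm = spec.matrix_from_frequencies(freqs, bg)
        pssm = spec.build_pssm(pfm, bg)
        assert pssm.values[3, 0] == pytest.approx(np.log2(10), abs=1e-9)

    def test_backgrounds_change_only_where_they_differ(self, rng):
        ws = random_windows(rng, 30)
        prot = spec.BackgroundModel.proteome_default()
        phos = spec.BackgroundModel.from_windows(random_windows(rng, 200))
        pfm = spec.build_pfm(ws, background=prot)
        p1 = spec.build_pssm(pfm, prot)
        p2 = spec.build_pssm(pfm, phos)
        assert p1.role == spec.ROLE_PSSM_PROTEOME
        assert p2.role == spec.ROLE_PSSM_PHOSPHO
        diff_bg = np.abs(phos.matrix(15) - prot.matrix(15)) > 1e-12
        diff_vals = np.abs(p1.values - p2.values) > 1e-12
        assert np.array_equal(diff_vals, diff_bg)


@pytest.fixture(scope="module")
def matrices():
    rng = np.random.default_rng(77)
    ws = random_windows(rng, 40)
    bg = spec.BackgroundModel.from_windows(random_windows(rng, 300))
    pfm = spec.build_pfm(ws, spec.sequence_weights(ws), background=bg)
    return pfm, spec.build_pssm(pfm, bg)


class TestScoringAndNormalization:
    def test_raw_score_matches_loop_oracle(self, matrices, rng):
        pfm, pssm = matrices
        for matrix in (pfm, pssm):
            for _ in range(50):
                w = random_windows(rng, 1)[0]
                base = (np.log2(matrix.values) if matrix.role == spec.ROLE_PFM
                        else matrix.values)
                expected = sum(
                    matrix.column_weights[i] * base[i, win.AA_INDEX[ch]]
                    for i, ch in enumerate(w.residues))
                assert matrix.score(w) == pytest.approx(expected, abs=1e-9)

    def test_extreme_windows_hit_exact_bounds(self, matrices):
        for matrix in matrices:
            base = (np.log2(matrix.values) if matrix.role == spec.ROLE_PFM
                    else matrix.values)
            table = matrix.column_weights[:, None] * base
            best = "".join(win.AMINO_ACIDS[a] for a in table.argmax(axis=1))
            worst = "".join(win.AMINO_ACIDS[a] for a in table.argmin(axis=1))
            assert matrix.score_normalized(win.window_from_string(best)) == 1.0
            assert matrix.score_normalized(win.window_from_string(worst)) == 0.0

    def test_random_windows_normalize_into_unit_interval(self, matrices, rng):
        enc = win.encode_windows(random_windows(rng, 10000))
        for matrix in matrices:
            s = matrix.score_normalized_many(enc)
            assert np.all((s >= 0.0) & (s <= 1.0))

    def test_pssm_midpoint_normalizes_to_half(self, matrices):
        _, pssm = matrices
        mid = 0.5 * (pssm.theoretical_min + pssm.theoretical_max)
        assert spec.minmax_normalize(pssm, mid) == pytest.approx(0.5, abs=1e-12)

    def test_normalize_matches_formula_on_random_raws(self, matrices, rng):
        pfm, pssm = matrices
        for _ in range(1000):
            raw = rng.uniform(pssm.theoretical_min, pssm.theoretical_max)
            expected = ((raw - pssm.theoretical_min)
                        / (pssm.theoretical_max - pssm.theoretical_min))
            assert pssm.normalize(raw) == pytest.approx(expected, abs=1e-9)
            raw = rng.uniform(pfm.theoretical_min, pfm.theoretical_max)
            lo = 2.0 ** (pfm.theoretical_min - pfm.theoretical_max)
            expected = (2.0 ** (raw - pfm.theoretical_max) - lo) / (1 - lo)
            assert pfm.normalize(raw) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_matrix_raises(self):
        bg = spec.BackgroundModel.proteome_default()
        flat = spec.matrix_from_frequencies(
            np.tile(bg.frequencies, (15, 1)), bg).with_column_weights(
            np.zeros(15))
        with pytest.raises(NormalizationError):
            flat.normalize(0.0)

    def test_pad_positions_score_background_equivalent(self, matrices):
        _, pssm = matrices
        padded = win.window_from_string("-------S-------")
        center = pssm.column_weights[7] * pssm.values[7, win.AA_INDEX["S"]]
        assert pssm.score(padded) == pytest.approx(center, abs=1e-12)

    def test_raw_ranges_differ_across_kinases_normalized_coincide(self, rng):
        bg = spec.BackgroundModel.from_windows(random_windows(rng, 300))
        ranges = []
        for _ in range(3):
            ws = random_windows(rng, 25)
            pssm = spec.build_pssm(
                spec.build_pfm(ws, background=bg), bg)
            ranges.append((pssm.theoretical_min, pssm.theoretical_max))
            enc = win.encode_windows(random_windows(rng, 200))
            s = pssm.score_normalized_many(enc)
            assert s.min() >= 0.0 and s.max() <= 1.0
        assert len({r for r in ranges}) == 3  # raw ranges kinase-specific


class TestColumnWeightDiscrimination:
    def test_relative_entropy_separates_planted_from_degenerate(self):
        """A planted (sharp) column should dominate a degenerate one more
        under relative-entropy weighting than under information content."""
        bg_vec = spec.PROTEOME_FREQS
        bg = spec.BackgroundModel("proteome", bg_vec)
        freqs = np.tile(bg_vec, (15, 1)).copy()
        sharp = np.full(20, 0.2 / 19)
        sharp[win.AA_INDEX["P"]] = 0.8
        freqs[3] = sharp  # planted position
        pfm = spec.matrix_from_frequencies(freqs, bg)

        def info_content(p):
            p = np.maximum(p, 1e-12)
            return np.log2(20) + np.sum(p * np.log2(p))

        kl_share = pfm.column_weights[3] / (pfm.column_weights.sum())
        ic = np.array([info_content(pfm.values[i]) for i in range(15)])
        ic_share = ic[3] / ic.sum()
        assert kl_share > ic_share

    def test_reweighted_copy_recomputes_extremes(self, rng):
        ws = random_windows(rng, 20)
        bg = spec.BackgroundModel.proteome_default()
        pfm = spec.build_pfm(ws, background=bg)
        doubled = pfm.with_column_weights(pfm.column_weights * 2)
        assert doubled.theoretical_max == pytest.approx(
            2 * pfm.theoretical_max, abs=1e-9)
        with pytest.raises(InputError):
            pfm.with_column_weights(-np.ones(15))
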