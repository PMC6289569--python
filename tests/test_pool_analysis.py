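"""Frequency profiles, RGB signatures, junction fingerprints, combinatorics, kinetics."""

import numpy as np
import pytest

from poolforge.pool_analysis import (
    FrequencyProfile,
    fit_ligation_kinetics,
    frequency_profile,
    generate_matched_pool,
    junction_fingerprint,
    pool_combinatorics,
    rgb_signature,
    rgb_to_int,
)
from poolforge.synthetic_data import PoolSpec, ProductSpec, make_pool, make_products


class TestFrequencyProfile:
    def test_identical_sequences_give_unit_vectors(self):
        prof = frequency_profile(["ACGU", "ACGU"])
        expected = np.eye(4)[[0, 1, 2, 3]]  # alphabet order A, C, G, U
        assert np.allclose(prof.freqs, expected)

    def test_mixed_lengths_error_points_to_split(self):
        with pytest.raises(ValueError, match="split_by_length"):
            frequency_profile(["ACGU", "ACGUA"])

    def test_uniform_random_converges_to_quarter(self, rng):
        n, L = 30_000, 40
        seqs = ["".join(row) for row in rng.choice(list("ACGU"), size=(n, L))]
        prof = frequency_profile(seqs)
        sd = np.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(prof.freqs - 0.25) < 5 * sd)

    def test_weighted_counts(self):
        from poolforge.io_formats import CollapsedRecord

        recs = [CollapsedRecord("AA", 3), CollapsedRecord("CC", 1)]
        prof = frequency_profile(recs, weighted=True)
        assert prof.freqs[0, 0] == pytest.approx(0.75)  # A at position 1


class TestRGBSignature:
    @pytest.mark.parametrize(
        "base,expected",
        [("C", (0, 0, 255)), ("U", (255, 0, 0)), ("A", (0, 255, 0)), ("G", (255, 255, 0))],
        ids=["C-blue", "U-red", "A-green", "G-yellow"],
    )
    def test_pure_base_colors(self, base, expected):
        prof = frequency_profile([base * 5])
        rgb = rgb_signature(prof)
        assert np.allclose(rgb, np.tile(expected, (5, 1)))

    def test_uniform_composition(self):
        prof = FrequencyProfile(freqs=np.full((1, 4), 0.25))
        rgb = rgb_signature(prof)
        assert np.allclose(rgb[0], (127.5, 127.5, 63.75))
        assert tuple(rgb_to_int(rgb)[0]) == (128, 128, 64)

    def test_idempotent_on_deterministic_profile(self):
        prof = FrequencyProfile(freqs=np.array([[0.1, 0.2, 0.3, 0.4]]))
        assert np.array_equal(rgb_signature(prof), rgb_signature(prof))

    def test_non_four_letter_alphabet_rejected(self):
        prof = FrequencyProfile(freqs=np.array([[0.5, 0.5]]), alphabet=("A", "U"))
        with pytest.raises(ValueError, match="4-letter"):
            rgb_signature(prof)


class TestJunctionFingerprint:
    def test_single_context_concentrates_mass(self):
        prods = ["AAACGGG", "UUUCGCC"]  # junction bond 4: C|G
        fp = junction_fingerprint(prods, junction_index=4)
        i, j = fp.alphabet.index("C"), fp.alphabet.index("G")
        assert fp.table[i, j] == pytest.approx(1.0)
        assert fp.table.sum() == pytest.approx(1.0)

    def test_unbiased_fixture_has_no_strong_enrichment(self, rng):
        n = 20_000
        seqs = ["".join(row) for row in rng.choice(list("ACGU"), size=(n, 10))]
        fp = junction_fingerprint(seqs, junction_index=5)
        se = np.sqrt((1 / 16) * (15 / 16) / n)
        assert np.all(np.abs(fp.table - 1 / 16) < 5 * se)
        assert np.all(np.abs(fp.enrichment) < 0.2)

    def test_mixture_fingerprint_is_weighted_mixture(self):
        a = ["AAACGGG"] * 3
        b = ["AAAUAGG"] * 1
        fp_mix = junction_fingerprint(a + b, junction_index=4)
        fp_a = junction_fingerprint(a, junction_index=4)
        fp_b = junction_fingerprint(b, junction_index=4)
        assert np.allclose(fp_mix.table, 0.75 * fp_a.table + 0.25 * fp_b.table)

    def test_recovers_injected_cpn_bias(self):
        spec = PoolSpec(length=20, n_unique=500, redundancy=1)
        bait, prey = make_pool(spec, seed=1), make_pool(spec, seed=2)
        pspec = ProductSpec(junction_bias={"CN": 8.0},
                            truncation_dist=("fixed", 0), n_products=10_000)
        prods = make_products(bait, prey, pspec, seed=3)
        fp = junction_fingerprint([p.seq for p in prods], junction_index=20)
        p_c = fp.marginal_5p[fp.alphabet.index("C")]
        # odds ratio vs the unligated input pool background recovers the factor
        last = [s[-1] for s in bait.entries]
        p_bg = last.count("C") / len(last)
        odds = (p_c / (1 - p_c)) / (p_bg / (1 - p_bg))
        p_exp = 8 * p_bg / (8 * p_bg + (1 - p_bg))
        se_p = np.sqrt(p_exp * (1 - p_exp) / 10_000)
        sigma_odds = (1 - p_bg) / p_bg / (1 - p_exp) ** 2 * se_p  # delta method
        assert abs(odds - 8.0) < 3 * sigma_odds


class TestGenerateMatchedPool:
    def test_degenerate_profile_gives_constant_pool(self):
        prof = frequency_profile(["CCCC"])
        assert generate_matched_pool(prof, n=7, seed=1) == ["CCCC"] * 7

    def test_profile_recovered_within_binomial_ci(self, rng):
        freqs = rng.dirichlet([5, 5, 5, 5], size=15)
        prof = FrequencyProfile(freqs=freqs)
        n = 50_000
        out = generate_matched_pool(prof, n=n, seed=2)
        recovered = frequency_profile(out)
        sd = np.sqrt(freqs * (1 - freqs) / n)
        assert np.all(np.abs(recovered.freqs - freqs) < 5 * np.maximum(sd, 1e-4))


class TestPoolCombinatorics:
    def test_published_eicosamer_pool_numbers(self):
        result = pool_combinatorics(10**15, length=20, alphabet_size=4)
        assert result["redundancy"] == 909
        assert round(result["amount_nmol"], 1) == 1.7
        assert result["diversity"] == 4**20
        assert result["binary_pairs"] == (4**20) ** 2 > 10**24

    def test_exact_integer_arithmetic_long_oligomers(self):
        result = pool_combinatorics(None, length=60, alphabet_size=4)
        assert result["diversity"] == 4**60  # exact, no float overflow
        assert result["binary_pairs"] == 4**120


class TestKineticsFit:
    def test_noiseless_recovery_is_exact(self):
        t = np.array([0, 1, 2, 4, 8, 16, 32, 64], dtype=float)
        y = 0.5 * (1 - np.exp(-0.1 * t))
        fit = fit_ligation_kinetics(t, y)
        assert fit.k_obs == pytest.approx(0.1, rel=1e-6)
        assert fit.plateau == pytest.approx(0.5, rel=1e-6)
        assert fit.residual_norm < 1e-8

    def test_flat_zero_yields_flagged(self):
        fit = fit_ligation_kinetics([0, 1, 2, 3], [0, 0, 0, 0])
        assert fit.plateau == 0.0
        assert "indeterminate_rate" in fit.flags

    def test_input_contracts(self):
        with pytest.raises(ValueError, match="3 timepoints"):
            fit_ligation_kinetics([0, 1], [0, 0.1])
        with pytest.raises(ValueError, match="fractions"):
            fit_ligation_kinetics([0, 1, 2], [0, 0.5, 1.5])

    def test_noisy_recovery_median_within_20_percent(self):
        t = np.array([0, 2, 5, 10, 15, 20, 30, 50], dtype=float)
        true_k, plateau = 0.1, 0.5
        clean = plateau * (1 - np.exp(-true_k * t))
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.clip(clean + rng.normal(0, 0.05 * plateau, size=t.size), 0, 1)
            fit = fit_ligation_kinetics(t, y)
            errors.append(abs(fit.k_obs - true_k) / true_k)
        assert np.median(errors) < 0.2
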