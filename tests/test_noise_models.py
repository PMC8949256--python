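"""Noise generators: closed-form moments, determinism, and composition."""

import numpy as np
import pytest

from ppgdenoise import evaluate as ev
from ppgdenoise.exceptions import ContractError, ParameterError
from ppgdenoise.noise import (
    SINGLE_NOISE_KINDS,
    NoiseChain,
    NoiseSpec,
    add_gaussian,
    add_poisson,
    add_salt_pepper,
    add_speckle,
    add_uniform,
    corrupt,
    derive_seed,
    from_unit,
    inject_motion_artifact,
    random_mixed_chain,
    synthesize_motion_artifact,
    to_unit,
)
from ppgdenoise.signal_core import Segment

from conftest import make_signed_segment, make_unit_segment

N_MC = 100_000


def const_unit(value, n=N_MC):
    return make_unit_segment(np.full(n, value))


class TestRangeMaps:
    def test_affine_endpoints(self):
        seg = make_signed_segment([-1.0, 0.0, 1.0])
        np.testing.assert_allclose(to_unit(seg).samples, [0.0, 0.5, 1.0])

    def test_inverse_pair(self):
        seg = make_signed_segment(np.linspace(-1, 1, 300))
        np.testing.assert_allclose(from_unit(to_unit(seg)).samples,
                                   seg.samples, atol=1e-15)

    def test_monotone(self):
        rng = np.random.default_rng(0)
        seg = make_signed_segment(np.sort(rng.uniform(-1, 1, 100)))
        u = to_unit(seg).samples
        assert np.all(np.diff(u) >= 0)

    def test_wrong_range_tag_rejected(self):
        with pytest.raises(ContractError):
            to_unit(make_unit_segment([0.5, 0.6]))
        with pytest.raises(ContractError):
            from_unit(make_signed_segment([-0.5, 0.5]))


class TestGaussian:
    def test_sigma_zero_identity(self):
        seg = make_unit_segment(np.linspace(0, 1, 300))
        out = add_gaussian(seg, sigma=0.0, seed=1)
        np.testing.assert_array_equal(out.samples, seg.samples)

    def test_variance_matches_sigma_squared(self):
        out = add_gaussian(const_unit(0.5), sigma=0.01, seed=2)
        var = np.var(out.samples - 0.5)
        assert abs(var - 1e-4) < 0.05 * 1e-4

    def test_clipped_at_one(self):
        out = add_gaussian(const_unit(1.0, 1000), sigma=0.3, seed=3)
        assert out.samples.max() <= 1.0


class TestPoisson:
    def test_zero_input_stays_zero(self):
        out = add_poisson(const_unit(0.0, 1000), scale=255, seed=1)
        assert np.all(out.samples == 0.0)

    def test_variance_matches_intensity_over_scale(self):
        out = add_poisson(const_unit(0.5), scale=255, seed=2)
        var = np.var(out.samples - 0.5)
        expect = 0.5 / 255
        assert abs(var - expect) < 0.10 * expect

    def test_mse_vanishes_with_scale(self):
        seg = const_unit(0.5, 10_000)
        mses = [np.mean((add_poisson(seg, scale=s, seed=4).samples - 0.5) ** 2)
                for s in (1e2, 1e4, 1e6)]
        assert mses[0] > mses[1] > mses[2]


class TestSaltPepper:
    def test_exact_hit_count_and_values(self):
        seg = make_unit_segment(np.full(300, 0.5))
        out = add_salt_pepper(seg, rate=0.05, seed=5)
        changed = out.samples != 0.5
        assert changed.sum() == 15  # round(0.05*300)
        assert set(np.unique(out.samples[changed])) <= {0.0, 1.0}

    def test_rate_zero_identity(self):
        seg = make_unit_segment(np.linspace(0, 1, 300))
        out = add_salt_pepper(seg, rate=0.0, seed=1)
        np.testing.assert_array_equal(out.samples, seg.samples)

    def test_rate_one_all_extremes(self):
        out = add_salt_pepper(const_unit(0.5, 1000), rate=1.0, seed=2)
        assert set(np.unique(out.samples)) <= {0.0, 1.0}

    def test_salt_and_pepper_equiprobable(self):
        out = add_salt_pepper(const_unit(0.5), rate=1.0, seed=3)
        frac_salt = np.mean(out.samples == 1.0)
        assert abs(frac_salt - 0.5) < 0.01


class TestSpeckle:
    def test_zero_signal_unchanged(self):
        out = add_speckle(const_unit(0.0, 1000), sigma=0.5, seed=1)
        assert np.all(out.samples == 0.0)

    def test_sigma_zero_identity(self):
        seg = make_unit_segment(np.linspace(0, 1, 300))
        np.testing.assert_array_equal(add_speckle(seg, 0.0, 1).samples,
                                      seg.samples)

    def test_mse_matches_x_squared_sigma_squared(self):
        out = add_speckle(const_unit(0.5), sigma=0.01, seed=2)
        m = np.mean((out.samples - 0.5) ** 2)
        expect = 0.25 * 1e-4
        assert abs(m - expect) < 0.05 * expect


class TestUniform:
    def test_degenerate_interval_identity(self):
        seg = make_unit_segment(np.linspace(0, 1, 300))
        out = add_uniform(seg, lo=0.0, hi=0.0, seed=1)
        np.testing.assert_array_equal(out.samples, seg.samples)

    def test_support_bound(self):
        out = add_uniform(const_unit(0.4, 10_000), lo=0.0, hi=0.1, seed=2)
        d = out.samples - 0.4
        assert d.min() >= 0.0 and d.max() <= 0.1

    def test_mean_offset(self):
        out = add_uniform(const_unit(0.4), lo=0.0, hi=0.1, seed=3)
        assert abs(np.mean(out.samples - 0.4) - 0.05) < 0.02 * 0.05


class TestCorrupt:
    def test_null_chain_is_identity(self, clean_segment):
        chain = NoiseChain([NoiseSpec("gaussian", {"sigma": 0.0})])
        pair = corrupt(clean_segment, chain)
        np.testing.assert_allclose(pair.noisy.samples, clean_segment.samples,
                                   atol=1e-15)

    def test_deterministic_given_chain(self, clean_segment):
        chain = random_mixed_chain(3, master_seed=17)
        a = corrupt(clean_segment, chain)
        b = corrupt(clean_segment, chain)
        assert np.array_equal(a.noisy.samples, b.noisy.samples)

    def test_single_spec_chain_equals_direct_call(self, clean_segment):
        chain = NoiseChain([NoiseSpec("gaussian", {"sigma": 0.05})],
                           master_seed=9)
        pair = corrupt(clean_segment, chain)
        direct = add_gaussian(to_unit(clean_segment), sigma=0.05,
                              seed=chain.stage_seed(0))
        np.testing.assert_allclose(pair.noisy.samples,
                                   from_unit(direct).samples, atol=1e-15)

    def test_serialization_round_trip_reproduces_noisy(self, clean_segment,
                                                       tmp_path):
        chain = random_mixed_chain(4, master_seed=23)
        chain.save(tmp_path / "chain.json")
        reloaded = NoiseChain.load(tmp_path / "chain.json")
        a = corrupt(clean_segment, chain).noisy.samples
        b = corrupt(clean_segment, reloaded).noisy.samples
        assert np.array_equal(a, b)

    def test_outputs_stay_in_signed_range(self, clean_segments):
        for k in range(2, 6):
            for seg in clean_segments:
                pair = corrupt(seg, random_mixed_chain(k, master_seed=k))
                assert pair.noisy.samples.min() >= -1.0
                assert pair.noisy.samples.max() <= 1.0

    def test_mse_nondecreasing_in_chain_length(self, clean_segment):
        # nested chains: prefixes of one random 5-kind chain, 200 seeds
        mean_mse = {k: 0.0 for k in range(1, 6)}
        n_seeds = 200
        for seed in range(n_seeds):
            full = random_mixed_chain(5, master_seed=seed)
            for k in range(1, 6):
                chain = NoiseChain(full.specs[:k], master_seed=seed)
                pair = corrupt(clean_segment, chain)
                mean_mse[k] += ev.mse(pair.noisy, pair.clean) / n_seeds
        values = [mean_mse[k] for k in range(1, 6)]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestRandomMixedChain:
    def test_k5_contains_every_kind_once(self):
        chain = random_mixed_chain(5, master_seed=1)
        assert sorted(s.kind for s in chain.specs) == sorted(SINGLE_NOISE_KINDS)

    def test_reproducible(self):
        a = random_mixed_chain(2, master_seed=7)
        b = random_mixed_chain(2, master_seed=7)
        assert [s.kind for s in a.specs] == [s.kind for s in b.specs]
        assert [a.stage_seed(i) for i in range(2)] == \
               [b.stage_seed(i) for i in range(2)]

    def test_pair_frequencies_uniform(self):
        # each unordered pair of 5 kinds should appear ~1/10 of the time
        from collections import Counter
        counts = Counter()
        n = 1000
        for seed in range(n):
            chain = random_mixed_chain(2, master_seed=seed)
            counts[frozenset(s.kind for s in chain.specs)] += 1
        assert len(counts) == 10
        sd = np.sqrt(n * 0.1 * 0.9)
        for c in counts.values():
            assert abs(c - n / 10) <= 3 * sd

    @pytest.mark.parametrize("k", [1, 6])
    def test_k_out_of_range(self, k):
        with pytest.raises(ParameterError):
            random_mixed_chain(k, master_seed=0)


class TestMotionArtifact:
    def test_reproducible_and_bounded(self):
        a = synthesize_motion_artifact(3000, 50, seed=3)
        b = synthesize_motion_artifact(3000, 50, seed=3)
        assert np.array_equal(a.samples, b.samples)
        assert a.samples.min() >= -1.0 and a.samples.max() <= 1.0

    def test_spectral_power_in_band(self):
        sig = synthesize_motion_artifact(50 * 60, 50, seed=8)
        freqs = np.fft.rfftfreq(len(sig), d=1 / 50)
        power = np.abs(np.fft.rfft(sig.samples)) ** 2
        in_band = power[(freqs >= 0.25) & (freqs <= 6.0)].sum()
        assert in_band / power.sum() > 0.90

    def test_window_size_and_locality(self, clean_segment):
        art_raw = synthesize_motion_artifact(300, 50, seed=4)
        art = Segment(art_raw.samples, 50, 6, "signed_unit")
        pair = inject_motion_artifact(clean_segment, art, ratio=0.3,
                                      start_index=0)
        changed = ~np.isclose(pair.noisy.samples, clean_segment.samples,
                              atol=1e-12)
        assert not changed[90:].any()       # locality outside the window
        assert changed[:90].sum() > 45      # most of the 90-sample window

    def test_zero_artifact_identity(self, clean_segment):
        art = Segment(np.zeros(300), 50, 6, "signed_unit")
        pair = inject_motion_artifact(clean_segment, art, ratio=0.5,
                                      start_index=10)
        np.testing.assert_allclose(pair.noisy.samples, clean_segment.samples,
                                   atol=1e-15)

    def test_out_of_bounds_window_rejected(self, clean_segment):
        art = Segment(np.zeros(300), 50, 6, "signed_unit")
        with pytest.raises(ParameterError):
            inject_motion_artifact(clean_segment, art, ratio=0.5,
                                   start_index=200)


class TestDeriveSeed:
    def test_deterministic_and_distinct(self):
        seeds = [derive_seed(123, i) for i in range(100)]
        assert seeds == [derive_seed(123, i) for i in range(100)]
        assert len(set(seeds)) == 100
        assert all(0 <= s < 2 ** 31 for s in seeds)
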