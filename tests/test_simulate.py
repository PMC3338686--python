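import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trflpdyn import (
    EnvSpec,
    ResponseSpec,
    SyntheticScenario,
    fixed_similarity_series,
    noise_free_scenario,
    default_scenario,
    render_peak_tables,
    simulate_campaign,
    simulate_env_series,
    simulate_profile_series,
    preprocess_peaks,
)


def scenario_with_env(env_specs, n_samples=24, **kw):
    return SyntheticScenario(
        n_samples=n_samples,
        trf_lengths_bp=(219,),
        env_specs=env_specs,
        response_specs={219: ResponseSpec("x", 0.0, 1.0)},
        **kw,
    )


class TestEnvSeries:
    def test_degenerate_noise_gives_constant_series(self):
        sc = scenario_with_env({"x": EnvSpec(mean=3.5, sd=0.0, rho=0.0)})
        env = simulate_env_series(sc)
        assert np.allclose(env["x"], 3.5)

    def test_nonstationary_rho_rejected_but_near_boundary_allowed(self):
        sc = scenario_with_env({"x": EnvSpec(0.0, 1.0, rho=0.99)})
        simulate_env_series(sc)  # fine
        sc_bad = scenario_with_env({"x": EnvSpec(0.0, 1.0, rho=1.0)})
        with pytest.raises(ValueError, match="stationar"):
            simulate_env_series(sc_bad)

    def test_lag1_autocorrelation_matches_rho(self):
        sc = scenario_with_env({"x": EnvSpec(0.0, 1.0, rho=0.8)}, n_samples=5000)
        x = simulate_env_series(sc)["x"].to_numpy()
        xc = x - x.mean()
        r1 = (xc[:-1] @ xc[1:]) / (xc @ xc)
        assert abs(r1 - 0.8) < 0.05

    def test_stationary_sd_matches_spec(self):
        sc = scenario_with_env({"x": EnvSpec(10.0, 2.0, rho=0.7)}, n_samples=5000)
        x = simulate_env_series(sc)["x"].to_numpy()
        assert abs(x.std() - 2.0) < 0.1


class TestProfileSeries:
    def test_driver_at_optimum_gives_height_everywhere(self):
        sc = SyntheticScenario(
            trf_lengths_bp=(219, 354),
            env_specs={"x": EnvSpec(5.0, 0.0, 0.0)},
            response_specs={
                219: ResponseSpec("x", optimum=5.0, tolerance=1.0, height=0.8),
                354: ResponseSpec("x", optimum=5.0, tolerance=1.0, height=0.2),
            },
        )
        env = simulate_env_series(sc)
        series = simulate_profile_series(sc, env)
        m = series.matrix()
        # unnormalized abundances are exactly h_k -> shares h_k / sum h
        assert np.allclose(m[219], 0.8)
        assert np.allclose(m[354], 0.2)

    def test_single_taxon_is_always_one(self):
        sc = scenario_with_env({"x": EnvSpec(0.0, 1.0, 0.0)})
        env = simulate_env_series(sc)
        series = simulate_profile_series(sc, env)
        assert np.allclose(series.matrix().to_numpy(), 1.0)

    def test_symmetric_optima_split_evenly(self):
        sc = SyntheticScenario(
            trf_lengths_bp=(219, 354),
            env_specs={"x": EnvSpec(0.0, 0.0, 0.0)},
            response_specs={
                219: ResponseSpec("x", optimum=-2.0, tolerance=1.5),
                354: ResponseSpec("x", optimum=2.0, tolerance=1.5),
            },
        )
        env = simulate_env_series(sc)
        m = simulate_profile_series(sc, env).matrix().to_numpy()
        assert np.allclose(m, 0.5)

    def test_missing_driver_named_in_error(self):
        sc = scenario_with_env({"x": EnvSpec(0.0, 1.0, 0.0)})
        env = simulate_env_series(sc).drop(columns=["x"])
        with pytest.raises(ValueError, match="'x'"):
            simulate_profile_series(sc, env)

    def test_profiles_sum_to_one(self, noise_free_campaign):
        _, series, _ = noise_free_campaign
        sums = series.matrix().to_numpy().sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-12


class TestRenderPeakTables:
    def test_zero_jitter_lengths_equal_bin_labels(self, noise_free_campaign):
        _, series, peaks = noise_free_campaign
        assert set(peaks["fragment_length"]) == {219.0, 354.0, 491.0}

    def test_noise_peaks_counted_per_sample(self):
        sc = default_scenario(seed=3)
        assert sc.n_noise_peaks == 3
        _, series, peaks = simulate_campaign(sc)
        counts = peaks.groupby("sample_id").size()
        assert (counts == sc.n_taxa + 3).all()

    def test_noise_stays_below_floor_and_off_true_bins(self):
        sc = default_scenario(seed=5)
        _, _, peaks = simulate_campaign(sc)
        for sid, g in peaks.groupby("sample_id"):
            rel = g["area"] / g["area"].sum()
            is_true = g["fragment_length"].round().isin(sc.trf_lengths_bp)
            assert (rel[~is_true] < 0.02).all()
            for length in g.loc[~is_true, "fragment_length"]:
                assert min(abs(length - b) for b in sc.trf_lengths_bp) > 2.0

    def test_roundtrip_recovers_true_profiles(self, noise_free_campaign):
        env, series, peaks = noise_free_campaign
        recovered, _ = preprocess_peaks(peaks, env)
        a = series.matrix()
        b = recovered.matrix()
        assert list(a.columns) == list(b.columns)
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 1e-6

    def test_roundtrip_with_noise_peaks_is_exact_after_renormalization(self):
        sc = default_scenario(seed=11)
        env, series, peaks = simulate_campaign(sc)
        recovered, _ = preprocess_peaks(peaks, env)
        assert np.abs(
            series.matrix().to_numpy() - recovered.matrix().to_numpy()
        ).max() < 1e-9

    def test_same_seed_bit_identical(self):
        a = simulate_campaign(default_scenario(seed=9))
        b = simulate_campaign(default_scenario(seed=9))
        assert a[0].equals(b[0])
        assert a[2].equals(b[2])
        assert (a[1].matrix() == b[1].matrix()).all().all()


class TestFixedSimilaritySeries:
    def test_target_one_means_zero_change(self):
        s = fixed_similarity_series(6, 1.0, seed=0)
        m = s.matrix().to_numpy()
        assert np.abs(np.diff(m, axis=0)).max() < 1e-12

    @pytest.mark.parametrize("target_r", [0.9, 0.75, 0.5, -0.2])
    def test_consecutive_pearson_equals_target(self, target_r):
        s = fixed_similarity_series(12, target_r, seed=4)
        m = s.matrix().to_numpy()
        for a, b in zip(m, m[1:]):
            r = np.corrcoef(a, b)[0, 1]
            assert abs(r - target_r) < 1e-9

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            fixed_similarity_series(5, -1.0)
        with pytest.raises(ValueError):
            fixed_similarity_series(5, 1.5)

    @settings(deadline=None, max_examples=25)
    @given(
        target_r=st.floats(min_value=-0.9, max_value=1.0),
        n=st.integers(min_value=2, max_value=30),
    )
    def test_profiles_are_valid_compositions(self, target_r, n):
        s = fixed_similarity_series(n, target_r, seed=2)
        m = s.matrix().to_numpy()
        assert (m > 0).all()
        assert np.abs(m.sum(axis=1) - 1.0).max() < 1e-12


class TestScenarioValidation:
    def test_duplicate_trf_lengths_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            SyntheticScenario(trf_lengths_bp=(219, 219))

    def test_noise_at_or_above_floor_rejected(self):
        with pytest.raises(ValueError, match="0.02"):
            SyntheticScenario(trf_lengths_bp=(219,), max_noise_abundance=0.02)

    def test_scenario_yaml_roundtrip(self, tmp_path):
        sc = default_scenario(seed=21)
        path = tmp_path / "scenario.yaml"
        sc.to_file(path)
        back = SyntheticScenario.from_file(path)
        assert back == sc
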