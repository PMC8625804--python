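import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hrmscan import (
    MeltCurve,
    SimulationSpec,
    SmoothingConfig,
    TransitionSpec,
    find_domains,
    melting_region,
    melting_temperature,
    normalize_domain,
    scan_domains,
    simulate_melt_curve,
    smooth_derivatives,
)
from hrmscan.errors import (
    ConfigError,
    DegenerateBaselines,
    GridNotUniform,
    NoDomainsFound,
    WindowTooLarge,
)
from hrmscan.melt_core import MeltDomain, peak_candidates


def logistic_spec(tm=80.0, slope=1.0, noise_sd=0.0, seed=0, background=(200.0, -2.0, 0.0)):
    return SimulationSpec(
        transitions=(TransitionSpec(tm=tm, slope=slope),),
        background=background, noise_sd=noise_sd, seed=seed,
    )


class TestSmoothingConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"window": 10},                      # even
            {"window": 3, "polyorder": 3},       # window <= polyorder
            {"polyorder": 1},                    # polyorder < 2
            {"domain_threshold": 0.0},
            {"domain_threshold": 1.5},
            {"peak_prominence": 1.0},
            {"region_pad": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SmoothingConfig(**kwargs)


class TestSmoothDerivatives:
    def test_constant_curve_has_zero_derivatives(self, grid):
        curve = MeltCurve("c", grid, np.full(grid.size, 1000.0))
        d = smooth_derivatives(curve)
        np.testing.assert_allclose(d.neg_dFdT, 0.0, atol=1e-9)
        np.testing.assert_allclose(d.d2, 0.0, atol=1e-9)

    def test_affine_curve_reproduced_exactly(self, grid):
        # Savitzky–Golay reproduces polynomials up to its order, so the
        # derivative of F = −2T + 300 is exact everywhere, edges included.
        curve = MeltCurve("a", grid, -2.0 * grid + 300.0)
        d = smooth_derivatives(curve)
        np.testing.assert_allclose(d.neg_dFdT, 2.0, atol=1e-8)
        np.testing.assert_allclose(d.d2, 0.0, atol=1e-8)

    def test_logistic_peak_at_midpoint(self):
        # closed form: the logistic's −dF/dT is maximal exactly at Tm
        curve = simulate_melt_curve(logistic_spec(tm=80.0))
        d = smooth_derivatives(curve)
        tm_est = d.grid[np.argmax(d.neg_dFdT)]
        assert tm_est == pytest.approx(80.0, abs=0.05)

    def test_logistic_derivative_matches_closed_form(self):
        spec = logistic_spec(tm=80.0, slope=1.0, background=(200.0, 0.0, 0.0))
        curve = simulate_melt_curve(spec)
        d = smooth_derivatives(curve)
        t = d.grid
        x = np.exp((t - 80.0) / 1.0)
        analytic = 1000.0 * x / (1.0 + x) ** 2  # −dF/dT of the logistic
        interior = slice(50, -50)
        np.testing.assert_allclose(
            d.neg_dFdT[interior], analytic[interior], atol=0.02 * analytic.max()
        )

    def test_window_larger_than_curve_rejected(self):
        t = 70 + 0.04 * np.arange(50)
        with pytest.raises(WindowTooLarge):
            smooth_derivatives(MeltCurve("c", t, np.ones(50)))

    def test_nonuniform_grid_rejected(self):
        t = np.sort(np.random.default_rng(0).uniform(70, 95, 200))
        with pytest.raises(GridNotUniform):
            smooth_derivatives(MeltCurve("c", t, np.ones(200)))


def brute_force_candidates(y, height_frac, prom_frac):
    """Independent oracle: exhaustive scan for strict local maxima above the
    height threshold, with prominence computed from first principles."""
    ymax = y.max()
    out = []
    for i in range(1, len(y) - 1):
        if not (y[i] > y[i - 1] and y[i] > y[i + 1]):
            continue
        if y[i] < height_frac * ymax:
            continue
        # prominence: on each side walk to the nearest strictly higher point
        # (or the end); the base is the lowest value on that walk
        left = y[:i][::-1]
        higher = np.nonzero(left > y[i])[0]
        left_base = left[: higher[0] + 1].min() if higher.size else left.min()
        right = y[i + 1:]
        higher = np.nonzero(right > y[i])[0]
        right_base = right[: higher[0] + 1].min() if higher.size else right.min()
        if y[i] - max(left_base, right_base) >= prom_frac * ymax:
            out.append(i)
    return out


class TestFindDomains:
    def test_single_transition_single_domain(self):
        curve = simulate_melt_curve(logistic_spec(tm=80.0))
        domains = scan_domains(curve)
        assert len(domains) == 1
        assert domains[0].peak_temp == pytest.approx(80.0, abs=0.05)
        assert domains[0].peak_height_rel == 1.0

    def test_two_well_separated_transitions(self):
        spec = SimulationSpec(
            transitions=(
                TransitionSpec(tm=75.0, slope=1.0, weight=0.6),
                TransitionSpec(tm=85.0, slope=1.0, weight=0.4),
            ),
            noise_sd=0.0,
        )
        domains = scan_domains(simulate_melt_curve(spec))
        assert len(domains) == 2
        assert domains[0].peak_temp == pytest.approx(75.0, abs=0.1)
        assert domains[1].peak_temp == pytest.approx(85.0, abs=0.1)
        # the two domains share the inter-domain derivative valley
        assert domains[0].domain_end == domains[1].domain_start
        assert 77.0 < domains[0].domain_end < 83.0

    def test_sub_threshold_shoulder_excluded(self):
        # a minor transition whose derivative peak is ~5% of the main one
        spec = SimulationSpec(
            transitions=(
                TransitionSpec(tm=80.0, slope=1.0, weight=1 / 1.05),
                TransitionSpec(tm=88.0, slope=1.0, weight=0.05 / 1.05),
            ),
            noise_sd=0.0,
        )
        domains = scan_domains(simulate_melt_curve(spec))
        assert [round(d.peak_temp) for d in domains] == [80]
        assert all(d.peak_height_rel >= 0.10 for d in domains)

    def test_matches_brute_force_oracle_on_random_curves(self):
        cfg = SmoothingConfig()
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(1, 5))
            tms = np.sort(rng.uniform(73, 87, n))
            w = rng.uniform(0.5, 1.5, n)
            spec = SimulationSpec(
                transitions=tuple(
                    TransitionSpec(tm=t, slope=float(rng.uniform(0.6, 1.5)),
                                   weight=wi / w.sum())
                    for t, wi in zip(tms, w)
                ),
                noise_sd=float(rng.uniform(0, 10)),
                seed=int(rng.integers(0, 2**31)),
            )
            deriv = smooth_derivatives(simulate_melt_curve(spec), cfg)
            expected = brute_force_candidates(
                deriv.neg_dFdT, cfg.domain_threshold, cfg.peak_prominence
            )
            got = peak_candidates(deriv, cfg).tolist()
            assert got == expected

    def test_count_recovery_across_transition_numbers(self, multi_transition_curve):
        for n in (1, 2, 3, 4):
            tms = [80 - 2.5 * (n - 1) + 5.0 * i for i in range(n)]
            domains = scan_domains(multi_transition_curve(tms))
            assert len(domains) == n

    @given(st.floats(0.11, 0.9), st.floats(0.11, 0.9))
    def test_threshold_monotonicity(self, th1, th2):
        lo, hi = sorted((th1, th2))
        spec = SimulationSpec(
            transitions=(
                TransitionSpec(tm=74.0, weight=0.5),
                TransitionSpec(tm=81.0, weight=0.3),
                TransitionSpec(tm=87.0, weight=0.2),
            ),
            noise_sd=3.0, seed=11,
        )
        deriv = smooth_derivatives(simulate_melt_curve(spec))
        n_lo = len(find_domains(deriv, SmoothingConfig(domain_threshold=lo)))
        n_hi = len(find_domains(deriv, SmoothingConfig(domain_threshold=hi)))
        assert n_hi <= n_lo

    def test_no_domains_returns_empty_with_warning(self, grid):
        # fluorescence *rising* with T: no melting transition at all
        curve = MeltCurve("r", grid, 100.0 + 2.0 * (grid - grid[0]))
        with pytest.raises(ValueError):
            find_domains(smooth_derivatives(curve))
        # shallow transition below threshold relative to a sharp one is
        # exercised above; an all-noise curve warns and returns []
        rng = np.random.default_rng(0)
        noisy = MeltCurve(
            "n", grid, 1000.0 - 0.5 * (grid - grid[0]) + rng.normal(0, 0.01, grid.size)
        )
        with pytest.warns(NoDomainsFound):
            assert find_domains(smooth_derivatives(noisy)) == []


class TestMeltingRegion:
    def test_pad_extends_two_degrees_each_side(self, grid):
        d = MeltDomain(0, 80.0, 1.0, 78.0, 84.0, 76.0, 86.0)
        assert melting_region(d, grid) == (76.0, 86.0)

    def test_region_clipped_to_grid(self):
        grid = 65.0 + 0.04 * np.arange(300)  # 65–76.96
        d = MeltDomain(0, 66.0, 1.0, 65.5, 70.0, 65.0, 72.0)
        lo, hi = melting_region(d, grid)
        assert lo == 65.0
        assert hi == pytest.approx(72.0)

    @given(st.floats(0, 5), st.floats(70, 80), st.floats(0.1, 5))
    def test_region_contains_domain(self, pad, start, width):
        grid = 65.0 + 0.04 * np.arange(751)
        d = MeltDomain(0, start + width / 2, 1.0, start, start + width,
                       start, start + width)
        lo, hi = melting_region(d, grid, SmoothingConfig(region_pad=pad))
        assert lo <= d.domain_start and hi >= d.domain_end


class TestNormalizeDomain:
    def test_baseline_windows_anchor_to_one_and_zero(self):
        curve = simulate_melt_curve(logistic_spec(noise_sd=5.0, seed=3))
        norm = normalize_domain(curve, (65.0, 95.0))
        n_base = max(5, round(0.10 * len(norm.grid)))
        assert np.mean(norm.values[:n_base]) == pytest.approx(1.0, abs=1e-9)
        assert np.mean(norm.values[-n_base:]) == pytest.approx(0.0, abs=1e-9)

    def test_linear_background_absorbed(self):
        flat = simulate_melt_curve(logistic_spec(background=(200.0, 0.0, 0.0)))
        tilted = simulate_melt_curve(logistic_spec(background=(200.0, -3.0, 0.0)))
        region = (65.0, 95.0)
        np.testing.assert_allclose(
            normalize_domain(tilted, region).values,
            normalize_domain(flat, region).values,
            atol=1e-6,
        )

    def test_logistic_midpoint_maps_to_half(self):
        curve = simulate_melt_curve(logistic_spec(tm=80.0))
        norm = normalize_domain(curve, (65.0, 95.0))
        at_tm = norm.values[np.argmin(np.abs(norm.grid - 80.0))]
        assert at_tm == pytest.approx(0.5, abs=0.02)

    def test_idempotent_up_to_affine(self):
        curve = simulate_melt_curve(logistic_spec(noise_sd=2.0, seed=5))
        region = (70.0, 92.0)
        once = normalize_domain(curve, region)
        rescaled = MeltCurve("n", once.grid, 1000.0 * (once.values + 0.1))
        twice = normalize_domain(rescaled, (float(once.grid[0]), float(once.grid[-1])))
        np.testing.assert_allclose(twice.values, once.values, atol=1e-6)

    def test_degenerate_baselines_rejected(self, grid):
        rising = MeltCurve("r", grid, 100.0 + 2.0 * (grid - grid[0]))
        with pytest.raises(DegenerateBaselines):
            normalize_domain(rising, (65.0, 95.0))

    def test_too_short_region_rejected(self):
        curve = simulate_melt_curve(logistic_spec())
        with pytest.raises(ValueError, match="< 20"):
            normalize_domain(curve, (80.0, 80.5))


class TestMeltingTemperature:
    def test_equals_domain_peak(self):
        curve = simulate_melt_curve(logistic_spec(tm=80.0))
        (domain,) = scan_domains(curve)
        assert melting_temperature(domain) == domain.peak_temp
        assert melting_temperature(domain) == pytest.approx(80.0, abs=0.05)

    def test_translation_equivariance(self):
        tm_est = {}
        for tm in (80.0, 81.0):
            (domain,) = scan_domains(simulate_melt_curve(logistic_spec(tm=tm)))
            tm_est[tm] = melting_temperature(domain)
        assert tm_est[81.0] - tm_est[80.0] == pytest.approx(1.0, abs=0.04)

    @pytest.mark.parametrize("slope", [0.5, 1.0, 2.0])
    def test_noise_free_recovery_within_half_grid_step(self, slope):
        (domain,) = scan_domains(simulate_melt_curve(logistic_spec(slope=slope)))
        assert melting_temperature(domain) == pytest.approx(80.0, abs=0.05)

    @pytest.mark.parametrize("slope", [0.5, 1.0, 2.0])
    def test_seed_averaged_recovery_at_one_percent_noise(self, slope):
        ests = []
        for seed in range(100):
            spec = logistic_spec(slope=slope, noise_sd=10.0, seed=seed)
            domains = scan_domains(simulate_melt_curve(spec))
            # at this noise level an occasional spurious minor peak appears;
            # the transition is always the tallest domain
            tallest = max(domains, key=lambda d: d.peak_height_rel)
            ests.append(melting_temperature(tallest))
        assert np.mean(ests) == pytest.approx(80.0, abs=0.1)
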