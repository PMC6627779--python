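import numpy as np
import pytest

from quenchbind import (
    IDFPoint,
    TitrationSeries,
    build_quench_curve,
    idf_extract,
    idf_pipeline,
    scatchard_fit,
    simulate_titration,
    SimConfig,
)
from quenchbind.idf import QuenchCurve, auto_levels


def _point(level, nu, lf):
    return IDFPoint(level, nu, lf, 0.0, 0.0, 2)


class TestQuenchCurve:
    def test_interpolant_reproduces_knots(self, noiseless_sim):
        _, series, _ = noiseless_sim
        curve = build_quench_curve(series[0])
        recon = curve.ligand_total_at(curve.delta_f_knots)
        assert recon == pytest.approx(curve.ligand_knots, rel=1e-12)

    def test_query_between_knots_is_bracketed(self, noiseless_sim):
        _, series, _ = noiseless_sim
        curve = build_quench_curve(series[0])
        mid = 0.5 * (curve.delta_f_knots[3] + curve.delta_f_knots[4])
        val = curve.ligand_total_at(mid)
        assert curve.ligand_knots[3] < val < curve.ligand_knots[4]

    def test_query_outside_range_raises(self, noiseless_sim):
        _, series, _ = noiseless_sim
        curve = build_quench_curve(series[0])
        with pytest.raises(ValueError, match="range"):
            curve.ligand_total_at(curve.delta_f_range[1] + 1.0)

    def test_non_monotone_beyond_tolerance_rejected(self):
        lig = np.arange(6, dtype=float) * 1e-6
        f = np.array([100.0, 90.0, 95.0, 70.0, 60.0, 50.0])  # 5-point ΔF drop
        series = TitrationSeries(4e-6, 288.0, lig, f)
        with pytest.raises(ValueError, match="monotone"):
            build_quench_curve(series)

    def test_small_inversions_merged_within_tolerance(self):
        lig = np.arange(6, dtype=float) * 1e-6
        f = np.array([100.0, 95.0, 95.5, 85.0, 80.0, 75.0])  # 0.5-point dip
        series = TitrationSeries(4e-6, 288.0, lig, f)
        curve = build_quench_curve(series)
        assert np.all(np.diff(curve.delta_f_knots) > 0)


class TestIDFExtract:
    def test_two_curve_hand_case(self):
        """[L]tot = 5 µM at [P] = 2 µM and 8 µM at [P] = 4 µM gives
        slope Σν = 1.5 and intercept [L]free = 2 µM."""
        # straight-line curves through the target points, same ΔF range
        df = np.array([1.0, 10.0, 20.0, 30.0, 40.0])
        c1 = QuenchCurve(2e-6, df, np.linspace(1e-6, 5e-6, 5))
        c2 = QuenchCurve(4e-6, df, np.linspace(2e-6, 8e-6, 5))
        points = idf_extract([c1, c2], levels=[40.0])
        assert len(points) == 1
        assert points[0].sigma_nu == pytest.approx(1.5, rel=1e-9)
        assert points[0].ligand_free == pytest.approx(2e-6, rel=1e-9)

    def test_noiseless_generator_matches_ground_truth(self, noiseless_sim):
        """Extracted (Σν, [L]free) agree with the mass-balance solver truth
        at every level."""
        config, series, truth = noiseless_sim
        curves = [build_quench_curve(s) for s in series]
        points = idf_extract(curves)
        assert len(points) == 10
        from quenchbind import binding_density, solve_free_ligand

        for p in points:
            # invert the transduction: level -> sigma_nu under the generator
            nu_true = p.delta_f_level / 100.0 * config.n_sites_true / config.q_max
            assert p.sigma_nu == pytest.approx(nu_true, rel=0.01)
            lf_true = nu_true / (config.k_b_true * (config.n_sites_true - nu_true))
            assert p.ligand_free == pytest.approx(lf_true, rel=0.01)

    def test_mass_conservation_at_every_curve(self, noiseless_sim):
        _, series, _ = noiseless_sim
        curves = [build_quench_curve(s) for s in series]
        points = idf_extract(curves)
        for p in points:
            for c in curves:
                l_tot = c.ligand_total_at(p.delta_f_level)
                residual = abs(l_tot - p.ligand_free - p.sigma_nu * c.protein_conc)
                assert residual / l_tot < 1e-3

    def test_identical_protein_concentrations_rejected(self, noiseless_sim):
        _, series, _ = noiseless_sim
        c = build_quench_curve(series[0])
        with pytest.raises(ValueError, match="distinct"):
            idf_extract([c, c])

    def test_single_curve_rejected(self, noiseless_sim):
        _, series, _ = noiseless_sim
        with pytest.raises(ValueError, match="2"):
            idf_extract([build_quench_curve(series[0])])

    def test_sigma_nu_monotone_in_level(self, noiseless_sim):
        _, series, _ = noiseless_sim
        curves = [build_quench_curve(s) for s in series]
        points = idf_extract(curves)
        nus = [p.sigma_nu for p in points]
        assert np.all(np.diff(nus) > 0)


class TestScatchard:
    def test_hand_regression_on_exact_line(self):
        """Points on the line y = n*Kb - Kb*x with Kb=1e5, n=2."""
        pts = [
            _point(10.0, 1.0, 1.0 / 1e5),  # y = 1e5
            _point(20.0, 1.5, 1.5 / 5e4),  # y = 5e4
            _point(30.0, 1.25, 1.25 / 7.5e4),  # y = 7.5e4
        ]
        fit = scatchard_fit(pts)
        assert fit.k_b == pytest.approx(1e5, rel=1e-9)
        assert fit.n_sites == pytest.approx(2.0, rel=1e-9)
        assert fit.cooperativity_flag.value == "non_cooperative_linear"

    def test_constant_binding_density_rejected(self):
        pts = [_point(10.0 * i, 1.0, 1e-6 * i) for i in range(1, 5)]
        with pytest.raises(ValueError, match="degenerate"):
            scatchard_fit(pts)

    def test_positive_slope_rejected(self):
        pts = [_point(10.0, 1.0, 1e-5), _point(20.0, 2.0, 1e-5), _point(30.0, 3.0, 1e-6)]
        with pytest.raises(ValueError, match="saturable"):
            scatchard_fit(pts)


class TestFullPipeline:
    def test_noiseless_recovery_of_generating_parameters(self, noiseless_sim):
        """Simulate → curves → IDF → Scatchard recovers n=3, Kb=7e4."""
        config, series, _ = noiseless_sim
        _, fit = idf_pipeline(series)
        assert fit.k_b == pytest.approx(config.k_b_true, rel=0.02)
        assert fit.n_sites == pytest.approx(config.n_sites_true, abs=0.05)
        assert fit.cooperativity_flag.value == "non_cooperative_linear"

    def test_noisy_recovery_median_over_seeds(self):
        """1% multiplicative intensity noise, 25 seeds: medians stay near
        truth (a lighter version of the 100-seed recovery study)."""
        kbs, ns = [], []
        for seed in range(25):
            series, _ = simulate_titration(SimConfig(noise_rel=0.01, seed=seed))
            try:
                _, fit = idf_pipeline(series)
            except ValueError:
                continue
            kbs.append(fit.k_b)
            ns.append(fit.n_sites)
        assert len(kbs) >= 20
        assert np.median(kbs) == pytest.approx(7e4, rel=0.15)
        assert abs(np.median(ns) - 3.0) < 0.5

    def test_auto_levels_span_common_range(self, noiseless_sim):
        _, series, _ = noiseless_sim
        curves = [build_quench_curve(s) for s in series]
        levels = auto_levels(curves)
        lo = max(c.delta_f_range[0] for c in curves)
        hi = min(c.delta_f_range[1] for c in curves)
        assert levels[0] > lo and levels[-1] < hi
        assert len(levels) == 10
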