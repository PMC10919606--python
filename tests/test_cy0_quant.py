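"""Richards fitting, Cy0 geometry, standard curves and quantification."""

import numpy as np
import pytest
from scipy import optimize

from dsrbqpcr.cy0_quant import (
    RichardsFit,
    build_standard_curve,
    compute_cy0,
    copies_from_mass,
    fit_richards,
    quantify_sample,
    richards,
    standard_curve_from_series,
)
from dsrbqpcr.qpcr_synth import AmplificationCurve, ReactionSpec, simulate_dilution_series, simulate_reaction


def sigfig(x, n=3):
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (n - 1))


class TestMassToCopies:
    def test_standard_series_endpoints(self):
        assert sigfig(copies_from_mass(0.1, 390)) == pytest.approx(2.34e8)
        assert sigfig(copies_from_mass(1e-7, 390)) == pytest.approx(2.34e2)

    def test_inverse_proportional_to_length(self):
        assert copies_from_mass(1.0, 780) == pytest.approx(copies_from_mass(1.0, 390) / 2)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            copies_from_mass(1.0, 0)


class TestCy0Geometry:
    def test_logistic_closed_form(self):
        # d = 1: inflection at c, tangent intercept c - 2b
        assert compute_cy0((2.0, 20.0, 1.0)) == pytest.approx(16.0)

    def numeric_tangent_intercept(self, b, c, d):
        """Independent oracle: locate the inflection by maximizing the
        numerical derivative of the plotted curve, then drop the tangent."""
        f = lambda x: richards(x, 0.0, 1.0, b, c, d)
        h = 1e-5
        df = lambda x: (f(x + h) - f(x - h)) / (2 * h)
        res = optimize.minimize_scalar(
            lambda x: -df(x), bounds=(c - 20 * b, c + 20 * b), method="bounded",
            options={"xatol": 1e-10},
        )
        x_star = res.x
        return x_star - f(x_star) / df(x_star)

    @pytest.mark.parametrize("b", [0.5, 1.0, 2.0, 4.0])
    @pytest.mark.parametrize("d", [0.2, 0.5, 1.0, 2.0, 5.0])
    def test_matches_numeric_tangent_oracle(self, b, d):
        c = 20.0
        assert compute_cy0((b, c, d)) == pytest.approx(
            self.numeric_tangent_intercept(b, c, d), abs=1e-6
        )

    def test_invariant_under_amplitude_scaling(self):
        fit = RichardsFit(fb=50.0, fmax=3000.0, b=1.5, c=22.0, d=0.8, rss=0.0, converged=True)
        scaled = RichardsFit(fb=50.0, fmax=9000.0, b=1.5, c=22.0, d=0.8, rss=0.0, converged=True)
        assert compute_cy0(fit) == compute_cy0(scaled)

    def test_translation_equivariance(self):
        base = compute_cy0((1.5, 20.0, 0.7))
        assert compute_cy0((1.5, 23.5, 0.7)) == pytest.approx(base + 3.5)

    def test_nonpositive_shape_rejected(self):
        with pytest.raises(ValueError):
            compute_cy0((1.0, 20.0, 0.0))


class TestRichardsFit:
    def test_recovers_exact_parameters_noiseless(self):
        truth = dict(fb=100.0, fmax=3000.0, b=1.5, c=22.0, d=0.8)
        x = np.arange(1, 41)
        curve = AmplificationCurve(x, richards(x, **truth))
        fit = fit_richards(curve)
        assert fit.converged
        for key, val in truth.items():
            assert getattr(fit, key) == pytest.approx(val, rel=1e-4)
        assert fit.cy0 == pytest.approx(compute_cy0((truth["b"], truth["c"], truth["d"])), abs=1e-4)

    def test_flat_curve_yields_no_fit(self):
        rng = np.random.default_rng(0)
        x = np.arange(1, 36)
        curve = AmplificationCurve(x, 100.0 + rng.normal(0, 1.0, size=35))
        fit = fit_richards(curve)
        assert not fit.converged
        assert np.isnan(fit.cy0)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            fit_richards(AmplificationCurve(np.arange(1, 6), np.zeros(5)))

    def test_fit_quality_on_simulated_reactions(self):
        spec = ReactionSpec(
            template_copies={"x": 1e5}, efficiency={"x": 0.95}, seed=4
        )
        curve = simulate_reaction(spec)
        fit = fit_richards(curve)
        assert fit.converged
        assert fit.rss < 0.01 * np.sum((curve.fluorescence - curve.fluorescence.mean()) ** 2)


class TestStandardCurve:
    def test_noiseless_doubling_slope(self):
        # E = 1: a 10-fold dilution shifts Cy0 by log2(10) ~ 3.32 cycles,
        # so the calibration slope is -1/log10(2)
        levels = [2.34e3 * 10**k for k in range(5)]
        curves = simulate_dilution_series(
            levels, replicates=1, efficiency=1.0, seed=0,
            noise_sd=0.0, baseline_drift=0.0, cycles=45,
        )
        cy0s, copies = [], []
        for c in curves:
            fit = fit_richards(c)
            assert fit.converged
            cy0s.append(fit.cy0)
            copies.append(c.metadata["copies_per_ul"])
        spacings = -np.diff(sorted(cy0s, reverse=True))
        assert np.std(spacings) < 0.05
        sc = build_standard_curve(cy0s, copies)
        assert sc.slope == pytest.approx(-1.0 / np.log10(2.0), rel=0.02)

    def test_collinear_points_r_squared_one(self):
        copies = [1e3, 1e4, 1e5, 1e6]
        cy0s = [30.0 - 3.32 * np.log10(c) for c in copies]
        sc = build_standard_curve(cy0s, copies)
        assert sc.r_squared == pytest.approx(1.0)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            build_standard_curve([20.0, 20.1], [1e5, 1e5])

    def test_default_noise_series_r_squared(self, standard_curve):
        assert standard_curve.r_squared > 0.99
        assert standard_curve.slope < 0
        assert standard_curve.detection_limit == pytest.approx(2.34e2)


class TestQuantification:
    def test_round_trip_on_calibration_point(self, standard_curve):
        cy0 = standard_curve.predicted_cy0(2.34e5)
        q = quantify_sample(cy0, standard_curve)
        assert q.estimated_copies_per_ul == pytest.approx(2.34e5)
        assert q.in_calibration_range

    def test_extrapolation_flagged(self, standard_curve):
        hot = standard_curve.predicted_cy0(2.34e8) - 2.0  # earlier than top level
        assert not quantify_sample(hot, standard_curve).in_calibration_range

    def test_invalid_calibration_rejected(self, standard_curve):
        from dataclasses import replace

        bad = replace(standard_curve, slope=0.5)
        with pytest.raises(ValueError):
            quantify_sample(20.0, bad)

    def test_series_requantification_error(self, standard_series, standard_curve):
        """Round trip: quantify the calibration wells through their own
        curve; median |log10 error| stays below 0.05."""
        errors = []
        for c in standard_series:
            fit = fit_richards(c)
            q = quantify_sample(fit.cy0, standard_curve)
            errors.append(
                abs(np.log10(q.estimated_copies_per_ul) - np.log10(c.metadata["copies_per_ul"]))
            )
        assert np.median(errors) < 0.05

    def test_cy0_strictly_decreasing_in_copies(self):
        cy0s = []
        for n0 in (1e3, 1e4, 1e5, 1e6):
            spec = ReactionSpec(
                template_copies={"x": n0}, efficiency={"x": 0.95}, noise_sd=0.0,
            )
            cy0s.append(fit_richards(simulate_reaction(spec)).cy0)
        assert np.all(np.diff(cy0s) < 0)

    def test_replicate_scatter_grows_at_low_template(self):
        """With Poisson sampling of input copies, low-template reactions
        give noisier Cy0 replicates than high-template ones."""
        rng = np.random.default_rng(12)

        def cy0_sd(n0, reps=8):
            vals = []
            for i in range(reps):
                drawn = rng.poisson(n0)
                spec = ReactionSpec(
                    template_copies={"x": float(max(drawn, 1))},
                    efficiency={"x": 0.95},
                    seed=int(rng.integers(2**31)),
                )
                vals.append(fit_richards(simulate_reaction(spec)).cy0)
            return np.std(vals)

        assert cy0_sd(100.0) > cy0_sd(1e6)
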