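"""Design matrix construction, unwrapping, WLS fitting, and B1 recovery."""

import numpy as np
import pytest

from bsmap import (
    BSPulse,
    PhantomSpec,
    build_design_matrix,
    bss_phase_constant,
    estimate_b1_classic,
    estimate_b1_glm,
    generate_ideal,
    temporal_unwrap,
    wls_fit,
    wrap_phase,
)
from bsmap.glm import COLUMN_NAMES, IdentifiabilityError

TE = np.array([2.38, 4.68, 11.42, 13.72, 16.02, 18.32, 20.62, 22.92]) * 1e-3


@pytest.fixture(scope="module")
def design():
    return build_design_matrix(TE, n_pre=2, offset_signs=(1, -1))


class TestDesignMatrix:
    def test_bss_column(self, design):
        expect = [0, 0, 1, 1, 1, 1, 1, 1, 0, 0, -1, -1, -1, -1, -1, -1]
        assert np.array_equal(design.X[:, 0], expect)

    def test_b0_column_is_te(self, design):
        assert np.allclose(design.X[:, 1], np.tile(TE, 2))

    def test_odd_even_offsets_same_sign(self, design):
        assert np.array_equal(design.X[:8, 2], [1, -1, 1, -1, 1, -1, 1, -1])
        assert np.array_equal(design.X[:, 3] + design.X[:, 4], np.ones(16))
        assert np.array_equal(design.X[:8, 5], [0, 0, 1, 1, 1, 1, 1, 1])
        assert np.array_equal(design.X[:8, 5], design.X[8:, 5])

    def test_full_rank(self, design):
        assert np.linalg.matrix_rank(design.X) == 6

    def test_collinear_offsets_rejected(self):
        """Two same-sign stacks make x_bss proportional to x_same_sign."""
        with pytest.raises(IdentifiabilityError, match="bss|same_sign"):
            build_design_matrix(TE, n_pre=2, offset_signs=(1, 1))

    def test_too_few_echoes_rejected(self):
        with pytest.raises(IdentifiabilityError):
            build_design_matrix(TE[:2], n_pre=2)


class TestTemporalUnwrap:
    def test_small_steps_pass_through(self):
        rng = np.random.default_rng(7)
        base = 0.3 * rng.standard_normal((16, 16))
        truth = np.stack([base + 0.4 * k for k in range(6)])[None]
        out = temporal_unwrap(wrap_phase(truth))
        assert np.allclose(out, truth, atol=1e-10)

    def test_large_interecho_ramp_recovered(self):
        """Inter-echo steps reaching 1.9*pi across a smooth 32x32 map.

        Per-voxel unwrapping would alias steps beyond pi; spatially
        unwrapping each difference map recovers the truth up to a single
        global 2*pi*n per echo (harmless: absorbed by the per-offset
        intercept regressors).
        """
        x = np.linspace(0, 1, 32)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        smooth = 0.4 * xx + 0.2 * yy**2
        step = 1.9 * np.pi * xx  # spans 0 .. 1.9*pi, crosses the pi boundary
        truth = np.stack([smooth + k * step for k in range(4)])[None]
        out = temporal_unwrap(wrap_phase(truth))
        d = out - truth
        for k in range(4):
            assert np.ptp(d[0, k]) < 1e-9  # spatially constant residual
            n = d[0, k].flat[0] / (2 * np.pi)
            assert abs(n - round(n)) < 1e-9  # ... and a whole number of turns

    def test_single_voxel_fallback(self):
        truth = np.array([[0.1, 2.0, 3.9, 5.8]])[:, :, None]
        out = temporal_unwrap(wrap_phase(truth))
        assert np.allclose(out, truth, atol=1e-10)


class TestWlsFit:
    def test_exact_recovery(self, design):
        rng = np.random.default_rng(0)
        beta = rng.standard_normal(6)
        Y = design.X @ beta
        fit = wls_fit(Y, design, np.full(16, 0.7))
        assert np.allclose(fit.beta, beta, atol=1e-12)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_weight_scale_invariance(self, design):
        rng = np.random.default_rng(1)
        Y = design.X @ rng.standard_normal(6) + 0.01 * rng.standard_normal(16)
        w = rng.uniform(0.5, 2.0, 16)
        f1 = wls_fit(Y, design, w)
        f2 = wls_fit(Y, design, 10 * w)
        assert np.allclose(f1.beta, f2.beta, atol=1e-12)

    def test_zero_weight_removes_corrupted_echo(self, design):
        rng = np.random.default_rng(2)
        beta = rng.standard_normal(6)
        Y = design.X @ beta
        Y[5] += 3.0  # corrupt one echo
        w = np.ones(16)
        w[5] = 0.0
        fit = wls_fit(Y, design, w)
        assert np.allclose(fit.beta, beta, atol=1e-12)

    def test_rank_deficient_voxel_flagged(self, design):
        w = np.zeros(16)
        w[:5] = 1.0  # five rows cannot identify six coefficients
        fit = wls_fit(np.zeros(16), design, w)
        assert not fit.valid
        assert np.all(np.isnan(fit.beta))

    def test_batched_matches_loop(self, design):
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((5, 16))
        w = rng.uniform(0.1, 1.0, (5, 16))
        batched = wls_fit(Y, design, w).beta
        for v in range(5):
            single = wls_fit(Y[v], design, w[v]).beta
            assert np.allclose(batched[v], single, atol=1e-10)


class TestComponentIsolation:
    """Each nuisance perturbation must move exactly one coefficient."""

    @pytest.fixture()
    def base_fit(self, design):
        rng = np.random.default_rng(4)
        self_beta = rng.standard_normal(6)
        Y = design.X @ self_beta
        return self_beta, Y

    def _refit(self, design, Y):
        return wls_fit(Y, design, np.ones(16)).beta

    @pytest.mark.parametrize(
        "perturb, moved",
        [
            ("b0", 1),
            ("odd_even", 2),
            ("same_sign", 5),
            ("offsets", None),
        ],
    )
    def test_single_coefficient_moves(self, design, base_fit, perturb, moved):
        beta, Y = base_fit
        c = 0.37
        if perturb == "b0":
            Y2 = Y + c * np.tile(TE, 2)
            expect = beta.copy()
            expect[1] += c
        elif perturb == "odd_even":
            Y2 = Y + c * design.X[:, 2]
            expect = beta.copy()
            expect[2] += c
        elif perturb == "same_sign":
            Y2 = Y + c * design.X[:, 5]
            expect = beta.copy()
            expect[5] += c
        else:  # global 2*pi on the first-echo reference of both stacks
            Y2 = Y + 2 * np.pi
            expect = beta.copy()
            expect[3] += 2 * np.pi
            expect[4] += 2 * np.pi
        assert np.allclose(self._refit(design, Y2), expect, atol=1e-10)


class TestEstimateB1:
    def test_noiseless_phantom_exact(self, small_phantom_spec):
        data = generate_ideal(small_phantom_spec)
        maps = estimate_b1_glm(data["phases"], data["magnitudes"],
                               data["te_list"], data["pulse"])
        rel = np.abs(maps["b1p_uT"] - data["truth"]["b1p_uT"]) / data["truth"]["b1p_uT"]
        assert np.nanmax(rel) < 1e-6
        assert maps["valid"].all()

    def test_offset_difference_biases_classic_not_glm(self, small_phantom_spec):
        """The interleave-bias mechanism: per-offset initial phases differ."""
        data = generate_ideal(small_phantom_spec)
        maps = estimate_b1_glm(data["phases"], data["magnitudes"],
                               data["te_list"], data["pulse"])
        rel = np.abs(maps["b1p_uT"] - data["truth"]["b1p_uT"]) / data["truth"]["b1p_uT"]
        assert np.nanmax(rel) < 1e-6  # GLM untouched by the offset difference

        k = data["n_pre"]
        classic = estimate_b1_classic(data["phases"][0, k], data["phases"][1, k],
                                      data["pulse"])
        const = bss_phase_constant(data["pulse"].with_offset_sign(1))
        eps = (small_phantom_spec.offset_plus_phase
               - small_phantom_spec.offset_minus_phase) / 2
        phi = data["truth"]["phi_bss"]
        expect = np.sqrt((phi + eps) / const.k_bss)  # closed-form biased value
        assert np.allclose(classic["b1p_uT"], expect, rtol=1e-9)

    def test_offset_coefficients_absorb_initial_phase(self, small_phantom_spec):
        data = generate_ideal(small_phantom_spec)
        maps = estimate_b1_glm(data["phases"], data["magnitudes"],
                               data["te_list"], data["pulse"])
        # per-offset intercepts recover the injected initial phases
        assert np.allclose(maps["beta_offset_plus"],
                           small_phantom_spec.offset_plus_phase, atol=1e-8)
        assert np.allclose(maps["beta_offset_minus"],
                           small_phantom_spec.offset_minus_phase, atol=1e-8)
        assert np.allclose(maps["beta_b0"],
                           2 * np.pi * data["truth"]["df_b0_hz"], atol=1e-6)

    def test_swap_stacks_flips_sign_keeps_b1(self, small_phantom_spec):
        data = generate_ideal(small_phantom_spec)
        ph, mg = data["phases"], data["magnitudes"]
        m1 = estimate_b1_glm(ph, mg, data["te_list"], data["pulse"])
        m2 = estimate_b1_glm(ph[::-1], mg[::-1], data["te_list"], data["pulse"],
                             offset_signs=(-1, 1))
        assert np.allclose(m2["beta_bss"], m1["beta_bss"], atol=1e-9)
        swapped = estimate_b1_glm(ph[::-1], mg[::-1], data["te_list"], data["pulse"])
        assert np.allclose(swapped["beta_bss"], -m1["beta_bss"], atol=1e-9)
        assert np.allclose(np.abs(swapped["beta_bss"]), np.abs(m1["beta_bss"]),
                           atol=1e-9)

    def test_geometry_mismatch_rejected(self, small_phantom_spec):
        data = generate_ideal(small_phantom_spec)
        with pytest.raises(ValueError):
            estimate_b1_glm(data["phases"], data["magnitudes"][:, :, :-1],
                            data["te_list"], data["pulse"])
        with pytest.raises(ValueError):
            estimate_b1_glm(data["phases"][:, :-1], data["magnitudes"][:, :-1],
                            data["te_list"], data["pulse"])


class TestNoisePropagation:
    def test_monte_carlo_sd_matches_analytic(self):
        """Empirical B1 SD over many identical voxels vs the WLS covariance.

        Complex noise sigma is set for SNR 50 at the first echo; phase
        noise per echo is then sigma/magnitude, and the B1 variance
        follows from the weighted-least-squares covariance through the
        delta method on B1 = sqrt(phi/k).
        """
        from bsmap import TissueClass

        tissue = TissueClass("gel", 0.55, 0.07)
        snr = 50.0
        mag1 = np.exp(-2.38e-3 / tissue.t2)
        spec = PhantomSpec(shape=(20, 20, 10), noise_sigma=mag1 / snr, seed=11,
                           efficiency_range=(1.0, 1.0), df_b0_amp=0.0,
                           tissues=(tissue,))
        data = generate_ideal(spec)
        maps = estimate_b1_glm(data["phases"], data["magnitudes"],
                               data["te_list"], data["pulse"],
                               mask=np.ones(spec.shape, bool))
        b1 = maps["b1p_uT"][np.isfinite(maps["b1p_uT"])]
        sd_emp = b1.std(ddof=1)

        # analytic: Cov(beta) = (X'WX)^-1 X'W S W X (X'WX)^-1
        design = build_design_matrix(data["te_list"])
        te = data["te_list"]
        mags = np.exp(-np.tile(te, 2) / tissue.t2)
        W = np.diag(mags)
        S = np.diag((spec.noise_sigma / mags) ** 2)
        A = np.linalg.inv(design.X.T @ W @ design.X)
        cov = A @ design.X.T @ W @ S @ W @ design.X @ A
        const = bss_phase_constant(data["pulse"].with_offset_sign(1))
        phi = const.k_bss * data["truth"]["b1p_uT"].ravel()[0] ** 2
        sd_ana = np.sqrt(cov[0, 0]) / (2 * np.sqrt(const.k_bss * phi))
        assert sd_emp == pytest.approx(sd_ana, rel=0.10)
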