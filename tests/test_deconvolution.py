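import numpy as np
import pytest
from scipy.integrate import quad

from cogwear.arousal import ImpulseSeries
from cogwear.deconvolution import (
    PhasicKernelParams,
    SkinConductanceTrace,
    TonicBasis,
    build_design_matrices,
    deconvolve_block,
    deconvolve_recording,
    impulses_to_marked_series,
    phasic_kernel,
    read_eda_csv,
    separate_tonic_phasic,
)
from cogwear.synthetic import synthesize_scr_trace

from conftest import detection_f1, make_scr_trace, make_sparse_impulses

KERNEL = PhasicKernelParams(tau_r=0.75, tau_d=2.0)


class TestPhasicKernel:
    def test_zero_at_origin_and_infinity(self):
        assert phasic_kernel(KERNEL, 0.0) == 0.0
        assert phasic_kernel(KERNEL, 1e4) == pytest.approx(0.0, abs=1e-12)
        assert phasic_kernel(KERNEL, -1.0) == 0.0

    def test_nonnegative(self):
        t = np.linspace(-2, 30, 500)
        assert np.all(phasic_kernel(KERNEL, t) >= 0)

    def test_peak_location_matches_dense_grid(self):
        t = np.linspace(0, 10, 200001)
        grid_argmax = t[np.argmax(phasic_kernel(KERNEL, t))]
        analytic = 0.75 * 2.0 / (2.0 - 0.75) * np.log(2.0 / 0.75)
        assert analytic == pytest.approx(1.177, abs=1e-3)
        assert grid_argmax == pytest.approx(analytic, abs=1e-4)
        assert KERNEL.peak_time == pytest.approx(analytic, abs=1e-12)

    def test_unit_mass(self):
        mass, _ = quad(lambda t: phasic_kernel(KERNEL, t), 0, 200)
        assert mass == pytest.approx(1.0, abs=1e-4)

    def test_degenerate_timing_rejected(self):
        with pytest.raises(ValueError):
            PhasicKernelParams(tau_r=2.0, tau_d=2.0)
        with pytest.raises(ValueError):
            PhasicKernelParams(tau_r=3.0, tau_d=2.0)


class TestDesignMatrices:
    def test_causality(self):
        H0, H1, _ = build_design_matrices(KERNEL, 0.25, 0.25, 80, 80)
        t_samp = (np.arange(80) + 1) * 0.25
        t_imp = np.arange(80) * 0.25
        future = t_samp[:, None] < t_imp[None, :]
        assert np.all(H1[future] == 0)

    def test_column_is_shifted_kernel(self):
        H0, H1, _ = build_design_matrices(KERNEL, 0.25, 0.25, 80, 80)
        i = 10  # impulse at t = 2.5 s
        t_samp = (np.arange(80) + 1) * 0.25
        expected = phasic_kernel(KERNEL, t_samp - 10 * 0.25)
        assert np.allclose(H1[:, i], expected)

    def test_initial_condition_decay(self):
        H0, _, _ = build_design_matrices(KERNEL, 0.25, 0.25, 40, 40)
        t_samp = (np.arange(40) + 1) * 0.25
        assert np.allclose(H0, np.exp(-t_samp / KERNEL.tau_d))

    def test_spline_partition_of_unity(self):
        _, _, H2 = build_design_matrices(
            KERNEL, 0.25, 0.25, 400, 400, TonicBasis(knot_spacing=10.0)
        )
        assert np.allclose(H2.sum(axis=1), 1.0, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_design_matrices(KERNEL, 0.25, 0.25, 100, 50)


class TestForwardModelConsistency:
    def test_noiseless_trace_equals_design_product(self):
        impulses, _, _ = make_sparse_impulses(0, n_steps=400)
        basis = TonicBasis()
        q_level = 1.3
        trace = synthesize_scr_trace(
            impulses, KERNEL, tonic_coeffs=q_level, y_p0=0.4, noise_sd=0.0,
            basis=basis,
        )
        M = len(trace)
        H0, H1, H2 = build_design_matrices(KERNEL, 0.25, 0.25, M, 400, basis)
        u = np.where(impulses.n == 1, np.nan_to_num(impulses.r), 0.0)
        u = np.maximum(u, 0.0)
        expected = H0 * 0.4 + H1 @ u + H2 @ np.full(H2.shape[1], q_level)
        assert np.max(np.abs(trace.y - expected)) < 1e-10

    def test_null_input_gives_zero_trace(self):
        imp = ImpulseSeries(n=np.zeros(80, int), r=np.full(80, np.nan))
        trace = synthesize_scr_trace(imp, KERNEL, tonic_coeffs=0.0,
                                     y_p0=0.0, noise_sd=0.0)
        assert np.allclose(trace.y, 0.0)


class TestBlockDeconvolution:
    def test_noiseless_impulse_recovery(self):
        """Five well-separated impulses recovered at the exact grid points
        with amplitudes within 10%."""
        n = np.zeros(800, int)
        r = np.full(800, np.nan)
        locs = [80, 200, 360, 500, 680]
        amps = [0.3, 0.15, 0.5, 0.2, 0.4]
        for loc, a in zip(locs, amps):
            n[loc] = 1
            r[loc] = a
        imp = ImpulseSeries(n=n, r=r, t_grid=0.25)
        trace = synthesize_scr_trace(imp, KERNEL, tonic_coeffs=1.5,
                                     y_p0=0.2, noise_sd=0.0)
        res = deconvolve_block(trace)
        detected = np.flatnonzero(res.u > 0.01)
        assert detection_f1(list(detected), locs, tol_steps=1) == 1.0
        for loc, a in zip(locs, amps):
            window = res.u[loc - 1 : loc + 2].sum()
            assert window == pytest.approx(a, rel=0.10)

    def test_flat_input_yields_tonic_only_fit(self):
        imp = ImpulseSeries(n=np.zeros(800, int), r=np.full(800, np.nan))
        trace = synthesize_scr_trace(imp, KERNEL, tonic_coeffs=1.5,
                                     y_p0=0.0, noise_sd=0.005, seed=4)
        res = deconvolve_block(trace)
        assert np.count_nonzero(res.u > 0.01) == 0

    def test_selection_score_non_increasing_over_sweeps(self):
        trace, *_ = make_scr_trace(3)
        res = deconvolve_block(trace)
        assert np.all(np.diff(res.objective_history) <= 1e-12)

    def test_reconstruction_identity(self):
        trace, *_ = make_scr_trace(4)
        res = deconvolve_block(trace)
        phasic, tonic = separate_tonic_phasic(res)
        # components reproduce the design-matrix forward model exactly
        from cogwear.deconvolution import build_design_matrices

        H0, H1, H2 = build_design_matrices(
            res.kernel, trace.t_y, res.t_u, len(trace), res.u.size
        )
        assert np.max(np.abs(phasic - (H0 * res.y_p0 + H1 @ res.u))) < 1e-10
        assert np.max(np.abs(tonic - H2 @ res.q)) < 1e-10
        resid = trace.y - phasic - tonic
        assert np.sqrt(np.mean(resid**2)) == pytest.approx(
            res.residual_rms, abs=1e-12
        )

    def test_tonic_matches_generating_spline(self):
        impulses, _, _ = make_sparse_impulses(5, n_steps=800)
        trace = synthesize_scr_trace(impulses, KERNEL, tonic_coeffs=1.5,
                                     y_p0=0.0, noise_sd=0.0)
        res = deconvolve_block(trace)
        _, tonic = separate_tonic_phasic(res)
        # interior only: spline edges trade off against the phasic tail
        sl = slice(40, 760)
        assert np.max(np.abs(tonic[sl] - 1.5)) < max(10 * res.residual_rms,
                                                     0.05)


class TestRecordingDeconvolution:
    def test_tiling_claims_every_grid_point_once(self):
        trace, *_ = make_scr_trace(6, n_steps=1600)  # 400 s
        res = deconvolve_recording(trace)
        assert res.u.size == 1600
        assert len(res.blocks) == 3
        assert res.phasic.size == len(trace)

    def test_short_recording_falls_back_to_single_block(self):
        trace, *_ = make_scr_trace(7, n_steps=400)  # 100 s < one block
        res = deconvolve_recording(trace)
        assert res.blocks is None
        assert res.u.size == 400

    def test_block_and_whole_trace_agree_away_from_margins(self):
        trace, locs, _, _ = make_scr_trace(8, n_steps=1200)  # 300 s
        blockwise = deconvolve_recording(trace)
        whole = deconvolve_block(trace)
        det_b = np.flatnonzero(blockwise.u > 0.02)
        det_w = np.flatnonzero(whole.u > 0.02)
        assert detection_f1(list(det_b), list(det_w), tol_steps=1) >= 0.8


class TestMarkedSeries:
    def test_thresholding(self):
        res_u = np.array([0.0, 0.2, 0.0])
        from cogwear.deconvolution import DeconvolutionResult

        res = DeconvolutionResult(
            u=res_u, q=np.zeros(3), y_p0=0.0, kernel=KERNEL, t_u=0.25,
            gcv=0.0, residual_rms=0.0, lam=0.0, phasic=np.zeros(3),
            tonic=np.zeros(3), y=np.zeros(3),
        )
        series = impulses_to_marked_series(res, threshold=0.0)
        assert list(series.n) == [0, 1, 0]
        assert series.r[1] == 0.2
        empty = impulses_to_marked_series(res, threshold=0.5)
        assert empty.n.sum() == 0

    def test_count_monotone_in_threshold(self):
        from cogwear.deconvolution import DeconvolutionResult

        rng = np.random.default_rng(0)
        u = np.abs(rng.normal(0, 0.1, 50))
        res = DeconvolutionResult(
            u=u, q=np.zeros(3), y_p0=0.0, kernel=KERNEL, t_u=0.25,
            gcv=0.0, residual_rms=0.0, lam=0.0, phasic=np.zeros(50),
            tonic=np.zeros(50), y=np.zeros(50),
        )
        counts = [
            impulses_to_marked_series(res, threshold=th).n.sum()
            for th in np.linspace(0, 0.3, 10)
        ]
        assert np.all(np.diff(counts) <= 0)


class TestEdaIO:
    def test_round_trip(self, tmp_path):
        trace = SkinConductanceTrace(
            y=np.linspace(1.0, 2.0, 40), t_y=0.25, start_time=1e9
        )
        path = tmp_path / "EDA.csv"
        with open(path, "w") as fh:
            fh.write(f"{trace.start_time}\n4\n")
            np.savetxt(fh, trace.y)
        back = read_eda_csv(path)
        assert back.t_y == 0.25
        assert back.start_time == 1e9
        assert np.allclose(back.y, trace.y)

    def test_malformed_rate_rejected(self, tmp_path):
        path = tmp_path / "EDA.csv"
        path.write_text("1e9\n0\n1.0\n1.1\n")
        with pytest.raises(ValueError, match="EDA"):
            read_eda_csv(path)
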