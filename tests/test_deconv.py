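"""SVD deconvolution: operators, residue recovery, perfusion parameters."""

import numpy as np
import pytest

from dscpipe import (
    ConcentrationSeries,
    DeconvolutionError,
    ResidueCurve,
    TerritoryTruth,
    build_convolution_matrix,
    compute_maps,
    gamma_variate_aif,
    perfusion_parameters,
    simulate_tissue_curve,
    svd_deconvolve,
)


def experiment_aif(dt, duration, t0=5.0):
    return gamma_variate_aif(np.arange(int(round(duration / dt))) * dt, t0=t0, amplitude=1.0)


class TestConvolutionMatrix:
    def test_unit_impulse_aif_gives_identity(self):
        aif = np.zeros(8)
        aif[0] = 1.0
        system = build_convolution_matrix(aif, dt=1.0, mode="simple")
        np.testing.assert_array_equal(system.matrix, np.eye(8))
        curve = np.arange(8.0)
        np.testing.assert_allclose(svd_deconvolve(system, curve).values, curve, atol=1e-12)

    def test_simple_matrix_equals_direct_convolution_sum(self, rng):
        # oracle: explicit double loop over the discretized convolution
        for _ in range(20):
            n = int(rng.integers(4, 25))
            dt = float(rng.uniform(0.2, 2.0))
            aif = rng.uniform(0, 1, n)
            x = rng.normal(0, 1, n)
            direct = np.array(
                [dt * sum(aif[i - j] * x[j] for j in range(i + 1)) for i in range(n)]
            )
            system = build_convolution_matrix(aif, dt, mode="simple")
            np.testing.assert_allclose(system.matrix @ x, direct, rtol=1e-12, atol=1e-12)

    def test_simple_matrix_is_lower_triangular_toeplitz(self):
        aif = np.arange(1.0, 6.0)
        m = build_convolution_matrix(aif, dt=2.0, mode="simple").matrix
        assert np.all(np.triu(m, 1) == 0)
        for i in range(5):
            for j in range(i + 1):
                assert m[i, j] == 2.0 * aif[i - j]

    def test_circulant_column_sums_constant(self, rng):
        aif = rng.uniform(0, 1, 12)
        system = build_convolution_matrix(aif, dt=1.5, mode="circulant")
        assert system.matrix.shape == (24, 24)
        np.testing.assert_allclose(
            system.matrix.sum(axis=0), 1.5 * aif.sum(), rtol=1e-12
        )

    def test_invalid_arguments(self):
        aif = np.ones(10)
        with pytest.raises(ValueError, match="mode"):
            build_convolution_matrix(aif, 1.0, mode="banana")
        with pytest.raises(ValueError, match="pad"):
            build_convolution_matrix(aif, 1.0, mode="circulant", pad_length=5)
        with pytest.raises(ValueError, match="truncation"):
            build_convolution_matrix(aif, 1.0, truncation=1.5)
        with pytest.raises(ValueError):
            build_convolution_matrix(np.ones(1), 1.0)

    def test_zero_aif_is_degenerate(self):
        system = build_convolution_matrix(np.zeros(8), 1.0, mode="simple")
        with pytest.raises(DeconvolutionError):
            svd_deconvolve(system, np.ones(8))


class TestResidueRecovery:
    def test_noise_free_simple_mode_recovers_flow(self):
        # fine sampling isolates deconvolution from discretization bias
        dt = 0.1
        aif = experiment_aif(dt, 60.0)
        truth = TerritoryTruth(label=1, side="left", cbf=60.0, mtt=4.0)
        curve = simulate_tissue_curve(aif, truth, dt)
        system = build_convolution_matrix(aif, dt, mode="simple", truncation=1e-8)
        cbf = perfusion_parameters(svd_deconvolve(system, curve)).cbf
        assert cbf == pytest.approx(60.0, rel=0.02)

    def test_circulant_recovers_mtt(self):
        dt = 0.25
        aif = experiment_aif(dt, 120.0)
        truth = TerritoryTruth(label=1, side="left", cbf=60.0, mtt=4.0)
        curve = simulate_tissue_curve(aif, truth, dt)
        system = build_convolution_matrix(aif, dt, mode="circulant", truncation=1e-5)
        p = perfusion_parameters(svd_deconvolve(system, curve))
        assert p.mtt == pytest.approx(4.0, rel=0.05)

    def test_delayed_curve_circulant_accurate_simple_low(self):
        # tissue lagging the AIF by 3 frames: the block-circulant operator
        # stays near truth while the causal operator underestimates
        dt, delay = 0.25, 3
        aif = experiment_aif(dt, 90.0)
        n = aif.size
        truth = TerritoryTruth(label=1, side="left", cbf=60.0, mtt=4.0)
        base = simulate_tissue_curve(aif, truth, dt)
        curve = np.concatenate([np.zeros(delay), base[: n - delay]])
        circ = perfusion_parameters(
            svd_deconvolve(
                build_convolution_matrix(aif, dt, "circulant", truncation=1e-4), curve
            )
        ).cbf
        simple = perfusion_parameters(
            svd_deconvolve(
                build_convolution_matrix(aif, dt, "simple", truncation=1e-4), curve
            )
        ).cbf
        assert circ == pytest.approx(60.0, rel=0.05)
        assert simple < circ

    def test_incompatible_curve_length_rejected(self):
        system = build_convolution_matrix(np.ones(10), 1.0, mode="circulant")
        with pytest.raises(ValueError, match="length"):
            svd_deconvolve(system, np.ones(15))


class TestPerfusionParameters:
    def test_geometric_residue(self):
        values = 2.0 * 0.5 ** np.arange(40)
        p = perfusion_parameters(ResidueCurve(values=values, dt=1.0))
        assert p.cbf == 2.0
        assert p.cbv == pytest.approx(4.0, rel=1e-9)
        assert p.mtt == pytest.approx(2.0, rel=1e-9)
        assert not p.flagged

    def test_zero_residue_flagged(self):
        p = perfusion_parameters(ResidueCurve(values=np.zeros(20), dt=1.0))
        assert p == (0.0, 0.0, 0.0, True)

    def test_negative_excursions_zeroed_for_area_only(self):
        values = np.array([2.0, -1.0, 1.0, 0.0])
        p = perfusion_parameters(ResidueCurve(values=values, dt=1.0))
        assert p.cbf == 2.0
        assert p.cbv == pytest.approx(3.0 / 2.0 * 2.0)  # area 3, identity re-applied

    def test_central_volume_identity_bit_exact(self, rng):
        for _ in range(50):
            values = rng.normal(0, 1, 30)
            p = perfusion_parameters(ResidueCurve(values=values, dt=1.5))
            if p.cbf > 0:
                assert p.mtt * p.cbf == p.cbv


class TestComputeMaps:
    def test_uniform_phantom_gives_constant_map(self):
        dt = 1.5
        aif = gamma_variate_aif(np.arange(40) * dt, t0=12.0, amplitude=1.0)
        truth = TerritoryTruth(label=1, side="left", cbf=50.0, mtt=4.0)
        curve = simulate_tissue_curve(aif, truth, dt)
        data = np.tile(curve, (4, 4, 2, 1))
        conc = ConcentrationSeries(
            data=data, s0=np.full((4, 4, 2), 100.0),
            brain_mask=np.ones((4, 4, 2), bool), dt=dt, te=0.03,
        )
        maps = compute_maps(conc, aif)
        inside = maps.cbf[maps.mask]
        assert inside.max() - inside.min() <= 0.01 * inside.mean()

    def test_two_compartment_flow_ratio_preserved(self):
        dt = 1.5
        aif = gamma_variate_aif(np.arange(50) * dt, t0=12.0, amplitude=1.0)
        hi = simulate_tissue_curve(
            aif, TerritoryTruth(label=1, side="left", cbf=60.0, mtt=4.0), dt
        )
        lo = simulate_tissue_curve(
            aif, TerritoryTruth(label=2, side="right", cbf=30.0, mtt=4.0), dt
        )
        data = np.zeros((4, 2, 1, 50))
        data[:, 0, 0] = hi
        data[:, 1, 0] = lo
        conc = ConcentrationSeries(
            data=data, s0=np.full((4, 2, 1), 100.0),
            brain_mask=np.ones((4, 2, 1), bool), dt=dt, te=0.03,
        )
        maps = compute_maps(conc, aif)
        ratio = maps.cbf[:, 0, 0].mean() / maps.cbf[:, 1, 0].mean()
        assert ratio == pytest.approx(2.0, rel=0.03)

    def test_masked_voxels_are_exact_zero(self, maps):
        for volume in (maps.cbf, maps.cbv, maps.mtt):
            assert np.all(volume[~maps.mask] == 0.0)

    def test_central_volume_identity_every_voxel(self, maps):
        sel = maps.mask & (maps.cbf > 0)
        assert np.array_equal(maps.mtt[sel] * maps.cbf[sel], maps.cbv[sel])

    def test_qc_counts_reported(self, maps):
        assert maps.qc["n_voxels"] == int(maps.mask.sum())
        assert maps.qc["n_flagged"] == int(maps.flagged.sum())
        assert 0.0 <= maps.qc["negative_residue_fraction"] <= 1.0

    def test_frame_count_mismatch_rejected(self, concentration):
        short_aif = np.ones(concentration.n_frames - 5)
        with pytest.raises(ValueError, match="frame"):
            compute_maps(concentration, short_aif)
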