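"""Ground-truth generator: bolus model, tissue curves, phantoms, cohorts."""

import numpy as np
import pandas as pd
import pytest

from dscpipe import (
    AifParams,
    CohortSpec,
    PhantomSpec,
    TerritoryTruth,
    build_phantom_atlas,
    default_territory_truths,
    estimate_baseline,
    gamma_variate_aif,
    signal_to_concentration,
    simulate_cohort,
    simulate_phantom_session,
    simulate_tissue_curve,
)
from dscpipe.synthetic import ARTERY_LABEL


class TestGammaVariateBolus:
    def test_zero_amplitude_gives_zero_curve(self):
        t = np.arange(60) * 1.5
        assert np.array_equal(gamma_variate_aif(t, amplitude=0.0), np.zeros(60))

    def test_zero_before_arrival_nonnegative_single_peak(self):
        t = np.linspace(0, 90, 901)
        curve = gamma_variate_aif(t, t0=10.0, alpha=3.0, beta=1.5, amplitude=5.0)
        assert np.all(curve[t <= 10.0] == 0)
        assert np.all(curve >= 0)
        peak = np.argmax(curve)
        assert np.all(np.diff(curve[: peak + 1]) >= 0)
        assert np.all(np.diff(curve[peak:]) <= 0)

    def test_peak_at_t0_plus_alpha_beta(self):
        # analytic mode at t0 + alpha*beta = 14.5 s, confirmed on a dense grid
        t_dense = np.linspace(0, 60, 60001)
        dense = gamma_variate_aif(t_dense, t0=10.0, alpha=3.0, beta=1.5, amplitude=1.0)
        assert t_dense[np.argmax(dense)] == pytest.approx(14.5, abs=2e-3)
        t = np.arange(40) * 1.5
        sampled = gamma_variate_aif(t, t0=10.0, alpha=3.0, beta=1.5, amplitude=1.0)
        assert t[np.argmax(sampled)] == t[np.argmin(np.abs(t - 14.5))]

    def test_amplitude_linearity(self):
        t = np.arange(50) * 1.2
        one = gamma_variate_aif(t, amplitude=3.0)
        two = gamma_variate_aif(t, amplitude=6.0)
        np.testing.assert_allclose(two, 2.0 * one, rtol=0, atol=0)

    @pytest.mark.parametrize("bad", [{"alpha": 0.0}, {"alpha": -1.0}, {"beta": 0.0}, {"t0": -1.0}])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            gamma_variate_aif(np.arange(30.0), **bad)


class TestTissueCurve:
    dt = 1.5

    def _aif(self, n=60, dt=1.5):
        return gamma_variate_aif(np.arange(n) * dt, t0=12.0, amplitude=1.0)

    def test_zero_flow_gives_zero_curve(self):
        truth = TerritoryTruth(label=1, side="left", cbf=0.0, mtt=4.0)
        assert np.array_equal(
            simulate_tissue_curve(self._aif(), truth, self.dt), np.zeros(60)
        )

    def test_impulse_residue_limit(self):
        # mtt << dt: convolution collapses to F * MTT * AIF pointwise
        aif = self._aif()
        truth = TerritoryTruth(label=1, side="left", cbf=50.0, mtt=self.dt / 1000)
        curve = simulate_tissue_curve(aif, truth, self.dt)
        np.testing.assert_allclose(curve, truth.cbf * truth.mtt * aif, rtol=1e-2)

    @pytest.mark.parametrize("mtt", [2.0, 4.0, 8.0])
    def test_area_identity_is_cbv(self, mtt):
        # integral of both sides: area(C) / area(AIF) = F * MTT = CBV,
        # for a window long enough to capture the bolus and residue tail
        dt = 0.25
        aif = gamma_variate_aif(np.arange(int(240 / dt)) * dt, t0=10.0, amplitude=1.0)
        truth = TerritoryTruth(label=1, side="left", cbf=30.0, mtt=mtt)
        curve = simulate_tissue_curve(aif, truth, dt)
        ratio = curve.sum() / aif.sum()
        assert ratio == pytest.approx(truth.cbv, rel=1e-6)

    def test_flow_linearity(self):
        aif = self._aif()
        low = simulate_tissue_curve(
            aif, TerritoryTruth(label=1, side="left", cbf=20.0, mtt=4.0), self.dt
        )
        high = simulate_tissue_curve(
            aif, TerritoryTruth(label=1, side="left", cbf=60.0, mtt=4.0), self.dt
        )
        np.testing.assert_allclose(high, 3.0 * low, rtol=1e-12)

    def test_delay_shifts_curve_later(self):
        aif = self._aif()
        t0 = simulate_tissue_curve(
            aif, TerritoryTruth(label=1, side="left", cbf=60.0, mtt=4.0), self.dt
        )
        t3 = simulate_tissue_curve(
            aif, TerritoryTruth(label=1, side="left", cbf=60.0, mtt=4.0, delay=3 * self.dt),
            self.dt,
        )
        np.testing.assert_allclose(t3[3:], t0[:-3], rtol=1e-9)

    def test_invalid_inputs_rejected(self):
        truth = TerritoryTruth(label=1, side="left", cbf=60.0, mtt=4.0)
        with pytest.raises(ValueError):
            simulate_tissue_curve(np.ones((4, 4)), truth, self.dt)
        with pytest.raises(ValueError):
            simulate_tissue_curve(self._aif(), truth, 0.0)
        with pytest.raises(ValueError):
            TerritoryTruth(label=1, side="left", cbf=-1.0, mtt=4.0)
        with pytest.raises(ValueError):
            TerritoryTruth(label=1, side="left", cbf=60.0, mtt=0.0)


class TestPhantomSession:
    def test_zero_concentration_gives_constant_baseline(self, atlas, truths):
        phantom = PhantomSpec(noise_sd=0.0)
        series, _ = simulate_phantom_session(
            phantom, atlas, truths, aif_params=AifParams(amplitude=0.0)
        )
        inside = atlas.labels > 0
        assert np.all(series.data[inside] == phantom.s0)

    def test_noise_free_concentration_roundtrip(self, phantom, atlas, truths, session, concentration):
        # inverting the signal equation recovers the simulated concentration
        series, _ = session
        t = phantom.times
        aif_true = gamma_variate_aif(t)
        artery = atlas.labels == ARTERY_LABEL
        np.testing.assert_allclose(
            concentration.data[artery], np.tile(aif_true, (artery.sum(), 1)),
            atol=1e-10 * aif_true.max(),
        )
        label = atlas.label_for("MCA-terminal", "left")
        expected = simulate_tissue_curve(aif_true, truths[label], phantom.dt)
        got = concentration.data[atlas.labels == label]
        np.testing.assert_allclose(got, np.tile(expected, (got.shape[0], 1)), atol=1e-10)

    def test_fixed_seed_is_bit_identical(self, atlas, truths):
        phantom = PhantomSpec(noise_sd=0.5, seed=17)
        a, _ = simulate_phantom_session(phantom, atlas, truths)
        b, _ = simulate_phantom_session(phantom, atlas, truths)
        assert np.array_equal(a.data, b.data)
        c, _ = simulate_phantom_session(
            PhantomSpec(noise_sd=0.5, seed=18), atlas, truths
        )
        assert not np.array_equal(a.data, c.data)

    def test_sidecar_central_volume_identity(self, session, atlas):
        _, sidecar = session
        for truth in sidecar.truths.values():
            assert truth.cbv == truth.cbf * truth.mtt
        maps = sidecar.truth_maps(atlas)
        sel = maps["cbf"] > 0
        assert np.array_equal(maps["cbv"][sel], (maps["cbf"] * maps["mtt"])[sel])

    def test_grid_mismatch_and_missing_truth_rejected(self, atlas, truths):
        with pytest.raises(ValueError, match="grid"):
            simulate_phantom_session(PhantomSpec(grid_shape=(16, 16, 6)), atlas, truths)
        incomplete = {k: v for k, v in truths.items() if k != 3}
        with pytest.raises(ValueError, match="missing"):
            simulate_phantom_session(PhantomSpec(), atlas, incomplete)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PhantomSpec(n_frames=10)
        with pytest.raises(ValueError):
            PhantomSpec(dt=0.0)
        with pytest.raises(ValueError):
            PhantomSpec(noise_sd=-1.0)


class TestPhantomAtlas:
    def test_all_territories_bilateral_with_artery(self, atlas):
        names = {name for name, side in atlas.dictionary.values() if side in ("left", "right")}
        assert len(names) == 5
        assert set(np.unique(atlas.labels)) == set(range(12))
        assert (atlas.labels == ARTERY_LABEL).sum() > 0

    def test_hemispheres_have_equal_voxel_counts(self, atlas):
        for name in ("ACA-terminal", "MCA-central", "PCA-terminal"):
            left = (atlas.labels == atlas.label_for(name, "left")).sum()
            right = (atlas.labels == atlas.label_for(name, "right")).sum()
            assert left == right > 0


class TestCohortGenerator:
    def test_null_cohort_pre_equals_intra(self):
        spec = CohortSpec(
            effect_map={"CHS": {}, "non-CHS": {}},
            between_subject_sd=0.0,
            baseline_asymmetry_sd=0.0,
            mtt_jitter_sd=0.0,
        )
        cohort = simulate_cohort(spec)
        for subject in cohort.manifest.subject_id.unique():
            assert cohort.truths[(subject, "pre")] == cohort.truths[(subject, "intra")]

    def test_designed_effect_exact_ratio(self):
        spec = CohortSpec(between_subject_sd=0.0, mtt_jitter_sd=0.0)
        cohort = simulate_cohort(spec)
        meta = cohort.manifest.drop_duplicates("subject_id").set_index("subject_id")
        for subject, row in meta.iterrows():
            factor = 1.143 if row.group == "CHS" else 1.0
            for label, (name, side) in cohort.atlas.dictionary.items():
                if side not in ("left", "right"):
                    continue
                pre = cohort.truths[(subject, "pre")][label]
                intra = cohort.truths[(subject, "intra")][label]
                if side == row.surgical_side and name == "MCA-terminal":
                    assert intra.cbf / pre.cbf == pytest.approx(factor, rel=1e-12)
                else:
                    assert intra.cbf == pre.cbf

    def test_manifest_counts_default_cohort(self):
        cohort = simulate_cohort(CohortSpec(n_chs=5, n_nonchs=9))
        assert cohort.manifest.subject_id.nunique() == 14
        assert len(cohort.manifest) == 28
        counts = cohort.manifest.drop_duplicates("subject_id").group.value_counts()
        assert counts["CHS"] == 5 and counts["non-CHS"] == 9
        assert set(cohort.manifest.session) == {"pre", "intra"}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_chs=0)
        with pytest.raises(ValueError):
            CohortSpec(effect_map={"CHS": {"nowhere": 0.1}})

    def test_determinism_and_seed_sensitivity(self):
        a = simulate_cohort(CohortSpec(seed=5))
        b = simulate_cohort(CohortSpec(seed=5))
        c = simulate_cohort(CohortSpec(seed=6))
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        assert a.truths == b.truths
        assert a.truths != c.truths

    def test_relative_truth_table_contralateral_is_unit_for_null(self):
        spec = CohortSpec(
            effect_map={"CHS": {}, "non-CHS": {}},
            between_subject_sd=0.0,
            baseline_asymmetry_sd=0.0,
            mtt_jitter_sd=0.0,
        )
        table = simulate_cohort(spec).relative_truth_table()
        assert np.allclose(table.relative_cbf, 1.0)
        assert np.allclose(table.relative_mtt, 1.0)

    def test_rendered_session_reflects_subject_truths(self):
        # end-to-end: rendered signal encodes that subject's territory truth
        spec = CohortSpec(n_chs=1, n_nonchs=1, seed=3)
        phantom = PhantomSpec(noise_sd=0.0, grid_shape=(16, 16, 6), n_frames=40)
        cohort = simulate_cohort(spec, phantom)
        subject = cohort.manifest.subject_id.iloc[0]
        series, sidecar = cohort.render_session(subject, "intra")
        s0, mask = estimate_baseline(series)
        conc = signal_to_concentration(series, s0, mask)
        aif_true = gamma_variate_aif(phantom.times)
        label = cohort.atlas.label_for("MCA-terminal", "left")
        expected = simulate_tissue_curve(aif_true, sidecar.truths[label], phantom.dt)
        got = conc.data[cohort.atlas.labels == label]
        np.testing.assert_allclose(got, np.tile(expected, (got.shape[0], 1)), atol=1e-9)
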