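"""Detection chain: background subtraction, candidates, fitting, QC."""

import numpy as np
import pandas as pd
import pytest

from smfish3d import (
    ImageStack, PipelineConfig, add_noise,
    background_subtract, detect_candidates, detect_spots, filter_spots,
    fit_gaussian_3d, mean_single_molecule_intensity, render_spot,
    sigma_ranges_from_config, simulate_field,
)
from conftest import match_to_truth, small_sim_config

VS = (200.0, 65.0, 65.0)
PSF = (350.0, 130.0, 130.0)
CFG = PipelineConfig()


def _stack(voxels):
    return ImageStack(np.asarray(voxels, float), VS, "RNA1")


def _spot_canvas(shape, positions, intensity, noise_bg=None, seed=0,
                 psf=PSF):
    canvas = np.zeros(shape)
    for p in positions:
        render_spot(canvas, p, intensity, psf, VS)
    if noise_bg is not None:
        canvas = add_noise(canvas, noise_bg, 2.0, np.random.default_rng(seed))
    return _stack(canvas)


class TestBackgroundSubtract:
    def test_constant_image_becomes_zero(self):
        out = background_subtract(_stack(np.full((21, 64, 64), 37.0)), config=CFG)
        assert np.allclose(out.voxels, 0.0, atol=1e-6)

    def test_radius_below_psf_rejected(self):
        with pytest.raises(ValueError, match="erode"):
            background_subtract(_stack(np.zeros((21, 64, 64))), ball_radius_nm=200.0)

    def test_spot_intensity_preserved_on_offset(self):
        """An isolated spot keeps its integrated intensity within 5%."""
        stack = _spot_canvas((31, 96, 96), [(15, 48, 48)], 5000.0)
        offset = _stack(stack.voxels + 100.0)
        sub = background_subtract(offset, config=CFG)
        rec = fit_gaussian_3d(sub, (15, 48, 48), config=CFG)
        assert rec.integrated_intensity == pytest.approx(5000.0, rel=0.05)

    def test_gradient_background_removed(self):
        """Residual background mean < 2% of the gradient amplitude."""
        z, y, x = np.mgrid[0:21, 0:64, 0:320].astype(float)
        grad = 50.0 * x / 319.0
        for p in [(10, 32, 80), (10, 32, 240)]:
            render_spot(grad, p, 5000.0, PSF, VS)
        sub = background_subtract(_stack(grad), config=CFG)
        resid = sub.voxels.copy()
        # mask out the spots themselves; the claim is about the background
        resid[:, 20:45, 68:92] = 0.0
        resid[:, 20:45, 228:252] = 0.0
        assert resid.mean() < 0.02 * 50.0


class TestDetectCandidates:
    def test_blank_noisy_fields_are_empty(self):
        """False-positive rate below one candidate per blank field."""
        total = 0
        for seed in range(5):
            cfg = small_sim_config(n_cells=0, seed=200 + seed)
            stacks, _ = simulate_field(cfg)
            sub = background_subtract(stacks["RNA1"], config=CFG)
            total += len(detect_candidates(sub, CFG.psf_sigma_nm,
                                           CFG.log_threshold_k))
        assert total < 5

    def test_well_separated_spots_recovered(self):
        """>= 49 of 50 isolated spots found within 2 voxels at SNR ~ 10."""
        rng = np.random.default_rng(7)
        shape = (31, 256, 256)
        positions = []
        grid = [(z, y, x)
                for z in (8, 22) for y in range(20, 240, 44)
                for x in range(20, 240, 44)]
        rng.shuffle(grid)
        positions = [(z + rng.uniform(-1, 1), y + rng.uniform(-2, 2),
                      x + rng.uniform(-2, 2)) for z, y, x in grid[:50]]
        stack = _spot_canvas(shape, positions, 4200.0, noise_bg=10.0, seed=7)
        sub = background_subtract(stack, config=CFG)
        cand = detect_candidates(sub, CFG.psf_sigma_nm, CFG.log_threshold_k)
        mt, _ = match_to_truth(cand.astype(float), np.array(positions), 2.0)
        assert len(mt) >= 49

    def test_adjacent_maxima_merged(self):
        """Two emitters one voxel apart collapse to a single candidate."""
        stack = _spot_canvas((21, 64, 64), [(10, 32, 32), (10, 32, 33)], 5000.0)
        cand = detect_candidates(stack, CFG.psf_sigma_nm, CFG.log_threshold_k)
        assert len(cand) == 1


class TestFitGaussian3D:
    def test_noiseless_subvoxel_recovery(self):
        """Exact model match: position within 0.05 voxel, sigmas within 2%."""
        true_pos = (15.37, 48.21, 47.64)
        stack = _spot_canvas((31, 96, 96), [true_pos], 5000.0)
        rec = fit_gaussian_3d(stack, (15, 48, 48), config=CFG)
        assert rec.qc_pass
        np.testing.assert_allclose(rec.position_zyx, true_pos, atol=0.05)
        np.testing.assert_allclose(rec.sigma_zyx_nm, PSF, rtol=0.02)
        assert rec.integrated_intensity == pytest.approx(5000.0, rel=0.02)

    def test_window_outside_stack_reports_edge(self):
        stack = _stack(np.zeros((21, 64, 64)))
        rec = fit_gaussian_3d(stack, (1, 2, 2), config=CFG)
        assert not rec.qc_pass and rec.reason == "edge"

    def test_flat_noise_windows_rejected_by_amplitude(self):
        """Fits at random positions of a blank noisy stack fail the
        auto amplitude threshold in >= 99/100 windows."""
        from smfish3d.detect import robust_noise_sd
        rng = np.random.default_rng(3)
        blank = add_noise(np.zeros((31, 192, 192)), 10.0, 2.0,
                          np.random.default_rng(9))
        sub = background_subtract(_stack(blank), config=CFG)
        thr = CFG.amplitude_k * robust_noise_sd(sub.voxels)
        records = []
        for i in range(100):
            seed = (rng.integers(5, 26), rng.integers(8, 184),
                    rng.integers(8, 184))
            records.append(fit_gaussian_3d(sub, seed, spot_id=i, config=CFG))
        table = pd.DataFrame([r.to_row() for r in records])
        table = filter_spots(table, (thr, np.inf),
                             sigma_ranges_from_config(CFG), CFG.residual_max)
        # noise either fits below the amplitude floor or collapses to
        # sub-PSF needles caught by the width band
        assert (~table.qc_pass).sum() >= 99
        assert set(table.loc[~table.qc_pass, "reason"]) <= {"amplitude", "width"}


class TestFilterSpots:
    def _table(self, **overrides):
        row = {
            "spot_id": 0, "channel": "RNA1", "z": 5.0, "y": 5.0, "x": 5.0,
            "z_nm": 1000.0, "y_nm": 325.0, "x_nm": 325.0,
            "amplitude": 40.0, "sigma_z_nm": 350.0, "sigma_y_nm": 130.0,
            "sigma_x_nm": 130.0, "local_background": 1.0,
            "integrated_intensity": 5000.0, "fit_residual": 0.1,
            "qc_pass": True, "reason": "",
        }
        row.update(overrides)
        return pd.DataFrame([row])

    def test_granule_width_rejected(self):
        """A signal 3x the PSF width is rejected with reason 'width'."""
        t = self._table(sigma_y_nm=390.0, sigma_x_nm=390.0)
        out = filter_spots(t, (10.0, np.inf), sigma_ranges_from_config(CFG), 0.5)
        assert not out.qc_pass.iloc[0]
        assert out.reason.iloc[0] == "width"

    def test_idempotent_on_passing_table(self):
        t = self._table()
        args = ((10.0, np.inf), sigma_ranges_from_config(CFG), 0.5)
        once = filter_spots(t, *args)
        twice = filter_spots(once, *args)
        pd.testing.assert_frame_equal(once, twice)
        pd.testing.assert_frame_equal(once, t)

    def test_inverted_ranges_rejected(self):
        with pytest.raises(ValueError):
            filter_spots(self._table(), (10.0, 5.0),
                         sigma_ranges_from_config(CFG), 0.5)

    def test_mixed_spots_and_granules(self):
        """>= 95/100 true spots kept, >= 18/20 wide granules removed."""
        rng = np.random.default_rng(5)
        shape = (31, 256, 256)
        spots = [(rng.uniform(8, 22), rng.uniform(16, 240), rng.uniform(16, 240))
                 for _ in range(100)]
        stack = np.zeros(shape)
        for p in spots:
            render_spot(stack, p, 5000.0, PSF, VS)
        granules = []
        g_psf = tuple(2.0 * s for s in PSF)
        while len(granules) < 20:
            p = (rng.uniform(8, 22), rng.uniform(16, 240), rng.uniform(16, 240))
            if all(np.linalg.norm(np.subtract(p, q)) > 12 for q in spots):
                granules.append(p)
                render_spot(stack, p, 10000.0, g_psf, VS)
        noisy = _stack(add_noise(stack, 10.0, 2.0, np.random.default_rng(8)))
        table = detect_spots(noisy, CFG)
        passed = table[table.qc_pass][["z", "y", "x"]].to_numpy()
        mt_spots, _ = match_to_truth(passed, np.array(spots), 2.0)
        mt_gran, _ = match_to_truth(passed, np.array(granules), 2.0)
        assert len(mt_spots) >= 95
        assert len(mt_gran) <= 2


class TestReferenceIntensity:
    def _spots(self, intensities, compartment="cytoplasmic"):
        return pd.DataFrame({
            "integrated_intensity": intensities,
            "qc_pass": True,
            "compartment": compartment,
        })

    @pytest.mark.parametrize("intensities,expected", [
        ([1.0, 1.0, 1.0], 1.0),
        ([2.0, 4.0, 6.0], 4.0),
    ])
    def test_arithmetic_mean(self, intensities, expected):
        spots = self._spots(intensities * 4)  # clear the min-spot floor
        assert mean_single_molecule_intensity(spots) == pytest.approx(expected)

    def test_fallback_to_all_spots(self, caplog):
        spots = pd.DataFrame({
            "integrated_intensity": [2.0] * 12,
            "qc_pass": True,
            "compartment": ["nuclear"] * 12,
        })
        with caplog.at_level("WARNING", logger="smfish3d"):
            val = mean_single_molecule_intensity(spots)
        assert val == 2.0
        assert any("falling back" in r.message for r in caplog.records)

    def test_zero_usable_spots_is_error(self):
        spots = self._spots([1.0]).assign(qc_pass=False)
        with pytest.raises(ValueError, match="pool"):
            mean_single_molecule_intensity(spots)


class TestDetectionInvariants:
    def test_offset_invariance(self):
        """A constant intensity offset does not change detections."""
        stack = _spot_canvas((31, 96, 96), [(15, 48, 48), (15, 20, 70)], 5000.0)
        t1 = detect_spots(stack, CFG)
        t2 = detect_spots(_stack(stack.voxels + 50.0), CFG)
        assert len(t1) == len(t2)
        np.testing.assert_allclose(
            t1[["z", "y", "x"]].to_numpy(), t2[["z", "y", "x"]].to_numpy(),
            atol=0.05)

    def test_intensity_linearity(self, ):
        """Doubling emitter brightness doubles recovered intensity within 3%."""
        pos = [(15, 30, 30), (15, 30, 66), (15, 66, 30), (15, 66, 66)]
        m = []
        for inten in (4000.0, 8000.0):
            stack = _spot_canvas((31, 96, 96), pos, inten, noise_bg=10.0, seed=4)
            t = detect_spots(stack, CFG)
            m.append(t[t.qc_pass].integrated_intensity.mean())
        assert m[1] / m[0] == pytest.approx(2.0, rel=0.03)

    def test_no_duplicate_spots(self, default_field, pipeline_config):
        stacks, _ = default_field
        t = detect_spots(stacks["RNA1"], pipeline_config)
        passed = t[t.qc_pass][["z", "y", "x"]].to_numpy()
        from scipy.spatial.distance import pdist
        if len(passed) > 1:
            assert pdist(passed).min() >= 1.0
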