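"""Ratio-imaging pipeline: corrections, per-cell ratios, in-situ calibration."""

import numpy as np
import pandas as pd
import pytest

import fretquant as fq
from fretquant.errors import DomainError
from fretquant.imaging import SpectralImageSet, preprocess
from fretquant.synthetic import gen_image_scene


def _uniform_set(tmr=200.0, fret=100.0, sir=50.0, shape=(32, 32), **kw):
    return SpectralImageSet(tmr=np.full(shape, tmr), fret=np.full(shape, fret),
                            sir=np.full(shape, sir), **kw)


class TestPreprocess:
    def test_uniform_flatfield_zero_background_is_identity(self):
        imgs = _uniform_set(flatfield={ch: np.ones((32, 32)) for ch in
                                       ("tmr", "fret", "sir")})
        out = preprocess(imgs)
        np.testing.assert_allclose(out.tmr, imgs.tmr)

    def test_vignette_closure(self):
        """Image s*v + b recovers s after flat-field and background correction."""
        yy, xx = np.mgrid[0:64, 0:64]
        v = 1.0 - 0.4 * ((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 32**2)
        s = 500.0
        raw = SpectralImageSet(tmr=s * v + 10.0, fret=s * v + 10.0, sir=s * v + 10.0,
                               flatfield={ch: v for ch in ("tmr", "fret", "sir")},
                               background={ch: 10.0 for ch in ("tmr", "fret", "sir")})
        out = preprocess(raw)
        # flat-field is mean-normalised, so the recovered scale is s * mean(v)
        np.testing.assert_allclose(out.tmr, s * v.mean(), rtol=1e-6)

    def test_background_roi_subtraction(self):
        imgs = _uniform_set(tmr=150.0)
        roi = np.zeros((32, 32), dtype=bool)
        roi[:4] = True
        imgs.tmr[roi] = 100.0
        imgs.background_roi = roi
        out = preprocess(imgs)
        assert out.tmr[10, 10] == pytest.approx(50.0)

    def test_nonpositive_flatfield_rejected(self):
        ff = np.ones((32, 32)); ff[0, 0] = 0.0
        imgs = _uniform_set(flatfield={"tmr": ff})
        with pytest.raises(DomainError, match="1 non-positive"):
            preprocess(imgs)

    def test_negative_pixels_tracked(self):
        imgs = _uniform_set(tmr=5.0, background={"tmr": 10.0})
        out = preprocess(imgs)
        assert out.meta["negative_pixels"]["tmr"] == 32 * 32


class TestBleedthrough:
    def test_recovery_from_single_label_controls(self, nadp_ratio_37C):
        donor = [preprocess(gen_image_scene(np.full(8, 50.0), nadp_ratio_37C,
                                            donor_only=True, seed=30 + i)[0])
                 for i in range(3)]
        acceptor = [preprocess(gen_image_scene(np.full(8, 50.0), nadp_ratio_37C,
                                               acceptor_only=True, seed=60 + i)[0])
                    for i in range(3)]
        k = fq.estimate_bleedthrough(donor, acceptor)
        assert k.alpha == pytest.approx(0.054, rel=0.02)
        assert k.beta == pytest.approx(0.051, rel=0.02)

    def test_zero_mixing_gives_zero_coefficients(self, nadp_ratio_37C):
        donor = [preprocess(gen_image_scene(np.full(6, 50.0), nadp_ratio_37C,
                                            donor_only=True, alpha=0.0, beta=0.0,
                                            seed=i)[0]) for i in range(3)]
        acceptor = [preprocess(gen_image_scene(np.full(6, 50.0), nadp_ratio_37C,
                                               acceptor_only=True, alpha=0.0,
                                               beta=0.0, seed=90 + i)[0])
                    for i in range(3)]
        k = fq.estimate_bleedthrough(donor, acceptor)
        assert k.alpha == pytest.approx(0.0, abs=2e-3)
        assert k.beta == pytest.approx(0.0, abs=2e-3)

    def test_exposure_invariance(self, nadp_ratio_37C):
        """Doubling the photon budget leaves the slope estimate unchanged."""
        ks = []
        for budget in (2000.0, 4000.0):
            donor = [preprocess(gen_image_scene(
                np.full(8, 50.0), nadp_ratio_37C, donor_only=True,
                photon_budget=budget, seed=7 + i)[0]) for i in range(3)]
            acceptor = [preprocess(gen_image_scene(
                np.full(8, 50.0), nadp_ratio_37C, acceptor_only=True,
                photon_budget=budget, seed=700 + i)[0]) for i in range(3)]
            ks.append(fq.estimate_bleedthrough(donor, acceptor))
        assert ks[1].alpha == pytest.approx(ks[0].alpha, rel=0.05)

    def test_too_few_signal_pixels(self):
        tiny = _uniform_set(shape=(8, 8))
        with pytest.raises(DomainError, match="signal pixels"):
            fq.estimate_bleedthrough([tiny], [tiny])


class TestCorrectFret:
    def test_hand_value(self):
        imgs = _uniform_set(tmr=5000.0, fret=1000.0, sir=2000.0)
        k = fq.BleedthroughCoeffs(alpha=0.054, beta=0.051)
        out = fq.correct_fret(imgs, k)
        assert out[0, 0] == pytest.approx(628.0)

    def test_zero_coefficients_identity(self):
        imgs = _uniform_set()
        k = fq.BleedthroughCoeffs(alpha=0.0, beta=0.0)
        np.testing.assert_array_equal(fq.correct_fret(imgs, k), imgs.fret)

    def test_linearity(self, nadp_ratio_37C):
        imgs, _ = gen_image_scene(np.full(6, 40.0), nadp_ratio_37C,
                                  noise=False, seed=0)
        pre = preprocess(imgs)
        k = fq.BleedthroughCoeffs(alpha=0.054, beta=0.051)
        scaled = SpectralImageSet(tmr=3 * pre.tmr, fret=3 * pre.fret, sir=3 * pre.sir)
        np.testing.assert_allclose(fq.correct_fret(scaled, k),
                                   3 * fq.correct_fret(pre, k), rtol=1e-12)

    def test_donor_only_corrects_to_zero_mean(self, nadp_ratio_37C):
        imgs, truth = gen_image_scene(np.full(8, 50.0), nadp_ratio_37C,
                                      donor_only=True, seed=5)
        pre = preprocess(imgs)
        k = fq.BleedthroughCoeffs(alpha=truth.alpha, beta=truth.beta)
        fc = fq.correct_fret(pre, k)
        cells = truth.masks > 0
        se = fc[cells].std() / np.sqrt(cells.sum())
        assert abs(fc[cells].mean()) < 2 * max(se, 0.5)


class TestPerCellRatio:
    def test_uniform_roi(self):
        imgs = _uniform_set(tmr=200.0, fret=100.0)
        masks = np.zeros((32, 32), dtype=int); masks[4:12, 4:12] = 1
        tab = fq.per_cell_ratio(imgs, masks)
        assert tab.loc[0, "ratio"] == pytest.approx(2.0)

    def test_disjoint_rois_independent(self):
        imgs = _uniform_set(tmr=200.0, fret=100.0)
        imgs.tmr[20:28, 20:28] = 400.0
        masks = np.zeros((32, 32), dtype=int)
        masks[4:12, 4:12] = 1; masks[20:28, 20:28] = 2
        tab = fq.per_cell_ratio(imgs, masks).set_index("roi")
        assert tab.loc[1, "ratio"] == pytest.approx(2.0)
        assert tab.loc[2, "ratio"] == pytest.approx(4.0)

    def test_nonpositive_fret_censored_not_nan_propagated(self):
        imgs = _uniform_set(fret=0.0)
        masks = np.ones((32, 32), dtype=int)
        tab = fq.per_cell_ratio(imgs, masks)
        assert bool(tab.loc[0, "censored"]) and np.isnan(tab.loc[0, "ratio"])

    def test_scene_recovery_within_three_percent(self, nadp_ratio_37C):
        imgs, truth = gen_image_scene(np.linspace(20, 120, 8), nadp_ratio_37C,
                                      seed=11)
        pre = preprocess(imgs)
        k = fq.BleedthroughCoeffs(alpha=truth.alpha, beta=truth.beta)
        tab = fq.per_cell_ratio(pre, truth.masks, k=k).set_index("roi")
        for _, row in truth.per_cell.iterrows():
            assert tab.loc[row.roi, "ratio"] == pytest.approx(row.R_truth, rel=0.03)


class TestInSituCalibration:
    def test_midpoint_composition(self, nadp_ratio_37C):
        basal = pd.DataFrame({"roi": [1], "ratio": [1.0], "censored": [False]})
        spy = pd.DataFrame({"roi": [1], "ratio": [1.7961], "censored": [False]})
        res = fq.calibrate_in_situ(basal, spy, nadp_ratio_37C)
        assert res.loc[0, "R_calibrated"] == pytest.approx(2.55, abs=1e-3)
        assert res.loc[0, "estimate"] == pytest.approx(30.0, rel=0.01)

    def test_fully_open_baseline_gives_zero_nad(self, nad_ratio_37C):
        basal = pd.DataFrame({"roi": [1], "ratio": [2.0], "censored": [False]})
        spy = pd.DataFrame({"roi": [1], "ratio": [2.0], "censored": [False]})
        res = fq.calibrate_in_situ(basal, spy, nad_ratio_37C)
        assert res.loc[0, "estimate"] == 0.0
        assert bool(res.loc[0, "censored"])     # clamped at the bound

    def test_population_closure(self, nadp_ratio_37C):
        truths = np.full(10, 55.0)
        imgs_b, truth = gen_image_scene(truths, nadp_ratio_37C, seed=71)
        imgs_s, _ = gen_image_scene(np.full(10, 1e9), nadp_ratio_37C, seed=71)
        k = fq.BleedthroughCoeffs(alpha=truth.alpha, beta=truth.beta)
        tb = fq.per_cell_ratio(preprocess(imgs_b), truth.masks, k=k)
        ts = fq.per_cell_ratio(preprocess(imgs_s), truth.masks, k=k)
        res = fq.calibrate_in_situ(tb, ts, nadp_ratio_37C)
        assert res["estimate"].mean() == pytest.approx(55.0, rel=0.10)

    def test_saturated_open_flag(self, nadp_ratio_37C):
        basal = pd.DataFrame({"roi": [1], "ratio": [2.0], "censored": [False]})
        spy = pd.DataFrame({"roi": [1], "ratio": [1.5], "censored": [False]})
        res = fq.calibrate_in_situ(basal, spy, nadp_ratio_37C)
        assert "artifact" in res.loc[0, "flags"]

    def test_fully_open_delta_r_is_one(self, nadp_ratio_37C):
        """A cell already fully open shows no further ratio change under SPY."""
        imgs_b, truth = gen_image_scene(np.full(6, 1e9), nadp_ratio_37C, seed=3)
        imgs_s, _ = gen_image_scene(np.full(6, 1e9), nadp_ratio_37C, seed=3)
        k = fq.BleedthroughCoeffs(alpha=truth.alpha, beta=truth.beta)
        tb = fq.per_cell_ratio(preprocess(imgs_b), truth.masks, k=k)
        ts = fq.per_cell_ratio(preprocess(imgs_s), truth.masks, k=k)
        res = fq.calibrate_in_situ(tb, ts, nadp_ratio_37C)
        np.testing.assert_allclose(res["delta_R"], 1.0, atol=0.02)


class TestTraces:
    def _frames(self, values, p, seed0=100, **kw):
        frames, truth = [], None
        for i, v in enumerate(values):
            imgs, tru = gen_image_scene(np.full(6, float(v)), p,
                                        seed=seed0, **kw)
            imgs.time_s = 10.0 * i
            if truth is None:
                truth = tru
            frames.append(preprocess(imgs))
        return frames, truth

    def test_constant_scene_flat_traces(self, nadp_ratio_37C):
        frames, truth = self._frames([50, 50, 50, 50], nadp_ratio_37C)
        k = fq.BleedthroughCoeffs(alpha=truth.alpha, beta=truth.beta)
        traces, pop = fq.extract_traces(frames, truth.masks, k=k)
        assert len(traces) == 6 and len(pop) == 4
        for tr in traces:
            assert np.nanstd(tr.ratio) / np.nanmean(tr.ratio) < 0.02

    def test_step_change_direction_matches_isotherm(self, nadp_ratio_37C):
        """A rise in the programmed NADPH/NADP+ ratio raises the emission ratio."""
        frames, truth = self._frames([30, 30, 90, 90], nadp_ratio_37C)
        k = fq.BleedthroughCoeffs(alpha=truth.alpha, beta=truth.beta)
        _, pop = fq.extract_traces(frames, truth.masks, k=k)
        assert pop["mean"].iloc[2] > pop["mean"].iloc[1] * 1.05

    def test_oxidative_stress_episode_plateaus(self, nadp_ratio_37C):
        """Programmed 70 -> 35 -> overshoot 150 -> 70 episode is recovered."""
        program = [70, 70, 35, 35, 150, 150, 70, 70]
        frames, truth = self._frames(program, nadp_ratio_37C)
        spy_frames, _ = self._frames([1e9], nadp_ratio_37C)
        k = fq.BleedthroughCoeffs(alpha=truth.alpha, beta=truth.beta)
        spy_tab = fq.per_cell_ratio(spy_frames[0], truth.masks, k=k)
        for f_idx, target in [(1, 70), (3, 35), (5, 150), (7, 70)]:
            basal_tab = fq.per_cell_ratio(frames[f_idx], truth.masks, k=k)
            res = fq.calibrate_in_situ(basal_tab, spy_tab, nadp_ratio_37C)
            assert res["estimate"].mean() == pytest.approx(target, rel=0.10)

    def test_censoring_monotone_in_snr(self, nadp_ratio_37C):
        censored = []
        for budget in (2000.0, 30.0):
            imgs, truth = gen_image_scene(np.full(8, 50.0), nadp_ratio_37C,
                                          photon_budget=budget, background=40.0,
                                          seed=9)
            k = fq.BleedthroughCoeffs(alpha=truth.alpha, beta=truth.beta)
            tab = fq.per_cell_ratio(preprocess(imgs), truth.masks, k=k)
            censored.append(int(tab["censored"].sum()))
        assert censored[1] >= censored[0]
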