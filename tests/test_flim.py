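"""TCSPC reconvolution model, fits and FRET-efficiency conversion."""

import numpy as np
import pytest

import fretquant as fq
from fretquant.errors import DomainError, FitError
from fretquant.flim import (DecayHistogram, DecayModelParams, IRF, default_grid,
                            fret_efficiency, gaussian_irf, mean_lifetime,
                            model_decay)
from fretquant.synthetic import gen_tcspc, three_exp_for_mean

EDGES = default_grid()


def delta_irf(edges=EDGES, at_bin=100):
    d = np.zeros(edges.size - 1)
    d[at_bin] = 1.0
    return IRF(bin_edges_ns=edges, density=d)


class TestModelDecay:
    def test_delta_irf_gives_pure_exponential(self):
        irf = delta_irf()
        p = DecayModelParams(amplitudes=(1.0,), lifetimes_ns=(2.0,))
        y = model_decay(p, irf)
        centers = 0.5 * (EDGES[:-1] + EDGES[1:])
        start = 100
        expected = np.exp(-(centers[start:] - centers[start]) / 2.0) * y[start]
        np.testing.assert_allclose(y[start:], expected, rtol=1e-9, atol=1e-12)
        assert np.all(y[:start] < 1e-12)      # FFT roundoff only before onset

    def test_amplitude_linearity(self):
        irf = gaussian_irf(EDGES)
        p1 = DecayModelParams(amplitudes=(0.6, 0.4), lifetimes_ns=(3.2, 1.8),
                              bkgr_dec=5.0)
        p2 = DecayModelParams(amplitudes=(1.2, 0.8), lifetimes_ns=(3.2, 1.8),
                              bkgr_dec=5.0)
        np.testing.assert_allclose(model_decay(p2, irf) - 5.0,
                                   2 * (model_decay(p1, irf) - 5.0),
                                   rtol=1e-9, atol=1e-12)

    def test_shift_moves_peak_by_set_amount(self):
        irf = gaussian_irf(EDGES, center_ns=5.0, fwhm_ns=0.1)
        shift = 0.8
        p0 = DecayModelParams(amplitudes=(1.0,), lifetimes_ns=(2.0,))
        p1 = DecayModelParams(amplitudes=(1.0,), lifetimes_ns=(2.0,),
                              shift_irf_ns=shift)
        y0, y1 = model_decay(p0, irf), model_decay(p1, irf)
        dt = EDGES[1] - EDGES[0]
        lag = (np.argmax(y1) - np.argmax(y0)) * dt
        assert lag == pytest.approx(shift, abs=2 * dt)

    def test_shift_beyond_quarter_window_rejected(self):
        irf = gaussian_irf(EDGES)
        p = DecayModelParams(amplitudes=(1.0,), lifetimes_ns=(2.0,),
                             shift_irf_ns=15.0)
        with pytest.raises(DomainError, match="quarter"):
            model_decay(p, irf)

    def test_photon_conservation(self):
        """Total modeled photons (minus background) equal sum(a_i tau_i)/dt."""
        irf = gaussian_irf(EDGES, center_ns=1.0)
        p = DecayModelParams(amplitudes=(0.7, 0.3), lifetimes_ns=(3.0, 1.0),
                             bkgr_dec=2.0)
        y = model_decay(p, irf)
        dt = EDGES[1] - EDGES[0]
        total = (y - 2.0).sum() * dt
        assert total == pytest.approx(0.7 * 3.0 + 0.3 * 1.0, rel=1e-3)

    def test_param_validation(self):
        with pytest.raises(DomainError):
            DecayModelParams(amplitudes=(1.0,), lifetimes_ns=(0.0,))
        with pytest.raises(DomainError):
            DecayModelParams(amplitudes=(-1.0,), lifetimes_ns=(2.0,))
        p = DecayModelParams(amplitudes=(0.3, 0.7), lifetimes_ns=(1.0, 3.0))
        assert p.lifetimes_ns == (3.0, 1.0)      # sorted descending
        assert p.amplitudes == (0.7, 0.3)


class TestFitDecay:
    @pytest.mark.parametrize("amps,taus", [
        ((1.0,), (2.5,)),
        ((0.6, 0.4), (3.2, 1.8)),
        ((0.5, 0.3, 0.2), (3.5, 1.2, 0.4)),
    ])
    def test_noiseless_self_consistency(self, amps, taus):
        truth = DecayModelParams(amplitudes=amps, lifetimes_ns=taus)
        h, irf = gen_tcspc(truth, total_counts=10**8, noise=False, seed=0)
        fit = fq.fit_decay(h, irf, n_components=len(amps))
        np.testing.assert_allclose(fit.params.lifetimes_ns, truth.lifetimes_ns,
                                   rtol=1e-3)
        a = np.asarray(fit.params.amplitudes)
        np.testing.assert_allclose(a / a.sum(), truth.amplitudes, rtol=2e-3)
        assert fit.chi2_red < 0.1

    def test_noiseless_two_component_tight_closure(self):
        truth = DecayModelParams(amplitudes=(0.6, 0.4), lifetimes_ns=(3.2, 1.8))
        h, irf = gen_tcspc(truth, total_counts=10**8, noise=False, seed=0)
        fit = fq.fit_decay(h, irf, 2)
        np.testing.assert_allclose(fit.params.lifetimes_ns, (3.2, 1.8), rtol=1e-4)

    def test_poisson_realization_recovery(self):
        truth = DecayModelParams(amplitudes=(0.6, 0.4), lifetimes_ns=(3.2, 1.8))
        h, irf = gen_tcspc(truth, total_counts=10**6, noise=True, seed=11)
        fit = fq.fit_decay(h, irf, 2)
        np.testing.assert_allclose(fit.params.lifetimes_ns, (3.2, 1.8), rtol=0.03)
        assert 0.85 <= fit.chi2_red <= 1.2
        assert fit.accepted

    def test_model_mismatch_rejected_not_silent(self):
        truth = DecayModelParams(amplitudes=(0.6, 0.4), lifetimes_ns=(3.2, 1.0))
        h, irf = gen_tcspc(truth, total_counts=10**6, noise=True, seed=5)
        fit = fq.fit_decay(h, irf, n_components=1)
        assert fit.chi2_red > 1.2 and not fit.accepted

    def test_chi2_calibration_mean_near_one(self):
        """True-model fits to Poisson data: mean chi2_red within [0.95, 1.05]."""
        truth = DecayModelParams(amplitudes=(0.6, 0.4), lifetimes_ns=(3.2, 1.8))
        _, irf = gen_tcspc(truth, total_counts=10**6, noise=False, seed=0)
        chis = []
        for s in range(40):
            h, _ = gen_tcspc(truth, total_counts=10**6, noise=True,
                             irf=irf, seed=1000 + s)
            chis.append(fq.fit_decay(h, irf, 2).chi2_red)
        assert 0.95 <= float(np.mean(chis)) <= 1.05

    def test_minimum_counts_enforced(self):
        truth = DecayModelParams(amplitudes=(1.0,), lifetimes_ns=(2.0,))
        h, irf = gen_tcspc(truth, total_counts=2000, noise=True, seed=0)
        with pytest.raises(FitError, match="counts"):
            fq.fit_decay(h, irf, 1)

    def test_grid_mismatch_rejected(self):
        truth = DecayModelParams(amplitudes=(1.0,), lifetimes_ns=(2.0,))
        h, _ = gen_tcspc(truth, total_counts=10**5, noise=True, seed=0)
        other_irf = gaussian_irf(default_grid(bin_ns=0.032))
        with pytest.raises(DomainError, match="grids"):
            fq.fit_decay(h, other_irf, 1)


class TestLifetimeAndEfficiency:
    def test_mean_lifetime_examples(self):
        p1 = DecayModelParams(amplitudes=(1.0,), lifetimes_ns=(2.5,))
        assert mean_lifetime(p1) == 2.5
        p2 = DecayModelParams(amplitudes=(0.5, 0.5), lifetimes_ns=(3.0, 1.0))
        assert mean_lifetime(p2) == pytest.approx(2.0)
        p3 = DecayModelParams(amplitudes=(2.0, 2.0), lifetimes_ns=(3.0, 1.0))
        assert mean_lifetime(p3) == pytest.approx(2.0)   # scale invariance

    def test_mean_lifetime_bounds(self):
        p = DecayModelParams(amplitudes=(0.2, 0.5, 0.3),
                             lifetimes_ns=(3.5, 1.2, 0.4))
        assert min(p.lifetimes_ns) <= mean_lifetime(p) <= max(p.lifetimes_ns)

    def test_fret_efficiency_examples(self):
        assert fret_efficiency(2.4, 2.4).value == 0.0
        assert fret_efficiency(1.2, 2.4).value == pytest.approx(0.5)
        assert fret_efficiency(0.0, 2.4).value == 1.0

    def test_fret_efficiency_tolerance_clamp(self):
        ok = fret_efficiency(2.42, 2.4)          # within 2% -> clamp to 0
        assert ok.value == 0.0 and ok.censored
        bad = fret_efficiency(3.0, 2.4)
        assert np.isnan(bad.value) and bad.censored
        with pytest.raises(DomainError):
            fret_efficiency(1.0, 0.0)


class TestQuantifyFlim:
    def _fits(self, ratio_truth, p, base_seed=77):
        donor = DecayModelParams(amplitudes=(0.6, 0.4), lifetimes_ns=(3.2, 1.8))
        tau_d = mean_lifetime(donor)
        e = (p.K50 * p.E_max + ratio_truth * p.E_min) / (p.K50 + ratio_truth)
        taus3 = (2.8, 1.6, 0.5)
        basal = DecayModelParams(amplitudes=three_exp_for_mean(taus3, (1 - e) * tau_d),
                                 lifetimes_ns=taus3)
        spy = DecayModelParams(
            amplitudes=three_exp_for_mean(taus3, (1 - p.E_min) * tau_d),
            lifetimes_ns=taus3)
        hd, irf = gen_tcspc(donor, total_counts=10**6, noise=True, seed=base_seed)
        hb, _ = gen_tcspc(basal, total_counts=10**6, noise=True, irf=irf,
                          seed=base_seed + 1)
        hs, _ = gen_tcspc(spy, total_counts=10**6, noise=True, irf=irf,
                          seed=base_seed + 2)
        return (fq.fit_decay(hd, irf, 2), fq.fit_decay(hb, irf, 3),
                fq.fit_decay(hs, irf, 3))

    def test_basal_equal_spy_is_boundary(self, nadp_flim_37C):
        fd, fb, _ = self._fits(55.8, nadp_flim_37C)
        q = fq.quantify_flim(fd, fb, fb, nadp_flim_37C)
        assert q.censored
        assert np.isinf(q.estimate) or np.isnan(q.estimate)

    def test_single_cell_recovery(self, nadp_flim_37C):
        q = fq.quantify_flim(*self._fits(55.8, nadp_flim_37C), nadp_flim_37C)
        assert not np.isnan(q.estimate)
        assert q.estimate == pytest.approx(55.8, rel=0.25)

    def test_rejected_fit_refused(self, nadp_flim_37C):
        fd, fb, fs = self._fits(55.8, nadp_flim_37C)
        fb.accepted = False
        with pytest.raises(FitError, match="rejected"):
            fq.quantify_flim(fd, fb, fs, nadp_flim_37C)


class TestHistogramValidation:
    def test_nonuniform_bins_rejected(self):
        edges = np.array([0.0, 1.0, 2.0, 4.0])
        with pytest.raises(DomainError, match="uniform"):
            DecayHistogram(bin_edges_ns=edges, counts=np.array([1, 2, 3]))

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            DecayHistogram(bin_edges_ns=np.array([0.0, 1, 2, 3]),
                           counts=np.array([1, -2, 3]))
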