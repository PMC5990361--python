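"""Synthetic data with known ground truth for every pipeline stage.

Each generator is a bit-reproducible function of its arguments and a seed,
and emulates the statistical structure the corresponding analysis assumes:

* titration responses — single-site isotherm expectation with
  multiplicative (lognormal, mean-one) replicate noise;
* emission spectra — linear mixing of open/closed endmember spectra that
  peak at the donor (577 nm) and acceptor (667 nm) wavelengths and share
  the isosbestic point at 645 nm;
* microscope scenes — elliptical cells with per-cell ground-truth analyte,
  channel intensities mixed by the bleed-through coefficients, a radial
  vignette, additive background and Poisson photon noise;
* TCSPC histograms — Poisson counts around an IRF-convolved
  multi-exponential expectation;
* cytometry events — lognormal scatter/fluorescence clouds for labeled
  singlets plus debris, doublet and unlabeled subpopulations, with
  condition effects as fold-shifts of the TMR/FRET ratio center;
* kinetic traces — exponential relaxations with additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .flim import (DecayHistogram, DecayModelParams, IRF, default_grid,
                   gaussian_irf, model_decay)
from .imaging import SpectralImageSet
from .isotherms import TitrationDataset
from .kinetics import KineticTrace
from .sensor import (AnalyteKind, CalibrationParams, ratio_from_analyte,
                     ratio_from_redox)

__all__ = [
    "ScenarioConfig", "gen_titration", "endmember_spectra", "gen_spectra",
    "gen_titration_with_spectra", "gen_image_scene", "gen_tcspc",
    "gen_cytometry", "gen_relaxation_trace", "gen_pseudo_first_order_series",
]


@dataclass
class ScenarioConfig:
    """Bundle of generator settings for a reproducible scenario.

    Defaults mirror the acquisition regimes the pipeline is designed for:
    1% multiplicative noise on plate-reader ratios (technical triplicates),
    photon-budget-limited widefield images, ~1e6-count ROI decay histograms
    and cytometry runs with a few percent debris/doublet/unlabeled events.
    """

    seed: int
    ratio_noise: float = 0.01            # lognormal sigma of titration replicates
    n_replicates: int = 3
    image_photon_budget: float = 2000.0  # peak expected counts per pixel
    decay_total_counts: int = 1_000_000
    debris_fraction: float = 0.05
    doublet_fraction: float = 0.08
    unlabeled_fraction: float = 0.10
    cells_per_image: int = 10
    cytometry_cv: float = 0.25           # lognormal sigma of event ratio spread

    def __post_init__(self):
        if self.seed is None:
            raise DomainError("a seed is mandatory")
        fracs = (self.debris_fraction, self.doublet_fraction, self.unlabeled_fraction)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) >= 1:
            raise DomainError("subpopulation fractions must be in [0,1] and sum < 1")
        if self.ratio_noise < 0 or self.image_photon_budget <= 0:
            raise DomainError("noise levels must be non-negative")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((int(self.seed), int(stream)))


def _lognormal_mean_one(rng, sigma, size):
    """Multiplicative noise with exact unit expectation."""
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

def gen_titration(p: CalibrationParams, axis: np.ndarray, *,
                  noise: float = 0.01, n_replicates: int = 3,
                  seed: int = 0) -> TitrationDataset:
    """Replicate emission ratios along a titration axis.

    Uses the concentration-axis isotherm when ``p`` carries ``c50`` and the
    redox-axis isotherm when it carries ``r50``; replicates are the exact
    forward model times mean-one lognormal noise.
    """
    axis = np.asarray(axis, dtype=float)
    if np.any(axis < 0):
        raise DomainError("titration axis must be non-negative")
    rng = np.random.default_rng(seed)
    if p.c50 is not None:
        expect = ratio_from_analyte(axis, p)
        kind = AnalyteKind.nad_plus_conc if p.sensor_kind.value == "NAD" \
            else AnalyteKind.nadp_plus_conc
        unit = p.c50_unit
    else:
        expect = ratio_from_redox(axis, p)
        kind, unit = AnalyteKind.redox_ratio, None
    resp = expect[:, None] * _lognormal_mean_one(rng, noise, (axis.size, n_replicates))
    return TitrationDataset(axis=axis, responses=resp, axis_kind=kind,
                            axis_unit=unit, metadata={"seed": seed, "noise": noise})


# ---------------------------------------------------------------------------
# emission spectra
# ---------------------------------------------------------------------------

WAVELENGTHS_NM = np.arange(540.0, 741.0, 1.0)
_DONOR_PEAK, _ACCEPTOR_PEAK, _ISOSBESTIC = 577.0, 667.0, 645.0


def _band(wl, peak, sigma_blue, sigma_red):
    """Asymmetric Gaussian emission band, unit peak (red-tailed)."""
    sigma = np.where(wl < peak, sigma_blue, sigma_red)
    return np.exp(-0.5 * ((wl - peak) / sigma) ** 2)


def endmember_spectra(wl: np.ndarray = WAVELENGTHS_NM):
    """Open- and closed-state endmember spectra sharing the isosbestic point.

    The open state is donor-dominated (high 577 nm), the closed state
    acceptor-dominated (high 667 nm); the closed acceptor weight is solved
    so both endmembers coincide exactly at 645 nm.
    """
    g_d = _band(wl, _DONOR_PEAK, 18.0, 35.0)
    g_a = _band(wl, _ACCEPTOR_PEAK, 20.0, 40.0)
    gd_iso = _band(np.array([_ISOSBESTIC]), _DONOR_PEAK, 18.0, 35.0)[0]
    ga_iso = _band(np.array([_ISOSBESTIC]), _ACCEPTOR_PEAK, 20.0, 40.0)[0]
    a_open, b_open = 1.0, 0.25
    a_closed = 0.30
    b_closed = b_open + (a_open - a_closed) * gd_iso / ga_iso
    s_open = a_open * g_d + b_open * g_a
    s_closed = a_closed * g_d + b_closed * g_a
    return s_open, s_closed


def gen_spectra(theta: Sequence[float], *, noise: float = 0.0,
                seed: int = 0, wl: np.ndarray = WAVELENGTHS_NM) -> np.ndarray:
    """Spectra (n_levels, n_wavelengths) at closed-state occupancies ``theta``."""
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > 1)):
        raise DomainError("occupancies must lie in [0, 1]")
    s_open, s_closed = endmember_spectra(wl)
    spectra = theta[:, None] * s_closed[None, :] + (1 - theta[:, None]) * s_open[None, :]
    if noise > 0:
        rng = np.random.default_rng(seed)
        spectra = spectra * _lognormal_mean_one(rng, noise, spectra.shape)
    return spectra


def gen_titration_with_spectra(axis: np.ndarray, half_sat: float, *,
                               kind: str = "redox", noise: float = 0.0,
                               seed: int = 0) -> TitrationDataset:
    """Spectral titration dataset from an occupancy-scale ground truth.

    Closed-state occupancy follows theta = 1/(1 + q/K50) on a redox axis
    or theta = c/(KD' + c) on a concentration axis; the emission-ratio
    responses are read off the generated spectra at 577/667 nm, so the
    ratio-scale half-response of this dataset deliberately differs from
    the occupancy-scale ``half_sat``.
    """
    axis = np.asarray(axis, dtype=float)
    if kind == "redox":
        theta = 1.0 / (1.0 + axis / half_sat)
        axis_kind, unit = AnalyteKind.redox_ratio, None
    elif kind == "analyte":
        theta = axis / (half_sat + axis)
        axis_kind, unit = AnalyteKind.nadp_plus_conc, "uM"
    else:
        raise DomainError("kind must be 'redox' or 'analyte'")
    wl = WAVELENGTHS_NM
    spectra = gen_spectra(theta, noise=noise, seed=seed, wl=wl)
    i_d = int(np.argmin(np.abs(wl - _DONOR_PEAK)))
    i_a = int(np.argmin(np.abs(wl - _ACCEPTOR_PEAK)))
    responses = (spectra[:, i_d] / spectra[:, i_a])[:, None]
    return TitrationDataset(axis=axis, responses=responses, axis_kind=axis_kind,
                            axis_unit=unit, wavelength_nm=wl, spectra=spectra,
                            metadata={"half_sat_truth": half_sat, "kind": kind})


# ---------------------------------------------------------------------------
# microscope scenes
# ---------------------------------------------------------------------------

@dataclass
class SceneTruth:
    """Ground truth accompanying a generated scene."""

    masks: np.ndarray
    per_cell: pd.DataFrame          # roi, analyte truth, R truth
    alpha: float
    beta: float
    background: dict
    vignette: np.ndarray


def _place_cells(rng, shape, n_cells, radius_px):
    """Non-overlapping ellipse label image; deterministic for a given rng."""
    masks = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    placed = 0
    guard = 0
    centers = []
    while placed < n_cells and guard < 500 * n_cells:
        guard += 1
        cy = rng.uniform(radius_px * 1.5, shape[0] - radius_px * 1.5)
        cx = rng.uniform(radius_px * 1.5, shape[1] - radius_px * 1.5)
        if any((cy - oy) ** 2 + (cx - ox) ** 2 < (3.0 * radius_px) ** 2
               for oy, ox in centers):
            continue
        ry = radius_px * rng.uniform(0.7, 1.3)
        rx = radius_px * rng.uniform(0.7, 1.3)
        ang = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(ang) + dx * np.sin(ang)
        v = -dy * np.sin(ang) + dx * np.cos(ang)
        ell = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        placed += 1
        masks[ell] = placed
        centers.append((cy, cx))
    if placed < n_cells:
        raise DomainError("could not place the requested number of cells")
    return masks


def gen_image_scene(truth_values: Sequence[float], p: CalibrationParams, *,
                    alpha: float = 0.054, beta: float = 0.051,
                    shape=(192, 192), cell_radius_px: float = 14.0,
                    vignette_strength: float = 0.3,
                    background: float = 20.0,
                    photon_budget: float = 2000.0,
                    sir_brightness: float = 0.8,
                    donor_only: bool = False,
                    acceptor_only: bool = False,
                    noise: bool = True,
                    seed: int = 0):
    """Three-channel widefield scene with per-cell analyte ground truth.

    ``truth_values`` is one analyte value per cell (NADPH/NADP+ ratio for
    NADP-type ``p``, concentration in c50 units for NAD-type).  Per-cell
    emission ratio R follows the sensor isotherm; the donor/FRET split of a
    per-cell brightness B is TMR = B R/(1+R), FRET = B/(1+R) so that
    TMR/FRET = R exactly.  The FRET channel is then mixed with the
    bleed-through coefficients, all channels multiplied by a radial
    vignette, offset by a constant background and Poisson-sampled.
    ``donor_only=True`` produces a single-label control (no acceptor: FRET
    and SiR carry only bleed-through and background); ``acceptor_only=True``
    the converse (no donor, no FRET transfer, SiR bright).

    Returns ``(SpectralImageSet, SceneTruth)``; the image set carries the
    vignette as its flat-field reference and the true scalar background.
    """
    if donor_only and acceptor_only:
        raise DomainError("choose at most one of donor_only / acceptor_only")
    rng = np.random.default_rng(seed)
    truth_values = np.asarray(truth_values, dtype=float)
    masks = _place_cells(rng, shape, truth_values.size, cell_radius_px)

    if p.r50 is not None:
        r_truth = ratio_from_redox(truth_values, p)
    else:
        r_truth = ratio_from_analyte(truth_values, p)

    tmr = np.zeros(shape)
    fret_true = np.zeros(shape)
    sir = np.zeros(shape)
    rows = []
    for i, (val, r) in enumerate(zip(truth_values, r_truth), start=1):
        sel = masks == i
        b = photon_budget * rng.uniform(0.7, 1.0)
        if not acceptor_only:
            tmr[sel] = b * r / (1.0 + r)
        if not donor_only:
            if not acceptor_only:
                fret_true[sel] = b / (1.0 + r)
            sir[sel] = b * sir_brightness
        rows.append({"roi": i, "analyte_truth": float(val), "R_truth": float(r),
                     "brightness": b})

    fret_raw = fret_true + alpha * tmr + beta * sir

    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    r2 = ((yy - shape[0] / 2) ** 2 + (xx - shape[1] / 2) ** 2)
    vignette = 1.0 - vignette_strength * r2 / r2.max()

    channels = {}
    for name, img in (("tmr", tmr), ("fret", fret_raw), ("sir", sir)):
        expected = img * vignette + background
        channels[name] = (rng.poisson(expected).astype(float) if noise
                          else expected)

    imgs = SpectralImageSet(
        tmr=channels["tmr"], fret=channels["fret"], sir=channels["sir"],
        flatfield={ch: vignette.copy() for ch in ("tmr", "fret", "sir")},
        background={ch: background for ch in ("tmr", "fret", "sir")},
        meta={"seed": seed, "donor_only": donor_only},
    )
    truth = SceneTruth(masks=masks, per_cell=pd.DataFrame(rows),
                       alpha=alpha, beta=beta,
                       background={ch: background for ch in ("tmr", "fret", "sir")},
                       vignette=vignette)
    return imgs, truth


# ---------------------------------------------------------------------------
# TCSPC decays
# ---------------------------------------------------------------------------

def gen_tcspc(truth: DecayModelParams, *, total_counts: int = 1_000_000,
              irf: Optional[IRF] = None, bin_ns: float = 0.016,
              window_ns: float = 50.0, irf_center_ns: float = 2.0,
              irf_fwhm_ns: float = 0.25, noise: bool = True,
              seed: int = 0):
    """Poisson TCSPC histogram (plus its IRF) from a decay-parameter truth.

    The expected curve is the reconvolution model scaled to
    ``total_counts``; each bin is drawn independently Poisson.  The default
    IRF is Gaussian with 250 ps FWHM on a 16 ps / 50 ns grid.
    """
    if total_counts <= 0:
        raise DomainError("total_counts must be > 0")
    edges = default_grid(bin_ns, window_ns) if irf is None else irf.bin_edges_ns
    if irf is None:
        irf = gaussian_irf(edges, center_ns=irf_center_ns, fwhm_ns=irf_fwhm_ns)
    expected = model_decay(truth, irf, edges)
    expected = expected * (total_counts / expected.sum())
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected) if noise else np.round(expected).astype(np.int64)
    return DecayHistogram(bin_edges_ns=edges, counts=counts,
                          meta={"seed": seed, "truth": truth}), irf


def three_exp_for_mean(taus: Sequence[float], target_mean_ns: float):
    """Amplitudes of a 3-exponential decay with a given amplitude-weighted mean.

    Fixes the relative weight of the two shorter components and solves the
    leading amplitude; used to build FRET-state fixtures whose <tau>
    corresponds to a chosen efficiency.
    """
    t = np.asarray(taus, dtype=float)
    if t.size != 3:
        raise DomainError("need exactly 3 lifetimes")
    if not (min(t) < target_mean_ns < max(t)):
        raise DomainError("target mean must lie between the extreme lifetimes")
    # amplitudes (w, (1-w)*0.6, (1-w)*0.4): mean = w t0 + (1-w)(0.6 t1 + 0.4 t2)
    rest = 0.6 * t[1] + 0.4 * t[2]
    w = (target_mean_ns - rest) / (t[0] - rest)
    if not (0 < w < 1):
        raise DomainError("target mean unreachable with this lifetime triple")
    return (float(w), float((1 - w) * 0.6), float((1 - w) * 0.4))


# ---------------------------------------------------------------------------
# cytometry events
# ---------------------------------------------------------------------------

_BASE = dict(FSC_A=5.0e4, SSC_A=3.0e4, SSC_W=1.0e3, TMR=1.0e4, SiR=8.0e3)
_UNLABELED = dict(TMR=100.0, FRET=60.0, SiR=80.0)
_DEBRIS_SCALE = 0.08


def gen_cytometry(conditions: dict, *, n_events: int = 5000,
                  n_replicates: int = 3, base_ratio: float = 2.0,
                  debris_fraction: float = 0.05,
                  doublet_fraction: float = 0.08,
                  unlabeled_fraction: float = 0.10,
                  ratio_cv: float = 0.25, scatter_cv: float = 0.20,
                  width_cv: float = 0.08, intensity_cv: float = 0.35,
                  seed: int = 0) -> pd.DataFrame:
    """Event table with labeled singlets plus debris/doublet/unlabeled clouds.

    ``conditions`` maps condition name to the fold-shift of the TMR/FRET
    ratio center relative to ``base_ratio`` (control should map to 1.0).
    Labeled singlets get lognormal scatter and TMR, and FRET = TMR/ratio
    with a lognormal per-event ratio around the condition center.  Debris
    sits at ``_DEBRIS_SCALE`` of the scatter scale with autofluorescent
    intensities; doublets double SSC-W and fluorescence; unlabeled events
    keep cell-like scatter with background fluorescence only.
    """
    fr = (debris_fraction, doublet_fraction, unlabeled_fraction)
    if any(not 0 <= f <= 1 for f in fr) or sum(fr) >= 1:
        raise DomainError("fractions must be in [0,1] and sum < 1")
    rng = np.random.default_rng(seed)
    frames = []
    for cond, fold in conditions.items():
        if fold <= 0:
            raise DomainError(f"fold-shift for {cond!r} must be > 0")
        center = base_ratio * fold
        for rep in range(1, n_replicates + 1):
            n_deb, n_dbl, n_unl = rng.multinomial(
                n_events, [*fr, 1.0 - sum(fr)])[:3]
            n_sng = n_events - n_deb - n_dbl - n_unl

            def singlets(n, width_factor=1.0, fluor_factor=1.0, scatter_factor=1.0):
                tmr = _BASE["TMR"] * rng.lognormal(0, intensity_cv, n) * fluor_factor
                ratio = center * rng.lognormal(0, ratio_cv, n)
                return pd.DataFrame({
                    "FSC_A": _BASE["FSC_A"] * rng.lognormal(0, scatter_cv, n) * scatter_factor,
                    "SSC_A": _BASE["SSC_A"] * rng.lognormal(0, scatter_cv, n) * scatter_factor,
                    "SSC_W": _BASE["SSC_W"] * rng.lognormal(0, width_cv, n) * width_factor,
                    "TMR": tmr,
                    "FRET": tmr / ratio,
                    "SiR": _BASE["SiR"] * rng.lognormal(0, intensity_cv, n) * fluor_factor,
                })

            parts = [singlets(n_sng)]
            if n_dbl:
                parts.append(singlets(n_dbl, width_factor=2.0, fluor_factor=2.0,
                                      scatter_factor=1.8))
            if n_deb:
                parts.append(pd.DataFrame({
                    "FSC_A": _BASE["FSC_A"] * _DEBRIS_SCALE * rng.lognormal(0, 0.3, n_deb),
                    "SSC_A": _BASE["SSC_A"] * _DEBRIS_SCALE * rng.lognormal(0, 0.3, n_deb),
                    "SSC_W": _BASE["SSC_W"] * rng.lognormal(0, width_cv, n_deb),
                    "TMR": _UNLABELED["TMR"] * rng.lognormal(0, 0.3, n_deb),
                    "FRET": _UNLABELED["FRET"] * rng.lognormal(0, 0.3, n_deb),
                    "SiR": _UNLABELED["SiR"] * rng.lognormal(0, 0.3, n_deb),
                }))
            if n_unl:
                parts.append(pd.DataFrame({
                    "FSC_A": _BASE["FSC_A"] * rng.lognormal(0, scatter_cv, n_unl),
                    "SSC_A": _BASE["SSC_A"] * rng.lognormal(0, scatter_cv, n_unl),
                    "SSC_W": _BASE["SSC_W"] * rng.lognormal(0, width_cv, n_unl),
                    "TMR": _UNLABELED["TMR"] * rng.lognormal(0, 0.3, n_unl),
                    "FRET": _UNLABELED["FRET"] * rng.lognormal(0, 0.3, n_unl),
                    "SiR": _UNLABELED["SiR"] * rng.lognormal(0, 0.3, n_unl),
                }))
            frame = pd.concat(parts, ignore_index=True)
            truth = (["singlet"] * n_sng + ["doublet"] * n_dbl
                     + ["debris"] * n_deb + ["unlabeled"] * n_unl)
            frame["truth_population"] = truth
            frame["condition"] = cond
            frame["replicate"] = rep
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def gen_relaxation_trace(k: float, *, t_max_s: float = 150.0, n_points: int = 60,
                         y0: float = 1.0, plateau: float = 0.0,
                         noise: float = 0.0, seed: int = 0) -> KineticTrace:
    """Single-exponential relaxation trace with additive Gaussian noise."""
    if k <= 0:
        raise DomainError("rate must be > 0")
    t = np.linspace(0.0, t_max_s, n_points)
    y = plateau + (y0 - plateau) * np.exp(-k * t)
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise * abs(y0 - plateau), size=t.size)
    return KineticTrace(time_s=t, signal=y, metadata={"k_truth": k, "seed": seed})


def gen_pseudo_first_order_series(k2_per_M_per_s: float,
                                  concentrations_uM: Sequence[float], *,
                                  k_off_per_s: float = 0.0,
                                  noise: float = 0.0, seed: int = 0,
                                  n_points: int = 40):
    """Pseudo-first-order labeling series: k_obs = k2 [S] + k_off per trace."""
    traces = []
    for j, c in enumerate(concentrations_uM):
        k_obs = k2_per_M_per_s * (c * 1e-6) + k_off_per_s
        if k_obs <= 0:
            raise DomainError("observed rate must be > 0 for every trace")
        t_max = 5.0 / k_obs
        tr = gen_relaxation_trace(k_obs, t_max_s=t_max, n_points=n_points,
                                  noise=noise, seed=seed + j)
        tr.substrate_conc_uM = float(c)
        traces.append(tr)
    return traces
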