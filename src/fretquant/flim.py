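"""TCSPC decay modeling: n-exponential reconvolution fits and FRET efficiency.

A time-correlated single-photon-counting histogram records photon arrival
times blurred by the instrument response function (IRF).  The expected
counts per bin are modeled as

    y(t) = scale * [ IRF' (x) sum_i alpha_i exp(-t / tau_i) ](t) + Bkgr_Dec

where ``IRF'`` is the measured IRF after background subtraction
(``Bkgr_IRF``) and a sub-bin temporal shift (``Shift_IRF``), ``(x)`` is
discrete linear convolution on the histogram grid, and ``Bkgr_Dec`` is a
constant decay background (dark counts / room light).

Fitting is Poisson-weighted least squares using variable projection: the
optimizer searches over the lifetimes (and the IRF shift when floated)
while the amplitudes and decay background — which enter linearly — are
solved at each step by non-negative least squares.  Weights start from the
observed counts (1/max(count, 1)) and are then iteratively reweighted from
the fitted model; observed-count weights alone are known to bias lifetime
estimates low in the sparse tail of the histogram.
Goodness of fit is the reduced chi-square over bins with expected count of
at least one; fits above the acceptance threshold (1.2 by default) are
returned flagged as rejected, never silently accepted.

The amplitude-weighted mean lifetime <tau> = sum(alpha_i tau_i)/sum(alpha_i)
of donor-only (tau_D) and FRET (tau_DA) samples gives the FRET efficiency
E = 1 - <tau_DA>/<tau_D>, which the sensor's occupancy-scale calibration
(K50 / KD') converts to free NADPH/NADP+ or NAD+.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import NamedTuple, Optional

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.signal import fftconvolve

from .errors import ConfigurationError, DomainError, FitError
from .sensor import (CalibrationParams, ConversionResult, SensorKind,
                     nad_from_efficiency, redox_from_efficiency)

__all__ = [
    "DecayHistogram", "IRF", "DecayModelParams", "DecayFit",
    "model_decay", "DecayModel", "fit_decay", "mean_lifetime",
    "fret_efficiency", "quantify_flim", "FlimQuantification",
    "default_grid", "gaussian_irf",
]

#: default TCSPC binning: 16 ps bins over a 50 ns window (20 MHz repetition)
DEFAULT_BIN_NS = 0.016
DEFAULT_WINDOW_NS = 50.0
CHI2_ACCEPT = 1.2


def default_grid(bin_ns: float = DEFAULT_BIN_NS,
                 window_ns: float = DEFAULT_WINDOW_NS) -> np.ndarray:
    """Uniform bin edges (ns) for the default TCSPC window."""
    n = int(round(window_ns / bin_ns))
    return np.arange(n + 1) * bin_ns


@dataclass
class DecayHistogram:
    """Photon counts per uniform time bin."""

    bin_edges_ns: np.ndarray
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.bin_edges_ns = np.asarray(self.bin_edges_ns, dtype=float)
        self.counts = np.asarray(self.counts)
        widths = np.diff(self.bin_edges_ns)
        if widths.size < 2 or np.any(widths <= 0):
            raise DomainError("bin edges must be increasing with >= 2 bins")
        if not np.allclose(widths, widths[0], rtol=1e-6):
            raise DomainError("binning must be uniform")
        if self.counts.shape != (widths.size,):
            raise DomainError("counts length must match the number of bins")
        if np.any(self.counts < 0):
            raise DomainError("counts must be >= 0")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise DomainError("counts must be integers")
        self.counts = np.round(self.counts).astype(np.int64)

    @property
    def dt_ns(self) -> float:
        return float(self.bin_edges_ns[1] - self.bin_edges_ns[0])

    @property
    def centers_ns(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ns[:-1] + self.bin_edges_ns[1:])

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass
class IRF:
    """Instrument response on the histogram grid, normalised to unit area."""

    bin_edges_ns: np.ndarray
    density: np.ndarray      # per-bin probability mass, sums to 1

    def __post_init__(self):
        self.bin_edges_ns = np.asarray(self.bin_edges_ns, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if np.any(d < 0):
            raise DomainError("IRF must be non-negative")
        s = d.sum()
        if s <= 0:
            raise DomainError("IRF has zero area")
        self.density = d / s

    @classmethod
    def from_histogram(cls, edges_ns, counts) -> "IRF":
        return cls(bin_edges_ns=edges_ns, density=np.asarray(counts, dtype=float))

    @property
    def dt_ns(self) -> float:
        return float(self.bin_edges_ns[1] - self.bin_edges_ns[0])


def gaussian_irf(edges_ns: np.ndarray, center_ns: float = 2.0,
                 fwhm_ns: float = 0.25) -> IRF:
    """Gaussian IRF of given FWHM centered at ``center_ns`` (fixture default)."""
    centers = 0.5 * (edges_ns[:-1] + edges_ns[1:])
    sigma = fwhm_ns / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    d = np.exp(-0.5 * ((centers - center_ns) / sigma) ** 2)
    return IRF(bin_edges_ns=edges_ns, density=d)


@dataclass(frozen=True)
class DecayModelParams:
    """Parameter vector of the n-exponential reconvolution model."""

    amplitudes: tuple          # alpha_i >= 0 (relative pre-exponential factors)
    lifetimes_ns: tuple        # tau_i > 0, sorted descending for identifiability
    bkgr_irf: float = 0.0
    shift_irf_ns: float = 0.0
    bkgr_dec: float = 0.0
    scale: float = 1.0

    def __post_init__(self):
        amps = tuple(float(a) for a in self.amplitudes)
        taus = tuple(float(t) for t in self.lifetimes_ns)
        if len(amps) != len(taus) or not amps:
            raise DomainError("amplitudes and lifetimes must match and be non-empty")
        if any(a < 0 for a in amps):
            raise DomainError("amplitudes must be >= 0")
        if any(t <= 0 for t in taus):
            raise DomainError("lifetimes must be > 0")
        order = np.argsort(taus)[::-1]
        object.__setattr__(self, "amplitudes", tuple(amps[i] for i in order))
        object.__setattr__(self, "lifetimes_ns", tuple(taus[i] for i in order))
        if self.bkgr_irf < 0 or self.bkgr_dec < 0 or self.scale <= 0:
            raise DomainError("backgrounds must be >= 0 and scale > 0")

    @property
    def n_components(self) -> int:
        return len(self.amplitudes)


def _prepare_irf(irf: IRF, bkgr_irf: float, shift_ns: float) -> np.ndarray:
    """Background-subtract and fractionally shift the IRF mass (area kept at 1)."""
    d = irf.density - bkgr_irf
    d = np.clip(d, 0.0, None)
    if d.sum() <= 0:
        raise DomainError("IRF background subtraction removed all mass")
    if shift_ns != 0.0:
        idx = np.arange(d.size, dtype=float)
        d = np.interp(idx - shift_ns / irf.dt_ns, idx, d, left=0.0, right=0.0)
        if d.sum() <= 0:
            raise DomainError("IRF shift moved all mass out of the window")
    return d / d.sum()


def _component_curves(taus, irf_mass: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Columns: unit-amplitude convolved exponentials on the bin grid."""
    decays = np.exp(-centers[None, :] / np.asarray(taus)[:, None])
    conv = fftconvolve(np.broadcast_to(irf_mass, decays.shape), decays, axes=1)
    return np.clip(conv[:, : centers.size].T, 0.0, None)


def model_decay(p: DecayModelParams, irf: IRF,
                bin_edges_ns: Optional[np.ndarray] = None) -> np.ndarray:
    """Expected counts per bin for parameter vector ``p``.

    The IRF grid must match the histogram grid.  The IRF shift is limited
    to a quarter of the window (larger shifts indicate a grid mismatch).
    """
    edges = irf.bin_edges_ns if bin_edges_ns is None else np.asarray(bin_edges_ns, float)
    if bin_edges_ns is not None and (
            edges.shape != irf.bin_edges_ns.shape
            or not np.allclose(edges, irf.bin_edges_ns)):
        raise DomainError("histogram and IRF grids differ")
    window = edges[-1] - edges[0]
    if abs(p.shift_irf_ns) > window / 4.0:
        raise DomainError(
            f"IRF shift {p.shift_irf_ns} ns exceeds a quarter window ({window/4:g} ns)"
        )
    centers = 0.5 * (edges[:-1] + edges[1:]) - edges[0]
    mass = _prepare_irf(irf, p.bkgr_irf, p.shift_irf_ns)
    basis = _component_curves(p.lifetimes_ns, mass, centers)
    y = p.scale * basis @ np.asarray(p.amplitudes, dtype=float) + p.bkgr_dec
    return np.clip(y, 0.0, None)


@dataclass
class DecayFit:
    """Reconvolution-fit result: estimates, uncertainties and diagnostics."""

    params: DecayModelParams
    stderr: dict                       # name -> s.e. (lifetimes/amplitudes arrays)
    chi2_red: float
    dof: int
    weighted_residuals: np.ndarray
    accepted: bool
    converged: bool
    threshold: float = CHI2_ACCEPT
    histogram: DecayHistogram = field(repr=False, default=None)
    irf: IRF = field(repr=False, default=None)

    def predict(self) -> np.ndarray:
        return model_decay(self.params, self.irf, self.histogram.bin_edges_ns)

    @property
    def mean_lifetime_ns(self) -> float:
        return mean_lifetime(self)

    def plot(self, axes=None):
        """Decay, fitted curve and weighted residual trace (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(2, 1, sharex=True,
                                   gridspec_kw={"height_ratios": [3, 1]})
        top, bottom = axes
        t = self.histogram.centers_ns
        top.semilogy(t, np.maximum(self.histogram.counts, 0.5), ",", color="C0")
        top.semilogy(t, np.maximum(self.predict(), 0.5), "-", color="C1",
                     label=f"chi2_red = {self.chi2_red:.3g}")
        top.set_ylabel("counts / bin")
        top.legend()
        bottom.plot(t, self.weighted_residuals, ",", color="C0")
        bottom.axhline(0, color="k", lw=0.5)
        bottom.set_xlabel("time (ns)")
        bottom.set_ylabel("weighted resid.")
        return axes

    def summary(self) -> str:
        p = self.params
        lines = [f"{p.n_components}-exponential reconvolution fit"]
        for i, (a, t) in enumerate(zip(p.amplitudes, p.lifetimes_ns), 1):
            se_t = self.stderr.get("lifetimes_ns", [np.nan] * p.n_components)[i - 1]
            lines.append(f"  tau_{i} = {t:.4g} ns +/- {se_t:.2g}   alpha_{i} = {a:.4g}")
        lines += [
            f"  decay background = {p.bkgr_dec:.4g} counts/bin",
            f"  IRF shift = {p.shift_irf_ns:+.4g} ns",
            f"  <tau> (amplitude-weighted) = {self.mean_lifetime_ns:.4g} ns",
            f"  reduced chi-square = {self.chi2_red:.4g} over {self.dof} dof "
            f"({'accepted' if self.accepted else 'REJECTED'}, threshold {self.threshold})",
        ]
        return "\n".join(lines)


class DecayModel:
    """n-exponential reconvolution model bound to one histogram + IRF."""

    def __init__(self, histogram: DecayHistogram, irf: IRF, n_components: int,
                 min_counts: int = 10_000):
        if histogram.bin_edges_ns.shape != irf.bin_edges_ns.shape \
                or not np.allclose(histogram.bin_edges_ns, irf.bin_edges_ns):
            raise DomainError("histogram and IRF grids differ")
        if n_components < 1 or n_components > 4:
            raise DomainError("n_components must be between 1 and 4")
        if histogram.total_counts < min_counts:
            raise FitError(
                f"histogram has {histogram.total_counts} counts; "
                f"fits require >= {min_counts}"
            )
        self.h = histogram
        self.irf = irf
        self.n = n_components

    # -- variable projection machinery ---------------------------------------

    def _linear_solve(self, taus, shift_ns, w, y):
        """Weighted NNLS for (amplitude_i * scale, bkgr_dec) at fixed lifetimes."""
        centers = self.h.centers_ns - self.h.bin_edges_ns[0]
        mass = _prepare_irf(self.irf, 0.0, shift_ns)
        basis = _component_curves(taus, mass, centers)
        design = np.column_stack([basis, np.ones(basis.shape[0])])
        coef, _ = nnls(design * w[:, None], y * w)
        resid = (design @ coef - y) * w
        return coef, design, resid

    def fit(self, fixed: Optional[dict] = None, fit_shift: bool = False,
            threshold: float = CHI2_ACCEPT,
            tau_bounds=(0.05, 20.0)) -> DecayFit:
        """Poisson-weighted reconvolution fit.

        ``fixed`` may pin ``lifetimes_ns`` (sequence) and/or
        ``shift_irf_ns``; initialisation is a log-spaced lifetime ladder
        with amplitudes from a non-negative linear solve, the lifetimes
        being refined last, which makes the fit deterministic for given
        data.
        """
        fixed = dict(fixed or {})
        y = self.h.counts.astype(float)
        # stage 0 weights from observed counts; later stages reweight from the
        # model (floored at one count), which removes the low-count bias of
        # observed-count weighting
        w = 1.0 / np.sqrt(np.maximum(y, 1.0))

        if "lifetimes_ns" in fixed:
            tau0 = np.asarray(fixed["lifetimes_ns"], dtype=float)
            if tau0.size != self.n:
                raise ConfigurationError("fixed lifetimes length != n_components")
            vary_tau = False
        else:
            tau0 = np.geomspace(0.3, 4.0, self.n) if self.n > 1 else np.array([2.0])
            vary_tau = True
        shift0 = float(fixed.get("shift_irf_ns", 0.0))
        vary_shift = fit_shift and "shift_irf_ns" not in fixed

        def pack(theta):
            k = 0
            taus = tau0
            if vary_tau:
                taus = np.exp(theta[k:k + self.n]); k += self.n
            shift = theta[k] if vary_shift else shift0
            return taus, shift

        def residual(theta):
            taus, shift = pack(theta)
            _, _, resid = self._linear_solve(taus, shift, w, y)
            return resid

        theta0, lo, hi = [], [], []
        if vary_tau:
            theta0 += list(np.log(tau0))
            lo += [np.log(tau_bounds[0])] * self.n
            hi += [np.log(tau_bounds[1])] * self.n
        if vary_shift:
            window = self.h.bin_edges_ns[-1] - self.h.bin_edges_ns[0]
            theta0.append(shift0); lo.append(-window / 4); hi.append(window / 4)

        theta = np.asarray(theta0)
        converged = True
        jac_nl = None
        n_irls = 3 if theta0 else 1
        for _ in range(n_irls):
            if theta0:
                sol = least_squares(residual, theta, bounds=(lo, hi),
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
                theta = sol.x
                taus, shift = pack(theta)
                converged = sol.status > 0
                jac_nl = sol.jac
            else:
                taus, shift = tau0, shift0
            coef, design, _ = self._linear_solve(taus, shift, w, y)
            w = 1.0 / np.sqrt(np.maximum(design @ coef, 1.0))

        coef, design, resid = self._linear_solve(taus, shift, w, y)
        amps, bkgr_dec = coef[:-1], float(coef[-1])
        if amps.sum() <= 0:
            raise FitError("all fitted amplitudes are zero")

        # chi-square over the statistically meaningful range: bins whose
        # expected count is at least one photon, minus the free parameters
        expected = design @ coef
        in_range = expected >= 1.0
        n_free = (self.n if vary_tau else 0) + self.n + 1 + (1 if vary_shift else 0)
        dof = int(np.sum(in_range)) - n_free
        if dof <= 0:
            raise FitError("no degrees of freedom left for chi-square")
        chi2_red = float(np.sum(resid[in_range] ** 2)) / dof

        stderr = self._stderr(jac_nl, taus, shift, design, w, vary_tau)
        order = np.argsort(taus)[::-1]
        params = DecayModelParams(
            amplitudes=tuple(amps[order]), lifetimes_ns=tuple(taus[order]),
            shift_irf_ns=float(shift), bkgr_dec=max(bkgr_dec, 0.0), scale=1.0,
        )
        return DecayFit(
            params=params, stderr=stderr, chi2_red=chi2_red, dof=dof,
            weighted_residuals=resid, accepted=bool(chi2_red < threshold),
            converged=bool(converged), threshold=threshold,
            histogram=self.h, irf=self.irf,
        )

    def _stderr(self, jac_nl, taus, shift, design, w, vary_tau):
        """Approximate standard errors from the weighted normal equations."""
        out = {"lifetimes_ns": np.full(self.n, np.nan),
               "amplitudes": np.full(self.n, np.nan),
               "bkgr_dec": np.nan}
        try:
            wd = design * w[:, None]
            cov_lin = np.linalg.inv(wd.T @ wd)
            se_lin = np.sqrt(np.diag(cov_lin))
            out["amplitudes"] = se_lin[:-1]
            out["bkgr_dec"] = float(se_lin[-1])
            if vary_tau and jac_nl is not None:
                jtj = jac_nl.T @ jac_nl
                cov_nl = np.linalg.inv(jtj)
                se_log_tau = np.sqrt(np.diag(cov_nl))[: self.n]
                out["lifetimes_ns"] = se_log_tau * taus   # delta method, tau=exp(x)
        except np.linalg.LinAlgError:
            pass
        return out


def fit_decay(h: DecayHistogram, irf: IRF, n_components: int,
              fixed: Optional[dict] = None, **kw) -> DecayFit:
    """Fit an n-exponential reconvolution model (wrapper over DecayModel)."""
    min_counts = kw.pop("min_counts", 10_000)
    return DecayModel(h, irf, n_components, min_counts=min_counts).fit(fixed=fixed, **kw)


def mean_lifetime(fit) -> float:
    """Amplitude-weighted mean lifetime <tau> = sum(a_i t_i) / sum(a_i) (ns)."""
    p = fit.params if isinstance(fit, DecayFit) else fit
    a = np.asarray(p.amplitudes, dtype=float)
    t = np.asarray(p.lifetimes_ns, dtype=float)
    if a.sum() <= 0:
        raise DomainError("all amplitudes are zero; mean lifetime undefined")
    return float(np.dot(a, t) / a.sum())


class Efficiency(NamedTuple):
    value: float
    censored: bool


def fret_efficiency(tau_da_ns: float, tau_d_ns: float,
                    tolerance: float = 0.02) -> Efficiency:
    """FRET efficiency E = 1 - <tau_DA>/<tau_D>.

    ``tau_DA`` exceeding ``tau_D`` by up to ``tolerance`` (relative) is
    treated as noise and clamped to E = 0 with a flag; a larger excess is
    censored (E = NaN) since it contradicts energy transfer.
    """
    if tau_d_ns <= 0:
        raise DomainError("donor lifetime must be > 0")
    if tau_da_ns < 0:
        raise DomainError("FRET-sample lifetime must be >= 0")
    e = 1.0 - tau_da_ns / tau_d_ns
    if e < 0:
        if tau_da_ns <= tau_d_ns * (1.0 + tolerance):
            return Efficiency(0.0, True)
        return Efficiency(float("nan"), True)
    if e > 1.0:
        return Efficiency(1.0, True)
    return Efficiency(float(e), False)


@dataclass
class FlimQuantification:
    """End-to-end FLIM readout for one ROI/cell."""

    tau_d_ns: float
    tau_basal_ns: float
    tau_spy_ns: float
    efficiency: float          # basal-state E
    efficiency_min: float      # fully opened (sulfapyridine) E
    estimate: float            # NADPH/NADP+ ratio or [NAD+] in KD' units
    censored: bool
    sensor_kind: SensorKind


def quantify_flim(donor_fit: DecayFit, basal_fit: DecayFit, spy_fit: DecayFit,
                  p: CalibrationParams, allow_rejected: bool = False) -> FlimQuantification:
    """Convert a donor-only / basal / sulfapyridine fit triple to an analyte value.

    The donor-only reference gives <tau_D>; the basal and sulfapyridine
    fits give E and the per-cell E_min; E_max and the half-saturation
    constant come from the occupancy-scale calibration ``p``.
    """
    p._require("E_max")
    for name, fit in (("donor", donor_fit), ("basal", basal_fit), ("spy", spy_fit)):
        if not fit.accepted and not allow_rejected:
            raise FitError(
                f"{name} decay fit rejected (chi2_red = {fit.chi2_red:.3g}); "
                "refusing to quantify from it"
            )
    tau_d = mean_lifetime(donor_fit)
    tau_basal = mean_lifetime(basal_fit)
    tau_spy = mean_lifetime(spy_fit)
    e_basal = fret_efficiency(tau_basal, tau_d)
    e_min = fret_efficiency(tau_spy, tau_d)
    censored = e_basal.censored or e_min.censored
    if not np.isfinite(e_basal.value) or not np.isfinite(e_min.value) \
            or not (e_min.value < p.E_max):
        return FlimQuantification(tau_d, tau_basal, tau_spy,
                                  e_basal.value, e_min.value,
                                  float("nan"), True, p.sensor_kind)
    eff_params = _dc_replace(p, E_min=float(e_min.value))
    if p.sensor_kind is SensorKind.NADP:
        conv: ConversionResult = redox_from_efficiency(
            e_basal.value, eff_params, on_unbounded="inf")
    else:
        conv = nad_from_efficiency(e_basal.value, eff_params, on_unbounded="inf")
    return FlimQuantification(
        tau_d_ns=tau_d, tau_basal_ns=tau_basal, tau_spy_ns=tau_spy,
        efficiency=float(e_basal.value), efficiency_min=float(e_min.value),
        estimate=float(conv.value),
        censored=bool(censored or conv.clamped),
        sensor_kind=p.sensor_kind,
    )
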