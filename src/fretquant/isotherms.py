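"""Titration calibration: single-site isotherm and occupancy fits.

The sensor's ratiometric response to its analyte follows a single binding
isotherm on the emission-ratio scale,

    analyte axis:  R(c) = R_max + (R_min - R_max) / (1 + c50 / c)
    redox axis:    R(q) = R_min + (R_max - R_min) / (1 + r50 / q)

fitted by (unweighted) least squares with R_max, R_min and the
half-response constant free, or with any subset fixed — redox titrations
conventionally fix R_max at the value obtained by adding a saturating
concentration of the free competing ligand.

Because donor and acceptor have different dynamic ranges, the emission
ratio is not affine in sensor occupancy, so the ratio-scale half-response
(c50/r50) differs from the occupancy-scale half-saturation (KD'/K50).  The
latter is obtained by normalising a single emission channel by the
isosbestic wavelength (645 nm), which makes the signal affine in occupancy,
and fitting the same functional form (:func:`fit_occupancy`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np
import pandas as pd

from .errors import DomainError, FitError
from .sensor import AnalyteKind

__all__ = [
    "TitrationDataset",
    "IsothermModel",
    "IsothermResults",
    "fit_isotherm",
    "fit_occupancy",
    "correct_redox_preparation",
    "interference_screen",
]

ISOSBESTIC_NM = 645.0
DONOR_PEAK_NM = 577.0
ACCEPTOR_PEAK_NM = 667.0


@dataclass
class TitrationDataset:
    """Replicate emission ratios (and optional spectra) along a titration axis.

    Parameters
    ----------
    axis : ascending analyte values (concentration in ``axis_unit``, or a
        dimensionless NADPH/NADP+ ratio for ``axis_kind='redox_ratio'``).
    responses : array (n_levels, n_replicates) of emission ratios; the
        conventional design is technical triplicates.
    wavelength_nm, spectra : optional emission spectra per level (spectra
        shape (n_levels, n_wavelengths)), used for occupancy fitting.
    """

    axis: np.ndarray
    responses: np.ndarray
    axis_kind: AnalyteKind = AnalyteKind.nadp_plus_conc
    axis_unit: Optional[str] = None
    wavelength_nm: Optional[np.ndarray] = None
    spectra: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if self.responses.shape[0] != self.axis.size:
            # allow (n_reps, n_levels) passed transposed only if unambiguous
            raise DomainError(
                f"responses first axis ({self.responses.shape[0]}) must match "
                f"the analyte axis length ({self.axis.size})"
            )
        if np.any(np.diff(self.axis) <= 0):
            raise DomainError("analyte axis must be strictly increasing")
        if np.any(self.axis < 0):
            raise DomainError("analyte axis must be non-negative")
        if np.any(self.responses < 0):
            raise DomainError("emission ratios/intensities must be >= 0")
        if self.spectra is not None:
            self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
            self.spectra = np.asarray(self.spectra, dtype=float)
            if self.spectra.shape != (self.axis.size, self.wavelength_nm.size):
                raise DomainError("spectra must be (n_levels, n_wavelengths)")
            if np.any(self.spectra < 0):
                raise DomainError("spectral intensities must be >= 0")

    @property
    def n_levels(self) -> int:
        return self.axis.size

    @property
    def mean_response(self) -> np.ndarray:
        return self.responses.mean(axis=1)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "TitrationDataset":
        """Build from a tidy table with columns analyte_value, replicate, ratio."""
        pivot = df.pivot_table(index="analyte_value", columns="replicate", values="ratio")
        axis = pivot.index.to_numpy(dtype=float)
        unit = None
        if "analyte_unit" in df.columns:
            units = df["analyte_unit"].dropna().unique()
            if len(units) > 1:
                raise DomainError(f"mixed analyte units {list(units)}")
            unit = units[0] if len(units) else None
        return cls(axis=axis, responses=pivot.to_numpy(dtype=float),
                   axis_unit=unit, **kw)


def _isotherm_analyte(x, r_max, r_min, half):
    with np.errstate(divide="ignore"):
        out = r_max + (r_min - r_max) / (1.0 + half / x)
    return np.where(x == 0, r_max, out)


def _isotherm_redox(x, r_max, r_min, half):
    with np.errstate(divide="ignore"):
        out = r_min + (r_max - r_min) / (1.0 + half / x)
    return np.where(x == 0, r_min, out)


@dataclass
class IsothermResults:
    """Estimates, uncertainties and diagnostics of a single isotherm fit."""

    model: "IsothermModel"
    R_max: float
    R_min: float
    half: float                      # c50 or r50, in the dataset's axis unit
    stderr: dict                     # parameter name -> s.e. (NaN if fixed)
    fixed: dict                      # name -> fixed value
    covar: Optional[np.ndarray]
    residuals: np.ndarray
    converged: bool
    extrapolated_half: bool          # axis did not bracket the half-response
    lmfit_result: lmfit.minimizer.MinimizerResult = field(repr=False, default=None)

    @property
    def fold_change(self) -> float:
        return self.R_max / self.R_min

    @property
    def half_name(self) -> str:
        return "c50" if self.model.kind == "analyte" else "r50"

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))

    def predict(self, x) -> np.ndarray:
        f = _isotherm_analyte if self.model.kind == "analyte" else _isotherm_redox
        return f(np.asarray(x, dtype=float), self.R_max, self.R_min, self.half)

    def summary(self) -> str:
        lines = [
            f"Single-site isotherm fit ({self.model.kind} axis)",
            f"  levels: {self.model.data.n_levels}, replicates: "
            f"{self.model.data.responses.shape[1]}",
        ]
        for name, val in (("R_max", self.R_max), ("R_min", self.R_min),
                          (self.half_name, self.half)):
            if name in self.fixed or (name == self.half_name and "half" in self.fixed):
                lines.append(f"  {name:6s} = {val:.6g} (fixed)")
            else:
                key = "half" if name == self.half_name else name
                lines.append(f"  {name:6s} = {val:.6g} +/- {self.stderr.get(key, float('nan')):.2g}")
        lines.append(f"  fold change R_max/R_min = {self.fold_change:.3g}")
        lines.append(f"  residual sum of squares = {self.rss:.3g}")
        if self.extrapolated_half:
            lines.append("  warning: axis does not bracket the half-response (extrapolated)")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data and fitted isotherm on a log analyte axis (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.model.data.axis, self.model.data.responses
        for rep in range(y.shape[1]):
            ax.plot(x, y[:, rep], "o", ms=4, alpha=0.6, color="C0")
        pos = x[x > 0]
        grid = np.geomspace(pos.min(), pos.max(), 200)
        ax.plot(grid, self.predict(grid), "-", color="C1",
                label=f"{self.half_name} = {self.half:.3g}")
        ax.set_xscale("log")
        ax.set_xlabel("analyte")
        ax.set_ylabel("emission ratio")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "model": self.model.kind,
            "R_max": self.R_max,
            "R_min": self.R_min,
            self.half_name: self.half,
            "stderr": {k: (None if np.isnan(v) else v) for k, v in self.stderr.items()},
            "fixed": self.fixed,
            "fold_change": self.fold_change,
            "rss": self.rss,
            "converged": self.converged,
            "extrapolated_half": self.extrapolated_half,
        }


class IsothermModel:
    """Single-binding-isotherm model of a titration dataset.

    ``kind='analyte'`` fits the decreasing concentration-axis form,
    ``kind='redox'`` the increasing NADPH/NADP+ form.  ``fit`` accepts a
    mapping of parameters to hold fixed (``R_max``, ``R_min``, ``half`` or
    the aliases ``c50``/``r50``).
    """

    _MIN_LEVELS = 5

    def __init__(self, data: TitrationDataset, kind: str = "analyte"):
        if kind not in ("analyte", "redox"):
            raise DomainError(f"kind must be 'analyte' or 'redox', got {kind!r}")
        if data.n_levels < self._MIN_LEVELS:
            raise FitError(
                f"need >= {self._MIN_LEVELS} analyte levels, got {data.n_levels}"
            )
        self.data = data
        self.kind = kind
        self._func = _isotherm_analyte if kind == "analyte" else _isotherm_redox

    # deterministic, data-driven starting values
    def _start(self):
        x, y = self.data.axis, self.data.mean_response
        n = x.size
        t = max(1, n // 3)
        low_med = float(np.median(y[:t]))     # response in the low-analyte tertile
        high_med = float(np.median(y[-t:]))
        if self.kind == "analyte":
            r_max0, r_min0 = low_med, high_med
        else:
            r_max0, r_min0 = high_med, low_med
        mid = 0.5 * (r_max0 + r_min0)
        half0 = float(x[np.argmin(np.abs(y - mid))])
        if half0 <= 0:
            pos = x[x > 0]
            half0 = float(pos[0]) if pos.size else 1.0
        return r_max0, r_min0, half0

    def fit(self, fixed: Optional[dict] = None) -> IsothermResults:
        fixed = dict(fixed or {})
        for alias in ("c50", "r50"):
            if alias in fixed:
                fixed["half"] = fixed.pop(alias)
        unknown = set(fixed) - {"R_max", "R_min", "half"}
        if unknown:
            raise DomainError(f"unknown fixed parameters {sorted(unknown)}")

        x = self.data.axis
        y = self.data.responses
        yflat = y.ravel()
        if np.ptp(yflat) < 1e-12 * max(1.0, np.abs(yflat).mean()):
            raise FitError("all responses equal; isotherm is unidentifiable")

        r_max0, r_min0, half0 = self._start()
        params = lmfit.Parameters()
        params.add("R_max", value=fixed.get("R_max", r_max0), min=0)
        params.add("R_min", value=fixed.get("R_min", r_min0), min=0)
        params.add("half", value=fixed.get("half", half0), min=0)
        for name in fixed:
            params[name].vary = False
        # keep the optimizer off the degenerate R_max <= R_min manifold
        if params["half"].value <= 0:
            params["half"].value = half0 if half0 > 0 else 1.0

        xi = np.repeat(x, y.shape[1])

        def residual(p):
            return self._func(xi, p["R_max"].value, p["R_min"].value,
                              p["half"].value) - yflat

        out = lmfit.minimize(residual, params, method="leastsq")
        pv = out.params
        r_max, r_min, half = (pv["R_max"].value, pv["R_min"].value, pv["half"].value)
        if not out.success or not np.isfinite([r_max, r_min, half]).all():
            raise FitError(f"isotherm fit did not converge: {out.message}")
        if not (r_max > r_min):
            raise FitError(
                f"fitted R_max ({r_max:.3g}) <= R_min ({r_min:.3g}); data do not "
                "define an isotherm of the requested orientation"
            )
        if half <= 0 or not half > 0:
            raise FitError(f"fitted half-response constant non-positive ({half:.3g})")

        stderr = {
            n: (float(pv[n].stderr) if pv[n].vary and pv[n].stderr is not None
                else float("nan"))
            for n in ("R_max", "R_min", "half")
        }
        pos = x[x > 0]
        extrapolated = not (pos.size and pos.min() <= half <= x.max())
        return IsothermResults(
            model=self,
            R_max=float(r_max), R_min=float(r_min), half=float(half),
            stderr=stderr, fixed=fixed,
            covar=getattr(out, "covar", None),
            residuals=np.asarray(out.residual, dtype=float),
            converged=bool(out.success),
            extrapolated_half=bool(extrapolated),
            lmfit_result=out,
        )


def fit_isotherm(data: TitrationDataset, model: str = "analyte",
                 fixed: Optional[dict] = None) -> IsothermResults:
    """Fit Eq-3/Eq-4 to a titration dataset (thin wrapper over IsothermModel)."""
    kind = {"analyte": "analyte", "analyte_eq3": "analyte",
            "redox": "redox", "redox_eq4": "redox"}.get(model)
    if kind is None:
        raise DomainError(f"unknown isotherm model {model!r}")
    return IsothermModel(data, kind=kind).fit(fixed=fixed)


def _channel_index(wl: np.ndarray, target: float) -> int:
    i = int(np.argmin(np.abs(wl - target)))
    if abs(wl[i] - target) > 1.0:
        raise DomainError(f"spectra do not sample {target:g} nm (nearest: {wl[i]:g} nm)")
    return i


def fit_occupancy(data: TitrationDataset, channel: str = "donor",
                  fixed: Optional[dict] = None) -> IsothermResults:
    """Occupancy-scale half-saturation constant (KD' or K50) from spectra.

    Normalising the donor (577 nm) or acceptor (667 nm) intensity by the
    isosbestic intensity (645 nm) yields a signal affine in sensor
    occupancy; fitting the single-site form on that signal returns the
    half-saturation constant directly (as ``.half`` of the results).
    """
    if data.spectra is None:
        raise DomainError("dataset carries no spectra; occupancy fit needs them")
    wl = data.wavelength_nm
    iso = data.spectra[:, _channel_index(wl, ISOSBESTIC_NM)]
    peak_nm = DONOR_PEAK_NM if channel == "donor" else ACCEPTOR_PEAK_NM
    sig = data.spectra[:, _channel_index(wl, peak_nm)]
    if np.any(iso <= 0):
        raise DomainError("isosbestic intensity must be > 0 at every level")
    norm = sig / iso

    # orientation: pick whichever form has the right monotone sense
    increasing = norm[-1] >= norm[0]
    kind = "redox" if increasing else "analyte"
    ds = TitrationDataset(axis=data.axis, responses=norm[:, None],
                          axis_kind=data.axis_kind, axis_unit=data.axis_unit)
    res = IsothermModel(ds, kind=kind).fit(fixed=fixed)
    return res


def correct_redox_preparation(prepared: Sequence, f: float) -> np.ndarray:
    """True NADPH/NADP+ ratios of prepared mixtures, given NADP+ contamination.

    Commercial NADPH stocks contain a fraction ``f`` of NADP+; a nominal
    mixture of ``a`` NADPH and ``b`` NADP+ therefore actually contains
    (1-f)a NADPH and b + f a NADP+.  Returns the corrected ratio per pair;
    pairs whose oxidised pool is exactly zero get an ``inf`` sentinel.
    """
    if not (0.0 <= f <= 1.0):
        raise DomainError(f"contamination fraction must be in [0, 1], got {f}")
    arr = np.asarray(prepared, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("prepared must be a sequence of (nadph, nadp+) pairs")
    if np.any(arr < 0):
        raise DomainError("amounts must be >= 0")
    a, b = arr[:, 0], arr[:, 1]
    num = (1.0 - f) * a
    den = b + f * a
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out = np.where(den == 0, np.where(num > 0, np.inf, 0.0), out)
    return out


def interference_screen(reference: TitrationDataset,
                        with_metabolite: dict,
                        model: str = "analyte",
                        fixed: Optional[dict] = None,
                        half_shift_threshold: float = 2.0,
                        fold_loss_threshold: float = 0.20) -> pd.DataFrame:
    """Screen additive titrations for interference with the sensor response.

    Each additive dataset is fitted like the reference; an additive is
    flagged when the half-response constant shifts by more than
    ``half_shift_threshold``-fold (either direction) or the dynamic range
    drops by more than ``fold_loss_threshold`` (fractional).  Fit failures
    are reported per additive rather than raised.
    """
    ref = fit_isotherm(reference, model=model, fixed=fixed)
    rows = []
    for name, ds in with_metabolite.items():
        row = {"additive": name}
        try:
            fit = fit_isotherm(ds, model=model, fixed=fixed)
        except FitError as exc:
            row.update(half_fold_shift=np.nan, fold_change_ratio=np.nan,
                       flagged=True, error=str(exc))
        else:
            shift = fit.half / ref.half
            fc_ratio = fit.fold_change / ref.fold_change
            flagged = (max(shift, 1.0 / shift) > half_shift_threshold
                       or fc_ratio < 1.0 - fold_loss_threshold)
            row.update(half_fold_shift=shift, fold_change_ratio=fc_ratio,
                       flagged=bool(flagged), error="")
        rows.append(row)
    return pd.DataFrame(rows, columns=["additive", "half_fold_shift",
                                       "fold_change_ratio", "flagged", "error"])
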