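"""Sensor switching and labeling kinetics.

Two regimes are covered:

* single-exponential relaxation toward a plateau (e.g. opening of the
  closed sensor after adding the free competing ligand), reported as the
  rate ``k`` and half-life ``t_half = ln 2 / k``;
* pseudo-first-order labeling series — one relaxation trace per substrate
  concentration with substrate in large excess — whose observed rates grow
  linearly with concentration; the slope is the second-order rate constant
  ``k2`` (M^-1 s^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np

from .errors import DomainError, FitError

__all__ = ["KineticTrace", "RelaxationModel", "RelaxationResults",
           "fit_relaxation", "SecondOrderResults", "fit_second_order"]

LN2 = float(np.log(2.0))


@dataclass
class KineticTrace:
    """A time-resolved signal (emission ratio or normalised fraction)."""

    time_s: np.ndarray
    signal: np.ndarray
    substrate_conc_uM: Optional[float] = None   # for pseudo-first-order series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.shape != self.signal.shape or self.time_s.ndim != 1:
            raise DomainError("time and signal must be matching 1-D arrays")
        if self.time_s.size < 8:
            raise DomainError(f"need >= 8 time points, got {self.time_s.size}")
        if np.any(np.diff(self.time_s) <= 0):
            raise DomainError("time grid must be strictly increasing")


@dataclass
class RelaxationResults:
    """Single-exponential relaxation fit y(t) = plateau + amp * exp(-k t)."""

    k: float                  # rate, s^-1
    plateau: float
    amplitude: float          # y(0) - plateau (signed)
    stderr: dict
    residuals: np.ndarray
    converged: bool
    non_monotone_warning: bool

    @property
    def t_half(self) -> float:
        return LN2 / self.k

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.plateau + self.amplitude * np.exp(-self.k * t)

    def summary(self) -> str:
        lines = [
            "Single-exponential relaxation fit",
            f"  k       = {self.k:.6g} s^-1 +/- {self.stderr.get('k', float('nan')):.2g}",
            f"  t_half  = {self.t_half:.6g} s",
            f"  plateau = {self.plateau:.6g}",
            f"  amplitude = {self.amplitude:.6g}",
        ]
        if self.non_monotone_warning:
            lines.append("  warning: trace is non-monotone beyond noise tolerance")
        return "\n".join(lines)


class RelaxationModel:
    """First-order relaxation model of a single kinetic trace."""

    def __init__(self, trace: KineticTrace):
        self.trace = trace

    def _start(self):
        t, y = self.trace.time_s, self.trace.signal
        plateau0 = float(np.mean(y[-max(2, y.size // 5):]))
        amp0 = float(y[0] - plateau0)
        # crude rate from the time at which the signal crosses half-amplitude
        target = plateau0 + 0.5 * amp0
        idx = np.argmin(np.abs(y - target))
        t50 = float(t[idx]) if t[idx] > 0 else float(t[1])
        return plateau0, amp0, LN2 / max(t50, 1e-12)

    def fit(self) -> RelaxationResults:
        t, y = self.trace.time_s, self.trace.signal
        plateau0, amp0, k0 = self._start()
        if abs(amp0) < 1e-12 * max(1.0, abs(plateau0)):
            raise FitError("trace has no amplitude; rate unidentifiable")
        params = lmfit.Parameters()
        params.add("k", value=k0, min=1e-12)
        params.add("plateau", value=plateau0)
        params.add("amplitude", value=amp0)

        def residual(p):
            return (p["plateau"].value
                    + p["amplitude"].value * np.exp(-p["k"].value * t)) - y

        out = lmfit.minimize(residual, params, method="leastsq")
        if not out.success:
            raise FitError(f"relaxation fit did not converge: {out.message}")
        pv = out.params
        resid = np.asarray(out.residual, dtype=float)
        # non-monotonicity check: a step against the relaxation direction that
        # dwarfs the typical frame-to-frame fluctuation
        scale = float(np.median(np.abs(np.diff(y)))) or 1e-12
        increments = np.diff(y)
        wrong_way = increments if amp0 > 0 else -increments
        non_monotone = bool(np.any(wrong_way > 5.0 * scale))
        stderr = {n: (float(pv[n].stderr) if pv[n].stderr is not None else float("nan"))
                  for n in ("k", "plateau", "amplitude")}
        return RelaxationResults(
            k=float(pv["k"].value), plateau=float(pv["plateau"].value),
            amplitude=float(pv["amplitude"].value), stderr=stderr,
            residuals=resid, converged=True, non_monotone_warning=non_monotone,
        )


def fit_relaxation(trace: KineticTrace) -> RelaxationResults:
    """Fit a floating-plateau single exponential; t_half = ln2 / k."""
    return RelaxationModel(trace).fit()


@dataclass
class SecondOrderResults:
    """k2 from the linear dependence of observed rates on substrate."""

    k2_per_M_per_s: float
    intercept_per_s: float
    k2_stderr: float
    k_obs: np.ndarray            # per-trace observed rates, s^-1
    conc_uM: np.ndarray

    def summary(self) -> str:
        return (
            "Pseudo-first-order series fit\n"
            f"  k2        = {self.k2_per_M_per_s:.4g} M^-1 s^-1 "
            f"+/- {self.k2_stderr:.2g}\n"
            f"  intercept = {self.intercept_per_s:.4g} s^-1\n"
            f"  concentrations (uM): {np.array2string(self.conc_uM, precision=3)}"
        )


def fit_second_order(series: Sequence[KineticTrace]) -> SecondOrderResults:
    """Second-order rate constant from a pseudo-first-order trace series.

    Each trace is fitted for its observed relaxation rate ``k_obs``; a
    weighted straight line of k_obs against substrate concentration (with a
    fitted intercept, the background/off rate) gives ``k2`` as the slope.
    """
    traces = [tr for tr in series]
    if len(traces) < 3:
        raise DomainError("need >= 3 substrate concentrations for a k2 fit")
    conc = np.array([tr.substrate_conc_uM for tr in traces], dtype=float)
    if np.any(~np.isfinite(conc)) or np.any(conc < 0):
        raise DomainError("every trace needs a non-negative substrate_conc_uM")
    k_obs = np.array([fit_relaxation(tr).k for tr in traces])
    A = np.vstack([conc, np.ones_like(conc)]).T
    coef, res_ss, *_ = np.linalg.lstsq(A, k_obs, rcond=None)
    slope_per_uM, intercept = float(coef[0]), float(coef[1])
    if slope_per_uM <= 0:
        raise FitError(f"fitted slope non-positive ({slope_per_uM:.3g} s^-1/uM)")
    dof = max(1, conc.size - 2)
    sigma2 = float(res_ss[0]) / dof if np.size(res_ss) else 0.0
    sxx = float(np.sum((conc - conc.mean()) ** 2))
    slope_se = np.sqrt(sigma2 / sxx) if sxx > 0 else float("nan")
    return SecondOrderResults(
        k2_per_M_per_s=slope_per_uM * 1e6,        # (s^-1 / uM) -> M^-1 s^-1
        intercept_per_s=intercept,
        k2_stderr=slope_se * 1e6,
        k_obs=k_obs, conc_uM=conc,
    )
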