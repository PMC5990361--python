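"""Sensor response model: isotherms linking readout to free NAD(P).

The semisynthetic NAD(P) sensors used here are intramolecular FRET switches:
an analyte-dependent equilibrium between an open (low-FRET) and a closed
(high-FRET) conformation.  Two readout scales exist:

* the **emission ratio** R = donor / acceptor intensity (TMR/SiR in a plate
  reader, TMR over the bleed-through-corrected FRET channel on a microscope),
  a hyperbolic but *non-affine* function of sensor occupancy, calibrated by
  the half-response constants ``c50`` (analyte concentration) or ``r50``
  (NADPH/NADP+ ratio); and
* the **FRET efficiency** E measured by fluorescence lifetime, affine in
  occupancy, calibrated by the half-saturation constants ``KD_prime``
  (NAD+) or ``K50`` (NADPH/NADP+).

Forward maps (analyte -> readout)::

    R(c) = R_max + (R_min - R_max) / (1 + c50 / c)          # NAD+/NADP+ conc.
    R(q) = R_min + (R_max - R_min) / (1 + r50 / q)          # q = NADPH/NADP+

Inverse maps (readout -> analyte)::

    q      = r50 * (R - R_min) / (R_max - R)
    [NAD+] = c50 * (R_max - R) / (R - R_min)
    q      = K50 * (E_max - E) / (E - E_min)
    [NAD+] = KD' * (E - E_min) / (E_max - E)

Readouts that fall outside the calibrated band because of noise are clamped
toward the nearest bound and flagged, never silently extrapolated (which
would yield negative concentrations).  The unbounded end of each inverse is
an error by default, or an explicit ``inf`` sentinel when requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple, Optional

import numpy as np

from .errors import ConfigurationError, DomainError
from .units import to_micromolar

__all__ = [
    "SensorKind",
    "CalibrationParams",
    "AnalyteState",
    "ConversionResult",
    "ratio_from_analyte",
    "ratio_from_redox",
    "redox_from_ratio",
    "nad_from_ratio",
    "redox_from_efficiency",
    "nad_from_efficiency",
    "load_calibrations",
    "get_calibration",
]


class SensorKind(str, Enum):
    """Which cofactor the sensor reports on."""

    NADP = "NADP"   # reads the free NADPH/NADP+ ratio
    NAD = "NAD"     # reads free NAD+ concentration


class AnalyteKind(str, Enum):
    nadp_plus_conc = "nadp_plus_conc"
    nad_plus_conc = "nad_plus_conc"
    redox_ratio = "redox_ratio"


@dataclass(frozen=True)
class AnalyteState:
    """A single point on a titration axis.

    ``value`` is a concentration (with ``unit``) for the concentration kinds
    and a dimensionless NADPH/NADP+ ratio for ``redox_ratio``; ``math.inf``
    is the explicit sentinel for a fully reduced pool.
    """

    kind: AnalyteKind
    value: float
    unit: Optional[str] = None

    def __post_init__(self):
        if not (self.value >= 0):  # also rejects NaN
            raise DomainError(f"analyte value must be >= 0, got {self.value}")
        if math.isinf(self.value) and self.kind is not AnalyteKind.redox_ratio:
            raise DomainError("infinite value only allowed for redox_ratio")
        if self.kind is AnalyteKind.redox_ratio:
            if self.unit not in (None, ""):
                raise DomainError("redox_ratio is dimensionless; no unit allowed")
        elif self.unit is None:
            raise DomainError(f"{self.kind.value} requires a concentration unit")

    @property
    def value_uM(self) -> float:
        if self.kind is AnalyteKind.redox_ratio:
            raise ConfigurationError("redox_ratio has no concentration")
        return to_micromolar(self.value, self.unit)


@dataclass(frozen=True)
class CalibrationParams:
    """One sensor / temperature / modality calibration set.

    Ratio-scale conversions need ``R_max``, ``R_min`` and exactly one of
    ``c50`` (NAD-type) or ``r50`` (NADP-type).  Efficiency-scale conversions
    need ``E_max``, ``E_min`` and one of ``KD_prime`` or ``K50``.  A set may
    carry only one of the two scales; operations raise
    :class:`ConfigurationError` when the field they need is absent.
    """

    sensor_kind: SensorKind
    R_max: Optional[float] = None
    R_min: Optional[float] = None
    c50: Optional[float] = None
    c50_unit: Optional[str] = None
    r50: Optional[float] = None
    KD_prime: Optional[float] = None
    KD_prime_unit: Optional[str] = None
    K50: Optional[float] = None
    E_max: Optional[float] = None
    E_min: Optional[float] = None
    temperature_C: Optional[float] = None
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sensor_kind", SensorKind(self.sensor_kind))
        if (self.R_max is None) != (self.R_min is None):
            raise ConfigurationError("R_max and R_min must be given together")
        if self.R_max is not None and not (self.R_max > self.R_min > 0):
            raise ConfigurationError(
                f"require R_max > R_min > 0, got {self.R_max}, {self.R_min}"
            )
        if (self.E_max is None) != (self.E_min is None):
            raise ConfigurationError("E_max and E_min must be given together")
        if self.E_max is not None and not (0 <= self.E_min < self.E_max <= 1):
            raise ConfigurationError(
                f"require 0 <= E_min < E_max <= 1, got {self.E_min}, {self.E_max}"
            )
        for name in ("c50", "r50", "KD_prime", "K50"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ConfigurationError(f"{name} must be > 0, got {v}")
        if self.c50 is not None and self.r50 is not None:
            raise ConfigurationError("give c50 or r50, not both")
        if self.c50 is not None and self.c50_unit is None:
            raise ConfigurationError("c50 requires c50_unit")
        if self.KD_prime is not None and self.KD_prime_unit is None:
            raise ConfigurationError("KD_prime requires KD_prime_unit")

    # -- required-field accessors -------------------------------------------------
    def _require(self, *names):
        for n in names:
            if getattr(self, n) is None:
                raise ConfigurationError(
                    f"calibration set {self.provenance!r} lacks {n!r} needed here"
                )

    @property
    def fold_change(self) -> float:
        """Dynamic range R_max / R_min of the ratio readout."""
        self._require("R_max", "R_min")
        return self.R_max / self.R_min


class ConversionResult(NamedTuple):
    """Value(s) on the analyte scale plus a clamped/censored flag."""

    value: object
    clamped: object


def _asfloat(x):
    a = np.asarray(x, dtype=float)
    return a, a.ndim == 0


# ---------------------------------------------------------------------------
# forward maps: analyte -> emission ratio
# ---------------------------------------------------------------------------

def ratio_from_analyte(c, p: CalibrationParams):
    """Emission ratio expected at free analyte concentration ``c``.

    ``c`` is in the unit of ``p.c50``.  Strictly decreasing single-site
    isotherm: R(0) = R_max (open sensor), R(inf) = R_min (saturated).
    """
    p._require("R_max", "R_min", "c50")
    c_arr, scalar = _asfloat(c)
    if np.any(c_arr < 0) or np.any(np.isnan(c_arr)):
        raise DomainError("analyte concentration must be >= 0")
    with np.errstate(divide="ignore"):
        r = p.R_max + (p.R_min - p.R_max) / (1.0 + p.c50 / c_arr)
    r = np.where(c_arr == 0, p.R_max, r)
    return float(r) if scalar else r


def ratio_from_redox(q, p: CalibrationParams):
    """Emission ratio expected at NADPH/NADP+ ratio ``q`` (dimensionless).

    Strictly increasing: R(0) = R_min (all NADP+, closed), R(inf) = R_max.
    """
    p._require("R_max", "R_min", "r50")
    q_arr, scalar = _asfloat(q)
    if np.any(q_arr < 0) or np.any(np.isnan(q_arr)):
        raise DomainError("redox ratio must be >= 0")
    with np.errstate(divide="ignore"):
        r = p.R_min + (p.R_max - p.R_min) / (1.0 + p.r50 / q_arr)
    r = np.where(q_arr == 0, p.R_min, r)
    r = np.where(np.isinf(q_arr), p.R_max, r)
    return float(r) if scalar else r


# ---------------------------------------------------------------------------
# inverse maps: readout -> analyte
# ---------------------------------------------------------------------------

def _invert(x, lo, hi, scale, orientation, on_unbounded):
    """Shared inversion kernel for the four hyperbolic inverse maps.

    orientation ``+1``: result = scale * (x - lo) / (hi - x) (0 at lo,
    unbounded at hi); ``-1``: result = scale * (hi - x) / (x - lo)
    (0 at hi, unbounded at lo).
    """
    arr, scalar = _asfloat(x)
    if np.any(np.isnan(arr)):
        raise DomainError("readout contains NaN")
    if orientation == +1:
        at_zero, at_inf = arr <= lo, arr >= hi
    else:
        at_zero, at_inf = arr >= hi, arr <= lo
    if np.any(at_inf) and on_unbounded == "raise":
        bound = "upper" if orientation == +1 else "lower"
        raise DomainError(
            f"readout at or beyond the {bound} calibration bound; the analyte "
            "scale is unbounded there (pass on_unbounded='inf' to censor)"
        )
    safe = np.clip(arr, np.nextafter(lo, hi), np.nextafter(hi, lo))
    if orientation == +1:
        out = scale * (safe - lo) / (hi - safe)
    else:
        out = scale * (hi - safe) / (safe - lo)
    out = np.where(at_zero, 0.0, out)
    out = np.where(at_inf, np.inf, out)
    clamped = at_zero | at_inf
    if scalar:
        return ConversionResult(float(out), bool(clamped))
    return ConversionResult(out, clamped)


def redox_from_ratio(R, p: CalibrationParams, on_unbounded: str = "raise") -> ConversionResult:
    """Free NADPH/NADP+ ratio from an emission ratio.

    q = r50 (R - R_min)/(R_max - R); exact inverse of :func:`ratio_from_redox`.
    R <= R_min clamps to 0 (flagged); R >= R_max raises, or censors to
    ``inf`` when ``on_unbounded='inf'``.
    """
    p._require("R_max", "R_min", "r50")
    return _invert(R, p.R_min, p.R_max, p.r50, +1, on_unbounded)


def nad_from_ratio(R, p: CalibrationParams, on_unbounded: str = "raise") -> ConversionResult:
    """Free [NAD+] (in the unit of c50) from an emission ratio.

    [NAD+] = c50 (R_max - R)/(R - R_min); strictly decreasing in R.
    """
    p._require("R_max", "R_min", "c50")
    return _invert(R, p.R_min, p.R_max, p.c50, -1, on_unbounded)


def redox_from_efficiency(E, p: CalibrationParams, on_unbounded: str = "raise") -> ConversionResult:
    """Free NADPH/NADP+ from a FRET efficiency.

    q = K50 (E_max - E)/(E - E_min); high FRET = closed = NADP+-bound,
    so q decreases with E.
    """
    p._require("E_max", "E_min", "K50")
    return _invert(E, p.E_min, p.E_max, p.K50, -1, on_unbounded)


def nad_from_efficiency(E, p: CalibrationParams, on_unbounded: str = "raise") -> ConversionResult:
    """Free [NAD+] (unit of KD_prime) from a FRET efficiency.

    [NAD+] = KD' (E - E_min)/(E_max - E); increasing in E (NAD+ closes
    the sensor).
    """
    p._require("E_max", "E_min", "KD_prime")
    return _invert(E, p.E_min, p.E_max, p.KD_prime, +1, on_unbounded)


# ---------------------------------------------------------------------------
# calibration registry
# ---------------------------------------------------------------------------

_FIELDS = {f for f in CalibrationParams.__dataclass_fields__}


def _params_from_mapping(name, doc) -> CalibrationParams:
    unknown = set(doc) - _FIELDS
    if unknown:
        raise ConfigurationError(f"registry entry {name!r}: unknown fields {sorted(unknown)}")
    doc = dict(doc)
    doc["sensor_kind"] = SensorKind(doc["sensor_kind"])
    try:
        return CalibrationParams(**doc)
    except ConfigurationError as exc:
        raise ConfigurationError(f"registry entry {name!r}: {exc}") from exc


def load_calibrations(path=None) -> dict:
    """Load a calibration registry (packaged defaults when ``path`` is None).

    The file maps names like ``nadp-37C-ratio`` to CalibrationParams fields;
    every entry is validated on load and errors name the offending entry and
    field.
    """
    import yaml

    if path is None:
        from importlib.resources import files

        text = files("fretquant.data").joinpath("calibrations.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: _params_from_mapping(name, doc) for name, doc in raw["calibrations"].items()}


_DEFAULT_REGISTRY = None


def get_calibration(name: str) -> CalibrationParams:
    """Fetch a named entry from the packaged registry (cached)."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = load_calibrations()
    try:
        return _DEFAULT_REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"no calibration named {name!r}; available: {sorted(_DEFAULT_REGISTRY)}"
        ) from None
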