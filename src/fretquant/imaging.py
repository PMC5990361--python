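"""Widefield ratio imaging: from raw channel images to per-cell NAD(P) values.

Acquisition produces three channels per frame — donor excitation/donor
emission (TMR), donor excitation/acceptor emission (FRET) and acceptor
excitation/acceptor emission (SiR).  The pipeline is:

1. flat-field correction (divide by the mean-normalised reference) and
   scalar background subtraction per channel;
2. bleed-through correction of the FRET channel,
   ``FRET_c = FRET_raw - alpha * TMR - beta * SiR``, with ``alpha`` (donor
   emission into the FRET channel) and ``beta`` (direct acceptor
   excitation) measured from single-labeled control images;
3. per-ROI emission ratio R = mean(TMR) / mean(FRET_c) (ratio of means,
   robust to low-count pixels);
4. in-situ calibration: saturating sulfapyridine fully opens the sensor,
   so the per-cell ratio change DR = R_SPY / R_basal anchors the basal
   readout to the in-vitro scale via R = R_max / DR, after which the
   sensor isotherm converts R to free NADPH/NADP+ or NAD+.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import theilslopes

from .errors import DomainError
from .sensor import CalibrationParams, nad_from_ratio, redox_from_ratio

__all__ = [
    "SpectralImageSet", "BleedthroughCoeffs", "CellTrace",
    "preprocess", "estimate_bleedthrough", "correct_fret",
    "per_cell_ratio", "calibrate_in_situ", "extract_traces",
]

CHANNELS = ("tmr", "fret", "sir")


@dataclass
class SpectralImageSet:
    """Registered donor / FRET / acceptor channel images of one frame."""

    tmr: np.ndarray
    fret: np.ndarray
    sir: np.ndarray
    flatfield: Optional[dict] = None          # channel -> reference image
    background: Optional[dict] = None         # channel -> scalar, or use roi
    background_roi: Optional[np.ndarray] = None   # bool mask of background pixels
    pixel_size_um: Optional[float] = None
    time_s: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for ch in CHANNELS:
            setattr(self, ch, np.asarray(getattr(self, ch), dtype=float))
        shapes = {getattr(self, ch).shape for ch in CHANNELS}
        if len(shapes) != 1:
            raise DomainError(f"channel shapes differ: {shapes}")
        if self.flatfield:
            for ch, ref in self.flatfield.items():
                if np.asarray(ref).shape != self.tmr.shape:
                    raise DomainError(f"flat-field for {ch!r} has wrong shape")

    @property
    def shape(self):
        return self.tmr.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise DomainError(f"unknown channel {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class BleedthroughCoeffs:
    """Spectral crosstalk coefficients of the FRET channel."""

    alpha: float      # donor emission detected in the FRET channel
    beta: float       # direct acceptor excitation at the donor line
    provenance: str = ""

    def __post_init__(self):
        if not (0 <= self.alpha < 1 and 0 <= self.beta < 1):
            raise DomainError(
                f"bleed-through coefficients must be in [0, 1), got "
                f"alpha={self.alpha}, beta={self.beta}"
            )


def preprocess(raw: SpectralImageSet) -> SpectralImageSet:
    """Background and flat-field correct every channel.

    The scalar background (camera offset plus stray light, the median over
    ``background_roi`` per channel or the scalars in ``raw.background``) is
    subtracted first, since it is added after the optics vignette the
    flat-field models; the channel is then divided by its mean-normalised
    flat-field reference, preserving the overall intensity scale.  Counts of
    negative pixels produced by the subtraction are tracked in
    ``meta['negative_pixels']``.
    """
    out = {}
    negatives = {}
    for ch in CHANNELS:
        img = raw.channel(ch).copy()
        if raw.background and ch in raw.background:
            bg = float(raw.background[ch])
        elif raw.background_roi is not None:
            roi = np.asarray(raw.background_roi, dtype=bool)
            if not roi.any():
                raise DomainError("background ROI selects no pixels")
            bg = float(np.median(img[roi]))
        else:
            bg = 0.0
        img = img - bg
        negatives[ch] = int(np.sum(img < 0))
        if raw.flatfield and ch in raw.flatfield:
            ref = np.asarray(raw.flatfield[ch], dtype=float)
            bad = int(np.sum(ref <= 0))
            if bad:
                raise DomainError(
                    f"flat-field for {ch!r} has {bad} non-positive pixels"
                )
            img = img / (ref / ref.mean())
        out[ch] = img
    meta = dict(raw.meta)
    meta["negative_pixels"] = negatives
    meta["preprocessed"] = True
    return replace(raw, tmr=out["tmr"], fret=out["fret"], sir=out["sir"],
                   flatfield=None, background=None, background_roi=None,
                   meta=meta)


def _robust_slope(x: np.ndarray, y: np.ndarray, max_pairs_n: int = 2000) -> float:
    """Theil–Sen slope through the origin region, least-squares fallback.

    Pixel counts routinely exceed what the pairwise-slope estimator can
    handle, so points are deterministically thinned (even strides over the
    x-sorted sample) before the robust fit.
    """
    if x.size > max_pairs_n:
        order = np.argsort(x, kind="stable")
        idx = order[np.linspace(0, x.size - 1, max_pairs_n).astype(int)]
        x, y = x[idx], y[idx]
    try:
        slope, _, _, _ = theilslopes(y, x)
        if np.isfinite(slope):
            return float(slope)
    except Exception:
        pass
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.dot(xc, yc) / np.dot(xc, xc))


def estimate_bleedthrough(donor_only: Sequence[SpectralImageSet],
                          acceptor_only: Sequence[SpectralImageSet],
                          signal_quantile: float = 0.80,
                          min_pixels: int = 100) -> BleedthroughCoeffs:
    """Estimate (alpha, beta) from single-labeled control image sets.

    ``alpha`` is the robust slope of FRET-channel vs TMR-channel intensity
    over signal pixels of donor-only samples; ``beta`` the slope of FRET vs
    SiR over acceptor-only samples.  Signal pixels are selected above the
    ``signal_quantile`` of the source channel, which keeps the regression
    on pixels where shot noise is small relative to signal.  Inputs must be
    preprocessed (flat-field / background corrected).
    """
    def collect(images, source):
        from scipy.ndimage import uniform_filter

        xs, ys, zs = [], [], []
        for im in images:
            src = im.channel(source)
            # selection and binning use a locally smoothed copy whose noise is
            # nearly independent of the per-pixel shot noise; regressing raw
            # pixels directly on themselves attenuates the slope
            smooth = uniform_filter(src, size=5)
            thr = np.quantile(smooth, signal_quantile)
            sel = smooth > thr
            xs.append(src[sel])
            ys.append(im.fret[sel])
            zs.append(smooth[sel])
        x = np.concatenate(xs) if xs else np.empty(0)
        y = np.concatenate(ys) if ys else np.empty(0)
        z = np.concatenate(zs) if zs else np.empty(0)
        if x.size < min_pixels:
            raise DomainError(
                f"only {x.size} signal pixels for the {source!r} control; "
                f"need >= {min_pixels}"
            )
        # aggregate into quantile bins of the smoothed intensity: bin means
        # average the shot noise away on both axes before the robust slope
        n_bins = min(40, max(5, x.size // 50))
        edges = np.quantile(z, np.linspace(0, 1, n_bins + 1))
        idx = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, n_bins - 1)
        bx = np.array([x[idx == b].mean() for b in range(n_bins) if np.any(idx == b)])
        by = np.array([y[idx == b].mean() for b in range(n_bins) if np.any(idx == b)])
        if bx.size < 3 or np.ptp(bx) <= 0:
            raise DomainError(
                f"{source!r} control has no intensity spread to regress on"
            )
        return _robust_slope(bx, by)

    alpha = collect(donor_only, "tmr")
    beta = collect(acceptor_only, "sir")
    return BleedthroughCoeffs(alpha=max(alpha, 0.0), beta=max(beta, 0.0),
                              provenance="estimated from single-label controls")


def correct_fret(imgs: SpectralImageSet, k: BleedthroughCoeffs) -> np.ndarray:
    """Bleed-through-corrected FRET image (signed float array)."""
    return imgs.fret - k.alpha * imgs.tmr - k.beta * imgs.sir


def per_cell_ratio(imgs: SpectralImageSet, masks: np.ndarray,
                   k: Optional[BleedthroughCoeffs] = None) -> pd.DataFrame:
    """Per-ROI emission ratio R = mean(TMR) / mean(FRET_c).

    ``masks`` is a label image (0 = background).  When ``k`` is given the
    FRET channel is bleed-through corrected first; otherwise ``imgs.fret``
    is taken as already corrected.  ROIs whose mean corrected FRET is not
    positive are censored (R = NaN, ``censored=True``) rather than
    propagating meaningless ratios.
    """
    masks = np.asarray(masks)
    if masks.shape != imgs.shape:
        raise DomainError("mask shape does not match the image channels")
    labels = np.unique(masks)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise DomainError("mask labels no ROI")
    fret_c = correct_fret(imgs, k) if k is not None else imgs.fret
    rows = []
    for lab in labels:
        sel = masks == lab
        tmr_mean = float(imgs.tmr[sel].mean())
        fret_mean = float(fret_c[sel].mean())
        neg_frac = float(np.mean(fret_c[sel] < 0))
        censored = fret_mean <= 0 or tmr_mean <= 0
        rows.append({
            "roi": int(lab),
            "ratio": (tmr_mean / fret_mean) if not censored else np.nan,
            "tmr_mean": tmr_mean,
            "fret_mean": fret_mean,
            "n_pixels": int(sel.sum()),
            "negative_pixel_fraction": neg_frac,
            "censored": bool(censored),
        })
    return pd.DataFrame(rows)


def calibrate_in_situ(basal: pd.DataFrame, spy: pd.DataFrame,
                      p: CalibrationParams,
                      delta_tolerance: float = 0.05) -> pd.DataFrame:
    """Convert matched basal/sulfapyridine ratio tables to analyte values.

    Per cell, DR = R_SPY / R_basal; since saturating sulfapyridine fully
    opens the sensor (readout R_max), the basal readout on the in-vitro
    scale is R = R_max / DR.  The sensor isotherm then yields the free
    NADPH/NADP+ ratio (NADP sensor) or [NAD+] (NAD sensor).  Cells with
    DR < 1 - ``delta_tolerance`` are flagged (the sensor cannot open
    further than fully open; such cells indicate an artifact).
    """
    p._require("R_max", "R_min")
    merged = basal.merge(spy, on="roi", suffixes=("_basal", "_spy"))
    if merged.empty:
        raise DomainError("no matching ROIs between basal and SPY tables")
    rows = []
    for _, rec in merged.iterrows():
        r_basal, r_spy = rec["ratio_basal"], rec["ratio_spy"]
        censored = bool(rec.get("censored_basal", False) or rec.get("censored_spy", False))
        flags = []
        if censored or not np.isfinite(r_basal) or not np.isfinite(r_spy):
            rows.append({"roi": int(rec["roi"]), "delta_R": np.nan,
                         "R_calibrated": np.nan, "estimate": np.nan,
                         "censored": True, "flags": "input censored"})
            continue
        delta = r_spy / r_basal
        if delta < 1.0 - delta_tolerance:
            flags.append("delta_R < 1: saturated-open or artifact")
        r_cal = p.R_max / max(delta, 1.0)   # clamp: sensor cannot exceed fully open
        if p.r50 is not None:
            conv = redox_from_ratio(r_cal, p, on_unbounded="inf")
        else:
            conv = nad_from_ratio(r_cal, p, on_unbounded="inf")
        if conv.clamped:
            flags.append("readout clamped at calibration bound")
        rows.append({
            "roi": int(rec["roi"]),
            "R_basal": float(r_basal),
            "R_spy": float(r_spy),
            "delta_R": float(delta),
            "R_calibrated": float(r_cal),
            "estimate": float(conv.value),
            "censored": bool(conv.clamped) or bool(flags),
            "flags": "; ".join(flags),
        })
    return pd.DataFrame(rows)


@dataclass
class CellTrace:
    """Per-frame emission ratio of one ROI across a time series."""

    roi: int
    time_s: np.ndarray
    ratio: np.ndarray
    annotations: dict = field(default_factory=dict)


def extract_traces(stack: Sequence[SpectralImageSet], masks: np.ndarray,
                   k: Optional[BleedthroughCoeffs] = None):
    """Per-cell ratio traces and the population mean +/- s.d. trace.

    ``stack`` is a time-ordered list of frames sharing the ROI masks (no
    registration is attempted).  Returns ``(traces, population)`` where
    ``population`` is a DataFrame with one row per frame (time_s, mean,
    sd, n).  Frames where a cell is censored leave a NaN gap in its trace.
    """
    if len(stack) == 0:
        raise DomainError("empty image stack")
    times = np.array([
        frame.time_s if frame.time_s is not None else float(i)
        for i, frame in enumerate(stack)
    ])
    tables = [per_cell_ratio(frame, masks, k=k) for frame in stack]
    rois = tables[0]["roi"].to_numpy()
    per_roi = {roi: np.full(len(stack), np.nan) for roi in rois}
    for t_idx, tab in enumerate(tables):
        for _, rec in tab.iterrows():
            if not rec["censored"]:
                per_roi[int(rec["roi"])][t_idx] = rec["ratio"]
    traces = [CellTrace(roi=int(r), time_s=times, ratio=per_roi[r]) for r in rois]
    mat = np.vstack([tr.ratio for tr in traces])
    population = pd.DataFrame({
        "time_s": times,
        "mean": np.nanmean(mat, axis=0),
        "sd": np.nanstd(mat, axis=0, ddof=1),
        "n": np.sum(np.isfinite(mat), axis=0),
    })
    return traces, population
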