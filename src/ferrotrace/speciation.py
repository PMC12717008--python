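"""Iron speciation arithmetic: ferrous fraction from a colorimetric
Fe2+/Fe3+ ratio, and EELS Fe L2,3 white-line integration with a
configurable ratio-to-valence calibration.

The white-line L3/L2 intensity ratio rises monotonically with the ferric
fraction Fe3+/sum(Fe); since published calibrations differ in background
treatment and integration windows, the mapping here is supplied as data
(anchor points) rather than hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.signal import find_peaks


def ferrous_fraction(fe2_to_fe3_ratio: float) -> float:
    """Fraction of total iron in the ferrous state given Fe2+/Fe3+ = r:
    r / (1 + r)."""
    if not np.isfinite(fe2_to_fe3_ratio) or fe2_to_fe3_ratio < 0:
        raise ValueError("Fe2+/Fe3+ ratio must be finite and non-negative")
    return fe2_to_fe3_ratio / (1.0 + fe2_to_fe3_ratio)


@dataclass(frozen=True)
class EelsSpectrum:
    """Background-subtracted or raw electron energy-loss spectrum."""

    energy_loss: np.ndarray  # eV, strictly increasing
    counts: np.ndarray       # non-negative intensities

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_loss, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "energy_loss", e)
        object.__setattr__(self, "counts", c)
        if e.ndim != 1 or e.shape != c.shape or e.size < 16:
            raise ValueError("energy and counts must be equal-length 1-d arrays, length >= 16")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy-loss grid must be strictly increasing")
        if np.any(~np.isfinite(c)) or np.any(c < 0):
            raise ValueError("counts must be finite and non-negative")


@dataclass(frozen=True)
class WhiteLineResult:
    l3_area: float
    l2_area: float
    ratio: float
    l3_peak_ev: float
    l2_peak_ev: float
    separation_ev: float


def _detect_edges(spec: EelsSpectrum) -> tuple[float, float]:
    """Locate the L3 (lower energy) and L2 white-line maxima."""
    peaks, props = find_peaks(spec.counts, prominence=spec.counts.max() * 0.05)
    if peaks.size < 2:
        raise ValueError("could not detect two white-line peaks")
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    e3, e2 = np.sort(spec.energy_loss[top2])
    return float(e3), float(e2)


def _arctan_step(e: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.arctan((e - centre) / width) / np.pi + 0.5


def _region_mean(spec: EelsSpectrum, lo: float, hi: float) -> float:
    mask = (spec.energy_loss >= lo) & (spec.energy_loss <= hi)
    return float(spec.counts[mask].mean()) if mask.any() else 0.0


def _continuum(spec: EelsSpectrum, model: str, p3: float, p2: float, half: float) -> np.ndarray:
    """Continuum estimate under the white lines.

    'none'         zero background;
    'linear'       straight line fitted to points outside the two peak
                   neighbourhoods;
    'double_arctan' (default) two arctan steps anchored at the edge
                   onsets, step heights set by the continuum levels
                   before L3, between the edges and after L2.
    """
    e = spec.energy_loss
    if model == "none":
        return np.zeros_like(e)
    margin = 2 * half
    if model == "linear":
        # wider exclusion: white-line tails bias a straight-line fit
        wide = 4 * half
        outside = (np.abs(e - p3) > wide) & (np.abs(e - p2) > wide)
        if outside.sum() < 2:
            raise ValueError("not enough points outside the peaks to fit a linear continuum")
        coef = np.polyfit(e[outside], spec.counts[outside], 1)
        return np.polyval(coef, e)
    if model == "double_arctan":
        pre = _region_mean(spec, e[0], p3 - margin)
        mid = _region_mean(spec, p3 + margin, p2 - margin)
        post = _region_mean(spec, p2 + margin, e[-1])
        bg = (
            pre
            + max(mid - pre, 0.0) * _arctan_step(e, p3 - half, half)
            + max(post - mid, 0.0) * _arctan_step(e, p2 - half, half)
        )
        return bg
    raise ValueError(f"unknown background model {model!r}")


def white_line_ratio(
    spectrum: EelsSpectrum,
    background_model: str = "double_arctan",
    windows: tuple[tuple[float, float], tuple[float, float]] | None = None,
    window_half_width_ev: float = 2.0,
) -> WhiteLineResult:
    """Integrate the Fe L3 and L2 white lines and report their ratio.

    Peaks are auto-detected (the two most prominent maxima); integration
    windows default to +-2 eV around each peak.  The configured continuum
    model is subtracted before trapezoidal integration.
    """
    e = spectrum.energy_loss
    if np.all(spectrum.counts == 0):
        raise ValueError("spectrum has no intensity (L2 area would be zero)")
    p3, p2 = _detect_edges(spectrum)
    net = spectrum.counts - _continuum(spectrum, background_model, p3, p2, window_half_width_ev)
    # refine the peak positions on the net signal: a sloping continuum
    # shifts the raw maxima and would bias the integration windows
    p3, p2 = (
        float(e[np.argmax(np.where(np.abs(e - p) <= 3.0, net, -np.inf))]) for p in (p3, p2)
    )
    if windows is None:
        h = window_half_width_ev
        windows = ((p3 - h, p3 + h), (p2 - h, p2 + h))
    for lo, hi in windows:
        if lo < e[0] or hi > e[-1]:
            raise ValueError(f"integration window ({lo}, {hi}) outside the energy grid")

    areas = []
    for lo, hi in windows:
        mask = (e >= lo) & (e <= hi)
        areas.append(float(np.trapezoid(net[mask], e[mask])))
    l3_area, l2_area = areas
    if l2_area <= 0:
        raise ValueError("non-positive L2 white-line area after background subtraction")
    return WhiteLineResult(
        l3_area=l3_area, l2_area=l2_area, ratio=l3_area / l2_area,
        l3_peak_ev=p3, l2_peak_ev=p2, separation_ev=p2 - p3,
    )


@dataclass(frozen=True)
class ValenceCalibration:
    """Monotone map from L3/L2 white-line ratio to ferric fraction.

    Supplied as anchor points (ratio, Fe3+/sum Fe) interpolated linearly.
    Extrapolation beyond the anchor span is refused unless explicitly
    allowed (clamped to the end members).
    """

    anchors: tuple[tuple[float, float], ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        a = np.asarray(self.anchors, dtype=float)
        if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] != 2:
            raise ValueError("need at least two (ratio, fraction) anchors")
        if np.any(np.diff(a[:, 0]) <= 0):
            raise ValueError("anchor ratios must be strictly increasing")
        if np.any(np.diff(a[:, 1]) < 0):
            raise ValueError("anchor fractions must be non-decreasing")
        if np.any(a[:, 1] < 0) or np.any(a[:, 1] > 1):
            raise ValueError("anchor fractions must lie in [0, 1]")

    @property
    def span(self) -> tuple[float, float]:
        return self.anchors[0][0], self.anchors[-1][0]


#: Synthetic default calibration, monotone and shaped like the published
#: universal white-line curves; it is NOT a published curve and carries
#: no claim of reproducing any particular reported valence value.
DEFAULT_VALENCE_CALIBRATION = ValenceCalibration(
    anchors=((3.0, 0.0), (4.0, 0.25), (4.7, 0.5), (5.3, 0.75), (5.8, 1.0)),
    name="synthetic-universal-shape",
)


def ferric_fraction_from_ratio(
    ratio: float,
    calibration: ValenceCalibration = DEFAULT_VALENCE_CALIBRATION,
    allow_extrapolation: bool = False,
) -> float:
    """Ferric fraction Fe3+/sum(Fe) at the given white-line ratio."""
    lo, hi = calibration.span
    if not lo <= ratio <= hi:
        if not allow_extrapolation:
            raise ValueError(
                f"ratio {ratio} outside calibration span ({lo}, {hi}); "
                "pass allow_extrapolation=True to clamp to the end members"
            )
    a = np.asarray(calibration.anchors, dtype=float)
    return float(np.interp(ratio, a[:, 0], a[:, 1]))
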