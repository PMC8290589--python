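"""Domain types for Raman spectra and hyperspectral maps, plus preprocessing.

The preprocessing chain mirrors standard confocal Raman practice for skin
cryosections: Savitzky–Golay smoothing, polynomial fluorescence-baseline
removal, suppression of low-signal pixels (judged on the amide-I region,
1530–1730 cm⁻¹), cropping to the low-wavenumber window of interest
(400–785 cm⁻¹), and vector (unit Euclidean norm) normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.signal import savgol_coeffs

logger = logging.getLogger(__name__)

__all__ = [
    "SkinDepthError",
    "InvalidConfigError",
    "InvalidInputError",
    "DegenerateInputError",
    "Spectrum",
    "SpectralMap",
    "PreprocessConfig",
    "smooth_savitzky_golay",
    "correct_baseline",
    "filter_low_signal",
    "crop",
    "vector_normalize",
    "preprocess_map",
]

QC_SIGNAL_KEY = "qc_signal_cts"  # cached band maximum, survives cropping


class SkinDepthError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(SkinDepthError):
    """A configuration value is inconsistent or out of range."""


class InvalidInputError(SkinDepthError):
    """Input data violate a precondition."""


class DegenerateInputError(SkinDepthError):
    """Input is structurally valid but degenerate (e.g. all-zero spectrum)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """One Raman acquisition.

    Parameters
    ----------
    wavenumbers:
        Raman shift axis in cm⁻¹, strictly increasing.
    intensities:
        Signal in counts (cts), same length as the axis, all finite.
    meta:
        Free-form provenance tags (processing history, cached QC values...).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise InvalidInputError("wavenumbers and intensities must be 1-D")
        if len(self.wavenumbers) != len(self.intensities):
            raise InvalidInputError(
                f"axis length {len(self.wavenumbers)} != intensity length "
                f"{len(self.intensities)}"
            )
        if len(self.wavenumbers) and np.any(np.diff(self.wavenumbers) <= 0):
            raise InvalidInputError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise InvalidInputError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def with_intensities(self, intensities: np.ndarray, **meta_updates) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.wavenumbers.copy(), np.asarray(intensities, float), meta)


@dataclass
class MapPixel:
    """A grid position (µm) holding one spectrum."""

    x: float
    y: float
    spectrum: Spectrum


@dataclass
class SpectralMap:
    """Grid of pixels, each holding a spectrum on a shared wavenumber axis.

    ``y`` increases into the skin; ``surface_y`` marks the depth origin
    (the skin surface), so depth = y − surface_y.
    """

    pixels: list[MapPixel]
    step: float = 5.0
    surface_y: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise InvalidConfigError("step must be positive")
        coords = [(p.x, p.y) for p in self.pixels]
        if len(set(coords)) != len(coords):
            raise InvalidInputError("(x, y) pixel coordinates must be unique")
        if self.pixels:
            axis0 = self.pixels[0].spectrum.wavenumbers
            for p in self.pixels[1:]:
                if not np.array_equal(p.spectrum.wavenumbers, axis0):
                    raise InvalidInputError("all map spectra must share one axis")
        if self.surface_y is None and self.pixels:
            self.surface_y = min(p.y for p in self.pixels)
        if self.surface_y is not None:
            for p in self.pixels:
                if p.y < self.surface_y - 1e-9:
                    raise InvalidInputError(
                        f"pixel y={p.y} above surface_y={self.surface_y}"
                    )

    def __len__(self) -> int:
        return len(self.pixels)

    def __iter__(self) -> Iterator[MapPixel]:
        return iter(self.pixels)

    @property
    def wavenumbers(self) -> np.ndarray:
        if not self.pixels:
            raise InvalidInputError("empty map has no axis")
        return self.pixels[0].spectrum.wavenumbers


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    Defaults follow the pipeline's published recipe: 2nd-order
    Savitzky–Golay smoothing, degree-7 polynomial baseline, suppression of
    pixels whose corrected signal stays under 400 cts in 1530–1730 cm⁻¹,
    and cropping to 400–785 cm⁻¹.  The smoothing window length (11 points)
    is a common spectroscopy default; it preserves peaks ≥3 channels wide.
    """

    sg_window: int = 11
    sg_order: int = 2
    baseline_degree: int = 7
    qc_band: tuple[float, float] = (1530.0, 1730.0)
    qc_threshold: float = 400.0
    crop_band: tuple[float, float] = (400.0, 785.0)
    baseline_tol: float = 1e-4
    baseline_max_iter: int = 100

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise InvalidConfigError("sg_window must be odd")
        if self.sg_window <= self.sg_order:
            raise InvalidConfigError("sg_window must exceed sg_order")
        for name in ("qc_band", "crop_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidConfigError(f"{name} must be ordered (low < high)")
        if self.qc_threshold < 0:
            raise InvalidConfigError("qc_threshold must be ≥ 0")
        if self.baseline_degree < 0:
            raise InvalidConfigError("baseline_degree must be ≥ 0")


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------


def smooth_savitzky_golay(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Savitzky–Golay smoothing: local least-squares polynomial fits.

    Interior points use the standard SG convolution over ``cfg.sg_window``
    points.  Edges use shrink-fit: the window is truncated to the available
    points and the polynomial refit there, so no data are invented beyond
    the spectrum ends.  Polynomials of degree ≤ ``sg_order`` are fixed
    points of the filter on any (possibly non-uniform index) sampling.
    """
    n = len(s)
    window, order = cfg.sg_window, cfg.sg_order
    if window > n:
        raise InvalidConfigError(
            f"sg_window={window} longer than spectrum length {n}"
        )
    half = window // 2
    y = s.intensities
    w = s.wavenumbers
    out = np.empty(n)
    gaps = np.diff(w)
    uniform = bool(np.allclose(gaps, gaps[0], rtol=1e-9, atol=0.0)) if n > 1 else True
    if uniform:
        # interior: one convolution with precomputed SG coefficients
        coeffs = savgol_coeffs(window, order)
        out[half : n - half] = np.convolve(y, coeffs, mode="valid")
        interior = ()
    else:
        # irregular axis: per-point local fit in wavenumber coordinates
        interior = range(half, n - half)
    edge = list(range(half)) + list(range(n - half, n))
    for i in list(interior) + edge:
        # shrink-fit at edges: truncate the window to the points that exist
        lo, hi = max(0, i - half), min(n, i + half + 1)
        t = w[lo:hi] - w[i]  # center on the evaluation point
        c = npoly.polyfit(t, y[lo:hi], min(order, hi - lo - 1))
        out[i] = c[0]
    return s.with_intensities(out, smoothed=True)


def _polynomial_baseline(
    wavenumbers: np.ndarray,
    intensities: np.ndarray,
    degree: int,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Iterative modified-polynomial baseline (fit, clip, refit).

    Returns (baseline, coefficients on the scaled axis, converged flag).
    Plain least squares bleeds peaks into the baseline; clipping the
    working signal to min(signal, fit) at each pass is the standard Raman
    remedy.  The axis is mapped to [-1, 1] for conditioning.
    """
    # design matrix built once; each iteration is a cheap projection
    t = 2.0 * (wavenumbers - wavenumbers[0]) / (wavenumbers[-1] - wavenumbers[0]) - 1.0
    V = np.vander(t, degree + 1, increasing=True)
    pinv = np.linalg.pinv(V)
    work = intensities.astype(float).copy()
    baseline = V @ (pinv @ work)
    converged = False
    scale = float(np.max(np.abs(intensities))) or 1.0
    for _ in range(max_iter):
        work = np.minimum(work, baseline)
        coef = pinv @ work
        new_baseline = V @ coef
        delta = np.max(np.abs(new_baseline - baseline)) / scale
        baseline = new_baseline
        if delta < tol:
            converged = True
            break
    return baseline, coef, converged


def correct_baseline(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Subtract an iteratively-refit polynomial baseline of the configured degree.

    The fitted coefficients (on the axis rescaled to [-1, 1]) are recorded
    in ``meta["baseline_coefficients"]``.  Non-convergence within the
    iteration budget logs a warning and returns the last iterate.
    """
    if len(s) <= cfg.baseline_degree + 1:
        raise InvalidInputError(
            f"spectrum length {len(s)} too short for degree "
            f"{cfg.baseline_degree} baseline"
        )
    baseline, coef, converged = _polynomial_baseline(
        s.wavenumbers, s.intensities, cfg.baseline_degree,
        cfg.baseline_tol, cfg.baseline_max_iter,
    )
    if not converged:
        warnings.warn("baseline iteration did not converge; using last iterate",
                      stacklevel=2)
        logger.warning("baseline iteration did not converge")
    return s.with_intensities(
        s.intensities - baseline,
        baseline_corrected=True,
        baseline_coefficients=coef.tolist(),
    )


def _band_max(s: Spectrum, band: tuple[float, float]) -> float | None:
    lo, hi = band
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        return None
    return float(np.max(s.intensities[mask]))


def qc_signal(s: Spectrum, cfg: PreprocessConfig) -> float:
    """Band maximum in the QC window, falling back to the cached meta value.

    The fallback lets the low-signal filter re-evaluate spectra that were
    already cropped past the QC band (e.g. on a second preprocessing pass).
    """
    value = _band_max(s, cfg.qc_band)
    if value is not None:
        return value
    if QC_SIGNAL_KEY in s.meta:
        return float(s.meta[QC_SIGNAL_KEY])
    raise InvalidConfigError(
        f"qc_band {cfg.qc_band} outside spectral axis and no cached QC value"
    )


def filter_low_signal(m: SpectralMap, cfg: PreprocessConfig) -> SpectralMap:
    """Suppress pixels whose QC-band maximum is strictly under the threshold.

    A pixel at exactly the threshold is retained ("under 400 cts" is
    strict).  Retained spectra are passed through untouched; removed pixel
    coordinates are logged.
    """
    kept: list[MapPixel] = []
    removed: list[tuple[float, float]] = []
    for p in m.pixels:
        if qc_signal(p.spectrum, cfg) >= cfg.qc_threshold:
            kept.append(p)
        else:
            removed.append((p.x, p.y))
    if removed:
        logger.info("suppressed %d low-signal pixel(s): %s", len(removed), removed)
    meta = dict(m.meta)
    meta["suppressed_pixels"] = removed
    return SpectralMap(kept, step=m.step, surface_y=m.surface_y, meta=meta)


def crop(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Keep channels with crop_band.low ≤ w ≤ crop_band.high (both ends in)."""
    lo, hi = cfg.crop_band
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        raise InvalidInputError(
            f"crop_band {cfg.crop_band} does not intersect the axis"
        )
    return Spectrum(s.wavenumbers[mask], s.intensities[mask], dict(s.meta))


def vector_normalize(s: Spectrum) -> Spectrum:
    """Scale intensities to unit Euclidean norm."""
    norm = float(np.linalg.norm(s.intensities))
    if norm == 0.0:
        raise DegenerateInputError("cannot vector-normalize an all-zero spectrum")
    return s.with_intensities(s.intensities / norm, vector_norm=norm)


def preprocess_map(m: SpectralMap, cfg: PreprocessConfig) -> SpectralMap:
    """Full chain: smooth → baseline → low-signal filter → crop → normalize.

    The QC decision uses the smoothed, baseline-corrected (pre-crop,
    pre-normalization) signal; that band maximum is cached in each
    spectrum's meta so the filter stays re-evaluable after cropping.
    Per-stage pixel counts are recorded in the output map's meta.
    """
    corrected: list[MapPixel] = []
    for p in m.pixels:
        s = smooth_savitzky_golay(p.spectrum, cfg)
        s = correct_baseline(s, cfg)
        s.meta[QC_SIGNAL_KEY] = qc_signal(s, cfg)
        corrected.append(MapPixel(p.x, p.y, s))
    stage = SpectralMap(corrected, step=m.step, surface_y=m.surface_y,
                        meta=dict(m.meta))
    filtered = filter_low_signal(stage, cfg)
    out_pixels = [
        MapPixel(p.x, p.y, vector_normalize(crop(p.spectrum, cfg)))
        for p in filtered.pixels
    ]
    meta = dict(filtered.meta)
    meta["pixel_counts"] = {
        "input": len(m),
        "after_filter": len(filtered),
        "output": len(out_pixels),
    }
    logger.info("preprocess: %d → %d pixels", len(m), len(out_pixels))
    return SpectralMap(out_pixels, step=m.step, surface_y=m.surface_y, meta=meta)
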