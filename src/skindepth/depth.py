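"""Depth profiles and penetration-depth estimation.

An abundance map is collapsed along x into a per-depth mean profile of the
tracked component; the penetration depth is read off as the deepest bin
whose mean abundance still reaches a configurable fraction (default 5%) of
the profile maximum.  Replicate estimates (the study design is 3 sections
× 3 acquisitions = 9 measures per sample) are aggregated as mean ± sample
SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import InvalidInputError
from .unmixing import AbundanceMap

__all__ = [
    "DepthProfile",
    "PenetrationEstimate",
    "depth_profile",
    "penetration_depth",
    "aggregate_replicates",
]

DEFAULT_THRESHOLD_FRACTION = 0.05


@dataclass
class DepthProfile:
    """Mean tracked-component abundance vs depth below the skin surface.

    ``mean_abundance`` is NaN for bins in which every pixel was
    QC-suppressed (``n_pixels == 0``); such bins are reported, never
    interpolated.
    """

    depths: np.ndarray          # µm from surface, bin centers, step-spaced
    mean_abundance: np.ndarray  # NaN where n_pixels == 0
    n_pixels: np.ndarray
    component: str = ""

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, float)
        self.mean_abundance = np.asarray(self.mean_abundance, float)
        self.n_pixels = np.asarray(self.n_pixels, int)
        if not (len(self.depths) == len(self.mean_abundance) == len(self.n_pixels)):
            raise InvalidInputError("profile arrays must have equal length")
        if len(self.depths) > 1 and np.any(np.diff(self.depths) <= 0):
            raise InvalidInputError("depths must be strictly increasing")
        defined = self.n_pixels > 0
        if np.any(self.mean_abundance[defined] < 0):
            raise InvalidInputError("mean abundance must be ≥ 0")
        if np.any(self.n_pixels < 0):
            raise InvalidInputError("n_pixels must be ≥ 0")


@dataclass
class PenetrationEstimate:
    depth: float                # µm; 0 with detected=False when no signal
    threshold_fraction: float
    profile: DepthProfile
    replicate_id: str | None = None
    detected: bool = True


def depth_profile(
    a: AbundanceMap,
    component: str,
    surface_y: float | None = None,
    step: float | None = None,
) -> DepthProfile:
    """Group pixels into step-spaced depth bins and average over x.

    ``surface_y`` defaults to the shallowest retained pixel (cryosection
    stage origins are arbitrary).  ``step`` defaults to the smallest
    positive spacing between distinct pixel depths.  Bins with no retained
    pixel get ``n_pixels = 0`` and NaN mean.
    """
    idx = a.component_index(component)
    if not a.pixels:
        return DepthProfile(np.array([]), np.array([]), np.array([], int), component)
    ys = np.array([p.y for p in a.pixels])
    if surface_y is None:
        surface_y = float(ys.min())
    elif surface_y > ys.min() + 1e-9:
        raise InvalidInputError("surface_y must not exceed the shallowest pixel y")
    depths = ys - surface_y
    if step is None:
        uniq = np.unique(np.round(depths, 9))
        gaps = np.diff(uniq)
        step = float(gaps.min()) if len(gaps) else 1.0
    n_bins = int(round(depths.max() / step)) + 1
    bin_depths = np.arange(n_bins) * step
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, int)
    for p, d in zip(a.pixels, depths):
        b = int(round(d / step))
        if abs(d - b * step) > step * 1e-6:
            raise InvalidInputError(
                f"pixel depth {d} µm is not on the {step} µm grid"
            )
        sums[b] += p.coefficients[idx]
        counts[b] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DepthProfile(bin_depths, means, counts, component)


def penetration_depth(
    p: DepthProfile,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    replicate_id: str | None = None,
) -> PenetrationEstimate:
    """Deepest bin whose mean abundance ≥ threshold_fraction × profile max.

    Bins with no retained pixels are excluded from the threshold logic.  A
    profile whose maximum is 0 yields depth 0 flagged as not detected.
    """
    if not 0 < threshold_fraction < 1:
        raise InvalidInputError("threshold_fraction must be in (0, 1)")
    defined = p.n_pixels > 0
    if not defined.any():
        raise InvalidInputError("profile has no bin with a defined mean")
    values = p.mean_abundance[defined]
    depths = p.depths[defined]
    peak = float(values.max())
    if peak <= 0:
        return PenetrationEstimate(0.0, threshold_fraction, p, replicate_id,
                                   detected=False)
    above = depths[values >= threshold_fraction * peak]
    return PenetrationEstimate(float(above.max()), threshold_fraction, p,
                               replicate_id, detected=True)


def aggregate_replicates(
    estimates: list[PenetrationEstimate],
) -> tuple[float, float | None, int]:
    """Mean and sample SD (n−1) of replicate penetration depths.

    SD is None (undefined) for a single replicate.
    """
    if not estimates:
        raise InvalidInputError("no estimates to aggregate")
    depths = np.array([e.depth for e in estimates], float)
    mean = float(depths.mean())
    sd = float(depths.std(ddof=1)) if len(depths) > 1 else None
    return mean, sd, len(depths)
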