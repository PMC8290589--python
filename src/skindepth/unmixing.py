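"""Non-negativity-constrained classical least squares (NCLS) unmixing.

Each preprocessed pixel spectrum is decomposed into non-negative
contributions of reference component spectra (skin constituents plus the
tracked exogenous species) by solving

    min_{c ≥ 0} ‖ s − R c ‖₂

with the Lawson–Hanson active-set solver.  The coefficient on the tracked
component, mapped over the grid, is the spatial distribution of the
antibody species through the cryosection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .spectra import (
    InvalidInputError,
    MapPixel,
    SpectralMap,
    Spectrum,
)

logger = logging.getLogger(__name__)

__all__ = ["ReferenceSet", "AbundancePixel", "AbundanceMap", "ncls_fit", "unmix_map"]


@dataclass
class ReferenceSet:
    """Named component spectra on one common axis, one flagged as the tracer.

    Parameters
    ----------
    components:
        ``(name, Spectrum)`` pairs; all spectra must share an identical
        wavenumber axis and none may be the zero vector.
    tracked:
        Name of the exogenous species being followed (e.g. ``"scFv"``).
    """

    components: list[tuple[str, Spectrum]]
    tracked: str

    def __post_init__(self) -> None:
        if len(self.components) < 2:
            raise InvalidInputError("a ReferenceSet needs ≥ 2 components")
        names = [n for n, _ in self.components]
        if len(set(names)) != len(names):
            raise InvalidInputError("component names must be unique")
        if self.tracked not in names:
            raise InvalidInputError(f"tracked component {self.tracked!r} not present")
        axis0 = self.components[0][1].wavenumbers
        for name, spec in self.components:
            if not np.array_equal(spec.wavenumbers, axis0):
                raise InvalidInputError(f"component {name!r} is on a different axis")
            if not np.any(spec.intensities):
                raise InvalidInputError(f"component {name!r} is the zero vector")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.components]

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.components[0][1].wavenumbers

    def matrix(self) -> np.ndarray:
        """Channels × components reference matrix R."""
        return np.column_stack([s.intensities for _, s in self.components])

    def is_rank_deficient(self) -> bool:
        return bool(np.linalg.matrix_rank(self.matrix()) < len(self.components))


@dataclass
class AbundancePixel:
    x: float
    y: float
    coefficients: np.ndarray  # per-component, ≥ 0, ordered as ReferenceSet
    residual_norm: float


@dataclass
class AbundanceMap:
    """Per-pixel non-negative component coefficients from unmixing."""

    pixels: list[AbundancePixel]
    component_names: list[str]
    tracked: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.pixels:
            p.coefficients = np.asarray(p.coefficients, float)
            if p.coefficients.shape != (len(self.component_names),):
                raise InvalidInputError("coefficient length mismatch")
            if np.any(p.coefficients < 0):
                raise InvalidInputError("coefficients must be non-negative")
            if not np.isfinite(p.residual_norm) or p.residual_norm < 0:
                raise InvalidInputError("residual_norm must be finite and ≥ 0")

    def __len__(self) -> int:
        return len(self.pixels)

    def component_index(self, name: str) -> int:
        try:
            return self.component_names.index(name)
        except ValueError:
            raise InvalidInputError(f"unknown component {name!r}") from None


def ncls_fit(s: Spectrum, refs: ReferenceSet) -> tuple[np.ndarray, float]:
    """Solve min_{c ≥ 0} ‖s − R c‖₂ for one spectrum.

    Returns the coefficient vector (ordered as ``refs.components``) and the
    achieved residual norm.  Deterministic for fixed input.  A
    rank-deficient reference matrix is solved anyway (the minimum-norm
    objective is still well defined) and only flagged by the caller.
    """
    if not np.array_equal(s.wavenumbers, refs.wavenumbers):
        raise InvalidInputError("spectrum is not on the reference axis")
    coef, residual = nnls(refs.matrix(), s.intensities)
    return coef, float(residual)


def unmix_map(m: SpectralMap, refs: ReferenceSet) -> AbundanceMap:
    """Apply :func:`ncls_fit` per pixel, preserving grid coordinates.

    Expects a preprocessed map (cropped to the reference axis); pixel count
    is conserved.  An empty map yields an empty AbundanceMap.
    """
    rank_deficient = refs.is_rank_deficient()
    if rank_deficient:
        logger.warning("reference matrix is rank deficient; solutions may be non-unique")
    pixels = []
    for p in m.pixels:
        coef, res = ncls_fit(p.spectrum, refs)
        pixels.append(AbundancePixel(p.x, p.y, coef, res))
    meta = {"rank_deficient": rank_deficient, "n_pixels": len(pixels)}
    meta.update({k: v for k, v in m.meta.items() if k == "pixel_counts"})
    return AbundanceMap(pixels, refs.names, refs.tracked, meta=meta)
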