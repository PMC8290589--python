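"""Synthetic data generators: reference spectra, hyperspectral skin maps
with known ground truth, and donor-structured assay plates.

The map simulator emulates a confocal Raman acquisition of a skin
cryosection: a 10 µm × 150 µm grid at 5 µm step, spectra on a 400–2300
cm⁻¹ axis, skin component signatures mixed by depth zone, an exogenous
tracer whose abundance decays past a logistic penetration front, a
fluorescence-like degree-7 polynomial baseline dominating the Raman peaks,
additive Gaussian shot-like noise, and a small number of low-signal pixels
that the QC filter should suppress.

The assay simulator produces donor-structured NHK plates: per-donor poly
I:C and hIL-4 + poly I:C anchors and dose responses following a monotone
saturating inhibition curve with a multiplicative donor random effect,
calibrated to the reference dataset's top-dose summary (mean ≈ 80%,
SD ≈ 36% at 600 nM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import InvalidConfigError, MapPixel, SpectralMap, Spectrum
from .unmixing import AbundanceMap, AbundancePixel, ReferenceSet

__all__ = [
    "ComponentSpec",
    "MapSimConfig",
    "AssaySimConfig",
    "make_references",
    "make_map",
    "make_assay",
]

MIN_PEAK_SEPARATION_CM1 = 15.0  # tracer vs skin peak positions


@dataclass(frozen=True)
class ComponentSpec:
    """Gaussian-peak mixture defining one reference component."""

    name: str
    peaks_cm1: tuple[float, ...]
    widths_cm1: tuple[float, ...]
    amplitudes_cts: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.peaks_cm1) == len(self.widths_cm1) == len(self.amplitudes_cts)):
            raise InvalidConfigError(f"component {self.name!r}: ragged peak lists")
        if not self.peaks_cm1 or all(a == 0 for a in self.amplitudes_cts):
            raise InvalidConfigError(
                f"component {self.name!r} would be a flat zero reference"
            )


def _default_components() -> tuple[ComponentSpec, ...]:
    # Skin constituents carry amide-I signal (1530–1730 cm⁻¹) so that
    # ordinary pixels clear the 400-cts QC threshold; the tracer's three
    # peaks sit inside the 400–785 cm⁻¹ window of interest, ≥15 cm⁻¹ from
    # any skin peak.
    return (
        ComponentSpec("keratin",
                      (526.0, 644.0, 1003.0, 1450.0, 1655.0),
                      (12.0, 12.0, 8.0, 14.0, 18.0),
                      (300.0, 250.0, 400.0, 350.0, 900.0)),
        ComponentSpec("collagen",
                      (570.0, 700.0, 1246.0, 1670.0),
                      (14.0, 12.0, 16.0, 18.0),
                      (250.0, 300.0, 400.0, 800.0)),
        ComponentSpec("lipid",
                      (430.0, 1080.0, 1300.0, 1440.0),
                      (10.0, 14.0, 16.0, 12.0),
                      (150.0, 300.0, 350.0, 500.0)),
        ComponentSpec("scFv",
                      (455.0, 590.0, 735.0),
                      (8.0, 8.0, 8.0),
                      (500.0, 600.0, 450.0)),
    )


# Depth-zone weights for (keratin, collagen, lipid): a stratum-corneum-like
# zone (0–20 µm), an epidermis-like zone (20–60 µm) and a dermis-like zone
# beyond — synthetic stand-ins, not anatomy.
_ZONES = (
    (20.0, {"keratin": 1.5, "collagen": 0.2, "lipid": 0.8}),
    (60.0, {"keratin": 1.0, "collagen": 0.5, "lipid": 0.4}),
    (np.inf, {"keratin": 0.3, "collagen": 1.5, "lipid": 0.3}),
)


@dataclass(frozen=True)
class MapSimConfig:
    """Acquisition geometry, tracer front, baseline and noise settings.

    All randomness is fixed by ``seed``.  The defaults reproduce the study
    acquisition: X extent 10 µm, Y extent 150 µm, 5 µm step (3 × 31 = 93
    pixels), spectral axis 400–2300 cm⁻¹.
    """

    seed: int = 0
    axis_cm1: tuple[float, float] = (400.0, 2300.0)
    axis_step_cm1: float = 2.0
    x_extent_um: float = 10.0
    y_extent_um: float = 150.0
    step_um: float = 5.0
    components: tuple[ComponentSpec, ...] = field(default_factory=_default_components)
    tracer: str = "scFv"
    tracer_front_um: float = 130.0
    front_softness_um: float = 1.0
    tracer_level: float = 1.0
    baseline_coeffs: tuple[float, ...] | str = "random"
    baseline_scale_cts: float = 3000.0
    noise_sd_cts: float = 20.0
    low_signal_pixels: int | tuple[tuple[float, float], ...] = 2

    def __post_init__(self) -> None:
        lo, hi = self.axis_cm1
        if not lo < hi or self.axis_step_cm1 <= 0:
            raise InvalidConfigError("bad spectral axis specification")
        if self.step_um <= 0 or self.x_extent_um < 0 or self.y_extent_um <= 0:
            raise InvalidConfigError("bad grid specification")
        if not 0.0 <= self.tracer_front_um <= self.y_extent_um:
            raise InvalidConfigError(
                f"tracer_front_um={self.tracer_front_um} outside "
                f"[0, {self.y_extent_um}]"
            )
        names = [c.name for c in self.components]
        if self.tracer not in names:
            raise InvalidConfigError(f"tracer {self.tracer!r} not among components")
        tracer_peaks = [p for c in self.components if c.name == self.tracer
                        for p in c.peaks_cm1]
        for p in tracer_peaks:
            if not 400.0 <= p <= 785.0:
                raise InvalidConfigError(
                    f"tracer peak {p} cm⁻¹ outside the 400–785 cm⁻¹ window"
                )
        skin_peaks = [p for c in self.components if c.name != self.tracer
                      for p in c.peaks_cm1]
        for tp in tracer_peaks:
            for sp in skin_peaks:
                if abs(tp - sp) < MIN_PEAK_SEPARATION_CM1:
                    raise InvalidConfigError(
                        f"tracer peak {tp} within {MIN_PEAK_SEPARATION_CM1} cm⁻¹ "
                        f"of skin peak {sp}"
                    )

    def wavenumber_axis(self) -> np.ndarray:
        lo, hi = self.axis_cm1
        n = int(round((hi - lo) / self.axis_step_cm1)) + 1
        return lo + self.axis_step_cm1 * np.arange(n)

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        nx = int(round(self.x_extent_um / self.step_um)) + 1
        ny = int(round(self.y_extent_um / self.step_um)) + 1
        return self.step_um * np.arange(nx), self.step_um * np.arange(ny)


def _gaussian_mixture(axis: np.ndarray, spec: ComponentSpec) -> np.ndarray:
    out = np.zeros_like(axis)
    for mu, w, a in zip(spec.peaks_cm1, spec.widths_cm1, spec.amplitudes_cts):
        out += a * np.exp(-0.5 * ((axis - mu) / w) ** 2)
    return out


def make_references(cfg: MapSimConfig) -> ReferenceSet:
    """Build the reference library on the full simulated axis.

    Deterministic for a given config (no randomness is involved); the
    tracer component has exactly three Gaussian peaks inside 400–785 cm⁻¹.
    """
    axis = cfg.wavenumber_axis()
    components = [
        (c.name, Spectrum(axis, _gaussian_mixture(axis, c), {"component": c.name}))
        for c in cfg.components
    ]
    return ReferenceSet(components, tracked=cfg.tracer)


def _skin_weights(depth: float) -> dict[str, float]:
    for limit, weights in _ZONES:
        if depth <= limit:
            return weights
    raise AssertionError("unreachable")


def _tracer_weight(depth: float, cfg: MapSimConfig) -> float:
    # logistic front: ~tracer_level above the front, → 0 below it
    z = (depth - cfg.tracer_front_um) / max(cfg.front_softness_um, 1e-9)
    if z > 500:
        return 0.0
    return cfg.tracer_level / (1.0 + np.exp(z))


def _baseline(axis: np.ndarray, cfg: MapSimConfig, rng: np.random.Generator) -> np.ndarray:
    t = 2.0 * (axis - axis[0]) / (axis[-1] - axis[0]) - 1.0
    if isinstance(cfg.baseline_coeffs, str):
        if cfg.baseline_coeffs != "random":
            raise InvalidConfigError("baseline_coeffs must be coefficients or 'random'")
        coef = rng.normal(size=8)
        shape = np.polynomial.polynomial.polyval(t, coef)
        span = np.ptp(shape) or 1.0
        # positive, fluorescence-like, 2–5× the Raman peak amplitudes
        scale = cfg.baseline_scale_cts * rng.uniform(2.0 / 3.0, 5.0 / 3.0) / span
        return (shape - shape.min()) * scale + 0.2 * cfg.baseline_scale_cts
    coef = np.asarray(cfg.baseline_coeffs, float)
    return np.polynomial.polynomial.polyval(t, coef)


def make_map(
    cfg: MapSimConfig,
    refs: ReferenceSet | None = None,
) -> tuple[SpectralMap, AbundanceMap]:
    """Simulate a noisy hyperspectral map plus its noise-free ground truth.

    Per pixel, the true abundance vector combines depth-zone skin weights
    with the logistic tracer front; the recorded spectrum is the reference
    mixture plus the polynomial baseline plus Gaussian noise.  Designated
    low-signal pixels are attenuated far below the QC threshold.  Returns
    ``(map, truth)`` with identical grids.
    """
    if refs is None:
        refs = make_references(cfg)
    rng = np.random.default_rng(cfg.seed)
    axis = cfg.wavenumber_axis()
    xs, ys = cfg.grid()
    ref_vectors = {name: spec.intensities for name, spec in refs.components}
    names = refs.names

    coords = [(x, y) for x in xs for y in ys]
    if isinstance(cfg.low_signal_pixels, int):
        n_low = cfg.low_signal_pixels
        if n_low > len(coords):
            raise InvalidConfigError("more low-signal pixels than grid points")
        chosen = rng.choice(len(coords), size=n_low, replace=False) if n_low else []
        low = {coords[i] for i in chosen}
    else:
        low = {(float(x), float(y)) for x, y in cfg.low_signal_pixels}

    pixels: list[MapPixel] = []
    truth: list[AbundancePixel] = []
    for x, y in coords:
        depth = y  # surface at y = 0 in simulation coordinates
        weights = dict(_skin_weights(depth))
        weights[cfg.tracer] = _tracer_weight(depth, cfg)
        attenuation = 0.05 if (x, y) in low else 1.0
        coeffs = np.array([attenuation * weights.get(n, 0.0) for n in names])
        clean = sum(c * ref_vectors[n] for c, n in zip(coeffs, names))
        signal = clean + _baseline(axis, cfg, rng)
        if cfg.noise_sd_cts > 0:
            signal = signal + rng.normal(0.0, cfg.noise_sd_cts, size=axis.shape)
        pixels.append(MapPixel(float(x), float(y),
                               Spectrum(axis, signal, {"x_um": x, "y_um": y})))
        truth.append(AbundancePixel(float(x), float(y), coeffs, 0.0))

    smap = SpectralMap(pixels, step=cfg.step_um, surface_y=0.0,
                       meta={"seed": cfg.seed,
                             "tracer_front_um": cfg.tracer_front_um,
                             "low_signal_pixels": sorted(low)})
    amap = AbundanceMap(truth, names, refs.tracked,
                        meta={"ground_truth": True, "seed": cfg.seed})
    return smap, amap


# ---------------------------------------------------------------------------
# Assay plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssaySimConfig:
    """Donor-structured NHK plate simulation.

    ``max_neutralization`` and ``half_effect_nM`` parameterize the
    saturating inhibition curve Emax·d/(d + K); with the defaults the
    expected neutralization at 600 nM is 80%.  ``donor_effect_sd`` is the
    sigma of a mean-one lognormal multiplier per donor (relative SD ≈ 0.42,
    i.e. ≈ 34 percentage points at the top dose); ``residual_sd`` is
    per-well noise as a fraction of the anchor gap.  ``polyIC_induction``
    is the poly I:C-alone IL-8 level in pg per µg protein and
    ``hIL4_potentiation`` the fold increase when hIL-4 is added.
    """

    seed: int = 0
    n_donors: int = 4
    doses_nM: tuple[float, ...] = (10.0, 100.0, 200.0, 400.0, 600.0)
    donor_effect_sd: float = 0.4
    max_neutralization: float = 1.0
    half_effect_nM: float = 150.0
    residual_sd: float = 0.05
    polyIC_induction: float = 10.0
    hIL4_potentiation: float = 2.5
    protein_mean_ug: float = 50.0
    protein_sd_ug: float = 5.0

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise InvalidConfigError("need at least one donor")
        d = np.asarray(self.doses_nM)
        if len(d) == 0 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise InvalidConfigError("doses must be positive and increasing")
        if self.half_effect_nM <= 0 or self.hIL4_potentiation <= 1:
            raise InvalidConfigError("bad inhibition-curve parameters")


def make_assay(cfg: AssaySimConfig) -> pd.DataFrame:
    """Simulate a plate: per-donor anchors plus dose responses.

    Responses are IL-8 well contents (pg/ml-equivalent) generated as a
    per-µg rate times the well's total protein, so that
    :func:`skindepth.assays.normalize_il8` recovers the rate.  Same seed →
    identical plate.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    sigma = cfg.donor_effect_sd
    for i in range(cfg.n_donors):
        donor = f"SD{i + 1:02d}"
        donor_level = float(np.exp(rng.normal(0.0, 0.15)))
        r100 = cfg.polyIC_induction * donor_level          # poly I:C alone
        r0 = r100 * cfg.hIL4_potentiation                  # + hIL-4
        gap = r0 - r100
        # mean-one lognormal donor sensitivity to the scFv
        f = float(rng.lognormal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0

        def emit(condition: str, dose: float, rate: float) -> None:
            protein = max(float(rng.normal(cfg.protein_mean_ug, cfg.protein_sd_ug)),
                          1.0)
            rows.append({"donor": donor, "condition": condition,
                         "dose_nM": dose, "response": rate * protein,
                         "total_protein_ug": protein})

        emit("polyIC", 0.0, r100 + rng.normal(0.0, cfg.residual_sd) * gap)
        emit("hIL4_polyIC", 0.0, r0 + rng.normal(0.0, cfg.residual_sd) * gap)
        for dose in cfg.doses_nM:
            neut = f * cfg.max_neutralization * dose / (dose + cfg.half_effect_nM)
            rate = r0 - neut * gap + rng.normal(0.0, cfg.residual_sd) * gap
            emit("scFv_dose", float(dose), rate)
    return pd.DataFrame(rows)
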