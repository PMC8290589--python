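# Methods

`skindepth` models two analyses around topical antibody delivery: (i) the
quantification, by confocal Raman microspectroscopy, of how deep an
exogenous antibody species (a ~25 kDa single-chain variable fragment,
scFv, versus a ~150 kDa full-size antibody, Ab) penetrates a skin
cryosection, and (ii) the statistics of an hIL-4 neutralization assay on
normal human keratinocytes (NHKs) expressed on a per-donor anchored
percentage scale.

## Spectral preprocessing

Each pixel of a hyperspectral map (spectra on a 400–2300 cm⁻¹ Raman-shift
axis, grid coordinates in µm) passes through five stages, in this order:

1. **Savitzky–Golay smoothing** — local least-squares polynomial fits of
   order 2 over an 11-point window. The window length is a package
   default (the recipe fixes only the order); 11 points at ~2 cm⁻¹
   spacing preserves peaks ≥3 channels wide. Edges use *shrink-fit*: the
   window is truncated to the points that exist and the polynomial refit
   there, so no data are invented beyond the spectrum ends. On a uniform
   axis the interior is a single convolution with the standard SG
   coefficients; on an irregular axis every point is fit locally in
   wavenumber coordinates, which keeps the defining property — exact
   reproduction of polynomials of degree ≤ 2 — on any sampling.
2. **Baseline correction** — fluorescence backgrounds are removed by an
   iterative modified-polynomial ("modpoly"-style) fit of degree 7: fit
   the polynomial by least squares on the axis rescaled to [−1, 1] (for
   conditioning), clip the working signal to min(signal, fit), refit;
   stop when the baseline changes by < 10⁻⁴ of the signal scale or after
   100 iterations (non-convergence logs a warning and keeps the last
   iterate). Plain one-shot least squares bleeds peaks into the baseline;
   clipping is the standard Raman remedy. Fitted coefficients are stored
   in the spectrum's metadata.
3. **Low-signal suppression** — a pixel is dropped when the *maximum* of
   its smoothed, baseline-corrected intensity inside 1530–1730 cm⁻¹ (the
   amide-I region) is strictly below 400 cts; a pixel at exactly 400 cts
   is retained. Band maximum (rather than band mean) is used because a
   quality criterion phrased as "an intensity under the threshold" reads
   most naturally as the peak signal. The band value is cached in the
   pixel's metadata so the filter can be re-evaluated after cropping.
4. **Cropping** to 400–785 cm⁻¹, inclusive at both ends.
5. **Vector normalization** — division by the Euclidean norm over the
   cropped range, making pixel intensities comparable regardless of
   focus and scattering efficiency. An all-zero spectrum is a hard error,
   never a silent division.

The composed pipeline is deterministic: identical input and configuration
give bit-identical output. Re-running it on its own output is supported
(the QC filter falls back to the cached band value) and leaves spectra
nearly unchanged (cosine similarity > 0.9 in tests), but repeated
baseline estimation on the peak-dominated cropped window is not an exact
identity and is not a recommended workflow.

## NCLS unmixing

Each preprocessed pixel spectrum *s* is decomposed against a reference
library *R* (skin components plus the tracked species, all cropped and
unit-normalized to keep coefficients on one scale) by classical least
squares under a non-negativity constraint:

    min‖s − Rc‖₂  subject to  c ≥ 0,

solved with the Lawson–Hanson active-set algorithm
(`scipy.optimize.nnls`). No sum-to-one constraint is imposed: the
coefficients are contributions, not fractional abundances, and unit-norm
preprocessing already makes them comparable across pixels. A
rank-deficient reference matrix is solved and flagged rather than
rejected — real reference sets can be nearly collinear and the residual
is still meaningful. Tests verify non-negativity, optimality against
random candidates and a brute-force grid oracle, agreement with
unconstrained least squares whenever that solution is already
non-negative, and 10⁻⁸-level recovery of exact mixtures.

## Depth profiling and penetration depth

The tracked component's coefficients are grouped into step-spaced depth
bins (depth = y − surface; the surface defaults to the shallowest
retained pixel, since cryosection stage origins are arbitrary) and
averaged over the x positions. Bins emptied by QC suppression are
reported with `n_pixels = 0` and an undefined mean — never interpolated.

The penetration depth is the deepest bin whose mean abundance is at least
a threshold fraction (default 5%) of the profile maximum, computed over
defined bins only. The 5% default is robust to the unmixing noise floor
and reproduces step-like synthetic fronts to within one 5 µm grid step;
it is configurable, and the estimate is monotone non-increasing in the
threshold. A profile whose maximum is zero returns depth 0 flagged "not
detected". Replicates (the study design reads 3 sections × 3 acquisitions
= 9 measures per sample) aggregate as arithmetic mean and sample SD
(n − 1; undefined for a single replicate).

## Neutralization statistics

For the NHK assay, IL-8 responses are first normalized per µg of total
protein in the well. Each donor's anchored neutralization percentage at
dose *d* is

    pct(d) = 100 · (r₀ − r_d) / (r₀ − r₁₀₀),

with the donor's own hIL-4 + poly I:C response as r₀ (0% neutralization)
and poly I:C alone as r₁₀₀ (100%). Anchors are never pooled across
donors — pooling would bias percentages by donor scale, and a dedicated
test guards against it. Percentages are unbounded; values below 0% and
above 100% occur in real donors and are preserved. For the HEK-Blue
reporter assay, OD620 responses are first expressed as percent of the
mean hIL-4-stimulated maximum, and the same anchored formula applies with
the stimulated condition as 0% and the unstimulated control as 100%.

Report tables round summary rows *half-up* to integer percent (so a mean
of 6.5 prints as 7; banker's rounding would print 6) and use sample SD
(n − 1), which matches the bundled reference dataset's printed summary at
every dose except its 100 nM SD, where the published value (35) differs
by one unit from what its own donor values give (34.45 → 34); the package
reports the recomputed value. Significance uses the two-tailed Student's
t-test — paired by donor for NHK dose-vs-control comparisons (donors are
matched units), unpaired for the reporter cell line — with the usual star
mapping at 0.05/0.01/0.001/0.0001. Zero-variance degenerate cases are
resolved explicitly (identical groups: t = 0, p = 1; constant nonzero
paired shift: p = 0, flagged) rather than returning NaN.

## Synthetic data

No spectra or plate data were deposited by the study the defaults
emulate, so the generators are first-class, tested code and define the
conditions everything else is validated under.

**Maps.** The default acquisition is X: 10 µm / Y: 150 µm at 5 µm step
(3 × 31 = 93 pixels), spectra at 2 cm⁻¹ spacing on 400–2300 cm⁻¹.
References are Gaussian-peak mixtures: three skin-like components
(keratin-, collagen- and lipid-like, with amide-I signal in 1530–1730
cm⁻¹ so ordinary pixels clear the 400 cts QC threshold) and a tracer
with exactly three peaks inside 400–785 cm⁻¹, each ≥ 15 cm⁻¹ from any
skin peak. True abundances combine three depth zones with distinct skin
weights (0–20 µm stratum-corneum-like, 20–60 µm epidermis-like, deeper
dermis-like — synthetic stand-ins, not anatomy) and a logistic tracer
front centred at the configured penetration depth (default softness 1
µm). Each pixel's spectrum adds a per-pixel random degree-7 polynomial
baseline scaled to ≈2–5× the Raman peak amplitudes (mimicking
fluorescence dominance) and additive Gaussian noise (default σ = 20 cts,
≈2% of the surface-level signal; Gaussian rather than Poisson for
simplicity and exact seedability). A configurable number of pixels
(default 2) is attenuated far below the QC threshold to exercise the
filter. The generator returns the noisy map *and* the noise-free
ground-truth abundances; all randomness derives from one seed.

**Plates.** Per donor, a poly I:C IL-8 level (default 10 pg/µg, with mild
donor variation), an hIL-4 potentiation factor (default 2.5×), and dose
responses following a saturating inhibition curve Emax·d/(d + K) with
Emax = 1.0 and K = 150 nM — which puts the expected neutralization at 600
nM at 80% — times a mean-one lognormal donor sensitivity (σ = 0.4,
relative SD ≈ 0.42, i.e. ≈ 34 percentage points at the top dose),
plus per-well noise at 5% of the anchor gap. These defaults were
calibrated once against the reference dataset's top-dose summary
(mean 80%, SD 36%). Well responses are generated as rate × total protein
(protein ~ N(50, 5) µg) so the protein normalization is exercised
end-to-end.

**What the simulations do not capture.** Physically realistic Raman
cross-sections, confocal depth attenuation and defocus, cosmic-ray
spikes, Poisson statistics, pig-versus-human skin differences, and real
anatomical layer boundaries. Passing tests therefore demonstrate that the
*algorithms* are correct and robust at the stated noise and baseline
levels — not that any particular real cryosection would yield the same
depths.

## Problem sizes and numerical choices

The validation suite uses 100 simulated maps per penetration condition
(fronts at 20 µm and 130 µm) and 200 simulated plates for the assay
calibration check; the acceptance script uses nine replicates per
condition (matching the study's replicate structure) and 80 maps for the
recovery rate. CSV floats are written with 12 significant digits, enough
for ~10⁻¹²-relative round-trips without noise-digit churn. Polynomial
fits use a [−1, 1]-rescaled axis; NCLS is deterministic; every pipeline
run writes a `provenance.json` (config snapshot + package version) from
which the run can be reproduced bit-identically.

## Known limitations

- The penetration criterion (deepest bin ≥ 5% of profile maximum) is one
  reasonable reading of "penetrated to depth X"; per-replicate maxima and
  aggregated estimates are both available, and the threshold is exposed.
- The baseline corrector assumes a polynomial-shaped background; sharp
  substrate artefacts would need a different model.
- The JCAMP-DX reader covers the `(X++(Y..Y))` and XY-pair table forms
  only, without compressed (DIF/DUP/SQZ) encodings.
- Repeated preprocessing is near-identity, not identity (see above).
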