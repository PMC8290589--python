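# skindepth

Tools for two linked questions in topical antibody delivery: **how deep
does an antibody format penetrate skin**, measured by confocal Raman
microspectroscopy of cryosections, and **how well does it neutralize its
cytokine target**, measured by donor-structured in vitro assays. The
motivating comparison is a ~25 kDa single-chain variable fragment (scFv)
against a ~150 kDa full-size antibody (Ab) on barrier-damaged skin, with
an anti-hIL-4 scFv assayed on normal human keratinocytes (NHKs).

The package is aimed at spectroscopists and pharmacology analysts who
have per-pixel Raman maps and plate tables (CSV) and want a reproducible,
tested path from raw spectra to a penetration depth in µm, and from raw
well responses to an anchored neutralization table with significance
calls. Since studies of this kind rarely deposit raw maps, `skindepth`
ships seeded synthetic generators that emulate the acquisition (10 µm ×
150 µm maps at 5 µm step, 400–2300 cm⁻¹ spectra, fluorescence baselines,
shot-like noise, low-signal pixels) and donor-structured plates, so every
stage is testable end-to-end with known ground truth.

## The method

**Penetration branch.** Each pixel spectrum is smoothed (2nd-order
Savitzky–Golay, 11-point window), baseline-corrected (iterative degree-7
polynomial), QC-filtered (pixels with a corrected band maximum under
400 cts in 1530–1730 cm⁻¹ are suppressed), cropped to 400–785 cm⁻¹ and
scaled to unit Euclidean norm. The preprocessed spectrum *s* is then
unmixed against a reference library *R* of skin components plus the
tracked species by classical least squares with a non-negativity
constraint (NCLS, Lawson–Hanson active set):

```
min ‖s − R c‖₂   s.t.  c ≥ 0
```

The tracked coefficient, averaged per depth bin, gives a depth profile;
the penetration depth is the deepest bin still reaching ≥ 5% (default) of
the profile maximum, and replicates aggregate as mean ± sample SD.

**Assay branch.** IL-8 responses are normalized per µg total protein,
then each donor's responses are mapped to an anchored percentage

```
pct = 100 · (r₀ − r_dose) / (r₀ − r₁₀₀)
```

with the donor's own hIL-4 + poly I:C response as the 0% anchor and poly
I:C alone as 100%. Per-dose summaries (half-up-rounded mean and sample
SD) and paired Student's t-tests complete the table. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Analyse the bundled reference neutralization dataset (four donors, five
scFv doses):

```
$ skindepth run-assay --out-dir out/assay
                        polyIC  hIL4_polyIC  10.0  100.0  200.0  400.0  600.0
donor
D1                       100.0          0.0 -39.0    4.0   26.0   44.0   84.0
D2                       100.0          0.0  69.0   84.0  118.0  113.0  127.0
D3                       100.0          0.0   3.0   21.0   31.0   46.0   43.0
D4                       100.0          0.0  -7.0   33.0   28.0   58.0   64.0
Average (%)              100.0          0.0   7.0   36.0   51.0   65.0   80.0
Standard deviation (%)     0.0          0.0  45.0   34.0   45.0   32.0   36.0
```

Each donor row is that donor's neutralization percentage at 10–600 nM
scFv on its own anchored scale (anchors exactly 100 and 0 by
construction; values outside [0, 100] are real and preserved). The
average climbs dose-dependently to 80% at 600 nM. Note D2 exceeding 100%
— its dose responses fell below its poly I:C-alone anchor.

Run the simulated penetration comparison (nine replicates per condition,
mirroring 3 sections × 3 acquisitions per sample):

```
$ skindepth run-penetration --seed 1 --out-dir out/pen
condition time  true_front_um  mean_depth_um  sd_depth_um  n_replicates
  scFv_6h  6 h           15.0           15.0          0.0             9
    Ab_6h  6 h           15.0           15.0          0.0             9
 scFv_24h 24 h          130.0          130.0          0.0             9
   Ab_24h 24 h           15.0           15.0          0.0             9
```

At default noise and baseline levels the pipeline recovers each
condition's true tracer front exactly at the 5 µm grid resolution: the
scFv-at-24 h condition reaches the upper-dermis depth scale (130 µm)
while the full-size antibody stays in the stratum-corneum range
(~15 µm). Individual stages are also exposed (`simulate-map`,
`preprocess`, `unmix`, `profile`, `simulate-assay`, `assay`), all
reading and writing plain CSV, with YAML configuration and a
`provenance.json` written beside every run's outputs.

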