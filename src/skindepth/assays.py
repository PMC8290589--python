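"""In vitro neutralization statistics.

Covers the two assay readouts around an anti-hIL-4 scFv:

* HEK-Blue IL-4/IL-13 reporter cells — SEAP optical density (OD620),
  expressed as percent of the mean response of cells stimulated with
  10 ng/ml hIL-4.
* Normal human keratinocytes (NHKs) — secreted IL-8 (pg/ml) normalized to
  total protein per well (µg, BCA), then converted per donor into an
  anchored neutralization percentage: the donor's hIL-4 + poly I:C
  response is 0% neutralization and its poly I:C-alone response is 100%:

      pct = 100 · (r₀ − r_dose) / (r₀ − r₁₀₀)

  Percentages are unbounded (values < 0 and > 100 occur in real donors).

Summary tables report per-dose mean and sample SD, rounded half-up to
integer percent; significance uses Student's t-test (paired by donor for
NHK dose-vs-control comparisons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import InvalidInputError

__all__ = [
    "CONDITIONS",
    "REFERENCE_DONOR_PERCENTAGES",
    "reference_plate",
    "round_half_up",
    "normalize_reporter",
    "normalize_il8",
    "neutralization_percent",
    "neutralization_table",
    "summarize_doses",
    "students_t",
    "significance_stars",
]

CONDITIONS = ("polyIC", "hIL4_polyIC", "scFv_dose", "untreated", "hIL4_max")

#: Published per-donor hIL-4 neutralization percentages in NHKs (percent of
#: the poly I:C-anchored scale) at five scFv doses — the reference dataset
#: this module's summary statistics are checked against.
REFERENCE_DONOR_PERCENTAGES: dict[str, dict[float, float]] = {
    "D1": {10: -39, 100: 4, 200: 26, 400: 44, 600: 84},
    "D2": {10: 69, 100: 84, 200: 118, 400: 113, 600: 127},
    "D3": {10: 3, 100: 21, 200: 31, 400: 46, 600: 43},
    "D4": {10: -7, 100: 33, 200: 28, 400: 58, 600: 64},
}


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going away from zero.

    Report tables use this (6.5 → 7); banker's rounding would give 6.
    """
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def reference_plate(r_hundred: float = 100.0, r_zero: float = 300.0) -> pd.DataFrame:
    """Synthetic plate whose derived percentages equal the reference dataset.

    Builds per-donor anchor responses and dose responses such that the
    anchored-percentage transform reproduces
    :data:`REFERENCE_DONOR_PERCENTAGES` exactly.  Useful as a fixture and
    for the end-to-end assay pipeline demo.
    """
    rows = []
    for donor, doses in REFERENCE_DONOR_PERCENTAGES.items():
        rows.append({"donor": donor, "condition": "polyIC", "dose_nM": 0.0,
                     "response": r_hundred, "total_protein_ug": 1.0})
        rows.append({"donor": donor, "condition": "hIL4_polyIC", "dose_nM": 0.0,
                     "response": r_zero, "total_protein_ug": 1.0})
        for dose, pct in doses.items():
            response = r_zero - pct / 100.0 * (r_zero - r_hundred)
            rows.append({"donor": donor, "condition": "scFv_dose",
                         "dose_nM": float(dose), "response": response,
                         "total_protein_ug": 1.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Normalizations
# ---------------------------------------------------------------------------


def normalize_reporter(measurements: pd.DataFrame) -> pd.DataFrame:
    """Express reporter OD620 as percent of the mean hIL-4-stimulated maximum.

    Requires an ``hIL4_max`` condition with positive mean response; adds a
    ``percent_of_max`` column.
    """
    maxima = measurements.loc[measurements["condition"] == "hIL4_max", "response"]
    if maxima.empty or maxima.mean() <= 0:
        raise InvalidInputError("missing or non-positive hIL4_max condition")
    out = measurements.copy()
    out["percent_of_max"] = 100.0 * out["response"] / maxima.mean()
    return out


def normalize_il8(measurements: pd.DataFrame) -> pd.DataFrame:
    """IL-8 per total protein: response (pg/ml-equivalent well content) / µg.

    Adds a ``response_per_ug`` column; zero or missing protein is an error.
    """
    protein = measurements["total_protein_ug"]
    if protein.isna().any() or (protein <= 0).any():
        raise InvalidInputError("total_protein_ug must be present and > 0")
    out = measurements.copy()
    out["response_per_ug"] = out["response"] / protein
    return out


# ---------------------------------------------------------------------------
# Anchored neutralization percentage
# ---------------------------------------------------------------------------


def neutralization_percent(r_dose, r_zero, r_hundred):
    """Anchored percentage: 100·(r₀ − r_dose)/(r₀ − r₁₀₀).

    ``r_zero`` is the donor's own hIL-4 + poly I:C response (0%
    neutralization), ``r_hundred`` the donor's poly I:C-alone response
    (100%).  Invariant under any positive affine transform applied to all
    three responses.  Accepts scalars or arrays.
    """
    r_zero = np.asarray(r_zero, float)
    r_hundred = np.asarray(r_hundred, float)
    if np.any(r_zero == r_hundred):
        raise InvalidInputError("degenerate anchors: r_zero equals r_hundred")
    result = 100.0 * (r_zero - np.asarray(r_dose, float)) / (r_zero - r_hundred)
    return float(result) if result.ndim == 0 else result


def neutralization_table(
    measurements: pd.DataFrame,
    response_col: str = "response",
) -> pd.DataFrame:
    """Per-donor anchored percentages as a donors × doses table.

    Each donor's percentages use that donor's own anchor conditions —
    never pooled anchors.  Donors missing either anchor are dropped with a
    warning; anchor columns ``polyIC`` and ``hIL4_polyIC`` are exactly 100
    and 0 by construction.
    """
    import logging

    log = logging.getLogger(__name__)
    doses = sorted(
        measurements.loc[measurements["condition"] == "scFv_dose", "dose_nM"].unique()
    )
    rows = {}
    for donor, grp in measurements.groupby("donor", sort=False):
        r100 = grp.loc[grp["condition"] == "polyIC", response_col]
        r0 = grp.loc[grp["condition"] == "hIL4_polyIC", response_col]
        if r100.empty or r0.empty:
            missing = [c for c, r in (("polyIC", r100), ("hIL4_polyIC", r0)) if r.empty]
            log.warning("donor %s lacks anchor condition(s) %s; excluded",
                        donor, missing)
            continue
        r100_m, r0_m = r100.mean(), r0.mean()
        row = {"polyIC": 100.0, "hIL4_polyIC": 0.0}
        for dose in doses:
            rd = grp.loc[(grp["condition"] == "scFv_dose")
                         & (grp["dose_nM"] == dose), response_col]
            if rd.empty:
                row[dose] = np.nan
            else:
                row[dose] = neutralization_percent(rd.mean(), r0_m, r100_m)
        rows[donor] = row
    if not rows:
        raise InvalidInputError("no donor has both anchor conditions")
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "donor"
    return table


def summarize_doses(table: pd.DataFrame, rounded: bool = True) -> pd.DataFrame:
    """Append per-dose mean and sample SD (n−1) rows to a percentage table.

    With ``rounded=True`` the summary rows (labelled ``Average (%)`` and
    ``Standard deviation (%)``) are rounded half-up to integer percent, as
    in the printed report layout; unrounded values are always available via
    ``rounded=False``.  SD over a single donor is NaN (undefined).
    """
    means = table.mean(axis=0, skipna=True)
    sds = table.std(axis=0, ddof=1, skipna=True)
    if rounded:
        means = means.map(lambda v: float(round_half_up(v)) if np.isfinite(v) else v)
        sds = sds.map(lambda v: float(round_half_up(v)) if np.isfinite(v) else v)
    out = table.copy()
    out.loc["Average (%)"] = means
    out.loc["Standard deviation (%)"] = sds
    return out


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------


@dataclass
class TTestResult:
    t: float
    p: float
    stars: str
    degenerate: bool = False


def significance_stars(p: float) -> str:
    """Map a two-tailed p-value to the usual star annotation."""
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < threshold:
            return stars
    return "NS"


def students_t(
    group_a,
    group_b,
    paired: bool = False,
) -> TTestResult:
    """Two-tailed Student's t-test (equal-variance unpaired, or paired).

    Zero-variance degenerate cases are resolved explicitly rather than
    propagating NaN: identical groups give t = 0, p = 1; a constant
    nonzero paired shift with no within-pair variance gives p = 0, flagged
    degenerate.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("each group needs n ≥ 2")
    if paired and len(a) != len(b):
        raise InvalidInputError("paired test requires equal group sizes")
    if paired:
        diff = a - b
        if diff.std(ddof=1) == 0:
            if diff.mean() == 0:
                return TTestResult(0.0, 1.0, "NS", degenerate=True)
            t = math.inf if diff.mean() > 0 else -math.inf
            return TTestResult(t, 0.0, "****", degenerate=True)
        res = stats.ttest_rel(a, b)
    else:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                return TTestResult(0.0, 1.0, "NS", degenerate=True)
            t = math.inf if a.mean() > b.mean() else -math.inf
            return TTestResult(t, 0.0, "****", degenerate=True)
        res = stats.ttest_ind(a, b, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    return TTestResult(t, p, significance_stars(p))
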