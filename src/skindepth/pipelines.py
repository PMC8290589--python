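"""End-to-end workflows: the penetration study and the neutralization study.

``run_penetration_pipeline`` chains simulate → preprocess → unmix →
depth-profile → aggregate for each labelled condition (tracer × time
point) and emits a comparison table; ``run_assay_pipeline`` chains
normalization → per-donor anchored percentages → summary table → paired
t-tests.  Both drop a provenance record beside their outputs so a run can
be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assays, io, simulate
from .depth import aggregate_replicates, depth_profile, penetration_depth
from .spectra import InvalidConfigError, PreprocessConfig, crop, preprocess_map, vector_normalize
from .unmixing import ReferenceSet, unmix_map

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionSpec",
    "PenetrationRunConfig",
    "AssayRunConfig",
    "prepare_references",
    "run_penetration_pipeline",
    "run_assay_pipeline",
]


def prepare_references(refs: ReferenceSet, cfg: PreprocessConfig) -> ReferenceSet:
    """Crop references to the analysis window and vector-normalize them.

    Unit-norm references keep the NCLS coefficients on a comparable scale
    with the unit-norm pixel spectra.
    """
    return ReferenceSet(
        [(name, vector_normalize(crop(spec, cfg))) for name, spec in refs.components],
        tracked=refs.tracked,
    )


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition of the penetration study."""

    label: str                 # e.g. "scFv_24h"
    tracer_front_um: float
    time_label: str = ""       # e.g. "24 h", free-form


@dataclass(frozen=True)
class PenetrationRunConfig:
    """Configuration of the simulated penetration comparison.

    The default conditions mirror the study design: at 6 h both species sit
    in the stratum corneum (front 15 µm); at 24 h the scFv reaches 130 µm
    while the full-size Ab stays at the surface.  Nine replicates per
    condition reproduce the 3 sections × 3 acquisitions scheme.
    """

    seed: int = 0
    conditions: tuple[ConditionSpec, ...] = (
        ConditionSpec("scFv_6h", 15.0, "6 h"),
        ConditionSpec("Ab_6h", 15.0, "6 h"),
        ConditionSpec("scFv_24h", 130.0, "24 h"),
        ConditionSpec("Ab_24h", 15.0, "24 h"),
    )
    n_replicates: int = 9
    threshold_fraction: float = 0.05
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    map_sim: simulate.MapSimConfig = field(default_factory=simulate.MapSimConfig)


@dataclass(frozen=True)
class AssayRunConfig:
    seed: int = 0
    plate_csv: str | None = None     # None → use the bundled reference plate
    simulate_plate: bool = False     # True → simulate instead
    assay_sim: simulate.AssaySimConfig = field(default_factory=simulate.AssaySimConfig)
    mode: str = "nhk"                # "nhk" or "reporter"


def _condition_estimates(
    cond: ConditionSpec,
    cfg: PenetrationRunConfig,
    refs_cropped: ReferenceSet,
    refs_full: ReferenceSet,
):
    estimates = []
    for rep in range(cfg.n_replicates):
        label_code = zlib.crc32(cond.label.encode()) % 100003
        rep_seed = (cfg.seed * 10007 + label_code * 211 + rep) % (2**31)
        sim_cfg = dataclasses.replace(cfg.map_sim, seed=rep_seed,
                                      tracer_front_um=cond.tracer_front_um)
        smap, _truth = simulate.make_map(sim_cfg, refs_full)
        pre = preprocess_map(smap, cfg.preprocess)
        amap = unmix_map(pre, refs_cropped)
        profile = depth_profile(amap, refs_cropped.tracked, surface_y=None,
                                step=cfg.map_sim.step_um)
        est = penetration_depth(profile, cfg.threshold_fraction,
                                replicate_id=f"{cond.label}/rep{rep}")
        estimates.append(est)
    return estimates


def run_penetration_pipeline(cfg: PenetrationRunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Run the full simulated penetration comparison; return the report table.

    Writes ``penetration_report.csv``, ``report.md``, per-condition depth
    profiles, and ``provenance.json`` into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    refs_full = simulate.make_references(cfg.map_sim)
    refs_cropped = prepare_references(refs_full, cfg.preprocess)

    rows = []
    for cond in cfg.conditions:
        estimates = _condition_estimates(cond, cfg, refs_cropped, refs_full)
        mean, sd, n = aggregate_replicates(estimates)
        rows.append({"condition": cond.label, "time": cond.time_label,
                     "true_front_um": cond.tracer_front_um,
                     "mean_depth_um": mean,
                     "sd_depth_um": np.nan if sd is None else sd,
                     "n_replicates": n})
        io.write_profile_csv(estimates[0].profile,
                             out / f"profile_{cond.label}.csv")
        logger.info("condition %s: depth %.1f ± %s µm (n=%d)",
                    cond.label, mean, "NA" if sd is None else f"{sd:.1f}", n)
    report = pd.DataFrame(rows)
    report.to_csv(out / "penetration_report.csv", index=False,
                  float_format=io.FLOAT_FORMAT)

    md = ["# Penetration depth report", "",
          "| condition | time | true front (µm) | estimated depth (µm) | SD | n |",
          "|---|---|---|---|---|---|"]
    for r in rows:
        sd_txt = "–" if not np.isfinite(r["sd_depth_um"]) else f"{r['sd_depth_um']:.1f}"
        md.append(f"| {r['condition']} | {r['time']} | {r['true_front_um']:.0f} "
                  f"| {r['mean_depth_um']:.1f} | {sd_txt} | {r['n_replicates']} |")
    (out / "report.md").write_text("\n".join(md) + "\n")
    logger.info("penetration pipeline finished in %.1f s", time.time() - t0)
    io.write_provenance(out, run="penetration", config=cfg)
    return report


def run_assay_pipeline(cfg: AssayRunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Run the neutralization analysis; return the summary table.

    With no plate CSV and ``simulate_plate=False`` the bundled reference
    donor dataset is analysed.  Writes ``neutralization_table.csv``,
    ``ttests.csv``, ``report.md`` and ``provenance.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    if cfg.plate_csv is not None:
        plate = io.read_plate_csv(cfg.plate_csv)
    elif cfg.simulate_plate:
        sim_cfg = dataclasses.replace(cfg.assay_sim, seed=cfg.seed)
        plate = simulate.make_assay(sim_cfg)
    else:
        plate = assays.reference_plate()

    if cfg.mode == "nhk":
        if "total_protein_ug" in plate.columns and plate["total_protein_ug"].notna().all():
            plate = assays.normalize_il8(plate)
            response_col = "response_per_ug"
        else:
            response_col = "response"
        table = assays.neutralization_table(plate, response_col=response_col)
    elif cfg.mode == "reporter":
        plate = assays.normalize_reporter(plate)
        table = assays.neutralization_table(
            plate.replace({"condition": {"hIL4_max": "hIL4_polyIC",
                                         "untreated": "polyIC"}}),
            response_col="percent_of_max",
        )
    else:
        raise InvalidConfigError(f"unknown assay mode {cfg.mode!r}")

    summary = assays.summarize_doses(table)
    summary.to_csv(out / "neutralization_table.csv",
                   float_format=io.FLOAT_FORMAT)

    # paired t-tests: percentages at each dose vs the 0% anchor column
    dose_cols = [c for c in table.columns if not isinstance(c, str)]
    tt_rows = []
    for dose in dose_cols:
        vals = table[dose].dropna()
        if len(vals) >= 2:
            res = assays.students_t(vals.to_numpy(),
                                    np.zeros(len(vals)), paired=True)
            tt_rows.append({"dose_nM": dose, "t": res.t, "p": res.p,
                            "stars": res.stars, "n": len(vals)})
    ttests = pd.DataFrame(tt_rows)
    ttests.to_csv(out / "ttests.csv", index=False, float_format=io.FLOAT_FORMAT)

    md = ["# Neutralization report", "", "```", summary.to_string(), "```", "",
          "Paired Student's t-test of per-donor neutralization vs the 0% anchor:",
          "```", ttests.to_string(index=False) if len(ttests) else "(insufficient donors)",
          "```"]
    (out / "report.md").write_text("\n".join(md) + "\n")
    logger.info("assay pipeline finished in %.1f s", time.time() - t0)
    io.write_provenance(out, run="assay", config=cfg)
    return summary
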