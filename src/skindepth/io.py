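"""CSV / JCAMP-DX / YAML input-output and provenance records.

CSV dialects (all headers required, floats written with 12 significant
digits so write-then-read round-trips within 1e-12):

* spectrum:   ``wavenumber_cm1,intensity_cts``
* map (long): ``x_um,y_um,wavenumber_cm1,intensity_cts``
* references: ``component,wavenumber_cm1,intensity``
* abundance:  ``x_um,y_um,<component columns...>,residual_norm``
* profile:    ``depth_um,mean_abundance,n_pixels``
* plate:      ``donor,condition,dose_nM,response,total_protein_ug``
"""

from __future__ import annotations

import dataclasses
import json
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .depth import DepthProfile
from .spectra import InvalidConfigError, InvalidInputError, MapPixel, SpectralMap, Spectrum
from .unmixing import AbundanceMap, AbundancePixel, ReferenceSet

FLOAT_FORMAT = "%.12g"

__all__ = [
    "read_spectrum_csv", "write_spectrum_csv",
    "read_map_csv", "write_map_csv",
    "read_references_csv", "write_references_csv",
    "read_abundance_csv", "write_abundance_csv",
    "read_profile_csv", "write_profile_csv",
    "read_plate_csv", "write_plate_csv",
    "read_jcamp", "load_yaml_config", "config_from_mapping",
    "write_provenance",
]


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{what} CSV missing column(s) {missing}")


def read_spectrum_csv(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    _require_columns(df, ["wavenumber_cm1", "intensity_cts"], "spectrum")
    return Spectrum(df["wavenumber_cm1"].to_numpy(),
                    df["intensity_cts"].to_numpy(),
                    {"source": str(path)})


def write_spectrum_csv(s: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"wavenumber_cm1": s.wavenumbers,
                  "intensity_cts": s.intensities}
                 ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_map_csv(path: str | Path, step: float = 5.0,
                 surface_y: float | None = None) -> SpectralMap:
    df = pd.read_csv(path)
    _require_columns(df, ["x_um", "y_um", "wavenumber_cm1", "intensity_cts"], "map")
    pixels = []
    for (x, y), grp in df.groupby(["x_um", "y_um"], sort=True):
        grp = grp.sort_values("wavenumber_cm1")
        pixels.append(MapPixel(float(x), float(y),
                               Spectrum(grp["wavenumber_cm1"].to_numpy(),
                                        grp["intensity_cts"].to_numpy())))
    return SpectralMap(pixels, step=step, surface_y=surface_y,
                       meta={"source": str(path)})


def write_map_csv(m: SpectralMap, path: str | Path) -> None:
    frames = [
        pd.DataFrame({"x_um": p.x, "y_um": p.y,
                      "wavenumber_cm1": p.spectrum.wavenumbers,
                      "intensity_cts": p.spectrum.intensities})
        for p in m.pixels
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=FLOAT_FORMAT)


def read_references_csv(path: str | Path, tracked: str) -> ReferenceSet:
    df = pd.read_csv(path)
    _require_columns(df, ["component", "wavenumber_cm1", "intensity"], "references")
    components = []
    for name, grp in df.groupby("component", sort=False):
        grp = grp.sort_values("wavenumber_cm1")
        components.append((str(name), Spectrum(grp["wavenumber_cm1"].to_numpy(),
                                               grp["intensity"].to_numpy())))
    return ReferenceSet(components, tracked=tracked)


def write_references_csv(refs: ReferenceSet, path: str | Path) -> None:
    frames = [
        pd.DataFrame({"component": name,
                      "wavenumber_cm1": spec.wavenumbers,
                      "intensity": spec.intensities})
        for name, spec in refs.components
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=FLOAT_FORMAT)


def read_abundance_csv(path: str | Path, tracked: str | None = None) -> AbundanceMap:
    df = pd.read_csv(path)
    _require_columns(df, ["x_um", "y_um", "residual_norm"], "abundance")
    names = [c for c in df.columns if c not in ("x_um", "y_um", "residual_norm")]
    if not names:
        raise InvalidInputError("abundance CSV has no component columns")
    pixels = [
        AbundancePixel(float(r["x_um"]), float(r["y_um"]),
                       np.array([r[n] for n in names], float),
                       float(r["residual_norm"]))
        for _, r in df.iterrows()
    ]
    return AbundanceMap(pixels, names, tracked or names[-1],
                        meta={"source": str(path)})


def write_abundance_csv(a: AbundanceMap, path: str | Path) -> None:
    rows = []
    for p in a.pixels:
        row = {"x_um": p.x, "y_um": p.y}
        row.update(dict(zip(a.component_names, p.coefficients)))
        row["residual_norm"] = p.residual_norm
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_profile_csv(path: str | Path, component: str = "") -> DepthProfile:
    df = pd.read_csv(path)
    _require_columns(df, ["depth_um", "mean_abundance", "n_pixels"], "profile")
    return DepthProfile(df["depth_um"].to_numpy(),
                        df["mean_abundance"].to_numpy(),
                        df["n_pixels"].to_numpy(int),
                        component)


def write_profile_csv(p: DepthProfile, path: str | Path) -> None:
    pd.DataFrame({"depth_um": p.depths,
                  "mean_abundance": p.mean_abundance,
                  "n_pixels": p.n_pixels}
                 ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


PLATE_COLUMNS = ["donor", "condition", "dose_nM", "response", "total_protein_ug"]


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PLATE_COLUMNS[:4], "plate")
    return df


def write_plate_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# JCAMP-DX (minimal single-spectrum reader)
# ---------------------------------------------------------------------------


def read_jcamp(path: str | Path) -> Spectrum:
    """Read a single spectrum from a JCAMP-DX file.

    Supports ``##XYDATA=(X++(Y..Y))`` with XFACTOR/YFACTOR and
    ``##XYPOINTS``/``##PEAK TABLE`` XY pair tables — the forms single
    Raman exports actually use.  Points are sorted to an increasing axis.
    """
    xfactor = yfactor = 1.0
    deltax = None
    mode = None
    xy_pairs: list[tuple[float, float]] = []
    lines: list[tuple[float, list[float]]] = []  # (x_start, y values)
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("$$"):
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.split("$$")[0].strip()
            if key == "XFACTOR":
                xfactor = float(value)
            elif key == "YFACTOR":
                yfactor = float(value)
            elif key == "DELTAX":
                deltax = float(value)
            elif key == "XYDATA":
                mode = "xydata"
            elif key in ("XYPOINTS", "PEAKTABLE"):
                mode = "xypoints"
            elif key == "END":
                mode = None
            continue
        tokens = line.replace(",", " ").replace(";", " ").split()
        if mode == "xydata":
            vals = [float(t) for t in tokens]
            lines.append((vals[0] * xfactor, [v * yfactor for v in vals[1:]]))
        elif mode == "xypoints":
            for xv, yv in zip(tokens[0::2], tokens[1::2]):
                xy_pairs.append((float(xv) * xfactor, float(yv) * yfactor))
    if lines:
        # (X++(Y..Y)): per-line x starts anchor an even grid; infer the
        # spacing from DELTAX or from consecutive line anchors
        if deltax is None:
            if len(lines) > 1:
                deltax = (lines[1][0] - lines[0][0]) / len(lines[0][1])
            else:
                raise InvalidInputError(
                    f"{path}: cannot infer DELTAX from a single XYDATA line"
                )
        for x0, yvals in lines:
            for j, y in enumerate(yvals):
                xy_pairs.append((x0 + j * deltax, y))
    if not xy_pairs:
        raise InvalidInputError(f"no spectral data found in {path}")
    xs_arr = np.array([p[0] for p in xy_pairs])
    ys_arr = np.array([p[1] for p in xy_pairs])
    order = np.argsort(xs_arr)
    return Spectrum(xs_arr[order], ys_arr[order], {"source": str(path)})


# ---------------------------------------------------------------------------
# YAML configuration and provenance
# ---------------------------------------------------------------------------


def config_from_mapping(cls, mapping: dict):
    """Instantiate a (possibly nested) dataclass, rejecting unknown keys.

    Nested mappings are recursed into dataclass-typed fields; lists become
    tuples (lists of mappings become tuples of the element dataclass when
    the field is annotated ``tuple[SomeDataclass, ...]``).
    """
    import typing

    hints = typing.get_type_hints(cls)
    field_info = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(mapping) - set(field_info)
    if unknown:
        raise InvalidConfigError(
            f"unknown key(s) {sorted(unknown)} for {cls.__name__}"
        )
    kwargs = {}
    for key, value in mapping.items():
        hint = hints.get(key)
        if isinstance(value, dict) and dataclasses.is_dataclass(hint):
            value = config_from_mapping(hint, value)
        elif isinstance(value, list):
            args = typing.get_args(hint) if hint else ()
            elem = args[0] if args else None
            if dataclasses.is_dataclass(elem) and all(
                isinstance(v, dict) for v in value
            ):
                value = tuple(config_from_mapping(elem, v) for v in value)
            else:
                value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def load_yaml_config(path: str | Path, cls):
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InvalidConfigError(f"{path} must contain a mapping")
    return config_from_mapping(cls, data)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def package_version() -> str:
    try:
        return metadata.version("skindepth")
    except metadata.PackageNotFoundError:
        return "unknown"


def write_provenance(out_dir: str | Path, **records) -> Path:
    """Write a provenance record (config snapshot + package version).

    Every pipeline run drops this next to its outputs so the run can be
    reproduced bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"package": "skindepth", "version": package_version()}
    payload.update({k: _jsonable(v) for k, v in records.items()})
    path = out / "provenance.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
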