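"""File formats: force curves, material cards, DIC fields, image stacks.

Force-displacement curves are delimited text (comma or tab, auto-detected
on read) with header ``displacement_mm,force_N[,time_s]``.  Material
cards are YAML key/value files.  DIC displacement/strain fields and
stress-strain curves are CSV.  Images are 8- or 16-bit grayscale PNG/TIFF
read and written through imageio, ordered by file name.

All quantities use the N-mm-MPa unit system (1 MPa = 1 N/mm^2); density
is stored in g/mm^3.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .dic import DICConfig, DisplacementField, StrainField
from .material import DamageConstants, MaterialCard, ThermalBlock
from .mechanics import ForceDisplacementCurve, StressStrainCurve

__all__ = [
    "ParseError", "read_force_curve", "write_force_curve",
    "read_material_card", "write_material_card",
    "read_stress_strain", "write_stress_strain",
    "write_fields", "read_fields",
    "read_image_stack", "write_image_stack",
    "RunConfig", "read_run_config",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line/key."""


def _write_csv(cols: dict, path) -> None:
    """CSV writer at full float precision (%.17g round-trips doubles)."""
    data = np.column_stack([np.asarray(v, dtype=float) for v in cols.values()])
    np.savetxt(path, data, delimiter=",", comments="",
               header=",".join(cols), fmt="%.17g")


# ---------------------------------------------------------------------------
# Force curves

def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","
    raise ParseError(f"{path}: file is empty")


def read_force_curve(path) -> ForceDisplacementCurve:
    """Read a texture-analyzer export: displacement (mm), force (N)[, time (s)].

    Comma or tab delimited; a header row is permitted.  Non-numeric data
    rows raise a :class:`ParseError` naming the line; non-monotone
    displacement raises a validation error.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(delim)]
            try:
                rows.append([float(p) for p in parts if p != ""])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ParseError(f"{path}: non-numeric data on line {lineno}: {line!r}")
    if not rows:
        raise ParseError(f"{path}: no numeric data rows")
    ncol = len(rows[0])
    if ncol < 2 or any(len(r) != ncol for r in rows):
        raise ParseError(f"{path}: need >=2 numeric columns with consistent width")
    arr = np.asarray(rows, dtype=float)
    time = arr[:, 2] if ncol >= 3 else None
    return ForceDisplacementCurve(displacement=arr[:, 0], force=arr[:, 1],
                                  time=time, metadata={"source": str(path)})


def write_force_curve(curve: ForceDisplacementCurve, path) -> None:
    """Write a curve as CSV with full float precision (round-trip safe)."""
    cols = {"displacement_mm": curve.displacement, "force_N": curve.force}
    if curve.time is not None:
        cols["time_s"] = curve.time
    _write_csv(cols, path)


# ---------------------------------------------------------------------------
# Material cards

_REQUIRED_KEYS = ("E", "nu", "rho", "A", "B", "n", "C", "eps_dot_ref",
                  "d1", "d2", "d3", "d4", "d5")


def read_material_card(path) -> MaterialCard:
    """Read a YAML material card.

    Requires E, nu, rho, A, B, n, C, eps_dot_ref and d1..d5; an optional
    ``thermal`` block (m, T_melt, T_material, T) enables the softening
    bracket, and defaults to disabled when absent.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a key/value mapping")
    for key in _REQUIRED_KEYS:
        if key not in data:
            raise ParseError(f"{path}: missing key {key}")
    thermal = None
    if "thermal" in data and data["thermal"] is not None:
        tb = data["thermal"]
        thermal = ThermalBlock(m=float(tb["m"]), T_melt=float(tb["T_melt"]),
                               T_material=float(tb["T_material"]), T=float(tb["T"]))
    return MaterialCard(
        E=float(data["E"]), poisson_nu=float(data["nu"]),
        density_rho=float(data["rho"]), A=float(data["A"]), B=float(data["B"]),
        n=float(data["n"]), C=float(data["C"]),
        eps_dot_ref=float(data["eps_dot_ref"]),
        damage=DamageConstants(*(float(data[f"d{i}"]) for i in range(1, 6))),
        thermal=thermal, name=str(data.get("name", path.stem)),
    )


def write_material_card(card: MaterialCard, path) -> None:
    data = {
        "name": card.name, "E": card.E, "nu": card.poisson_nu,
        "rho": card.density_rho, "A": card.A, "B": card.B, "n": card.n,
        "C": card.C, "eps_dot_ref": card.eps_dot_ref,
        **card.damage.as_dict(),
    }
    if card.thermal is not None:
        data["thermal"] = dataclasses.asdict(card.thermal)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Stress-strain curves and DIC fields

_SS_COLUMNS = ("eps_eng", "sigma_eng_MPa", "eps_true", "sigma_true_MPa",
               "eps_elastic", "eps_plastic")


def write_stress_strain(curve: StressStrainCurve, path) -> None:
    n = curve.eps_eng.size
    blank = np.full(n, np.nan)
    _write_csv({
        "eps_eng": curve.eps_eng, "sigma_eng_MPa": curve.sigma_eng,
        "eps_true": curve.eps_true, "sigma_true_MPa": curve.sigma_true,
        "eps_elastic": curve.eps_elastic if curve.eps_elastic is not None else blank,
        "eps_plastic": curve.eps_plastic if curve.eps_plastic is not None else blank,
    }, path)


def read_stress_strain(path) -> StressStrainCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _SS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    el = df["eps_elastic"].to_numpy()
    pl = df["eps_plastic"].to_numpy()
    return StressStrainCurve(
        eps_eng=df["eps_eng"].to_numpy(), sigma_eng=df["sigma_eng_MPa"].to_numpy(),
        eps_true=df["eps_true"].to_numpy(), sigma_true=df["sigma_true_MPa"].to_numpy(),
        eps_elastic=None if np.all(np.isnan(el)) else el,
        eps_plastic=None if np.all(np.isnan(pl)) else pl,
    )


def write_fields(displacement: DisplacementField, strain: StrainField | None,
                 path) -> None:
    """Write DIC fields as CSV, one row per grid point.

    Columns: x_px, y_px, u_px, v_px, corr, Exx, Eyy, Exy, valid.
    Pixel-centered coordinates, origin top-left; u positive rightward,
    v positive downward.
    """
    X, Y = np.meshgrid(displacement.grid_x, displacement.grid_y)
    n = X.size
    nan = np.full(n, np.nan)
    _write_csv({
        "x_px": X.ravel(), "y_px": Y.ravel(),
        "u_px": displacement.u.ravel(), "v_px": displacement.v.ravel(),
        "corr": displacement.correlation.ravel(),
        "Exx": strain.Exx.ravel() if strain is not None else nan,
        "Eyy": strain.Eyy.ravel() if strain is not None else nan,
        "Exy": strain.Exy.ravel() if strain is not None else nan,
        "valid": displacement.valid_mask.ravel().astype(float),
    }, path)


def read_fields(path) -> tuple:
    df = pd.read_csv(path, float_precision="round_trip")
    gx = np.unique(df["x_px"].to_numpy())
    gy = np.unique(df["y_px"].to_numpy())
    shape = (gy.size, gx.size)

    def grid(col):
        return df[col].to_numpy().reshape(shape)

    disp = DisplacementField(grid_x=gx, grid_y=gy, u=grid("u_px"), v=grid("v_px"),
                             correlation=grid("corr"),
                             valid_mask=grid("valid").astype(bool))
    strain = StrainField(grid_x=gx, grid_y=gy, Exx=grid("Exx"), Eyy=grid("Eyy"),
                         Exy=grid("Exy"),
                         valid_mask=np.isfinite(grid("Exx")))
    return disp, strain


# ---------------------------------------------------------------------------
# Image stacks

def read_image_stack(paths) -> list:
    """Read grayscale frames, file-name ordered, as float arrays."""
    frames = []
    for p in sorted(Path(p) for p in paths):
        img = np.asarray(iio.imread(p), dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=2)
        frames.append(img)
    return frames


def write_image_stack(frames, directory, prefix: str = "frame",
                      bit_depth: int = 8) -> list:
    """Write frames as numbered grayscale PNGs; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    top = 2 ** bit_depth - 1
    paths = []
    for i, frame in enumerate(frames):
        out = directory / f"{prefix}_{i:04d}.png"
        iio.imwrite(out, np.rint(np.clip(frame, 0, top)).astype(dtype))
        paths.append(out)
    return paths


# ---------------------------------------------------------------------------
# Run configuration

_TEST_TYPES = ("ring_tensile", "penetration_cyl", "penetration_sph",
               "penetration_con")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Top-level run description: what to test, how fast, with which card.

    A fixed seed reproduces all stochastic outputs bit-identically for a
    fixed library version.
    """

    test_type: str
    speed: float
    material_card_path: str
    dic: DICConfig = dataclasses.field(default_factory=DICConfig)
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.test_type not in _TEST_TYPES:
            raise ValueError(f"test_type must be one of {_TEST_TYPES}")
        if self.speed <= 0:
            raise ValueError("speed must be positive")


def read_run_config(path, **overrides) -> RunConfig:
    """Read a YAML run config; keyword overrides take precedence."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    dic = DICConfig(**data.pop("dic", {}))
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(dic=dic, **data)
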