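"""Spectrum/EEM/sample-sheet CSV I/O and run configuration.

Conventions owned here:

* wavelengths are physical nm everywhere — no index-based addressing;
* all grids are uniform; non-uniform input is linearly resampled with a
  warning;
* intensities are arbitrary fluorescence units (AFU), no radiometric
  calibration;
* every file written starts with ``#``-prefixed metadata comments carrying
  the package version and, where known, the sample seed, for provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, SpectrumFormatError
from .grids import WavelengthGrid
from .simulate import EEM, LINEAR_RANGES, NoiseModel, SampleSpec

_AXIS_KINDS = ("emission", "excitation", "synchronous-emission")


@dataclass
class Spectrum1D:
    """A 1-D fluorescence trace on a strictly ascending wavelength axis."""

    axis_kind: str
    wavelengths: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axis_kind not in _AXIS_KINDS:
            raise ValueError(
                f"axis_kind must be one of {_AXIS_KINDS}, got {self.axis_kind!r}"
            )
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities differ in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        has_dl = "delta_lambda" in self.meta
        if self.axis_kind == "synchronous-emission" and not has_dl:
            raise ValueError(
                "synchronous-emission spectra must carry meta['delta_lambda']"
            )
        if self.axis_kind != "synchronous-emission" and has_dl:
            raise ValueError(
                "delta_lambda is only meaningful for synchronous-emission"
            )


def _provenance_lines(meta: Mapping[str, Any]) -> list[str]:
    from . import __version__

    lines = [f"# syncfluor {__version__}"]
    for key in sorted(meta):
        lines.append(f"# {key}={meta[key]}")
    return lines


def _read_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def write_spectrum_csv(spectrum: Spectrum1D, path) -> Path:
    """Write a two-column ``wavelength_nm,intensity`` CSV with metadata."""
    path = Path(path)
    meta = dict(spectrum.meta)
    meta["axis_kind"] = spectrum.axis_kind
    with open(path, "w") as fh:
        for line in _provenance_lines(meta):
            fh.write(line + "\n")
        fh.write("wavelength_nm,intensity\n")
        for w, i in zip(spectrum.wavelengths, spectrum.intensities):
            fh.write(f"{w:.12g},{i:.12g}\n")
    return path


def read_spectrum_csv(path) -> Spectrum1D:
    """Read a spectrum CSV written by :func:`write_spectrum_csv`.

    Rows with non-ascending wavelengths are sorted (with a warning);
    non-uniform spacing is linearly resampled onto a uniform grid (with a
    warning); duplicate wavelengths are a hard error naming the wavelength.
    """
    path = Path(path)
    if not path.exists():
        raise SpectrumFormatError(f"spectrum file not found: {path}")
    meta = _read_meta(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001 — surface as named parse error
        raise SpectrumFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    required = {"wavelength_nm", "intensity"}
    if not required.issubset(df.columns):
        raise SpectrumFormatError(
            f"{path}: missing column(s) {sorted(required - set(df.columns))}"
        )
    for col in required:
        if not np.issubdtype(df[col].dtype, np.number):
            raise SpectrumFormatError(f"{path}: non-numeric values in {col!r}")

    wl = df["wavelength_nm"].to_numpy(dtype=float)
    inten = df["intensity"].to_numpy(dtype=float)
    dupes = pd.Series(wl)[pd.Series(wl).duplicated()]
    if not dupes.empty:
        raise SpectrumFormatError(
            f"{path}: duplicate wavelength {dupes.iloc[0]:g} nm"
        )
    if np.any(np.diff(wl) < 0):
        warnings.warn(
            f"{path}: wavelengths not ascending; rows sorted", stacklevel=2
        )
        order = np.argsort(wl)
        wl, inten = wl[order], inten[order]
    steps = np.diff(wl)
    step = float(np.median(steps))
    if np.max(np.abs(steps - step)) > 1e-6 * max(step, 1.0):
        warnings.warn(
            f"{path}: non-uniform wavelength spacing; resampled to "
            f"{step:g} nm grid", stacklevel=2,
        )
        uniform = np.arange(wl[0], wl[-1] + step / 2, step)
        inten = np.interp(uniform, wl, inten)
        wl = uniform

    axis_kind = meta.pop("axis_kind", "emission")
    meta.pop("syncfluor", None)
    out_meta: dict[str, Any] = dict(meta)
    if "delta_lambda" in out_meta:
        out_meta["delta_lambda"] = float(out_meta["delta_lambda"])
    return Spectrum1D(axis_kind, wl, inten, out_meta)


def write_eem_csv(eem: EEM, path) -> Path:
    """Write an EEM as long-form ``ex_nm,em_nm,intensity`` CSV."""
    path = Path(path)
    meta: dict[str, Any] = {}
    if isinstance(eem.provenance, SampleSpec):
        meta["seed"] = eem.provenance.seed
        for name, c in sorted(eem.provenance.concentrations.items()):
            meta[f"conc_{name}"] = c
    elif eem.provenance is not None:
        meta["source"] = eem.provenance
    ex = eem.ex_grid.axis
    em = eem.em_grid.axis
    with open(path, "w") as fh:
        for line in _provenance_lines(meta):
            fh.write(line + "\n")
        fh.write("ex_nm,em_nm,intensity\n")
        for i, x in enumerate(ex):
            row = eem.intensities[i]
            for j, m in enumerate(em):
                fh.write(f"{x:.12g},{m:.12g},{row[j]:.12g}\n")
    return path


def read_eem_csv(path) -> EEM:
    """Read a long-form EEM CSV; the rectangular grid is inferred and
    validated (missing cells are a hard error reporting their count)."""
    path = Path(path)
    if not path.exists():
        raise SpectrumFormatError(f"EEM file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001
        raise SpectrumFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    required = {"ex_nm", "em_nm", "intensity"}
    if not required.issubset(df.columns):
        raise SpectrumFormatError(
            f"{path}: missing column(s) {sorted(required - set(df.columns))}"
        )
    pivot = df.pivot_table(
        index="ex_nm", columns="em_nm", values="intensity", aggfunc="first"
    )
    n_missing = int(pivot.isna().to_numpy().sum())
    if n_missing:
        cell = "cell" if n_missing == 1 else "cells"
        raise SpectrumFormatError(f"{path}: {n_missing} missing grid {cell}")
    ex_grid = WavelengthGrid.from_axis(pivot.index.to_numpy(dtype=float))
    em_grid = WavelengthGrid.from_axis(pivot.columns.to_numpy(dtype=float))
    return EEM(ex_grid, em_grid, pivot.to_numpy(dtype=float),
               provenance=str(path))


def write_sample_sheet(samples, path) -> Path:
    """Write ``sample_id,analyte,conc_ug_per_ml`` rows for a panel."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _provenance_lines({}):
            fh.write(line + "\n")
        fh.write("sample_id,analyte,conc_ug_per_ml\n")
        for k, spec in enumerate(samples):
            for name, c in sorted(spec.concentrations.items()):
                fh.write(f"{k},{name},{c:.12g}\n")
    return path


def read_sample_sheet(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SpectrumFormatError(f"sample sheet not found: {path}")
    df = pd.read_csv(path, comment="#")
    required = {"sample_id", "analyte", "conc_ug_per_ml"}
    if not required.issubset(df.columns):
        raise SpectrumFormatError(
            f"{path}: missing column(s) {sorted(required - set(df.columns))}"
        )
    return df


_DEFAULT_LEVELS = {
    "ATO": [0.4, 1.0, 2.0, 3.0, 4.5, 6.0],
    "ASP": [1.0, 2.0, 4.0, 6.0, 8.0, 10.0],
}


@dataclass
class RunConfig:
    """Run-level settings with instrument-procedure defaults.

    ``delta_lambda`` defaults to the working synchronous offset (80 nm) and
    ``derivative_interval`` to the 15-point differentiation window; both can
    be perturbed for robustness studies.  ``measurement_wavelengths`` map
    each analyte to a wavelength in nm or ``"auto"`` (zero-crossing
    selection).
    """

    delta_lambda: float = 80.0
    derivative_interval: int = 15
    derivative_mode: str = "savgol"
    measurement_wavelengths: dict[str, Any] = field(
        default_factory=lambda: {"ATO": "auto", "ASP": "auto"}
    )
    calibration_levels: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_LEVELS.items()}
    )
    replicates: int = 3
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    sensitivity_floor: float = 0.3
    min_flank: float = 0.0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not (self.delta_lambda > 0):
            raise ConfigError("delta_lambda must be > 0 nm")
        if self.derivative_interval % 2 == 0 or self.derivative_interval < 3:
            raise ConfigError(
                f"derivative_interval must be odd and >= 3 (the window is "
                f"centred on each point); got {self.derivative_interval}"
            )
        if self.derivative_mode not in ("savgol", "difference"):
            raise ConfigError(
                f"derivative_mode must be 'savgol' or 'difference', "
                f"got {self.derivative_mode!r}"
            )
        if not (0 < self.sensitivity_floor < 1):
            raise ConfigError("sensitivity_floor must be in (0, 1)")
        for analyte, levels in self.calibration_levels.items():
            lo, hi = LINEAR_RANGES.get(analyte, (0.0, float("inf")))
            for lev in levels:
                if not (lo <= lev <= hi):
                    raise ConfigError(
                        f"{analyte} calibration level {lev} outside linear "
                        f"range [{lo}, {hi}] ug/mL"
                    )

    def to_dict(self) -> dict[str, Any]:
        return {
            "delta_lambda": self.delta_lambda,
            "derivative_interval": self.derivative_interval,
            "derivative_mode": self.derivative_mode,
            "measurement_wavelengths": dict(self.measurement_wavelengths),
            "calibration_levels": {
                k: list(v) for k, v in self.calibration_levels.items()
            },
            "replicates": self.replicates,
            "noise": {
                "additive_sd": self.noise.additive_sd,
                "proportional_cv": self.noise.proportional_cv,
            },
            "seed": self.seed,
            "sensitivity_floor": self.sensitivity_floor,
            "min_flank": self.min_flank,
            "out_dir": self.out_dir,
        }


_CONFIG_KEYS = set(RunConfig().to_dict())


def load_config(path=None) -> RunConfig:
    """Load a YAML run config; unspecified keys take procedure defaults
    (delta-lambda 80 nm, 15-point interval, auto wavelengths)."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a key-value mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
    if "noise" in raw:
        raw = dict(raw)
        raw["noise"] = NoiseModel(**raw["noise"])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def perturbed(config: RunConfig, **changes) -> RunConfig:
    """A copy of ``config`` with the given fields replaced."""
    return replace(config, **changes)
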