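"""Synthetic EEM generator (the in-silico instrument).

Fluorescence is modelled as linear and additive: the intensity surface of a
mixture is the concentration-weighted sum of the pure components' separable
Gaussian bands, plus a flat non-fluorescent excipient background, plus
instrument noise (additive Gaussian + proportional Gaussian).  Inner-filter
and quenching effects are not modelled; concentrations are assumed to stay
inside the validated linear ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import GridError
from .fluorophores import FluorophoreModel, default_models
from .grids import DEFAULT_EM_GRID, DEFAULT_EX_GRID, WavelengthGrid

#: Validated linear ranges, ug/mL (concentration vs derivative amplitude).
LINEAR_RANGES: dict[str, tuple[float, float]] = {
    "ATO": (0.4, 6.0),
    "ASP": (1.0, 10.0),
}

#: Fixed ASP:ATO ratio of the laboratory-prepared mixture series.
MIXTURE_RATIO = 3.75


@dataclass(frozen=True)
class NoiseModel:
    """Instrument repeatability model.

    additive_sd
        SD of zero-mean additive Gaussian noise, AFU.
    proportional_cv
        CV of multiplicative Gaussian noise (fraction of signal).

    Defaults put the replicate scatter of quantified concentrations near
    0.7% RSD, inside the 0.3-2.0% repeatability band a validated
    spectrofluorimetric assay exhibits.
    """

    additive_sd: float = 0.15
    proportional_cv: float = 0.0035

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.proportional_cv < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def is_noiseless(self) -> bool:
        return self.additive_sd == 0 and self.proportional_cv == 0


NOISELESS = NoiseModel(0.0, 0.0)


@dataclass(frozen=True)
class SampleSpec:
    """Provenance of one simulated sample."""

    concentrations: Mapping[str, float]
    background_level: float = 0.0
    replicate_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(
                    f"negative concentration for analyte {name!r}: {c}"
                )
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")


@dataclass
class EEM:
    """Excitation-emission matrix: intensities indexed [ex, em], AFU."""

    ex_grid: WavelengthGrid
    em_grid: WavelengthGrid
    intensities: np.ndarray
    provenance: SampleSpec | str | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.ex_grid.n, self.em_grid.n):
            raise GridError(
                f"intensity matrix shape {self.intensities.shape} does not "
                f"match grids ({self.ex_grid.n}, {self.em_grid.n})"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("EEM intensities must be finite")


#: Default flat excipient background, AFU (small, structureless — the
#: formulation matrix is non-fluorescent).
DEFAULT_BACKGROUND = 2.0


def simulate_eem(
    models: Sequence[tuple[FluorophoreModel, float]],
    grids: tuple[WavelengthGrid, WavelengthGrid] = (
        DEFAULT_EX_GRID,
        DEFAULT_EM_GRID,
    ),
    noise: NoiseModel = NOISELESS,
    background: float = 0.0,
    seed: int = 0,
    replicate_id: int = 0,
) -> EEM:
    """Simulate one EEM for a mixture of Gaussian-band fluorophores.

    ``models`` is a sequence of (model, concentration ug/mL) pairs.  The
    noiseless surface is exactly additive in the components, so a mixture
    EEM equals the elementwise sum of the single-analyte EEMs plus the
    background.  Identical arguments give a bit-identical EEM.
    """
    ex_grid, em_grid = grids
    conc: dict[str, float] = {}
    for model, c in models:
        if c < 0:
            raise ValueError(
                f"negative concentration for analyte {model.name!r}: {c}"
            )
        conc[model.name] = conc.get(model.name, 0.0) + c
    if background < 0:
        raise ValueError("background must be >= 0")

    ex = ex_grid.axis
    em = em_grid.axis
    intensity = np.full((ex_grid.n, em_grid.n), float(background))
    for model, c in models:
        if c == 0:
            continue
        ex_prof = np.exp(-((ex - model.ex_max) ** 2) / (2 * model.ex_width**2))
        em_prof = np.exp(-((em - model.em_max) ** 2) / (2 * model.em_width**2))
        intensity += c * model.brightness * np.outer(ex_prof, em_prof)

    if not noise.is_noiseless:
        rng = np.random.default_rng(seed)
        intensity = (
            intensity
            + noise.additive_sd * rng.standard_normal(intensity.shape)
            + intensity * noise.proportional_cv
            * rng.standard_normal(intensity.shape)
        )

    spec = SampleSpec(
        concentrations=conc,
        background_level=background,
        replicate_id=replicate_id,
        seed=seed,
    )
    return EEM(ex_grid, em_grid, intensity, provenance=spec)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-sample seeds derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def generate_calibration_panel(
    analyte: str,
    levels: Sequence[float],
    co_analyte: tuple[str, float] | None = None,
    replicates: int = 1,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
    models: Sequence[FluorophoreModel] | None = None,
    grids: tuple[WavelengthGrid, WavelengthGrid] = (
        DEFAULT_EX_GRID,
        DEFAULT_EM_GRID,
    ),
    background: float = DEFAULT_BACKGROUND,
) -> list[tuple[SampleSpec, EEM]]:
    """One EEM per level x replicate for a single-analyte dilution series.

    Levels must lie inside the analyte's declared linear range.  Per-sample
    seeds are spawned deterministically from ``seed`` so a panel is fully
    reproducible.
    """
    if len(levels) == 0:
        raise ValueError("calibration level list must not be empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    by_name = {m.name: m for m in (models or default_models())}
    if analyte not in by_name:
        raise ValueError(f"unknown analyte {analyte!r}")
    lo, hi = LINEAR_RANGES.get(analyte, (0.0, np.inf))
    for lev in levels:
        if not (lo <= lev <= hi):
            raise ValueError(
                f"{analyte} level {lev} ug/mL outside linear range "
                f"[{lo}, {hi}]"
            )

    seeds = _child_seeds(seed, len(levels) * replicates)
    panel: list[tuple[SampleSpec, EEM]] = []
    k = 0
    for lev in levels:
        for rep in range(replicates):
            comps = [(by_name[analyte], float(lev))]
            if co_analyte is not None:
                co_name, co_level = co_analyte
                comps.append((by_name[co_name], float(co_level)))
            eem = simulate_eem(
                comps, grids=grids, noise=noise,
                background=background, seed=int(seeds[k]), replicate_id=rep,
            )
            panel.append((eem.provenance, eem))
            k += 1
    return panel


def generate_mixture_panel(
    pairs: Sequence[tuple[float, float]],
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
    models: Sequence[FluorophoreModel] | None = None,
    grids: tuple[WavelengthGrid, WavelengthGrid] = (
        DEFAULT_EX_GRID,
        DEFAULT_EM_GRID,
    ),
    background: float = DEFAULT_BACKGROUND,
) -> list[tuple[SampleSpec, EEM]]:
    """EEMs for binary mixtures given as (ASP ug/mL, ATO ug/mL) pairs."""
    if len(pairs) == 0:
        raise ValueError("mixture pair list must not be empty")
    asp, ato = (models or default_models())[:2]
    seeds = _child_seeds(seed, len(pairs))
    panel = []
    for k, (c_asp, c_ato) in enumerate(pairs):
        eem = simulate_eem(
            [(asp, float(c_asp)), (ato, float(c_ato))],
            grids=grids, noise=noise, background=background,
            seed=int(seeds[k]),
        )
        panel.append((eem.provenance, eem))
    return panel


def mixture_ratio_series() -> list[tuple[float, float]]:
    """The laboratory-mixture series: ATO 0.5-2.5 ug/mL at a fixed
    1:3.75 ATO:ASP ratio, as (ASP, ATO) pairs."""
    ato_levels = [0.5, 1.0, 1.5, 2.0, 2.5]
    return [(round(MIXTURE_RATIO * c, 6), c) for c in ato_levels]


def simulate_tablet_panel(
    content_fraction: Mapping[str, float],
    dilution_concs_ato: Sequence[float] = (0.5, 1.0, 1.5, 2.0, 2.5),
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
    models: Sequence[FluorophoreModel] | None = None,
    background: float = DEFAULT_BACKGROUND,
) -> list[tuple[SampleSpec, EEM]]:
    """Simulate the five-dilution tablet assay series.

    The tablet label claims a fixed 1:3.75 ATO:ASP ratio (20 mg + 75 mg).
    ``dilution_concs_ato`` gives the claim-implied nominal ATO
    concentration at each dilution; the true simulated content is the claim
    scaled by ``content_fraction`` per analyte (1.0 = exactly as labelled).
    """
    asp, ato = (models or default_models())[:2]
    f_ato = float(content_fraction.get("ATO", 1.0))
    f_asp = float(content_fraction.get("ASP", 1.0))
    seeds = _child_seeds(seed, len(dilution_concs_ato))
    panel = []
    for k, c_ato_nom in enumerate(dilution_concs_ato):
        c_ato = f_ato * c_ato_nom
        c_asp = f_asp * MIXTURE_RATIO * c_ato_nom
        eem = simulate_eem(
            [(asp, c_asp), (ato, c_ato)],
            noise=noise, background=background, seed=int(seeds[k]),
        )
        panel.append((eem.provenance, eem))
    return panel
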