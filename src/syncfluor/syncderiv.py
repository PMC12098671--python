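"""Synchronous spectra, first derivatives, zero crossings, offset scanning.

The synchronous spectrum is the diagonal slice of the EEM taken with a
constant offset: S(lam_em) = EEM(lam_ex = lam_em - delta_lambda, lam_em),
reported on the emission axis.  Its smoothed first derivative (signed,
AFU/nm) is the quantitative response: analyte A is read at a wavelength
where interferent B's derivative crosses zero for every B concentration,
so A's calibration is interference-free (the zero-crossing technique).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import savgol_filter

from .exceptions import GridError, NumericError
from .simulate import EEM, SampleSpec
from .spectra_io import Spectrum1D

MIN_OVERLAP_POINTS = 20


@dataclass
class SynchronousSpectrum(Spectrum1D):
    """Constant-offset synchronous trace indexed by emission wavelength."""

    delta_lambda: float = 0.0

    def __init__(self, delta_lambda, wavelengths, intensities, meta=None):
        meta = dict(meta or {})
        meta["delta_lambda"] = float(delta_lambda)
        super().__init__("synchronous-emission", wavelengths, intensities, meta)
        self.delta_lambda = float(delta_lambda)
        if not (self.delta_lambda > 0):
            raise ValueError("delta_lambda must be > 0 nm")

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])


@dataclass
class DerivativeSpectrum:
    """Signed first derivative of a synchronous trace, AFU/nm."""

    wavelengths: np.ndarray
    amplitudes: np.ndarray
    interval: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.wavelengths.shape != self.amplitudes.shape:
            raise ValueError("wavelengths and amplitudes differ in length")
        if self.interval % 2 == 0 or self.interval < 3:
            raise ValueError("interval must be odd and >= 3")

    @property
    def edge_guard(self) -> int:
        """Points at each end fitted by the edge polynomial; excluded from
        zero-crossing searches."""
        return self.interval // 2


def synchronous_spectrum(eem: EEM, delta_lambda: float) -> SynchronousSpectrum:
    """Extract the constant-offset diagonal slice of an EEM.

    The output wavelengths are the subset of the emission grid for which
    the excitation partner ``lam_em - delta_lambda`` lies inside the
    excitation grid; off-grid excitation values are bilinearly interpolated.
    """
    if not (delta_lambda > 0):
        raise ValueError("delta_lambda must be > 0 nm")
    em = eem.em_grid.axis
    ex_lo, ex_hi = eem.ex_grid.start, eem.ex_grid.stop
    mask = (em - delta_lambda >= ex_lo - 1e-9) & (em - delta_lambda <= ex_hi + 1e-9)
    if mask.sum() < MIN_OVERLAP_POINTS:
        lo = eem.em_grid.start - eem.ex_grid.stop
        hi = eem.em_grid.stop - eem.ex_grid.start
        raise GridError(
            f"delta_lambda {delta_lambda} nm leaves {int(mask.sum())} "
            f"overlap points (< {MIN_OVERLAP_POINTS}); usable offsets lie "
            f"within ({lo:g}, {hi:g}) nm"
        )
    em_sel = em[mask]
    interp = RegularGridInterpolator(
        (eem.ex_grid.axis, em), eem.intensities, method="linear",
        bounds_error=False, fill_value=None,
    )
    pts = np.column_stack([np.clip(em_sel - delta_lambda, ex_lo, ex_hi), em_sel])
    intensities = interp(pts)
    meta: dict = {}
    if isinstance(eem.provenance, SampleSpec):
        meta["seed"] = eem.provenance.seed
        meta["concentrations"] = dict(eem.provenance.concentrations)
    return SynchronousSpectrum(delta_lambda, em_sel, intensities, meta)


def first_derivative(
    s: SynchronousSpectrum, interval: int = 15, mode: str = "savgol"
) -> DerivativeSpectrum:
    """Smoothed first derivative of a synchronous trace.

    ``mode="savgol"`` (default) applies a Savitzky-Golay first derivative
    of polynomial order 2 with an ``interval``-point window, scaled to
    per-nm units; the edges keep the original length via the filter's
    polynomial edge fit.  ``mode="difference"`` is a plain centred lagged
    difference spanning ``interval`` points, for comparison with
    instruments whose "data interval" means a differentiation gap.
    Amplitudes are positive where intensity rises with wavelength.
    """
    n = len(s.wavelengths)
    if interval % 2 == 0 or interval < 3:
        raise ValueError(f"interval must be odd and >= 3, got {interval}")
    if interval > n // 2:
        raise NumericError(
            f"spectrum has {n} points; too short for an {interval}-point "
            f"derivative window"
        )
    step = s.step
    if mode == "savgol":
        amp = savgol_filter(
            s.intensities, window_length=interval, polyorder=2,
            deriv=1, delta=step, mode="interp",
        )
    elif mode == "difference":
        half = interval // 2
        amp = np.gradient(s.intensities, step)  # one-sided at the edges
        core = (s.intensities[2 * half:] - s.intensities[:-2 * half]) / (
            2 * half * step
        )
        amp[half:n - half] = core
    else:
        raise ValueError(f"unknown derivative mode {mode!r}")
    meta = dict(s.meta)
    meta["mode"] = mode
    return DerivativeSpectrum(s.wavelengths.copy(), amp, interval, meta)


def find_zero_crossings(
    d: DerivativeSpectrum, min_flank: float = 0.0
) -> list[float]:
    """Wavelengths where the derivative changes sign.

    Crossings are refined by linear interpolation between the bracketing
    samples.  A crossing is suppressed when the flanking |amplitude| is
    below ``min_flank`` on both sides (noise guard).  Edge-fitted points
    are excluded from the search.
    """
    if min_flank < 0:
        raise ValueError("min_flank must be >= 0")
    g = d.edge_guard
    lam = d.wavelengths[g:len(d.wavelengths) - g]
    amp = d.amplitudes[g:len(d.amplitudes) - g]
    out: list[float] = []
    for i in range(len(amp) - 1):
        a, b = amp[i], amp[i + 1]
        if a == 0.0 and b == 0.0:
            continue
        if a == 0.0:
            # counted when the previous non-zero sample had opposite sign
            continue
        if b == 0.0:
            j = i + 1
            while j < len(amp) and amp[j] == 0.0:
                j += 1
            if j < len(amp) and a * amp[j] < 0:
                out.append(float(lam[i + 1]))
            continue
        if a * b < 0:
            x = lam[i] + (lam[i + 1] - lam[i]) * a / (a - b)
            if max(abs(a), abs(b)) >= min_flank or min_flank == 0.0:
                if abs(a) >= min_flank or abs(b) >= min_flank:
                    out.append(float(x))
    return out


def amplitude_at(d: DerivativeSpectrum, wavelength: float) -> float:
    """Signed derivative amplitude at ``wavelength``, linearly interpolated."""
    lo, hi = d.wavelengths[0], d.wavelengths[-1]
    if not (lo - 1e-9 <= wavelength <= hi + 1e-9):
        raise ValueError(
            f"wavelength {wavelength} nm outside spectrum range "
            f"[{lo:g}, {hi:g}] nm"
        )
    return float(np.interp(wavelength, d.wavelengths, d.amplitudes))


def _panel_to_derivatives(panel, delta_lambda, interval, mode="savgol"):
    """(conc, DerivativeSpectrum) pairs for a pure-analyte panel."""
    out = []
    for spec, eem in panel:
        conc = spec.concentrations
        if len(conc) != 1:
            raise ValueError("pure panels must contain single-analyte samples")
        (name, c), = conc.items()
        d = first_derivative(
            synchronous_spectrum(eem, delta_lambda), interval, mode
        )
        out.append((name, float(c), d))
    return out


def scan_delta_lambda(
    pure_panels: dict,
    candidates,
    interval: int = 15,
    sensitivity_floor: float = 0.3,
    separation_cap: float = 50.0,
):
    """Score candidate synchronous offsets and pick the best.

    ``pure_panels`` maps each analyte name to its pure dilution panel
    (list of (SampleSpec, EEM), >= 2 concentrations).  For each candidate
    offset, both channels' measurement wavelengths are auto-selected by the
    zero-crossing rule, calibration slopes are fitted, and the candidate is
    scored as ``|slope_A| * |slope_B| * min(separation_nm, cap)``.  Returns
    ``(best_offset, table)`` with the full score table as a DataFrame;
    unusable candidates score ``-inf`` and are flagged.  Ties break toward
    the smallest offset.
    """
    from .quant import select_measurement_wavelength  # avoid import cycle

    candidates = sorted(float(c) for c in candidates)
    if not candidates:
        raise ValueError("candidate list must not be empty")
    names = sorted(pure_panels)
    if len(names) != 2:
        raise ValueError("exactly two pure-analyte panels are required")
    a_name, b_name = names
    rows = []
    for dl in candidates:
        row = {
            "delta_lambda_nm": dl, "score": -np.inf,
            f"lambda_{a_name}": np.nan, f"lambda_{b_name}": np.nan,
            f"slope_{a_name}": np.nan, f"slope_{b_name}": np.nan,
            "flag": "",
        }
        try:
            derivs = {
                name: [
                    (c, d) for _, c, d in _panel_to_derivatives(
                        pure_panels[name], dl, interval
                    )
                ]
                for name in names
            }
        except GridError:
            row["flag"] = "no overlap"
            rows.append(row)
            continue
        try:
            lam: dict[str, float] = {}
            slope: dict[str, float] = {}
            for analyte, other in ((a_name, b_name), (b_name, a_name)):
                interferent = [d for _, d in derivs[other]]
                ref_conc, ref = max(derivs[analyte], key=lambda t: t[0])
                lam[analyte] = select_measurement_wavelength(
                    interferent, ref, sensitivity_floor
                )
                concs = np.array([c for c, _ in derivs[analyte]])
                amps = np.array(
                    [amplitude_at(d, lam[analyte]) for _, d in derivs[analyte]]
                )
                slope[analyte] = float(np.polyfit(concs, amps, 1)[0])
        except NumericError:
            row["flag"] = "unresolvable"
            rows.append(row)
            continue
        sep = min(abs(lam[a_name] - lam[b_name]), separation_cap)
        score = abs(slope[a_name]) * abs(slope[b_name]) * sep
        row.update({
            "score": score,
            f"lambda_{a_name}": lam[a_name], f"lambda_{b_name}": lam[b_name],
            f"slope_{a_name}": slope[a_name], f"slope_{b_name}": slope[b_name],
            "flag": "unresolvable" if score == 0 else "",
        })
        rows.append(row)
    table = pd.DataFrame(rows)
    finite = table["score"][np.isfinite(table["score"])]
    if finite.empty:
        raise NumericError("no candidate offset produced usable channels")
    best_idx = int(table["score"].idxmax())  # first max -> smallest offset
    return float(table.loc[best_idx, "delta_lambda_nm"]), table
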