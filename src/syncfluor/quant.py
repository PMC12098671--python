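"""Calibration and quantification via the zero-crossing technique.

The modelling surface follows the model/results split: a
:class:`SyncDerivCalibration` is built from a calibration panel (levels +
first-derivative amplitudes at the channel's measurement wavelength) and
``fit()`` returns a :class:`CalibrationResults` carrying the regression
estimates, the intercept scatter used for LOD/LOQ, diagnostics and a
``summary()`` table; prediction and the mixture/standard-addition/tablet
workflows consume the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .exceptions import NumericError, UnresolvableChannelsError
from .simulate import EEM, LINEAR_RANGES, SampleSpec
from .spectra_io import RunConfig
from .syncderiv import (
    DerivativeSpectrum,
    amplitude_at,
    first_derivative,
    synchronous_spectrum,
)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Table-style rounding (half away from zero), used only for reports."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def select_measurement_wavelength(
    interferent_panel: list[DerivativeSpectrum],
    analyte_reference: DerivativeSpectrum,
    sensitivity_floor: float = 0.3,
) -> float:
    """Pick the analyte's measurement wavelength on the shared grid.

    Finds the grid wavelength minimising the worst-case interferent
    |derivative| across the panel, restricted to wavelengths where the
    analyte reference |derivative| is at least ``sensitivity_floor`` times
    its own maximum — i.e. the interferent's concentration-stable zero
    crossing that still carries usable analyte signal.  Ties break toward
    the strongest analyte signal.  When the interferent actually changes
    sign next to the grid minimiser, the wavelength is refined to the
    interpolated crossing (sub-grid accuracy matters: reading even half a
    grid step off the crossing leaks interferent signal into the channel).
    """
    from .syncderiv import find_zero_crossings
    if len(interferent_panel) < 3:
        raise ValueError("interferent panel needs >= 3 concentrations")
    lam = analyte_reference.wavelengths
    for d in interferent_panel:
        if len(d.wavelengths) != len(lam) or not np.allclose(
            d.wavelengths, lam
        ):
            raise ValueError("panel spectra must share the analyte's grid")
    g = max([analyte_reference.edge_guard] + [d.edge_guard for d in interferent_panel])
    sl = slice(g, len(lam) - g)
    ref_abs = np.abs(analyte_reference.amplitudes[sl])
    floor = sensitivity_floor * ref_abs.max()
    usable = ref_abs >= floor
    if ref_abs.max() == 0 or not usable.any():
        raise UnresolvableChannelsError(
            "channels unresolvable at this delta-lambda: no wavelength "
            "carries sufficient analyte signal"
        )
    worst = np.max(
        np.abs(np.stack([d.amplitudes[sl] for d in interferent_panel])), axis=0
    )
    worst = np.where(usable, worst, np.inf)
    best = worst.min()
    tied = np.flatnonzero(worst <= best * (1 + 1e-12) + 1e-300)
    pick = tied[np.argmax(ref_abs[tied])]
    picked = float(lam[sl][pick])
    # sub-grid refinement: snap to the interferent's interpolated zero
    # crossing when one lies within a grid step of the picked point
    strongest = max(
        interferent_panel, key=lambda d: np.abs(d.amplitudes[sl]).max()
    )
    if np.abs(strongest.amplitudes[sl]).max() > 0:
        step = float(lam[1] - lam[0])
        crossings = find_zero_crossings(strongest)
        near = [x for x in crossings if abs(x - picked) <= step]
        if near:
            picked = min(near, key=lambda x: abs(x - picked))
    return picked


@dataclass
class ConcentrationEstimate:
    """A predicted concentration with its range flag (no silent
    extrapolation: out-of-range values always carry the flag)."""

    value: float
    analyte: str
    below_range: bool = False
    above_range: bool = False

    @property
    def in_range(self) -> bool:
        return not (self.below_range or self.above_range)


@dataclass
class RecoveryRecord:
    """added/found pair with percent recovery (100 * found / added)."""

    added: float
    found: float
    percent_recovery: float
    context: str = "mixture"
    flagged: bool = False

    @classmethod
    def compute(cls, added: float, found: float, context: str = "mixture"):
        if not (added > 0):
            raise ValueError("added concentration must be > 0")
        return cls(
            added=float(added),
            found=float(found),
            percent_recovery=100.0 * found / added,
            context=context,
            flagged=found < 0,
        )


class SyncDerivCalibration:
    """Linear calibration model: derivative amplitude vs concentration.

    Parameters
    ----------
    levels : array-like
        Concentrations, ug/mL (>= 3 distinct values).
    amplitudes : array-like
        Signed first-derivative amplitudes at the measurement wavelength.
        Signed values are calibrated as-is; negative-slope channels are
        legal.
    analyte : str
    measurement_wavelength : float, nm
    replicate_ids : array-like of int, optional
        Groups points into replicate curves; the SD of the per-replicate
        intercepts is the sigma used for LOD/LOQ (needs >= 2 groups).
    """

    def __init__(
        self,
        levels,
        amplitudes,
        analyte: str,
        measurement_wavelength: float,
        replicate_ids=None,
        level_range: tuple[float, float] | None = None,
        delta_lambda: float | None = None,
        interval: int | None = None,
    ):
        self.levels = np.asarray(levels, dtype=float)
        self.amplitudes = np.asarray(amplitudes, dtype=float)
        if self.levels.shape != self.amplitudes.shape:
            raise ValueError("levels and amplitudes differ in length")
        if len(np.unique(self.levels)) < 3:
            raise NumericError("calibration needs >= 3 distinct levels")
        self.analyte = analyte
        self.measurement_wavelength = float(measurement_wavelength)
        self.replicate_ids = (
            None if replicate_ids is None
            else np.asarray(replicate_ids, dtype=int)
        )
        if level_range is None:
            level_range = (float(self.levels.min()), float(self.levels.max()))
        self.level_range = level_range
        self.delta_lambda = delta_lambda
        self.interval = interval

    @classmethod
    def from_panel(
        cls,
        panel,
        analyte: str,
        measurement_wavelength: float,
        config: RunConfig,
    ) -> "SyncDerivCalibration":
        """Build the model by running the full spectral pipeline on a
        calibration panel of (SampleSpec, EEM) pairs."""
        levels, amps, reps = [], [], []
        for spec, eem in panel:
            if analyte not in spec.concentrations:
                raise ValueError(
                    f"panel sample lacks analyte {analyte!r}"
                )
            d = first_derivative(
                synchronous_spectrum(eem, config.delta_lambda),
                config.derivative_interval,
                config.derivative_mode,
            )
            levels.append(spec.concentrations[analyte])
            amps.append(amplitude_at(d, measurement_wavelength))
            reps.append(spec.replicate_id)
        return cls(
            levels, amps, analyte, measurement_wavelength,
            replicate_ids=reps,
            level_range=LINEAR_RANGES.get(analyte),
            delta_lambda=config.delta_lambda,
            interval=config.derivative_interval,
        )

    def fit(self) -> "CalibrationResults":
        """Ordinary least squares of amplitude on concentration."""
        res = stats.linregress(self.levels, self.amplitudes)
        sigma_intercept = None
        if self.replicate_ids is not None:
            intercepts = []
            for rep in np.unique(self.replicate_ids):
                m = self.replicate_ids == rep
                if len(np.unique(self.levels[m])) >= 3:
                    intercepts.append(
                        stats.linregress(
                            self.levels[m], self.amplitudes[m]
                        ).intercept
                    )
            if len(intercepts) >= 2:
                sigma_intercept = float(np.std(intercepts, ddof=1))
        return CalibrationResults(
            model=self,
            slope=float(res.slope),
            intercept=float(res.intercept),
            r=float(res.rvalue),
            stderr_slope=float(res.stderr),
            sigma_intercept=sigma_intercept,
        )


@dataclass
class CalibrationResults:
    """Fitted calibration line for one analyte channel."""

    model: SyncDerivCalibration
    slope: float
    intercept: float
    r: float
    stderr_slope: float
    sigma_intercept: float | None

    @property
    def analyte(self) -> str:
        return self.model.analyte

    @property
    def measurement_wavelength(self) -> float:
        return self.model.measurement_wavelength

    @property
    def level_range(self) -> tuple[float, float]:
        return self.model.level_range

    @property
    def r_squared(self) -> float:
        return self.r**2

    @property
    def nobs(self) -> int:
        return len(self.model.levels)

    def predict(self, amplitude: float) -> ConcentrationEstimate:
        """Invert the line: C = (amplitude - intercept) / slope."""
        if self.slope == 0:
            raise NumericError(
                f"{self.analyte}: zero calibration slope, cannot invert"
            )
        c = (amplitude - self.intercept) / self.slope
        lo, hi = self.level_range
        return ConcentrationEstimate(
            value=float(c),
            analyte=self.analyte,
            below_range=c < lo,
            above_range=c > hi,
        )

    def summary(self) -> str:
        lo, hi = self.level_range
        sig = (
            "unavailable (needs >= 2 replicate curves)"
            if self.sigma_intercept is None
            else f"{self.sigma_intercept:.6g}"
        )
        lines = [
            f"Calibration: {self.analyte}",
            f"  measurement wavelength : {self.measurement_wavelength:.1f} nm",
            f"  linear range           : {lo:g}-{hi:g} ug/mL",
            f"  n points               : {self.nobs}",
            f"  slope                  : {self.slope:.6g} (AFU/nm)/(ug/mL)",
            f"  intercept              : {self.intercept:.6g} AFU/nm",
            f"  r                      : {self.r:.6f}",
            f"  r^2                    : {self.r_squared:.4f}",
            f"  sigma(intercepts)      : {sig}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "measurement_wavelength": self.measurement_wavelength,
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "r_squared": self.r_squared,
            "sigma_intercept": self.sigma_intercept,
            "level_range": list(self.level_range),
            "n": self.nobs,
            "delta_lambda": self.model.delta_lambda,
            "interval": self.model.interval,
            "levels": self.model.levels.tolist(),
            "amplitudes": self.model.amplitudes.tolist(),
            "replicate_ids": (
                None if self.model.replicate_ids is None
                else self.model.replicate_ids.tolist()
            ),
        }


def auto_calibrate(
    config: RunConfig,
    noise=None,
    replicates: int = 1,
    seed: int = 0,
) -> dict[str, CalibrationResults]:
    """Calibrate both channels with auto-selected measurement wavelengths.

    Measurement wavelengths come from noiseless reference panels via the
    zero-crossing rule (unless the config pins them); the calibration
    lines are then fitted on panels generated with ``noise`` (noiseless by
    default) at the config's calibration levels.
    """
    from .fluorophores import default_models
    from .simulate import NOISELESS, generate_calibration_panel

    noise = NOISELESS if noise is None else noise
    ref_panels = {
        m.name: generate_calibration_panel(
            m.name, config.calibration_levels[m.name][:3],
            noise=NOISELESS, seed=0, background=0.0,
        )
        for m in default_models()
    }
    ref_derivs = {
        name: [
            (
                spec.concentrations[name],
                first_derivative(
                    synchronous_spectrum(eem, config.delta_lambda),
                    config.derivative_interval,
                    config.derivative_mode,
                ),
            )
            for spec, eem in panel
        ]
        for name, panel in ref_panels.items()
    }
    curves: dict[str, CalibrationResults] = {}
    for analyte, other in (("ASP", "ATO"), ("ATO", "ASP")):
        want = config.measurement_wavelengths.get(analyte, "auto")
        if want == "auto":
            ref = max(ref_derivs[analyte], key=lambda t: t[0])[1]
            lam = select_measurement_wavelength(
                [d for _, d in ref_derivs[other]], ref,
                config.sensitivity_floor,
            )
        else:
            lam = float(want)
        panel = generate_calibration_panel(
            analyte, config.calibration_levels[analyte],
            replicates=replicates, noise=noise,
            seed=(seed * 1009 + sum(ord(c) for c in analyte)) % (2**31),
        )
        curves[analyte] = SyncDerivCalibration.from_panel(
            panel, analyte, lam, config
        ).fit()
    return curves


def calibration_from_dict(d: dict) -> CalibrationResults:
    """Rebuild a fitted calibration from its ``to_dict`` serialisation."""
    model = SyncDerivCalibration(
        d["levels"], d["amplitudes"], d["analyte"],
        d["measurement_wavelength"],
        replicate_ids=d.get("replicate_ids"),
        level_range=tuple(d["level_range"]),
        delta_lambda=d.get("delta_lambda"),
        interval=d.get("interval"),
    )
    return model.fit()


def fit_calibration(
    levels,
    amplitudes,
    analyte: str = "analyte",
    measurement_wavelength: float = float("nan"),
    replicate_ids=None,
) -> CalibrationResults:
    """Convenience wrapper: build the model and fit in one call."""
    return SyncDerivCalibration(
        levels, amplitudes, analyte, measurement_wavelength,
        replicate_ids=replicate_ids,
    ).fit()


def predict_concentration(
    curve: CalibrationResults, amplitude: float
) -> ConcentrationEstimate:
    """Functional alias for :meth:`CalibrationResults.predict`."""
    return curve.predict(amplitude)


@dataclass
class MixtureResult:
    estimate: ConcentrationEstimate
    recovery: RecoveryRecord | None = None


def analyze_mixture(
    eem: EEM,
    curves: dict[str, CalibrationResults],
    config: RunConfig,
) -> dict[str, MixtureResult]:
    """Quantify every calibrated analyte in one mixture EEM.

    Runs synchronous extraction -> derivative -> amplitude at each
    channel's measurement wavelength -> inverse prediction.  When the EEM
    carries simulated truth, a recovery record is attached.
    """
    for analyte, curve in curves.items():
        if curve.model.delta_lambda is not None and not np.isclose(
            curve.model.delta_lambda, config.delta_lambda
        ):
            raise ValueError(
                f"{analyte}: calibration delta-lambda "
                f"{curve.model.delta_lambda} != config {config.delta_lambda}"
            )
    d = first_derivative(
        synchronous_spectrum(eem, config.delta_lambda),
        config.derivative_interval,
        config.derivative_mode,
    )
    out: dict[str, MixtureResult] = {}
    truth = (
        eem.provenance.concentrations
        if isinstance(eem.provenance, SampleSpec)
        else {}
    )
    for analyte, curve in curves.items():
        est = curve.predict(amplitude_at(d, curve.measurement_wavelength))
        rec = None
        if truth.get(analyte, 0) > 0:
            rec = RecoveryRecord.compute(
                truth[analyte], est.value, context="mixture"
            )
        out[analyte] = MixtureResult(est, rec)
    return out


def standard_addition(
    base_found: float, added: float, total_found: float
) -> RecoveryRecord:
    """Spike-recovery accounting: pure found = total found - base found.

    Percent recovery is 100 * pure_found / added.  A negative pure-found is
    kept but flagged.
    """
    if not (added > 0):
        raise ValueError("added concentration must be > 0")
    if total_found < 0:
        raise ValueError("total_found must be >= 0")
    pure_found = total_found - base_found
    return RecoveryRecord(
        added=float(added),
        found=float(pure_found),
        percent_recovery=100.0 * pure_found / added,
        context="standard-addition",
        flagged=pure_found < 0,
    )


def tablet_assay(
    sample_eems,
    curves: dict[str, CalibrationResults],
    config: RunConfig,
    nominal: dict[str, list[float]],
) -> dict[str, dict]:
    """Assay a dilution series of a tablet extract against its label claim.

    ``nominal`` maps each analyte to the claim-implied concentration at
    each dilution (ug/mL).  Returns per-analyte mean %R and sample %RSD
    over the determinations, plus the per-level recovery records.
    """
    import warnings as _warnings

    if len(sample_eems) != 5:
        _warnings.warn(
            f"tablet assay expects 5 dilution levels, got "
            f"{len(sample_eems)}; computing anyway", stacklevel=2,
        )
    for analyte, noms in nominal.items():
        if len(noms) != len(sample_eems):
            raise ValueError(
                f"{analyte}: {len(noms)} nominal levels for "
                f"{len(sample_eems)} samples"
            )
        if any(n <= 0 for n in noms):
            raise ValueError(f"{analyte}: nominal claims must be > 0")
    out: dict[str, dict] = {}
    records: dict[str, list[RecoveryRecord]] = {a: [] for a in nominal}
    for k, eem in enumerate(sample_eems):
        res = analyze_mixture(eem, curves, config)
        for analyte in nominal:
            est = res[analyte].estimate
            records[analyte].append(
                RecoveryRecord.compute(
                    nominal[analyte][k], est.value, context="tablet"
                )
            )
    for analyte, recs in records.items():
        pct = np.array([r.percent_recovery for r in recs])
        mean = float(pct.mean())
        sd = float(pct.std(ddof=1)) if len(pct) > 1 else 0.0
        out[analyte] = {
            "records": recs,
            "mean_percent_recovery": mean,
            "percent_rsd": 100.0 * sd / mean,
        }
    return out
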