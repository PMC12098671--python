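"""ICH-style validation battery: linearity, LOD/LOQ, accuracy, precision,
robustness, and two-method statistical comparison.

Conventions: standard deviations are sample (n-1) throughout; %RSD is
100*SD/mean; the recovery acceptance band is 98.0-102.0% and the precision
limit 2.0% RSD; LOD = 3.3*sigma/|S| and LOQ = 10*sigma/|S| with sigma the
SD of calibration-line y-intercepts and S the slope, so LOQ/LOD = 10/3.3
identically.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, NumericError
from .fluorophores import FluorophoreModel, default_models
from .quant import CalibrationResults, RecoveryRecord
from .simulate import (
    DEFAULT_BACKGROUND,
    LINEAR_RANGES,
    NOISELESS,
    NoiseModel,
    simulate_eem,
)
from .spectra_io import RunConfig, perturbed
from .syncderiv import amplitude_at, first_derivative, synchronous_spectrum

RSD_LIMIT = 2.0
RECOVERY_BAND = (98.0, 102.0)


@dataclass
class PrecisionSummary:
    values: list[float]
    mean: float
    sd: float
    percent_rsd: float

    @property
    def passes(self) -> bool:
        return self.percent_rsd <= RSD_LIMIT


def precision_summary(values) -> PrecisionSummary:
    """Mean, sample SD and %RSD of a set of percent values."""
    values = [float(v) for v in values]
    if len(values) < 2:
        raise ValueError("precision summary needs n >= 2 values")
    arr = np.asarray(values)
    mean = float(arr.mean())
    if mean == 0:
        raise NumericError("%RSD undefined: mean of values is zero")
    sd = float(arr.std(ddof=1))
    return PrecisionSummary(values, mean, sd, 100.0 * sd / abs(mean))


LodLoq = namedtuple("LodLoq", ["lod", "loq"])


def lod_loq(sigma_intercept: float, slope: float) -> LodLoq:
    """Detection and quantification limits from intercept scatter and slope."""
    if slope == 0:
        raise NumericError("zero slope: LOD/LOQ undefined")
    if sigma_intercept < 0:
        raise ValueError("sigma must be >= 0")
    s = abs(slope)
    return LodLoq(3.3 * sigma_intercept / s, 10.0 * sigma_intercept / s)


@dataclass
class MethodComparison:
    """Pooled-variance two-sample t and variance-ratio F at 95% confidence.

    The t statistic is reported unsigned (absolute difference of means);
    F uses the larger/smaller convention so F >= 1.
    """

    n1: int
    n2: int
    mean1: float
    mean2: float
    var1: float
    var2: float
    t_statistic: float
    f_statistic: float
    df_t: int
    df_f: tuple[int, int]
    critical_t: float
    critical_f: float

    @property
    def t_significant(self) -> bool:
        return self.t_statistic > self.critical_t

    @property
    def f_significant(self) -> bool:
        return self.f_statistic > self.critical_f


def compare_methods(
    summary1: tuple[int, float, float], summary2: tuple[int, float, float]
) -> MethodComparison:
    """Compare two methods from (n, mean %R, variance of %R) summaries."""
    n1, m1, v1 = summary1
    n2, m2, v2 = summary2
    if n1 < 2 or n2 < 2:
        raise ValueError("both methods need n >= 2")
    if v1 < 0 or v2 < 0:
        raise ValueError("variances must be >= 0")
    if v1 == 0 and v2 == 0:
        raise NumericError("both variances are zero: comparison undefined")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    t_stat = abs(m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if v1 >= v2:
        f_stat = v1 / v2 if v2 > 0 else np.inf
        df_f = (n1 - 1, n2 - 1)
    else:
        f_stat = v2 / v1
        df_f = (n2 - 1, n1 - 1)
    return MethodComparison(
        n1=n1, n2=n2, mean1=float(m1), mean2=float(m2),
        var1=float(v1), var2=float(v2),
        t_statistic=float(t_stat), f_statistic=float(f_stat),
        df_t=df, df_f=df_f,
        critical_t=float(stats.t.ppf(0.975, df)),
        critical_f=float(stats.f.ppf(0.95, *df_f)),
    )


def _quantify_mixture_sample(
    conc: dict[str, float],
    curves: dict[str, CalibrationResults],
    config: RunConfig,
    noise: NoiseModel,
    seed: int,
    models: tuple[FluorophoreModel, ...] | None = None,
) -> dict[str, float]:
    """Simulate one mixture sample and return found concentrations."""
    models = models or default_models()
    comps = [(m, conc.get(m.name, 0.0)) for m in models]
    eem = simulate_eem(
        comps, noise=noise, background=DEFAULT_BACKGROUND, seed=seed
    )
    d = first_derivative(
        synchronous_spectrum(eem, config.delta_lambda),
        config.derivative_interval,
        config.derivative_mode,
    )
    return {
        a: c.predict(amplitude_at(d, c.measurement_wavelength)).value
        for a, c in curves.items()
    }


#: Assay concentrations used by the recovery study (ug/mL); the 80/100/120%
#: levels are fractions of these.
ASSAY_CONC = {"ATO": 1.0, "ASP": 2.0}
#: Concentration levels used by the precision study (ug/mL).
PRECISION_LEVELS = {"ATO": [1.0, 2.0, 3.0], "ASP": [2.0, 4.0, 6.0]}


def accuracy_study(
    curves: dict[str, CalibrationResults],
    config: RunConfig,
    assay_conc: dict[str, float] | None = None,
    level_fractions=(0.8, 1.0, 1.2),
    replicates: int = 3,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> dict[str, dict]:
    """Recovery study at 80/100/120% of the assay concentration.

    Nine determinations per analyte (3 levels x ``replicates``); returns
    mean %R with the 98.0-102.0% pass flag and the raw recovery records.
    """
    assay_conc = dict(assay_conc or ASSAY_CONC)
    noise = config.noise if noise is None else noise
    for analyte, c in assay_conc.items():
        if c <= 0:
            raise ValueError(f"{analyte}: assay concentration must be > 0")
        lo, hi = LINEAR_RANGES.get(analyte, (0, np.inf))
        for f in level_fractions:
            if not (lo <= f * c <= hi):
                raise ValueError(
                    f"{analyte}: level {f * c:g} ug/mL outside linear range "
                    f"[{lo}, {hi}]"
                )
    seeds = np.random.SeedSequence(seed).generate_state(
        len(level_fractions) * replicates
    ) % (2**31)
    records: dict[str, list[RecoveryRecord]] = {a: [] for a in assay_conc}
    k = 0
    for f in level_fractions:
        conc = {a: f * c for a, c in assay_conc.items()}
        for _ in range(replicates):
            found = _quantify_mixture_sample(
                conc, curves, config, noise, int(seeds[k])
            )
            for a in assay_conc:
                records[a].append(
                    RecoveryRecord.compute(conc[a], found[a], "accuracy")
                )
            k += 1
    out = {}
    for a, recs in records.items():
        pct = [r.percent_recovery for r in recs]
        mean = float(np.mean(pct))
        out[a] = {
            "records": recs,
            "mean_percent_recovery": mean,
            "passes": RECOVERY_BAND[0] <= mean <= RECOVERY_BAND[1],
        }
    return out


def precision_study(
    curves: dict[str, CalibrationResults],
    config: RunConfig,
    levels: dict[str, list[float]] | None = None,
    replicates: int = 3,
    days: int = 3,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> dict[str, dict]:
    """Repeatability (intra-day) and intermediate (inter-day) precision.

    Both analytes are co-simulated level-by-level (three levels each).
    Repeatability is the %RSD of the nine day-one recoveries; intermediate
    precision pools all ``days`` days, each day re-seeded.
    """
    levels = {k: list(v) for k, v in (levels or PRECISION_LEVELS).items()}
    noise = config.noise if noise is None else noise
    n_levels = {len(v) for v in levels.values()}
    if len(n_levels) != 1:
        raise ValueError("all analytes need the same number of levels")
    (nlev,) = n_levels
    day_seeds = np.random.SeedSequence(seed).generate_state(days) % (2**31)
    per_day: dict[str, list[list[float]]] = {a: [] for a in levels}
    for d in range(days):
        seeds = np.random.SeedSequence(int(day_seeds[d])).generate_state(
            nlev * replicates
        ) % (2**31)
        day_recs: dict[str, list[float]] = {a: [] for a in levels}
        k = 0
        for i in range(nlev):
            conc = {a: levels[a][i] for a in levels}
            for _ in range(replicates):
                found = _quantify_mixture_sample(
                    conc, curves, config, noise, int(seeds[k])
                )
                for a in levels:
                    day_recs[a].append(100.0 * found[a] / conc[a])
                k += 1
        for a in levels:
            per_day[a].append(day_recs[a])
    out = {}
    for a, days_list in per_day.items():
        rep = precision_summary(days_list[0])
        inter = precision_summary([v for day in days_list for v in day])
        out[a] = {
            "repeatability": rep,
            "intermediate": inter,
        }
    return out


#: Robustness perturbation bounds: axis -> maximum |delta| accepted.
ROBUSTNESS_BOUNDS = {"delta_lambda": 2.0, "brightness": 0.05}


def _rederive_curves(config: RunConfig) -> dict[str, CalibrationResults]:
    """Noiseless re-calibration for the configured conditions.

    Measurement wavelengths are re-selected and the pure-analyte
    calibration lines re-fitted at the config's synchronous offset — the
    full procedure a laboratory repeats when it changes an instrument
    setting.
    """
    from .quant import auto_calibrate

    return auto_calibrate(config)


def robustness_sweep(
    base_config: RunConfig,
    perturbations: list[tuple[str, float]],
    curves: dict[str, CalibrationResults],
    sample_conc: dict[str, float] | None = None,
    seed: int = 0,
    noise: NoiseModel = NOISELESS,
) -> dict[str, dict[str, PrecisionSummary]]:
    """Re-quantify a fixed mid-range mixture under {-d, 0, +d} per axis.

    Axes:

    ``delta_lambda``
        The synchronous-offset instrument setting.  The whole procedure is
        re-run at each offset — measurement wavelengths re-selected and
        the calibration lines re-fitted — because an offset change applies
        to standards and samples alike.
    ``brightness``
        Fractional jitter of both fluorophores' brightness, the in-silico
        stand-in for small pH/buffer-volume changes.  It perturbs the
        sample only and is read against the base calibration: chemistry
        drift at measurement time is exactly what robustness probes.

    Returns per-axis, per-analyte %RSD of the three determinations with
    the 2% pass flag.
    """
    sample_conc = dict(sample_conc or {"ASP": 6.0, "ATO": 2.0})
    results: dict[str, dict[str, PrecisionSummary]] = {}
    for axis, delta in perturbations:
        if axis not in ROBUSTNESS_BOUNDS:
            raise ValueError(f"unknown robustness axis {axis!r}")
        if abs(delta) > ROBUSTNESS_BOUNDS[axis]:
            raise ValueError(
                f"{axis} perturbation {delta} outside configured bound "
                f"+/-{ROBUSTNESS_BOUNDS[axis]}"
            )
        found: dict[str, list[float]] = {a: [] for a in curves}
        for sign in (-1.0, 0.0, +1.0):
            if axis == "delta_lambda":
                cfg = perturbed(
                    base_config,
                    delta_lambda=base_config.delta_lambda + sign * delta,
                )
                cond_curves = _rederive_curves(cfg)
                models = default_models()
            else:
                cfg = base_config
                cond_curves = curves
                models = tuple(
                    FluorophoreModel(
                        m.name, m.ex_max, m.em_max, m.ex_width, m.em_width,
                        m.brightness * (1.0 + sign * delta),
                    )
                    for m in default_models()
                )
            vals = _quantify_mixture_sample(
                sample_conc, cond_curves, cfg, noise, seed, models=models
            )
            for a in curves:
                found[a].append(vals[a])
        results[f"{axis} (+/-{delta:g})"] = {
            a: precision_summary(v) for a, v in found.items()
        }
    return results


_REPORT_ROWS = [
    "Wavelength (nm)",
    "Linearity range (ug/mL)",
    "Determination coefficient (r^2)",
    "Intercept",
    "Slope",
    "LOD (ug/mL)",
    "LOQ (ug/mL)",
    "Accuracy (%R)",
    "Repeatability (%RSD)",
    "Intermediate precision (%RSD)",
    "Robustness (%RSD)",
]


@dataclass
class ValidationReport:
    """Per-analyte validation blocks plus the method comparison."""

    analytes: dict[str, dict] = field(default_factory=dict)
    comparison: MethodComparison | None = None

    _REQUIRED = (
        "wavelength", "range", "r_squared", "intercept", "slope",
        "lod", "loq", "accuracy_mean_r", "repeatability_rsd",
        "intermediate_rsd", "robustness_rsd",
    )

    def missing_blocks(self) -> list[str]:
        out = []
        for analyte, block in self.analytes.items():
            for key in self._REQUIRED:
                if key not in block:
                    out.append(f"{analyte}.{key}")
        return out


def render_report(report: ValidationReport, path) -> Path:
    """Write the validation report as CSV plus a human-readable text file.

    Emits one row per validation parameter per analyte; a consistency
    warning is appended when LOQ/LOD deviates from the forced 10/3.3 ratio.
    Returns the CSV path (the text file sits next to it with a .txt suffix).
    """
    missing = report.missing_blocks()
    if missing:
        raise DataError(f"validation report incomplete: missing {missing}")
    path = Path(path)
    rows = []
    warnings_out = []
    for analyte, block in report.analytes.items():
        lo, hi = block["range"]
        values = {
            "Wavelength (nm)": f"{block['wavelength']:.1f}",
            "Linearity range (ug/mL)": f"{lo:g}-{hi:g}",
            "Determination coefficient (r^2)": f"{block['r_squared']:.4f}",
            "Intercept": f"{block['intercept']:.4f}",
            "Slope": f"{block['slope']:.4f}",
            "LOD (ug/mL)": f"{block['lod']:.4g}",
            "LOQ (ug/mL)": f"{block['loq']:.4g}",
            "Accuracy (%R)": f"{block['accuracy_mean_r']:.2f}",
            "Repeatability (%RSD)": f"{block['repeatability_rsd']:.3f}",
            "Intermediate precision (%RSD)":
                f"{block['intermediate_rsd']:.3f}",
            "Robustness (%RSD)": "; ".join(
                f"{axis}: {rsd:.3f}"
                for axis, rsd in block["robustness_rsd"].items()
            ),
        }
        for label in _REPORT_ROWS:
            rows.append(
                {"analyte": analyte, "parameter": label,
                 "value": values[label]}
            )
        if block["lod"] > 0:
            ratio = block["loq"] / block["lod"]
            if abs(ratio - 10.0 / 3.3) > 1e-9:
                warnings_out.append(
                    f"WARNING: {analyte} LOQ/LOD ratio {ratio:.4f} != "
                    f"10/3.3 = {10/3.3:.4f}"
                )
    pd.DataFrame(rows).to_csv(path, index=False)

    txt_path = path.with_suffix(".txt")
    with open(txt_path, "w") as fh:
        fh.write("Validation report\n=================\n\n")
        for analyte, block in report.analytes.items():
            fh.write(f"[{analyte}]\n")
            for row in rows:
                if row["analyte"] == analyte:
                    fh.write(f"  {row['parameter']:<34s} {row['value']}\n")
            fh.write("\n")
        if report.comparison is not None:
            c = report.comparison
            fh.write(
                "Method comparison (95% confidence)\n"
                f"  t = {c.t_statistic:.3f} (critical {c.critical_t:.3f}, "
                f"df {c.df_t})\n"
                f"  F = {c.f_statistic:.3f} (critical {c.critical_f:.3f}, "
                f"df {c.df_f})\n\n"
            )
        for w in warnings_out:
            fh.write(w + "\n")
    return path
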