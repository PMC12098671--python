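"""End-to-end synthetic run: simulate, scan, calibrate, quantify, validate.

``run_demo`` regenerates a complete analytical campaign on the
default simulated analytes: pure calibration panels, the synchronous-offset
scan, zero-crossing calibration of both channels, a laboratory-mixture
recovery series, a standard-addition study on a tablet-like sample, and the
full validation report.  Every stochastic step derives from one master seed
so reruns are bit-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import SyncfluorError
from .fluorophores import default_models
from .quant import (
    SyncDerivCalibration,
    analyze_mixture,
    select_measurement_wavelength,
    standard_addition,
    tablet_assay,
)
from .simulate import (
    DEFAULT_BACKGROUND,
    MIXTURE_RATIO,
    NOISELESS,
    generate_calibration_panel,
    generate_mixture_panel,
    simulate_eem,
    simulate_tablet_panel,
    mixture_ratio_series,
)
from .spectra_io import (
    RunConfig,
    perturbed,
    write_sample_sheet,
    write_spectrum_csv,
)
from .syncderiv import (
    first_derivative,
    scan_delta_lambda,
    synchronous_spectrum,
)
from .validation import (
    MethodComparison,
    ValidationReport,
    accuracy_study,
    compare_methods,
    lod_loq,
    precision_study,
    precision_summary,
    render_report,
    robustness_sweep,
)

# Fixed per-stage seed offsets from the master seed (reproducible partial
# reruns); all child seeds stay below 2**31.
_STAGE_OFFSETS = {
    "panel_ASP": 101,
    "panel_ATO": 102,
    "mixtures": 303,
    "std_add_base": 404,
    "std_add_spikes": 405,
    "accuracy": 505,
    "precision": 606,
    "assay_a": 707,
    "assay_b": 708,
}


@dataclass
class RunManifest:
    """Record of one demo run: config, seeds, artifacts, timings."""

    master_seed: int
    version: str
    config: dict
    stage_seeds: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    completed: bool = False

    def write(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(
                {
                    "master_seed": self.master_seed,
                    "version": self.version,
                    "config": self.config,
                    "stage_seeds": self.stage_seeds,
                    "artifacts": {
                        k: [str(p) for p in v] if isinstance(v, list)
                        else str(v)
                        for k, v in self.artifacts.items()
                    },
                    "stage_seconds": self.stage_seconds,
                    "completed": self.completed,
                },
                fh,
                indent=2,
            )
        return path


def _stage_seed(master: int, stage: str) -> int:
    return (int(master) * 1009 + _STAGE_OFFSETS[stage]) % (2**31)


def run_demo(
    seed: int = 0,
    out_dir: str | Path = "demo_out",
    config: RunConfig | None = None,
    scan_candidates=tuple(range(20, 121, 10)),
    log=print,
) -> RunManifest:
    """Run the full synthetic campaign; returns the manifest.

    Any stage failure aborts with the stage name attached and the partial
    manifest written to ``out_dir/manifest.json``.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig(seed=seed)
    manifest = RunManifest(
        master_seed=seed, version=__version__, config=config.to_dict()
    )
    asp, ato = default_models()
    stage = "init"
    try:
        # ---- stage 1: simulate panels -------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        log(f"[{stage}] calibration panels, replicates={config.replicates}")
        panels = {}
        for model in (asp, ato):
            s = _stage_seed(seed, f"panel_{model.name}")
            manifest.stage_seeds[f"panel_{model.name}"] = s
            panels[model.name] = generate_calibration_panel(
                model.name,
                config.calibration_levels[model.name],
                replicates=config.replicates,
                noise=config.noise,
                seed=s,
            )
            sheet = write_sample_sheet(
                [spec for spec, _ in panels[model.name]],
                out / f"sample_sheet_{model.name}.csv",
            )
            manifest.artifacts[f"sample_sheet_{model.name}"] = sheet
        # noiseless reference panels for wavelength selection and the scan
        ref_panels = {
            m.name: generate_calibration_panel(
                m.name,
                config.calibration_levels[m.name][:3],
                noise=NOISELESS,
                seed=0,
                background=0.0,
            )
            for m in (asp, ato)
        }
        manifest.stage_seconds[stage] = time.perf_counter() - t0

        # ---- stage 2: offset scan -----------------------------------
        stage = "scan"
        t0 = time.perf_counter()
        log(f"[{stage}] offsets {min(scan_candidates)}-{max(scan_candidates)} nm")
        best_dl, scan_table = scan_delta_lambda(
            ref_panels,
            scan_candidates,
            interval=config.derivative_interval,
            sensitivity_floor=config.sensitivity_floor,
        )
        scan_path = out / "scan_table.csv"
        scan_table.to_csv(scan_path, index=False)
        manifest.artifacts["scan_table"] = scan_path
        log(f"[{stage}] best delta-lambda: {best_dl:g} nm")
        config = perturbed(config, delta_lambda=float(best_dl))
        manifest.config = config.to_dict()
        manifest.stage_seconds[stage] = time.perf_counter() - t0

        # ---- stage 3: calibrate both channels -----------------------
        stage = "calibrate"
        t0 = time.perf_counter()
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
        curves = {}
        for analyte, other in (("ASP", "ATO"), ("ATO", "ASP")):
            want = config.measurement_wavelengths.get(analyte, "auto")
            if want == "auto":
                ref = max(ref_derivs[analyte], key=lambda t: t[0])[1]
                lam = select_measurement_wavelength(
                    [d for _, d in ref_derivs[other]],
                    ref,
                    config.sensitivity_floor,
                )
            else:
                lam = float(want)
            curves[analyte] = SyncDerivCalibration.from_panel(
                panels[analyte], analyte, lam, config
            ).fit()
            log(
                f"[{stage}] {analyte}: lambda={lam:.1f} nm, "
                f"slope={curves[analyte].slope:.4f}, "
                f"r^2={curves[analyte].r_squared:.5f}"
            )
        calib_path = out / "calibration.json"
        with open(calib_path, "w") as fh:
            json.dump(
                {
                    "delta_lambda": config.delta_lambda,
                    "interval": config.derivative_interval,
                    "curves": {a: c.to_dict() for a, c in curves.items()},
                },
                fh,
                indent=2,
            )
        manifest.artifacts["calibration"] = calib_path
        manifest.stage_seconds[stage] = time.perf_counter() - t0

        # ---- stage 4: laboratory mixtures ---------------------------
        stage = "mixtures"
        t0 = time.perf_counter()
        s = _stage_seed(seed, "mixtures")
        manifest.stage_seeds["mixtures"] = s
        mix_panel = generate_mixture_panel(
            mixture_ratio_series(), noise=config.noise, seed=s
        )
        rows = ["analyte,added_ug_per_ml,found_ug_per_ml,percent_recovery"]
        recs = {"ASP": [], "ATO": []}
        for spec, eem in mix_panel:
            res = analyze_mixture(eem, curves, config)
            for analyte, r in res.items():
                rec = r.recovery
                rows.append(
                    f"{analyte},{rec.added:g},{rec.found:.6g},"
                    f"{rec.percent_recovery:.4f}"
                )
                recs[analyte].append(rec.percent_recovery)
        for analyte, pct in recs.items():
            summ = precision_summary(pct)
            rows.append(
                f"{analyte},mean,,{summ.mean:.4f}"
            )
            rows.append(f"{analyte},percent_rsd,,{summ.percent_rsd:.4f}")
        mix_path = out / "mixtures.csv"
        mix_path.write_text("\n".join(rows) + "\n")
        manifest.artifacts["mixtures"] = mix_path
        # QC traces mirroring the pure/mixture synchronous overlay
        qc_paths = []
        for label, comps in (
            ("asp6", [(asp, 6.0)]),
            ("ato2", [(ato, 2.0)]),
            ("mix", [(asp, 6.0), (ato, 2.0)]),
        ):
            eem = simulate_eem(comps, background=DEFAULT_BACKGROUND)
            sp = synchronous_spectrum(eem, config.delta_lambda)
            qc_paths.append(
                write_spectrum_csv(sp, out / f"sync_{label}.csv")
            )
        manifest.artifacts["qc_spectra"] = qc_paths
        manifest.stage_seconds[stage] = time.perf_counter() - t0

        # ---- stage 5: standard addition -----------------------------
        stage = "std_add"
        t0 = time.perf_counter()
        base_conc = {"ATO": 2.0, "ASP": 2.0 * MIXTURE_RATIO}
        s_base = _stage_seed(seed, "std_add_base")
        s_spike = _stage_seed(seed, "std_add_spikes")
        manifest.stage_seeds["std_add"] = [s_base, s_spike]
        base_seeds = np.random.SeedSequence(s_base).generate_state(5) % (2**31)
        base_found = {"ASP": [], "ATO": []}
        for bs in base_seeds:
            eem = simulate_eem(
                [(asp, base_conc["ASP"]), (ato, base_conc["ATO"])],
                noise=config.noise, background=DEFAULT_BACKGROUND,
                seed=int(bs),
            )
            res = analyze_mixture(eem, curves, config)
            for a in base_found:
                base_found[a].append(res[a].estimate.value)
        base_mean = {a: float(np.mean(v)) for a, v in base_found.items()}
        spikes = {"ATO": [0.5, 1.0, 1.5, 2.0],
                  "ASP": [1.875, 3.75, 5.625, 7.5]}
        spike_seeds = np.random.SeedSequence(s_spike).generate_state(12) % (
            2**31
        )
        rows = [
            "analyte,base_found_ug_per_ml,added_ug_per_ml,"
            "pure_found_ug_per_ml,percent_recovery"
        ]
        sa_recs = {"ASP": [], "ATO": []}
        for k in range(4):
            total_conc = {
                a: base_conc[a] + spikes[a][k] for a in base_conc
            }
            # each spiked level is the average of three determinations
            totals: dict[str, list[float]] = {a: [] for a in base_conc}
            for rep in range(3):
                eem = simulate_eem(
                    [(asp, total_conc["ASP"]), (ato, total_conc["ATO"])],
                    noise=config.noise, background=DEFAULT_BACKGROUND,
                    seed=int(spike_seeds[3 * k + rep]),
                )
                res = analyze_mixture(eem, curves, config)
                for a in base_conc:
                    totals[a].append(res[a].estimate.value)
            for a in base_conc:
                rec = standard_addition(
                    base_mean[a], spikes[a][k], float(np.mean(totals[a]))
                )
                sa_recs[a].append(rec.percent_recovery)
                rows.append(
                    f"{a},{base_mean[a]:.4f},{rec.added:g},"
                    f"{rec.found:.4f},{rec.percent_recovery:.4f}"
                )
        for a, pct in sa_recs.items():
            summ = precision_summary(pct)
            rows.append(f"{a},mean,,,{summ.mean:.4f}")
            rows.append(f"{a},percent_rsd,,,{summ.percent_rsd:.4f}")
        sa_path = out / "standard_addition.csv"
        sa_path.write_text("\n".join(rows) + "\n")
        manifest.artifacts["standard_addition"] = sa_path
        manifest.stage_seconds[stage] = time.perf_counter() - t0

        # ---- stage 6: validation report -----------------------------
        stage = "validate"
        t0 = time.perf_counter()
        s_acc = _stage_seed(seed, "accuracy")
        s_prec = _stage_seed(seed, "precision")
        manifest.stage_seeds["accuracy"] = s_acc
        manifest.stage_seeds["precision"] = s_prec
        acc = accuracy_study(curves, config, seed=s_acc)
        prec = precision_study(curves, config, seed=s_prec)
        robust = robustness_sweep(
            config,
            [("delta_lambda", 1.0), ("brightness", 0.01)],
            curves,
            noise=config.noise,
        )
        # two independently seeded assay runs stand in for the two methods
        comparison: MethodComparison | None = None
        assay_summaries = []
        for key in ("assay_a", "assay_b"):
            s_assay = _stage_seed(seed, key)
            manifest.stage_seeds[key] = s_assay
            tab_panel = simulate_tablet_panel(
                {"ATO": 1.0, "ASP": 1.0}, noise=config.noise, seed=s_assay
            )
            nominal = {
                "ATO": [0.5, 1.0, 1.5, 2.0, 2.5],
                "ASP": [c * MIXTURE_RATIO for c in (0.5, 1.0, 1.5, 2.0, 2.5)],
            }
            res = tablet_assay(
                [eem for _, eem in tab_panel], curves, config, nominal
            )
            assay_summaries.append(res)
        report = ValidationReport()
        for analyte, curve in curves.items():
            sigma = curve.sigma_intercept or 0.0
            limits = lod_loq(sigma, curve.slope)
            report.analytes[analyte] = {
                "wavelength": curve.measurement_wavelength,
                "range": curve.level_range,
                "r_squared": curve.r_squared,
                "intercept": curve.intercept,
                "slope": curve.slope,
                "lod": limits.lod,
                "loq": limits.loq,
                "accuracy_mean_r": acc[analyte]["mean_percent_recovery"],
                "repeatability_rsd":
                    prec[analyte]["repeatability"].percent_rsd,
                "intermediate_rsd":
                    prec[analyte]["intermediate"].percent_rsd,
                "robustness_rsd": {
                    axis: by_analyte[analyte].percent_rsd
                    for axis, by_analyte in robust.items()
                },
            }
        pct_a = [
            r.percent_recovery
            for res in (assay_summaries[0],)
            for a in res
            for r in res[a]["records"]
        ]
        pct_b = [
            r.percent_recovery
            for res in (assay_summaries[1],)
            for a in res
            for r in res[a]["records"]
        ]
        sa = precision_summary(pct_a)
        sb = precision_summary(pct_b)
        comparison = compare_methods(
            (len(pct_a), sa.mean, sa.sd**2), (len(pct_b), sb.mean, sb.sd**2)
        )
        report.comparison = comparison
        report_path = render_report(report, out / "validation_report.csv")
        manifest.artifacts["validation_report"] = report_path
        manifest.artifacts["validation_report_txt"] = report_path.with_suffix(
            ".txt"
        )
        manifest.stage_seconds[stage] = time.perf_counter() - t0
        manifest.completed = True
    except Exception as exc:
        manifest.write(out / "manifest.json")
        raise SyncfluorError(f"demo stage {stage!r} failed: {exc}") from exc

    manifest_path = manifest.write(out / "manifest.json")
    manifest.artifacts["manifest"] = manifest_path
    log(f"done: {len(manifest.artifacts)} artifact entries in {out}")
    return manifest
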