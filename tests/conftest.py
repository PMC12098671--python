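import pytest

from syncfluor import default_models
from syncfluor.quant import SyncDerivCalibration, select_measurement_wavelength
from syncfluor.simulate import NOISELESS, NoiseModel, generate_calibration_panel
from syncfluor.spectra_io import RunConfig
from syncfluor.syncderiv import first_derivative, synchronous_spectrum


def derivative_panel(panel, config):
    """(conc, derivative spectrum) pairs for a pure-analyte panel."""
    out = []
    for spec, eem in panel:
        (name, c), = spec.concentrations.items()
        d = first_derivative(
            synchronous_spectrum(eem, config.delta_lambda),
            config.derivative_interval,
            config.derivative_mode,
        )
        out.append((c, d))
    return out


def auto_wavelengths(config):
    """Zero-crossing measurement wavelengths from noiseless 3-level panels."""
    panels = {
        m.name: generate_calibration_panel(
            m.name, config.calibration_levels[m.name][:3],
            noise=NOISELESS, seed=0, background=0.0,
        )
        for m in default_models()
    }
    derivs = {n: derivative_panel(p, config) for n, p in panels.items()}
    lam = {}
    for analyte, other in (("ASP", "ATO"), ("ATO", "ASP")):
        ref = max(derivs[analyte], key=lambda t: t[0])[1]
        lam[analyte] = select_measurement_wavelength(
            [d for _, d in derivs[other]], ref, config.sensitivity_floor
        )
    return lam


def build_curves(config, lam, noise, replicates, seed):
    curves = {}
    for analyte in ("ASP", "ATO"):
        panel = generate_calibration_panel(
            analyte, config.calibration_levels[analyte],
            replicates=replicates, noise=noise, seed=seed,
        )
        curves[analyte] = SyncDerivCalibration.from_panel(
            panel, analyte, lam[analyte], config
        ).fit()
    return curves


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def wavelengths(cfg):
    return auto_wavelengths(cfg)


@pytest.fixture(scope="session")
def noiseless_curves(cfg, wavelengths):
    """Six-level noiseless calibration of both channels."""
    return build_curves(cfg, wavelengths, NOISELESS, replicates=1, seed=0)


@pytest.fixture(scope="session")
def noisy_curves(cfg, wavelengths):
    """Six-level, triplicate calibration at the default noise level."""
    return build_curves(cfg, wavelengths, NoiseModel(), replicates=3, seed=11)
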