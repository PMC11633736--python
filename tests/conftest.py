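import pytest

import inspiresim as ins


@pytest.fixture(scope="session")
def library():
    return ins.SPECIES_PRESETS


@pytest.fixture(scope="session")
def short_train():
    """Pulse train with a short (two-IR-period) dwell for fast tests."""
    return ins.PulseTrainConfig(dwell=20e-6)


@pytest.fixture(scope="session")
def thermal():
    return ins.ThermalConfig()


@pytest.fixture(scope="session")
def psfs():
    return ins.PSFModel(fwhm=398.0), ins.PSFModel(fwhm=561.0)


@pytest.fixture(scope="session")
def gains():
    # k_srl per mW^2, k_pt per mW: delta_srl ~ 1e-3 at 140/140 mW,
    # delta_pt = 0.018 at 5 mW on a unit-response species.
    return (5e-8, 0.0036)


@pytest.fixture(scope="session")
def oil_exc():
    return ins.ExcitationConfig(
        ir_wavenumber=1750.0, raman_wavenumber=2850.0,
        p_pump=315.0, p_stokes=315.0, p_ir=5.0,
    )


@pytest.fixture(scope="session")
def oil_deltas(library, gains, oil_exc):
    """Film-like operating point: modulation depths of a uniform oil sample."""
    k_srl, k_pt = gains
    dsrl = k_srl * oil_exc.p_pump * oil_exc.p_stokes * ins.evaluate_spectrum(
        library["oil"], oil_exc.raman_wavenumber, "raman"
    )
    dpt = k_pt * oil_exc.p_ir * ins.evaluate_spectrum(
        library["oil"], oil_exc.ir_wavenumber, "ir"
    )
    return float(dsrl), float(dpt)
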