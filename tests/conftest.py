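import numpy as np
import pytest

from synscreen.growth import (
    ROLE_NEGATIVE_CONTROL,
    ROLE_POSITIVE_CONTROL,
    ROLE_SAMPLE,
    GrowthParams,
    PlateSpec,
    StrainSpec,
    simulate_plate,
)

# shared plate design: PC ratio 0.30/0.35, NC ratio 0.08/0.35
PC = StrainSpec("PC", ROLE_POSITIVE_CONTROL, dmso_rate=0.35, mtx_rate=0.30)
NC = StrainSpec("NC1", ROLE_NEGATIVE_CONTROL, dmso_rate=0.35, mtx_rate=0.08)


def make_plate(extra_strains=(), seed=0, noise_sd=0.0, **kwargs):
    growth = GrowthParams(noise_sd=noise_sd)
    spec = PlateSpec(strains=(PC, NC, *extra_strains), seed=seed, growth=growth, **kwargs)
    return simulate_plate(spec)


def analytic_score(mtx_rate, dmso_rate=0.35):
    """Score expected from the configured rate ratios alone."""
    rho = mtx_rate / dmso_rate
    rho_nc = NC.mtx_rate / NC.dmso_rate
    rho_pc = PC.mtx_rate / PC.dmso_rate
    return (rho - rho_nc) / (rho_pc - rho_nc)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
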