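import numpy as np
import pytest

from nativems.mass_model import ComplexComposition, PtmRule, SubunitSpec
from nativems.spectrum_io import Spectrum


@pytest.fixture
def fixed_registry():
    """Two fixed-mass subunits mirroring typical chromophorylated chains."""
    a = SubunitSpec(
        id="A", role="alpha", fixed_mass=17000.0,
        ptms=(PtmRule("PCB", 586.7, 1), PtmRule("Met-loss", -131.2, 1)),
    )
    b = SubunitSpec(
        id="B", role="beta", fixed_mass=17000.0,
        ptms=(PtmRule("PCB", 586.7, 2), PtmRule("methylation", 14.0, 1)),
    )
    return {"A": a, "B": b}


def gaussian_spectrum(
    centers, heights, sigma=0.5, grid=(4000.0, 6000.0, 0.05),
    noise_sigma=0.0, seed=0, offset=0.0,
):
    """Profile spectrum with Gaussian peaks planted at known positions."""
    low, high, step = grid
    mz = np.arange(low, high, step)
    y = np.full_like(mz, offset)
    for c, h in zip(centers, heights):
        y += h * np.exp(-((mz - c) ** 2) / (2 * sigma**2))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0, noise_sigma, len(mz))
        y = np.clip(y, 0, None)
    return Spectrum(mz=mz, intensity=y, window=(low, high))


@pytest.fixture
def make_gaussian_spectrum():
    return gaussian_spectrum


def envelope_spectrum(masses, abundances=None, **kwargs):
    """Noiseless-by-default simulated spectrum of fixed-mass species."""
    from nativems.synthetic import SimScenario, simulate_spectrum

    abundances = abundances or [1.0] * len(masses)
    species = []
    for i, (m, a) in enumerate(zip(masses, abundances)):
        reg = {
            f"X{i}": SubunitSpec(id=f"X{i}", role="alpha", fixed_mass=m / 2),
            f"Y{i}": SubunitSpec(id=f"Y{i}", role="beta", fixed_mass=m / 2),
        }
        species.append(
            (ComplexComposition.from_members({f"X{i}": 1, f"Y{i}": 1}, reg), a)
        )
    scenario = SimScenario(species=species, **kwargs)
    return simulate_spectrum(scenario)


@pytest.fixture
def make_envelope_spectrum():
    return envelope_spectrum
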