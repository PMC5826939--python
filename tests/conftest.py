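import numpy as np
import pytest

from hepatoquant.synthetic import (
    DEFAULT_AXIS,
    ElectropherogramSpec,
    IsoformSpec,
    TissuePhantomSpec,
    generate_phantom,
    make_reference_spectra,
)


@pytest.fixture(scope="session")
def axis():
    return DEFAULT_AXIS


@pytest.fixture(scope="session")
def references(axis):
    return make_reference_spectra(axis)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small noiseless NASH-mode phantom with its ground truth."""
    spec = TissuePhantomSpec(
        height_px=120, width_px=120, mode="nash", target_lipid_fraction=0.28,
        noise_sigma=0.0, seed=3,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-noise NASH-mode phantom with its ground truth."""
    spec = TissuePhantomSpec(height_px=150, width_px=150, mode="nash", seed=5)
    return generate_phantom(spec)


@pytest.fixture
def three_isoform_spec():
    return ElectropherogramSpec(
        unmodified_pI=6.4,
        isoforms=(
            IsoformSpec("unmodified", 0.0, 0.5),
            IsoformSpec("phospho", -0.15, 0.3),
            IsoformSpec("acetyl", -0.50, 0.2),
        ),
        seed=101,
    )


def phasor_oracle(spectrum: np.ndarray, harmonic: int = 1) -> tuple[float, float]:
    """Brute-force DFT-ratio oracle: per-channel complex phase accumulation."""
    n = len(spectrum)
    z = 0.0 + 0.0j
    total = 0.0
    for k in range(n):
        z += spectrum[k] * np.exp(2j * np.pi * harmonic * k / n)
        total += spectrum[k]
    if total == 0:
        return 0.0, 0.0
    return (z / total).real, (z / total).imag


def paired_t_oracle(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Textbook paired two-tailed t-test: t = mean(d) / (sd(d)/sqrt(n))."""
    from scipy.stats import t as t_dist

    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2.0 * t_dist.sf(abs(t_stat), df=n - 1)
    return t_stat, p
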