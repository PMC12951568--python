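import numpy as np
import pytest

from photosar.spectra import Spectrum
from photosar.synthetic import GeneratorConfig


@pytest.fixture
def flat_profile():
    """Unit transmittance over the full generator wavelength range."""
    wl = 300.0 + 0.5 * np.arange(1201)
    return Spectrum(kind="transmittance", wavelengths_nm=wl, values=np.ones_like(wl))


@pytest.fixture
def noise_free_cfg():
    return GeneratorConfig(seed=0, poisson_counts=False, viability_noise_pct=0.0)


def make_spectrum(kind="absorption", lo=400.0, hi=800.0, n=801, values=None, **kw):
    wl = np.linspace(lo, hi, n)
    if values is None:
        values = np.zeros(n)
    elif np.isscalar(values):
        values = np.full(n, float(values))
    if kind == "emission":
        kw.setdefault("excitation_nm", 610.0)
    return Spectrum(kind=kind, wavelengths_nm=wl, values=np.asarray(values, float), **kw)
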