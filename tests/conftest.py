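import numpy as np
import pytest

from structms.spectra import Spectrum
from structms.constants import PROTON_MASS_DA


def make_envelope(mass: float, z_min: int = 19, z_max: int = 23, intensity: float = 1000.0) -> Spectrum:
    """Noiseless charge-state envelope of a single species."""
    zs = np.arange(z_min, z_max + 1)
    mz = (mass + zs * PROTON_MASS_DA) / zs
    order = np.argsort(mz)
    return Spectrum(mz=mz[order], intensity=np.full(zs.size, intensity))


@pytest.fixture
def dimer_envelope() -> Spectrum:
    return make_envelope(112266.4)
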