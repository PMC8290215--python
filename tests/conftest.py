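from __future__ import annotations

import numpy as np
import pytest

from aminopet import BasalGangliaSpec, PhantomSpec, TumorSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20170915)


def small_spec(**overrides) -> PhantomSpec:
    """A 64³ @ 2 mm phantom small enough for unit tests.

    The tumour sits far enough off-midline that the mirrored contralateral
    ROI stays clear of the infiltration region, and its peak T/N of 3.5
    puts both the 1.7 and the 2.0 iso-surfaces (14.4 / 12 mm) beyond the
    10 mm enhancement radius.
    """
    kw = dict(
        shape=(64, 64, 64),
        spacing=(2.0, 2.0, 2.0),
        brain_semiaxes_mm=(50.0, 55.0, 45.0),
        basal_ganglia=(BasalGangliaSpec(center_offset_mm=(24.0, 18.0, 0.0)),
                       BasalGangliaSpec(center_offset_mm=(-24.0, 18.0, 0.0))),
        tumor=TumorSpec(center_offset_mm=(-16.0, -12.0, 6.0),
                        enhancement_radius_mm=10.0,
                        infiltration_radius_mm=20.0,
                        peak_tn_ratio=3.5),
        noise_sigma_fraction=0.0,
        psf_fwhm_mm=0.0,
        seed=11,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(small_spec())


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(small_spec(noise_sigma_fraction=0.05, psf_fwhm_mm=4.0))
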