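import dataclasses

import numpy as np
import pytest

import melphasor as mp


@pytest.fixture(scope="session")
def acq() -> mp.AcquisitionConfig:
    """Default acquisition: 80 MHz, 256 time bins, 32 x 8.9 nm channels."""
    return mp.AcquisitionConfig()


@pytest.fixture(scope="session")
def acq_small() -> mp.AcquisitionConfig:
    return mp.AcquisitionConfig(image_shape=(32, 32))


@pytest.fixture(scope="session")
def eumelanin() -> mp.EndmemberSpec:
    return mp.EUMELANIN


@pytest.fixture(scope="session")
def pheomelanin() -> mp.EndmemberSpec:
    return mp.PHEOMELANIN


@pytest.fixture(scope="session")
def endmember_pair(acq) -> mp.EndmemberPair:
    """Analytic phasor positions of the two default melanin endmembers."""
    a = mp.multi_exp_phasor(mp.EUMELANIN.lifetime_components, acq.omega_ns)
    b = mp.multi_exp_phasor(mp.PHEOMELANIN.lifetime_components, acq.omega_ns)
    return mp.EndmemberPair(a=a, b=b, label_a="eumelanin", label_b="pheomelanin")


def single_exp_spec(tau_ns: float) -> mp.EndmemberSpec:
    """A pure single-exponential species (spectrum fields are placeholders)."""
    return mp.EndmemberSpec(
        name=f"tau{tau_ns}",
        lifetime_components=((tau_ns, 1.0),),
        spectrum_peak_nm=550.0,
        spectrum_fwhm_nm=30.0,
    )


def with_shape(acq: mp.AcquisitionConfig, shape) -> mp.AcquisitionConfig:
    return dataclasses.replace(acq, image_shape=tuple(shape))


@pytest.fixture(scope="session")
def uniform_field() -> mp.PhasorField:
    """A fully unmasked constant phasor field for geometry tests."""
    shape = (20, 20)
    return mp.PhasorField(
        g=np.full(shape, 0.6),
        s=np.full(shape, 0.3),
        intensity=np.full(shape, 100.0),
        mask=np.ones(shape, dtype=bool),
    )
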