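import numpy as np
import pytest

from echomod import (
    FieldConditions,
    HyperfineCoupling,
    NucleusSpec,
    Orientation,
    PulseTiming3p,
    Quadrupole,
    SpinSystem,
    nucleus,
)


@pytest.fixture(scope="session")
def field():
    return FieldConditions(b0_gauss=3316.0, mw_freq_GHz=9.7)


@pytest.fixture(scope="session")
def hf_n15():
    # reference His remote-15N hyperfine: A_xx = A_yy = 3.2, A_zz = 2.0 MHz
    return HyperfineCoupling(a_iso_MHz=2.8, t_dip_MHz=-0.4)


@pytest.fixture(scope="session")
def sys_one_n15(hf_n15):
    return SpinSystem(nuclei=(NucleusSpec(nucleus("15N"), hf_n15),))


@pytest.fixture(scope="session")
def sys_two_n15(hf_n15):
    return SpinSystem(nuclei=(NucleusSpec(nucleus("15N", count=2), hf_n15),))


@pytest.fixture(scope="session")
def sys_n14():
    return SpinSystem(
        nuclei=(
            NucleusSpec(
                nucleus("14N"),
                HyperfineCoupling(a_iso_MHz=1.85, t_dip_MHz=-0.1),
                Quadrupole(K_MHz=0.4167, eta=0.6),
            ),
        )
    )


@pytest.fixture(scope="session")
def orientation():
    return Orientation(theta=np.pi / 4, phi=0.3)


@pytest.fixture(scope="session")
def short_timing():
    # small T grid keeps brute-force oracle comparisons fast
    return PulseTiming3p(tau=210.0, T_start=12.0, dT=16.0, n_points=48)
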