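"""Reference spin systems and a seeded synthetic-trace generator.

``make_fixture`` produces experimental-like 3-pulse ESEEM traces: the
noiseless simulated envelope times an exponential echo decay, plus white
Gaussian noise at a stated signal-to-noise ratio.  Fixtures carry their
ground truth (the processed noiseless peak list and the closed-form
transition frequencies), so recovery can be checked end to end without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dfield
from typing import Optional

import numpy as np

from .eseem import PulseTiming3p, TimeTrace1D, eseem_powder
from .processing import PeakList, pick_peaks, process_trace
from .spin import (
    FieldConditions,
    HyperfineCoupling,
    NucleusSpec,
    Quadrupole,
    SpinSystem,
    n14_cancellation_frequencies,
    n15_frequencies,
    nucleus,
)

#: observation field of the reference experiments (echo maximum of Cu2+)
REFERENCE_FIELD = FieldConditions(b0_gauss=3316.0, mw_freq_GHz=9.7)


def his_n15_system(count: int = 2, a_iso: float = 2.8, t_dip: float = -0.4) -> SpinSystem:
    """15N-labelled histidine remote nitrogen(s) coupled to Cu2+.

    Defaults are the reference hyperfine values A_iso = 2.8 MHz,
    T = -0.4 MHz (A_xx = A_yy = 3.2, A_zz = 2.0 MHz).
    """
    return SpinSystem(
        nuclei=(NucleusSpec(nucleus("15N", count=count), HyperfineCoupling(a_iso, t_dip)),)
    )


def remote_n14_system(
    K: float = 0.4167, eta: float = 0.6, a_iso: float = 1.85, t_dip: float = -0.1
) -> SpinSystem:
    """Natural-abundance histidine remote 14N near exact cancellation.

    K and eta reproduce the nuclear-quadrupole triplet at 0.5 / 1.0 /
    1.5 MHz; A_iso places the system near the cancellation condition
    A ~ 2 nu_nz at 3316 G so the double-quantum line falls at ~4.2 MHz.
    """
    return SpinSystem(
        nuclei=(
            NucleusSpec(
                nucleus("14N"), HyperfineCoupling(a_iso, t_dip), Quadrupole(K, eta)
            ),
        )
    )


@dataclass
class Fixture:
    noiseless: TimeTrace1D
    noisy: TimeTrace1D
    truth_peaks: PeakList
    params: dict = _dfield(default_factory=dict)


def predicted_frequencies(system: SpinSystem, field: FieldConditions) -> dict:
    """Closed-form transition frequencies of every nucleus entry.

    For I = 1/2: powder-edge and 45-degree nu_alpha / nu_beta plus the
    combination 2 nu_alpha for equivalent nuclei; for I = 1 the
    exact-cancellation NQI triplet and DQ line.
    """
    out: dict[str, float] = {}
    for idx, e in enumerate(system.nuclei):
        tag = f"{e.nucleus.isotope}[{idx}]"
        if e.nucleus.I == 0.5:
            na, nb, _ = n15_frequencies(e.hyperfine, np.pi / 4, e.nucleus, field)
            out[f"{tag}:nu_alpha"] = na
            out[f"{tag}:nu_beta"] = nb
            if e.nucleus.count >= 2:
                out[f"{tag}:2nu_alpha"] = 2 * na
        elif e.nucleus.I == 1.0 and e.quadrupole is not None:
            n0, nm, np_, ndq = n14_cancellation_frequencies(
                e.quadrupole, e.hyperfine, e.nucleus, field
            )
            out[f"{tag}:nu_0"] = n0
            out[f"{tag}:nu_minus"] = nm
            out[f"{tag}:nu_plus"] = np_
            out[f"{tag}:nu_dq"] = ndq
    return out


def make_fixture(
    system: SpinSystem,
    timing: Optional[PulseTiming3p] = None,
    decay_tau_ns: float = 4000.0,
    snr: float = 20.0,
    seed: int = 0,
    field: Optional[FieldConditions] = None,
    grid_size: int = 150,
    engine: str = "auto",
) -> Fixture:
    """Synthetic noisy 3-pulse ESEEM trace with known ground truth.

    SNR is defined as the peak-to-peak amplitude of the noiseless decayed
    envelope divided by the noise standard deviation.  Regeneration from
    the same parameters and seed is bit-identical.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    timing = timing or PulseTiming3p()
    field = field or REFERENCE_FIELD
    if engine == "auto":
        engine = "analytic" if system.max_I <= 0.5 else "matrix"
    env = eseem_powder(system, timing, grid_size=grid_size, engine=engine, field=field)
    decay = np.exp(-timing.t_axis / decay_tau_ns)
    clean = env.values * decay
    noiseless = TimeTrace1D(
        timing.t_axis, clean,
        {**env.metadata, "decay_tau_ns": decay_tau_ns},
    )
    sigma = float(np.ptp(clean)) / snr if np.isfinite(snr) else 0.0
    rng = np.random.default_rng(seed)
    noisy_vals = clean + rng.normal(0.0, sigma, size=clean.shape) if sigma > 0 else clean.copy()
    noisy = TimeTrace1D(
        timing.t_axis, noisy_vals,
        {**noiseless.metadata, "snr": snr, "seed": seed},
    )
    spec = process_trace(noiseless, background="exponential", window="chebyshev")
    truth = pick_peaks(spec, min_height_frac=0.05, box=0.1)
    return Fixture(
        noiseless=noiseless,
        noisy=noisy,
        truth_peaks=truth,
        params={
            "decay_tau_ns": decay_tau_ns,
            "snr": snr,
            "seed": seed,
            "grid_size": grid_size,
            "engine": engine,
            "predicted_frequencies": predicted_frequencies(system, field),
        },
    )
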