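"""Reference analyses of the canonical Cu2+-histidine systems.

Each function runs one of the headline simulations end to end — spin
system -> pulse-sequence engine -> powder average -> processing -> peak
measurement — and returns the measured quantities.  They are used by the
test suite and the reproduction script, and double as worked examples of
the API.

Measurement conventions (see docs/methods.md for rationale):

* Extended powder ridges (the principal HYSCORE cross peak, the
  2 nu_alpha ESEEM combination ridge) are located by their
  magnitude-weighted centroid over the closed-form ridge region; the
  absolute maximum of a plateau-shaped ridge sits on edge singularities
  and is unstable under processing choices.
* Compact lines (NQI triplet, DQ line, HYSCORE combination cross peaks)
  are located by interpolated local maxima from the peak picker.
* 2D spectra use a first-order polynomial background along each time
  axis; higher orders visibly distort sub-MHz modulation components over
  the 4-8 us acquisition windows.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .design import proton_blindspot_tau, recommend, tau_intensity_curve
from .eseem import PulseTiming3p, eseem_powder
from .fixtures import REFERENCE_FIELD, his_n15_system, remote_n14_system
from .hyscore import PulseTiming4p, hyscore_powder, hyscore_tau_sum
from .processing import (
    line_prominence,
    pick_peaks,
    process_trace,
    region_centroid,
)
from .spin import FieldConditions, i_half_frequency_ranges, nucleus

HYSCORE_BACKGROUND = "polynomial1"
TAU_SWEEP_NS = tuple(range(100, 401, 20))


def _n15_bands(system, field):
    hf = system.nuclei[0].hyperfine
    return i_half_frequency_ranges(hf, nucleus("15N"), field)


def hyscore_cross_peaks(
    grid_size: int = 100,
    n_points: int = 128,
    zerofill: int = 1024,
    field: Optional[FieldConditions] = None,
) -> dict:
    """Cross-peak positions for two equivalent 15N at tau = 210 ns.

    Returns the principal (nu_alpha, nu_beta) ridge centroid and the
    position of the (2 nu_alpha, nu_beta) combination cross peak from the
    processed (+,+)-quadrant spectrum.
    """
    field = field or REFERENCE_FIELD
    system = his_n15_system(count=2)
    (na_lo, na_hi), (nb_lo, nb_hi) = _n15_bands(system, field)
    timing = PulseTiming4p(tau=210.0, n1=n_points, n2=n_points)
    trace = hyscore_powder(system, timing, grid_size=grid_size, field=field)
    spec = process_trace(trace, background=HYSCORE_BACKGROUND, zerofill=zerofill)
    principal = region_centroid(spec, (na_lo, na_hi), (nb_lo, nb_hi))
    comb = [
        p for p in pick_peaks(spec, min_height_frac=0.02, box=0.1)
        if na_hi + 0.05 <= p.nu1 <= 2 * na_hi + 0.15
        and nb_lo - 0.2 <= p.nu2 <= nb_hi + 0.2
    ]
    if not comb:
        raise RuntimeError("combination cross peak not found")
    return {
        "principal_nu1_MHz": principal[0],
        "principal_nu2_MHz": principal[1],
        "combination_nu1_MHz": comb[0].nu1,
        "combination_nu2_MHz": comb[0].nu2,
        "n_points": n_points,
    }


def hyscore_progression_ratios(
    count: int,
    tau_list: Sequence[float] = TAU_SWEEP_NS,
    grid_size: int = 100,
    n_points: int = 256,
    zerofill: int = 1024,
    field: Optional[FieldConditions] = None,
) -> dict:
    """Peak-height ratios of the (m nu_alpha, nu_beta) progression.

    Uses the tau-averaged (blind-spot-suppressed) spectrum, as the
    reference protocol does for multi-nucleus simulations.  Progression
    members are the distinct off-diagonal picked peaks with nu_2 in the
    nu_beta band, ordered by ascending nu_1; heights are reported
    relative to the first (principal) member.
    """
    field = field or REFERENCE_FIELD
    system = his_n15_system(count=count)
    (na_lo, na_hi), (nb_lo, nb_hi) = _n15_bands(system, field)
    timing = PulseTiming4p(tau=210.0, n1=n_points, n2=n_points)
    spec = hyscore_tau_sum(
        system, timing, list(tau_list), grid_size=grid_size, field=field,
        background=HYSCORE_BACKGROUND, zerofill=zerofill,
    )
    peaks = [
        p for p in pick_peaks(spec, min_height_frac=0.02, box=0.12)
        if p.nu1 < p.nu2
        and abs(p.nu1 - p.nu2) >= 0.3
        and nb_lo - 0.4 <= p.nu2 <= nb_hi + 0.2
        and na_lo - 0.05 <= p.nu1 <= count * na_hi + 0.2
    ]
    peaks.sort(key=lambda p: p.nu1)
    if not peaks:
        raise RuntimeError("no progression peaks found")
    h1 = peaks[0].height
    return {
        "positions_MHz": [(p.nu1, p.nu2) for p in peaks],
        "ratios": [p.height / h1 for p in peaks],
        "n_points": n_points,
    }


def n14_eseem_lines(
    grid_size: int = 100,
    field: Optional[FieldConditions] = None,
) -> dict:
    """NQI triplet and DQ line of the remote 14N powder 3-pulse ESEEM."""
    field = field or REFERENCE_FIELD
    system = remote_n14_system()
    timing = PulseTiming3p()  # tau 210 ns, T = 12 + 16 n, 602 points
    trace = eseem_powder(system, timing, grid_size=grid_size, engine="matrix",
                         field=field)
    spec = process_trace(trace, background="polynomial3")
    peaks = pick_peaks(spec, min_height_frac=0.05, box=0.12)
    nqi = sorted(p.nu1 for p in peaks if p.nu1 < 2.0)[:3]
    high = [p.nu1 for p in peaks if 2.0 <= p.nu1 < 6.0]
    if len(nqi) < 3 or not high:
        raise RuntimeError("expected three NQI lines below 2 MHz and a DQ line")
    return {
        "nqi_MHz": nqi,
        "nqi_highest_MHz": max(nqi),
        "dq_MHz": max(high),
        "n_points": timing.n_points,
    }


def eseem_combination_line(
    grid_size: int = 200,
    field: Optional[FieldConditions] = None,
) -> dict:
    """The 2 nu_alpha ESEEM line of two equivalent 15N vs the one-nucleus
    control.

    The line position is the magnitude centroid over the closed-form
    combination band; presence/absence is judged by prominence above the
    local baseline, which is ~0 for the control because only the leakage
    skirt of the fundamental ridge enters the band.
    """
    field = field or REFERENCE_FIELD
    timing = PulseTiming3p()
    (na_lo, na_hi), _ = _n15_bands(his_n15_system(1), field)
    band = (na_hi + 0.02, 2 * na_hi)
    out = {}
    for label, count in (("two", 2), ("one", 1)):
        trace = eseem_powder(his_n15_system(count), timing, grid_size=grid_size,
                             field=field)
        spec = process_trace(trace, background="polynomial3")
        prom, _ = line_prominence(spec, band)
        out[label] = (spec, prom)
    spec2, prom2 = out["two"]
    _, prom1 = out["one"]
    return {
        "position_MHz": region_centroid(spec2, band),
        "prominence_two": prom2,
        "prominence_one": prom1,
        "control_fraction": prom1 / prom2 if prom2 > 0 else np.inf,
        "n_points": timing.n_points,
    }


def acquisition_design_numbers(field: Optional[FieldConditions] = None) -> dict:
    """Proton blind-spot tau and the analytic nu_alpha optimum."""
    field = field or REFERENCE_FIELD
    taus = np.arange(100.0, 401.0, 2.0)
    curve = tau_intensity_curve(his_n15_system(2), "nu_alpha", taus,
                                powder_grid=100, field=field)
    plan = recommend(remote_n14_system(), his_n15_system(2), taus,
                     T_options=(12.0, 400.0), field=field)
    return {
        "proton_blindspot_tau_ns": proton_blindspot_tau(field, harmonic=3),
        "nu_alpha_optimal_tau_ns": float(taus[int(np.argmax(curve))]),
        "recommended_tau_ns": plan.recommended_tau_ns,
        "recommended_T_start_ns": plan.recommended_T_start_ns,
    }
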