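"""Acquisition-parameter optimization for mixed 14N/15N ESEEM.

Three pieces reproduce the experiment-design workflow: the proton
blind-spot calculator (tau = n / nu_H suppresses the 1H matrix line),
per-transition intensity-versus-tau curves from the analytic product-rule
prefactors (nu_alpha, nu_beta and the 2 nu_alpha combination line) or
from the matrix-engine line amplitudes (14N double-quantum line), and a
joint max-min recommendation that picks the tau serving every diagnostic
transition of both isotopologues at once while sitting on a proton blind
spot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dfield
from typing import Optional, Sequence

import numpy as np

from .eseem import RAD_PER_MHZ_NS, _branch_amplitudes
from .spin import (
    FieldConditions,
    GYROMAGNETIC_MHZ_PER_T,
    GAUSS_TO_TESLA,
    Orientation,
    SpinSystem,
    n15_frequencies,
    powder_orientations,
)


@dataclass
class AcquisitionPlan:
    """tau/T recommendation plus the per-transition curves behind it."""

    recommended_tau_ns: float
    recommended_T_start_ns: float
    curves: dict  # label -> (tau_grid ns, normalized amplitude)
    notes: list[str] = _dfield(default_factory=list)


def proton_blindspot_tau(field: FieldConditions, harmonic: int = 3) -> float:
    """tau (ns) at the n-th proton blind spot: tau = n / nu_H."""
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    nu_h = GYROMAGNETIC_MHZ_PER_T["1H"] * field.b0_gauss * GAUSS_TO_TESLA  # MHz
    return 1e3 * harmonic / nu_h


TRANSITIONS = ("nu_alpha", "nu_beta", "2nu_alpha")


def tau_intensity_curve(
    system: SpinSystem,
    transition: str,
    tau_range: Sequence[float],
    powder_grid: int = 100,
    field: Optional[FieldConditions] = None,
) -> np.ndarray:
    """Powder-averaged amplitude prefactor of a 15N transition versus tau.

    From the expanded product rule, the spectral amplitude of nu_alpha is
    proportional to c (k/2)(1 - cos 2 pi nu_beta tau) per nucleus entry
    (nu_beta: alpha <-> beta swap), and the combination line 2 nu_alpha,
    which requires c >= 2 equivalent nuclei, carries the pair prefactor
    (c choose 2)(k^2/8)(1 - cos 2 pi nu_beta tau)^2.
    """
    if transition not in TRANSITIONS:
        raise ValueError(f"unknown transition {transition!r}; use one of {TRANSITIONS}")
    field = field or FieldConditions(3316.0)
    taus = np.asarray(tau_range, dtype=float)
    if powder_grid == 1:
        orients = [Orientation(theta=np.pi / 4, weight=1.0)]
    else:
        orients = powder_orientations(powder_grid)
    curve = np.zeros_like(taus)
    for e in system.nuclei:
        c = e.nucleus.count
        for o in orients:
            nu_a, nu_b, k = n15_frequencies(e.hyperfine, o.theta, e.nucleus, field)
            xb = 1 - np.cos(RAD_PER_MHZ_NS * nu_b * taus)
            xa = 1 - np.cos(RAD_PER_MHZ_NS * nu_a * taus)
            if transition == "nu_alpha":
                curve += o.weight * c * (k / 2) * xb
            elif transition == "nu_beta":
                curve += o.weight * c * (k / 2) * xa
            else:
                curve += o.weight * (c * (c - 1) / 2) * (k**2 / 8) * xb**2
    return curve


def dq_intensity_curve(
    system: SpinSystem,
    tau_range: Sequence[float],
    powder_grid: int = 50,
    n_phi: int = 8,
    field: Optional[FieldConditions] = None,
) -> np.ndarray:
    """Amplitude of the 14N double-quantum line versus tau.

    For each orientation the DQ transition is identified as the largest
    eigenvalue gap over both manifolds (the Delta m_I = 2 line of the
    non-cancelled manifold); its 3-pulse line amplitude from the matrix
    engine is powder averaged.
    """
    from .spin import sublevel_hamiltonians

    field = field or FieldConditions(3316.0)
    taus = np.asarray(tau_range, dtype=float)
    orients = powder_orientations(powder_grid, n_phi=n_phi)
    curve = np.zeros_like(taus)
    for o in orients:
        for e in system.nuclei:
            Ha, Hb = sublevel_hamiltonians(e, o, field)
            ea, Ua = np.linalg.eigh(Ha)
            eb, Ub = np.linalg.eigh(Hb)
            M = Ua.conj().T @ Ub
            d = len(ea)
            wa = RAD_PER_MHZ_NS * ea
            wb = RAD_PER_MHZ_NS * eb
            # the non-cancelled manifold carries the larger total spread
            use_alpha = (ea.max() - ea.min()) >= (eb.max() - eb.min())
            pa = np.exp(-1j * np.outer(taus, wa))  # (ntau, d)
            pb = np.exp(-1j * np.outer(taus, wb))
            if use_alpha:
                i, j = int(np.argmax(ea)), int(np.argmin(ea))
                # C_ij(tau) = pa_i conj(pa_j) (sum_k M_ik pb_k M*_jk)
                #            * (sum_k M_jk pb*_k M*_ik) / d
                s1 = np.einsum("k,tk,k->t", M[i], pb, M[j].conj())
                s2 = np.einsum("k,tk,k->t", M[j], pb.conj(), M[i].conj())
                Cij = pa[:, i] * pa[:, j].conj() * s1 * s2 / d
                s1j = np.einsum("k,tk,k->t", M[j], pb, M[i].conj())
                s2j = np.einsum("k,tk,k->t", M[i], pb.conj(), M[j].conj())
                Cji = pa[:, j] * pa[:, i].conj() * s1j * s2j / d
            else:
                # beta-branch coefficients in the b eigenbasis
                k_, l_ = int(np.argmax(eb)), int(np.argmin(eb))
                # Ntil = M^dag N M with N = (M diag(pb) M^dag) * pa^conj(row)
                N_t = np.einsum("ik,tk,jk,tj->tij", M, pb, M.conj(), pa.conj())
                Ntil_t = np.einsum("ki,tij,jl->tkl", M.conj().T, N_t, M)
                W_t = np.einsum("tk,ki,ti,il->tkl", pb.conj(), M.conj().T, pa, M)
                Cij = Ntil_t[:, l_, k_] * W_t[:, k_, l_] / d
                Cji = Ntil_t[:, k_, l_] * W_t[:, l_, k_] / d
            amp = np.abs(Cij + Cji.conj())
            curve += o.weight * e.nucleus.count * amp
    return curve


def recommend(
    system14: Optional[SpinSystem],
    system15: Optional[SpinSystem],
    tau_range: Sequence[float],
    T_options: Sequence[float] = (12.0,),
    field: Optional[FieldConditions] = None,
    powder_grid: int = 50,
    blindspot_window_ns: float = 5.0,
) -> AcquisitionPlan:
    """Joint tau/T recommendation for mixed 14N/15N acquisition.

    The candidate tau values are the exact proton blind spots n / nu_H
    inside the scanned range (so the 1H matrix line is fully suppressed);
    among them the one maximizing the minimum normalized amplitude over
    the diagnostic transitions (14N nu_dq; 15N nu_alpha, nu_beta and, for
    equivalent nuclei, 2 nu_alpha) is recommended.  The smallest offered
    initial T is recommended, since short T captures the broad fast-
    decaying components.  If no blind spot falls in range the
    unconstrained optimum over the scanned grid is returned with a
    warning note; ``blindspot_window_ns`` widens the candidate set to
    grid points near a blind spot.
    """
    if system14 is None and system15 is None:
        raise ValueError("at least one system is required")
    field = field or FieldConditions(3316.0)
    taus = np.asarray(tau_range, dtype=float)

    def all_curves(tau_grid: np.ndarray) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        if system15 is not None:
            labels = ["nu_alpha", "nu_beta"]
            if any(e.nucleus.count >= 2 for e in system15.nuclei):
                labels.append("2nu_alpha")
            for lab in labels:
                out[f"15N:{lab}"] = tau_intensity_curve(
                    system15, lab, tau_grid, powder_grid=powder_grid, field=field
                )
        if system14 is not None:
            out["14N:nu_dq"] = dq_intensity_curve(
                system14, tau_grid, powder_grid=powder_grid, field=field
            )
        return out

    curves = all_curves(taus)
    norm = {lab: c / c.max() if c.max() > 0 else c for lab, c in curves.items()}

    nu_h = GYROMAGNETIC_MHZ_PER_T["1H"] * field.b0_gauss * GAUSS_TO_TESLA
    harmonics = np.arange(1, int(np.ceil(taus.max() * nu_h * 1e-3)) + 2)
    bs = 1e3 * harmonics / nu_h
    cand = bs[(bs >= taus.min() - blindspot_window_ns) & (bs <= taus.max() + blindspot_window_ns)]
    cand = np.clip(cand, taus.min(), taus.max())

    notes = []
    if len(cand):
        cand_curves = all_curves(cand)
        scale = {lab: curves[lab].max() for lab in curves}
        cand_norm = np.stack([
            cand_curves[lab] / scale[lab] if scale[lab] > 0 else cand_curves[lab]
            for lab in curves
        ])
        best = int(np.argmax(cand_norm.min(axis=0)))
        tau_best = float(cand[best])
    else:
        objective = np.min(np.stack(list(norm.values())), axis=0)
        tau_best = float(taus[int(np.argmax(objective))])
        notes.append(
            "no proton blind spot inside the scanned range; "
            "returning unconstrained optimum"
        )
    t0 = float(min(T_options))
    notes.append(
        "shortest initial T recommended: broad components decay before "
        "long T_start values"
    )
    return AcquisitionPlan(
        recommended_tau_ns=tau_best,
        recommended_T_start_ns=t0,
        curves={lab: (taus, norm[lab]) for lab in norm},
        notes=notes,
    )
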