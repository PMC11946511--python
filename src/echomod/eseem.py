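"""3-pulse (stimulated-echo) ESEEM simulation.

Three routes compute the envelope E(tau, T) for the sequence
pi/2 - tau - pi/2 - T - pi/2 - tau - echo with ideal pulses:

``eseem_analytic``
    The Mims product rule for I = 1/2 nuclei.  Each nucleus contributes a
    manifold factor 1 - (k/2)(1 - cos 2 pi nu_beta tau)(1 - cos 2 pi
    nu_alpha (tau + T)) (and the alpha/beta swap), raised to the
    equivalence count c; the two manifold products are averaged.  For
    c >= 2 the expanded product contains combination terms at 2 nu_alpha
    and 2 nu_beta — the signature of multiple equivalent nuclei.

``eseem_matrix``
    The general Mims trace engine: per-nucleus eigen-decompositions of the
    two sub-Hamiltonians and the overlap matrix M = U_alpha^dag U_beta,
    valid for I = 1/2 and I = 1 (quadrupole included).  Per-nucleus complex
    branch amplitudes multiply across nuclei (product rule), the two
    branches are averaged and the real part is taken.

``brute_force_oracle``
    Full electron (x) nuclear density-matrix propagation through the pulse
    sequence with four-step phase cycling.  Slow, dimension-capped, and
    kept deliberately independent of the other two routes.

No relaxation decay is included; decay belongs to the fixture generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dfield
from typing import Literal, Optional

import numpy as np

from .spin import (
    FieldConditions,
    NucleusSpec,
    Orientation,
    SpinSystem,
    UnsupportedIsotopeError,
    n15_frequencies,
    powder_orientations,
    spin_matrices,
    sublevel_hamiltonians,
)

#: phase accumulated per (MHz * ns): 2 pi * 1e-3 rad
RAD_PER_MHZ_NS = 2e-3 * np.pi


@dataclass(frozen=True)
class PulseTiming3p:
    """Timing of the stimulated-echo sequence (ns).

    Defaults mirror the reference acquisition: tau = 210 ns, T from 12 ns
    in 16 ns steps for 602 points.
    """

    tau: float = 210.0
    T_start: float = 12.0
    dT: float = 16.0
    n_points: int = 602

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.dT <= 0:
            raise ValueError("tau and dT must be > 0")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def t_axis(self) -> np.ndarray:
        return self.T_start + self.dT * np.arange(self.n_points)


@dataclass
class TimeTrace1D:
    """Echo-amplitude envelope on a T grid (dimensionless)."""

    t_axis: np.ndarray
    values: np.ndarray
    metadata: dict = _dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_axis = np.asarray(self.t_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t_axis.shape != self.values.shape:
            raise ValueError("axis and values shapes differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")


def _require_spin_half(system: SpinSystem, caller: str) -> None:
    for e in system.nuclei:
        if abs(e.nucleus.I - 0.5) > 1e-12:
            raise UnsupportedIsotopeError(
                f"{caller} handles I = 1/2 only; use eseem_matrix for I = 1"
            )


def eseem_analytic(
    system: SpinSystem,
    timing: PulseTiming3p,
    orientation: Orientation,
    field: Optional[FieldConditions] = None,
) -> TimeTrace1D:
    """Mims product-rule envelope for an all-I=1/2 system at one orientation."""
    field = field or FieldConditions(3316.0)
    _require_spin_half(system, "eseem_analytic")
    T = timing.t_axis
    tau = timing.tau
    Ea = np.ones_like(T)
    Eb = np.ones_like(T)
    for e in system.nuclei:
        nu_a, nu_b, k = n15_frequencies(
            e.hyperfine, orientation.theta, e.nucleus, field
        )
        wa, wb = RAD_PER_MHZ_NS * nu_a, RAD_PER_MHZ_NS * nu_b
        fa = 1.0 - (k / 2) * (1 - np.cos(wb * tau)) * (1 - np.cos(wa * (tau + T)))
        fb = 1.0 - (k / 2) * (1 - np.cos(wa * tau)) * (1 - np.cos(wb * (tau + T)))
        c = e.nucleus.count
        Ea = Ea * fa**c
        Eb = Eb * fb**c
    values = 0.5 * (Ea + Eb)
    return TimeTrace1D(
        t_axis=T,
        values=values,
        metadata={"engine": "analytic", "tau_ns": tau, "normalized_first_point": False},
    )


# ---------------------------------------------------------------------------
# Matrix (Mims trace) engine
# ---------------------------------------------------------------------------

def _branch_amplitudes(
    entry: NucleusSpec,
    tau: float,
    orientation: Orientation,
    field: FieldConditions,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-nucleus 3-pulse branch line content at fixed tau.

    Returns (freq_a, coef_a, freq_b, coef_b): angular frequencies (rad/ns)
    and complex coefficients such that the alpha-branch amplitude is
    T_alpha(T) = sum_j coef_a[j] exp(-i freq_a[j] T), and likewise for beta.
    Derived by expanding Tr[G_a(tau) G_m(T) N G_m(T)^dag G_b(tau)^dag]/d
    in the respective eigenbases.  N = A_tau^dag with A_tau = e^{-i H_a tau}
    e^{+i H_b tau} is the tau-encoded nuclear operator stored as electron
    polarization by the second pulse; only the electron-coherence pathway
    that refocuses the resonance offset over the two tau intervals
    contributes to the echo, which selects this single term.
    """
    Ha, Hb = sublevel_hamiltonians(entry, orientation, field)
    ea, Ua = np.linalg.eigh(Ha)
    eb, Ub = np.linalg.eigh(Hb)
    wa = RAD_PER_MHZ_NS * ea  # rad/ns
    wb = RAD_PER_MHZ_NS * eb
    d = len(ea)
    M = Ua.conj().T @ Ub

    pa = np.exp(-1j * wa * tau)
    pb = np.exp(-1j * wb * tau)
    # N (a-basis) = A_tau^dag = M e^{-i Lb tau} M^dag e^{+i La tau}
    N = (M @ (pb[:, None] * M.conj().T)) * pa.conj()[None, :]
    # alpha branch: C_ij = e^{-i wa_i tau} N_ij R_ji / d, R = M e^{i Lb tau} M^dag
    R = M @ (pb.conj()[:, None] * M.conj().T)
    Ca = (pa[:, None] * N) * R.T / d
    freq_a = (wa[:, None] - wa[None, :]).ravel()
    # beta branch: C'_lk over (wb_l - wb_k); C'_lk = Ntil_lk W_kl / d,
    # W = e^{i Lb tau} M^dag e^{-i La tau} M
    Ntil = M.conj().T @ N @ M
    W = pb.conj()[:, None] * (M.conj().T @ (pa[:, None] * M))
    Cb = Ntil * W.T / d
    freq_b = (wb[:, None] - wb[None, :]).ravel()
    return freq_a, Ca.ravel(), freq_b, Cb.ravel()


def eseem_matrix(
    system: SpinSystem,
    timing: PulseTiming3p,
    orientation: Orientation,
    field: Optional[FieldConditions] = None,
) -> TimeTrace1D:
    """General-spin stimulated-echo envelope at one orientation."""
    field = field or FieldConditions(3316.0)
    T = timing.t_axis
    Ea = np.ones_like(T, dtype=complex)
    Eb = np.ones_like(T, dtype=complex)
    for e in system.nuclei:
        fa, ca, fb, cb = _branch_amplitudes(e, timing.tau, orientation, field)
        Ta = np.exp(-1j * np.outer(T, fa)) @ ca
        Tb = np.exp(-1j * np.outer(T, fb)) @ cb
        c = e.nucleus.count
        Ea = Ea * Ta**c
        Eb = Eb * Tb**c
    values = 0.5 * (Ea + Eb).real
    return TimeTrace1D(
        t_axis=T,
        values=values,
        metadata={"engine": "matrix", "tau_ns": timing.tau, "normalized_first_point": False},
    )


EngineName = Literal["analytic", "matrix"]


def eseem_powder(
    system: SpinSystem,
    timing: PulseTiming3p,
    grid_size: int = 200,
    engine: EngineName = "analytic",
    field: Optional[FieldConditions] = None,
    n_phi: Optional[int] = None,
    orientations: Optional[list[Orientation]] = None,
) -> TimeTrace1D:
    """Powder-averaged 3-pulse ESEEM envelope.

    ``grid_size`` counts theta nodes (Gauss-Legendre in cos theta); a phi
    grid is added automatically for non-axial systems.  An explicit
    ``orientations`` list (weights summing to 1) overrides the grid.
    """
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    field = field or FieldConditions(3316.0)
    if n_phi is None:
        n_phi = 1 if system.is_axial_collinear() else 12
    fn = eseem_analytic if engine == "analytic" else eseem_matrix
    orients = orientations if orientations is not None else powder_orientations(
        grid_size, n_phi=n_phi
    )
    acc = np.zeros(timing.n_points)
    for o in orients:
        acc += o.weight * fn(system, timing, o, field).values
    return TimeTrace1D(
        t_axis=timing.t_axis,
        values=acc,
        metadata={
            "engine": engine,
            "tau_ns": timing.tau,
            "powder_grid": grid_size,
            "n_phi": n_phi,
            "normalized_first_point": False,
        },
    )


# ---------------------------------------------------------------------------
# Brute-force density-matrix oracle
# ---------------------------------------------------------------------------

def _full_operators(system: SpinSystem, orientation: Orientation, field: FieldConditions):
    """Electron operators and full rotating-frame Hamiltonian (rad/ns units).

    Equivalent copies are expanded into explicit tensor factors, so the
    Hilbert dimension is 2 * prod (2 I_i + 1)^{c_i}.
    """
    dims = []
    entries = []
    for e in system.nuclei:
        for _ in range(e.nucleus.count):
            dims.append(e.nucleus.dim)
            entries.append(e)
    n_nuc_dim = int(np.prod(dims)) if dims else 1
    dim = 2 * n_nuc_dim
    if dim > 64:
        raise ValueError(f"Hilbert dimension {dim} exceeds oracle cap 64")

    Sx_e, Sy_e, Sz_e = spin_matrices(0.5)

    def embed_e(op_e):
        return np.kron(op_e, np.eye(n_nuc_dim, dtype=complex))

    def embed_n(idx, op_n):
        left = int(np.prod(dims[:idx])) if idx else 1
        right = int(np.prod(dims[idx + 1:])) if idx + 1 < len(dims) else 1
        full = np.kron(np.kron(np.eye(left, dtype=complex), op_n), np.eye(right, dtype=complex))
        return np.kron(np.eye(2, dtype=complex), full)

    n = orientation.direction()
    H = np.zeros((dim, dim), dtype=complex)
    Sz_full = embed_e(Sz_e)
    for idx, e in enumerate(entries):
        ops = spin_matrices(e.nucleus.I)
        a_vec = n @ e.hyperfine.tensor()
        hf_n = sum(a_vec[j] * ops[j] for j in range(3))
        # S_z-conditioned hyperfine: S_z (x) (a . I)
        left = int(np.prod(dims[:idx])) if idx else 1
        right = int(np.prod(dims[idx + 1:])) if idx + 1 < len(dims) else 1
        hf_full = np.kron(np.kron(np.eye(left, dtype=complex), hf_n), np.eye(right, dtype=complex))
        H += np.kron(Sz_e, hf_full)
        nu_nz = field.nu_nz(e.nucleus)
        Hn = -nu_nz * sum(n[j] * ops[j] for j in range(3))
        if e.quadrupole is not None:
            Q = e.quadrupole.tensor()
            Hn = Hn + sum(Q[j, k] * (ops[j] @ ops[k]) for j in range(3) for k in range(3))
        H += embed_n(idx, Hn)
    H *= RAD_PER_MHZ_NS  # MHz -> rad/ns
    return H, embed_e(Sx_e), embed_e(Sy_e), Sz_full


def _propagator(H: np.ndarray, t: float) -> np.ndarray:
    ev, U = np.linalg.eigh(H)
    return (U * np.exp(-1j * ev * t)) @ U.conj().T


#: number of electron resonance offsets in the echo-selection comb
N_OFFSETS = 8


def _stimulated_echo_signal(H, Sx, Sy, Sz, timing: PulseTiming3p) -> np.ndarray:
    """Phase-cycled, offset-averaged stimulated-echo amplitude (unnormalized).

    Echo formation is emulated by averaging over a comb of electron
    resonance offsets Delta with Delta * tau = 2 pi j / N: pathways that do
    not refocus the offset over the two tau intervals acquire phases
    exp(i m Delta tau) with m != 0 and cancel exactly, as they would under
    a broad inhomogeneous line.
    """
    T = timing.t_axis
    out = np.zeros(len(T))

    def pulse(phase, beta=np.pi / 2):
        ax = Sx * np.cos(phase) + Sy * np.sin(phase)
        ev, U = np.linalg.eigh(ax)
        return (U * np.exp(-1j * beta * ev)) @ U.conj().T

    for j in range(N_OFFSETS):
        delta = 2 * np.pi * j / (N_OFFSETS * timing.tau)  # rad/ns
        Hj = H + delta * Sz
        U_tau = _propagator(Hj, timing.tau)
        U_t0 = _propagator(Hj, timing.T_start)
        U_dT = _propagator(Hj, timing.dT)
        # four-step cycle on the first two pi/2 pulses: (+x,+x) - (-x,+x)
        # - (+x,-x) + (-x,-x); detection folded through pulse 3 + tau.
        P3 = pulse(0.0)
        D = P3.conj().T @ U_tau.conj().T @ Sy @ U_tau @ P3
        for ph1, ph2, sign in ((0, 0, 1), (np.pi, 0, -1), (0, np.pi, -1), (np.pi, np.pi, 1)):
            P1, P2 = pulse(ph1), pulse(ph2)
            rho = P1 @ Sz @ P1.conj().T
            rho = U_tau @ rho @ U_tau.conj().T
            rho = P2 @ rho @ P2.conj().T
            rho = U_t0 @ rho @ U_t0.conj().T
            for i in range(len(T)):
                out[i] += sign * np.trace(rho @ D).real
                rho = U_dT @ rho @ U_dT.conj().T
    return out / N_OFFSETS


def brute_force_oracle(
    system: SpinSystem,
    timing: PulseTiming3p,
    orientation: Orientation,
    field: Optional[FieldConditions] = None,
) -> TimeTrace1D:
    """Full density-matrix 3-pulse ESEEM at one orientation (test oracle).

    Propagates S_z through ideal instantaneous pulses and free evolution
    under the S_z-conditioned Hamiltonian, with four-step phase cycling,
    and normalizes against the same propagation with couplings removed so
    that the unmodulated echo is 1.
    """
    field = field or FieldConditions(3316.0)
    H, Sx, Sy, Sz = _full_operators(system, orientation, field)
    sig = _stimulated_echo_signal(H, Sx, Sy, Sz, timing)
    # reference: identical sequence, hyperfine and quadrupole switched off
    bare = SpinSystem(
        nuclei=tuple(
            NucleusSpec(
                nucleus=e.nucleus,
                hyperfine=type(e.hyperfine)(0.0, 0.0),
                quadrupole=None,
            )
            for e in system.nuclei
        ),
        g_iso=system.g_iso,
    )
    H0, Sx0, Sy0, Sz0 = _full_operators(bare, orientation, field)
    ref = _stimulated_echo_signal(H0, Sx0, Sy0, Sz0, timing)
    if np.any(np.abs(ref) < 1e-12):
        raise RuntimeError("degenerate reference echo in oracle normalization")
    return TimeTrace1D(
        t_axis=timing.t_axis,
        values=sig / ref,
        metadata={"engine": "oracle", "tau_ns": timing.tau, "normalized_first_point": False},
    )
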