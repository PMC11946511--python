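"""Spin-system primitives for pulsed-EPR (ESEEM/HYSCORE) simulation.

The electron is treated as an effective S = 1/2 with isotropic g; every
coupled nucleus is described by its spin, gyromagnetic ratio, an axial
hyperfine tensor (A_iso, T_dip) and, for I >= 1, a nuclear quadrupole
tensor (K, eta).  Nuclear transition frequencies follow from the two
m_S-conditioned nuclear sub-Hamiltonians

    H(m_S) = m_S (a . I) - nu_nz (n . I) + H_Q ,

where ``a`` is the row of the hyperfine tensor along the static field
direction ``n`` and nu_nz = |gamma| B0 is the nuclear Zeeman frequency.
Closed forms are provided for the two standard regimes the package targets:
I = 1/2 (nu_alpha / nu_beta lines) and I = 1 near exact cancellation
(pure-quadrupole triplet plus the double-quantum line).

Units: frequencies MHz, times ns, fields gauss (converted to tesla
internally), angles radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

GAUSS_TO_TESLA = 1e-4

#: Nuclear gyromagnetic ratios in MHz per tesla (signed, standard tables).
GYROMAGNETIC_MHZ_PER_T = {
    "1H": 42.5775,
    "14N": 3.0777,
    "15N": -4.3157,
}

NUCLEAR_SPIN = {"1H": 0.5, "14N": 1.0, "15N": 0.5}


class UnsupportedIsotopeError(ValueError):
    """Raised when an operation gets a nuclear spin it cannot handle."""


@dataclass(frozen=True)
class Nucleus:
    """A nuclear species, possibly present as several equivalent copies.

    ``count`` > 1 means that many magnetically equivalent nuclei (identical
    tensors and frames); the simulation engines exploit equivalence through
    the product rule instead of enlarging the Hilbert space.
    """

    isotope: str
    I: float
    gamma_MHz_per_T: float
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.gamma_MHz_per_T == 0:
            raise ValueError("gyromagnetic ratio must be nonzero")
        twoI = 2 * self.I
        if self.I <= 0 or abs(twoI - round(twoI)) > 1e-12:
            raise ValueError("I must be a positive multiple of 1/2")

    @property
    def dim(self) -> int:
        return int(round(2 * self.I + 1))


def nucleus(isotope: str, count: int = 1) -> Nucleus:
    """Build a :class:`Nucleus` from the built-in isotope table."""
    try:
        return Nucleus(
            isotope=isotope,
            I=NUCLEAR_SPIN[isotope],
            gamma_MHz_per_T=GYROMAGNETIC_MHZ_PER_T[isotope],
            count=count,
        )
    except KeyError:
        raise UnsupportedIsotopeError(
            f"unknown isotope {isotope!r}; known: {sorted(NUCLEAR_SPIN)}"
        ) from None


@dataclass(frozen=True)
class HyperfineCoupling:
    """Axial hyperfine tensor: A_xx = A_yy = A_iso - T, A_zz = A_iso + 2T."""

    a_iso_MHz: float
    t_dip_MHz: float = 0.0
    euler_rad: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vals = (self.a_iso_MHz, self.t_dip_MHz, *self.euler_rad)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("hyperfine parameters must be finite")

    @property
    def principal_values(self) -> tuple[float, float, float]:
        a, t = self.a_iso_MHz, self.t_dip_MHz
        return (a - t, a - t, a + 2 * t)

    def tensor(self) -> np.ndarray:
        """3x3 hyperfine tensor in the molecular frame (MHz)."""
        R = rotation_matrix(self.euler_rad)
        return R @ np.diag(self.principal_values) @ R.T


@dataclass(frozen=True)
class Quadrupole:
    """Nuclear quadrupole tensor for I >= 1; K = e^2 q Q / 4h for I = 1."""

    K_MHz: float
    eta: float = 0.0
    euler_rad: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.K_MHz < 0:
            raise ValueError("K must be >= 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")

    def tensor(self) -> np.ndarray:
        """Traceless quadrupole coupling tensor in the molecular frame.

        Principal values (-K(1-eta), -K(1+eta), 2K) reproduce
        H_Q = K [3 I_z^2 - I(I+1) + eta (I_x^2 - I_y^2)] in the PAS.
        """
        K, eta = self.K_MHz, self.eta
        pas = np.diag([-K * (1 - eta), -K * (1 + eta), 2 * K])
        R = rotation_matrix(self.euler_rad)
        return R @ pas @ R.T


@dataclass(frozen=True)
class NucleusSpec:
    """One entry of a spin system: nucleus + couplings."""

    nucleus: Nucleus
    hyperfine: HyperfineCoupling
    quadrupole: Optional[Quadrupole] = None

    def __post_init__(self) -> None:
        if self.quadrupole is not None and self.nucleus.I < 1:
            raise ValueError("quadrupole coupling requires I >= 1")


@dataclass(frozen=True)
class SpinSystem:
    """An electron (isotropic g) plus an ordered list of coupled nuclei."""

    nuclei: tuple[NucleusSpec, ...]
    g_iso: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "nuclei", tuple(self.nuclei))

    @property
    def max_I(self) -> float:
        return max((e.nucleus.I for e in self.nuclei), default=0.0)

    @property
    def hilbert_dim(self) -> int:
        """Dimension of electron x nuclear space with all equivalent copies."""
        d = 2
        for e in self.nuclei:
            d *= e.nucleus.dim ** e.nucleus.count
        return d

    def is_axial_collinear(self) -> bool:
        """True when a theta-only powder grid suffices (no eta, no tilts)."""
        for e in self.nuclei:
            if any(abs(a) > 1e-12 for a in e.hyperfine.euler_rad):
                return False
            if e.quadrupole is not None and (
                e.quadrupole.eta > 1e-12
                or any(abs(a) > 1e-12 for a in e.quadrupole.euler_rad)
            ):
                return False
        return True


@dataclass(frozen=True)
class FieldConditions:
    """Static field (gauss) and, informationally, the microwave frequency."""

    b0_gauss: float
    mw_freq_GHz: float = 9.7

    def __post_init__(self) -> None:
        if self.b0_gauss <= 0:
            raise ValueError("B0 must be > 0")

    def nu_nz(self, nuc: Nucleus) -> float:
        """Nuclear Zeeman frequency magnitude in MHz."""
        return abs(nuc.gamma_MHz_per_T) * self.b0_gauss * GAUSS_TO_TESLA


@dataclass(frozen=True)
class Orientation:
    """Direction of B0 in the molecular frame with a powder weight."""

    theta: float
    phi: float = 0.0
    weight: float = 1.0

    def direction(self) -> np.ndarray:
        st, ct = math.sin(self.theta), math.cos(self.theta)
        return np.array([st * math.cos(self.phi), st * math.sin(self.phi), ct])


def rotation_matrix(euler_rad: tuple[float, float, float]) -> np.ndarray:
    """zyz (intrinsic) Euler rotation used for all tensor frames."""
    if all(abs(a) < 1e-15 for a in euler_rad):
        return np.eye(3)
    return Rotation.from_euler("ZYZ", euler_rad).as_matrix()


def spin_matrices(I: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cartesian spin matrices (Ix, Iy, Iz) for arbitrary spin I."""
    d = int(round(2 * I + 1))
    m = I - np.arange(d)  # I, I-1, ..., -I
    Iz = np.diag(m).astype(complex)
    # <m+1| I+ |m> = sqrt(I(I+1) - m(m+1)) couples column j+1 -> row j
    lp = np.sqrt(I * (I + 1) - m[1:] * (m[1:] + 1))
    Ip = np.zeros((d, d), dtype=complex)
    Ip[np.arange(d - 1), np.arange(1, d)] = lp
    Im = Ip.conj().T
    Ix = (Ip + Im) / 2
    Iy = (Ip - Im) / 2j
    return Ix, Iy, Iz


# ---------------------------------------------------------------------------
# Closed-form transition frequencies
# ---------------------------------------------------------------------------

def n15_frequencies(
    hf: HyperfineCoupling,
    theta: float,
    nuc: Nucleus,
    field: FieldConditions,
) -> tuple[float, float, float]:
    """I = 1/2 transition frequencies and modulation depth.

    With A = A_iso + T (3 cos^2 theta - 1) and B = 3 T sin theta cos theta,
    the two manifold frequencies are sqrt((nu_nz -/+ A/2)^2 + (B/2)^2),
    returned sorted so that nu_alpha < nu_beta, together with the standard
    modulation depth k = (B nu_nz / (nu_alpha nu_beta))^2.
    """
    if abs(nuc.I - 0.5) > 1e-12:
        raise UnsupportedIsotopeError(
            f"n15_frequencies requires I = 1/2, got I = {nuc.I}"
        )
    nu_nz = field.nu_nz(nuc)
    ct, st = math.cos(theta), math.sin(theta)
    A = hf.a_iso_MHz + hf.t_dip_MHz * (3 * ct * ct - 1)
    B = 3 * hf.t_dip_MHz * st * ct
    nu1 = math.hypot(nu_nz - A / 2, B / 2)
    nu2 = math.hypot(nu_nz + A / 2, B / 2)
    nu_a, nu_b = sorted((nu1, nu2))
    prod = nu_a * nu_b
    k = (B * nu_nz / prod) ** 2 if prod > 0 else 0.0
    return nu_a, nu_b, min(k, 1.0)


def n14_cancellation_frequencies(
    q: Quadrupole,
    hf: HyperfineCoupling,
    nuc: Nucleus,
    field: FieldConditions,
) -> tuple[float, float, float, float]:
    """Exact-cancellation frequencies for an I = 1 nucleus.

    Returns (nu_0, nu_minus, nu_plus, nu_dq): the three pure-quadrupole
    lines of the cancelled electron manifold,

        nu_0 = 2 K eta,  nu_minus = K (3 - eta),  nu_plus = K (3 + eta),

    which satisfy nu_0 + nu_minus = nu_plus exactly, and the double-quantum
    line of the non-cancelled manifold

        nu_dq = 2 sqrt((nu_nz + A_iso/2)^2 + K^2 (3 + eta^2)).
    """
    if abs(nuc.I - 1.0) > 1e-12:
        raise UnsupportedIsotopeError(
            f"n14_cancellation_frequencies requires I = 1, got I = {nuc.I}"
        )
    nu_nz = field.nu_nz(nuc)
    K, eta = q.K_MHz, q.eta
    nu0 = 2 * K * eta
    num = K * (3 - eta)
    nup = K * (3 + eta)
    nudq = 2 * math.sqrt((nu_nz + hf.a_iso_MHz / 2) ** 2 + K * K * (3 + eta * eta))
    return nu0, num, nup, nudq


# ---------------------------------------------------------------------------
# General sub-Hamiltonians
# ---------------------------------------------------------------------------

def sublevel_hamiltonians(
    entry: NucleusSpec,
    orientation: Orientation,
    field: FieldConditions,
) -> tuple[np.ndarray, np.ndarray]:
    """m_S = +/- 1/2 nuclear sub-Hamiltonians (MHz) for one nucleus entry.

    Eigenvalue differences of H_alpha (H_beta) are the nuclear transition
    frequencies of the corresponding electron manifold.  Everything is
    expressed in the molecular frame; only eigenvalue gaps matter.
    """
    nuc = entry.nucleus
    if nuc.I not in (0.5, 1.0):
        raise UnsupportedIsotopeError(
            f"simulation engines support I in {{1/2, 1}}, got {nuc.I}"
        )
    n = orientation.direction()
    Ax = entry.hyperfine.tensor()
    a_vec = n @ Ax  # hyperfine field seen by the nucleus, MHz
    nu_nz = field.nu_nz(nuc)

    Ix, Iy, Iz = spin_matrices(nuc.I)
    ops = (Ix, Iy, Iz)
    H_hf = sum(a_vec[j] * ops[j] for j in range(3)) * 0.5
    H_z = -nu_nz * sum(n[j] * ops[j] for j in range(3))
    H = H_z
    if entry.quadrupole is not None:
        Q = entry.quadrupole.tensor()
        H_q = sum(
            Q[j, k] * (ops[j] @ ops[k]) for j in range(3) for k in range(3)
        )
        H = H + H_q
    return H + H_hf, H - H_hf


def manifold_frequencies(
    entry: NucleusSpec, orientation: Orientation, field: FieldConditions
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted transition frequencies (MHz) of the two manifolds."""
    Ha, Hb = sublevel_hamiltonians(entry, orientation, field)
    out = []
    for H in (Ha, Hb):
        ev = np.linalg.eigvalsh(H)
        gaps = np.abs(ev[:, None] - ev[None, :])
        iu = np.triu_indices(len(ev), k=1)
        out.append(np.sort(gaps[iu]))
    return out[0], out[1]


def i_half_frequency_ranges(
    hf: HyperfineCoupling,
    nuc: Nucleus,
    field: FieldConditions,
    n_theta: int = 181,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Powder extents of the I = 1/2 ridges: ((nu_a min, max), (nu_b min, max))."""
    thetas = np.linspace(0.0, np.pi / 2, n_theta)
    na, nb = np.empty(n_theta), np.empty(n_theta)
    for i, th in enumerate(thetas):
        na[i], nb[i], _ = n15_frequencies(hf, float(th), nuc, field)
    return (float(na.min()), float(na.max())), (float(nb.min()), float(nb.max()))


# ---------------------------------------------------------------------------
# Powder grids
# ---------------------------------------------------------------------------

def powder_orientations(
    n_theta: int, n_phi: int = 1, phi_max: float = math.pi / 2
) -> list[Orientation]:
    """Powder grid: Gauss-Legendre nodes in cos(theta) on [0, 1].

    For axial collinear systems ``n_phi = 1`` (phi = 0) suffices; tensors
    with eta > 0 or tilted frames need a phi grid (midpoint rule on
    [0, phi_max], exploiting the D2h symmetry of collinear tensors).
    Weights sum to 1.
    """
    if n_theta < 1:
        raise ValueError("n_theta must be >= 1")
    x, w = np.polynomial.legendre.leggauss(n_theta)
    cos_t = 0.5 * (x + 1.0)  # map [-1, 1] -> [0, 1]
    w = w / w.sum()
    thetas = np.arccos(cos_t)
    phis = (np.arange(n_phi) + 0.5) * (phi_max / n_phi)
    return [
        Orientation(theta=float(t), phi=float(p), weight=float(wt) / n_phi)
        for t, wt in zip(thetas, w)
        for p in phis
    ]
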