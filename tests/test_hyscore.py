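"""HYSCORE engine: cross peaks, blind spots, tau summing, oracle agreement."""

import numpy as np
import pytest

from echomod import (
    HyperfineCoupling,
    NucleusSpec,
    Orientation,
    PulseTiming4p,
    SpinSystem,
    height_at,
    hyscore_brute_force,
    hyscore_powder,
    hyscore_single,
    hyscore_tau_sum,
    i_half_frequency_ranges,
    n15_frequencies,
    nucleus,
    pick_peaks,
    process_trace,
)

SMALL = PulseTiming4p(tau=210.0, t_start=40.0, dt=32.0, n1=12, n2=12)


def rel_rms(a, b):
    return np.sqrt(np.mean((a - b) ** 2)) / max(np.sqrt(np.mean(b**2)), 1e-300)


class TestOracleAgreement:
    @pytest.mark.parametrize("count", [1, 2])
    def test_spin_half_vs_full_propagation(self, count, hf_n15, orientation, field):
        sysc = SpinSystem(nuclei=(NucleusSpec(nucleus("15N", count=count), hf_n15),))
        vf = hyscore_single(sysc, SMALL, orientation, field).values
        vb = hyscore_brute_force(sysc, SMALL, orientation, field).values
        assert rel_rms(vf, vb) < 1e-6

    def test_n14_vs_full_propagation(self, sys_n14, field):
        o = Orientation(theta=0.9, phi=0.5)
        vf = hyscore_single(sys_n14, SMALL, o, field).values
        vb = hyscore_brute_force(sys_n14, SMALL, o, field).values
        assert rel_rms(vf, vb) < 1e-6

    def test_zero_couplings_featureless(self, field, orientation):
        sys0 = SpinSystem(nuclei=(NucleusSpec(nucleus("15N"), HyperfineCoupling(0.0)),))
        vf = hyscore_single(sys0, SMALL, orientation, field).values
        assert np.allclose(vf, 1.0, atol=1e-12)


class TestSingleCrystalPeaks:
    def test_cross_peak_at_closed_form_frequencies(self, sys_one_n15, field):
        # single orientation: one (nu_a, nu_b)/(nu_b, nu_a) pair, positions
        # within 0.02 MHz of the closed forms (independent re-derivation)
        o = Orientation(theta=np.pi / 4)
        na, nb, _ = n15_frequencies(
            sys_one_n15.nuclei[0].hyperfine, o.theta, nucleus("15N"), field
        )
        timing = PulseTiming4p(n1=256, n2=256)
        tr = hyscore_single(sys_one_n15, timing, o, field)
        spec = process_trace(tr, background="polynomial1", zerofill=1024)
        peaks = [
            p for p in pick_peaks(spec, min_height_frac=0.2, box=0.1)
            if p.nu1 > 0.05 and p.nu2 > 0.05
        ]
        assert len(peaks) >= 2
        top = peaks[0]
        lo, hi = sorted((top.nu1, top.nu2))
        assert lo == pytest.approx(na, abs=0.02)
        assert hi == pytest.approx(nb, abs=0.02)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_systems_match_closed_forms(self, seed, field):
        rng = np.random.default_rng(seed)
        hf = HyperfineCoupling(rng.uniform(0.5, 3.5), rng.uniform(-0.8, -0.1))
        theta = rng.uniform(0.3, 1.2)
        o = Orientation(theta=theta)
        na, nb, k = n15_frequencies(hf, theta, nucleus("15N"), field)
        if k < 0.05:
            pytest.skip("modulation too shallow to locate peaks")
        sysr = SpinSystem(nuclei=(NucleusSpec(nucleus("15N"), hf),))
        tr = hyscore_single(sysr, PulseTiming4p(n1=256, n2=256), o, field)
        spec = process_trace(tr, background="polynomial1", zerofill=1024)
        h = height_at(spec, na, nb, box=0.05)
        assert h > 0.3 * spec.magnitude.max()

    def test_blind_spot_tau_kills_cross_peak(self, sys_one_n15, field):
        o = Orientation(theta=np.pi / 4)
        na, nb, _ = n15_frequencies(
            sys_one_n15.nuclei[0].hyperfine, o.theta, nucleus("15N"), field
        )
        timing_ref = PulseTiming4p(tau=210.0, n1=128, n2=128)
        timing_bs = PulseTiming4p(tau=1000.0 / na, n1=128, n2=128)  # nu_a tau = 1
        h = {}
        for label, tm in (("ref", timing_ref), ("bs", timing_bs)):
            tr = hyscore_single(sys_one_n15, tm, o, field)
            spec = process_trace(tr, background="polynomial1", zerofill=512)
            h[label] = height_at(spec, na, nb, box=0.08)
        assert h["bs"] < 0.01 * h["ref"]


class TestPowderSpectra:
    def test_diagonal_symmetry(self, sys_two_n15, field):
        timing = PulseTiming4p(n1=64, n2=64)
        tr = hyscore_powder(sys_two_n15, timing, grid_size=40, field=field)
        spec = process_trace(tr, background="polynomial1", zerofill=256)
        assert np.allclose(spec.magnitude, spec.magnitude.T, rtol=1e-6, atol=1e-9)

    def test_isotropic_powder_equals_single_crystal(self, field):
        sys0 = SpinSystem(nuclei=(NucleusSpec(nucleus("15N"), HyperfineCoupling(2.0, 0.0)),))
        timing = PulseTiming4p(n1=32, n2=32)
        pw = hyscore_powder(sys0, timing, grid_size=12, field=field).values
        sc = hyscore_single(sys0, timing, Orientation(theta=0.3), field).values
        assert np.allclose(pw, sc, atol=1e-10)

    def test_weak_coupling_converges_to_diagonal_larmor_peak(self, field):
        sysw = SpinSystem(
            nuclei=(NucleusSpec(nucleus("15N"), HyperfineCoupling(0.05, -0.01)),)
        )
        nu_nz = field.nu_nz(nucleus("15N"))
        timing = PulseTiming4p(n1=128, n2=128)
        tr = hyscore_powder(sysw, timing, grid_size=40, field=field)
        spec = process_trace(tr, background="polynomial1", zerofill=512)
        peaks = [p for p in pick_peaks(spec, 0.3, 0.1) if p.nu1 > 0.3]
        assert peaks, "no peak found"
        top = peaks[0]
        assert top.nu1 == pytest.approx(nu_nz, abs=0.1)
        assert top.nu2 == pytest.approx(nu_nz, abs=0.1)

    @pytest.mark.parametrize(
        "t_dip,expect_present",
        [(-0.1, False), (-0.4, True)],
    )
    def test_combination_cross_peak_needs_dipolar_coupling(
        self, t_dip, expect_present, field
    ):
        """(2 nu_a, nu_b) resolved at T = -0.4 MHz but not at T = -0.1 MHz.

        For the weak dipolar coupling nu_alpha itself is ~0.1 MHz, so the
        doubled-frequency feature lies inside the fundamental linewidth:
        the nu_beta band then shows a single nu_1 cluster, whereas at
        T = -0.4 MHz a second cluster at roughly doubled nu_1 is resolved.
        """
        hf = HyperfineCoupling(2.8, t_dip)
        sys2 = SpinSystem(nuclei=(NucleusSpec(nucleus("15N", count=2), hf),))
        timing = PulseTiming4p(n1=256, n2=256)
        tr = hyscore_powder(sys2, timing, grid_size=60, field=field)
        spec = process_trace(tr, background="polynomial1", zerofill=512)
        (_, _), (nb_lo, nb_hi) = i_half_frequency_ranges(hf, nucleus("15N"), field)
        peaks = pick_peaks(spec, min_height_frac=0.05, box=0.1)
        nu1s = sorted(
            p.nu1 for p in peaks
            if nb_lo - 0.3 <= p.nu2 <= nb_hi + 0.1 and p.nu1 < p.nu2
        )
        assert nu1s, "no cross peak found"
        resolved = (nu1s[-1] - nu1s[0]) >= 0.2
        assert resolved == expect_present

    def test_strong_dipolar_coupling_adds_double_combination(self, field):
        """(2 nu_a, 2 nu_b) appears above the 5% contour at T = -1.2 MHz."""
        hf = HyperfineCoupling(2.8, -1.2)
        sys2 = SpinSystem(nuclei=(NucleusSpec(nucleus("15N", count=2), hf),))
        timing = PulseTiming4p(n1=128, n2=128)
        tr = hyscore_powder(sys2, timing, grid_size=60, field=field)
        spec = process_trace(tr, background="polynomial1", zerofill=512)
        (na_lo, na_hi), (nb_lo, nb_hi) = i_half_frequency_ranges(
            hf, nucleus("15N"), field
        )
        dd = _region_max(spec, (2 * na_lo, 2 * na_hi), (max(2 * nb_lo, nb_hi + 0.2), 2 * nb_hi))
        assert dd > 0.05 * spec.magnitude.max()


def _region_max(spec, r1, r2):
    m1 = (spec.f1_MHz >= r1[0]) & (spec.f1_MHz <= r1[1])
    m2 = (spec.f2_MHz >= r2[0]) & (spec.f2_MHz <= r2[1])
    if not (m1.any() and m2.any()):
        return 0.0
    return float(spec.magnitude[np.ix_(m1, m2)].max())


class TestTauSum:
    def test_single_tau_list_matches_single_spectrum(self, sys_two_n15, field):
        timing = PulseTiming4p(n1=48, n2=48)
        s1 = hyscore_tau_sum(sys_two_n15, timing, [210.0], grid_size=20, field=field,
                             zerofill=256)
        tr = hyscore_powder(sys_two_n15, timing, grid_size=20, field=field)
        s2 = process_trace(tr, background="polynomial1", zerofill=256)
        assert np.allclose(s1.magnitude, s2.magnitude, rtol=1e-12)

    def test_empty_tau_list_rejected(self, sys_two_n15):
        with pytest.raises(ValueError):
            hyscore_tau_sum(sys_two_n15, SMALL, [])

    def test_tau_sum_has_no_blind_spot_zeros(self, sys_one_n15, field):
        # averaged over 100:20:400 ns, every nuclear frequency below
        # Nyquist retains nonzero amplitude on the diagonal ridge region
        timing = PulseTiming4p(n1=64, n2=64)
        taus = list(range(100, 401, 20))
        spec = hyscore_tau_sum(sys_one_n15, timing, taus, grid_size=30, field=field,
                               zerofill=256)
        hf = sys_one_n15.nuclei[0].hyperfine
        (na_lo, na_hi), (nb_lo, nb_hi) = i_half_frequency_ranges(hf, nucleus("15N"), field)
        h = _region_max(spec, (na_lo, na_hi), (nb_lo, nb_hi))
        assert h > 0.05 * spec.magnitude.max()
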