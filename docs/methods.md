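# Methods

## Scope and assumptions

`echomod` simulates stimulated-echo (3-pulse) ESEEM and 4-pulse HYSCORE
for an effective electron spin S = 1/2 with isotropic g, coupled to any
mixture of I = 1/2 and I = 1 nuclei.  The modelling assumptions are:

* **Ideal, instantaneous pulses.**  Finite pulse lengths (8/16 ns in the
  reference acquisition) and transfer-amplitude effects are ignored.
* **No relaxation.**  Simulated envelopes do not decay; an exponential
  decay is applied only by the synthetic-trace generator.
* **Full powder at a single field.**  Electron g anisotropy and
  orientation selection are ignored: the observation field sits at the
  echo maximum near g_⊥, where most orientations contribute.  This is
  the main idealization relative to experiment — see *Limitations*.
* **Equivalent nuclei** are entries with `count > 1`: identical tensors
  and frames.  They enter the product rule as exact elementwise powers
  of the per-nucleus branch amplitude, which is algebraically identical
  to enlarging the Hilbert space with identical copies (verified against
  the brute-force propagator).

## Spin Hamiltonian

Each nucleus contributes two sub-Hamiltonians, one per electron
manifold, expressed in the molecular frame:

    H(m_S) = m_S Σ_j a_j I_j − ν_nz Σ_j n_j I_j + Σ_jk Q_jk I_j I_k

with `n` the unit field direction, `a = n·A` the hyperfine field row,
and `Q` the traceless quadrupole tensor with principal values
(−K(1−η), −K(1+η), 2K), reproducing K[3I_z² − I(I+1) + η(I_x² − I_y²)]
in its principal axis system.  Tensor orientations are zyz Euler
rotations and default to collinear.  Nuclear gyromagnetic ratios are
hardcoded (¹H 42.5775, ¹⁴N 3.0777, ¹⁵N −4.3157 MHz/T); only |γ| enters
the frequencies.  Frequencies are MHz, times ns, fields gauss.

For I = 1/2 the closed forms (ν_α, ν_β sorted ascending, depth k) agree
with the eigenvalue gaps to < 10⁻⁹ MHz on random parameter sweeps; for
I = 1 at the cancellation point (A_iso = 2ν_nz, θ = 0) the NQI triplet
closed forms agree to < 10⁻⁶ MHz.

The ¹⁴N reference parameters K = 0.4167 MHz, η = 0.6 are not
independently measured values: they are inverted from the observed NQI
triplet 0.5 / 1.0 / 1.5 MHz through ν₀ = 2Kη, ν∓ = K(3∓η), under the
standard labelling in which the smallest line is ν₀.  Experimental work
on this system labels the 0.5 MHz line ν−; the standard expressions do
not admit that ordering for η ≤ 1, so the package keeps the standard
labels and notes the mismatch here.  A_iso = 1.85 MHz is chosen so the
system sits near exact cancellation at 3316 G and the double-quantum
line falls at 4.18 MHz.

## Echo envelopes

**Pathway selection.**  With ideal pulses and an on-resonance electron,
every coherence-transfer pathway contributes at the nominal echo time,
so phase cycling alone does not isolate the stimulated echo.  Echo
formation is restored by the resonance-offset average: only the pathway
whose electron coherence refocuses the offset over the two τ intervals
survives a broad inhomogeneous line.  In the factorized engines this
selects a single stored nuclear operator, N = e^{+iH_β τ} e^{−iH_α τ}
(the Hermitian conjugate of the τ-encoded propagator mismatch); the
brute-force oracle implements the same physics literally by averaging
over a comb of eight offsets with Δτ = 2πj/8, which cancels all
non-refocusing pathway phases exactly.

**3-pulse.**  The engine expands
Tr[G_α(τ) G_m(T) N G_m(T)† G_β(τ)†]/d (m = α, β) in the respective
eigenbases, giving per-nucleus complex branch amplitudes as short
spectral sums over eigenvalue-gap frequencies.  The envelope is
E = Re{(Π_i T_i^α)^{c_i} + (Π_i T_i^β)^{c_i}}/2.  For pure I = 1/2
systems this reproduces the textbook product-rule expression

    E_α factor = 1 − (k/2)(1 − cos 2πν_β τ)(1 − cos 2πν_α(τ+T))

to machine precision; expanding the c-th power of that factor is what
produces the 2ν_α (and 2ν_β) combination lines for c ≥ 2.

**4-pulse.**  The mixing π pulse swaps the manifold between t₁ and t₂;
the engine evaluates the two branch grids as bilinear forms
u(t₁)ᵀ A v(t₂) over eigenvalue-gap frequency pairs, so a full 256×256
powder simulation of four equivalent ¹⁵N costs the same as one nucleus.
Both engines agree with the full electron⊗nuclear density-matrix
propagation to < 10⁻⁶ relative error (tests); the oracle caps the
Hilbert dimension at 64.

**Powder averaging** uses Gauss–Legendre nodes in cosθ (default 200 for
1D, 100 for 2D); a φ grid (midpoints on [0, π/2], 12 nodes for 1D, 8 for
2D) is added automatically when a quadrupole with η > 0 or a tilted
tensor breaks axial symmetry.  Doubling the θ grid beyond 200 changes
the reference traces by < 0.5% RMS.

## Processing chain

Normalization divides by the first-point echo amplitude.  Background
subtraction fits a·exp(−t/t_c)+c (falling back to a cubic polynomial
with a warning if the fit fails) or a polynomial of chosen order; 2D
traces are fit sequentially along t₁ then t₂.  Apodization windows are
one-sided (maximum at t = 0): Dolph–Chebyshev at 100 dB sidelobe
attenuation by default, or Hamming, or none.  Spectra are magnitude
FFTs after
zero-filling to 2048 (1D) or 1024×1024 (2D); the DC term is removed
before transforming.  The 100 dB attenuation is this package's default;
published chains typically name the window without its parameter.  Peak
positions are refined by parabolic interpolation, beating the 0.03 MHz
bin width.

For 2D spectra the default background is **first order** along each
axis: the acquisition windows are only 4–8 µs, so a cubic fit absorbs a
visible fraction of sub-MHz modulation (it splits the ν_α ridge and
biases combination/principal height ratios upward by ~0.15), while a
linear fit removes the echo-decay baseline without touching resolvable
frequencies.

## Measurement conventions

Two conventions are used when reading numbers off processed spectra,
chosen by the shape of the feature:

* **Compact lines** (NQI triplet, DQ line, HYSCORE combination cross
  peaks) are located by the interpolated local maximum from the peak
  picker.
* **Extended powder ridges** (the principal (ν_α, ν_β) HYSCORE ridge,
  the 2ν_α ESEEM band) are located by the magnitude-weighted centroid
  over the closed-form ridge region (frequency extents computed from
  the system's own parameters).  An ideal powder ridge is a plateau
  whose absolute maximum sits on orientation-density edge singularities
  and moves by >0.1 MHz under small processing changes; the centroid is
  stable and corresponds to where the broadened contour of a real
  measurement peaks.
* **Presence/absence of a line** is judged by its prominence above the
  local linear baseline across the search band.  This matters for the
  2ν_α ESEEM line: the fundamental ridge is only marginally resolved in
  a 9.6 µs record, and its magnitude-spectrum leakage skirt (≈25% of
  the ridge height one linewidth away) would otherwise masquerade as
  amplitude in the combination band.  The skirt is monotone, so its
  prominence is ~0, while a genuine combination line stands out; the
  one-nucleus control shows < 20% of the two-nucleus prominence.
* **Progression ratios** for m = 1…c equivalent nuclei are peak heights
  of the distinct off-diagonal picked peaks with ν₂ in the ν_β band,
  ordered by ascending ν₁, relative to the first.  A fixed ±0.15 MHz box
  around predicted positions (m·ν_α, ν_β) was considered and rejected:
  the m-th combination ridge spans m×(the fundamental extent), so for
  m ≥ 3 such boxes overlap the tails of neighbouring ridges and inflate
  the ratios severalfold.  Ratios are measured on τ-summed spectra
  (τ = 100–400 ns in 20 ns steps, averaging processed magnitude
  spectra), which removes the strong τ-dependent amplitude bias of any
  single τ; at τ = 210 ns alone the blind-spot factors suppress the
  principal peak (sin πν_ατ ≈ 0.2) relative to the combination peak.

## Acquisition design

The transition-intensity-versus-τ curves use the analytic product-rule
prefactors: ν_α amplitude ∝ c(k/2)(1 − cos 2πν_β τ) (swap for ν_β), and
the 2ν_α pair prefactor (c choose 2)(k²/8)(1 − cos 2πν_β τ)², powder
averaged; the ¹⁴N double-quantum amplitude comes from the matrix-engine
line coefficients of the largest eigenvalue gap.  "Intensity" is a
spectral-height proxy, not an integrated area; the ν_α curve correlates
with full simulate-and-process heights at r > 0.99 over a τ grid.

The joint recommendation constrains τ to the exact proton blind spots
n/ν_H inside the scanned range (the ¹H matrix line is best suppressed
exactly on the blind spot) and picks the harmonic maximizing the minimum
normalized amplitude across ¹⁴N ν_dq and ¹⁵N ν_α, ν_β, 2ν_α.  At 3316 G
this selects the third harmonic, 212.5 ns.  The smallest offered initial
T is always recommended, because broad fast-decaying components are lost
at long T_start.

## Synthetic traces

`make_fixture` emulates the reference acquisition: the simulated powder
envelope times exp(−T/4000 ns) (a typical stimulated-echo decay at 18 K)
plus white Gaussian noise, with SNR defined as peak-to-peak signal over
noise σ and default 20.  It reproduces bit-identically from (parameters,
seed).  What it does **not** emulate: hyperfine/quadrupole strain,
orientation selection, finite-pulse transfer amplitudes, t₁-noise or
baseline drifts.  Passing the closed-loop recovery tests therefore shows
the pipeline is correct and noise-robust, not that every real-data
pathology is handled.

## Numerical choices

* Frequencies are handled as angular factors 2πν·10⁻³ rad/ns.
* Eigen-decompositions use `numpy.linalg.eigh`; branch amplitudes are
  assembled in the sub-Hamiltonian eigenbases, so cost scales with
  (2I+1)² per nucleus, independent of equivalence count.
* The powder grid is deterministic (no Monte Carlo); all simulations are
  bit-reproducible.
* Peak picking breaks ties by ascending frequency; merged maxima closer
  than the `box` parameter keep the higher peak.
* Degenerate inputs: zero first-point amplitude, empty τ lists, zero
  modulation depth, and unsupported spins raise typed errors rather than
  returning NaNs.

## Limitations

The known systematic gap to experiment is orientation selection plus
strain broadening: ideal full-powder ridges concentrate intensity at
slightly different points than the blob centers of real, broadened
spectra — on the order of 0.05–0.1 MHz for the principal HYSCORE ridge
coordinates.  The centroid convention above absorbs most of this; users
fitting real data should treat absolute ridge-maximum positions with
that caveat.  Combination-line intensity ratios additionally depend on
apodization and background order (a cubic instead of linear 2D
background alone shifts the two-nucleus ratio by ~0.15 in this
package's own simulations), which is why the package fixes one
documented processing chain and reports ratios only from τ-summed
spectra.
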