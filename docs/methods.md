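# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.  Everything below is implemented and exercised
by `tests/`; no number here comes from anywhere but the package's own
computations.

## Wavepacket model and equations of motion

The dynamical object is a single normalized Gaussian in Hagedorn's
parameterization, defined by a real center `(q_t, p_t)`, complex D×D width
matrices `(Q_t, P_t)`, and the classical action `S_t`, in mass-scaled
vibrational coordinates with hbar = 1 (so the kinetic operator is
`-1/2 ∇²`).  Replacing the potential by its second-order expansion about
the instantaneous center (the local harmonic approximation) makes the
Gaussian ansatz exact, with

- `q̇ = p`, `ṗ = −∇V(q_t)`  — the center follows the classical trajectory
  of the *full* potential;
- `Q̇ = P`, `Ṗ = −(∇²V(q_t)) Q`  — the width evolves under the local
  Hessian only;
- `Ṡ = |p|²/2 − V(q_t)`  — the action accumulates the Lagrangian.

The Hagedorn relations `QᵀP − PᵀQ = 0` and `Q†P − P†Q = 2iI` encode
symplecticity and normalization: they guarantee `Q_t` stays invertible and
the packet stays L²-normalized.  Both are asserted as runtime invariants
rather than assumed.

The initial state is the ground vibrational eigenstate of the harmonic fit
to the initial-state surface: `Q₀ = κ^(−1/4)`, `P₀ = iκ^(1/4)` with κ the
initial-state Hessian in the propagation coordinates, placed at the
Franck–Condon point with zero momentum.  For molecular inputs κ is rotated
into the excited-state modes through the Duschinsky matrix `J = L_eᵀ R L_g`.

## Integrator

One step of the second-order symplectic splitting is applied in
kick–drift–kick order, jointly to `(q, p)` and `(Q, P)`:

```
p½ = p − (Δt/2) ∇V(q_n)        P½ = P − (Δt/2) H_n Q_n
q_{n+1} = q + Δt p½            Q_{n+1} = Q + Δt P½
p_{n+1} = p½ − (Δt/2) ∇V(q_{n+1})   (same for P with H_{n+1})
```

The KDK ordering was chosen over the drift-first twin because the single
per-step gradient/Hessian evaluation then falls exactly on the recorded
snapshot positions (the trailing kick reuses it), which makes the stored
per-step PES data and the energy monitor unambiguous.  The action uses the
matching discrete Lagrangian `Δt|p½|²/2 − Δt(V_n + V_{n+1})/2`.  Each
sub-step is a linear symplectic map, so both Hagedorn relations are
conserved to roundoff (measured ~1e−14 over 1000 steps at Δt = 8 a.u.),
the packet norm likewise, and the center energy oscillates with an O(Δt²)
amplitude (measured halving ratio 4.00 on a Morse trajectory).  The
dominant error is an effective frequency shift ≈ ω(ωΔt)²/24 per mode,
which informs the step sizes used in the exactness tests.

Negative local-Hessian eigenvalues along a trajectory are allowed — the
equations of motion remain well defined — and no regularization is applied.

## Autocorrelation and spectrum

`C(t) = ⟨ψ₀|ψ_t⟩` is evaluated in closed form; the Gaussian integral
collapses to

```
C(t) = 2^(D/2) det(X_t)^(−1/2) exp(b·M⁻¹b/2 + c),   X_t = i(P₀†Q_t − Q₀†P_t),
```

with `M, b, c` the quadratic/linear/constant parts of the combined
exponent.  The square-root branch of `det X_t` is tracked continuously
along the time grid (phase unwrapping), which keeps the phase of `C(t)`
smooth through the zeros of `det Q_t`; at `t = 0`, `X = 2I` and `C = 1`
exactly.  The half-trajectory evaluation trick is deliberately not used —
`C(t)` comes directly from `⟨ψ₀|ψ_t⟩` — because directness makes the
oracle tests (Franck–Condon sums) one-to-one.

The spectrum is `Re ∫₀^T C(t) e^(iωt) e^(−Γ|t|) dt` on a zero-padded (≥8×)
FFT grid, without the ω prefactor by default: relative intensities within
a narrow band are insensitive to it and every analysis statistic is
invariant under intensity rescaling; a flag restores it.  The damping
`Γ = HWHM` (cm⁻¹ → hartree) gives each line an exact Lorentzian of that
half-width.  A phase `e^(iE₀t)` with E₀ the initial-state zero-point energy
converts final-state energies to transition energies.

**Truncation ringing.**  If `ΓT` is only a few, the truncated transform
rings at the few-percent level, which can inject spurious peaks into peak
tables.  An optional Hann half-window (`window="hann"`) apodizes the
correlation; all lines share the slightly broadened shape, so peak
positions and relative intensities are unchanged.  The bundled demo uses
it (its two-mode correlation is strongly recurrent); the lineshape tests
use the pure exponential damping.

## Geometry machinery

Translations are removed by the center-of-mass shift, rotations by the
Eckart frame: the proper rotation minimizing the squared mass-scaled
distance to the reference, computed by the mass-weighted Kabsch SVD with a
determinant correction.  The stationarity condition of that minimization is
the rotational Eckart condition, so aligned displacements carry no
first-order rotational component.  Normal modes diagonalize
`m^(−1/2) H m^(−1/2)`; the 6 modes of smallest |eigenvalue| (5 when the
inertia tensor is rank-2) are projected out — by magnitude, not by
nearness to zero, so the construction stays robust at non-stationary
(vertical-expansion) reference points.  Mode order is ascending frequency;
eigenvector signs are fixed by making the largest-magnitude component
positive, so mode labels are reproducible.  Frequencies use a
sign-preserving square root: negative entries flag imaginary frequencies.

Isotope masses come from a bundled table (AME2020/CODATA values); the
potential never sees masses, so isotopologues share surfaces bitwise.

## Franck–Condon closed forms

Displaced-only oscillators use the Poisson law in the Huang–Rhys parameter
`S = sqrt(μk) Δq²/2` (the standard convention; validated against direct
quadrature of harmonic-oscillator overlaps).  Displaced + distorted pairs
use a stable three-term Hermite recursion for `⟨n_e|0_g⟩` that reduces
exactly to the Poisson law at `k_e = k_g` and obeys the parity selection
rule at `Δq = 0`.  Multidimensional Duschinsky-rotated FC sums are *not*
implemented: multidimensional harmonic spectra are obtained through the
time-dependent route, which is exact on quadratic surfaces — the route is
itself verified against the 1D closed forms to 5e−4 relative intensity.

## Analysis statistics

- **Envelope width**: `2·sqrt(Σwᵢ(ωᵢ−ω̄)²/Σwᵢ)` with intensity weights;
  invariant under rigid shifts and rescaling.  For a Poisson progression
  this is `2ω√S` exactly.
- **Peak correspondence** across isotopologues is by progression index from
  the 0–0 peak, not nearest wavenumber — index pairing is stable when the
  spacing changes by tens of percent.
- **Best-fit rigid shift** minimizes the mean absolute peak-position error;
  the minimizer is the median of per-peak differences.
- **MIME frequency**: `t_M` minimizes `Σ dq_j²(ω_j t − 2πn_j)²` with `n_j`
  the nearest integers, solved self-consistently from the closed-form
  quadratic minimizer.  The mismatch has a trivial zero at `t → 0` (all
  `n_j = 0`); seeding at the dominant mode's period and forcing its `n ≥ 1`
  selects the physical recurrence.  The `dq²` weighting is the default
  convention; `|dq|` is available as an option.
- **Dominant mode frequencies** come from the Hann-windowed, zero-padded
  DFT of each center coordinate, with quadratic peak interpolation (the
  window suppresses the leakage bias of a non-integer number of periods).

## The bundled demo and what it does (not) show

The demo surface couples a Morse stretch (`De = 0.18 Eh`, frequency ≈
1860 cm⁻¹ for the all-light masses) to a quartic-corrected harmonic bend
(≈ 930 cm⁻¹) through a weak bilinear term, offset by 0.21 Eh — the energy
scale and 2:1 stretch/bend ratio of an XH3-type first absorption band.
Four mass patterns use the symmetric-stretch and umbrella reduced masses of
an XH3 unit with 0–3 of the light atoms at double mass.  The ground state
is a displaced harmonic fit (3337/950 cm⁻¹ light-pattern frequencies),
displaced mostly along the bend (−0.55 bohr) and slightly along the stretch
(−0.05 bohr), putting the model in the bend-dominated single-progression
regime.  Broadening uses per-pattern HWHMs of 170/137/95/110 cm⁻¹ — peak
widths are phenomenological throughout; nothing in the package models
their physical origin.

What the passing demo shows: the qualitative isotope trends (monotone
contraction of peak spacing ∝ μ^(−1/2) and of envelope width ∝ μ^(−1/4),
MIME frequency locked to the bend) survive anharmonicity, mode coupling,
and the full numerical chain.  What it does not show: quantitative accuracy
for any real molecule (two modes instead of 3N−6, no rotational contour,
no nonadiabatic decay, no dissociative channel — the model is bound by
construction, emulating only the quasi-bound Franck–Condon region), and
nothing about the accuracy of the local harmonic approximation far from
the trajectory.

## Numerical choices and degenerate inputs

- Atomic units everywhere internally; conversions only at I/O boundaries
  (XYZ in Å, spectra in cm⁻¹, 1 a.u. time ≈ 0.024 fs).
- Hessian symmetry is enforced on input (tolerance 1e−8 relative) and
  preserved by explicit symmetrization after transforms.
- Peak detection uses local maxima above a relative threshold with
  3-point quadratic refinement; stick spectra bypass detection.
- `fit_spectral_shift` and `peak_spacing_shifts` truncate to the shorter
  peak table and flag it, rather than failing, when counts differ.
- Surfaces reject evaluation outside their validity domain (e.g. Morse at
  r ≤ 0 when the coordinate is radial) instead of returning garbage; the
  propagator wraps such failures with the offending step index.
- Degenerate-mode Duschinsky blocks are permutation-like up to sign; the
  sign convention above fixes the representative.

## Test problem sizes

The exactness checks propagate 1D harmonic models for 60 000 steps at
Δt = 2 a.u. (so the damped correlation decays to ~1e−5 and Lorentzian tail
overlap stays below the 1e−3 intensity tolerance); conservation checks use
the protocol's 1000 × 8 a.u.; the ODE-oracle comparison uses a weakly
anharmonic low-frequency Morse at Δt = 1 a.u. over 600 a.u., where the
splitting's predicted center error (≈ 3e−7 of the amplitude) sits well
below the 1e−6 assertion.  The demo runs 4 × 1000 steps.  The full suite
completes in under a minute on one CPU.

## Known limitations

Single-trajectory, single-Gaussian: no wavepacket splitting, tunneling,
or interference between trajectories; Condon approximation only (constant
transition dipole); rotations are removed, not modeled; harmonic-fit
initial state only.  The MIME weight convention and the spectral ω
prefactor are field conventions exposed as options, not derived facts.
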