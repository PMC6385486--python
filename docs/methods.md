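# Methods

## The model

The package computes solvation and electron-transfer (ET) quantities by
minimizing a classical free-energy functional of the molecular solvent
density ρ(r, Ω) — position **and** orientation resolved, so the
functional lives on a 6D grid.  The functional is defined relative to
the homogeneous solvent, F[ρ] = Θ[ρ] − Θ_H, so its minimum is the
solvation free energy of the rigid solute that generates the external
potential.  It splits into three parts:

- **Ideal term** — the entropy of the non-interacting molecular fluid,
  F_id = k_B T ∫∫ [ρ ln(ρ/ρ_H) − Δρ] dr dΩ with Δρ = ρ − ρ_H and
  ρ_H = n_H/(8π²/σ_sym).  A *quadratic* mode replaces it with its
  second-order expansion (k_B T/2) ∫∫ Δρ²/ρ_H.  With the quadratic
  ideal term the whole functional is quadratic in Δρ: this is the exact
  linear-response (Marcus) reference model, and all Marcus-limit
  equalities hold in it to numerical precision.  The quadratic form is a
  Taylor expansion, not a bound — it overshoots the exact entropy for
  ρ > ρ_H and undershoots below.
- **External term** — F_ext = ∫∫ ρ V with
  V(r, Ω) = Σ_ij v_ij(|r_iΩ − r_j|) summed over solvent sites i
  (rotated into the lab frame, r_iΩ = r + R(θ,φ,ψ)·b_i, ZYZ Euler
  convention) and solute sites j.  Lennard-Jones terms use
  Lorentz–Berthelot mixing, minimum image, and a real-space cutoff of
  min(box)/2 with no tail correction.  Electrostatics is periodic:
  solute charges are spread with a Gaussian of width one voxel, the
  Poisson equation is solved in reciprocal space with the k = 0 mode
  zeroed (tinfoil/neutralizing background), and solvent sites read the
  potential back by trilinear interpolation.  An open-boundary direct
  sum exists for validation.  V is capped at 100 k_B T; ρ_H e^{−βV}
  underflows far below that, and the cap keeps gradients finite.
- **Excess term** — the hypernetted-chain (HNC) quadratic form
  F_exc = −(k_B T/2) ∫∫∫∫ Δρ c Δρ driven by the bulk direct correlation
  function c(|r−r′|, Ω, Ω′).  Bridge corrections beyond HNC are out of
  scope.

Units are Å, kJ/mol, elementary charges and kelvin throughout, with
e²/(4πε₀) = 1389.35457 kJ·Å/mol and k_B = 0.0083144621 kJ/mol/K.

## Correlation kernels

The kernel is represented by rotational-invariant projections
ĉ^{mnl}_{μν}(k).  Version 1 convolves the m = n ≤ 1, μ = ν = 0 sector:
the isotropic channel ĉ_S(k) acting on the number-density deviation
Δn(r) and the longitudinal/transverse dipole channels ĉ_L, ĉ_T acting
on the polarization density P(r) = ∫ u(Ω) Δρ dΩ, where u is the
molecular (body z) axis.  Internally the dipole sector is stored in the
invariant basis c_Δ = (c_L + 2c_T)/3, c_D = (c_L − c_T)/3, and the
convolution is three FFTs plus per-orientation channel algebra:

    γ̂(k, Ω) = ĉ_S Δn̂ + ĉ_Δ (u·P̂) + ĉ_D [3(u·k̂)(k̂·P̂) − u·P̂].

At k = 0 the longitudinal/transverse split is direction-free by
convention (k̂ ≡ 0 there).  The table reader accepts arbitrary
higher-order blocks — a production water kernel is external data with
many more projections — and preserves them on round trip, but the
convolution refuses non-zero blocks beyond its sector rather than
silently dropping them.

The built-in `dipolar-toy` kernel uses Gaussian channels
a·exp(−k²w²/2).  Defaults a_S = −30 Å³, a_L = −20 Å³, a_T = +5 Å³,
w = 1 Å reproduce the sign structure of a polar liquid (reduced
compressibility, dielectric screening in the longitudinal channel) at
amplitudes far below the HNC stability bounds for this solvent density
(1/n_H ≈ 30 Å³ for the S channel, 3/n_H ≈ 90 Å³ for the dipole
channels), so the quadratic form stays positive definite.

The bulk-pressure estimate used to size the pressure correction is
P = n_H k_B T − (k_B T/2) n_H² ĉ₀₀₀(0); when a table lacks k = 0 the
value is obtained by quadratic extrapolation from the three smallest k.
The correction itself, ΔF = −P·ΔV with ΔV the solvent-depletion partial
molar volume, also accepts a user-supplied pressure so a better
estimate can be substituted without code changes.

## Minimization

Exact ideal mode minimizes over u with ρ = ρ_H e^u (positivity built
in) using L-BFGS with the analytic gradient
∂F/∂u = ρ·[k_B T ln(ρ/ρ_H) + V − k_B T γ]·(measure).  Initialization is
u = −βV — the exact solution at zero kernel and a good basin otherwise
— and is deterministic; reruns are byte-identical.  Default tolerances:
per-node gradient 1e-8 kJ/mol, relative F change 1e-10, 2000 iterations
maximum; non-convergence flags the result rather than raising.

Quadratic ideal mode minimizes over Δρ directly (variables scaled so
the ideal Hessian block is the identity).  The linear-response
minimizer legitimately undershoots zero where βV > 1, which the e^u
substitution cannot represent; a dense direct solve of the stationarity
equations on a 6³×8 grid agrees with the L-BFGS result to ~1e-15 in F
and serves as the oracle in the tests.  `DensityField` therefore
enforces non-negativity by default but admits signed fields when
constructed with `validate=False`.

The post-hoc corrections (finite size, pressure) are additive to final
free energies and never enter gradients.  The finite-size form is the
cubic-lattice Wigner correction −ξ_EW q² C (1 − 1/ε_s)/(2L) with
ξ_EW = −2.837297; both ξ and ε_s are configurable so alternative
published forms can be matched exactly.  Being constant per redox
state, corrections shift the reaction free energy ΔW but cancel in
every reorganization free energy; exact identities are always checked
on uncorrected quantities.

## Electron transfer

The two redox states share their Lennard-Jones sites and differ by
point charges, so they define functionals F_0, F_1 differing only in
the external term, and the interpolated family V_η = V_0 + η(V_1 − V_0)
is affine pointwise.  For each η the functional F_η is minimized
(warm-started from the previous η by default) and the scan records the
mean vertical energy gap ⟨ΔE⟩_η = ∫∫ ρ_η (V_1 − V_0), the minimized
F_η[ρ_η], and the cross-evaluations F_0[ρ_η], F_1[ρ_η] with their
ideal/external/excess decompositions.  F_1's external term is
integrated independently of F_0's so the Warshel identity
F_1[ρ_η] − F_0[ρ_η] = ⟨ΔE⟩_η remains a live numerical check of the
bookkeeping rather than an identity by construction.

From the endpoints: ΔW = F_1[ρ_1] − F_0[ρ_0],
λ_0 = F_0[ρ_1] − F_0[ρ_0], λ_1 = F_1[ρ_0] − F_1[ρ_1], and the
linear-response estimate λ_LR = (⟨ΔE⟩_0 − ⟨ΔE⟩_1)/2.  (One printed
form of the λ_1 relation carries a stray subscript; the implementation
uses λ_1 = ⟨ΔE⟩_0 − ΔW, which is forced by the λ_LR limit.)  The
ideal and excess contributions to λ_0 and λ_1 are exactly opposite —
both are differences of the same state-independent terms between ρ_0
and ρ_1 — which the tests assert.

The diabatic curves are the point sets (⟨ΔE⟩_η, F_A[ρ_η]).  The
Marcus-style curvature fit W(x) = (x − x_min)²/(4λ) + W_min uses only
points within 90 kJ/mol of the minimum (configurable); collinear
windowed points are rejected as degenerate.  Diagnostics recompute,
for every scan: the Warshel residual, the curve-crossing location on
the gap axis (exactly 0 when the scan brackets it), monotonicity
violations of ⟨ΔE⟩_η (the underlying grand potential is convex in η,
so the gap must be strictly monotone), the thermodynamic-cycle route
F̃_0(η) = F_η[ρ_η] + ⟨V_0 − V_η⟩_η against the direct F_0[ρ_η], and —
given a second scan with a reparametrized schedule s(η) — whether both
point sets lie on one curve.  The invariance check interpolates with a
not-a-knot cubic spline, which is exact on polynomial curves through
cubic; piecewise-linear interpolation would contribute O(Δx²) ≈ 4e-3
spurious deviation on a parabolic curve sampled at 11 points.

The distance scan places a single-site redox couple at height z above
an uncharged Lennard-Jones wall (a square single-layer (100) lattice)
and repeats the endpoint calculation per z.  Solutes act on the solvent
only; merging wall and redox site into one solute can therefore never
create direct wall–solute interaction terms, which a test verifies via
additivity of the composite potential.

## Structure observables

The solvent charge density ρ_c(r) convolves each orientation's density
with the molecular charge form factor Σ_i q_i e^{−ik·r_iΩ} in
reciprocal space; global neutrality holds for any field because each
molecule is neutral.  Point placement is band-limited by the grid and
rings near sharp features; an optional Gaussian smearing (use the
electrostatic solver's one-voxel width for consistency) damps it.
Spherical averages are volume-weighted shell means over minimum-image
distances, with empty shells reported as NaN rather than zero.  The
partial molar volume is the bare depletion integral
ΔV = −(1/n_H) ∫ Δn dr — no compressibility term — which equals the
excluded volume exactly for a hard core.

Hard cores are put on the grid by `hard_core_potential`, which stores
per voxel the Boltzmann-consistent value of the voxel's in-sphere
fraction (4³ sub-samples by default).  A sharp indicator evaluated at
voxel nodes misplaces the boundary by up to half a voxel and its volume
error fluctuates at the ±1% level on a 0.5 Å grid; the sub-voxel
average reduces this to ~0.1%.

## The toy study system

Desk-scale studies use a 3-site neutral dipolar solvent (dipole along
the body z-axis, n_H = 0.0333 Å⁻³, T = 298.15 K — ambient-water-like
numbers, σ_sym = 1) with the default dipolar-toy kernel, and
single-site Lennard-Jones solutes (σ = 4.404 Å, ε = 0.4190 kJ/mol, the
classic chloride-like model; charges in [−1, 1] e).  Orientation grids
are 2×2×2 Gauss–Legendre×uniform products, exact through first-order
Wigner functions — sufficient for a kernel acting through density and
polarization only.  (The production-style default for a C2v solvent is
7×7×4 with σ_sym = 2, i.e. 196 orientations.)

Two couples are used deliberately: a charge-inverting couple
(+0.5 → −0.5 e), whose symmetry puts ΔW ≈ 0 so the sampled gap range
brackets the curve crossing at zero; and a neutral → anion-like couple
(0 → −0.5 e) for the exact-mode monotonicity study.  Grid sizes per
study: 32³ on a (16 Å)³ box for the hard-core limit and the Marcus
scan, 24³ on (12 Å)³ for structure, 16³ for invariance and exact-mode
scans, 6³ × 8 orientations for the brute-force convolution oracles.

What the toy conditions do **not** emulate: the strong short-range
orientational correlations of hydrogen-bonded water (the real kernel
carries many rotational-invariant projections beyond the dipole
sector), production resolution (120³ × 196), and solutes larger than a
few sites.  Passing tests therefore validate the formalism, the exact
identities, the discretization and the minimizer — not quantitative
agreement with any particular liquid; that requires an externally
obtained tabulated kernel.

## Known limitations

- Kernel convolution is truncated at the dipole sector (m ≤ 1, μ = ν = 0);
  higher-order tabulated blocks are stored but not convolved.
- The exact ideal mode with strong kernels is not provably convex; the
  minimizer records its (deterministic) initialization so reruns are
  reproducible, and warm starts along η can be disabled to probe
  initialization dependence.
- The finite-size and pressure corrections are standard stand-in forms
  with configurable constants, not fits to any particular published
  protocol.
- Product orientation quadratures only (no Lebedev grids); uniform
  rectangular spatial grids only.
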