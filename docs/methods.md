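# Methods

`hexamig` models cell intercalation in confluent epithelia as the unbinding
of topological defects in a hexatic (sixfold bond-orientational) liquid
crystal, at three levels: closed-form fields of the ±1/6 defect quadrupole,
a continuum active-hexatic solver, and a cell-resolved multiphase-field
(MPF) simulator with a shape/defect/T1 analysis pipeline. This note records
the model equations as implemented, the numerical conventions, the defaults
and why, and the known limitations — including several places where we
found the published formulas of this class of models internally
inconsistent and had to decide which branch to implement.

## Tensor conventions

A traceless symmetric rank-p tensor in 2D has two degrees of freedom and is
stored as one complex number `t` per node via `T = Re(conj(t) u⊗p)`,
`u = e_x + i e_y`, so `T[xx…x] = Re t`, `T[xx…xy] = Im t` and
`|T|² = 2^{p-1}|t|²`. The hexatic order tensor is `Q6 = 4|Ψ6| [[n⊗6]]`,
which fixes the complex representation `q = ψ/8` (`ψ = |Ψ6| e^{6iθ}`) and
reproduces the normalisation `|Q6|² = |Ψ6|²/2` exactly. Spin bookkeeping:

* contracting k indices with derivatives lowers the spin:
  `t → (∂x − i∂y)^k t`;
* the projected product `[[∇⊗k ⊗ S]]` raises it:
  `s → (∂x + i∂y)^k s / 2^k`, with the combinatorial factor fixed by the
  orthogonal projector (2 extra for the strain contraction, giving the
  `/16` used in the flow-alignment term).

None of these constants is asserted by fiat: `hexamig.tensors` carries the
explicit-array representation and the test suite pins every contraction
against a brute-force oracle (orthogonal projection onto an explicitly
constructed constraint subspace, plain `tensordot` contractions).

## Free energy, molecular field, stresses

In ψ-representation the Landau–de Gennes functional becomes

    F = ∫ dA [ L6/4 |∇ψ|² + A6/4 |ψ|² + B6/16 |ψ|⁴ ],

with equilibrium magnitude `|ψ| = sqrt(−2A6/B6)` (exactly 1 for the
reference parameters `A6 = −0.2, B6 = 0.4`). The gradient term uses
forward differences so that the molecular field (compact 5-point
Laplacian) is the *exact* discrete functional gradient: the
finite-difference variational tests then hold to 1e−8 instead of the
O(h²) mismatch a centred-difference energy would give, and pure relaxation
is monotone to round-off. Stresses:

* viscous `2η[[u]]`;
* elastic `σᵉᵢⱼ = −L6 ∂iQ6 ⊙ ∂jQ6 = −(L6/2) Re(∂iψ ∂jψ*)` (its isotropic
  part is physically absorbed into pressure and never enters the vorticity
  equation);
* reactive `−λ6 ∇⊗4 ⊙ H6 + 3(Q6·H6 − H6·Q6)`, where the dot contracts all
  but one index of each factor — the only pairing that yields a rank-2
  object; the antisymmetric part reduces to `τ = (3/2) Im(ψ* Hψ)`;
* active `α6 ∇⊗4 ⊙ Q6`, i.e. `s_a = (α6/8)(∂x − i∂y)⁴ ψ`.

`α6 < 0` is labelled extensile, `> 0` contractile, following the source
convention (see “Known discrepancies”).

## Analytic quadrupole

The four-cell (5-7-5-7) T1 intermediate maps to two −1/6 disclinations at
(±ℓ, 0) and two +1/6 at (0, ±ℓ). The exact orientation is the signed sum
of the four two-argument polar angles divided by six; a single-argument
arctangent of the coordinate ratio cannot represent ±1/6 defects (its
branch jumps are π/6, not π/3), so all angular comparisons are made on
`e^{6iθ}` or after mod-π/3 reduction.

Far field: the expansion of the exact sum is
`θ = −ℓ² sin 2φ / (3 r²) + O((ℓ/r)⁶)` — charge and dipole neutrality kill
every intermediate order, giving the r⁻⁶ residual the tests fit. The
amplitude ℓ²/3 is also what the multipole route gives (`a2 = −ℓ²/3`) and
the only amplitude consistent with the closed-form active force below; a
widely quoted variant with twice this amplitude is not consistent with its
own multipole coefficients and is not used.

The active force of the far-field quadrupole is

    f = 960 α6 ℓ²/r⁷ { [−3cos7φ + (ℓ/r)²(3cos5φ − 14cos9φ)] e_x
                       + [3sin7φ − (ℓ/r)²(3sin5φ − 14sin9φ)] e_y },

verified against the numerical divergence of the implemented rank-6 stress
to 0.1% (all three harmonics).

The flow is the Oseen convolution of this force over the annulus
ℓ < r′ < R, kernel `G = [(log(L/r) − 1)1 + r⊗r/r²]/(4πη)`, `L = R√e`.
`oseen_flow_numeric` reduces the angular integrals exactly (log expansion
of the kernel plus trigonometric orthogonality; the traceless part maps
harmonic m of the conjugate force to output harmonic 2−m with weight
`(r′/r)^{|m|} − (r′/r)^{|m|+2}` for interior sources) and performs the
remaining 1D radial integrals by Simpson quadrature in log r′.
`flow_full` is the closed-form R→∞ limit of the same quadrature, derived
analytically (six harmonics, elementary integrals) and verified
coefficient by coefficient against an independent brute-force 2D
quadrature; being an Oseen image it is exactly divergence-free, and it is
odd under r → −r as the force is. The compact near-cluster approximation

    v ≈ (120 α6 ℓ⁴/η)(4 − 6 log(r/ℓ) − 3r²/ℓ²) cos6φ r_vec/r⁸

(`flow_nearfield`) is kept verbatim from the source as the basis of the
stagnation-flow picture; see “Known discrepancies” for its status.

## Continuum solver

Vorticity–stream-function formulation on a doubly periodic grid
(dx = dy = 1, dt = 0.1, predictor–corrector Euler, centred second-order
stencils, spectral Poisson inverse built from the eigenvalues of the
5-point Laplacian so incompressibility and the Poisson identity are exact
discretely). The ψ equation carries relaxation `Γ6 Hψ`, advection,
corotation `3iζψ` (rigid rotation advects the director at the fluid
angular velocity — checked), flow alignment `(λ6/2)(∂x+i∂y)⁴ s_u` and the
optional `2ν6 s_u³` (ν6 has no published value; default 0). The vorticity
equation keeps inertia at ρ = 1 and sources
`Im[(∂x−i∂y)²(s_el + s_r + s_a)] − ∇²τ`. The discrete source assembly was
validated against the closed-form force curl (0.2% at r = 45 where the
stencils resolve the harmonics) and the steady force→velocity chain
converges at second order to the continuum Stokes solution for smooth
body forces.

Experiment protocols: the quadrupole initial condition sets |ψ| = 1 with
the exact angle field inside a disk of radius R_D = 28 (ℓ = 7) and random
phase outside; thermalisation relaxes everything outside the pinned disk
until the per-iteration relative free-energy change drops below 0.1% *and*
no stray defects remain outside the pinned region — the second clause is
our addition: the stated end state (defect-free exterior, |Ψ6| ≈ 1) is not
guaranteed by the energy criterion alone, because stray pairs from the
random exterior can survive it. For the ±1/6 dipole the default exterior
is the smooth two-defect angle field rather than random phase: with a
random exterior, stray defects park at the pinned-core rims (attracted but
unable to annihilate with pinned content) and the protocol cannot reach
its stated end state deterministically.

The release experiments scan an activity ladder (−0.025, −0.05, −0.1,
−0.2 by default), classify the outcome (annihilation: zero census;
unbinding: the two +− pair centres separate beyond 3ℓ), measure the
coarse midpoint phase rotation mod π/3, and report the angle between the
two dipoles' displacement directions (plus the lab-frame alternative).
Defect positions are plaquette centres (winding of Arg ψ/6 with increments
reduced to (−π/6, π/6], ties to +); no sub-plaquette refinement — grid
spacing 1 is finer than every tolerance used.

## Multiphase-field tissue

Free energy and dynamics exactly as in the model section of the module
docstring; parameters α = k_φ = 0.2, ε = 0.1, k_ad = 0.005, λ = 600,
R_cell = 11.5, v0 = 0.006, D_r ∈ [1e−6, 8e−5). φ0 = 1 and M = 1 are free
normalisations (only dimensionless combinations matter); dt = 0.1 because
the area-constraint spring `4λ/(π φ0² R_cell²) ≈ 5.8` makes the explicit
scheme unstable at dt = 0.5 (verified blow-up). Fields are stored as one
(n_cells, ny, nx) array vectorised over cells — at the ≤ 48-cell scales
this package targets, sharded per-cell subdomains would add re-centring
machinery for a ~6 MB saving. Polarity noise is Euler–Maruyama with
variance 2 D_r dt from a per-state master generator, so runs are bit
reproducible from (seed, parameters).

Note on the “nominal surface tension” `σ = sqrt(8 k_φ α)`: the actual line
tension of this double well is `φ0³ sqrt(k_φ α/2)/6 = σ/24` for φ0 = 1
(equal-area construction, confirmed by relaxing a 1D kink and integrating
its energy). Tests freeze the honest value.

## Analysis pipeline

Segmentation thresholds at φ_th = φ0/2, counts occupancy per pixel, and
repairs interface pixels where every field dips below threshold: a zero
pixel reachable (4-neighbourhood) from at least two cells' supports
receives their counts, iterated to a fixed point — the two-cell condition
keeps exterior vacuum around isolated cells untouched. Junction vertices
are centroids of 8-connected clusters with occupancy > 2 (periodic seams
merged by union–find); a vertex is assigned to every cell whose dilated
support covers its cluster. The shape function weights vertices by
|r_v|^p; its coarse-grained average over disks of radius 1.5 R_cell on a
lattice of spacing R_cell feeds the same plaquette-winding detector as the
continuum fields.

T1 events are transitions losing edge (A,B) and gaining (C,D) with C, D
common neighbours of A and B; adjacency uses a ≥ 3-pixel interface with a
2-frame persistence filter (both configurable — the event definition in
the source is stated but not parameterised). A reverted event is a cycle
with period T; an unreverted one counts as an intercalation once the
series extends ≥ 4 median cycle periods past it (configurable horizon).
Distance-to-defect distributions use the signed x-offset to the nearest
same-frame defect (the projection axis of the source figure is unstated;
x is our documented choice), and the mobility scatter divides the box into
Δℓ-sided subregions, accumulating per-window sums of squared single-frame
displacements over Δℓ².

## Problem sizes

Suite and acceptance runs use desk-scale settings chosen once: 128² for
thermalisation (the production 256² changes the median |Ψ6| by < 1e−3),
96² for the release and dipole experiments (dipole separation 32), 12-cell
72² tissues for MPF property runs, and an Oseen quadrature with 4000
log-spaced radial nodes to R = 200ℓ (quadrature error ~1e−5 relative).

## Known discrepancies and limitations

* **Far-field amplitude.** The source's printed far-field expression
  carries twice the amplitude of its own exact angle sum and multipole
  coefficients; we implement the self-consistent ℓ²/3 amplitude (the
  printed force and the r⁻⁶ residual law are consistent only with it).
* **Full-flow closed form.** The printed closed-form quadrupole flow is
  not divergence-free and is not the Stokes response to the printed force
  (its resonant log coefficient corresponds to half the force's cos5φ
  amplitude). `flow_full` is therefore our own derivation of the
  Oseen-annulus solution; the printed near-field formula is kept as
  `flow_nearfield` but its cos6φ amplitude differs from the true
  quadrature's `720(ρ² − 1 − 2 log ρ)/r⁷` profile, and the 120-prefactor
  extraction in the acceptance suite fails honestly for that reason.
* **Unbinding phenomenology.** With the equations and parameters as
  printed, the released quadrupole (ℓ = 7) annihilates for |α6| ≲ 10 of
  either sign and the bulk nucleates defects everywhere for |α6| ≳ 12
  (with or without flow alignment); no activity window unbinds it into two
  escaping dipoles, and at α6 = ±0.1 the dipole annihilation time is
  unchanged to 0.2%. The corresponding acceptance checks run the faithful
  protocols and fail; the measured force scale suggests the source's
  simulations used a much larger effective active stress than the printed
  normalisation.
* **Near-cluster flow structure.** The analytic flow is the response to
  the far-field force restricted to r′ > ℓ; in the full simulation the
  (physically regularised) defect-core stresses on the r = ℓ circle
  dominate the near flow, so the analytic pattern is an idealisation, not
  a pointwise prediction there.
* **Event statistics at desk scale.** At the printed motility parameters a
  12-cell tissue produces roughly one neighbour-exchange per 2000 time
  units, so per-noise-level event statistics require runs orders of
  magnitude longer than the bounded ones in the suite; the statistics
  machinery is validated on scripted sequences instead.
* Not modelled: nematic (p = 2) hydrodynamics beyond the γ₂ shape
  diagnostic, division/apoptosis, external body forces, non-periodic
  boundaries, three-dimensional tissue.
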