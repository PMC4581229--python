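# Methods

## Model

A protein is coarse-grained to one bead per residue at its Cα position.
Beads closer than a cutoff `r_c` (default **12.0 Å**) are joined by identical
Hookean springs of constant γ, giving the anisotropic network model (ANM)
potential

    V = ½ γ ΔRᵀ H ΔR

with `ΔR` the 3N vector of bead displacements and `H` the Hessian of the
pairwise distance-restraint energy at the reference coordinates: for spring
(i, j) with reference length `d0` and unit bond vector `r̂`, the off-diagonal
3×3 block is `−r̂ r̂ᵀ` and the diagonal blocks accumulate the negatives.
The cutoff comparison is a strict `<`; a pair at exactly `r_c` gets no
spring.  Eigendecomposition `H = U Λ Uᵀ` yields the normal modes; for a
connected, genuinely three-dimensional structure exactly six eigenvalues are
zero (rigid translations/rotations) and are excluded from every fluctuation
sum.  Degenerate geometries have more zero modes — a collinear model keeps
5 rigid modes but loses none of its stretching mode, while a *planar*
network gains one free out-of-plane motion per bead — so the six-zero-mode
property is a statement about non-coplanar structures.

Units are reduced, `kBT = γ = 1`.  Every ranking-type output (mode MSFIC
shares, normalized correlations, perturbation ranks) is invariant to the
`kBT/γ` prefactor.  Absolute scale enters only through the optional
calibration of γ against experimental B-factors, `B_i = (8π²/3)⟨|ΔR_i|²⟩`:
since `B_calc ∝ 1/γ`, the least-squares through-origin fit gives
`γ = Σ B_unit² / Σ B_unit·B_exp` where `B_unit` are B-factors computed at
γ = 1.  This estimator is B²-weighted, so its variance is governed by the
few most mobile residues; on small bead models a single 10%-noise draw can
err by more than its nominal ~2% standard error, which is why the test suite
judges the calibration by the mean error over fixed-seed noise replicates.

## The function-related internal coordinate

A scalar collective variable Δr is defined as the weighted mean of a few
inter-residue distances — for a membrane transporter, the Cα–Cα separations
of residue pairs spanning the channel's cytoplasmic gate, so Δr measures the
gate opening.  Linearized at the reference structure, Δr = aᵀΔR with the
3N gradient `a` assembled from per-pair unit bond vectors (weights default
to 1/P and are normalized to sum to 1).  Because each pair contributes
antiparallel unit vectors, `a` is exactly orthogonal to the rigid-body
space.

To make Δr a coordinate axis, one Cartesian coordinate (index m) is replaced
by it:

    q = A ΔR,   A = I except row m = aᵀ
    H' = (A⁻¹)ᵀ H A⁻¹

`m` is chosen as `argmax |a_k|` (ties to the lowest index), which maximizes
`|det A| = |a_m|` and the conditioning of the transform.  `A⁻¹` is identity
except row m (`−a_k/a_m`, and `1/a_m` at m), so both transforms are applied
in O(N) without forming matrices, and `H'` is assembled by rank-one updates
and explicitly symmetrized (`(M + Mᵀ)/2`) — congruence is symmetric
analytically but round-off breaks it at ~1e−12.  Congruence preserves
inertia, so `H'` has the same zero-mode count as `H`.  Only the first-order
(linear) coordinate change is used; no second-order corrections.

## Per-mode gate fluctuation (MSFIC)

With `H' = U' Λ' U'ᵀ` and nonzero mixed modes indexed k = 1, 2, … ascending,

    ⟨(Δr)²⟩_k = (kBT/γ) λ'_k⁻¹ ([u'_k]_m)²

is mode k's contribution to the gate fluctuation.  Summed over **all**
nonzero mixed modes this equals the direct route `(kBT/γ)·aᵀH⁺a` exactly —
an identity that holds because `a ⊥ null(H)` (variational argument on the
quadratic form), and the package's primary conservation check.  The default
analysis window is the **30** slowest nonzero modes; a mode is flagged
"distinct" when its MSFIC reaches **0.5 ×** the window maximum (both are
parameters — the threshold operationalizes "relatively large", for which no
published cutoff exists).

## The correlation field (functional motion)

The functional motion is the cross-covariance between the gate coordinate
and each residue's displacement over the analysis window:
`⟨Δr ΔR_i⟩ = (aᵀC)` restricted to residue i, where `C` is the Cartesian
back-transform `A⁻¹ C' A⁻ᵀ` of the window-limited mixed covariance
`C' = (kBT/γ) Σ_k λ'_k⁻¹ u'_k u'_kᵀ`.

One numerical choice matters here.  Dropping the six zero modes of `H'` is
not the same ensemble restriction as dropping the six rigid modes of `H`
(the null spaces are related by the non-orthogonal `A`), and the raw row of
the mixed pseudo-inverse consequently contains a spurious rigid-body
component: on a two-bead model it yields arrows of unequal magnitude, and on
an exactly C2-symmetric dimer an asymmetric field.  The package therefore
evaluates the field in the rigid-body-free (Eckart) frame: `C` is projected
onto the orthogonal complement of the six rigid-body vectors before the row
is extracted.  With this projection the full-spectrum field coincides
exactly with the direct Cartesian route `aᵀH⁺`, and symmetry of the
structure propagates to the field.  The rigid basis is built with an SVD
rank cut (5 vectors for collinear structures, where axial rotation moves
nothing).

Normalization: `|⟨Δr ΔR_i⟩| / sqrt(⟨Δr²⟩·⟨|ΔR_i|²⟩)` with all three factors
computed from the same projected, window-limited covariance, which makes the
Cauchy–Schwarz bound (values in [0, 1]) rigorous; residues that do not move
over the window get 0.  For arrow export the field vectors are rescaled to
unit maximum length — the covariance-weighted mode sum *is* the
cross-covariance row, so these arrows are the functional displacement.

A truncation caveat: the mixed eigenbasis is not symmetry-adapted (the
transform privileges coordinate m), so a truncated window can break exact
structural symmetry of the field at the few-percent level.  The artifact
vanishes over the full spectrum; symmetry-based checks therefore use the
full window, and the truncated mixed-mode route is never asserted equal to
the truncated Cartesian-mode route (they differ by construction).

## Spring-perturbation scan

Stiffening one spring, γ_ij → γ_ij + δγ, changes the Hessian by the spring's
super-element scaled by δγ (36 nonzero entries).  The first-order response
of the gate fluctuation is

    δ⟨(Δr)²⟩ = −(kBT/γ²) (G δH' G)_mm

with `G` the window-limited inverse of `H'` and `δH'` the transformed
perturbation.  Writing `y = A⁻¹ G e_m` this collapses per spring to
`−(kBT/γ)(δγ/γ)·(r̂·(y_j − y_i))²/d0⁰…` — algebraically identical, O(1) per
spring after one O(3N·k) precomputation, and verified in the tests against a
full rebuild-and-re-decompose finite difference (1% agreement at
δγ/γ = 1e−4, with first-order convergence).  Because every rigid-body
vector is annihilated by any spring super-element, the scan is automatically
free of the rigid-frame artifact discussed above.

Conventions: responses are reported per unit fractional stiffening
(δγ/γ = 1; the response is linear in δγ so this cannot change ranks);
ranking is by |δ⟨(Δr)²⟩| (full-spectrum stiffening responses are ≤ 0 by
first-order theory, so magnitude and most-negative orderings coincide
there); selection takes the top fraction (default **5%**, count rounded up)
with boundary ties all included.  The mode-limited finite-difference
comparison is made only for the full-spectrum variant: truncated-window
first-order theory omits retained/discarded-mode cross terms, so the
window-limited scores are a ranking statistic, not a derivative estimate.
Perturbations are applied one spring at a time; grouping selected
interactions into structural regions is annotation left to the user.

## Synthetic structures

The generator produces deterministic bead models exercising every code
path: `two_node` (one spring; every closed form is analytic),
`chain`/`ring` (degenerate geometries for the zero-mode logic),
`c2_dimer` (two random compact blobs exactly symmetric under a 180°
rotation about z plus chain swap — the symmetry oracle), and `clamshell`
(two elongated lobes hinged near the origin, opening in the x–z plane; gate
pairs across the mouth give a transporter-like gating geometry).  Random
kinds enforce a minimum bead separation of 3.5 Å, a connected contact graph
at the default cutoff, exactly six zero modes, and a stiffness floor
(first nonzero eigenvalue ≥ 1e−4 × λ_max) that rejects draws containing
near-mechanisms — a barely constrained bead would otherwise carry a
B-factor hundreds of times the median, unlike any real protein.  Rejected
draws are retried with a sub-seed, so generation is deterministic given
(kind, n, seed).

What the synthetic models do **not** emulate: polypeptide connectivity and
secondary structure, realistic contact-density gradients (surface loops vs
core), residue identity, and crystallographic artifacts.  Passing tests on
them therefore validate the linear algebra, the transforms, the symmetry
behavior and the statistical procedures — not biological conclusions about
any particular protein, which require a real structure (see the BtuCD–BtuF
example; crystal structures are not bundled and must be supplied by the
user).

## Numerical choices and problem sizes

- Eigensolves use dense symmetric LAPACK routines; a partial solve
  (lowest-k eigenpairs) is available and used for structures above a few
  hundred residues, where only the ~36 slowest modes are analyzed.  For
  partial solves the zero-mode threshold uses a Gershgorin bound on λ_max.
- Zero modes are detected by a relative threshold 1e−8 × λ_max, with a
  warning (not an error) when the count differs from six.
- Degenerate eigenvalues are reported in stable ascending order; tests on
  symmetric systems compare subspace-level quantities, not individual
  vectors.
- Test and acceptance problem sizes — 28–80-bead synthetic models, 10⁵
  Monte-Carlo samples, 20 calibration replicates — were chosen so the whole
  suite completes in seconds while every tolerance retains a comfortable
  margin.

## Known limitations

- One scalar distance-average coordinate; no angles, dihedrals, or multiple
  simultaneous coordinates.
- Cutoff-ANM only: uniform force constant, no distance weighting, no
  residue-specific springs, no Gaussian network variant.
- The 30-mode window convention follows the source analysis; window-limited
  quantities depend on whether truncation is done in mixed or Cartesian
  modes, and both routes are exposed (`msfic_profile` vs
  `ic_variance_direct`) but only their full-spectrum totals are equal.
- Ligands, nucleotides and waters are never network nodes; membrane and
  solvent environments are not modeled.
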