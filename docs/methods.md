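# Methods

This note records the modelling assumptions, numerical choices and known
limitations of the package, at the level of detail a user extending it
needs.  All units are SI (s, mm, cells/mm³); time-facing interfaces in the
experiments layer use days (1 d = 86 400 s).

## The microscale process

A cell is a piecewise diffusion Markov process U_t = (X_t, Z_t, V_t) with
characteristic triple (flow, jump rate, transition kernel):

- Between jumps, position follows dX = v dt + σ dW with the velocity v
  frozen, and the internal variable obeys the linear relaxation
  dz/dt = −[(k⁺A + k⁻) z − f′(A)⟨v, ∇A⟩].  z measures the deviation of the
  bound-integrin fraction from its local steady state y* = k⁺A/(k⁺A+k⁻)
  and lives in (y*−1, y*) ⊂ (−1, 1).
- Jumps occur with state-dependent hazard λ(z) = λ₀ − λ₁z, floored at zero
  (the floor is logged if it ever activates; it cannot under admissible
  parameters).
- At a jump the cell draws a fresh direction from the local fibre
  orientation distribution and keeps speed α exactly.

**Jump-time sampling** uses thinning with the constant bound
λ̄ = λ₀ + |λ₁| (valid since |z| < 1): candidate times are Exp(λ̄), the flow
is advanced to each candidate, and the candidate is accepted with
probability λ(z)/λ̄.  This is exact in distribution and avoids inverting
the survival function through the ODE.  For λ₁ = 0 the law is exactly
Exp(λ₀), which the tests verify by Kolmogorov–Smirnov; for frozen z the
thinning sampler is cross-checked against inverse-CDF sampling.

**Flow integration.**  Between jumps the position SDE has constant
coefficients, so the Euler–Maruyama update is *exact* for any step length;
no small position step is needed.  The z-equation is integrated with an
exact exponential step, z ← (z − b/a)e^{−a·h} + b/a, with a = k⁺A + k⁻ and
b = f′(A)⟨v, ∇A⟩ frozen at the current position per substep.  The substep
h therefore only needs to resolve the variation of the tissue along the
path: h = min(0.2/(k⁺+k⁻), 0.25·Δx/α) (the second term only for gridded
environments).  At the default rates this gives h ≈ 4.5 s against a
z-relaxation time of ≈ 23 s and cell displacements of ≈ 1 µm per substep —
two orders of magnitude below the grid resolution.

**Velocity kernel.**  Directions are sampled by rejection against the
uniform circular proposal with the exact bound
sup q = λ_max(D₂)/(2π√det D₂).  Acceptance is 1 for isotropic tensors and
≈ (λ_min/λ_max)^{1/2} in general.  An independent route — the angle of a
draw from N(0, D₂) has exactly the ODF law — serves as a sampling oracle
in the tests, never as the implementation.

**Boundaries.**  Paths are free; outside the tissue mask the environment
is extended by nearest-masked-node values.  Cell-scale boundary behaviour
is not part of the macroscopic derivation, and at the shipped speeds a
cell moves ≈ 18 mm/day·10⁻³, so excursions are negligible on study
horizons.

Ensembles use one `numpy` SeedSequence split into per-path child streams,
so results are reproducible and order-independent.

## The orientation distribution function in 2D

The model runs on a 2D slice while diffusion tensors are 3×3.  The slice
ODF is taken as the two-dimensional analogue of the quadratic-form ODF,

q(x, v̂) = 1 / (2π √det D₂ · v̂ᵀD₂⁻¹v̂),  v̂ ∈ S¹,

with D₂ the in-plane 2×2 block.  The exponent d/2 (3/2 on the sphere, 1 on
the circle) makes the density *exactly* normalised — it is the angular law
of a centred Gaussian with covariance D₂ — and for in-plane diagonal
tensors admits closed forms used as test oracles (e.g. q = 1/π along the
leading axis of diag(4, 1), and a direction second moment with
V₁₁ = √a/(√a+√b)).  Restricting the 3D exponent to the circle and
renormalising numerically would distort the angular profile; the
dimensional analogue preserves both the quadratic-form shape and the
normalisation.  Angular quadrature uses the trapezoid rule on 720 uniform
directions, spectrally accurate for these smooth periodic densities.

Synthetic tensors set the out-of-plane eigenvalue to the smaller in-plane
eigenvalue, and the standard three-eigenvalue FA formula is applied to the
stored 3×3 tensor.

## Macroscopic coefficients

- D_T(x) = (α²/λ₀) ∫ q(x, v̂) v̂⊗v̂ dv̂, with the speed factored out of the
  direction integral; trace D_T = α²/λ₀ identically.
- P_T = ∇·D_T componentwise (central differences, one-sided at the mask
  boundary).  This is the drift of the myopic-diffusion identity
  ∇∇:(D_T M) = ∇·(D_T∇M + (∇·D_T)M), the dimensionally consistent reading
  of the drift produced by the parabolic limit.
- l(A) = λ₁ f′(A)/(λ₀ + Ak⁺ + k⁻); haptotactic velocity h = l·D_T·∇A.
- Effective tensor D_eff = D_T + (σ²/2)I; advective flux velocity
  drift = P_T − h.
- A(x) = FA(𝔻(x)) inside the mask, 0 outside; ∇A by the same masked
  stencils.

σ is stored as the SDE amplitude (mm·s^{−1/2}); the macroscopic addition
is σ²/2.  The literature often quotes σ with diffusivity units — the
numeric values are taken as the amplitude, and only σ² enters the
macroscopic equation, so the ambiguity affects labelling, not dynamics.

k⁺ = 0.034 s⁻¹ and k⁻ = 0.01 s⁻¹ are adopted from the receptor-binding
literature this model family builds on; they enter y*, f′, l(A) and the
z-relaxation rate.

## The macroscopic solver

Cell-centred conservative finite volumes on the structured masked grid:

- each interior face carries one flux expression
  F = D_n ∂_n M + D_t ∂_t M + u_f·M_donor shared with opposite signs by its
  two cells, so columns of the transport operator sum to zero and total
  mass is conserved to solver accuracy (measured drift ≲ 10⁻¹⁵ relative
  per step);
- normal-derivative fluxes are central (order 2); cross-derivative terms
  average the tangential-derivative stencils of the two adjacent cells
  (order 2, verified by manufactured solutions); advective fluxes are
  upwinded (donor = the cell the mass flows from), robust for the strong
  haptotaxis sweeps at |λ₁| = 5;
- no-flux boundaries arise by construction: no face, no flux;
- time stepping is IMEX: implicit Euler for transport (one sparse LU
  back-solve per step; the factorisation is reused across steps) and
  explicit logistic reaction μ₀(1 − M/K_M)A·M, whose per-step increment is
  ≈ 7·10⁻² per day at most — far below the stability limit;
- negative undershoots (possible with tensor cross terms) are clipped to
  zero and the clipped mass is accumulated in a report; on all shipped
  scenarios the clipped total is zero or negligible, and it is never
  silent.

A Galerkin finite-element discretisation would be the natural alternative;
the finite-volume form was chosen for exact discrete conservation and
trivial masked geometry at equal (second) spatial order.

Verification: manufactured anisotropic-diffusion solutions converge at
order ≈ 2; a free Gaussian grows its variance as 2dt to machine precision
(implicit Euler propagates second moments of the discrete operator
exactly); the 1D logistic front travels at 2√(dμ₀) within the Bramson
finite-time correction; a comparison-principle check confirms larger σ
never reduces far-field density on a ring scenario.

## Experiments

The tumour seed is the Gaussian-like aggregate
M₀ = 0.1 K_M · exp(−((x−x₀)² + (y−y₀)²)/8), centred at (−35, −41) mm.  The
peak of 0.1 K_M is a package default chosen so the onset is growth-limited
rather than immediate; both peak and centre are configurable.

τ_OSM is the first instant max_x M > M_crit = 0.6 K_M, reduced over masked
nodes by the maximum (the first location to cross; a domain-mean reduction
is available).  The crossing is interpolated linearly between time steps.
Peak and mass are recorded at every step, so sweeps can stop at the
crossing.

**Sweep design.**  One parameter varies at a time from the baseline
λ₀ = λ₁ = 0.8 s⁻¹.  The turning-rate sweeps (λ₀, λ₁) run at σ = 0, matching
the design of the parameter studies they mirror; the σ sweep varies
σ ∈ [0.01, 0.2].  At the shipped speeds α²/λ₀ ~ 5·10⁻⁸ mm²/s while
σ²/2 ≥ 5·10⁻⁵ mm²/s, so any nonzero σ baseline would drown the
turning-rate effects entirely — the σ = 0 baseline is what makes the λ₀
and λ₁ responses observable at all.

**The brain-slice scenario** (96×96 nodes at 0.5 mm, an elliptical mask
over [−59, −11.5]×[−65, −17.5] mm) emulates a fractional-anisotropy map of
parenchyma: a smoothly varying background with FA ∈ [0.2, 0.45] and
smoothly rotating fibre orientation, a strongly aligned annular arc
(FA ≈ 0.88 at its crest, Gaussian cross-profile, ≈ 13 mm from the tumour
seed), and a vertical para-midline bundle, blended in tensor space so A
and ∇A are smooth.  Deliberately *not* emulated: CSF/ventricle
compartments (A ≈ 0), grey/white contrast boundaries, B-field noise, and
partial-volume artefacts.  Tests passing on this scenario show the model
machinery responds correctly to smooth anisotropic tissue; they do not
certify behaviour at sharp tissue interfaces or in patient geometry.

On this scenario the onset time responds as the macroscopic structure
predicts: σ delays the onset (the added isotropic diffusion drains the
density peak), λ₀ advances it (D_T ∝ 1/λ₀: faster turning means less
peak-draining anisotropic spread), and λ₁ — entering only through the
haptotactic advection l(A)D_T∇A, bounded by the same small D_T scale —
shifts it by well under a day across [−5, 5] s⁻¹.  The absolute τ_OSM
values are properties of the synthetic tissue and seed, not of any
patient dataset.

## Micro → macro validation

Nothing in the code ties the simulator to the PDE; their agreement is
checked by simulation, with every check seeded and serialisable:

- waiting times vs Exp(λ₀) (KS, n = 10⁴, significance 0.01; below 100
  samples the check reports "underpowered" instead of a verdict);
- sampled directions vs quadrature bin masses of q (χ², 36 bins, n = 10⁵);
- MSD slope over the second half of [0, T], T = 25/λ₀, vs
  2(α²/λ₀ + σ²); tolerance 5%, sized so the ballistic correction
  (relative size ≈ 1/(λ₀T)) and Monte-Carlo error at n = 10⁴ both fit;
- L1 distance ≤ 0.1 between the normalised ensemble histogram (n = 2·10⁴)
  and the μ₀ = 0 macroscopic solution from the matching point source, in
  isotropic and fibre-bundle tissue.  The comparison grid spans ±6.5
  diffusive standard deviations per axis with per-axis spacing (equal
  cells-per-σ resolution), a node sits exactly at the path origin, the
  PDE uses graded implicit-Euler stages (fine while the point source is
  narrow), and both densities are smoothed with the same 2-cell Gaussian
  kernel — identical smoothing removes binning noise without biasing the
  comparison.  Measured distances are ≈ 0.03–0.04 against the 0.1
  threshold, the margin covering Monte-Carlo noise and the finite-time
  (ballistic) correction the parabolic limit neglects.

The tolerances (5%, 0.01, 0.1) are engineering choices sized by the
Monte-Carlo error at the stated sample sizes, not theoretical constants.

## Known limitations

- The mesoscopic kinetic equation itself is not solved; the hierarchy is
  validated micro ↔ macro only.
- Proliferation exists only in the macroscopic limit form μ(M)A·M; the
  microscale process does not divide, and tumour cannot grow where A = 0.
- The admissibility condition λ₀ ≥ max(λ₁·sup y*, −λ₁(1 − inf y*)) is
  enforced at construction; sensitivity sweeps outside the admissible band
  require `strict_turning=False` and rely
  on the hazard floor.
- Upwind advection is first-order; with |λ₁| large and sharp ∇A the
  haptotactic term is diffused by the scheme.  The diffusion terms remain
  second-order.
- Position jumps, treatment effects, acidosis coupling and 3D geometry are
  out of scope.
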