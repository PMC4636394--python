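# Methods

## The contact-network model

A cluster of n two-state channels occupies distinct sites of an integer
lattice. The adjacency matrix **A** has (A)ᵢⱼ = 1 iff channels i and j are
nearest neighbors (4-neighborhood; diagonal contacts are excluded, which
underestimates open probabilities slightly but keeps every degree ≤ 4 and
hence λ₁ < 4 for any cluster). The state is X̄(t) ∈ {0,1}ⁿ; channel i
closes at rate δ when open and opens at rate β·Yᵢ(t) when closed, where
Yᵢ = Σⱼ (A)ᵢⱼXⱼ is its number of open neighbors. The spontaneous opening
rate with no open neighbor is taken as zero (it is ~10⁻⁶ ms⁻¹ in detailed
biophysical models, negligible on the spark-initiation timescale), so the
all-closed state is absorbing.

A trial starts with one channel open ("initiator"). A Ca²⁺ spark is
declared when the open count N_O reaches 4 — the level at which detailed
3-D models give >95% probability of a full spark — with the initiator
counted, so a spark needs three additional recruitments. A trial fails
when N_O hits 0. Both states are absorbing for simulation purposes; the
stopping rule at N_O = 4 is our choice (the failure rule is forced — no
opening is possible from the empty state), and absorption probabilities
are insensitive to it only at threshold 4 itself, which is the quantity
reported.

## Mean-field and linearized dynamics

The first-moment mean-field approximation (higher moments closed at zero)
gives dp̄/dt = (β diag{ū−p̄}**A** − δI)p̄. Linearizing about p̄ = 0 yields
the LCN model dp̄/dt = (β**A** − δI)p̄, solved exactly over the eigenmodes
of the symmetric matrix **A** = **V D Vᵀ**:

    p̄(t) = Σᵢ e^{(βλᵢ−δ)t} v̄ᵢ (v̄ᵢᵀ p̄(0)).

Stability: all modes decay iff βλ₁ − δ < 0, i.e. λ₁ < δ/β. Summing the
solution entries with initiator-j initial conditions gives the expected
open-channel count vector

    E[n̄_O(t)] = Σᵢ e^{(βλᵢ−δ)t} (ūᵀv̄ᵢ) v̄ᵢ,

and with a uniformly random initiator E[N_O(t)] = (1/n) Σᵢ e^{(βλᵢ−δ)t}
(ūᵀv̄ᵢ)². The per-mode weights bᵢ(t) = e^{(βλᵢ−δ)t}ūᵀv̄ᵢ and
cᵢ(t) = bᵢūᵀv̄ᵢ/n, and the fractional contributions c̄ᵢ = cᵢ/Σⱼcⱼ, are
evaluated at t̂ = 8 ms by default (the spark-initiation window; results
are insensitive between 4 and 12 ms). Σᵢcᵢ(0) = 1 exactly because
Σᵢ(ūᵀv̄ᵢ)² = ‖ū‖² = n.

Known ordering: the mean-field solution upper-bounds the true occupation
probabilities, and the LCN solution upper-bounds the mean-field one (the
linearization drops the negative −β diag{p̄}**A**p̄ term). Both facts are
asserted as tests. The LCN deviates most near threshold (δ/β ≈ λ₁) and
its entries exceed 1 in supra-threshold regimes — a documented artifact,
reported unclipped.

## Numerical choices

- Eigensolver: `numpy.linalg.eigh` (full decomposition; all modes are
  needed and n is at most a few hundred). Eigenvalues are reported in
  descending order. Sign convention: each eigenvector's entry sum is made
  positive (first nonzero entry positive for zero-sum vectors), so
  centrality maps are platform-reproducible. Eigenvalues closer than 1e-8
  are flagged as a degenerate block: individual vectors inside a block are
  solver-dependent, but block sums of cᵢ are well defined.
- Connectivity is enforced before any spectral/mean-field analysis
  (Perron–Frobenius structure is assumed throughout); disconnected input
  raises with a pointer to largest-component extraction.
- Walk counts W_k = ūᵀ**A**ᵏū use arbitrary-precision integers (W₃₀ on a
  49-channel cluster already overflows int64).
- Nonlinear mean-field ODE: `scipy.integrate.solve_ivp` (LSODA),
  rtol 1e-8, atol 1e-10. The vector field preserves [0,1]ⁿ; trajectories
  are reported without clipping and tested to stay in range.
- Gillespie simulation: statistically exact CTMC sampling with incremental
  propensity bookkeeping (O(degree) per event). Spark-probability
  estimators sample the embedded jump chain only — absorption
  probabilities of a CTMC depend solely on the jump chain, so skipping
  waiting-time draws is exact, not an approximation. Full trajectories
  (with exponential waiting times) come from `simulate_trial`. RNG: every
  trial runs on a deterministic substream `SeedSequence(seed, trial)`, so
  any single trial replays in isolation. A 10⁶-event cap guards runaway
  supra-threshold runs with absorption disabled.
- Exact oracle: for n ≤ 12 the absorption probability (reach N_O =
  threshold before 0) is solved over all configurations with 1..threshold−1
  channels open via a sparse linear system; used to validate the SSA.
- Perturbation scan: Δλ₁ for a removal that disconnects the cluster is
  computed on the largest remaining component and flagged; the theory does
  not define Δλ₁ for disconnected remainders, and this choice mirrors how
  split clusters are analyzed in practice.
- Mode-truncation correlations (ρ_k) are Pearson by default (configurable
  to Spearman); modes are selected as the dominant one plus the largest
  remaining fractional contributions, not by eigenvalue rank, because
  ūᵀv̄ᵢ can vanish for the second eigenvalue's vector.

## Diffusion calibration of β

An open channel is a continuous point source in a semi-infinite volume;
at steady state a neighbor at distance r sees C = i_RyR/(2π z F d_C r).
With Hill-type activation, β = k⁺C^η. Defaults: i_RyR = 0.15 pA, z = 2,
d_C = 146 µm²/s (calibrated down from a 250 µm²/s cytosolic estimate so
that β comes out at its nominal 0.115 ms⁻¹), r = 31 nm, k⁺ = 1.107×10⁻⁴
µM⁻η·ms⁻¹, η = 2.1, δ = 0.5 ms⁻¹. These give C ≈ 27.33 µM, β ≈ 0.1151
ms⁻¹, δ/β ≈ 4.343 (4.35 with β rounded to three decimals), and δ/β ≈ 6.30
at r = 37 nm (checkerboard-like spacing). Unit caveat: k⁺ is sometimes
printed per second in the source literature, but only a per-millisecond
k⁺ is consistent with the three independently printed values (0.115,
4.35, 6.3); the package stores it per millisecond and flags the
discrepancy rather than silently rescaling. All unit conversion goes
through SI in one function; a dimensional-analysis test pins the path.

## Synthetic clusters: what they emulate and what they do not

Real cluster geometries come from super-resolution imaging. The package's
stand-ins are: solid rectangles (idealized compact clusters), random
accretion blobs (Eden growth: start at the origin, repeatedly occupy a
uniformly random empty site adjacent to the cluster — connected,
irregular-boundary shapes), and dumbbells (two square lobes joined by a
narrow bridge, the bottleneck morphology that produces functional
subdomains). Accretion blobs reproduce the class-level statistics the
theory addresses (λ₁ distribution, threshold collapse, intra-cluster
gradients) but not the specific morphology distribution of imaged
clusters — a green threshold-collapse test establishes the spectral
scaling law on this family, not agreement with any particular imaging
dataset. Sizes default to the imaged range (tens of channels); spacing
defaults to 31 nm.

A dumbbell with equal lobes is mirror-symmetric: the subdomain-splitting
eigenmode is then odd, its overlap ūᵀv̄ vanishes, and it contributes
nothing to E[n̄_O] — the subdomain phenomenology (large second c̄ᵢ, low
ρ₁) requires unequal lobes, so the generator takes an optional second
lobe size and the subdomain tests use an asymmetric dumbbell with an
equal-size solid control.

Image reconstruction mirrors the percentile-thresholding protocol used
with STED data: the threshold is a percentile of *all* pixels (uniform
over the image, background included), the image is partitioned into
spacing-sized bins, and a bin is occupied iff its maximum intensity is at
or above the threshold (ties occupied; bin-maximum pooling is robust to
sub-bin placement of point-spread peaks and is switchable to mean). The
largest 4-connected component is returned with a component count. Raising
the percentile can only shrink the occupied set, hence never increases n
or λ₁ — asserted as a property.

## Known limitations and open points

- A published supra-threshold ensemble value for the scaled-β experiment
  (mean p_S at β = 2δ/λ₁) is not reproduced by the model as defined here:
  with the exact dynamics validated against the CTMC oracle, every tested
  cluster family gives ≈ 0.33–0.44 (ensemble mean ≈ 0.36), versus ≈ 0.28
  reported alongside threshold (≈ 0.14) and sub-threshold (≈ 0.029)
  values that this implementation does reproduce. No variant of the
  stopping rule, spark threshold, or activation saturation reconciles all
  three published values simultaneously; the corresponding acceptance
  check is left failing by design rather than tuned.
- Diagonal and distance-weighted coupling, heterogeneous spacing,
  L-type-channel triggering, luminal-store depletion, and second-order
  (pair-approximation) contact models are out of scope.
- The CSV coordinate dialect (`row,col` header, one channel per line, the
  record order defining channel indices) is this package's own; external
  coordinate files in physical units can be loaded with `units="nm"`,
  which snaps positions to the lattice by rounding against the spacing.
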