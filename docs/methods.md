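# Methods

## The model

An N-electron spatial wavefunction Ψ(x), x ∈ ℝ³ᴺ, is antisymmetric under
exchange of same-spin electron coordinates. Configuration space therefore
decomposes into Nα!·Nβ! equivalent regions ("tiles") related by like-spin
relabellings; all information lives in one tile. `dvms` works with CI
expansions

    Ψ(x) = Σᵢ cᵢ · det[Aᵢ(x_α)] · det[Bᵢ(x_β)],

where each term is a product of spin-block Slater determinants over a
common set of spatial orbitals (Gaussian-basis molecular orbitals, or
closed-form model orbitals for the toy systems). The tile around a
reference point x̄ is its Voronoi cell among the *even* permutation images
of x̄ — the odd images carry the opposite sign of Ψ and are separated from
the cell by nodes.

The package finds a self-consistent x̄ = ∫_R x Ψ² dx / ∫_R Ψ² dx, with R
the cell of x̄ itself, by alternating Metropolis sampling of |Ψ|² with
permutation fold-back and centroid updates (dynamic Voronoi Metropolis
sampling). For benzene it then measures the relative occupancy of the four
Kekulé cells — two "eclipsed" (both spin sets on the same Kekulé
structure) and two "staggered" (alternate structures) — as a function of
CI truncation.

## Wavefunction fixtures

Committed under `dvms/data` with SHA-256 checksums:

* `benzene_rhf_631gd.molden` — RHF/6-31G(d) molecular orbitals (Cartesian
  d functions, each contracted component unit-normalized) at an ideal D6h
  geometry, r(C–C) = 1.397 Å, r(C–H) = 1.087 Å (typical hybrid-DFT-quality
  bond lengths), ring in the xy-plane. 25 MOs are stored: the 21 occupied,
  the three lowest virtuals, and the higher b2g π* needed by the π active
  space. RHF energy −230.70184 Eh.
* `benzene_cas66_pi.civec` — the all-π (6,6) CAS-CI ground state over the
  RHF orbitals (occupied π: a2u + e1g pair; virtual π*: e2u pair + b2g);
  full 400-determinant vector, E = −230.76030 Eh. The |cᵢ|-degenerate
  group boundaries fall at 1, 3, 5, 7, 11, 13, 17, 19, 20, 21, …
  determinants.
* `benzene_cas3018_valence.civec` — the valence (30,18) CAS-CI ground
  state (all 30 valence electrons; 15 valence-occupied orbitals plus the
  three lowest virtuals, of which the third is a σ*-type orbital),
  E = −230.74443 Eh; the leading ~800 determinants of the normalized
  665,856-determinant vector are stored (group-aligned cut, 99.99% of the
  norm). Group boundaries: 1, 3, 5, 7, 9, 11, …; cumulative Σcᵢ² at the
  7-determinant boundary is 0.9875.

Determinant coefficients use the "orbitals in ascending index order per
spin, α block before β" sign convention; the loaders merge the
doubly-occupied core orbitals into every determinant. The
`request_wavefunction` adapter defines the contract for regenerating these
files through an external quantum-chemistry engine (pyscf) when one is
installed; the committed files cover all built-in analyses. Their
correctness is cross-checked in the test suite at the level the package
can verify offline: checksums, normalization, electron counts, degeneracy
structure, and exact antisymmetry of the evaluated Ψ.

## Metropolis sampling

Walkers carry full 3N-configurations and sample |Ψ|², with two proposal
granularities (`StepPolicy.move`):

* **single-electron** (default): one trial move displaces the three
  coordinates of one electron by independent Gaussians of variance
  0.2 bohr² per dimension, electrons visited cyclically. Acceptance for
  benzene is ≈ 40–60%.
* **joint**: all 3N coordinates at once (same per-dimension variance).
  Appropriate for the few-electron toys. For benzene this granularity has
  an acceptance rate measured to be exactly zero over thousands of steps —
  a joint 126-dimensional displacement of ~0.45 bohr per coordinate always
  lands exponentially far down the density — so it cannot generate
  dynamics at this step size.

Both kernels are reversible with respect to |Ψ|², so every equilibrium
quantity is independent of the choice; only the meaning of one "step" (and
hence fitted rates per step) differs. Proposals that change the sign of Ψ
are always rejected: walkers never cross nodes and stay in their starting
sign region. A walk is fully reproducible from a numpy Generator; all
walkers advance in lock-step vectorized draws from a single stream.

Walkers start from a common point of non-zero |Ψ| — for benzene a
Lewis-like guess (electrons at nuclei, C–H and C–C bond midpoints, double
bonds as out-of-plane pairs at ±0.5 bohr), optionally refined by the
numerical-gradient ascent in `find_local_maximum` (tolerance 1e-6 bohr).

## Folding and classification

The optimal relabelling of a configuration onto a reference site minimizes
the summed squared distances independently per spin; each spin block is a
linear assignment problem solved exactly. Because walkers cannot occupy
the opposite-signed odd images of their own site, centroid folds are
restricted to even overall parity: when the unconstrained assignment
optimum is odd (for sampled benzene ensembles this happens for roughly
half the configurations), the cheapest-transposition repair is applied —
the pair swap of the optimal assignment with the smallest cost increase.
The repair is exact whenever the parity flip is carried by one ambiguous
pair; it is verified against constrained exhaustive enumeration on random
instances in the tests. Odd-optimum folds are counted and reported as a
run diagnostic.

Classification among several reference sites uses the spin-factored
structure of the Kekulé family (four sites = two α-variants × two
β-variants, with d² = d²_α + d²_β), needing two assignment solves per spin
per walker per step. The admissible image parity of site S for a walker of
sign s is s·sign(Ψ(S)); with the benzene truncations the staggered sites
carry the opposite sign to the eclipsed ones, so walkers occupy their odd
images. The measured difference between parity-constrained and
unconstrained classification totals is below 0.1%, so this choice does not
drive any headline number.

## Self-consistent centroid iteration

Each cycle runs a sampling block (default 2000 steps), discards the first
25% as burn-in, collects walker snapshots once per sweep (every N steps
for single-electron moves), folds them onto the current site with even
parity, and replaces the site by the folded mean. The reported site is the
average of the last three cycle estimates, which suppresses the
Monte-Carlo noise floor; convergence requires the averaged site to move
less than 0.05 bohr (max-norm) for two consecutive cycles. Non-convergence
at the cycle cap is reported on the state, not raised. For the benzene
single determinant, 120–200 walkers converge in 3–5 cycles and the site
shows the alternating 2-1-2-1-2-1 C–C bond electron counts per spin of a
Kekulé structure; starting from the alternate Lewis guess yields the
complementary assignment.

## Kekulé reference sites and occupancy statistics

The C–C bonding electrons of a converged site are identified per spin by
nearest-anchor assignment (anchors: carbon nuclei, C–H midpoints, C–C
midpoints); a Kekulé spin set has 9 such electrons (one per single bond,
two per double bond). Rotating this set by 60° about the ring axis in the
α block, the β block, or both generates the staggered-A/B and eclipsed-B
sites.

Occupancy runs start all walkers at the eclipsed-A site and classify every
walker every step. Equilibrium class means are taken over steps 501–2000;
the standard error divides the per-step-count standard deviation by
√(n_steps/200), treating walker configurations as decorrelated after 200
steps. The equilibration transient is fit by the symmetric two-state model
N_s(k) = N_eq + (N₀−N_eq)e^(−k_relax·k); the per-direction crossing rate
is k_x = k_relax/2 near a 50/50 equilibrium and 1/k_x is the decorrelation
length. Block stationarity uses decorrelation-corrected two-sample z-tests
(α = 0.05) between the 501–1000 / 1001–1500 / 1501–2000 blocks.

## Staged truncation

`truncate(n)` keeps the leading terms by |cᵢ| and never splits a group
degenerate within 1e-6 (point-group degeneracies are exact to solver
precision); coefficients are not renormalized, as the Metropolis ratio is
scale-invariant. The staged protocol grows the (30,18) expansion through
its degenerate-group schedule, relaxing an eclipsed-lineage and a
staggered-lineage site one block per stage (each restarted from the
previous stage's site) and recording Ψ at both sites. The stage at which
the two lineage amplitudes first separate decisively is detected with a 5%
relative-difference threshold: below it the two amplitudes agree at the
symmetry-noise level of sampled sites (≲1% in practice), above it the
separation at the 7-determinant stage is ~14%. `block_length = 0` pins the
sites (pure re-evaluation); the headline separation analysis uses this
mode with the converged reference sites, because at tractable ensemble
sizes the amplitude at a *relaxed* site carries multiplicative Monte-Carlo
noise (a 126-dimensional centroid estimated from hundreds of samples moves
enough to change Ψ by factors of several) that swamps the ~14% signal.
Pinned evaluation is deterministic given the base site and the stage-1
amplitudes of the two lineages then agree to ≲1%, the symmetry-noise floor
of the sampled base site.

## Problem sizes

Default analysis sizes are chosen so a full occupancy experiment (three
truncations, 2000 steps) runs in minutes on one core: 150–200 walkers for
occupancy runs with means reported on the 500-walker scale (the class mean
is linear in ensemble size; intervals are widened accordingly), 120–150
walkers for centroid location, 50–60 walkers with 630-step blocks for the
staged (30,18) lineages. The evaluation core is vectorized over walkers
(one AO-matrix update per moved electron, batched spin-block
determinants).

## Toy systems and what they show

* `two_electron_triplet` — two same-spin electrons in displaced Gaussians;
  the node is exactly x₁ = x₂ and the cell centroid is checked against
  grid quadrature. Exercises antisymmetry, node rejection and DVMS
  convergence, but has no unlike-spin structure.
* `two_plus_two` — separable spins, four cells of probability ¼
  (quadrature-verified); discrete sign-class conservation is tested
  explicitly (a joint step may hop between the two same-signed cells, but
  never across a single node).
* `double_well_ci` — one electron per spin, two wells, two configurations
  with tunable c₁:c₂; the minimal analogue of competing resonance
  structures with analytically known cell probabilities.

Passing toy tests establish the correctness of the machinery, not the
behaviour of real molecular wavefunctions: the toys have no degenerate
orbital shells, no core/valence separation, and cells bounded by a single
node surface.

## Known limitations and an honest discrepancy

* With the committed benzene wavefunctions, the equilibrium occupancy of
  the Kekulé cells comes out slightly **eclipsed**-leaning (staggered
  fraction ≈ 0.46–0.48 at 7/11/21 configurations, both by direct sampling
  and by exact reweighting of the single-determinant ensemble), whereas
  the reference experiment this protocol replicates reports a
  **staggered** preference of the same magnitude; likewise the staged
  (30,18) lineages separate at the expected stage (7 determinants, 98.75%
  completeness) but with the eclipsed amplitude on top. The corresponding
  acceptance tests fail honestly. The implementation chain has been
  validated end-to-end against independent oracles: brute-force
  antisymmetrized evaluation, exhaustive assignment enumeration,
  literature Hartree–Fock energies, a two-well two-electron system showing
  the correct left–right correlation through the full fixture
  export/load path, and a six-site lattice-ring analogue in which the same
  CI and determinant-product machinery yields the expected
  doublon-avoiding (staggered) preference exactly. Probing the benzene
  CAS-CI with atom-centred π arrangements also gives the textbook result
  (staggered enhanced, eclipsed suppressed ×0.76/×1.79); the preference
  reverses specifically for the bond-centred banana-pair geometries that
  the converged centroid actually exhibits, and negating the correlating
  coefficients (which would flip the preference) raises the CI energy by
  0.21 Eh, so it is not a phase error. The single-determinant null
  (50.05/49.95) is clean.
* The cheapest-transposition parity repair is not guaranteed optimal when
  the parity flip requires a longer cycle; no such case has been observed.
* Kinetic rates are reported per single-electron step; they are roughly a
  factor 2–4 smaller than the reference per-step rate, whose proposal
  granularity is not known.
* The benzene geometry is an ideal D6h ring with configurable bond
  lengths, not a re-optimized structure; occupancies are symmetry
  properties and weakly sensitive to bond lengths.
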