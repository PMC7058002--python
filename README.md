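# dvms — dynamic Voronoi Metropolis sampling of many-electron wavefunctions

An N-electron wavefunction Ψ(x) lives in 3N dimensions (126 for benzene)
and is antisymmetric under exchange of same-spin electrons, so its
configuration space splits into Nα!·Nβ! equivalent **tiles** related by
like-spin relabellings. One tile contains everything the wavefunction has
to say, and its centroid x̄ — projected onto the three dimensions of each
electron — is a directly interpretable electronic structure: for benzene
it is a Kekulé structure, with alternating one- and two-electron C–C
bonds per spin.

`dvms` implements the full workflow around this idea for CI expansions
Ψ = Σᵢ cᵢ ψᵢ of Slater-determinant products over Gaussian-basis molecular
orbitals:

* signed, vectorized evaluation of Ψ, its truncations (degenerate |cᵢ|
  groups kept as sets) and cumulative completeness Σcᵢ²;
* Metropolis sampling of |Ψ|² with node-crossing rejection (walkers never
  change sign region);
* folding of walkers into the reference tile by the optimal like-spin
  relabelling (a linear assignment problem per spin, restricted to
  even-parity images, with parity bookkeeping);
* the self-consistent centroid iteration x̄ ⇄ R (the "dynamic" part);
* the benzene analysis: four Kekulé reference sites (eclipsed ×2,
  staggered ×2, related by 60° rotations of the C–C bonding electron spin
  sets), on-the-fly walker classification, decorrelation-corrected
  equilibrium occupancies, a two-state kinetic fit, and a staged-truncation
  protocol that follows both Kekulé lineages as configurations are added;
* cross-section exports (Gaussian cube) and site geometry exports (XYZ).

Committed text fixtures provide benzene RHF/6-31G(d) orbitals at an ideal
D6h geometry together with the all-π (6,6) CAS-CI vector and the leading
terms of the valence (30,18) CAS-CI vector, so everything runs without a
quantum-chemistry engine. Analytic toy systems (1–3 electrons per spin,
known nodes, tiles and centroids) back every stage with exact oracles.

## Worked example

```python
import dvms

# geometry + pi-space (6,6) CAS-CI from the committed fixtures
geometry, ci = dvms.load_benzene_ci("cas66")
print(f"terms: {len(ci)}   norm^2: {ci.norm_squared():.6f}")

for n in (1, 7, 11, 21):
    ci_n = ci.truncate(n)
    print(f"truncated to {len(ci_n):3d} determinants: "
          f"completeness {dvms.completeness(ci, ci_n):.4f}")

x_ecl = dvms.lewis_guess(geometry)                  # eclipsed Kekulé guess
x_stag = dvms.lewis_guess(geometry, staggered=True)
print(f"Psi(eclipsed guess)  = {ci.value(x_ecl):+.3e}")
print(f"Psi(staggered guess) = {ci.value(x_stag):+.3e}")
```

prints

```
terms: 400   norm^2: 1.000000
truncated to   1 determinants: completeness 0.9058
truncated to   7 determinants: completeness 0.9667
truncated to  11 determinants: completeness 0.9787
truncated to  21 determinants: completeness 0.9928
Psi(eclipsed guess)  = +2.258e-04
Psi(staggered guess) = -2.056e-04
```

The truncation sizes 7, 11, 21 are degenerate-group boundaries of the
(6,6) vector. The two Lewis-like guesses carry opposite signs of Ψ: the
staggered arrangement differs from the eclipsed one by an odd permutation
composed with a rotation, so walkers reach staggered structures through
odd permutation images of the staggered reference site.

The `dvms` command line drives full runs from a YAML config
(`dvms dvms cfg.yaml`, `dvms occupancy cfg.yaml`, `dvms staged cfg.yaml`,
`dvms cross-sections …`, `dvms verify-fixtures`); every output directory
receives the config copy and per-run metadata.

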