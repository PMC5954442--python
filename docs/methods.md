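# Methods

## The model

A cryo-EM reconstruction reports the *ensemble-averaged* electron density of
a (possibly heterogeneous) population of particles, contaminated by noise
that varies across the map. `cryometa` models this situation with Bayesian
metainference: N replicas of the structural model, X = [X_r], evolve under a
physical prior p(X_r), and the data enter through a Gaussian likelihood on
ensemble-averaged observables,

    p(d_i | X, σ_B, σ_SEM) = N( d_i − f_i(X) ; 0, σ_B² + σ_SEM² ),

where f_i(X) = (1/N) Σ_r f_i(X_r) is the replica average of the forward
model, σ_B is the unknown noise in data point i, and σ_SEM is the
statistical error of estimating the ensemble average with finitely many
replicas.

### Observables: Gaussian-mixture overlaps

The experimental map is condensed into a Gaussian mixture model (the
data-GMM φ_D, components ω_i N(x_i, Σ_i), weights normalized to 1). Each
component is treated as one quasi-independent data point. The observable
attached to component i is its overlap with a density:

    ov(φ, φ_D,i) = ∫ φ(x) φ_D,i(x) dx.

The data value is the self-overlap d_i = ovDD_i = ov(φ_D, φ_D,i); the
prediction is the replica-averaged model overlap f_i = ov̄MD_i. For two
Gaussians the overlap is analytic,

    ov = ω_a ω_b (2π)^{-3/2} det(Σ_a+Σ_b)^{-1/2}
         exp(−½ dᵀ(Σ_a+Σ_b)^{-1} d),   d = μ_a − μ_b,

and a mixture/component overlap is the sum of pair terms. All lengths are
nm; map files in Å are converted at the I/O boundary.

### Forward model

Each heavy atom is one isotropic Gaussian. Its weight and variance come
from a one-Gaussian least-squares fit to the tabulated five-Gaussian
electron atomic scattering factors over spatial frequency 0–0.5 Å⁻¹; with
the convention f(s) = w·exp(−2π²σ²s²) the fitted amplitude is the weight
and σ² = B/(2π²). The fitted per-element table (H, C, N, O, P, S) ships as
`data/scattering_single_gaussian.tsv` and is regenerable with
`forward.fit_single_gaussian_factors`. Coarse-grained beads get one
Gaussian with σ equal to the bead size (proportionality constant 1.0) and a
user-chosen weight.

Only (model particle, data component) pairs whose Gaussian exponent factor
exp(−½ dᵀS⁻¹d) exceeds a cutoff (default 0.01) enter the overlap sums; the
neighbor list is rebuilt every 100 integration steps. The cutoff is applied
to the dimensionless exponent factor — a scale-free convention validated by
a <1% truncation error on the benchmark systems.

### Marginalized score

σ_SEM,i is set proportional to the data point, σ_SEM,i = α·ovDD_i. α = 0.01
is the strongest restraint appropriate for noise-free synthetic maps;
α = 0.1 suits noisy experimental data. Placing a scale-free Jeffreys prior
on the *total* uncertainty σ = √(σ_B²+σ_SEM²) over [σ_SEM, ∞) and
integrating it out (substitute u = 1/σ; the integrand becomes a plain
Gaussian in u) gives the closed-form energy

    E = −k_BT Σ_i log[ (1/(2Δ_i)) · erf( Δ_i / (√2 σ_SEM,i) ) ],
    Δ_i = ovDD_i − ov̄MD_i.

The score is even in Δ_i, harmonic for |Δ_i| ≲ σ_SEM,i and logarithmic for
large |Δ_i|, which automatically down-weights outliers (unexplainable
density). For |Δ|/(√2σ) < 10⁻⁴ the erf ratio is evaluated by its Maclaurin
series; the Δ → 0 limit is 1/(√(2π)σ_SEM). Only energy differences are
meaningful. Forces follow by the chain rule with
∂ov̄_i/∂x_k^r = (1/N)∂ov_i^r/∂x_k and ∂ov/∂μ = −ov·S⁻¹d; they are verified
against central finite differences in the test suite.

The non-marginalized path (explicit σ_B per replica and component, sampled
by Metropolis-within-Gibbs in log σ under a Jeffreys prior on a bounded
support) is provided for completeness; the marginalized path is the
default and is what the applications use.

### Noise inference

After sampling, the per-component noise is estimated a posteriori from the
saved trajectory of deviations Δ_i(t): under the Gaussian likelihood with a
Jeffreys prior on σ_B (support [10⁻⁶, 10³]·ovDD_i, integrated on a log
grid) the posterior median σ̂_B,i is reported together with the relative
error σ̂_B,i/ovDD_i. An error density map distributes these relative errors
over space, weighting by each component's density. The posterior-median
estimator recovers an injected noise scale within 10% from 10⁴ frames (test
suite). Components covering density the model cannot explain acquire large
persistent Δ_i and hence large relative errors — this is how unmodelled
molecules (lipids, detergents) are flagged in real maps.

## Fitting the data-GMM

Voxel centres are weighted by their (negative-clipped) density and a GMM is
fitted by weighted EM (k-means++ initialization, covariance eigenvalues
floored at (voxel/2)² per axis, relative log-likelihood tolerance 10⁻⁶).
High component counts are reached by divide and conquer: fit K₀ = 4
components, partition the voxels by maximum responsibility, re-fit each
partition with 4 children re-weighted by the parent mass, and repeat until
a component budget or target cross-correlation is reached. Because hard
partitions leave boundary artifacts, a final global EM refinement (up to 50
sweeps over the full mixture) polishes the flat result; on the packaged
60-bead two-lobe structure this lifts the 200-component fit from CC ≈ 0.985
to CC ≈ 0.9998.

## Sampling

Replicas evolve in lockstep under overdamped Langevin dynamics,
x ← x + D·F·dt/k_BT + √(2D·dt)·ξ, at T = 300 K with bead diffusion
D = 0.01 nm²/ps and dt = 0.002 ps. The step obeys the stiffest mode of the
toy prior (stability factor k·D·dt/k_BT ≈ 0.5 for the angle terms). The
restraint is recomputed every 2 steps and applied as an impulse scaled by
the stride. Near a perfect fit the marginalized score's harmonic core has
curvature ~(α·ovDD)⁻², far stiffer than the overdamped step resolves, so
the deterministic per-particle drift is trust-region capped at 0.02 nm per
step; the cap only engages during transient relaxation. All randomness
derives from per-replica streams spawned from one master seed, making runs
bit-reproducible.

### Toy prior

The packaged prior is a bead chain with harmonic bonds (b₀ = 0.15–0.18 nm,
k = 1000 kJ/mol/nm²), harmonic angles at π (arms; k = 300 kJ/mol/rad²),
and a quartic double well on the central hinge angle with minima at
π/2 ± 0.6 rad and a 5 kJ/mol barrier. The wells sit symmetrically about
π/2, where the sin θ volume element of the angle coordinate is symmetric,
so equal wells imply equal populations — the prior itself is neutral
between the two states. The planar straight-arm conformers are exact
minima of the potential. The hinge-angle marginal of the ideal chain is
analytic (∝ sin θ · e^{−U(θ)/k_BT}), which the prior-only sampler
reproduces (test suite).

### Metadynamics

Well-tempered metadynamics deposits Gaussian hills on a scalar CV at a
fixed pace, each scaled by exp(−V(s)/k_BΔT), ΔT = (γ−1)T. All replicas
share one bias (multiple walkers), and the bias can be restricted to an
annealing segment (``bias_until``) preceding unbiased production. The
default CV is the replica's own restraint energy; the hinged chain also
exposes the *inter-arm angle* (angle between the two arm end-to-end
vectors) as a CV for driving whole-arm conformational transitions — a
local 3-bead hinge angle is a poor choice, since the chain can satisfy it
with a local kink while the arms, and hence the map overlap, stay put.
Bias on/off consistency of the reweighted well free-energy gap is
verified on the prior-only double well.

## The two-state benchmark

The generator builds a 30-bead hinged chain, rasterizes the open and
closed conformers through the coarse-grained forward model and averages
the two maps with weights (w, 1−w) on a shared grid (voxel 0.12 nm,
~48 voxels across). Three generator choices make the synthetic map behave
like a real one:

* **Bead-resolved heterogeneity.** Bead masses carry a ±30% contrast
  between the arms plus an aperiodic ±15% per-bead modulation (a fixed
  pseudo-random "sequence"). A mass-uniform chain would make the map
  blind to chain reversal and register-shifted fits — degeneracies that
  chemically heterogeneous molecules do not have.
* **Density-bridged states.** The hinge wells sit at π/2 ± 0.4 rad
  (inter-conformer backbone RMSD ≈ 0.5 nm), so the transition path stays
  within the restraint's guidance range, as for a realistic
  conformational change of a few Å RMSD.
* **Matched mass scale.** Bead weights are normalized so the model's
  total mass equals the normalized data-GMM's, making ovDD and ov̄MD
  directly comparable.

A 150-component data-GMM is fitted to the mixture map and, with α = 0.01
and N = 4 replicas, the posterior is explored in three phases:

1. **State refinement** — each prior conformer is relaxed against the map
   by a single-replica run (8000 steps), the analogue of refining a
   deposited starting structure into the density.
2. **Composition selection** — all N+1 assignments of replicas to the two
   refined state models are enumerated, each relaxed for 8000 unbiased
   steps, and the assignment with the lowest settled replica-averaged
   restraint energy is kept. This is where the mixing weights are
   inferred: nothing but the map decides how many replicas settle in each
   state, and the restraint energy separates neighbouring assignments by
   ≳100 kJ/mol, far above the ~10 kJ/mol fluctuation of a relaxation
   mean. Enumeration is exact and cheap because the toy prior has exactly
   two states; for a system with unknown states the sampler's
   well-tempered metadynamics provides the general (stochastic) route to
   the same selection.
3. **Production** — 40000 unbiased steps; frames every 250 steps.

The pooled production frames (first 20% discarded) are clustered with the
GROMOS algorithm at a 0.35 nm backbone-RMSD cutoff; clusters above 10%
population are mapped to the nearest ground-truth conformer by center
RMSD. Recovered populations are the major-cluster fractions; split-half
standard deviations quantify convergence. With injected spurious density
(off-model components ≥1 nm from every bead carrying 10% of the weight)
the same pipeline feeds the noise estimator, and spurious components must
show a several-fold larger relative error than clean ones.

Problem sizes (30 beads, 150 data components, 4 replicas, ~10⁵ steps
across the three phases) were chosen so one full experiment completes in
about two minutes on a single CPU while every qualitative feature of the
full-scale problem — ensemble averaging, state disentanglement,
population inference, noise inference — is retained.

## Analysis components

* Superposition RMSD uses the Kabsch SVD solution with the proper-rotation
  sign fix; an independent quaternion implementation cross-checks it in the
  tests. All-pairs matrices run on batched 3×3 SVDs.
* GROMOS clustering counts neighbors within the cutoff among unassigned
  frames, promotes the most-connected frame to a center, removes the
  cluster, and repeats; ties break to the lowest frame index (determinism).
* Free-energy surfaces are Boltzmann-inverted histograms, −k_BT log p,
  shifted to min 0, with unvisited bins flagged as +∞ and optional frame
  weights for biased data.

## What the synthetic benchmark does and does not show

The generator emulates the *logic* of validating ensemble inference on a
conformational mixture: known ground-truth states, a map that is a genuine
ensemble average, unknown weights, and localized spurious density. It does
not emulate atomistic force fields, solvent, real cryo-EM noise spectra,
B-factor/CTF effects, or map reconstruction artifacts; passing the
benchmark demonstrates the statistical machinery (replica averaging,
marginalized noise model, population and noise recovery), not force-field
accuracy on real proteins.

## Numerical choices and degenerate inputs

* Covariances must have eigenvalues > 10⁻¹⁰ nm² (overlap kernel) and are
  floored at (voxel/2)² in EM fits.
* Negative map values are clipped to zero before fitting (negative voxels
  are reconstruction noise; EM weights must be non-negative).
* Empty neighbor subsets yield zero overlap; a neighbor list older than
  its update interval is refused.
* local/global map correlations clip to [−1, 1]; zero-variance windows
  report 0.
* Forces above 10⁶ kJ/mol/nm trigger one halved step, then an abort with
  diagnostics.

## Known limitations

* The overdamped integrator with a drift cap does not sample the stiff
  harmonic core of the α = 0.01 restraint exactly; the benchmark's claims
  are about state populations and noise assignment, which are insensitive
  to this.
* The composition-selection protocol infers the posterior-preferred
  replica-to-state assignment and largely freezes it for production; with
  N = 4 replicas the recoverable populations are quantized near multiples
  of 1/4 plus production-time fluctuations. Enumerating assignments is
  specific to a prior with a known, small set of states; it is an
  initialization strategy for a desk-scale sampler, not a claim about how
  a full molecular-dynamics stack would traverse the same posterior.
* The divide-and-conquer recursion is a reconstruction (split by maximum
  responsibility, fixed branching, global polish); other splits reaching
  the same CC are possible.
* mmCIF, FSC-based map comparison, sharpening and symmetry averaging are
  out of scope.
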