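# Methods

`confex` quantifies two-state conformational exchange between a major
conformer B and a minor conformer E — the situation of a protein whose
buried/exposed side-chain states interconvert on the µs–ms timescale —
from two complementary directions: relaxation-dispersion NMR
observables, and state-space trajectories analysed with Markov state
models (MSMs) and transition path theory (TPT). This note records the
models, the defaults and why, the numerical choices, and what the
synthetic-data tests do and do not establish.

## Two-state CPMG relaxation dispersion

The observable is the effective transverse relaxation rate
R2,eff(ν_CPMG) = −ln(I/I0)/T_CPMG measured over a constant-time CPMG
element. For two-site exchange B ⇌ E with populations (1−pE, pE),
exchange rate kex = k_BE + k_EB, chemical-shift difference Δω and a
shared intrinsic rate R2,0, transverse magnetization evolves under the
Bloch–McConnell matrix

    L = K − R2,0·I − i·diag(0, Δω),   K = [[−k_BE, k_EB], [k_BE, −k_EB]]

with k_BE = pE·kex. One echo element is δ–π–2δ–π–δ with δ = 1/(4ν);
ideal π pulses act as complex conjugation, so the element propagator is
the matrix P₁·conj(P₂)·P₁ with P₁ = expm(Lδ), P₂ = P₁². T_CPMG·ν must
be a positive integer (one element at the minimum frequency 1/T_CPMG);
incommensurate values are rejected rather than rounded. The returned
rate is −ln(|M_B(T_CPMG)|/(1−pE))/T_CPMG starting from equilibrium
populations. The 2×2 matrix exponential is evaluated in closed form
from the eigenvalues (with a series fallback at degeneracy), batched
over ν.

Approximations, stated once: ideal pulses, in-phase single-quantum
magnetization only, no TROSY/anti-TROSY interconversion, no
off-resonance effects, a single R2,0 per profile shared by both states.

The Carver–Richards closed form is implemented as an independent
analytical route. It is exactly the per-echo asymptotic
(dominant-eigenvalue) decay of the same propagator — verified to agree
with the echo-element spectral radius at machine precision — while the
finite-time propagation retains a transient amplitude term that decays
as 1/T_CPMG and can reach several percent of R2,eff in slow exchange at
experimental T_CPMG (~20 ms). The cross-validation test therefore
compares the two routes in the long-train regime (T_CPMG = 0.5 s) where
their domains of validity coincide; the difference at short T_CPMG is
finite-duration physics, not numerical error. The `arccosh` in the
closed form is evaluated on the complex plane and the real part taken,
which handles the argument dipping below 1 in near-degenerate regimes.

### Global fitting

All profiles at one temperature are fit together: global (kex, pE),
one Δω per residue in ppm (so profiles at different fields share it;
conversion uses |γ(¹⁵N)| = 2.71262e7 and |γ(¹H)| = 2.67522e8
rad s⁻¹ T⁻¹), and one R2,0 per profile. The objective is
Σ((R2,eff − model)/σ)², minimized with a trust-region reflective
least-squares solver, multi-started over kex ∈ {500, 2000, 8000} s⁻¹ ×
pE ∈ {0.01, 0.05, 0.2} with the lowest χ² kept. The sign of Δω is not
identifiable from CPMG data, so Δω ≥ 0 is imposed. A dataset whose
dispersion amplitude is indistinguishable from zero (pE·Δω² ≈ 0) is
flagged `unidentifiable` instead of being silently returned.

Uncertainties come from a residual-resampling bootstrap: standardized
residuals are pooled, inflated by √(n/(n−p)) to undo the deflation of
fitted residuals, resampled, rescaled by each point's σ and added to
the fitted model; each replicate is refit from the converged solution.
In a 100-repeat calibration at the fixture noise level the central 95%
interval covers the generating kex ≳ 94% of the time. Single-field
data leaves pE and Δω nearly degenerate (replicates drift toward the
pE = 0.5 boundary); the calibration fixture therefore uses two fields
(11.7 and 18.8 T), the standard experimental remedy.

## Thermokinetics

Directional rates follow from k_BE = pE·kex and k_EB = (1−pE)·kex,
with first-order error propagation. Each direction is fit to
ln k = ln A − Ea/(R·T) by weighted least squares (weights 1/σ_lnk²,
σ_lnk = σ_k/k); weighting matters because the low-temperature pE
errors are strongly heteroscedastic and an unweighted fit visibly
shifts ΔH. With σ supplied the parameter covariance is the known-σ
expression (XᵀWX)⁻¹; without σ it is scaled by the residual variance.
R = 8.314 J mol⁻¹ K⁻¹; temperatures are converted as K = °C + 273.15
exactly; k_BT(310.15 K) = 2.578 kJ mol⁻¹ is used for k_BT-denominated
outputs.

Equilibrium thermodynamics (E relative to B): ΔH = Ea(B→E) − Ea(E→B),
ΔG(T) = −RT·ln(k_BE/k_EB), ΔS = (ΔH − ΔG)/T. ΔH‡ is reported as the
Arrhenius Ea of k_BE; the Ea − RT variant is a documented option, with
Ea the default since the underlying fit form of the experimental
analysis is not uniquely determined. Extrapolation errors use the
delta method, with an optional seeded parametric Monte Carlo (default
10⁴ draws) as a cross-check.

The activation free energy uses the transition-path-time rate relation

    k = (2 τ_TPT)⁻¹ · exp(−ΔG‡ / k_BT)

whose pre-exponential factor (2τ_TPT)⁻¹ ~ 10⁷ s⁻¹ is appropriate for
collective conformational transitions; the Eyring prefactor k_BT/h
~ 6×10¹² s⁻¹ describes bond vibrations and overestimates such barriers
by >10 k_BT. An Eyring-based estimate is provided only as a flagged
comparison. 2kτ ≥ 1 is reported as a `barrierless` flag, not an
exception. ΔS‡ = (ΔH‡ − ΔG‡)/T.

## Markov state models

Frames are assigned to microstates by seeded k-means; the minimal
superposition utility (Kabsch, SVD with proper-rotation correction) is
provided for RMSD-type features. Counts C_ij at lag τ use sliding
windows and never cross trajectory boundaries. States outside the
largest strongly connected component are trimmed and reported; an
ambiguous largest component is an error, not a guess.

The reversible estimator row-normalizes (C+Cᵀ)/2, which satisfies
detailed balance by construction with π proportional to the
symmetrized row sums, and yields a real spectrum via symmetrization by
√π. This closed form is adequate for well-sampled, equilibrium-start
synthetic data; the maximum-likelihood detailed-balance iteration is a
known extension and would be needed for enrichment-biased sampling
(see the protocol note below). The non-reversible estimator
row-normalizes C directly with π from the leading left eigenvector.
Implied timescales are t_i = −τ/ln λ_i (i ≥ 2); t₁ is infinite;
eigenvalues at 1 within 1e-12 report an infinite timescale, complex or
non-positive ones a NaN flagged per entry. Eigenvalue ordering is a
stable descending sort with a deterministic eigenvector sign
convention. Populations propagate as P(nτ) = P(0)·T(τ)ⁿ.

Macrostate lumping is spectral (PCCA+-style): the top n right
eigenvectors span a simplex whose vertices are found by the
inner-simplex index search, memberships follow from the vertex-matrix
inverse, and assignment is crisp argmax. A missing spectral gap or
complex eigenvalue at the cut attaches a warning. The
Chapman–Kolmogorov test compares model predictions P(nτ) against
direct estimates at lag nτ, weighting each state set by its empirical
start counts so the n = 1 entry is exactly self-consistent for the
non-reversible estimator.

Two-state reduction takes kex = 1/t₂ (the slowest implied timescale)
and pE = π(E)/(π(E)+π(B)) over caller-defined state sets, with
bootstrap σ over whole-trajectory resampling. Free-energy surfaces
reweight each frame by π(its microstate)/(frames in that microstate),
so the surface reflects the model's stationary distribution rather
than raw sampling; F = −k_BT·ln(histogram), minimum at zero, empty
bins +∞; 1-D projections sum probability, not F.

## Transition path theory

Forward committors solve (I − T_II)q = T_IB·1 on the intermediates
with q(A) = 0, q(B) = 1, after an explicit reachability check that
names states from which the sink is unreachable. Backward committors
use the time-reversed chain and equal 1 − q⁺ for reversible models.
Reactive flux is f_ij = π_i·q⁻_i·T_ij·q⁺_j (i ≠ j), net flux
max(f − fᵀ, 0); divergence-free at intermediates. Pathways are peeled
off by deterministic widest-path (max-bottleneck) search — a modified
Dijkstra with lexicographic tie-breaks — subtracting each bottleneck
flux until the accumulated fraction reaches `stop_fraction` (default
0.999). Transition-path durations are extracted from labeled
trajectories as last-exit-from-source to first-entry-to-sink, with
strict set membership by default and a disc-core helper for
continuous trajectories; forward and backward segments are pooled and
tagged.

## Synthetic data: what it emulates and what it does not

Every generator is a pure function of (specification, seed).

**Dispersion datasets** apply the Bloch–McConnell forward model and add
homoscedastic Gaussian noise to R2,eff. The default σ of 0.3 s⁻¹ is a
fixture choice (a plausible repeat-measurement error for well-resolved
amide data); no canonical value exists, and a per-point σ column
override is supported. Not emulated: peak overlap, baseline and phase
errors, pulse imperfections, TROSY selection — so passing recovery
tests shows the fitting machinery is correct, not that real spectra of
arbitrary quality would yield these uncertainties.

**Markov trajectories** are sampled exactly from a rate or transition
matrix. The 19-state fixture places a minor E well (state 0), a major
four-state B block (15–18) and shallow intermediate traps on a chain
with cross-links, with rates k_ij = exp(−(B_ij − E_i)) from a
detailed-balanced energy/barrier table, globally rescaled so the
slowest relaxation time is exactly 3 µs at a frame interval of 7.5 ns.
Its stationary minor-state fraction is ≈1.6%.

The recovery protocol for this fixture — 20 equilibrium-start
trajectories of 933 steps (≈140 µs aggregate), symmetrized reversible
estimation at lag 22.5 ns — was chosen by an explicit power analysis:
at 3 µs relaxation, 140 µs of data contains at most ~46 relaxation
units, so any estimator of kex carries ≳14% relative standard error;
the measured protocol error is +4% ± 14.5%. A 15% recovery check at
this data volume is therefore a ~1σ statement and can fail for an
unlucky realization; that is a property of the data volume, not of the
estimator. Enriched minor-state starts (the strategy a simulation
study would use) were evaluated and rejected here because they bias
the symmetrized estimator's stationary vector, while the
non-reversible estimator that tolerates them has larger timescale
variance.

**Langevin trajectories** integrate overdamped dynamics
x ← x − (D/k_BT)∇U·dt + √(2D·dt)·η (Euler–Maruyama, numba-compiled,
noise from a seeded internal generator) on potentials built from
Gaussian wells plus harmonic confinement. The scheme's stationary
error is controlled by the precondition dt·|∇²U|·D/k_BT < 0.1 at the
stiffest well; escape beyond the confining region raises an unstable-dt
error. The rugged fixture (versioned YAML) has two deep wells (E, B)
and two shallow intermediate traps; the symmetric double-well fixture
(depth 6.5 k_BT, width 0.35, confinement 1.0) is used for barrier
tests. Its reference barrier is the y-integrated 1-D potential of mean
force computed by quadrature — for a 2-D landscape this, not the bare
saddle energy along the connecting line, is what a 1-D rate relation
can recover; the two differ by the transverse-width entropy
(≈1.8 k_BT here). With cores of radius 0.5 around the well centers,
the rate/τ_TPT inversion recovers this barrier to well within 1 k_BT
(typically ~0.5 k_BT) across seeds.

## Problem sizes used in the test suite

The suite runs the full analysis at sizes a laptop handles in minutes:
140 µs-equivalent Markov data (≈19k frames), 2×10⁶ Langevin steps
(~80 barrier crossings), and a 100-repeat bootstrap calibration with
50 replicates per repeat on two-field, two-residue datasets. These
sizes were chosen so each check retains its statistical meaning —
larger data would tighten the checks but not change what they test.

## Known limitations

- No three-state or CEST/R1ρ exchange models; no TROSY interference.
- Reversible estimation by symmetrization assumes near-equilibrium
  sampling; no maximum-likelihood reversible estimator yet.
- PCCA+ uses crisp assignment; fuzzy memberships are discarded.
- The pathway decomposition is deterministic bottleneck subtraction;
  path counts depend on the state-space resolution and the stop
  fraction, so only within-fixture comparisons are meaningful.
- The Langevin integrator is 2-D and overdamped by design.
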