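# Methods

## The surrogate bridge model

The package analyses proton dynamics in intramolecular O–H···O bridges.
Real source data for such analyses are ab initio MD trajectories; to make
every stage testable at desk scale, `hbridge.model` provides a surrogate
with the same statistical structure.  Each bridge is reduced to two
coordinates — the donor–proton distance r and the donor–acceptor distance
R — moving on

    V_b(r, R) = D_d [1 − exp(−a_d (r − ρ))]²
              + D_a [1 − exp(−a_a (R − r − ρ))]²
              + k_R/2 (R − R₀)²,

with a bilinear inter-bridge coupling λ_c q₁ q₂ in the signed Voronoi
coordinates q_b = r_b − R_b/2.  The first Morse well is the covalent O–H
bond, the second is the O–H bond of the proton-transferred tautomer, and
the harmonic term stands in for everything that holds the O···O distance
near its equilibrium (ring strain, crystal packing).  The model is **not**
a fit to any quantum-chemical surface; it is the simplest form that
reproduces the qualitative features that matter for the analyses: a deep
donor-side minimum near r ≈ 1 Å, a shallow acceptor-side minimum, a barrier
of a few kcal/mol that falls as the bridge compresses, and O···O breathing
around 2.55 Å.

### Parameter calibration

Two facing Morse wells that share one equilibrium length ρ interact
strongly: both terms relax simultaneously when R → 2ρ, which pulls the
bridge inward with a force of order 10² kcal/mol/Å.  The harmonic constant
k_R must be stiff enough to resist this, and R₀ then sits well above the
observed mean bridge length.  The shipped defaults were calibrated once,
by 2D Boltzmann quadrature at 295 K, to land in the regimes a
Car–Parrinello simulation of a naphthazarin-like system shows:

| preset | D_d | D_a | a | ρ | k_R | R₀ | λ_c | behaviour at 295 K |
|---|---|---|---|---|---|---|---|---|
| `gas_phase` (default) | 110 | 107.6 | 3.1 | 0.98 | 450 | 2.796 | −2 | barrier 5.0 kcal/mol at R = 2.55, deep min 1.05 Å, ~89% donor residence, ⟨R⟩ = 2.550 ± 0.071 Å, harmonic νOH ≈ 3290 cm⁻¹ |
| `solid_state` | 110 | 110 | 3.1 | 0.98 | 450 | 2.803 | −2 | symmetric wells: ~50/50 proton sharing (strongly delocalized regime) |
| `low_barrier` | 110 | 107.4 | 3.0 | 0.99 | 500 | 2.789 | 0 | barrier 3.2 kcal/mol; uncoupled, for quadrature comparisons |

(energies kcal/mol, lengths Å, a in Å⁻¹, k in kcal mol⁻¹ Å⁻².)  Masses are
the bare proton (1.0078 amu) for r and half an oxygen mass (7.9997 amu) as
an effective breathing mass for R.  `characterize_model` (dense grid scan
with parabolic refinement) is the tool that validates any parameter set.

### Dynamics

BAOAB Langevin splitting with an exact Ornstein–Uhlenbeck noise step; per
step one Gaussian draw per degree of freedom in the fixed order
(r₁, R₁, r₂, R₂) from a single `numpy` PCG64 stream seeded from
`settings.seed`, so trajectories are reproducible to the bit on a given
platform.  Defaults: 295 K, friction 1 ps⁻¹, dt = 0.25 fs (resolves a
3400 cm⁻¹ oscillation with >30 samples per period; the Verlet frequency
warp at ω dt ≈ 0.15 is below 0.1%), 10 000 discarded equilibration steps,
21 ps production.  BAOAB samples the configurational Boltzmann density with
O(dt²) bias, which at these settings is far below the Monte-Carlo noise of
any run we perform; the 1 ns acceptance run reproduces quadrature
possession fractions to better than one percentage point.

The initial state is the donor-side minimum with Maxwell–Boltzmann
velocities; the discarded equilibration removes the dependence on it.
The output stride is a free choice (the source trajectories this emulates
do not document theirs) and is recorded in the run manifest.

## What the surrogate does and does not emulate

It reproduces: double-well proton potentials whose barrier and asymmetry
respond to R, ~90% donor residence (gas-like) down to 50/50 (symmetric
preset), O···O oscillation near 2.55 Å, νOH spectral weight in the
2200–3400 cm⁻¹ region, correlated double-bridge motion with the
same-site quadrants favoured for λ_c < 0, and proton-transfer events as
crossings of the Voronoi midplane.  It omits: all electronic structure,
the remaining 3N−8 molecular modes (so spectra contain only the two model
modes, not the 700–1700 cm⁻¹ heavy-atom region a full simulation shows),
periodic boundary conditions and genuine crystal environments, and any
quantitative claim about specific compounds.  Green tests therefore show
the analysis chain is correct on Boltzmann-exact double-well data, not
that a particular molecule behaves this way.

## Analysis conventions

- **Voronoi possession**: donor frame ⇔ d_DH < d_HA.  Exact ties are
  counted as donor and reported separately (a measure-zero event kept
  explicit rather than ambiguous).  Fractions are exact complements.
- **Transfer events**: sign changes of s = d_DH − d_HA whose new sign
  persists at least `min_dwell` (default 10 fs ≈ one O–H vibrational
  period); shorter recrossings are counted as barrier recrossings, not
  events.  There is no community-standard numerical definition of a
  "proton-sharing event"; this operationalization is flagged in reports.
- **Joint histograms**: default 0.02 Å bins over [0.8, 1.8] Å; out-of-range
  samples accumulate in edge bins (logged) so the density mass is exactly 1.
- **Synchronicity**: quadrant occupancies of (q₁, q₂); the center region
  |q_b| < ε on both bridges (default ε = 0.05 Å, a free choice) is the
  signature a synchronous double transfer would leave.
- **VACF/spectra**: C(k) is estimated over all time origins (FFT method)
  and normalized to C(0) = 1.  The windowed one-sided VACF (default Hann
  lag window, max_lag = min(2048, N/2)) is extended evenly to N = 2L − 2
  samples and cosine-transformed, which makes the spectrum exactly real
  and Parseval-exact; wavenumbers are j/(c N dt) with resolution
  1/(c N dt).  Tiny negative bins from the windowed estimator are clipped
  and logged.  Band regions: bins ≥ 5% of the maximum, gaps ≤ 50 cm⁻¹
  merged — both thresholds are conventions, recorded in output metadata.
- **Scan analysis**: barriers are read from the discrete points only; the
  uncertainty is half the largest energy step between the discrete maximum
  and its neighbours, i.e. the resolution the scan itself supports near
  the transition state.  A 3-point parabolic refinement is available but
  clearly labelled, since discrete-accuracy values are the convention for
  reported scan barriers.  Profiles are analysed relative to the deep
  minimum, so the analysis is invariant under constant energy shifts.

## The NQE workflow

Five snapshots (endpoint-inclusive, constant frame intervals — whether the
source protocols include endpoints is not documented; this convention is
ours) are reduced to donor/proton/acceptor coordinates.  Proton scan
positions lie on the circle through the three atoms — the arc accounts for
the bent O–H···O path — parameterized by donor distance, uniformly spaced
on [0.80, d_OO − 0.80] Å with N = 16 + clamp(round((d_OO − 2.40)/0.05),
0, 4) points (16 for compressed bridges up to 20 for long ones).  The
margins and count rule are config-overridable.

The profile is fitted with a 9th-degree polynomial in the conditioned
coordinate u = (d − d_mid)/half-range.  Outside the sampled range the
potential continues as V(endpoint) + κ (d − endpoint)² with κ =
200 kcal mol⁻¹ Å⁻² — a degree-9 polynomial extrapolates to ±∞, and the
wall guarantees confinement on the solver domain without touching the
fitted region (continuous, though not C¹, at the joins).

The vibrational Schrödinger equation is solved on 400 uniform interior
points of (0.7, 2.0) Å with Dirichlet walls.  The kinetic operator is the
sine-DVR (Colbert–Miller) matrix, built from its spectral definition
T = F diag(k_n²/2m) Fᵀ with box momenta k_n = nπ/L — exact for box states
and spectrally accurate for smooth potentials (grid doubling moves the
lowest three levels by < 10⁻⁸ cm⁻¹ on the test wells).  Internal units are
atomic (1 hartree = 627.509474 kcal/mol = 219474.6313632 cm⁻¹, 1 bohr =
0.529177210903 Å, 1 amu = 1822.888486 mₑ).  The particle mass defaults to
the bare proton, and the thermal average uses Boltzmann weights over the
three lowest levels at 295 K; both are interpretive choices (a reduced
O–H mass and other weighting schemes are defensible) and are exposed as
settings.  A warning is emitted when the ground state puts more than 10⁻³
probability in the outermost grid points, which signals a non-confining
potential at a boundary.

## Degenerate inputs and tie-breaks

Non-physical geometries (r ≤ 0, R ≤ r) raise domain errors; integrator
divergence aborts with the step number; XYZ parse errors name the frame or
line; profiles that are monotone or single-welled are flagged instead of
analysed; colinear arc geometries degenerate to the straight segment
(tolerance 10⁻⁶ Å off the chord); zero-variance velocities make the VACF
normalization undefined and raise.

## Problem sizes

The test suite and the acceptance script use: 2 ps runs for smoke and
pipeline tests, 20 ps at 15 K for the harmonic-regime spectral check
(cold enough that anharmonic softening stays below one resolution
element), 60–100 ps for statistical sanity checks, and a single 1 ns
low-barrier run (stride 10, 4×10⁵ frames) for the quadrature comparison —
chosen so the donor-fraction Monte-Carlo error (~1 pp) sits well inside
the ±5 pp assertion band.  The vibrational solver runs at its default 400
points; the independent finite-difference cross-check uses 3000 points.

## Known limitations

- The spectra of the surrogate contain only two modes per bridge; band
  shapes are not comparable to full vibrational spectra.
- The NQE treatment is 1D and adiabatic: heavy-atom relaxation along the
  proton path and multidimensional tunneling are outside its scope.
- The quadratic continuation of fitted potentials is not differentiable at
  the sampled-range boundary; eigenvalues are insensitive to this kink in
  practice, but a C¹ continuation would be needed for force-based uses.
- `TableBackend` requires exact distance matches; it is an exchange
  format for externally computed single points, not an interpolator.
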