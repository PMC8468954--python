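# hbridge

Analysis toolkit for the dynamics of intramolecular O–H···O hydrogen
bridges of the kind found in naphthazarin-type chelate rings: proton
transfer statistics from molecular-dynamics trajectories, vibrational power
spectra, discrete proton-potential scans, and an a posteriori estimate of
nuclear quantum effects (NQE) on the bridge proton.

It is aimed at people who have (or want to emulate) ab initio MD
trajectories of medium-strong hydrogen bonds and need the standard
post-processing chain as tested, reusable code:

- **`hbridge.model`** — a surrogate two-bridge Hamiltonian and Langevin
  sampler.  Each bridge is reduced to the donor–proton distance *r* and the
  donor–acceptor distance *R* with potential

  V(r, R) = D_d [1 − e^(−a_d (r−ρ))]² + D_a [1 − e^(−a_a (R−r−ρ))]² + ½ k_R (R−R₀)²,

  two facing Morse wells (covalent O–H and the proton-transferred form)
  plus a harmonic bridge-breathing term; the bridges couple through
  λ_c q₁ q₂ with q = r − R/2.  BAOAB Langevin dynamics at 295 K generates
  trajectories whose configurational statistics are Boltzmann, so every
  analysis stage can be validated against direct quadrature.
- **`hbridge.io`** — multi-frame XYZ read/write (with a velocity companion
  file), central-difference velocity derivation, bridge atom selection.
- **`hbridge.dynamics`** — distance time series, Voronoi proton-possession
  statistics (the proton belongs to the donor while d(D–H) < d(H–A)),
  dwell-filtered proton-transfer events, joint donor–proton histograms and
  double-transfer synchronicity quadrants.
- **`hbridge.spectra`** — velocity autocorrelation functions and their
  cosine-transform power spectra, plus absorption band-region extraction.
- **`hbridge.scan`** — uniform-increment proton-potential profiles (default
  0.05 Å) and discrete two-minimum/barrier analysis with a half-step
  uncertainty.
- **`hbridge.nqe`** — snapshot extraction, arc-based proton path generation
  (16–20 points depending on bridge length), 9th-degree polynomial
  potential fits, a sine-DVR grid solution of the 1D vibrational
  Schrödinger equation (400 points on 0.7–2.0 Å) and the 295 K thermal
  expectation ⟨r⟩ over the three lowest levels.

## Worked example

```python
import hbridge as hb

params = hb.ModelPotentialParams.gas_phase()
settings = hb.SimulationSettings(seed=7, production_length=21.0, output_stride=4)
run = hb.simulate_bridges(params, settings)      # 21 ps, 295 K
traj = hb.embed_trajectory(run)                  # 6-atom XYZ representation

ch = hb.characterize_model(params, R_fixed=2.55)
b1 = hb.BridgeDefinition(0, 1, 2, label="O8-HBP1...O1")
s1 = hb.compute_bridge_series(traj, b1)
stats = hb.possession_statistics(s1)
events = hb.detect_transfer_events(s1, min_dwell=10.0)

spec = hb.power_spectrum(hb.velocity_autocorrelation(run.v_r, max_lag=2048),
                         dt=1.0)                 # 0.25 fs x stride 4
report = hb.nqe_report(traj, b1, hb.ModelArcBackend(params), n_snapshots=5)
```

printed (seed 7):

```
barrier  = 5.03 kcal/mol, deep minimum at 1.049 A, asymmetry 1.44 kcal/mol
O8-HBP1...O1: donor 92.8% / acceptor 7.2%, 74 transfer events, <d_OO> = 2.555 A
proton spectrum peak: 3186 cm^-1 (resolution 8.1 cm^-1)
 time_fs  d_OO_A  classical_d_DH_A  quantum_r_A
     0.0   2.532             1.044        1.193
  5250.0   2.603             1.064        1.127
 10500.0   2.584             1.024        1.144
 15750.0   2.596             1.048        1.132
 21000.0   2.545             1.041        1.183
```

Reading the numbers: the default (gas-like) parameterization is an
asymmetric double well — a 5 kcal/mol barrier with the deep minimum on the
donor side near 1 Å — so the proton resides at the donor roughly 90% of the
time and crosses back and forth in short-lived transfer events.  The proton
velocity power spectrum peaks near 3200 cm⁻¹ (the νOH stretch region of a
medium-strong hydrogen bond), and the quantum expectation value of the
donor–proton distance is systematically larger than the classical value —
zero-point motion delocalizes the proton toward the bridge midpoint.

The same operations are available from the shell:

```sh
hbridge simulate --preset gas --seed 7 --length 21 --out run
hbridge possession --traj run.xyz --vel run.vel.xyz --dt 0.25 --bridge 0,1,2
hbridge spectrum --traj run.xyz --vel run.vel.xyz --dt 0.25 --atoms 1,4 --out spec.csv
hbridge scan generate --R 2.55 --start 0.80 --n 20 --inc 0.05 --out scan.csv
hbridge scan analyze --profile scan.csv
hbridge nqe run --traj run.xyz --dt 0.25 --bridge 0,1,2 --out nqe.csv
```

Externally computed proton potentials (e.g. from DFT scans) enter through
the CSV dialect `distance_A,energy_kcal_mol` accepted by `scan analyze` and
`hbridge.scan.load_profile_csv`.

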