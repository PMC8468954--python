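"""Surrogate two-bridge proton-transfer model and Langevin propagator.

The model stands in for an ab initio potential energy surface of a molecule
with two intramolecular O-H...O bridges.  Each bridge is reduced to two
coordinates: the donor-proton distance r and the donor-acceptor distance R.
The per-bridge potential is a pair of facing Morse wells (covalent O-H on the
donor side, O-H formed after proton transfer on the acceptor side) plus a
harmonic restraint on the bridge length,

    V_b(r, R) = D_d [1 - exp(-a_d (r - rho))]^2
              + D_a [1 - exp(-a_a (R - r - rho))]^2
              + k_R/2 (R - R_0)^2,

and the two bridges talk through a bilinear coupling of their signed Voronoi
coordinates q_b = r_b - R_b/2 (negative while the proton is on the donor
side):

    V_c = lambda_c q_1 q_2.

For suitable parameters V_b has a deep donor-side minimum near r ~ 1 Å, a
shallow acceptor-side minimum and a barrier of a few kcal/mol, which is the
qualitative structure seen in quantum-chemical proton-potential scans of
naphthazarin-type chelate rings.  Dynamics is sampled with a BAOAB Langevin
splitting at a given temperature, so long trajectories are Boltzmann
distributed over (r, R) and can be checked against direct quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .constants import KB_KCAL, KCAL_TO_AMU_A2_FS2

__all__ = [
    "ModelPotentialParams",
    "SimulationSettings",
    "ReducedTrajectory",
    "ModelCharacterization",
    "IntegratorDivergence",
    "evaluate_model_potential",
    "characterize_model",
    "boltzmann_bridge_statistics",
    "boltzmann_quadrant_occupancy",
    "simulate_bridges",
    "embed_trajectory",
    "write_manifest",
]


class IntegratorDivergence(RuntimeError):
    """Raised when the Langevin integrator produces non-finite coordinates."""


@dataclass(frozen=True)
class ModelPotentialParams:
    """Parameters of the two-bridge surrogate Hamiltonian.

    Energies in kcal/mol, lengths in Å, masses in amu.  The defaults are the
    calibrated gas-like parameter set: at 295 K they give a double-well proton
    profile with a ~5 kcal/mol barrier at R = 2.55 Å, a deep minimum near
    1.05 Å, ~89% donor-site residence and an O···O distribution centred on
    2.55 Å with 0.07 Å spread.
    """

    D_d: float = 110.0        # donor-well Morse depth
    a_d: float = 3.1          # donor Morse range, 1/Å
    D_a: float = 107.6        # acceptor-well Morse depth
    a_a: float = 3.1          # acceptor Morse range, 1/Å
    rho: float = 0.98         # equilibrium covalent O-H distance, Å
    k_R: float = 450.0        # donor-acceptor harmonic constant, kcal/mol/Å^2
    R_0: float = 2.796        # harmonic-term equilibrium bridge length, Å
    lambda_c: float = -2.0    # inter-bridge bilinear coupling, kcal/mol/Å^2
    m_H: float = 1.0078       # proton mass, amu
    m_R: float = 7.9997       # effective bridge-breathing mass, amu

    def __post_init__(self) -> None:
        for name in ("D_d", "D_a", "a_d", "a_a", "k_R", "m_H", "m_R"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if 2.0 * self.rho >= self.R_0:
            raise ValueError(
                f"need 2*rho < R_0, got rho={self.rho}, R_0={self.R_0}"
            )

    # -- presets ---------------------------------------------------------
    @classmethod
    def gas_phase(cls) -> "ModelPotentialParams":
        """Asymmetric double well, ~90% donor residence (gas-like regime)."""
        return cls()

    @classmethod
    def solid_state(cls) -> "ModelPotentialParams":
        """Symmetric double well (equal Morse depths): ~50/50 proton sharing,
        emulating the strongly delocalised solid-state regime."""
        return cls(D_a=110.0, R_0=2.803)

    @classmethod
    def low_barrier(cls) -> "ModelPotentialParams":
        """Softer, uncoupled parameterization with a ~3 kcal/mol barrier.

        lambda_c = 0 so each bridge is an independent 2D system; used when
        comparing sampled statistics against 2D Boltzmann quadrature.
        """
        return cls(D_a=107.4, a_d=3.0, a_a=3.0, rho=0.99, k_R=500.0,
                   R_0=2.789, lambda_c=0.0)

    def replace(self, **kw) -> "ModelPotentialParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SimulationSettings:
    """Langevin run settings: 295 K, 0.25 fs step, 21 ps production and a
    10 000-step discarded equilibration by default."""

    temperature: float = 295.0          # K
    time_step: float = 0.25             # fs
    friction: float = 1.0               # 1/ps
    n_equilibration_steps: int = 10000
    production_length: float = 21.0     # ps
    seed: int = 0
    output_stride: int = 1              # store every n-th production step

    def __post_init__(self) -> None:
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if self.production_length <= 0:
            raise ValueError("production_length must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.n_equilibration_steps < 0:
            raise ValueError("n_equilibration_steps must be >= 0")
        if self.output_stride < 1:
            raise ValueError("output_stride must be >= 1")

    @property
    def n_production_steps(self) -> int:
        return int(round(self.production_length * 1000.0 / self.time_step))

    def replace(self, **kw) -> "SimulationSettings":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class ReducedTrajectory:
    """Time series of the reduced coordinates of both bridges.

    Arrays have shape (n_frames, 2); column b is bridge b+1.  Velocities are
    in Å/fs.  Construction enforces 0 < r < R on every frame.
    """

    time: np.ndarray            # fs, absolute
    r: np.ndarray               # donor-proton distances
    R: np.ndarray               # donor-acceptor distances
    v_r: np.ndarray
    v_R: np.ndarray
    params: ModelPotentialParams
    settings: SimulationSettings

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("r", "R", "v_r", "v_R"):
            a = getattr(self, name)
            if a.shape != (n, 2):
                raise ValueError(f"{name} must have shape ({n}, 2), got {a.shape}")
        if not (np.all(self.r > 0) and np.all(self.r < self.R)):
            bad = int(np.argmax(~((self.r > 0) & (self.r < self.R)).all(axis=1)))
            raise ValueError(f"frame {bad}: reduced state violates 0 < r < R")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def voronoi_coordinate(self) -> np.ndarray:
        """Signed Voronoi coordinate q = r - R/2 per bridge, shape (n, 2)."""
        return self.r - 0.5 * self.R


# ---------------------------------------------------------------------------
# potential
# ---------------------------------------------------------------------------

def _bridge_potential(params: ModelPotentialParams, r, R):
    ed = np.exp(-params.a_d * (np.asarray(r, float) - params.rho))
    ea = np.exp(-params.a_a * (np.asarray(R, float) - np.asarray(r, float) - params.rho))
    return (params.D_d * (1.0 - ed) ** 2
            + params.D_a * (1.0 - ea) ** 2
            + 0.5 * params.k_R * (np.asarray(R, float) - params.R_0) ** 2)


def evaluate_model_potential(params: ModelPotentialParams, r, R):
    """Single-bridge potential V_b(r, R) in kcal/mol.

    Accepts scalars or broadcastable arrays.  Raises ``ValueError`` for
    non-physical geometries (r <= 0 or R <= r).
    """
    r = np.asarray(r, float)
    R = np.asarray(R, float)
    if np.any(r <= 0) or np.any(R <= r):
        raise ValueError("non-physical arguments: require 0 < r < R")
    out = _bridge_potential(params, r, R)
    return float(out) if out.ndim == 0 else out


def coupling_energy(params: ModelPotentialParams, r1, R1, r2, R2):
    """Inter-bridge coupling lambda_c * q1 * q2, q_b = r_b - R_b/2."""
    q1 = np.asarray(r1, float) - 0.5 * np.asarray(R1, float)
    q2 = np.asarray(r2, float) - 0.5 * np.asarray(R2, float)
    return params.lambda_c * q1 * q2


@dataclass(frozen=True)
class ModelCharacterization:
    """Double-well structure of the proton profile at fixed bridge length."""

    R_fixed: float
    single_minimum: bool
    r_min_deep: float
    e_min_deep: float
    r_min_shallow: float | None = None
    e_min_shallow: float | None = None
    r_barrier: float | None = None
    barrier: float | None = None      # E(max) - E(deep), kcal/mol
    asymmetry: float | None = None    # E(shallow) - E(deep), kcal/mol


def characterize_model(params: ModelPotentialParams, R_fixed: float,
                       n_grid: int = 20001, margin: float = 0.6,
                       ) -> ModelCharacterization:
    """Locate minima and barrier of V(r; R_fixed) by dense grid scan.

    The scan covers r in [margin, R_fixed - margin]; local extrema are
    refined with a parabolic fit through the bracketing grid points.  If the
    profile has a single minimum the result carries ``single_minimum=True``
    and no barrier.
    """
    if R_fixed <= 2 * margin:
        raise ValueError("R_fixed too small for the scan window")
    rr = np.linspace(margin, R_fixed - margin, n_grid)
    vv = _bridge_potential(params, rr, R_fixed)

    interior = np.arange(1, n_grid - 1)
    is_min = (vv[interior] < vv[interior - 1]) & (vv[interior] <= vv[interior + 1])
    mins = interior[is_min]

    def _refine(i: int) -> tuple[float, float]:
        # parabola through (i-1, i, i+1)
        x = rr[i - 1:i + 2]
        y = vv[i - 1:i + 2]
        denom = (y[0] - 2 * y[1] + y[2])
        if denom == 0:
            return float(rr[i]), float(vv[i])
        h = rr[1] - rr[0]
        dx = 0.5 * h * (y[0] - y[2]) / denom
        c = np.polyfit(x, y, 2)
        xm = float(rr[i] + dx)
        return xm, float(np.polyval(c, xm))

    if len(mins) < 2:
        i0 = int(mins[0]) if len(mins) else int(np.argmin(vv))
        r0, e0 = _refine(i0) if 0 < i0 < n_grid - 1 else (float(rr[i0]), float(vv[i0]))
        return ModelCharacterization(R_fixed, True, r0, e0)

    i1, i2 = int(mins[0]), int(mins[-1])
    deep, shallow = (i1, i2) if vv[i1] <= vv[i2] else (i2, i1)
    imax = i1 + int(np.argmax(vv[i1:i2 + 1]))
    r_deep, e_deep = _refine(deep)
    r_shal, e_shal = _refine(shallow)
    r_max, e_max = _refine(imax)
    return ModelCharacterization(
        R_fixed, False, r_deep, e_deep, r_shal, e_shal, r_max,
        barrier=e_max - e_deep, asymmetry=e_shal - e_deep,
    )


# ---------------------------------------------------------------------------
# Boltzmann quadrature oracles
# ---------------------------------------------------------------------------

def _config_weight(params: ModelPotentialParams, temperature: float,
                   r_lim=(0.6, 2.6), R_lim=(2.15, 3.10),
                   n_r: int = 1201, n_R: int = 701):
    r = np.linspace(*r_lim, n_r)
    R = np.linspace(*R_lim, n_R)
    RR, rr = np.meshgrid(R, r, indexing="ij")
    v = _bridge_potential(params, rr, RR)
    w = np.where(rr < RR - 0.4, np.exp(-(v - v.min()) / (KB_KCAL * temperature)), 0.0)
    return r, R, rr, RR, w


def boltzmann_bridge_statistics(params: ModelPotentialParams,
                                temperature: float = 295.0,
                                **grid_kw) -> dict:
    """Single-bridge configurational Boltzmann statistics by 2D quadrature.

    Integrates exp(-V(r,R)/kT) over the (r, R) plane (trapezoid rule; the
    coupling term is not included, so this is exact only for lambda_c = 0)
    and returns donor-site fraction (% of weight with r < R/2), mean and
    standard deviation of R and the mean of r.
    """
    r, R, rr, RR, w = _config_weight(params, temperature, **grid_kw)

    def integ(f):
        return float(np.trapezoid(np.trapezoid(f, r, axis=1), R))

    Z = integ(w)
    donor = integ(np.where(rr < 0.5 * RR, w, 0.0)) / Z
    mean_R = integ(w * RR) / Z
    var_R = integ(w * RR ** 2) / Z - mean_R ** 2
    mean_r = integ(w * rr) / Z
    return {
        "donor_fraction_pct": 100.0 * donor,
        "acceptor_fraction_pct": 100.0 * (1.0 - donor),
        "mean_R": mean_R,
        "std_R": math.sqrt(max(var_R, 0.0)),
        "mean_r": mean_r,
    }


def boltzmann_quadrant_occupancy(params: ModelPotentialParams,
                                 temperature: float = 295.0,
                                 n_q: int = 801, **grid_kw) -> dict:
    """Quadrant occupancies (%) of the coupled two-bridge Boltzmann density.

    Exploits that the coupling depends only on q_b = r_b - R_b/2: the
    single-bridge weight is binned onto a q grid, and the 4D integral
    factorizes into a 2D integral over (q1, q2) with the bilinear coupling
    factor.  Keys: DD, DA, AD, AA (bridge-1 site first; D = donor, q < 0).
    """
    r, R, rr, RR, w = _config_weight(params, temperature, **grid_kw)
    q = rr - 0.5 * RR
    q_edges = np.linspace(q.min() - 1e-9, q.max() + 1e-9, n_q + 1)
    # weight per q bin: integrate w over the strip q in [edge_i, edge_i+1]
    dr = r[1] - r[0]
    dR = R[1] - R[0]
    g, _ = np.histogram(q.ravel(), bins=q_edges, weights=(w * dr * dR).ravel())
    qc = 0.5 * (q_edges[:-1] + q_edges[1:])
    beta = 1.0 / (KB_KCAL * temperature)
    # 2D coupled density over (q1, q2)
    corr = np.exp(-beta * params.lambda_c * np.outer(qc, qc))
    dens = np.outer(g, g) * corr
    Z = dens.sum()
    neg = qc < 0
    occ = {
        "DD": float(dens[np.ix_(neg, neg)].sum() / Z),
        "DA": float(dens[np.ix_(neg, ~neg)].sum() / Z),
        "AD": float(dens[np.ix_(~neg, neg)].sum() / Z),
        "AA": float(dens[np.ix_(~neg, ~neg)].sum() / Z),
    }
    return {k: 100.0 * v for k, v in occ.items()}


# ---------------------------------------------------------------------------
# Langevin dynamics
# ---------------------------------------------------------------------------

_NOISE_CHUNK = 65536


def _forces(p: ModelPotentialParams, r1, R1, r2, R2):
    """Gradient of V_total; returns (-dV/dr1, -dV/dR1, -dV/dr2, -dV/dR2)."""
    ed1 = math.exp(-p.a_d * (r1 - p.rho))
    ea1 = math.exp(-p.a_a * (R1 - r1 - p.rho))
    ed2 = math.exp(-p.a_d * (r2 - p.rho))
    ea2 = math.exp(-p.a_a * (R2 - r2 - p.rho))
    q1 = r1 - 0.5 * R1
    q2 = r2 - 0.5 * R2
    dV_r1 = (2 * p.D_d * p.a_d * (1 - ed1) * ed1
             - 2 * p.D_a * p.a_a * (1 - ea1) * ea1 + p.lambda_c * q2)
    dV_R1 = (2 * p.D_a * p.a_a * (1 - ea1) * ea1
             + p.k_R * (R1 - p.R_0) - 0.5 * p.lambda_c * q2)
    dV_r2 = (2 * p.D_d * p.a_d * (1 - ed2) * ed2
             - 2 * p.D_a * p.a_a * (1 - ea2) * ea2 + p.lambda_c * q1)
    dV_R2 = (2 * p.D_a * p.a_a * (1 - ea2) * ea2
             + p.k_R * (R2 - p.R_0) - 0.5 * p.lambda_c * q1)
    return -dV_r1, -dV_R1, -dV_r2, -dV_R2


def total_potential(params: ModelPotentialParams, r1, R1, r2, R2):
    """V_1 + V_2 + V_c in kcal/mol (scalars or arrays)."""
    return (_bridge_potential(params, r1, R1)
            + _bridge_potential(params, r2, R2)
            + coupling_energy(params, r1, R1, r2, R2))


def simulate_bridges(params: ModelPotentialParams,
                     settings: SimulationSettings,
                     initial_state: tuple | None = None) -> ReducedTrajectory:
    """Propagate the two-bridge model with BAOAB Langevin dynamics.

    The integrator performs, per step, a velocity half-kick (B), a half
    drift (A), an exact Ornstein-Uhlenbeck velocity update (O, one Gaussian
    draw per degree of freedom in the fixed order r1, R1, r2, R2), a second
    half drift (A) and a final half-kick (B).  Equilibration steps are
    discarded; production frames are stored every ``output_stride`` steps
    with absolute time stamps starting at 0 fs for the first stored frame.

    Deterministic given ``settings.seed``.  Raises
    :class:`IntegratorDivergence` if coordinates stop being finite.
    """
    p = params
    s = settings
    dt = s.time_step
    gamma = s.friction * 1e-3                     # 1/ps -> 1/fs
    kT = KB_KCAL * s.temperature * KCAL_TO_AMU_A2_FS2   # amu Å^2/fs^2
    masses = (p.m_H, p.m_R, p.m_H, p.m_R)
    inv_m = tuple(1.0 / m for m in masses)
    # force unit conversion baked into the half-kick factor
    kick = tuple(0.5 * dt * KCAL_TO_AMU_A2_FS2 / m for m in masses)
    c1 = math.exp(-gamma * dt) if gamma > 0 else 1.0
    if s.temperature > 0 and gamma > 0:
        sig = tuple(math.sqrt((1.0 - c1 * c1) * kT / m) for m in masses)
    else:
        sig = (0.0, 0.0, 0.0, 0.0)

    if initial_state is None:
        ch = characterize_model(p, p.R_0, n_grid=4001)
        x = [ch.r_min_deep, p.R_0, ch.r_min_deep, p.R_0]
    else:
        x = [float(v) for v in initial_state]
    v = [0.0, 0.0, 0.0, 0.0]
    if s.temperature > 0:
        rng0 = np.random.default_rng(np.random.SeedSequence([int(s.seed), 1]))
        draws = rng0.standard_normal(4)
        v = [math.sqrt(kT / m) * d for m, d in zip(masses, draws)]

    rng = np.random.default_rng(np.random.SeedSequence([int(s.seed), 0]))

    n_equil = s.n_equilibration_steps
    n_prod = s.n_production_steps
    n_total = n_equil + n_prod
    stride = s.output_stride
    n_out = n_prod // stride + 1
    out = np.empty((n_out, 8))
    out_i = 0

    f = _forces(p, x[0], x[1], x[2], x[3])
    noise = np.empty((0, 4))
    noise_i = 0
    half_dt = 0.5 * dt

    for step in range(n_total + 1):
        if step >= n_equil and (step - n_equil) % stride == 0 and out_i < n_out:
            out[out_i] = (x[0], x[1], x[2], x[3], v[0], v[1], v[2], v[3])
            out_i += 1
        if step == n_total:
            break
        if noise_i >= len(noise):
            noise = rng.standard_normal((_NOISE_CHUNK, 4))
            noise_i = 0
        xi = noise[noise_i]
        noise_i += 1
        try:
            # B
            v = [vi + ki * fi for vi, ki, fi in zip(v, kick, f)]
            # A
            x = [xi_ + half_dt * vi for xi_, vi in zip(x, v)]
            # O
            v = [c1 * vi + si * z for vi, si, z in zip(v, sig, xi)]
            # A
            x = [xi_ + half_dt * vi for xi_, vi in zip(x, v)]
            ok = (x[0] == x[0] and x[1] == x[1] and x[2] == x[2]
                  and x[3] == x[3]
                  and abs(x[0]) < 1e3 and abs(x[1]) < 1e3
                  and abs(x[2]) < 1e3 and abs(x[3]) < 1e3)
            if not ok:
                raise IntegratorDivergence(
                    f"non-finite coordinates at step {step} "
                    f"(of {n_total}); state={x}"
                )
            # B
            f = _forces(p, x[0], x[1], x[2], x[3])
            v = [vi + ki * fi for vi, ki, fi in zip(v, kick, f)]
        except OverflowError as exc:
            raise IntegratorDivergence(
                f"energy overflow at step {step} (of {n_total}); "
                f"time step {dt} fs is likely too large"
            ) from exc

    out = out[:out_i]
    time = np.arange(out_i) * (stride * dt)
    return ReducedTrajectory(
        time=time,
        r=out[:, [0, 2]].copy(),
        R=out[:, [1, 3]].copy(),
        v_r=out[:, [4, 6]].copy(),
        v_R=out[:, [5, 7]].copy(),
        params=p,
        settings=s,
    )


# ---------------------------------------------------------------------------
# embedding & manifest
# ---------------------------------------------------------------------------

#: y offset of the second bridge in the Cartesian embedding, Å.
BRIDGE2_Y_OFFSET = 5.0


def embed_trajectory(states: ReducedTrajectory):
    """Embed the reduced coordinates as a 6-atom Cartesian trajectory.

    Atom order (O, H, O, O, H, O): bridge 1 colinear on the x axis at y = 0
    with donor at the origin, proton at (r1, 0, 0), acceptor at (R1, 0, 0);
    bridge 2 in the same layout at y = 5 Å.  Velocities are embedded along x
    the same way (the donors are fixed).
    """
    from .io import Trajectory

    n = states.n_frames
    pos = np.zeros((n, 6, 3))
    vel = np.zeros((n, 6, 3))
    pos[:, 1, 0] = states.r[:, 0]
    pos[:, 2, 0] = states.R[:, 0]
    pos[:, 4, 0] = states.r[:, 1]
    pos[:, 5, 0] = states.R[:, 1]
    pos[:, 3:6, 1] = BRIDGE2_Y_OFFSET
    vel[:, 1, 0] = states.v_r[:, 0]
    vel[:, 2, 0] = states.v_R[:, 0]
    vel[:, 4, 0] = states.v_r[:, 1]
    vel[:, 5, 0] = states.v_R[:, 1]
    dt = states.settings.time_step * states.settings.output_stride
    return Trajectory(
        labels=["O", "H", "O", "O", "H", "O"],
        positions=pos,
        velocities=vel,
        dt=dt,
        t0=float(states.time[0]) if n else 0.0,
    )


def write_manifest(path, params: ModelPotentialParams,
                   settings: SimulationSettings) -> None:
    """Write a key=value run manifest (parameters, settings, seed, stride)."""
    with open(path, "w") as fh:
        fh.write("# hbridge simulation manifest\n")
        for k, v in params.to_dict().items():
            fh.write(f"params.{k} = {v!r}\n")
        for k, v in settings.to_dict().items():
            fh.write(f"settings.{k} = {v!r}\n")
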