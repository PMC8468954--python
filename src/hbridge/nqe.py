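"""A posteriori nuclear quantum effects for the bridge proton.

Workflow: extract snapshots from a trajectory at constant time intervals,
generate proton positions along the circular arc defined by the donor,
proton and acceptor coordinates, score them with an energy backend, fit the
resulting profile with a 9th-degree polynomial, solve the one-dimensional
vibrational Schrödinger equation on a uniform grid (sine discrete variable
representation with Dirichlet walls), and Boltzmann-average the per-state
expectation values of the donor-proton distance operator over the lowest
vibrational levels.  Comparing the resulting quantum <r> with the classical
donor-proton distance of each snapshot quantifies how much zero-point
motion and thermal excitation delocalize the proton along the bridge.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AMU_ME, BOHR_A, HARTREE_CM1, HARTREE_KCAL, KB_KCAL
from .io import BridgeDefinition, Trajectory, bridge_atoms

__all__ = [
    "Snapshot",
    "ProtonPotential1D",
    "SolverSettings",
    "VibrationalSolution",
    "extract_snapshots",
    "arc_positions",
    "fit_potential",
    "solve_bound_states",
    "thermal_expectation",
    "nqe_report",
]


@dataclass(frozen=True)
class Snapshot:
    """One trajectory frame reduced to a single bridge."""

    frame_index: int
    time: float                 # fs
    donor: np.ndarray           # (3,) Å
    proton: np.ndarray
    acceptor: np.ndarray
    d_OO: float
    d_DH: float                 # classical donor-proton distance

    def __post_init__(self) -> None:
        if not (self.d_OO > self.d_DH > 0):
            raise ValueError(
                f"snapshot frame {self.frame_index}: require "
                f"d_OO > d_DH > 0, got d_OO={self.d_OO}, d_DH={self.d_DH}"
            )


@dataclass
class ProtonPotential1D:
    """Degree-9 polynomial proton potential with quadratic continuation.

    The polynomial is fitted in the conditioned coordinate
    u = (d - d_mid) / half_range; outside the sampled range [d_min, d_max]
    the potential continues as V(endpoint) + kappa (d - endpoint)^2, which
    keeps the solver domain confining regardless of how the polynomial
    extrapolates.  Evaluation is continuous at the range boundaries.
    """

    coefficients: np.ndarray    # ascending powers of u
    d_min: float
    d_max: float
    kappa: float                # kcal/mol/Å^2 wall stiffness
    rms_residual: float         # kcal/mol
    distances: np.ndarray = field(default_factory=lambda: np.empty(0))
    energies: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def _u(self, d):
        mid = 0.5 * (self.d_min + self.d_max)
        half = 0.5 * (self.d_max - self.d_min)
        return (np.asarray(d, float) - mid) / half

    def __call__(self, d):
        d = np.asarray(d, float)
        dc = np.clip(d, self.d_min, self.d_max)
        v = np.polynomial.polynomial.polyval(self._u(dc), self.coefficients)
        below = d < self.d_min
        above = d > self.d_max
        v = v + np.where(below, self.kappa * (d - self.d_min) ** 2, 0.0)
        v = v + np.where(above, self.kappa * (d - self.d_max) ** 2, 0.0)
        return float(v) if v.ndim == 0 else v


@dataclass(frozen=True)
class SolverSettings:
    """Grid, mass and thermal settings of the 1D vibrational solver."""

    n_grid: int = 400           # grid points
    d_lo: float = 0.7           # Å
    d_hi: float = 2.0           # Å
    mass: float = 1.0078        # amu (bare proton)
    temperature: float = 295.0  # K
    n_levels: int = 3           # levels in the thermal average

    def __post_init__(self) -> None:
        if self.n_grid < 16:
            raise ValueError("n_grid must be >= 16")
        if not self.d_lo < self.d_hi:
            raise ValueError("need d_lo < d_hi")
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")


@dataclass
class VibrationalSolution:
    """Eigenpairs of the 1D vibrational problem on a uniform grid.

    ``wavefunctions[n]`` is normalized so that sum(psi^2) * dx = 1; energies
    are reported in kcal/mol and cm^-1 relative to the potential zero.
    """

    grid: np.ndarray                 # Å, interior points
    energies_kcal: np.ndarray        # nondecreasing
    energies_cm1: np.ndarray
    wavefunctions: np.ndarray        # (n_states, n_grid)
    mean_r: np.ndarray               # per-state <r>, Å
    settings: SolverSettings

    @property
    def n_states(self) -> int:
        return len(self.energies_kcal)


def extract_snapshots(traj: Trajectory, bridge: BridgeDefinition,
                      n: int) -> list[Snapshot]:
    """n snapshots at constant frame intervals, endpoints included.

    Frame indices are round(k (F-1)/(n-1)) for k = 0..n-1 when n >= 2; a
    single snapshot takes the last frame (the best-equilibrated one).
    """
    F = traj.n_frames
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > F:
        raise ValueError(f"cannot extract {n} snapshots from {F} frames")
    if n == 1:
        indices = [F - 1]
    else:
        indices = [int(round(k * (F - 1) / (n - 1))) for k in range(n)]
    dpa = bridge_atoms(traj, bridge)
    times = traj.times
    out = []
    for i in indices:
        donor, proton, acceptor = dpa[i]
        out.append(Snapshot(
            frame_index=i,
            time=float(times[i]),
            donor=donor.copy(), proton=proton.copy(), acceptor=acceptor.copy(),
            d_OO=float(np.linalg.norm(acceptor - donor)),
            d_DH=float(np.linalg.norm(proton - donor)),
        ))
    return out


def arc_position_count(d_OO: float, base_count: int = 16,
                       spacing_ref: float = 2.40, spacing_step: float = 0.05,
                       max_extra: int = 4) -> int:
    """Number of arc scan points: 16 for short bridges, up to 20 for long.

    N = base + clamp(round((d_OO - spacing_ref) / spacing_step), 0, max_extra).
    """
    extra = int(round((d_OO - spacing_ref) / spacing_step))
    return base_count + min(max(extra, 0), max_extra)


def arc_positions(donor, proton, acceptor, margin: float = 0.80,
                  count: int | None = None, colinear_tol: float = 1e-6,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Proton scan positions on the arc through donor, proton and acceptor.

    Positions lie on the unique circle through the three points (on the
    proton's side of the donor-acceptor chord) and are parameterized by
    their distance to the donor, uniformly spaced from ``margin`` to
    d_OO - ``margin``.  If the three points are colinear within
    ``colinear_tol`` of the chord the path degenerates to the straight
    donor-acceptor segment.  Returns (positions (N, 3), donor distances (N,)).
    """
    D = np.asarray(donor, float)
    H = np.asarray(proton, float)
    A = np.asarray(acceptor, float)
    if (np.allclose(D, H, atol=1e-9) or np.allclose(D, A, atol=1e-9)
            or np.allclose(H, A, atol=1e-9)):
        raise ValueError("degenerate geometry: coincident points")
    d_OO = float(np.linalg.norm(A - D))
    if count is None:
        count = arc_position_count(d_OO)
    if d_OO - 2 * margin <= 0:
        raise ValueError(
            f"bridge too short for margin {margin} Å (d_OO = {d_OO:.3f} Å)"
        )
    targets = np.linspace(margin, d_OO - margin, count)

    chord = (A - D) / d_OO
    # perpendicular offset of the proton from the chord
    w = (H - D) - np.dot(H - D, chord) * chord
    h = float(np.linalg.norm(w))
    if h <= colinear_tol:
        pos = D[None, :] + targets[:, None] * chord[None, :]
        return pos, targets

    # circumcenter of the three points lies in their plane
    n_hat = w / h
    # center = D + alpha*chord + beta*n_hat; equidistance conditions
    a1 = float(np.dot(H - D, chord))
    alpha = 0.5 * d_OO
    beta = (a1 * a1 + h * h - d_OO * a1) / (2.0 * h)
    center = D + alpha * chord + beta * n_hat
    radius = float(np.linalg.norm(D - center))

    # angles of D, A and the proton-side direction around the center
    def angle_of(P):
        v = P - center
        return math.atan2(float(np.dot(v, n_hat)), float(np.dot(v, chord)))

    th_D = angle_of(D)
    th_H = angle_of(H)
    # walk from the donor toward the acceptor through the proton's side:
    # chord distance from D grows as 2 R sin(|dth|/2)
    s = math.copysign(1.0, _wrapped(th_H - th_D))
    dth = 2.0 * np.arcsin(np.clip(targets / (2.0 * radius), -1.0, 1.0))
    angles = th_D + s * dth
    pos = (center[None, :]
           + radius * np.cos(angles)[:, None] * chord[None, :]
           + radius * np.sin(angles)[:, None] * n_hat[None, :])
    return pos, targets


def _wrapped(angle: float) -> float:
    while angle > math.pi:
        angle -= 2 * math.pi
    while angle < -math.pi:
        angle += 2 * math.pi
    return angle


def fit_potential(distances, energies, degree: int = 9,
                  kappa: float = 200.0) -> ProtonPotential1D:
    """Least-squares polynomial fit of a proton potential profile.

    Performed in the shifted/scaled coordinate u = (d - d_mid)/half_range
    for conditioning.  Requires more points than the degree; energies are
    used as given (no re-zeroing).
    """
    d = np.asarray(distances, float)
    e = np.asarray(energies, float)
    if d.shape != e.shape or d.ndim != 1:
        raise ValueError("distances and energies must be 1D of equal length")
    if len(d) <= degree:
        raise ValueError(
            f"need more than degree+1 = {degree + 1} points for a degree-"
            f"{degree} fit (got {len(d)}); lower the degree"
        )
    d_min, d_max = float(d.min()), float(d.max())
    mid = 0.5 * (d_min + d_max)
    half = 0.5 * (d_max - d_min)
    u = (d - mid) / half
    coeffs = np.polynomial.polynomial.polyfit(u, e, degree)
    resid = np.polynomial.polynomial.polyval(u, coeffs) - e
    return ProtonPotential1D(
        coefficients=coeffs, d_min=d_min, d_max=d_max, kappa=kappa,
        rms_residual=float(np.sqrt(np.mean(resid ** 2))),
        distances=d.copy(), energies=e.copy(),
    )


def _sine_dvr_kinetic(n: int, length_bohr: float, mass_me: float) -> np.ndarray:
    """Sine-DVR kinetic matrix (hartree) for n interior points on (0, L).

    Built from its spectral definition T = F diag(k_m^2 / 2m) F^T with the
    orthogonal sine transform F_im = sqrt(2/(n+1)) sin(m pi i/(n+1)) and
    particle-in-a-box momenta k_m = m pi / L — exact for box eigenstates and
    spectrally accurate for smooth potentials.
    """
    i = np.arange(1, n + 1)
    F = np.sqrt(2.0 / (n + 1)) * np.sin(np.pi * np.outer(i, i) / (n + 1))
    k = np.pi * i / length_bohr
    eps = (k * k) / (2.0 * mass_me)
    return (F * eps) @ F.T


def solve_bound_states(potential, settings: SolverSettings,
                       n_states: int | None = None) -> VibrationalSolution:
    """Solve the 1D vibrational Schrödinger equation on a uniform grid.

    ``potential`` is a callable d[Å] -> V[kcal/mol] (for instance a
    :class:`ProtonPotential1D`).  The grid holds ``settings.n_grid`` interior
    points of (d_lo, d_hi) with Dirichlet (hard-wall) boundaries; the
    kinetic operator is the sine discrete variable representation.  At least
    ``settings.n_levels + 2`` states are returned.

    Emits a warning if the ground state leaks into the outermost two grid
    points (non-confining potential at a boundary); raises on non-finite
    potential values.
    """
    s = settings
    n = s.n_grid
    if n_states is None:
        n_states = max(s.n_levels + 2, 6)
    n_states = min(n_states, n)
    dx = (s.d_hi - s.d_lo) / (n + 1)
    grid = s.d_lo + dx * np.arange(1, n + 1)
    v_kcal = np.asarray(potential(grid), float)
    if not np.all(np.isfinite(v_kcal)):
        bad = grid[~np.isfinite(v_kcal)]
        raise ValueError(f"potential is not finite at grid points {bad[:5]}")

    length_bohr = (s.d_hi - s.d_lo) / BOHR_A
    mass_me = s.mass * AMU_ME
    H = _sine_dvr_kinetic(n, length_bohr, mass_me)
    H[np.diag_indices(n)] += v_kcal / HARTREE_KCAL

    from scipy.linalg import eigh
    evals, evecs = eigh(H, subset_by_index=(0, n_states - 1))

    psi = (evecs / math.sqrt(dx)).T           # rows: states; sum psi^2 dx = 1
    mean_r = (evecs ** 2 * grid[:, None]).sum(axis=0)

    edge_mass = float(np.sum(evecs[:2, 0] ** 2) + np.sum(evecs[-2:, 0] ** 2))
    if edge_mass > 1e-3:
        warnings.warn(
            f"ground state has probability {edge_mass:.2e} in the outermost "
            f"grid points; the potential may not confine on "
            f"[{s.d_lo}, {s.d_hi}] Å", stacklevel=2,
        )
    e_kcal = evals * HARTREE_KCAL
    return VibrationalSolution(
        grid=grid,
        energies_kcal=e_kcal,
        energies_cm1=evals * HARTREE_CM1,
        wavefunctions=psi,
        mean_r=mean_r,
        settings=s,
    )


def thermal_expectation(solution: VibrationalSolution,
                        temperature: float | None = None,
                        levels: int | None = None,
                        ) -> tuple[float, np.ndarray]:
    """Boltzmann-weighted <r> over the lowest vibrational levels.

    w_n ∝ exp(-(E_n - E_0)/kT), normalized over the included levels; at
    T = 0 only the ground state contributes.  Returns (thermal <r> in Å,
    weights).  Invariant under a constant shift of all energies.
    """
    T = solution.settings.temperature if temperature is None else temperature
    m = solution.settings.n_levels if levels is None else levels
    if m < 1:
        raise ValueError("levels must be >= 1")
    if solution.n_states < m:
        raise ValueError(
            f"solution has {solution.n_states} states, need {m}"
        )
    e = solution.energies_kcal[:m]
    if T <= 0:
        w = np.zeros(m)
        w[0] = 1.0
    else:
        w = np.exp(-(e - e[0]) / (KB_KCAL * T))
        w = w / w.sum()
    return float(np.dot(w, solution.mean_r[:m])), w


def nqe_report(traj: Trajectory, bridge: BridgeDefinition, backend,
               settings: SolverSettings | None = None,
               n_snapshots: int = 5, degree: int = 9,
               kappa: float = 200.0, margin: float = 0.80) -> pd.DataFrame:
    """Full NQE pipeline: snapshots -> arc -> fit -> solve -> thermal <r>.

    ``backend`` must provide ``profile_energies(snapshot, positions,
    distances) -> energies`` (kcal/mol).  Returns one row per snapshot with
    the bridge length, the classical donor-proton distance and the quantum
    expectation value of the distance operator.
    """
    if settings is None:
        settings = SolverSettings()
    snapshots = extract_snapshots(traj, bridge, n_snapshots)
    rows = []
    for snap in snapshots:
        try:
            pos, dists = arc_positions(snap.donor, snap.proton,
                                       snap.acceptor, margin=margin)
            energies = np.asarray(
                backend.profile_energies(snap, pos, dists), float)
            pot = fit_potential(dists, energies, degree=degree, kappa=kappa)
            sol = solve_bound_states(pot, settings)
            r_q, _ = thermal_expectation(sol)
        except Exception as exc:
            raise RuntimeError(
                f"NQE pipeline failed at snapshot frame {snap.frame_index} "
                f"(t = {snap.time} fs): {exc}"
            ) from exc
        rows.append({
            "frame_index": snap.frame_index,
            "time_fs": snap.time,
            "d_OO_A": snap.d_OO,
            "classical_d_DH_A": snap.d_DH,
            "quantum_r_A": r_q,
            "fit_rms_kcal_mol": pot.rms_residual,
            "n_scan_points": len(dists),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ModelArcBackend:
    """Scores arc positions with the surrogate model potential.

    The surrogate potential is a function of (r, R) only, so arc positions
    are scored through their donor-proton distance at the snapshot's bridge
    length.
    """

    params: "object"   # ModelPotentialParams

    def profile_energies(self, snapshot: Snapshot, positions, distances):
        from .model import evaluate_model_potential
        return evaluate_model_potential(
            self.params, np.asarray(distances, float), snapshot.d_OO)
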