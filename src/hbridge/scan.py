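"""Discrete proton-potential profiles: scan grids, backends, barrier analysis.

A proton-potential profile is a set of energies on a uniformly spaced grid
of O-H distances, the way constrained quantum-chemical scans report them.
The barrier of a double-well profile is read off the discrete points only
(no interpolation): the uncertainty of the reported barrier is half the
largest energy step between the discrete maximum and its neighbours, which
is the resolution the scan itself supports near the transition state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .model import ModelPotentialParams, evaluate_model_potential

logger = logging.getLogger(__name__)

__all__ = [
    "PotentialProfile",
    "ProfileAnalysis",
    "EnergyBackend",
    "ModelPotentialBackend",
    "TableBackend",
    "scan_positions",
    "evaluate_profile",
    "analyze_profile",
    "load_profile_csv",
    "save_profile_csv",
    "CSV_COLUMNS",
]

CSV_COLUMNS = ("distance_A", "energy_kcal_mol")


@runtime_checkable
class EnergyBackend(Protocol):
    """Anything that can score a list of O-H distances with energies."""

    tag: str

    def energies(self, distances: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class ModelPotentialBackend:
    """Scores distances with the built-in surrogate potential at fixed R."""

    params: ModelPotentialParams
    R: float
    tag: str = "model"

    def energies(self, distances: np.ndarray) -> np.ndarray:
        return evaluate_model_potential(self.params, np.asarray(distances), self.R)


@dataclass
class TableBackend:
    """Scores distances by exact lookup in a (distance, energy) table."""

    distances: np.ndarray
    table_energies: np.ndarray
    tag: str = "table"

    def energies(self, distances: np.ndarray) -> np.ndarray:
        out = np.empty(len(distances))
        for i, d in enumerate(np.asarray(distances, float)):
            j = np.flatnonzero(np.isclose(self.distances, d, atol=1e-9))
            if len(j) == 0:
                raise ValueError(f"distance {d} Å not present in the table")
            out[i] = self.table_energies[j[0]]
        return out


@dataclass
class PotentialProfile:
    """Energies on a uniformly spaced grid of O-H distances.

    Energies are stored relative to the profile minimum; the subtracted
    offset is kept in ``energy_offset`` so absolute energies can be
    recovered.
    """

    distances: np.ndarray       # Å, strictly increasing, uniform spacing
    energies: np.ndarray        # kcal/mol, min = 0
    increment: float            # Å
    backend: str = ""
    energy_offset: float = 0.0  # kcal/mol subtracted from the raw energies

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, float)
        self.energies = np.asarray(self.energies, float)
        if len(self.distances) != len(self.energies):
            raise ValueError("distances and energies must have equal length")
        if len(self.distances) < 3:
            raise ValueError("a profile needs at least 3 points")
        steps = np.diff(self.distances)
        if np.any(steps <= 0):
            raise ValueError("distances must be strictly increasing")
        if np.any(np.abs(steps - self.increment) > 1e-9):
            raise ValueError("distances must be uniformly spaced "
                             f"(increment {self.increment} Å to 1e-9)")

    def __len__(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class ProfileAnalysis:
    """Double-well structure read off a discrete profile."""

    single_minimum: bool
    r_deep: float
    e_deep: float
    r_shallow: float | None = None
    e_shallow: float | None = None
    r_barrier: float | None = None
    barrier: float | None = None              # E(max) - E(deep)
    barrier_uncertainty: float | None = None  # half local energy step
    asymmetry: float | None = None            # E(shallow) - E(deep)
    barrier_parabolic: float | None = None    # optional 3-point refinement
    relative_energies: np.ndarray | None = None


def scan_positions(start: float, count: int, increment: float) -> np.ndarray:
    """Arithmetic scan grid start, start+increment, ... (count points)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    if increment <= 0:
        raise ValueError("increment must be positive")
    return start + increment * np.arange(count)


def evaluate_profile(backend: EnergyBackend,
                     distances: np.ndarray) -> PotentialProfile:
    """Score a scan grid with a backend and build a relative-energy profile."""
    distances = np.asarray(distances, float)
    if len(distances) < 3:
        raise ValueError("need at least 3 scan positions")
    increment = float(distances[1] - distances[0])
    try:
        energies = np.asarray(backend.energies(distances), float)
    except Exception as exc:
        raise RuntimeError(f"energy backend {backend.tag!r} failed: {exc}") from exc
    if energies.shape != distances.shape or not np.all(np.isfinite(energies)):
        bad = distances[~np.isfinite(np.broadcast_to(energies, distances.shape))]
        raise RuntimeError(
            f"energy backend {backend.tag!r} returned non-finite energies "
            f"at distances {bad}"
        )
    offset = float(energies.min())
    return PotentialProfile(
        distances=distances,
        energies=energies - offset,
        increment=increment,
        backend=backend.tag,
        energy_offset=offset,
    )


def analyze_profile(profile: PotentialProfile,
                    parabolic_refinement: bool = False) -> ProfileAnalysis:
    """Extract minima, barrier and its discretization uncertainty.

    The deep minimum is the global discrete minimum.  The shallow minimum is
    the lowest other discrete local minimum; the barrier is the highest
    discrete point between the two minima, measured from the deep minimum.
    The uncertainty is half the largest energy difference between the
    discrete maximum and its two neighbours — i.e. half the local energy
    step of the scan near the transition state.  Monotone or single-minimum
    profiles are flagged instead of analysed.

    ``parabolic_refinement`` additionally reports a 3-point parabolic
    estimate of the barrier top; the headline numbers stay discrete.
    """
    if len(profile) < 5:
        raise ValueError("need at least 5 points to analyze a profile")
    e = profile.energies
    d = profile.distances
    n = len(e)
    i_deep = int(np.argmin(e))
    interior = np.arange(1, n - 1)
    local_min = interior[(e[interior] < e[interior - 1])
                         & (e[interior] <= e[interior + 1])]
    others = [int(i) for i in local_min if i != i_deep]
    rel = e - e[i_deep]
    if not others:
        return ProfileAnalysis(
            single_minimum=True, r_deep=float(d[i_deep]),
            e_deep=float(e[i_deep]), relative_energies=rel,
        )
    i_shal = min(others, key=lambda i: e[i])
    lo, hi = sorted((i_deep, i_shal))
    i_max = lo + int(np.argmax(e[lo:hi + 1]))
    step_lo = abs(e[i_max] - e[i_max - 1]) if i_max > 0 else 0.0
    step_hi = abs(e[i_max] - e[i_max + 1]) if i_max < n - 1 else 0.0
    uncertainty = 0.5 * max(step_lo, step_hi)
    barrier = float(e[i_max] - e[i_deep])
    parab = None
    if parabolic_refinement and 0 < i_max < n - 1:
        y0, y1, y2 = e[i_max - 1], e[i_max], e[i_max + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            parab = float(y1 - 0.125 * (y0 - y2) ** 2 / denom - e[i_deep])
    return ProfileAnalysis(
        single_minimum=False,
        r_deep=float(d[i_deep]), e_deep=float(e[i_deep]),
        r_shallow=float(d[i_shal]), e_shallow=float(e[i_shal]),
        r_barrier=float(d[i_max]),
        barrier=barrier,
        barrier_uncertainty=float(uncertainty),
        asymmetry=float(e[i_shal] - e[i_deep]),
        barrier_parabolic=parab,
        relative_energies=rel,
    )


def load_profile_csv(path) -> PotentialProfile:
    """Read a profile from CSV with columns distance_A, energy_kcal_mol.

    Rows are sorted by distance if needed (with a logged warning), since
    externally produced scan tables are not always ordered.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing CSV columns {missing}; "
                         f"expected header {','.join(CSV_COLUMNS)}")
    d = df[CSV_COLUMNS[0]].to_numpy(float)
    e = df[CSV_COLUMNS[1]].to_numpy(float)
    if np.any(np.diff(d) <= 0):
        logger.warning("%s: distances not sorted; sorting on read", path)
        order = np.argsort(d)
        d, e = d[order], e[order]
    increment = float(d[1] - d[0])
    offset = float(e.min())
    return PotentialProfile(
        distances=d, energies=e - offset, increment=increment,
        backend="csv", energy_offset=offset,
    )


def save_profile_csv(profile: PotentialProfile, path,
                     absolute: bool = False) -> None:
    """Write a profile in the shared CSV dialect (relative energies unless
    ``absolute``)."""
    e = profile.energies + (profile.energy_offset if absolute else 0.0)
    pd.DataFrame({CSV_COLUMNS[0]: profile.distances,
                  CSV_COLUMNS[1]: e}).to_csv(path, index=False)
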