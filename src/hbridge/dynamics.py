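"""Hydrogen-bridge distance analytics.

Per-frame bridge distances (donor-acceptor, donor-proton, proton-acceptor),
Voronoi proton-possession statistics, dwell-filtered proton-transfer event
detection, joint donor-proton distance histograms and double-proton-transfer
synchronicity summaries.

The Voronoi criterion assigns the bridge proton to the donor whenever the
donor-proton distance is shorter than the proton-acceptor distance.  Exact
ties (a measure-zero event on real trajectories) are assigned to the donor
and reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import BridgeDefinition, Trajectory, bridge_atoms

logger = logging.getLogger(__name__)

__all__ = [
    "BridgeSeries",
    "PossessionStats",
    "TransferEvent",
    "Density2D",
    "SynchronicityStats",
    "compute_bridge_series",
    "possession_statistics",
    "detect_transfer_events",
    "joint_histogram",
    "synchronicity_summary",
]


@dataclass
class BridgeSeries:
    """Per-frame structural parameters of one O-H...O bridge (all Å, fs)."""

    time: np.ndarray
    d_OO: np.ndarray
    d_DH: np.ndarray
    d_HA: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.d_OO = np.asarray(self.d_OO, float)
        self.d_DH = np.asarray(self.d_DH, float)
        self.d_HA = np.asarray(self.d_HA, float)
        n = len(self.time)
        if not (len(self.d_OO) == len(self.d_DH) == len(self.d_HA) == n):
            raise ValueError("all series must have equal length")
        if n and (self.d_OO.min() <= 0 or self.d_DH.min() <= 0
                  or self.d_HA.min() <= 0):
            raise ValueError("distances must be positive")
        # triangle inequality, with slack for round-off on colinear geometries
        tol = 1e-9
        if n and not (
            np.all(np.abs(self.d_DH - self.d_HA) <= self.d_OO + tol)
            and np.all(self.d_OO <= self.d_DH + self.d_HA + tol)
        ):
            bad = int(np.argmax(
                (np.abs(self.d_DH - self.d_HA) > self.d_OO + tol)
                | (self.d_OO > self.d_DH + self.d_HA + tol)
            ))
            raise ValueError(f"frame {bad}: triangle inequality violated")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def voronoi_signed(self) -> np.ndarray:
        """s = d_DH - d_HA; negative while the proton sits on the donor."""
        return self.d_DH - self.d_HA


@dataclass(frozen=True)
class PossessionStats:
    """Voronoi residence statistics of one bridge proton."""

    donor_fraction: float     # %
    acceptor_fraction: float  # %
    n_frames: int
    n_donor: int
    n_acceptor: int
    n_ties: int

    def to_dict(self) -> dict:
        return {
            "donor_fraction_pct": self.donor_fraction,
            "acceptor_fraction_pct": self.acceptor_fraction,
            "n_frames": self.n_frames,
            "n_donor": self.n_donor,
            "n_acceptor": self.n_acceptor,
            "n_ties": self.n_ties,
        }


@dataclass(frozen=True)
class TransferEvent:
    """A dwell-filtered proton-transfer event."""

    time: float        # onset, fs
    direction: str     # "donor_to_acceptor" or "acceptor_to_donor"
    dwell: float       # persistence of the new site, fs


@dataclass
class Density2D:
    """Normalized 2D probability density (Å^-2) over two distance axes."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray   # shape (nx, ny)

    @property
    def mass(self) -> float:
        dx = np.diff(self.x_edges)[:, None]
        dy = np.diff(self.y_edges)[None, :]
        return float(np.sum(self.density * dx * dy))


@dataclass(frozen=True)
class SynchronicityStats:
    """Quadrant occupancies (%) of the two-bridge Voronoi configuration.

    First letter: bridge 1 site, second: bridge 2 (D donor, A acceptor).
    ``center`` is the fraction of frames with both protons within ``eps``
    of the Voronoi midplane — a populated center would indicate synchronous
    double proton transfer.
    """

    DD: float
    DA: float
    AD: float
    AA: float
    center: float
    eps: float
    n_frames: int

    def to_dict(self) -> dict:
        return {"DD_pct": self.DD, "DA_pct": self.DA, "AD_pct": self.AD,
                "AA_pct": self.AA, "center_pct": self.center,
                "eps_A": self.eps, "n_frames": self.n_frames}


def compute_bridge_series(traj: Trajectory,
                          bridge: BridgeDefinition) -> BridgeSeries:
    """Euclidean bridge distances per frame for one bridge selection."""
    dpa = bridge_atoms(traj, bridge)
    donor, proton, acceptor = dpa[:, 0], dpa[:, 1], dpa[:, 2]
    return BridgeSeries(
        time=traj.times,
        d_OO=np.linalg.norm(acceptor - donor, axis=1),
        d_DH=np.linalg.norm(proton - donor, axis=1),
        d_HA=np.linalg.norm(acceptor - proton, axis=1),
        label=bridge.label,
    )


def possession_statistics(series: BridgeSeries) -> PossessionStats:
    """Percentages of frames the proton spends at donor vs acceptor site.

    Donor frames are those with d_DH < d_HA (ties count as donor and are
    reported); fractions are exact complements summing to 100%.
    """
    n = len(series)
    if n == 0:
        raise ValueError("empty series")
    s = series.voronoi_signed
    n_acc = int(np.count_nonzero(s > 0))
    n_tie = int(np.count_nonzero(s == 0))
    n_don = n - n_acc
    donor_pct = 100.0 * n_don / n
    return PossessionStats(
        donor_fraction=donor_pct,
        acceptor_fraction=100.0 - donor_pct,
        n_frames=n,
        n_donor=n_don,
        n_acceptor=n_acc,
        n_ties=n_tie,
    )


def detect_transfer_events(series: BridgeSeries,
                           min_dwell: float = 10.0) -> list[TransferEvent]:
    """Sign changes of d_DH - d_HA whose new sign persists >= min_dwell fs.

    The signed coordinate is reduced to a site sequence (ties -> donor);
    maximal constant-site runs shorter than ``min_dwell`` are treated as
    barrier recrossings and discarded, so reported events alternate in
    direction.  The dwell of an event is the time from its onset to the
    onset of the next event (or the end of the series).
    """
    if len(series) == 0:
        raise ValueError("empty series")
    if min_dwell < 0:
        raise ValueError("min_dwell must be >= 0")
    site = (series.voronoi_signed > 0).astype(np.int8)  # 0 donor, 1 acceptor
    t = series.time
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.0
    # maximal runs
    change = np.flatnonzero(np.diff(site)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(site)]])

    events: list[TransferEvent] = []
    current = int(site[0])
    onsets: list[tuple[float, int]] = []
    for s0, e0 in zip(starts[1:], ends[1:]):
        run_site = int(site[s0])
        duration = (e0 - s0) * dt
        if run_site != current and duration >= min_dwell:
            onsets.append((float(t[s0]), run_site))
            current = run_site
    end_time = float(t[-1])
    for i, (onset, new_site) in enumerate(onsets):
        nxt = onsets[i + 1][0] if i + 1 < len(onsets) else end_time
        direction = ("donor_to_acceptor" if new_site == 1
                     else "acceptor_to_donor")
        events.append(TransferEvent(onset, direction, nxt - onset))
    return events


def joint_histogram(series1: BridgeSeries, series2: BridgeSeries,
                    bin_width: float = 0.02,
                    d_range: tuple[float, float] = (0.8, 1.8)) -> Density2D:
    """Joint probability density of the two donor-proton distances (Å^-2).

    Axes are d_DH of bridge 1 (x) and bridge 2 (y).  Samples outside
    ``d_range`` are accumulated in the edge bins (and logged), so the
    density integrates to exactly 1.
    """
    if len(series1) != len(series2):
        raise ValueError("series length mismatch")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = d_range
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    x = series1.d_DH
    y = series2.d_DH
    n_out = int(np.count_nonzero((x < lo) | (x > edges[-1])
                                 | (y < lo) | (y > edges[-1])))
    if n_out:
        logger.warning(
            "joint_histogram: %d of %d samples outside [%g, %g]; "
            "accumulated in edge bins", n_out, len(x), lo, edges[-1],
        )
    eps = 1e-12 * max(1.0, abs(edges[-1]))
    xc = np.clip(x, lo + eps, edges[-1] - eps)
    yc = np.clip(y, lo + eps, edges[-1] - eps)
    counts, _, _ = np.histogram2d(xc, yc, bins=[edges, edges])
    density = counts / (counts.sum() * bin_width * bin_width)
    return Density2D(x_edges=edges, y_edges=edges.copy(), density=density)


def synchronicity_summary(series1: BridgeSeries, series2: BridgeSeries,
                          eps: float = 0.05) -> SynchronicityStats:
    """Quadrant occupancies of the (q1, q2) Voronoi plane, in %.

    q_b = d_DH - d_HA per bridge; D means q <= 0 (ties -> donor).  The
    center region counts frames with |q_b| < eps on both bridges — its
    occupancy measures how often the two protons are simultaneously shared,
    the signature a synchronous double proton transfer would leave.
    """
    if len(series1) != len(series2):
        raise ValueError("series length mismatch")
    if eps <= 0:
        raise ValueError("eps must be positive")
    n = len(series1)
    if n == 0:
        raise ValueError("empty series")
    q1 = series1.voronoi_signed
    q2 = series2.voronoi_signed
    a1 = q1 > 0
    a2 = q2 > 0
    pct = 100.0 / n
    return SynchronicityStats(
        DD=pct * np.count_nonzero(~a1 & ~a2),
        DA=pct * np.count_nonzero(~a1 & a2),
        AD=pct * np.count_nonzero(a1 & ~a2),
        AA=pct * np.count_nonzero(a1 & a2),
        center=pct * np.count_nonzero((np.abs(q1) < eps) & (np.abs(q2) < eps)),
        eps=eps,
        n_frames=n,
    )
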