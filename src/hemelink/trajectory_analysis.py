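"""Trajectory statistics: water residence near Fe, distances, H-bond occupancy.

Trajectories are frame stacks over a fixed topology (a :class:`Structure`
providing atom naming for frame 0).  No periodic-boundary imaging is applied:
frames are assumed whole and centred on the site of interest.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from hemelink.errors import CriteriaError, ValidationError
from hemelink.structure_io import DEFAULT_WATER_RESNAMES, Structure

DEFAULT_RESIDENCE_CUTOFF = 3.5  # Å
DEFAULT_BIN_WIDTH = 0.05  # Å


@dataclass
class Trajectory:
    """A fixed-topology frame stack; coordinates in Å."""

    topology: Structure
    frames: list[np.ndarray]
    dt_label: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("a Trajectory needs at least one frame")
        n = len(self.topology.models[0])
        cleaned = []
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValidationError(
                    f"frame {i} has shape {f.shape}, expected ({n}, 3)"
                )
            cleaned.append(f)
        self.frames = cleaned

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @classmethod
    def from_structure(cls, structure: Structure, dt_label: str = "") -> "Trajectory":
        """Treat a multi-model structure as a trajectory over model-0 topology."""
        frames = [structure.coords(m) for m in range(structure.n_models)]
        return cls(topology=structure, frames=frames, dt_label=dt_label)


class HBondMode(enum.Enum):
    HEAVY_ONLY = "heavy_only"
    WITH_HYDROGENS = "with_hydrogens"


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    ``da_max`` bounds the donor-acceptor heavy-atom distance; ``dha_min_deg``
    is the minimum D-H...A angle, applied only in ``with_hydrogens`` mode.
    """

    da_max: float = 3.5
    dha_min_deg: float = 120.0
    mode: HBondMode = HBondMode.HEAVY_ONLY

    def __post_init__(self) -> None:
        if self.da_max <= 0:
            raise ValidationError("da_max must be positive")
        if not 0.0 <= self.dha_min_deg <= 180.0:
            raise ValidationError("dha_min_deg must be within [0, 180]")


@dataclass
class ResidenceProfile:
    cutoff: float
    per_frame_min_dist: np.ndarray  # NaN where no water exists at all
    occupancy: float
    mean: Optional[float]
    sd: Optional[float]
    histogram: tuple[np.ndarray, np.ndarray]  # (bin edges, counts)
    modes: list[float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError("occupancy outside [0, 1]")


def _water_oxygen_handles(
    topology: Structure, water_resnames: Sequence[str]
) -> list[int]:
    return [
        i
        for i, a in enumerate(topology.models[0])
        if a.resname in water_resnames and a.element == "O"
    ]


def distance_series(
    trajectory: Trajectory, a: int, b: int, bin_width: float = DEFAULT_BIN_WIDTH
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Per-frame |a-b| distances: sample mean, (n-1) sd, histogram."""
    coords = np.stack(trajectory.frames)
    d = np.linalg.norm(coords[:, a, :] - coords[:, b, :], axis=1)
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    edges, counts = _histogram(d, bin_width)
    return mean, sd, (edges, counts)


def _histogram(values: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    if len(values) == 0:
        return np.array([]), np.array([], dtype=int)
    lo = math.floor(values.min() / bin_width) * bin_width
    hi = math.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return edges, counts


def water_residence(
    trajectory: Trajectory,
    fe: int,
    cutoff: float = DEFAULT_RESIDENCE_CUTOFF,
    water_resnames: Sequence[str] = DEFAULT_WATER_RESNAMES,
    bin_width: float = DEFAULT_BIN_WIDTH,
    all_frames_stats: bool = False,
) -> ResidenceProfile:
    """Minimum Fe-O(water) distance per frame and site-occupancy statistics.

    Mean/sd are over frames with a water inside ``cutoff`` (the occupying
    frames); pass ``all_frames_stats=True`` for statistics over every frame's
    minimum distance regardless of the cutoff.
    """
    waters = _water_oxygen_handles(trajectory.topology, water_resnames)
    if not waters:
        empty = np.full(trajectory.n_frames, np.nan)
        return ResidenceProfile(
            cutoff=cutoff,
            per_frame_min_dist=empty,
            occupancy=0.0,
            mean=None,
            sd=None,
            histogram=(np.array([]), np.array([], dtype=int)),
            modes=[],
        )
    coords = np.stack(trajectory.frames)
    d = np.linalg.norm(
        coords[:, waters, :] - coords[:, [fe], :], axis=2
    ).min(axis=1)
    inside = d <= cutoff
    occupancy = float(inside.mean())
    contributing = d if all_frames_stats else d[inside]
    if len(contributing) == 0:
        mean = sd = None
        hist = (np.array([]), np.array([], dtype=int))
        modes: list[float] = []
    else:
        mean = float(contributing.mean())
        sd = float(contributing.std(ddof=1)) if len(contributing) > 1 else 0.0
        hist = _histogram(contributing, bin_width)
        modes = detect_modes(hist)
    return ResidenceProfile(
        cutoff=cutoff,
        per_frame_min_dist=d,
        occupancy=occupancy,
        mean=mean,
        sd=sd,
        histogram=hist,
        modes=modes,
    )


def hbond_occupancy(
    trajectory: Trajectory,
    donor: int,
    hydrogens: Sequence[int],
    acceptor: int,
    criteria: HBondCriteria = HBondCriteria(),
) -> float:
    """Fraction of frames in which the donor-acceptor pair is hydrogen bonded.

    ``heavy_only`` mode applies the distance criterion alone; the
    ``with_hydrogens`` mode additionally requires at least one D-H...A angle
    above the threshold and therefore needs hydrogen handles.
    """
    if criteria.mode is HBondMode.WITH_HYDROGENS and not hydrogens:
        raise CriteriaError("with_hydrogens mode requires hydrogen handles")
    coords = np.stack(trajectory.frames)
    d_pos = coords[:, donor, :]
    a_pos = coords[:, acceptor, :]
    da = np.linalg.norm(d_pos - a_pos, axis=1)
    ok = da <= criteria.da_max
    if criteria.mode is HBondMode.WITH_HYDROGENS:
        angle_ok = np.zeros(len(coords), dtype=bool)
        for h in hydrogens:
            h_pos = coords[:, h, :]
            v1 = d_pos - h_pos
            v2 = a_pos - h_pos
            cosang = np.einsum("ij,ij->i", v1, v2) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            angle_ok |= ang >= criteria.dha_min_deg
        ok &= angle_ok
    return float(ok.mean())


def detect_modes(
    histogram: tuple[np.ndarray, np.ndarray],
    smoothing: int = 3,
    min_separation: float = 0.15,
    prominence_frac: float = 0.10,
) -> list[float]:
    """Mode centres of a box-smoothed histogram.

    Local maxima of the smoothed counts are kept if they exceed
    ``prominence_frac`` of the global maximum and are at least
    ``min_separation`` apart (taller peaks win).  A flat histogram collapses
    to a single mode at the count-weighted centre.
    """
    edges, counts = histogram
    if len(counts) == 0:
        raise ValidationError("empty histogram")
    centres = 0.5 * (edges[:-1] + edges[1:])
    if len(counts) == 1:
        return [float(centres[0])]
    counts = np.asarray(counts, dtype=float)
    if smoothing > 1:
        kernel = np.ones(smoothing) / smoothing
        smooth = np.convolve(counts, kernel, mode="same")
    else:
        smooth = counts.copy()
    peak = smooth.max()
    if peak <= 0:
        raise ValidationError("histogram has no counts")
    if np.allclose(smooth, smooth[0]):
        centre = float(np.average(centres, weights=counts)) if counts.sum() else float(centres.mean())
        return [centre]
    # local maxima, plateau-aware: strictly above one neighbour, >= the other
    candidates = []
    for i in range(len(smooth)):
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i < len(smooth) - 1 else -np.inf
        if smooth[i] >= left and smooth[i] >= right and (
            smooth[i] > left or smooth[i] > right
        ):
            candidates.append(i)
    candidates = [i for i in candidates if smooth[i] >= prominence_frac * peak]
    # enforce separation, keeping taller peaks first
    kept: list[int] = []
    for i in sorted(candidates, key=lambda i: -smooth[i]):
        if all(abs(centres[i] - centres[j]) >= min_separation for j in kept):
            kept.append(i)
    return sorted(float(centres[i]) for i in kept)
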