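"""Seeded generators for haem sites, trajectories, stick spectra and ESP fits.

Every generator realizes its requested parameters exactly (before optional
noise) and returns machine-checkable ground truth alongside the data, so the
analysis modules can be validated without any external input.  All randomness
flows from the spec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from hemelink.errors import SpecError, ValidationError
from hemelink.esp_charges import ChargeSet, ESPFitProblem, predict_esp
from hemelink.haem_geometry import GeometryReport
from hemelink.spectra import HC_EV_NM, StickSpectrum
from hemelink.structure_io import AtomRecord, Structure
from hemelink.trajectory_analysis import Trajectory

# ---------------------------------------------------------------------------
# Idealized porphine template (planar, fourfold symmetric)
# ---------------------------------------------------------------------------

#: N4 circumradius default (Å).
DEFAULT_RING_RADIUS_N = 2.05

# radial distance / half-azimuth (deg) of the alpha and beta pyrrole carbons,
# and the meso-carbon radius, chosen to give chemically plausible bond lengths
_ALPHA_RADIUS, _ALPHA_HALF_DEG = 3.05, 20.0
_BETA_RADIUS, _BETA_HALF_DEG = 4.25, 9.5
_MESO_RADIUS = 3.45

#: Default CD-C2A distance used when the spec leaves it unset (SC-like).
DEFAULT_SC_CD_C2A = 3.70


@dataclass(frozen=True)
class PorphyrinSpec:
    """Parameters of one idealized haem-c site."""

    ring_radius_n: float = DEFAULT_RING_RADIUS_N
    fe_oop: float = 0.0  # signed; + = distal (water) side
    fe_his_n: float = 2.10
    fe_water: Optional[float] = 2.11
    lys_nz_cha: float = 1.45
    lys_cd_c2a: Optional[float] = None
    c3a_cma: float = 1.43
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ring_radius_n", "fe_his_n", "lys_nz_cha", "c3a_cma"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        for name in ("fe_water", "lys_cd_c2a"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise SpecError(f"{name} must be positive when present")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")


def _polar(radius: float, azimuth_deg: float, z: float = 0.0) -> np.ndarray:
    a = math.radians(azimuth_deg)
    return np.array([radius * math.cos(a), radius * math.sin(a), z])


def make_porphyrin(spec: PorphyrinSpec) -> tuple[Structure, GeometryReport]:
    """Build an idealized planar haem-c site realizing the spec exactly.

    Returns the structure (chain A: HEC 201, HIS 144 NE2, LYS 78 NZ/CE/CD,
    optional HOH 301) together with the ground-truth descriptor report of the
    noise-free geometry.
    """
    ring_azimuth = {"A": 0.0, "B": 90.0, "C": 180.0, "D": 270.0}
    # meso carbons: CHA between rings D and A, then counterclockwise
    meso_azimuth = {"CHA": 315.0, "CHB": 45.0, "CHC": 135.0, "CHD": 225.0}

    atoms: list[tuple[str, str, str, int, np.ndarray]] = []  # name, resname, elem, resseq, pos
    for ring, az in ring_azimuth.items():
        atoms.append((f"N{ring}", "HEC", "N", 201, _polar(spec.ring_radius_n, az)))
        atoms.append((f"C1{ring}", "HEC", "C", 201, _polar(_ALPHA_RADIUS, az - _ALPHA_HALF_DEG)))
        atoms.append((f"C4{ring}", "HEC", "C", 201, _polar(_ALPHA_RADIUS, az + _ALPHA_HALF_DEG)))
        atoms.append((f"C2{ring}", "HEC", "C", 201, _polar(_BETA_RADIUS, az - _BETA_HALF_DEG)))
        atoms.append((f"C3{ring}", "HEC", "C", 201, _polar(_BETA_RADIUS, az + _BETA_HALF_DEG)))
    for name, az in meso_azimuth.items():
        atoms.append((name, "HEC", "C", 201, _polar(_MESO_RADIUS, az)))

    c3a = _polar(_BETA_RADIUS, _BETA_HALF_DEG)
    cma = c3a + spec.c3a_cma * c3a / np.linalg.norm(c3a)  # radially outward
    atoms.append(("CMA", "HEC", "C", 201, cma))

    # ring-C substituent stubs (thioether-side carbons)
    c2c = _polar(_BETA_RADIUS, 180.0 - _BETA_HALF_DEG)
    cac = c2c + 1.50 * c2c / np.linalg.norm(c2c)
    cbc = cac + 1.50 * c2c / np.linalg.norm(c2c)
    atoms.append(("CAC", "HEC", "C", 201, cac))
    atoms.append(("CBC", "HEC", "C", 201, cbc))

    fe = np.array([0.0, 0.0, spec.fe_oop])
    atoms.append(("FE", "HEC", "FE", 201, fe))

    his_n = fe - np.array([0.0, 0.0, spec.fe_his_n])  # proximal side
    atoms.append(("NE2", "HIS", "N", 144, his_n))

    cha = _polar(_MESO_RADIUS, meso_azimuth["CHA"])
    c2a = _polar(_BETA_RADIUS, -_BETA_HALF_DEG)
    cd_c2a = spec.lys_cd_c2a if spec.lys_cd_c2a is not None else DEFAULT_SC_CD_C2A
    lys_nz = cha + np.array([0.0, 0.0, spec.lys_nz_cha])
    lys_cd = c2a + np.array([0.0, 0.0, cd_c2a])
    lys_ce = 0.5 * (lys_nz + lys_cd)
    atoms.append(("NZ", "LYS", "N", 78, lys_nz))
    atoms.append(("CE", "LYS", "C", 78, lys_ce))
    atoms.append(("CD", "LYS", "C", 78, lys_cd))

    if spec.fe_water is not None:
        water = fe + np.array([0.0, 0.0, spec.fe_water])  # distal side
        atoms.append(("O", "HOH", "O", 301, water))

    rng = np.random.default_rng(spec.seed)
    records = []
    for serial, (name, resname, element, resseq, pos) in enumerate(atoms, start=1):
        if spec.noise_sd > 0:
            pos = pos + rng.normal(0.0, spec.noise_sd, size=3)
        records.append(
            AtomRecord(
                serial=serial,
                name=name,
                altloc="",
                resname=resname,
                chain="A",
                resseq=resseq,
                element=element,
                occupancy=1.0,
                bfactor=0.0,
                pos=pos,
            )
        )
    structure = Structure(models=[records], source_format="pdb", id="synthetic-haem")

    fe_pyr = math.hypot(spec.ring_radius_n, spec.fe_oop)
    truth = GeometryReport(
        fe_his_n=spec.fe_his_n,
        fe_water=spec.fe_water,
        fe_pyr_n={r: fe_pyr for r in "ABCD"},
        lys_nz_cha=spec.lys_nz_cha,
        lys_cd_c2a=cd_c2a,
        c3a_cma=spec.c3a_cma,
        fe_oop=abs(spec.fe_oop),
        fe_oop_signed=spec.fe_oop,
        ring_rms_dev=0.0,
        chain="A",
        label="ground-truth",
    )
    return structure, truth


def add_water(structure: Structure, pos, resseq: int = 302) -> Structure:
    """Append a water oxygen to every model (same position in each)."""
    pos = np.asarray(pos, dtype=float)
    for atoms in structure.models:
        atoms.append(
            AtomRecord(
                serial=len(atoms) + 1,
                name="O",
                altloc="",
                resname="HOH",
                chain="A",
                resseq=resseq,
                element="O",
                occupancy=1.0,
                bfactor=0.0,
                pos=pos,
            )
        )
    return structure


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectorySpec:
    """Gaussian-mixture Fe-water distances plus an exact H-bond frame count."""

    n_frames: int
    fe_water_distribution: tuple[tuple[float, float, float], ...] = (
        (1.0, 3.3, 0.1),
    )  # (weight, mu Å, sigma Å)
    hbond_satisfied_fraction: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")
        weights = [w for w, _, _ in self.fe_water_distribution]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise SpecError("mixture weights must sum to 1")
        if any(w < 0 or mu <= 0 or sd < 0 for w, mu, sd in self.fe_water_distribution):
            raise SpecError("mixture components need weight >= 0, mu > 0, sigma >= 0")
        if self.hbond_satisfied_fraction is not None and not (
            0.0 <= self.hbond_satisfied_fraction <= 1.0
        ):
            raise SpecError("hbond_satisfied_fraction must be in [0, 1]")


#: D-A distances (Å) used for constructed satisfied / unsatisfied H-bond frames.
HBOND_ON_DISTANCE = 2.80
HBOND_OFF_DISTANCE = 5.00


def make_trajectory(
    spec: TrajectorySpec, topology: Structure
) -> tuple[Trajectory, dict]:
    """Generate frames over ``topology`` realizing the spec exactly.

    The water oxygen nearest Fe in the topology is moved each frame to a
    distance drawn from the Gaussian mixture, in a random direction from Fe.
    When ``hbond_satisfied_fraction`` is set, a *second* water is required; it
    is placed at a bonded D-A distance from pyrrole nitrogen ND in exactly
    ``round(fraction * n_frames)`` randomly chosen frames and far otherwise.

    Returns the trajectory plus ground truth: sampled distances, component
    labels, the satisfied-frame mask and the donor/acceptor handles.
    """
    atoms = topology.models[0]
    fe = next((i for i, a in enumerate(atoms) if a.element == "FE"), None)
    if fe is None:
        raise SpecError("topology has no Fe atom")
    waters = [
        i
        for i, a in enumerate(atoms)
        if a.resname in ("HOH", "WAT", "TIP3", "SOL") and a.element == "O"
    ]
    if not waters:
        raise SpecError("topology has no water oxygen")
    fe_pos = atoms[fe].pos
    waters.sort(key=lambda i: float(np.linalg.norm(atoms[i].pos - fe_pos)))
    mix_water = waters[0]

    nd = next((i for i, a in enumerate(atoms) if a.name == "ND"), None)
    hbond_water = None
    n_on = 0
    if spec.hbond_satisfied_fraction is not None:
        if len(waters) < 2:
            raise SpecError("hbond_satisfied_fraction requires a second water")
        if nd is None:
            raise SpecError("topology has no pyrrole ND acceptor")
        hbond_water = waters[1]
        n_on = round(spec.hbond_satisfied_fraction * spec.n_frames)

    rng = np.random.default_rng(spec.seed)
    weights = np.array([w for w, _, _ in spec.fe_water_distribution])
    mus = np.array([mu for _, mu, _ in spec.fe_water_distribution])
    sds = np.array([sd for _, _, sd in spec.fe_water_distribution])

    components = rng.choice(len(weights), size=spec.n_frames, p=weights)
    distances = np.abs(rng.normal(mus[components], sds[components]))

    on_mask = np.zeros(spec.n_frames, dtype=bool)
    if hbond_water is not None:
        on_frames = rng.choice(spec.n_frames, size=n_on, replace=False)
        on_mask[on_frames] = True
        nd_pos = atoms[nd].pos
        nd_out = nd_pos.copy()
        nd_out[2] = 0.0
        nd_dir = nd_out / np.linalg.norm(nd_out)  # radially outward, in plane

    base = topology.coords(0)
    frames = []
    for k in range(spec.n_frames):
        coords = base.copy()
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords[mix_water] = fe_pos + distances[k] * direction
        if hbond_water is not None:
            d = HBOND_ON_DISTANCE if on_mask[k] else HBOND_OFF_DISTANCE
            coords[hbond_water] = atoms[nd].pos + d * nd_dir
        frames.append(coords)

    trajectory = Trajectory(topology=topology, frames=frames, dt_label="synthetic")
    truth = {
        "fe": fe,
        "mix_water": mix_water,
        "distances": distances,
        "components": components,
        "hbond_donor": hbond_water,
        "hbond_acceptor": nd,
        "hbond_mask": on_mask,
        "n_hbond_frames": int(on_mask.sum()),
    }
    return trajectory, truth


# ---------------------------------------------------------------------------
# Stick spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StickSpectrumSpec:
    """One dominant Soret-like line plus weak seeded background states."""

    soret_nm: float
    soret_f: float = 1.0
    n_background_states: int = 20
    background_f_max: float = 0.2
    energy_range: tuple[float, float] = (1.8, 5.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.soret_nm <= 0:
            raise SpecError("soret_nm must be positive")
        if self.soret_f <= self.background_f_max:
            raise SpecError(
                "soret_f must exceed background_f_max so the dominant-line "
                "assignment is guaranteed"
            )
        if self.background_f_max < 0 or self.n_background_states < 0:
            raise SpecError("background parameters must be non-negative")
        if not 0 < self.energy_range[0] < self.energy_range[1]:
            raise SpecError("bad energy_range")


def make_stick_spectrum(
    spec: StickSpectrumSpec,
    label: str = "",
    redox_state: Optional[str] = None,
) -> StickSpectrum:
    """Stick spectrum whose strongest line sits exactly at hc/soret_nm."""
    rng = np.random.default_rng(spec.seed)
    soret_ev = HC_EV_NM / spec.soret_nm
    lines = [(soret_ev, spec.soret_f)]
    lo, hi = spec.energy_range
    for _ in range(spec.n_background_states):
        lines.append(
            (float(rng.uniform(lo, hi)), float(rng.uniform(0.0, spec.background_f_max)))
        )
    lines.sort(key=lambda t: t[0])  # upstream codes emit ascending energies
    return StickSpectrum(transitions=lines, label=label, redox_state=redox_state)


# ---------------------------------------------------------------------------
# ESP fit problems
# ---------------------------------------------------------------------------

_VDW_LIKE_RADIUS = 1.7  # Å
_MK_SCALES = (1.4, 1.6, 1.8, 2.0)


def make_esp_problem(
    n_atoms: int,
    layout: str = "random",
    true_charges: Optional[Sequence[float]] = None,
    grid_density: int = 30,
    noise_sd: float = 0.0,
    seed: int = 0,
    neutral_groups: Sequence[tuple[Sequence[int], float]] = (),
    equivalence_sets: Sequence[Sequence[int]] = (),
    restraint_weight: float = 0.0,
) -> tuple[ESPFitProblem, ChargeSet]:
    """Build a seeded shell-grid ESP problem from known point charges.

    Grid points lie on spheres of 1.4-2.0 x a van-der-Waals-like radius
    around each atom, excluding points inside the smallest shell of any other
    atom.  The returned ground truth is the generating :class:`ChargeSet`.
    Declared constraints must be consistent with the true charges.
    """
    if n_atoms < 1:
        raise SpecError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)

    if layout == "random":
        positions = []
        while len(positions) < n_atoms:
            cand = rng.uniform(-2.5, 2.5, size=3)
            if all(np.linalg.norm(cand - p) > 1.2 for p in positions):
                positions.append(cand)
        positions = np.array(positions)
    elif layout == "ring":
        angles = 2 * np.pi * np.arange(n_atoms) / n_atoms
        positions = np.column_stack(
            [2.0 * np.cos(angles), 2.0 * np.sin(angles), np.zeros(n_atoms)]
        )
    else:
        raise SpecError(f"unknown layout {layout!r}")

    if true_charges is None:
        q = rng.uniform(-0.5, 0.5, size=n_atoms)
        q -= q.mean()  # neutral overall by default
    else:
        q = np.asarray(true_charges, dtype=float)
        if len(q) != n_atoms:
            raise SpecError("true_charges length must equal n_atoms")

    total = float(q.sum())
    for idx, target in neutral_groups:
        if abs(q[list(idx)].sum() - target) > 1e-9:
            raise SpecError(f"group {tuple(idx)} inconsistent with true charges")
    for idx in equivalence_sets:
        if np.ptp(q[list(idx)]) > 1e-9:
            raise SpecError(f"equivalence set {tuple(idx)} inconsistent with truth")

    shells = []
    exclusion = _MK_SCALES[0] * _VDW_LIKE_RADIUS
    for scale in _MK_SCALES:
        radius = scale * _VDW_LIKE_RADIUS
        for centre in positions:
            raw = rng.normal(size=(grid_density, 3))
            raw /= np.linalg.norm(raw, axis=1, keepdims=True)
            pts = centre + radius * raw
            dists = np.linalg.norm(
                pts[:, None, :] - positions[None, :, :], axis=2
            )
            keep = dists.min(axis=1) >= exclusion - 1e-9
            shells.append(pts[keep])
    grid = np.concatenate(shells)

    esp = predict_esp(positions, q, grid)
    if noise_sd > 0:
        esp = esp + rng.normal(0.0, noise_sd, size=len(esp))

    problem = ESPFitProblem(
        atom_positions=positions,
        grid_points=grid,
        grid_esp=esp,
        total_charge=total,
        neutral_groups=[(tuple(i), t) for i, t in neutral_groups],
        equivalence_sets=[tuple(i) for i in equivalence_sets],
        restraint_weight=restraint_weight,
    )
    truth = ChargeSet(charges=q, residual_rms=0.0, constraint_violation_max=0.0)
    return problem, truth
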