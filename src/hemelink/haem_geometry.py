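"""Haem-c site descriptors, crosslink classification and bond character.

The descriptor vector mirrors the standard crystallographic report for a
crosslinked haem-c site: coordination distances, crosslink bond lengths, the
iron out-of-plane displacement (distance from Fe to the unweighted centroid
of the four pyrrole nitrogens) and the RMS deviation of the 24-atom
macrocycle core from its least-squares plane.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from hemelink.errors import (
    GeometryError,
    UnsupportedPairError,
    ValidationError,
)
from hemelink.structure_io import HaemSiteMap, Structure


class CrosslinkClass(enum.Enum):
    """Lys-to-haem crosslink state."""

    SC = "SC"  # single: NZ-CHA bonded only
    DC = "DC"  # double: NZ-CHA and CD-C2A both bonded
    AMBIGUOUS = "AMBIGUOUS"  # CD-C2A in the intermediate band
    NONE = "NONE"  # NZ-CHA not bonded


class BondCharacter(enum.Enum):
    SINGLE = "SINGLE"
    DOUBLE = "DOUBLE"
    INTERMEDIATE = "INTERMEDIATE"


#: Heavy-atom distance (Å) at or below which two atoms count as bonded.
DEFAULT_BOND_MAX = 1.80
#: CD-C2A distance (Å) at or above which the second crosslink is clearly absent.
DEFAULT_AMBIGUOUS_MAX = 2.80

#: C-C bond-character cut points (Å): <= double_max -> DOUBLE, >= single_min -> SINGLE.
DEFAULT_CC_DOUBLE_MAX = 1.40
DEFAULT_CC_SINGLE_MIN = 1.48


@dataclass
class GeometryReport:
    """Descriptor vector for one haem-c site.

    ``fe_oop`` is unsigned; ``fe_oop_signed`` is positive when Fe sits on the
    distal side of the pyrrole-N4 plane (opposite the proximal His nitrogen).
    Absent quantities (e.g. no coordinated water) are ``None``.
    """

    fe_his_n: float
    fe_water: Optional[float]
    fe_pyr_n: dict[str, float]
    lys_nz_cha: float
    lys_cd_c2a: Optional[float]
    c3a_cma: float
    fe_oop: float
    fe_oop_signed: float
    ring_rms_dev: Optional[float]
    crosslink_class: Optional[CrosslinkClass] = None
    c3a_cma_character: Optional[BondCharacter] = None
    chain: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.fe_pyr_n) != 4:
            raise ValidationError("fe_pyr_n must have exactly 4 entries")
        for name, value in self.as_dict().items():
            if value is not None and name.startswith(("fe_", "lys_", "c3a")) and not name.endswith("signed"):
                if value < 0:
                    raise ValidationError(f"{name} is negative")
        if abs(self.fe_oop - abs(self.fe_oop_signed)) > 1e-9:
            raise ValidationError("fe_oop must equal |fe_oop_signed|")

    @property
    def fe_pyr_n_min(self) -> float:
        return min(self.fe_pyr_n.values())

    @property
    def fe_pyr_n_max(self) -> float:
        return max(self.fe_pyr_n.values())

    def as_dict(self) -> dict[str, Optional[float]]:
        """Flat numeric view used by :func:`compare_reports` and CSV export."""
        d = {
            "fe_his_n": self.fe_his_n,
            "fe_water": self.fe_water,
            "lys_nz_cha": self.lys_nz_cha,
            "lys_cd_c2a": self.lys_cd_c2a,
            "c3a_cma": self.c3a_cma,
            "fe_oop": self.fe_oop,
            "fe_oop_signed": self.fe_oop_signed,
            "ring_rms_dev": self.ring_rms_dev,
        }
        for ring, value in self.fe_pyr_n.items():
            d[f"fe_pyr_n_{ring}"] = value
        return d


def _fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points; returns (centroid, unit normal)."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear (or coincident) points leave two near-zero singular values
    if points.shape[0] >= 3 and s[1] < 1e-8 * max(s[0], 1e-30):
        raise GeometryError("degenerate (collinear) atom arrangement")
    return centroid, vt[2]


#: Atom-name stems of the 24-atom porphine macrocycle core.
MACROCYCLE_NAMES = tuple(
    f"{stem}{ring}"
    for ring in "ABCD"
    for stem in ("N", "C1", "C2", "C3", "C4")
) + ("CHA", "CHB", "CHC", "CHD")


def compute_descriptors(
    structure: Structure,
    site: HaemSiteMap,
    model: int = 0,
    label: str = "",
) -> GeometryReport:
    """Compute the descriptor vector for a mapped haem site.

    Classifications (crosslink state, C3A-CMA bond character) are filled in
    with default thresholds; re-run the classifiers for custom thresholds.
    """
    atoms = structure.models[model]
    pos = lambda h: atoms[h].pos

    fe = pos(site.fe)
    n4 = np.array([pos(h) for h in (site.na, site.nb, site.nc, site.nd)])
    centroid = n4.mean(axis=0)
    _, normal = _fit_plane(n4)

    fe_oop = float(np.linalg.norm(fe - centroid))
    side_fe = float(np.dot(fe - centroid, normal))
    side_his = float(np.dot(pos(site.his_n) - centroid, normal))
    # positive sign = Fe displaced to the distal side (away from proximal His)
    if side_fe == 0.0:
        fe_oop_signed = fe_oop if side_his <= 0 else -fe_oop
    else:
        fe_oop_signed = fe_oop if side_fe * side_his < 0 else -fe_oop

    dist = lambda h1, h2: float(np.linalg.norm(pos(h1) - pos(h2)))

    fe_pyr_n = {
        ring: dist(site.fe, handle)
        for ring, handle in site.pyrrole_n_handles().items()
    }

    ring_rms = None
    core = [
        a.pos
        for a in atoms
        if a.name in MACROCYCLE_NAMES
        and a.chain == site.chain
        and a.resname == atoms[site.fe].resname
    ]
    if len(core) >= 3:
        core = np.asarray(core)
        c, nrm = _fit_plane(core)
        ring_rms = float(np.sqrt(np.mean(((core - c) @ nrm) ** 2)))

    report = GeometryReport(
        fe_his_n=dist(site.fe, site.his_n),
        fe_water=dist(site.fe, site.water_o) if site.water_o is not None else None,
        fe_pyr_n=fe_pyr_n,
        lys_nz_cha=dist(site.lys_nz, site.cha),
        lys_cd_c2a=dist(site.lys_cd, site.c2a),
        c3a_cma=dist(site.c3a, site.cma),
        fe_oop=fe_oop,
        fe_oop_signed=fe_oop_signed,
        ring_rms_dev=ring_rms,
        chain=site.chain,
        label=label,
    )
    report.crosslink_class = classify_crosslink(
        report.lys_nz_cha, report.lys_cd_c2a
    )
    report.c3a_cma_character = assign_bond_character(report.c3a_cma)
    return report


def classify_crosslink(
    lys_nz_cha: float,
    lys_cd_c2a: Optional[float],
    bond_max: float = DEFAULT_BOND_MAX,
    ambiguous_max: float = DEFAULT_AMBIGUOUS_MAX,
) -> CrosslinkClass:
    """Classify the Lys-haem crosslink state from the two contact distances.

    An NZ-CHA distance within ``bond_max`` is required for any crosslink.
    Given that, the CD-C2A distance decides: bonded (<= ``bond_max``) -> DC,
    clearly unbonded (>= ``ambiguous_max``) or absent -> SC, in between ->
    AMBIGUOUS.
    """
    if bond_max >= ambiguous_max:
        raise ValidationError("bond_max must be < ambiguous_max")
    if lys_nz_cha < 0 or (lys_cd_c2a is not None and lys_cd_c2a < 0):
        raise ValidationError("distances must be non-negative")
    if lys_nz_cha > bond_max:
        return CrosslinkClass.NONE
    if lys_cd_c2a is None or lys_cd_c2a >= ambiguous_max:
        return CrosslinkClass.SC
    if lys_cd_c2a <= bond_max:
        return CrosslinkClass.DC
    return CrosslinkClass.AMBIGUOUS


def assign_bond_character(
    length: float,
    pair: tuple[str, str] = ("C", "C"),
    double_max: float = DEFAULT_CC_DOUBLE_MAX,
    single_min: float = DEFAULT_CC_SINGLE_MIN,
) -> BondCharacter:
    """Assign single/double/intermediate character to a bond length."""
    if length <= 0:
        raise ValidationError("bond length must be positive")
    if tuple(e.upper() for e in pair) != ("C", "C"):
        raise UnsupportedPairError(
            f"no bond-character table for pair {pair!r} (only C-C supported)"
        )
    if double_max >= single_min:
        raise ValidationError("double_max must be < single_min")
    if length <= double_max:
        return BondCharacter.DOUBLE
    if length >= single_min:
        return BondCharacter.SINGLE
    return BondCharacter.INTERMEDIATE


def compare_reports(a: GeometryReport, b: GeometryReport) -> dict[str, Optional[float]]:
    """Signed per-descriptor deltas ``b - a``; absent values propagate as None."""
    da, db = a.as_dict(), b.as_dict()
    if set(da) != set(db):
        raise ValidationError("reports have different descriptor schemas")
    return {
        k: (None if da[k] is None or db[k] is None else db[k] - da[k])
        for k in da
    }
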