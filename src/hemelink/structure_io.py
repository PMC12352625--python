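"""Coordinate-file I/O, altloc resolution and haem-c site mapping.

Structures are held as plain lists of :class:`AtomRecord` per model, in Å.
PDB and mmCIF parsing is delegated to :mod:`biotite`; XYZ frames (which carry
element symbols only) are parsed directly.  Atom *handles* are integer indices
into a model's atom list.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from hemelink.errors import (
    AmbiguousSiteError,
    ParseError,
    SiteNotFoundError,
    ValidationError,
)

#: Residue names accepted as a haem group, in preference order.
DEFAULT_HAEM_RESNAMES = ("HEC", "HEM", "HEB")

#: Residue names accepted as water.
DEFAULT_WATER_RESNAMES = ("HOH", "WAT", "TIP3", "SOL")

#: Default search cutoff (Å) for the distal water oxygen around Fe.
DEFAULT_WATER_CUTOFF = 4.0


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one model.

    Coordinates are Å.  ``altloc`` is a single character or ``""`` when the
    atom has no alternate location.
    """

    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    element: str
    occupancy: float
    bfactor: float
    pos: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=float))
        if self.pos.shape != (3,):
            raise ValidationError(f"atom {self.name}: pos must be a 3-vector")
        if not np.all(np.isfinite(self.pos)):
            raise ValidationError(f"atom {self.name}: non-finite coordinates")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError(
                f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]"
            )


@dataclass
class Structure:
    """An ordered list of models, each an ordered list of atoms."""

    models: list[list[AtomRecord]]
    source_format: str = "pdb"
    id: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise ValidationError("a Structure needs at least one model")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def atoms(self, model: int = 0) -> list[AtomRecord]:
        return self.models[model]

    def coords(self, model: int = 0) -> np.ndarray:
        """(N, 3) coordinate array for one model."""
        return np.array([a.pos for a in self.models[model]], dtype=float)


@dataclass(frozen=True)
class HaemSiteMap:
    """Integer atom handles for the named atoms of a P460 haem-c site.

    All handles index into a single model's atom list; ``water_o`` is ``None``
    when no water oxygen lies within the search cutoff of Fe.
    """

    fe: int
    na: int
    nb: int
    nc: int
    nd: int
    cha: int
    c2a: int
    c3a: int
    cma: int
    cac: int
    cbc: int
    his_n: int
    lys_nz: int
    lys_cd: int
    lys_ce: int
    chain: str
    water_o: Optional[int] = None

    def pyrrole_n_handles(self) -> dict[str, int]:
        return {"A": self.na, "B": self.nb, "C": self.nc, "D": self.nd}


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_FORMAT_BY_SUFFIX = {
    ".pdb": "pdb",
    ".ent": "pdb",
    ".cif": "mmcif",
    ".mmcif": "mmcif",
    ".xyz": "xyz",
}


def _sniff_format(path: Path, format_hint: Optional[str]) -> str:
    if format_hint is not None:
        fmt = format_hint.lower()
        if fmt not in ("pdb", "mmcif", "xyz"):
            raise ValidationError(f"unknown format hint {format_hint!r}")
        return fmt
    fmt = _FORMAT_BY_SUFFIX.get(path.suffix.lower())
    if fmt is None:
        raise ValidationError(
            f"cannot infer format of {path.name!r}; pass format_hint"
        )
    return fmt


def _from_atom_array(arr, serial_offset: int = 0) -> list[AtomRecord]:
    """Convert a biotite AtomArray (altloc='all') to AtomRecord list."""
    atoms = []
    has_altloc = "altloc_id" in arr.get_annotation_categories()
    has_occ = "occupancy" in arr.get_annotation_categories()
    has_b = "b_factor" in arr.get_annotation_categories()
    has_id = "atom_id" in arr.get_annotation_categories()
    for i in range(arr.array_length()):
        altloc = arr.altloc_id[i].strip() if has_altloc else ""
        if altloc == ".":
            altloc = ""
        atoms.append(
            AtomRecord(
                serial=int(arr.atom_id[i]) if has_id else serial_offset + i + 1,
                name=str(arr.atom_name[i]),
                altloc=altloc,
                resname=str(arr.res_name[i]),
                chain=str(arr.chain_id[i]),
                resseq=int(arr.res_id[i]),
                element=str(arr.element[i]).upper(),
                occupancy=float(arr.occupancy[i]) if has_occ else 1.0,
                bfactor=float(arr.b_factor[i]) if has_b else 0.0,
                pos=np.asarray(arr.coord[i], dtype=float),
            )
        )
    return atoms


def _read_pdb(path: Path) -> Structure:
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb_file = PDBFile.read(str(path))
    except Exception as exc:  # biotite raises a mix of errors on bad files
        raise ParseError(f"{path}: {exc}") from exc
    n_models = pdb_file.get_model_count()
    models = []
    for m in range(1, n_models + 1):
        arr = pdb_file.get_structure(
            model=m,
            altloc="all",
            extra_fields=["occupancy", "b_factor", "atom_id"],
        )
        models.append(_from_atom_array(arr))
    return Structure(models=models, source_format="pdb", id=path.stem)


def _read_mmcif(path: Path) -> Structure:
    from biotite.structure.io.pdbx import CIFFile, get_structure

    try:
        cif = CIFFile.read(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    stack = get_structure(
        cif, altloc="all", extra_fields=["occupancy", "b_factor", "atom_id"]
    )
    models = [_from_atom_array(stack[m]) for m in range(stack.stack_depth())]
    return Structure(models=models, source_format="mmcif", id=path.stem)


def _read_xyz(path: Path) -> Structure:
    """Parse an XYZ frame stack: count line, comment line, element x y z rows."""
    models: list[list[AtomRecord]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ParseError(
                f"{path}: line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from exc
        if i + 2 + n > len(lines):
            raise ParseError(f"{path}: truncated frame starting at line {i + 1}")
        atoms = []
        for j in range(n):
            lineno = i + 2 + j
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: line {lineno + 1}: expected 'element x y z'"
                )
            try:
                pos = np.array([float(p) for p in parts[1:4]])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno + 1}: bad coordinate in {parts[1:4]}"
                ) from exc
            element = parts[0].upper()
            atoms.append(
                AtomRecord(
                    serial=j + 1,
                    name=element,
                    altloc="",
                    resname="UNK",
                    chain="A",
                    resseq=1,
                    element=element,
                    occupancy=1.0,
                    bfactor=0.0,
                    pos=pos,
                )
            )
        models.append(atoms)
        i += 2 + n
    if not models:
        raise ParseError(f"{path}: no frames found")
    return Structure(models=models, source_format="xyz", id=path.stem)


def read_structure(path, format_hint: Optional[str] = None) -> Structure:
    """Read a PDB, mmCIF or XYZ file into a :class:`Structure`.

    Parameters
    ----------
    path
        File to read.
    format_hint
        One of ``"pdb"``, ``"mmcif"``, ``"xyz"``; inferred from the suffix
        when omitted.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path, format_hint)
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "mmcif":
        return _read_mmcif(path)
    return _read_xyz(path)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_pdb(structure: Structure, path) -> None:
    """Write all models in fixed-column PDB format (HETATM for non-polymer)."""
    multi = structure.n_models > 1
    with open(path, "w") as fh:
        for m, atoms in enumerate(structure.models, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for a in atoms:
                record = "HETATM" if a.resname in ("HOH", "WAT", "UNK") or a.resname.startswith("HE") else "ATOM  "
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    f"{record}{a.serial:5d} {name}{a.altloc or ' '}"
                    f"{a.resname:<3s} {a.chain:1s}{a.resseq:4d}    "
                    f"{a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}"
                    f"{a.occupancy:6.2f}{a.bfactor:6.2f}"
                    f"          {a.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_xyz(structure: Structure, path) -> None:
    """Write all models as an XYZ frame stack (element symbols only)."""
    with open(path, "w") as fh:
        for m, atoms in enumerate(structure.models):
            fh.write(f"{len(atoms)}\n")
            fh.write(f"{structure.id or 'hemelink'} frame {m}\n")
            for a in atoms:
                fh.write(
                    f"{a.element:<2s} {a.pos[0]:15.6f} {a.pos[1]:15.6f} {a.pos[2]:15.6f}\n"
                )


# ---------------------------------------------------------------------------
# Altloc resolution
# ---------------------------------------------------------------------------


def resolve_altlocs(
    structure: Structure, policy: str = "max_occupancy_then_min_b"
) -> Structure:
    """Keep one copy of each (chain, resseq, name) per model.

    The retained copy has maximal occupancy; ties are broken by minimal
    B-factor, then by altloc label order.  Atoms without alternate locations
    pass through unchanged, so the operation is idempotent.
    """
    if policy != "max_occupancy_then_min_b":
        raise ValidationError(f"unknown altloc policy {policy!r}")
    new_models = []
    for atoms in structure.models:
        best: dict[tuple, AtomRecord] = {}
        order: list[tuple] = []
        for a in atoms:
            key = (a.chain, a.resseq, a.name)
            if key not in best:
                best[key] = a
                order.append(key)
            else:
                b = best[key]
                if (-a.occupancy, a.bfactor, a.altloc) < (
                    -b.occupancy,
                    b.bfactor,
                    b.altloc,
                ):
                    best[key] = a
        new_models.append([replace(best[k], altloc="") for k in order])
    return Structure(
        models=new_models, source_format=structure.source_format, id=structure.id
    )


# ---------------------------------------------------------------------------
# Haem-site mapping
# ---------------------------------------------------------------------------

_HAEM_ATOM_NAMES = {
    "fe": "FE",
    "na": "NA",
    "nb": "NB",
    "nc": "NC",
    "nd": "ND",
    "cha": "CHA",
    "c2a": "C2A",
    "c3a": "C3A",
    "cma": "CMA",
    "cac": "CAC",
    "cbc": "CBC",
}


def default_site_config() -> dict:
    """Default naming tables and cutoffs for :func:`map_haem_site`."""
    return {
        "haem_resnames": list(DEFAULT_HAEM_RESNAMES),
        "water_resnames": list(DEFAULT_WATER_RESNAMES),
        "water_cutoff": DEFAULT_WATER_CUTOFF,
        "haem_atoms": dict(_HAEM_ATOM_NAMES),
    }


def _dist(a: AtomRecord, b: AtomRecord) -> float:
    return float(np.linalg.norm(a.pos - b.pos))


def map_haem_site(
    structure: Structure,
    chain: str,
    config: Optional[dict] = None,
    model: int = 0,
) -> HaemSiteMap:
    """Resolve the named haem-c site atoms on ``chain`` to handles.

    The crosslinking lysine is the LYS whose NZ is nearest the haem CHA; the
    proximal histidine nitrogen is the HIS nitrogen nearest Fe; the distal
    water is the water oxygen nearest Fe if within ``config['water_cutoff']``.

    For XYZ input (no residue metadata) supply ``config['index_table']``
    mapping handle names directly to atom indices.
    """
    cfg = default_site_config()
    if config:
        cfg.update(config)
    atoms = structure.models[model]

    if "index_table" in cfg and cfg["index_table"]:
        table = dict(cfg["index_table"])
        return HaemSiteMap(chain=chain, **table)
    if structure.source_format == "xyz":
        raise ValidationError(
            "XYZ input has no residue metadata; provide config['index_table']"
        )

    haem_residues: dict[tuple, dict[str, int]] = {}
    for i, a in enumerate(atoms):
        if a.chain == chain and a.resname in cfg["haem_resnames"]:
            haem_residues.setdefault((a.resname, a.resseq), {})[a.name] = i
    if not haem_residues:
        raise SiteNotFoundError(
            f"no haem residue ({'/'.join(cfg['haem_resnames'])}) on chain {chain!r}"
        )
    if len(haem_residues) > 1:
        cands = ", ".join(f"{rn} {rs}" for rn, rs in sorted(haem_residues))
        raise AmbiguousSiteError(
            f"multiple haem residues on chain {chain!r}: {cands}"
        )
    name_to_idx = next(iter(haem_residues.values()))

    handles: dict[str, int] = {}
    for handle, atom_name in cfg["haem_atoms"].items():
        if atom_name not in name_to_idx:
            raise SiteNotFoundError(
                f"haem atom {atom_name!r} not found on chain {chain!r}"
            )
        handles[handle] = name_to_idx[atom_name]
    fe = atoms[handles["fe"]]
    for h in ("na", "nb", "nc", "nd"):
        if not atoms[handles[h]].element.startswith("N"):
            raise ValidationError(f"pyrrole handle {h} is not a nitrogen")
    if fe.element != "FE":
        raise ValidationError("fe handle does not resolve to an iron atom")

    # proximal His N: His nitrogen nearest Fe (tolerates ND1/NE2 naming variants)
    his_n, his_d = None, math.inf
    for i, a in enumerate(atoms):
        if a.resname == "HIS" and a.element == "N" and a.name != "N":
            d = _dist(a, fe)
            if d < his_d:
                his_n, his_d = i, d
    if his_n is None:
        raise SiteNotFoundError("no histidine sidechain nitrogen found")

    # crosslinking Lys: the LYS whose NZ is nearest the haem CHA
    cha = atoms[handles["cha"]]
    lys_key, lys_d = None, math.inf
    for i, a in enumerate(atoms):
        if a.resname == "LYS" and a.name == "NZ":
            d = _dist(a, cha)
            if d < lys_d:
                lys_key, lys_d = (a.chain, a.resseq), d
    if lys_key is None:
        raise SiteNotFoundError("no lysine NZ found for crosslink mapping")
    lys_atoms = {
        a.name: i
        for i, a in enumerate(atoms)
        if (a.chain, a.resseq) == lys_key and a.resname == "LYS"
    }
    for needed in ("NZ", "CD", "CE"):
        if needed not in lys_atoms:
            raise SiteNotFoundError(
                f"crosslinking Lys {lys_key} lacks atom {needed}"
            )

    # distal water: nearest water O to Fe within cutoff
    water_o, water_d = None, float(cfg["water_cutoff"])
    for i, a in enumerate(atoms):
        if a.resname in cfg["water_resnames"] and a.element == "O":
            d = _dist(a, fe)
            if d <= water_d:
                water_o, water_d = i, d

    return HaemSiteMap(
        chain=chain,
        water_o=water_o,
        his_n=his_n,
        lys_nz=lys_atoms["NZ"],
        lys_cd=lys_atoms["CD"],
        lys_ce=lys_atoms["CE"],
        **handles,
    )
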