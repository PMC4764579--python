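"""Shared coordinate data model and file I/O.

The pipeline exchanges three kinds of data: multi-model PDB coordinate
files (NMR ensembles, trajectory frames), CCP4/MRC density maps, and
plain-text distance-restraint tables.  This module defines the in-memory
containers (:class:`Atom`, :class:`Structure`, :class:`DensityMap`,
:class:`RestraintSet`) and the readers/writers.

Conventions
-----------
* Residue numbering is 1-based PDB convention.  Insertion codes are not
  supported and raise a parse error.
* Hydrogens are parsed and kept; heavy-atom filtering happens downstream
  (in :mod:`toxinterface.contacts` and the SASA code), in one place.
* Density-map axis order is normalized to (x, y, z) at read time; all
  downstream code assumes canonical order.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Atomic masses (amu) for elements the pipeline handles.  Lookup is
#: total: an element missing from this table raises, never a default.
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "ZN": 65.38,
    "FE": 55.845,
    "SE": 78.971,
}

#: Two-letter element symbols that can appear left-justified in a PDB
#: atom-name field (column 13).  "CA" here means calcium; a C-alpha atom
#: name is right-justified (" CA ") and resolves to carbon.
_TWO_LETTER = {"CL", "BR", "NA", "MG", "CA", "ZN", "FE", "SE"}


class PDBParseError(ValueError):
    """Malformed PDB record; message carries the offending line number."""


class UnknownElementError(ValueError):
    """Element symbol not in the mass table."""


def element_mass(element: str) -> float:
    key = element.strip().upper()
    try:
        return ATOMIC_MASS[key]
    except KeyError:
        raise UnknownElementError(
            f"unknown element symbol {element!r}; known: {sorted(ATOMIC_MASS)}"
        ) from None


@dataclass(frozen=True)
class Atom:
    """A single atom in one model of a structure.

    Coordinates are in Angstrom; ``model_id`` is the 1-based frame/model
    index.  ``mass`` is looked up from :data:`ATOMIC_MASS` and is always
    positive.
    """

    serial: int
    name: str
    element: str
    mass: float
    res_name: str
    res_seq: int
    chain_id: str
    coords: np.ndarray
    model_id: int = 1

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be positive")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.res_name)

    def label(self) -> str:
        return f"{self.chain_id}{self.res_seq}{self.res_name}"


@dataclass
class Structure:
    """An ordered collection of atoms, possibly over several models.

    Models represent NMR ensemble members or trajectory frames.  When
    there is more than one model, every model must contain the same atom
    roster (same serial/name/residue sequence), which :meth:`validate`
    enforces.
    """

    atoms: list[Atom] = field(default_factory=list)
    title: str = ""

    def __post_init__(self):
        self.atoms = sorted(self.atoms, key=lambda a: (a.model_id, a.serial))

    @property
    def model_ids(self) -> list[int]:
        return sorted({a.model_id for a in self.atoms})

    @property
    def n_models(self) -> int:
        return len(self.model_ids)

    def model(self, model_id: int) -> list[Atom]:
        out = [a for a in self.atoms if a.model_id == model_id]
        if not out:
            raise KeyError(f"no model {model_id}; have {self.model_ids}")
        return out

    def iter_models(self) -> Iterable[tuple[int, list[Atom]]]:
        for mid in self.model_ids:
            yield mid, self.model(mid)

    def coords(self, model_id: int | None = None) -> np.ndarray:
        atoms = self.model(model_id) if model_id is not None else self.atoms
        return np.array([a.coords for a in atoms])

    def validate(self) -> None:
        """Check the same-roster invariant across models."""
        rosters = {}
        for mid, atoms in self.iter_models():
            rosters[mid] = [(a.serial, a.name, a.res_name, a.res_seq, a.chain_id)
                            for a in atoms]
        vals = list(rosters.values())
        for mid, roster in rosters.items():
            if roster != vals[0]:
                raise ValueError(f"model {mid} has a different atom roster")

    def with_atoms(self, atoms: Sequence[Atom]) -> "Structure":
        return Structure(atoms=list(atoms), title=self.title)


@dataclass
class DensityMap:
    """A 3-D scalar density grid with voxel spacing and origin (Angstrom).

    ``grid[i, j, k]`` is the density at position
    ``origin + (i, j, k) * voxel`` — axis order is always (x, y, z).
    """

    grid: np.ndarray
    voxel: np.ndarray
    origin: np.ndarray
    normalized_flag: bool = False

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.voxel = np.broadcast_to(np.asarray(self.voxel, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("grid must be 3-D with >=2 samples per axis")
        if np.any(self.voxel <= 0):
            raise ValueError("voxel spacing must be positive on all axes")

    def normalized(self) -> "DensityMap":
        """Return a copy rescaled to unit maximum (positive peak = 1)."""
        peak = self.grid.max()
        if peak <= 0:
            raise ValueError("cannot normalize a map with non-positive maximum")
        return DensityMap(self.grid / peak, self.voxel, self.origin,
                          normalized_flag=True)

    def same_grid_as(self, other: "DensityMap") -> bool:
        return (self.grid.shape == other.grid.shape
                and np.allclose(self.voxel, other.voxel)
                and np.allclose(self.origin, other.origin))


@dataclass(frozen=True)
class Restraint:
    """Upper-bound distance restraint between two atom selectors."""

    selector_a: tuple[str, int, str]  # (chain_id, res_seq, atom_name)
    selector_b: tuple[str, int, str]
    upper_bound: float

    def __post_init__(self):
        if self.upper_bound <= 0:
            raise ValueError("restraint upper bound must be positive")


@dataclass
class RestraintSet:
    entries: list[Restraint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


# ---------------------------------------------------------------------------
# PDB

def _infer_element(name_field: str) -> str:
    """Infer the element from a raw 4-char atom-name field.

    Right-justified one-letter elements (" CA " = C-alpha) vs
    left-justified two-letter elements ("CA  " = calcium, "FE  ") follow
    standard PDB column justification; leading digits (e.g. "1HB2")
    indicate hydrogens and are stripped.
    """
    raw = name_field
    stripped = raw.strip().lstrip("0123456789")
    if not stripped:
        raise UnknownElementError(f"cannot infer element from atom name {raw!r}")
    if raw[:1] != " " and stripped[:2].upper() in _TWO_LETTER:
        return stripped[:2].upper()
    return stripped[0].upper()


def parse_pdb(text: str) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    One :class:`Atom` per ATOM/HETATM record.  The element comes from
    columns 77-78 when present, otherwise it is inferred from the atom
    name.  MODEL/ENDMDL blocks are optional; single-model files get
    ``model_id = 1``.  Non-blank insertion codes are rejected.
    """
    atoms: list[Atom] = []
    title_parts: list[str] = []
    model_id = 0
    in_model = False
    seen_record = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            try:
                model_id = int(line[6:].split()[0])
            except (IndexError, ValueError):
                raise PDBParseError(f"line {lineno}: malformed MODEL record")
            in_model = True
        elif rec == "ENDMDL":
            in_model = False
        elif rec.startswith("TITLE"):
            title_parts.append(line[10:].strip())
        elif rec in ("ATOM  ", "HETATM"):
            seen_record = True
            if not in_model and model_id == 0:
                model_id = 1
            try:
                serial = int(line[6:11])
                name_field = line[12:16]
                icode = line[26:27]
                res_name = line[17:20].strip()
                chain_id = line[21:22]
                res_seq = int(line[22:26])
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed fixed-width ATOM/HETATM record"
                ) from None
            if icode.strip():
                raise PDBParseError(
                    f"line {lineno}: insertion code {icode!r} not supported"
                )
            elem_field = line[76:78].strip() if len(line) >= 78 else ""
            element = elem_field.upper() if elem_field else _infer_element(name_field)
            mass = element_mass(element)
            atoms.append(Atom(serial=serial, name=name_field.strip(),
                              element=element, mass=mass, res_name=res_name,
                              res_seq=res_seq, chain_id=chain_id,
                              coords=np.array(xyz), model_id=max(model_id, 1)))
    if not seen_record:
        raise PDBParseError("no ATOM/HETATM records found")
    s = Structure(atoms=atoms, title=" ".join(title_parts))
    s.validate()
    return s


def _format_atom_name(atom: Atom) -> str:
    name = atom.name
    if len(name) >= 4:
        return name[:4]
    # one-letter elements are right-shifted by one column
    if len(atom.element) == 1 and not name[:1].isdigit():
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure) -> str:
    """Serialize a :class:`Structure` as fixed-width PDB text.

    Coordinates are printed with 3 decimals; multi-model structures are
    wrapped in MODEL/ENDMDL blocks.  Hybrid-36 numbering is not
    supported: ``serial > 99999`` or ``res_seq > 9999`` raise.
    """
    if not structure.atoms:
        raise ValueError("cannot write an empty structure")
    lines: list[str] = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    multi = structure.n_models > 1
    for mid, atoms in structure.iter_models():
        if multi:
            lines.append(f"MODEL     {mid:4d}")
        for a in atoms:
            if a.serial > 99999:
                raise ValueError(f"serial {a.serial} > 99999 (no hybrid-36 support)")
            if a.res_seq > 9999:
                raise ValueError(f"res_seq {a.res_seq} > 9999 (no hybrid-36 support)")
            x, y, z = a.coords
            lines.append(
                f"ATOM  {a.serial:5d} {_format_atom_name(a)} "
                f"{a.res_name:<3s} {a.chain_id}{a.res_seq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element.upper():>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# CCP4/MRC maps (via gemmi; axis order normalized to x,y,z on read)

def read_map(path: str) -> DensityMap:
    """Read a CCP4/MRC 2014 density map.

    Axis order is normalized to (x, y, z) regardless of the header's
    MAPC/MAPR/MAPS permutation.  The voxel size comes from the cell
    dimensions divided by the sampling; the origin from the header
    ORIGIN fields (plus any start-index offset).
    """
    try:
        m = gemmi.read_ccp4_map(str(path), setup=True)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"not a valid CCP4/MRC map: {path} ({exc})") from exc
    cell = m.grid.unit_cell
    if not (np.isclose(cell.alpha, 90) and np.isclose(cell.beta, 90)
            and np.isclose(cell.gamma, 90)):
        raise NotImplementedError("non-orthogonal map cells are not supported")
    grid = np.array(m.grid.array, dtype=float)
    voxel = np.array(m.grid.spacing, dtype=float)
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=float)
    return DensityMap(grid=grid, voxel=voxel, origin=origin)


def write_map(density: DensityMap, path: str) -> None:
    """Write a :class:`DensityMap` as a CCP4/MRC file (canonical axis order)."""
    nx, ny, nz = density.grid.shape
    g = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(g.array)[:] = density.grid.astype(np.float32)
    g.unit_cell = gemmi.UnitCell(nx * density.voxel[0], ny * density.voxel[1],
                                 nz * density.voxel[2], 90.0, 90.0, 90.0)
    g.spacegroup = gemmi.SpaceGroup("P1")
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for w, v in zip((50, 51, 52), density.origin):
        m.set_header_float(w, float(v))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Restraint tables

def parse_restraints(text: str) -> RestraintSet:
    """Parse a whitespace-delimited restraint table.

    Each data line is ``chainA resA atomA chainB resB atomB upper``;
    ``#`` comment lines and blank lines are skipped.  This simplified
    format is a stand-in for refinement-package restraint dialects,
    which are not standardized in plain text.
    """
    entries: list[Restraint] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) != 7:
            raise PDBParseError(
                f"line {lineno}: expected 7 fields "
                f"(chainA resA atomA chainB resB atomB upper), got {len(fields)}"
            )
        try:
            res_a, res_b = int(fields[1]), int(fields[4])
            upper = float(fields[6])
        except ValueError:
            raise PDBParseError(f"line {lineno}: malformed numeric field") from None
        if upper <= 0:
            raise ValueError(f"line {lineno}: upper bound must be positive, got {upper}")
        entries.append(Restraint(
            selector_a=(fields[0], res_a, fields[2]),
            selector_b=(fields[3], res_b, fields[5]),
            upper_bound=upper,
        ))
    return RestraintSet(entries=entries)


# ---------------------------------------------------------------------------
# Atom selection helper shared by the analysis modules

@dataclass(frozen=True)
class Selection:
    """A declarative atom filter over chains / residues / atom names.

    ``None`` fields match everything.  ``res_seqs`` may be an explicit
    collection of residue numbers.
    """

    chains: frozenset[str] | None = None
    res_seqs: frozenset[int] | None = None
    res_names: frozenset[str] | None = None
    atom_names: frozenset[str] | None = None
    heavy_only: bool = False

    @classmethod
    def make(cls, chains=None, res_seqs=None, res_names=None, atom_names=None,
             heavy_only=False) -> "Selection":
        conv = lambda v: None if v is None else frozenset(
            [v] if isinstance(v, (str, int)) else v)
        return cls(chains=conv(chains), res_seqs=conv(res_seqs),
                   res_names=conv(res_names), atom_names=conv(atom_names),
                   heavy_only=heavy_only)

    def matches(self, atom: Atom) -> bool:
        if self.heavy_only and atom.is_hydrogen:
            return False
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.res_seqs is not None and atom.res_seq not in self.res_seqs:
            return False
        if self.res_names is not None and atom.res_name not in self.res_names:
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        return True

    def apply(self, atoms: Iterable[Atom]) -> list[Atom]:
        return [a for a in atoms if self.matches(a)]


def parse_selection(expr: str) -> Selection:
    """Parse a small selection expression used by the CLI.

    Grammar: comma/space separated clauses ``chain A B``, ``resid 2-31``
    (or single numbers), ``resname TRP``, ``name CA CB``, ``heavy``.
    """
    chains: set[str] = set()
    res_seqs: set[int] = set()
    res_names: set[str] = set()
    atom_names: set[str] = set()
    heavy = False
    tokens = expr.replace(",", " ").split()
    i = 0
    mode = None
    while i < len(tokens):
        tok = tokens[i]
        low = tok.lower()
        if low in ("chain", "resid", "resname", "name"):
            mode = low
        elif low == "heavy":
            heavy = True
        elif mode == "chain":
            chains.add(tok)
        elif mode == "resid":
            if "-" in tok:
                a, b = tok.split("-")
                res_seqs.update(range(int(a), int(b) + 1))
            else:
                res_seqs.add(int(tok))
        elif mode == "resname":
            res_names.add(tok.upper())
        elif mode == "name":
            atom_names.add(tok.upper())
        else:
            raise ValueError(f"cannot parse selection token {tok!r} in {expr!r}")
        i += 1
    return Selection.make(chains=chains or None, res_seqs=res_seqs or None,
                          res_names=res_names or None,
                          atom_names=atom_names or None, heavy_only=heavy)
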