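"""Structures, atom typing, and the common reference frame.

Pocket descriptors are only comparable when every conformation sits in the
same coordinate frame: the anchor atom (the heme iron for cytochromes P450)
at the origin and the anchor plane (the heme ring) in the xy-plane, with +z
pointing into the pocket.  This module parses PDB files (via biotite), assigns
van der Waals radii and partial charges from plain tabular tables, computes
the anchor reference frame, and superposes structures on a matched atom
selection (Kabsch, proper rotations only).

Radii default to a Bondi-type element table; charges default to a simplified
force-field-like residue/atom table packaged with the code.  Both are
user-overridable from TSV files, since the descriptors only require radii and
charges that are *consistent* across the structures being compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

logger = logging.getLogger(__name__)

__all__ = [
    "Atom", "Structure", "ReferenceFrame",
    "read_structure", "write_structure",
    "assign_radii", "assign_charges",
    "load_radii_table", "load_charge_table",
    "compute_reference_frame", "superpose",
    "select_atoms",
    "BONDI_RADII", "DEFAULT_CHARGES", "BACKBONE_NAMES",
    "DEFAULT_EXCLUDED_RESNAMES", "WATER_ION_RESNAMES",
    "FormatError", "SelectionError", "PairingError", "DegenerateGeometryError",
    "RadiusLookupError", "EmptyStructureError",
]


class FormatError(ValueError):
    """Unparsable structure file."""


class EmptyStructureError(ValueError):
    """A model with no atoms was requested."""


class SelectionError(ValueError):
    """An atom selection matched nothing (or the wrong count)."""


class PairingError(ValueError):
    """Superposition selections could not be paired."""


class DegenerateGeometryError(ValueError):
    """Plane-defining atoms are collinear or otherwise degenerate."""


class RadiusLookupError(KeyError):
    """Elements missing from the radius table with no fallback configured."""


# Bondi-type van der Waals radii, Å.  Metals get rounded literature values;
# only consistency across compared structures matters for the descriptors.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "FE": 2.00, "ZN": 1.39, "MG": 1.73, "NA": 2.27, "K": 2.75,
    "CA": 2.31, "MN": 2.05, "CU": 1.40, "SE": 1.90,
}

# Simplified residue/atom partial charges, e.  "*" matches any residue.
# Backbone amide dipole plus the strongly charged side-chain termini; apolar
# carbons and hydrogens default to 0 through the fallback.
DEFAULT_CHARGES: dict[tuple[str, str], float] = {
    ("*", "N"): -0.31, ("*", "H"): 0.31, ("*", "HN"): 0.31,
    ("*", "C"): 0.45, ("*", "O"): -0.45,
    ("*", "OXT"): -0.635, ("*", "OT1"): -0.635, ("*", "OT2"): -0.635,
    ("ASP", "CG"): 0.27, ("ASP", "OD1"): -0.635, ("ASP", "OD2"): -0.635,
    ("GLU", "CD"): 0.27, ("GLU", "OE1"): -0.635, ("GLU", "OE2"): -0.635,
    ("LYS", "NZ"): 0.129, ("LYS", "HZ1"): 0.248, ("LYS", "HZ2"): 0.248,
    ("LYS", "HZ3"): 0.248, ("LYS", "CE"): 0.127,
    ("ARG", "CZ"): 0.52, ("ARG", "NH1"): -0.26, ("ARG", "NH2"): -0.26,
    ("ARG", "NE"): -0.26, ("ARG", "HE"): 0.30,
    ("ARG", "HH11"): 0.31, ("ARG", "HH12"): 0.31,
    ("ARG", "HH21"): 0.31, ("ARG", "HH22"): 0.31,
    ("HIS", "ND1"): -0.30, ("HIS", "NE2"): -0.30,
    ("SER", "OG"): -0.548, ("SER", "HG"): 0.398,
    ("THR", "OG1"): -0.548, ("THR", "HG1"): 0.398,
    ("TYR", "OH"): -0.548, ("TYR", "HH"): 0.398,
    ("ASN", "OD1"): -0.45, ("ASN", "ND2"): -0.72,
    ("ASN", "HD21"): 0.36, ("ASN", "HD22"): 0.36, ("ASN", "CG"): 0.45,
    ("GLN", "OE1"): -0.45, ("GLN", "NE2"): -0.72,
    ("GLN", "HE21"): 0.36, ("GLN", "HE22"): 0.36, ("GLN", "CD"): 0.45,
    ("CYS", "SG"): -0.30, ("MET", "SD"): -0.30,
    ("TRP", "NE1"): -0.30, ("TRP", "HE1"): 0.30,
    ("HEM", "FE"): 0.40, ("HEM", "NA"): -0.10, ("HEM", "NB"): -0.10,
    ("HEM", "NC"): -0.10, ("HEM", "ND"): -0.10,
}

BACKBONE_NAMES = ("N", "CA", "C", "O")

WATER_ION_RESNAMES = frozenset(
    {"HOH", "WAT", "SOL", "TIP", "TIP3", "SPC",
     "NA", "CL", "K", "MG", "ZN", "CA", "MN", "IOD", "BR"}
)
#: Residues excluded from site tracing by default: heme plus waters/ions.
DEFAULT_EXCLUDED_RESNAMES = frozenset({"HEM", "HEC"}) | WATER_ION_RESNAMES


@dataclass
class Atom:
    """One atom with descriptor-relevant annotations.

    ``vdw_radius`` (Å) and ``partial_charge`` (e) start as NaN/0 and are
    filled by :func:`assign_radii` / :func:`assign_charges`.
    """

    element: str
    name: str
    residue_name: str
    residue_id: int
    coordinates: np.ndarray
    vdw_radius: float = float("nan")
    partial_charge: float = 0.0
    is_excluded: bool = False
    is_backbone: bool = False


@dataclass
class Structure:
    """An ordered collection of atoms for one conformation."""

    id: str
    atoms: list[Atom]
    frame_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.atoms:
            raise EmptyStructureError(f"structure {self.id!r} has no atoms")

    # --- array views (recomputed on demand; atom lists are small) ---
    def coords(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy with replaced coordinates (same atoms/annotations)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coordinates=c.copy()) for a, c in zip(self.atoms, coords)]
        return Structure(id=self.id, atoms=atoms, frame_index=self.frame_index,
                         meta=dict(self.meta))


@dataclass(frozen=True)
class ReferenceFrame:
    """Rigid map ``x -> rotation @ x + translation`` into the anchor frame."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-9:
            raise ValueError(f"rotation must be proper (det=+1), got det={det}")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def apply_structure(self, structure: Structure) -> Structure:
        return structure.with_coords(self.apply(structure.coords()))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _guess_element(atom_name: str, res_name: str) -> str:
    name = atom_name.strip()
    if res_name.strip().upper() in ("HEM", "HEC") and name.upper().startswith("FE"):
        return "FE"
    stripped = name.lstrip("0123456789")
    if not stripped:
        return name[:1].upper()
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG"):
        # two-letter elements only when the PDB name starts in column 13
        if len(name) == 4 or name[0].isdigit():
            return stripped[0].upper()
        return stripped[:2].upper()
    return stripped[0].upper()


def read_structure(path, model_index: Optional[int] = None,
                   drop_waters_ions: bool = False,
                   structure_id: Optional[str] = None) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path
        PDB file with ATOM/HETATM records (single- or multi-model).
    model_index
        1-based MODEL number for multi-model files; default is the first model.
    drop_waters_ions
        Drop residues in :data:`WATER_ION_RESNAMES`.
    structure_id
        Identifier; defaults to the file stem.
    """
    path = Path(path)
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        model = 1 if model_index is None else int(model_index)
        array = pdb_file.get_structure(model=model)
    except Exception as exc:  # pinpoint the offending line for the user
        lineno = _first_bad_line(path)
        where = f" (line {lineno})" if lineno else ""
        raise FormatError(f"cannot parse {path}{where}: {exc}") from exc

    if array.array_length() == 0:
        raise EmptyStructureError(f"{path}: model {model_index} has no atoms")

    atoms: list[Atom] = []
    for i in range(array.array_length()):
        res_name = str(array.res_name[i]).strip()
        if drop_waters_ions and res_name.upper() in WATER_ION_RESNAMES:
            continue
        name = str(array.atom_name[i]).strip()
        element = str(array.element[i]).strip().upper()
        if not element:
            element = _guess_element(name, res_name)
        atoms.append(Atom(
            element=element,
            name=name,
            residue_name=res_name,
            residue_id=int(array.res_id[i]),
            coordinates=np.array(array.coord[i], dtype=float),
            is_backbone=name in BACKBONE_NAMES and not bool(array.hetero[i]),
        ))
    if not atoms:
        raise EmptyStructureError(f"{path}: no atoms left after filtering")
    return Structure(
        id=structure_id or path.stem,
        atoms=atoms,
        frame_index=(model if model_index is not None else 0),
    )


def _first_bad_line(path: Path) -> Optional[int]:
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38]); float(line[38:46]); float(line[46:54])
                    except (ValueError, IndexError):
                        return lineno
    except OSError:
        return None
    return None


def write_structure(structure: Structure, path) -> None:
    """Write a structure back out as a single-model PDB file."""
    n = len(structure.atoms)
    array = struc.AtomArray(n)
    for i, a in enumerate(structure.atoms):
        array.coord[i] = a.coordinates
        array.atom_name[i] = a.name
        array.res_name[i] = a.residue_name
        array.res_id[i] = a.residue_id
        array.element[i] = a.element
        array.chain_id[i] = "A"
        array.hetero[i] = a.residue_name.upper() in DEFAULT_EXCLUDED_RESNAMES
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(array)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Radius and charge assignment
# ---------------------------------------------------------------------------

def load_radii_table(path) -> dict[str, float]:
    """Load a 2-column TSV (element, radius_Å); '#' comments allowed."""
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("element", "elem"):
                continue
            table[fields[0].upper()] = float(fields[1])
    return table


def load_charge_table(path) -> dict[tuple[str, str], float]:
    """Load a 3-column TSV (residue_name, atom_name, charge_e)."""
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("residue_name", "resname"):
                continue
            table[(fields[0].upper(), fields[1].upper())] = float(fields[2])
    return table


def assign_radii(structure: Structure,
                 table: Optional[Mapping[str, float]] = None,
                 fallback: Optional[float] = None) -> Structure:
    """Assign per-atom van der Waals radii from an element table.

    Unknown elements take ``fallback`` (logged); with no fallback a
    :class:`RadiusLookupError` lists every missing symbol.
    """
    table = BONDI_RADII if table is None else {k.upper(): v for k, v in table.items()}
    missing = sorted({a.element.upper() for a in structure.atoms}
                     - set(table.keys()))
    if missing and fallback is None:
        raise RadiusLookupError(
            f"no vdW radius for elements {missing} and no fallback configured")
    if missing:
        logger.warning("%s: elements %s not in radius table; using fallback %.2f Å",
                       structure.id, missing, fallback)
    atoms = [replace(a, vdw_radius=table.get(a.element.upper(), fallback))
             for a in structure.atoms]
    return Structure(id=structure.id, atoms=atoms,
                     frame_index=structure.frame_index, meta=dict(structure.meta))


def assign_charges(structure: Structure,
                   table: Optional[Mapping[tuple[str, str], float]] = None,
                   fallback: float = 0.0) -> Structure:
    """Assign per-atom partial charges from a (residue, atom)->e table.

    A ``("*", atom_name)`` key matches any residue.  Unmatched atoms get
    ``fallback`` and their count is logged.
    """
    if table is None:
        table = DEFAULT_CHARGES
    else:
        table = {(r.upper(), a.upper()): q for (r, a), q in table.items()}
    atoms = []
    unmatched = 0
    for a in structure.atoms:
        key = (a.residue_name.upper(), a.name.upper())
        if key in table:
            q = table[key]
        elif ("*", a.name.upper()) in table:
            q = table[("*", a.name.upper())]
        else:
            q = fallback
            unmatched += 1
        atoms.append(replace(a, partial_charge=q))
    if unmatched:
        logger.info("%s: %d/%d atoms not in charge table; fallback %.3f e",
                    structure.id, unmatched, len(atoms), fallback)
    out = Structure(id=structure.id, atoms=atoms,
                    frame_index=structure.frame_index, meta=dict(structure.meta))
    out.meta["n_unmatched_charges"] = unmatched
    return out


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

SelectionSpec = Union[Callable[[Atom], bool], Mapping[str, object]]


def _as_set(value) -> set:
    if isinstance(value, str):
        return {value}
    if isinstance(value, Iterable):
        return set(value)
    return {value}


def select_atoms(structure: Structure, spec: SelectionSpec) -> np.ndarray:
    """Indices of atoms matching a selection.

    ``spec`` is either a predicate ``Atom -> bool`` or a mapping over the
    fields ``atom_name`` / ``residue_name`` / ``element`` / ``residue_id``
    (values may be scalars or sets; all given fields must match).
    """
    if callable(spec):
        return np.array([i for i, a in enumerate(structure.atoms) if spec(a)],
                        dtype=int)
    names = _as_set(spec["atom_name"]) if "atom_name" in spec else None
    resnames = _as_set(spec["residue_name"]) if "residue_name" in spec else None
    elements = _as_set(spec["element"]) if "element" in spec else None
    resids = _as_set(spec["residue_id"]) if "residue_id" in spec else None
    idx = []
    for i, a in enumerate(structure.atoms):
        if names is not None and a.name not in names:
            continue
        if resnames is not None and a.residue_name not in resnames:
            continue
        if elements is not None and a.element.upper() not in elements:
            continue
        if resids is not None and a.residue_id not in resids:
            continue
        idx.append(i)
    return np.array(idx, dtype=int)


#: Default anchor: the heme iron.
DEFAULT_ANCHOR_SPEC = {"residue_name": ("HEM", "HEC"), "atom_name": ("FE",)}
#: Default plane: the four pyrrole nitrogens of the heme.
DEFAULT_PLANE_SPEC = {"residue_name": ("HEM", "HEC"),
                      "atom_name": ("NA", "NB", "NC", "ND")}


# ---------------------------------------------------------------------------
# Reference frame and superposition
# ---------------------------------------------------------------------------

def compute_reference_frame(structure: Structure,
                            anchor_spec: SelectionSpec = None,
                            plane_spec: SelectionSpec = None,
                            above_spec: SelectionSpec = None) -> ReferenceFrame:
    """Frame mapping the anchor to the origin and the anchor plane to xy.

    The best-fit (least-squares) plane through the plane-defining atoms is
    rotated into the xy-plane.  The +z side is chosen so the "above" atom
    (or, by default, the structure centroid) ends up at positive z.  The
    in-plane rotation is fixed by placing the first plane atom at azimuth 0,
    which makes the frame deterministic and idempotent.

    Falls back from the pyrrole nitrogens to all heavy heme atoms when fewer
    than 3 nitrogens are present.
    """
    anchor_idx = select_atoms(structure, anchor_spec or DEFAULT_ANCHOR_SPEC)
    if len(anchor_idx) == 0:
        raise SelectionError("anchor selection matched no atom")
    if len(anchor_idx) > 1:
        raise SelectionError(f"anchor selection matched {len(anchor_idx)} atoms; "
                             "expected exactly one")
    anchor = structure.atoms[anchor_idx[0]].coordinates.astype(float)

    plane_idx = select_atoms(structure, plane_spec or DEFAULT_PLANE_SPEC)
    if plane_spec is None and len(plane_idx) < 3:
        plane_idx = select_atoms(
            structure,
            lambda a: a.residue_name.upper() in ("HEM", "HEC")
            and a.element.upper() != "H" and a.element.upper() != "FE")
    if len(plane_idx) < 3:
        raise SelectionError("need at least 3 plane-defining atoms")

    plane = structure.coords()[plane_idx] - anchor
    centered = plane - plane.mean(axis=0)
    # smallest principal axis of the plane atoms = plane normal
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-8 * max(s[0], 1e-30):
        raise DegenerateGeometryError("plane-defining atoms are collinear")
    normal = vt[2]

    if above_spec is not None:
        above_idx = select_atoms(structure, above_spec)
        if len(above_idx) == 0:
            raise SelectionError("'above' selection matched no atom")
        probe = structure.coords()[above_idx].mean(axis=0) - anchor
    else:
        probe = structure.coords().mean(axis=0) - anchor
    if normal @ probe < 0:
        normal = -normal

    # rotation 1: normal -> +z
    r1 = _rotation_onto_z(normal)
    # rotation 2: first plane atom to azimuth 0 (fixes the in-plane freedom)
    p0 = r1 @ plane[0]
    az = np.arctan2(p0[1], p0[0])
    ca, sa = np.cos(-az), np.sin(-az)
    r2 = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    rotation = r2 @ r1
    translation = -rotation @ anchor
    return ReferenceFrame(rotation=rotation, translation=translation)


def _rotation_onto_z(v: np.ndarray) -> np.ndarray:
    """Minimal proper rotation taking unit vector v to +z."""
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(v @ z)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])  # 180° about x
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def superpose(mobile: Structure, reference: Structure,
              selection: SelectionSpec = None) -> tuple[Structure, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The optimal proper rotation (Kabsch, via SVD with determinant
    correction) is computed over the matched selection (default: backbone
    atoms N/CA/C/O in order of appearance) and applied to the whole mobile
    structure.

    Returns
    -------
    (Structure, float)
        The transformed mobile structure and the minimum RMSD (Å) over the
        selection.
    """
    if selection is None:
        selection = {"atom_name": BACKBONE_NAMES}
    mi = select_atoms(mobile, selection)
    ri = select_atoms(reference, selection)
    if len(mi) != len(ri):
        raise PairingError(f"selection sizes differ: {len(mi)} vs {len(ri)}")
    if len(mi) < 3:
        raise PairingError(f"need >= 3 matched atoms, got {len(mi)}")

    x = mobile.coords()[mi]
    y = reference.coords()[ri]
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    # Kabsch with proper-rotation correction
    h = x0.T @ y0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transformed = (mobile.coords() - xc) @ rot.T + yc
    rmsd = float(np.sqrt(np.mean(np.sum((x0 @ rot.T - y0) ** 2, axis=1))))
    return mobile.with_coords(transformed), rmsd
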