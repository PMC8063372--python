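"""Structure ingestion and preparation.

Reads protonated PDB structures, attaches per-atom masses, van der Waals
radii and hydropathy indices, adds the seeded Gaussian perturbation to the
indices, and places the structure in the canonical pore-aligned frame
(mass-weighted atomic center at the origin, pore axis on +z oriented from
the extracellular toward the intracellular side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.PDB.PDBIO import PDBIO

from ._resources import hydropathy_resource_path, load_masses, load_vdw_radii

logger = logging.getLogger(__name__)

_SOLVENT_RESNAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "TIP3", "SOL"}


class StructureError(ValueError):
    """Raised for unusable structures (empty file, degenerate geometry...)."""


class LookupTableError(KeyError):
    """Raised in strict mode when an atom has no hydropathy-table entry."""


@dataclass
class AtomRecord:
    """One atom with its coordinates and physical properties.

    ``hi`` is the per-atom hydropathy index (kcal/mol); ``hi_noisy`` is the
    same index after the additive Gaussian perturbation used to keep the
    cumulative moments away from exact zeros.
    """

    serial: int
    element: str
    atom_name: str
    residue_name: str
    residue_number: int
    segment_id: str
    center: np.ndarray
    mass: float = np.nan
    vdw_radius: float = np.nan
    hi: float = np.nan
    hi_noisy: float = np.nan


class Structure:
    """Array-backed atom collection.

    Columns are kept as parallel numpy arrays for speed; :meth:`atom`
    materialises a single :class:`AtomRecord` view when convenient.
    """

    def __init__(
        self,
        serial: np.ndarray,
        element: np.ndarray,
        atom_name: np.ndarray,
        residue_name: np.ndarray,
        residue_number: np.ndarray,
        segment_id: np.ndarray,
        coords: np.ndarray,
    ):
        n = len(serial)
        self.serial = np.asarray(serial, dtype=np.int64)
        self.element = np.asarray(element, dtype=object)
        self.atom_name = np.asarray(atom_name, dtype=object)
        self.residue_name = np.asarray(residue_name, dtype=object)
        self.residue_number = np.asarray(residue_number, dtype=np.int64)
        self.segment_id = np.asarray(segment_id, dtype=object)
        self.coords = np.asarray(coords, dtype=np.float64).reshape(n, 3)
        self.mass = np.full(n, np.nan)
        self.vdw_radius = np.full(n, np.nan)
        self.hi = np.full(n, np.nan)
        self.hi_noisy = np.full(n, np.nan)
        self.frame_applied: bool = False
        # rigid transform applied by center_and_align: x' = R @ (x + t)
        self.frame_rotation: np.ndarray = np.eye(3)
        self.frame_translation: np.ndarray = np.zeros(3)
        self.noise_seed: int | None = None
        self.noise_sigma: float | None = None

    # -- construction ----------------------------------------------------
    @classmethod
    def from_atoms(cls, atoms: list[AtomRecord]) -> "Structure":
        if not atoms:
            raise StructureError("cannot build a Structure from zero atoms")
        s = cls(
            serial=np.array([a.serial for a in atoms]),
            element=np.array([a.element for a in atoms], dtype=object),
            atom_name=np.array([a.atom_name for a in atoms], dtype=object),
            residue_name=np.array([a.residue_name for a in atoms], dtype=object),
            residue_number=np.array([a.residue_number for a in atoms]),
            segment_id=np.array([a.segment_id for a in atoms], dtype=object),
            coords=np.array([a.center for a in atoms], dtype=float),
        )
        s.mass = np.array([a.mass for a in atoms], dtype=float)
        s.vdw_radius = np.array([a.vdw_radius for a in atoms], dtype=float)
        s.hi = np.array([a.hi for a in atoms], dtype=float)
        s.hi_noisy = np.array([a.hi_noisy for a in atoms], dtype=float)
        return s

    # -- basic views ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def total_mass(self) -> float:
        return float(np.sum(self.mass))

    @property
    def atomic_center(self) -> np.ndarray:
        """Mass-weighted atomic center (Å)."""
        m = self.mass
        if np.any(np.isnan(m)):
            raise StructureError("masses not assigned; run assign_properties first")
        return (m[:, None] * self.coords).sum(axis=0) / m.sum()

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serial[i]),
            element=str(self.element[i]),
            atom_name=str(self.atom_name[i]),
            residue_name=str(self.residue_name[i]),
            residue_number=int(self.residue_number[i]),
            segment_id=str(self.segment_id[i]),
            center=self.coords[i].copy(),
            mass=float(self.mass[i]),
            vdw_radius=float(self.vdw_radius[i]),
            hi=float(self.hi[i]),
            hi_noisy=float(self.hi_noisy[i]),
        )

    def copy(self) -> "Structure":
        s = Structure(
            self.serial.copy(),
            self.element.copy(),
            self.atom_name.copy(),
            self.residue_name.copy(),
            self.residue_number.copy(),
            self.segment_id.copy(),
            self.coords.copy(),
        )
        s.mass = self.mass.copy()
        s.vdw_radius = self.vdw_radius.copy()
        s.hi = self.hi.copy()
        s.hi_noisy = self.hi_noisy.copy()
        s.frame_applied = self.frame_applied
        s.frame_rotation = self.frame_rotation.copy()
        s.frame_translation = self.frame_translation.copy()
        s.noise_seed = self.noise_seed
        s.noise_sigma = self.noise_sigma
        return s


# ---------------------------------------------------------------------------
# hydropathy lookup table
# ---------------------------------------------------------------------------
class HydropathyTable:
    """Per-atom hydropathy index lookup keyed by (residue_name, atom_name).

    Entries support a trailing-``*`` wildcard on the atom name and a ``*``
    residue wildcard; element-level defaults are stored under the atom key
    ``@<element>`` and act as the non-strict fallback.  ``hydrophobic_sign``
    records which sign the shipped scale uses for hydrophobic atoms.
    """

    def __init__(self, entries: dict[tuple[str, str], float], hydrophobic_sign: int = 1):
        self.entries = dict(entries)
        self.hydrophobic_sign = int(hydrophobic_sign)
        self._exact: dict[tuple[str, str], float] = {}
        self._wild: dict[str, list[tuple[str, float]]] = {}
        for (res, atom), v in self.entries.items():
            if atom.endswith("*"):
                self._wild.setdefault(res, []).append((atom[:-1], v))
            else:
                self._exact[(res, atom)] = v
        for res in self._wild:  # longest prefix wins
            self._wild[res].sort(key=lambda t: -len(t[0]))

    @classmethod
    def from_file(cls, path: str | Path | None = None, hydrophobic_sign: int = 1) -> "HydropathyTable":
        p = Path(path) if path is not None else hydropathy_resource_path()
        entries: dict[tuple[str, str], float] = {}
        with open(p) as fh:
            header_seen = False
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if not header_seen:
                    header_seen = True
                    continue
                res, atom, value = line.split("\t")
                entries[(res.upper(), atom.upper())] = float(value)
        return cls(entries, hydrophobic_sign=hydrophobic_sign)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("residue_name\tatom_name\thi\n")
            for (res, atom), v in sorted(self.entries.items()):
                fh.write(f"{res}\t{atom}\t{v!r}\n")

    def _match(self, res: str, atom: str) -> float | None:
        if (res, atom) in self._exact:
            return self._exact[(res, atom)]
        for prefix, v in self._wild.get(res, []):
            if atom.startswith(prefix):
                return v
        return None

    def lookup(self, residue_name: str, atom_name: str, element: str, strict: bool = False) -> float:
        """Resolve the hydropathy index of one atom.

        Falls back to the element-level default (with a warning) unless
        ``strict`` is set, in which case a missing entry raises
        :class:`LookupTableError`.
        """
        res = residue_name.upper().strip()
        atom = atom_name.upper().strip()
        v = self._match(res, atom)
        if v is None:
            v = self._match("*", atom)
        if v is not None:
            return v
        if strict:
            raise LookupTableError(f"no hydropathy entry for ({residue_name}, {atom_name})")
        v = self._exact.get(("*", "@" + element.upper().strip()))
        if v is not None:
            logger.warning(
                "hydropathy fallback to element default for (%s, %s) [element %s]",
                residue_name, atom_name, element,
            )
            return v
        logger.warning("no hydropathy entry or element default for (%s, %s); using 0", residue_name, atom_name)
        return 0.0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------
def read_structure(path: str | Path, format: str = "pdb", exclude_solvent: bool = True) -> Structure:
    """Read a (protonated) PDB file into a :class:`Structure`.

    Hydrogens are retained: the cumulative hydropathy moments take them
    explicitly into account.  Solvent HETATM records (waters) are dropped by
    default.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"structure file not found: {path}")
    parser = PDBParser(QUIET=True)
    model = parser.get_structure("s", str(path))
    atoms: list[AtomRecord] = []
    for atom in model.get_atoms():
        residue = atom.get_parent()
        resname = residue.get_resname().strip()
        if exclude_solvent and resname.upper() in _SOLVENT_RESNAMES:
            continue
        chain = residue.get_parent().id
        element = (atom.element or "").strip() or atom.get_name().strip()[0]
        atoms.append(
            AtomRecord(
                serial=int(atom.get_serial_number()),
                element=element.upper(),
                atom_name=atom.get_name().strip(),
                residue_name=resname,
                residue_number=int(residue.get_id()[1]),
                segment_id=str(chain),
                center=np.asarray(atom.get_coord(), dtype=float),
            )
        )
    if not atoms:
        raise StructureError(f"no atoms parsed from {path}")
    return Structure.from_atoms(atoms)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write the structure as a PDB file (coordinates at PDB precision)."""
    builder = StructureBuilder()
    builder.init_structure("s")
    builder.init_model(0)
    current_chain = None
    current_res = None
    for i in range(structure.n_atoms):
        chain = str(structure.segment_id[i]) or "A"
        if chain != current_chain:
            builder.init_chain(chain)
            builder.init_seg("    ")
            current_chain = chain
            current_res = None
        key = (chain, int(structure.residue_number[i]), str(structure.residue_name[i]))
        if key != current_res:
            builder.init_residue(str(structure.residue_name[i]), " ", int(structure.residue_number[i]), " ")
            current_res = key
        builder.init_atom(
            str(structure.atom_name[i]),
            structure.coords[i].astype(np.float64),
            0.0,
            1.0,
            " ",
            str(structure.atom_name[i]).ljust(4)[:4],
            serial_number=int(structure.serial[i]),
            element=str(structure.element[i]),
        )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def assign_properties(
    structure: Structure,
    table: HydropathyTable | None = None,
    masses: dict[str, float] | None = None,
    vdw_radii: dict[str, float] | None = None,
    strict: bool = False,
) -> Structure:
    """Attach mass, van der Waals radius and hydropathy index to every atom.

    Masses and vdW radii come from element tables; the hydropathy index from
    the (residue, atom)-keyed table with its documented fallback rule.
    Mutates ``structure`` in place and returns it.
    """
    table = table if table is not None else HydropathyTable.from_file()
    masses = masses if masses is not None else load_masses()
    vdw_radii = vdw_radii if vdw_radii is not None else load_vdw_radii()
    n = structure.n_atoms
    mass = np.empty(n)
    vdw = np.empty(n)
    hi = np.empty(n)
    for i in range(n):
        el = str(structure.element[i]).upper()
        if el not in masses:
            raise LookupTableError(f"no mass for element {el!r}")
        if el not in vdw_radii:
            raise LookupTableError(f"no vdW radius for element {el!r}")
        mass[i] = masses[el]
        vdw[i] = vdw_radii[el]
        hi[i] = table.lookup(
            str(structure.residue_name[i]), str(structure.atom_name[i]), el, strict=strict
        )
    structure.mass = mass
    structure.vdw_radius = vdw
    structure.hi = hi
    return structure


def add_index_noise(structure: Structure, sigma: float = 0.001, seed: int | None = 0) -> Structure:
    """Set ``hi_noisy = hi + w`` with ``w ~ N(0, sigma^2)`` i.i.d., seeded.

    The weak perturbation guarantees the cumulative moments are non-zero at
    every defined scale without affecting their scaling behaviour.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if np.any(np.isnan(structure.hi)):
        raise StructureError("hydropathy indices not assigned; run assign_properties first")
    rng = np.random.default_rng(seed)
    structure.hi_noisy = structure.hi + rng.normal(0.0, sigma, structure.n_atoms)
    structure.noise_seed = seed
    structure.noise_sigma = sigma
    return structure


def _rotation_onto_z(axis: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking ``axis`` (unit) onto +z (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    s = float(np.linalg.norm(v))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about x
        return np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def center_and_align(
    structure: Structure,
    pore_axis_hint: np.ndarray | tuple = (0.0, 0.0, 1.0),
    es_end: str = "low_z",
) -> Structure:
    """Place the structure in the canonical pore-aligned frame.

    The mass-weighted atomic center is moved to the origin, and the
    mass-weighted inertia eigenvector with the largest |dot| against
    ``pore_axis_hint`` is mapped onto +z by the minimal rigid rotation.
    ``es_end`` states on which z end of the *input* frame the extracellular
    side lies; the canonical frame keeps the extracellular side at low z so
    that +z points toward the intracellular side.
    """
    if np.any(np.isnan(structure.mass)):
        raise StructureError("masses not assigned; run assign_properties first")
    hint = np.asarray(pore_axis_hint, dtype=float)
    hint = hint / np.linalg.norm(hint)
    center = structure.atomic_center
    x = structure.coords - center
    # collinearity check: rank of the centered cloud
    if structure.n_atoms >= 3:
        svals = np.linalg.svd(x, compute_uv=False)
        if svals[1] <= 1e-9 * max(svals[0], 1.0):
            raise StructureError("degenerate (collinear) structure; cannot define a pore frame")
    m = structure.mass
    r2 = np.einsum("ij,ij->i", x, x)
    inertia = np.eye(3) * float(np.sum(m * r2)) - np.einsum("i,ij,ik->jk", m, x, x)
    evals, evecs = np.linalg.eigh(inertia)
    dots = evecs.T @ hint
    axis = evecs[:, int(np.argmax(np.abs(dots)))]
    if axis @ hint < 0:
        axis = -axis
    rot = _rotation_onto_z(axis)
    if es_end in ("high_z", "+z"):
        # flip so the extracellular side ends at low z
        rot = np.diag([1.0, -1.0, -1.0]) @ rot
    elif es_end not in ("low_z", "-z"):
        raise ValueError(f"es_end must be 'low_z'/'-z' or 'high_z'/'+z', got {es_end!r}")
    structure.coords = (structure.coords - center) @ rot.T
    # cumulative transform from the originally read frame: x' = R x + t
    structure.frame_rotation = rot @ structure.frame_rotation
    structure.frame_translation = rot @ (structure.frame_translation - center)
    structure.frame_applied = True
    return structure


def apply_frame(structure: Structure, points: np.ndarray) -> np.ndarray:
    """Map points from the originally read frame into the current frame."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = pts @ structure.frame_rotation.T + structure.frame_translation
    return out.reshape(np.shape(points))


# -- serialisation of prepared atom tables (TSV round trip) -----------------
_ATOM_TABLE_COLUMNS = [
    "serial", "element", "atom_name", "residue_name", "residue_number",
    "segment_id", "x", "y", "z", "mass", "vdw_radius", "hi", "hi_noisy",
]


def write_atom_table(structure: Structure, path: str | Path) -> None:
    """Write the fully prepared per-atom table (lossless, full precision)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_ATOM_TABLE_COLUMNS) + "\n")
        for i in range(structure.n_atoms):
            c = structure.coords[i]
            fh.write(
                f"{structure.serial[i]}\t{structure.element[i]}\t{structure.atom_name[i]}\t"
                f"{structure.residue_name[i]}\t{structure.residue_number[i]}\t{structure.segment_id[i]}\t"
                f"{c[0]!r}\t{c[1]!r}\t{c[2]!r}\t{structure.mass[i]!r}\t{structure.vdw_radius[i]!r}\t"
                f"{structure.hi[i]!r}\t{structure.hi_noisy[i]!r}\n"
            )


def read_atom_table(path: str | Path) -> Structure:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    s = Structure(
        serial=df["serial"].to_numpy(),
        element=df["element"].to_numpy(dtype=object),
        atom_name=df["atom_name"].astype(str).to_numpy(dtype=object),
        residue_name=df["residue_name"].astype(str).to_numpy(dtype=object),
        residue_number=df["residue_number"].to_numpy(),
        segment_id=df["segment_id"].astype(str).to_numpy(dtype=object),
        coords=df[["x", "y", "z"]].to_numpy(),
    )
    s.mass = df["mass"].to_numpy(dtype=float)
    s.vdw_radius = df["vdw_radius"].to_numpy(dtype=float)
    s.hi = df["hi"].to_numpy(dtype=float)
    s.hi_noisy = df["hi_noisy"].to_numpy(dtype=float)
    s.frame_applied = True
    return s
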