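"""Molecular data model and helix-bundle construction.

Provides the atom/residue/helix containers used throughout the package, an
ideal alpha-helix builder parametrized by rise and twist, rigid helix
orientation transforms (axial rotation chi, then tilt theta about an
in-membrane-plane axis set by phi), Ballesteros-Weinstein residue numbering,
and a narrow fixed-column PDB dialect for I/O.

Coordinate convention: right-handed, membrane normal along +z, angles in
degrees, distances in Angstrom. Residue indices are 1-based sequence
positions.
"""
from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field

import numpy as np

from . import residues as rt
from .geometry import place_atom, rotation_about_axis

__all__ = [
    "Atom", "Residue", "Helix", "HelixOrientation", "HelixBundle", "BWMap",
    "Structure", "build_ideal_helix", "build_side_chain", "helix_axis",
    "apply_orientation", "bw_map_build", "bw_resolve", "bw_inverse",
    "read_structure", "write_structure",
]

# cylindrical offsets of backbone atoms relative to the CA trace, frozen from
# an internal-coordinate helix built at phi=-57, psi=-47 (radius, phase
# offset in degrees, axial offset in Angstrom)
CA_RADIUS = 2.278
_BACKBONE_OFFSETS = {
    "N": (1.554, -26.68, -0.921),
    "C": (1.663, 26.84, 1.064),
    "O": (1.914, 20.36, 2.252),
    "CB": (3.327, 16.81, -0.770),
}
_H_OFFSET = (1.534, -19.12, -1.910)

_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "H": "H"}


@dataclass
class Atom:
    """A named point atom with element, charge and van der Waals class."""
    name: str
    element: str
    coord: np.ndarray
    partial_charge: float = 0.0
    vdw_class: str | None = None
    formal_charge: int = 0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"atom {self.name} has empty element")
        if self.vdw_class is None:
            self.vdw_class = self.element


@dataclass
class Residue:
    index: int
    name: str
    chain: str = "A"
    atoms: list = field(default_factory=list)
    bw_label: str | None = None
    alanized_from: str | None = None
    his_charged: bool = False

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.index} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def is_water(self) -> bool:
        return self.name in ("HOH", "WAT", "TIP")

    def backbone_complete(self) -> bool:
        return all(self.has_atom(n) for n in ("N", "CA", "C"))

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclass
class Helix:
    helix_id: int
    residues: list
    hinge_index: int | None = None  # residue index the tilt axis passes through

    @property
    def atoms(self):
        return [a for r in self.residues for a in r.atoms]

    def residue(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"helix {self.helix_id} has no residue {index}")

    def default_hinge(self) -> int:
        if self.hinge_index is not None:
            return self.hinge_index
        return self.residues[len(self.residues) // 2].index

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atom("CA").coord for r in self.residues])


@dataclass
class HelixOrientation:
    """Tilt polar angle theta, tilt azimuth phi, axial rotation chi (degrees)."""
    theta: float = 0.0
    phi: float = 0.0
    chi: float = 0.0

    def __post_init__(self):
        for v in (self.theta, self.phi, self.chi):
            if not np.isfinite(v):
                raise ValueError("orientation angles must be finite")


@dataclass
class HelixBundle:
    helices: list
    orientations: dict = field(default_factory=dict)  # helix_id -> HelixOrientation
    loops: list = field(default_factory=list)

    def __post_init__(self):
        ids = [h.helix_id for h in self.helices]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate helix ids in bundle")

    def helix(self, helix_id: int) -> Helix:
        for h in self.helices:
            if h.helix_id == helix_id:
                return h
        raise KeyError(f"no helix {helix_id}")

    @property
    def residues(self):
        return [r for h in self.helices for r in h.residues] + list(self.loops)

    def copy(self) -> "HelixBundle":
        return copy.deepcopy(self)


@dataclass
class Structure:
    """Generic container: a flat, ordered list of residues (one model)."""
    residues: list = field(default_factory=list)

    @property
    def atoms(self):
        return [a for r in self.residues for a in r.atoms]

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


def _residue_list(structure):
    if hasattr(structure, "residues"):
        return structure.residues
    return list(structure)


# ---------------------------------------------------------------------------
# ideal helix construction

def build_side_chain(residue: Residue, chi_angles=None) -> Residue:
    """(Re)build the side chain of ``residue`` from its backbone in place.

    Atoms beyond CB are removed and rebuilt from the internal-coordinate
    template of ``residue.name`` with the given chi angles (default: all
    180 degrees, extended).
    """
    name = residue.name
    if name not in rt.SIDE_CHAIN_TEMPLATES:
        raise KeyError(f"unsupported residue type {name!r}")
    template = rt.SIDE_CHAIN_TEMPLATES[name]
    nchi = rt.n_chi(name)
    if chi_angles is None:
        chi_angles = [180.0] * nchi
    if len(chi_angles) != nchi:
        raise ValueError(f"{name} takes {nchi} chi angles, got {len(chi_angles)}")
    backbone = {"N", "CA", "C", "O", "CB", "H", "OXT"}
    residue.atoms = [a for a in residue.atoms if a.name in backbone]
    placed = {a.name: a.coord for a in residue.atoms}
    for aname, element, refs, bond, angle, tors in template:
        if isinstance(tors, tuple):
            _, k, offset = tors
            tval = chi_angles[k - 1] + offset
        else:
            tval = tors
        try:
            a, b, c = (placed[r] for r in refs)
        except KeyError as e:
            raise ValueError(
                f"residue {name}{residue.index} missing backbone atom {e}") from e
        coord = place_atom(a, b, c, bond, angle, tval)
        placed[aname] = coord
        residue.atoms.append(Atom(aname, element, coord,
                                  partial_charge=rt.charge_of(name, aname)))
    return residue


def build_ideal_helix(sequence: str, rise: float = 1.5, twist: float = 100.0,
                      helix_id: int = 1, start_index: int = 1,
                      chain: str = "A", phase: float = 0.0) -> Helix:
    """Build an ideal alpha-helix with its axis along +z.

    ``sequence`` is a one-letter amino-acid string; ``rise`` (A/residue) and
    ``twist`` (degrees/residue) parametrize the CA trace, which starts at
    z=0 with azimuthal ``phase``. Backbone N/CA/C/O, amide H (from residue 2)
    and the side chain (extended rotamer) are placed from frozen local-frame
    offsets.
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have at least 2 residues")
    if rise <= 0:
        raise ValueError("rise must be positive")
    residues_out = []
    for i, letter in enumerate(sequence):
        if letter not in rt.ONE_TO_THREE:
            raise ValueError(
                f"unknown amino-acid letter {letter!r} at position {i + 1}")
        name = rt.ONE_TO_THREE[letter]
        res = Residue(index=start_index + i, name=name, chain=chain)
        ca_phase = phase + i * twist
        z0 = i * rise

        def cyl(radius, dphase, dz):
            a = np.deg2rad(ca_phase + dphase)
            return np.array([radius * np.cos(a), radius * np.sin(a), z0 + dz])

        coords = {"CA": cyl(CA_RADIUS, 0.0, 0.0)}
        for aname, (r_, p_, z_) in _BACKBONE_OFFSETS.items():
            if aname == "CB" and name == "GLY":
                continue
            coords[aname] = cyl(r_, p_, z_)
        order = ["N", "CA", "C", "O"] + (["CB"] if name != "GLY" else [])
        for aname in order:
            res.atoms.append(Atom(aname, _ELEMENT_OF[aname], coords[aname],
                                  partial_charge=rt.charge_of(name, aname)))
        if i > 0:
            hr, hp, hz = _H_OFFSET
            res.atoms.append(Atom("H", "H", cyl(hr, hp, hz),
                                  partial_charge=rt.charge_of(name, "H")))
        build_side_chain(res)
        residues_out.append(res)
    return Helix(helix_id=helix_id, residues=residues_out)


# ---------------------------------------------------------------------------
# axis estimation and orientation transforms

def helix_axis(helix: Helix, window: int = 4):
    """Least-squares axis of a helix from sliding-window CA centroids.

    Returns ``(point, direction)`` where ``point`` is the centroid mean and
    ``direction`` the unit axis pointing from the first toward the last
    residue. Requires >= 5 residues.
    """
    ca = helix.ca_coords()
    if len(ca) < 5:
        raise ValueError(
            f"helix {helix.helix_id}: need >= 5 residues for axis estimation")
    cents = np.array([ca[i:i + window].mean(axis=0)
                      for i in range(len(ca) - window + 1)])
    mean = cents.mean(axis=0)
    _, _, vt = np.linalg.svd(cents - mean)
    direction = vt[0]
    if np.dot(direction, ca[-1] - ca[0]) < 0:
        direction = -direction
    return mean, direction


def _transform_helix(helix: Helix, R: np.ndarray, pivot: np.ndarray) -> None:
    for a in (at for r in helix.residues for at in r.atoms):
        a.coord = R @ (a.coord - pivot) + pivot


def apply_orientation(helix: Helix, o: HelixOrientation,
                      hinge: int | None = None) -> Helix:
    """Return a copy of ``helix`` after a rigid orientation change.

    Composition (fixed convention): axial rotation chi about the helix's own
    axis first, then tilt by theta about an axis through the hinge CA whose
    in-membrane-plane (xy) direction makes angle phi with +x.
    """
    out = copy.deepcopy(helix)
    hinge_idx = hinge if hinge is not None else out.default_hinge()
    hinge_ca = out.residue(hinge_idx).atom("CA").coord.copy()
    point, direction = helix_axis(out)
    # chi about own axis (through the axis point)
    if o.chi % 360.0 != 0.0:
        _transform_helix(out, rotation_about_axis(direction, o.chi), point)
    if o.theta != 0.0:
        tilt_axis = np.array([np.cos(np.deg2rad(o.phi)),
                              np.sin(np.deg2rad(o.phi)), 0.0])
        _transform_helix(out, rotation_about_axis(tilt_axis, o.theta), hinge_ca)
    return out


def apply_combo(bundle: HelixBundle, orientations: dict) -> HelixBundle:
    """Apply a per-helix orientation mapping, returning a new bundle."""
    out = bundle.copy()
    new_helices = []
    for h in out.helices:
        o = orientations.get(h.helix_id)
        if o is None or (o.theta == 0.0 and o.phi == 0.0 and o.chi % 360.0 == 0.0):
            new_helices.append(h)
        else:
            new_helices.append(apply_orientation(h, o))
    out.helices = new_helices
    out.orientations = dict(orientations)
    return out


# ---------------------------------------------------------------------------
# Ballesteros-Weinstein numbering

_BW_RE = re.compile(r"^(\d+)\.(\d+)$")


@dataclass
class BWMap:
    """Per-helix anchors for Ballesteros-Weinstein numbering.

    ``anchors`` maps helix number -> (residue_index, anchor_position); the
    anchor position is conventionally 50 (the most conserved residue of the
    helix). Optional ``ranges`` (helix -> (first, last) residue index) enable
    inverse lookup without naming the helix.
    """
    anchors: dict
    ranges: dict = field(default_factory=dict)


def bw_map_build(anchors: dict, ranges: dict | None = None) -> BWMap:
    clean = {}
    for h, pair in anchors.items():
        idx, pos = pair
        clean[int(h)] = (int(idx), int(pos))
    return BWMap(anchors=clean, ranges=dict(ranges or {}))


def bw_resolve(bw_map: BWMap, label: str) -> int:
    """Residue index for a BW label like ``"3.36"``."""
    m = _BW_RE.match(label.strip())
    if not m:
        raise ValueError(f"malformed BW label {label!r}")
    helix, pos = int(m.group(1)), int(m.group(2))
    if helix not in bw_map.anchors:
        raise KeyError(f"no BW anchor for helix {helix}")
    anchor_idx, anchor_pos = bw_map.anchors[helix]
    return anchor_idx + (pos - anchor_pos)


def bw_inverse(bw_map: BWMap, residue_index: int, helix: int | None = None) -> str:
    """BW label ``"h.x"`` for a residue index (helix inferred from ranges)."""
    if helix is None:
        for h, (lo, hi) in bw_map.ranges.items():
            if lo <= residue_index <= hi:
                helix = h
                break
        else:
            raise KeyError(
                f"residue {residue_index} not inside any helix range; "
                "pass helix= explicitly")
    anchor_idx, anchor_pos = bw_map.anchors[helix]
    return f"{helix}.{anchor_pos + (residue_index - anchor_idx)}"


# ---------------------------------------------------------------------------
# PDB subset I/O
#
# Dialect: ATOM/HETATM/TER/END(MDL)/MODEL records only; alternate locations
# keep conformer "A"; insertion codes are rejected. MODEL/ENDMDL gives
# multi-frame files.

def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(structure, path, models=None) -> None:
    """Write a structure (bundle, Structure, or residue list) as PDB.

    ``models``: optional list of structures written as MODEL/ENDMDL frames
    (``structure`` is then ignored).
    """
    frames = models if models is not None else [structure]
    multi = models is not None and len(frames) > 1
    with open(path, "w") as fh:
        for mi, frame in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {mi:4d}\n")
            serial = 1
            last_chain = None
            for res in _residue_list(frame):
                if last_chain is not None and res.chain != last_chain:
                    fh.write("TER\n")
                last_chain = res.chain
                record = "HETATM" if res.name in ("LIG", "HOH") else "ATOM  "
                for a in res.atoms:
                    x, y, z = a.coord
                    fh.write(
                        f"{record}{serial:5d} {_format_atom_name(a.name, a.element)}"
                        f" {res.name:>3s} {res.chain:1s}{res.index:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {a.element:>2s}\n")
                    serial += 1
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


class PDBFormatError(ValueError):
    pass


def _parse_atom_line(line: str, lineno: int) -> tuple:
    if len(line.rstrip("\n")) < 54:
        raise PDBFormatError(f"line {lineno}: ATOM record too short")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21]
        resseq = int(line[22:26])
        icode = line[26]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as e:
        raise PDBFormatError(f"line {lineno}: malformed ATOM record ({e})") from e
    if icode.strip():
        raise PDBFormatError(
            f"line {lineno}: insertion codes are not supported "
            f"(residue {resname} {resseq}{icode})")
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = name[0]
    return serial, name, altloc, resname, chain, resseq, x, y, z, element


def read_structure(path, model: int | None = None, parameterize: bool = True):
    """Read a PDB-subset file into a :class:`Structure` (or list of them).

    Single-model files return one Structure; multi-model files return a list
    unless ``model`` selects one (1-based). Empty files are an error.
    ``parameterize`` assigns tabulated partial charges by residue/atom name.
    """
    frames = [[]]
    current = {}
    order = []
    n_atom_lines = 0

    def flush():
        nonlocal current, order
        for key in order:
            frames[-1].append(current[key])
        current, order = {}, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                (serial, name, altloc, resname, chain, resseq,
                 x, y, z, element) = _parse_atom_line(line, lineno)
                if altloc not in (" ", "A"):
                    continue  # keep conformer A only
                n_atom_lines += 1
                key = (chain, resseq, resname)
                if key not in current:
                    current[key] = Residue(index=resseq, name=resname, chain=chain)
                    order.append(key)
                q = rt.charge_of(resname, name) if parameterize else 0.0
                current[key].atoms.append(
                    Atom(name, element, np.array([x, y, z]), partial_charge=q))
            elif rec.startswith("MODEL"):
                if current:
                    flush()
                if frames[-1]:
                    frames.append([])
            elif rec.startswith("ENDMDL"):
                flush()
                frames.append([])
            elif rec.startswith(("TER", "END")):
                continue
            elif line.strip() == "":
                continue
            # other records silently ignored (REMARK etc.)
    flush()
    frames = [f for f in frames if f]
    if n_atom_lines == 0:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")
    structures = [Structure(residues=f) for f in frames]
    if model is not None:
        return structures[model - 1]
    if len(structures) == 1:
        return structures[0]
    return structures
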