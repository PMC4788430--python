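"""Construction of coarse-grained tail-on-scaffold systems and all-atom structures.

The synthetic system is a flexible, partially charged bead chain (the
"tail", mobile) whose last bead is tethered to a rigid, negatively
charged scaffold (the "rest") that mimics a wrapped double-stranded
polyanion.  The module also provides a small PDB reader/writer and an
atom-selection grammar for the all-atom analysis path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

TAIL = "TAIL"
REST = "REST"

#: 1-based tail positions carrying +1 charge by default (lysine/arginine-like
#: spacing along the 40-bead chain).
DEFAULT_CHARGED_POSITIONS: tuple[int, ...] = (2, 4, 8, 9, 14, 17, 18, 23, 26, 27, 36, 37, 40)


class ConfigurationError(ValueError):
    """Raised when a system configuration field is invalid."""


@dataclass(frozen=True)
class ScaffoldSpec:
    """Geometry and charges of the rigid scaffold.

    Two parallel strands of "phosphate-like" beads are laid out either
    along an arc (mimicking a wrapped double helix) or a straight rod,
    with a fixed axial rise per position.
    """

    n_positions: int = 30
    strands: int = 2
    geometry: str = "arc"  # "arc" | "straight"
    charge: float = -1.0
    radius: float = 1.6
    rise: float = 3.4
    strand_separation: float = 8.0
    arc_radius: float = 45.0

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise ConfigurationError("scaffold_spec.n_positions must be >= 1")
        if self.strands < 1:
            raise ConfigurationError("scaffold_spec.strands must be >= 1")
        if self.radius <= 0:
            raise ConfigurationError("scaffold_spec.radius must be > 0")
        if self.geometry not in ("arc", "straight"):
            raise ConfigurationError(
                f"scaffold_spec.geometry must be 'arc' or 'straight', got {self.geometry!r}"
            )

    @property
    def n_beads(self) -> int:
        return self.n_positions * self.strands


@dataclass(frozen=True)
class ToySystemConfig:
    """Configuration of the synthetic tail-on-scaffold system."""

    n_tail_beads: int = 40
    charge_pattern: tuple[float, ...] | None = None  # per-bead; None -> default
    scaffold_spec: ScaffoldSpec = field(default_factory=ScaffoldSpec)
    bead_radius: float = 1.6
    bond_length: float = 3.8
    #: scaffold position the tail root bonds to; None -> middle.  An
    #: asymmetric tether (e.g. 9 positions from one end, mirroring a tail
    #: that emerges near where the wrapped polyanion exits) is configurable.
    tether_position: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tail_beads < 2:
            raise ConfigurationError("n_tail_beads must be >= 2")
        if self.bead_radius <= 0:
            raise ConfigurationError("bead_radius must be > 0")
        if self.bond_length <= 0:
            raise ConfigurationError("bond_length must be > 0")
        if self.charge_pattern is not None and len(self.charge_pattern) != self.n_tail_beads:
            raise ConfigurationError(
                f"charge_pattern has {len(self.charge_pattern)} entries, "
                f"expected n_tail_beads = {self.n_tail_beads}"
            )

    def tail_charges(self) -> np.ndarray:
        if self.charge_pattern is not None:
            return np.asarray(self.charge_pattern, dtype=float)
        charges = np.zeros(self.n_tail_beads)
        for pos in DEFAULT_CHARGED_POSITIONS:
            if 1 <= pos <= self.n_tail_beads:
                charges[pos - 1] = 1.0
        return charges


@dataclass
class CGSystem:
    """A bead-level system: coordinates, charges, radii, bonds and regions.

    ``bonds`` rows are (i, j, rest_length).  ``position_index`` maps each
    scaffold bead to its axial position along the scaffold (-1 for tail
    beads); it drives the per-position contact analysis.
    """

    positions: np.ndarray  # (N, 3)
    charges: np.ndarray  # (N,)
    radii: np.ndarray  # (N,)
    bonds: np.ndarray  # (n_bonds, 3): i, j, rest length
    region: np.ndarray  # (N,) of TAIL / REST
    mobile: np.ndarray  # (N,) bool
    position_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.positions)
        self.positions = np.asarray(self.positions, dtype=float).reshape(n, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.mobile = np.asarray(self.mobile, dtype=bool)
        self.region = np.asarray(self.region, dtype="U4")
        if self.bonds is None or len(self.bonds) == 0:
            self.bonds = np.zeros((0, 3))
        self.bonds = np.asarray(self.bonds, dtype=float).reshape(-1, 3)
        if np.any(self.radii <= 0):
            raise ConfigurationError("all bead radii must be > 0")
        idx = self.bonds[:, :2].astype(int)
        if len(idx) and (idx.min() < 0 or idx.max() >= n or np.any(idx[:, 0] == idx[:, 1])):
            raise ConfigurationError("bonds must connect two distinct in-range beads")
        if not np.all(np.isin(self.region, [TAIL, REST])):
            raise ConfigurationError(f"region labels must be {TAIL!r} or {REST!r}")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def tail_indices(self) -> np.ndarray:
        return np.flatnonzero(self.region == TAIL)

    @property
    def rest_indices(self) -> np.ndarray:
        return np.flatnonzero(self.region == REST)

    def copy(self) -> "CGSystem":
        return CGSystem(
            positions=self.positions.copy(),
            charges=self.charges.copy(),
            radii=self.radii.copy(),
            bonds=self.bonds.copy(),
            region=self.region.copy(),
            mobile=self.mobile.copy(),
            position_index=None if self.position_index is None else self.position_index.copy(),
        )

    def position_groups(self) -> list[np.ndarray]:
        """Scaffold bead indices grouped by axial position."""
        if self.position_index is None:
            raise ValueError("system carries no scaffold position labels")
        groups = []
        for p in range(int(self.position_index.max()) + 1):
            groups.append(np.flatnonzero(self.position_index == p))
        return groups

    # -- serialization (documented structured-text format) ------------------

    FORMAT_VERSION = 1

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"# tailensemble cgsystem text format\nversion {self.FORMAT_VERSION}\n")
        buf.write(f"n_beads {self.n_beads}\n")
        pidx = self.position_index
        for i in range(self.n_beads):
            p = -1 if pidx is None else int(pidx[i])
            x, y, z = self.positions[i]
            buf.write(
                f"bead {i} {x:.17g} {y:.17g} {z:.17g} {self.charges[i]:.17g} "
                f"{self.radii[i]:.17g} {self.region[i]} {int(self.mobile[i])} {p}\n"
            )
        for i, j, r0 in self.bonds:
            buf.write(f"bond {int(i)} {int(j)} {r0:.17g}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "CGSystem":
        lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
        version = None
        n = None
        beads: list[tuple] = []
        bonds: list[tuple] = []
        for ln in lines:
            parts = ln.split()
            if parts[0] == "version":
                version = int(parts[1])
            elif parts[0] == "n_beads":
                n = int(parts[1])
            elif parts[0] == "bead":
                beads.append(parts[1:])
            elif parts[0] == "bond":
                bonds.append(parts[1:])
        if version != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported cgsystem format version: {version}")
        if n is None or len(beads) != n:
            raise ValueError("bead count mismatch in cgsystem file")
        beads.sort(key=lambda b: int(b[0]))
        pos = np.array([[float(b[1]), float(b[2]), float(b[3])] for b in beads])
        charges = np.array([float(b[4]) for b in beads])
        radii = np.array([float(b[5]) for b in beads])
        region = np.array([b[6] for b in beads], dtype="U4")
        mobile = np.array([bool(int(b[7])) for b in beads])
        pidx = np.array([int(b[8]) for b in beads])
        bond_arr = np.array([[float(b[0]), float(b[1]), float(b[2])] for b in bonds]).reshape(-1, 3)
        return cls(pos, charges, radii, bond_arr, region, mobile,
                   position_index=None if np.all(pidx < 0) else pidx)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


def _scaffold_layout(spec: ScaffoldSpec) -> tuple[np.ndarray, np.ndarray]:
    """Bead coordinates and per-bead position index for the scaffold."""
    coords = np.zeros((spec.n_beads, 3))
    pidx = np.zeros(spec.n_beads, dtype=int)
    half = spec.strand_separation / 2.0
    k = 0
    for p in range(spec.n_positions):
        for s in range(spec.strands):
            z = (2 * s - (spec.strands - 1)) * half if spec.strands > 1 else 0.0
            if spec.geometry == "straight":
                coords[k] = (p * spec.rise, 0.0, z)
            else:  # arc in the xy plane
                theta = p * spec.rise / spec.arc_radius
                coords[k] = (
                    spec.arc_radius * np.cos(theta),
                    spec.arc_radius * np.sin(theta),
                    z,
                )
            pidx[k] = p
            k += 1
    return coords, pidx


def build_tail_scaffold_system(config: ToySystemConfig) -> CGSystem:
    """Build the synthetic system: mobile charged tail tethered to a rigid scaffold.

    Tail beads occupy indices ``0 .. n_tail-1`` (bead ``n_tail-1`` is the
    root, bonded to the tether scaffold bead); scaffold beads follow.
    Deterministic for a given config.
    """
    spec = config.scaffold_spec
    n_tail = config.n_tail_beads
    scaffold_xyz, scaffold_pidx = _scaffold_layout(spec)

    tether_pos = config.tether_position
    if tether_pos is None:
        tether_pos = spec.n_positions // 2
    if not 0 <= tether_pos < spec.n_positions:
        raise ConfigurationError(
            f"tether_position {tether_pos} outside scaffold positions [0, {spec.n_positions})"
        )
    tether_global = n_tail + tether_pos * spec.strands  # strand 0 bead

    # Initial tail: straight line pointing away from the scaffold.
    anchor = scaffold_xyz[tether_pos * spec.strands]
    if spec.geometry == "arc":
        outward = anchor - np.array([0.0, 0.0, anchor[2]])
        outward /= np.linalg.norm(outward)
    else:
        outward = np.array([0.0, 1.0, 0.0])
    tail_xyz = np.array(
        [anchor + (n_tail - i) * config.bond_length * outward for i in range(n_tail)]
    )

    positions = np.vstack([tail_xyz, scaffold_xyz])
    charges = np.concatenate([config.tail_charges(), np.full(spec.n_beads, spec.charge)])
    radii = np.concatenate(
        [np.full(n_tail, config.bead_radius), np.full(spec.n_beads, spec.radius)]
    )
    region = np.array([TAIL] * n_tail + [REST] * spec.n_beads, dtype="U4")
    mobile = np.array([True] * n_tail + [False] * spec.n_beads)
    bonds = [(i, i + 1, config.bond_length) for i in range(n_tail - 1)]
    bonds.append((n_tail - 1, tether_global, config.bond_length))
    pidx = np.concatenate([np.full(n_tail, -1, dtype=int), scaffold_pidx])
    return CGSystem(positions, charges, radii, np.array(bonds, dtype=float),
                    region, mobile, position_index=pidx)


def apply_acetylation(system: CGSystem, bead_indices: Sequence[int],
                      radius_increment: float = 0.0) -> CGSystem:
    """Neutralize the charge of the listed tail beads (acetylation analog).

    Returns a modified copy; the input system is untouched.  Indices are
    global bead indices and must lie in the TAIL region.  Neutralizing an
    already-neutral bead is a no-op.
    """
    out = system.copy()
    tail = set(system.tail_indices.tolist())
    for i in bead_indices:
        i = int(i)
        if i not in tail:
            raise ValueError(f"bead {i} is not a TAIL bead; acetylation applies to the tail only")
        out.charges[i] = 0.0
        out.radii[i] += radius_increment
    return out


def tail_position_to_index(position: int) -> int:
    """Map a 1-based tail position (residue-style numbering) to a bead index."""
    if position < 1:
        raise ValueError("tail positions are 1-based")
    return position - 1


def initial_conformations(system: CGSystem, n: int, seed: int,
                          relax_steps: int = 150) -> np.ndarray:
    """Generate ``n`` distinct self-avoiding tail conformations.

    The tail is regrown from its root by a self-avoiding random walk with
    fixed bond length, then briefly relaxed by damped steepest descent on
    the full potential at lambda = 1.  The scaffold is untouched.
    Deterministic for a given seed.

    Returns an array of shape (n, N, 3).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from . import energetics  # deferred: energetics imports this module's types

    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0x1C5)))
    tail = system.tail_indices
    n_tail = len(tail)
    root = tail[-1]
    tether = None
    for i, j, r0 in system.bonds:
        i, j = int(i), int(j)
        if i == root and system.region[j] == REST:
            tether = j
        elif j == root and system.region[i] == REST:
            tether = i
    bond_length = float(system.bonds[0, 2])

    eng = energetics.CGEnergetics(system, energetics.ForceFieldParams())
    out = np.empty((n, system.n_beads, 3))
    for k in range(n):
        coords = _grow_tail(system, tail, tether, bond_length, rng)
        coords = _relax(eng, system, coords, relax_steps)
        out[k] = coords
    return out


def _grow_tail(system: CGSystem, tail: np.ndarray, tether: int | None,
               bond_length: float, rng: np.random.Generator,
               max_restarts: int = 200, max_tries: int = 60) -> np.ndarray:
    coords = system.positions.copy()
    # the tether bead is a bonded neighbor of the root: not a clash obstacle
    rest = [i for i in system.rest_indices if i != tether]
    obstacles = coords[rest]
    obstacle_r = system.radii[rest]
    start = coords[tether] if tether is not None else coords[tail[-1]]
    for _ in range(max_restarts):
        placed = []
        ok = True
        prev = start
        for bead in tail[::-1]:  # root first
            r_b = system.radii[bead]
            for _ in range(max_tries):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                cand = prev + bond_length * v
                # clash against scaffold and already-placed tail beads
                if np.any(np.linalg.norm(obstacles - cand, axis=1) < 0.85 * (obstacle_r + r_b)):
                    continue
                if len(placed) > 1:
                    prior = np.array([p for _, p in placed[:-1]])
                    if np.any(np.linalg.norm(prior - cand, axis=1) < 0.85 * 2 * r_b):
                        continue
                placed.append((bead, cand))
                prev = cand
                break
            else:
                ok = False
                break
        if ok:
            for bead, p in placed:
                coords[bead] = p
            return coords
    raise RuntimeError("self-avoiding tail placement failed after bounded retries")


def _relax(eng, system: CGSystem, coords: np.ndarray, n_steps: int,
           step_size: float = 0.02, max_disp: float = 0.5) -> np.ndarray:
    coords = coords.copy()
    mobile = system.mobile
    for _ in range(n_steps):
        f = eng.forces(coords, 1.0)
        d = step_size * f
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        d = np.where(norm > max_disp, d * (max_disp / np.maximum(norm, 1e-12)), d)
        coords[mobile] += d[mobile]
    return coords


# ---------------------------------------------------------------------------
# All-atom structures: PDB reading/writing and atom selection
# ---------------------------------------------------------------------------

_AMINO = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "ALY", "MSE", "HSD", "HSE", "HSP", "HID", "HIE", "HIP",
}
_NUCLEIC = {"DA", "DT", "DG", "DC", "DU", "DI", "A", "T", "G", "C", "U", "I"}


class PDBParseError(ValueError):
    """Raised on a malformed PDB record; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    resname: str
    resseq: int
    icode: str
    chain_id: str
    occupancy: float
    hetatm: bool


@dataclass
class Structure:
    """All-atom PDB content: one atom table plus one or more coordinate sets."""

    atoms: list[Atom]
    models: list[np.ndarray]  # each (n_atoms, 3)
    model_index: int = 0

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return self.models[self.model_index]

    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms], dtype="U2")


def _deduce_element(name: str, resname: str) -> str:
    stripped = name.strip()
    # Leading digits ("1HB2") always indicate hydrogen branch naming.
    core = stripped.lstrip("0123456789")
    if not core:
        return ""
    if core[0] in "Hh" and (stripped[0].isdigit() or resname not in ("HG", "HG2")):
        return "H"
    two = core[:2].upper()
    if two in ("FE", "ZN", "MG", "MN", "CL", "BR", "NA", "CA") and len(stripped) >= 2 \
            and name[:2].strip().upper() == two and not name.startswith(" "):
        # Two-letter elements are left-justified in columns 13-14.
        return two.capitalize()
    return core[0].upper()


def read_pdb(path: str | Path, model_index: int = 0) -> Structure:
    """Parse ATOM/HETATM records from a PDB file.

    Multi-model files expose each MODEL as a coordinate set; ``model_index``
    selects the active one.  Hydrogens are retained (downstream operations
    take an ``exclude_hydrogens`` flag).
    """
    path = Path(path)
    atoms: list[Atom] = []
    models: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] = []
    in_model = False
    first_model_done = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                in_model = True
                current = []
            elif rec == "ENDMDL":
                models.append(current)
                first_model_done = True
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    serial = int(line[6:11])
                    name = line[12:16]
                    resname = line[17:20].strip()
                    chain_id = line[21]
                    resseq = int(line[22:26])
                    icode = line[26].strip()
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    occ_field = line[54:60].strip()
                    occupancy = float(occ_field) if occ_field else 1.0
                    elem_field = line[76:78].strip() if len(line) > 76 else ""
                except (ValueError, IndexError) as exc:
                    raise PDBParseError(f"malformed {rec.strip()} record ({exc})", lineno) from None
                if not np.all(np.isfinite([x, y, z])):
                    raise PDBParseError("non-finite coordinates", lineno)
                element = elem_field.capitalize() if elem_field else _deduce_element(name, resname)
                if not element:
                    raise PDBParseError(f"cannot deduce element for atom name {name!r}", lineno)
                if not first_model_done:
                    atoms.append(Atom(serial, name.strip(), element, resname, resseq,
                                      icode, chain_id, occupancy, rec == "HETATM"))
                current.append((x, y, z))
    if current and not first_model_done:
        models.append(current)
    elif current and first_model_done and in_model:
        models.append(current)
    if not models or not atoms:
        raise PDBParseError("no ATOM/HETATM records found", 0)
    coord_sets = []
    for m in models:
        if len(m) != len(atoms):
            # tolerate truncated trailing models only if identical length
            raise ValueError(
                f"model atom count {len(m)} differs from first model ({len(atoms)})"
            )
        coord_sets.append(np.asarray(m, dtype=float))
    if not 0 <= model_index < len(coord_sets):
        raise IndexError(f"model_index {model_index} out of range (file has {len(coord_sets)})")
    return Structure(atoms=atoms, models=coord_sets, model_index=model_index)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the active model back out (round-trip aid, minimal records)."""
    with open(path, "w") as fh:
        coords = structure.coords
        for atom, (x, y, z) in zip(structure.atoms, coords):
            rec = "HETATM" if atom.hetatm else "ATOM  "
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            fh.write(
                f"{rec}{atom.serial:5d} {name:<4s} {atom.resname:<3s} {atom.chain_id}"
                f"{atom.resseq:4d}{atom.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}          "
                f"{atom.element.upper():>2s}\n"
            )
        fh.write("END\n")


@dataclass(frozen=True)
class AtomSelection:
    """Ordered, unique atom indices into a Structure plus their provenance."""

    indices: np.ndarray
    expression: str

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selection indices must be unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


class SelectionError(ValueError):
    """Raised on a malformed selection expression; carries the offset."""

    def __init__(self, message: str, position: int):
        super().__init__(f"at position {position}: {message}")
        self.position = position


def select_atoms(structure: Structure, expression: str) -> AtomSelection:
    """Select atoms with a small 'and'-combined grammar.

    Clauses: ``chain <id>...``, ``resid <a>-<b>`` or ``resid <n>...``,
    ``name <atom-name>...``, ``heavy`` (non-hydrogen), ``protein``,
    ``nucleic``.  Clause order is irrelevant; the result preserves file
    order.  An empty result is allowed.
    """
    mask = np.ones(structure.n_atoms, dtype=bool)
    clauses = expression.split(" and ")
    offset = 0
    for clause in clauses:
        pos = expression.find(clause, offset)
        offset = pos + len(clause)
        tokens = clause.split()
        if not tokens:
            raise SelectionError("empty clause", pos)
        key, args = tokens[0], tokens[1:]
        if key == "chain":
            if not args:
                raise SelectionError("'chain' needs at least one id", pos)
            sub = np.array([a.chain_id in args for a in structure.atoms])
        elif key == "resid":
            if not args:
                raise SelectionError("'resid' needs a range or numbers", pos)
            wanted: set[int] = set()
            for a in args:
                if "-" in a[1:]:
                    lo, hi = a.split("-", 1) if not a.startswith("-") else (None, None)
                    try:
                        lo_i, hi_i = int(lo), int(hi)
                    except (TypeError, ValueError):
                        raise SelectionError(f"bad resid range {a!r}", pos) from None
                    wanted.update(range(lo_i, hi_i + 1))
                else:
                    try:
                        wanted.add(int(a))
                    except ValueError:
                        raise SelectionError(f"bad resid {a!r}", pos) from None
            sub = np.array([a.resseq in wanted for a in structure.atoms])
        elif key == "name":
            if not args:
                raise SelectionError("'name' needs at least one atom name", pos)
            sub = np.array([a.name in args for a in structure.atoms])
        elif key == "heavy":
            if args:
                raise SelectionError("'heavy' takes no arguments", pos)
            sub = np.array([a.element != "H" for a in structure.atoms])
        elif key == "protein":
            sub = np.array([a.resname in _AMINO for a in structure.atoms])
        elif key == "nucleic":
            sub = np.array([a.resname in _NUCLEIC for a in structure.atoms])
        else:
            raise SelectionError(f"unknown keyword {key!r}", pos)
        mask &= sub
    return AtomSelection(indices=np.flatnonzero(mask), expression=expression)
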