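"""Structure and trajectory I/O plus named domain selections.

Structures are read from PDB (fixed-column v3.3) or mmCIF files through
:mod:`gemmi` and converted to a lightweight in-memory table of atoms with one
or more coordinate sets (models).  Trajectories are multi-model PDB files or
plain-text XYZ blocks tied to a topology :class:`Structure`.

Residue numbering follows the author-assigned (auth) numbering throughout,
with 1-based inclusive residue ranges, because that is how domain boundaries
are conventionally published (e.g. a nucleotide-exchange-factor beta-wing as
residues 160-217).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("hspdyn")

#: Backbone heavy atoms used by default for domain selections.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


class StructureParseError(ValueError):
    """Raised when a structure or trajectory file cannot be parsed."""


class EmptySelectionError(ValueError):
    """Raised when a domain definition matches no atoms."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One atom record (coordinates live in the parent Structure's models)."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class Structure:
    """Atom table plus one or more coordinate sets sharing that table.

    ``coords`` has shape ``(n_models, n_atoms, 3)`` in Angstrom.  All models
    share atom identity and ordering.
    """

    atoms: list[Atom]
    coords: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coordinate set has {self.coords.shape[1]} atoms, "
                f"atom table has {len(self.atoms)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_models(self) -> int:
        return int(self.coords.shape[0])

    def model(self, index: int = 0) -> np.ndarray:
        """Coordinates of one model, shape ``(n_atoms, 3)``."""
        return self.coords[index]

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def with_coords(self, coords: np.ndarray, name: str | None = None) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        return Structure(self.atoms, np.array(coords, dtype=float),
                         name=self.name if name is None else name)


@dataclass(frozen=True)
class DomainDefinition:
    """A named region: chain + inclusive residue ranges + atom-name filter.

    ``atom_names=None`` selects every atom of the matched residues; the
    default is the four backbone heavy atoms.  Ranges match on residue number
    only; insertion-code variants of a numbered residue are included.
    """

    label: str
    chain_id: str
    residue_ranges: tuple[tuple[int, int], ...]
    atom_names: frozenset[str] | None = BACKBONE_ATOMS

    def __post_init__(self) -> None:
        ranges = tuple((int(a), int(b)) for a, b in self.residue_ranges)
        if not ranges:
            raise ValueError(f"domain {self.label!r}: no residue ranges")
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError(f"domain {self.label!r}: range {lo}-{hi} has start > end")
        object.__setattr__(self, "residue_ranges", ranges)
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", frozenset(self.atom_names))

    def contains_residue(self, residue_number: int) -> bool:
        return any(lo <= residue_number <= hi for lo, hi in self.residue_ranges)


#: Built-in domain definitions from the mitochondrial Hsp70 (mortalin) /
#: GrpEL1 system, keyed by the published author residue numbering.
BUILTIN_DOMAINS: dict[str, DomainDefinition] = {
    "grpel1b-beta-wing": DomainDefinition("grpel1b-beta-wing", "B", ((160, 217),)),
    "sbd-alpha-lid": DomainDefinition("sbd-alpha-lid", "A", ((556, 639),)),
    "sbd-beta": DomainDefinition("sbd-beta", "A", ((440, 555),)),
    "sbd-alpha-beta": DomainDefinition("sbd-alpha-beta", "A", ((440, 639),)),
}


@dataclass(frozen=True)
class AtomSelection:
    """Ordered, duplicate-free atom indices into a Structure."""

    structure: Structure
    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 1:
            raise ValueError("indices must be 1-D")
        if idx.size and (idx.min() < 0 or idx.max() >= self.structure.n_atoms):
            raise ValueError("selection indices out of range")
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("selection indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def atoms(self) -> list[Atom]:
        return [self.structure.atoms[i] for i in self.indices]

    def coords(self, model: int = 0) -> np.ndarray:
        return self.structure.coords[model, self.indices]


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinate tensor tied to a topology Structure."""

    topology: Structure
    coords: np.ndarray
    frame_interval: float = 2.0  # ps between saved frames

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"trajectory has {self.coords.shape[1]} atoms per frame, "
                f"topology has {self.topology.n_atoms}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite trajectory coordinates")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_GEMMI_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Multiple MODEL blocks become multiple coordinate sets.  HETATM records are
    retained and flagged.  Alternate locations are collapsed to the
    highest-occupancy conformer (ties keep the first encountered).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in _GEMMI_FORMATS:
        raise ValueError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    if format == "pdb" or (format == "auto" and path.suffix.lower() in (".pdb", ".ent")):
        _validate_pdb_coordinate_lines(path)
    try:
        st = gemmi.read_structure(str(path), format=_GEMMI_FORMATS[format])
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line in its message
        raise StructureParseError(f"{path}: {exc}") from exc
    return _from_gemmi(st, name=path.stem)


def _validate_pdb_coordinate_lines(path: Path) -> None:
    """Reject ATOM/HETATM records whose fixed-column x/y/z fields are not numeric.

    gemmi is deliberately lenient here; a silently zeroed coordinate would
    poison every downstream geometry measure, so we fail loudly instead.
    """
    with open(path, errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fld = line[lo:hi].strip()
                try:
                    float(fld)
                except ValueError:
                    raise StructureParseError(
                        f"{path}:{lineno}: malformed coordinate field "
                        f"{fld!r} in {line.rstrip()!r}") from None


def _pick_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Collapse altlocs: keep the highest-occupancy conformer per atom name."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[n] for n in order]


def _from_gemmi(st: gemmi.Structure, name: str = "") -> Structure:
    if len(st) == 0:
        raise StructureParseError(f"{name or 'structure'}: no models")
    atoms: list[Atom] = []
    keep: list[tuple[int, int, str, str]] = []  # chain idx, res idx, name, altloc
    model0 = st[0]
    for ci, chain in enumerate(model0):
        for ri, residue in enumerate(chain):
            for atom in _pick_altloc(residue):
                atoms.append(Atom(
                    serial=atom.serial,
                    atom_name=atom.name,
                    element=atom.element.name,
                    residue_name=residue.name,
                    residue_number=residue.seqid.num,
                    insertion_code=(residue.seqid.icode or " ").strip() or "",
                    chain_id=chain.name,
                    occupancy=atom.occ,
                    b_factor=atom.b_iso,
                    is_hetero=(residue.het_flag == "H"),
                ))
                keep.append((ci, ri, atom.name, atom.altloc))
    if not atoms:
        raise StructureParseError(f"{name or 'structure'}: zero atoms")

    coords = np.empty((len(st), len(atoms), 3), dtype=float)
    for mi, model in enumerate(st):
        for k, (ci, ri, aname, altloc) in enumerate(keep):
            try:
                group = model[ci][ri][aname]
                atom = next((a for a in group if a.altloc == altloc), group[0])
            except (IndexError, RuntimeError) as exc:
                raise StructureParseError(
                    f"model {mi + 1} does not match model 1 atom table "
                    f"(missing {aname} in chain {model0[ci].name})"
                ) from exc
            coords[mi, k] = (atom.pos.x, atom.pos.y, atom.pos.z)
    return Structure(atoms, coords, name=name)


def read_trajectory(path: str | Path, topology: Structure,
                    format: str = "auto", frame_interval: float = 2.0) -> Trajectory:
    """Read a trajectory from a multi-model PDB or a plain-text XYZ file.

    Every frame must contain exactly ``topology.n_atoms`` atoms; a mismatch
    raises naming the offending frame index.  ``frame_interval`` (ps) is
    metadata supplied by the caller/config, not read from the file.
    """
    path = Path(path)
    if format == "auto":
        format = "xyz" if path.suffix.lower() == ".xyz" else "pdb"
    if format == "pdb":
        st = read_structure(path, format="pdb")
        frames = st.coords
    elif format == "xyz":
        frames = _read_xyz_frames(path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    for i, frame in enumerate(frames):
        if frame.shape[0] != topology.n_atoms:
            raise StructureParseError(
                f"{path}: frame {i} has {frame.shape[0]} atoms, "
                f"topology has {topology.n_atoms}"
            )
    return Trajectory(topology, np.asarray(frames, dtype=float),
                      frame_interval=frame_interval)


def _read_xyz_frames(path: Path) -> list[np.ndarray]:
    """Parse XYZ blocks: atom count line, comment line, then element x y z."""
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    pos = 0
    n_lines = len(lines)
    while pos < n_lines:
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except (ValueError, IndexError):
            raise StructureParseError(
                f"{path}:{pos + 1}: expected atom count, got {lines[pos]!r}")
        block = lines[pos + 2: pos + 2 + n]
        if len(block) < n:
            raise StructureParseError(
                f"{path}: frame {len(frames)} truncated "
                f"({len(block)} of {n} atom lines)")
        xyz = np.empty((n, 3), dtype=float)
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise StructureParseError(
                    f"{path}:{pos + 3 + j}: malformed XYZ atom line {ln!r}")
            try:
                xyz[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise StructureParseError(
                    f"{path}:{pos + 3 + j}: malformed XYZ atom line {ln!r}") from exc
        frames.append(xyz)
        pos += 2 + n
    if not frames:
        raise StructureParseError(f"{path}: no frames")
    return frames


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_structure(structure: Structure, path: str | Path) -> None:
    """Write all models of a Structure as (multi-model) PDB via gemmi."""
    st = gemmi.Structure()
    st.name = structure.name or "hspdyn"
    for mi in range(structure.n_models):
        model = gemmi.Model(mi + 1)
        chains: dict[str, gemmi.Chain] = {}
        residues: dict[tuple[str, int, str], gemmi.Residue] = {}
        for atom, xyz in zip(structure.atoms, structure.coords[mi]):
            if atom.chain_id not in chains:
                chains[atom.chain_id] = gemmi.Chain(atom.chain_id)
                model.add_chain(chains[atom.chain_id])
            key = atom.residue_key
            if key not in residues:
                res = gemmi.Residue()
                res.name = atom.residue_name
                res.seqid = gemmi.SeqId(atom.residue_number, atom.insertion_code or " ")
                res.het_flag = "H" if atom.is_hetero else "A"
                # gemmi copies on add; keep the live reference
                chain = model[atom.chain_id]
                chain.add_residue(res)
                residues[key] = chain[len(chain) - 1]
            ga = gemmi.Atom()
            ga.name = atom.atom_name
            ga.element = gemmi.Element(atom.element or atom.atom_name[:1])
            ga.pos = gemmi.Position(*xyz)
            ga.occ = atom.occupancy
            ga.b_iso = atom.b_factor
            ga.serial = atom.serial
            residues[key].add_atom(ga)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_trajectory_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as concatenated XYZ blocks (one block per frame)."""
    elements = [a.element or "C" for a in traj.topology.atoms]
    with open(path, "w") as fh:
        for fi in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {fi} t={fi * traj.frame_interval:.3f} ps\n")
            for el, (x, y, z) in zip(elements, traj.coords[fi]):
                fh.write(f"{el:<2s} {x:12.6f} {y:12.6f} {z:12.6f}\n")


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def select_atoms(structure: Structure, definition: DomainDefinition) -> AtomSelection:
    """Resolve a :class:`DomainDefinition` to an ordered atom selection.

    Raises :class:`EmptySelectionError` when nothing matches (a silent empty
    selection would corrupt every downstream average).  Residues missing some
    of the requested atom names are kept with the atoms they do have, with a
    logged warning.
    """
    if definition.chain_id not in structure.chain_ids():
        raise EmptySelectionError(
            f"domain {definition.label!r}: chain {definition.chain_id!r} "
            f"not in structure (chains: {structure.chain_ids()})")
    idx: list[int] = []
    per_residue: dict[tuple[int, str], set[str]] = {}
    for i, atom in enumerate(structure.atoms):
        if atom.chain_id != definition.chain_id:
            continue
        if not definition.contains_residue(atom.residue_number):
            continue
        if definition.atom_names is not None and atom.atom_name not in definition.atom_names:
            continue
        idx.append(i)
        per_residue.setdefault((atom.residue_number, atom.insertion_code),
                               set()).add(atom.atom_name)
    if not idx:
        raise EmptySelectionError(
            f"domain {definition.label!r}: no atoms match chain "
            f"{definition.chain_id!r}, ranges {definition.residue_ranges}, "
            f"atoms {sorted(definition.atom_names) if definition.atom_names else 'any'}")
    if definition.atom_names is not None:
        incomplete = [key for key, names in per_residue.items()
                      if names != definition.atom_names]
        if incomplete:
            logger.warning(
                "domain %r: %d residue(s) missing some of %s; kept partial residues",
                definition.label, len(incomplete), sorted(definition.atom_names))
    return AtomSelection(structure, np.array(idx, dtype=np.intp),
                         label=definition.label)


def select_all(structure: Structure, label: str = "all") -> AtomSelection:
    return AtomSelection(structure, np.arange(structure.n_atoms, dtype=np.intp),
                         label=label)


def select_atom(structure: Structure, chain_id: str, residue_number: int,
                atom_name: str) -> AtomSelection:
    """Select a single named atom (e.g. the CA of one residue)."""
    for i, a in enumerate(structure.atoms):
        if (a.chain_id == chain_id and a.residue_number == residue_number
                and a.atom_name == atom_name):
            return AtomSelection(structure, np.array([i], dtype=np.intp),
                                 label=f"{chain_id}:{residue_number}:{atom_name}")
    raise EmptySelectionError(
        f"atom {chain_id}:{residue_number}:{atom_name} not found")


def load_domain_annotations(path: str | Path | None = None,
                            group: str | None = None) -> dict[str, DomainDefinition]:
    """Load named domain definitions from a JSON annotation file.

    Without ``path``, the package's bundled Hsp70/exchange-factor annotation
    (subdomain lobes, reference helices, stalk and beta-wing spans keyed to
    author numbering) is used; that file is an editable starting point, not a
    crystallographic assignment.  ``group`` picks one top-level section
    (e.g. "mortalin"); otherwise all sections are merged.
    """
    import json
    from importlib import resources

    if path is None:
        text = (resources.files("hspdyn") / "data" / "nbd_annotations.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    sections = {k: v for k, v in raw.items() if not k.startswith("_")}
    if group is not None:
        sections = {group: sections[group]}
    out: dict[str, DomainDefinition] = {}
    for sec in sections.values():
        for label, entry in sec.items():
            out[label] = DomainDefinition(
                label, entry["chain"],
                tuple((int(a), int(b)) for a, b in entry["ranges"]),
                frozenset(entry["atoms"]) if "atoms" in entry else BACKBONE_ATOMS)
    return out


def union(*selections: AtomSelection) -> AtomSelection:
    """Union of selections on the same structure, in structure order."""
    if not selections:
        raise ValueError("no selections")
    struct = selections[0].structure
    for s in selections[1:]:
        if s.structure is not struct:
            raise ValueError("selections refer to different structures")
    idx = np.unique(np.concatenate([s.indices for s in selections]))
    return AtomSelection(struct, idx, label="+".join(s.label for s in selections))
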