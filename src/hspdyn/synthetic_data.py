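"""Seeded generators for structures and trajectories with known ground truth.

Every analysis stage in this package (superposition, rotation/bend geometry,
interfaces, network models, angle/substate statistics) can be exercised with
these fixtures, with the true rotation angle, bend, separation or substate
occupancy known by construction — no experimental data or download required.

All generators are pure functions of their arguments including the seed.
Each derives an independent random stream from (seed, generator-name), so
adding a generator never shifts the outputs of the others.

The fixtures are deliberately idealised: helical CA spirals with dummy
backbone atoms at fixed offsets (adequate for selection and surface-area
tests, not stereochemically exact), and trajectories whose anchor-defined
angle follows a prescribed mixture of Gaussian angular substates plus
isotropic positional noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import (Atom, AtomSelection, DomainDefinition, Structure,
                           Trajectory, select_atoms)
from .traj_analysis import VectorDefinition

#: Fixed offsets (A) of dummy backbone atoms from their residue's CA.
_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.50, -0.60]),
    "C": np.array([1.20, -0.40, 0.55]),
    "O": np.array([1.90, 0.60, 1.10]),
}
_ATOM_ORDER = ("N", "CA", "C", "O")
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent deterministic stream per (seed, generator-name)."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(int(seed) & 0x7FFFFFFF,
                                                        spawn_key=(key,)))


def _structure_from_calpha(ca: np.ndarray, chain_id: str = "A",
                           start_residue: int = 1, start_serial: int = 1,
                           name: str = "synthetic") -> Structure:
    """Build a Structure (N, CA, C, O per residue) around a CA trace."""
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = start_serial
    for i, pos in enumerate(ca):
        for aname in _ATOM_ORDER:
            xyz = pos if aname == "CA" else pos + _BACKBONE_OFFSETS[aname]
            atoms.append(Atom(serial, aname, _ELEMENTS[aname], "ALA",
                              start_residue + i, "", chain_id))
            coords.append(xyz)
            serial += 1
    return Structure(atoms, np.asarray(coords)[None], name=name)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def make_ideal_helix(n_res: int, rise: float = 1.5, twist: float = 100.0,
                     radius: float = 2.3, chain_id: str = "A",
                     start_residue: int = 1) -> Structure:
    """Canonical alpha-helical CA spiral about the z axis, plus dummy backbone.

    Default rise/twist/radius match an ideal alpha helix (1.5 A rise,
    100 degrees per residue, 2.3 A CA radius).  Deterministic: identical
    inputs give bitwise-identical coordinates.
    """
    if n_res < 4:
        raise ValueError("need at least 4 residues for a helix")
    i = np.arange(n_res, dtype=float)
    theta = np.radians(twist) * i
    ca = np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                          rise * i])
    return _structure_from_calpha(ca, chain_id=chain_id,
                                  start_residue=start_residue,
                                  name=f"helix{n_res}")


def make_bent_stalk(n_res: int, bend: float, split: int) -> Structure:
    """A helical stalk with a known kink at a residue junction.

    Residues after ``split`` are rotated by ``bend`` degrees about an axis
    perpendicular to the proximal helix axis (the y axis, with the helix
    built along z), through the CA of the split residue, so the distal
    segment's axis makes exactly ``bend`` degrees with the proximal one.
    """
    if not (3 < split < n_res - 3):
        raise ValueError(
            f"split {split} leaves fewer than 4 residues on one side of a "
            f"{n_res}-residue stalk")
    helix = make_ideal_helix(n_res)
    coords = helix.coords.copy()
    ca_split = None
    for i, atom in enumerate(helix.atoms):
        if atom.residue_number == split and atom.atom_name == "CA":
            ca_split = coords[0, i].copy()
    assert ca_split is not None
    rot = Rotation.from_rotvec(np.radians(bend) * np.array([0.0, 1.0, 0.0]))
    distal = np.array([a.residue_number > split for a in helix.atoms])
    coords[0, distal] = rot.apply(coords[0, distal] - ca_split) + ca_split
    return Structure(helix.atoms, coords, name=f"stalk{n_res}-bend{bend:g}")


def make_rotated_pair(base: Structure, probe: DomainDefinition, angle: float,
                      seed: int = 0) -> tuple[Structure, Structure]:
    """Copy of ``base`` plus a copy with the probe region rotated.

    The probe atoms are rotated by ``angle`` degrees about a seeded random
    axis through the probe centroid; everything else is untouched, so the
    rotation is exactly recoverable by superposing on the complement.
    """
    if not (0.0 <= angle <= 180.0):
        raise ValueError("angle must be in [0, 180] degrees")
    sel = select_atoms(base, probe)
    if angle == 0.0:
        return (base.with_coords(base.coords.copy()),
                base.with_coords(base.coords.copy()))
    rng = _stream(seed, "make_rotated_pair")
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    centroid = sel.coords().mean(axis=0)
    rot = Rotation.from_rotvec(np.radians(angle) * axis)
    coords = base.coords.copy()
    coords[0, sel.indices] = rot.apply(coords[0, sel.indices] - centroid) + centroid
    return (base.with_coords(base.coords.copy()),
            base.with_coords(coords, name=f"{base.name}-rot{angle:g}"))


def make_two_domain_complex(size_a: int, size_b: int, separation: float,
                            seed: int = 0) -> Structure:
    """Two compact helical bodies on chains A and B at a given separation.

    Chain B is re-oriented by a seeded random rotation about its centroid and
    placed so the CA-centroid distance along x equals ``separation``.
    """
    if size_a < 5 or size_b < 5:
        raise ValueError("each body needs at least 5 residues")
    a = make_ideal_helix(size_a, chain_id="A")
    b = make_ideal_helix(size_b, chain_id="B")
    rng = _stream(seed, "make_two_domain_complex")
    quat = rng.normal(size=4)
    rot = Rotation.from_quat(quat / np.linalg.norm(quat))
    cb = b.model(0).mean(axis=0)
    b_coords = rot.apply(b.model(0) - cb)
    ca_centroid = a.model(0).mean(axis=0)
    b_coords += ca_centroid + np.array([separation, 0.0, 0.0])
    serial0 = a.atoms[-1].serial + 1
    atoms = list(a.atoms) + [
        Atom(serial0 + i, at.atom_name, at.element, at.residue_name,
             at.residue_number, at.insertion_code, "B")
        for i, at in enumerate(b.atoms)]
    coords = np.concatenate([a.model(0), b_coords])[None]
    return Structure(atoms, coords, name=f"complex-{separation:g}A")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstateGenSpec:
    """Prescription for a synthetic angular-substate trajectory.

    ``occupancies`` are the per-region probabilities of independent draws;
    alternatively supply a row-stochastic ``transition_matrix`` for Markov
    dynamics (its stationary distribution is then the ground truth).
    ``noise_sigma`` is isotropic Gaussian positional noise (A) added to all
    atoms after the anchor geometry is set.
    """

    centers: tuple[float, ...]
    widths: tuple[float, ...]
    occupancies: tuple[float, ...] | None = None
    transition_matrix: tuple[tuple[float, ...], ...] | None = None
    noise_sigma: float = 0.0
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.centers)
        if len(self.widths) != k:
            raise ValueError("centers and widths differ in length")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if (self.occupancies is None) == (self.transition_matrix is None):
            raise ValueError(
                "specify exactly one of occupancies or transition_matrix")
        if self.occupancies is not None:
            occ = tuple(float(o) for o in self.occupancies)
            if len(occ) != k or any(o < 0 for o in occ):
                raise ValueError("occupancies must be k non-negative numbers")
            if abs(sum(occ) - 1.0) > 1e-9:
                raise ValueError("occupancies must sum to 1")
            object.__setattr__(self, "occupancies", occ)
        else:
            tm = np.asarray(self.transition_matrix, dtype=float)
            if tm.shape != (k, k) or np.any(tm < 0) or \
                    not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("transition_matrix must be k x k row-stochastic")


def make_angle_trajectory(topology: Structure,
                          anchors: tuple[VectorDefinition, VectorDefinition],
                          spec: SubstateGenSpec,
                          frame_interval: float = 2.0) -> Trajectory:
    """Trajectory whose anchor-vector angle follows prescribed substates.

    Per frame a region is drawn (independently with the given occupancies,
    or by a Markov chain), a target angle is sampled from that region's
    Gaussian, and the second vector's tip atom is repositioned so the
    inter-vector angle equals the target exactly; isotropic Gaussian noise
    (``spec.noise_sigma``) is then added to all atoms.
    """
    vec_a, vec_b = anchors
    ia0, ia1 = vec_a.resolve(topology)
    ib0, ib1 = vec_b.resolve(topology)
    if len({ia0, ia1, ib1}) < 3:
        raise ValueError("anchor atoms must be distinct enough to pose the "
                         "second vector independently of the first")
    rng = _stream(spec.seed, "make_angle_trajectory")
    k = len(spec.centers)

    if spec.occupancies is not None:
        regions = rng.choice(k, size=spec.n_frames, p=spec.occupancies)
    else:
        tm = np.asarray(spec.transition_matrix, dtype=float)
        regions = np.empty(spec.n_frames, dtype=int)
        state = 0
        for f in range(spec.n_frames):
            regions[f] = state
            state = rng.choice(k, p=tm[state])

    centers = np.asarray(spec.centers)
    widths = np.asarray(spec.widths)
    targets = rng.normal(centers[regions], widths[regions])
    targets = np.clip(targets, 0.1, 179.9)

    base = topology.model(0)
    v = base[ia1] - base[ia0]
    nv = np.linalg.norm(v)
    w0 = base[ib1] - base[ib0]
    nw = np.linalg.norm(w0)
    if nv < 1e-9 or nw < 1e-9:
        raise ValueError("coincident anchor atoms: cannot realise target angles")
    u = v / nv
    # in-plane perpendicular for continuity; fall back to any perpendicular
    p = w0 - np.dot(w0, u) * u
    if np.linalg.norm(p) < 1e-9:
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, u)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        p = helper - np.dot(helper, u) * u
    p /= np.linalg.norm(p)

    coords = np.repeat(base[None], spec.n_frames, axis=0)
    rad = np.radians(targets)
    tips = (base[ib0][None]
            + nw * (np.cos(rad)[:, None] * u[None] + np.sin(rad)[:, None] * p[None]))
    coords[:, ib1] = tips
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
    return Trajectory(topology, coords, frame_interval=frame_interval)
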