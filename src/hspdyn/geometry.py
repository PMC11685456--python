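"""Conformational-change geometry: rotations, bends, displacements,
interface contacts and buried surface area.

These are the measurements used to compare chaperone conformations: the
outward rotation of the nucleotide-binding-domain IIB lobe when a nucleotide
exchange factor is bound, the bending of the exchange factor's long
alpha-helical stalk, the translation of the substrate-binding domain, and the
residue contacts / buried surface area at each protein-protein interface.

SASA is computed with the Shrake-Rupley sphere-point method on a
deterministic golden-spiral lattice, so results are reproducible bit-for-bit
at a fixed point count.  Buried surface area between two selections A and B
follows the standard definition

    BSA_total = SASA(A alone) + SASA(B alone) - SASA(A u B)

with the per-interface convention (half the total) as the default, matching
common interface-server practice; both conventions are always derivable from
the returned report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomSelection, DomainDefinition, Structure, select_atoms
from .superpose import DegenerateGeometryError, kabsch_fit

logger = logging.getLogger("hspdyn")


# ---------------------------------------------------------------------------
# axes and angles
# ---------------------------------------------------------------------------

def principal_axis(coords: np.ndarray) -> np.ndarray:
    """First principal direction of a point set, oriented first -> last point.

    Used as the axis of a helix (or helix segment) given its CA trace.
    Raises for degenerate (near-isotropic or coincident) point sets where the
    leading direction is not well defined.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 3:
        raise ValueError("need an (n>=3, 3) coordinate array")
    centered = coords - coords.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-10:
        raise DegenerateGeometryError("all points coincident")
    if s[1] / s[0] > 0.99:
        raise DegenerateGeometryError(
            "point set is nearly isotropic; principal axis undefined")
    axis = vt[0]
    if np.dot(coords[-1] - coords[0], axis) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length vector")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def subdomain_rotation(struct_a: Structure, struct_b: Structure,
                       align: tuple[AtomSelection, AtomSelection],
                       probe: tuple[AtomSelection, AtomSelection],
                       method: str = "axis-angle") -> float:
    """Rotation of a probe region between two conformations, in degrees.

    Both structures are first superposed on the ``align`` selections (the
    stationary frame of reference, e.g. nucleotide-binding-domain lobes IA
    and IB).  With ``method="axis-angle"`` the rotation magnitude of the
    optimal rigid fit between the paired probe selections is returned; with
    ``method="helix-axis"`` the angle between the probe selections' principal
    axes (e.g. an inward-facing alpha-helix used as a lever arm).
    """
    align_a, align_b = align
    probe_a, probe_b = probe
    if len(align_a) != len(align_b):
        raise ValueError(
            f"align selections differ in size: {len(align_a)} vs {len(align_b)}")
    if len(probe_a) != len(probe_b):
        raise ValueError(
            f"probe selections differ in size: {len(probe_a)} vs {len(probe_b)}")
    transform, _ = kabsch_fit(align_b.coords(), align_a.coords())
    pb = transform.apply(probe_b.coords())
    pa = probe_a.coords()
    if method == "axis-angle":
        fit, _ = kabsch_fit(pa, pb)
        return fit.angle_degrees
    if method == "helix-axis":
        return angle_between(principal_axis(pa), principal_axis(pb))
    raise ValueError(f"unknown method {method!r}; expected axis-angle or helix-axis")


def stalk_bend_angle(struct: Structure, stalk: DomainDefinition, split: int,
                     reference: Structure | str = "self") -> float:
    """Bend of a long helical stalk, in degrees.

    ``split`` is the residue number separating the proximal from the distal
    segment.  With ``reference="self"`` the angle between the two segments'
    principal axes is returned — an approximation suited to stalks that are
    straight when unbent.  With an external (straight) reference structure,
    the proximal segments are superposed first and the angle between the
    distal-segment axes is returned, which is the published way of measuring
    stalk bending against a predicted straight dimer.
    """
    prox_def, dist_def = _split_domain(stalk, split)
    prox = select_atoms(struct, prox_def)
    dist = select_atoms(struct, dist_def)
    _require_segment(prox, "proximal")
    _require_segment(dist, "distal")
    if isinstance(reference, str):
        if reference != "self":
            raise ValueError("reference must be a Structure or 'self'")
        return angle_between(principal_axis(prox.coords()),
                             principal_axis(dist.coords()))
    ref_prox = select_atoms(reference, prox_def)
    ref_dist = select_atoms(reference, dist_def)
    _require_segment(ref_prox, "reference proximal")
    _require_segment(ref_dist, "reference distal")
    if len(ref_prox) != len(prox):
        raise ValueError("proximal segments differ in atom count between "
                         "structure and reference")
    transform, _ = kabsch_fit(prox.coords(), ref_prox.coords())
    moved_dist = transform.apply(dist.coords())
    return angle_between(principal_axis(moved_dist),
                         principal_axis(ref_dist.coords()))


def _split_domain(stalk: DomainDefinition, split: int) -> tuple[DomainDefinition, DomainDefinition]:
    lo = min(r[0] for r in stalk.residue_ranges)
    hi = max(r[1] for r in stalk.residue_ranges)
    if not (lo < split < hi):
        raise ValueError(f"split {split} outside stalk range {lo}-{hi}")
    prox = DomainDefinition(f"{stalk.label}-proximal", stalk.chain_id,
                            ((lo, split),), stalk.atom_names)
    dist = DomainDefinition(f"{stalk.label}-distal", stalk.chain_id,
                            ((split + 1, hi),), stalk.atom_names)
    return prox, dist


def _require_segment(sel: AtomSelection, what: str, min_residues: int = 6) -> None:
    n_res = len({a.residue_key for a in sel.atoms})
    if n_res < min_residues:
        raise ValueError(
            f"{what} segment has {n_res} residues; need >= {min_residues} "
            "on each side of the split for a stable axis")


def centroid_displacement(struct_a: Structure, struct_b: Structure,
                          align: tuple[AtomSelection, AtomSelection],
                          probe: tuple[AtomSelection, AtomSelection]) -> float:
    """Distance (Angstrom) between probe centroids after alignment.

    Quantifies domain translations such as a substrate-binding domain
    shifting away from an exchange-factor beta-wing.
    """
    align_a, align_b = align
    probe_a, probe_b = probe
    if len(align_a) != len(align_b) or len(probe_a) != len(probe_b):
        raise ValueError("paired selections differ in size")
    transform, _ = kabsch_fit(align_b.coords(), align_a.coords())
    cb = transform.apply(probe_b.coords()).mean(axis=0)
    ca = probe_a.coords().mean(axis=0)
    return float(np.linalg.norm(ca - cb))


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)
# ---------------------------------------------------------------------------

#: Bondi-style van der Waals radii, Angstrom.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "ZN": 1.39, "MG": 1.73, "FE": 1.40, "CA": 2.31,
    "NA": 2.27, "K": 2.75,
}


@dataclass(frozen=True)
class SASAParams:
    """Parameters of the Shrake-Rupley solvent-accessible-surface computation.

    probe_radius : solvent probe, 1.4 A (water) by default.
    points_per_atom : sphere-lattice resolution; 960 points gives per-atom
        areas converged to ~1-2%.
    fallback_radius : used (with a warning) for elements absent from the
        radii table; set to None to make unknown elements an error.
    """

    probe_radius: float = 1.4
    points_per_atom: int = 960
    radii: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    fallback_radius: float | None = 1.7

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        if self.points_per_atom < 100:
            raise ValueError("points_per_atom must be >= 100")

    def radius_of(self, element: str) -> float:
        r = self.radii.get(element.upper())
        if r is not None:
            return r
        if self.fallback_radius is None:
            raise KeyError(f"no van der Waals radius for element {element!r}")
        logger.warning("no vdW radius for element %r; using fallback %.2f A",
                       element, self.fallback_radius)
        return self.fallback_radius


def _golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa_of_coords(coords: np.ndarray, radii: np.ndarray,
                   params: SASAParams = SASAParams()) -> np.ndarray:
    """Per-atom SASA (A^2) of an arbitrary sphere set."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = coords.shape[0]
    if radii.shape != (n,):
        raise ValueError("radii must match coords")
    expanded = radii + params.probe_radius
    unit = _golden_spiral_points(params.points_per_atom)
    tree = cKDTree(coords)
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], expanded[i] + expanded.max())
                     if j != i and np.linalg.norm(coords[j] - coords[i]) < expanded[i] + expanded[j]]
        accessible = np.ones(params.points_per_atom, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        frac = accessible.mean()
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return areas


def sasa(structure: Structure, params: SASAParams = SASAParams(),
         model: int = 0, selection: AtomSelection | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area of a structure (A^2).

    When ``selection`` is given, only those atoms exist for the computation
    (context atoms are removed entirely, as needed for buried-area terms).
    """
    if selection is None:
        coords = structure.model(model)
        elements = [a.element for a in structure.atoms]
    else:
        coords = selection.coords(model)
        elements = [a.element for a in selection.atoms]
    radii = np.array([params.radius_of(el) for el in elements])
    return sasa_of_coords(coords, radii, params)


def buried_surface_area(structure: Structure, sel_a: AtomSelection,
                        sel_b: AtomSelection,
                        params: SASAParams = SASAParams(),
                        convention: str = "per-interface",
                        model: int = 0) -> float:
    """Buried surface area between two disjoint selections (A^2).

    ``convention="total"`` returns SASA(A) + SASA(B) - SASA(A u B);
    ``convention="per-interface"`` (default) returns half of that.
    """
    if convention not in ("per-interface", "total"):
        raise ValueError("convention must be 'per-interface' or 'total'")
    if np.intersect1d(sel_a.indices, sel_b.indices).size:
        raise ValueError("selections overlap; buried area is undefined")
    from .structure_io import union  # local import avoids cycle at module load
    both = union(sel_a, sel_b)
    area_a = sasa(structure, params, model, sel_a).sum()
    area_b = sasa(structure, params, model, sel_b).sum()
    area_ab = sasa(structure, params, model, both).sum()
    total = max(0.0, float(area_a + area_b - area_ab))
    return total / 2.0 if convention == "per-interface" else total


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

#: Charged side-chain heavy atoms for salt-bridge detection.
_POSITIVE_ATOMS = {("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
                   ("LYS", "NZ"), ("HIS", "ND1"), ("HIS", "NE2")}
_NEGATIVE_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"),
                   ("GLU", "OE1"), ("GLU", "OE2")}


@dataclass(frozen=True)
class ContactCutoffs:
    """Distance cutoffs (A) for contact classification; literature-standard."""

    salt_bridge: float = 4.0   # oppositely charged side-chain heavy atoms
    hbond: float = 3.5         # N/O donor-acceptor heavy atoms
    vdw: float = 4.5           # any heavy-atom pair


@dataclass(frozen=True)
class Contact:
    residue_a: tuple[str, int, str]   # (chain, resnum, resname)
    residue_b: tuple[str, int, str]
    min_distance: float
    contact_class: str                # salt-bridge | hbond-capable | vdw


@dataclass
class InterfaceReport:
    """Residue contacts and buried surface area for one chain/domain pair."""

    partner_a: str
    partner_b: str
    contacts: list[Contact]
    buried_area: float | None = None
    buried_area_convention: str = "per-interface"

    def to_dict(self) -> dict:
        return {
            "partner_a": self.partner_a,
            "partner_b": self.partner_b,
            "buried_area": self.buried_area,
            "buried_area_convention": self.buried_area_convention,
            "n_contacts": len(self.contacts),
            "contacts": [
                {"residue_a": list(c.residue_a), "residue_b": list(c.residue_b),
                 "min_distance": c.min_distance, "class": c.contact_class}
                for c in self.contacts],
        }


def contact_map(structure: Structure, sel_a: AtomSelection, sel_b: AtomSelection,
                cutoffs: ContactCutoffs = ContactCutoffs(),
                sasa_params: SASAParams | None = None,
                bsa_convention: str = "per-interface",
                model: int = 0) -> InterfaceReport:
    """Residue-residue contacts between two disjoint selections.

    Every residue pair with a heavy-atom distance within the vdW cutoff is
    listed; the class is upgraded to hbond-capable when N/O heavy atoms of
    the pair are within the hydrogen-bond cutoff, and to salt-bridge when
    oppositely charged side-chain groups are within the salt-bridge cutoff.
    Pass ``sasa_params`` to also compute the pair's buried surface area.
    """
    if np.intersect1d(sel_a.indices, sel_b.indices).size:
        raise ValueError("selections overlap")
    heavy_a = [(i, structure.atoms[i]) for i in sel_a.indices
               if structure.atoms[i].element.upper() != "H"]
    heavy_b = [(i, structure.atoms[i]) for i in sel_b.indices
               if structure.atoms[i].element.upper() != "H"]
    coords = structure.model(model)
    contacts: dict[tuple, dict] = {}
    if heavy_a and heavy_b:
        xa = coords[[i for i, _ in heavy_a]]
        xb = coords[[i for i, _ in heavy_b]]
        tree_b = cKDTree(xb)
        pairs = tree_b.query_ball_point(xa, cutoffs.vdw)
        for ia, neighbor_list in enumerate(pairs):
            atom_a = heavy_a[ia][1]
            for ib in neighbor_list:
                atom_b = heavy_b[ib][1]
                d = float(np.linalg.norm(xa[ia] - xb[ib]))
                key = (atom_a.residue_key, atom_b.residue_key)
                rec = contacts.setdefault(key, {
                    "res_a": (atom_a.chain_id, atom_a.residue_number, atom_a.residue_name),
                    "res_b": (atom_b.chain_id, atom_b.residue_number, atom_b.residue_name),
                    "min_d": d, "class": "vdw"})
                rec["min_d"] = min(rec["min_d"], d)
                cls = _classify_pair(atom_a, atom_b, d, cutoffs)
                rec["class"] = _strongest(rec["class"], cls)
    report_contacts = [
        Contact(rec["res_a"], rec["res_b"], rec["min_d"], rec["class"])
        for rec in sorted(contacts.values(),
                          key=lambda r: (r["res_a"], r["res_b"]))]
    bsa = None
    if sasa_params is not None:
        bsa = buried_surface_area(structure, sel_a, sel_b, sasa_params,
                                  convention=bsa_convention, model=model)
    return InterfaceReport(sel_a.label, sel_b.label, report_contacts,
                           buried_area=bsa,
                           buried_area_convention=bsa_convention)


_CLASS_RANK = {"vdw": 0, "hbond-capable": 1, "salt-bridge": 2}


def _strongest(a: str, b: str) -> str:
    return a if _CLASS_RANK[a] >= _CLASS_RANK[b] else b


def _classify_pair(atom_a, atom_b, d: float, cutoffs: ContactCutoffs) -> str:
    key_a = (atom_a.residue_name, atom_a.atom_name)
    key_b = (atom_b.residue_name, atom_b.atom_name)
    opposite = ((key_a in _POSITIVE_ATOMS and key_b in _NEGATIVE_ATOMS)
                or (key_a in _NEGATIVE_ATOMS and key_b in _POSITIVE_ATOMS))
    if opposite and d <= cutoffs.salt_bridge:
        return "salt-bridge"
    if (atom_a.element.upper() in ("N", "O") and atom_b.element.upper() in ("N", "O")
            and d <= cutoffs.hbond):
        return "hbond-capable"
    return "vdw"
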