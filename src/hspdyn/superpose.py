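"""Least-squares rigid superposition, RMSD, and per-domain deviation series.

The Kabsch algorithm gives the closed-form rotation minimising the RMSD
between two paired point sets; the reflection branch of the SVD is corrected
so a proper rotation (det = +1) is always returned.  Trajectory series align
each frame to a reference frame on a chosen domain before measuring, which
removes collective rigid-body motion so that only internal flexibility is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import AtomSelection, Trajectory


class DegenerateGeometryError(ValueError):
    """Point set too degenerate (collinear / coincident) for a unique fit."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation: x -> R x + t."""

    rotation: np.ndarray    # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @property
    def angle_degrees(self) -> float:
        """Rotation magnitude in [0, 180] degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between paired coordinates, no fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid fit of ``mobile`` onto ``reference``.

    Returns the transform that minimises RMSD and the minimised RMSD itself.
    Requires >= 3 non-collinear paired points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point counts differ: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("expected (n, 3) coordinate arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    x = mobile - cm
    y = reference - cr
    # collinearity check: second singular value of either centered set ~ 0
    for pts, lbl in ((x, "mobile"), (y, "reference")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[0] < 1e-10 or s[1] / s[0] < 1e-8:
            raise DegenerateGeometryError(
                f"{lbl} points are (nearly) collinear; rotation is not unique")
    H = x.T @ y
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    transform = RigidTransform(R, t)
    return transform, rmsd(transform.apply(mobile), reference)


# ---------------------------------------------------------------------------
# trajectory series
# ---------------------------------------------------------------------------

@dataclass
class DeviationSeries:
    """Per-frame deviations (Angstrom) with frame times and summary stats."""

    values: np.ndarray        # (n_frames,) or (n_frames, n_atoms)
    times: np.ndarray         # ps
    label: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if np.asarray(self.values).size > 1 else 0.0


def domain_rmsd_series(traj: Trajectory, domain: AtomSelection,
                       reference_frame: int = 0) -> DeviationSeries:
    """Per-frame RMSD of one domain after aligning each frame on that domain.

    Each frame is first superposed onto the reference frame using the domain
    selection itself, so rigid collective motion is removed and the series
    reports internal flexibility only.
    """
    if len(domain) == 0:
        raise ValueError("empty domain selection")
    if not (0 <= reference_frame < traj.n_frames):
        raise IndexError(
            f"reference frame {reference_frame} out of range "
            f"(trajectory has {traj.n_frames} frames)")
    idx = domain.indices
    ref = traj.coords[reference_frame, idx]
    values = np.empty(traj.n_frames)
    for fi in range(traj.n_frames):
        _, values[fi] = kabsch_fit(traj.coords[fi, idx], ref)
    return DeviationSeries(values, traj.times, label=domain.label)


def per_atom_deviation_series(traj: Trajectory, atoms: AtomSelection,
                              alignment: AtomSelection,
                              reference_frame: int = 0) -> DeviationSeries:
    """Per-atom Euclidean deviation from reference, after external alignment.

    Frames are superposed on ``alignment``; deviations are then measured for
    each atom in ``atoms`` against its reference-frame position.  Used for
    anchor-residue CA motion underlying vector-angle analyses.
    """
    if len(atoms) == 0 or len(alignment) == 0:
        raise ValueError("empty selection")
    if not (0 <= reference_frame < traj.n_frames):
        raise IndexError(f"reference frame {reference_frame} out of range")
    aidx = alignment.indices
    tidx = atoms.indices
    ref_align = traj.coords[reference_frame, aidx]
    ref_atoms = traj.coords[reference_frame, tidx]
    values = np.empty((traj.n_frames, len(atoms)))
    for fi in range(traj.n_frames):
        transform, _ = kabsch_fit(traj.coords[fi, aidx], ref_align)
        moved = transform.apply(traj.coords[fi, tidx])
        values[fi] = np.linalg.norm(moved - ref_atoms, axis=1)
    return DeviationSeries(values, traj.times, label=atoms.label)
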