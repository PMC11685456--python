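"""Anisotropic network model (ANM) built from scratch.

An ANM treats each residue's CA atom as a node and connects node pairs
within a cutoff distance (default 10 A) by identical Hookean springs of
stiffness gamma (default 1, arbitrary units).  The 3N x 3N Hessian of the
harmonic potential

    E = (gamma / 2) * sum_{|r0_ij| <= cutoff} (|r_ij| - |r0_ij|)^2

has, for each interacting pair, the off-diagonal 3x3 super-element
-gamma * (r_ij r_ij^T) / |r_ij|^2 evaluated at the reference geometry, and
diagonal super-elements equal to minus the sum of the row's off-diagonal
blocks — which makes every block row sum to zero (translational invariance)
and gives a connected network exactly six zero-frequency rigid-body modes.

The low-frequency non-rigid modes approximate the molecule's collective
functional motions; mean-square fluctuations and normalized
cross-correlations follow from the pseudo-inverse-like sum over retained
modes, MSF_i = sum_k |u_k,i|^2 / lambda_k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .structure_io import AtomSelection, Structure

logger = logging.getLogger("hspdyn")

#: Residue-node count above which the partial (Lanczos) eigensolver is used.
DENSE_SOLVER_MAX_NODES = 2000

#: Relative tolerance (of the largest eigenvalue) below which an eigenvalue
#: is classified as a rigid-body mode.
RIGID_MODE_RTOL = 1e-8


class RigidModeCountError(RuntimeError):
    """Connected-network sanity check failed: rigid-mode count is not 6."""


@dataclass
class ANMModel:
    """Result of an ANM eigen-analysis.

    eigenvalues are ascending and exclude rigid modes; ``modes`` holds the
    corresponding orthonormal 3N-component eigenvectors as columns.
    """

    node_coords: np.ndarray      # (N, 3)
    cutoff: float
    gamma: float
    eigenvalues: np.ndarray      # (K,)
    modes: np.ndarray            # (3N, K)
    n_rigid_skipped: int

    @property
    def n_nodes(self) -> int:
        return int(self.node_coords.shape[0])

    @property
    def n_modes(self) -> int:
        return int(self.eigenvalues.size)

    def mode_vectors(self, k: int) -> np.ndarray:
        """Mode k as per-node 3-vectors, shape (N, 3)."""
        return self.modes[:, k].reshape(self.n_nodes, 3)


def build_hessian(node_coords: np.ndarray, cutoff: float = 10.0,
                  gamma: float = 1.0) -> np.ndarray:
    """Dense 3N x 3N ANM Hessian at the reference geometry."""
    coords = np.asarray(node_coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    diff = coords[:, None, :] - coords[None, :, :]          # r_i - r_j
    d2 = np.sum(diff * diff, axis=2)
    off = ~np.eye(n, dtype=bool)
    if np.any(d2[off] < 1e-12):
        i, j = np.argwhere((d2 < 1e-12) & off)[0]
        raise ValueError(f"coincident nodes {i} and {j}")
    contact = (d2 <= cutoff * cutoff) & off
    H = np.zeros((n, n, 3, 3))
    ii, jj = np.nonzero(contact)
    dv = diff[ii, jj]
    H[ii, jj] = -gamma * dv[:, :, None] * dv[:, None, :] / d2[ii, jj][:, None, None]
    H[np.arange(n), np.arange(n)] = -H.sum(axis=1)
    H = H.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    return (H + H.T) / 2.0  # symmetrize away rounding noise


def compute_modes(hessian: np.ndarray, n_modes: int = 10,
                  node_coords: np.ndarray | None = None,
                  cutoff: float = 10.0, gamma: float = 1.0) -> ANMModel:
    """Lowest non-rigid eigenpairs of an ANM Hessian.

    Eigenvalues below ``RIGID_MODE_RTOL`` times the largest are classified as
    rigid-body modes and skipped; a connected 3-D network must yield exactly
    six, so any other count raises :class:`RigidModeCountError` (signalling a
    disconnected or degenerate network).  Retained eigenvectors get a
    deterministic sign (first non-zero component positive).
    """
    H = np.asarray(hessian, dtype=float)
    dim = H.shape[0]
    if H.shape != (dim, dim) or dim % 3:
        raise ValueError("hessian must be square with 3N rows")
    if not np.allclose(H, H.T, atol=1e-10):
        raise ValueError("hessian must be symmetric")
    n_nodes = dim // 3
    if node_coords is None:
        node_coords = np.full((n_nodes, 3), np.nan)
    if n_nodes <= DENSE_SOLVER_MAX_NODES:
        evals, evecs = scipy.linalg.eigh(H)
    else:
        k = min(dim - 1, n_modes + 6)
        evals, evecs = scipy.sparse.linalg.eigsh(H, k=k, sigma=-1e-3, which="LM")
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]
    scale = float(np.max(np.abs(evals))) or 1.0
    rigid = evals < RIGID_MODE_RTOL * scale
    n_rigid = int(np.count_nonzero(rigid))
    if n_rigid != 6:
        raise RigidModeCountError(
            f"expected 6 rigid-body modes, found {n_rigid}; the elastic "
            "network is likely disconnected (or degenerate) at this cutoff")
    keep = np.nonzero(~rigid)[0][:n_modes]
    if keep.size < n_modes:
        logger.warning("only %d non-rigid modes available (requested %d)",
                       keep.size, n_modes)
    modes = evecs[:, keep].copy()
    for k in range(modes.shape[1]):
        nz = np.nonzero(np.abs(modes[:, k]) > 1e-8)[0]
        if nz.size and modes[nz[0], k] < 0:
            modes[:, k] = -modes[:, k]
    return ANMModel(np.asarray(node_coords, dtype=float), cutoff, gamma,
                    evals[keep].copy(), modes, n_rigid)


def anm_from_calpha(structure: Structure, cutoff: float = 10.0,
                    gamma: float = 1.0, n_modes: int = 10,
                    model: int = 0) -> ANMModel:
    """Convenience: CA nodes from a structure -> Hessian -> modes."""
    idx, coords = calpha_nodes(structure, model)
    H = build_hessian(coords, cutoff, gamma)
    return compute_modes(H, n_modes, node_coords=coords, cutoff=cutoff, gamma=gamma)


def calpha_nodes(structure: Structure, model: int = 0
                 ) -> tuple[dict[tuple[str, int, str], int], np.ndarray]:
    """One node per residue at its CA; residues lacking CA are dropped."""
    node_map: dict[tuple[str, int, str], int] = {}
    coords: list[np.ndarray] = []
    dropped: set[tuple[str, int, str]] = set()
    for i, atom in enumerate(structure.atoms):
        key = atom.residue_key
        # exclude calcium ions, whose atom name is also CA
        if atom.atom_name == "CA" and atom.element.upper() != "CA":
            if key not in node_map:
                node_map[key] = len(coords)
                coords.append(structure.coords[model, i])
    for atom in structure.atoms:
        if atom.residue_key not in node_map:
            dropped.add(atom.residue_key)
    if dropped:
        logger.warning("dropped %d residue(s) without CA from ANM nodes", len(dropped))
    if not coords:
        raise ValueError("no CA atoms in structure")
    return node_map, np.asarray(coords)


def extend_modes(model: ANMModel, full_structure: Structure,
                 node_map: dict[tuple[str, int, str], int]) -> np.ndarray:
    """Extend CA-node modes to every atom of the structure.

    Each atom inherits the mode 3-vector of its residue's node; columns are
    re-normalised to unit length.  Returns a (3 * n_atoms, K) array.
    """
    missing = sorted({a.residue_key for a in full_structure.atoms
                      if a.residue_key not in node_map})
    if missing:
        raise ValueError(f"residues without an ANM node: {missing}")
    n_atoms = full_structure.n_atoms
    extended = np.empty((3 * n_atoms, model.n_modes))
    for i, atom in enumerate(full_structure.atoms):
        node = node_map[atom.residue_key]
        extended[3 * i:3 * i + 3] = model.modes[3 * node:3 * node + 3]
    norms = np.linalg.norm(extended, axis=0)
    return extended / norms


def mean_square_fluctuations(model: ANMModel) -> np.ndarray:
    """Per-node MSF_i = sum_k |u_k,i|^2 / lambda_k (units ~ A^2 / gamma)."""
    if model.n_modes < 1:
        raise ValueError("no retained modes")
    u = model.modes.reshape(model.n_nodes, 3, model.n_modes)
    return np.einsum("ixk,ixk,k->i", u, u, 1.0 / model.eigenvalues)


def cross_correlations(model: ANMModel) -> np.ndarray:
    """Normalised inter-node motion correlations C_ij in [-1, 1], C_ii = 1."""
    if model.n_modes < 1:
        raise ValueError("no retained modes")
    u = model.modes.reshape(model.n_nodes, 3, model.n_modes)
    cov = np.einsum("ixk,jxk,k->ij", u, u, 1.0 / model.eigenvalues)
    d = np.sqrt(np.diag(cov))
    c = cov / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def write_nmd(model: ANMModel, path, names: list[str] | None = None,
              title: str = "hspdyn ANM") -> None:
    """Write modes in NMD plain text for standard normal-mode viewers."""
    n = model.n_nodes
    if names is None:
        names = ["CA"] * n
    with open(path, "w") as fh:
        fh.write(f"title {title}\n")
        fh.write("names " + " ".join(names) + "\n")
        fh.write("coordinates " + " ".join(
            f"{v:.3f}" for v in model.node_coords.ravel()) + "\n")
        for k in range(model.n_modes):
            fh.write(f"mode {k + 1} {model.eigenvalues[k]:.6g} "
                     + " ".join(f"{v:.6f}" for v in model.modes[:, k]) + "\n")
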