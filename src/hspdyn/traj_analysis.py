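"""Trajectory angular-motion analysis: anchor vectors, per-frame angles,
kernel density curves, and substate occupancies.

A conformational reaction coordinate is defined by two inter-residue vectors
(each from one anchor CA to another, e.g. substrate-binding-domain lid
residue 569 -> 597 versus 569 -> an exchange-factor beta-wing residue); the
per-frame angle between the vectors tracks lateral/medial domain motion.
Substates are contiguous angular ranges; occupancancy is the percentage of
frames whose angle falls in each range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .structure_io import Structure, Trajectory


@dataclass(frozen=True)
class AtomRef:
    chain_id: str
    residue_number: int
    atom_name: str = "CA"

    def resolve(self, structure: Structure) -> int:
        for i, a in enumerate(structure.atoms):
            if (a.chain_id == self.chain_id
                    and a.residue_number == self.residue_number
                    and a.atom_name == self.atom_name):
                return i
        raise KeyError(f"atom {self.chain_id}:{self.residue_number}:"
                       f"{self.atom_name} not found in topology")

    @classmethod
    def parse(cls, text: str) -> "AtomRef":
        """Parse 'chain:resnum[:atom]' (atom defaults to CA)."""
        parts = text.split(":")
        if len(parts) == 2:
            return cls(parts[0], int(parts[1]))
        if len(parts) == 3:
            return cls(parts[0], int(parts[1]), parts[2])
        raise ValueError(f"cannot parse atom reference {text!r}")


@dataclass(frozen=True)
class VectorDefinition:
    """A labelled vector from one anchor atom to another."""

    label: str
    from_atom: AtomRef
    to_atom: AtomRef

    def __post_init__(self) -> None:
        if self.from_atom == self.to_atom:
            raise ValueError(f"vector {self.label!r}: identical anchor atoms")

    def resolve(self, structure: Structure) -> tuple[int, int]:
        return self.from_atom.resolve(structure), self.to_atom.resolve(structure)


#: Anchor vectors of the mortalin/GrpEL1 study, author numbering: v1 within
#: the SBDalpha lid (CA 569 -> CA 597, chain A = mortalin), v2 to GrpEL1-B
#: CA 200 and v3 to GrpEL1-B CA 98 (chain B).
BUILTIN_VECTORS: dict[str, VectorDefinition] = {
    "v1": VectorDefinition("v1", AtomRef("A", 569), AtomRef("A", 597)),
    "v2": VectorDefinition("v2", AtomRef("A", 569), AtomRef("B", 200)),
    "v3": VectorDefinition("v3", AtomRef("A", 569), AtomRef("B", 98)),
}


@dataclass
class AngleSeries:
    """Per-frame inter-vector angle in degrees, in [0, 180]."""

    angles: np.ndarray
    times: np.ndarray
    pair_label: str = ""

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size and (self.angles.min() < 0 or self.angles.max() > 180):
            raise ValueError("angles must lie in [0, 180] degrees")

    @property
    def n_frames(self) -> int:
        return int(self.angles.size)


@dataclass(frozen=True)
class SubstateSpec:
    """Ordered contiguous angular bins with labels.

    ``edges`` has one more entry than ``labels``; bins are half-open
    [lo, hi) except the last, which is closed.
    """

    edges: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 2:
            raise ValueError("need at least 2 edges")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("edges must be strictly increasing")
        labels = tuple(self.labels) or tuple(
            f"{a:g}-{b:g}" for a, b in zip(edges, edges[1:]))
        if len(labels) != len(edges) - 1:
            raise ValueError("need one label per bin")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "labels", labels)

    @property
    def n_regions(self) -> int:
        return len(self.edges) - 1


@dataclass
class OccupancyReport:
    """Percentage of frames per angular region."""

    labels: tuple[str, ...]
    percentages: np.ndarray
    counts: np.ndarray
    total_frames: int
    out_of_range_frames: int = 0

    def to_dict(self) -> dict:
        return {
            "total_frames": self.total_frames,
            "out_of_range_frames": self.out_of_range_frames,
            "regions": [
                {"label": l, "count": int(c), "percent": float(p)}
                for l, c, p in zip(self.labels, self.counts, self.percentages)],
        }


def angle_series(traj: Trajectory, a: VectorDefinition,
                 b: VectorDefinition) -> AngleSeries:
    """Angle between two anchor-defined vectors at every frame, degrees.

    theta = arccos(v.w / (|v||w|)), with the cosine clamped to [-1, 1];
    a zero-length vector in any frame is an error naming that frame.
    """
    ia0, ia1 = a.resolve(traj.topology)
    ib0, ib1 = b.resolve(traj.topology)
    v = traj.coords[:, ia1] - traj.coords[:, ia0]
    w = traj.coords[:, ib1] - traj.coords[:, ib0]
    nv = np.linalg.norm(v, axis=1)
    nw = np.linalg.norm(w, axis=1)
    bad = np.nonzero((nv < 1e-12) | (nw < 1e-12))[0]
    if bad.size:
        raise ValueError(f"zero-length anchor vector at frame {bad[0]}")
    cosine = np.clip(np.sum(v * w, axis=1) / (nv * nw), -1.0, 1.0)
    return AngleSeries(np.degrees(np.arccos(cosine)), traj.times,
                       pair_label=f"{a.label}-{b.label}")


def substate_occupancy(series: AngleSeries, spec: SubstateSpec) -> OccupancyReport:
    """Fraction of frames in each angular region, as percentages.

    Bins are half-open [lo, hi) with the last bin closed; frames outside the
    spec's range are counted separately (percentages are over all frames, so
    they sum to 100 only when the spec covers the data).
    """
    if series.n_frames == 0:
        raise ValueError("empty angle series")
    edges = np.asarray(spec.edges)
    counts = np.zeros(spec.n_regions, dtype=int)
    for k in range(spec.n_regions):
        lo, hi = edges[k], edges[k + 1]
        if k == spec.n_regions - 1:
            in_bin = (series.angles >= lo) & (series.angles <= hi)
        else:
            in_bin = (series.angles >= lo) & (series.angles < hi)
        counts[k] = int(np.count_nonzero(in_bin))
    total = series.n_frames
    out_of_range = total - int(counts.sum())
    return OccupancyReport(spec.labels, counts / total * 100.0, counts,
                           total, out_of_range)


def region_boundaries_from_printed(ranges: list[tuple[float, float]],
                                   labels: tuple[str, ...] = ()) -> SubstateSpec:
    """Contiguous bin edges from printed, gapped angular ranges.

    Published substate ranges leave small gaps at reporting precision
    (e.g. ...-95.9 then 96-...); edges are placed at the gap midpoints
    (95.95) so every angle maps to exactly one region.
    """
    if not ranges:
        raise ValueError("no ranges")
    for (lo, hi) in ranges:
        if hi <= lo:
            raise ValueError(f"invalid printed range ({lo}, {hi})")
    for (_, hi_prev), (lo_next, _) in zip(ranges, ranges[1:]):
        if lo_next <= hi_prev:
            raise ValueError(
                f"printed ranges overlap or are unordered: "
                f"...-{hi_prev} then {lo_next}-...")
    edges = [ranges[0][0]]
    for (_, hi_prev), (lo_next, _) in zip(ranges, ranges[1:]):
        edges.append((hi_prev + lo_next) / 2.0)
    edges.append(ranges[-1][1])
    return SubstateSpec(tuple(edges), labels)


#: Published substate ranges: lateral motion (v1/v3 angle) of the wild-type
#: complex and medial motion (v1/v2 angle) of the Y173A mutant complex.
PRINTED_SUBSTATES = {
    "lateral-wt": [(78.0, 95.9), (96.0, 105.0), (105.1, 134.0)],
    "medial-y173a": [(74.0, 86.9), (87.0, 96.0), (96.1, 114.0)],
}


@dataclass
class DensityCurve:
    grid: np.ndarray      # degrees
    density: np.ndarray   # 1/degree, integrates to ~1
    bandwidth: float      # kernel sd in degrees


def angle_kde(series: AngleSeries, bandwidth: str | float = "silverman",
              grid_step: float = 0.1) -> DensityCurve:
    """Gaussian-kernel density of the angle distribution on a regular grid.

    The grid spans [min - 5, max + 5] degrees.  ``bandwidth`` is either
    "silverman" (rule-of-thumb, the default) or a fixed kernel standard
    deviation in degrees.  A constant series cannot use the Silverman rule.
    """
    x = series.angles
    if x.size < 2:
        raise ValueError("need at least 2 angles for a density estimate")
    if bandwidth == "silverman":
        if np.ptp(x) < 1e-12:
            raise ValueError(
                "constant angle series: Silverman's rule gives zero "
                "bandwidth; pass a fixed bandwidth in degrees instead")
        kde = gaussian_kde(x, bw_method="silverman")
        sigma = float(np.sqrt(kde.covariance[0, 0]))
        evaluate = kde
    else:
        sigma = float(bandwidth)
        if sigma <= 0:
            raise ValueError("fixed bandwidth must be > 0 degrees")

        def evaluate(g: np.ndarray) -> np.ndarray:
            # direct Gaussian kernel sum; handles zero-variance data, which
            # scipy's covariance-based estimator cannot
            z = (g[:, None] - x[None, :]) / sigma
            return np.exp(-0.5 * z * z).sum(axis=1) / (
                x.size * sigma * np.sqrt(2.0 * np.pi))

    # pad the grid so the kernel tails are captured (>= 4 sd on each side)
    pad = max(5.0, 4.0 * sigma)
    grid = np.arange(x.min() - pad, x.max() + pad + grid_step, grid_step)
    return DensityCurve(grid, evaluate(grid), sigma)


def kde_mode(curve: DensityCurve) -> float:
    """Angle (degrees) at the density maximum."""
    return float(curve.grid[int(np.argmax(curve.density))])
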