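"""In-memory containers shared across the pipeline.

Conventions
-----------
* Streamlines are ``(V, 3)`` float arrays of vertices in world millimetres
  (RAS+), matching the coordinate frame TCK files use natively and the frame
  nibabel converts TRK files into on load.
* Volumes carry a 4x4 voxel-to-world affine; the centre of voxel ``(i, j, k)``
  sits at ``affine @ (i, j, k, 1)``.
* Connectome matrices are dense, symmetric, with a zero diagonal.  Streamline
  counts (NOS) are integers; scalar weights (e.g. R1 in 1/s) are floats with
  0 marking an absent edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Tractogram",
    "ScalarVolume",
    "LabelVolume",
    "WeightedConnectome",
    "Cohort",
]

_SYM_ATOL = 1e-9


@dataclass
class Tractogram:
    """A set of streamlines sharing one spatial reference."""

    streamlines: list
    space: str = "RASmm"

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for idx, s in enumerate(self.streamlines):
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 1:
                raise ValueError(f"streamline {idx} is not a (V, 3) polyline")
            if not np.all(np.isfinite(s)):
                raise ValueError(f"streamline {idx} has non-finite coordinates")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class ScalarVolume:
    """A 3-D scalar field (e.g. a quantitative R1 map, 1/s) on a voxel grid."""

    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("scalar grid must be 3-D")
        self.affine = _check_affine(self.affine)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm coordinates to (fractional) voxel indices."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return points @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class LabelVolume:
    """Integer parcellation volume; label 0 is background."""

    grid: np.ndarray
    affine: np.ndarray
    label_table: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("label grid must be 3-D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            rounded = np.rint(np.asarray(self.grid, dtype=float))
            if not np.allclose(self.grid, rounded):
                raise ValueError("label grid must hold integer labels")
            self.grid = rounded.astype(np.int32)
        self.affine = _check_affine(self.affine)
        present = set(int(v) for v in np.unique(self.grid)) - {0}
        if not self.label_table:
            self.label_table = {lab: f"region_{lab}" for lab in sorted(present)}
        else:
            missing = present - set(self.label_table)
            if missing:
                raise ValueError(f"labels missing from label_table: {sorted(missing)}")
        self._kdtree = None  # built lazily for nearest-label queries

    @property
    def labels(self) -> list:
        return sorted(self.label_table)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return points @ inv[:3, :3].T + inv[:3, 3]

    def labelled_voxel_index(self):
        """KD-tree over world-mm centres of labelled voxels (cached)."""
        if self._kdtree is None:
            from scipy.spatial import cKDTree

            ijk = np.argwhere(self.grid != 0)
            world = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
            labels = self.grid[tuple(ijk.T)]
            self._kdtree = (cKDTree(world), labels)
        return self._kdtree


@dataclass
class WeightedConnectome:
    """Symmetric edge-weight matrix over an ordered node list.

    ``kind`` distinguishes streamline-count weights (``"nos"``) from
    bundle-median scalar weights (``"scalar"``).
    """

    nodes: np.ndarray
    weights: np.ndarray
    kind: str = "nos"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.nodes)
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match {n} nodes"
            )
        asym = np.abs(self.weights - self.weights.T)
        if asym.max(initial=0.0) > _SYM_ATOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(
                f"matrix asymmetric beyond {_SYM_ATOL} at ({self.nodes[i]}, {self.nodes[j]})"
            )
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be zero")
        if self.kind == "nos":
            if np.any(self.weights < 0):
                raise ValueError("NOS weights must be non-negative")
            # subject-level counts are integers; across-subject medians
            # (flagged in provenance) may be half-integers
            if not self.provenance.get("median_across_subjects") and not np.allclose(
                self.weights, np.rint(self.weights)
            ):
                raise ValueError("NOS weights must be non-negative integers")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def support(self) -> np.ndarray:
        """Boolean edge-presence matrix."""
        return self.weights != 0

    def copy_with(self, weights: np.ndarray, **kwargs) -> "WeightedConnectome":
        out = dict(nodes=self.nodes.copy(), weights=weights, kind=self.kind,
                   provenance=dict(self.provenance))
        out.update(kwargs)
        return WeightedConnectome(**out)


@dataclass
class Cohort:
    """Per-subject (NOS, scalar) connectome pairs over a shared node list."""

    subjects: list
    nodes: np.ndarray = None

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("cohort is empty")
        first_nodes = self.subjects[0][0].nodes
        if self.nodes is None:
            self.nodes = np.asarray(first_nodes)
        for idx, (nos, sca) in enumerate(self.subjects):
            if not np.array_equal(nos.nodes, self.nodes) or not np.array_equal(
                sca.nodes, self.nodes
            ):
                raise ValueError(f"subject {idx} node list differs from cohort")
            if not np.array_equal(nos.support(), sca.support()):
                raise ValueError(f"subject {idx}: NOS and scalar supports differ")

    def __len__(self) -> int:
        return len(self.subjects)

    def nos_stack(self) -> np.ndarray:
        """(n_subjects, N, N) array of NOS matrices."""
        return np.stack([nos.weights for nos, _ in self.subjects])

    def scalar_stack(self) -> np.ndarray:
        return np.stack([sca.weights for _, sca in self.subjects])
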