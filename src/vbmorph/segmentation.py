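"""TOF-like volume segmentation and surface reconstruction.

The reconstruction stage mirrors a standard angiographic workflow: a
double-threshold segmentation (defaults 850 and 2500 gray levels), selection
of the largest connected components to isolate the three main arteries,
marching-cubes surface extraction, and Taubin (lambda | mu) smoothing, which
removes staircase artifacts without the volume shrinkage of a plain
Laplacian filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage, sparse
from skimage import measure

from .volume import IntensityVolume, SegmentationMask

__all__ = [
    "SurfaceMesh",
    "threshold_segment",
    "largest_components",
    "mask_to_mesh",
    "taubin_smooth",
    "DEFAULT_LOWER",
    "DEFAULT_UPPER",
]

DEFAULT_LOWER = 850.0
DEFAULT_UPPER = 2500.0

# 26-connectivity for vessel foreground (standard digital-topology pairing
# with 6-connected background)
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SurfaceMesh:
    """Triangulated surface in physical (mm) coordinates."""

    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray     # (m, 3) int vertex indices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("faces reference non-existent vertices")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @property
    def volume(self) -> float:
        """Enclosed volume (mm^3) via the divergence theorem."""
        return float(abs(self.to_trimesh().volume))

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def save(self, path) -> None:
        """Write STL or PLY; format chosen from the file extension."""
        self.to_trimesh().export(str(path))

    @classmethod
    def load(cls, path) -> "SurfaceMesh":
        m = trimesh.load_mesh(str(path), process=False)
        return cls(np.asarray(m.vertices), np.asarray(m.faces))


def threshold_segment(volume: IntensityVolume,
                      lower: float = DEFAULT_LOWER,
                      upper: float = DEFAULT_UPPER) -> SegmentationMask:
    """Double-threshold segmentation: voxels with lower <= I <= upper."""
    if lower >= upper:
        raise ValueError(f"lower threshold ({lower}) must be below upper ({upper})")
    mask = (volume.data >= lower) & (volume.data <= upper)
    return SegmentationMask(mask, volume.spacing, volume.origin)


def largest_components(mask: SegmentationMask, k: int = 1) -> SegmentationMask:
    """Keep the k largest 26-connected foreground components.

    Equal-sized components are ordered by the lexicographically smaller
    centroid (in voxel index space) so the selection is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not mask.data.any():
        raise ValueError("empty mask: no components to select")
    labels, n = ndimage.label(mask.data, structure=_STRUCT_26)
    if n <= k:
        return SegmentationMask(mask.data.copy(), mask.spacing, mask.origin)
    sizes = np.bincount(labels.ravel())[1:]
    centroids = ndimage.center_of_mass(mask.data, labels, index=np.arange(1, n + 1))
    order = sorted(range(n), key=lambda i: (-sizes[i], tuple(centroids[i])))
    keep = np.zeros(n + 1, dtype=bool)
    keep[[i + 1 for i in order[:k]]] = True
    return SegmentationMask(keep[labels], mask.spacing, mask.origin)


def mask_to_mesh(mask: SegmentationMask) -> SurfaceMesh:
    """Marching-cubes isosurface of the binary mask at level 0.5, in mm.

    The mask is zero-padded by one voxel so surfaces touching the grid
    boundary still close.
    """
    if not mask.data.any():
        raise ValueError("empty mask: nothing to mesh")
    padded = np.pad(mask.data.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=tuple(mask.spacing))
    verts = verts + (mask.origin - mask.spacing)  # undo the pad offset
    return SurfaceMesh(verts, faces)


def _uniform_adjacency(n_vertices: int, faces: np.ndarray) -> sparse.csr_matrix:
    """Row-normalized vertex adjacency (uniform umbrella weights)."""
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    A = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)),
                          shape=(n_vertices, n_vertices))
    deg = np.asarray(A.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    return sparse.diags(1.0 / deg) @ A


def taubin_smooth(mesh: SurfaceMesh, lam: float = 0.5, mu: float = -0.53,
                  iters: int = 10) -> SurfaceMesh:
    """Taubin lambda|mu smoothing with uniform Laplacian weights.

    Each iteration applies a shrinking step ``v += lam * (avg(N(v)) - v)``
    followed by an inflating step with ``mu < 0``; choosing
    ``0 < lam < -mu`` puts the filter in Taubin's pass-band regime, which
    suppresses high-frequency staircase noise while nearly preserving
    volume. Vertex count and connectivity are unchanged.
    """
    if iters < 0:
        raise ValueError("iters must be >= 0")
    if len(mesh.faces) == 0:
        raise ValueError("degenerate mesh: no faces")
    if iters == 0:
        return SurfaceMesh(mesh.vertices.copy(), mesh.faces.copy())
    W = _uniform_adjacency(len(mesh.vertices), mesh.faces)
    v = mesh.vertices.copy()
    for _ in range(iters):
        v = v + lam * (W @ v - v)
        v = v + mu * (W @ v - v)
    return SurfaceMesh(v, mesh.faces.copy())
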