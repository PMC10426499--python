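"""Shape-and-size descriptors of the binary ROI (14 features).

Mesh-based quantities (volume, surface, diameters) come from a marching-
cubes surface of the mask; axis lengths come from the PCA of the physical
voxel coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

SHAPE_NAMES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


def _mesh(mask: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    padded = np.pad(mask, 1).astype(np.float64)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 4:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _max_inplane_diameter(
    vox: np.ndarray, spacing: np.ndarray, plane_axes: tuple[int, int], slice_axis: int
) -> float:
    """Largest in-plane physical distance between ROI voxels sharing a slice."""
    best = 0.0
    for s in np.unique(vox[:, slice_axis]):
        pts = vox[vox[:, slice_axis] == s][:, plane_axes] * spacing[list(plane_axes)]
        if len(pts) < 2:
            continue
        if len(pts) > 30:
            try:
                pts = pts[ConvexHull(pts).vertices]
            except Exception:
                pass
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        best = max(best, float(d2.max()))
    return float(np.sqrt(best))


def shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=np.float64)
    nvox = int(mask.sum())
    voxel_volume = float(np.prod(spacing))

    verts, faces = _mesh(mask, spacing)
    mesh_volume = _mesh_volume(verts, faces)
    surface = float(measure.mesh_surface_area(verts, faces))

    vox = np.argwhere(mask)
    coords = vox.astype(np.float64) * spacing

    # axis lengths: 4 * sqrt(eigenvalue) of the coordinate covariance
    if nvox > 1:
        eig = np.linalg.eigvalsh(np.cov(coords, rowvar=False))
        eig = np.clip(eig, 0.0, None)[::-1]  # descending
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(e) for e in eig)

    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface if surface > 0 else 0.0

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": nvox * voxel_volume,
        "SurfaceArea": surface,
        "SurfaceVolumeRatio": surface / mesh_volume if mesh_volume > 0 else np.inf,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": _max_pairwise(verts),
        # slice = fixed z, column = fixed y, row = fixed x (axis order x,y,z)
        "Maximum2DDiameterSlice": _max_inplane_diameter(vox, spacing, (0, 1), 2),
        "Maximum2DDiameterColumn": _max_inplane_diameter(vox, spacing, (0, 2), 1),
        "Maximum2DDiameterRow": _max_inplane_diameter(vox, spacing, (1, 2), 0),
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0,
    }
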