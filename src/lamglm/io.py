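"""Volume and surface I/O (NIfTI-1, FreeSurfer / GIfTI surfaces)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import Grid
from .surfaces import LayerBoundaries

__all__ = [
    "grid_from_affine",
    "load_volume",
    "save_volume",
    "read_surface_geometry",
    "TriangleSurface",
    "save_boundaries",
    "load_boundaries",
]


def grid_from_affine(shape, affine: np.ndarray) -> Grid:
    """Grid from a NIfTI affine; requires axis-aligned (diagonal) voxels."""
    affine = np.asarray(affine, dtype=float)
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise ValueError(
            "only axis-aligned affines are supported; resample the volume first"
        )
    return Grid(tuple(shape[:3]), np.diag(rot), affine[:3, 3])


def load_volume(path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    return data, grid_from_affine(data.shape, img.affine)


def save_volume(data: np.ndarray, grid: Grid, path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def read_surface_geometry(path) -> tuple[np.ndarray, np.ndarray]:
    """Vertices (mm) and faces from FreeSurfer binary or GIfTI surfaces."""
    path = Path(path)
    if path.suffix == ".gii":
        img = nib.load(str(path))
        verts = img.agg_data("pointset")
        faces = img.agg_data("triangle")
        return np.asarray(verts, dtype=float), np.asarray(faces, dtype=int)
    verts, faces = nib.freesurfer.read_geometry(str(path))
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=int)


@dataclass(frozen=True)
class TriangleSurface:
    """A closed triangle mesh usable as a layering input surface."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = "surface"

    def signed_distance(self, grid: Grid) -> np.ndarray:
        """Signed distance volume (negative inside), via trimesh."""
        import trimesh  # heavier dependency, only needed for mesh input

        mesh = trimesh.Trimesh(self.vertices, self.faces, process=False)
        if not mesh.is_watertight:
            raise ValueError(
                f"surface {self.name!r} is not watertight; provide a closed "
                "mesh or a binary mask instead"
            )
        pts = np.stack(grid.meshgrid(), axis=-1).reshape(-1, 3)
        # trimesh convention: positive inside; flip to negative-inside
        sd = -trimesh.proximity.signed_distance(mesh, pts)
        return sd.reshape(grid.shape)

    def save_gifti(self, path) -> None:
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    self.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    self.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))


def save_boundaries(boundaries: LayerBoundaries, path) -> None:
    """Persist layer boundaries (npz) for the design step."""
    np.savez_compressed(
        path,
        shape=np.asarray(boundaries.grid.shape),
        voxel_size=boundaries.grid.voxel_size,
        origin=boundaries.grid.origin,
        support=boundaries.support,
        indices=boundaries.indices,
        offsets=boundaries.offsets,
        normals=boundaries.normals,
        depth=boundaries.depth,
        thickness=boundaries.thickness,
        alphas=boundaries.alphas,
    )


def load_boundaries(path) -> LayerBoundaries:
    with np.load(path) as z:
        grid = Grid(tuple(z["shape"]), z["voxel_size"], z["origin"])
        return LayerBoundaries(
            grid=grid,
            support=z["support"],
            indices=z["indices"],
            offsets=z["offsets"],
            normals=z["normals"],
            depth=z["depth"],
            thickness=z["thickness"],
            alphas=z["alphas"],
        )
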