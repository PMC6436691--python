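"""Ground-truth model cortex.

A folded two-dimensional ribbon of k layers between a white-matter and a
pial boundary, relaxed so that every mesh cell has equal area (Bok's
equivolume principle), then rotated, extruded translationally to 3-D and
rasterised to per-voxel layer occupancy fractions.  The rasterised volume
is the gold standard against which layer-extraction methods are scored.

The ribbon midline is one full sinusoid period, so it contains one gyral
and one sulcal bend of equal magnitude.  Equal-area relaxation moves the
interior boundary vertices along the (straight) mesh columns joining the
fixed outer boundaries, with a displacement proportional to the area
imbalance of the adjacent cells -- a deterministic spring-mass analogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from matplotlib.path import Path as MplPath

from .grid import Grid

__all__ = [
    "ModelCortex",
    "GroundTruthVolume",
    "ExtrudedSurface",
    "RelaxationInfo",
    "init_cortex",
    "annulus_cortex",
    "relax_equivolume",
    "rasterise_cortex",
    "downsample_volume",
    "indicator_volume",
]


def _polygon_area(quad_corners):
    """Signed shoelace area of quads given corners (4, ..., 2)."""
    area = np.zeros(quad_corners.shape[1:-1])
    for a in range(4):
        p = quad_corners[a]
        q = quad_corners[(a + 1) % 4]
        area += p[..., 0] * q[..., 1] - q[..., 0] * p[..., 1]
    return 0.5 * area


@dataclass(frozen=True)
class ModelCortex:
    """Layered quadrilateral mesh of a 2-D cortical ribbon.

    ``boundaries`` has shape ``(k+1, n_columns+1, 2)`` in mm; boundary 0 is
    the white-matter surface, boundary k the pial surface.  Cells are the
    implicit quadrilaterals between consecutive boundaries and consecutive
    vertex columns.
    """

    boundaries: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 3 or b.shape[0] < 2 or b.shape[1] < 2 or b.shape[2] != 2:
            raise ValueError("boundaries must have shape (k+1, n_columns+1, 2)")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_layers(self) -> int:
        return self.boundaries.shape[0] - 1

    @property
    def n_columns(self) -> int:
        return self.boundaries.shape[1] - 1

    @property
    def cell_areas(self) -> np.ndarray:
        """Signed areas (mm^2) of the (k, n_columns) mesh cells."""
        b = self.boundaries
        corners = np.stack(
            [b[:-1, :-1], b[:-1, 1:], b[1:, 1:], b[1:, :-1]]
        )  # counter-clockwise when boundary 0 is below boundary k
        return _polygon_area(corners)

    def wm_boundary(self) -> np.ndarray:
        return self.boundaries[0]

    def pial_boundary(self) -> np.ndarray:
        return self.boundaries[-1]


@dataclass(frozen=True)
class RelaxationInfo:
    converged: bool
    n_iter: int
    max_deviation: float
    history: np.ndarray  # max relative area deviation per iteration


def _sine_midline(amplitude, wavelength, margin, n_dense=20001):
    """Dense sample of the sinusoid midline and its unit normals/curvature."""
    x = np.linspace(-margin, wavelength + margin, n_dense)
    w = 2 * np.pi / wavelength
    y = amplitude * np.sin(w * x)
    dy = amplitude * w * np.cos(w * x)
    speed = np.hypot(1.0, dy)
    tangent = np.stack([1.0 / speed, dy / speed], axis=-1)
    normal = np.stack([-tangent[:, 1], tangent[:, 0]], axis=-1)
    d2y = -amplitude * w**2 * np.sin(w * x)
    curvature = d2y / speed**3
    arclength = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
    return np.stack([x, y], axis=-1), normal, curvature, arclength


def init_cortex(
    n_columns: int = 256,
    k: int = 6,
    amplitude: float = 4.0,
    wavelength: float = 16.0,
    thickness: float = 3.0,
    margin: float = 2.0,
) -> ModelCortex:
    """Construct an equidistantly layered, folded 2-D cortex mesh.

    The midline is ``y = amplitude * sin(2 pi x / wavelength)`` over one
    full period (one gyrus, one sulcus) plus ``margin`` mm of run-in at
    either end.  k+1 boundary polylines are offset at equal spacing
    ``thickness / k`` along the local midline normal; mesh columns are
    placed so that every column strip between the outer boundaries has the
    same area (cells are then equalised depth-wise by
    :func:`relax_equivolume`).

    Raises ``ValueError`` if the ribbon would self-intersect, i.e. if the
    midline radius of curvature drops below half the thickness.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    centre, normal, curvature, arclength = _sine_midline(amplitude, wavelength, margin)
    half = thickness / 2.0
    if np.max(np.abs(curvature)) * half >= 1.0:
        raise ValueError(
            "ribbon self-intersects: amplitude too large for wavelength "
            f"(min radius of curvature {1.0 / np.max(np.abs(curvature)):.2f} mm "
            f"< half thickness {half:.2f} mm)"
        )

    # columns at equal arclength, then refined so outer-strip areas equalise
    s_cols = np.linspace(0.0, arclength[-1], n_columns + 1)
    offsets = np.linspace(-half, half, k + 1)
    for _ in range(8):
        c = np.empty((n_columns + 1, 2))
        m = np.empty((n_columns + 1, 2))
        for d in range(2):
            c[:, d] = np.interp(s_cols, arclength, centre[:, d])
            m[:, d] = np.interp(s_cols, arclength, normal[:, d])
        m /= np.linalg.norm(m, axis=-1, keepdims=True)
        wm = c - half * m
        pial = c + half * m
        strip = _polygon_area(np.stack([wm[:-1], wm[1:], pial[1:], pial[:-1]]))
        cum = np.concatenate([[0.0], np.cumsum(strip)])
        target = np.linspace(0.0, cum[-1], n_columns + 1)
        s_new = np.interp(target, cum, s_cols)
        shift = np.max(np.abs(s_new - s_cols))
        s_cols = s_new
        if shift < 1e-10 * arclength[-1]:
            break

    boundaries = c[None, :, :] + offsets[:, None, None] * m[None, :, :]
    mesh = ModelCortex(boundaries)
    if np.any(mesh.cell_areas <= 0):
        raise ValueError("mesh construction produced non-positive cell areas")
    return mesh


def annulus_cortex(
    r_in: float = 2.0,
    r_out: float = 4.0,
    k: int = 2,
    n_columns: int = 128,
    span: float = np.pi,
) -> ModelCortex:
    """Half-annulus validation mesh with equidistant initial layering.

    The equal-area split of an annulus is analytic -- for k=2 the interior
    boundary relaxes to radius ``sqrt((r_in**2 + r_out**2) / 2)`` -- which
    makes this geometry an exact oracle for the equivolume machinery.
    """
    theta = np.linspace(span, 0.0, n_columns + 1)  # orientation: j x depth = +z
    radii = np.linspace(r_in, r_out, k + 1)
    ring = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    return ModelCortex(radii[:, None, None] * ring[None, :, :])


def relax_equivolume(
    mesh: ModelCortex,
    tol: float = 1e-3,
    damping: float = 0.5,
    max_iter: int = 20000,
) -> tuple[ModelCortex, RelaxationInfo]:
    """Relax interior boundary vertices until all cell areas are equal.

    Vertices are confined to the straight mesh columns joining the fixed
    outer boundaries.  Each iteration displaces every interior vertex
    along its column in proportion to the area imbalance between the
    adjacent cells above and below (damped by ``damping``), the discrete
    analogue of a spring-mass system settling into the equivolume state.

    Converged when ``max |area/target - 1| <= tol`` with
    ``target = total area / n_cells``; raises ``RuntimeError`` with the
    residual if the iteration cap is reached first.
    """
    b = mesh.boundaries.copy()
    k, nc1 = b.shape[0] - 1, b.shape[1]
    base = b[0]
    chord = b[-1] - b[0]
    length = np.linalg.norm(chord, axis=-1)
    direction = chord / length[:, None]
    # project current boundary vertices onto their column chords
    u = np.einsum("ijd,jd->ij", b - base[None], direction)

    history = []
    target = None
    for it in range(max_iter):
        pts = base[None] + u[..., None] * direction[None]
        corners = np.stack([pts[:-1, :-1], pts[:-1, 1:], pts[1:, 1:], pts[1:, :-1]])
        areas = _polygon_area(corners)  # (k, nc)
        if target is None:
            target = areas.sum() / areas.size
        dev = np.max(np.abs(areas / target - 1.0))
        history.append(dev)
        if dev <= tol:
            return (
                ModelCortex(pts),
                RelaxationInfo(True, it, float(dev), np.asarray(history)),
            )
        if k == 1:
            break  # outer boundaries fixed: nothing to move
        # mean adjacent-cell area above/below each interior vertex
        pad = np.pad(areas, ((0, 0), (1, 1)), mode="edge")
        below = 0.5 * (pad[:-1, :-1] + pad[:-1, 1:])  # (k-1, nc+1)
        above = 0.5 * (pad[1:, :-1] + pad[1:, 1:])
        # local column spacing: area transferred per unit displacement
        row = pts[1:-1]
        width = np.empty((k - 1, nc1))
        width[:, 1:-1] = 0.5 * (
            np.linalg.norm(row[:, 2:] - row[:, 1:-1], axis=-1)
            + np.linalg.norm(row[:, 1:-1] - row[:, :-2], axis=-1)
        )
        width[:, 0] = np.linalg.norm(row[:, 1] - row[:, 0], axis=-1)
        width[:, -1] = np.linalg.norm(row[:, -1] - row[:, -2], axis=-1)
        u[1:-1] += damping * (above - below) / width
        # keep boundaries strictly ordered along each column
        eps = 1e-6 * length[None]
        np.clip(u[1:-1], eps, length[None] - eps, out=u[1:-1])
        for i in range(1, k):
            np.maximum(u[i], u[i - 1] + 1e-6 * length, out=u[i])

    raise RuntimeError(
        f"equivolume relaxation did not reach tol={tol:g} within "
        f"{max_iter} iterations (residual {history[-1]:.3g})"
    )


def _rotation(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


@dataclass(frozen=True)
class ExtrudedSurface:
    """A 2-D polyline surface extruded along the grid z axis.

    ``polyline`` is in mesh coordinates (mm); world in-plane coordinates
    are ``rotation @ p + translation``.  The enclosed ("inside") region is
    the side of the polyline reached along the negative local normal (the
    white-matter side), so signed distances are negative there.
    """

    polyline: np.ndarray
    rotation: np.ndarray
    translation: np.ndarray
    name: str = "surface"
    end_directions: np.ndarray = None  # (2, 2) closure rays toward the deep side

    def world_polyline(self) -> np.ndarray:
        return self.polyline @ self.rotation.T + self.translation

    def _below_path(self) -> MplPath:
        # close the "inside" region with rays along the lateral end columns
        # (shared by all boundaries of one mesh) so that consecutive
        # below-regions nest exactly; default closure is straight down
        p = self.polyline
        if self.end_directions is None:
            d0 = dlast = np.array([0.0, -1.0])
        else:
            d0, dlast = self.end_directions
        L = 10.0 * (np.ptp(p[:, 0]) + np.ptp(p[:, 1]) + 1.0)
        closed = np.vstack([p[0] + L * d0, p, p[-1] + L * dlast])
        return MplPath(closed)

    def signed_distance_points(self, points_world_xy: np.ndarray) -> np.ndarray:
        """Exact signed distance (mm) from in-plane world points."""
        pts = (points_world_xy - self.translation) @ self.rotation
        seg_a = self.polyline[:-1]
        seg = self.polyline[1:] - seg_a
        seg_len2 = np.einsum("sd,sd->s", seg, seg)
        dist2 = np.full(pts.shape[0], np.inf)
        chunk = 4096
        for lo in range(0, pts.shape[0], chunk):
            p = pts[lo : lo + chunk]
            diff = p[:, None, :] - seg_a[None, :, :]
            tpar = np.clip(np.einsum("psd,sd->ps", diff, seg) / seg_len2, 0.0, 1.0)
            proj = diff - tpar[..., None] * seg[None]
            dist2[lo : lo + chunk] = np.min(np.einsum("psd,psd->ps", proj, proj), axis=1)
        dist = np.sqrt(dist2)
        inside = self._below_path().contains_points(pts)
        return np.where(inside, -dist, dist)

    def signed_distance(self, grid: Grid) -> np.ndarray:
        """Signed distance volume on ``grid`` (z-invariant extrusion)."""
        gx, gy = grid.meshgrid(axes=(0, 1))
        pts = np.stack([gx.ravel(), gy.ravel()], axis=-1)
        sdf2d = self.signed_distance_points(pts).reshape(grid.shape[0], grid.shape[1])
        return np.broadcast_to(sdf2d[:, :, None], grid.shape).copy()

    def to_mesh(self, z_extent: tuple[float, float], n_z: int = 2):
        """Triangulated world-space surface (vertices, faces) for export."""
        line = self.world_polyline()
        zs = np.linspace(z_extent[0], z_extent[1], n_z)
        verts = np.concatenate(
            [np.column_stack([line, np.full(len(line), z)]) for z in zs]
        )
        faces = []
        npl = len(line)
        for zi in range(n_z - 1):
            for i in range(npl - 1):
                a = zi * npl + i
                faces.append([a, a + 1, a + npl])
                faces.append([a + 1, a + npl + 1, a + npl])
        return verts, np.asarray(faces, dtype=int)


@dataclass(frozen=True)
class GroundTruthVolume:
    """Rasterised model cortex: per-voxel true layer volume fractions."""

    grid: Grid
    occupancy: np.ndarray  # (nx, ny, nz, k)
    wm_fraction: np.ndarray
    exterior_fraction: np.ndarray
    surfaces: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_layers(self) -> int:
        return self.occupancy.shape[-1]

    @property
    def in_cortex(self) -> np.ndarray:
        return self.occupancy.sum(axis=-1)

    @property
    def wm_mask(self) -> np.ndarray:
        return self.wm_fraction > 0.5

    @property
    def gm_mask(self) -> np.ndarray:
        return self.in_cortex > 0.5

    @property
    def exterior_mask(self) -> np.ndarray:
        return self.exterior_fraction > 0.5

    def layer_volumes(self) -> np.ndarray:
        """Total volume (mm^3) of each layer over the grid."""
        voxel_volume = float(np.prod(self.grid.voxel_size))
        return self.occupancy.sum(axis=(0, 1, 2)) * voxel_volume


def _boundary_surface(
    mesh: ModelCortex, i: int, rotation, translation, name: str = None
) -> ExtrudedSurface:
    """Boundary i as an extruded surface, closed along the end columns."""
    cols = mesh.pial_boundary() - mesh.wm_boundary()
    dirs = np.stack([-cols[0], -cols[-1]])
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    return ExtrudedSurface(
        mesh.boundaries[i],
        np.asarray(rotation, dtype=float),
        np.asarray(translation, dtype=float),
        name or f"boundary{i}",
        dirs,
    )


def _centred_origin(grid_shape, voxel_size) -> np.ndarray:
    shape = np.asarray(grid_shape, dtype=float)
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    return -(shape - 1.0) * vs / 2.0


def rasterise_cortex(
    mesh: ModelCortex,
    rotation: float = 30.0,
    grid_shape=(64, 64, 64),
    voxel_size: float = 0.5,
    subsamples: int = 8,
) -> GroundTruthVolume:
    """Rotate, extrude and rasterise the mesh to layer-occupancy fractions.

    The mesh is rotated in-plane by ``rotation`` degrees (breaking
    alignment between the cortical sheet and the voxel grid), extruded
    along z through the full grid depth, and sampled with
    ``subsamples``^3 regularly spaced points per voxel.  Because the
    extrusion is translational along the grid z axis, the z sub-samples of
    a voxel coincide by construction, so the in-plane ``subsamples``^2
    lattice decides the occupancy exactly.
    """
    R = _rotation(rotation)
    k = mesh.n_layers
    allpts = mesh.boundaries.reshape(-1, 2) @ R.T
    lo = allpts.min(axis=0)
    hi = allpts.max(axis=0)
    extent = np.asarray(grid_shape[:2]) * voxel_size
    if np.any(hi - lo > extent):
        need = np.ceil((hi - lo) / voxel_size).astype(int)
        raise ValueError(
            f"ribbon extent {hi - lo} mm exceeds grid extent {extent} mm; "
            f"use at least {tuple(need)} in-plane voxels"
        )
    translation = -(lo + hi) / 2.0
    grid = Grid(grid_shape, voxel_size, _centred_origin(grid_shape, voxel_size))

    # in-plane sub-pixel lattice
    sub = ((np.arange(subsamples) + 0.5) / subsamples - 0.5) * voxel_size
    xs = (grid.axis_coords(0)[:, None] + sub[None, :]).ravel()
    ys = (grid.axis_coords(1)[:, None] + sub[None, :]).ravel()
    px, py = np.meshgrid(xs, ys, indexing="ij")
    pts_world = np.stack([px.ravel(), py.ravel()], axis=-1)
    pts_mesh = (pts_world - translation) @ R

    # count, per point, how many boundary surfaces it lies *above*
    above_count = np.zeros(pts_mesh.shape[0], dtype=np.int8)
    for i in range(k + 1):
        path = _boundary_surface(mesh, i, R, translation)._below_path()
        above_count += ~path.contains_points(pts_mesh)
    nx, ny = grid.shape[0], grid.shape[1]
    region = (
        above_count.reshape(nx, subsamples, ny, subsamples)
        .transpose(0, 2, 1, 3)
        .reshape(nx, ny, subsamples**2)
    )

    n_sub = subsamples**2
    occupancy2d = np.empty((nx, ny, k))
    for j in range(k):
        # above boundaries 0..j (j+1 of them) and below the rest -> layer j
        occupancy2d[:, :, j] = (region == j + 1).sum(axis=-1) / n_sub
    wm2d = (region == 0).sum(axis=-1) / n_sub
    ext2d = (region == k + 1).sum(axis=-1) / n_sub

    occupancy = np.broadcast_to(occupancy2d[:, :, None, :], grid.shape + (k,)).copy()
    wm_fraction = np.broadcast_to(wm2d[:, :, None], grid.shape).copy()
    exterior_fraction = np.broadcast_to(ext2d[:, :, None], grid.shape).copy()
    surfaces = {
        "wm": _boundary_surface(mesh, 0, R, translation, "wm"),
        "pial": _boundary_surface(mesh, k, R, translation, "pial"),
    }
    return GroundTruthVolume(
        grid=grid,
        occupancy=occupancy,
        wm_fraction=wm_fraction,
        exterior_fraction=exterior_fraction,
        surfaces=surfaces,
        meta={
            "rotation_deg": float(rotation),
            "subsamples": int(subsamples),
            "translation": translation,
            "rotation_matrix": R,
            "n_layers": k,
        },
    )


def _block_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    sh = arr.shape
    if any(s % factor for s in sh[:3]):
        raise ValueError(f"dims {sh[:3]} not divisible by factor {factor}")
    view = arr.reshape(
        sh[0] // factor, factor, sh[1] // factor, factor, sh[2] // factor, factor,
        *sh[3:],
    )
    return view.mean(axis=(1, 3, 5))


def downsample_volume(vol, factor: int):
    """Block-mean downsampling of a scalar volume or a GroundTruthVolume."""
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if isinstance(vol, GroundTruthVolume):
        if factor == 1:
            return vol
        return replace(
            vol,
            grid=vol.grid.downsampled(factor),
            occupancy=_block_mean(vol.occupancy, factor),
            wm_fraction=_block_mean(vol.wm_fraction, factor),
            exterior_fraction=_block_mean(vol.exterior_fraction, factor),
        )
    arr = np.asarray(vol, dtype=float)
    if factor == 1:
        return arr
    return _block_mean(arr, factor)


def indicator_volume(gt: GroundTruthVolume, layer: int) -> np.ndarray:
    """Volume with unit signal in true layer ``layer`` (0-based, 0 = deepest).

    Each voxel holds the true partial volume of that layer, i.e. the image
    an idealised scanner would record if exactly one lamina were active.
    """
    if not 0 <= layer < gt.n_layers:
        raise ValueError(f"layer must be in [0, {gt.n_layers - 1}]")
    return gt.occupancy[..., layer].copy()
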