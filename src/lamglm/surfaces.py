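"""Equivolume cortical layering between the WM and pial surfaces.

The cortical ribbon is represented implicitly by two signed distance
functions (negative inside the enclosed region).  Depth structure comes
from the solution of the Laplace equation with Dirichlet conditions 0 on
the white-matter side and 1 beyond the pial surface: its streamlines
connect the two surfaces without crossing, and the local WM->pial
direction is the (unit) gradient of the potential, computed spectrally
with a Tukey low-pass window so that the voxelwise mean curvature (half
the divergence of the normal field) is well behaved.

Layer boundaries are then placed per voxel at depths that divide the
local streamline volume into the requested fractions.  In the extruded
(single principal curvature) geometry the cross-section of a cortical
column widens linearly with depth, ``w(u) = w0 * (1 + c (u - u0))`` with
``c`` the divergence of the normal field at the voxel, so the boundary for
cumulative volume fraction alpha solves a quadratic; for ``c -> 0`` it
reduces to the equidistant ``alpha * T``.  For genuinely 3-D folds the
same formula with ``c = 2 x mean curvature`` is a first-order
approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.signal.windows import tukey
from scipy.sparse.linalg import cg

from .grid import Grid

__all__ = [
    "DepthField",
    "LayerBoundaries",
    "signed_distance",
    "solve_laplace",
    "gradient_field",
    "mean_curvature",
    "equivolume_offsets",
    "compute_layering",
]


@dataclass(frozen=True)
class DepthField:
    """Per-voxel depth structure of the cortical ribbon."""

    grid: Grid
    sdf_wm: np.ndarray  # mm, negative inside the WM surface
    sdf_pial: np.ndarray  # mm, negative inside the pial surface
    potential: np.ndarray  # Laplace solution, 0 at WM, 1 at pial
    normal_field: np.ndarray  # (..., 3) unit WM->pial streamline direction
    curvature: np.ndarray  # mean curvature, 1/mm

    @property
    def ribbon_mask(self) -> np.ndarray:
        return (self.sdf_wm > 0) & (self.sdf_pial < 0)


@dataclass(frozen=True)
class LayerBoundaries:
    """Per-voxel equivolume layer-boundary offsets.

    For each supported voxel (``support`` mask; ``indices`` are its voxel
    coordinates) ``offsets[v]`` holds k+1 ascending signed distances (mm)
    from the voxel centre along ``normals[v]`` to the layer boundary
    surfaces; boundary 0 is the WM crossing and boundary k the pial
    crossing.  ``alphas`` are the cumulative volume fractions labelling
    the level set.
    """

    grid: Grid
    support: np.ndarray  # bool volume
    indices: np.ndarray  # (M, 3) int
    offsets: np.ndarray  # (M, k+1) mm
    normals: np.ndarray  # (M, 3)
    depth: np.ndarray  # (M,) mm from WM surface
    thickness: np.ndarray  # (M,) mm
    alphas: np.ndarray  # (k+1,)

    @property
    def n_layers(self) -> int:
        return self.offsets.shape[1] - 1

    def lookup(self) -> np.ndarray:
        """Flat volume -> row index map (-1 where unsupported)."""
        lut = np.full(self.grid.shape, -1, dtype=np.int64)
        lut[tuple(self.indices.T)] = np.arange(len(self.indices))
        return lut


def signed_distance(surface, grid: Grid) -> np.ndarray:
    """Euclidean signed distance volume to a closed surface.

    ``surface`` may be a boolean inside-mask on ``grid`` (the SDF is then
    derived from exact Euclidean distance transforms, accurate to about
    half a voxel at the interface) or any object exposing
    ``signed_distance(grid)`` (e.g. the simulator's extruded polyline
    surfaces, which are exact).
    """
    if hasattr(surface, "signed_distance"):
        return surface.signed_distance(grid)
    mask = np.asarray(surface)
    if mask.dtype != bool:
        raise TypeError("mask surface must be a boolean array")
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {grid.shape}")
    if not mask.any() or mask.all():
        raise ValueError("mask must contain both inside and outside voxels")
    sampling = grid.voxel_size
    h = float(np.mean(sampling))
    d_in = ndimage.distance_transform_edt(mask, sampling=sampling)
    d_out = ndimage.distance_transform_edt(~mask, sampling=sampling)
    return np.where(mask, -(d_in - h / 2), d_out - h / 2)


def solve_laplace(
    wm_mask: np.ndarray,
    ribbon_mask: np.ndarray,
    pial_mask: np.ndarray,
    grid: Grid,
    tol: float = 1e-6,
) -> np.ndarray:
    """Discrete harmonic potential in the ribbon, 0 at WM and 1 at pial.

    Seven-point Laplacian with Dirichlet values on the two boundary sets
    and homogeneous Neumann closure against any unlabelled voxels, solved
    by conjugate gradients (the system is symmetric positive definite).
    Ribbon components that touch only one boundary set are flagged with a
    warning; their potential saturates at that boundary's value.
    """
    shape = ribbon_mask.shape
    if wm_mask.shape != shape or pial_mask.shape != shape:
        raise ValueError("mask shapes differ")
    if np.any(wm_mask & ribbon_mask) or np.any(pial_mask & ribbon_mask):
        raise ValueError("boundary masks must not overlap the ribbon")

    labels, n_comp = ndimage.label(ribbon_mask)
    for comp in range(1, n_comp + 1):
        grown = ndimage.binary_dilation(labels == comp)
        if not (grown & wm_mask).any() or not (grown & pial_mask).any():
            warnings.warn(
                f"ribbon component {comp} touches only one boundary set; "
                "its potential is ill-determined",
                RuntimeWarning,
            )

    idx = np.full(shape, -1, dtype=np.int64)
    n = int(ribbon_mask.sum())
    idx[ribbon_mask] = np.arange(n)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    rhs = np.zeros(n)
    inv_h2 = 1.0 / grid.voxel_size**2
    here = np.nonzero(ribbon_mask)
    for axis in range(3):
        w = inv_h2[axis]
        for step in (-1, 1):
            nb = [here[0].copy(), here[1].copy(), here[2].copy()]
            nb[axis] = nb[axis] + step
            valid = (nb[axis] >= 0) & (nb[axis] < shape[axis])
            nbv = tuple(a[valid] for a in nb)
            src = idx[here][valid]
            in_ribbon = ribbon_mask[nbv]
            in_pial = pial_mask[nbv]
            coupled = in_ribbon | in_pial | wm_mask[nbv]  # others: Neumann
            np.add.at(diag, src[coupled], w)
            tgt = idx[nbv]
            rows.append(src[in_ribbon])
            cols.append(tgt[in_ribbon])
            vals.append(np.full(int(in_ribbon.sum()), -w))
            np.add.at(rhs, src[in_pial], w)  # Dirichlet value 1

    A = sparse.csr_matrix(
        (
            np.concatenate(vals + [diag]),
            (
                np.concatenate(rows + [np.arange(n)]),
                np.concatenate(cols + [np.arange(n)]),
            ),
        ),
        shape=(n, n),
    )
    x, info = cg(A, rhs, x0=np.full(n, 0.5), rtol=tol * 1e-2, maxiter=20 * max(shape))
    if info != 0:
        warnings.warn(f"Laplace CG did not fully converge (info={info})", RuntimeWarning)
    residual = np.abs(A @ x - rhs) / np.maximum(diag, 1e-30)
    if np.max(residual) > tol:
        warnings.warn(
            f"Laplace residual {np.max(residual):.3g} above tol {tol:g}",
            RuntimeWarning,
        )
    potential = np.zeros(shape)
    potential[pial_mask] = 1.0
    potential[ribbon_mask] = np.clip(x, 0.0, 1.0)
    # unlabelled voxels keep the nearest labelled value for smooth filtering
    unlabelled = ~(ribbon_mask | wm_mask | pial_mask)
    if unlabelled.any():
        _, nearest = ndimage.distance_transform_edt(unlabelled, return_indices=True)
        potential[unlabelled] = potential[tuple(nearest)][unlabelled]
    return potential


def _spectral_gradient(volume: np.ndarray, grid: Grid, tukey_alpha: float):
    """Gradient via FFT with a separable Tukey low-pass window."""
    spec = np.fft.fftn(volume)
    derivs = []
    for axis, n in enumerate(volume.shape):
        freq = np.fft.fftfreq(n, d=grid.voxel_size[axis])
        # tukey() peaks mid-array; shift so the flat top is centred on DC
        win = np.fft.ifftshift(tukey(n, alpha=tukey_alpha, sym=False))
        shape = [1, 1, 1]
        shape[axis] = n
        spec = spec * win.reshape(shape)
        derivs.append((2j * np.pi * freq).reshape(shape))
    out = np.empty(volume.shape + (3,))
    for axis in range(3):
        out[..., axis] = np.real(np.fft.ifftn(spec * derivs[axis]))
    return out


def gradient_field(
    potential: np.ndarray,
    grid: Grid,
    tukey_alpha: float = 0.5,
    ribbon_mask: np.ndarray = None,
    fallback: np.ndarray = None,
) -> np.ndarray:
    """Unit WM->pial direction field from the Laplace potential.

    The gradient is taken in the Fourier domain after multiplying the
    spectrum with a separable Tukey window of parameter ``tukey_alpha``
    (0 = no taper, i.e. the plain spectral derivative), then normalised.
    Voxels with (numerically) zero gradient fall back to the gradient of
    ``fallback`` (typically a signed-distance average) with a warning.
    """
    g = _spectral_gradient(potential, grid, tukey_alpha)
    norm = np.linalg.norm(g, axis=-1)
    bad = norm < 1e-12
    check = bad if ribbon_mask is None else (bad & ribbon_mask)
    if check.any():
        warnings.warn(
            f"{int(check.sum())} ribbon voxels had zero potential gradient; "
            "falling back to the SDF gradient there",
            RuntimeWarning,
        )
    if bad.any() and fallback is not None:
        fg = np.stack(np.gradient(fallback, *grid.voxel_size, edge_order=1), axis=-1)
        g[bad] = fg[bad]
        norm = np.linalg.norm(g, axis=-1)
        bad = norm < 1e-12
    g[bad] = [0.0, 0.0, 1.0]  # arbitrary unit direction far from the ribbon
    norm = np.linalg.norm(g, axis=-1)
    return g / norm[..., None]


def mean_curvature(normal_field: np.ndarray, grid: Grid) -> np.ndarray:
    """Half the divergence of the unit normal field (1/mm).

    Positive where laminar surfaces are convex toward the pial side; for a
    sphere of radius r with outward normals this is 1/r, for an extruded
    cylinder 1/(2r).
    """
    div = np.zeros(normal_field.shape[:-1])
    for axis in range(3):
        div += np.gradient(
            normal_field[..., axis], grid.voxel_size[axis], axis=axis, edge_order=1
        )
    return 0.5 * div


def equivolume_offsets(
    sdf_wm: np.ndarray,
    sdf_pial: np.ndarray,
    curvature: np.ndarray,
    normal_field: np.ndarray,
    grid: Grid,
    k: int = 6,
    layer_fractions_spec=None,
    support: np.ndarray = None,
    min_width: float = 0.05,
) -> LayerBoundaries:
    """Place per-voxel equivolume layer boundaries along the normal field.

    For a voxel at depth ``u0 = sdf_wm`` with local thickness
    ``T = sdf_wm - sdf_pial`` and column widening rate
    ``c = 2 x mean curvature``, the boundary at cumulative volume fraction
    alpha sits at the depth ``d`` solving

        int_0^d (1 + c (u - u0)) du = alpha * int_0^T (1 + c (u - u0)) du,

    whose numerically stable root is ``d = 2 alpha F_T / (b + sqrt(b^2 +
    2 c alpha F_T))`` with ``b = 1 - c u0`` and ``F_T`` the right-hand
    integral.  Offsets are ``d - u0``, distances from the voxel centre
    along the normal; boundaries 0 and k land exactly on the WM and pial
    surface crossings for any curvature, and ``c -> 0`` recovers the
    equidistant ``alpha T``.  Curvatures so strong that the column width
    would vanish inside the ribbon (width < ``min_width``) are clamped
    with a warning.
    """
    if layer_fractions_spec is None:
        alphas = np.linspace(0.0, 1.0, k + 1)
    else:
        fr = np.asarray(layer_fractions_spec, dtype=float)
        if np.any(fr <= 0):
            raise ValueError("layer fractions must be positive")
        alphas = np.concatenate([[0.0], np.cumsum(fr / fr.sum())])
        k = len(fr)
    if support is None:
        ribbon = (sdf_wm > 0) & (sdf_pial < 0)
        support = ndimage.binary_dilation(ribbon, iterations=2)
    support = support & (sdf_wm - sdf_pial > 0)

    indices = np.argwhere(support)
    u0 = sdf_wm[support]
    T = (sdf_wm - sdf_pial)[support]
    c = 2.0 * curvature[support]
    # clamp so the column width 1 + c (u - u0) stays >= min_width on [0, T]
    c_max = (1.0 - min_width) / np.maximum(u0, 1e-9)
    c_min = -(1.0 - min_width) / np.maximum(T - u0, 1e-9)
    n_clamped = int(np.sum((c > c_max) | (c < c_min)))
    if n_clamped:
        warnings.warn(
            f"curvature clamped in {n_clamped} voxels (column width would "
            f"fall below {min_width})",
            RuntimeWarning,
        )
    c = np.clip(c, c_min, c_max)

    b = 1.0 - c * u0
    F_T = T * b + 0.5 * c * T**2
    a = alphas[None, :]
    disc = np.maximum(b[:, None] ** 2 + 2.0 * c[:, None] * a * F_T[:, None], 0.0)
    depth_a = 2.0 * a * F_T[:, None] / (b[:, None] + np.sqrt(disc))
    offsets = depth_a - u0[:, None]
    # enforce ordering against numerical ties
    offsets = np.maximum.accumulate(offsets, axis=1)
    return LayerBoundaries(
        grid=grid,
        support=support,
        indices=indices,
        offsets=offsets,
        normals=normal_field[support],
        depth=u0,
        thickness=T,
        alphas=alphas,
    )


def compute_layering(
    wm_surface,
    pial_surface,
    grid: Grid,
    k: int = 6,
    upsample: int = 2,
    tukey_alpha: float = 0.5,
    laplace_tol: float = 1e-6,
    layer_fractions_spec=None,
) -> tuple[LayerBoundaries, DepthField]:
    """Full layering pipeline: surfaces -> equivolume boundaries.

    Runs on a grid upsampled by ``upsample`` in each dimension (layering
    on a finer-than-acquisition grid stabilises the partial-volume
    estimates); the returned boundaries live on that upsampled grid and
    are aggregated back to the native grid by the design-matrix builder.
    """
    fine = grid.upsampled(upsample) if upsample > 1 else grid

    def to_fine(surface):
        # binary masks given at native resolution are block-replicated
        if isinstance(surface, np.ndarray) and surface.shape == tuple(grid.shape):
            for axis in range(3):
                surface = np.repeat(surface, upsample, axis=axis)
        return surface

    if upsample > 1:
        wm_surface = to_fine(wm_surface)
        pial_surface = to_fine(pial_surface)
    sdf_wm = signed_distance(wm_surface, fine)
    sdf_pial = signed_distance(pial_surface, fine)
    ribbon = (sdf_wm > 0) & (sdf_pial < 0)
    wm_side = sdf_wm <= 0
    pial_side = (sdf_pial >= 0) & ~wm_side & ~ribbon
    potential = solve_laplace(wm_side, ribbon, pial_side, fine, tol=laplace_tol)
    normals = gradient_field(
        potential,
        fine,
        tukey_alpha=tukey_alpha,
        ribbon_mask=ribbon,
        fallback=0.5 * (sdf_wm + sdf_pial),
    )
    curv = mean_curvature(normals, fine)
    boundaries = equivolume_offsets(
        sdf_wm,
        sdf_pial,
        curv,
        normals,
        fine,
        k=k,
        layer_fractions_spec=layer_fractions_spec,
    )
    depth_field = DepthField(
        grid=fine,
        sdf_wm=sdf_wm,
        sdf_pial=sdf_pial,
        potential=potential,
        normal_field=normals,
        curvature=curv,
    )
    return boundaries, depth_field
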