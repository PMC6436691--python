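"""Exact plane--cube intersection geometry.

A voxel is modelled as an axis-aligned unit cube centred at the origin.  A
cortical layer boundary passing through the voxel is locally a plane with
unit normal ``n`` at signed distance ``t`` from the voxel centre (positive
toward the pial side).  This module computes, in closed form,

* the area of the polygon where the plane cuts the cube,
* the cumulative volume of the cube on the negative side of the plane, and
* the per-layer volume fractions for a stack of parallel boundary planes,

which together are the partial-volume primitive behind the spatial-GLM
design matrix.

The closed form is the classical corner-sum (clipped-simplex) expression:
with the cube mapped to ``[0,1]^3`` and all normal components positive,

    V(s) = sum_{c in {0,1}^3} (-1)^{|c|} max(0, s - n.c)^3 / (6 n1 n2 n3)

and the cut area is its derivative in ``s``.  Normals with (near-)zero
components reduce to the analogous 2-D and 1-D formulas, which avoids
catastrophic cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "PlaneCut",
    "LayerSlab",
    "intersection_area",
    "cumulative_volume",
    "layer_fractions",
    "cut_area",
    "cut_volume",
    "slab_fractions",
    "scale_to_voxel",
]

#: components of |n| below this are treated as exactly zero (the formula
#: then drops to a lower-dimensional cut); the induced volume error is O(eps)
_EPS_COMPONENT = 1e-7

_UNIT_TOL = 1e-12


def _validate_normals(normals: np.ndarray) -> np.ndarray:
    normals = np.asarray(normals, dtype=float)
    if normals.shape[-1] != 3:
        raise ValueError("normal must be a 3-vector (or array of them)")
    norms = np.linalg.norm(normals, axis=-1)
    if not np.allclose(norms, 1.0, rtol=0.0, atol=_UNIT_TOL):
        worst = float(np.max(np.abs(norms - 1.0)))
        raise ValueError(
            f"normal must have unit length (max |norm - 1| = {worst:.3g}); "
            "divide the vector by its Euclidean norm first"
        )
    return normals


@dataclass(frozen=True)
class PlaneCut:
    """A plane cutting the unit voxel cube.

    Parameters
    ----------
    normal:
        Unit 3-vector, the plane normal (dimensionless).
    offset:
        Signed distance of the plane from the voxel centre along
        ``normal``, in voxel-edge units.
    """

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        object.__setattr__(self, "normal", _validate_normals(self.normal))
        if not np.isfinite(self.offset):
            raise ValueError("offset must be finite (got NaN/inf)")
        object.__setattr__(self, "offset", float(self.offset))


@dataclass(frozen=True)
class LayerSlab:
    """A stack of parallel layer-boundary planes through one voxel.

    ``boundary_offsets`` are k+1 strictly ascending signed distances from
    the voxel centre along the shared ``normal``; the first may be ``-inf``
    and the last ``+inf`` (half-open outermost compartments).
    """

    normal: np.ndarray
    boundary_offsets: np.ndarray = field(default=None)

    def __post_init__(self):
        object.__setattr__(self, "normal", _validate_normals(self.normal))
        offs = np.asarray(self.boundary_offsets, dtype=float)
        if offs.ndim != 1 or offs.size < 2:
            raise ValueError("boundary_offsets must be a 1-D sequence of >= 2 offsets")
        if np.any(np.isnan(offs)):
            raise ValueError("boundary_offsets must not contain NaN")
        if not np.all(np.diff(offs) > 0):
            raise ValueError("boundary_offsets must be strictly ascending")
        object.__setattr__(self, "boundary_offsets", offs)


def _corner_sum(a: np.ndarray, s: np.ndarray, power: int, dims) -> np.ndarray:
    """sum over cube corners of (-1)^|c| relu(s - a.c)^power, for axes `dims`."""
    out = np.zeros(np.broadcast_shapes(a.shape[:-1], s.shape), dtype=float)
    for corner in product((0, 1), repeat=len(dims)):
        shift = np.zeros_like(out)
        for bit, axis in zip(corner, dims):
            if bit:
                shift = shift + a[..., axis]
        term = np.maximum(0.0, s - shift) ** power
        out += term if sum(corner) % 2 == 0 else -term
    return out


def cut_volume(normals: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Vectorised cumulative cut volume of the unit cube.

    Parameters
    ----------
    normals:
        Array of unit normals, shape ``(..., 3)``.
    offsets:
        Signed plane offsets from the cube centre, broadcastable against
        ``normals[..., 0]``.  ``+/-inf`` are accepted and saturate to 1/0.

    Returns
    -------
    Volume fraction of the cube on the side ``x . n <= offset``, in [0, 1].
    """
    normals = np.asarray(normals, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    a = np.abs(normals)  # reflection symmetry of the centred cube
    half = 0.5 * a.sum(axis=-1)
    # map to the [0,1]^3 cube: s in [0, sum(a)]
    s = offsets + half
    out = np.zeros(np.broadcast_shapes(a.shape[:-1], offsets.shape), dtype=float)
    a = np.broadcast_to(a, out.shape + (3,))
    s = np.broadcast_to(s, out.shape)

    small = a < _EPS_COMPONENT
    # saturation handles +/-inf offsets as well
    hi = s >= np.broadcast_to(2 * half, out.shape)
    mid = (s > 0) & ~hi
    out[hi] = 1.0

    codes = small @ np.array([4, 2, 1])
    for code in np.unique(codes[mid]):
        rows = mid & (codes == code)
        axes = tuple(i for i in range(3) if not (code >> (2 - i)) & 1)
        d = len(axes)
        aa = a[rows]
        ss = s[rows]
        if d == 0:
            out[rows] = 0.5  # degenerate normal: treat as central plane
            continue
        denom = np.prod([aa[:, ax] for ax in axes], axis=0)
        fact = {1: 1.0, 2: 2.0, 3: 6.0}[d]
        vals = _corner_sum(aa, ss, d, axes) / (fact * denom)
        out[rows] = np.clip(vals, 0.0, 1.0)
    return out


def cut_area(normals: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Vectorised plane--cube intersection area (voxel-face units)."""
    normals = np.asarray(normals, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    a = np.abs(normals)
    half = 0.5 * a.sum(axis=-1)
    s = offsets + half
    out = np.zeros(np.broadcast_shapes(a.shape[:-1], offsets.shape), dtype=float)
    a = np.broadcast_to(a, out.shape + (3,))
    s = np.broadcast_to(s, out.shape)

    small = a < _EPS_COMPONENT
    nsmall = small.sum(axis=-1)
    inside = (s > 0) & (s < np.broadcast_to(2 * half, out.shape))
    codes = small @ np.array([4, 2, 1])
    for code in np.unique(codes[inside]):
        rows = inside & (codes == code)
        axes = tuple(np.nonzero([not (code >> (2 - i)) & 1 for i in range(3)])[0])
        d = len(axes)
        aa = a[rows]
        ss = s[rows]
        if d == 3:
            denom = aa[:, 0] * aa[:, 1] * aa[:, 2]
            out[rows] = _corner_sum(aa, ss, 2, axes) / (2.0 * denom)
        elif d == 2:
            # cut is a rectangle: (length in the square) x 1
            denom = aa[:, axes[0]] * aa[:, axes[1]]
            out[rows] = _corner_sum(aa, ss, 1, axes) / denom
        elif d == 1:
            out[rows] = 1.0  # axis-aligned plane cuts a full unit face
        else:
            out[rows] = 0.0
    return np.maximum(out, 0.0)


def slab_fractions(normals: np.ndarray, boundary_offsets: np.ndarray) -> np.ndarray:
    """Per-layer volume fractions for stacks of parallel planes.

    Parameters
    ----------
    normals:
        Unit normals, shape ``(..., 3)``.
    boundary_offsets:
        Ascending offsets, shape ``(..., k+1)``; ``+/-inf`` allowed.

    Returns
    -------
    Fractions of shape ``(..., k)``; each in [0, 1], differences of the
    cumulative cut volume at consecutive offsets.
    """
    boundary_offsets = np.asarray(boundary_offsets, dtype=float)
    normals = np.asarray(normals, dtype=float)
    cum = cut_volume(normals[..., None, :], boundary_offsets)
    return np.maximum(np.diff(cum, axis=-1), 0.0)


def intersection_area(cut: PlaneCut) -> float:
    """Area of the convex polygon where ``cut``'s plane meets the unit voxel."""
    return float(cut_area(cut.normal, np.asarray(cut.offset)))


def cumulative_volume(cut: PlaneCut) -> float:
    """Volume of the unit voxel on the negative side of ``cut``'s plane."""
    return float(cut_volume(cut.normal, np.asarray(cut.offset)))


def layer_fractions(slab: LayerSlab) -> np.ndarray:
    """Volume fraction of the voxel between consecutive boundary planes."""
    return slab_fractions(slab.normal, slab.boundary_offsets)


def scale_to_voxel(normal: np.ndarray, offset_mm, edges_mm) -> tuple[np.ndarray, np.ndarray]:
    """Convert a world-space plane to unit-cube coordinates of an anisotropic voxel.

    A voxel with edge lengths ``edges_mm`` becomes the unit cube under the
    stretch ``x -> x / edges``; a plane with world unit normal ``normal`` at
    ``offset_mm`` from the voxel centre maps to normal ``n * edges`` (then
    renormalised) with the offset divided by ``||n * edges||``.
    """
    normal = np.asarray(normal, dtype=float)
    edges = np.asarray(edges_mm, dtype=float)
    scaled = normal * edges
    norm = np.linalg.norm(scaled, axis=-1, keepdims=True)
    return scaled / norm, np.asarray(offset_mm, dtype=float) / norm[..., 0]
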