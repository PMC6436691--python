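"""The spatial design matrix: layer volume distribution over an ROI.

Row v of the n x k matrix X gives the distribution of voxel v's volume
over the k layers; column j is the volume of layer j across voxels.  Rows
are computed from the per-voxel layer-boundary offsets either with the
voxel-orientation-specific cube-cut geometry (mode ``oriented``) or with
the orientation-averaged cumulative partial-volume kernel (mode
``average_kernel``), the classical approximation that treats every voxel
as an average over all cube orientations.

Boundary offsets live on the upsampled layering grid; a native voxel's
row is computed from the mean of its sub-voxels' boundary offsets
(re-expressed about the native voxel centre) through a single cube-cut
per voxel (``aggregate="offsets"``, the default), or alternatively as the
mean of the sub-voxel fraction rows (``aggregate="fractions"``).  Rows
are not renormalised: a voxel half outside the cortex contributes half a
voxel of volume, which is exactly what the GLM weighting needs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .geometry import cut_volume, slab_fractions
from .grid import Grid
from .surfaces import LayerBoundaries

__all__ = [
    "LayerDesign",
    "build_design",
    "average_orientation_kernel",
    "condition_report",
]


@dataclass(frozen=True)
class LayerDesign:
    """n x k layer volume distribution over an ROI."""

    X: np.ndarray  # (n, k) volume fractions
    voxel_index: np.ndarray  # (n, 3) native-grid indices
    voxel_xyz: np.ndarray  # (n, 3) world mm
    grid: Grid
    mode: str  # "oriented" | "average_kernel"
    meta: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return self.X.shape[0]

    @property
    def n_layers(self) -> int:
        return self.X.shape[1]

    def layer_labels(self) -> list:
        return [f"layer{j + 1}" for j in range(self.n_layers)]  # 1 = deepest

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.voxel_index, columns=["i", "j", "k"])
        df[["x_mm", "y_mm", "z_mm"]] = self.voxel_xyz
        df[self.layer_labels()] = self.X
        return df

    def save(self, path) -> None:
        """Write the design as CSV plus a JSON sidecar with grid metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "mode": self.mode,
            "n_layers": self.n_layers,
            "grid_shape": list(self.grid.shape),
            "voxel_size_mm": self.grid.voxel_size.tolist(),
            "origin_mm": self.grid.origin.tolist(),
            **{k: v for k, v in self.meta.items() if np.isscalar(v)},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


_KERNEL_OFFSETS = np.linspace(-np.sqrt(3) / 2, np.sqrt(3) / 2, 513)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=-1,
    )


@lru_cache(maxsize=1)
def _kernel_spline() -> CubicSpline:
    normals = _fibonacci_sphere(20000)
    table = cut_volume(normals[:, None, :], _KERNEL_OFFSETS[None, :]).mean(axis=0)
    # symmetrise: K(t) = 1 - K(-t) holds exactly for the true average
    table = 0.5 * (table + 1.0 - table[::-1])
    table[0] = 0.0
    table[-1] = 1.0
    return CubicSpline(_KERNEL_OFFSETS, table)


def average_orientation_kernel(offset) -> np.ndarray:
    """Orientation-averaged cumulative partial-volume kernel K(t).

    The mean over uniformly distributed cube orientations of the
    cumulative cut volume at signed plane offset ``t`` (voxel-edge units):
    the average projection profile of a cube onto a line.  Tabulated once
    by Fibonacci-sphere quadrature and interpolated with a cubic spline
    (a piecewise cubic polynomial); K(t) = 0 for t <= -sqrt(3)/2, 1 for
    t >= sqrt(3)/2 and K(t) = 1 - K(-t).
    """
    t = np.asarray(offset, dtype=float)
    out = np.empty(np.broadcast(t).shape)
    tt = np.broadcast_to(t, out.shape)
    lo = tt <= _KERNEL_OFFSETS[0]
    hi = tt >= _KERNEL_OFFSETS[-1]
    mid = ~(lo | hi)
    out[lo] = 0.0
    out[hi] = 1.0
    out[mid] = np.clip(_kernel_spline()(tt[mid]), 0.0, 1.0)
    if np.isscalar(offset) or np.ndim(offset) == 0:
        return float(out)
    return out


def _fraction_rows(normals: np.ndarray, offsets_vox: np.ndarray, mode: str):
    """Layer fractions for plane stacks at offsets in voxel-edge units."""
    if mode == "oriented":
        return slab_fractions(normals, offsets_vox)
    if mode == "average_kernel":
        cum = average_orientation_kernel(offsets_vox)
        return np.maximum(np.diff(cum, axis=-1), 0.0)
    raise ValueError(f"unknown design mode: {mode!r}")


def build_design(
    boundaries: LayerBoundaries,
    roi_mask: np.ndarray,
    native_grid: Grid = None,
    mode: str = "oriented",
    aggregate: str = "offsets",
) -> LayerDesign:
    """Assemble the layer volume distribution X over ``roi_mask``.

    ``boundaries`` live on the (possibly upsampled) layering grid;
    ``roi_mask`` and the returned design live on ``native_grid`` (defaults
    to the layering grid itself).  With ``aggregate="offsets"`` each
    native voxel gets the mean of its sub-voxels' boundary offsets,
    shifted to the native voxel centre along the local normal, and one
    cube-cut computes its row; with ``aggregate="fractions"`` the
    sub-voxel fraction rows themselves are averaged.  Sub-voxels outside
    the boundary support count as empty (outside the cortex).  Raises if
    a layer column is identically zero, which would make the design rank
    deficient.
    """
    fine = boundaries.grid
    if native_grid is None:
        native_grid = fine
    ratios = [fs // ns for fs, ns in zip(fine.shape, native_grid.shape)]
    if len(set(ratios)) != 1 or any(
        fs != r * ns for fs, ns, r in zip(fine.shape, native_grid.shape, ratios)
    ):
        raise ValueError(
            f"layering grid {fine.shape} is not an integer refinement of "
            f"native grid {native_grid.shape}"
        )
    factor = ratios[0]
    if roi_mask.shape != native_grid.shape:
        raise ValueError("roi_mask must live on the native grid")
    h_nat = float(np.mean(native_grid.voxel_size))
    if not np.allclose(native_grid.voxel_size, h_nat) or not np.allclose(
        fine.voxel_size, fine.voxel_size[0]
    ):
        raise NotImplementedError("anisotropic grids are not supported here")

    k = boundaries.n_layers
    voxel_index = np.argwhere(roi_mask)
    n = len(voxel_index)
    lut = boundaries.lookup()

    # fine-grid indices of each native voxel's factor^3 sub-voxels
    block = np.stack(
        np.meshgrid(*[np.arange(factor)] * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    sub_idx = voxel_index[:, None, :] * factor + block[None, :, :]  # (n, f^3, 3)
    rows = lut[sub_idx[..., 0], sub_idx[..., 1], sub_idx[..., 2]]  # (n, f^3)
    valid = rows >= 0
    safe = np.where(valid, rows, 0)

    sub_off = boundaries.offsets[safe]  # (n, f^3, k+1) mm
    sub_nrm = boundaries.normals[safe]  # (n, f^3, 3)
    if aggregate == "offsets":
        c_sub = fine.origin + fine.voxel_size * sub_idx
        c_nat = native_grid.origin + native_grid.voxel_size * voxel_index
        shift = np.einsum("nsd,nsd->ns", c_sub - c_nat[:, None, :], sub_nrm)
        off_c = sub_off + shift[..., None]
        counts = valid.sum(axis=1)
        w = np.where(valid, 1.0, 0.0)
        with np.errstate(invalid="ignore"):
            mean_off = np.einsum("ns,nsj->nj", w, off_c) / counts[:, None]
            mean_nrm = np.einsum("ns,nsd->nd", w, sub_nrm)
        nlen = np.linalg.norm(mean_nrm, axis=-1, keepdims=True)
        mean_nrm = np.divide(mean_nrm, nlen, out=np.zeros_like(mean_nrm), where=nlen > 0)
        mean_off = np.maximum.accumulate(mean_off, axis=1) / h_nat
        X = np.zeros((n, k))
        occ = counts > 0
        X[occ] = _fraction_rows(mean_nrm[occ], mean_off[occ], mode)
    elif aggregate == "fractions":
        h_fine = float(np.mean(fine.voxel_size))
        flat_nrm = sub_nrm.reshape(-1, 3)
        flat_off = sub_off.reshape(-1, k + 1) / h_fine
        frac = _fraction_rows(flat_nrm, flat_off, mode).reshape(n, -1, k)
        frac[~valid] = 0.0
        X = frac.mean(axis=1)
    else:
        raise ValueError("aggregate must be 'offsets' or 'fractions'")
    empty_rows = ~np.any(X > 0, axis=1)
    if empty_rows.any():
        warnings.warn(
            f"{int(empty_rows.sum())} ROI voxels have no cortical content "
            "(zero design rows)",
            RuntimeWarning,
        )
    colsum = X.sum(axis=0)
    if np.any(colsum <= 0):
        dead = [f"layer{j + 1}" for j in np.nonzero(colsum <= 0)[0]]
        raise ValueError(
            f"design is rank deficient: layer(s) {', '.join(dead)} have no "
            "volume in the ROI"
        )
    xyz = native_grid.origin + native_grid.voxel_size * voxel_index
    return LayerDesign(
        X=X,
        voxel_index=voxel_index,
        voxel_xyz=xyz,
        grid=native_grid,
        mode=mode,
        meta={"upsample_factor": factor, "n_layers": k},
    )


def condition_report(design: LayerDesign) -> dict:
    """Diagnostics of the design: rank, conditioning, column structure.

    Warns when the number of layers exceeds the typical number of voxels
    across the cortical thickness, the regime where the design becomes
    increasingly ill-conditioned and the GLM solution unstable.
    """
    X = design.X
    colsum = X.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        colcorr = np.corrcoef(X.T)
    rank = int(np.linalg.matrix_rank(X))
    sv = np.linalg.svd(X, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    report = {
        "n_voxels": design.n_voxels,
        "n_layers": design.n_layers,
        "column_sums": colsum,
        "column_correlations": colcorr,
        "rank": rank,
        "condition_number": cond,
        "full_rank": rank == design.n_layers,
    }
    vpt = design.meta.get("voxels_per_thickness")
    if vpt is not None:
        report["voxels_per_thickness"] = float(vpt)
        if design.n_layers > float(vpt):
            report["ill_conditioned_regime"] = True
            warnings.warn(
                f"{design.n_layers} layers exceed ~{float(vpt):.1f} voxels "
                "across the cortical thickness; expect an ill-conditioned "
                "design",
                RuntimeWarning,
            )
    return report
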