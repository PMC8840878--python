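"""Thin-plate-spline warps between mean shapes and deformation maps.

Group differences in shape are visualized by interpolating a thin-plate
spline (TPS) that carries a reference configuration (e.g. the low
vulnerability mean) exactly onto a target (the high vulnerability mean),
optionally exaggerated by a magnification factor.  Local expansion and
contraction are mapped by the log determinant of the warp's analytic
Jacobian on a grid: positive (red) cells expand, negative (blue) cells
contract, zero is shape-preserving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path as FilePath
from typing import Callable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.path import Path as MplPath

from .procrustes import AlignedDataset

__all__ = [
    "TPSWarp",
    "DeformationGrid",
    "mean_shape",
    "tps_warp",
    "jacobian_field",
    "render_deformation",
]

logger = logging.getLogger(__name__)

# deterministic SVG output: fixed hash salt, no timestamps
matplotlib.rcParams["svg.hashsalt"] = "gearmorph"


def _tps_u(r2: np.ndarray) -> np.ndarray:
    """TPS kernel U(r) = r^2 log r^2 with U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


@dataclass
class TPSWarp:
    """Interpolating thin-plate spline from ``reference`` landmarks onto
    ``reference + magnification * (target - reference)``.

    ``affine`` is a 3 x 2 matrix (row 0: translation, rows 1-2: linear
    part); ``weights`` is the k x 2 non-affine coefficient matrix.
    """

    reference: np.ndarray
    target: np.ndarray
    magnification: float
    affine: np.ndarray
    weights: np.ndarray

    @property
    def magnified_target(self) -> np.ndarray:
        return self.reference + self.magnification * (self.target - self.reference)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the warp at an m x 2 array of points."""
        pts = np.atleast_2d(np.asarray(points, float))
        d2 = ((pts[:, None, :] - self.reference[None, :, :]) ** 2).sum(-1)
        u = _tps_u(d2)
        return (
            self.affine[0]
            + pts @ self.affine[1:]
            + u @ self.weights
        )

    def jacobian(self, points: np.ndarray) -> np.ndarray:
        """Analytic Jacobians of the warp: m x 2 x 2 (d output / d input)."""
        pts = np.atleast_2d(np.asarray(points, float))
        diff = pts[:, None, :] - self.reference[None, :, :]  # m x k x 2
        r2 = (diff**2).sum(-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = 2.0 * (np.log(r2) + 1.0)
        g = np.where(r2 > 0, g, 0.0)  # grad U = 2 dx (log r^2 + 1); 0 at the knot
        # dU/dp: m x k x 2
        du = g[:, :, None] * diff
        jac = np.empty((pts.shape[0], 2, 2))
        # rows: output dim, cols: input dim
        jac[:, 0, :] = self.affine[1:, 0][None, :] + np.einsum(
            "mki,k->mi", du, self.weights[:, 0]
        )
        jac[:, 1, :] = self.affine[1:, 1][None, :] + np.einsum(
            "mki,k->mi", du, self.weights[:, 1]
        )
        return jac


@dataclass
class DeformationGrid:
    """log-Jacobian-determinant field of a warp over an r x c lattice."""

    grid_x: np.ndarray  # r x c
    grid_y: np.ndarray
    log_jacobian: np.ndarray  # r x c, NaN outside the mask or at fold-overs
    n_foldover: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x": self.grid_x.ravel(),
                "y": self.grid_y.ravel(),
                "log_jacobian": self.log_jacobian.ravel(),
            }
        )


def mean_shape(
    aligned: AlignedDataset, selector: Callable[[str], bool] | None = None
) -> np.ndarray:
    """Coordinate-wise mean of the aligned configurations whose id passes
    ``selector`` (all fish when None)."""
    if selector is None:
        mask = np.ones(aligned.n, bool)
    else:
        mask = np.array([bool(selector(i)) for i in aligned.ids])
    if not mask.any():
        raise ValueError("selector matched no specimens")
    return aligned.shape_coordinates[mask].mean(axis=0)


def tps_warp(
    reference: np.ndarray, target: np.ndarray, magnification: float = 1.0
) -> TPSWarp:
    """Solve the TPS interpolation mapping ``reference`` landmarks exactly
    onto the (magnified) ``target`` landmarks."""
    ref = np.asarray(reference, float)
    tgt = np.asarray(target, float)
    if ref.shape != tgt.shape or ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("reference and target must be matching k x 2 arrays")
    if magnification < 0:
        raise ValueError("magnification must be non-negative")
    k = ref.shape[0]
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
    off_diag = d2[~np.eye(k, dtype=bool)]
    if off_diag.size and off_diag.min() == 0:
        raise ValueError("coincident reference landmarks: TPS system is singular")
    kmat = _tps_u(d2)
    p = np.hstack([np.ones((k, 1)), ref])
    l = np.zeros((k + 3, k + 3))
    l[:k, :k] = kmat
    l[:k, k:] = p
    l[k:, :k] = p.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = ref + magnification * (tgt - ref)
    try:
        sol = np.linalg.solve(l, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular TPS system") from exc
    weights, affine = sol[:k], sol[k:]
    return TPSWarp(
        reference=ref,
        target=tgt,
        magnification=float(magnification),
        affine=affine,
        weights=weights,
    )


def jacobian_field(
    warp: TPSWarp,
    grid: tuple[int, int] = (100, 100),
    mask: np.ndarray | None = None,
    pad: float = 0.05,
) -> DeformationGrid:
    """log-Jacobian-determinant of the warp over a padded reference grid.

    Positive values mark local expansion, negative contraction.  Cells
    outside the optional ``mask`` polygon are NaN; fold-over cells
    (non-positive determinant) are NaN and counted with a warning.
    """
    rows, cols = grid
    lo = warp.reference.min(axis=0)
    hi = warp.reference.max(axis=0)
    span = hi - lo
    lo = lo - pad * span
    hi = hi + pad * span
    xs = np.linspace(lo[0], hi[0], cols)
    ys = np.linspace(lo[1], hi[1], rows)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    jac = warp.jacobian(pts)
    det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
    fold = det <= 0
    n_fold = int(fold.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        logdet = np.where(fold, np.nan, np.log(np.where(fold, 1.0, det)))
    if mask is not None:
        inside = MplPath(np.asarray(mask, float)).contains_points(pts)
        logdet = np.where(inside, logdet, np.nan)
        n_fold = int((fold & inside).sum())
    if n_fold:
        logger.warning("%d grid cells fold over (non-positive Jacobian)", n_fold)
    return DeformationGrid(
        grid_x=gx, grid_y=gy, log_jacobian=logdet.reshape(rows, cols), n_foldover=n_fold
    )


def render_deformation(
    warp: TPSWarp,
    path: str | FilePath,
    style: str = "heatmap",
    grid: tuple[int, int] = (100, 100),
    mask: np.ndarray | None = None,
    arrows: bool = False,
    title: str | None = None,
) -> FilePath:
    """Render a deformation grid or expansion/contraction heat map.

    ``heatmap`` draws the log-Jacobian field on a diverging scale (red =
    expansion, blue = contraction) with the warped landmarks overlaid;
    ``grid`` draws the classic warped lattice.  Output (SVG or PNG by
    extension) is deterministic given identical inputs.
    """
    if style not in ("heatmap", "grid"):
        raise ValueError("style must be 'heatmap' or 'grid'")
    out = FilePath(path)
    fig, ax = plt.subplots(figsize=(6, 4))
    if style == "heatmap":
        field = jacobian_field(warp, grid=grid, mask=mask)
        vmax = np.nanmax(np.abs(field.log_jacobian)) or 1.0
        mesh = ax.pcolormesh(
            field.grid_x,
            field.grid_y,
            field.log_jacobian,
            cmap="RdBu_r",
            vmin=-vmax,
            vmax=vmax,
            shading="auto",
        )
        fig.colorbar(mesh, ax=ax, label="log Jacobian determinant")
        warped = warp(warp.reference)
        ax.plot(warped[:, 0], warped[:, 1], "k.", ms=3)
        if arrows:
            disp = warped - warp.reference
            ax.quiver(
                warp.reference[:, 0],
                warp.reference[:, 1],
                disp[:, 0],
                disp[:, 1],
                angles="xy",
                scale_units="xy",
                scale=1,
                width=0.002,
                color="k",
            )
    else:
        rows, cols = grid if max(grid) <= 40 else (20, 20)
        lo = warp.reference.min(axis=0)
        hi = warp.reference.max(axis=0)
        span = hi - lo
        lo, hi = lo - 0.05 * span, hi + 0.05 * span
        xs = np.linspace(lo[0], hi[0], cols)
        ys = np.linspace(lo[1], hi[1], rows)
        dense = 10 * max(rows, cols)
        for y in ys:
            line = np.column_stack([np.linspace(lo[0], hi[0], dense), np.full(dense, y)])
            w = warp(line)
            ax.plot(w[:, 0], w[:, 1], "-", color="0.4", lw=0.6)
        for x in xs:
            line = np.column_stack([np.full(dense, x), np.linspace(lo[1], hi[1], dense)])
            w = warp(line)
            ax.plot(w[:, 0], w[:, 1], "-", color="0.4", lw=0.6)
        warped = warp(warp.reference)
        ax.plot(warped[:, 0], warped[:, 1], "k.", ms=4)
    ax.set_aspect("equal")
    ax.invert_yaxis()  # landmarks are digitized in image convention
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out, metadata={"Date": None} if out.suffix == ".svg" else None)
    plt.close(fig)
    return out
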