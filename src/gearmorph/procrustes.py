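"""Generalized Procrustes analysis (GPA) with sliding semi-landmarks.

Superimposition removes translation (centering), size (unit centroid
size) and orientation (least-squares rotation, reflections forbidden)
from each configuration, leaving shape variation only.  Semi-landmarks —
points along curves without point-to-point homology — are additionally
slid along the local chord direction between their neighbours to
minimize either thin-plate-spline bending energy or summed squared
Procrustes distance to the consensus, interleaved with re-alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .tps_io import LandmarkConfiguration, LandmarkDataset, SliderTable

__all__ = [
    "AlignedDataset",
    "centroid_size",
    "gpa_align",
    "slide_semilandmarks",
    "procrustes_distance",
    "bending_energy_matrix",
    "tangent_project",
]

logger = logging.getLogger(__name__)

SLIDE_METHODS = ("bending_energy", "procrustes_distance")


@dataclass
class AlignedDataset:
    """Procrustes shape coordinates for a cohort.

    ``shape_coordinates`` is n x k x 2; each configuration is centred at
    the origin with unit centroid size (to 1e-8) and ``consensus`` is
    their coordinate-wise mean.  ``centroid_sizes`` are the pre-scaling
    sizes in the input units.  ``slide_log`` records the sliding
    objective after each outer iteration (empty without sliders).
    """

    shape_coordinates: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    ids: list[str]
    slide_log: list[float] = field(default_factory=list)
    converged: bool = True
    excluded_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.shape_coordinates.shape[0]

    @property
    def k(self) -> int:
        return self.shape_coordinates.shape[1]

    def check(self, atol: float = 1e-8) -> None:
        """Assert the alignment invariants (centred, unit size, consensus)."""
        cent = self.shape_coordinates.mean(axis=1)
        if not np.allclose(cent, 0, atol=atol):
            raise AssertionError("configurations are not centred")
        cs = np.sqrt((self.shape_coordinates**2).sum(axis=(1, 2)))
        if not np.allclose(cs, 1, atol=atol):
            raise AssertionError("configurations do not have unit centroid size")
        if not np.allclose(self.consensus, self.shape_coordinates.mean(axis=0), atol=atol):
            raise AssertionError("consensus is not the mean of aligned configurations")


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances from the
    centroid.  Returns 0 (with a warning) for fully coincident points."""
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centred = pts - pts.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs == 0.0:
        logger.warning("degenerate configuration: all landmarks coincident")
    return cs


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (2x2, det=+1) minimizing ||x @ R - target||_F."""
    u, _, vt = np.linalg.svd(x.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def _center_scale(pts: np.ndarray) -> tuple[np.ndarray, float]:
    centred = pts - pts.mean(axis=0)
    cs = np.sqrt((centred**2).sum())
    return centred / cs, float(cs)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations.

    ``b`` is optimally translated, scaled and rotated (no reflection)
    onto the unit-size centred ``a``; the distance is the remaining
    root-summed-squared coordinate difference.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"configuration shapes differ: {a.shape} vs {b.shape}")
    ac, _ = _center_scale(a)
    bc, _ = _center_scale(b)
    r = _optimal_rotation(bc, ac)
    br = bc @ r
    beta = float((br * ac).sum())  # optimal scale of b onto a
    return float(np.sqrt(max(((beta * br - ac) ** 2).sum(), 0.0)))


# ---------------------------------------------------------------------------
# Thin-plate-spline bending energy (used for semi-landmark sliding)
# ---------------------------------------------------------------------------

def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2, with U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """k x k bending-energy matrix of the TPS anchored on ``reference``.

    The quadratic form ``y^T Be y`` (applied per coordinate axis) is the
    bending energy of the spline deforming the reference into targets y.
    """
    ref = np.asarray(reference, float)
    k = ref.shape[0]
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
    kmat = _tps_kernel(d2)
    p = np.hstack([np.ones((k, 1)), ref])
    l = np.zeros((k + 3, k + 3))
    l[:k, :k] = kmat
    l[:k, k:] = p
    l[k:, :k] = p.T
    try:
        linv = np.linalg.inv(l)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular bending-energy system (coincident reference landmarks?)"
        ) from exc
    return linv[:k, :k]


def _slider_arrays(sliders: SliderTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rows = sliders.rows
    return rows[:, 0] - 1, rows[:, 1] - 1, rows[:, 2] - 1


def _tangents(points: np.ndarray, before: np.ndarray, after: np.ndarray) -> np.ndarray:
    """Unit chord directions between each slider's neighbours (m x 2)."""
    chord = points[after] - points[before]
    norm = np.linalg.norm(chord, axis=1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("coincident slider neighbours: tangent undefined")
    return chord / norm


def _slide_one(
    y: np.ndarray,
    consensus: np.ndarray,
    slide_idx: np.ndarray,
    before: np.ndarray,
    after: np.ndarray,
    tangents: np.ndarray,
    method: str,
    be: np.ndarray | None,
) -> np.ndarray:
    """Slide one specimen's semi-landmarks along their tangents.

    Steps are clamped to half the distance to the nearer neighbour so
    points cannot cross along the curve (keeps the tangent linearization
    valid and the outer iteration stable).
    """
    out = y.copy()
    resid = y - consensus
    if method == "procrustes_distance":
        # foot of the perpendicular from the consensus point onto the tangent
        t = -(resid[slide_idx] * tangents).sum(axis=1)
    else:
        be_ss = be[np.ix_(slide_idx, slide_idx)]
        a = np.zeros((len(slide_idx), len(slide_idx)))
        rhs = np.zeros(len(slide_idx))
        for d in range(2):
            ud = tangents[:, d]
            a += np.outer(ud, ud) * be_ss
            rhs -= ud * (be[slide_idx, :] @ resid[:, d])
        try:
            t = np.linalg.solve(a, rhs)
        except np.linalg.LinAlgError:
            t, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    gap = np.minimum(
        np.linalg.norm(y[slide_idx] - y[before], axis=1),
        np.linalg.norm(y[after] - y[slide_idx], axis=1),
    )
    t = np.clip(t, -0.5 * gap, 0.5 * gap)
    out[slide_idx] = y[slide_idx] + t[:, None] * tangents
    return out


def slide_semilandmarks(
    aligned: AlignedDataset,
    sliders: SliderTable,
    method: str = "bending_energy",
) -> AlignedDataset:
    """One sliding pass: move each specimen's semi-landmarks along their
    neighbour chords to minimize the chosen objective vs the consensus.

    Fixed landmarks are untouched (asserted).  The returned dataset has a
    refreshed consensus but is *not* re-normalized; :func:`gpa_align`
    interleaves normalization and re-alignment.
    """
    be = bending_energy_matrix(aligned.consensus) if method == "bending_energy" else None
    return _slide_with_be(aligned, sliders, method, be)


def _slide_with_be(
    aligned: AlignedDataset,
    sliders: SliderTable,
    method: str,
    be: np.ndarray | None,
) -> AlignedDataset:
    if method not in SLIDE_METHODS:
        raise ValueError(f"method must be one of {SLIDE_METHODS}, got {method!r}")
    before, slide_idx, after = _slider_arrays(sliders)
    coords = aligned.shape_coordinates
    if slide_idx.max() >= coords.shape[1]:
        raise ValueError("slider index outside the landmark range")
    new = np.empty_like(coords)
    for i in range(coords.shape[0]):
        try:
            tangents = _tangents(coords[i], before, after)
        except ValueError as exc:
            raise ValueError(f"specimen {aligned.ids[i]!r}: {exc}") from exc
        new[i] = _slide_one(
            coords[i], aligned.consensus, slide_idx, before, after, tangents, method, be
        )
    fixed_mask = np.ones(coords.shape[1], bool)
    fixed_mask[slide_idx] = False
    assert np.array_equal(new[:, fixed_mask], coords[:, fixed_mask]), (
        "fixed landmarks moved during sliding"
    )
    return AlignedDataset(
        shape_coordinates=new,
        centroid_sizes=aligned.centroid_sizes,
        consensus=new.mean(axis=0),
        ids=list(aligned.ids),
        slide_log=list(aligned.slide_log),
        converged=aligned.converged,
        excluded_ids=list(aligned.excluded_ids),
    )


def _slide_objective(
    coords: np.ndarray, consensus: np.ndarray, method: str, be: np.ndarray | None
) -> float:
    resid = coords - consensus
    if method == "procrustes_distance" or be is None:
        return float((resid**2).sum())
    return float(sum(np.einsum("nk,kl,nl->", resid[..., d], be, resid[..., d]) for d in range(2)))


def _converge_rotations(
    coords: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Iterate rotate-onto-consensus / update-consensus to a fixed point."""
    consensus, _ = _center_scale(coords.mean(axis=0))
    converged = False
    for _ in range(max_iter):
        for i in range(coords.shape[0]):
            coords[i] = coords[i] @ _optimal_rotation(coords[i], consensus)
        new_consensus, _ = _center_scale(coords.mean(axis=0))
        if np.sqrt(((new_consensus - consensus) ** 2).sum()) < tol:
            consensus = new_consensus
            converged = True
            break
        consensus = new_consensus
    return coords, consensus, converged


def gpa_align(
    dataset: LandmarkDataset,
    sliders: SliderTable | None = None,
    slide_method: str = "bending_energy",
    tol: float = 1e-10,
    max_iter: int = 100,
    max_slide_iter: int = 5,
) -> AlignedDataset:
    """Generalized least-squares Procrustes superimposition.

    Each configuration is centred, scaled to unit centroid size and
    rotated onto the running consensus; with ``sliders``, semi-landmark
    sliding is interleaved with re-alignment for up to
    ``max_slide_iter`` outer iterations.  Degenerate (zero-size)
    configurations are excluded with a warning.
    """
    if slide_method not in SLIDE_METHODS:
        raise ValueError(f"slide_method must be one of {SLIDE_METHODS}")
    if sliders is not None:
        sliders.validate_against(dataset)

    raw = dataset.coords()
    ids = dataset.ids
    sizes = np.array([centroid_size(c) for c in raw])
    keep = sizes > 0
    excluded = [i for i, ok in zip(ids, keep) if not ok]
    if excluded:
        logger.warning("excluding degenerate configurations: %s", excluded)
    raw = raw[keep]
    sizes_kept = sizes[keep]
    ids_kept = [i for i, ok in zip(ids, keep) if ok]
    if raw.shape[0] == 0:
        raise ValueError("no non-degenerate configurations to align")

    coords = (raw - raw.mean(axis=1, keepdims=True)) / sizes_kept[:, None, None]
    # seed orientation: rotate everything onto the first specimen
    for i in range(1, coords.shape[0]):
        coords[i] = coords[i] @ _optimal_rotation(coords[i], coords[0])

    coords, consensus, converged = _converge_rotations(coords, tol, max_iter)
    slide_log: list[float] = []

    if sliders is not None and sliders.m > 0:
        # the bending-energy metric is anchored on the initial consensus and
        # held fixed across outer iterations so the objective is comparable
        be = bending_energy_matrix(consensus) if slide_method == "bending_energy" else None
        prev_obj = _slide_objective(coords, consensus, slide_method, be)
        for _ in range(max_slide_iter):
            prev_coords, prev_consensus = coords.copy(), consensus.copy()
            interim = AlignedDataset(
                shape_coordinates=coords,
                centroid_sizes=sizes_kept,
                consensus=consensus,
                ids=ids_kept,
            )
            slid = _slide_with_be(interim, sliders, slide_method, be)
            coords = slid.shape_coordinates
            # sliding perturbs centring/size: re-normalize, then re-align
            cent = coords - coords.mean(axis=1, keepdims=True)
            cs = np.sqrt((cent**2).sum(axis=(1, 2)))
            coords = cent / cs[:, None, None]
            coords, consensus, conv2 = _converge_rotations(coords, tol, max_iter)
            converged = converged and conv2
            obj = _slide_objective(coords, consensus, slide_method, be)
            if obj > prev_obj:  # guarded acceptance: never let the objective rise
                coords, consensus = prev_coords, prev_consensus
                break
            slide_log.append(obj)
            if prev_obj - obj < tol * max(1.0, abs(prev_obj)):
                break
            prev_obj = obj

    if not converged:
        logger.warning("GPA did not converge within %d iterations", max_iter)
    return AlignedDataset(
        shape_coordinates=coords,
        centroid_sizes=sizes_kept,
        consensus=coords.mean(axis=0),
        ids=ids_kept,
        slide_log=slide_log,
        converged=converged,
        excluded_ids=excluded,
    )


def tangent_project(aligned: AlignedDataset) -> np.ndarray:
    """Orthogonal projection of aligned shapes into the tangent space at
    the consensus; returns an n x 2k matrix of tangent coordinates."""
    n, k, _ = aligned.shape_coordinates.shape
    flat = aligned.shape_coordinates.reshape(n, 2 * k)
    c = aligned.consensus.reshape(1, 2 * k)
    c = c / np.linalg.norm(c)
    resid = flat - flat @ c.T @ c  # remove the component along the consensus
    return resid
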