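"""Subset-based 2-D digital image correlation (DIC).

Tracks a regular grid of small pixel windows (subsets) from a reference
speckle image into a deformed image.  For every grid point the integer
displacement is the argmax of the zero-normalized cross-correlation
(ZNCC) over a search window — ZNCC is invariant to affine intensity
changes of the deformed frame, which makes the match robust to lighting
drift.  An optional paraboloid fit to the 3x3 ZNCC neighborhood of the
peak refines the displacement to subpixel precision.  Strains are
computed from the displacement field by local least-squares plane fits;
the default measure is Green-Lagrange, appropriate for the large
deformations gels undergo before failure.

Coordinates are pixel-centered with the origin at the top-left corner:
x increases rightward (columns), y downward (rows); u is positive
rightward and v positive downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["DICConfig", "DisplacementField", "StrainField",
           "match_subsets", "compute_strain", "track_sequence"]

_FLAT_EPS = 1e-12

# Pseudoinverse for the quadratic fit f = a + b x + c y + d x^2 + e y^2 + f xy
# on the 3x3 stencil x, y in {-1, 0, 1} (row-major y, x order).
_YY, _XX = np.mgrid[-1:2, -1:2]
_QUAD_PINV = np.linalg.pinv(np.column_stack([
    np.ones(9), _XX.ravel(), _YY.ravel(),
    _XX.ravel() ** 2, _YY.ravel() ** 2, (_XX * _YY).ravel(),
]))


@dataclass(frozen=True)
class DICConfig:
    """Subset-matching and strain parameters (all lengths in pixels).

    ``strain_window`` is the odd side length, in grid nodes, of the
    neighborhood used for the local plane fit.
    """

    subset_size: int = 21
    grid_spacing: int = 5
    search_radius: int = 15
    subpixel: str = "paraboloid"        # none | paraboloid
    strain_window: int = 5
    min_correlation: float = 0.5
    strain_measure: str = "green_lagrange"  # green_lagrange | small

    def __post_init__(self) -> None:
        if self.subset_size < 9 or self.subset_size % 2 == 0:
            raise ValueError("subset_size must be odd and >= 9")
        if self.grid_spacing < 1 or self.search_radius < 1:
            raise ValueError("grid_spacing and search_radius must be >= 1")
        if self.subpixel not in ("none", "paraboloid"):
            raise ValueError("subpixel must be 'none' or 'paraboloid'")
        if self.strain_window < 3 or self.strain_window % 2 == 0:
            raise ValueError("strain_window must be odd and >= 3")
        if self.strain_measure not in ("green_lagrange", "small"):
            raise ValueError("unknown strain measure")


@dataclass
class DisplacementField:
    """DIC grid output: displacements, peak correlation and validity."""

    grid_x: np.ndarray  # 1-D x coordinates of grid columns (px)
    grid_y: np.ndarray  # 1-D y coordinates of grid rows (px)
    u: np.ndarray       # (ny, nx) x-displacement (px)
    v: np.ndarray       # (ny, nx) y-displacement (px)
    correlation: np.ndarray
    valid_mask: np.ndarray
    metadata: dict = field(default_factory=dict)


@dataclass
class StrainField:
    """Strain components on the same grid as the displacement field."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    Exx: np.ndarray
    Eyy: np.ndarray
    Exy: np.ndarray
    valid_mask: np.ndarray


def _grid_coords(shape: tuple, config: DICConfig) -> tuple:
    half = config.subset_size // 2
    h, w = shape
    gx = np.arange(half, w - half, config.grid_spacing)
    gy = np.arange(half, h - half, config.grid_spacing)
    return gx, gy


def _zncc_map(s_centered: np.ndarray, norm_s: float, region: np.ndarray,
              m: int) -> np.ndarray:
    """ZNCC of one zero-mean subset against every window of a region."""
    windows = sliding_window_view(region, (m, m))
    cross = np.einsum("ijkl,kl->ij", windows, s_centered)
    wsum = windows.sum(axis=(2, 3))
    wsq = np.einsum("ijkl,ijkl->ij", windows, windows)
    var = wsq - wsum * wsum / (m * m)
    norm_w = np.sqrt(np.maximum(var, 0.0))
    zncc = np.full(cross.shape, -2.0)
    ok = norm_w > _FLAT_EPS
    zncc[ok] = cross[ok] / (norm_s * norm_w[ok])
    return zncc


def _pick_peak(zncc: np.ndarray, du0: int, dv0: int) -> tuple:
    """Peak with deterministic tie-breaking.

    Exact ties are broken by smallest displacement magnitude, then by
    row-major order over the correlation map.
    """
    cmax = float(zncc.max())
    ties = np.argwhere(zncc == cmax)
    if len(ties) == 1:
        iv, iu = ties[0]
    else:
        best = None
        for k, (tv, tu) in enumerate(ties):
            mag = (du0 + tu) ** 2 + (dv0 + tv) ** 2
            if best is None or (mag, k) < best[:2]:
                best = (mag, k, tv, tu)
        iv, iu = best[2], best[3]
    return int(iv), int(iu), cmax


def _paraboloid_offset(patch: np.ndarray) -> tuple:
    """Subpixel peak offset from a quadratic fit to a 3x3 ZNCC patch."""
    coef = _QUAD_PINV @ patch.ravel()
    _, b, c, d, e, f = coef
    hess = np.array([[2.0 * d, f], [f, 2.0 * e]])
    det = hess[0, 0] * hess[1, 1] - hess[0, 1] * hess[1, 0]
    if hess[0, 0] >= 0 or det <= 0:  # not a strict maximum
        return 0.0, 0.0
    ox, oy = np.linalg.solve(hess, [-b, -c])
    return float(np.clip(ox, -1.0, 1.0)), float(np.clip(oy, -1.0, 1.0))


def match_subsets(ref_image, def_image, config: DICConfig | None = None, *,
                  seed_u=None, seed_v=None) -> DisplacementField:
    """Match speckle subsets between a reference and a deformed image.

    For each grid point the integer displacement maximizing the ZNCC over
    the search window is found (optionally seeded by a prior estimate per
    grid point), then refined by the paraboloid subpixel stage.  Subsets
    that are intensity-flat, extend beyond either image, or correlate
    below ``min_correlation`` are masked invalid rather than raising.
    """
    if config is None:
        config = DICConfig()
    ref = np.asarray(ref_image, dtype=float)
    dfm = np.asarray(def_image, dtype=float)
    if ref.shape != dfm.shape:
        raise ValueError("reference and deformed images must share a shape")
    half, R = config.subset_size // 2, config.search_radius
    m = config.subset_size
    h, w = ref.shape
    gx, gy = _grid_coords(ref.shape, config)
    ny, nx = gy.size, gx.size
    u = np.zeros((ny, nx))
    v = np.zeros((ny, nx))
    corr = np.full((ny, nx), -2.0)
    valid = np.zeros((ny, nx), dtype=bool)

    for iy, y in enumerate(gy):
        for ix, x in enumerate(gx):
            subset = ref[y - half:y + half + 1, x - half:x + half + 1]
            s = subset - subset.mean()
            norm_s = float(np.sqrt((s * s).sum()))
            if norm_s <= _FLAT_EPS:
                continue  # flat subset: no texture to match
            su = int(round(seed_u[iy, ix])) if seed_u is not None else 0
            sv = int(round(seed_v[iy, ix])) if seed_v is not None else 0
            du_lo = max(su - R, half - x)
            du_hi = min(su + R, w - 1 - half - x)
            dv_lo = max(sv - R, half - y)
            dv_hi = min(sv + R, h - 1 - half - y)
            if du_lo > du_hi or dv_lo > dv_hi:
                continue  # search window entirely outside the image
            region = dfm[y + dv_lo - half:y + dv_hi + half + 1,
                         x + du_lo - half:x + du_hi + half + 1]
            zncc = _zncc_map(s, norm_s, region, m)
            iv, iu, cmax = _pick_peak(zncc, du_lo, dv_lo)
            if cmax <= -2.0 + 1e-9:
                continue
            du, dv = du_lo + iu, dv_lo + iv
            ox = oy = 0.0
            # A numerically perfect peak is already the exact answer; the
            # paraboloid stage could only perturb it.
            if (config.subpixel == "paraboloid" and cmax < 1.0 - 1e-9
                    and 0 < iu < zncc.shape[1] - 1
                    and 0 < iv < zncc.shape[0] - 1):
                ox, oy = _paraboloid_offset(zncc[iv - 1:iv + 2, iu - 1:iu + 2])
            u[iy, ix] = du + ox
            v[iy, ix] = dv + oy
            corr[iy, ix] = cmax
            valid[iy, ix] = cmax >= config.min_correlation
    return DisplacementField(grid_x=gx, grid_y=gy, u=u, v=v,
                             correlation=corr, valid_mask=valid,
                             metadata={"subset_size": m, "search_radius": R})


def compute_strain(fld: DisplacementField, config: DICConfig | None = None
                   ) -> StrainField:
    """Strain field from local least-squares plane fits of (u, v).

    Displacement gradients at each grid node come from fitting planes to
    the valid displacements in a ``strain_window`` x ``strain_window``
    node neighborhood.  Nodes with fewer than 3 valid neighbors (or a
    degenerate fit) are masked invalid.  The Green-Lagrange tensor is

        Exx = du/dx + ((du/dx)^2 + (dv/dx)^2) / 2,

    and symmetrically for Eyy and Exy; ``strain_measure='small'`` drops
    the quadratic terms.
    """
    if config is None:
        config = DICConfig()
    if fld.valid_mask.sum() < 9:
        raise ValueError("need at least a 3x3 block of valid grid points")
    ny, nx = fld.u.shape
    rad = config.strain_window // 2
    Exx = np.full((ny, nx), np.nan)
    Eyy = np.full((ny, nx), np.nan)
    Exy = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)
    gl = config.strain_measure == "green_lagrange"

    for iy in range(ny):
        for ix in range(nx):
            if not fld.valid_mask[iy, ix]:
                continue
            ys = slice(max(iy - rad, 0), min(iy + rad + 1, ny))
            xs = slice(max(ix - rad, 0), min(ix + rad + 1, nx))
            mask = fld.valid_mask[ys, xs]
            if mask.sum() < 3:
                continue
            X, Y = np.meshgrid(fld.grid_x[xs], fld.grid_y[ys])
            A = np.column_stack([
                np.ones(mask.sum()),
                (X[mask] - fld.grid_x[ix]),
                (Y[mask] - fld.grid_y[iy]),
            ])
            if np.linalg.matrix_rank(A) < 3:
                continue
            cu, *_ = np.linalg.lstsq(A, fld.u[ys, xs][mask], rcond=None)
            cv, *_ = np.linalg.lstsq(A, fld.v[ys, xs][mask], rcond=None)
            ux, uy = cu[1], cu[2]
            vx, vy = cv[1], cv[2]
            if gl:
                Exx[iy, ix] = ux + 0.5 * (ux * ux + vx * vx)
                Eyy[iy, ix] = vy + 0.5 * (uy * uy + vy * vy)
                Exy[iy, ix] = 0.5 * (uy + vx + ux * uy + vx * vy)
            else:
                Exx[iy, ix] = ux
                Eyy[iy, ix] = vy
                Exy[iy, ix] = 0.5 * (uy + vx)
            valid[iy, ix] = True
    return StrainField(grid_x=fld.grid_x, grid_y=fld.grid_y,
                       Exx=Exx, Eyy=Eyy, Exy=Exy, valid_mask=valid)


def track_sequence(stack, config: DICConfig | None = None) -> list:
    """Track a frame sequence against its first (reference) frame.

    Returns one ``(DisplacementField, StrainField)`` pair per frame, in
    order (the reference matched against itself gives the zero field).
    Large cumulative motion is handled by seeding each frame's search at
    the previous frame's solution.
    """
    if config is None:
        config = DICConfig()
    frames = [np.asarray(f, dtype=float) for f in stack]
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all frames must share the reference frame's shape")
    ref = frames[0]
    out = []
    seed_u = seed_v = None
    for fr in frames:
        fld = match_subsets(ref, fr, config, seed_u=seed_u, seed_v=seed_v)
        strain = compute_strain(fld, config)
        out.append((fld, strain))
        seed_u = np.where(fld.valid_mask, fld.u, 0.0)
        seed_v = np.where(fld.valid_mask, fld.v, 0.0)
    return out
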