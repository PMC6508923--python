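"""Nonrigid B-spline free-form-deformation registration.

A sparse control grid carries per-point displacement vectors; the dense
per-voxel field is their cubic tensor-product B-spline expansion,
``T(x) = x + sum_z B(||x - z||) dz``.  The dissimilarity is the (mean)
sum of absolute differences between the target and the trilinearly warped
source.  Optimization is deterministic discrete ICM over per-control-point
candidate displacements with a first-order smoothness penalty over
grid neighbors, run coarse-to-fine on an image pyramid.

Displacements are stored in full-resolution voxel units throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage

from .volio import GrayVolume, LabelMap

__all__ = [
    "ControlGrid",
    "DeformationField",
    "RegistrationConfig",
    "bspline_expand",
    "sad_energy",
    "register",
    "warp_volume",
    "warp_labels",
    "atlas_gate",
]


def bspline_basis(u: float) -> tuple[float, float, float, float]:
    """The four cubic B-spline blending weights at fractional offset u."""
    v = 1.0 - u
    return (
        v**3 / 6.0,
        (3 * u**3 - 6 * u**2 + 4) / 6.0,
        (-3 * u**3 + 3 * u**2 + 3 * u + 1) / 6.0,
        u**3 / 6.0,
    )


@dataclass
class ControlGrid:
    """Control-point lattice covering the volume plus one boundary ring.

    ``displacements`` has shape ``(nx+3, ny+3, nz+3, 3)`` where ``n*`` is the
    cell count per axis; array index ``i`` holds grid index ``i - 1`` so the
    ring at grid index -1 sits at array index 0.
    """

    spacing_vox: tuple[int, int, int]
    shape: tuple[int, int, int]
    displacements: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.spacing_vox = tuple(int(s) for s in self.spacing_vox)
        if any(s < 1 for s in self.spacing_vox):
            raise ValueError("control spacing must be >= 1 voxel")
        ncells = tuple(
            max(1, int(np.ceil((n - 1) / s))) for n, s in zip(self.shape, self.spacing_vox)
        )
        self.ncells = ncells
        want = tuple(c + 3 for c in ncells) + (3,)
        if self.displacements is None:
            self.displacements = np.zeros(want)
        elif tuple(self.displacements.shape) != want:
            raise ValueError(
                f"displacement array shape {self.displacements.shape} != expected {want}"
            )


@dataclass
class DeformationField:
    """Dense per-voxel displacement (voxels) plus its generating grid."""

    disp: np.ndarray  # shape (nx, ny, nz, 3)
    grid: ControlGrid | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.disp.shape[:3]


@dataclass
class RegistrationConfig:
    pyramid: tuple[int, ...] = (4, 2, 1)
    grid_spacing_vox: int = 8  # per pyramid level => 32/16/8 full-res voxels
    steps_per_level: tuple[tuple[int, ...], ...] = ((4, 2), (2, 1), (1,))
    sweeps_per_level: int = 3
    smooth_lambda: float = 0.1
    max_disp_vox: float = 16.0
    max_bad_steps: int = 3
    prealign: bool = True


def _axis_tables(n: int, spacing: int, ncells: int):
    """Per-voxel cell index and 4 basis weights along one axis."""
    x = np.arange(n, dtype=np.float64)
    t = x / spacing
    i = np.minimum(np.floor(t).astype(np.int64), ncells - 1)
    u = t - i
    w = np.empty((n, 4))
    v = 1.0 - u
    w[:, 0] = v**3 / 6.0
    w[:, 1] = (3 * u**3 - 6 * u**2 + 4) / 6.0
    w[:, 2] = (-3 * u**3 + 3 * u**2 + 3 * u + 1) / 6.0
    w[:, 3] = u**3 / 6.0
    return i, w


def bspline_expand(grid: ControlGrid, shape: tuple[int, int, int] | None = None) -> DeformationField:
    """Dense field from the control grid by tensor-product cubic B-splines."""
    if shape is None:
        shape = grid.shape
    if tuple(shape) != tuple(grid.shape):
        raise ValueError(f"grid covers {grid.shape}, not {shape}")
    nx, ny, nz = shape
    ix, wx = _axis_tables(nx, grid.spacing_vox[0], grid.ncells[0])
    iy, wy = _axis_tables(ny, grid.spacing_vox[1], grid.ncells[1])
    iz, wz = _axis_tables(nz, grid.spacing_vox[2], grid.ncells[2])
    D = grid.displacements
    out = np.zeros(shape + (3,))
    for a in range(4):
        cx = D[ix + a]  # (nx, ncy+3, ncz+3, 3); grid index ix-1+a -> array ix+a
        for b in range(4):
            cxy = cx[:, iy + b]  # (nx, ny, ncz+3, 3)
            wab = wx[:, a][:, None, None, None] * wy[:, b][None, :, None, None]
            for c in range(4):
                w = wab * wz[:, c][None, None, :, None]
                out += w * cxy[:, :, iz + c]
    return DeformationField(disp=out, grid=grid)


def _coords(shape, disp):
    idx = np.indices(shape, dtype=np.float64)
    return idx + np.moveaxis(disp, -1, 0)


def warp_volume(source: np.ndarray, fld: DeformationField, cval: float = 0.0) -> np.ndarray:
    """Trilinear warp: out(x) = source(x + disp(x)); outside samples -> cval."""
    return ndimage.map_coordinates(
        np.asarray(source, dtype=np.float64), _coords(fld.shape, fld.disp), order=1, cval=cval
    )


def warp_labels(m: LabelMap, fld: DeformationField) -> LabelMap:
    """Nearest-neighbor label transport along the field."""
    out = ndimage.map_coordinates(m.labels, _coords(fld.shape, fld.disp), order=0, cval=0)
    return LabelMap(out.astype(m.labels.dtype), label_set=m.label_set, spacing=m.spacing)


def sad_energy(target: GrayVolume | np.ndarray, source: GrayVolume | np.ndarray, fld: DeformationField) -> float:
    """Mean absolute intensity difference between target and warped source."""
    tgt = target.data if isinstance(target, GrayVolume) else np.asarray(target)
    src = source.data if isinstance(source, GrayVolume) else np.asarray(source)
    if tgt.shape != src.shape or tgt.shape != fld.shape:
        raise ValueError("target, source and field must share one grid")
    warped = warp_volume(src, fld, cval=float(src.min()))
    return float(np.mean(np.abs(np.asarray(tgt, dtype=np.float64) - warped)))


# ---------------------------------------------------------------------------
# ICM optimizer (numba)


@njit(cache=True)
def _basis4(u):
    v = 1.0 - u
    return np.array(
        [
            v * v * v / 6.0,
            (3 * u * u * u - 6 * u * u + 4) / 6.0,
            (-3 * u * u * u + 3 * u * u + 3 * u + 1) / 6.0,
            u * u * u / 6.0,
        ]
    )


@njit(cache=True, inline="always")
def _point_weight(x, spacing, gi, ncells):
    """Basis weight of control grid index ``gi`` at voxel coordinate ``x``."""
    t = x / spacing
    i = int(t)
    if i > ncells - 1:
        i = ncells - 1
    a = gi - i + 1
    if a < 0 or a > 3:
        return 0.0
    u = t - i
    v = 1.0 - u
    if a == 0:
        return v * v * v / 6.0
    if a == 1:
        return (3 * u * u * u - 6 * u * u + 4) / 6.0
    if a == 2:
        return (-3 * u * u * u + 3 * u * u + 3 * u + 1) / 6.0
    return u * u * u / 6.0


@njit(cache=True, inline="always")
def _sample(src, x, y, z, cval):
    nx, ny, nz = src.shape
    if x < 0 or y < 0 or z < 0 or x > nx - 1 or y > ny - 1 or z > nz - 1:
        return cval
    x0 = int(x)
    y0 = int(y)
    z0 = int(z)
    if x0 > nx - 2:
        x0 = nx - 2
    if y0 > ny - 2:
        y0 = ny - 2
    if z0 > nz - 2:
        z0 = nz - 2
    fx = x - x0
    fy = y - y0
    fz = z - z0
    c000 = src[x0, y0, z0]
    c100 = src[x0 + 1, y0, z0]
    c010 = src[x0, y0 + 1, z0]
    c110 = src[x0 + 1, y0 + 1, z0]
    c001 = src[x0, y0, z0 + 1]
    c101 = src[x0 + 1, y0, z0 + 1]
    c011 = src[x0, y0 + 1, z0 + 1]
    c111 = src[x0 + 1, y0 + 1, z0 + 1]
    c00 = c000 + fx * (c100 - c000)
    c10 = c010 + fx * (c110 - c010)
    c01 = c001 + fx * (c101 - c001)
    c11 = c011 + fx * (c111 - c011)
    c0 = c00 + fy * (c10 - c00)
    c1 = c01 + fy * (c11 - c01)
    return c0 + fz * (c1 - c0)


@njit(cache=True)
def _local_energy(tgt, src, disp, sx, sy, sz, ncx, ncy, ncz, gi, gj, gk, dx, dy, dz, cval):
    """B-spline-weighted SAD over the central two support cells of one control
    point, evaluated with its displacement perturbed by (dx, dy, dz)."""
    nx, ny, nz = tgt.shape
    x0 = max(0, (gi - 1) * sx)
    x1 = min(nx, (gi + 1) * sx)
    y0 = max(0, (gj - 1) * sy)
    y1 = min(ny, (gj + 1) * sy)
    z0 = max(0, (gk - 1) * sz)
    z1 = min(nz, (gk + 1) * sz)
    e = 0.0
    wsum = 0.0
    for x in range(x0, x1):
        wxv = _point_weight(float(x), float(sx), gi, ncx)
        for y in range(y0, y1):
            wyv = _point_weight(float(y), float(sy), gj, ncy)
            wxy = wxv * wyv
            for z in range(z0, z1):
                w = wxy * _point_weight(float(z), float(sz), gk, ncz)
                if w <= 0.0:
                    continue
                sxp = x + disp[x, y, z, 0] + w * dx
                syp = y + disp[x, y, z, 1] + w * dy
                szp = z + disp[x, y, z, 2] + w * dz
                e += w * abs(tgt[x, y, z] - _sample(src, sxp, syp, szp, cval))
                wsum += w
    if wsum <= 0.0:
        return 0.0
    return e / wsum


@njit(cache=True)
def _apply_delta(disp, sx, sy, sz, ncx, ncy, ncz, gi, gj, gk, dx, dy, dz):
    """Add the B-spline-weighted delta over the full 4-cell support."""
    nx, ny, nz, _ = disp.shape
    x0 = max(0, (gi - 2) * sx)
    x1 = min(nx, (gi + 2) * sx)
    y0 = max(0, (gj - 2) * sy)
    y1 = min(ny, (gj + 2) * sy)
    z0 = max(0, (gk - 2) * sz)
    z1 = min(nz, (gk + 2) * sz)
    for x in range(x0, x1):
        wxv = _point_weight(float(x), float(sx), gi, ncx)
        if wxv == 0.0:
            continue
        for y in range(y0, y1):
            wxy = wxv * _point_weight(float(y), float(sy), gj, ncy)
            if wxy == 0.0:
                continue
            for z in range(z0, z1):
                w = wxy * _point_weight(float(z), float(sz), gk, ncz)
                if w == 0.0:
                    continue
                disp[x, y, z, 0] += w * dx
                disp[x, y, z, 1] += w * dy
                disp[x, y, z, 2] += w * dz


@njit(cache=True)
def _smooth_term(ctrl, ai, aj, ak, d0, d1, d2):
    """First-order smoothness: sum of Euclidean distances to 6-neighbor
    control displacements (candidate value (d0,d1,d2) at array idx (ai,aj,ak))."""
    na, nb, nc, _ = ctrl.shape
    s = 0.0
    for axis in range(3):
        for sgn in (-1, 1):
            bi, bj, bk = ai, aj, ak
            if axis == 0:
                bi += sgn
            elif axis == 1:
                bj += sgn
            else:
                bk += sgn
            if bi < 0 or bj < 0 or bk < 0 or bi >= na or bj >= nb or bk >= nc:
                continue
            e0 = d0 - ctrl[bi, bj, bk, 0]
            e1 = d1 - ctrl[bi, bj, bk, 1]
            e2 = d2 - ctrl[bi, bj, bk, 2]
            s += (e0 * e0 + e1 * e1 + e2 * e2) ** 0.5
    return s


@njit(cache=True)
def _icm_sweep(tgt, src, disp, ctrl, sx, sy, sz, steps, lam, max_disp, cval):
    """One raster sweep of ICM over control points; returns accepted moves."""
    na, nb, nc, _ = ctrl.shape
    ncx, ncy, ncz = na - 3, nb - 3, nc - 3
    moved = 0
    for ai in range(na):
        gi = ai - 1
        for aj in range(nb):
            gj = aj - 1
            for ak in range(nc):
                gk = ak - 1
                d0 = ctrl[ai, aj, ak, 0]
                d1 = ctrl[ai, aj, ak, 1]
                d2 = ctrl[ai, aj, ak, 2]
                e_cur = _local_energy(
                    tgt, src, disp, sx, sy, sz, ncx, ncy, ncz, gi, gj, gk, 0.0, 0.0, 0.0, cval
                ) + lam * _smooth_term(ctrl, ai, aj, ak, d0, d1, d2)
                best_e = e_cur
                best_axis = -1
                best_delta = 0.0
                for axis in range(3):
                    for si in range(len(steps)):
                        for sgn in (-1.0, 1.0):
                            delta = sgn * steps[si]
                            nd0, nd1, nd2 = d0, d1, d2
                            if axis == 0:
                                nd0 += delta
                            elif axis == 1:
                                nd1 += delta
                            else:
                                nd2 += delta
                            if abs(nd0) > max_disp or abs(nd1) > max_disp or abs(nd2) > max_disp:
                                continue
                            dx = nd0 - d0
                            dy = nd1 - d1
                            dz = nd2 - d2
                            e = _local_energy(
                                tgt, src, disp, sx, sy, sz, ncx, ncy, ncz,
                                gi, gj, gk, dx, dy, dz, cval,
                            ) + lam * _smooth_term(ctrl, ai, aj, ak, nd0, nd1, nd2)
                            if e < best_e - 1e-12:
                                best_e = e
                                best_axis = axis
                                best_delta = delta
                if best_axis >= 0:
                    dx = best_delta if best_axis == 0 else 0.0
                    dy = best_delta if best_axis == 1 else 0.0
                    dz = best_delta if best_axis == 2 else 0.0
                    _apply_delta(disp, sx, sy, sz, ncx, ncy, ncz, gi, gj, gk, dx, dy, dz)
                    ctrl[ai, aj, ak, 0] += dx
                    ctrl[ai, aj, ak, 1] += dy
                    ctrl[ai, aj, ak, 2] += dz
                    moved += 1
    return moved


def _downsample(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return np.asarray(data, dtype=np.float64)
    return ndimage.zoom(np.asarray(data, dtype=np.float64), 1.0 / factor, order=1)


def _center_of_mass_shift(tgt: np.ndarray, src: np.ndarray) -> np.ndarray:
    """Translation aligning the source intensity centroid onto the target's."""

    def com(a):
        a = a - a.min()
        s = a.sum()
        if s <= 0:
            return np.zeros(3)
        return np.array(ndimage.center_of_mass(a))

    return com(src) - com(tgt)


def register(
    target: GrayVolume | np.ndarray,
    source: GrayVolume | np.ndarray,
    cfg: RegistrationConfig | None = None,
) -> DeformationField:
    """Estimate the deformation warping ``source`` onto ``target``.

    Returns a dense field whose SAD energy never exceeds the identity
    field's; deterministic given inputs and cfg.
    """
    cfg = cfg or RegistrationConfig()
    tgt_full = np.asarray(target.data if isinstance(target, GrayVolume) else target, dtype=np.float64)
    src_full = np.asarray(source.data if isinstance(source, GrayVolume) else source, dtype=np.float64)
    if tgt_full.shape != src_full.shape:
        raise ValueError("target and source must be on the same grid")
    shift = (
        _center_of_mass_shift(tgt_full, src_full) if cfg.prealign else np.zeros(3)
    )
    prev_disp = None  # full-res voxel units, at previous level's grid shape
    prev_factor = None
    grid = None
    for factor, steps in zip(cfg.pyramid, cfg.steps_per_level):
        tgt = _downsample(tgt_full, factor)
        src = _downsample(src_full, factor)
        grid = ControlGrid(
            spacing_vox=(cfg.grid_spacing_vox,) * 3, shape=tgt.shape
        )
        # initialize control displacements (level-voxel units) from the
        # coarser level's dense field, or from the pre-alignment shift
        sx, sy, sz = grid.spacing_vox
        na, nb, nc, _ = grid.displacements.shape
        if prev_disp is None:
            grid.displacements[..., :] = shift / factor
        else:
            scale = prev_factor / factor
            for ai in range(na):
                for aj in range(nb):
                    for ak in range(nc):
                        # control point position in previous-level voxels
                        px = (ai - 1) * sx / scale
                        py = (aj - 1) * sy / scale
                        pz = (ak - 1) * sz / scale
                        vals = [
                            ndimage.map_coordinates(
                                prev_disp[..., c], [[px], [py], [pz]], order=1, mode="nearest"
                            )[0]
                            for c in range(3)
                        ]
                        grid.displacements[ai, aj, ak] = np.array(vals) * scale
        disp = bspline_expand(grid).disp
        step_arr = np.array(steps, dtype=np.float64)
        for _ in range(cfg.sweeps_per_level):
            moved = _icm_sweep(
                tgt,
                src,
                disp,
                grid.displacements,
                sx,
                sy,
                sz,
                step_arr,
                cfg.smooth_lambda,
                cfg.max_disp_vox / factor,
                float(src.min()),
            )
            if moved == 0:
                break
        prev_disp = disp
        prev_factor = factor
    final = bspline_expand(grid)
    # guarantee: never worse than the identity field
    ident = DeformationField(disp=np.zeros(tgt_full.shape + (3,)), grid=None)
    if sad_energy(tgt_full, src_full, final) > sad_energy(tgt_full, src_full, ident):
        return ident
    return final


# ---------------------------------------------------------------------------
# Atlas selection


def atlas_gate(
    target: GrayVolume | np.ndarray,
    candidate: GrayVolume | np.ndarray,
    mask: np.ndarray | None = None,
    threshold: float = 0.5,
) -> tuple[float, bool]:
    """Mean slice-wise 2-D Pearson correlation and the >= 0.5 selection gate.

    A slice with zero variance on either side contributes r = 0.  With a
    mask, correlations are computed over masked in-plane voxels only.
    """
    tgt = np.asarray(target.data if isinstance(target, GrayVolume) else target, dtype=np.float64)
    cnd = np.asarray(
        candidate.data if isinstance(candidate, GrayVolume) else candidate, dtype=np.float64
    )
    if tgt.shape[2] != cnd.shape[2]:
        raise ValueError("slice counts differ; crop to a common slab first")
    rs = []
    for k in range(tgt.shape[2]):
        a, b = tgt[:, :, k], cnd[:, :, k]
        if mask is not None:
            mk = np.asarray(mask)[:, :, k] > 0
            a, b = a[mk], b[mk]
        a, b = a.ravel(), b.ravel()
        if a.size < 2 or a.std() == 0 or b.std() == 0:
            rs.append(0.0)
            continue
        rs.append(float(np.corrcoef(a, b)[0, 1]))
    mean_r = float(np.mean(rs)) if rs else 0.0
    return mean_r, mean_r >= threshold
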