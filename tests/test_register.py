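import numpy as np
import pytest

import sys

import thighseg.register  # noqa: F401

reg = sys.modules["thighseg.register"]
from thighseg.volio import GrayVolume, LabelMap


def brute_bspline_expand(grid):
    """Direct tensor-product evaluation of the FFD at every voxel."""

    def basis(u):
        v = 1.0 - u
        return [
            v**3 / 6,
            (3 * u**3 - 6 * u**2 + 4) / 6,
            (-3 * u**3 + 3 * u**2 + 3 * u + 1) / 6,
            u**3 / 6,
        ]

    nx, ny, nz = grid.shape
    out = np.zeros((nx, ny, nz, 3))
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                acc = np.zeros(3)
                tx = x / grid.spacing_vox[0]
                ty = y / grid.spacing_vox[1]
                tz = z / grid.spacing_vox[2]
                ix = min(int(tx), grid.ncells[0] - 1)
                iy = min(int(ty), grid.ncells[1] - 1)
                iz = min(int(tz), grid.ncells[2] - 1)
                bx = basis(tx - ix)
                by = basis(ty - iy)
                bz = basis(tz - iz)
                for a in range(4):
                    for b in range(4):
                        for c in range(4):
                            w = bx[a] * by[b] * bz[c]
                            acc += w * grid.displacements[ix + a, iy + b, iz + c]
                out[x, y, z] = acc
    return out


def test_expand_identity_for_zero_grid():
    grid = reg.ControlGrid(spacing_vox=(4, 4, 4), shape=(9, 9, 9))
    fld = reg.bspline_expand(grid)
    np.testing.assert_array_equal(fld.disp, 0.0)


def test_expand_matches_brute_force_tensor_product():
    rng = np.random.default_rng(19)
    grid = reg.ControlGrid(spacing_vox=(4, 4, 4), shape=(9, 9, 9))
    grid.displacements[:] = rng.normal(size=grid.displacements.shape)
    fld = reg.bspline_expand(grid)
    np.testing.assert_allclose(fld.disp, brute_bspline_expand(grid), atol=1e-9)


def test_expand_single_point_support_and_peak():
    grid = reg.ControlGrid(spacing_vox=(4, 4, 4), shape=(17, 17, 17))
    # grid index (2,2,2) -> array index (3,3,3); center voxel x=8 has u=0
    grid.displacements[3, 3, 3] = (1.0, 0.0, 0.0)
    fld = reg.bspline_expand(grid)
    # peak at the control point equals the central weight (2/3)^3
    assert fld.disp[8, 8, 8, 0] == pytest.approx((2.0 / 3.0) ** 3)
    # support limited to +-2 cells (8 voxels) per axis
    assert np.all(fld.disp[:1] == 0) and np.all(fld.disp[16:] == 0)
    nz = np.argwhere(np.abs(fld.disp[..., 0]) > 1e-12)
    assert nz[:, 0].min() >= 1 and nz[:, 0].max() <= 15


def test_expand_is_linear():
    rng = np.random.default_rng(23)
    grid = reg.ControlGrid(spacing_vox=(4, 4, 4), shape=(9, 9, 9))
    grid.displacements[:] = rng.normal(size=grid.displacements.shape)
    doubled = reg.ControlGrid(
        spacing_vox=(4, 4, 4), shape=(9, 9, 9), displacements=2.0 * grid.displacements
    )
    np.testing.assert_allclose(
        reg.bspline_expand(doubled).disp, 2.0 * reg.bspline_expand(grid).disp, atol=1e-12
    )


def test_sad_energy_properties():
    rng = np.random.default_rng(31)
    a = rng.normal(size=(12, 12, 8))
    ident = reg.DeformationField(np.zeros((12, 12, 8, 3)))
    assert reg.sad_energy(a, a, ident) == 0.0
    b = np.roll(a, 2, axis=0)
    shift = np.zeros((12, 12, 8, 3))
    shift[..., 0] = 2.0
    assert reg.sad_energy(a, b, reg.DeformationField(shift)) <= reg.sad_energy(a, b, ident)
    assert reg.sad_energy(a, b, ident) >= 0.0


def test_warp_labels_identity_shift_and_label_set():
    lab = np.zeros((8, 8, 8), dtype=np.int16)
    lab[4, 4, 4] = 3
    m = LabelMap(lab, label_set=(0, 3), spacing=(1, 1, 1))
    ident = reg.DeformationField(np.zeros((8, 8, 8, 3)))
    np.testing.assert_array_equal(reg.warp_labels(m, ident).labels, lab)
    shift = np.zeros((8, 8, 8, 3))
    shift[..., 1] = 1.0  # out(x) = src(x + 1) moves the label to y=3
    out = reg.warp_labels(m, reg.DeformationField(shift))
    assert out.labels[4, 3, 4] == 3
    assert set(np.unique(out.labels)) <= set(m.label_set)


def test_register_identity_recovery():
    rng = np.random.default_rng(2)
    a = rng.normal(size=(32, 32, 16)) * 10
    fld = reg.register(a, a, reg.RegistrationConfig(pyramid=(2, 1), steps_per_level=((2, 1), (1,))))
    assert np.abs(fld.disp).max() <= 0.5


def test_register_never_worse_than_identity():
    rng = np.random.default_rng(3)
    a = rng.normal(size=(24, 24, 12))
    b = rng.normal(size=(24, 24, 12))
    cfg = reg.RegistrationConfig(pyramid=(2, 1), steps_per_level=((2, 1), (1,)), sweeps_per_level=1)
    fld = reg.register(a, b, cfg)
    ident = reg.DeformationField(np.zeros((24, 24, 12, 3)))
    assert reg.sad_energy(a, b, fld) <= reg.sad_energy(a, b, ident) + 1e-12


def test_atlas_gate_extremes_and_noise():
    rng = np.random.default_rng(3)
    a = rng.normal(size=(16, 16, 50))
    r, sel = reg.atlas_gate(a, a)
    assert r == pytest.approx(1.0)
    assert sel
    r_neg, sel_neg = reg.atlas_gate(a, -a)
    assert r_neg == pytest.approx(-1.0)
    assert not sel_neg
    b = rng.normal(size=(16, 16, 50))
    r_ind, sel_ind = reg.atlas_gate(a, b)
    assert abs(r_ind) < 0.1
    assert not sel_ind


def test_atlas_gate_constant_slice_counts_as_zero():
    a = np.zeros((8, 8, 2))
    a[:, :, 1] = np.arange(64).reshape(8, 8)
    b = a.copy()
    r, _ = reg.atlas_gate(a, b)
    assert r == pytest.approx(0.5)  # slice 0 constant -> r=0; slice 1 -> r=1
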