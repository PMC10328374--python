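"""Synthetic cortical cross-sections: elliptical annuli with spherical pores."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..geometry import Labels, VoxelGrid

__all__ = ["GeometryTruth", "gen_cross_section"]


@dataclass
class GeometryTruth:
    """Closed-form geometry of an elliptical annulus cross-section.

    Semi-axes in mm, ``outer = (a, b)`` along (x, y).  All derived areas and
    moments are computed analytically on construction.
    """

    outer_semi_axes: tuple[float, float]
    inner_semi_axes: tuple[float, float]
    pore_fraction: float = 0.0
    voxel_size: float = 0.006
    bone_intensity: float = 1.0
    noise_sd: float = 0.0
    true_areas: dict = field(init=False)
    true_moments: dict = field(init=False)
    true_c: float = field(init=False)

    def __post_init__(self) -> None:
        a, b = self.outer_semi_axes
        ai, bi = self.inner_semi_axes
        if not (0 < ai < a and 0 < bi < b):
            raise ValueError("inner semi-axes must be strictly inside the outer")
        if not 0 <= self.pore_fraction < 0.5:
            raise ValueError("pore_fraction must be in [0, 0.5)")
        tt = np.pi * a * b
        ma = np.pi * ai * bi
        self.true_areas = {"Tt_Ar": tt, "Ma_Ar": ma, "Ct_Ar": tt - ma}
        ixx = np.pi / 4 * (a * b**3 - ai * bi**3)   # bending about x
        iyy = np.pi / 4 * (a**3 * b - ai**3 * bi)   # bending about y
        self.true_moments = {"I_min": min(ixx, iyy), "I_max": max(ixx, iyy)}
        # extreme fiber distance from the I_min bending axis
        self.true_c = b if ixx <= iyy else a


def gen_cross_section(
    truth: GeometryTruth,
    seed: int,
    n_slices: int = 8,
    pore_radius_range: tuple[float, float] = (0.010, 0.024),
):
    """Voxelize an elliptical annulus with non-overlapping spherical pores.

    Returns ``(grid, labels, truth)`` where ``labels`` uses the compartment
    codes of :class:`osteoquant.geometry.Labels`.  Pores are placed fully
    inside the cortex (a one-voxel bone shell is kept around each) until the
    pore voxel fraction pore/(pore+bone) reaches ``truth.pore_fraction``.
    """
    a, b = truth.outer_semi_axes
    ai, bi = truth.inner_semi_axes
    dx = truth.voxel_size
    if min(a - ai, b - bi) < 3 * dx:
        raise ValueError("voxel size too coarse to resolve the cortex (< 3 voxels)")

    rng = np.random.default_rng(seed)
    margin = 3 * dx
    nx = int(np.ceil(2 * (a + margin) / dx))
    ny = int(np.ceil(2 * (b + margin) / dx))
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dx
    xx, yy = np.meshgrid(x, y)
    inside_outer = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    inside_inner = (xx / ai) ** 2 + (yy / bi) ** 2 <= 1.0

    plane = np.full((ny, nx), Labels.BACKGROUND, dtype=np.uint8)
    plane[inside_outer & ~inside_inner] = Labels.BONE
    plane[inside_inner] = Labels.MARROW
    labels = np.repeat(plane[None, :, :], n_slices, axis=0)

    if truth.pore_fraction > 0:
        _carve_pores(labels, truth.pore_fraction, pore_radius_range, dx, rng)

    values = np.where(labels == Labels.BONE, truth.bone_intensity, 0.0)
    if truth.noise_sd > 0:
        values = values + rng.normal(0.0, truth.noise_sd, size=values.shape)
    grid = VoxelGrid(values=values, voxel_size=dx)
    return grid, labels, truth


def _carve_pores(labels, target_fraction, radius_range, dx, rng, max_attempts=200_000):
    """Convert bone voxels to pores until pore/(pore+bone) >= target."""
    nz, ny, nx = labels.shape
    bone_total = int((labels == Labels.BONE).sum())
    pore_count = 0
    attempts = 0
    r_lo, r_hi = radius_range
    bone_idx = np.argwhere(labels == Labels.BONE)
    while pore_count / bone_total < target_fraction and attempts < max_attempts:
        attempts += 1
        r_mm = rng.uniform(r_lo, r_hi)
        r = r_mm / dx
        center = bone_idx[rng.integers(len(bone_idx))]
        cz, cy, cx = center
        ir = int(np.ceil(r)) + 1
        # spheres may be clipped by the z faces of the stack (a thin slab cuts
        # through pores) but must stay enclosed in-plane
        sl = (
            slice(max(0, cz - ir), min(nz, cz + ir + 1)),
            slice(max(0, cy - ir), min(ny, cy + ir + 1)),
            slice(max(0, cx - ir), min(nx, cx + ir + 1)),
        )
        sub = labels[sl]
        gz, gy, gx = np.ogrid[sl]
        d2 = (gz - cz) ** 2 + (gy - cy) ** 2 + (gx - cx) ** 2
        shell = d2 <= (r + 1.0) ** 2  # pore plus a one-voxel guard band
        core = d2 <= r * r
        # the guard band must be bone or pore so pores never touch marrow,
        # background, or an existing pore (cores stay disjoint)
        if np.any((sub[shell] != Labels.BONE)):
            continue
        sub[core] = Labels.PORE
        pore_count += int(core.sum())
    # pore fraction is over the cortical compartment: pore/(pore+bone);
    # bone_total fixed above equals pore + bone after carving
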