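"""Synthetic microstructure phantoms and cohort simulation.

Every downstream stage — segmentation, VOI handling, direct-3D morphometry,
plate separation, longitudinal statistics — is testable without scan data
via phantoms whose ground truth is known by construction:

* parallel slabs (exact thickness/separation/BV-TV oracle),
* square lattices of z-aligned rods (analytic thickness and BV/TV),
* thresholded Gaussian random fields (exact BV/TV control, trabecular-like
  texture),
* a cortical plate with drilled through-pores over a trabecular compartment
  (plate thickness and porosity oracle),
* a paired-limb longitudinal cohort whose group means/SDs follow a stated
  design (growth trend plus group effects), with a shared per-animal random
  effect producing the declared inter-limb correlation.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io_volumes import BinaryVolume, GrayVolume


@dataclass
class PhantomTruth:
    """Ground-truth parameters recorded by a generator; ``None`` = not defined."""

    bvtv_true: float | None = None        # fraction in [0, 1]
    thickness_true: float | None = None   # μm
    separation_true: float | None = None  # μm
    plate_thickness_true: float | None = None  # μm
    plate_porosity_true: float | None = None   # %
    description: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bvtv_true is not None and not 0 <= self.bvtv_true <= 1:
            raise ValueError("bvtv_true must be a fraction in [0, 1]")
        for name in ("thickness_true", "separation_true",
                     "plate_thickness_true"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0 when set")
        if (self.plate_porosity_true is not None
                and not 0 <= self.plate_porosity_true <= 100):
            raise ValueError("plate_porosity_true must be in [0, 100]%")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _vox(length_um: float, spacing: float) -> int:
    return int(round(length_um / spacing))


def make_slab_phantom(thickness: float, gap: float, spacing: float,
                      dims: tuple[int, int, int] = (128, 64, 64),
                      ) -> tuple[BinaryVolume, PhantomTruth]:
    """Parallel bone slabs normal to z with period ``thickness + gap`` (μm).

    The z-extent is trimmed to whole periods so that voxel counting
    reproduces the analytic BV/TV exactly when thickness and gap are voxel
    multiples.
    """
    if thickness < 2 * spacing or gap < 2 * spacing:
        raise ValueError(
            "unresolvable structure: slab and gap must each span >= 2 voxels"
        )
    t_vox, g_vox = _vox(thickness, spacing), _vox(gap, spacing)
    period = t_vox + g_vox
    nz, ny, nx = dims
    n_periods = nz // period
    if n_periods < 3:
        raise ValueError(
            f"dims must accommodate >= 3 periods ({period} voxels each)"
        )
    nz = n_periods * period
    z = np.arange(nz)
    bone_z = (z % period) < t_vox
    vox = np.zeros((nz, ny, nx), dtype=bool)
    vox[bone_z] = True
    truth = PhantomTruth(
        bvtv_true=thickness / (thickness + gap),
        thickness_true=thickness,
        separation_true=gap,
        description={"generator": "slab", "thickness_um": thickness,
                     "gap_um": gap, "spacing_um": spacing,
                     "dims": [nz, ny, nx]},
    )
    return BinaryVolume(vox, spacing), truth


def make_rod_phantom(radius: float, pitch: float, spacing: float,
                     dims: tuple[int, int, int] = (64, 128, 128),
                     ) -> tuple[BinaryVolume, PhantomTruth]:
    """Square lattice of z-aligned cylindrical rods.

    Truth: thickness = 2·radius; BV/TV = π·radius²/pitch² (pre-discretization).
    The in-plane extent is trimmed to whole lattice cells with rod axes at
    cell centers, so no rod is truncated by the volume border.
    """
    if radius < 2 * spacing:
        raise ValueError("unresolvable structure: radius must span >= 2 voxels")
    if pitch < 2 * radius:
        raise ValueError("overlapping rods: pitch must be >= 2·radius")
    p_vox = _vox(pitch, spacing)
    r_vox = radius / spacing
    nz, ny, nx = dims
    cy, cx = ny // p_vox, nx // p_vox
    if cy < 1 or cx < 1:
        raise ValueError("dims too small for one lattice cell")
    ny, nx = cy * p_vox, cx * p_vox
    y = np.arange(ny)
    x = np.arange(nx)
    # rod axes on voxel centers (cleanest discrete circles), one per cell
    offy = (y % p_vox) - p_vox // 2
    offx = (x % p_vox) - p_vox // 2
    d2 = offy[:, None] ** 2 + offx[None, :] ** 2
    disk = d2 <= r_vox**2 + 1e-9
    vox = np.broadcast_to(disk, (nz, ny, nx)).copy()
    truth = PhantomTruth(
        bvtv_true=np.pi * radius**2 / pitch**2,
        thickness_true=2 * radius,
        description={"generator": "rod", "radius_um": radius,
                     "pitch_um": pitch, "spacing_um": spacing,
                     "dims": [nz, ny, nx]},
    )
    return BinaryVolume(vox, spacing), truth


def make_grf_phantom(target_bvtv: float, corr_length: float, spacing: float,
                     dims: tuple[int, int, int] = (128, 128, 128),
                     seed: int = 0) -> tuple[BinaryVolume, PhantomTruth]:
    """Trabecular-like texture: smoothed Gaussian noise thresholded at the
    empirical quantile that yields exactly the target bone-voxel count.

    The Gaussian smoothing kernel has σ = corr_length (μm).  Thresholding by
    the empirical quantile (a deterministic top-k selection with stable tie
    break) makes BV/TV exact to one voxel regardless of kernel normalization.
    """
    if not 0 < target_bvtv < 1:
        raise ValueError("target_bvtv must lie strictly in (0, 1)")
    if min(dims) < 4:
        raise ValueError("degenerate dims")
    rng = np.random.default_rng(seed)
    f = ndi.gaussian_filter(rng.standard_normal(dims),
                            sigma=corr_length / spacing)
    n = f.size
    k = int(round(target_bvtv * n))
    order = np.argsort(f.ravel(), kind="stable")
    vox = np.zeros(n, dtype=bool)
    vox[order[n - k:]] = True
    vox = vox.reshape(dims)
    truth = PhantomTruth(
        bvtv_true=k / n,
        description={"generator": "grf", "target_bvtv": target_bvtv,
                     "corr_length_um": corr_length, "spacing_um": spacing,
                     "dims": list(dims), "seed": seed},
    )
    return BinaryVolume(vox, spacing), truth


def make_subchondral_phantom(
    plate_thickness: float,
    pore_fraction: float,
    spacing: float,
    dims: tuple[int, int, int] = (96, 96, 96),
    seed: int = 0,
    marrow_gap: float | None = None,
    trabecular_spec: dict | None = None,
    noise_sigma: float = 10.0,
    blur_sigma: float = 0.6,
) -> tuple[GrayVolume, BinaryVolume, PhantomTruth]:
    """A cortical plate over a trabecular compartment, with drilled pores.

    Geometry along z (articular side at low z): 2 empty slices, then a solid
    plate of the given thickness with cylindrical through-pores drilled to
    remove the requested fraction of the plate-region volume (pore columns
    rounded to the nearest whole column, kept away from the lateral border
    so the pores are enclosed by plate), then a marrow gap (default 174 μm),
    then z-aligned rods until the bottom.  The grayscale companion renders
    bone at 200 and marrow at 50 with Gaussian blur and noise for
    segmentation tests.
    """
    if not 0 <= pore_fraction < 50:
        raise ValueError("pore_fraction must lie in [0, 50)%")
    pt_vox = _vox(plate_thickness, spacing)
    if pt_vox < 2:
        raise ValueError("unresolvable plate: must span >= 2 voxels")
    nz, ny, nx = dims
    gap_um = 174.0 if marrow_gap is None else marrow_gap
    gap_vox = _vox(gap_um, spacing)
    z0 = 2
    z_trab = z0 + pt_vox + gap_vox
    if z_trab >= nz - 4:
        raise ValueError("dims too shallow for plate + gap + trabeculae")
    vox = np.zeros((nz, ny, nx), dtype=bool)
    vox[z0:z0 + pt_vox] = True

    # drill through-pores: whole columns, exact count from the fraction.
    # Pores are radius-2 disks (13 columns, ~43 μm canals at 8.7 μm) on a
    # jittered grid — localized blobs can never encircle plate, so the
    # footprint stays connected — plus one partial blob for the remainder.
    rng = np.random.default_rng(seed)
    n_cols = ny * nx
    k_target = int(round(pore_fraction / 100.0 * n_cols))
    pore2d = np.zeros((ny, nx), dtype=bool)
    margin = 4
    r_pore = 2
    disk_off = np.mgrid[-r_pore:r_pore + 1, -r_pore:r_pore + 1]
    d2 = (disk_off**2).sum(axis=0)
    disk_dy, disk_dx = disk_off[0][d2 <= r_pore**2], disk_off[1][d2 <= r_pore**2]
    order = np.argsort(d2[d2 <= r_pore**2], kind="stable")
    disk_dy, disk_dx = disk_dy[order], disk_dx[order]
    disk_area = disk_dy.size  # 13
    cell = 2 * r_pore + 3
    gy = np.arange(margin + r_pore, ny - margin - r_pore, cell)
    gx = np.arange(margin + r_pore, nx - margin - r_pore, cell)
    cells = [(y, x) for y in gy for x in gx]
    n_full, rem = divmod(k_target, disk_area)
    if n_full + (rem > 0) > len(cells):
        raise ValueError("pore_fraction too high for the in-plane extent")
    rng.shuffle(cells)
    for i in range(n_full + (rem > 0)):
        cy, cx = cells[i]
        cy += rng.integers(-1, 2)
        cx += rng.integers(-1, 2)
        take = disk_area if i < n_full else rem
        pore2d[cy + disk_dy[:take], cx + disk_dx[:take]] = True
    footprint = ~pore2d
    lab, ncomp = ndi.label(footprint,
                           structure=np.ones((3, 3), dtype=int))
    if ncomp != 1:
        raise ValueError("pore_fraction leaves the plate disconnected in-plane")
    vox[z0:z0 + pt_vox, pore2d] = False

    # trabecular compartment: z-aligned rods on a square lattice
    spec = {"radius_um": 5 * spacing, "pitch_um": 16 * spacing}
    if trabecular_spec:
        spec.update(trabecular_spec)
    p_vox = _vox(spec["pitch_um"], spacing)
    r_vox = spec["radius_um"] / spacing
    offy = (np.arange(ny) % p_vox) - (p_vox - 1) / 2.0
    offx = (np.arange(nx) % p_vox) - (p_vox - 1) / 2.0
    disk = offy[:, None] ** 2 + offx[None, :] ** 2 <= r_vox**2 + 1e-9
    vox[z_trab:] = disk

    n_plate_region = pt_vox * n_cols
    n_pores = int(pore2d.sum()) * pt_vox
    truth = PhantomTruth(
        plate_thickness_true=plate_thickness,
        plate_porosity_true=100.0 * n_pores / n_plate_region,
        description={"generator": "subchondral",
                     "plate_thickness_um": plate_thickness,
                     "pore_fraction_pct": pore_fraction,
                     "marrow_gap_um": gap_um, "spacing_um": spacing,
                     "dims": list(dims), "seed": seed,
                     "trabecular_spec": spec,
                     "plate_z": [z0, z0 + pt_vox]},
    )
    gray = np.where(vox, 200.0, 50.0)
    if blur_sigma > 0:
        gray = ndi.gaussian_filter(gray, blur_sigma)
    if noise_sigma > 0:
        gray = gray + rng.normal(0.0, noise_sigma, size=gray.shape)
    gray = np.clip(np.round(gray), 0, 255).astype(np.uint8)
    return (GrayVolume(gray, spacing), BinaryVolume(vox, spacing), truth)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortDesign:
    """Design of a paired-limb longitudinal cohort.

    ``effects`` has one row per (parameter, compartment, week, limb) with
    columns ``mean`` and ``sd``; ``limb`` is ``"MIA"`` or ``"control"``.
    ``correlation`` is the within-animal correlation shared by both limbs
    and all timepoints (a compound-symmetric animal random effect).
    """

    effects: pd.DataFrame
    n_animals: int = 12
    correlation: float = 0.7
    seed: int = 0

    REQUIRED = ("parameter", "compartment", "week", "limb", "mean", "sd")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.effects.columns]
        if missing:
            raise ValueError(f"design table missing columns {missing}")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must lie in [0, 1)")
        if (self.effects["sd"] < 0).any():
            raise ValueError("SDs must be >= 0")
        if (self.effects["mean"] <= 0).any():
            raise ValueError("means must be positive for length/volume data")

    @property
    def timepoints(self) -> list:
        return sorted(self.effects["week"].unique().tolist())


def simulate_cohort(design: CohortDesign) -> pd.DataFrame:
    """Draw a long-format cohort: one row per
    (animal, limb, week, compartment, parameter, value).

    Model per parameter × compartment: value = μ(limb, week) +
    SD(limb, week)·(√ρ·A + √(1−ρ)·ε), with A a per-animal standard normal
    shared across limbs and weeks and ε i.i.d. standard normal.  This gives
    each cell the designed mean and SD, inter-limb correlation ρ, and makes
    paired comparisons more powerful than unpaired ones — the point of a
    contralateral-control design.
    """
    rng = np.random.default_rng(design.seed)
    rho = design.correlation
    rows = []
    eff = design.effects.sort_values(
        ["parameter", "compartment", "week", "limb"]
    )
    for (param, comp), grp in eff.groupby(["parameter", "compartment"],
                                          sort=True):
        a = rng.standard_normal(design.n_animals)
        for _, r in grp.iterrows():
            eps = rng.standard_normal(design.n_animals)
            vals = r["mean"] + r["sd"] * (np.sqrt(rho) * a
                                          + np.sqrt(1 - rho) * eps)
            for i in range(design.n_animals):
                rows.append({
                    "animal": i + 1,
                    "limb": r["limb"],
                    "week": r["week"],
                    "compartment": comp,
                    "parameter": param,
                    "value": float(vals[i]),
                })
    return pd.DataFrame(rows)
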