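"""Direct-3D trabecular morphometry: BV, BV/TV, Tb.Th, Tb.Sp, Tb.N.

Thickness is measured model-independently by maximal-sphere fitting: the
local thickness at a voxel is the diameter of the largest sphere that fits
entirely inside the structure and covers that voxel.  The map is computed
from the Euclidean distance transform by sphere propagation — for each
distance value, in descending order, every voxel reachable by a sphere of
that radius inherits its diameter unless a larger sphere already claimed it.

Distance convention: sphere radii equal the distance from a voxel center to
the nearest background voxel *center* (the standard voxel-based direct
method).  A slab that is k voxel layers thick therefore reads exactly
k·spacing; an isolated voxel reads 2 voxels.  The volume border counts as
background for every domain (spheres may not leave the image), which avoids
inflating either thickness or separation with out-of-field space.

Mean Tb.Th averages the map over all bone voxels inside the VOI
(volume-weighted); Tb.Sp applies the identical machinery to the marrow
domain (VOI minus bone).  Tb.N is derived as (BV/TV)/Tb.Th and reported per
millimetre.  All internal lengths are in μm; volumes in mm³.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage as ndi

from .io_volumes import BinaryVolume
from .voi import VoiMask

UM3_PER_MM3 = 1e9


@dataclass
class ThicknessMap:
    """Local thickness values (μm) on a stated domain; zero elsewhere."""

    values: np.ndarray
    domain: np.ndarray  # boolean mask where the map is defined
    domain_kind: str  # {"bone", "background"}
    spacing: float

    def mean(self, where: np.ndarray | None = None) -> float:
        """Mean thickness over the domain (optionally restricted)."""
        sel = self.domain if where is None else (self.domain & where)
        if not sel.any():
            raise ValueError("empty thickness domain")
        return float(self.values[sel].mean())

    def max(self) -> float:
        if not self.domain.any():
            raise ValueError("empty thickness domain")
        return float(self.values[self.domain].max())


@dataclass
class MorphometrySet:
    """One compartment's trabecular morphometry record."""

    compartment: str
    bv: float  # mm³
    tv: float  # mm³
    bvtv: float  # %
    tbth: float  # μm
    tbsp: float  # μm
    tbn: float  # 1/mm
    threshold: int | None = None
    voi_id: str | None = None

    def __post_init__(self) -> None:
        if self.tv <= 0:
            raise ValueError("TV must be positive")
        if not -1e-9 <= self.bvtv <= 100 + 1e-9:
            raise ValueError("BV/TV must lie in [0, 100]%")


def local_thickness_map(domain: np.ndarray, spacing: float) -> np.ndarray:
    """Sphere-propagation local thickness (μm) of a boolean domain.

    Returns an array of the domain's shape, zero off-domain.  The volume
    border is treated as background (spheres must fit inside the image).
    """
    domain = np.asarray(domain, dtype=bool)
    out = np.zeros(domain.shape, dtype=np.float64)
    if not domain.any():
        return out
    padded = np.pad(domain, 1)
    edt = ndi.distance_transform_edt(padded)[1:-1, 1:-1, 1:-1]
    radius = np.where(domain, edt, 0.0)
    # exact distinct radii, largest first; rounding only clears float dust
    radii = np.unique(np.round(radius[domain], 6))[::-1]
    covered = ~domain
    n_remaining = int(domain.sum())
    for rv in radii:
        if rv <= 0 or n_remaining == 0:
            break
        centers = domain & (np.abs(radius - rv) < 1e-6)
        # restrict the coverage EDT to the centers' bounding box + radius
        idx = np.nonzero(centers)
        m = int(np.ceil(rv)) + 1
        lo = [max(int(i.min()) - m, 0) for i in idx]
        hi = [min(int(i.max()) + m + 1, s)
              for i, s in zip(idx, domain.shape)]
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        dist = ndi.distance_transform_edt(~centers[box])
        newly = domain[box] & ~covered[box] & (dist <= rv + 1e-6)
        out[box][newly] = 2.0 * rv * spacing
        covered[box] |= newly
        n_remaining -= int(newly.sum())
    return out


def local_thickness(mask: BinaryVolume, domain_kind: str,
                    voi: VoiMask | None = None) -> ThicknessMap:
    """Thickness map of the bone phase or of the marrow space within a VOI.

    ``domain_kind='bone'`` computes on the full bone mask (the VOI only
    restricts where means are later taken); ``'background'`` computes on
    VOI ∖ bone, with the VOI boundary acting as a hard wall.
    """
    if domain_kind == "bone":
        domain = mask.voxels
    elif domain_kind == "background":
        if voi is None:
            raise ValueError("background domain requires a VOI")
        domain = voi.voxels & ~mask.voxels
    else:
        raise ValueError(f"unknown domain {domain_kind!r}")
    if not domain.any():
        raise ValueError(f"empty {domain_kind} domain")
    values = local_thickness_map(domain, mask.spacing)
    return ThicknessMap(values, domain, domain_kind, mask.spacing)


def mean_thickness(tmap: ThicknessMap,
                   where: np.ndarray | None = None) -> float:
    """Volume-weighted mean local thickness (μm) over the map's domain."""
    return tmap.mean(where)


def bone_volume(mask: BinaryVolume,
                voi: VoiMask) -> tuple[float, float, float]:
    """(BV mm³, TV mm³, BV/TV %) by direct voxel counting within the VOI."""
    if mask.voxels.shape != voi.voxels.shape:
        raise ValueError("mask and VOI shapes differ")
    if mask.spacing != voi.spacing:
        raise ValueError("mask and VOI spacings differ")
    n_voi = int(voi.voxels.sum())
    if n_voi == 0:
        raise ValueError("empty VOI")
    n_bone = int((mask.voxels & voi.voxels).sum())
    vox_mm3 = mask.spacing**3 / UM3_PER_MM3
    bv = n_bone * vox_mm3
    tv = n_voi * vox_mm3
    return bv, tv, 100.0 * n_bone / n_voi


def trabecular_number(bvtv: float, tbth: float) -> float:
    """Tb.N (1/mm) derived as (BV/TV)/Tb.Th with BV/TV in % and Tb.Th in μm."""
    if bvtv == 0:
        return 0.0
    if tbth <= 0:
        raise ValueError("Tb.Th must be > 0 to derive Tb.N")
    return (bvtv / 100.0) / (tbth / 1000.0)


def compute_morphometry(mask: BinaryVolume, vois: Mapping[str, VoiMask],
                        ) -> dict[str, MorphometrySet]:
    """Full trabecular morphometry for medial, lateral, and total VOIs.

    The bone thickness map is computed once on the whole mask and averaged
    per compartment; the marrow (Tb.Sp) map is computed per compartment on
    VOI ∖ bone.  Total is the union of medial and lateral, so total BV is
    exactly the sum of the parts.
    """
    for c in ("medial", "lateral"):
        if c not in vois:
            raise ValueError(f"missing {c} VOI")
    comps: dict[str, VoiMask] = {
        "medial": vois["medial"],
        "lateral": vois["lateral"],
        "total": vois.get("total",
                          vois["medial"].union(vois["lateral"])),
    }
    bone_map = local_thickness_map(mask.voxels, mask.spacing)
    out: dict[str, MorphometrySet] = {}
    for name, voi in comps.items():
        bv, tv, bvtv = bone_volume(mask, voi)
        in_voi_bone = mask.voxels & voi.voxels
        if in_voi_bone.any():
            tbth = float(bone_map[in_voi_bone].mean())
            tbn = trabecular_number(bvtv, tbth)
        else:
            tbth = float("nan")
            tbn = 0.0
        marrow = voi.voxels & ~mask.voxels
        if marrow.any():
            tbsp = float(
                local_thickness_map(marrow, mask.spacing)[marrow].mean()
            )
        else:
            tbsp = float("nan")
        out[name] = MorphometrySet(name, bv, tv, bvtv, tbth, tbsp, tbn,
                                   threshold=mask.threshold)
    return out
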