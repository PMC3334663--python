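"""Uniform-threshold segmentation of grayscale micro-CT volumes.

Longitudinal bone studies binarize every stack of a study with a single
global grey-level threshold so that timepoints and limbs remain comparable.
The threshold is either user-fixed or suggested once, on a designated
calibration volume, by Otsu's between-class-variance criterion, then reused
study-wide.

Conventions (fixed so results are bit-exact): a voxel is bone iff its
intensity is >= the threshold; bone components use 26-connectivity and
background cavities 6-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .io_volumes import BinaryVolume, GrayVolume


@dataclass(frozen=True)
class ThresholdChoice:
    """A study-wide segmentation threshold and how it was chosen."""

    value: int
    method: str = "fixed"  # {"fixed", "bimodal-automatic"}

    def __post_init__(self) -> None:
        if not 0 <= self.value <= 255:
            raise ValueError(f"threshold must be in [0, 255], got {self.value}")
        if self.method not in ("fixed", "bimodal-automatic"):
            raise ValueError(f"unknown threshold method {self.method!r}")


def apply_threshold(gray: GrayVolume, t: ThresholdChoice | int) -> BinaryVolume:
    """Binarize: bone iff intensity >= t.value.  Spacing and provenance kept."""
    if isinstance(t, (int, np.integer)):
        t = ThresholdChoice(int(t))
    return BinaryVolume(gray.voxels >= t.value, gray.spacing, t.value)


def suggest_threshold(gray: GrayVolume) -> ThresholdChoice:
    """Suggest the between-class-variance-maximizing (Otsu) threshold.

    Deterministic; intended to be run once on a calibration volume and then
    applied uniformly.  Raises on a constant image, whose histogram admits
    no split.
    """
    vox = gray.voxels
    if vox.min() == vox.max():
        raise ValueError("cannot suggest a threshold for a constant image")
    t = threshold_otsu(vox)
    # threshold_otsu returns the highest intensity of the lower class; our
    # bone rule is >=, so bone starts one grey level above it.
    return ThresholdChoice(int(t) + 1, "bimodal-automatic")


def despeckle(mask: BinaryVolume, min_size: int) -> BinaryVolume:
    """Remove small speckles: 26-connected bone islands and 6-connected
    background cavities with fewer than ``min_size`` voxels.

    Disabled (identity) at ``min_size == 0``; it is an optional cleanup, not
    part of the standard quantification path.
    """
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    if min_size == 0:
        return BinaryVolume(mask.voxels.copy(), mask.spacing, mask.threshold)
    # max_size removes components <= its value; "< min_size" semantics
    bone = remove_small_objects(mask.voxels, max_size=min_size - 1,
                                connectivity=3)
    # fill small enclosed background cavities (6-connected)
    bg_lab, n = ndi.label(~bone, structure=ndi.generate_binary_structure(3, 1))
    if n:
        sizes = np.bincount(bg_lab.ravel())
        small = np.flatnonzero(sizes < min_size)
        small = small[small > 0]
        if small.size:
            bone = bone | np.isin(bg_lab, small)
    return BinaryVolume(bone, mask.spacing, mask.threshold)
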