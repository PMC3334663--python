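"""Macroscopic cartilage grading and OARSI histopathology score arithmetic.

Macroscopic lesions are graded 0–4 per tibial compartment (0 = normal
appearance … 4 = large erosion with large areas of subchondral bone
exposure) by one or more blinded observers; the joint grade combines the
medial and lateral grades (sum by default, range 0–8) and is summarized as
mean ± SD across observers and animals.

The OARSI osteoarthritis score is grade (1–6 depth of cartilage lesion; 0
for no activity) × stage (0–4 extent), giving a 0–24 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MACRO_GRADE_MAX = 4
OARSI_GRADE_RANGE = (0, 6)
OARSI_STAGE_RANGE = (0, 4)


@dataclass(frozen=True)
class MacroscopicGrade:
    """One observer's macroscopic grade for one compartment."""

    observer: str
    compartment: str  # {"medial", "lateral"}
    grade: int

    def __post_init__(self) -> None:
        if self.grade not in range(MACRO_GRADE_MAX + 1):
            raise ValueError(
                f"macroscopic grade must be 0–{MACRO_GRADE_MAX}, "
                f"got {self.grade}"
            )
        if self.compartment not in ("medial", "lateral"):
            raise ValueError("compartment must be medial or lateral")


@dataclass(frozen=True)
class OarsiScore:
    """OARSI score: grade × stage, 0 (no activity) to 24 (maximal)."""

    grade: int
    stage: int

    def __post_init__(self) -> None:
        if not OARSI_GRADE_RANGE[0] <= self.grade <= OARSI_GRADE_RANGE[1]:
            raise ValueError(f"OARSI grade must be in {OARSI_GRADE_RANGE}")
        if not OARSI_STAGE_RANGE[0] <= self.stage <= OARSI_STAGE_RANGE[1]:
            raise ValueError(f"OARSI stage must be in {OARSI_STAGE_RANGE}")

    @property
    def score(self) -> int:
        return self.grade * self.stage


def oarsi(grade: int, stage: int) -> OarsiScore:
    """Build an OARSI score from its grade and stage components."""
    return OarsiScore(int(grade), int(stage))


def joint_grade(grades: list[MacroscopicGrade],
                combiner: str = "sum") -> tuple[float, float, list[float]]:
    """Combined joint grade: per observer, combine medial + lateral, then
    mean ± SD across observers.

    Returns (mean, sd, per-observer combined values).  The combination rule
    is ``"sum"`` (default, 0–8 scale) or ``"mean"`` (0–4 scale); both are
    exposed because published combined grades do not always state the rule.
    """
    if not grades:
        raise ValueError("need at least one grade")
    if combiner not in ("sum", "mean"):
        raise ValueError("combiner must be 'sum' or 'mean'")
    per_obs: dict[str, dict[str, int]] = {}
    for g in grades:
        per_obs.setdefault(g.observer, {})[g.compartment] = g.grade
    combined = []
    for obs, comps in sorted(per_obs.items()):
        if set(comps) != {"medial", "lateral"}:
            raise ValueError(
                f"observer {obs!r} must grade both compartments"
            )
        total = comps["medial"] + comps["lateral"]
        combined.append(total / 2.0 if combiner == "mean" else float(total))
    arr = np.asarray(combined)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, combined
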