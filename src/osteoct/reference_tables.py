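"""Published summary statistics for the low-dose MIA rat study modeled here.

These are the group-level summaries (mean ± SD per limb, per compartment,
per post-injection week) of tibial subchondral trabecular morphometry and
subchondral plate metrics from a 12-animal paired-limb cohort: 0.2 mg MIA
in the right knee, saline in the contralateral control, scanned in vivo at
2, 6, and 10 weeks.  They serve two purposes:

* worked-number checks — derived columns (percent difference, Tb.N, total
  plate values) can be recomputed from the printed means;
* default cohort designs for the simulator, so the statistics module is
  exercised on data shaped like the real study.

BV is recorded on the published scale; note that the published BV
magnitudes are inconsistent with mm³ for a 0.45 mm-high VOI (the package's
own pipeline reports true mm³).
"""

from __future__ import annotations

import pandas as pd

from .phantoms import CohortDesign

# (parameter, compartment, week) -> (MIA mean, MIA sd, control mean, control sd)
_TRABECULAR = {
    ("BV", "medial", 2): (613, 97, 745, 118),
    ("BV", "lateral", 2): (647, 120, 711, 130),
    ("BV", "total", 2): (1260, 202, 1456, 239),
    ("BV", "medial", 6): (1177, 211, 993, 214),
    ("BV", "lateral", 6): (1145, 168, 948, 169),
    ("BV", "total", 6): (2322, 341, 1941, 370),
    ("BV", "medial", 10): (1481, 271, 1179, 229),
    ("BV", "lateral", 10): (1229, 133, 1205, 241),
    ("BV", "total", 10): (2710, 326, 2384, 454),
    ("BV/TV", "medial", 2): (16.8, 2.6, 20.4, 3.2),
    ("BV/TV", "lateral", 2): (15.1, 2.8, 16.7, 3.0),
    ("BV/TV", "total", 2): (15.9, 2.5, 18.6, 3.0),
    ("BV/TV", "medial", 6): (32.7, 6.5, 27.5, 6.6),
    ("BV/TV", "lateral", 6): (27.2, 3.6, 22.2, 3.8),
    ("BV/TV", "total", 6): (30.0, 4.2, 24.8, 5.0),
    ("BV/TV", "medial", 10): (39.8, 7.7, 33.6, 7.6),
    ("BV/TV", "lateral", 10): (29.0, 3.2, 28.2, 6.0),
    ("BV/TV", "total", 10): (34.4, 4.8, 30.9, 6.4),
    ("Tb.Th", "medial", 2): (94, 5, 92, 3),
    ("Tb.Th", "lateral", 2): (89, 4, 87, 3),
    ("Tb.Th", "total", 2): (91, 4, 90, 3),
    ("Tb.Th", "medial", 6): (124, 11, 100, 9),
    ("Tb.Th", "lateral", 6): (117, 9, 95, 5),
    ("Tb.Th", "total", 6): (120, 9, 97, 7),
    ("Tb.Th", "medial", 10): (149, 19, 110, 12),
    ("Tb.Th", "lateral", 10): (128, 17, 105, 8),
    ("Tb.Th", "total", 10): (138, 18, 108, 10),
    ("Tb.N", "medial", 2): (1.8, 0.3, 2.2, 0.3),
    ("Tb.N", "lateral", 2): (1.7, 0.3, 1.9, 0.3),
    ("Tb.N", "total", 2): (1.7, 0.2, 2.1, 0.3),
    ("Tb.N", "medial", 6): (2.5, 0.5, 2.7, 0.5),
    ("Tb.N", "lateral", 6): (2.2, 0.3, 2.3, 0.3),
    ("Tb.N", "total", 6): (2.3, 0.3, 2.5, 0.4),
    ("Tb.N", "medial", 10): (2.6, 0.5, 3.1, 0.4),
    ("Tb.N", "lateral", 10): (2.3, 0.3, 2.7, 0.3),
    ("Tb.N", "total", 10): (2.5, 0.3, 2.9, 0.4),
    ("Tb.Sp", "medial", 2): (270, 16, 243, 17),
    ("Tb.Sp", "lateral", 2): (272, 16, 256, 17),
    ("Tb.Sp", "total", 2): (271, 13, 250, 14),
    ("Tb.Sp", "medial", 6): (240, 19, 203, 24),
    ("Tb.Sp", "lateral", 6): (250, 16, 221, 14),
    ("Tb.Sp", "total", 6): (245, 15, 212, 16),
    ("Tb.Sp", "medial", 10): (241, 32, 207, 20),
    ("Tb.Sp", "lateral", 10): (258, 17, 223, 15),
    ("Tb.Sp", "total", 10): (245, 22, 215, 15),
}

# subchondral plate thickness, Pl.Th (μm); total = mean of medial/lateral
# computed per animal in the source, so the printed total may differ from
# the mean of the printed sides by rounding.
_PLATE_TH = {
    ("medial", 2): (114, 7, 105, 7),
    ("lateral", 2): (101, 6, 109, 7),
    ("total", 2): (107, 4, 107, 8),
    ("medial", 6): (146, 32, 119, 32),
    ("lateral", 6): (130, 17, 120, 26),
    ("total", 6): (138, 23, 118, 26),
    ("medial", 10): (181, 27, 175, 31),
    ("lateral", 10): (166, 18, 178, 24),
    ("total", 10): (177, 19, 177, 25),
}

# plate porosity is published only as percent differences (MIA vs control)
_PLATE_POR_PCT_DIFF = {
    ("medial", 2): 23, ("lateral", 2): 24, ("total", 2): 24,
    ("medial", 6): 63, ("lateral", 6): 69, ("total", 6): 66,
    ("medial", 10): 66, ("lateral", 10): 77, ("total", 10): 71,
}

#: Subchondral cysts were seen on micro-CT in 8 of 12 animals.
CYST_COUNT = (8, 12)

#: OARSI histopathology score bounds: grade 0–6 times stage 0–4.
OARSI_GRADE_MAX = 6
OARSI_STAGE_MAX = 4

N_ANIMALS = 12
WEEKS = (2, 6, 10)
VOI_N_SLICES = 52
STACK_N_SLICES = 1800
SPACING_UM = 8.7


def trabecular_summary() -> pd.DataFrame:
    """Published trabecular summary, long format (one row per cell)."""
    rows = []
    for (param, comp, week), (m_oa, s_oa, m_ct, s_ct) in _TRABECULAR.items():
        rows.append({"parameter": param, "compartment": comp, "week": week,
                     "mia_mean": m_oa, "mia_sd": s_oa,
                     "control_mean": m_ct, "control_sd": s_ct})
    return pd.DataFrame(rows)


def plate_summary() -> pd.DataFrame:
    """Published plate thickness summary (μm), long format."""
    rows = []
    for (comp, week), (m_oa, s_oa, m_ct, s_ct) in _PLATE_TH.items():
        rows.append({"parameter": "Pl.Th", "compartment": comp, "week": week,
                     "mia_mean": m_oa, "mia_sd": s_oa,
                     "control_mean": m_ct, "control_sd": s_ct})
    return pd.DataFrame(rows)


def plate_porosity_pct_diff() -> pd.DataFrame:
    """Published plate porosity percent differences (MIA vs control, %)."""
    rows = [{"parameter": "Pl.Por", "compartment": c, "week": w,
             "pct_diff": v}
            for (c, w), v in _PLATE_POR_PCT_DIFF.items()]
    return pd.DataFrame(rows)


def _design_from_summary(summary: pd.DataFrame, parameters=None,
                         compartments=("total",), n_animals=N_ANIMALS,
                         correlation=0.7, seed=0) -> CohortDesign:
    df = summary
    if parameters is not None:
        df = df[df["parameter"].isin(parameters)]
    df = df[df["compartment"].isin(compartments)]
    rows = []
    for _, r in df.iterrows():
        for limb, mcol, scol in (("MIA", "mia_mean", "mia_sd"),
                                 ("control", "control_mean", "control_sd")):
            rows.append({"parameter": r["parameter"],
                         "compartment": r["compartment"],
                         "week": r["week"], "limb": limb,
                         "mean": r[mcol], "sd": r[scol]})
    return CohortDesign(pd.DataFrame(rows), n_animals=n_animals,
                        correlation=correlation, seed=seed)


def reference_cohort_design(parameters=None, compartments=("total",),
                            n_animals=N_ANIMALS, correlation=0.7,
                            seed=0) -> CohortDesign:
    """Cohort design following the published trabecular summaries.

    Defaults to the total compartment, 12 animals, inter-limb correlation
    0.7 (an assumption of this package; the published summaries do not
    constrain it).
    """
    return _design_from_summary(trabecular_summary(), parameters,
                                compartments, n_animals, correlation, seed)


def null_cohort_design(mean=250.0, sd=15.0, n_animals=N_ANIMALS,
                       weeks=WEEKS, correlation=0.7, seed=0,
                       parameter="Tb.Sp", compartment="total") -> CohortDesign:
    """A no-effect design: both limbs share the same mean/SD at every week."""
    rows = [{"parameter": parameter, "compartment": compartment, "week": w,
             "limb": limb, "mean": mean, "sd": sd}
            for w in weeks for limb in ("MIA", "control")]
    return CohortDesign(pd.DataFrame(rows), n_animals=n_animals,
                        correlation=correlation, seed=seed)
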