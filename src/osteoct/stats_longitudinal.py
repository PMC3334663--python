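"""Longitudinal paired-limb inference and table-style reporting.

The analysis recipe for a contralateral-control design: per parameter and
compartment, a two-way repeated-measures ANOVA with time (weeks) and limb
(MIA vs control) as within-subject factors establishes whether there is a
time effect and a time-by-group interaction; if the relevant F is
significant, paired t-tests compare the limbs at each timepoint, with
p-values adjusted by Holm's Bonferroni stepdown over the per-parameter
family of timepoint comparisons.  Normality is screened with Shapiro–Wilk.
The family-wise error rate is controlled at α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
LIMBS = ("MIA", "control")


@dataclass
class LongitudinalDataset:
    """Long-format paired-limb cohort records.

    Columns: animal, limb (MIA/control), week, compartment, parameter,
    value.  Inference requires complete pairs: every included animal must
    have both limbs at every timepoint for the analysed parameter.
    """

    records: pd.DataFrame

    REQUIRED = ("animal", "limb", "week", "compartment", "parameter", "value")

    def __post_init__(self) -> None:
        if self.records.empty:
            raise ValueError("empty dataset")
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        if not np.isfinite(self.records["value"]).all():
            raise ValueError("dataset contains non-finite values")
        bad = set(self.records["limb"]) - set(LIMBS)
        if bad:
            raise ValueError(f"unknown limb labels {sorted(bad)}")

    @property
    def parameters(self) -> list[str]:
        return sorted(self.records["parameter"].unique())

    @property
    def compartments(self) -> list[str]:
        return sorted(self.records["compartment"].unique())

    @property
    def weeks(self) -> list:
        return sorted(self.records["week"].unique())

    @property
    def n_animals(self) -> int:
        return self.records["animal"].nunique()

    def matrix(self, parameter: str, compartment: str) -> pd.DataFrame:
        """Complete-case cell table indexed by animal with (week, limb)
        columns; raises if any animal is missing a cell."""
        df = self.records
        df = df[(df["parameter"] == parameter)
                & (df["compartment"] == compartment)]
        if df.empty:
            raise ValueError(
                f"no records for {parameter!r} in {compartment!r}"
            )
        wide = df.pivot_table(index="animal", columns=["week", "limb"],
                              values="value", aggfunc="first")
        if wide.isna().any().any():
            bad = wide.index[wide.isna().any(axis=1)].tolist()
            raise ValueError(
                f"incomplete paired design; offending animals: {bad}"
            )
        return wide

    @classmethod
    def from_csv(cls, path) -> "LongitudinalDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


@dataclass
class AnovaResult:
    """Two-way within-subject ANOVA effects for one parameter/compartment."""

    parameter: str
    compartment: str
    f_time: float
    p_time: float
    f_group: float
    p_group: float
    f_interaction: float
    p_interaction: float
    df_error_time: float
    df_error_interaction: float

    def __post_init__(self) -> None:
        for f in (self.f_time, self.f_group, self.f_interaction):
            if f < 0:
                raise ValueError("F statistics must be >= 0")
        for p in (self.p_time, self.p_group, self.p_interaction):
            if not 0 <= p <= 1:
                raise ValueError("p-values must lie in [0, 1]")


@dataclass
class ComparisonResult:
    """One limb comparison at one timepoint."""

    parameter: str
    compartment: str
    week: object
    mean_mia: float
    sd_mia: float
    mean_control: float
    sd_control: float
    pct_diff: float
    t: float
    p_raw: float
    p_holm: float = field(default=np.nan)
    significant: bool = False


def check_normality(values) -> float:
    """Shapiro–Wilk p-value for a sample of 3 to 5000 observations."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or not 3 <= x.size <= 5000:
        raise ValueError("Shapiro–Wilk needs a 1D sample with 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample")
    return float(stats.shapiro(x).pvalue)


def rm_anova(dataset: LongitudinalDataset, parameter: str,
             compartment: str) -> AnovaResult:
    """Two-way repeated-measures ANOVA (time × limb, both within-subject).

    Sums of squares are computed from cell and marginal means of the
    balanced complete design; each effect is tested against its own
    subject-by-effect interaction mean square.  Exactly-null effects (e.g.
    limbs identical within every animal) report F = 0, p = 1 rather than a
    0/0 artifact.  No sphericity correction is applied by default (use
    ``greenhouse_geisser_epsilon`` to gauge the need).
    """
    wide = dataset.matrix(parameter, compartment)
    n = len(wide)
    if n < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 animals")
    weeks = sorted({w for w, _ in wide.columns})
    if len(weeks) < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 timepoints")
    data = np.stack([
        np.column_stack([wide[(w, limb)].to_numpy(dtype=float)
                         for limb in LIMBS])
        for w in weeks
    ], axis=1)  # (subjects, weeks, limbs)
    a, b = len(weeks), len(LIMBS)
    grand = data.mean()
    A = data.mean(axis=(0, 2))   # week marginals
    B = data.mean(axis=(0, 1))   # limb marginals
    S = data.mean(axis=(1, 2))   # subject marginals
    SA = data.mean(axis=2)
    SB = data.mean(axis=1)
    AB = data.mean(axis=0)
    sq = lambda x: float((np.asarray(x) ** 2).sum())
    ss_a = n * b * sq(A - grand)
    ss_b = n * a * sq(B - grand)
    ss_ab = n * sq(AB[None] - A[:, None] - B[None] + grand)
    ss_sa = b * sq(SA - S[:, None] - A[None] + grand)
    ss_sb = a * sq(SB - S[:, None] - B[None] + grand)
    ss_sab = sq(data - SA[:, :, None] - SB[:, None, :] - AB[None]
                + S[:, None, None] + A[None, :, None] + B[None, None, :]
                - grand)
    scale = max(sq(data - grand), 1.0)

    def f_test(ss_eff, df_eff, ss_err, df_err):
        if ss_eff <= 1e-12 * scale:
            return 0.0, 1.0
        if ss_err <= 1e-12 * scale:
            return float("inf"), 0.0
        f = (ss_eff / df_eff) / (ss_err / df_err)
        return f, float(stats.f.sf(f, df_eff, df_err))

    f_t, p_t = f_test(ss_a, a - 1, ss_sa, (n - 1) * (a - 1))
    f_g, p_g = f_test(ss_b, b - 1, ss_sb, (n - 1) * (b - 1))
    f_i, p_i = f_test(ss_ab, (a - 1) * (b - 1), ss_sab,
                      (n - 1) * (a - 1) * (b - 1))
    return AnovaResult(
        parameter, compartment,
        f_time=f_t, p_time=p_t, f_group=f_g, p_group=p_g,
        f_interaction=f_i, p_interaction=p_i,
        df_error_time=float((n - 1) * (a - 1)),
        df_error_interaction=float((n - 1) * (a - 1) * (b - 1)),
    )


def holm_adjust(pvals) -> np.ndarray:
    """Holm's Bonferroni stepdown adjustment, returned in input order.

    Sort ascending; adjusted_(i) = max_{j<=i} (m - j + 1)·p_(j), capped at 1.
    Dominates the raw p-values and is dominated by plain Bonferroni.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1D")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = (m - np.arange(m)) * p[order]
    adj = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def percent_difference(oa_mean: float, ctl_mean: float) -> float:
    """Percent difference of the MIA (OA) mean relative to control:
    100·(OA − CTL)/CTL."""
    if ctl_mean == 0:
        raise ValueError("control mean must be nonzero")
    return 100.0 * (oa_mean - ctl_mean) / ctl_mean


def paired_tests(dataset: LongitudinalDataset, parameter: str,
                 compartment: str, alpha: float = ALPHA,
                 gate: bool = True) -> list[ComparisonResult]:
    """Paired t-tests (MIA vs control) per timepoint, Holm-adjusted.

    With ``gate=True`` the tests run only when the ANOVA shows a
    significant limb or time-by-limb effect at ``alpha`` (returns an empty
    list otherwise); disable the gate for calibration studies.  The Holm
    family is the set of timepoint comparisons within this parameter ×
    compartment.
    """
    wide = dataset.matrix(parameter, compartment)
    if len(wide) < 2:
        raise ValueError("paired tests need >= 2 pairs")
    if gate:
        a = rm_anova(dataset, parameter, compartment)
        if a.p_group >= alpha and a.p_interaction >= alpha:
            return []
    results = []
    for week in sorted({w for w, _ in wide.columns}):
        x = wide[(week, "MIA")].to_numpy(dtype=float)
        y = wide[(week, "control")].to_numpy(dtype=float)
        d = x - y
        if np.allclose(d, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(x, y)
        results.append(ComparisonResult(
            parameter, compartment, week,
            mean_mia=float(x.mean()), sd_mia=float(x.std(ddof=1)),
            mean_control=float(y.mean()), sd_control=float(y.std(ddof=1)),
            pct_diff=percent_difference(x.mean(), y.mean()),
            t=float(t), p_raw=float(p),
        ))
    adj = holm_adjust([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_holm = float(pa)
        r.significant = bool(pa < alpha)
    return results


def paired_tests_over_time(dataset: LongitudinalDataset, parameter: str,
                           compartment: str, limb: str,
                           alpha: float = ALPHA) -> list[ComparisonResult]:
    """Within-limb comparisons between timepoints (all pairs), one Holm
    family per parameter × compartment × limb."""
    wide = dataset.matrix(parameter, compartment)
    weeks = sorted({w for w, _ in wide.columns})
    results = []
    for i, w1 in enumerate(weeks):
        for w2 in weeks[i + 1:]:
            x = wide[(w2, limb)].to_numpy(dtype=float)
            y = wide[(w1, limb)].to_numpy(dtype=float)
            if np.allclose(x - y, 0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(x, y)
            results.append(ComparisonResult(
                parameter, compartment, (w1, w2),
                mean_mia=float(x.mean()), sd_mia=float(x.std(ddof=1)),
                mean_control=float(y.mean()), sd_control=float(y.std(ddof=1)),
                pct_diff=percent_difference(x.mean(), y.mean()),
                t=float(t), p_raw=float(p),
            ))
    adj = holm_adjust([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_holm = float(pa)
        r.significant = bool(pa < alpha)
    return results


#: Rounding for table views: parameter -> decimals (lengths as integers,
#: percentages / Tb.N / %d to one decimal).
_TABLE_DECIMALS = {"BV": 0, "BV/TV": 1, "Tb.Th": 0, "Tb.Sp": 0, "Tb.N": 1,
                   "Pl.Th": 0, "Pl.Por": 1}


def build_tables(dataset: LongitudinalDataset, alpha: float = ALPHA,
                 gate: bool = True) -> pd.DataFrame:
    """Summary table: per parameter × compartment × week, group mean ± SD,
    percent difference, raw and Holm-adjusted p, significance flag.

    ``mean_sd_*`` columns carry the rounded "mean ± SD" presentation; the
    numeric columns keep full precision.  Gated-out parameters report the
    descriptives with missing p-values (no comparisons were licensed).
    """
    rows = []
    for param in dataset.parameters:
        df_p = dataset.records[dataset.records["parameter"] == param]
        for comp in sorted(df_p["compartment"].unique()):
            comparisons = paired_tests(dataset, param, comp,
                                       alpha=alpha, gate=gate)
            by_week = {c.week: c for c in comparisons}
            wide = dataset.matrix(param, comp)
            nd = _TABLE_DECIMALS.get(param, 1)
            for week in sorted({w for w, _ in wide.columns}):
                x = wide[(week, "MIA")]
                y = wide[(week, "control")]
                c = by_week.get(week)
                rows.append({
                    "parameter": param, "compartment": comp, "week": week,
                    "mia_mean": x.mean(), "mia_sd": x.std(ddof=1),
                    "control_mean": y.mean(), "control_sd": y.std(ddof=1),
                    "pct_diff": percent_difference(x.mean(), y.mean()),
                    "p_raw": c.p_raw if c else np.nan,
                    "p_holm": c.p_holm if c else np.nan,
                    "significant": c.significant if c else False,
                    "mean_sd_mia": _fmt(x.mean(), x.std(ddof=1), nd),
                    "mean_sd_control": _fmt(y.mean(), y.std(ddof=1), nd),
                })
    if not rows:
        raise ValueError("no analysable records")
    return pd.DataFrame(rows)


def _fmt(mean: float, sd: float, nd: int) -> str:
    if nd == 0:
        return f"{mean:.0f} ± {sd:.0f}"
    return f"{mean:.{nd}f} ± {sd:.{nd}f}"


def greenhouse_geisser_epsilon(dataset: LongitudinalDataset, parameter: str,
                               compartment: str, limb: str) -> float:
    """Greenhouse–Geisser sphericity epsilon for the time factor within one
    limb (1 = spherical; lower values call for correction)."""
    wide = dataset.matrix(parameter, compartment)
    weeks = sorted({w for w, _ in wide.columns})
    X = np.column_stack([wide[(w, limb)].to_numpy(dtype=float)
                         for w in weeks])
    S = np.cov(X, rowvar=False)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * ((S**2).sum() - 2 * k * (row_means**2).sum()
                     + k**2 * grand**2)
    return float(num / den)
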