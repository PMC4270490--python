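"""The dual-significance statistical framework and figure-style reports.

Each comparison of an experimental genotype against its control is made
twice: a classical pooled-variance two-sample Student's t-test, and a
one-way ANOVA across all groups of the experiment.  A difference counts as
significant only when BOTH tests pass the threshold; stars follow the usual
convention (* p<0.05, ** p<0.01, both tests).  Descriptives are mean and
sample standard deviation (n-1 denominator).  No multiple-testing correction
is applied; reports state the number of comparisons so users can add their
own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "ComparisonResult",
    "describe",
    "students_t",
    "one_way_anova",
    "dual_significance",
    "build_report",
]


@dataclass
class GroupSample:
    """One genotype/condition's measurements."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("values must be a non-empty 1D array")

    @property
    def n(self) -> int:
        return len(self.values)


def describe(values) -> tuple[float, float | None, int]:
    """Mean, sample SD (n-1; None when n == 1) and n."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot describe an empty group")
    sd = float(v.std(ddof=1)) if v.size > 1 else None
    return float(v.mean()), sd, int(v.size)


def students_t(a, b) -> float:
    """Two-sided pooled-variance two-sample Student's t-test p-value.

    Degenerate samples (zero pooled variance) give p = 1 when the means are
    equal and p = 0 (with a warning) when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test needs n >= 2 per group")
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if sp2 == 0:
        if a.mean() == b.mean():
            return 1.0
        warnings.warn(
            "zero pooled variance with unequal means: p = 0", stacklevel=2
        )
        return 0.0
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    df = len(a) + len(b) - 2
    return float(2.0 * sps.t.sf(abs(t), df))


def one_way_anova(groups) -> float:
    """Omnibus one-way ANOVA p-value across >= 2 groups (each n >= 2).

    For two groups the F statistic equals the square of the Student's t
    statistic on the same data, so the p-values agree exactly.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs n >= 2 in every group")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    k = len(groups)
    n_tot = len(all_vals)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_tot - k
    ms_w = ss_within / df_w
    if ms_w == 0:
        if ss_between == 0:
            return 1.0
        warnings.warn(
            "zero within-group variance with unequal means: p = 0", stacklevel=2
        )
        return 0.0
    f = (ss_between / df_b) / ms_w
    return float(sps.f.sf(f, df_b, df_w))


@dataclass
class ComparisonResult:
    """Outcome of one experimental-vs-control comparison under the dual rule."""

    p_t: float
    p_anova: float
    significant_05: bool
    significant_01: bool
    stars: str

    def __post_init__(self) -> None:
        if self.significant_01 and not self.significant_05:
            raise ValueError("significance at 0.01 implies significance at 0.05")


def dual_significance(
    p_t: float, p_anova: float, alpha_levels: tuple[float, float] = (0.05, 0.01)
) -> ComparisonResult:
    """Apply the dual rule: significant at alpha iff BOTH p-values < alpha.

    Stars: "**" when both p < 0.01, "*" when both p < 0.05 only, "" otherwise.
    """
    for p in (p_t, p_anova):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"invalid p-value {p}")
    a05, a01 = max(alpha_levels), min(alpha_levels)
    sig05 = p_t < a05 and p_anova < a05
    sig01 = p_t < a01 and p_anova < a01
    stars = "**" if sig01 else ("*" if sig05 else "")
    return ComparisonResult(
        p_t=p_t, p_anova=p_anova, significant_05=sig05, significant_01=sig01, stars=stars
    )


def build_report(
    measurements: pd.DataFrame,
    control_label: str | None = None,
    min_cohort: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Figure-style tables from a tidy measurement frame.

    ``measurements`` must have columns genotype, unit_id, metric, value.
    For every metric: per-genotype mean/SD/n, then each non-control genotype
    compared to the control (t-test + omnibus ANOVA over all genotypes of
    that metric) with dual-rule stars.  A cohort smaller than ``min_cohort``
    triggers a warning recorded in the descriptives table.
    """
    required = {"genotype", "unit_id", "metric", "value"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    genotypes = list(dict.fromkeys(measurements["genotype"]))
    control_label = control_label or genotypes[0]
    desc_rows, comp_rows = [], []
    for metric, sub in measurements.groupby("metric", sort=False):
        groups = {
            g: sub.loc[sub.genotype == g, "value"].to_numpy() for g in genotypes
            if (sub.genotype == g).any()
        }
        for g, vals in groups.items():
            mean, sd, n = describe(vals)
            desc_rows.append(
                {
                    "metric": metric,
                    "genotype": g,
                    "mean": mean,
                    "sd": sd,
                    "n": n,
                    "below_min_cohort": bool(min_cohort and n < min_cohort),
                }
            )
        testable = {g: v for g, v in groups.items() if len(v) >= 2}
        if control_label in testable and len(testable) >= 2:
            p_anova = one_way_anova(list(testable.values()))
            for g, vals in testable.items():
                if g == control_label:
                    continue
                p_t = students_t(testable[control_label], vals)
                res = dual_significance(p_t, p_anova)
                comp_rows.append(
                    {
                        "metric": metric,
                        "genotype": g,
                        "control": control_label,
                        "p_t": p_t,
                        "p_anova": p_anova,
                        "significant_05": res.significant_05,
                        "significant_01": res.significant_01,
                        "stars": res.stars,
                    }
                )
    descriptives = pd.DataFrame(desc_rows)
    comparisons = pd.DataFrame(comp_rows)
    if len(comparisons):
        comparisons.attrs["n_comparisons"] = len(comparisons)
    for row in desc_rows:
        if row["below_min_cohort"]:
            warnings.warn(
                f"cohort {row['genotype']}/{row['metric']} has n={row['n']} "
                f"< configured minimum {min_cohort}",
                stacklevel=2,
            )
    return {"descriptives": descriptives, "comparisons": comparisons}
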