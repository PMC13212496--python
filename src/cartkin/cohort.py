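"""Cohort-level comparison of estimated kinetic parameters with outcomes.

Products are grouped by clinical endpoint — day-28 and day-90 response
(responders R pool complete and partial responses; non-responders NR are
progressive disease), relapse through day 180 among initial responders,
cytokine release syndrome, neurotoxicity — optionally within a disease
subset.  Effector parameters (kc, Kmr, n, kp2, Kmp, CE) are compared
between groups with a two-sided Wilcoxon rank-sum test at alpha = 0.05
without multiplicity correction (a Benjamini-Hochberg option exists for
users who want it); tumor-control parameters kp1 and CT, and the
negligible-magnitude decay rate kd, are excluded.  Effect sizes are
rank-biserial correlation magnitudes with bootstrap percentile intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OutcomeRecord",
    "CohortComparison",
    "SCHEMES",
    "COMPARED_PARAMETERS",
    "assign_groups",
    "rank_sum_test",
    "effect_size",
    "composition_correlation",
    "run_cohort_analysis",
    "benjamini_hochberg",
]

SCHEMES = ("day28", "day90", "relapse180", "crs", "neurotox")

#: parameters compared across outcome groups; kp1/CT describe the tumor
#: control and kd is negligible in magnitude, so they are excluded
COMPARED_PARAMETERS = ("kc", "Kmr", "n", "kp2", "Kmp", "CE")

#: combined sample size at or below which the exact rank-sum null is used
EXACT_LIMIT = 12


@dataclass(frozen=True)
class OutcomeRecord:
    """Clinical endpoints for one product/patient."""

    response_day28: str  # "R" or "NR"
    response_day90: str  # "R" or "NR"
    relapse_day180: str  # "yes", "no", or "na" (non-responders)
    crs: str             # "yes"/"no"
    neurotoxicity: str   # "yes"/"no"
    disease: str | None = None

    def __post_init__(self) -> None:
        for name, allowed in (
            ("response_day28", {"R", "NR"}),
            ("response_day90", {"R", "NR"}),
            ("relapse_day180", {"yes", "no", "na"}),
            ("crs", {"yes", "no"}),
            ("neurotoxicity", {"yes", "no"}),
        ):
            if getattr(self, name) not in allowed:
                raise ValueError(f"{name} must be one of {sorted(allowed)}")
        if (
            self.relapse_day180 != "na"
            and self.response_day28 == "NR"
            and self.response_day90 == "NR"
        ):
            raise ValueError("relapse is defined only for initial responders")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CohortComparison:
    """Result of one parameter-by-grouping comparison."""

    parameter: str
    grouping: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float | None
    p_value: float | None
    effect_size: float | None
    effect_ci: tuple | None
    test: str
    skipped_reason: str | None = None


def assign_groups(
    outcomes: Sequence[OutcomeRecord],
    scheme: str,
    disease_subset: str | None = None,
    relapse_base: str = "any",
) -> list:
    """Label each record with its group under a comparison scheme.

    Returns one label per record; ``None`` marks records excluded from
    the scheme (wrong disease subset, or non-responders in the relapse
    scheme).  ``relapse_base`` selects the responder base population for
    the relapse scheme: responders at ``"day28"``, ``"day90"``, or at
    either timepoint (``"any"``, the default).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")

    labels: list = []
    for rec in outcomes:
        if disease_subset is not None and rec.disease != disease_subset:
            labels.append(None)
            continue
        if scheme == "day28":
            labels.append(rec.response_day28)
        elif scheme == "day90":
            labels.append(rec.response_day90)
        elif scheme == "crs":
            labels.append(rec.crs)
        elif scheme == "neurotox":
            labels.append(rec.neurotoxicity)
        else:  # relapse180
            if relapse_base == "day28":
                responder = rec.response_day28 == "R"
            elif relapse_base == "day90":
                responder = rec.response_day90 == "R"
            elif relapse_base == "any":
                responder = "R" in (rec.response_day28, rec.response_day90)
            else:
                raise ValueError("relapse_base must be 'day28', 'day90' or 'any'")
            if not responder or rec.relapse_day180 == "na":
                labels.append(None)
            else:
                labels.append(rec.relapse_day180)

    present = sorted({lab for lab in labels if lab is not None})
    if len(present) < 2:
        raise ValueError(
            f"scheme {scheme!r} produced fewer than two non-empty groups "
            f"(found {present})"
        )
    return labels


def rank_sum_test(group_a, group_b, method: str = "auto") -> tuple:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``method='auto'`` uses the exact null distribution when the combined
    sample is small (<= 12) and tie-free, and the normal approximation
    with tie and continuity corrections otherwise.  Returns the
    Mann-Whitney U statistic for the first group and the two-sided p.
    If every value in both groups is identical the test is degenerate
    and (U, 1.0) is returned.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups need at least one value")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(combined).size < combined.size
    if method == "auto":
        method = "exact" if (combined.size <= EXACT_LIMIT and not has_ties) else "asymptotic"
    if method == "exact" and has_ties:
        raise ValueError("exact method is not defined with ties")
    res = stats.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def rank_biserial(group_a, group_b) -> float:
    """Rank-biserial correlation magnitude, |1 - 2U/(n_a*n_b)|."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
    return float(abs(1.0 - 2.0 * u / (a.size * b.size)))


def effect_size(
    group_a,
    group_b,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple:
    """Rank-biserial effect-size magnitude with a bootstrap percentile CI.

    Groups are resampled independently with replacement; the CI is the
    percentile interval of the resampled estimates.  Degenerate groups
    (no variation anywhere) yield (0.0, None).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least two values")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return 0.0, None
    estimate = rank_biserial(a, b)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = rng.choice(a, size=a.size, replace=True)
        rb = rng.choice(b, size=b.size, replace=True)
        boots[i] = rank_biserial(ra, rb)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return estimate, (float(lo), float(hi))


def composition_correlation(values, composition) -> tuple:
    """Spearman rank correlation between a parameter and a composition
    variable (e.g. CD4:CD8 ratio), two-sided and unadjusted."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(composition, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired observations")
    if np.all(y == y[0]):
        raise ValueError("composition variable is constant; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def run_cohort_analysis(
    params_table: pd.DataFrame,
    outcomes: Sequence[OutcomeRecord],
    schemes: Iterable[str] = SCHEMES,
    parameters: Iterable[str] = COMPARED_PARAMETERS,
    disease_subset: str | None = None,
    relapse_base: str = "any",
    n_boot: int = 2000,
    seed: int = 0,
    adjust: bool = False,
) -> list:
    """Run every scheme-by-parameter comparison for a fitted cohort.

    ``params_table`` has one row per product with parameter columns; rows
    align with ``outcomes``.  Comparisons whose groups are empty or too
    small are recorded as skipped rather than failing the whole run.
    ``adjust=True`` appends Benjamini-Hochberg adjusted p-values (the
    default keeps unadjusted p-values only).
    """
    if len(params_table) != len(outcomes):
        raise ValueError("params_table rows must align with outcomes")
    results: list = []
    for scheme in schemes:
        try:
            labels = assign_groups(outcomes, scheme, disease_subset, relapse_base)
        except ValueError as exc:
            for parameter in parameters:
                results.append(CohortComparison(
                    parameter=parameter, grouping=scheme, group_a="", group_b="",
                    n_a=0, n_b=0, statistic=None, p_value=None, effect_size=None,
                    effect_ci=None, test="wilcoxon-rank-sum",
                    skipped_reason=str(exc),
                ))
            continue
        groups = sorted({lab for lab in labels if lab is not None})
        g_a, g_b = groups[0], groups[1]
        mask_a = np.array([lab == g_a for lab in labels])
        mask_b = np.array([lab == g_b for lab in labels])
        for parameter in parameters:
            values = params_table[parameter].to_numpy(dtype=float)
            a, b = values[mask_a], values[mask_b]
            if a.size < 2 or b.size < 2:
                results.append(CohortComparison(
                    parameter=parameter, grouping=scheme, group_a=g_a, group_b=g_b,
                    n_a=int(a.size), n_b=int(b.size), statistic=None, p_value=None,
                    effect_size=None, effect_ci=None, test="wilcoxon-rank-sum",
                    skipped_reason="fewer than two products in a group",
                ))
                continue
            stat, p = rank_sum_test(a, b)
            es, ci = effect_size(a, b, n_boot=n_boot, seed=seed)
            results.append(CohortComparison(
                parameter=parameter, grouping=scheme, group_a=g_a, group_b=g_b,
                n_a=int(a.size), n_b=int(b.size), statistic=stat, p_value=p,
                effect_size=es, effect_ci=ci, test="wilcoxon-rank-sum",
            ))
    if adjust:
        tested = [r for r in results if r.p_value is not None]
        adjusted = benjamini_hochberg([r.p_value for r in tested])
        lookup = {id(r): q for r, q in zip(tested, adjusted)}
        results = [
            (r if id(r) not in lookup else CohortComparison(
                **{**asdict(r), "test": r.test + "+BH",
                   "p_value": float(lookup[id(r)])}))
            for r in results
        ]
    return results


def comparisons_to_frame(comparisons: Sequence[CohortComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        row = asdict(c)
        ci = row.pop("effect_ci")
        row["ci_lo"] = None if ci is None else ci[0]
        row["ci_hi"] = None if ci is None else ci[1]
        rows.append(row)
    return pd.DataFrame(rows)
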