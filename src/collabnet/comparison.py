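"""Pre/intra period hypothesis tests and outcome comparison.

Three designs are implemented:

* **specialty level** — for each (specialty, metric) pair, the per-clinician
  values of that metric in the pre-period network are compared against the
  per-clinician values in the intra-period network (two independent arrays,
  Mann-Whitney U).  With the default six specialties and three metrics this
  is a family of 18 tests, Bonferroni-corrected with m = tests actually run.
* **network level** — for each metric, the array of per-specialty mean
  values (one cell per specialty) in the pre network is compared against the
  same array for the intra network; family of 3.
* **outcomes** — Mann-Whitney on length of stay between the two patient
  cohorts, plus a descriptive table of sex, race, ethnicity and discharge
  disposition counts and percentages per period.

Mann-Whitney U uses midranks for ties; the p-value is exact (full
enumeration of labelings) when both samples have n ≤ 8 and there are no
ties, and otherwise a normal approximation with tie-corrected variance and
continuity correction.  All tests are two-sided at α = 0.05 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sociometrics import METRICS

logger = logging.getLogger(__name__)

#: The six specialties of interest, in reporting order.
DEFAULT_SPECIALTIES: tuple[str, ...] = (
    "nicu_nurse",
    "nurse_practitioner",
    "resident",
    "respiratory_therapist",
    "cardiac_icu_nurse",
    "neonatologist",
)

_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of x, p-value).

    ``method='auto'`` uses exact enumeration when both samples have n ≤ 8
    and the pooled data is tie-free, else the tie-corrected normal
    approximation with continuity correction.  ``'exact'`` and ``'normal'``
    force the respective computation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    if method == "auto":
        pooled = np.concatenate([x, y])
        tie_free = len(np.unique(pooled)) == pooled.size
        method = "exact" if (x.size <= 8 and y.size <= 8 and tie_free) else "normal"
    scipy_method = {"exact": "exact", "normal": "asymptotic"}.get(method)
    if scipy_method is None:
        raise ValueError(f"method must be auto|exact|normal, got {method!r}")
    res = stats.mannwhitneyu(
        x, y, alternative=_ALTERNATIVES[alternative], method=scipy_method,
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m · p_raw)."""
    return min(1.0, m * p_raw)


@dataclass
class ComparisonResult:
    """One hypothesis test in a correction family."""

    design: str                      # specialty_level | network_level | outcome
    metric: str                      # eigenvector | betweenness | eccentricity | los
    specialty: str | None
    n_pre: int
    n_intra: int
    median_pre: float
    median_intra: float
    u_statistic: float
    p_raw: float
    m: int = 1
    p_adjusted: float = field(default=np.nan)
    alpha: float = 0.05

    def finalize(self, m: int) -> "ComparisonResult":
        self.m = m
        self.p_adjusted = bonferroni(self.p_raw, m)
        return self

    @property
    def significant(self) -> bool:
        return bool(self.p_adjusted < self.alpha)


def results_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tabulate results as the canonical comparison CSV layout."""
    return pd.DataFrame(
        [
            {
                "design": r.design,
                "metric": r.metric,
                "specialty": r.specialty if r.specialty is not None else "",
                "n_pre": r.n_pre,
                "n_intra": r.n_intra,
                "median_pre": r.median_pre,
                "median_intra": r.median_intra,
                "U": r.u_statistic,
                "p_raw": r.p_raw,
                "m": r.m,
                "p_adjusted": r.p_adjusted,
            }
            for r in results
        ]
    )


def _one_test(design, metric, specialty, x, y, alternative) -> ComparisonResult:
    u, p = mann_whitney_u(x, y, alternative=alternative)
    return ComparisonResult(
        design=design, metric=metric, specialty=specialty,
        n_pre=len(x), n_intra=len(y),
        median_pre=float(np.median(x)), median_intra=float(np.median(y)),
        u_statistic=u, p_raw=p,
    )


def specialty_level_compare(
    table_pre: pd.DataFrame,
    table_intra: pd.DataFrame,
    specialties: Sequence[str] = DEFAULT_SPECIALTIES,
    alternative: str = "two_sided",
) -> list[ComparisonResult]:
    """One Mann-Whitney test per (specialty × metric).

    A specialty absent from either period is skipped with a logged reason
    and the Bonferroni family size m shrinks accordingly; m is the number
    of tests actually run.
    """
    results: list[ComparisonResult] = []
    for spec in specialties:
        pre = table_pre[table_pre["specialty"] == spec]
        intra = table_intra[table_intra["specialty"] == spec]
        if pre.empty or intra.empty:
            logger.warning(
                "specialty_level_compare: skipping %r (n_pre=%d, n_intra=%d)",
                spec, len(pre), len(intra),
            )
            continue
        for metric in METRICS:
            results.append(
                _one_test("specialty_level", metric, spec,
                          pre[metric].to_numpy(), intra[metric].to_numpy(),
                          alternative)
            )
    m = len(results)
    for r in results:
        r.finalize(m)
    return results


def network_level_compare(
    table_pre: pd.DataFrame,
    table_intra: pd.DataFrame,
    alternative: str = "two_sided",
) -> list[ComparisonResult]:
    """Whole-network comparison over arrays of specialty means.

    For each metric the test compares one array per period whose cells are
    the mean metric value of each specialty present in that period's
    network.  Requires at least two specialties per period; m = 3.
    """
    results: list[ComparisonResult] = []
    for table in (table_pre, table_intra):
        if table["specialty"].nunique() < 2:
            raise ValueError("network_level_compare requires >= 2 specialties "
                             "in each period")
    for metric in METRICS:
        means_pre = table_pre.groupby("specialty")[metric].mean().to_numpy()
        means_intra = table_intra.groupby("specialty")[metric].mean().to_numpy()
        results.append(
            _one_test("network_level", metric, None, means_pre, means_intra,
                      alternative)
        )
    for r in results:
        r.finalize(len(results))
    return results


_CATEGORICALS = {
    "sex": ("female", "male", "unknown"),
    "race": ("white", "african_american", "asian", "other"),
    "ethnicity": ("non_hispanic", "latino", "unknown"),
    "disposition": ("home", "expired", "hospice", "short_term_hospital", "other"),
}


def outcomes_compare(
    patients_pre: pd.DataFrame,
    patients_intra: pd.DataFrame,
    alternative: str = "two_sided",
) -> tuple[list[ComparisonResult], pd.DataFrame]:
    """Length-of-stay test plus the descriptive cohort table.

    Returns the (single-member, m=1) family containing the Mann-Whitney
    test on LOS, and a descriptive frame of counts and percentages for sex,
    race, ethnicity and discharge disposition per period, with LOS and age
    median (IQR) rows.
    """
    los_pre = patients_pre["los_days"].to_numpy(dtype=float)
    los_intra = patients_intra["los_days"].to_numpy(dtype=float)
    res = _one_test("outcome", "los", None, los_pre, los_intra, alternative)
    res.finalize(1)

    rows = []
    n_pre, n_intra = len(patients_pre), len(patients_intra)
    for col in ("los_days", "age_days"):
        stats_ = []
        for tab in (patients_pre, patients_intra):
            v = tab[col].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(v, [25, 50, 75]) if len(v) else (np.nan,) * 3
            stats_.append(f"{med:.1f} ({q1:.1f}-{q3:.1f})")
        rows.append({"characteristic": col, "level": "median (IQR)",
                     "pre": stats_[0], "intra": stats_[1]})
    for col, levels in _CATEGORICALS.items():
        for lev in levels:
            c_pre = int((patients_pre[col] == lev).sum())
            c_intra = int((patients_intra[col] == lev).sum())
            rows.append({
                "characteristic": col, "level": lev,
                "pre": f"{c_pre} ({100 * c_pre / max(n_pre, 1):.1f})",
                "intra": f"{c_intra} ({100 * c_intra / max(n_intra, 1):.1f})",
            })
    return [res], pd.DataFrame(rows)


def text_report(
    results: Sequence[ComparisonResult],
    descriptive: pd.DataFrame | None = None,
) -> str:
    """Human-readable report of all comparison families."""
    lines = ["Collaboration-network period comparison", "=" * 40, ""]
    df = results_frame(list(results))
    for design, block in df.groupby("design", sort=False):
        lines.append(f"[{design}]  (Bonferroni m = {int(block['m'].iloc[0])})")
        for row in block.itertuples(index=False):
            star = " *" if row.p_adjusted < 0.05 else ""
            spec = f" {row.specialty}" if row.specialty else ""
            lines.append(
                f"  {row.metric:<12}{spec:<22} "
                f"median {row.median_pre:.4g} vs {row.median_intra:.4g}  "
                f"U={row.U:.1f}  p={row.p_raw:.3g}  "
                f"p_adj={row.p_adjusted:.3g}{star}"
            )
        lines.append("")
    if descriptive is not None:
        lines.append("[cohort characteristics]")
        lines.append(descriptive.to_string(index=False))
        lines.append("")
    return "\n".join(lines)
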