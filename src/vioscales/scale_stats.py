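"""Characterization of the 0-6 scales.

Descriptive medians/IQR per violence-situation profile, nonparametric
between-physician comparisons (Kruskal-Wallis global test with tie
correction, Conover-Iman pairwise post-hoc on the shared pooled ranking,
Bonferroni adjustment), and univariate linear regressions of days of total
incapacity to work (TIW) on each scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata, t as t_dist

from .cohort import Cohort, SCALE_COLUMNS, SYMPTOM_COLUMNS

__all__ = [
    "TestResult",
    "RegressionResult",
    "describe_by_profile",
    "kruskal_wallis",
    "conover_posthoc",
    "ols_univariate",
    "physician_rating_comparison",
]


@dataclass
class TestResult:
    statistic: float
    df: object
    p_raw: float
    p_adjusted: float | None = None


@dataclass
class RegressionResult:
    """Univariate OLS slope of TIW (days) per scale point, with 95% CI."""

    scale: str
    beta: float
    ci_low: float
    ci_high: float
    n: int


def describe_by_profile(cohort: Cohort, labels) -> pd.DataFrame:
    """Median (IQR) of every scale and symptom counts (%) per profile.

    One row per scale/symptom, one column per profile plus ``all``.  IQR is
    the 25th-75th percentile with linear interpolation.  Empty cells are
    flagged as ``""``.
    """
    df = cohort.df
    lab = np.asarray(labels)
    groups = {str(c): df[lab == c] for c in pd.unique(lab[~pd.isna(lab)])}
    groups = dict(sorted(groups.items()))
    groups["all"] = df
    rows = []
    for scale in SCALE_COLUMNS:
        row: dict[str, object] = {"variable": scale, "type": "scale"}
        for name, g in groups.items():
            vals = pd.to_numeric(g[scale], errors="coerce").dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                row[name] = ""
            else:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                row[name] = f"{med:g} ({q1:g}-{q3:g})"
        rows.append(row)
    for col in SYMPTOM_COLUMNS:
        if col not in df.columns:
            continue
        row = {"variable": col, "type": "symptom"}
        for name, g in groups.items():
            vals = pd.to_numeric(g[col], errors="coerce").dropna()
            if len(vals) == 0:
                row[name] = ""
            else:
                cnt = int(vals.sum())
                row[name] = f"{cnt} ({100.0 * cnt / len(vals):.1f}%)"
        rows.append(row)
    return pd.DataFrame(rows)


def _pooled_ranks(groups: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled, method="average")
    sizes = np.array([len(g) for g in groups])
    return ranks, sizes


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with the chi-square approximation.

    H is divided by ``1 - sum(t^3 - t) / (N^3 - N)``; if every pooled value
    is identical the statistic is 0 and p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n_total = int(sum(len(g) for g in groups))
    if n_total < 3 or any(len(g) == 0 for g in groups):
        raise ValueError("need nonempty groups with total N >= 3")
    ranks, sizes = _pooled_ranks(groups)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    h = 0.0
    for i in range(len(groups)):
        r = ranks[offsets[i]:offsets[i + 1]]
        h += r.sum() ** 2 / sizes[i]
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(np.concatenate(groups), return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    correction = 1.0 - tie_sum / (n_total**3 - n_total)
    if correction <= 0:  # all values identical
        return TestResult(statistic=0.0, df=len(groups) - 1, p_raw=1.0)
    h /= correction
    dof = len(groups) - 1
    return TestResult(statistic=float(h), df=dof, p_raw=float(chi2.sf(h, dof)))


def conover_posthoc(groups: Sequence[Sequence[float]], adjust: bool = True) -> pd.DataFrame:
    """Conover-Iman pairwise comparisons after Kruskal-Wallis.

    Uses the same pooled tie-corrected ranking as the global test:

        t_ij = (Rbar_i - Rbar_j) / sqrt(S^2 ((N-1-H)/(N-k)) (1/n_i + 1/n_j))

    with ``S^2 = (sum R_l^2 - N (N+1)^2 / 4) / (N - 1)`` over the pooled
    ranks and two-sided p from Student t with N - k degrees of freedom.
    Bonferroni multiplies p by the number of pairs, capped at 1.

    Raises
    ------
    ValueError
        If ``N - 1 - H <= 0``, which leaves the pairwise statistic undefined.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    global_test = kruskal_wallis(groups)
    h = global_test.statistic
    ranks, sizes = _pooled_ranks(groups)
    n_total = int(sizes.sum())
    if n_total - 1 - h <= 0:
        raise ValueError("Conover statistic undefined: N - 1 - H <= 0")
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4.0) / (n_total - 1)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = [
        ranks[offsets[i]:offsets[i + 1]].mean() for i in range(k)
    ]
    dof = n_total - k
    scale_factor = s2 * (n_total - 1 - h) / dof
    n_pairs = k * (k - 1) // 2
    rows = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(scale_factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            t_stat = 0.0
        else:
            t_stat = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = float(2.0 * t_dist.sf(abs(t_stat), dof))
        p_adj = min(1.0, n_pairs * p_raw) if adjust else None
        rows.append(
            {
                "group_i": i,
                "group_j": j,
                "statistic": float(t_stat),
                "df": dof,
                "p_raw": p_raw,
                "p_adjusted": p_adj,
            }
        )
    return pd.DataFrame(rows)


def ols_univariate(cohort: Cohort | pd.DataFrame, scale: str,
                   outcome: str = "tiw_days") -> RegressionResult:
    """Univariate least-squares regression of the outcome on one scale.

    Complete-case: rows with a missing scale or outcome are dropped.  The
    CI is normal-theory 95%.
    """
    import statsmodels.api as sm

    df = cohort.df if isinstance(cohort, Cohort) else cohort
    x = pd.to_numeric(df[scale], errors="coerce")
    y = pd.to_numeric(df[outcome], errors="coerce")
    keep = x.notna() & y.notna()
    x, y = x[keep].astype(float), y[keep].astype(float)
    if len(x) < 3:
        raise ValueError(f"need >=3 complete ({scale}, {outcome}) pairs, got {len(x)}")
    if x.nunique() < 2:
        raise ValueError(f"scale {scale!r} has zero variance among complete cases")
    model = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
    beta = float(model.params[1])
    ci = model.conf_int(alpha=0.05)
    return RegressionResult(
        scale=scale,
        beta=beta,
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        n=int(len(x)),
    )


def physician_rating_comparison(
    cohort: Cohort,
    labels,
    scale: str,
    alpha: float = 0.05,
) -> dict:
    """Compare one scale's ratings across physicians, overall and per profile.

    Runs the Kruskal-Wallis global test and the Bonferroni-adjusted Conover
    post-hoc across physicians on the whole cohort, then stratified within
    each violence-situation profile.  Returns the test results plus counts
    of significant physician pairs, exposing how much apparent
    between-physician disagreement is explained by case-mix differences.
    """
    df = cohort.df
    lab = np.asarray(labels)
    scores = pd.to_numeric(df[scale], errors="coerce")
    physicians = sorted(df["physician_id"].dropna().unique().tolist())
    if len(physicians) < 2:
        raise ValueError("need at least 2 physicians")

    def _strata_result(mask: np.ndarray) -> dict | None:
        present = []
        phys_used = []
        for p in physicians:
            vals = scores[(df["physician_id"] == p).to_numpy() & mask].dropna().to_numpy()
            if len(vals) >= 2:
                present.append(vals)
                phys_used.append(p)
        if len(present) < 2:
            return None
        global_test = kruskal_wallis(present)
        try:
            pairwise = conover_posthoc(present, adjust=True)
        except ValueError:
            pairwise = pd.DataFrame()
        if len(pairwise):
            pairwise = pairwise.assign(
                physician_i=[phys_used[i] for i in pairwise["group_i"]],
                physician_j=[phys_used[j] for j in pairwise["group_j"]],
            )
            n_sig = int((pairwise["p_adjusted"] < alpha).sum())
        else:
            n_sig = 0
        return {
            "global": global_test,
            "pairwise": pairwise,
            "n_significant_pairs": n_sig,
            "n_pairs": len(pairwise),
            "physicians": phys_used,
        }

    overall = _strata_result(np.ones(len(df), dtype=bool))
    per_profile = {}
    for c in pd.unique(lab[~pd.isna(lab)]):
        res = _strata_result(lab == c)
        if res is not None:
            per_profile[c] = res
    return {"scale": scale, "overall": overall, "per_profile": per_profile, "alpha": alpha}
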