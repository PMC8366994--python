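"""Cohort-level statistics for quantitative inclusion analysis.

Covers the study's statistics layer:

* Lin's concordance correlation coefficient (agreement between the
  automated and manual measurement methods), with a Fisher-z 95% CI.
* "High accumulator" classification: Tukey upper-fence outliers
  (value >= Q3 + 1.5*IQR) plus quartile labels.
* Normality-gated group comparisons: D'Agostino-Pearson per group, then
  Mann-Whitney U (2 groups) or Kruskal-Wallis with Dunn's multiple
  comparisons (>= 3 groups); an optional log10 path runs one-way ANOVA
  with Tukey's HSD on log-transformed values (zeros excluded, logged).
* Cohort summaries: median/IQR (or mean +/- SD where Gaussian) per
  stratum with fold changes between adjacent ordered strata.

Dunn's post-hoc z-test is implemented here directly (rank-sum z with tie
correction); Kruskal-Wallis, Mann-Whitney, ANOVA, Tukey HSD and the
D'Agostino-Pearson omnibus test come from scipy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Canonical cohort-table columns.  External tables (CSV/XLSX) are bound
#: to these names via a column-mapping config, so arbitrary supplementary
#: headers can be consumed without code changes.
COHORT_COLUMNS = {
    "subject_id": str,
    "sex": str,  # M | F
    "metavir": int,  # 0..4
    "pasd_pct_area": float,
    "polymer_pct_area": float,
    "total_pct_area": float,
    "mean_globule_size_um2": float,
    "globules_per_mm2": float,
    "degeneration": bool,
    "foci_per_mm2": float,
}
_REQUIRED = ["subject_id", "sex", "metavir", "pasd_pct_area"]


def load_cohort_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a per-subject cohort table from CSV or XLSX.

    ``column_map`` maps canonical names (keys of :data:`COHORT_COLUMNS`)
    to the file's actual headers.  Missing optional columns are allowed;
    missing required ones raise.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        inv = {src: dst for dst, src in column_map.items()}
        df = df.rename(columns=inv)
    df = df[[c for c in COHORT_COLUMNS if c in df.columns]]
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    if df["subject_id"].duplicated().any():
        raise ValueError("cohort table has duplicate subject ids")
    stages = pd.to_numeric(df["metavir"], errors="raise")
    if not stages.isin(range(5)).all():
        raise ValueError("metavir stages must be in 0..4")
    for col in df.columns:
        if COHORT_COLUMNS[col] is float:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    neg = [
        c for c in df.columns
        if c.endswith("pct_area") and (df[c].dropna() < 0).any()
    ]
    if neg:
        raise ValueError(f"negative percentages in columns: {neg}")
    return df.reset_index(drop=True)


# --- Lin's concordance correlation coefficient -------------------------


def lin_ccc(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    ``rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)`` using
    population (1/n) moments.  The confidence interval applies Lin's
    asymptotic variance to the z-transform of ``rho_c``.

    Degenerate inputs: two constant, equal vectors agree perfectly
    (``rho_c = 1``); a constant paired against a varying vector has no
    covariance (``rho_c = 0``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")

    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        return 1.0, 1.0, 1.0  # both constant with equal means
    ccc = 2 * sxy / denom

    # Lin (1989) variance of the z-transformed CCC
    if sx2 > 0 and sy2 > 0 and abs(ccc) < 1:
        r = sxy / np.sqrt(sx2 * sy2)
        u2 = (mx - my) ** 2 / np.sqrt(sx2 * sy2)
        if r != 0:
            var_z = (
                (1 - r**2) * ccc**2 / ((1 - ccc**2) * r**2)
                + 2 * ccc**3 * (1 - ccc) * u2 / (r * (1 - ccc**2) ** 2)
                - ccc**4 * u2**2 / (2 * r**2 * (1 - ccc**2) ** 2)
            ) / (n - 2)
            var_z = max(var_z, 0.0)
            z = np.arctanh(np.clip(ccc, -1 + 1e-12, 1 - 1e-12))
            zcrit = sps.norm.ppf(1 - alpha / 2)
            lo = float(np.tanh(z - zcrit * np.sqrt(var_z)))
            hi = float(np.tanh(z + zcrit * np.sqrt(var_z)))
            return float(ccc), lo, hi
    return float(ccc), float(ccc), float(ccc)


# --- high-accumulator classification ----------------------------------


@dataclass
class AccumulatorClassification:
    """Quartile labels and Tukey upper-fence outlier flags."""

    q1: float
    median: float
    q3: float
    iqr: float
    upper_fence: float
    quartile_labels: list[str]  # per subject, "Q1".."Q4"
    outlier_flags: list[bool]

    @property
    def n_outliers(self) -> int:
        return int(sum(self.outlier_flags))


def classify_accumulators(
    values: Sequence[float],
) -> AccumulatorClassification:
    """Partition subjects into quartiles and flag high accumulators.

    Quartiles use linear-interpolation quantiles (numpy's default,
    R type 7).  The upper fence is ``Q3 + 1.5 * IQR`` and values at or
    above it are flagged.  Zero-IQR guard: when all quartiles collapse
    no subject is flagged (otherwise every subject would be).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 4:
        raise ValueError("need at least 4 values")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    fence = q3 + 1.5 * iqr
    if iqr > 0:
        flags = (v >= fence).tolist()
    else:
        flags = [False] * v.size
    labels = []
    for val in v:
        if val <= q1:
            labels.append("Q1")
        elif val <= med:
            labels.append("Q2")
        elif val <= q3:
            labels.append("Q3")
        else:
            labels.append("Q4")
    return AccumulatorClassification(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        iqr=float(iqr),
        upper_fence=float(fence),
        quartile_labels=labels,
        outlier_flags=flags,
    )


# --- group comparisons -------------------------------------------------


@dataclass
class GroupComparison:
    """Result of a normality-gated comparison across groups."""

    test: str  # kruskal_wallis | mann_whitney | anova_log10
    statistic: float
    p_value: float
    groups: list[str]
    group_sizes: dict[str, int]
    normality: dict[str, float]  # group -> D'Agostino-Pearson p (NaN if n<8)
    posthoc: list[dict] = field(default_factory=list)
    n_zeros_excluded: int = 0


def dunn_posthoc(
    samples: Mapping[str, np.ndarray], adjust: str | None = None
) -> list[dict]:
    """Dunn's multiple-comparison z-test after Kruskal-Wallis.

    Ranks are pooled over all groups; for groups i, j the statistic is
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))``
    with tie correction ``T = sum(t^3 - t) / (12 (N - 1))``.  P-values
    are two-sided normal; ``adjust="bonferroni"`` multiplies by the
    number of pairs.
    """
    names = list(samples)
    pooled = np.concatenate([samples[g] for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))

    mean_ranks, sizes, idx = {}, {}, 0
    for g in names:
        n_g = samples[g].size
        mean_ranks[g] = ranks[idx : idx + n_g].mean()
        sizes[g] = n_g
        idx += n_g

    pairs = list(combinations(names, 2))
    out = []
    for a, b in pairs:
        se = np.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * len(pairs))
        out.append(
            {"group_a": a, "group_b": b, "z": float(z), "p_adj": float(p)}
        )
    return out


def compare_groups(
    table: pd.DataFrame,
    value_col: str,
    group_col: str,
    log10_anova: bool = False,
    dunn_adjust: str | None = None,
) -> GroupComparison:
    """Compare a measurement across groups with the study's test battery.

    Runs D'Agostino-Pearson normality per group (reported, not gating
    the nonparametric path), then Mann-Whitney U for two groups or
    Kruskal-Wallis (tie-corrected) with Dunn's post-hoc for three or
    more.  With ``log10_anova`` the values are log10-transformed (zeros
    excluded with a logged count) and analysed by one-way ANOVA with
    Tukey's HSD instead.
    """
    sub = table[[value_col, group_col]].dropna()
    grouped = {
        str(g): np.asarray(vals[value_col], dtype=float)
        for g, vals in sub.groupby(group_col, sort=True)
    }
    grouped = {g: v for g, v in grouped.items() if v.size > 0}
    if len(grouped) < 2:
        raise ValueError("need at least 2 non-empty groups")
    small = [g for g, v in grouped.items() if v.size < 2]
    if small:
        raise ValueError(f"groups with n < 2: {small}")

    normality = {}
    for g, v in grouped.items():
        if v.size >= 8:
            normality[g] = float(sps.normaltest(v).pvalue)
        else:
            normality[g] = float("nan")  # omnibus test needs n >= 8

    names = list(grouped)
    n_zeros = 0
    if log10_anova:
        logged = {}
        for g, v in grouped.items():
            keep = v > 0
            n_zeros += int((~keep).sum())
            logged[g] = np.log10(v[keep])
        if n_zeros:
            logger.info(
                "log10 path excluded %d zero values in %s", n_zeros, value_col
            )
        bad = [g for g, v in logged.items() if v.size < 2]
        if bad:
            raise ValueError(f"groups with n < 2 after zero exclusion: {bad}")
        stat, p = sps.f_oneway(*logged.values())
        tk = sps.tukey_hsd(*logged.values())
        posthoc = [
            {
                "group_a": names[i],
                "group_b": names[j],
                "p_adj": float(tk.pvalue[i, j]),
            }
            for i, j in combinations(range(len(names)), 2)
        ]
        return GroupComparison(
            test="anova_log10",
            statistic=float(stat),
            p_value=float(p),
            groups=names,
            group_sizes={g: int(v.size) for g, v in logged.items()},
            normality=normality,
            posthoc=posthoc,
            n_zeros_excluded=n_zeros,
        )

    if len(grouped) == 2:
        a, b = grouped.values()
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison(
            test="mann_whitney",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            groups=names,
            group_sizes={g: int(v.size) for g, v in grouped.items()},
            normality=normality,
        )

    pooled = np.concatenate(list(grouped.values()))
    if np.all(pooled == pooled[0]):  # scipy rejects the all-tied case
        stat, p = 0.0, 1.0
        posthoc = [
            {"group_a": a, "group_b": b, "z": 0.0, "p_adj": 1.0}
            for a, b in combinations(names, 2)
        ]
    else:
        stat, p = sps.kruskal(*grouped.values())
        posthoc = dunn_posthoc(grouped, adjust=dunn_adjust)
    return GroupComparison(
        test="kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
        groups=names,
        group_sizes={g: int(v.size) for g, v in grouped.items()},
        normality=normality,
        posthoc=posthoc,
    )


# --- cohort summaries --------------------------------------------------


def summarize_cohort(
    table: pd.DataFrame,
    value_col: str,
    stratify_by: str,
) -> pd.DataFrame:
    """Per-stratum summary with fold changes between adjacent strata.

    Each stratum reports n, median and IQR; columns whose pooled values
    pass D'Agostino-Pearson normality (p > 0.05) additionally report
    mean +/- SD as the primary location/scale.  ``fold_change`` is the
    ratio of a stratum's median to the previous (ordered) stratum's.
    Empty strata are omitted with a warning.
    """
    sub = table[[value_col, stratify_by]].dropna()
    rows = []
    prev_median = None
    for stratum, vals in sub.groupby(stratify_by, sort=True):
        v = np.asarray(vals[value_col], dtype=float)
        if v.size == 0:
            logger.warning("stratum %s empty for %s; omitted", stratum, value_col)
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        gaussian = False
        if v.size >= 8:
            gaussian = sps.normaltest(v).pvalue > 0.05
        fold = float(med / prev_median) if prev_median not in (None, 0) else np.nan
        rows.append(
            {
                "stratum": stratum,
                "n": int(v.size),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "gaussian": gaussian,
                "fold_change": fold,
            }
        )
        prev_median = med
    return pd.DataFrame(rows)
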