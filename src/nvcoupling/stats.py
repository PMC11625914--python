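"""Cohort statistics: progression stratification, group-effect scan with FDR,
cognition correlations, ROC discrimination, and summary-statistics utilities.

The group-effect model per NVC column is NVC ~ group + age + sex.  With one
observation per subject per column this is an ordinary least-squares fit; the
group effect is tested with a partial F comparing the nested model without
the group factor.  FDR is Benjamini-Hochberg within one matrix's columns.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.metrics import roc_curve

from .types import DegeneracyError, NvcMatrix

PROGRESSION_LABELS = ("VFP", "FP", "SP")  # most to least negative centroid


# --------------------------------------------------------------------------
# progression stratification
# --------------------------------------------------------------------------

@dataclass
class ProgressionAssignment:
    labels: np.ndarray          # per-patient label from PROGRESSION_LABELS
    centroids: np.ndarray       # ascending (most negative first)
    sizes: np.ndarray
    monthly_rates: np.ndarray   # centroid / 12

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster": PROGRESSION_LABELS,
            "centroid": self.centroids,
            "n": self.sizes,
            "monthly_rate": self.monthly_rates,
        })


def monthly_rate(delta_alsfrs: float, months: float = 12.0) -> float:
    """Convert a 12-month ALSFRS-R change to points/month."""
    return delta_alsfrs / months


def cluster_progression(delta: np.ndarray, k: int = 3,
                        seed: int = 0) -> ProgressionAssignment:
    """1-D k-means stratification of ΔALSFRS-R into VFP/FP/SP.

    k-means++ initialization with 100 restarts and a fixed seed; cluster
    labels are assigned by ascending centroid (most negative = VFP).
    """
    delta = np.asarray(delta, dtype=float)
    if np.unique(delta).size < k:
        raise DegeneracyError(f"fewer than {k} distinct values for {k}-means")
    km = KMeans(n_clusters=k, init="k-means++", n_init=100, random_state=seed)
    raw = km.fit_predict(delta.reshape(-1, 1))
    centroids = km.cluster_centers_.ravel()
    order = np.argsort(centroids)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    idx = relabel[raw]
    names = np.asarray(PROGRESSION_LABELS if k == 3 else
                       [f"C{i}" for i in range(k)])
    return ProgressionAssignment(
        labels=names[idx],
        centroids=centroids[order],
        sizes=np.bincount(idx, minlength=k),
        monthly_rates=centroids[order] / 12.0,
    )


def optimal_1d_partition(values: np.ndarray, k: int = 3) -> tuple[np.ndarray, float]:
    """Exhaustive optimal k-cluster partition of sorted 1-D data.

    Optimal 1-D k-means partitions are contiguous in sorted order; this
    enumerates all contiguous splits and returns (labels in original order,
    within-cluster sum of squares). Independent oracle for cluster_progression.
    """
    values = np.asarray(values, dtype=float)
    order = np.argsort(values)
    x = values[order]
    n = len(x)

    def wss(seg):
        return float(np.sum((seg - seg.mean()) ** 2))

    from itertools import combinations
    best, best_cuts = np.inf, None
    for cuts in combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        total = sum(wss(x[bounds[i]:bounds[i + 1]]) for i in range(k))
        if total < best:
            best, best_cuts = total, bounds
    lab_sorted = np.empty(n, dtype=int)
    for i in range(k):
        lab_sorted[best_cuts[i]:best_cuts[i + 1]] = i
    labels = np.empty(n, dtype=int)
    labels[order] = lab_sorted
    return labels, best


# --------------------------------------------------------------------------
# group-effect scan
# --------------------------------------------------------------------------

@dataclass
class GroupEffectResult:
    table: pd.DataFrame  # per unit: F, p, q, significant, n
    model: str
    excluded: dict = field(default_factory=dict)

    @property
    def significant_units(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()


def _encode_design(group: pd.Series, age: pd.Series, sex: pd.Series
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    """Full and reduced design matrices for NVC ~ group + age + sex."""
    levels = pd.unique(group)
    if len(levels) < 2:
        raise ValueError("need at least 2 group levels")
    g_dummies = pd.get_dummies(pd.Categorical(group), drop_first=True).to_numpy(float)
    sex_num = pd.get_dummies(pd.Categorical(sex), drop_first=True).to_numpy(float)
    n = len(group)
    covars = np.column_stack([np.ones(n), np.asarray(age, float), sex_num])
    full = np.column_stack([covars, g_dummies])
    return full, covars, g_dummies.shape[1]


def partial_f_test(y: np.ndarray, full: np.ndarray, reduced: np.ndarray,
                   df_diff: int) -> tuple[float, float]:
    """Partial F comparing nested OLS fits; returns (F, p)."""
    ok = np.isfinite(y)
    y, full, reduced = y[ok], full[ok], reduced[ok]
    rss_f = _rss(y, full)
    rss_r = _rss(y, reduced)
    df_resid = len(y) - full.shape[1]
    if df_resid <= 0:
        return np.nan, np.nan
    f = ((rss_r - rss_f) / df_diff) / (rss_f / df_resid) if rss_f > 0 else np.inf
    p = float(sps.f.sf(f, df_diff, df_resid)) if np.isfinite(f) else 0.0
    return float(f), p


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def group_effect_scan(matrix: NvcMatrix, clinical: pd.DataFrame,
                      grouping: str = "group", fdr_q: float = 0.05
                      ) -> GroupEffectResult:
    """Per-column test of the group factor in NVC ~ group + age + sex, with
    BH-FDR across the matrix's columns.

    ``clinical`` must be indexed by subject id and contain ``grouping``,
    ``age`` and ``sex`` columns for every matrix row.  Constant columns are
    excluded from the FDR family with a reason.
    """
    clin = clinical.loc[matrix.data.index]
    counts = clin[grouping].value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError(f"need >= 2 subjects in each of >= 2 groups, got {dict(counts)}")
    full, reduced, df_diff = _encode_design(clin[grouping], clin["age"], clin["sex"])
    rows, excluded = [], {}
    for col in matrix.data.columns:
        y = matrix.data[col].to_numpy(float)
        finite = y[np.isfinite(y)]
        if finite.size < full.shape[1] + 1 or np.ptp(finite) == 0:
            excluded[col] = "constant or insufficient data"
            rows.append((col, np.nan, np.nan))
            continue
        f, p = partial_f_test(y, full, reduced, df_diff)
        rows.append((col, f, p))
    table = pd.DataFrame(rows, columns=["unit", "F", "p"]).set_index("unit")
    q, reject = bh_fdr(table["p"].to_numpy(), q=fdr_q)
    table["q"] = q
    table["significant"] = reject
    table["n"] = int(len(clin))
    return GroupEffectResult(
        table=table,
        model=f"NVC ~ {grouping} + age + sex (OLS, partial F, df1={df_diff})",
        excluded=excluded)


def bh_fdr(p: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up. Returns (adjusted q values, reject flags).

    NaN p values are excluded from the family but keep their position
    (NaN adjusted value, False flag).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    adj = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return adj, reject
    ps = p[ok]
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    # enforce monotone non-decreasing adjusted values
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_ok = np.empty(m)
    adj_ok[order] = np.minimum(ranked, 1.0)
    adj[ok] = adj_ok
    reject[ok] = adj_ok <= q
    return adj, reject


# --------------------------------------------------------------------------
# cognition correlations
# --------------------------------------------------------------------------

def correlate_with_scores(nvc_column: pd.Series, scores: pd.DataFrame,
                          fdr_q: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of one NVC column with each cognitive score column.

    Pairwise-complete observations, two-sided p from the t distribution with
    n - 2 df, BH-FDR across the score family.  Returns a DataFrame indexed by
    score name with r, n, p, q, significant (NaN row with reason on zero
    variance or n < 4).
    """
    rows = []
    for name in scores.columns:
        pair = pd.concat([nvc_column, scores[name]], axis=1).dropna()
        n = len(pair)
        if n < 4:
            rows.append((name, np.nan, n, np.nan, "fewer than 4 paired observations"))
            continue
        x, y = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((name, np.nan, n, np.nan, "zero variance"))
            continue
        r, p = sps.pearsonr(x, y)
        rows.append((name, float(r), n, float(p), None))
    out = pd.DataFrame(rows, columns=["score", "r", "n", "p", "reason"]).set_index("score")
    q, reject = bh_fdr(out["p"].to_numpy(), q=fdr_q)
    out["q"] = q
    out["significant"] = reject
    return out


# --------------------------------------------------------------------------
# ROC discrimination
# --------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    ci: tuple[float, float]
    fpr: np.ndarray
    tpr: np.ndarray
    positive_label: object
    method: str

    @property
    def trapezoid_auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray,
                     positive: object) -> float:
    """AUC as the Mann-Whitney U statistic / (n1*n2), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == positive]
    neg = scores[np.asarray(labels) != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def roc_auc(scores: np.ndarray, labels: np.ndarray, positive: object = None,
            n_boot: int = 2000, seed: int = 0, ci_method: str = "bootstrap"
            ) -> RocResult:
    """ROC curve, Mann-Whitney AUC and its confidence interval.

    CI by stratified bootstrap percentile (2.5/97.5) with ``n_boot``
    resamples by default; ``ci_method='delong'`` uses the DeLong asymptotic
    normal interval instead.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if positive is None:
        positive = classes[0]
    auc = mann_whitney_auc(scores, labels, positive)
    y = (labels == positive).astype(int)
    fpr, tpr, _ = roc_curve(y, scores)
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
            ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
            idx = np.concatenate([pi, ni])
            boots[b] = mann_whitney_auc(scores[idx], labels[idx], positive)
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    elif ci_method == "delong":
        ci = _delong_ci(scores, y, auc)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RocResult(auc=auc, ci=ci, fpr=fpr, tpr=tpr,
                     positive_label=positive, method=ci_method)


def _delong_ci(scores: np.ndarray, y: np.ndarray, auc: float,
               level: float = 0.95) -> tuple[float, float]:
    """DeLong variance of the AUC via placement values."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    zq = sps.norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(var)
    return (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))


# --------------------------------------------------------------------------
# summary-statistics utilities (printed-table reconstruction)
# --------------------------------------------------------------------------

@dataclass
class SummaryGroup:
    """Printed (n, mean, SD) triplet of one group cell."""

    n: int
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.sd > 0 and self.n < 2:
            raise ValueError("sd requires n >= 2")


def pooled_mean(groups: list[SummaryGroup]) -> float:
    """n-weighted grand mean of the group means."""
    if not groups:
        raise ValueError("need at least one group")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups])
    return float((n * m).sum() / n.sum())


def anova_from_summary(groups: list[SummaryGroup]
                       ) -> tuple[float, int, int, float]:
    """One-way ANOVA reconstructed from (n, mean, SD) summaries.

    SSB = sum n_g (m_g - grand)^2, SSW = sum (n_g - 1) s_g^2,
    F = (SSB/(G-1)) / (SSW/(N-G)); exact for unrounded summaries.
    Returns (F, df1, df2, p); F is +inf when SSW = 0 with SSB > 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.n < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups])
    s = np.array([g.sd for g in groups])
    grand = (n * m).sum() / n.sum()
    ssb = float((n * (m - grand) ** 2).sum())
    ssw = float(((n - 1) * s ** 2).sum())
    df1, df2 = len(groups) - 1, int(n.sum()) - len(groups)
    if ssw == 0:
        f = np.inf if ssb > 0 else 0.0
    else:
        f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return float(f), df1, df2, p


def chi_square_counts(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared on a contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal in contingency table")
    expected = np.outer(rows, cols) / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, float(sps.chi2.sf(chi2, df))


def tukey_hsd_from_summary(groups: list[SummaryGroup]) -> pd.DataFrame:
    """Pairwise Tukey HSD contrasts from (n, mean, SD) summaries."""
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([g.n for g in groups], dtype=float)
    s = np.array([g.sd for g in groups])
    df2 = int(n.sum()) - k
    msw = float(((n - 1) * s ** 2).sum()) / df2 if df2 > 0 else np.nan
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = groups[i].mean - groups[j].mean
            se = np.sqrt(msw / 2 * (1 / n[i] + 1 / n[j]))
            if se == 0:
                q_stat, p = np.inf if diff != 0 else 0.0, 0.0 if diff != 0 else 1.0
            else:
                q_stat = abs(diff) / se
                p = float(sps.studentized_range.sf(q_stat, k, df2))
            rows.append((i, j, diff, q_stat, p))
    return pd.DataFrame(rows, columns=["group_i", "group_j", "diff", "q", "p"])
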