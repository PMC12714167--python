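"""Group-level statistics: normality-gated omnibus tests, correlations,
differential-expression screening and ROC analysis.

The omnibus test family follows a per-group Shapiro-Wilk gate at alpha 0.05
with an all-groups-pass rule: if every group looks normal, one-way ANOVA
with t-based post hocs; otherwise Kruskal-Wallis with rank-sum post hocs.
Categorical variables route to a chi-square test of independence. Post-hoc
p-values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparisonResult",
    "RocResult",
    "compare_groups",
    "correlate",
    "partial_correlation",
    "deg_overlap",
    "roc_auc",
]

SHAPIRO_ALPHA = 0.05


@dataclass
class GroupComparisonResult:
    variable: str
    test: str  # "anova" | "kruskal" | "chi2"
    statistic: float
    p: float
    df: float | None = None
    posthoc: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class RocResult:
    name: str
    auc: float
    positive_label: object

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")


def _is_categorical(values: np.ndarray) -> bool:
    return values.dtype.kind in "OUSb"


def _normality_gate(groups: list[np.ndarray]) -> bool:
    """True when every group passes Shapiro-Wilk at alpha 0.05."""
    for g in groups:
        if len(g) >= 3 and stats.shapiro(g).pvalue < SHAPIRO_ALPHA:
            return False
    return True


def compare_groups(
    values,
    labels,
    variable: str = "",
    posthoc: bool = True,
) -> GroupComparisonResult:
    """Omnibus comparison of one variable across groups.

    Numeric input: Shapiro-Wilk gate, then ANOVA or Kruskal-Wallis, with
    matching pairwise post hocs (Welch t or Mann-Whitney) BH-adjusted.
    Categorical input: chi-square on the label x category contingency table.
    """
    values = np.asarray(values)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    group_names = sorted(pd.unique(labels))
    if len(group_names) < 2:
        raise ValueError("need at least two groups")

    if _is_categorical(values):
        table = pd.crosstab(pd.Series(labels), pd.Series(values))
        chi2, p, dof, _ = stats.chi2_contingency(table)
        return GroupComparisonResult(variable, "chi2", float(chi2), float(p), dof)

    values = values.astype(float)
    groups = [values[labels == g] for g in group_names]
    if any(len(g) < 3 for g in groups):
        raise ValueError("every group needs at least 3 observations")
    if np.ptp(values) == 0:
        raise ValueError("constant variable")

    normal = _normality_gate(groups)
    if normal:
        stat, p = stats.f_oneway(*groups)
        test = "anova"
    else:
        stat, p = stats.kruskal(*groups)
        test = "kruskal"

    ph = None
    if posthoc:
        rows = []
        for a, b in itertools.combinations(range(len(group_names)), 2):
            if normal:
                pp = stats.ttest_ind(groups[a], groups[b]).pvalue
            else:
                pp = stats.mannwhitneyu(
                    groups[a], groups[b], alternative="two-sided"
                ).pvalue
            rows.append((group_names[a], group_names[b], float(pp)))
        ph = pd.DataFrame(rows, columns=["group_a", "group_b", "p"])
        ph["p_adj"] = stats.false_discovery_control(ph["p"].to_numpy(), method="bh")
    return GroupComparisonResult(variable, test, float(stat), float(p), posthoc=ph)


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares residuals of y on [1, X]."""
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def correlate(x, y, method: str = "pearson", covariates=None) -> tuple[float, float]:
    """Correlation between two vectors, optionally partialling out covariates.

    Returns ``(r, p)``. With covariates, both vectors are residualized on
    them by least squares and the p-value uses n - 2 - q degrees of
    freedom, q the number of covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    if covariates is not None:
        return partial_correlation(x, y, covariates, method=method)
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def partial_correlation(x, y, covariates, method: str = "pearson") -> tuple[float, float]:
    """Pearson correlation of the covariate-residualized vectors.

    The p-value comes from the t distribution with ``n - 2 - q`` degrees of
    freedom. Rank-deficient covariates are rejected with the name/index of
    the collinear column.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if method != "pearson":
        raise ValueError("partial correlation is Pearson-only")
    names = list(covariates.columns) if hasattr(covariates, "columns") else list(
        range(C.shape[1])
    )
    # all-zero columns carry no information: partialling on them reduces to
    # the plain correlation rather than a rank error
    nonzero = [j for j in range(C.shape[1]) if np.any(C[:, j] != 0)]
    C = C[:, nonzero]
    names = [names[j] for j in nonzero]
    if C.shape[1] == 0:
        C = np.zeros((len(x), 0))
    # detect collinearity among [1 | C]
    design = np.column_stack([np.ones(len(x)), C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        for j in range(C.shape[1]):
            sub = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(f"covariate {names[j]!r} is collinear")
        raise ValueError("rank-deficient covariate matrix")
    rx = _residualize(x, C)
    ry = _residualize(y, C)
    q = C.shape[1]
    n = len(x)
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - q
    if df <= 0:
        raise ValueError("not enough observations for the covariate count")
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


def deg_overlap(
    hub_genes: set[str] | list[str],
    dataset: pd.DataFrame,
    group_col: str = "group",
    alpha: float = 0.05,
) -> dict:
    """Differential-expression screen and overlap with a hub-gene list.

    ``dataset`` holds samples in rows: a group column plus one numeric
    column per gene. Per gene, a two-sample test gated by Shapiro-Wilk
    normality (t-test if both groups pass, rank-sum otherwise) flags DEGs
    at ``p < alpha``; the candidate set is ``DEGs & hub_genes``. Genes in
    the hub list but absent from the dataset are ignored with a warning in
    the returned record.
    """
    hub = set(hub_genes)
    groups = pd.unique(dataset[group_col])
    if len(groups) != 2:
        raise ValueError(f"expected two groups, got {len(groups)}")
    gene_cols = [c for c in dataset.columns if c != group_col]
    missing = hub - set(gene_cols)

    a = dataset[dataset[group_col] == groups[0]]
    b = dataset[dataset[group_col] == groups[1]]
    pvals = {}
    for gene in gene_cols:
        ga, gb = a[gene].to_numpy(float), b[gene].to_numpy(float)
        if np.ptp(np.concatenate([ga, gb])) == 0:
            pvals[gene] = 1.0
            continue
        if _normality_gate([ga, gb]):
            pvals[gene] = float(stats.ttest_ind(ga, gb).pvalue)
        else:
            pvals[gene] = float(
                stats.mannwhitneyu(ga, gb, alternative="two-sided").pvalue
            )
    degs = {g for g, p in pvals.items() if p < alpha}
    return {
        "p_values": pvals,
        "degs": degs,
        "overlap": degs & hub,
        "missing_hub_genes": missing,
    }


def roc_auc(scores, labels, positive_label=None, name: str = "") -> RocResult:
    """AUC from the Mann-Whitney rank statistic, ties counted as 1/2.

    ``AUC = U / (n_pos * n_neg)`` where U is the number of
    (positive, negative) score pairs won by the positive class, tied pairs
    contributing 0.5. Swapping the positive class gives ``1 - AUC``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {len(classes)}")
    if positive_label is None:
        positive_label = classes[1]
    pos = labels == positive_label
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return RocResult(name=name, auc=float(u / (n1 * n0)), positive_label=positive_label)
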