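"""Weighted gene coexpression network analysis on a regional expression atlas.

Samples are brain regions and variables are genes: from the genes x regions
matrix, an unsigned adjacency ``a_ij = |cor(g_i, g_j)|^beta`` is built with
the soft power beta chosen by scale-free topology fit (smallest power whose
signed model fit R^2 reaches the target, 0.85 by default). The adjacency is
transformed into the topological overlap matrix (TOM), which credits shared
neighbours; 1 - TOM is the dissimilarity for average-linkage hierarchical
clustering. Branches are cut with a simplified dynamic rule (static height
cut, small clusters to background, then merging of modules with similar
eigengenes), modules are summarized by their eigengene (first principal
component over regions), and module-trait association uses Pearson
correlation with Benjamini-Hochberg FDR. Hub genes are screened by module
membership |MM| > 0.8 and gene significance |GS| > 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "MODULE_COLORS",
    "ModuleSet",
    "adjacency",
    "select_soft_power",
    "tom",
    "detect_modules",
    "module_eigengene",
    "module_trait",
    "hub_genes",
]

#: Standard module color order: modules are named by descending size.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)

BACKGROUND = "grey"


@dataclass
class ModuleSet:
    """Gene-to-module assignment plus per-module eigengenes."""

    labels: pd.Series  # gene -> color, BACKGROUND for unassigned
    eigengenes: pd.DataFrame  # regions x module colors
    variance_explained: dict[str, float] = field(default_factory=dict)

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def genes(self, color: str) -> list[str]:
        return list(self.labels.index[self.labels == color])

    @property
    def module_colors(self) -> list[str]:
        return [c for c in self.eigengenes.columns]


def adjacency(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency ``|cor(g_i, g_j)|^beta``.

    ``expr`` is genes x regions; correlation is across regions. Diagonal
    is 1 by convention.
    """
    if beta < 1:
        raise ValueError("beta must be a positive integer")
    cor = np.corrcoef(expr.to_numpy(float))
    cor = np.nan_to_num(cor, nan=0.0)
    a = np.abs(cor) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit.

    Connectivity values are binned; log10(frequency) is regressed on
    log10(mean connectivity per bin). The returned index is
    ``-sign(slope) * R^2`` so only a *decreasing* distribution (the
    scale-free direction) scores positively. A degenerate (all-equal)
    distribution scores 0.
    """
    k = np.asarray(connectivity, dtype=float)
    if np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq, mean_k = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() > 0 and k[sel].mean() > 0:
            freq.append(sel.sum())
            mean_k.append(k[sel].mean())
    if len(freq) < 3:
        return 0.0
    x, y = np.log10(mean_k), np.log10(freq)
    fit = stats.linregress(x, y)
    return float(-np.sign(fit.slope) * fit.rvalue**2)


def select_soft_power(
    expr: pd.DataFrame,
    candidate_powers=range(1, 21),
    target_r2: float = 0.85,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft power by scale-free topology analysis.

    Returns the smallest candidate whose signed fit R^2 reaches
    ``target_r2`` plus the full power/R^2/mean-connectivity table. If no
    power reaches the target — typical when the coexpression structure is
    block-like rather than scale-free — a warning is raised and the
    standard sample-size-based default for unsigned networks is used
    (9 below 20 samples, 8 below 30, 7 below 40, 6 otherwise); blindly
    maximizing the fit index favours extreme powers that erase all
    adjacency.
    """
    powers = list(candidate_powers)
    if not powers:
        raise ValueError("no candidate powers")
    if expr.shape[0] < 20:
        raise ValueError("need at least 20 genes for a degree distribution")
    cor = np.abs(np.nan_to_num(np.corrcoef(expr.to_numpy(float)), nan=0.0))
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in powers:
        a = cor**beta
        k = a.sum(axis=1)
        rows.append((beta, scale_free_fit(k), float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "fit_r2", "mean_connectivity"])
    ok = table[table["fit_r2"] >= target_r2]
    if len(ok):
        return int(ok["power"].iloc[0]), table
    n_samples = expr.shape[1]
    fallback = 9 if n_samples < 20 else 8 if n_samples < 30 else 7 if n_samples < 40 else 6
    fallback = min(max(fallback, min(powers)), max(powers))
    warnings.warn(
        f"no candidate power reached R^2 >= {target_r2}; "
        f"using the unsigned-network default beta={fallback} "
        f"for {n_samples} samples",
        stacklevel=2,
    )
    return fallback, table


def tom(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix of an adjacency in [0, 1].

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for i != j,
    where ``l_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i`` is node
    connectivity (excluding the diagonal); ``TOM_ii = 1``.
    """
    a = np.asarray(adj, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    # with a zero diagonal, (a @ a)_ij already sums over u not in {i, j}
    l = a @ a
    num = l + a
    den = np.minimum(k[:, None], k[None, :]) + 1.0 - a
    t = num / den
    np.fill_diagonal(t, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(t, index=adj.index, columns=adj.columns)
    return t


def module_eigengene(
    expr: pd.DataFrame, module_genes
) -> tuple[pd.Series, float]:
    """First principal component of a module's standardized region profiles.

    Returns the eigengene (unit-norm score vector over regions) and its
    explained-variance fraction. The sign is oriented so that the mean
    correlation with the module's genes is positive; constant gene rows are
    dropped with a warning.
    """
    sub = expr.loc[list(module_genes)]
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 genes for an eigengene")
    vals = sub.to_numpy(float)
    sd = vals.std(axis=1)
    if np.any(sd == 0):
        warnings.warn(
            f"{int((sd == 0).sum())} constant gene rows dropped from PCA",
            stacklevel=2,
        )
        vals = vals[sd > 0]
        if vals.shape[0] < 2:
            raise ValueError("fewer than 2 non-constant genes")
        sd = sd[sd > 0]
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    # regions x genes; eigengene = first left singular vector over regions
    u, s, _ = np.linalg.svd(z.T, full_matrices=False)
    me = u[:, 0]
    mean_cor = np.mean([np.corrcoef(me, row)[0, 1] for row in z])
    if mean_cor < 0:
        me = -me
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return pd.Series(me, index=expr.columns), var_explained


def detect_modules(
    expr: pd.DataFrame,
    dissimilarity: pd.DataFrame | np.ndarray,
    min_module_size: int = 100,
    cut_height_quantile: float = 0.99,
    merge_eigengene_dissim: float = 0.25,
) -> ModuleSet:
    """Average-linkage module detection with a simplified dynamic cut.

    The 1-TOM dendrogram is cut at ``cut_height_quantile`` of its maximum
    merge height; clusters below ``min_module_size`` fall into the grey
    background. Modules whose eigengenes are closer than
    ``merge_eigengene_dissim`` (1 - correlation) are merged, and surviving
    modules are named by descending size using the standard color order.
    Detection is deterministic.
    """
    d = np.asarray(dissimilarity, dtype=float)
    genes = list(expr.index)
    if d.shape != (len(genes), len(genes)):
        raise ValueError("dissimilarity does not match expression genes")
    if len(genes) < min_module_size:
        warnings.warn("fewer genes than min_module_size; all background",
                      stacklevel=2)
        return ModuleSet(
            labels=pd.Series(BACKGROUND, index=genes),
            eigengenes=pd.DataFrame(index=expr.columns),
        )

    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    cut = cut_height_quantile * Z[:, 2].max()
    raw = fcluster(Z, t=cut, criterion="distance")

    labels = pd.Series(BACKGROUND, index=genes, dtype=object)
    clusters = [
        np.flatnonzero(raw == c)
        for c in np.unique(raw)
        if (raw == c).sum() >= min_module_size
    ]
    clusters.sort(key=len, reverse=True)
    for tmp_id, idx in enumerate(clusters):
        labels.iloc[idx] = f"M{tmp_id}"

    labels = _merge_similar_modules(expr, labels, merge_eigengene_dissim)

    # rename by descending size in the canonical color order
    sizes = labels[labels != BACKGROUND].value_counts()
    rename = {old: MODULE_COLORS[i % len(MODULE_COLORS)]
              for i, old in enumerate(sizes.index)}
    labels = labels.map(lambda v: rename.get(v, BACKGROUND))

    mes, ve = {}, {}
    for color in [c for c in MODULE_COLORS if c in set(labels)]:
        mes[color], ve[color] = module_eigengene(expr, labels.index[labels == color])
    eigengenes = pd.DataFrame(mes, index=expr.columns)
    return ModuleSet(labels=labels, eigengenes=eigengenes, variance_explained=ve)


def _merge_similar_modules(
    expr: pd.DataFrame, labels: pd.Series, threshold: float
) -> pd.Series:
    """Iteratively merge the closest eigengene pair while below threshold."""
    labels = labels.copy()
    while True:
        mods = sorted(set(labels) - {BACKGROUND})
        if len(mods) < 2:
            return labels
        mes = {m: module_eigengene(expr, labels.index[labels == m])[0] for m in mods}
        best, best_d = None, np.inf
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                dd = 1.0 - float(np.corrcoef(mes[mods[i]], mes[mods[j]])[0, 1])
                if dd < best_d:
                    best, best_d = (mods[i], mods[j]), dd
        if best_d >= threshold:
            return labels
        labels[labels == best[1]] = best[0]


def module_trait(
    eigengenes: pd.DataFrame, traits: pd.DataFrame | pd.Series
) -> pd.DataFrame:
    """Pearson module-trait correlations with BH-FDR over all cells.

    ``eigengenes`` is regions x modules; ``traits`` one or more per-region
    vectors. Regions missing in either side are excluded pairwise; fewer
    than 4 overlapping regions is an error.
    """
    if isinstance(traits, pd.Series):
        traits = traits.to_frame(traits.name or "trait")
    rows = []
    for mod in eigengenes.columns:
        for tr in traits.columns:
            pair = pd.concat(
                [eigengenes[mod], traits[tr]], axis=1, join="inner"
            ).dropna()
            if len(pair) < 4:
                raise ValueError(
                    f"fewer than 4 overlapping regions for {mod} x {tr}"
                )
            r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append((mod, tr, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["module", "trait", "r", "p"])
    out["p_adj"] = (
        stats.false_discovery_control(out["p"].to_numpy(), method="bh")
        if len(out)
        else np.array([], dtype=float)
    )
    return out


def hub_genes(
    expr: pd.DataFrame,
    module_set: ModuleSet,
    trait: pd.Series,
    mm_threshold: float = 0.8,
    gs_threshold: float = 0.5,
) -> pd.DataFrame:
    """Screen hub genes by module membership and gene significance.

    MM is the correlation of a gene's region profile with its own module
    eigengene; GS is its correlation with the trait. A gene is a hub when
    ``|MM| > mm_threshold`` and ``|GS| > gs_threshold``. Background genes
    are excluded. Returns a per-gene table with columns
    module / MM / GS / hub.
    """
    if not (0 < mm_threshold < 1 and 0 < gs_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    trait = trait.reindex(expr.columns)
    ok_regions = trait.notna()
    rows = []
    for gene, color in module_set.labels.items():
        if color == BACKGROUND:
            continue
        prof = expr.loc[gene]
        me = module_set.eigengenes[color]
        mm = float(np.corrcoef(prof, me)[0, 1]) if prof.std() > 0 else 0.0
        gs = (
            float(np.corrcoef(prof[ok_regions], trait[ok_regions])[0, 1])
            if prof[ok_regions].std() > 0 and trait[ok_regions].std() > 0
            else 0.0
        )
        rows.append((gene, color, mm, gs))
    if not rows:
        return pd.DataFrame(
            columns=["module", "MM", "GS", "hub"], index=pd.Index([], name="gene")
        )
    out = pd.DataFrame(rows, columns=["gene", "module", "MM", "GS"]).set_index("gene")
    out["hub"] = (out["MM"].abs() > mm_threshold) & (out["GS"].abs() > gs_threshold)
    return out
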